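"""Synthetic multi-source modality panels with known ground truth.

The real feeds behind the analysis (Burbio, MCH, the Return-to-Learn
tracker, state dashboards) are proprietary, so every downstream stage is
exercised against simulated panels instead: district modality paths are
drawn from the fitted national transition dynamics, each source then
reports a noisy version of the path through its fitted emission matrix,
and per-source coverage is thinned to match the published district-week
counts — including the structural gaps (state dashboards only coming
online late in the school year, the MCH survey going quiet for a
two-month block).

The default generator therefore *is* a statement of the published
model: its transition matrix, emission matrices and coverage rates are
the published point estimates, which is what makes parameter-recovery
testing meaningful.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .hmm import HMMParams, ParameterError
from .panel_io import MODALITY_LABELS, N_STATES, SOURCES, ObservationPanel

# ---------------------------------------------------------------------------
# Published point estimates used as generator ground truth

#: Weekly modality transition matrix (rows: current remote/hybrid/in-person).
PAPER_TRANSITION = np.array(
    [
        [0.903, 0.079, 0.018],
        [0.014, 0.961, 0.025],
        [0.004, 0.013, 0.983],
    ]
)

#: Per-source emission matrices (rows: true modality; cols: reported modality).
PAPER_EMISSIONS: dict[str, np.ndarray] = {
    "BURBIO": np.array(
        [
            [0.805, 0.145, 0.050],
            [0.067, 0.617, 0.317],  # rows renormalised on construction (printed rounding)
            [0.016, 0.161, 0.823],
        ]
    ),
    "MCH": np.array(
        [
            [0.795, 0.178, 0.027],
            [0.090, 0.775, 0.135],
            [0.055, 0.347, 0.598],
        ]
    ),
    "R2LT": np.array(
        [
            [0.992, 0.008, 0.001],  # printed row sums 1.001; renormalised
            [0.002, 0.997, 0.001],
            [0.001, 0.001, 0.997],  # printed row sums 0.999
        ]
    ),
    "SD": np.array(
        [
            [0.642, 0.330, 0.028],
            [0.003, 0.863, 0.134],
            [0.001, 0.042, 0.956],  # printed row sums 0.999
        ]
    ),
}

#: Published district-week report counts per source and the full inference grid.
PAPER_DISTRICT_WEEKS: dict[str, int] = {
    "BURBIO": 37_589,
    "MCH": 58_137,
    "R2LT": 343_596,
    "SD": 24_732,
}
PAPER_N_DISTRICTS = 14_688
PAPER_GRID_WEEKS = 42  # 616,896 district-weeks / 14,688 districts
PAPER_TOTAL_DISTRICT_WEEKS = PAPER_N_DISTRICTS * PAPER_GRID_WEEKS

#: Default initial modality distribution (early-autumn national shares;
#: configurable — the fitted model publishes no initial distribution).
DEFAULT_PI = np.array([0.25, 0.35, 0.40])

_DEFAULT_START_WEEK = "2020-W36"  # week containing 2020-09-01


def paper_params(pi: np.ndarray | None = None) -> HMMParams:
    """Published transition/emission point estimates as :class:`HMMParams`.

    Printed rows are rounded to three decimals and can sum to 0.999 or
    1.001; each row is renormalised to be exactly stochastic.
    """
    emissions = {}
    for s, e in PAPER_EMISSIONS.items():
        emissions[s] = e / e.sum(axis=1, keepdims=True)
    T = PAPER_TRANSITION / PAPER_TRANSITION.sum(axis=1, keepdims=True)
    return HMMParams(pi=DEFAULT_PI if pi is None else pi, T=T, emissions=emissions)


# ---------------------------------------------------------------------------
# Generator specification

@dataclass
class GeneratorSpec:
    """Everything needed to simulate a multi-source panel.

    ``presence`` maps each source either to a scalar per-district-week
    presence probability or to a length-``n_weeks`` array of weekly
    probabilities (zero outside a source's active window).  Presence is
    independent across districts, weeks and sources given those
    windows.
    """

    n_districts: int
    n_weeks: int
    params: HMMParams
    presence: dict[str, float | np.ndarray]
    seed: int = 0
    start_week: str = _DEFAULT_START_WEEK
    states: tuple[str, ...] = ("AL", "CA", "NY", "OH", "TX")
    strata: dict[str, float] | None = None  # urban-rural class -> probability

    def __post_init__(self) -> None:
        if self.n_districts < 1 or self.n_weeks < 1:
            raise ParameterError("n_districts and n_weeks must be positive")
        if set(self.presence) != set(SOURCES):
            raise ParameterError(f"presence must cover exactly the sources {SOURCES}")
        norm: dict[str, np.ndarray] = {}
        for s in SOURCES:
            p = np.broadcast_to(np.asarray(self.presence[s], float), (self.n_weeks,)).copy()
            if (p < 0).any() or (p > 1).any():
                raise ParameterError(f"presence probabilities for {s} must lie in [0, 1]")
            norm[s] = p
        self.presence = norm

    @property
    def week_ids(self) -> list[str]:
        from datetime import timedelta

        from .panel_io import date_to_week, week_to_date

        d0 = week_to_date(self.start_week)
        return [date_to_week(d0 + timedelta(weeks=k)) for k in range(self.n_weeks)]


@dataclass
class TruePaths:
    """Ground-truth modality path per district (codes 1..3)."""

    paths: np.ndarray  # (n_districts, n_weeks) int8
    district_ids: np.ndarray
    week_ids: list[str]

    def to_frame(self) -> pd.DataFrame:
        d_idx, w_idx = np.indices(self.paths.shape)
        return pd.DataFrame(
            {
                "district_id": np.asarray(self.district_ids)[d_idx.ravel()],
                "week": np.asarray(self.week_ids, dtype=object)[w_idx.ravel()],
                "source": "TRUTH",
                "modality": [MODALITY_LABELS[c] for c in self.paths.ravel()],
            }
        )


def _district_ids(n: int) -> np.ndarray:
    width = max(4, len(str(n - 1)))
    return np.array([f"d{i:0{width}d}" for i in range(n)])


def simulate_truth(spec: GeneratorSpec) -> TruePaths:
    """Draw each district's modality path from the Markov chain.

    Week-1 states come from the initial distribution, later weeks from
    the transition-matrix row of the current state.  Bit-reproducible
    for a fixed seed.
    """
    rng = np.random.default_rng([spec.seed, 0])
    D, W = spec.n_districts, spec.n_weeks
    T_cum = spec.params.T.cumsum(axis=1)
    paths = np.empty((D, W), dtype=np.int8)
    state = rng.choice(N_STATES, size=D, p=spec.params.pi)
    paths[:, 0] = state + 1
    for t in range(1, W):
        u = rng.random(D)
        state = (u[:, None] > T_cum[state]).sum(axis=1)
        paths[:, t] = state + 1
    return TruePaths(paths=paths, district_ids=_district_ids(D), week_ids=spec.week_ids)


def simulate_observations(truth: TruePaths, spec: GeneratorSpec) -> ObservationPanel:
    """Thin and corrupt the true paths into a multi-source panel.

    Each (district, week, source) cell is present independently with the
    source's presence probability for that week; a present cell reports
    a modality drawn from the source's emission row for the true state.
    District windows span the full simulated grid, so all-missing weeks
    remain part of each sequence.
    """
    D, W = truth.paths.shape
    if (D, W) != (spec.n_districts, spec.n_weeks):
        raise ParameterError("truth dimensions do not match spec")
    rng = np.random.default_rng([spec.seed, 1])
    state0 = truth.paths.astype(np.int64) - 1
    obs = np.zeros((D, W, len(SOURCES)), dtype=np.int8)
    for s, src in enumerate(SOURCES):
        present = rng.random((D, W)) < spec.presence[src][None, :]
        E_cum = spec.params.emissions[src].cumsum(axis=1)
        u = rng.random((D, W))
        report = (u[:, :, None] > E_cum[state0]).sum(axis=2) + 1
        obs[:, :, s] = np.where(present, report, 0)

    rng_meta = np.random.default_rng([spec.seed, 2])
    states = rng_meta.choice(spec.states, size=D)
    districts = pd.DataFrame(
        {
            "district_id": truth.district_ids,
            "district_name": [f"District {i}" for i in range(D)],
            "state": states,
        }
    )
    if spec.strata:
        classes = list(spec.strata)
        probs = np.array([spec.strata[c] for c in classes], float)
        districts["stratum"] = rng_meta.choice(classes, size=D, p=probs / probs.sum())
    window = np.tile([0, W], (D, 1))
    return ObservationPanel(districts, list(truth.week_ids), obs, window=window)


def default_paper_spec(
    n_districts: int = PAPER_N_DISTRICTS,
    n_weeks: int = PAPER_GRID_WEEKS,
    seed: int = 0,
) -> GeneratorSpec:
    """Generator spec matching the published model and coverage structure.

    Presence probabilities are the published per-source district-week
    counts divided by the full inference grid (14,688 districts x 42
    weeks = 616,896 district-weeks): BURBIO ≈ 0.061, MCH ≈ 0.094,
    R2LT ≈ 0.557, SD ≈ 0.040.  Those ratios are *marginal* coverage
    rates, so where a source has a restricted active window — state
    dashboards only in the final ~40% of weeks, MCH silent for a
    contiguous 8-week block — the within-window probability is scaled up
    by ``n_weeks / n_active_weeks`` to keep expected report counts at
    the published level.
    """
    marginal = {
        s: PAPER_DISTRICT_WEEKS[s] / PAPER_TOTAL_DISTRICT_WEEKS for s in SOURCES
    }
    presence: dict[str, float | np.ndarray] = {}
    presence["BURBIO"] = marginal["BURBIO"]
    presence["R2LT"] = marginal["R2LT"]

    # State dashboards: active only over the final ~40% of the year.
    sd = np.zeros(n_weeks)
    sd_start = int(np.ceil(0.6 * n_weeks))
    n_active = n_weeks - sd_start
    sd[sd_start:] = min(1.0, marginal["SD"] * n_weeks / max(n_active, 1))
    presence["SD"] = sd

    # MCH: inactive for a contiguous 8-week block (Feb-Mar of the school year).
    mch = np.zeros(n_weeks)
    block_start = int(round(n_weeks * 22 / 42))
    block_len = min(8, n_weeks)
    active = np.ones(n_weeks, dtype=bool)
    active[block_start : block_start + block_len] = False
    n_active = int(active.sum())
    mch[active] = min(1.0, marginal["MCH"] * n_weeks / max(n_active, 1))
    presence["MCH"] = mch

    return GeneratorSpec(
        n_districts=n_districts,
        n_weeks=n_weeks,
        params=paper_params(),
        presence=presence,
        seed=seed,
    )
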