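"""Factored-emission hidden Markov model over weekly modality sequences.

The hidden state is a district's true learning modality (remote, hybrid,
in-person) evolving as a first-order Markov chain with a time-invariant
3x3 transition matrix.  Each of the four report sources emits, in weeks
where it covers the district, a noisy categorical observation of the
hidden state through its own 3x3 emission matrix; the per-week emission
probability is the product over the *present* sources, so missing
sources are marginalised out exactly (an all-missing week contributes a
factor of 1 and still carries transition structure).

Fitting is unsupervised Baum-Welch (EM) pooled over many independent
district sequences, with per-week scaling for numerical stability.  The
likelihood is invariant under permutation of the hidden-state indices;
resolving that label switching is the job of :mod:`modalhmm.labeling`.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field

import numpy as np

from .panel_io import MODALITY_LABELS, N_STATES, SOURCES, ObservationPanel

logger = logging.getLogger("modalhmm")

_ROW_SUM_TOL = 1e-9
_EMISSION_FLOOR = 1e-10  # zero-count cells are floored so decoding never hits log(0)
_TINY = 1e-300


class FitError(RuntimeError):
    """Raised when a model cannot be fit (e.g. a panel with no observations)."""


class ParameterError(ValueError):
    """Raised for invalid stochastic matrices or distributions."""


def _check_stochastic(mat: np.ndarray, name: str) -> np.ndarray:
    mat = np.asarray(mat, dtype=float)
    if not np.all(np.isfinite(mat)) or (mat < 0).any():
        raise ParameterError(f"{name} must be finite and non-negative")
    sums = mat.sum(axis=-1)
    if not np.allclose(sums, 1.0, atol=_ROW_SUM_TOL):
        raise ParameterError(f"rows of {name} must sum to 1 (got {sums})")
    return mat


@dataclass
class HMMParams:
    """Initial distribution, transition matrix and per-source emissions.

    ``T[i, j]`` is the probability of moving from modality ``i+1`` to
    ``j+1`` in one week; ``emissions[src][i, j]`` the probability that
    source ``src`` reports modality ``j+1`` when the true modality is
    ``i+1``.  All rows are stochastic.
    """

    pi: np.ndarray
    T: np.ndarray
    emissions: dict[str, np.ndarray]

    def __post_init__(self) -> None:
        self.pi = _check_stochastic(np.asarray(self.pi, float).reshape(N_STATES), "pi")
        self.T = _check_stochastic(np.asarray(self.T, float).reshape(N_STATES, N_STATES), "T")
        if set(self.emissions) != set(SOURCES):
            raise ParameterError(f"emissions must have exactly the slots {SOURCES}")
        self.emissions = {
            s: _check_stochastic(np.asarray(self.emissions[s], float).reshape(N_STATES, N_STATES), s)
            for s in SOURCES
        }

    # -- serialisation -------------------------------------------------------

    def to_json(self, path=None) -> str:
        payload = {
            "pi": self.pi.tolist(),
            "T": self.T.tolist(),
            "emissions": {s: e.tolist() for s, e in self.emissions.items()},
        }
        text = json.dumps(payload, indent=1)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text + "\n")
        return text

    @classmethod
    def from_json(cls, source) -> "HMMParams":
        if isinstance(source, str) and source.lstrip().startswith("{"):
            payload = json.loads(source)
        else:
            with open(source) as fh:
                payload = json.load(fh)
        return cls(payload["pi"], payload["T"], payload["emissions"])

    # -- label permutation ---------------------------------------------------

    def permute(self, perm: np.ndarray) -> "HMMParams":
        """Relabel hidden states: new state ``perm[i]`` is old state ``i``.

        ``perm`` is a permutation of ``0..2`` (zero-based).  Posteriors
        and paths decoded under the permuted parameters are the same
        permutation of those decoded under the originals.
        """
        perm = np.asarray(perm)
        inv = np.empty_like(perm)
        inv[perm] = np.arange(N_STATES)
        return HMMParams(
            pi=self.pi[inv],
            T=self.T[np.ix_(inv, inv)],
            emissions={s: e[inv] for s, e in self.emissions.items()},
        )


@dataclass
class FitResult:
    """Outcome of a Baum-Welch fit."""

    params: HMMParams
    loglik_trace: np.ndarray
    n_iter: int
    converged: bool
    seed: int | None = None


@dataclass
class DecodedPanel:
    """Posterior state inference for every district-week of a panel.

    ``posterior[d, w]`` is the smoothed distribution over hidden states;
    ``map_state`` its argmax (lowest index wins ties) and
    ``viterbi_state`` the state on the jointly most probable path, both
    as codes 1..3 (0 outside a district's week window).  ``labeled`` is
    False until a state labeling has been applied, i.e. state indices
    are arbitrary cluster labels, not modalities.
    """

    district_ids: np.ndarray
    week_ids: list[str]
    posterior: np.ndarray  # (D, W, 3); NaN outside windows
    map_state: np.ndarray  # (D, W) int8 codes 1..3, 0 = outside window
    viterbi_state: np.ndarray
    valid: np.ndarray  # (D, W) bool
    districts: "object" = None  # optional district metadata DataFrame
    labeled: bool = False

    @property
    def confidence(self) -> np.ndarray:
        """Max posterior probability per district-week (NaN outside windows)."""
        with np.errstate(invalid="ignore"):
            return np.nanmax(self.posterior, axis=2)

    def to_frame(self, threshold: float = 0.75):
        """Long table with posterior columns, decoded states and confidence flag."""
        import pandas as pd

        d_idx, w_idx = np.nonzero(self.valid)
        post = self.posterior[d_idx, w_idx]
        return pd.DataFrame(
            {
                "district_id": np.asarray(self.district_ids)[d_idx],
                "week": np.asarray(self.week_ids, dtype=object)[w_idx],
                "p_remote": post[:, 0],
                "p_hybrid": post[:, 1],
                "p_in_person": post[:, 2],
                "map_modality": [MODALITY_LABELS[c] for c in self.map_state[d_idx, w_idx]],
                "viterbi_modality": [MODALITY_LABELS[c] for c in self.viterbi_state[d_idx, w_idx]],
                "high_confidence": (post.max(axis=1) >= threshold).astype(int),
            }
        )


# ---------------------------------------------------------------------------
# Sequence plumbing
#
# A "sequence" is a (L, 4) integer array in panel encoding: 0 = missing,
# 1..3 modality codes, one column per source in SOURCES order.  Batch
# internals use zero-based codes with -1 = missing, left-aligned with
# tail padding; an all-missing padded week has emission likelihood 1 and
# scaling constant 1, so it perturbs neither posteriors nor the
# likelihood inside the real window.


def _as_batch(seq: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    seq = np.asarray(seq)
    if seq.ndim != 2 or seq.shape[1] != len(SOURCES):
        raise ValueError(f"sequence must be (L, {len(SOURCES)}), got {seq.shape}")
    X = seq.astype(np.int16)[None, :, :] - 1  # missing 0 -> -1
    return X, np.array([seq.shape[0]])


def _emission_lik(params: HMMParams, X: np.ndarray) -> np.ndarray:
    """Per-week emission likelihood, shape (D, L, 3): product over present sources."""
    D, L, S = X.shape
    lik = np.ones((D, L, N_STATES))
    for s, src in enumerate(SOURCES):
        o = X[:, :, s]
        present = o >= 0
        if present.any():
            # E.T[obs, state] = E[state, obs]
            lik[present] *= params.emissions[src].T[o[present]]
    return lik


def _forward_backward_batch(params: HMMParams, X: np.ndarray, lengths: np.ndarray):
    """Scaled forward-backward over left-aligned padded sequences.

    Returns (alpha, beta, c, gamma, lik, loglik_per_seq); alpha/beta are
    scaled, gamma row-normalised, c the per-week scaling constants.
    """
    D, L, _ = X.shape
    lik = _emission_lik(params, X)
    alpha = np.empty((D, L, N_STATES))
    c = np.empty((D, L))
    a = params.pi[None, :] * lik[:, 0]
    c[:, 0] = a.sum(axis=1)
    np.maximum(c[:, 0], _TINY, out=c[:, 0])
    alpha[:, 0] = a / c[:, 0, None]
    for t in range(1, L):
        a = (alpha[:, t - 1] @ params.T) * lik[:, t]
        c[:, t] = a.sum(axis=1)
        np.maximum(c[:, t], _TINY, out=c[:, t])
        alpha[:, t] = a / c[:, t, None]

    beta = np.empty((D, L, N_STATES))
    beta[:, L - 1] = 1.0
    for t in range(L - 2, -1, -1):
        beta[:, t] = (lik[:, t + 1] * beta[:, t + 1]) @ params.T.T / c[:, t + 1, None]

    gamma = alpha * beta
    gamma /= np.maximum(gamma.sum(axis=2, keepdims=True), _TINY)

    t_idx = np.arange(L)[None, :]
    valid = t_idx < lengths[:, None]
    loglik = np.where(valid, np.log(c), 0.0).sum(axis=1)
    return alpha, beta, c, gamma, lik, loglik


# ---------------------------------------------------------------------------
# Public single-sequence operations


def emission_prob(params: HMMParams, state: int, obs_vector) -> float:
    """Probability of one week's multi-source observation given the true state.

    ``obs_vector`` holds one entry per source in ``SOURCES`` order, each
    a modality code 1..3 or 0/None for missing.  Missing sources are
    marginalised out (factor 1); with every source missing the result is
    exactly 1.
    """
    if state not in (1, 2, 3):
        raise ParameterError(f"state must be a modality code 1..3, got {state}")
    p = 1.0
    for s, src in enumerate(SOURCES):
        o = obs_vector[s]
        if o is None or o == 0:
            continue
        p *= params.emissions[src][state - 1, int(o) - 1]
    return float(p)


def sequence_loglik(params: HMMParams, seq: np.ndarray) -> float:
    """Log marginal probability of one district's observation sequence.

    Computed with per-week scaling so long sequences do not underflow.
    """
    X, lengths = _as_batch(seq)
    *_, loglik = _forward_backward_batch(params, X, lengths)
    return float(loglik[0])


def forward_backward(params: HMMParams, seq: np.ndarray):
    """Posterior state marginals and transition posteriors for one sequence.

    Returns ``(gamma, xi, loglik)``: ``gamma[t]`` the smoothed state
    distribution at week ``t``; ``xi[t]`` the joint posterior of the
    state pair at weeks ``(t, t+1)`` (sums to 1 over its 9 cells).
    """
    X, lengths = _as_batch(seq)
    L = int(lengths[0])
    if L < 1:
        raise ValueError("sequence must have length >= 1")
    alpha, beta, c, gamma, lik, loglik = _forward_backward_batch(params, X, lengths)
    xi = np.empty((L - 1, N_STATES, N_STATES))
    for t in range(L - 1):
        xi[t] = (
            alpha[0, t, :, None]
            * params.T
            * (lik[0, t + 1] * beta[0, t + 1])[None, :]
            / c[0, t + 1]
        )
    return gamma[0, :L], xi, float(loglik[0])


def viterbi(params: HMMParams, seq: np.ndarray) -> np.ndarray:
    """Most probable hidden-state path (codes 1..3) for one sequence."""
    X, lengths = _as_batch(seq)
    return _viterbi_batch(params, X, lengths)[0]


def _viterbi_batch(params: HMMParams, X: np.ndarray, lengths: np.ndarray) -> np.ndarray:
    D, L, _ = X.shape
    log_lik = np.log(np.maximum(_emission_lik(params, X), _TINY))
    logT = np.log(np.maximum(params.T, _TINY))
    delta = np.empty((D, L, N_STATES))
    psi = np.zeros((D, L, N_STATES), dtype=np.int8)
    delta[:, 0] = np.log(np.maximum(params.pi, _TINY))[None, :] + log_lik[:, 0]
    for t in range(1, L):
        scores = delta[:, t - 1, :, None] + logT[None]  # (D, prev, next)
        psi[:, t] = scores.argmax(axis=1)  # first max => lowest prev index
        delta[:, t] = scores.max(axis=1) + log_lik[:, t]

    path = np.zeros((D, L), dtype=np.int8)
    cur = np.zeros(D, dtype=np.int64)
    rows = np.arange(D)
    for t in range(L - 1, -1, -1):
        at_end = lengths - 1 == t
        if at_end.any():
            cur[at_end] = delta[at_end, t].argmax(axis=1)
        inside = lengths - 1 > t
        if inside.any():
            cur[inside] = psi[rows[inside], t + 1, cur[inside]]
        path[:, t] = np.where(t < lengths, cur + 1, 0)
    return path


# ---------------------------------------------------------------------------
# Baum-Welch


def _initial_params(rng: np.random.Generator) -> HMMParams:
    """Diagonal-dominant seeded initialisation.

    Emissions start at 0.8 on-diagonal / 0.1 off plus uniform noise of
    magnitude 0.05; the transition matrix starts sticky (0.9 diagonal).
    This mirrors the diagonal-dominant structure the model converges to
    while leaving enough randomness for restarts to explore distinct
    local maxima.
    """

    def noisy(base: np.ndarray, mag: float) -> np.ndarray:
        m = base + rng.uniform(0.0, mag, base.shape)
        return m / m.sum(axis=-1, keepdims=True)

    eye = np.eye(N_STATES)
    emissions = {
        s: noisy(0.8 * eye + 0.1 * (1 - eye), 0.05) for s in SOURCES
    }
    T = noisy(0.9 * eye + 0.05 * (1 - eye), 0.05)
    pi = noisy(np.full(N_STATES, 1.0 / N_STATES), 0.05)
    return HMMParams(pi=pi, T=T, emissions=emissions)


def _em_run(
    X: np.ndarray,
    lengths: np.ndarray,
    params: HMMParams,
    tol: float,
    max_iter: int,
) -> tuple[HMMParams, np.ndarray, bool]:
    D, L, S = X.shape
    t_idx = np.arange(L)[None, :]
    valid = t_idx < lengths[:, None]
    trace: list[float] = []
    converged = False
    for _ in range(max_iter + 1):
        alpha, beta, c, gamma, lik, ll_per_seq = _forward_backward_batch(params, X, lengths)
        ll = float(ll_per_seq.sum())
        trace.append(ll)
        if len(trace) >= 2:
            prev = trace[-2]
            if ll - prev < tol * abs(prev):
                converged = True
                break
        if len(trace) == max_iter + 1:
            break

        # M-step: pool expected counts across independent sequences
        pi = gamma[:, 0].sum(axis=0)
        pi /= pi.sum()

        xi_sum = np.zeros((N_STATES, N_STATES))
        for t in range(L - 1):
            m = lengths > t + 1
            if not m.any():
                continue
            w = lik[m, t + 1] * beta[m, t + 1] / c[m, t + 1, None]
            xi_sum += np.einsum("di,dj->ij", alpha[m, t], w) * params.T
        T = xi_sum / np.maximum(xi_sum.sum(axis=1, keepdims=True), _TINY)

        emissions = {}
        for s, src in enumerate(SOURCES):
            o = X[:, :, s]
            present = (o >= 0) & valid
            num = np.zeros((N_STATES, N_STATES))
            for j in range(N_STATES):
                sel = present & (o == j)
                if sel.any():
                    num[:, j] = gamma[sel].sum(axis=0)
            den = num.sum(axis=1, keepdims=True)
            E = np.where(den > 0, num / np.maximum(den, _TINY), 1.0 / N_STATES)
            E = np.maximum(E, _EMISSION_FLOOR)
            E /= E.sum(axis=1, keepdims=True)
            emissions[src] = E
        params = HMMParams(pi=pi, T=T, emissions=emissions)
    return params, np.asarray(trace), converged


def baum_welch(
    panel: ObservationPanel,
    init: HMMParams | None = None,
    *,
    seed: int | None = None,
    restarts: int = 5,
    tol: float = 1e-6,
    max_iter: int = 500,
) -> FitResult:
    """Fit the multi-source HMM to a panel by pooled Baum-Welch EM.

    All district sequences are treated as independent realisations of
    one national model.  Each source's emission matrix is re-estimated
    only from district-weeks where that source is present; the initial
    distribution from week-1 posteriors.  Stops when the relative
    total-log-likelihood improvement falls below ``tol`` or after
    ``max_iter`` EM updates.

    With ``init`` given, a single run starts from it; otherwise
    ``restarts`` seeded diagonal-dominant initialisations are tried and
    the best final likelihood kept.
    """
    if tol < 0 or max_iter < 1:
        raise ParameterError("tol must be >= 0 and max_iter >= 1")
    if panel.n_observations == 0:
        raise FitError("cannot fit: panel contains no observations")
    X, lengths = panel.sequences()
    keep = lengths > 0
    X, lengths = X[keep], lengths[keep]

    if init is not None:
        params, trace, converged = _em_run(X, lengths, init, tol, max_iter)
        return FitResult(params, trace, n_iter=len(trace) - 1, converged=converged)

    seeds = np.random.SeedSequence(seed).generate_state(restarts) >> 1  # keep < 2^31
    best: FitResult | None = None
    for s in seeds:
        rng = np.random.default_rng(int(s))
        params, trace, converged = _em_run(X, lengths, _initial_params(rng), tol, max_iter)
        result = FitResult(params, trace, n_iter=len(trace) - 1, converged=converged, seed=int(s))
        logger.info("restart seed=%d loglik=%.3f iters=%d", int(s), trace[-1], len(trace) - 1)
        if best is None or trace[-1] > best.loglik_trace[-1]:
            best = result
    assert best is not None
    return best


def posterior_decode(params: HMMParams, panel: ObservationPanel) -> DecodedPanel:
    """Smoothed posterior, MAP state and Viterbi path for every district-week.

    Ties in the posterior argmax and in the Viterbi backtrace resolve to
    the lowest state index, so the output is deterministic.
    """
    X, lengths = panel.sequences()
    D, W = panel.n_districts, panel.n_weeks
    posterior = np.full((D, W, N_STATES), np.nan)
    map_state = np.zeros((D, W), dtype=np.int8)
    vit_state = np.zeros((D, W), dtype=np.int8)
    valid = np.zeros((D, W), dtype=bool)
    if D and X.shape[1]:
        *_, gamma, _, _ = _forward_backward_batch(params, X, lengths)
        paths = _viterbi_batch(params, X, lengths)
        for d in range(D):
            lo, hi = panel.window[d]
            n = hi - lo
            if n <= 0:
                continue
            posterior[d, lo:hi] = gamma[d, :n]
            map_state[d, lo:hi] = gamma[d, :n].argmax(axis=1) + 1
            vit_state[d, lo:hi] = paths[d, :n]
            valid[d, lo:hi] = True
    return DecodedPanel(
        district_ids=panel.districts.district_id.to_numpy(),
        week_ids=list(panel.week_ids),
        posterior=posterior,
        map_state=map_state,
        viterbi_state=vit_state,
        valid=valid,
        districts=panel.districts.copy(),
    )
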