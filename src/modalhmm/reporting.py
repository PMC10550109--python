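"""Agreement statistics and modality trend aggregations.

Three descriptive outputs sit on top of the fused modalities:

* pairwise agreement between trackers (the four sources plus the model
  output), as the share of district-weeks covered by both where the two
  reports match;
* a one-sided paired t-test of whether the model agrees with a given
  tracker more than each single source does, pairing on weekly
  agreement proportions;
* weekly modality shares — the fraction of districts in each modality
  per week — nationally or stratified by state or urban-rural class,
  optionally restricted to high-confidence district-weeks.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats

from .hmm import DecodedPanel
from .panel_io import MODALITY_LABELS, SOURCES, CrosswalkTable, ObservationPanel

_SHARE_COLS = ["share_remote", "share_hybrid", "share_in_person"]


class ReportingError(ValueError):
    pass


# ---------------------------------------------------------------------------
# Tracker tables


def tracker_tables(
    panel: ObservationPanel,
    inferred: DecodedPanel | None = None,
    *,
    use_viterbi: bool = False,
) -> dict[str, pd.DataFrame]:
    """Long modality tables (district_id, week, modality code) per tracker.

    One table per source plus, when a labeled decode is supplied, an
    ``HMM`` tracker holding the inferred modality (posterior MAP by
    default).
    """
    trackers = {s: panel.source_frame(s) for s in SOURCES}
    if inferred is not None:
        if not inferred.labeled:
            raise ReportingError("inferred panel must be labeled before comparison")
        state = inferred.viterbi_state if use_viterbi else inferred.map_state
        d_idx, w_idx = np.nonzero(inferred.valid)
        trackers["HMM"] = pd.DataFrame(
            {
                "district_id": np.asarray(inferred.district_ids)[d_idx],
                "week": np.asarray(inferred.week_ids, dtype=object)[w_idx],
                "modality": state[d_idx, w_idx].astype(int),
            }
        )
    return trackers


# ---------------------------------------------------------------------------
# Pairwise agreement


def pairwise_agreement(
    trackers: dict[str, pd.DataFrame], *, by_week: bool = False
) -> pd.DataFrame:
    """Agreement between every pair of trackers on their shared coverage.

    For each unordered pair, the denominator is the set of
    district-weeks where both report; the agreement is the matching
    fraction (NaN, not 0, when the overlap is empty).  With ``by_week``
    the same statistics are returned per week.
    """
    if len(trackers) < 2:
        raise ReportingError("need at least two trackers")
    rows = []
    for a, b in combinations(trackers, 2):
        merged = trackers[a].merge(
            trackers[b], on=["district_id", "week"], suffixes=("_a", "_b")
        )
        if by_week:
            for week, grp in merged.groupby("week", sort=True):
                n = len(grp)
                m = int((grp.modality_a == grp.modality_b).sum())
                rows.append((a, b, week, n, m, m / n if n else np.nan))
        else:
            n = len(merged)
            m = int((merged.modality_a == merged.modality_b).sum())
            rows.append((a, b, n, m, m / n if n else np.nan))
    cols = ["tracker_a", "tracker_b"] + (["week"] if by_week else []) + [
        "n_overlap",
        "n_match",
        "agreement",
    ]
    return pd.DataFrame(rows, columns=cols)


@dataclass
class TTestResult:
    """One-sided paired comparison of weekly agreement series."""

    comparator: str
    statistic: float
    pvalue: float
    n_weeks: int
    mean_hmm: float
    mean_comparator: float


def agreement_ttest(
    tracker: str,
    panel: ObservationPanel,
    inferred: DecodedPanel,
) -> dict[str, TTestResult]:
    """Does the model agree with ``tracker`` more than each single source?

    Builds, per week, the proportion of shared district-weeks where
    ``tracker`` matches the fused modality and where it matches each
    remaining source, then runs a one-sided paired t-test (alternative:
    model agreement greater) across weeks present in both series.

    A degenerate all-zero difference series returns statistic 0 and
    one-sided p = 0.5 rather than NaN.
    """
    trackers = tracker_tables(panel, inferred)
    if tracker not in trackers:
        raise ReportingError(f"unknown tracker {tracker!r}")
    weekly = pairwise_agreement(trackers, by_week=True)

    def series(a: str, b: str) -> pd.Series:
        key = {a, b}
        sel = weekly[(weekly.tracker_a.isin(key)) & (weekly.tracker_b.isin(key))]
        return sel.set_index("week").agreement.dropna()

    hmm_series = series(tracker, "HMM")
    results: dict[str, TTestResult] = {}
    for other in trackers:
        if other in (tracker, "HMM"):
            continue
        other_series = series(tracker, other)
        weeks = hmm_series.index.intersection(other_series.index)
        if len(weeks) == 0:
            continue  # comparator never co-reports with the tracker: undefined
        if len(weeks) < 2:
            raise ReportingError(
                f"fewer than 2 paired weeks for {tracker} vs {other} (got {len(weeks)})"
            )
        x = hmm_series.loc[weeks].to_numpy()
        y = other_series.loc[weeks].to_numpy()
        diff = x - y
        if np.allclose(diff, 0.0):
            stat, p = 0.0, 0.5
        else:
            stat, p = stats.ttest_rel(x, y, alternative="greater")
        results[other] = TTestResult(
            comparator=other,
            statistic=float(stat),
            pvalue=float(p),
            n_weeks=len(weeks),
            mean_hmm=float(x.mean()),
            mean_comparator=float(y.mean()),
        )
    return results


# ---------------------------------------------------------------------------
# Weekly shares and trends


def weekly_shares(
    inferred: DecodedPanel,
    crosswalk: CrosswalkTable | None = None,
    strata: str = "none",
    *,
    high_confidence_only: bool = False,
    threshold: float = 0.75,
) -> pd.DataFrame:
    """Fraction of districts in each modality per week (and stratum).

    The denominator is the districts with an inferred modality that week
    (after confidence filtering when requested).  ``strata`` is one of
    ``none``, ``state``, ``urban_rural``; districts missing from the
    crosswalk land in an ``unclassified`` stratum.
    """
    if not inferred.labeled:
        raise ReportingError("inferred panel must be labeled before aggregation")
    if strata not in ("none", "state", "urban_rural"):
        raise ReportingError(f"unknown strata choice {strata!r}")
    frame = inferred.to_frame(threshold=threshold)
    if high_confidence_only:
        frame = frame[frame.high_confidence == 1]
    if frame.empty:
        raise ReportingError("no district-weeks to aggregate")

    if strata == "state":
        meta = inferred.districts.set_index("district_id").state
        frame["stratum"] = frame.district_id.map(meta).fillna("unknown")
    elif strata == "urban_rural":
        if crosswalk is None:
            raise ReportingError("urban_rural stratification requires a crosswalk")
        frame["stratum"] = crosswalk.classify(frame.district_id).to_numpy()

    keys = ["week"] + (["stratum"] if strata != "none" else [])
    counts = (
        frame.groupby(keys + ["map_modality"], sort=True)
        .size()
        .unstack("map_modality", fill_value=0)
        .reindex(columns=list(MODALITY_LABELS.values()), fill_value=0)
    )
    n = counts.sum(axis=1)
    shares = counts.div(n, axis=0)
    shares.columns = _SHARE_COLS
    shares["n_districts"] = n.astype(int)
    return shares.reset_index()


def state_endpoint_summary(trend: pd.DataFrame, weeks: list[str]) -> pd.DataFrame:
    """Per-state in-person percentage at chosen weeks, plus the net change.

    ``trend`` must be a state-stratified table from
    :func:`weekly_shares`.  Output columns hold in-person percentages
    (0–100) at each requested week and ``change`` = last − first in
    percentage points; states with no districts at a requested week are
    omitted.
    """
    if "stratum" not in trend.columns:
        raise ReportingError("trend table must be stratified by state")
    missing = [w for w in weeks if w not in set(trend.week)]
    if missing:
        raise ReportingError(f"requested week(s) {missing} not present in trend table")
    wide = (
        trend[trend.week.isin(weeks)]
        .pivot(index="stratum", columns="week", values="share_in_person")
        .reindex(columns=weeks)
        .dropna()
        * 100.0
    )
    wide.columns = [f"in_person_pct_{w}" for w in weeks]
    wide["change"] = wide.iloc[:, -1] - wide.iloc[:, 0]
    wide.index.name = "state"
    return wide.reset_index()
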