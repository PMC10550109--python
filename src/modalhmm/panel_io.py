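"""Observation-panel data model and CSV I/O.

A *panel* is a long-format table of weekly learning-modality reports for
US school districts: each row says that one source (Burbio, MCH, the
Return-to-Learn tracker, or a state dashboard) reported one modality
(fully remote, hybrid, or fully in-person) for one district in one ISO
week.  Coverage is sparse and sources disagree; absence of a row means
the source did not report that district-week (there is no sentinel
modality for "missing").

Internally observations live in a dense integer array indexed by
(district, week, source) with 0 meaning missing and codes 1..3 for
remote / hybrid / in-person.  Each district carries a contiguous week
*window* from its first to its last reported week (or a configured
school-year window); interior weeks with no reports stay in the window
as all-missing columns because the Markov chain still transitions
through them.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from datetime import date, timedelta

import numpy as np
import pandas as pd

logger = logging.getLogger("modalhmm")

# ---------------------------------------------------------------------------
# Modality and source vocabularies

#: Modality codes are fixed: 1 = fully remote, 2 = hybrid, 3 = fully in-person.
MODALITY_LABELS: dict[int, str] = {1: "remote", 2: "hybrid", 3: "in_person"}
MODALITY_CODES: dict[str, int] = {v: k for k, v in MODALITY_LABELS.items()}
#: Accepted spelling variants in input CSVs.
_MODALITY_ALIASES: dict[str, int] = {
    "remote": 1,
    "hybrid": 2,
    "in_person": 3,
    "in-person": 3,
    "inperson": 3,
}

#: The four report sources, in emission-matrix slot order.
SOURCES: tuple[str, ...] = ("BURBIO", "MCH", "R2LT", "SD")
SOURCE_INDEX: dict[str, int] = {s: i for i, s in enumerate(SOURCES)}

N_STATES = 3
MISSING = 0  # panel encoding of an absent report

#: The six NCHS urban-rural county classes.
URBAN_RURAL_CLASSES: tuple[str, ...] = (
    "large central metro",
    "large fringe metro",
    "medium metro",
    "small metro",
    "micropolitan",
    "non-core",
)

#: Name keywords marking districts that are virtual by design (excluded
#: because they do not offer in-person learning even outside a pandemic).
VIRTUAL_KEYWORDS: tuple[str, ...] = (
    "online",
    "cyber",
    "distance",
    "remote",
    "virtual",
    "digital",
)


class PanelSchemaError(ValueError):
    """An input file is missing required columns."""


class PanelParseError(ValueError):
    """An input file contains an unparseable or contradictory row."""


# ---------------------------------------------------------------------------
# ISO week arithmetic

def week_to_date(week_id: str) -> date:
    """Monday of an ISO year-week string like ``2020-W37``."""
    try:
        year_s, week_s = week_id.split("-W")
        return date.fromisocalendar(int(year_s), int(week_s), 1)
    except Exception as exc:  # noqa: BLE001 - rewrap with the offending token
        raise PanelParseError(f"invalid ISO week identifier {week_id!r}") from exc


def date_to_week(d: date) -> str:
    iso = d.isocalendar()
    return f"{iso.year}-W{iso.week:02d}"


def week_range(first: str, last: str) -> list[str]:
    """Contiguous ISO week identifiers from ``first`` to ``last`` inclusive."""
    start, stop = week_to_date(first), week_to_date(last)
    if stop < start:
        raise ValueError(f"week range reversed: {first} > {last}")
    n = (stop - start).days // 7 + 1
    return [date_to_week(start + timedelta(weeks=k)) for k in range(n)]


# ---------------------------------------------------------------------------
# Panel container

@dataclass
class ObservationPanel:
    """Dense weekly multi-source modality reports for a set of districts.

    Parameters
    ----------
    districts
        One row per district with columns ``district_id``,
        ``district_name``, ``state`` and optionally ``stratum``; row
        order matches the first axis of ``obs``.
    week_ids
        Contiguous ISO week grid shared by all districts.
    obs
        ``(n_districts, n_weeks, 4)`` int8 array; 0 = missing, else a
        modality code in {1, 2, 3}.  Source order follows ``SOURCES``.
    window
        ``(n_districts, 2)`` half-open ``[start, stop)`` week-index
        window per district.  Observations outside a district's window
        are not allowed.
    """

    districts: pd.DataFrame
    week_ids: list[str]
    obs: np.ndarray
    window: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.districts = self.districts.reset_index(drop=True)
        self.obs = np.asarray(self.obs, dtype=np.int8)
        if self.obs.shape != (len(self.districts), len(self.week_ids), len(SOURCES)):
            raise ValueError(
                f"obs shape {self.obs.shape} does not match "
                f"{len(self.districts)} districts x {len(self.week_ids)} weeks x {len(SOURCES)} sources"
            )
        if self.window is None:
            self.window = self._derive_windows()
        self.window = np.asarray(self.window, dtype=np.int64).reshape(len(self.districts), 2)
        self.validate()

    # -- construction helpers ------------------------------------------------

    def _derive_windows(self) -> np.ndarray:
        any_obs = (self.obs != MISSING).any(axis=2)
        window = np.zeros((len(self.districts), 2), dtype=np.int64)
        for d in range(len(self.districts)):
            weeks = np.flatnonzero(any_obs[d])
            if weeks.size:
                window[d] = (weeks[0], weeks[-1] + 1)
        return window

    def validate(self) -> None:
        bad = ~np.isin(self.obs, [MISSING, 1, 2, 3])
        if bad.any():
            raise PanelParseError(
                f"panel contains modality codes outside {{1,2,3}}: {np.unique(self.obs[bad])}"
            )
        if len(self.week_ids) and week_range(self.week_ids[0], self.week_ids[-1]) != list(self.week_ids):
            raise PanelParseError("week grid is not contiguous and strictly increasing")
        if ((self.window[:, 0] > self.window[:, 1]) | (self.window[:, 1] > len(self.week_ids))).any():
            raise ValueError("invalid district week windows")
        # no report may fall outside its district's window
        for d in range(self.n_districts):
            lo, hi = self.window[d]
            outside = (self.obs[d, :lo] != MISSING).any() or (self.obs[d, hi:] != MISSING).any()
            if outside:
                raise PanelParseError(
                    f"district {self.districts.district_id.iloc[d]!r} has reports outside its window"
                )
        if self.districts.district_id.duplicated().any():
            raise PanelParseError("duplicate district ids in panel")

    # -- basic queries -------------------------------------------------------

    @property
    def n_districts(self) -> int:
        return len(self.districts)

    @property
    def n_weeks(self) -> int:
        return len(self.week_ids)

    @property
    def n_observations(self) -> int:
        return int((self.obs != MISSING).sum())

    def source_frame(self, source: str) -> pd.DataFrame:
        """Long table (district_id, week, modality code) for one source."""
        s = SOURCE_INDEX[source]
        d_idx, w_idx = np.nonzero(self.obs[:, :, s] != MISSING)
        return pd.DataFrame(
            {
                "district_id": self.districts.district_id.to_numpy()[d_idx],
                "week": np.asarray(self.week_ids, dtype=object)[w_idx],
                "modality": self.obs[d_idx, w_idx, s].astype(int),
            }
        )

    def to_frame(self) -> pd.DataFrame:
        """Long-format view of all present observations."""
        frames = []
        for source in SOURCES:
            f = self.source_frame(source)
            f.insert(2, "source", source)
            frames.append(f)
        out = pd.concat(frames, ignore_index=True)
        meta = self.districts.set_index("district_id")
        out.insert(1, "district_name", out.district_id.map(meta.district_name))
        out.insert(2, "state", out.district_id.map(meta.state))
        out["modality"] = out.modality.map(MODALITY_LABELS)
        return out.sort_values(["district_id", "week", "source"], kind="stable").reset_index(drop=True)

    def sequences(self) -> tuple[np.ndarray, np.ndarray]:
        """Left-aligned per-district sequences for the HMM.

        Returns
        -------
        X : ``(n_districts, max_len, 4)`` int8 array, ``-1`` = missing,
            values ``0..2`` are zero-based modality codes; each district's
            window is left-aligned and tail-padded with missing.
        lengths : per-district window lengths.
        """
        lengths = self.window[:, 1] - self.window[:, 0]
        max_len = int(lengths.max()) if len(lengths) else 0
        X = np.full((self.n_districts, max_len, len(SOURCES)), -1, dtype=np.int8)
        for d in range(self.n_districts):
            lo, hi = self.window[d]
            X[d, : hi - lo] = self.obs[d, lo:hi].astype(np.int16) - 1
        return X, lengths

    def __eq__(self, other: object) -> bool:  # observation-level equality
        if not isinstance(other, ObservationPanel):
            return NotImplemented
        cols = ["district_id", "district_name", "state"]
        a = self.districts[cols].sort_values("district_id").reset_index(drop=True)
        b = other.districts[cols].sort_values("district_id").reset_index(drop=True)
        if not a.equals(b):
            return False
        return self.to_frame().equals(other.to_frame())


# ---------------------------------------------------------------------------
# CSV I/O

_PANEL_COLUMNS = ("district_id", "week", "source", "modality")


def read_panel(path, *, window: tuple[str, str] | None = None) -> ObservationPanel:
    """Read a long-format panel CSV into a validated :class:`ObservationPanel`.

    The file must have columns ``district_id, week, source, modality``
    (``district_name`` and ``state`` are optional and default to the id
    and ``""``).  Duplicate rows with identical modality are
    deduplicated with a warning; duplicates with conflicting modalities
    are rejected.

    Parameters
    ----------
    window
        Optional ``(first_week, last_week)`` school-year window applied
        to every district instead of its observed first/last week.
    """
    df = pd.read_csv(path, dtype=str)
    missing_cols = [c for c in _PANEL_COLUMNS if c not in df.columns]
    if missing_cols:
        raise PanelSchemaError(f"panel file {path} missing columns {missing_cols}")
    if "district_name" not in df.columns:
        df["district_name"] = df["district_id"]
    if "state" not in df.columns:
        df["state"] = ""

    bad_source = ~df.source.isin(SOURCES)
    if bad_source.any():
        row = df.index[bad_source][0]
        raise PanelParseError(f"unknown source {df.source.iloc[row]!r} at row {row + 2} of {path}")
    codes = df.modality.str.strip().str.lower().map(_MODALITY_ALIASES)
    if codes.isna().any():
        row = int(codes.index[codes.isna()][0])
        raise PanelParseError(
            f"unknown modality token {df.modality.iloc[row]!r} at row {row + 2} of {path}"
        )
    df["modality_code"] = codes.astype(int)

    key = ["district_id", "week", "source"]
    dup = df.duplicated(key, keep=False)
    if dup.any():
        conflicts = df[dup].groupby(key)["modality_code"].nunique()
        if (conflicts > 1).any():
            k = conflicts.index[conflicts > 1][0]
            raise PanelParseError(f"conflicting duplicate reports for (district, week, source) {k}")
        n_before = len(df)
        df = df.drop_duplicates(key)
        logger.warning("deduplicated %d identical duplicate rows", n_before - len(df))

    districts = (
        df.groupby("district_id", sort=True)
        .agg(district_name=("district_name", "first"), state=("state", "first"))
        .reset_index()
    )
    if df.empty:
        return ObservationPanel(districts, [], np.zeros((0, 0, len(SOURCES)), dtype=np.int8))

    for w in df.week.unique():
        week_to_date(w)  # validates token format
    if window is None:
        weeks = week_range(min(df.week, key=week_to_date), max(df.week, key=week_to_date))
    else:
        weeks = week_range(*window)
    week_pos = {w: i for i, w in enumerate(weeks)}
    if not df.week.isin(week_pos).all():
        w = df.week[~df.week.isin(week_pos)].iloc[0]
        raise PanelParseError(f"week {w} falls outside the configured window")

    d_pos = {d: i for i, d in enumerate(districts.district_id)}
    obs = np.zeros((len(districts), len(weeks), len(SOURCES)), dtype=np.int8)
    obs[
        df.district_id.map(d_pos).to_numpy(),
        df.week.map(week_pos).to_numpy(),
        df.source.map(SOURCE_INDEX).to_numpy(),
    ] = df.modality_code.to_numpy()

    win = None
    if window is not None:
        win = np.tile([0, len(weeks)], (len(districts), 1))
    return ObservationPanel(districts, weeks, obs, window=win)


def write_panel(panel: ObservationPanel, path) -> None:
    """Write a panel as long CSV; missing observations are absent rows."""
    panel.to_frame().to_csv(path, index=False)


def filter_virtual_districts(panel: ObservationPanel) -> ObservationPanel:
    """Drop districts whose names mark them as virtual-by-design.

    Matches the keywords ``online, cyber, distance, remote, virtual,
    digital`` as case-insensitive substrings anywhere in the district
    name.  Idempotent.
    """
    names = panel.districts.district_name.fillna("").str.lower()
    drop = np.zeros(len(names), dtype=bool)
    for kw in VIRTUAL_KEYWORDS:
        drop |= names.str.contains(kw, regex=False).to_numpy()
    if drop.any():
        logger.info("filter_virtual_districts removed %d of %d districts", int(drop.sum()), len(drop))
    keep = ~drop
    return ObservationPanel(
        panel.districts[keep],
        list(panel.week_ids),
        panel.obs[keep],
        window=panel.window[keep],
    )


# ---------------------------------------------------------------------------
# Crosswalk

@dataclass
class CrosswalkTable:
    """District → (county, urban-rural class) lookup.

    Districts absent from the table are reported downstream under an
    ``unclassified`` stratum rather than dropped.
    """

    rows: pd.DataFrame  # district_id, county_fips, urban_rural_class

    def __post_init__(self) -> None:
        self.rows = self.rows.reset_index(drop=True)
        if self.rows.district_id.duplicated().any():
            raise PanelParseError("district appears more than once in crosswalk")
        bad = ~self.rows.urban_rural_class.isin(URBAN_RURAL_CLASSES)
        if bad.any():
            raise PanelParseError(
                f"unknown urban-rural class {self.rows.urban_rural_class[bad].iloc[0]!r}"
            )

    def classify(self, district_ids) -> pd.Series:
        """Urban-rural class per district id, ``'unclassified'`` if absent."""
        lookup = self.rows.set_index("district_id").urban_rural_class
        out = pd.Series(district_ids, name="urban_rural_class").map(lookup)
        return out.fillna("unclassified")


def read_crosswalk(path) -> CrosswalkTable:
    """Read a district→county urban-rural crosswalk CSV."""
    df = pd.read_csv(path, dtype=str)
    required = ["district_id", "urban_rural_class"]
    missing_cols = [c for c in required if c not in df.columns]
    if missing_cols:
        raise PanelSchemaError(f"crosswalk file {path} missing columns {missing_cols}")
    if "county_fips" not in df.columns:
        df["county_fips"] = ""
    return CrosswalkTable(df[["district_id", "county_fips", "urban_rural_class"]])
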