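"""Ring-width and trial-design I/O, and per-tree chronology assembly.

Supports the Tucson/RWL decadal text format (both the 0.01 mm dialect with
``999`` terminators and the 0.001 mm dialect with ``-9999`` terminators)
and a long-form CSV interchange format (core_id, tree_id, year, width_mm).
Widths are always held in millimetres in memory.

A *core* is one increment-borer sample; a *tree* usually contributes two
cores (north and south side of the stem), which are averaged year by year
into a single tree-level chronology before any statistical analysis.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Callable, Iterable, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: Analysis window used throughout: the years with complete ring coverage.
DEFAULT_WINDOW = (1988, 2017)


class RingDataError(ValueError):
    """Malformed or inconsistent ring-width data."""


@dataclass
class RingSeries:
    """Annual ring widths of a single increment core, in mm by calendar year."""

    core_id: str
    tree_id: str
    years: np.ndarray  # int, strictly increasing
    widths: np.ndarray  # mm, >= 0
    missing_rings: np.ndarray = field(default_factory=lambda: np.array([], dtype=int))
    #: calendar years recorded with the missing-ring code (width 0)

    def __post_init__(self):
        self.years = np.asarray(self.years, dtype=int)
        self.widths = np.asarray(self.widths, dtype=float)
        self.missing_rings = np.asarray(self.missing_rings, dtype=int)
        if len(self.years) != len(self.widths):
            raise RingDataError(f"{self.core_id}: years/widths length mismatch")
        if len(self.years) < 1:
            raise RingDataError(f"{self.core_id}: empty series")
        if np.any(np.diff(self.years) <= 0):
            raise RingDataError(f"{self.core_id}: years not strictly increasing")
        if not np.all(np.isfinite(self.widths)) or np.any(self.widths < 0):
            raise RingDataError(f"{self.core_id}: widths must be finite and >= 0")

    def __eq__(self, other) -> bool:
        return (
            isinstance(other, RingSeries)
            and self.core_id == other.core_id
            and self.tree_id == other.tree_id
            and np.array_equal(self.years, other.years)
            and np.allclose(self.widths, other.widths, atol=1e-9)
            and np.array_equal(np.sort(self.missing_rings), np.sort(other.missing_rings))
        )


@dataclass
class TreeChronology:
    """Per-tree ring-width series (mean over cores) with its own mean/SD.

    ``raw_mean`` and ``raw_sd`` are computed over the analysis window and
    stored so that standardization can be exactly reversed after detrending;
    ``detrended_mm`` stays ``None`` until a common spline has been removed.
    """

    tree_id: str
    provenance_id: str
    region: str
    block: int
    years: np.ndarray
    width_mm: np.ndarray
    n_cores: np.ndarray
    raw_mean: float
    raw_sd: float
    detrended_mm: np.ndarray | None = None

    def width_at(self, year: int) -> float:
        idx = np.searchsorted(self.years, year)
        if idx >= len(self.years) or self.years[idx] != year:
            raise KeyError(f"tree {self.tree_id}: year {year} not in chronology")
        return float(self.width_mm[idx])

    def detrended_at(self, year: int) -> float:
        if self.detrended_mm is None:
            raise RingDataError(f"tree {self.tree_id}: not detrended yet")
        idx = np.searchsorted(self.years, year)
        if idx >= len(self.years) or self.years[idx] != year:
            raise KeyError(f"tree {self.tree_id}: year {year} not in chronology")
        return float(self.detrended_mm[idx])


DESIGN_COLUMNS = [
    "tree_id",
    "provenance_id",
    "region",
    "block",
    "plot",
    "height_cm",
    "dbh_mm",
    "survival",
]


@dataclass
class TrialDesign:
    """Common-garden design table: tree -> provenance -> region, block, plot.

    Carries the field traits (height at age 32 in cm, DBH at age 27 in mm,
    survival 0/1) alongside the design structure.
    """

    table: pd.DataFrame

    def __post_init__(self):
        missing = [c for c in DESIGN_COLUMNS if c not in self.table.columns]
        if missing:
            raise RingDataError(f"design table missing columns: {missing}")
        t = self.table
        if t["tree_id"].duplicated().any():
            dups = t.loc[t["tree_id"].duplicated(), "tree_id"].tolist()
            raise RingDataError(f"duplicate tree ids in design: {dups[:5]}")
        surv = t["survival"].dropna()
        if not surv.isin([0, 1]).all():
            raise RingDataError("survival must be 0/1")

    @property
    def regions(self) -> list[str]:
        return sorted(self.table["region"].unique())

    def row_for(self, tree_id: str) -> pd.Series:
        rows = self.table[self.table["tree_id"] == tree_id]
        if rows.empty:
            raise KeyError(f"tree {tree_id} not in design")
        return rows.iloc[0]


# ---------------------------------------------------------------------------
# Tucson / RWL decadal format
# ---------------------------------------------------------------------------

_TERMINATORS = {"999": 0.01, "-9999": 0.001}


def _default_tree_of_core(core_id: str) -> str:
    """Map a core id to its tree id: strip a trailing letter suffix if any."""
    if len(core_id) > 1 and core_id[-1].isalpha() and not core_id[-2].isalpha():
        return core_id[:-1]
    return core_id


def read_rwl(
    path: str | Path,
    tree_of_core: Callable[[str], str] = _default_tree_of_core,
) -> list[RingSeries]:
    """Read a Tucson/RWL decadal ring-width file.

    The measurement unit is auto-detected per series from the terminator
    value: ``999`` marks the 0.01 mm dialect, ``-9999`` the 0.001 mm one.
    A data value of 0 is the missing-ring code; it is kept as width 0.0
    and the year recorded in ``missing_rings``.
    """
    path = Path(path)
    raw: dict[str, dict[int, float]] = {}
    missing: dict[str, list[int]] = {}
    open_unit: dict[str, float | None] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip():
                continue
            core_id = line[:8].strip()
            rest = line[8:].split()
            if not core_id or len(rest) < 2:
                raise RingDataError(f"{path}:{lineno}: malformed decade line")
            try:
                decade = int(rest[0])
            except ValueError:
                raise RingDataError(
                    f"{path}:{lineno}: bad decade year {rest[0]!r}"
                ) from None
            values = rest[1:]
            store = raw.setdefault(core_id, {})
            missing.setdefault(core_id, [])
            open_unit.setdefault(core_id, None)
            for offset, tok in enumerate(values):
                if tok in _TERMINATORS:
                    open_unit[core_id] = _TERMINATORS[tok]
                    break
                try:
                    v = int(tok)
                except ValueError:
                    raise RingDataError(
                        f"{path}:{lineno}: bad width value {tok!r}"
                    ) from None
                year = decade + offset
                if year in store:
                    raise RingDataError(
                        f"{path}:{lineno}: duplicate measurement for "
                        f"core {core_id}, year {year}"
                    )
                store[year] = v
                if v == 0:
                    missing[core_id].append(year)
    out = []
    for core_id, store in raw.items():
        unit = open_unit[core_id]
        if unit is None:
            raise RingDataError(f"{path}: series {core_id} has no terminator")
        years = np.array(sorted(store), dtype=int)
        widths = np.array([store[y] for y in years], dtype=float) * unit
        out.append(
            RingSeries(
                core_id=core_id,
                tree_id=tree_of_core(core_id),
                years=years,
                widths=widths,
                missing_rings=np.array(missing[core_id], dtype=int),
            )
        )
    return out


def write_rwl(series: Sequence[RingSeries], path: str | Path, unit: float = 0.001) -> None:
    """Write series in Tucson decadal format (default 0.001 mm dialect)."""
    if unit not in (0.01, 0.001):
        raise ValueError("unit must be 0.01 or 0.001 mm")
    terminator = "999" if unit == 0.01 else "-9999"
    with open(path, "w") as fh:
        for s in series:
            if np.any(np.diff(s.years) != 1):
                raise RingDataError(
                    f"{s.core_id}: gaps in years cannot be represented in RWL"
                )
            y0, y1 = int(s.years[0]), int(s.years[-1])
            vals = {int(y): w for y, w in zip(s.years, s.widths)}
            year = y0
            while year <= y1:
                decade_end = (year // 10) * 10 + 9
                stop = min(decade_end, y1)
                toks = [f"{s.core_id:<8s}{year:4d}"]
                for y in range(year, stop + 1):
                    toks.append(f"{int(round(vals[y] / unit)):6d}")
                if stop == y1:
                    toks.append(f"{terminator:>6s}")
                fh.write("".join(toks) + "\n")
                year = stop + 1


# ---------------------------------------------------------------------------
# Long CSV interchange
# ---------------------------------------------------------------------------

def read_rings_csv(path: str | Path) -> list[RingSeries]:
    """Read the long-form interchange CSV: core_id, tree_id, year, width_mm."""
    df = pd.read_csv(path, dtype={"core_id": str, "tree_id": str})
    needed = {"core_id", "tree_id", "year", "width_mm"}
    if not needed.issubset(df.columns):
        raise RingDataError(f"{path}: need columns {sorted(needed)}")
    if df.duplicated(["core_id", "year"]).any():
        bad = df[df.duplicated(["core_id", "year"])].iloc[0]
        raise RingDataError(
            f"{path}: duplicate (core, year) = ({bad.core_id}, {bad.year})"
        )
    out = []
    for (core_id, tree_id), g in df.groupby(["core_id", "tree_id"], sort=True):
        g = g.sort_values("year")
        w = g["width_mm"].to_numpy(dtype=float)
        out.append(
            RingSeries(
                core_id=str(core_id),
                tree_id=str(tree_id),
                years=g["year"].to_numpy(dtype=int),
                widths=w,
                missing_rings=g["year"].to_numpy(dtype=int)[w == 0.0],
            )
        )
    return out


def write_rings_csv(series: Sequence[RingSeries], path: str | Path) -> None:
    rows = []
    for s in series:
        for y, w in zip(s.years, s.widths):
            rows.append((s.core_id, s.tree_id, int(y), float(w)))
    pd.DataFrame(rows, columns=["core_id", "tree_id", "year", "width_mm"]).to_csv(
        path, index=False
    )


def read_design_csv(path: str | Path) -> TrialDesign:
    df = pd.read_csv(path, dtype={"tree_id": str, "provenance_id": str, "plot": str})
    return TrialDesign(df)


def write_design_csv(design: TrialDesign, path: str | Path) -> None:
    design.table.to_csv(path, index=False)


# ---------------------------------------------------------------------------
# Chronology assembly
# ---------------------------------------------------------------------------

def build_tree_chronologies(
    series: Iterable[RingSeries],
    design: TrialDesign,
    window: tuple[int, int] = DEFAULT_WINDOW,
) -> list[TreeChronology]:
    """Average cores per tree into chronologies over the analysis window.

    Per year, the width is the arithmetic mean of all cores measured in that
    year and ``n_cores`` records how many contributed. The per-tree mean and
    sample SD (``ddof=1``) over the window are stored for standardization.

    Raises
    ------
    RingDataError
        If a tree is absent from the design (all offenders listed) or a
        tree's windowed series has zero variance (cannot be normalized).
    """
    lo, hi = window
    by_tree: dict[str, list[RingSeries]] = {}
    for s in series:
        by_tree.setdefault(s.tree_id, []).append(s)

    unknown = sorted(t for t in by_tree if t not in set(design.table["tree_id"]))
    if unknown:
        raise RingDataError(f"trees not in design table: {unknown}")

    chronos: list[TreeChronology] = []
    for tree_id in sorted(by_tree):
        cores = by_tree[tree_id]
        all_years = np.unique(np.concatenate([c.years for c in cores]))
        all_years = all_years[(all_years >= lo) & (all_years <= hi)]
        if len(all_years) == 0:
            logger.warning("tree %s: no rings inside window %s; excluded", tree_id, window)
            continue
        if len(cores) > 1:
            shared = set(cores[0].years)
            for c in cores[1:]:
                shared &= set(c.years)
            if not shared:
                raise RingDataError(f"tree {tree_id}: cores have no overlapping year")
        sums = np.zeros(len(all_years))
        counts = np.zeros(len(all_years), dtype=int)
        for c in cores:
            mask = (c.years >= lo) & (c.years <= hi)
            idx = np.searchsorted(all_years, c.years[mask])
            sums[idx] += c.widths[mask]
            counts[idx] += 1
        mean_w = sums / counts
        raw_mean = float(np.mean(mean_w))
        raw_sd = float(np.std(mean_w, ddof=1)) if len(mean_w) > 1 else 0.0
        if raw_sd <= 0.0:
            # a degenerate but representable chronology; normalization (and
            # hence detrending) will refuse it downstream
            logger.warning("tree %s: zero-variance series in window", tree_id)
        row = design.row_for(tree_id)
        chronos.append(
            TreeChronology(
                tree_id=tree_id,
                provenance_id=str(row["provenance_id"]),
                region=str(row["region"]),
                block=int(row["block"]),
                years=all_years,
                width_mm=mean_w,
                n_cores=counts,
                raw_mean=raw_mean,
                raw_sd=raw_sd,
            )
        )
    return chronos


def chronologies_to_frame(chronos: Sequence[TreeChronology]) -> pd.DataFrame:
    """Long-format view of chronologies (one row per tree-year)."""
    rows = []
    for c in chronos:
        det = c.detrended_mm if c.detrended_mm is not None else [np.nan] * len(c.years)
        for y, w, n, d in zip(c.years, c.width_mm, c.n_cores, det):
            rows.append((c.tree_id, c.provenance_id, c.region, c.block, int(y), w, int(n), d))
    return pd.DataFrame(
        rows,
        columns=[
            "tree_id", "provenance_id", "region", "block",
            "year", "width_mm", "n_cores", "detrended_mm",
        ],
    )
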