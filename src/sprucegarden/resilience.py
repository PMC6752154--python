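"""Lloret drought indices: resistance, recovery, resilience.

All indices are ratios of detrended growth (mm) so that trees and events
are comparable on a common scale:

    resistance  Rt_e = D_e / preD      (growth kept during the event year)
    recovery    Rc_e = postD / D_e     (rebound after the event)
    resilience  Rs   = postD / preD    (performance after vs. before)

with preD and postD the arithmetic mean detrended growth over shared
pre- and post-disturbance reference windows. Sharing one pre and one post
window across both drought events (the events here were too close for
full recovery in between) makes Rs = Rt_e * Rc_e an exact identity for
every event.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .ringio import TreeChronology, TrialDesign


@dataclass
class EventScheme:
    """Drought event years plus shared pre/post reference windows."""

    event_years: tuple[int, ...] = (1999, 2002)
    pre_window: tuple[int, int] = (1993, 1997)
    post_window: tuple[int, int] = (2003, 2007)

    def __post_init__(self):
        self.event_years = tuple(sorted(int(y) for y in self.event_years))
        if not self.event_years:
            raise ValueError("need at least one event year")
        if self.pre_window[0] > self.pre_window[1] or self.post_window[0] > self.post_window[1]:
            raise ValueError("windows must be non-empty (lo <= hi)")
        if self.pre_window[1] >= self.event_years[0]:
            raise ValueError("pre-window must end before the first event")
        if self.post_window[0] <= self.event_years[-1]:
            raise ValueError("post-window must start after the last event")

    def all_years(self) -> list[int]:
        return (
            list(range(self.pre_window[0], self.pre_window[1] + 1))
            + list(self.event_years)
            + list(range(self.post_window[0], self.post_window[1] + 1))
        )


@dataclass
class ResilienceSet:
    """Per-tree Lloret indices and the growth means they are built from."""

    tree_id: str
    pre_mean: float  # mm, mean detrended growth over the pre-window
    post_mean: float  # mm
    event_growth: dict[int, float]  # mm in each event year
    resistance: dict[int, float] = field(default_factory=dict)
    recovery: dict[int, float] = field(default_factory=dict)
    resilience: float = float("nan")


def compute_resilience(
    chrono: TreeChronology,
    scheme: EventScheme = EventScheme(),
    growth_floor: float | None = None,
) -> ResilienceSet:
    """Lloret indices for one tree on its detrended series.

    Parameters
    ----------
    chrono
        A detrended chronology (``detrended_mm`` must be filled).
    scheme
        Event years and shared reference windows.
    growth_floor
        Off by default. If set, event-year or pre-window growth at or
        below zero is replaced by this small positive floor instead of
        raising; detrending can occasionally push a weak ring to <= 0.
    """
    if chrono.detrended_mm is None:
        raise ValueError(f"tree {chrono.tree_id}: detrend before computing indices")
    have = set(int(y) for y in chrono.years)
    for y in scheme.all_years():
        if y not in have:
            raise ValueError(f"tree {chrono.tree_id}: year {y} missing from chronology")

    def window_mean(lo: int, hi: int) -> float:
        mask = (chrono.years >= lo) & (chrono.years <= hi)
        return float(np.mean(chrono.detrended_mm[mask]))

    def guard(v: float, what: str) -> float:
        if v > 0:
            return v
        if growth_floor is not None:
            return growth_floor
        raise ValueError(
            f"tree {chrono.tree_id}: nonpositive {what} ({v:.4g} mm); "
            "index undefined (set growth_floor to substitute a small value)"
        )

    pre = guard(window_mean(*scheme.pre_window), "pre-disturbance growth")
    post = window_mean(*scheme.post_window)
    out = ResilienceSet(
        tree_id=chrono.tree_id, pre_mean=pre, post_mean=post, event_growth={}
    )
    for e in scheme.event_years:
        d = guard(chrono.detrended_at(e), f"growth in event year {e}")
        out.event_growth[e] = d
        out.resistance[e] = d / pre
        out.recovery[e] = post / d
    out.resilience = post / pre
    return out


def resilience_frame(
    sets: list[ResilienceSet], design: TrialDesign
) -> pd.DataFrame:
    """One row per tree: design columns plus Rt/Rc per event and Rs."""
    rows = []
    for s in sets:
        d = design.row_for(s.tree_id)
        row = {
            "tree_id": s.tree_id,
            "provenance_id": d["provenance_id"],
            "region": d["region"],
            "block": d["block"],
        }
        for e in sorted(s.resistance):
            row[f"resistance_{e}"] = s.resistance[e]
            row[f"recovery_{e}"] = s.recovery[e]
        row["resilience"] = s.resilience
        rows.append(row)
    return pd.DataFrame(rows)


def regional_resilience_table(
    sets: list[ResilienceSet],
    design: TrialDesign,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Regional BLUEs with SEs and Tukey letters for every Lloret index.

    Uses the core-sampling mixed model (one tree per provenance per block):
    region as the fixed effect, block as a random effect. Returns a table
    in the familiar region x index layout: one row per region, per-index
    ``<index>``, ``<index>_se`` and ``<index>_letters`` columns.
    """
    from .inference import fit_lmm_blues

    df = resilience_frame(sets, design)
    regions = sorted(df["region"].unique())
    if len(regions) < 2:
        raise ValueError("need >= 2 regions for a regional table")
    if df["block"].nunique() < 2:
        raise ValueError("need >= 2 blocks for a regional table")
    index_cols = [c for c in df.columns if c.startswith(("resistance_", "recovery_"))]
    index_cols.append("resilience")
    out = pd.DataFrame({"region": regions})
    for col in index_cols:
        est = fit_lmm_blues(df, response=col, preset="cores", alpha=alpha)
        t = est.table.set_index("region").loc[regions]
        out[col] = t["estimate"].to_numpy()
        out[f"{col}_se"] = t["se"].to_numpy()
        out[f"{col}_letters"] = t["letters"].to_numpy()
    return out
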