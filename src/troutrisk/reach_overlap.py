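"""River-reach co-occurrence summaries: where do trout meet at-risk natives?

Works on a reach table: one row per elementary river segment carrying its
length in km, a trout occurrence value, and one occurrence column per native
species.  Occurrence values are booleans or probabilities in [0, 1];
probabilities are binarised at a recorded threshold tau (value >= tau means
present).  For each risk tier the summary reports

* ``extent_km`` — summed length of reaches hosting at least one species of
  the tier,
* ``overlap_km`` — the subset of that extent where trout also occur,
* ``overlap_pct`` — 100 * overlap_km / extent_km (None for an empty extent),

plus the total trout extent and the length where trout co-occur with at
least one native species of any tier.  A reach hosting species of several
tiers counts toward every tier it hosts.  Lengths are attributes; no network
topology is used.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from .risk_classes import RiskClassification

__all__ = ["ReachTable", "TierOverlap", "OverlapSummary", "load_reach_table",
           "write_reach_table", "threshold_presence", "summarize_overlap"]

_RESERVED = ("reach_id", "length_km", "trout")


@dataclass(frozen=True)
class ReachTable:
    """Validated per-reach lengths and occurrence values.

    ``data`` columns: reach_id, length_km, trout, then one column per
    species (canonical keys).  Occurrence values live in [0, 1]; plain
    booleans are stored as 0.0/1.0.
    """

    data: pd.DataFrame

    def __post_init__(self) -> None:
        df = self.data
        for col in _RESERVED:
            if col not in df.columns:
                raise ValueError(f"reach table missing required column {col!r}")
        if df["reach_id"].duplicated().any():
            dupes = df.loc[df["reach_id"].duplicated(), "reach_id"].tolist()
            raise ValueError(f"duplicate reach ids: {dupes[:5]}")
        if (df["length_km"] < 0).any():
            bad = df.loc[df["length_km"] < 0, "reach_id"].iloc[0]
            raise ValueError(f"negative length_km at reach {bad!r}")
        occ = df[[c for c in df.columns if c not in ("reach_id", "length_km")]]
        arr = occ.to_numpy(dtype=float)
        if np.isnan(arr).any() or (arr < 0).any() or (arr > 1).any():
            col = occ.columns[np.argwhere(~((arr >= 0) & (arr <= 1)))[0][1]]
            raise ValueError(f"occurrence values outside [0, 1] in column {col!r}")

    @property
    def species_columns(self) -> tuple[str, ...]:
        return tuple(c for c in self.data.columns if c not in _RESERVED)

    @property
    def total_length_km(self) -> float:
        return float(self.data["length_km"].sum())

    def __len__(self) -> int:
        return len(self.data)


@dataclass(frozen=True)
class TierOverlap:
    tier: str
    extent_km: float
    overlap_km: float
    overlap_pct: float | None  # None when the tier occupies no length

    def __post_init__(self) -> None:
        if self.overlap_km > self.extent_km + 1e-9:
            raise ValueError(f"{self.tier}: overlap exceeds extent")


@dataclass(frozen=True)
class OverlapSummary:
    """Per-tier extents/overlaps plus network-wide totals, at a recorded tau."""

    tiers: Mapping[str, TierOverlap]
    trout_extent_km: float
    any_species_overlap_km: float
    total_length_km: float
    tau: float
    unclassified_species: tuple[str, ...] = field(default_factory=tuple)

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {
                "tier": t.tier,
                "extent_km": t.extent_km,
                "overlap_km": t.overlap_km,
                "overlap_pct": t.overlap_pct,
            }
            for t in self.tiers.values()
        ]
        return pd.DataFrame(rows).set_index("tier")


def load_reach_table(path: str | Path) -> ReachTable:
    """Read a reach table from comma-separated text and validate it."""
    df = pd.read_csv(path)
    if df.empty:
        raise ValueError(f"{path}: empty reach table")
    return ReachTable(df)


def write_reach_table(table: ReachTable, path: str | Path) -> None:
    table.data.to_csv(path, index=False)


def threshold_presence(values, tau: float) -> np.ndarray:
    """Binarise occurrence values: present iff value >= tau.

    Booleans pass through unchanged (as booleans of themselves); tau must
    lie in [0, 1].
    """
    if not 0.0 <= tau <= 1.0:
        raise ValueError(f"tau must be in [0, 1], got {tau}")
    arr = np.asarray(values)
    if arr.dtype == bool:
        return arr.copy()
    arr = arr.astype(float)
    if ((arr < 0) | (arr > 1)).any():
        raise ValueError("occurrence values must lie in [0, 1]")
    return arr >= tau


def summarize_overlap(
    reaches: ReachTable,
    classification: RiskClassification | Mapping[str, str],
    tau: float = 0.5,
) -> OverlapSummary:
    """Per-tier river-length extent and trout overlap at threshold ``tau``.

    Every classified species must appear as a reach-table column (missing
    species raise, listing them); reach-table species columns absent from
    the classification are reported in ``unclassified_species``, not
    silently dropped.
    """
    tiers_map = (classification.tiers if isinstance(classification,
                                                    RiskClassification)
                 else dict(classification))
    cols = set(reaches.species_columns)
    missing = sorted(set(tiers_map) - cols)
    if missing:
        raise ValueError(f"classified species missing from reach table: {missing}")
    unclassified = tuple(sorted(cols - set(tiers_map)))

    length = reaches.data["length_km"].to_numpy(dtype=float)
    trout = threshold_presence(reaches.data["trout"].to_numpy(), tau)
    trout_extent = float(length[trout].sum())

    tier_names: list[str] = []
    for t in tiers_map.values():
        if t not in tier_names:
            tier_names.append(t)

    tiers: dict[str, TierOverlap] = {}
    any_native = np.zeros(len(reaches), dtype=bool)
    for tier in tier_names:
        members = [sp for sp, t in tiers_map.items() if t == tier]
        occ = threshold_presence(
            reaches.data[members].to_numpy(dtype=float), tau
        ).any(axis=1)
        any_native |= occ
        extent = float(length[occ].sum())
        overlap = float(length[occ & trout].sum())
        pct = None if extent == 0 else 100.0 * overlap / extent
        tiers[tier] = TierOverlap(tier=tier, extent_km=extent,
                                  overlap_km=overlap, overlap_pct=pct)
    any_overlap = float(length[any_native & trout].sum())
    return OverlapSummary(
        tiers=tiers,
        trout_extent_km=trout_extent,
        any_species_overlap_km=any_overlap,
        total_length_km=reaches.total_length_km,
        tau=tau,
        unclassified_species=unclassified,
    )
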