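"""Risk-assessment matrix: data model, I/O and weighted species risk scores.

The screening matrix scores each native fish species from 1 (low risk) to 3
(high risk) on a set of biological risk factors describing its exposure and
resilience to trout pressures (habitat/diet/diel overlap, fecundity, age at
maturity, larval dispersal, adult body size).  Factors judged most influential
on population-level risk carry weight 2, the rest weight 1, and a species'
total risk score is the weighted sum of its factor scores.

The canonical seven-factor configuration (weights 1,1,1,2,1,2,2) gives totals
in [10, 30].  An optional eighth threat-status factor is defined in the data
model (:data:`THREAT_STATUS_FACTOR`) but excluded from the default scoring.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "RiskFactor",
    "TraitScoreTable",
    "SpeciesRiskResult",
    "TraitTableError",
    "DEFAULT_FACTORS",
    "DEFAULT_WEIGHTS",
    "THREAT_STATUS_FACTOR",
    "load_trait_table",
    "packaged_trait_table",
    "write_trait_table",
    "compute_risk_scores",
    "scores_frame",
    "score_bounds",
    "normalize_species_key",
]

VALID_SCORES = frozenset({1, 2, 3})


class TraitTableError(ValueError):
    """Raised when a trait table or weight vector fails validation."""


def normalize_species_key(binomial: str) -> str:
    """Normalise a binomial name to a canonical key (lowercase, underscores)."""
    return "_".join(binomial.strip().lower().split())


@dataclass(frozen=True)
class RiskFactor:
    """One column of the screening matrix.

    Parameters
    ----------
    factor_id : str
        Short machine name (for example ``"larval_dispersal"``).
    label : str
        Human-readable name.
    weight : int
        Positive integer weight; influential factors carry 2.
    score_levels : mapping of int to str
        Criterion text for levels 1..3.
    """

    factor_id: str
    label: str
    weight: int
    score_levels: Mapping[int, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.weight < 1:
            raise TraitTableError(
                f"factor {self.factor_id!r}: weight must be >= 1, got {self.weight}"
            )
        if self.score_levels and set(self.score_levels) != VALID_SCORES:
            raise TraitTableError(
                f"factor {self.factor_id!r}: score levels must be exactly {{1, 2, 3}}"
            )


# Canonical seven factors, in matrix column order.
DEFAULT_FACTORS: tuple[RiskFactor, ...] = (
    RiskFactor(
        "overlapping_mesohabitat",
        "Overlapping mesohabitat",
        1,
        {1: "No or rare overlap", 2: "Intermittent overlap", 3: "Persistent overlap"},
    ),
    RiskFactor(
        "diet_similarities",
        "Diet similarities",
        1,
        {
            1: "No or few similarities",
            2: "Similar (aquatic invertebrates)",
            3: "Very similar (aquatic & terrestrial invertebrates / piscivorous)",
        },
    ),
    RiskFactor(
        "diel_activity",
        "Diel activity patterns",
        1,
        {
            1: "No or rare overlap",
            2: "Intermittent overlap",
            3: "Similar diel patterns to trout",
        },
    ),
    RiskFactor(
        "fecundity_egg_size",
        "Fecundity and egg size",
        2,
        {1: "Many", 2: "Few, small eggs", 3: "Few, large eggs"},
    ),
    RiskFactor(
        "age_at_maturity",
        "Age at reproductive maturity",
        1,
        {1: "1 year", 2: "1-3 years", 3: "> 3 years"},
    ),
    RiskFactor(
        "larval_dispersal",
        "Larval dispersal ability",
        2,
        {
            1: "Diadromous",
            2: "Non-diadromous, widespread dispersal",
            3: "Non-diadromous, limited dispersal",
        },
    ),
    RiskFactor(
        "adult_size",
        "Adult body length",
        2,
        {1: "> 12 cm", 2: "8-12 cm", 3: "< 8 cm"},
    ),
)

#: Optional eighth factor: national threat-classification status.  Supported by
#: the data model but excluded from the default totals, which use the seven
#: factors above.
THREAT_STATUS_FACTOR = RiskFactor(
    "threat_status",
    "Threat classification status",
    2,
    {
        1: "Not Threatened",
        2: "Declining / Naturally uncommon / Nationally vulnerable / Data deficient",
        3: "Nationally endangered / Nationally critical",
    },
)

DEFAULT_WEIGHTS: tuple[int, ...] = tuple(f.weight for f in DEFAULT_FACTORS)


@dataclass(frozen=True)
class TraitScoreTable:
    """A validated species x factor score matrix.

    ``scores`` is an integer array of shape ``(n_species, n_factors)`` with
    every entry in {1, 2, 3}; ``species`` holds canonical binomial keys and
    ``common_names`` the display names, aligned by row.
    """

    species: tuple[str, ...]
    factors: tuple[RiskFactor, ...]
    scores: np.ndarray
    common_names: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        scores = np.asarray(self.scores, dtype=int)
        object.__setattr__(self, "scores", scores)
        if scores.ndim != 2 or scores.shape != (len(self.species), len(self.factors)):
            raise TraitTableError(
                f"score matrix shape {scores.shape} does not match "
                f"{len(self.species)} species x {len(self.factors)} factors"
            )
        if len(set(self.species)) != len(self.species):
            dupes = sorted({s for s in self.species if self.species.count(s) > 1})
            raise TraitTableError(f"duplicate species identifiers: {dupes}")
        bad = ~np.isin(scores, list(VALID_SCORES))
        if bad.any():
            i, j = np.argwhere(bad)[0]
            raise TraitTableError(
                f"score {scores[i, j]} outside {{1, 2, 3}} for species "
                f"{self.species[i]!r}, factor {self.factors[j].factor_id!r}"
            )
        if self.common_names and len(self.common_names) != len(self.species):
            raise TraitTableError("common_names length does not match species")

    @property
    def n_species(self) -> int:
        return len(self.species)

    @property
    def n_factors(self) -> int:
        return len(self.factors)

    @property
    def weights(self) -> np.ndarray:
        return np.array([f.weight for f in self.factors], dtype=int)

    @property
    def factor_ids(self) -> tuple[str, ...]:
        return tuple(f.factor_id for f in self.factors)

    def to_frame(self) -> pd.DataFrame:
        """Return the score matrix as a DataFrame indexed by species key."""
        return pd.DataFrame(
            self.scores, index=list(self.species), columns=list(self.factor_ids)
        )

    def display_name(self, key: str) -> str:
        if self.common_names:
            return self.common_names[self.species.index(key)]
        return key


@dataclass(frozen=True)
class SpeciesRiskResult:
    """Weighted risk score of one species: per-factor contributions + total."""

    species: str
    contributions: Mapping[str, int]
    total: int

    def __post_init__(self) -> None:
        if sum(self.contributions.values()) != self.total:
            raise TraitTableError(
                f"{self.species}: total {self.total} != sum of contributions"
            )


def load_trait_table(path: str | Path) -> TraitScoreTable:
    """Read a trait-score table from the comma-separated matrix dialect.

    Layout: a header row of factor ids (after ``species`` and an optional
    ``common_name`` column), a second row whose first field is ``weight``
    giving the per-factor integer weights, then one row per species.

    Raises
    ------
    TraitTableError
        On an empty file, a missing weight row, a missing cell, a score
        outside {1, 2, 3}, or duplicate species, naming the offending
        row/column.
    """
    path = Path(path)
    with open(path, newline="", encoding="utf-8") as fh:
        rows = [row for row in csv.reader(fh) if any(cell.strip() for cell in row)]
    if not rows:
        raise TraitTableError(f"{path}: empty trait table")
    header = [c.strip() for c in rows[0]]
    if not header or header[0] != "species":
        raise TraitTableError(f"{path}: first header column must be 'species'")
    has_common = len(header) > 1 and header[1] == "common_name"
    first_factor = 2 if has_common else 1
    factor_ids = header[first_factor:]
    if not factor_ids:
        raise TraitTableError(f"{path}: no factor columns")
    if len(rows) < 2 or rows[1][0].strip().lower() != "weight":
        raise TraitTableError(f"{path}: second row must be the 'weight' row")

    def parse_int(cell: str, what: str) -> int:
        cell = cell.strip()
        if not cell:
            raise TraitTableError(f"{path}: missing {what}")
        try:
            return int(cell)
        except ValueError as exc:
            raise TraitTableError(f"{path}: non-integer {what}: {cell!r}") from exc

    weight_cells = rows[1][first_factor:]
    if len(weight_cells) != len(factor_ids):
        raise TraitTableError(f"{path}: weight row has {len(weight_cells)} entries "
                              f"for {len(factor_ids)} factors")
    weights = [parse_int(c, f"weight for factor {fid!r}")
               for c, fid in zip(weight_cells, factor_ids)]

    known = {f.factor_id: f for f in (*DEFAULT_FACTORS, THREAT_STATUS_FACTOR)}
    factors = []
    for fid, w in zip(factor_ids, weights):
        proto = known.get(fid)
        if proto is not None:
            factors.append(RiskFactor(fid, proto.label, w, proto.score_levels))
        else:
            factors.append(RiskFactor(fid, fid.replace("_", " ").capitalize(), w))

    species, common_names, score_rows = [], [], []
    for ridx, row in enumerate(rows[2:], start=3):
        cells = [c.strip() for c in row]
        if len(cells) != len(header):
            raise TraitTableError(
                f"{path} row {ridx}: expected {len(header)} cells, got {len(cells)}"
            )
        key = normalize_species_key(cells[0])
        if not key:
            raise TraitTableError(f"{path} row {ridx}: empty species identifier")
        species.append(key)
        common_names.append(cells[1] if has_common else key)
        score_rows.append(
            [parse_int(c, f"score (row {ridx}, factor {fid!r})")
             for c, fid in zip(cells[first_factor:], factor_ids)]
        )
    if not species:
        raise TraitTableError(f"{path}: no species rows")
    return TraitScoreTable(
        species=tuple(species),
        factors=tuple(factors),
        scores=np.array(score_rows, dtype=int),
        common_names=tuple(common_names),
    )


def packaged_trait_table() -> TraitScoreTable:
    """Load the packaged 35-species x 7-factor screening matrix fixture."""
    ref = resources.files("troutrisk.data").joinpath("nz_fish_traits.csv")
    with resources.as_file(ref) as path:
        return load_trait_table(path)


def write_trait_table(table: TraitScoreTable, path: str | Path) -> None:
    """Write a table in the same dialect :func:`load_trait_table` reads."""
    path = Path(path)
    with open(path, "w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(["species", "common_name", *table.factor_ids])
        writer.writerow(["weight", "", *[f.weight for f in table.factors]])
        names = table.common_names or table.species
        for key, name, row in zip(table.species, names, table.scores):
            writer.writerow([key, name, *row.tolist()])


def _check_weights(weights: Sequence[int] | np.ndarray, n_factors: int | None = None
                   ) -> np.ndarray:
    w = np.asarray(weights, dtype=int)
    if w.ndim != 1 or w.size == 0:
        raise TraitTableError("weight vector must be non-empty and 1-D")
    if (w < 1).any():
        raise TraitTableError(f"weights must be >= 1, got {w.tolist()}")
    if n_factors is not None and w.size != n_factors:
        raise TraitTableError(
            f"weight vector length {w.size} does not match {n_factors} factors"
        )
    return w


def compute_risk_scores(
    table: TraitScoreTable, weights: Sequence[int] | np.ndarray | None = None
) -> list[SpeciesRiskResult]:
    """Weighted total risk score per species.

    The total is the weighted sum of the species' factor scores; species order
    is preserved.  ``weights`` defaults to the table's own factor weights.
    """
    w = table.weights if weights is None else _check_weights(weights, table.n_factors)
    contribs = table.scores * w  # (n_species, n_factors)
    totals = contribs.sum(axis=1)
    return [
        SpeciesRiskResult(
            species=sp,
            contributions=dict(zip(table.factor_ids, row.tolist())),
            total=int(total),
        )
        for sp, row, total in zip(table.species, contribs, totals)
    ]


def scores_frame(
    table: TraitScoreTable, weights: Sequence[int] | np.ndarray | None = None
) -> pd.DataFrame:
    """Per-factor contributions and totals as a DataFrame indexed by species."""
    results = compute_risk_scores(table, weights)
    frame = pd.DataFrame(
        [dict(r.contributions, total=r.total) for r in results],
        index=[r.species for r in results],
    )
    frame.index.name = "species"
    return frame


def score_bounds(weights: Sequence[int] | np.ndarray) -> tuple[int, int]:
    """(min, max) achievable totals: all factors at 1 vs all at 3.

    With the default weights (1,1,1,2,1,2,2) this is (10, 30).
    """
    w = _check_weights(weights)
    return int(w.sum()), int(3 * w.sum())
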