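"""Synthetic trait tables and river-reach networks with planted structure.

The national distribution dataset behind the co-occurrence figures (random
forest predictions over a ~590,000-reach hydrological network averaging
roughly 0.7 km per reach) is external, so pipeline stages are exercised on
synthetic networks whose key quantities are planted and therefore known:

* reach lengths are lognormal with a configurable mean (default 0.7 km);
* each risk tier is planted on a disjoint random subset of reaches whose
  summed length is a set fraction of total network length (defaults follow
  the national picture: roughly 4% high, 15% moderate, 58% minor);
* trout are placed on a length-weighted fraction of each tier's extent
  (defaults near the national overlaps: 10%, 8.9%, 7.5%), so the pipeline's
  estimated overlap percentages can be checked against the planted truth;
* in probability mode occurrences become beta-distributed values whose
  medians straddle the presence threshold 0.5, emulating probabilistic
  occurrence predictions.

Planting is length-weighted (fractions of summed km, not reach counts)
because the quantities of interest are km totals.  Everything is seeded.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .reach_overlap import ReachTable
from .trait_matrix import (DEFAULT_FACTORS, DEFAULT_WEIGHTS, RiskFactor,
                           TraitScoreTable)

__all__ = ["NetworkSpec", "TraitTableSpec", "generate_reach_table",
           "generate_trait_table"]


def _default_species() -> dict[str, str]:
    return {
        "galaxias_synthetica_a": "High",
        "galaxias_synthetica_b": "High",
        "gobiomorphus_synthetica_a": "Moderate",
        "gobiomorphus_synthetica_b": "Moderate",
        "anguilla_synthetica_a": "Minor",
        "anguilla_synthetica_b": "Minor",
    }


@dataclass(frozen=True)
class NetworkSpec:
    """Recipe for a synthetic reach network with planted tier structure.

    Fractions are of summed river length.  ``species_tiers`` maps species
    key -> tier name; every tier named there needs an extent fraction.
    ``beta_concentration`` scales both beta distributions in probability
    mode (occupied ~ Beta(0.8c, 0.2c), unoccupied ~ Beta(0.2c, 0.8c)).
    """

    n_reaches: int = 10_000
    mean_length_km: float = 0.7
    length_sigma: float = 0.8
    species_tiers: Mapping[str, str] = field(default_factory=_default_species)
    extent_fraction: Mapping[str, float] = field(
        default_factory=lambda: {"High": 0.039, "Moderate": 0.145, "Minor": 0.584}
    )
    overlap_fraction: Mapping[str, float] = field(
        default_factory=lambda: {"High": 0.10, "Moderate": 0.089, "Minor": 0.075}
    )
    probability_mode: bool = False
    beta_concentration: float = 10.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_reaches < 1:
            raise ValueError("n_reaches must be >= 1")
        if self.mean_length_km <= 0:
            raise ValueError("mean_length_km must be positive")
        tiers = set(self.species_tiers.values())
        missing = tiers - set(self.extent_fraction)
        if missing:
            raise ValueError(f"tiers without extent_fraction: {sorted(missing)}")
        for name, frac in {**self.extent_fraction, **self.overlap_fraction}.items():
            if not 0.0 <= frac <= 1.0:
                raise ValueError(f"fraction for {name!r} outside [0, 1]: {frac}")
        used = {t: f for t, f in self.extent_fraction.items() if t in tiers}
        if sum(used.values()) > 1.0:
            raise ValueError(
                f"planted extent fractions sum to {sum(used.values()):.3f} > 1; "
                "tiers occupy disjoint reaches"
            )
        for tier, frac in self.overlap_fraction.items():
            if frac > 0 and self.extent_fraction.get(tier, 0.0) == 0 and tier in tiers:
                raise ValueError(
                    f"tier {tier!r}: cannot plant overlap on an empty extent"
                )


def _greedy_take(order: np.ndarray, lengths: np.ndarray,
                 target_km: float) -> np.ndarray:
    """First reaches of ``order`` whose cumulative length reaches target_km."""
    if target_km <= 0:
        return order[:0]
    cum = np.cumsum(lengths[order])
    n_take = int(np.searchsorted(cum, target_km, side="left")) + 1
    return order[: min(n_take, order.size)]


def generate_reach_table(spec: NetworkSpec) -> ReachTable:
    """Generate a reach table with the planted extents and trout overlaps.

    Tier extents are disjoint: a shuffled reach order is consumed greedily,
    tier by tier, until each tier's summed length reaches its planted
    fraction of the total.  Each extent reach hosts one randomly chosen
    species of its tier; trout are then planted on a greedy length-weighted
    subset of each tier's extent matching the tier's overlap fraction.
    Greedy cut-off error is at most one reach length.
    """
    rng = np.random.default_rng(spec.seed)
    mu = np.log(spec.mean_length_km) - spec.length_sigma**2 / 2.0
    lengths = rng.lognormal(mean=mu, sigma=spec.length_sigma, size=spec.n_reaches)
    total = float(lengths.sum())

    species = list(spec.species_tiers)
    occ = {sp: np.zeros(spec.n_reaches, dtype=bool) for sp in species}
    trout = np.zeros(spec.n_reaches, dtype=bool)

    tiers: list[str] = []
    for t in spec.species_tiers.values():
        if t not in tiers:
            tiers.append(t)

    order = rng.permutation(spec.n_reaches)
    cursor = 0
    for tier in tiers:
        members = [sp for sp, t in spec.species_tiers.items() if t == tier]
        target = spec.extent_fraction[tier] * total
        chosen = _greedy_take(order[cursor:], lengths, target)
        cursor += chosen.size
        if chosen.size:
            picks = rng.integers(0, len(members), size=chosen.size)
            for m, sp in enumerate(members):
                occ[sp][chosen[picks == m]] = True
        # trout on a length-weighted fraction of this tier's extent
        o_frac = spec.overlap_fraction.get(tier, 0.0)
        if chosen.size and o_frac > 0:
            sub = rng.permutation(chosen)
            trout[_greedy_take(sub, lengths, o_frac * float(lengths[chosen].sum()))] = True

    df = pd.DataFrame({
        "reach_id": [f"r{i:07d}" for i in range(spec.n_reaches)],
        "length_km": lengths,
    })
    if spec.probability_mode:
        c = spec.beta_concentration
        def probs(mask: np.ndarray) -> np.ndarray:
            out = rng.beta(0.2 * c, 0.8 * c, size=mask.size)
            out[mask] = rng.beta(0.8 * c, 0.2 * c, size=int(mask.sum()))
            return out
        df["trout"] = probs(trout)
        for sp in species:
            df[sp] = probs(occ[sp])
    else:
        df["trout"] = trout.astype(float)
        for sp in species:
            df[sp] = occ[sp].astype(float)
    return ReachTable(df)


@dataclass(frozen=True)
class TraitTableSpec:
    """Recipe for a random trait table: uniform scores in {1, 2, 3}."""

    n_species: int = 35
    n_factors: int = 7
    weights: Sequence[int] | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_species < 1:
            raise ValueError("n_species must be >= 1")
        if self.n_factors < 1:
            raise ValueError("n_factors must be >= 1")
        if self.weights is not None and len(self.weights) != self.n_factors:
            raise ValueError("weights length must equal n_factors")


def generate_trait_table(spec: TraitTableSpec) -> TraitScoreTable:
    """Random valid trait table; scores i.i.d. uniform on {1, 2, 3}."""
    rng = np.random.default_rng(spec.seed)
    if spec.weights is not None:
        weights = tuple(int(w) for w in spec.weights)
    elif spec.n_factors == len(DEFAULT_WEIGHTS):
        weights = DEFAULT_WEIGHTS
    else:
        weights = tuple([1] * spec.n_factors)
    if spec.n_factors == len(DEFAULT_FACTORS) and weights == DEFAULT_WEIGHTS:
        factors = DEFAULT_FACTORS
    else:
        factors = tuple(
            RiskFactor(f"factor_{i + 1}", f"Synthetic factor {i + 1}", w)
            for i, w in enumerate(weights)
        )
    scores = rng.integers(1, 4, size=(spec.n_species, spec.n_factors))
    species = tuple(f"species_{i + 1:04d}" for i in range(spec.n_species))
    return TraitScoreTable(species=species, factors=factors, scores=scores,
                           common_names=species)
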