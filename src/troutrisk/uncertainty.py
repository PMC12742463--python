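"""Monte Carlo perturbation of scores and weights.

Because both score allocation and factor weighting rest on expert judgement,
the per-species totals carry structural uncertainty.  Each Monte Carlo
iteration restarts from the pristine matrix, draws a fixed number of elements
(score cells and weight entries pooled together) without replacement, and
perturbs them: a visited score moves +/-1 with equal probability and is
clamped into {1, 2, 3}; a visited weight of 2 is redrawn uniformly from
{1, 2}; a visited weight of 1 is left unchanged (weight perturbation is
therefore downward-only).  Totals are recomputed per iteration and summarised
by per-species medians, quartiles, and the rank correlation between the
unperturbed totals and the medians.

Defaults follow the published procedure: 10,000 iterations, 30 elements per
iteration.  Each iteration draws from its own counter-derived substream of
the root seed, so results do not depend on execution order.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .trait_matrix import TraitScoreTable, _check_weights

__all__ = ["PerturbationConfig", "MCResult", "perturb_once", "run_monte_carlo",
           "summarize_mc"]


@dataclass(frozen=True)
class PerturbationConfig:
    """Settings for the score/weight perturbation simulation.

    n_iterations : number of Monte Carlo iterations (default 10,000).
    n_elements : elements altered per iteration, drawn without replacement
        from the pooled score cells and weight entries (default 30).
    seed : root seed for the pseudo-random stream.
    """

    n_iterations: int = 10_000
    n_elements: int = 30
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_iterations < 1:
            raise ValueError(f"n_iterations must be >= 1, got {self.n_iterations}")
        if self.n_elements < 0:
            raise ValueError(f"n_elements must be >= 0, got {self.n_elements}")


@dataclass(frozen=True)
class MCResult:
    """Iteration x species totals plus per-species summaries."""

    species: tuple[str, ...]
    score_matrix: np.ndarray  # (n_iterations, n_species) integer totals
    raw_totals: np.ndarray  # unperturbed totals, aligned to species
    config: PerturbationConfig
    medians: np.ndarray = field(init=False)
    lower_quartile: np.ndarray = field(init=False)
    upper_quartile: np.ndarray = field(init=False)

    def __post_init__(self) -> None:
        m = np.asarray(self.score_matrix)
        if m.ndim != 2 or m.shape[1] != len(self.species):
            raise ValueError("score_matrix shape does not match species")
        object.__setattr__(self, "medians", np.median(m, axis=0))
        object.__setattr__(self, "lower_quartile", np.percentile(m, 25, axis=0))
        object.__setattr__(self, "upper_quartile", np.percentile(m, 75, axis=0))

    @property
    def rank_stability(self) -> float:
        """Spearman rank correlation between raw totals and MC medians."""
        if np.ptp(self.medians) == 0 and np.ptp(self.raw_totals) == 0:
            return 1.0
        rho = stats.spearmanr(self.raw_totals, self.medians).statistic
        return float(rho)

    def to_long_frame(self) -> pd.DataFrame:
        """(iteration, species, total) long table of every simulated score."""
        n_iter, n_sp = self.score_matrix.shape
        return pd.DataFrame(
            {
                "iteration": np.repeat(np.arange(n_iter), n_sp),
                "species": np.tile(np.asarray(self.species, dtype=object), n_iter),
                "total": self.score_matrix.ravel(),
            }
        )


def _pool_size(table: TraitScoreTable, weights: np.ndarray) -> int:
    return table.scores.size + weights.size


def perturb_once(
    table: TraitScoreTable,
    weights,
    n_elements: int,
    rng: np.random.Generator,
) -> tuple[np.ndarray, np.ndarray]:
    """One perturbation draw starting from the pristine matrix and weights.

    Returns (perturbed score matrix, perturbed weight vector).  Exactly
    ``n_elements`` distinct elements of the pooled set are visited.
    """
    w = _check_weights(weights, table.n_factors)
    pool = _pool_size(table, w)
    if n_elements > pool:
        raise ValueError(
            f"n_elements={n_elements} exceeds pool of {pool} selectable elements"
        )
    scores = table.scores.copy()
    w = w.copy()
    if n_elements == 0:
        return scores, w
    chosen = rng.choice(pool, size=n_elements, replace=False)
    score_idx = chosen[chosen < scores.size]
    weight_idx = chosen[chosen >= scores.size] - scores.size
    if score_idx.size:
        steps = rng.choice([-1, 1], size=score_idx.size)
        flat = scores.ravel()
        flat[score_idx] = np.clip(flat[score_idx] + steps, 1, 3)
    if weight_idx.size:
        # only weights currently equal to 2 are reassigned, uniformly to 1 or 2
        draws = rng.integers(1, 3, size=weight_idx.size)
        mask = w[weight_idx] == 2
        w[weight_idx[mask]] = draws[mask]
    return scores, w


def run_monte_carlo(
    table: TraitScoreTable,
    weights=None,
    config: PerturbationConfig | None = None,
) -> MCResult:
    """Run the full perturbation simulation and collect per-iteration totals."""
    config = config or PerturbationConfig()
    w0 = table.weights if weights is None else _check_weights(weights, table.n_factors)
    pool = _pool_size(table, w0)
    if config.n_elements > pool:
        raise ValueError(
            f"n_elements={config.n_elements} exceeds pool of {pool} elements"
        )
    raw_totals = table.scores @ w0
    seeds = np.random.SeedSequence(config.seed).spawn(config.n_iterations)
    out = np.empty((config.n_iterations, table.n_species), dtype=int)
    for i, ss in enumerate(seeds):
        scores, w = perturb_once(table, w0, config.n_elements, np.random.default_rng(ss))
        out[i] = scores @ w
    return MCResult(species=table.species, score_matrix=out,
                    raw_totals=np.asarray(raw_totals, dtype=int), config=config)


def summarize_mc(result: MCResult, raw_totals=None) -> pd.DataFrame:
    """Per-species summary table ordered by descending median.

    Columns: raw_total, median, q1, q3, iqr.  Ties in median are broken by
    raw total (descending) then species id.  ``raw_totals`` may be a mapping
    or aligned vector; defaults to the totals stored in the result.
    """
    if raw_totals is None:
        raw = np.asarray(result.raw_totals, dtype=float)
    elif hasattr(raw_totals, "keys"):
        missing = set(result.species) ^ set(raw_totals.keys())
        if missing:
            raise ValueError(f"species mismatch between result and raw totals: "
                             f"{sorted(missing)}")
        raw = np.array([raw_totals[sp] for sp in result.species], dtype=float)
    else:
        raw = np.asarray(raw_totals, dtype=float)
        if raw.size != len(result.species):
            raise ValueError("raw_totals length does not match result species")
    frame = pd.DataFrame(
        {
            "species": list(result.species),
            "raw_total": raw,
            "median": result.medians,
            "q1": result.lower_quartile,
            "q3": result.upper_quartile,
        }
    )
    frame["iqr"] = frame["q3"] - frame["q1"]
    frame = frame.sort_values(
        ["median", "raw_total", "species"], ascending=[False, False, True]
    ).reset_index(drop=True)
    frame.attrs["rank_stability"] = result.rank_stability
    return frame
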