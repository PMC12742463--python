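"""End-to-end pipeline runner with a reproducibility manifest.

Ties the stages together: weighted scoring, Monte Carlo uncertainty,
natural-breaks classification, optional threat regression and reach-overlap
summary.  Stage outputs are written with stable filenames into a run
directory together with a manifest echoing the effective configuration, so
a rerun with the same config reproduces identical tabular outputs.
"""

from __future__ import annotations

import json
import logging
import sys
from dataclasses import asdict, dataclass, field
from pathlib import Path

import yaml

from . import __version__
from .model import TroutRiskModel
from .plotting import render_boxplot
from .threat_regression import encode_threat_status

__all__ = ["PipelineConfig", "run_pipeline"]

log = logging.getLogger("troutrisk")


@dataclass(frozen=True)
class PipelineConfig:
    """Effective settings of one pipeline run (echoed into the manifest)."""

    trait_table: str | None = None  # None -> packaged screening matrix
    status_table: str | None = None
    reach_table: str | None = None
    n_iterations: int = 10_000
    n_elements: int = 30
    k: int = 3
    tau: float = 0.5
    seed: int = 0
    out_dir: str = "troutrisk_run"
    boxplot: bool = True
    write_mc_long: bool = False

    @classmethod
    def from_yaml(cls, path: str | Path, **overrides) -> "PipelineConfig":
        with open(path, encoding="utf-8") as fh:
            data = yaml.safe_load(fh) or {}
        unknown = set(data) - set(cls.__dataclass_fields__)
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        data.update({k: v for k, v in overrides.items() if v is not None})
        return cls(**data)


def _stage(name: str):
    log.info("stage: %s", name)


def run_pipeline(config: PipelineConfig) -> Path:
    """Run every configured stage; returns the run directory."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    logging.basicConfig(stream=sys.stderr, level=logging.INFO,
                        format="%(levelname)s %(message)s")

    _stage("load")
    try:
        trait_path = config.trait_table or _packaged_path()
        model = TroutRiskModel.from_csv(
            trait_path, config.status_table, config.reach_table
        )
    except Exception as exc:
        raise RuntimeError(f"stage 'load' failed: {exc}") from exc

    _stage("fit")
    results = model.fit(
        n_iterations=config.n_iterations,
        n_elements=config.n_elements,
        seed=config.seed,
        k=config.k,
        tau=config.tau,
    )

    _stage("write")
    results.scores.to_csv(out / "scores.csv")
    summary = results.mc_summary
    summary.to_csv(out / "mc_summary.csv", index=False)
    if config.write_mc_long:
        results.mc_result.to_long_frame().to_csv(out / "mc_long.csv", index=False)

    cls = results.classification
    cls_frame = results.scores[["total"]].copy()
    cls_frame["tier"] = [cls.tiers[sp] for sp in cls_frame.index]
    cls_frame.to_csv(out / "classification.csv")
    with open(out / "breaks.json", "w", encoding="utf-8") as fh:
        json.dump(
            {"k": cls.break_set.k, "breaks": list(cls.break_set.breaks),
             "gvf": cls.break_set.gvf, "within_ssd": cls.break_set.within_ssd},
            fh, indent=2,
        )

    if results.regression is not None:
        r = results.regression
        with open(out / "regression.json", "w", encoding="utf-8") as fh:
            json.dump(
                {"slope": r.slope, "intercept": r.intercept,
                 "r_squared": r.r_squared,
                 "adjusted_r_squared": r.adjusted_r_squared,
                 "f_statistic": r.f_statistic, "df": list(r.df),
                 "p_value": r.p_value, "n": r.n},
                fh, indent=2,
            )

    if results.overlap is not None:
        results.overlap.to_frame().to_csv(out / "overlap_summary.csv")

    if config.boxplot:
        overlay = None
        if model.statuses:
            overlay = encode_threat_status(model.statuses, drop_unmapped=True)
        names = {sp: model.table.display_name(sp) for sp in model.table.species}
        render_boxplot(results.mc_result, out / "boxplot.png",
                       threat_ordinals=overlay, display_names=names)

    manifest = {
        "troutrisk_version": __version__,
        "config": asdict(config),
        "rank_stability": results.rank_stability,
        "tier_counts": cls.tier_counts,
    }
    with open(out / "manifest.yaml", "w", encoding="utf-8") as fh:
        yaml.safe_dump(manifest, fh, sort_keys=True)
    return out


def _packaged_path() -> Path:
    from importlib import resources

    ref = resources.files("troutrisk.data").joinpath("nz_fish_traits.csv")
    with resources.as_file(ref) as p:
        return Path(p)
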