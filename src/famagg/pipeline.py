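"""Config-driven orchestration: participants -> phenotypes -> familial
aggregation -> heritability, with a provenance manifest.

``run_pipeline`` executes the full analysis on a pedigree file and a
phenotype CSV: energy filtering, energy adjustment, optional food-group
aggregation, per-trait age adjustment and normalization, relative-pair
classification, familial correlations per pair class, and the heritability
fits (Gibbs MCMC and/or profile maximum likelihood) per trait.  Every
output is written under the run directory together with a machine-readable
manifest (settings, seed, row-count deltas, checksums).
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .correlation import correlation_report
from .heritability import (
    MCMCSettings,
    design_matrix,
    fit_gaussian_mcmc,
    fit_gaussian_ml,
)
from .pedigree import classify_pairs, kinship, read_pedigree
from .phenotypes import (
    PhenotypeTable,
    aggregate_groups,
    energy_adjust,
    filter_energy,
    prepare_trait,
    read_phenotypes,
)

__all__ = ["RunConfig", "run_pipeline", "describe"]

log = logging.getLogger("famagg")


@dataclass
class RunConfig:
    pedigree: str
    phenotypes: str
    out_dir: str
    traits: list[str]
    energy_lo: float = 800.0
    energy_hi: float = 4200.0
    food_groups: dict[str, list[str]] = field(default_factory=dict)
    exclude_if: list[str] = field(default_factory=list)  # boolean columns
    prep_method: str = "inverse_normal"
    age_adjust_per_sex: bool = False
    pair_classes: list[str] | None = None
    alpha: float = 0.05
    covariates: list[str] = field(default_factory=lambda: ["age", "sex"])
    mcmc: dict = field(default_factory=lambda: {"n_iter": 20_000, "n_burnin": 10_000, "thin": 10, "n_chains": 2})
    arm: str = "mcmc"  # mcmc | ml | both
    seed: int = 0

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        return cls(**raw)

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=True)


def describe(t: PhenotypeTable) -> pd.DataFrame:
    """Per-sex descriptive table: mean and SD for numeric columns, percent
    for non-numeric (categorical) columns."""
    rows = []
    sexes = list(t.data["sex"].unique())
    for col in t.data.columns:
        if col == "sex":
            continue
        row: dict[str, object] = {"variable": col}
        for s in sexes:
            sub = t.data.loc[t.data["sex"] == s, col]
            if pd.api.types.is_numeric_dtype(sub):
                row[f"{s}_mean"] = float(sub.mean())
                row[f"{s}_sd"] = float(sub.std(ddof=1)) if len(sub) > 1 else 0.0
            else:
                top = sub.mode()
                level = top.iloc[0] if len(top) else ""
                row[f"{s}_percent_{level}"] = 100.0 * float((sub == level).mean())
        rows.append(row)
    return pd.DataFrame(rows)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def run_pipeline(cfg: RunConfig) -> Path:
    """Run the end-to-end analysis; returns the run directory."""
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    flow: list[dict] = []

    ped = read_pedigree(cfg.pedigree)
    table = read_phenotypes(cfg.phenotypes)
    flow.append({"stage": "load", "rows": len(table)})
    log.info("loaded %d individuals (%d in pedigree)", len(table), len(ped))

    for col in cfg.exclude_if:
        before = len(table)
        keep = ~table.data[col].astype(bool)
        table = PhenotypeTable(table.data.loc[keep].copy(), table.traits, table.state)
        flow.append({"stage": f"exclude_{col}", "rows": len(table), "dropped": before - len(table)})

    table, report = filter_energy(table, cfg.energy_lo, cfg.energy_hi)
    report.to_csv(out / "exclusion_report.csv", index=False)
    flow.append({"stage": "filter_energy", "rows": len(table), "dropped": len(report)})
    log.info("energy filter dropped %d rows, %d remain", len(report), len(table))

    table = energy_adjust(table)
    if cfg.food_groups:
        table = aggregate_groups(table, cfg.food_groups)
    describe(table).to_csv(out / "descriptives.csv", index=False)

    for trait in cfg.traits:
        table = prepare_trait(
            table, trait, method=cfg.prep_method, per_sex=cfg.age_adjust_per_sex
        )
    flow.append({"stage": "prepare", "rows": len(table)})

    pairs = classify_pairs(ped)
    corr = correlation_report(
        table, pairs, cfg.traits, alpha=cfg.alpha, classes=cfg.pair_classes
    )
    corr.to_csv(out / "correlations.csv", index=False, float_format="%.10g")

    km = kinship(ped)
    pheno_ids = [i for i in km.ids if i in table.data.index]
    sub = table.data.loc[pheno_ids]
    complete = sub[cfg.covariates].notna().all(axis=1)
    if (~complete).any():
        log.info("dropping %d rows with missing covariates", int((~complete).sum()))
    sub = sub.loc[complete]
    pheno_ids = list(sub.index)
    a_matrix = km.subset(pheno_ids).relationship()
    x, names = design_matrix(sub, cfg.covariates)

    settings = MCMCSettings(**{**cfg.mcmc, "seed": cfg.seed})
    heritability_files = []
    for trait in cfg.traits:
        y = sub[trait].to_numpy(dtype=float)
        summary: dict = {"trait": trait, "n": len(y), "fixed_effects": names}
        if cfg.arm in ("mcmc", "both"):
            fit = fit_gaussian_mcmc(y, x, a_matrix, settings)
            summary.update(fit.summary())
        if cfg.arm in ("ml", "both"):
            ml = fit_gaussian_ml(y, x, a_matrix)
            summary["ml"] = {
                "sigma_g2": ml.sigma_g2,
                "sigma_e2": ml.sigma_e2,
                "h2": ml.h2,
                "loglik": ml.loglik,
                "lrt_stat": ml.lrt_stat,
                "lrt_p": ml.lrt_p,
                "flags": list(ml.flags),
            }
        path = out / f"heritability_{trait}.json"
        path.write_text(json.dumps(summary, indent=2, default=float))
        heritability_files.append(path.name)
        log.info("heritability fit written for %s", trait)

    outputs = [
        "exclusion_report.csv",
        "descriptives.csv",
        "correlations.csv",
        *heritability_files,
    ]
    manifest = {
        "famagg_version": __version__,
        "numpy_version": np.__version__,
        "seed": cfg.seed,
        "config": asdict(cfg),
        "participant_flow": flow,
        "outputs": {name: _sha256(out / name) for name in outputs},
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, default=float))
    return out
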