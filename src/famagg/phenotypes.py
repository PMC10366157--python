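"""Phenotype preparation: energy filtering, energy adjustment, food-group
aggregation, age adjustment and normalization.

The preparation chain mirrors standard food-frequency-questionnaire practice:
implausible energy reporters are excluded (outside 800-4200 kcal/d, strict
inequalities), servings are expressed per 1000 kcal of energy intake, food
groups are row-wise sums of their member items, and each analysis trait is
residualized on age and normalized (rank-based inverse-normal with the Blom
offset by default; Box-Cox followed by z-scoring as the alternative).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "PhenotypeTable",
    "PhenotypeError",
    "DegenerateTraitError",
    "read_phenotypes",
    "filter_energy",
    "energy_adjust",
    "aggregate_groups",
    "prepare_trait",
    "inverse_normal_transform",
    "boxcox_fit",
    "age_residual",
]

ENERGY_LO = 800.0
ENERGY_HI = 4200.0


class PhenotypeError(Exception):
    pass


class DegenerateTraitError(PhenotypeError):
    """Trait has no usable variation after adjustment."""


@dataclass
class PhenotypeTable:
    """Per-individual covariates plus named trait columns.

    ``data`` is indexed by individual_id; ``state`` tracks the preparation
    stage: raw -> energy_adjusted -> prepared.
    """

    data: pd.DataFrame
    traits: list[str]
    state: str = "raw"

    def __post_init__(self) -> None:
        if self.data.index.has_duplicates:
            dups = self.data.index[self.data.index.duplicated()].tolist()
            raise PhenotypeError(f"duplicate individual ids: {dups[:5]}")
        missing = [t for t in self.traits if t not in self.data.columns]
        if missing:
            raise PhenotypeError(f"trait columns not in table: {missing}")

    def __len__(self) -> int:
        return len(self.data)

    def copy(self) -> "PhenotypeTable":
        return PhenotypeTable(self.data.copy(), list(self.traits), self.state)


def read_phenotypes(path: str | Path, traits: Sequence[str] | None = None) -> PhenotypeTable:
    """Read a phenotype CSV with header; index column ``individual_id``.

    If ``traits`` is None, every numeric column other than the covariates
    (age, sex, energy, family_id) is taken as a trait.
    """
    df = pd.read_csv(path, dtype={"individual_id": str})
    if "individual_id" not in df.columns:
        raise PhenotypeError("phenotype CSV must have an 'individual_id' column")
    df = df.set_index("individual_id")
    if traits is None:
        reserved = {"age", "sex", "energy", "family_id"}
        traits = [
            c
            for c in df.columns
            if c not in reserved and pd.api.types.is_numeric_dtype(df[c])
        ]
    return PhenotypeTable(df, list(traits))


def filter_energy(
    t: PhenotypeTable, lo: float = ENERGY_LO, hi: float = ENERGY_HI
) -> tuple[PhenotypeTable, pd.DataFrame]:
    """Drop energy mis-reporters: rows with energy < lo or > hi (boundary
    values retained).  Returns the filtered table and an exclusion report
    with one row per excluded individual (id, reason, energy)."""
    if t.state != "raw":
        raise PhenotypeError(f"filter_energy expects a raw table, got {t.state}")
    if not lo < hi:
        raise ValueError(f"need lo < hi, got {lo} >= {hi}")
    energy = pd.to_numeric(t.data["energy"], errors="coerce")
    invalid = energy.isna() | (energy <= 0)
    low = ~invalid & (energy < lo)
    high = ~invalid & (energy > hi)
    reason = pd.Series("retained", index=t.data.index)
    reason[low] = "low_energy"
    reason[high] = "high_energy"
    reason[invalid] = "invalid_energy"
    excluded = reason != "retained"
    report = pd.DataFrame(
        {
            "individual_id": t.data.index[excluded],
            "reason": reason[excluded].to_numpy(),
            "energy": energy[excluded].to_numpy(),
        }
    )
    kept = PhenotypeTable(t.data.loc[~excluded].copy(), list(t.traits), "raw")
    return kept, report


def energy_adjust(t: PhenotypeTable) -> PhenotypeTable:
    """Express every trait as servings per 1000 kcal: x / (energy/1000)."""
    if t.state != "raw":
        raise PhenotypeError(f"energy_adjust expects a raw table, got {t.state}")
    energy = pd.to_numeric(t.data["energy"], errors="coerce")
    if (energy.isna() | (energy <= 0)).any():
        raise PhenotypeError(
            "non-positive or missing energy present; run filter_energy first"
        )
    out = t.data.copy()
    out[t.traits] = out[t.traits].div(energy / 1000.0, axis=0)
    return PhenotypeTable(out, list(t.traits), "energy_adjusted")


def aggregate_groups(
    t: PhenotypeTable, groups: Mapping[str, Sequence[str]]
) -> PhenotypeTable:
    """Add food-group columns as row-wise sums of member items.

    Groups may overlap (e.g. total meat contains red meat).  An empty member
    list yields a column of zeros; unknown items raise."""
    out = t.data.copy()
    new_traits = list(t.traits)
    for name, items in groups.items():
        unknown = [i for i in items if i not in out.columns]
        if unknown:
            raise PhenotypeError(f"group {name!r} references unknown items {unknown}")
        out[name] = out[list(items)].sum(axis=1) if items else 0.0
        if name not in new_traits:
            new_traits.append(name)
    return PhenotypeTable(out, new_traits, t.state)


def inverse_normal_transform(x: np.ndarray) -> np.ndarray:
    """Rank-based inverse-normal transform with the Blom offset.

    Ranks (average rank on ties) are mapped through the standard-normal
    quantile function at (r - 3/8)/(n + 1/4), then the scores are z-scored
    so the output has sample mean 0 and variance 1 exactly.
    """
    x = np.asarray(x, dtype=float)
    n = len(x)
    r = stats.rankdata(x, method="average")
    q = stats.norm.ppf((r - 0.375) / (n + 0.25))
    return (q - q.mean()) / q.std(ddof=0)


def boxcox_fit(x: np.ndarray) -> tuple[np.ndarray, float]:
    """Box-Cox transform with lambda by profile maximum likelihood.

    Values are shifted positive first if needed (minimum moved to
    1e-3 * sd above zero).  Returns (transformed values, fitted lambda).
    """
    x = np.asarray(x, dtype=float)
    scale = np.std(x, ddof=0)
    if x.min() <= 0:
        x = x - x.min() + 1e-3 * scale
    bc, lam = stats.boxcox(x)
    return bc, float(lam)


def age_residual(x: np.ndarray, age: np.ndarray) -> np.ndarray:
    """Residual of a simple linear regression on age, keeping the trait's
    location (age is centered, so the fitted intercept is the mean)."""
    age_c = age - age.mean()
    denom = float(age_c @ age_c)
    slope = float(age_c @ x) / denom if denom > 0 else 0.0
    return x - slope * age_c


def prepare_trait(
    t: PhenotypeTable,
    trait: str,
    method: str = "inverse_normal",
    age_col: str = "age",
    per_sex: bool = False,
) -> PhenotypeTable:
    """Age-adjust then normalize one trait; marks the table ``prepared``.

    Age adjustment regresses the trait on age (simple linear fit, pooled
    across sexes unless ``per_sex``) and keeps the residuals.  Normalization
    is either the rank-based inverse-normal transform or Box-Cox (lambda by
    maximum likelihood, values shifted positive if needed) followed by
    z-scoring.
    """
    if t.state not in {"energy_adjusted", "prepared"}:
        raise PhenotypeError(
            f"prepare_trait expects an energy_adjusted table, got {t.state}"
        )
    if method not in {"inverse_normal", "boxcox_then_zscore"}:
        raise ValueError(f"unknown method {method!r}")
    if len(t) < 3:
        raise PhenotypeError(f"need at least 3 rows to prepare a trait, got {len(t)}")
    out = t.data.copy()
    x = pd.to_numeric(out[trait], errors="coerce").to_numpy(dtype=float)
    age = pd.to_numeric(out[age_col], errors="coerce").to_numpy(dtype=float)
    if np.isnan(x).any() or np.isnan(age).any():
        raise PhenotypeError(f"missing values in {trait!r} or {age_col!r}")

    if per_sex:
        resid = np.empty_like(x)
        for s in out["sex"].unique():
            mask = (out["sex"] == s).to_numpy()
            resid[mask] = age_residual(x[mask], age[mask])
    else:
        resid = age_residual(x, age)

    scale = np.std(resid, ddof=0)
    if scale < 1e-12 * (1.0 + abs(np.mean(resid))):
        raise DegenerateTraitError(
            f"trait {trait!r} has no variation after age adjustment"
        )

    if method == "inverse_normal":
        out[trait] = inverse_normal_transform(resid)
    else:
        bc, _lam = boxcox_fit(resid)
        out[trait] = (bc - bc.mean()) / bc.std(ddof=0)
    return PhenotypeTable(out, list(t.traits), "prepared")
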