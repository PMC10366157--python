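"""Familial-aggregation correlations (ICCs) for relative-pair classes.

Role-distinguishable classes (parent-offspring by sex, brother-sister,
spouse, grandparent, avuncular) use the interclass estimator: the
product-moment correlation over ordered pairs, role A against role B.
Exchangeable classes (sister-sister, brother-brother, half-sibling, cousin)
use the intraclass estimator via double entry: each pair contributes both
orderings, with a common mean and variance.  Standard errors come from a
leave-one-family-out jackknife, because pairs within a family are not
independent; p-values are two-sided normal on icc/se.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .pedigree import PAIR_CLASSES, RelativePair
from .phenotypes import PhenotypeTable

__all__ = [
    "EXCHANGEABLE_CLASSES",
    "CorrelationEstimate",
    "interclass_correlation",
    "intraclass_double_entry",
    "pair_correlation",
    "correlation_report",
]

#: classes whose members have no natural role ordering
EXCHANGEABLE_CLASSES = frozenset(
    {"sister-sister", "brother-brother", "half-sibling", "cousin"}
)


@dataclass
class CorrelationEstimate:
    trait: str
    pair_class: str
    icc: float
    se: float
    n_pairs: int
    p_value: float
    significant: bool
    ci_low: float
    ci_high: float
    reason: str | None = None  # set when the estimate is suppressed

    @property
    def suppressed(self) -> bool:
        return self.reason is not None


def interclass_correlation(xa: np.ndarray, xb: np.ndarray) -> float:
    """Product-moment correlation over ordered pairs (role A, role B)."""
    return float(np.corrcoef(xa, xb)[0, 1])


def intraclass_double_entry(xa: np.ndarray, xb: np.ndarray) -> float:
    """Intraclass correlation by double entry: each pair is entered in both
    orderings and a single product-moment correlation (common mean and
    variance) is computed over the 2n entries."""
    first = np.concatenate([xa, xb])
    second = np.concatenate([xb, xa])
    return float(np.corrcoef(first, second)[0, 1])


def _estimator(cls: str):
    return intraclass_double_entry if cls in EXCHANGEABLE_CLASSES else interclass_correlation


def _suppressed(trait: str, cls: str, n: int, reason: str) -> CorrelationEstimate:
    nan = float("nan")
    return CorrelationEstimate(trait, cls, nan, nan, n, nan, False, nan, nan, reason)


def pair_correlation(
    t: PhenotypeTable,
    pairs: Iterable[RelativePair],
    trait: str,
    cls: str,
    alpha: float = 0.05,
) -> CorrelationEstimate:
    """Familial correlation for one trait and one pair class.

    Uses every pair of the class whose two members are both phenotyped; an
    individual appearing in many pairs is retained in all of them.  Requires
    at least 3 usable pairs spanning at least 2 families; otherwise the
    estimate is suppressed with a reason.
    """
    if t.state != "prepared":
        raise ValueError(f"pair_correlation expects a prepared table, got {t.state}")
    values = t.data[trait]
    xa_l: list[float] = []
    xb_l: list[float] = []
    fam_l: list[str] = []
    for p in pairs:
        if p.pair_class != cls:
            continue
        if p.id_a not in values.index or p.id_b not in values.index:
            continue
        va, vb = values.loc[p.id_a], values.loc[p.id_b]
        if pd.isna(va) or pd.isna(vb):
            continue
        xa_l.append(float(va))
        xb_l.append(float(vb))
        fam_l.append(p.family_id)

    n = len(xa_l)
    if n < 3:
        return _suppressed(trait, cls, n, "too_few_pairs")
    xa = np.array(xa_l)
    xb = np.array(xb_l)
    fams = np.array(fam_l)
    est = _estimator(cls)
    if cls in EXCHANGEABLE_CLASSES:
        degenerate = np.std(np.concatenate([xa, xb])) == 0
    else:
        degenerate = np.std(xa) == 0 or np.std(xb) == 0
    if degenerate:
        return _suppressed(trait, cls, n, "zero_variance")
    icc = est(xa, xb)

    uniq = np.unique(fams)
    if len(uniq) < 2:
        return _suppressed(trait, cls, n, "too_few_families")
    loo = []
    for f in uniq:
        keep = fams != f
        a, b = xa[keep], xb[keep]
        if len(a) < 2:
            continue
        with np.errstate(invalid="ignore"):
            v = est(a, b)
        if np.isfinite(v):
            loo.append(v)
    loo = np.asarray(loo)
    g = len(loo)
    if g < 2:
        return _suppressed(trait, cls, n, "too_few_families")
    se = float(np.sqrt((g - 1) / g * np.sum((loo - loo.mean()) ** 2)))
    if se == 0.0:
        # identical leave-one-out estimates (e.g. perfectly correlated data)
        p_value = 0.0 if icc != 0 else 1.0
        se = float(se)
    else:
        p_value = float(2.0 * stats.norm.sf(abs(icc) / se))
    ci_low = icc - 1.96 * se
    ci_high = icc + 1.96 * se
    return CorrelationEstimate(
        trait, cls, float(icc), se, n, p_value, p_value < alpha, ci_low, ci_high
    )


def correlation_report(
    t: PhenotypeTable,
    pairs: Sequence[RelativePair],
    traits: Sequence[str],
    alpha: float = 0.05,
    classes: Sequence[str] | None = None,
    significant_only: bool = False,
) -> pd.DataFrame:
    """All trait x pair-class correlation estimates as a tidy table.

    One row per combination, with the 95% CI (icc +/- 1.96 se).  By default
    non-significant rows are flagged, not dropped; ``significant_only``
    reproduces a report-significant-only convention.
    """
    classes = list(classes) if classes is not None else list(PAIR_CLASSES)
    rows = []
    for trait in traits:
        for cls in classes:
            e = pair_correlation(t, pairs, trait, cls, alpha=alpha)
            rows.append(
                {
                    "trait": e.trait,
                    "pair_class": e.pair_class,
                    "n_pairs": e.n_pairs,
                    "icc": e.icc,
                    "se": e.se,
                    "ci_low": e.ci_low,
                    "ci_high": e.ci_high,
                    "p_value": e.p_value,
                    "significant": e.significant,
                    "reason": e.reason or "",
                }
            )
    df = pd.DataFrame(rows)
    if significant_only:
        df = df[df["significant"]].reset_index(drop=True)
    return df
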