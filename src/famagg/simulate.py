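"""Synthetic multi-generation family data with known generative parameters.

The generator emulates the pedigree envelope of an Iranian family cohort:
families of roughly 3-32 members (a mix of singletons, nuclear families and
three-generation extensions), sibship sizes 1-6 with mean about 1.6, and
FFQ-like phenotypes — a latent Gaussian trait composed of additive genetic,
couple-shared-environment and residual variance, back-transformed to
positive serving counts, plus reported energy intakes of which a configured
fraction falls outside the 800-4200 kcal/d plausibility window.

Every stage of the analysis pipeline can be tested against the generative
truth: for a pair with kinship phi the latent-trait covariance is
2*phi*sigma_g^2 (plus the couple term within spouse pairs), and an
end-to-end run should recover h2_true when the couple component is off.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .pedigree import Individual, Pedigree, kinship
from .phenotypes import PhenotypeTable

__all__ = ["SimulationConfig", "simulate_pedigrees", "simulate_phenotypes"]


@dataclass
class SimulationConfig:
    """Generative parameters; defaults emulate the cohort envelope.

    Variances are proportions of a unit phenotypic variance:
    h2_true + c2_couple <= 1, residual gets the remainder.
    """

    n_families: int = 4338
    generations: int = 3
    sibship_dist: tuple[float, ...] = (0.60, 0.25, 0.08, 0.04, 0.02, 0.01)
    singleton_rate: float = 0.28
    extension_prob: float = 0.15  # per-child chance of marrying and having kids
    h2_true: float = 0.25
    c2_couple: float = 0.20
    spousal_r: float = 0.25
    age_effect: float = 0.01  # latent-trait units per year
    sex_effect: float = 0.20  # male minus female mean shift
    energy_mean: float = 2200.0
    energy_sd: float = 500.0
    misreport_rate: float = 0.064  # fraction outside the 800-4200 window
    n_traits: int = 1
    trait_prefix: str = "intake"
    serving_scale: float = 0.5  # servings/1000kcal = exp(serving_scale * latent)
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.h2_true + self.c2_couple <= 1.0:
            raise ValueError("need h2_true + c2_couple in [0, 1]")
        if not np.isclose(sum(self.sibship_dist), 1.0):
            raise ValueError("sibship_dist must sum to 1")
        if not 0.0 <= self.spousal_r < 1.0:
            raise ValueError("spousal_r must be in [0, 1)")
        if self.generations not in (2, 3):
            raise ValueError("generations must be 2 or 3")

    @property
    def trait_names(self) -> list[str]:
        if self.n_traits == 1:
            return [self.trait_prefix]
        return [f"{self.trait_prefix}_{k + 1}" for k in range(self.n_traits)]


def _draw_sibship(rng: np.random.Generator, dist: Sequence[float]) -> int:
    return int(rng.choice(np.arange(1, len(dist) + 1), p=np.asarray(dist)))


def simulate_pedigrees(cfg: SimulationConfig) -> Pedigree:
    """Simulate pedigrees: founder couples, sibships, optional marrying-in
    third generation, and a configured share of singletons."""
    rng = np.random.default_rng(cfg.seed)
    inds: list[Individual] = []
    for f in range(cfg.n_families):
        fid = f"F{f:05d}"
        if rng.random() < cfg.singleton_rate:
            sex = "male" if rng.random() < 0.5 else "female"
            inds.append(Individual(f"{fid}_S0", fid, None, None, sex))
            continue
        dad, mom = f"{fid}_P1", f"{fid}_P2"
        inds.append(Individual(dad, fid, None, None, "male"))
        inds.append(Individual(mom, fid, None, None, "female"))
        n_child = _draw_sibship(rng, cfg.sibship_dist)
        child_ids = []
        for c in range(n_child):
            cid = f"{fid}_C{c + 1}"
            sex = "male" if rng.random() < 0.5 else "female"
            inds.append(Individual(cid, fid, dad, mom, sex))
            child_ids.append((cid, sex))
        if cfg.generations == 3:
            # each child may marry in a new founder and have a sibship of
            # their own; two extended children give the pedigree cousins
            for c, (cid, csex) in enumerate(child_ids):
                if rng.random() >= cfg.extension_prob:
                    continue
                spouse = f"{fid}_M{c + 1}"
                ssex = "female" if csex == "male" else "male"
                inds.append(Individual(spouse, fid, None, None, ssex))
                father, mother = (cid, spouse) if csex == "male" else (spouse, cid)
                for g in range(_draw_sibship(rng, cfg.sibship_dist)):
                    gid = f"{fid}_G{c + 1}_{g + 1}"
                    sex = "male" if rng.random() < 0.5 else "female"
                    inds.append(Individual(gid, fid, father, mother, sex))
    return Pedigree(inds)


def _couples(ped: Pedigree, members: Sequence[str]) -> list[tuple[str, str]]:
    seen = set()
    out = []
    for i in members:
        f, m = ped.parents(i)
        if f is not None and m is not None and (f, m) not in seen:
            seen.add((f, m))
            out.append((f, m))
    return out


def _ages(ped: Pedigree, rng: np.random.Generator) -> pd.Series:
    """Generation-dependent adult ages (years)."""
    mean_by_gen = {0: 52.0, 1: 27.0, 2: 20.0}
    sd_by_gen = {0: 9.0, 1: 5.0, 2: 2.0}
    ages = {}
    for i in ped.ids:
        g = min(ped.generation[i], 2)
        ages[i] = float(np.clip(rng.normal(mean_by_gen[g], sd_by_gen[g]), 18.0, 90.0))
    return pd.Series(ages)


def simulate_phenotypes(
    ped: Pedigree, cfg: SimulationConfig
) -> tuple[PhenotypeTable, dict]:
    """Simulate raw phenotypes on a pedigree.

    Each trait's latent value is

        latent = age_effect*(age - mean age) + sex_effect*1[male] + g + c + e

    with g ~ N(0, sigma_g^2 A) drawn family-by-family through the Cholesky
    factor of the within-family relationship matrix, c a couple-shared
    effect (spouses share one draw; nobody inherits it), and e residual;
    founder-couple residuals are drawn jointly with correlation spousal_r (a
    Gaussian copula on the residual ranks).  Reported servings/day are
    exp(serving_scale * latent) * energy/1000, so the per-1000 kcal intake
    is a monotone positive transform of the latent trait.  Energy is
    plausible (inside 800-4200 kcal/d) except for a misreport_rate fraction
    pushed outside the window.

    Returns the raw PhenotypeTable and a truth dict holding the generative
    parameters and the latent traits.
    """
    rng = np.random.default_rng(cfg.seed + 1)
    ids = list(ped.ids)
    index = {iid: k for k, iid in enumerate(ids)}
    n = len(ids)

    sigma_g2 = cfg.h2_true
    sigma_c2 = cfg.c2_couple
    sigma_e2 = 1.0 - sigma_g2 - sigma_c2

    ages = _ages(ped, rng)
    sexes = pd.Series({i: ped.individuals[i].sex for i in ids})
    male = (sexes == "male").astype(float)

    latents = np.zeros((n, cfg.n_traits))
    for fid, members in ped.families.items():
        sub = ped.subset(fid)
        order = sub.ids
        rows = np.array([index[i] for i in order])
        a_fam = kinship(sub).relationship(jitter=1e-10)
        chol = np.linalg.cholesky(a_fam)
        couples = _couples(ped, order)
        couple_rows = {}
        for ci, (f, m) in enumerate(couples):
            couple_rows[index[f]] = ci
            couple_rows[index[m]] = ci
        for t in range(cfg.n_traits):
            g = np.sqrt(sigma_g2) * (chol @ rng.standard_normal(len(order)))
            c = np.zeros(len(order))
            if sigma_c2 > 0 and couples:
                cdraw = rng.normal(0.0, np.sqrt(sigma_c2), size=len(couples))
                for k, row in enumerate(rows):
                    if row in couple_rows:
                        c[k] = cdraw[couple_rows[row]]
            e = rng.normal(0.0, np.sqrt(sigma_e2), size=len(order))
            if cfg.spousal_r > 0 and sigma_e2 > 0:
                # correlate residuals within each couple (Gaussian copula)
                for ci, (f, m) in enumerate(couples):
                    kf = order.index(f)
                    km = order.index(m)
                    z1, z2 = rng.standard_normal(2)
                    e[kf] = np.sqrt(sigma_e2) * z1
                    e[km] = np.sqrt(sigma_e2) * (
                        cfg.spousal_r * z1 + np.sqrt(1 - cfg.spousal_r**2) * z2
                    )
            latents[rows, t] += g + c + e

    age_arr = ages.loc[ids].to_numpy()
    latents += (
        cfg.age_effect * (age_arr - age_arr.mean())[:, None]
        + cfg.sex_effect * male.loc[ids].to_numpy()[:, None]
    )

    # energy: plausible inside the window, misreports pushed outside it
    misreport = rng.random(n) < cfg.misreport_rate
    energy = np.clip(
        rng.normal(cfg.energy_mean, cfg.energy_sd, size=n), 810.0, 4190.0
    )
    low_side = rng.random(n) < 0.5
    energy[misreport & low_side] = rng.uniform(300.0, 795.0, size=int((misreport & low_side).sum()))
    energy[misreport & ~low_side] = rng.uniform(4205.0, 5200.0, size=int((misreport & ~low_side).sum()))

    data = pd.DataFrame(
        {
            "family_id": [ped.individuals[i].family_id for i in ids],
            "age": age_arr,
            "sex": sexes.loc[ids].to_numpy(),
            "energy": energy,
        },
        index=pd.Index(ids, name="individual_id"),
    )
    names = cfg.trait_names
    for t, name in enumerate(names):
        data[name] = np.exp(cfg.serving_scale * latents[:, t]) * energy / 1000.0

    truth = {
        "config": asdict(cfg),
        "sigma_g2": sigma_g2,
        "sigma_c2": sigma_c2,
        "sigma_e2": sigma_e2,
        "latent": pd.DataFrame(latents, index=data.index, columns=names),
    }
    return PhenotypeTable(data, names, "raw"), truth
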