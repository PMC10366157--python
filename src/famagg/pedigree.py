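"""Pedigree parsing, relative-pair classification, and kinship matrices.

A pedigree is a directed acyclic graph of individuals with parent links and
sex.  From it this module derives the two objects every downstream analysis
needs: the taxonomy of relative pairs (parent-offspring, siblings by sex,
spouses, grandparents, avuncular, half-siblings, cousins) and the kinship
matrix ``phi`` computed by the classical recursive tabular method, whose
doubled form ``A = 2*phi`` is the covariance structure of additive genetic
effects.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

import networkx as nx
import numpy as np
import pandas as pd

__all__ = [
    "Individual",
    "Pedigree",
    "RelativePair",
    "KinshipMatrix",
    "PedigreeError",
    "CycleError",
    "ValidationError",
    "read_pedigree",
    "classify_pairs",
    "kinship",
    "PAIR_CLASSES",
    "FIRST_DEGREE",
    "SECOND_DEGREE",
]

MISSING_PARENT = {"0", "", "na", "nan", "none", ".", "-9"}

#: canonical pair-class labels, in reporting order
PAIR_CLASSES = (
    "father-son",
    "father-daughter",
    "mother-son",
    "mother-daughter",
    "sister-sister",
    "brother-brother",
    "brother-sister",
    "spouse",
    "grandparent",
    "avuncular",
    "half-sibling",
    "cousin",
)

FIRST_DEGREE = frozenset(
    {
        "father-son",
        "father-daughter",
        "mother-son",
        "mother-daughter",
        "sister-sister",
        "brother-brother",
        "brother-sister",
    }
)
SECOND_DEGREE = frozenset({"grandparent", "avuncular", "half-sibling", "cousin"})


class PedigreeError(Exception):
    """Base class for pedigree structural problems."""


class CycleError(PedigreeError):
    """Parent links form a cycle (an individual is its own ancestor)."""


class ValidationError(PedigreeError):
    """Row-level inconsistency: duplicate ids, sex-inconsistent parents."""


@dataclass(frozen=True)
class Individual:
    individual_id: str
    family_id: str
    father_id: str | None
    mother_id: str | None
    sex: str  # "male" | "female" | "unknown"


@dataclass(frozen=True)
class RelativePair:
    """An unordered relative pair with a unique class label.

    For role-distinguishable classes ``id_a`` carries the canonical first
    role: the parent, the grandparent, the aunt/uncle, the brother in a
    brother-sister pair, the male spouse.  Exchangeable classes order ids
    lexicographically.
    """

    id_a: str
    id_b: str
    pair_class: str
    degree: str  # "first" | "second" | "spousal"
    family_id: str


def _parse_sex(token: object) -> str:
    s = str(token).strip().lower()
    if s in {"1", "m", "male"}:
        return "male"
    if s in {"2", "f", "female"}:
        return "female"
    return "unknown"


class Pedigree:
    """Validated family graph with generation indices (founders = 0)."""

    def __init__(self, individuals: Iterable[Individual]):
        self.individuals: dict[str, Individual] = {}
        for ind in individuals:
            if ind.individual_id in self.individuals:
                raise ValidationError(
                    f"duplicate individual id {ind.individual_id!r}"
                )
            self.individuals[ind.individual_id] = ind
        self._materialize_missing_parents()
        self._validate_parent_sex()
        self.generation = self._generations()
        # canonical order: generation, then id — makes every derived object
        # independent of input row order
        self.ids: list[str] = sorted(
            self.individuals, key=lambda i: (self.generation[i], i)
        )
        self._children: dict[str, set[str]] = {i: set() for i in self.individuals}
        for ind in self.individuals.values():
            for p in (ind.father_id, ind.mother_id):
                if p is not None:
                    self._children[p].add(ind.individual_id)

    # -- construction helpers -------------------------------------------------

    def _materialize_missing_parents(self) -> None:
        """A parent referenced by id but absent from the rows becomes a founder."""
        extra: dict[str, Individual] = {}
        for ind in self.individuals.values():
            for pid, sex in ((ind.father_id, "male"), (ind.mother_id, "female")):
                if pid is not None and pid not in self.individuals:
                    prev = extra.get(pid)
                    if prev is not None and prev.sex != sex:
                        raise ValidationError(
                            f"parent {pid!r} referenced as both father and mother"
                        )
                    extra[pid] = Individual(pid, ind.family_id, None, None, sex)
        self.individuals.update(extra)

    def _validate_parent_sex(self) -> None:
        bad: list[str] = []
        for ind in self.individuals.values():
            f = self.individuals.get(ind.father_id) if ind.father_id else None
            m = self.individuals.get(ind.mother_id) if ind.mother_id else None
            if f is not None and f.sex == "female":
                bad.append(f"{ind.individual_id}: father {f.individual_id} has sex=female")
            if m is not None and m.sex == "male":
                bad.append(f"{ind.individual_id}: mother {m.individual_id} has sex=male")
        if bad:
            raise ValidationError("sex-inconsistent parent links: " + "; ".join(bad))

    def _generations(self) -> dict[str, int]:
        g = nx.DiGraph()
        g.add_nodes_from(self.individuals)
        for ind in self.individuals.values():
            for p in (ind.father_id, ind.mother_id):
                if p is not None:
                    g.add_edge(p, ind.individual_id)
        if not nx.is_directed_acyclic_graph(g):
            cycle = nx.find_cycle(g)
            path = " -> ".join(str(e[0]) for e in cycle) + f" -> {cycle[-1][1]}"
            raise CycleError(f"pedigree contains a cycle: {path}")
        gen: dict[str, int] = {}
        for node in nx.topological_sort(g):
            preds = list(g.predecessors(node))
            gen[node] = 0 if not preds else 1 + max(gen[p] for p in preds)
        return gen

    # -- queries --------------------------------------------------------------

    def __len__(self) -> int:
        return len(self.individuals)

    def parents(self, iid: str) -> tuple[str | None, str | None]:
        ind = self.individuals[iid]
        return ind.father_id, ind.mother_id

    def parent_set(self, iid: str) -> frozenset[str]:
        return frozenset(p for p in self.parents(iid) if p is not None)

    def children(self, iid: str) -> frozenset[str]:
        return frozenset(self._children[iid])

    def is_founder(self, iid: str) -> bool:
        return not self.parent_set(iid)

    @property
    def founders(self) -> list[str]:
        return [i for i in self.ids if self.is_founder(i)]

    @property
    def families(self) -> dict[str, list[str]]:
        fams: dict[str, list[str]] = {}
        for i in self.ids:
            fams.setdefault(self.individuals[i].family_id, []).append(i)
        return fams

    def subset(self, family_id: str) -> "Pedigree":
        return Pedigree(
            ind for ind in self.individuals.values() if ind.family_id == family_id
        )

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for i in self.ids:
            ind = self.individuals[i]
            rows.append(
                {
                    "family_id": ind.family_id,
                    "individual_id": i,
                    "father_id": ind.father_id or "0",
                    "mother_id": ind.mother_id or "0",
                    "sex": ind.sex,
                    "generation": self.generation[i],
                }
            )
        return pd.DataFrame(rows)

    def write(self, path: str | Path) -> None:
        """Write a whitespace-delimited PLINK .fam-style file (sex 1/2/0)."""
        code = {"male": "1", "female": "2", "unknown": "0"}
        with open(path, "w") as fh:
            for i in self.ids:
                ind = self.individuals[i]
                fh.write(
                    f"{ind.family_id} {i} {ind.father_id or 0} "
                    f"{ind.mother_id or 0} {code[ind.sex]}\n"
                )


def read_pedigree(path: str | Path) -> Pedigree:
    """Read a PLINK .fam-style pedigree file.

    Columns: FID IID PAT MAT SEX (extra columns ignored); 0 or empty marks a
    missing parent.  Whitespace- and comma-delimited dialects are
    auto-detected from the first non-empty line.
    """
    path = Path(path)
    with open(path) as fh:
        first = ""
        for line in fh:
            if line.strip():
                first = line
                break
    sep = "," if "," in first else r"\s+"
    df = pd.read_csv(path, sep=sep, header=None, dtype=str, comment="#")
    if df.shape[1] < 5:
        raise ValidationError(
            f"pedigree file {path} has {df.shape[1]} columns, need at least 5 "
            "(FID IID PAT MAT SEX)"
        )
    inds = []
    for row in df.itertuples(index=False):
        fid, iid, pat, mat, sex = (str(v).strip() for v in row[:5])
        pat_id = None if pat.lower() in MISSING_PARENT else pat
        mat_id = None if mat.lower() in MISSING_PARENT else mat
        inds.append(Individual(iid, fid, pat_id, mat_id, _parse_sex(sex)))
    return Pedigree(inds)


# -- relative-pair classification ---------------------------------------------


def _full_sibs(ped: Pedigree, a: str, b: str) -> bool:
    pa, pb = ped.parent_set(a), ped.parent_set(b)
    return len(pa) == 2 and pa == pb


def _classify_one(ped: Pedigree, a: str, b: str) -> tuple[str, str, str] | None:
    """Return (class, id_a, id_b) or None.  Rules are ancestor-path based and
    checked in closeness priority so each pair gets exactly one class."""
    sex = {i: ped.individuals[i].sex for i in (a, b)}
    pa, pb = ped.parent_set(a), ped.parent_set(b)

    # parent-offspring
    for par, chi in ((a, b), (b, a)):
        if par in ped.parent_set(chi):
            role = "father" if sex[par] == "male" else "mother" if sex[par] == "female" else None
            kid = "son" if sex[chi] == "male" else "daughter" if sex[chi] == "female" else None
            if role is None or kid is None:
                return None
            return f"{role}-{kid}", par, chi

    shared = pa & pb
    if len(pa) == 2 and pa == pb:  # full siblings
        sx = sorted((sex[a], sex[b]))
        if "unknown" in sx:
            return None
        if sx == ["female", "female"]:
            return "sister-sister", *sorted((a, b))
        if sx == ["male", "male"]:
            return "brother-brother", *sorted((a, b))
        bro, sis = (a, b) if sex[a] == "male" else (b, a)
        return "brother-sister", bro, sis
    if len(shared) == 1:
        return "half-sibling", *sorted((a, b))

    # grandparent: a is parent of one of b's parents (or symmetric)
    for gp, gc in ((a, b), (b, a)):
        if any(gp in ped.parent_set(p) for p in ped.parent_set(gc)):
            return "grandparent", gp, gc

    # avuncular: a is a full sibling of one of b's parents (or symmetric)
    for av, niece in ((a, b), (b, a)):
        if any(_full_sibs(ped, av, p) for p in ped.parent_set(niece)):
            return "avuncular", av, niece

    # first cousins: a parent of each are full siblings
    if any(_full_sibs(ped, p, q) for p in pa for q in pb):
        return "cousin", *sorted((a, b))

    # spouses: share at least one common offspring
    if ped.children(a) & ped.children(b):
        if sex[a] == "male" or sex[b] == "female":
            return "spouse", a, b
        return "spouse", b, a

    return None


def classify_pairs(ped: Pedigree) -> list[RelativePair]:
    """Enumerate all classifiable relative pairs, one class per pair.

    Pairs are only sought within a family (individuals in different families
    share no ancestry by construction).  Unclassifiable pairs are omitted.
    """
    out: list[RelativePair] = []
    for fid, members in ped.families.items():
        for a, b in itertools.combinations(members, 2):
            res = _classify_one(ped, a, b)
            if res is None:
                continue
            cls, ia, ib = res
            degree = (
                "first"
                if cls in FIRST_DEGREE
                else "spousal" if cls == "spouse" else "second"
            )
            out.append(RelativePair(ia, ib, cls, degree, fid))
    return out


# -- kinship ------------------------------------------------------------------


@dataclass
class KinshipMatrix:
    """Symmetric matrix of kinship coefficients phi over ``ids``.

    ``relationship()`` returns the additive relationship matrix A = 2*phi,
    optionally with a small diagonal jitter for Cholesky robustness.
    """

    ids: list[str]
    phi: np.ndarray
    _index: dict[str, int] = field(init=False, repr=False)

    def __post_init__(self) -> None:
        self._index = {iid: k for k, iid in enumerate(self.ids)}

    def coeff(self, a: str, b: str) -> float:
        return float(self.phi[self._index[a], self._index[b]])

    def inbreeding(self, iid: str) -> float:
        """f_i, from the diagonal phi_ii = 0.5*(1+f_i)."""
        return 2.0 * self.coeff(iid, iid) - 1.0

    def relationship(self, jitter: float = 0.0) -> np.ndarray:
        a = 2.0 * self.phi
        if jitter:
            a = a + jitter * np.eye(len(self.ids))
        return a

    def subset(self, ids: Iterable[str]) -> "KinshipMatrix":
        ids = list(ids)
        idx = np.array([self._index[i] for i in ids])
        return KinshipMatrix(ids, self.phi[np.ix_(idx, idx)])

    def to_long(self) -> pd.DataFrame:
        n = len(self.ids)
        iu = np.triu_indices(n)
        return pd.DataFrame(
            {
                "id_a": [self.ids[i] for i in iu[0]],
                "id_b": [self.ids[j] for j in iu[1]],
                "phi": self.phi[iu],
            }
        )

    def to_square_csv(self, path: str | Path) -> None:
        pd.DataFrame(self.phi, index=self.ids, columns=self.ids).to_csv(path)

    def to_long_csv(self, path: str | Path) -> None:
        self.to_long().to_csv(path, index=False)


def kinship(ped: Pedigree) -> KinshipMatrix:
    """Kinship matrix by the recursive tabular method.

    Individuals are processed in generation order (parents always precede
    children); for individual i with parents (p, q):

        phi_ij = 0.5 * (phi_pj + phi_qj)   for previously processed j != i
        phi_ii = 0.5 * (1 + phi_pq)

    with missing-parent terms equal to 0, so founders get phi_ii = 0.5 and
    are unrelated to everyone processed before them.
    """
    order = ped.ids
    index = {iid: k for k, iid in enumerate(order)}
    n = len(order)
    phi = np.zeros((n, n))
    for k, iid in enumerate(order):
        f, m = ped.parents(iid)
        fi = index[f] if f is not None else None
        mi = index[m] if m is not None else None
        row = np.zeros(k)
        if fi is not None:
            row += phi[fi, :k]
        if mi is not None:
            row += phi[mi, :k]
        phi[k, :k] = 0.5 * row
        phi[:k, k] = phi[k, :k]
        f_self = phi[fi, mi] if (fi is not None and mi is not None) else 0.0
        phi[k, k] = 0.5 * (1.0 + f_self)
    return KinshipMatrix(list(order), phi)
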