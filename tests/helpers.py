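"""Independent oracles used by the test suite.

Everything here is deliberately written from first principles — exhaustive
ancestor-path inspection, Monte-Carlo gene dropping, explicit sum formulas,
full-covariance multivariate-normal likelihoods — so the package
implementations are checked against code that shares none of their
machinery.
"""

from __future__ import annotations

import itertools
import math

import numpy as np

from famagg.pedigree import Pedigree


# -- brute-force relative-pair classification ---------------------------------


def _ancestor_paths(ped: Pedigree, iid: str) -> set[tuple[str, int]]:
    """All (ancestor, depth) pairs reachable by walking parent links."""
    out: set[tuple[str, int]] = set()
    frontier = [(iid, 0)]
    while frontier:
        node, depth = frontier.pop()
        for p in ped.parents(node):
            if p is not None:
                out.add((p, depth + 1))
                frontier.append((p, depth + 1))
    return out


def oracle_classify(ped: Pedigree) -> dict[str, int]:
    """Class counts by exhaustive ancestor-path inspection.

    Reimplements the pair taxonomy independently: for every within-family
    pair, paths to all ancestors are enumerated and pattern-matched in the
    same closeness priority the package documents.
    """

    def parents(i):
        return {p for p in ped.parents(i) if p is not None}

    def kids(i):
        return set(ped.children(i))

    def fullsib(i, j):
        pi, pj = parents(i), parents(j)
        return len(pi) == 2 and pi == pj

    counts: dict[str, int] = {}
    for fid, members in ped.families.items():
        for a, b in itertools.combinations(sorted(members), 2):
            sa = ped.individuals[a].sex
            sb = ped.individuals[b].sex
            anc_a = _ancestor_paths(ped, a)
            anc_b = _ancestor_paths(ped, b)
            label = None
            if (a, 1) in anc_b or (b, 1) in anc_a:
                par, chi = (a, b) if (a, 1) in anc_b else (b, a)
                ps = ped.individuals[par].sex
                cs = ped.individuals[chi].sex
                if ps != "unknown" and cs != "unknown":
                    role = "father" if ps == "male" else "mother"
                    kid = "son" if cs == "male" else "daughter"
                    label = f"{role}-{kid}"
            elif fullsib(a, b):
                if "unknown" not in (sa, sb):
                    if sa == sb:
                        label = "sister-sister" if sa == "female" else "brother-brother"
                    else:
                        label = "brother-sister"
            elif len(parents(a) & parents(b)) == 1:
                label = "half-sibling"
            elif (a, 2) in anc_b or (b, 2) in anc_a:
                label = "grandparent"
            elif any(
                fullsib(a, p) for p in parents(b)
            ) or any(fullsib(b, p) for p in parents(a)):
                label = "avuncular"
            elif any(fullsib(p, q) for p in parents(a) for q in parents(b)):
                label = "cousin"
            elif kids(a) & kids(b):
                label = "spouse"
            if label is not None:
                counts[label] = counts.get(label, 0) + 1
    return counts


# -- gene-dropping kinship oracle ----------------------------------------------


def gene_drop_phi(
    ped: Pedigree, n_drops: int = 100_000, seed: int = 0, chunk: int = 10_000
) -> np.ndarray:
    """Monte-Carlo kinship estimate by gene dropping.

    Every founder (and every missing parental side) contributes two unique
    allele labels; alleles are dropped through the pedigree with independent
    Mendelian coin flips per drop.  phi_ij is estimated as the probability
    that one allele picked at random from i equals one picked at random from
    j (two independent picks for the diagonal).
    """
    rng = np.random.default_rng(seed)
    order = ped.ids
    n = len(order)
    idx = {iid: k for k, iid in enumerate(order)}
    a0 = np.empty((n, n_drops), dtype=np.int32)
    a1 = np.empty((n, n_drops), dtype=np.int32)
    next_allele = 0
    for k, iid in enumerate(order):
        f, m = ped.parents(iid)
        for slot, parent in ((a0, f), (a1, m)):
            if parent is None:
                slot[k] = next_allele  # unique constant allele, no descent
                next_allele += 1
            else:
                pi = idx[parent]
                coin = rng.integers(0, 2, n_drops).astype(bool)
                slot[k] = np.where(coin, a1[pi], a0[pi])
    pick_x = rng.integers(0, 2, (n, n_drops)).astype(bool)
    pick_y = rng.integers(0, 2, (n, n_drops)).astype(bool)
    x = np.where(pick_x, a1, a0)
    y = np.where(pick_y, a1, a0)

    counts = np.zeros((n, n), dtype=np.int64)
    for lo in range(0, n_drops, chunk):
        sl = slice(lo, min(lo + chunk, n_drops))
        counts += (x[:, None, sl] == x[None, :, sl]).sum(axis=2)
    phi_hat = counts / n_drops
    np.fill_diagonal(phi_hat, (x == y).mean(axis=1))
    return phi_hat


# -- explicit ICC formulas -----------------------------------------------------


def interclass_oracle(xa, xb) -> float:
    """Product-moment correlation over ordered pairs, written as raw sums."""
    n = len(xa)
    ma = sum(xa) / n
    mb = sum(xb) / n
    num = sum((a - ma) * (b - mb) for a, b in zip(xa, xb))
    da = math.sqrt(sum((a - ma) ** 2 for a in xa))
    db = math.sqrt(sum((b - mb) ** 2 for b in xb))
    return num / (da * db)


def double_entry_oracle(xa, xb) -> float:
    """Intraclass correlation by double entry, written as raw sums over the
    2n entries with a single common mean and variance."""
    entries = [(a, b) for a, b in zip(xa, xb)] + [(b, a) for a, b in zip(xa, xb)]
    m = sum(u for u, _ in entries) / len(entries)
    num = sum((u - m) * (v - m) for u, v in entries)
    den = sum((u - m) ** 2 for u, _ in entries)
    return num / den


# -- full-covariance ML grid oracle --------------------------------------------


def mvn_profile_grid(
    y: np.ndarray, x: np.ndarray, a_matrix: np.ndarray, rhos: np.ndarray,
    jitter: float = 1e-8,
) -> np.ndarray:
    """Profile log-likelihood over rho via dense multivariate-normal algebra.

    At each rho the covariance V = rho*(A + jitter*I) + (1-rho)*I is built
    in full, beta by GLS and the total variance in closed form, and the
    log-likelihood evaluated with explicit solves and slogdet — no
    eigendecomposition shared with the implementation under test.
    """
    n = len(y)
    aj = a_matrix + jitter * np.eye(n)
    lls = []
    for rho in rhos:
        v = rho * aj + (1.0 - rho) * np.eye(n)
        vi = np.linalg.inv(v)
        beta = np.linalg.solve(x.T @ vi @ x, x.T @ vi @ y)
        r = y - x @ beta
        sp2 = float(r @ vi @ r) / n
        _sign, logdet = np.linalg.slogdet(v)
        lls.append(-0.5 * (n * math.log(2.0 * math.pi * sp2) + logdet + n))
    return np.array(lls)
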