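"""Pedigree parsing, pair classification, and kinship recursion."""

import itertools

import numpy as np
import pytest

from famagg.pedigree import (
    CycleError,
    Individual,
    Pedigree,
    ValidationError,
    classify_pairs,
    kinship,
    read_pedigree,
    FIRST_DEGREE,
)
from helpers import oracle_classify

TRIO = """\
FAM1 DAD 0 0 1
FAM1 MOM 0 0 2
FAM1 KID DAD MOM 2
"""


def write(tmp_path, text, name="ped.fam"):
    p = tmp_path / name
    p.write_text(text)
    return p


class TestReadPedigree:
    def test_trio_whitespace(self, tmp_path):
        ped = read_pedigree(write(tmp_path, TRIO))
        assert len(ped) == 3
        assert set(ped.founders) == {"DAD", "MOM"}
        assert ped.generation["KID"] == 1

    def test_trio_csv_dialect(self, tmp_path):
        csv = TRIO.replace(" ", ",")
        ped = read_pedigree(write(tmp_path, csv))
        assert set(ped.founders) == {"DAD", "MOM"}

    def test_referenced_absent_parent_becomes_founder(self, tmp_path):
        ped = read_pedigree(write(tmp_path, "F1 KID PA MA 1\n"))
        assert set(ped.founders) == {"PA", "MA"}
        assert ped.individuals["PA"].sex == "male"

    def test_sex_inconsistent_mother_raises(self, tmp_path):
        text = "F1 MOM 0 0 1\nF1 KID 0 MOM 2\n"  # mother recorded male
        with pytest.raises(ValidationError, match="MOM"):
            read_pedigree(write(tmp_path, text))

    def test_duplicate_iid_raises(self, tmp_path):
        text = TRIO + "FAM1 KID 0 0 1\n"
        with pytest.raises(ValidationError, match="duplicate"):
            read_pedigree(write(tmp_path, text))

    def test_cycle_raises_and_names_cycle(self, tmp_path):
        text = "F1 A B 0 1\nF1 B A 0 1\n"
        with pytest.raises(CycleError, match="A"):
            read_pedigree(write(tmp_path, text))

    def test_32_member_family(self, tmp_path):
        # couple + 6 children, each child married with 3 kids = 32 members
        lines = ["F1 P1 0 0 1", "F1 P2 0 0 2"]
        for c in range(6):
            lines.append(f"F1 C{c} P1 P2 1")
            lines.append(f"F1 M{c} 0 0 2")
            for g in range(3):
                lines.append(f"F1 G{c}_{g} C{c} M{c} 2")
        ped = read_pedigree(write(tmp_path, "\n".join(lines)))
        assert max(len(v) for v in ped.families.values()) == 32

    def test_row_order_irrelevant(self, tmp_path, sim_pedigree_200):
        path = tmp_path / "sim.fam"
        sim_pedigree_200.write(path)
        lines = path.read_text().strip().split("\n")
        shuffled = list(lines)
        np.random.default_rng(0).shuffle(shuffled)
        path2 = write(tmp_path, "\n".join(shuffled), "shuffled.fam")
        k1 = kinship(read_pedigree(path))
        k2 = kinship(read_pedigree(path2))
        assert k1.ids == k2.ids
        assert np.array_equal(k1.phi, k2.phi)
        p1 = classify_pairs(read_pedigree(path))
        p2 = classify_pairs(read_pedigree(path2))
        assert sorted((p.id_a, p.id_b, p.pair_class) for p in p1) == sorted(
            (p.id_a, p.id_b, p.pair_class) for p in p2
        )


class TestClassifyPairs:
    def test_trio(self, tmp_path):
        ped = read_pedigree(write(tmp_path, TRIO))
        pairs = classify_pairs(ped)
        assert {p.pair_class for p in pairs} == {"father-daughter", "mother-daughter", "spouse"}
        assert len(pairs) == 3

    def test_nuclear_family_combinatorics(self):
        rows = [("D", None, None, "male"), ("M", None, None, "female")]
        rows += [(f"G{i}", "D", "M", "female") for i in (1, 2)]
        rows += [("B1", "D", "M", "male")]
        ped = Pedigree(Individual(i, "F", f, m, s) for i, f, m, s in rows)
        counts = {}
        for p in classify_pairs(ped):
            counts[p.pair_class] = counts.get(p.pair_class, 0) + 1
        assert counts["sister-sister"] == 1
        assert counts["brother-sister"] == 2
        assert counts["spouse"] == 1
        parent_offspring = sum(
            v for k, v in counts.items() if k.split("-")[0] in ("father", "mother")
        )
        assert parent_offspring == 6

    def test_all_twelve_classes_present(self, extended_pedigree):
        classes = {p.pair_class for p in classify_pairs(extended_pedigree)}
        assert {
            "father-son", "father-daughter", "mother-son", "mother-daughter",
            "sister-sister", "brother-brother", "brother-sister", "spouse",
            "grandparent", "avuncular", "half-sibling", "cousin",
        } <= classes

    def test_role_ordering(self, extended_pedigree):
        pairs = {(p.id_a, p.id_b): p.pair_class for p in classify_pairs(extended_pedigree)}
        assert pairs.get(("GF", "C1")) == "grandparent"  # grandparent first
        assert pairs.get(("U", "C1")) == "avuncular"  # aunt/uncle first
        assert pairs.get(("GF", "GM")) == "spouse"  # male spouse first

    def test_partition_no_pair_twice(self, sim_pedigree_200):
        pairs = classify_pairs(sim_pedigree_200)
        keys = [frozenset((p.id_a, p.id_b)) for p in pairs]
        assert len(keys) == len(set(keys))

    def test_first_degree_total(self, sim_pedigree_200):
        pairs = classify_pairs(sim_pedigree_200)
        po = [p for p in pairs if p.pair_class.split("-")[0] in ("father", "mother")]
        sib = [p for p in pairs if p.pair_class in ("sister-sister", "brother-brother", "brother-sister")]
        first = [p for p in pairs if p.degree == "first"]
        assert len(first) == len(po) + len(sib)
        assert all(p.pair_class in FIRST_DEGREE for p in first)

    def test_matches_bruteforce_oracle(self, sim_pedigree_200, extended_pedigree):
        for ped in (sim_pedigree_200, extended_pedigree):
            counts = {}
            for p in classify_pairs(ped):
                counts[p.pair_class] = counts.get(p.pair_class, 0) + 1
            assert counts == oracle_classify(ped)


class TestKinship:
    def test_classic_coefficients(self, extended_pedigree):
        km = kinship(extended_pedigree)
        assert km.coeff("GF", "U") == 0.25  # parent-offspring
        assert km.coeff("U", "A") == 0.25  # full sibs
        assert km.coeff("H1", "H2") == 0.125  # half sibs
        assert km.coeff("GF", "C1") == 0.125  # grandparent
        assert km.coeff("U", "C1") == 0.125  # avuncular
        assert km.coeff("N", "C1") == 0.0625  # first cousins
        assert km.coeff("GF", "GM") == 0.0  # unrelated spouses
        assert km.coeff("GF", "GF") == 0.5  # non-inbred self

    def test_child_of_first_cousins(self, inbred_pedigree):
        km = kinship(inbred_pedigree)
        assert km.coeff("K1", "K2") == 0.0625
        assert km.inbreeding("X") == pytest.approx(0.0625)
        assert km.coeff("X", "X") == pytest.approx(0.53125)

    def test_symmetry_and_psd(self, sim_pedigree_200):
        km = kinship(sim_pedigree_200)
        assert np.array_equal(km.phi, km.phi.T)
        assert km.phi.min() >= 0.0 and km.phi.max() <= 1.0
        a = km.relationship(jitter=1e-8)
        eigvals = np.linalg.eigvalsh(a)
        assert eigvals.min() > -1e-9

    def test_consistency_with_pair_classes(self, sim_pedigree_200):
        """Non-inbred pedigrees: kinship is pinned down by the pair class."""
        km = kinship(sim_pedigree_200)
        expected = {
            "father-son": 0.25, "father-daughter": 0.25,
            "mother-son": 0.25, "mother-daughter": 0.25,
            "sister-sister": 0.25, "brother-brother": 0.25, "brother-sister": 0.25,
            "grandparent": 0.125, "avuncular": 0.125, "half-sibling": 0.125,
            "cousin": 0.0625, "spouse": 0.0,
        }
        for p in classify_pairs(sim_pedigree_200):
            assert km.coeff(p.id_a, p.id_b) == pytest.approx(expected[p.pair_class])

    def test_long_export_roundtrip(self, extended_pedigree, tmp_path):
        km = kinship(extended_pedigree)
        long = km.to_long()
        assert len(long) == len(km.ids) * (len(km.ids) + 1) // 2
        km.to_square_csv(tmp_path / "phi.csv")
        import pandas as pd

        back = pd.read_csv(tmp_path / "phi.csv", index_col=0)
        assert np.allclose(back.to_numpy(), km.phi)
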