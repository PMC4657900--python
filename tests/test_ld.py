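"""Linkage disequilibrium statistics, LD tables, regions, block sorting."""

import numpy as np
import pytest

from vgwas.ld import block_sort, ld_pair, ld_table, region_in_ld, region_to_bed

from conftest import make_genotypes


def vectors_from_counts(n11, n10, n01, n00):
    a = np.concatenate([np.ones(n11 + n10), np.zeros(n01 + n00)])
    b = np.concatenate([np.ones(n11), np.zeros(n10), np.ones(n01), np.zeros(n00)])
    return a, b


class TestLdPair:
    def test_identical_vectors_complete_ld(self):
        x = np.array([1.0, 0, 0, 1, 0, 1, 0, 0])
        s = ld_pair(x, x)
        assert s.Dprime == pytest.approx(1.0)
        assert s.r2 == pytest.approx(1.0)

    def test_hand_computed_counts(self):
        a, b = vectors_from_counts(5, 0, 15, 80)
        s = ld_pair(a, b)
        assert s.Dprime == pytest.approx(1.0)
        assert s.r2 == pytest.approx(0.2105, abs=1e-3)
        assert s.D == pytest.approx(0.04)

    def test_independent_vectors_low_r2(self):
        rng = np.random.default_rng(0)
        a = (rng.random(10000) < 0.3).astype(float)
        b = (rng.random(10000) < 0.4).astype(float)
        assert ld_pair(a, b).r2 < 0.01

    def test_symmetry_and_label_swap_invariance(self):
        rng = np.random.default_rng(1)
        a = (rng.random(200) < 0.3).astype(float)
        b = np.where(rng.random(200) < 0.8, a, 1 - a)
        s = ld_pair(a, b)
        assert ld_pair(b, a).r2 == pytest.approx(s.r2)
        assert ld_pair(1 - a, b).r2 == pytest.approx(s.r2)
        assert ld_pair(1 - a, b).Dprime == pytest.approx(s.Dprime)
        assert ld_pair(a, 1 - b).Dprime == pytest.approx(s.Dprime)

    def test_brute_force_two_by_two_oracle(self):
        rng = np.random.default_rng(2)
        for _ in range(20):
            a = (rng.random(18) < rng.uniform(0.2, 0.8)).astype(float)
            b = (rng.random(18) < rng.uniform(0.2, 0.8)).astype(float)
            if a.std() == 0 or b.std() == 0:
                continue
            s = ld_pair(a, b)
            pA, pB = a.mean(), b.mean()
            p11 = np.mean((a == 1) & (b == 1))
            D = p11 - pA * pB
            dmax = (min(pA * (1 - pB), (1 - pA) * pB) if D >= 0
                    else min(pA * pB, (1 - pA) * (1 - pB)))
            assert s.D == pytest.approx(D)
            assert s.Dprime == pytest.approx(abs(D) / dmax if dmax else 0.0)
            assert s.r2 == pytest.approx(D**2 / (pA * (1 - pA) * pB * (1 - pB)))

    def test_missing_pairwise_complete(self):
        a = np.array([1.0, 0, 1, 0, np.nan, 1])
        b = np.array([1.0, 0, 1, 0, 1, np.nan])
        s = ld_pair(a, b)
        assert s.r2 == pytest.approx(1.0)

    def test_monomorphic_rejected(self):
        with pytest.raises(ValueError, match="monomorphic"):
            ld_pair(np.zeros(10), np.arange(10) % 2)


class TestLdTable:
    def test_perfect_ld_layout(self):
        x = np.array([1.0, 0, 1, 0, 0])
        g = make_genotypes(np.column_stack([x, x]), marker_ids=["A", "B"])
        t = ld_table(g, ["A", "B"])
        assert t.loc["A", "B"] == pytest.approx(1.0)  # r2 above diagonal
        assert t.loc["B", "A"] == pytest.approx(1.0)  # D' below
        assert np.all(np.diag(t.values) == 1.0)

    def test_nested_alleles_dprime_one_r2_below_one(self):
        # rare alleles nested within a commoner haplotype: the deletion/
        # duplication vs block signature
        rng = np.random.default_rng(3)
        n = 200
        block = np.zeros(n)
        block[:60] = 1.0
        nested = np.zeros(n)
        nested[:12] = 1.0  # all nested carriers sit on the block
        g = make_genotypes(np.column_stack([block, nested]),
                           marker_ids=["vB", "DEL"])
        t = ld_table(g, ["vB", "DEL"])
        assert t.loc["DEL", "vB"] == pytest.approx(1.0)  # D'
        assert t.loc["vB", "DEL"] < 1.0                  # r2

    def test_single_marker_table(self):
        x = np.array([1.0, 0, 1])
        g = make_genotypes(x[:, None], marker_ids=["A"])
        t = ld_table(g, ["A"])
        assert t.shape == (1, 1)
        assert t.loc["A", "A"] == 1.0


class TestRegionInLd:
    def _block_matrix(self):
        rng = np.random.default_rng(4)
        n = 120
        lead = (rng.random(n) < 0.3).astype(float)
        cols, pos, ids = [], [], []
        for j in range(10):  # planted block in perfect LD
            cols.append(lead.copy())
            pos.append(1000 + j * 100)
            ids.append(f"blk{j}")
        for j in range(5):   # unlinked flankers
            cols.append((rng.random(n) < 0.4).astype(float))
            pos.append(3000 + j * 100)
            ids.append(f"out{j}")
        return make_genotypes(np.column_stack(cols), chrom="2",
                              positions=pos, marker_ids=ids), ids

    def test_planted_block_spanned_exactly(self):
        g, ids = self._block_matrix()
        region, members = region_in_ld(g, "blk0")
        assert region == ("2", 1000, 1900)
        assert set(members) == {f"blk{j}" for j in range(10)}

    def test_threshold_strictly_exceeded(self):
        # a marker at exactly r2 = threshold is excluded
        n = 100
        lead = np.repeat([1.0, 0.0], [50, 50])
        partner = np.concatenate([np.ones(30), np.zeros(20),
                                  np.zeros(42), np.ones(8)])
        g = make_genotypes(np.column_stack([lead, partner]), chrom="1",
                           positions=[10, 20], marker_ids=["lead", "p"])
        r2 = ld_pair(lead, partner).r2
        region, members = region_in_ld(g, "lead", r2_min=r2)
        assert members == ["lead"]
        region, members = region_in_ld(g, "lead", r2_min=r2 - 1e-9)
        assert "p" in members

    def test_lead_only_degenerate_interval(self):
        rng = np.random.default_rng(5)
        lead = (rng.random(80) < 0.3).astype(float)
        other = (rng.random(80) < 0.4).astype(float)
        g = make_genotypes(np.column_stack([lead, other]), chrom="3",
                           positions=[500, 900], marker_ids=["lead", "o"])
        region, members = region_in_ld(g, "lead", r2_min=0.4)
        assert region == ("3", 500, 500)
        assert members == ["lead"]

    def test_bed_conversion_half_open(self):
        assert region_to_bed(("2", 1000, 1900)) == "2\t999\t1900"


class TestBlockSort:
    def test_class_sizes_match_lead_frequency(self, default_pop):
        order = block_sort(default_pop.genotypes, "vB00")
        sizes = order["cls"].value_counts()
        assert sizes.sum() == 340
        minor = min(sizes)
        assert minor == round(0.29 * 340)

    def test_high_variance_class_labelled_hv(self):
        rng = np.random.default_rng(6)
        x = np.repeat([1.0, 0.0], [30, 70])
        y = rng.normal(0, np.where(x == 1, 3.0, 0.5))
        g = make_genotypes(x[:, None], marker_ids=["lead"])
        order = block_sort(g, "lead", phenotype=y)
        hv_accs = set(order.loc[order["cls"] == "hv", "accession_id"])
        carriers = {g.accession_ids[i] for i in range(100) if x[i] == 1}
        assert hv_accs == carriers

    def test_missing_calls_listed_separately(self):
        x = np.array([1.0, 0.0, np.nan, 0.0])
        g = make_genotypes(x[:, None], marker_ids=["lead"])
        order = block_sort(g, "lead")
        assert order.iloc[-1]["cls"] == "missing"
        assert (order["cls"] == "missing").sum() == 1
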