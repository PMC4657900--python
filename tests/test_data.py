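"""Genotype/phenotype containers, readers, QC filters."""

import numpy as np
import pytest

from vgwas.data import (HeterozygoteError, PhenotypeTable,
                        StructuralVariantCall, accession_means, merge_structural,
                        qc_filter, read_genotypes, write_genotypes_csv)

from conftest import make_genotypes


CSV_TEXT = """accession_id,chr1_100,chr1_200
acc1,A,G
acc2,A,G
acc3,G,G
"""

VCF_TEXT = """##fileformat=VCFv4.2
##contig=<ID=1>
#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\tacc1\tacc2\tacc3
1\t100\tchr1_100\tA\tG\t.\t.\t.\tGT\t0/0\t0/0\t1/1
1\t200\tchr1_200\tG\t.\t.\t.\t.\tGT\t0/0\t0/0\t0/0
"""


class TestReadGenotypes:
    def test_csv_minor_allele_by_frequency(self, tmp_path):
        p = tmp_path / "g.csv"
        p.write_text(CSV_TEXT)
        g = read_genotypes(p)
        m0 = g.markers[0]
        assert (m0.major_allele, m0.minor_allele) == ("A", "G")
        assert m0.maf == pytest.approx(1 / 3)
        np.testing.assert_array_equal(g.calls[:, 0], [0, 0, 1])
        # second column monomorphic G
        assert g.markers[1].maf == 0.0

    def test_diploid_cell_allele_counting(self, tmp_path):
        # one heterozygous "AG" cell among three diploid calls: G count 1 of 6
        p = tmp_path / "g.csv"
        p.write_text("accession_id,m1\na1,AA\na2,AG\na3,AA\n")
        g = read_genotypes(p, strict_inbred=False)
        assert g.markers[0].maf == pytest.approx(1 / 6)
        assert np.isnan(g.calls[1, 0])  # lenient: het becomes missing

    def test_strict_mode_rejects_heterozygote(self, tmp_path):
        p = tmp_path / "g.csv"
        p.write_text("accession_id,m1\na1,AA\na2,A/G\n")
        with pytest.raises(HeterozygoteError):
            read_genotypes(p)

    def test_vcf_missing_call_rate(self, tmp_path):
        text = VCF_TEXT.replace("0/0\t0/0\t1/1", "0/0\t./.\t1/1")
        p = tmp_path / "g.vcf"
        p.write_text(text)
        g = read_genotypes(p)
        assert g.call_rate()[0] == pytest.approx(2 / 3)

    def test_csv_and_vcf_agree(self, tmp_path):
        pc = tmp_path / "g.csv"
        pv = tmp_path / "g.vcf"
        pc.write_text(CSV_TEXT)
        pv.write_text(VCF_TEXT)
        gc = read_genotypes(pc)
        gv = read_genotypes(pv)
        np.testing.assert_array_equal(gc.calls, gv.calls)
        assert gc.accession_ids == gv.accession_ids
        assert [m.maf for m in gc.markers] == [m.maf for m in gv.markers]

    def test_round_trip_preserves_everything(self, tmp_path):
        # calls follow the minor-allele coding convention (1 less frequent)
        calls = np.array([[0, 0, 1, 0],
                          [1, np.nan, 0, 0],
                          [0, 1, 0, 1],
                          [0, 0, 0, 0],
                          [1, 0, 1, np.nan],
                          [0, 0, 0, 0]], dtype=float)
        g = make_genotypes(calls, marker_ids=[f"chr1_{j+1}" for j in range(4)])
        path = tmp_path / "rt.csv"
        write_genotypes_csv(g, path)
        g2 = read_genotypes(path)
        assert np.array_equal(g.calls, g2.calls, equal_nan=True)
        assert g.marker_ids == g2.marker_ids
        assert g.accession_ids == g2.accession_ids


class TestQcFilter:
    def _matrix(self, mafs, n=100, seed=0):
        rng = np.random.default_rng(seed)
        cols = []
        for maf in mafs:
            k = max(int(round(maf * n)), 0)
            col = np.zeros(n)
            col[rng.choice(n, k, replace=False)] = 1.0
            cols.append(col)
        return make_genotypes(np.column_stack(cols))

    def test_maf_boundary_inclusive(self):
        g = self._matrix([0.04, 0.05, 0.30])
        out = qc_filter(g)
        assert out.marker_ids == ["m1", "m2"]
        assert out.filter_log["removed_maf"] == 1

    def test_planted_low_maf_markers_all_removed(self):
        rng = np.random.default_rng(1)
        mafs = np.concatenate([rng.uniform(0.06, 0.5, 900),
                               rng.uniform(0.005, 0.035, 100)])
        g = self._matrix(rng.permutation(mafs), n=200, seed=2)
        out = qc_filter(g)
        assert out.n_markers == 900
        assert out.filter_log["removed_total"] == 100

    def test_callrate_filter_and_idempotence(self):
        calls = np.ones((20, 2))
        calls[:10, 0] = 0.0
        calls[:2, 1] = np.nan
        calls[2:11, 1] = 0.0
        g = make_genotypes(calls)
        out = qc_filter(g, callrate_min=0.95)
        assert out.marker_ids == ["m0"]
        again = qc_filter(out, callrate_min=0.95)
        assert again.marker_ids == out.marker_ids
        np.testing.assert_array_equal(again.calls, out.calls)

    def test_post_filter_maf_never_below_min(self):
        rng = np.random.default_rng(3)
        calls = (rng.random((60, 50)) < rng.uniform(0.0, 0.5, 50)).astype(float)
        out = qc_filter(make_genotypes(calls), maf_min=0.1)
        assert np.all(out.maf() >= 0.1)

    def test_all_removed_warns(self):
        g = self._matrix([0.01, 0.02])
        with pytest.warns(UserWarning, match="every marker"):
            qc_filter(g)


class TestPhenotypes:
    def test_accession_means(self):
        p = PhenotypeTable.from_records([("a", 1, 2.0), ("a", 2, 4.0), ("b", 1, 5.0)])
        out = accession_means(p)
        assert out.loc["a", "mean"] == pytest.approx(3.0)
        assert out.loc["a", "n"] == 2
        assert out.loc["b", "mean"] == pytest.approx(5.0)
        assert out.loc["b", "n"] == 1

    def test_nonpositive_rejected(self):
        with pytest.raises(ValueError, match="> 0"):
            PhenotypeTable.from_records([("a", 1, -1.0)])

    def test_generator_table_has_all_replicates(self, default_pop):
        out = accession_means(default_pop.phenotypes)
        assert len(out) == 340
        assert (out["n"] == 6).all()


class TestMergeStructural:
    def _base(self, n=340):
        rng = np.random.default_rng(4)
        calls = (rng.random((n, 3)) < 0.3).astype(float)
        return make_genotypes(calls)

    def test_del_count_bookkeeping(self):
        g = self._base()
        typed = g.accession_ids[:283]
        carriers = set(typed[:20])
        sv = [StructuralVariantCall(a, "DEL", "present" if a in carriers else "absent")
              for a in typed]
        out = merge_structural(g, sv, {"DEL": {"present": 1, "absent": 0}})
        col = out.column("DEL")
        assert np.nansum(col) == 20
        assert int(np.isnan(col).sum()) == 340 - 283

    def test_dup_multiallelic_binary_coding(self):
        g = self._base(6)
        sv = [StructuralVariantCall(a, "DUP", lab) for a, lab in
              zip(g.accession_ids, ["DUP326", "DUP322", "reference",
                                    "DUP326", "reference", "DUP322"])]
        coding = {"DUP": {"DUP326": 1, "DUP322": 0, "reference": 0}}
        out = merge_structural(g, sv, coding)
        np.testing.assert_array_equal(out.column("DUP"), [1, 0, 0, 1, 0, 0])

    def test_empty_sv_is_identity(self):
        g = self._base(5)
        assert merge_structural(g, [], {}) is g

    def test_unknown_allele_label_rejected(self):
        g = self._base(5)
        sv = [StructuralVariantCall(g.accession_ids[0], "DEL", "mystery")]
        with pytest.raises(ValueError, match="unknown allele label"):
            merge_structural(g, sv, {"DEL": {"present": 1, "absent": 0}})
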