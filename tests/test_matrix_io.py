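"""Expression/gene-set/variant containers, TSV and VCF round trips, TPM."""

import numpy as np
import pandas as pd
import pytest

from ovuln.io import (
    read_expression_matrix,
    read_gene_sets,
    read_genomic_profiles,
    read_variants,
    write_expression_matrix,
    write_gene_sets,
    write_genomic_profiles,
    write_variants_tsv,
    write_variants_vcf,
)
from ovuln.matrix import (
    ExpressionMatrix,
    GeneSet,
    GenomicProfile,
    log2_tpm1,
    normalize_tpm_log,
    tpm_from_counts,
)
from ovuln.simulate import generate_variants


def _counts(values, genes, samples):
    return ExpressionMatrix(pd.DataFrame(values, index=genes, columns=samples), "counts")


class TestExpressionMatrix:
    def test_round_trip_is_bit_exact(self, tmp_path):
        rng = np.random.default_rng(0)
        m = ExpressionMatrix(
            pd.DataFrame(
                rng.uniform(0, 12, (15, 6)),
                index=[f"G{i}" for i in range(15)],
                columns=[f"S{i}" for i in range(6)],
            ),
            "log2tpm1",
        )
        path = tmp_path / "expr.tsv"
        write_expression_matrix(m, path)
        back = read_expression_matrix(path, "log2tpm1")
        assert back.gene_ids == m.gene_ids and back.sample_ids == m.sample_ids
        np.testing.assert_array_equal(back.values, m.values)

    def test_small_tsv_shape(self, tmp_path):
        path = tmp_path / "e.tsv"
        path.write_text("gene\tA\tB\nG1\t1.0\t2.0\nG2\t3.0\t4.0\n")
        m = read_expression_matrix(path, "log2tpm1")
        assert m.values.shape == (2, 2)

    def test_duplicate_gene_rejected(self, tmp_path):
        path = tmp_path / "e.tsv"
        path.write_text("gene\tA\nG1\t1.0\nG1\t2.0\n")
        with pytest.raises(ValueError, match="duplicate"):
            read_expression_matrix(path, "log2tpm1")

    def test_non_numeric_cell_rejected(self, tmp_path):
        path = tmp_path / "e.tsv"
        path.write_text("gene\tA\nG1\toops\n")
        with pytest.raises(ValueError, match="non-numeric"):
            read_expression_matrix(path, "log2tpm1")

    def test_missing_values_rejected(self):
        df = pd.DataFrame([[1.0, np.nan]], index=["G1"], columns=["A", "B"])
        with pytest.raises(ValueError, match="missing"):
            ExpressionMatrix(df, "log2tpm1")

    def test_negative_log_layer_rejected(self):
        df = pd.DataFrame([[-0.1]], index=["G1"], columns=["A"])
        with pytest.raises(ValueError, match="non-negative"):
            ExpressionMatrix(df, "log2tpm1")

    def test_tpm_layer_validates_column_sums(self):
        df = pd.DataFrame([[5e5], [4e5]], index=["G1", "G2"], columns=["A"])
        with pytest.raises(ValueError, match="sum to 1e6"):
            ExpressionMatrix(df, "tpm")


class TestTPMNormalization:
    def test_single_gene_forced_to_1e6(self):
        counts = _counts([[7.0]], ["G1"], ["A"])
        out = normalize_tpm_log(counts, {"G1": 1500})
        assert out.layer == "log2tpm1"
        assert out.values[0, 0] == pytest.approx(np.log2(1e6 + 1))

    def test_equal_counts_equal_lengths_split_evenly(self):
        counts = _counts([[10.0], [10.0]], ["G1", "G2"], ["A"])
        tpm = tpm_from_counts(counts, {"G1": 1000, "G2": 1000})
        np.testing.assert_allclose(tpm.values[:, 0], [5e5, 5e5])

    def test_three_gene_hand_computation(self):
        # counts 10/20/30 with lengths 1000/2000/1000 -> rates .01/.01/.03
        counts = _counts([[10.0], [20.0], [30.0]], ["G1", "G2", "G3"], ["A"])
        tpm = tpm_from_counts(counts, {"G1": 1000, "G2": 2000, "G3": 1000})
        np.testing.assert_allclose(tpm.values[:, 0], [2e5, 2e5, 6e5])
        logged = log2_tpm1(tpm)
        np.testing.assert_allclose(logged.values[:, 0], np.log2(np.array([2e5, 2e5, 6e5]) + 1))

    def test_tpm_conservation_and_scale_invariance(self):
        rng = np.random.default_rng(1)
        genes = [f"G{i}" for i in range(40)]
        counts = rng.integers(1, 1000, (40, 8)).astype(float)
        lengths = {g: float(l) for g, l in zip(genes, rng.integers(200, 5000, 40))}
        m = _counts(counts, genes, [f"S{i}" for i in range(8)])
        tpm = tpm_from_counts(m, lengths)
        np.testing.assert_allclose(tpm.values.sum(axis=0), 1e6, rtol=1e-6)
        # multiplying one sample's counts by a constant leaves its TPM unchanged
        scaled = counts.copy()
        scaled[:, 3] *= 17.0
        tpm2 = tpm_from_counts(_counts(scaled, genes, [f"S{i}" for i in range(8)]), lengths)
        np.testing.assert_allclose(tpm2.values[:, 3], tpm.values[:, 3], rtol=1e-12)

    def test_all_zero_sample_names_sample(self):
        counts = _counts([[0.0, 1.0]], ["G1"], ["bad", "ok"])
        with pytest.raises(ValueError, match="bad"):
            tpm_from_counts(counts, {"G1": 1000})

    def test_missing_gene_length_rejected(self):
        counts = _counts([[1.0]], ["G1"], ["A"])
        with pytest.raises(ValueError, match="G1"):
            tpm_from_counts(counts, {})


class TestGeneSets:
    def test_one_line_gmt(self, tmp_path):
        path = tmp_path / "s.gmt"
        path.write_text("SIG1\tdesc\tA\tB\tC\tD\tE\n")
        sets = read_gene_sets(path)
        assert len(sets) == 1 and len(sets[0]) == 5

    def test_empty_file_gives_empty_list(self, tmp_path):
        path = tmp_path / "s.gmt"
        path.write_text("")
        assert read_gene_sets(path) == []

    def test_duplicate_genes_collapse(self, tmp_path):
        path = tmp_path / "s.gmt"
        path.write_text("SIG1\tdesc\tA\tB\tA\tC\tB\n")
        (s,) = read_gene_sets(path)
        assert s.genes == ["A", "B", "C"]

    def test_short_line_rejected(self, tmp_path):
        path = tmp_path / "s.gmt"
        path.write_text("SIG1\tdesc\n")
        with pytest.raises(ValueError, match="GMT"):
            read_gene_sets(path)

    def test_round_trip(self, tmp_path):
        sets = [GeneSet("A", ["X", "Y"]), GeneSet("B", ["Z"])]
        path = tmp_path / "s.gmt"
        write_gene_sets(sets, path)
        back = read_gene_sets(path)
        assert [(s.name, s.genes) for s in back] == [(s.name, s.genes) for s in sets]

    def test_empty_gene_set_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            GeneSet("E", [])


class TestVariantIO:
    def test_tsv_round_trip_preserves_fields(self, tmp_path):
        variants = generate_variants(25, seed=3)
        path = tmp_path / "v.tsv"
        write_variants_tsv(variants, path)
        assert read_variants(path) == variants

    def test_vcf_round_trip_preserves_filter_fields(self, tmp_path):
        variants = generate_variants(10, seed=4)
        path = tmp_path / "v.vcf"
        write_variants_vcf(variants, path)
        back = read_variants(path)
        assert len(back) == len(variants)
        for a, b in zip(back, variants):
            assert (a.chrom, a.pos, a.ref, a.alt) == (b.chrom, b.pos, b.ref, b.alt)
            assert a.supporting_callers == b.supporting_callers
            assert a.tumor_vaf == pytest.approx(b.tumor_vaf, abs=1e-6)
            assert a.normal_vaf == pytest.approx(b.normal_vaf, abs=1e-6)
            assert a.consequence == b.consequence
            assert a.pathogenicity_class == b.pathogenicity_class

    def test_caller_count_from_flags(self, tmp_path):
        path = tmp_path / "v.tsv"
        path.write_text(
            "chrom\tpos\tref\talt\tmutect2\tsomaticsniper\tvarscan2\tstrelka2\t"
            "tumor_vaf\tnormal_vaf\tconsequence\tclinvar_class\n"
            "chr1\t100\tA\tT\t1\t0\t1\t0\t0.2\t0.01\tnonsynonymous_snv\t5\n"
        )
        (v,) = read_variants(path)
        assert v.caller_count == 2

    def test_vaf_out_of_range_rejected(self, tmp_path):
        path = tmp_path / "v.tsv"
        path.write_text(
            "chrom\tpos\tref\talt\tmutect2\tsomaticsniper\tvarscan2\tstrelka2\t"
            "tumor_vaf\tnormal_vaf\tconsequence\tclinvar_class\n"
            "chr1\t100\tA\tT\t1\t1\t0\t0\t1.5\t0.01\tnonsynonymous_snv\t5\n"
        )
        with pytest.raises(ValueError, match=r"\[0, 1\]"):
            read_variants(path)


class TestGenomicProfiles:
    def test_round_trip(self, tmp_path):
        profiles = [
            GenomicProfile("S1", 10, 20, 30, 5, 100, True, 0.8),
            GenomicProfile("S2", 1, 2, 3, 0, 10, False, None),
        ]
        path = tmp_path / "p.tsv"
        write_genomic_profiles(profiles, path)
        assert read_genomic_profiles(path) == profiles

    def test_sig3_exceeding_total_rejected(self):
        with pytest.raises(ValueError, match="exceeds"):
            GenomicProfile("S1", 0, 0, 0, 11, 10, False, None)

    def test_beta_out_of_range_rejected(self):
        with pytest.raises(ValueError, match="beta"):
            GenomicProfile("S1", 0, 0, 0, 0, 10, False, 1.2)
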