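"""SGA calling: mutation filter, CNV concordance test, matrix assembly."""

import numpy as np
import pandas as pd
import pytest
from scipy import integrate

from oncothemes import (
    CnvCall,
    MutationRecord,
    build_sga_matrix,
    call_functional_mutations,
    cnv_concordance_test,
)
from oncothemes.sga import read_mutations


def _normal_tail_oracle(x, mu, sigma, upper):
    """Numerical integration of the normal density (independent of scipy.stats.norm.sf/cdf usage in the implementation path)."""
    pdf = lambda t: np.exp(-0.5 * ((t - mu) / sigma) ** 2) / (sigma * np.sqrt(2 * np.pi))
    if upper:
        val, _ = integrate.quad(pdf, x, mu + 40 * sigma)
    else:
        val, _ = integrate.quad(pdf, mu - 40 * sigma, x)
    return val


class TestFunctionalMutations:
    def test_damaging_missense_included(self):
        recs = [MutationRecord("s1", "g1", "missense", "probably_damaging")]
        assert call_functional_mutations(recs) == {("s1", "g1")}

    def test_benign_missense_excluded(self):
        recs = [MutationRecord("s1", "g1", "missense", "benign")]
        assert call_functional_mutations(recs) == set()

    @pytest.mark.parametrize(
        "vclass", ["frame_shift", "nonsense", "splice_site", "multi_nucleotide"]
    )
    def test_truncating_classes_included_regardless_of_label(self, vclass):
        recs = [MutationRecord("s1", "g1", vclass)]
        assert call_functional_mutations(recs) == {("s1", "g1")}

    def test_other_class_excluded(self):
        recs = [MutationRecord("s1", "g1", "other")]
        assert call_functional_mutations(recs) == set()

    def test_duplicates_collapse_to_one_pair(self):
        recs = [
            MutationRecord("s1", "g1", "nonsense"),
            MutationRecord("s1", "g1", "missense", "benign"),
            MutationRecord("s1", "g1", "missense", "benign"),
        ]
        assert call_functional_mutations(recs) == {("s1", "g1")}

    def test_unknown_variant_class_rejected(self):
        with pytest.raises(ValueError, match="variant_class"):
            MutationRecord("s1", "g1", "weird_class")

    def test_parser_reports_line_of_bad_class(self, tmp_path):
        path = tmp_path / "mut.tsv"
        path.write_text(
            "sample_id\tgene_id\tvariant_class\timpact_label\n"
            "s1\tg1\tnonsense\tunknown\n"
            "s2\tg2\tgarbage\tunknown\n"
        )
        with pytest.raises(ValueError, match="mut.tsv:3"):
            read_mutations(path)

    def test_maf_style_columns_accepted(self, tmp_path):
        path = tmp_path / "maf.tsv"
        path.write_text(
            "Tumor_Sample_Barcode\tHugo_Symbol\tVariant_Classification\timpact\n"
            "s1\tTP53\tMissense_Mutation\tprobably damaging\n"
            "s2\tTP53\tFrame_Shift_Del\t\n"
        )
        recs = read_mutations(path)
        assert call_functional_mutations(recs) == {("s1", "TP53"), ("s2", "TP53")}


def _expr(genes, samples, values):
    return pd.DataFrame(values, index=genes, columns=samples)


class TestCnvConcordance:
    def test_low_level_cnv_ignored(self):
        expr = _expr(["g1"], ["s1", "s2", "s3"], [[100.0, 0.1, -0.1]])
        calls = [CnvCall("s1", "g1", 1)]
        assert cnv_concordance_test(calls, expr) == set()

    def test_three_sigma_amplification_kept(self):
        # neutral samples give mu~0 sigma~1; s1 at +3 sd -> p ~ 0.00135
        neutral = list(np.linspace(-1.5, 1.5, 21))
        samples = [f"n{i}" for i in range(21)] + ["s1"]
        expr = _expr(["g1"], samples, [neutral + [3.0 * float(np.std(neutral, ddof=1))]])
        calls = [CnvCall("s1", "g1", 2)]
        assert cnv_concordance_test(calls, expr, 0.01) == {("s1", "g1")}

    def test_mean_expression_dropped(self):
        neutral = list(np.linspace(-1.5, 1.5, 21))
        expr = _expr(["g1"], [f"n{i}" for i in range(21)] + ["s1"], [neutral + [0.0]])
        calls = [CnvCall("s1", "g1", 2)]
        # p = 0.5 at the mean
        assert cnv_concordance_test(calls, expr, 0.01) == set()

    def test_deletion_uses_lower_tail(self):
        neutral = list(np.linspace(-1.5, 1.5, 21))
        sd = float(np.std(neutral, ddof=1))
        expr = _expr(
            ["g1"], [f"n{i}" for i in range(21)] + ["s1", "s2"],
            [neutral + [-3.0 * sd, +3.0 * sd]],
        )
        kept = cnv_concordance_test(
            [CnvCall("s1", "g1", -2), CnvCall("s2", "g1", -2)], expr, 0.01
        )
        # deletion with *high* expression is discordant
        assert kept == {("s1", "g1")}

    def test_pvalues_match_integration_oracle(self, rng):
        from oncothemes.sga import cnv_pvalue

        for _ in range(100):
            mu = rng.normal(0, 5)
            sigma = rng.uniform(0.2, 3.0)
            x = mu + rng.normal(0, 2.5) * sigma
            assert abs(cnv_pvalue(x, mu, sigma, 2) - _normal_tail_oracle(x, mu, sigma, True)) < 1e-8
            assert abs(cnv_pvalue(x, mu, sigma, -2) - _normal_tail_oracle(x, mu, sigma, False)) < 1e-8

    def test_threshold_monotonicity(self, rng):
        genes = ["g1"]
        samples = [f"s{i}" for i in range(30)]
        expr = _expr(genes, samples, rng.normal(0, 1, size=(1, 30)))
        calls = [CnvCall(s, "g1", 2) for s in samples[:10]]
        previous: set = set()
        for thr in [1e-4, 1e-3, 1e-2, 0.1, 0.5]:
            kept = cnv_concordance_test(calls, expr, thr)
            assert previous <= kept
            previous = kept

    def test_zero_variance_gene_skipped(self, caplog):
        expr = _expr(["g1"], ["a", "b", "c"], [[1.0, 1.0, 5.0]])
        calls = [CnvCall("c", "g1", 2)]
        with caplog.at_level("WARNING"):
            assert cnv_concordance_test(calls, expr) == set()
        assert "variance" in caplog.text

    def test_gene_missing_from_expression_skipped(self, caplog):
        expr = _expr(["g1"], ["a", "b", "c"], [[0.0, 1.0, 9.0]])
        calls = [CnvCall("c", "gX", 2)]
        with caplog.at_level("WARNING"):
            assert cnv_concordance_test(calls, expr) == set()
        assert "absent" in caplog.text


class TestBuildSgaMatrix:
    def test_recurrence_filter_removes_rare_genes(self):
        pairs = {(f"t{i}", "rare") for i in range(19)} | {
            (f"t{i}", "common") for i in range(25)
        }
        mat = build_sga_matrix(pairs, set(), min_recurrence=20)
        assert mat.genes == ["common"]
        assert (mat.events.sum(axis=0) >= 20).all()

    def test_min_recurrence_one_keeps_raw_union(self):
        mut = {("t1", "g1"), ("t2", "g2")}
        cnv = {("t1", "g2")}
        mat = build_sga_matrix(mut, cnv, min_recurrence=1)
        assert set(mat.event_pairs()) == mut | cnv

    def test_union_is_binary(self):
        mat = build_sga_matrix({("t1", "g1")}, {("t1", "g1")}, min_recurrence=1)
        assert mat.events.max() == 1

    def test_empty_union_rejected(self):
        with pytest.raises(ValueError, match="no SGA events"):
            build_sga_matrix(set(), set())

    def test_emptied_tumors_are_retained(self):
        pairs = {(f"t{i}", "common") for i in range(20)} | {("lonely", "rare")}
        mat = build_sga_matrix(pairs, set(), min_recurrence=20)
        assert "lonely" in mat.tumors
        assert mat.events[mat.tumors.index("lonely")].sum() == 0
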