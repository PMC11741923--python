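"""Venn partitioning, signature derivation, PC1 scoring, phenotype correlation."""

import numpy as np
import pandas as pd
import pytest

from reverseq.core import GeneSet, PhenotypeTable, ValidationError
from reverseq.signature import (consistent_deg_sets, correlate_phenotypes,
                                derive_signature, pc1_score)
from reverseq.synth import gen_phenotypes

from conftest import contrast_frame


def _timecourse_contrasts(patterns, alpha=0.05):
    """Build per-timepoint contrast tables from an explicit design.

    ``patterns`` maps gene -> {timepoint: signed significance}: -1/+1 means
    significant down/up at that timepoint, 0 not significant.
    """
    genes = list(patterns)
    out = {}
    for t in (6.0, 12.0, 24.0):
        lfc = [patterns[g].get(t, 0) * 1.0 or 0.1 for g in genes]
        q = [0.01 if patterns[g].get(t, 0) != 0 else 0.8 for g in genes]
        out[t] = contrast_frame(genes, lfc, q)
    return out


DESIGNED = {
    "g_all_dn": {6.0: -1, 12.0: -1, 24.0: -1},
    "g_all_dn2": {6.0: -1, 12.0: -1, 24.0: -1},
    "g_late_dn": {12.0: -1, 24.0: -1},
    "g_early_dn": {6.0: -1},
    "g_all_up": {6.0: 1, 12.0: 1, 24.0: 1},
    "g_mixed": {6.0: -1, 12.0: 1, 24.0: -1},
    "g_single_24": {24.0: -1},
    "g_null": {},
}


class TestVennPartition:
    def test_designed_patterns_partition_exactly(self):
        part = consistent_deg_sets(_timecourse_contrasts(DESIGNED), direction="down")
        assert part.all_timepoints == {"g_all_dn", "g_all_dn2"}
        assert part.cell(12.0, 24.0) == {"g_late_dn"}
        assert part.cell(6.0) == {"g_early_dn"}
        assert part.cell(24.0) == {"g_single_24"}
        # mixed-direction gene appears only in the cells of its down timepoints
        assert "g_mixed" in part.cell(6.0, 24.0)
        up = consistent_deg_sets(_timecourse_contrasts(DESIGNED), direction="up")
        assert up.all_timepoints == {"g_all_up"}

    def test_cells_disjoint_and_union_matches_per_timepoint_sets(self):
        part = consistent_deg_sets(_timecourse_contrasts(DESIGNED), direction="down")
        cells = list(part.cells.values())
        total = sum(len(c) for c in cells)
        assert len(part.union) == total  # pairwise disjoint
        expected_union = {g for g, pat in DESIGNED.items()
                          if any(v == -1 for v in pat.values())}
        assert part.union == expected_union

    def test_mismatched_namespaces_rejected(self):
        contrasts = _timecourse_contrasts(DESIGNED)
        contrasts[6.0] = contrasts[6.0].iloc[:-1]
        with pytest.raises(ValidationError, match="namespace"):
            consistent_deg_sets(contrasts)

    def test_needs_two_timepoints(self):
        with pytest.raises(ValidationError):
            consistent_deg_sets({6.0: contrast_frame(["g"], [1.0], [0.01])})


@pytest.fixture(scope="module")
def partition():
    return consistent_deg_sets(_timecourse_contrasts(DESIGNED), direction="down")


class TestDeriveSignature:
    def test_intersection_with_reference(self, partition):
        ref = GeneSet("REF", "", frozenset({"g_all_dn", "g_late_dn", "decoy"}))
        sig = derive_signature(partition, ref)
        assert sig.members == {"g_all_dn"}

    def test_monotone_in_reference(self, partition):
        small = GeneSet("S", "", frozenset({"g_all_dn"}))
        big = GeneSet("B", "", frozenset({"g_all_dn", "g_all_dn2", "decoy"}))
        assert derive_signature(partition, small).members <= \
            derive_signature(partition, big).members

    def test_disjoint_reference_returns_none_with_warning(self, partition, caplog):
        ref = GeneSet("R", "", frozenset({"nope1", "nope2"}))
        with caplog.at_level("WARNING", logger="reverseq"):
            assert derive_signature(partition, ref) is None
        assert any("does not intersect" in r.message for r in caplog.records)

    def test_other_cells_addressable(self, partition):
        ref = GeneSet("R", "", frozenset({"g_late_dn"}))
        sig = derive_signature(partition, ref, cell="12,24")
        assert sig.members == {"g_late_dn"}
        with pytest.raises(ValidationError, match="cell"):
            derive_signature(partition, ref, cell="7,13")


class TestPC1Score:
    def test_two_perfectly_correlated_genes(self):
        base = np.array([1.0, 2.0, 3.0, 4.0, 5.0])
        expr = pd.DataFrame([base, 10 * base + 3], index=["a", "b"],
                            columns=[f"s{i}" for i in range(5)])
        res = pc1_score(expr)
        assert res.variance_fraction == pytest.approx(1.0)

    def test_orientation_follows_mean_expression(self, rng):
        expr = pd.DataFrame(rng.normal(size=(6, 12)),
                            index=[f"g{i}" for i in range(6)],
                            columns=[f"s{i}" for i in range(12)])
        expr["s0"] += 3.0  # uniformly high member expression in s0
        res = pc1_score(expr)
        assert res.scores["s0"] >= res.scores.median()

    def test_invariant_to_gene_order_and_gene_rescaling(self, rng):
        expr = pd.DataFrame(rng.normal(size=(8, 10)),
                            index=[f"g{i}" for i in range(8)],
                            columns=[f"s{i}" for i in range(10)])
        res = pc1_score(expr)
        shuffled = expr.iloc[::-1] * 5.0 + 2.0  # affine per-gene, reordered
        res2 = pc1_score(shuffled)
        assert np.allclose(res.scores, res2.scores, atol=1e-8)

    def test_recovers_planted_factor(self, rng):
        """One-factor model, 17 genes x 20 samples, loadings 1, noise 0.3."""
        factor = rng.normal(size=20)
        expr = pd.DataFrame(
            np.outer(np.ones(17), factor) + rng.normal(0, 0.3, size=(17, 20)),
            index=[f"g{i}" for i in range(17)], columns=[f"s{i}" for i in range(20)])
        res = pc1_score(expr)
        assert 0.55 <= res.variance_fraction <= 0.95
        assert np.corrcoef(res.scores, factor)[0, 1] > 0.95

    def test_degenerate_inputs_rejected(self):
        expr = pd.DataFrame(np.ones((3, 5)), index=list("abc"),
                            columns=[f"s{i}" for i in range(5)])
        with pytest.raises(ValidationError):
            pc1_score(expr)  # no member has variance


class TestCorrelatePhenotypes:
    def test_phenotype_equal_to_score(self, rng):
        score = pd.Series(rng.normal(size=15), index=[f"s{i}" for i in range(15)])
        phen = PhenotypeTable(score.to_frame("p1"))
        out = correlate_phenotypes(score.to_frame("score"), phen)
        assert out.loc[0, "r"] == pytest.approx(1.0)
        assert out.loc[0, "pvalue"] < 1e-12

    def test_null_phenotypes_rarely_q_significant(self, rng):
        score = pd.Series(rng.normal(size=30), index=[f"s{i}" for i in range(30)])
        phen, _ = gen_phenotypes(score, [0.0] * 20, noise_sd=1.0, seed=11)
        out = correlate_phenotypes(score.to_frame("score"), phen)
        assert (out.qvalue < 0.05).sum() == 0

    def test_coupled_phenotype_detected_with_noise(self, rng):
        score = pd.Series(rng.normal(size=30), index=[f"s{i}" for i in range(30)])
        phen, _ = gen_phenotypes(score, [1.0], noise_sd=0.5, seed=5)
        out = correlate_phenotypes(score.to_frame("score"), phen)
        assert out.loc[0, "qvalue"] < 0.05

    def test_insufficient_pairs_flagged_not_fatal(self, rng):
        score = pd.Series(rng.normal(size=10), index=[f"s{i}" for i in range(10)])
        tab = pd.DataFrame({"p1": score.values, "p2": [np.nan] * 8 + [1.0, 2.0]},
                           index=score.index)
        out = correlate_phenotypes(score.to_frame("score"), PhenotypeTable(tab))
        sparse = out[out.phenotype == "p2"]
        assert sparse.r.isna().all()
        full = out[out.phenotype == "p1"]
        assert full.qvalue.notna().all()
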