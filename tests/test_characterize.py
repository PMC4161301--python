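"""Sign algebra, genomic classes, Fisher comparisons and enrichment scans."""

from itertools import permutations

import numpy as np
import pytest

from esnpquartets.characterize import (
    all_sign_configurations,
    classify_category,
    classify_cis_trans,
    classify_consistency,
    cis_count,
    coexpression_comparison,
    compare_categorical,
    gwas_overlap_test,
    orient_edges,
    shared_annotation_test,
    source_annotation_bin,
    target_coexpression,
)
from esnpquartets.datatypes import (
    ExpressionMatrix,
    GeneRecord,
    GenotypeMatrix,
    Quartet,
    SnpRecord,
)

from conftest import fisher_two_sided_enumeration


class TestSignAlgebra:
    def test_sixteen_configurations_eight_consistent(self):
        configs = all_sign_configurations()
        assert len(configs) == 16
        consistent = [c for c in configs if classify_consistency(c)]
        assert len(consistent) == 8
        assert len([c for c in configs if not classify_consistency(c)]) == 8

    def test_parity_law_equals_sign_product(self):
        for c in all_sign_configurations():
            n_up = sum(e == +1 for e in c)
            assert classify_consistency(c) == (n_up % 2 == 0) == (np.prod(c) == 1)

    def test_consistent_configs_partition_into_four_pairs(self):
        groups = {}
        for c in all_sign_configurations():
            if classify_consistency(c):
                groups.setdefault(classify_category(c), []).append(c)
        assert len(groups) == 4
        assert all(len(v) == 2 for v in groups.values())
        assert set(groups) == {(g, s) for g in ("same", "opposite") for s in ("same", "opposite")}

    def test_global_negation_maps_to_category_partner(self):
        """Negating all four edges gives the other member of the same
        category; negating one source's two edges flips the snps axis."""
        for c in all_sign_configurations():
            if not classify_consistency(c):
                continue
            partner = tuple(-e for e in c)
            assert classify_consistency(partner)
            assert classify_category(partner) == classify_category(c)
            assert partner != c
            one_source = (-c[0], -c[1], c[2], c[3])
            g_axis, s_axis = classify_category(c)
            flipped = "opposite" if s_axis == "same" else "same"
            assert classify_category(one_source) == (g_axis, flipped)

    @pytest.mark.parametrize(
        "config,expected",
        [
            ((+1, +1, +1, +1), ("same", "same")),
            ((+1, -1, +1, -1), ("opposite", "same")),
            ((+1, +1, -1, -1), ("same", "opposite")),
            ((+1, -1, -1, +1), ("opposite", "opposite")),
        ],
    )
    def test_category_examples(self, config, expected):
        assert classify_category(config) == expected

    def test_inconsistent_configuration_has_no_category(self):
        with pytest.raises(ValueError):
            classify_category((+1, +1, +1, -1))

    def test_swapping_sources_or_targets_preserves_labels(self):
        """Source swap permutes edges (0,1,2,3)->(2,3,0,1); target swap
        ->(1,0,3,2).  Consistency and category are invariant under both."""
        for c in all_sign_configurations():
            src_swap = (c[2], c[3], c[0], c[1])
            tgt_swap = (c[1], c[0], c[3], c[2])
            assert classify_consistency(src_swap) == classify_consistency(c)
            assert classify_consistency(tgt_swap) == classify_consistency(c)
            if classify_consistency(c):
                assert classify_category(src_swap) == classify_category(c)
                assert classify_category(tgt_swap) == classify_category(c)


def _fixture_quartet(**kw):
    defaults = dict(
        snp1_id="sA", snp2_id="sB", gene1_id="gA", gene2_id="gB",
        triplet1_kind="mutual", triplet2_kind="directional",
    )
    defaults.update(kw)
    return Quartet(**defaults)


class TestOrientEdges:
    def test_all_positive_betas(self):
        q = _fixture_quartet()
        betas = {(s, g): 0.5 for s in ("sA", "sB") for g in ("gA", "gB")}
        assert orient_edges(q, betas) == (+1, +1, +1, +1)
        assert q.consistent and q.category == ("same", "same")

    def test_one_negative_beta_is_inconsistent(self):
        q = _fixture_quartet()
        betas = {("sA", "gA"): 1.0, ("sA", "gB"): 1.0, ("sB", "gA"): 1.0, ("sB", "gB"): -1.0}
        assert orient_edges(q, betas) == (+1, +1, +1, -1)
        assert q.consistent is False and q.category is None

    def test_signs_match_correlation_signs(self):
        """Edge signs equal the Pearson-correlation signs of count vs expr."""
        from esnpquartets.association import associate

        rng = np.random.default_rng(31)
        for _ in range(20):
            s = rng.binomial(2, 0.4, 60).astype(float)
            if np.ptp(s) == 0:
                continue
            y = rng.standard_normal(60)
            rec = associate(s, y)
            assert np.sign(rec.beta) == np.sign(np.corrcoef(s, y)[0, 1])

    def test_zero_slope_is_an_error(self):
        q = _fixture_quartet()
        betas = {(s, g): 1.0 for s in ("sA", "sB") for g in ("gA", "gB")}
        betas[("sB", "gB")] = 0.0
        with pytest.raises(ValueError):
            orient_edges(q, betas)


def _geo(snp_positions, gene_spans, n=10):
    samples = [f"S{i}" for i in range(n)]
    snps = [SnpRecord(sid, c, p, 0.3, "exon") for sid, c, p in snp_positions]
    rng = np.random.default_rng(0)
    geno = GenotypeMatrix(samples, snps, rng.binomial(2, 0.3, (n, len(snps))).astype(float))
    genes = [GeneRecord(g, c, s, e) for g, c, s, e in gene_spans]
    expr = ExpressionMatrix(samples, genes, rng.standard_normal((n, len(genes))))
    return geno, expr


class TestCisTrans:
    def test_snp_inside_span_is_cis(self):
        geno, expr = _geo(
            [("sA", "1", 150), ("sB", "9", 5)],
            [("gA", "1", 100, 200), ("gB", "2", 100, 200)],
        )
        q = _fixture_quartet()
        assert cis_count(q, geno, expr) == 1
        assert classify_cis_trans(q, geno, expr) == "one_cis"

    def test_sources_absent_from_target_chromosomes_is_two_trans(self):
        geno, expr = _geo(
            [("sA", "7", 150), ("sB", "8", 150)],
            [("gA", "1", 100, 200), ("gB", "2", 100, 200)],
        )
        q = _fixture_quartet()
        assert classify_cis_trans(q, geno, expr) == "two_trans"

    def test_classes_match_brute_force_containment(self):
        rng = np.random.default_rng(5)
        for _ in range(30):
            sp = [("sA", str(rng.integers(1, 4)), int(rng.integers(1, 500))),
                  ("sB", str(rng.integers(1, 4)), int(rng.integers(1, 500)))]
            gs = []
            for g in ("gA", "gB"):
                start = int(rng.integers(1, 400))
                gs.append((g, str(rng.integers(1, 4)), start, start + int(rng.integers(10, 200))))
            geno, expr = _geo(sp, gs)
            q = _fixture_quartet()
            brute = sum(
                1
                for sid, sc, spos in sp
                for gid, gc, gstart, gend in gs
                if sc == gc and gstart <= spos <= gend
            )
            assert cis_count(q, geno, expr) == brute

    def test_dependency_class_map(self):
        assert _fixture_quartet(triplet1_kind="mutual", triplet2_kind="mutual").dependency_class == "mutual_mutual"
        assert _fixture_quartet().dependency_class == "mixed"
        assert _fixture_quartet(triplet1_kind="directional", triplet2_kind="directional",
                                ).dependency_class == "directional_directional"

    def test_annotation_bins(self):
        geno, expr = _geo(
            [("sA", "1", 150), ("sB", "9", 5)],
            [("gA", "1", 100, 200), ("gB", "2", 100, 200)],
        )
        snps = [
            SnpRecord("sA", "1", 150, 0.3, "both"),
            SnpRecord("sB", "9", 5, 0.3, "tf"),
        ]
        geno = GenotypeMatrix(geno.samples, snps, geno.counts)
        assert source_annotation_bin(_fixture_quartet(), geno) == "exon+tf"


class TestCoexpression:
    def test_identical_and_mirror_targets(self):
        samples = [f"S{i}" for i in range(20)]
        rng = np.random.default_rng(3)
        base = rng.standard_normal(20)
        genes = [GeneRecord("gA", "1", 1, 10), GeneRecord("gB", "2", 1, 10)]
        expr = ExpressionMatrix(samples, genes, np.column_stack([base, -base]))
        q = _fixture_quartet()
        r, abs_r = target_coexpression(q, expr)
        assert r == pytest.approx(-1.0)
        assert abs_r == pytest.approx(1.0)

    def test_matches_numpy_correlation(self):
        rng = np.random.default_rng(9)
        samples = [f"S{i}" for i in range(40)]
        vals = rng.standard_normal((40, 2))
        genes = [GeneRecord("gA", "1", 1, 10), GeneRecord("gB", "2", 1, 10)]
        expr = ExpressionMatrix(samples, genes, vals)
        r, _ = target_coexpression(_fixture_quartet(), expr)
        assert r == pytest.approx(np.corrcoef(vals[:, 0], vals[:, 1])[0, 1])

    def test_rank_comparison_detects_shift(self):
        rng = np.random.default_rng(0)
        hi = list(rng.uniform(0.7, 0.95, 40))
        lo = list(rng.uniform(0.0, 0.3, 40))
        assert coexpression_comparison(hi, lo) < 1e-6


class TestFisher:
    def test_balanced_table_gives_p_one(self):
        assert compare_categorical([[5, 5], [5, 5]]) == pytest.approx(1.0)

    def test_diagonal_table_matches_enumeration(self):
        table = [[10, 0], [0, 10]]
        assert compare_categorical(table) == pytest.approx(
            fisher_two_sided_enumeration(table), abs=1e-12
        )

    def test_mhc_convention_check(self):
        """7 of 82 real vs 4 of 342 permuted MHC quartets: p below 0.0014."""
        assert compare_categorical([[7, 75], [4, 338]]) < 0.0014

    def test_random_tables_match_enumeration(self):
        rng = np.random.default_rng(12)
        for _ in range(200):
            t = rng.integers(0, 12, size=(2, 2))
            if t.sum() == 0:
                continue
            assert compare_categorical(t.tolist()) == pytest.approx(
                fisher_two_sided_enumeration(t.tolist()), abs=1e-9
            )

    def test_all_zero_table_rejected(self):
        with pytest.raises(ValueError):
            compare_categorical([[0, 0], [0, 0]])


class TestEnrichment:
    def _quartets(self, pairs, perm_index=None):
        out = []
        for i, (g1, g2) in enumerate(pairs):
            a, b = sorted([g1, g2])
            out.append(
                Quartet(
                    snp1_id=f"sa{i}", snp2_id=f"sb{i}", gene1_id=a, gene2_id=b,
                    triplet1_kind="mutual", triplet2_kind="mutual",
                    perm_index=perm_index,
                )
            )
        return out

    def test_shared_term_detection(self):
        real = self._quartets([("g1", "g2"), ("g3", "g4")])
        perm = self._quartets([("g5", "g6")], perm_index=0)
        terms = {"g1": {"T"}, "g2": {"T"}, "g3": {"T"}, "g4": {"U"}, "g5": set()}
        res = shared_annotation_test(real, perm, terms)
        assert res["real_sharing_fraction"] == pytest.approx(0.5)
        assert res["permuted_sharing_fraction"] == 0.0

    def test_sharing_fraction_matches_brute_force(self):
        rng = np.random.default_rng(21)
        genes = [f"g{i}" for i in range(30)]
        terms = {g: set(rng.choice(["A", "B", "C", "D"], rng.integers(0, 3), replace=False))
                 for g in genes}
        pairs = [tuple(rng.choice(genes, 2, replace=False)) for _ in range(25)]
        real = self._quartets(pairs)
        res = shared_annotation_test(real, real, terms)
        brute = np.mean([len(terms[a] & terms[b]) > 0 for a, b in
                         [q.gene_pair for q in real]])
        assert res["real_sharing_fraction"] == pytest.approx(brute)

    def test_gwas_overlap_empty_list_gives_p_one(self):
        geno, expr = _geo(
            [(f"sa{i}", "1", 100 + i) for i in range(2)] + [(f"sb{i}", "2", 100 + i) for i in range(2)],
            [("gA", "3", 1, 10), ("gB", "4", 1, 10), ("host", "1", 50, 500)],
        )
        real = self._quartets([("gA", "gB")])
        res = gwas_overlap_test(real, real, geno, set(), {g.gene_id: g for g in expr.genes})
        assert res["fisher_p"] == 1.0 and res["real_fraction"] == 0.0

    def test_gwas_overlap_full_coverage(self):
        geno, expr = _geo(
            [("sa0", "1", 100), ("sb0", "2", 100)],
            [("gA", "3", 1, 10), ("gB", "4", 1, 10),
             ("host1", "1", 50, 500), ("host2", "2", 50, 500)],
        )
        real = self._quartets([("gA", "gB")])
        spans = {g.gene_id: g for g in expr.genes}
        res = gwas_overlap_test(real, real, geno, {"host1", "host2"}, spans)
        assert res["real_fraction"] == 1.0
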