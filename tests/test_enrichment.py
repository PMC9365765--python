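from math import comb

import numpy as np
import pytest

from coreperiphery import (
    Partition,
    bh_fdr,
    enrich_cluster,
    enrichment_fold,
    hypergeom_upper,
    regroup_control,
    summarize_cells,
    term_table_v,
)


class TestHypergeomUpper:
    def test_exact_enumeration_small(self):
        # P(X >= 4) = C(4,4) C(6,1) / C(10,5)
        assert hypergeom_upper(10, 4, 5, 4) == pytest.approx(6 / 252)

    def test_zero_overlap_certain(self):
        assert hypergeom_upper(100, 10, 20, 0) == 1.0

    def test_single_outcome(self):
        assert hypergeom_upper(20, 5, 5, 5) == pytest.approx(1 / comb(20, 5))

    def test_tail_by_summation(self):
        N, B, n = 30, 8, 12
        for b in range(1, 9):
            expected = sum(
                comb(B, x) * comb(N - B, n - x) / comb(N, n) for x in range(b, min(B, n) + 1)
            )
            assert hypergeom_upper(N, B, n, b) == pytest.approx(expected, rel=1e-10)

    def test_monotone_in_overlap(self):
        ps = [hypergeom_upper(100, 20, 30, b) for b in range(0, 21)]
        assert all(a >= b for a, b in zip(ps, ps[1:]))

    def test_inconsistent_counts_rejected(self):
        with pytest.raises(ValueError):
            hypergeom_upper(10, 4, 5, 6)


class TestEnrichmentFold:
    @pytest.mark.parametrize(
        "b,B,n,N,printed",
        [
            (51, 75, 212, 745, 2.38),   # chromatin organization
            (33, 48, 212, 745, 2.41),   # histone modification
            (107, 251, 212, 745, 1.49), # regulation of gene expression
            (15, 15, 326, 745, 2.3),    # membrane depolarization
        ],
    )
    def test_reported_folds(self, b, B, n, N, printed):
        fold = enrichment_fold(N, B, n, b)
        assert fold == pytest.approx((b / n) / (B / N), rel=1e-12)
        assert abs(fold - printed) / printed < 0.011  # printed values are low-precision displays

    def test_no_enrichment_is_one(self):
        assert enrichment_fold(100, 10, 50, 5) == pytest.approx(1.0)

    def test_degenerate_rejected(self):
        with pytest.raises(ValueError):
            enrichment_fold(100, 0, 50, 0)
        with pytest.raises(ValueError):
            enrichment_fold(100, 10, 0, 0)

    def test_fold_p_coherence(self):
        # fold > 1 exactly when the target fraction beats the background fraction
        rng = np.random.default_rng(0)
        for _ in range(50):
            N = int(rng.integers(20, 200))
            B = int(rng.integers(1, N))
            n = int(rng.integers(1, N))
            b = int(rng.integers(0, min(B, n) + 1))
            if b == 0:
                continue
            fold = enrichment_fold(N, B, n, b)
            assert (fold > 1) == (b / n > B / N)


def brute_force_bh(pvals):
    m = len(pvals)
    order = sorted(range(m), key=lambda i: pvals[i])
    q = [0.0] * m
    running = 1.0
    for rank in range(m, 0, -1):
        i = order[rank - 1]
        running = min(running, pvals[i] * m / rank)
        q[i] = running
    return q


class TestBhFdr:
    def test_single_p_unchanged(self):
        assert bh_fdr([0.03]) == [0.03]

    def test_hand_computed_cases(self):
        assert bh_fdr([0.01, 0.02, 0.03, 0.04]) == pytest.approx([0.04] * 4)
        assert bh_fdr([0.001, 0.5]) == pytest.approx([0.002, 0.5])

    def test_matches_brute_force_on_random_vectors(self):
        rng = np.random.default_rng(42)
        for _ in range(1000):
            p = rng.random(int(rng.integers(1, 40))).tolist()
            assert bh_fdr(p) == pytest.approx(brute_force_bh(p), rel=1e-12)

    def test_matches_statsmodels(self):
        from statsmodels.stats.multitest import multipletests

        rng = np.random.default_rng(7)
        p = rng.random(25)
        q_sm = multipletests(p, method="fdr_bh")[1]
        assert bh_fdr(p.tolist()) == pytest.approx(q_sm.tolist(), rel=1e-12)

    def test_family_size_override(self):
        assert bh_fdr([0.01], m=10) == pytest.approx([0.1])
        with pytest.raises(ValueError):
            bh_fdr([0.1, 0.2], m=1)

    def test_q_at_least_p(self):
        rng = np.random.default_rng(9)
        p = rng.random(30).tolist()
        assert all(q >= pi - 1e-15 for q, pi in zip(bh_fdr(p), p))


def make_annotations():
    signal = frozenset(f"t{i}" for i in range(15))
    noise = frozenset(f"t{i}" for i in range(5, 10)) | frozenset(f"u{i}" for i in range(10))
    return {
        "SIG": ("signal", signal),
        "NOISE": ("noise", noise),
        "ABSENT": ("not in background", frozenset({"zzz"})),
    }


class TestEnrichCluster:
    def test_signal_detected_noise_not(self):
        background = {f"t{i}" for i in range(20)} | {f"u{i}" for i in range(80)}
        target = {f"t{i}" for i in range(20)}
        records, overlaps = enrich_cluster(target, background, make_annotations())
        by_id = {r.term_id: r for r in records}
        assert "ABSENT" not in by_id  # zero background members -> not tested
        assert by_id["SIG"].significant
        assert by_id["SIG"].b == 15
        assert overlaps["SIG"] == frozenset(f"t{i}" for i in range(15))
        assert not by_id["NOISE"].significant

    def test_target_equals_background(self):
        background = {f"t{i}" for i in range(20)}
        records, _ = enrich_cluster(background, background, make_annotations())
        assert all(r.fold == pytest.approx(1.0) for r in records if r.b > 0)
        assert not any(r.significant for r in records)

    def test_records_sorted_by_q(self):
        background = {f"t{i}" for i in range(20)} | {f"u{i}" for i in range(80)}
        records, _ = enrich_cluster({f"t{i}" for i in range(20)}, background, make_annotations())
        qs = [r.q for r in records]
        assert qs == sorted(qs)

    def test_empty_target_rejected(self):
        with pytest.raises(ValueError):
            enrich_cluster(set(), {"a"}, make_annotations())

    def test_target_outside_background_rejected(self):
        with pytest.raises(ValueError):
            enrich_cluster({"a"}, {"b"}, make_annotations())


class TestSummarizeCells:
    def test_union_semantics(self):
        from coreperiphery.enrichment import EnrichmentRecord

        rec = lambda tid, q: EnrichmentRecord(
            term_id=tid, term_name=tid, N=100, B=10, n=20, b=5,
            fold=2.0, p=1e-5, q=q, significant=True,
        )
        cell_genes = {"CC1": {f"g{i}" for i in range(1, 12)}}
        overlaps = {
            "CC1": {
                "T1": frozenset(f"g{i}" for i in range(1, 6)),
                "T2": frozenset(f"g{i}" for i in range(3, 9)),
            }
        }
        out = summarize_cells(cell_genes, {"CC1": [rec("T1", 0.01), rec("T2", 0.001)]}, overlaps)
        assert out[0].genes_enriched == 8  # union of g1..g5 and g3..g8, not 11
        assert out[0].n_terms == 2
        assert out[0].median_neglog_q == pytest.approx(np.median([-np.log10(0.01), -np.log10(0.001)]))

    def test_no_significant_terms(self):
        out = summarize_cells({"CC1": {"a", "b"}}, {}, {})
        assert out[0].n_terms == 0
        assert out[0].median_neglog_q is None
        assert out[0].enriched_ratio == 0.0

    def test_ratio(self):
        from coreperiphery.enrichment import EnrichmentRecord

        rec = EnrichmentRecord(
            term_id="T", term_name="T", N=745, B=30, n=100, b=12,
            fold=2.0, p=1e-6, q=1e-4, significant=True,
        )
        genes = {f"g{i}" for i in range(100)}
        overlaps = {"CC4:FC4": {"T": frozenset(f"g{i}" for i in range(12))}}
        out = summarize_cells({"CC4:FC4": genes}, {"CC4:FC4": [rec]}, overlaps)
        assert out[0].enriched_ratio == pytest.approx(0.12)


class TestRegroupControl:
    def make_clusters(self):
        membership = {f"t{i}": 0 for i in range(20)}
        membership.update({f"u{i}": 1 for i in range(20)})
        return Partition(membership=membership)

    def test_replicate_counts(self):
        ctrl = regroup_control(self.make_clusters(), make_annotations(), n_replicates=10, seed=0)
        assert len(ctrl.terms_per_replicate) == 10
        assert len(ctrl.genes_per_replicate) == 10

    def test_annotation_free_universe_all_zero(self):
        ann = {"X": ("elsewhere", frozenset({"zzz"}))}
        ctrl = regroup_control(self.make_clusters(), ann, n_replicates=3, seed=0)
        assert ctrl.terms_per_replicate == (0, 0, 0)
        assert ctrl.mean_genes == 0.0

    def test_regrouped_below_true_clustering(self):
        clusters = self.make_clusters()
        ann = make_annotations()
        background = set(clusters.membership)
        true_terms = 0
        for genes in clusters.communities():
            records, _ = enrich_cluster(set(genes), background, ann)
            true_terms += sum(r.significant for r in records)
        ctrl = regroup_control(clusters, ann, n_replicates=10, seed=1)
        assert ctrl.mean_terms < true_terms


class TestTermTableV:
    def test_diagonal_concentration_is_one(self):
        assert term_table_v(np.array([[5.0, 0.0], [0.0, 7.0]])).v == pytest.approx(1.0)

    def test_uniform_counts_zero(self):
        assert term_table_v(np.array([[3.0, 3.0], [3.0, 3.0]])).v == pytest.approx(0.0)

    def test_mapping_input_matches_matrix(self):
        counts = {"CC1:FC1": 4, "CC1:FC2": 1, "CC2:FC1": 0, "CC2:FC2": 6}
        v_map = term_table_v(counts, shape=(2, 2)).v
        v_mat = term_table_v(np.array([[4.0, 1.0], [0.0, 6.0]])).v
        assert v_map == pytest.approx(v_mat)

    def test_degenerate_rejected(self):
        with pytest.raises(ValueError):
            term_table_v(np.array([[3.0, 3.0]]))
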