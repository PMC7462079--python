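"""Pair enumeration, per-fragment joint classification, Fisher/BH, regression."""

import math
from math import comb

import numpy as np
import pysam
import pytest
from hypothesis import given, settings, strategies as st

from edsplice.cooccur import (
    JointCounts,
    bh_adjust,
    classify_fragment,
    enumerate_pairs,
    fisher_exact,
    levels_and_regression,
    run_cooccurrence,
    CooccurrencePair,
)
from edsplice.genome_io import SiteDef, SpliceSite, derive_splice_sites


def brute_force_fisher(table) -> float:
    """Independent oracle: enumerate every 2x2 table with the observed
    margins and sum the probabilities of those no more probable than the
    observed one (with the customary 1+1e-7 tie tolerance)."""
    (a, b), (c, d) = table
    r1, c1, n = a + b, a + c, a + b + c + d
    denom = comb(n, c1)

    def prob(k):
        if k < 0 or k > r1 or c1 - k < 0 or c1 - k > n - r1:
            return 0.0
        return comb(r1, k) * comb(n - r1, c1 - k) / denom

    p_obs = prob(a)
    return sum(p for k in range(0, min(r1, c1) + 1)
               if (p := prob(k)) <= p_obs * (1 + 1e-7))


def make_pair(boundary=100, intron=(100, 300), site_pos=98, strand="+",
              kind="donor", context=None):
    ss = SpliceSite("chrT", strand, kind, boundary, intron[0], intron[1], "t")
    offset = (boundary - site_pos) if strand == "+" else (site_pos - boundary)
    if context is None:
        context = "intronic" if intron[0] <= site_pos < intron[1] else "exonic"
    return CooccurrencePair(ss, SiteDef("chrT", site_pos, strand, "es"),
                            offset, context)


def make_read(start, cigar, seq, header=None):
    header = header or pysam.AlignmentHeader.from_dict(
        {"HD": {"VN": "1.6"}, "SQ": [{"SN": "chrT", "LN": 100000}]}
    )
    a = pysam.AlignedSegment(header)
    a.query_name = "frag"
    a.reference_id = 0
    a.reference_start = start
    a.mapping_quality = 60
    a.cigartuples = cigar
    a.query_sequence = seq
    a.query_qualities = pysam.qualitystring_to_array("I" * len(seq))
    return a


class TestEnumeratePairs:
    def setup_method(self):
        self.ss = [SpliceSite("chrT", "+", "donor", 100, 100, 300, "t")]

    def test_exonic_site_two_nt_upstream(self):
        pairs = enumerate_pairs(self.ss, [SiteDef("chrT", 98, "+", "es")], 50)
        (p,) = pairs
        assert p.es_offset == 2 and p.site_context == "exonic"

    def test_site_beyond_window_not_paired(self):
        assert enumerate_pairs(self.ss, [SiteDef("chrT", 151, "+", "es")], 50) == []

    def test_window_zero_pairs_only_the_boundary_base(self):
        on = enumerate_pairs(self.ss, [SiteDef("chrT", 100, "+", "es")], 0)
        off = enumerate_pairs(self.ss, [SiteDef("chrT", 101, "+", "es")], 0)
        assert len(on) == 1 and on[0].es_offset == 0 and off == []

    def test_conflicting_strand_skipped_with_warning(self, caplog):
        import logging

        with caplog.at_level(logging.WARNING, logger="edsplice.cooccur"):
            pairs = enumerate_pairs(self.ss, [SiteDef("chrT", 98, "-", "es")], 50)
        assert pairs == [] and "conflict" in caplog.text


class TestClassifyFragment:
    def test_spliced_edited_exonic(self):
        pair = make_pair()
        read = make_read(50, [(0, 50), (3, 200), (0, 50)],
                         "A" * 48 + "G" + "A" * 51)  # site 98 -> query 48
        label, _ = classify_fragment([read], pair)
        assert label == "spliced_edited"

    def test_unspliced_unedited(self):
        pair = make_pair()
        read = make_read(50, [(0, 100)], "A" * 100)
        label, _ = classify_fragment([read], pair)
        assert label == "unspliced_unedited"

    def test_intronic_site_mode_contract(self):
        pair = make_pair(site_pos=150)  # intronic
        spliced = make_read(50, [(0, 50), (3, 200), (0, 50)], "A" * 100)
        label, reason = classify_fragment([spliced], pair, mode="strict")
        assert label is None and reason == "intronic_unobservable"
        label, _ = classify_fragment([spliced], pair, mode="absence_as_unedited")
        assert label == "spliced_unedited"

    def test_short_anchor_excluded(self):
        pair = make_pair()
        read = make_read(97, [(0, 3), (3, 200), (0, 97)], "A" * 100)
        label, reason = classify_fragment([read], pair)
        assert label is None

    def test_novel_junction_tallied(self):
        pair = make_pair()
        read = make_read(50, [(0, 50), (3, 150), (0, 50)], "A" * 100)
        label, reason = classify_fragment([read], pair)
        assert label is None and reason == "novel_junction"

    def test_other_annotated_junction_not_novel(self):
        pair = make_pair()
        read = make_read(350, [(0, 20), (3, 100), (0, 20)], "A" * 40)
        label, reason = classify_fragment(
            [read], pair, annotated_introns=frozenset({(370, 470)})
        )
        assert label is None and reason == "uninformative_splice"

    def test_every_fragment_gets_label_or_reason(self):
        pair = make_pair()
        reads = [
            make_read(50, [(0, 50), (3, 200), (0, 50)], "A" * 100),
            make_read(50, [(0, 100)], "C" * 100),
            make_read(500, [(0, 100)], "A" * 100),
            make_read(97, [(0, 3), (3, 200), (0, 3)], "A" * 6),
        ]
        for r in reads:
            label, reason = classify_fragment([r], pair)
            assert (label in {"spliced_edited", "spliced_unedited",
                              "unspliced_edited", "unspliced_unedited"}) ^ bool(reason)


class TestFisher:
    def test_diagonal_table_small_p_and_corrected_or(self):
        res = fisher_exact(JointCounts(n_se=5, n_su=0, n_ue=0, n_uu=5))
        assert res.p == pytest.approx(2 / 252, abs=1e-12)
        assert res.odds_ratio == pytest.approx(121.0)

    def test_flat_table_p_one(self):
        res = fisher_exact(JointCounts(n_se=1, n_su=1, n_ue=1, n_uu=1))
        assert res.p == pytest.approx(1.0)

    def test_transpose_symmetry(self):
        a = fisher_exact(JointCounts(n_se=7, n_su=2, n_ue=3, n_uu=9))
        b = fisher_exact(JointCounts(n_se=7, n_su=3, n_ue=2, n_uu=9))
        assert a.p == pytest.approx(b.p, abs=1e-12)

    def test_zero_margin_is_untestable_not_p_one(self):
        res = fisher_exact(JointCounts(n_se=0, n_su=0, n_ue=3, n_uu=9))
        assert not res.testable and math.isnan(res.p)
        assert "margin" in res.reason

    def test_agrees_with_enumeration_oracle(self):
        rng = np.random.default_rng(42)
        for _ in range(200):
            cells = rng.multinomial(int(rng.integers(1, 31)),
                                    rng.dirichlet(np.ones(4)))
            jc = JointCounts(*map(int, cells))
            res = fisher_exact(jc)
            if not res.testable:
                continue
            expected = brute_force_fisher(jc.table())
            assert res.p == pytest.approx(expected, abs=1e-12)


class TestBH:
    def test_hand_stepped_example(self):
        np.testing.assert_allclose(bh_adjust([0.01, 0.02, 0.03]),
                                   [0.03, 0.03, 0.03])

    def test_single_p_unchanged(self):
        assert bh_adjust([0.2])[0] == pytest.approx(0.2)

    def test_constant_vector_unchanged(self):
        np.testing.assert_allclose(bh_adjust([0.4] * 5), [0.4] * 5)

    def test_q_never_below_p(self):
        rng = np.random.default_rng(1)
        p = rng.uniform(size=50)
        assert (bh_adjust(p) >= p - 1e-15).all()

    @settings(derandomize=True, max_examples=100)
    @given(st.lists(st.floats(0.0, 1.0), min_size=1, max_size=40))
    def test_agrees_with_sort_cummin_oracle(self, p):
        p = np.asarray(p)
        order = np.argsort(p, kind="mergesort")
        m = len(p)
        ranked = p[order] * m / np.arange(1, m + 1)
        q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
        expected = np.empty(m)
        expected[order] = np.minimum(q_sorted, 1.0)
        np.testing.assert_allclose(bh_adjust(p), expected, atol=1e-12)


class TestRegression:
    def test_exact_line(self):
        per_sample = {
            "a": JointCounts(n_se=0, n_su=20, n_ue=0, n_uu=80),    # eps 0.0 psi 0.2
            "b": JointCounts(n_se=25, n_su=20, n_ue=25, n_uu=30),  # eps 0.5 psi 0.45
            "c": JointCounts(n_se=70, n_su=0, n_ue=30, n_uu=0),    # eps 1.0 psi 0.7
        }
        res = levels_and_regression(per_sample, {"a": "WT", "b": "WT", "c": "KO"})
        assert res.slope == pytest.approx(0.5)
        assert res.intercept == pytest.approx(0.2)
        assert res.r2 == pytest.approx(1.0)

    def test_single_sample_is_an_error(self):
        with pytest.raises(ValueError, match=">= 2 samples"):
            levels_and_regression({"a": JointCounts(n_se=5, n_su=5)}, {})

    def test_zero_editing_variance_flagged_not_raised(self):
        per_sample = {
            "a": JointCounts(n_se=5, n_su=5, n_ue=5, n_uu=5),
            "b": JointCounts(n_se=6, n_su=6, n_ue=4, n_uu=4),
        }
        res = levels_and_regression(per_sample, {})
        assert not res.defined and math.isnan(res.slope)


class TestRunCooccurrence:
    def test_fixture_pairs_recover_truth_direction(self, fixture_run):
        layout = fixture_run["layout"]
        from edsplice.genome_io import load_gene_models

        models = load_gene_models(str(fixture_run["dir"] / "models.gtf"))
        splice_sites = [s for m in models for s in derive_splice_sites(m)]
        sites = [s.as_sitedef() for s in layout.sites]
        pairs = enumerate_pairs(splice_sites, sites, 50)
        res = run_cooccurrence(fixture_run["bams"], pairs,
                               fixture_run["genotypes"], models=models)
        assert len(res) == len(pairs)
        by_site = res.set_index("site_name")
        # strong positive coupling (theta=6) -> OR > 1, strong negative -> < 1
        assert by_site.loc["siteA", "odds_ratio"] > 1
        assert by_site.loc["siteB", "odds_ratio"] < 1
        # regression slope sign follows the coupling of the exonic pairs
        assert by_site.loc["siteA", "slope"] > 0
        assert by_site.loc["siteB", "slope"] < 0
        # classification completeness: informative + excluded fragments > 0
        tot = (by_site[["n_se", "n_su", "n_ue", "n_uu"]].sum(axis=1)
               + by_site["n_excluded"])
        assert (tot > 0).all()
        # q is BH over the testable pairs, so q >= p
        t = res[res["testable"]]
        assert (t["q"] >= t["fisher_p"] - 1e-15).all()

    def test_empty_pair_list_is_empty_success(self, fixture_run):
        res = run_cooccurrence(fixture_run["bams"], [],
                               fixture_run["genotypes"])
        assert len(res) == 0
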