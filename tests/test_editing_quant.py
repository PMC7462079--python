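"""Pileup counting, the coverage/replicate/SNP filters, and Welch calling."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from edsplice.editing_quant import (
    call_differential,
    editing_level_matrix,
    filter_sites,
    quantify_editing,
    remove_snps,
    welch_test,
)
from edsplice.genome_io import SiteDef, SnpSet
from edsplice.simdata import (GeneSpec, SimDesign, SiteSpec, simulate_all,
                              sample_names)

GROUPS = {"WT": ["WT1", "WT2", "WT3"], "KO": ["KO1", "KO2", "KO3"]}


def counts_frame(per_sample_cov, name="s", chrom="c", pos=100, strand="+",
                 edited_fraction=0.5):
    rows = []
    for sample, cov in per_sample_cov.items():
        e = int(round(cov * edited_fraction))
        rows.append({"name": name, "chrom": chrom, "pos": pos, "strand": strand,
                     "sample": sample, "edited": e, "unedited": cov - e,
                     "other": 0})
    return pd.DataFrame(rows)


class TestQuantify:
    def test_plus_strand_g_over_a(self, toy_bam_factory):
        # 4 G-fragments and 6 A-fragments over a + strand site at 50
        reads = [(f"g{i}", 0, 20, [(0, 60)], "A" * 30 + "G" + "A" * 29)
                 for i in range(4)]
        reads += [(f"a{i}", 0, 20, [(0, 60)], "A" * 60) for i in range(6)]
        bam = toy_bam_factory(reads)
        df = quantify_editing({"s1": bam}, [SiteDef("chrT", 50, "+", "site")])
        row = df.iloc[0]
        assert (row.edited, row.unedited, row.other) == (4, 6, 0)
        assert editing_level_matrix(df).loc["site", "s1"] == pytest.approx(0.4)

    def test_minus_strand_site_counts_c_as_edited(self, toy_bam_factory):
        reads = [(f"c{i}", 16, 20, [(0, 60)], "T" * 30 + "C" + "T" * 29)
                 for i in range(3)]
        reads += [(f"t{i}", 16, 20, [(0, 60)], "T" * 60) for i in range(7)]
        bam = toy_bam_factory(reads)
        df = quantify_editing({"s1": bam}, [SiteDef("chrT", 50, "-", "site")])
        row = df.iloc[0]
        assert (row.edited, row.unedited) == (3, 7)

    def test_non_a_g_bases_counted_as_other(self, toy_bam_factory):
        reads = [("x", 0, 20, [(0, 60)], "A" * 30 + "C" + "A" * 29),
                 ("y", 0, 20, [(0, 60)], "A" * 60)]
        bam = toy_bam_factory(reads)
        df = quantify_editing({"s1": bam}, [SiteDef("chrT", 50, "+", "site")])
        assert (df.iloc[0].other, df.iloc[0].unedited) == (1, 1)

    def test_non_a_reference_site_rejected(self, toy_bam_factory,
                                           toy_fasta_factory):
        fa = toy_fasta_factory({"chrT": "ACGT" * 25})
        bam = toy_bam_factory([("x", 0, 0, [(0, 20)], "A" * 20)])
        with pytest.raises(ValueError, match="badsite"):
            quantify_editing({"s1": bam}, [SiteDef("chrT", 1, "+", "badsite")],
                             genome=fa)

    def test_simulated_level_within_binomial_error(self, tmp_path):
        eps, cov = 0.25, 400
        design = SimDesign(
            seed=13, n_wt=1, n_ko=1, coverage=cov,
            genes=(GeneSpec("g", "+", (150, 150), (120,)),),
            sites=(SiteSpec("s", "g", offset=2, eps_wt=eps, eps_ko=eps,
                            psi_wt=0.7, psi_ko=0.7),),
        )
        layout, _ = simulate_all(design, tmp_path)
        bams = {s: str(tmp_path / f"{s}.bam") for s in sample_names(design)}
        df = quantify_editing(bams, [layout.sites[0].as_sitedef()],
                              genome=str(tmp_path / "genome.fa"))
        levels = editing_level_matrix(df)
        tol = 3 * np.sqrt(eps * (1 - eps) / cov)
        for level in levels.iloc[0]:
            assert abs(level - eps) < tol

    def test_count_conservation_per_site_and_sample(self, fixture_run):
        df = quantify_editing(
            fixture_run["bams"],
            [s.as_sitedef() for s in fixture_run["layout"].sites],
        )
        # every counted fragment lands in exactly one of the three tallies
        assert (df[["edited", "unedited", "other"]] >= 0).all().all()
        assert (df["edited"] + df["unedited"] + df["other"] > 0).all()


class TestFilters:
    def test_five_reads_in_two_of_three_kept(self):
        df = counts_frame({"WT1": 5, "WT2": 5, "WT3": 0,
                           "KO1": 5, "KO2": 5, "KO3": 5})
        assert filter_sites(df, GROUPS)["name"].nunique() == 1

    def test_single_qualifying_wt_sample_dropped(self):
        df = counts_frame({"WT1": 5, "WT2": 4, "WT3": 4,
                           "KO1": 9, "KO2": 9, "KO3": 9})
        assert len(filter_sites(df, GROUPS)) == 0

    def test_min_cov_one_is_identity(self):
        df = counts_frame({s: 2 for g in GROUPS.values() for s in g})
        out = filter_sites(df, GROUPS, min_cov=1)
        pd.testing.assert_frame_equal(out.reset_index(drop=True), df)

    def test_empty_group_is_an_error(self):
        df = counts_frame({"WT1": 5})
        with pytest.raises(ValueError, match="zero samples"):
            filter_sites(df, {"WT": [], "KO": ["KO1"]})

    def test_raising_min_cov_never_adds_sites(self):
        rng = np.random.default_rng(0)
        frames = []
        for i in range(30):
            covs = {s: int(rng.integers(0, 12))
                    for g in GROUPS.values() for s in g}
            frames.append(counts_frame(covs, name=f"s{i}"))
        df = pd.concat(frames, ignore_index=True)
        kept = [filter_sites(df, GROUPS, min_cov=c)["name"].nunique()
                for c in range(1, 12)]
        assert kept == sorted(kept, reverse=True)

    def test_remove_snps(self):
        df = pd.concat(
            [counts_frame({"WT1": 5}, name="hit", chrom="chr1", pos=100),
             counts_frame({"WT1": 5}, name="other_contig", chrom="chr2",
                          pos=100)],
            ignore_index=True,
        )
        out = remove_snps(df, SnpSet([("chr1", 100)]))
        assert set(out["name"]) == {"other_contig"}
        pd.testing.assert_frame_equal(remove_snps(df, SnpSet()), df)


class TestWelch:
    def test_closed_form_example(self):
        res = welch_test([0.4, 0.5, 0.6], [0.0, 0.1, 0.2])
        assert res.t == pytest.approx(4.89898, abs=1e-5)
        assert res.df == pytest.approx(4.0, abs=1e-9)
        assert res.p == pytest.approx(0.0080, abs=1e-3)

    def test_identical_groups_give_p_one(self):
        res = welch_test([0.1, 0.2, 0.3], [0.1, 0.2, 0.3])
        assert res.t == 0.0 and res.p == 1.0

    def test_label_swap_flips_t_keeps_p(self):
        a, b = [0.4, 0.5, 0.6], [0.0, 0.1, 0.2]
        r1, r2 = welch_test(a, b), welch_test(b, a)
        assert r1.t == pytest.approx(-r2.t)
        assert r1.p == pytest.approx(r2.p)

    def test_degenerate_variance_contracts(self):
        same = welch_test([0.2, 0.2], [0.2, 0.2])
        assert same.p == 1.0 and same.degenerate
        diff = welch_test([0.3, 0.3], [0.1, 0.1])
        assert diff.p == 0.0 and diff.degenerate

    def test_too_few_values_rejected(self):
        with pytest.raises(ValueError):
            welch_test([0.5], [0.1, 0.2])

    def test_matches_scipy_on_random_data(self):
        rng = np.random.default_rng(7)
        for _ in range(50):
            x = rng.normal(0, 1, size=rng.integers(3, 9))
            y = rng.normal(0.3, 2, size=rng.integers(3, 9))
            res = welch_test(x, y)
            ref = stats.ttest_ind(x, y, equal_var=False)
            assert res.t == pytest.approx(ref.statistic, rel=1e-12)
            assert res.p == pytest.approx(ref.pvalue, rel=1e-9)


class TestDifferentialCalling:
    def _frame(self, wt_levels, ko_levels, cov=10, name="s"):
        rows = []
        for g, levels in (("WT", wt_levels), ("KO", ko_levels)):
            for i, lv in enumerate(levels):
                rows.append({"name": name, "chrom": "c", "pos": 1, "strand": "+",
                             "sample": f"{g}{i + 1}",
                             "edited": int(round(lv * cov)),
                             "unedited": cov - int(round(lv * cov)), "other": 0})
        return pd.DataFrame(rows)

    def test_ko_drop_called_decrease(self):
        df = self._frame([0.4, 0.5, 0.6], [0.0, 0.1, 0.2])
        out = call_differential(df, GROUPS, alpha=0.1)
        assert out.iloc[0].cls == "decrease"
        assert out.iloc[0].delta == pytest.approx(-0.4)

    def test_p_above_alpha_is_steady(self):
        df = self._frame([0.4, 0.5, 0.6], [0.0, 0.1, 0.2])
        out = call_differential(df, GROUPS, alpha=0.005)
        assert out.iloc[0].cls == "steady"

    def test_insufficient_group_skipped_with_reason(self):
        df = self._frame([0.4, 0.5, 0.6], [0.1])
        out = call_differential(df, GROUPS)
        assert out.iloc[0].cls == "untested"
        assert "KO" in out.iloc[0].status

    def test_output_sorted_by_p(self):
        df = pd.concat(
            [self._frame([0.4, 0.5, 0.6], [0.0, 0.1, 0.2], name="strong"),
             self._frame([0.42, 0.5, 0.58], [0.38, 0.5, 0.55], name="weak")],
            ignore_index=True,
        )
        out = call_differential(df, GROUPS)
        tested = out[out.status.str.startswith("tested")]
        assert list(tested.p) == sorted(tested.p)
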