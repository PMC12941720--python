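"""GBS computation and the within-family comparative statistics, checked
against the published seven-member worked example and independent oracles."""

import numpy as np
import pandas as pd
import pytest

from famburden.burden import (
    BurdenError,
    BurdenTable,
    carrier_comparison,
    compute_gbs,
    contribution_percentages,
    gene_deltas,
    generation_summary,
    generation_trend,
    icc_oneway,
    relative_discordance,
    round_half_up,
    summarize,
)
from famburden.panel import GenotypeMatrix, VariantPanel, VariantRecord
from famburden.pedigree import load_pedigree


def _micro_panel():
    return VariantPanel(
        [
            VariantRecord("rs1", "1", 100, "A", "G", "G", "geneA"),
            VariantRecord("rs2", "1", 200, "A", "G", "G", "geneA"),
            VariantRecord("rs3", "1", 300, "C", "T", "T", "geneA"),
        ]
    )


def _micro_matrix(rows):
    samples = list(rows)
    calls = np.empty((len(samples), 3), dtype=object)
    for i, s in enumerate(samples):
        for j, c in enumerate(rows[s]):
            calls[i, j] = tuple(sorted(c)) if c else None
    return GenotypeMatrix(samples, ["rs1", "rs2", "rs3"], calls)


class TestComputeGbs:
    def test_hand_counted_micro_panel(self):
        gm = _micro_matrix({"s1": [("G", "G"), ("A", "G"), ("C", "C")]})
        bt = compute_gbs(gm, _micro_panel())
        assert bt.total("s1") == 3  # 2 + 1 + 0
        assert bt.gene_count("s1", "geneA") == 3

    def test_all_non_risk_and_all_risk(self):
        gm = _micro_matrix(
            {
                "none": [("A", "A"), ("A", "A"), ("C", "C")],
                "all": [("G", "G"), ("G", "G"), ("T", "T")],
            }
        )
        bt = compute_gbs(gm, _micro_panel())
        assert bt.total("none") == 0
        assert bt.total("all") == 2 * 3

    def test_missing_call_is_contract_violation(self):
        gm = _micro_matrix({"s1": [("G", "G"), None, ("C", "C")]})
        with pytest.raises(BurdenError, match="missing"):
            compute_gbs(gm, _micro_panel())

    def test_decomposition_identity_and_permutation_invariance(self, sim_family, sim_burden):
        bt = sim_burden
        for iid in bt.individuals:
            assert bt.total(iid) == sum(bt.gene_count(iid, g) for g in bt.genes)
            assert 0 <= bt.total(iid) <= 2 * len(sim_family.panel)
        # reorder samples and snps: identical outputs
        gm = sim_family.genotypes
        rev = gm.subset_samples(list(reversed(gm.samples)))
        panel_rev = VariantPanel(list(reversed(sim_family.panel.records)))
        bt2 = compute_gbs(rev, panel_rev)
        for iid in bt.individuals:
            assert bt2.total(iid) == bt.total(iid)
            for g in bt.genes:
                assert bt2.gene_count(iid, g) == bt.gene_count(iid, g)

    def test_matches_truth_haplotype_count(self, sim_family, sim_burden):
        # two independent counting paths: emitted genotypes vs truth haplotypes
        assert dict(sim_burden.totals) == sim_family.truth["true_totals"]


class TestSummarize:
    def test_family_totals(self, core):
        s = summarize(list(core.totals.values()), "family")
        assert round_half_up(s.mean) == 46.9
        assert round_half_up(s.sd) == 8.8
        assert (s.min, s.max) == (37, 61)

    def test_generation_two(self):
        s = summarize([41, 45])
        assert round_half_up(s.mean) == 43.0
        assert round_half_up(s.sd) == 2.8

    def test_constant_vector_sd_zero(self):
        assert summarize([5, 5, 5]).sd == 0

    def test_singleton_has_no_sd(self):
        s = summarize([7])
        assert s.sd is None and s.mean == 7

    def test_empty_rejected(self):
        with pytest.raises(BurdenError):
            summarize([])


class TestRelativeDiscordance:
    def test_sibling_pair(self):
        delta, rel = relative_discordance(37, 61)
        assert delta == 24
        assert round_half_up(rel) == 64.9

    @pytest.mark.parametrize("a,b,delta,rel", [(10, 10, 0, 0.0), (10, 15, 5, 50.0)])
    def test_simple_cases(self, a, b, delta, rel):
        d, r = relative_discordance(a, b)
        assert (d, r) == (delta, rel)

    def test_nonpositive_rejected(self):
        with pytest.raises(BurdenError):
            relative_discordance(0, 5)


class TestGeneDeltas:
    def test_identical_individuals_all_zero(self):
        counts = pd.DataFrame({"g1": [3, 3], "g2": [2, 2]}, index=["a", "b"])
        bt = BurdenTable(counts, {"g1": 5, "g2": 5})
        gd = gene_deltas(bt, "a", "b")
        assert (gd["signed_delta"] == 0).all()

    def test_signed_deltas_sum_to_total_delta(self, sim_burden):
        a, b = sim_burden.individuals[-2:]  # the sib pair
        gd = gene_deltas(sim_burden, a, b)
        assert gd["signed_delta"].sum() == sim_burden.total(b) - sim_burden.total(a)
        assert (gd["abs_delta"] >= gd["signed_delta"].abs()).all()

    def test_planted_differences(self):
        counts = pd.DataFrame({"g1": [1, 4], "g2": [5, 2]}, index=["a", "b"])
        bt = BurdenTable(counts, {"g1": 3, "g2": 3})
        gd = gene_deltas(bt, "a", "b")
        assert gd.loc["g1", "signed_delta"] == 3
        assert gd.loc["g2", "signed_delta"] == -3

    def test_unknown_id(self, sim_burden):
        with pytest.raises(BurdenError, match="unknown"):
            gene_deltas(sim_burden, "nope", sim_burden.individuals[0])


class TestContributionPercentages:
    def test_published_family_means(self, core):
        pct = contribution_percentages(core.gene_means, core.total_mean_display)
        rounded = {g: round_half_up(v) for g, v in pct.items()}
        assert rounded == {
            "CR1": 38.6,
            "PICALM": 20.0,
            "ABCA7": 13.0,
            "CLU": 11.3,
            "BIN1": 10.7,
            "APOE": 6.2,
        }

    def test_full_share(self):
        assert contribution_percentages({"g": 5.0}, 5.0)["g"] == 100.0

    def test_sums_to_hundred_when_total_is_sum(self):
        means = {"a": 3.0, "b": 7.0}
        pct = contribution_percentages(means, 10.0)
        assert sum(pct.values()) == pytest.approx(100.0)

    def test_nonpositive_total_rejected(self):
        with pytest.raises(BurdenError):
            contribution_percentages({"g": 1.0}, 0.0)


class TestCarrierComparison:
    def test_published_carrier_split(self, core):
        bt = BurdenTable.from_totals(core.totals)
        cc = carrier_comparison(bt, core.carrier_flags)
        assert round_half_up(cc.carriers.mean) == 48.3
        assert round_half_up(cc.carriers.sd) == 11.4
        assert round_half_up(cc.non_carriers.mean) == 45.8
        assert round_half_up(cc.non_carriers.sd) == 8.1
        assert round_half_up(cc.mean_difference) == 2.6

    def test_identical_groups_zero_difference(self):
        bt = BurdenTable.from_totals({"a": 10, "b": 10, "c": 10, "d": 10})
        cc = carrier_comparison(bt, {"a": True, "b": True, "c": False, "d": False})
        assert cc.mean_difference == 0

    def test_singleton_groups(self):
        bt = BurdenTable.from_totals({"a": 10, "b": 20})
        cc = carrier_comparison(bt, {"a": True, "b": False})
        assert cc.carriers.mean == 10 and cc.carriers.sd is None
        assert cc.non_carriers.mean == 20 and cc.non_carriers.sd is None

    def test_empty_group_rejected(self):
        bt = BurdenTable.from_totals({"a": 10})
        with pytest.raises(BurdenError):
            carrier_comparison(bt, {"a": True})


class TestGenerationSummary:
    def test_published_generation_summaries(self, core, core_family_ped):
        ped = load_pedigree(core_family_ped)
        bt = BurdenTable.from_totals(core.totals)
        g1, g2, g3 = generation_summary(bt, ped)
        assert (round_half_up(g1.mean), round_half_up(g1.sd)) == (48.0, 7.9)
        assert (g1.min, g1.max) == (39, 54)
        assert (round_half_up(g2.mean), round_half_up(g2.sd)) == (43.0, 2.8)
        assert (g2.min, g2.max) == (41, 45)
        assert (round_half_up(g3.mean), round_half_up(g3.sd)) == (49.0, 17.0)
        assert (g3.min, g3.max) == (37, 61)

    def test_single_generation(self, core_family_ped):
        ped = load_pedigree(core_family_ped)
        bt = BurdenTable.from_totals({"J-003": 10, "J-005": 12, "J-006": 14})
        out = generation_summary(bt, ped)
        assert len(out) == 1 and out[0].n == 3


class TestIcc:
    def test_zero_within_group_variance(self):
        res = icc_oneway([10, 10, 20, 20], ["a", "a", "b", "b"])
        assert res.icc == pytest.approx(1.0)
        assert res.msw == 0

    def test_hand_anova(self):
        res = icc_oneway([1, 2, 3, 4], ["a", "a", "b", "b"])
        assert res.msb == pytest.approx(4.0)
        assert res.msw == pytest.approx(0.5)
        assert res.icc == pytest.approx(0.7778, abs=1e-4)

    def test_matches_pingouin_balanced(self):
        import pingouin as pg

        vals = [1.0, 2.0, 3.0, 4.0, 5.0, 6.0]
        groups = ["a", "a", "b", "b", "c", "c"]
        ours = icc_oneway(vals, groups).icc
        df = pd.DataFrame(
            {"targets": groups, "raters": ["r1", "r2"] * 3, "ratings": vals}
        )
        ref = pg.intraclass_corr(df, "targets", "raters", "ratings")
        theirs = float(ref.loc[ref["Type"] == "ICC(1,1)", "ICC"].iloc[0])
        assert ours == pytest.approx(theirs)

    def test_matches_statsmodels_mean_squares_unbalanced(self, core):
        import statsmodels.api as sm
        import statsmodels.formula.api as smf

        vals = list(core.totals.values())
        gens = [core.generations[i] for i in core.totals]
        ours = icc_oneway(vals, gens)
        df = pd.DataFrame({"v": vals, "g": gens})
        table = sm.stats.anova_lm(smf.ols("v ~ C(g)", data=df).fit())
        assert ours.msb == pytest.approx(table.loc["C(g)", "mean_sq"])
        assert ours.msw == pytest.approx(table.loc["Residual", "mean_sq"])

    def test_shuffled_groups_center_near_zero(self, rng):
        vals = rng.normal(size=30)
        iccs = []
        for _ in range(200):
            groups = rng.permutation(np.repeat(["a", "b", "c"], 10))
            iccs.append(icc_oneway(vals, groups).icc)
        assert abs(float(np.mean(iccs))) < 0.1

    def test_empty_group_rejected(self):
        with pytest.raises(BurdenError):
            icc_oneway([1, 2], ["a", "a"])


class TestGenerationTrend:
    def test_constant_values_zero_slope(self):
        t = generation_trend([5, 5, 5, 5], [1, 1, 2, 3])
        assert t.slope == 0 and t.r == 0

    def test_exactly_linear(self):
        t = generation_trend([2, 4, 6], [1, 2, 3])
        assert t.slope == pytest.approx(2.0)
        assert t.r == pytest.approx(1.0)

    def test_closed_form_on_family_layout(self, core):
        vals = np.array(list(core.totals.values()), dtype=float)
        gens = np.array([core.generations[i] for i in core.totals], dtype=float)
        t = generation_trend(vals, gens)
        slope = ((gens - gens.mean()) * (vals - vals.mean())).sum() / (
            (gens - gens.mean()) ** 2
        ).sum()
        assert t.slope == pytest.approx(slope)
        assert t.intercept == pytest.approx(vals.mean() - slope * gens.mean())

    def test_identical_generations_rejected(self):
        with pytest.raises(BurdenError):
            generation_trend([1, 2], [1, 1])
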