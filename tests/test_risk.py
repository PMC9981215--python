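"""Gene groups, ELN classification, enhanced scheme and outcome evaluation."""

import itertools
import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from panmyeloid.cohort import MutationEvent, PatientRecord
from panmyeloid.risk import (
    AxisGeneGroups,
    aml_analysis_subset,
    assign_axis_groups,
    assign_risk,
    cr_flag,
    eln2017_classify,
    eln_enhanced,
    eln_from_record,
    evaluate_binary,
    evaluate_survival,
    fisher_exact_2x2,
    mdseb_stratify,
    mutation_load,
)


def mk_patient(pid="p", dx="AML", age=40.0, genes=(), flags=None, **kw):
    return PatientRecord(
        pid, dx, age,
        karyotype_flags=flags or {},
        mutation_events=[MutationEvent(pid, g) for g in genes],
        **kw,
    )


class TestAxisGroups:
    CLUSTERS = {
        "C0": ["JAK2"],
        "C1": ["ASXL1", "SRSF2"],
        "C2": ["TET2", "DNMT3A"],
        "C3": ["NRAS", "NPM1"],
    }
    RATES = {
        "JAK2": 0.002, "ASXL1": 0.10, "SRSF2": 0.005, "TET2": 0.14,
        "DNMT3A": 0.13, "NRAS": 0.15, "NPM1": 0.10,
    }

    def groups(self):
        return assign_axis_groups(
            self.CLUSTERS, ["C0", "C1", "C2", "C3"], self.RATES
        )

    def test_leftmost_cluster_is_L_regardless_of_rate(self):
        g = self.groups()
        assert g.mapping["JAK2"] == "L"  # rate 0.2% but L is exempt

    def test_low_rate_gene_in_middle_block_falls_to_other(self):
        g = self.groups()
        assert g.mapping["SRSF2"] == "other"  # 0.5% < 1% filter
        assert g.mapping["ASXL1"] == "ML"

    def test_rightmost_block_with_sufficient_rate_is_R(self):
        g = self.groups()
        assert g.mapping["NRAS"] == "R"
        assert g.mapping["TET2"] == "MR"

    def test_mapping_partitions_all_genes(self):
        g = self.groups()
        assert set(g.mapping) == {x for genes in self.CLUSTERS.values() for x in genes}
        assert sum(g.sizes.values()) == len(g.mapping)

    def test_gene_missing_from_spectra_rejected(self):
        rates = dict(self.RATES)
        del rates["NPM1"]
        with pytest.raises(KeyError, match="NPM1"):
            assign_axis_groups(self.CLUSTERS, ["C0", "C1", "C2", "C3"], rates)


class TestMutationLoad:
    def test_rmr_load_sums_events_across_groups(self):
        g = AxisGeneGroups(mapping={"NRAS": "R", "TET2": "MR", "ASXL1": "ML"})
        p = mk_patient(genes=["NRAS", "NRAS", "TET2", "ASXL1"])
        assert mutation_load(p, g, "R+MR") == 3
        assert mutation_load(p, g, "L+ML") == 1

    def test_no_events_zero_load(self):
        g = AxisGeneGroups(mapping={"NRAS": "R"})
        assert mutation_load(mk_patient(), g, "R+MR") == 0

    def test_eln_counted_gene_counted_again_in_load(self):
        # NPM1 drives the ELN class AND counts in the R+MR load
        g = AxisGeneGroups(mapping={"NPM1": "R"})
        p = mk_patient(genes=["NPM1"])
        assert eln_from_record(p) == "Favorable"
        assert mutation_load(p, g, "R+MR") == 1


class TestELN2017:
    def test_core_bullet_lookups(self):
        assert eln2017_classify({"t(8;21)": 1}, set()) == "Favorable"
        assert eln2017_classify({}, {"TP53"}) == "Adverse"
        assert eln2017_classify({}, set()) == "Intermediate"

    def test_npm1_flt3_interaction(self):
        assert eln2017_classify({}, {"NPM1"}) == "Favorable"
        assert eln2017_classify({}, {"NPM1", "FLT3"}, flt3_itd_class="low") == "Favorable"
        assert eln2017_classify({}, {"NPM1", "FLT3"}, flt3_itd_class="high") == "Intermediate"
        assert eln2017_classify({}, {"FLT3"}, flt3_itd_class="high") == "Adverse"

    def test_cebpa_biallelic_favorable(self):
        assert eln2017_classify({}, set(), cebpa_class="dm") == "Favorable"
        assert eln2017_classify({}, set(), cebpa_class="sm") == "Intermediate"

    def test_runx1_asxl1_suppressed_by_favorable_subtype(self):
        assert eln2017_classify({"t(8;21)": 1}, {"RUNX1"}) == "Favorable"
        assert eln2017_classify({}, {"RUNX1"}) == "Adverse"

    def test_adverse_cytogenetics_take_precedence(self):
        assert eln2017_classify({"t(8;21)": 1, "complex": 1}, set()) == "Adverse"

    def test_adverse_karyotype_lesions(self):
        for lesion in ("-7", "inv(3)", "abn(17p)", "monosomal", "t(6;9)"):
            assert eln2017_classify({lesion: 1}, set()) == "Adverse"


class TestEnhancedScheme:
    @pytest.mark.parametrize(
        "eln, load, expected",
        [
            ("Favorable", 0, 1),
            ("Favorable", 2, 1),
            ("Favorable", 3, 2),
            ("Intermediate", 1, 2),
            ("Intermediate", 2, 2),
            ("Intermediate", 3, 3),
            ("Adverse", 0, 3),
            ("Adverse", 5, 3),
        ],
    )
    def test_rule_table(self, eln, load, expected):
        assert eln_enhanced(eln, load) == expected

    def test_monotone_in_load_and_class(self):
        order = {"Favorable": 0, "Intermediate": 1, "Adverse": 2}
        for eln in order:
            groups = [eln_enhanced(eln, load) for load in range(6)]
            assert groups == sorted(groups)
        for load in range(6):
            by_class = [
                eln_enhanced(c, load)
                for c in ("Favorable", "Intermediate", "Adverse")
            ]
            assert by_class == sorted(by_class)

    @pytest.mark.parametrize("load, expected", [(3, "High"), (2, "Low"), (0, "Low")])
    def test_mdseb_threshold(self, load, expected):
        assert mdseb_stratify(load) == expected


class TestCRFlags:
    def test_aml_mrd_rule(self):
        assert cr_flag(mk_patient(mrd=0.0005)) == 1
        assert cr_flag(mk_patient(mrd=0.002)) == 0

    def test_mdseb_blast_rule(self):
        p = mk_patient(
            dx="MDS", mdseb_flag=1, blasts_pretreatment=12.0, blasts_posttreatment=5.0
        )
        assert cr_flag(p) == 1  # 5 <= 5 and 58% decrease
        p2 = mk_patient(
            dx="MDS", mdseb_flag=1, blasts_pretreatment=12.0, blasts_posttreatment=7.2
        )
        assert cr_flag(p2) == 0  # only a 40% decrease

    def test_missing_outcome_not_evaluable(self):
        assert cr_flag(mk_patient()) is None

    def test_analysis_subset_filters(self):
        keep = mk_patient("keep", age=30)
        drops = [
            mk_patient("child", age=10),
            mk_patient("m3", age=30, m3_flag=1),
            mk_patient("sec", age=30, denovo_flag=0),
            mk_patient("alt", age=30, standard_induction_flag=0),
            mk_patient("mds", dx="MDS", age=30),
        ]
        subset = aml_analysis_subset([keep] + drops)
        assert [p.patient_id for p in subset] == ["keep"]
        mrc = mk_patient("mrc", age=30, mrc_flag=1)
        assert mrc in aml_analysis_subset([mrc])
        assert mrc not in aml_analysis_subset([mrc], exclude_mrc=True)


class TestBinaryEvaluation:
    def test_perfect_predictor_auroc_one(self):
        groups = [1] * 10 + [3] * 10
        cr = [1] * 10 + [0] * 10
        assert evaluate_binary(groups, cr).auroc == 1.0

    def test_fisher_matches_hypergeometric_enumeration(self):
        table = [[10, 0], [0, 10]]
        p = fisher_exact_2x2(table)
        # exact two-sided p: sum of point probabilities <= observed
        from scipy.stats import hypergeom

        rv = hypergeom(20, 10, 10)
        obs = rv.pmf(10)
        expected = sum(rv.pmf(k) for k in range(11) if rv.pmf(k) <= obs + 1e-12)
        assert p == pytest.approx(expected, abs=1e-6)

    def test_planted_odds_ratio_recovered(self):
        # logistic outcome with OR 0.25 for the high-load indicator
        rng = np.random.default_rng(3)
        n = 2000
        high = rng.random(n) < 0.4
        logit = 0.5 + math.log(0.25) * high
        cr = rng.random(n) < 1 / (1 + np.exp(-logit))
        out = evaluate_binary(
            high.astype(int), cr.astype(int),
            covariates=pd.DataFrame({"high_load": high.astype(float)}),
        )
        coef = out.logistic.loc["high_load", "coef"]
        se = out.logistic.loc["high_load", "se"]
        assert coef - 1.96 * se < math.log(0.25) < coef + 1.96 * se
        assert out.logistic.loc["high_load", "p"] < 0.001

    def test_perfect_separation_flagged_with_fallback(self):
        x = np.array([0.0] * 20 + [1.0] * 20)
        y = np.array([0] * 20 + [1] * 20)
        out = evaluate_binary(
            1 - y, y, covariates=pd.DataFrame({"x": x})
        )
        assert out.separation_flagged
        assert out.logistic is not None

    def test_single_class_outcome_rejected(self):
        with pytest.raises(ValueError):
            evaluate_binary([1, 2], [1, 1])


class TestSurvivalEvaluation:
    def test_identical_hazards_give_null_concordance(self):
        rng = np.random.default_rng(4)
        n = 900
        groups = rng.integers(1, 4, size=n)
        t = rng.exponential(1000, size=n)
        e = np.ones(n, dtype=int)
        out = evaluate_survival(groups, t, e)
        # null C is 0.5; SE for Harrell's C at this n is well below 0.02
        assert abs(out.concordance - 0.5) < 0.05

    def test_ordered_hazards_give_ordered_survival(self):
        rng = np.random.default_rng(5)
        hazards = {1: 0.5 / 1000, 2: 1.0 / 1000, 3: 2.0 / 1000}
        groups = np.repeat([1, 2, 3], 300)
        t = np.concatenate(
            [rng.exponential(1 / hazards[g], size=300) for g in (1, 2, 3)]
        )
        e = np.ones(len(t), dtype=int)
        out = evaluate_survival(groups, t, e)
        assert out.concordance > 0.6
        medians = {
            g: np.median(t[groups == g]) for g in (1, 2, 3)
        }
        assert medians[1] > medians[2] > medians[3]
        assert all(p < 0.01 for p in out.pairwise_cox_p.values())
        assert set(out.pairwise_cox_p) == {"1_vs_2", "1_vs_3", "2_vs_3"}

    def test_nonoverlapping_groups_have_perfect_concordance(self):
        groups = [1] * 5 + [2] * 5
        t = [100, 110, 120, 130, 140, 10, 20, 30, 40, 50]
        e = [1] * 10
        assert evaluate_survival(groups, t, e).concordance == 1.0

    def test_greenwood_se_matches_manual_formula(self):
        t = [1.0, 2.0, 3.0, 4.0, 5.0]
        e = [1, 1, 0, 1, 1]
        with pytest.raises(ValueError):
            evaluate_survival([1] * 5, t, e)  # only one group with events
        out = evaluate_survival(
            [1, 1, 1, 1, 1, 2, 2], t + [6.0, 7.0], e + [1, 0]
        )
        km1 = out.km_curves[out.km_curves.group == 1]
        # first event at t=1: S=4/5, Var = S^2 * 1/(5*4)
        row = km1[km1.time == 1.0].iloc[0]
        assert row.survival == pytest.approx(0.8)
        assert row.greenwood_se == pytest.approx(0.8 * np.sqrt(1 / 20))


class TestAssignRisk:
    def test_end_to_end_assignment(self):
        g = AxisGeneGroups(mapping={"NRAS": "R", "TET2": "MR", "ASXL1": "ML", "JAK2": "L"})
        p = mk_patient(genes=["NRAS", "NRAS", "TET2", "TET2"], flags={"complex": 1})
        a = assign_risk(p, g, use_recorded_eln=False)
        assert a.eln_class == "Adverse"
        assert a.load_rmr == 4
        assert a.enhanced_group == 3
        assert a.mdseb_stratum == "Low"
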