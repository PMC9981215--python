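"""Spectra, age comparisons, cluster loads and correlation analyses."""

import itertools

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from panmyeloid.cohort import MutationEvent, PatientRecord
from panmyeloid.phenogenetics import (
    CorrelationMatrix,
    age_stratified_compare,
    block_compare,
    cluster_cluster_correlation,
    cluster_load,
    load_matrix,
    mutation_spectra,
    pheno_gene_correlation,
)


def mk_patient(pid, dx="AML", age=40.0, genes=(), flags=None):
    return PatientRecord(
        pid, dx, age,
        karyotype_flags=flags or {},
        mutation_events=[MutationEvent(pid, g) for g in genes],
    )


class TestSpectra:
    def test_toy_rate_seven_of_ten(self):
        patients = [
            mk_patient(f"p{i}", "MPN", genes=["JAK2"] if i < 7 else [])
            for i in range(10)
        ]
        table = mutation_spectra(patients, ["JAK2"], diseases=["MPN"])
        assert table.rates.loc["JAK2", "MPN"] == 0.7
        assert table.carriers.loc["JAK2", "MPN"] == 7
        assert table.totals["MPN"] == 10

    def test_absent_aberration_zero_everywhere(self, small_cohort):
        records, _ = small_cohort
        table = mutation_spectra(records, ["ZZZ9"])
        assert (table.rates.loc["ZZZ9"] == 0).all()

    def test_empty_disease_excluded_with_warning(self):
        patients = [mk_patient("a", "AML")]
        with pytest.warns(UserWarning, match="MDS"):
            table = mutation_spectra(patients, ["JAK2"], diseases=["AML", "MDS"])
        assert list(table.rates.columns) == ["AML"]

    def test_rates_are_exact_count_ratios(self, small_cohort):
        records, _ = small_cohort
        variables = sorted({v for r in records for v in r.gene_variables})[:10]
        table = mutation_spectra(records, variables)
        np.testing.assert_array_equal(
            table.rates.to_numpy(),
            table.carriers.to_numpy() / table.totals.to_numpy()[None, :],
        )

    def test_ranking_ties_broken_by_name(self):
        patients = [mk_patient("a", "MPN", genes=["AAA", "BBB"])]
        ranked = mutation_spectra(patients, ["BBB", "AAA"], diseases=["MPN"]).ranked("MPN")
        assert list(ranked.index) == ["AAA", "BBB"]


class TestAgeCompare:
    def test_identical_proportions_give_p_one(self):
        patients = (
            [mk_patient(f"k{i}", age=10, genes=["X"] if i < 3 else []) for i in range(10)]
            + [mk_patient(f"a{i}", age=40, genes=["X"] if i < 6 else []) for i in range(20)]
        )
        out = age_stratified_compare(patients, "AML", ["X"])
        assert out.loc["X", "chi2"] == pytest.approx(0.0)
        assert out.loc["X", "p"] == pytest.approx(1.0)

    def test_matches_independent_chi_square_oracle(self):
        # strata 100 vs 100; carriers 30 vs 5
        patients = (
            [mk_patient(f"k{i}", age=10, genes=["X"] if i < 30 else []) for i in range(100)]
            + [mk_patient(f"a{i}", age=40, genes=["X"] if i < 5 else []) for i in range(100)]
        )
        out = age_stratified_compare(patients, "AML", ["X"])
        oracle = stats.chi2_contingency(
            np.array([[30, 70], [5, 95]]), correction=False
        )
        assert out.loc["X", "p"] == pytest.approx(oracle.pvalue, abs=1e-6)

    def test_zero_carrier_aberration_reported_missing(self):
        patients = [mk_patient("k", age=10), mk_patient("a", age=40)]
        out = age_stratified_compare(patients, "AML", ["X"])
        assert np.isnan(out.loc["X", "p"])

    def test_empty_stratum_named(self):
        patients = [mk_patient("a", age=40)]
        with pytest.raises(ValueError, match="pediatric"):
            age_stratified_compare(patients, "AML", ["X"])


class TestClusterLoad:
    def test_two_variants_of_one_gene_count_twice(self):
        p = mk_patient("a", genes=["NRAS", "NRAS"])
        assert cluster_load(p, {"NRAS"}) == 2
        assert cluster_load(p, {"NRAS"}, gene_level=True) == 1

    def test_no_events_and_outside_cluster(self):
        assert cluster_load(mk_patient("a"), {"NRAS"}) == 0
        assert cluster_load(mk_patient("a", genes=["TP53"]), {"NRAS"}) == 0

    def test_gene_variables_resolve_to_parent_gene(self):
        p = mk_patient("a", genes=["FLT3-ITD", "FLT3-TKD"])
        assert cluster_load(p, {"FLT3"}) == 2


class TestCorrelations:
    def test_self_correlation_is_one(self):
        patients = [
            mk_patient(f"p{i}", genes=["NRAS"] * (i % 3)) for i in range(30)
        ]
        loads = load_matrix(patients, {"c": {"NRAS"}})
        features = loads.rename(columns={"c": "load_copy"})
        out = pheno_gene_correlation(patients, {"c": {"NRAS"}}, features)
        assert out.r.loc["load_copy", "c"] == pytest.approx(1.0)

    def test_independent_noise_has_small_r(self):
        rng = np.random.default_rng(0)
        patients = [
            mk_patient(f"p{i}", genes=["NRAS"] * int(rng.integers(0, 4)))
            for i in range(1000)
        ]
        features = pd.DataFrame(
            {"noise": rng.normal(size=1000)},
            index=[p.patient_id for p in patients],
        )
        out = pheno_gene_correlation(patients, {"c": {"NRAS"}}, features)
        assert abs(out.r.loc["noise", "c"]) < 0.1

    def test_planted_coefficient_recovered(self, small_cohort, schema):
        # bm_blast_pct is generated as baseline + 3*load_R + 1*load_MR + noise;
        # the expected r follows from the realized load variance
        records, truth = small_cohort
        clusters = {"R": {"FLT3-ITD", "NPM1", "KIT", "NRAS", "WT1"}}
        aml = [r for r in records if r.diagnosis == "AML"]
        loads = load_matrix(aml, clusters)["R"].to_numpy(dtype=float)
        feats = pd.DataFrame(
            {"bm_blast_pct": [r.smear["bm_blast_pct"] for r in aml]},
            index=[r.patient_id for r in aml],
        ).astype(float)
        out = pheno_gene_correlation(aml, clusters, feats)
        measured = out.r.loc["bm_blast_pct", "R"]
        mask = feats["bm_blast_pct"].notna().to_numpy()
        # residual around the load signal: noise sd 1 plus the MR-load term
        signal = 3.0 * loads[mask]
        expected = np.corrcoef(
            signal, feats["bm_blast_pct"].to_numpy()[mask]
        )[0, 1]
        n = mask.sum()
        se = (1 - expected**2) / np.sqrt(n - 3)
        assert abs(measured - expected) < 3 * se + 0.1

    def test_zero_variance_feature_reported_missing(self):
        patients = [mk_patient(f"p{i}", genes=["NRAS"] * (i % 2)) for i in range(10)]
        features = pd.DataFrame(
            {"flat": np.ones(10)}, index=[p.patient_id for p in patients]
        )
        out = pheno_gene_correlation(patients, {"c": {"NRAS"}}, features)
        assert np.isnan(out.r.loc["flat", "c"])

    def test_karyotype_cluster_copying_gene_cluster_gives_r_one(self):
        patients = []
        for i in range(40):
            carrier = i % 2 == 0
            patients.append(
                mk_patient(
                    f"p{i}",
                    genes=["NRAS"] if carrier else [],
                    flags={"+8": int(carrier)},
                )
            )
        out = cluster_cluster_correlation(
            patients, {"G": {"NRAS"}}, {"K": ["+8"]}
        )
        assert out.r.loc["G", "K"] == pytest.approx(1.0)

    def test_independent_clusters_have_null_r(self):
        rng = np.random.default_rng(1)
        patients = []
        for i in range(1192):
            patients.append(
                mk_patient(
                    f"p{i}",
                    genes=["NRAS"] if rng.random() < 0.3 else [],
                    flags={"+8": int(rng.random() < 0.3)},
                )
            )
        out = cluster_cluster_correlation(patients, {"G": {"NRAS"}}, {"K": ["+8"]})
        r = out.r.loc["G", "K"]
        assert abs(r) < 3 / np.sqrt(1192)
        assert abs(r) <= 1.0


class TestBlockCompare:
    def _matrix(self, values):
        r = pd.DataFrame(
            np.array(values).reshape(1, -1),
            index=["f"],
            columns=[f"c{i}" for i in range(len(values))],
        )
        return CorrelationMatrix(r=r, n=r * 0 + 100)

    def test_separated_blocks_match_exact_enumeration(self):
        m = self._matrix([0.8, 0.7, 0.9, -0.8, -0.7, -0.9])
        block_a = [("f", "c0"), ("f", "c1"), ("f", "c2")]
        block_b = [("f", "c3"), ("f", "c4"), ("f", "c5")]
        p = block_compare(m, block_a, block_b)
        # exact two-sided rank-sum p by enumerating all 6-choose-3 splits
        values = [0.8, 0.7, 0.9, -0.8, -0.7, -0.9]
        observed = sum(stats.rankdata(values)[:3])
        stat_dist = [
            sum(stats.rankdata(values)[list(c)])
            for c in itertools.combinations(range(6), 3)
        ]
        mean = np.mean(stat_dist)
        extreme = np.mean(
            [abs(s - mean) >= abs(observed - mean) - 1e-12 for s in stat_dist]
        )
        assert p == pytest.approx(extreme, abs=1e-6)

    def test_symmetric_in_block_order(self):
        m = self._matrix([0.1, 0.5, 0.2, 0.9, 0.3, 0.8])
        a = [("f", "c0"), ("f", "c1"), ("f", "c2")]
        b = [("f", "c3"), ("f", "c4"), ("f", "c5")]
        assert block_compare(m, a, b) == pytest.approx(block_compare(m, b, a))

    def test_overlapping_blocks_rejected(self):
        m = self._matrix([0.1, 0.2, 0.3, 0.4])
        with pytest.raises(ValueError, match="disjoint"):
            block_compare(m, [("f", "c0"), ("f", "c1")], [("f", "c1"), ("f", "c2")])

    def test_tiny_block_rejected(self):
        m = self._matrix([0.1, 0.2, 0.3])
        with pytest.raises(ValueError):
            block_compare(m, [("f", "c0")], [("f", "c1"), ("f", "c2")])
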