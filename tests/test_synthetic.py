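"""Synthetic study generator: determinism, geometry, hubs, volumes, outcomes."""

import dataclasses

import numpy as np
import pytest
from scipy import ndimage

from netimpact.atlas import betweenness_centrality
from netimpact.cognition import classify_cohort
from netimpact.stats import ModelSpec, fit_gee_logistic
from netimpact.synthetic import (
    SimulationConfig,
    calibrate_intercept,
    generate_connectome,
    generate_covariates,
    generate_lesions,
    generate_parcellation,
    simulate_cohort_table,
    simulate_study,
)

SMALL = SimulationConfig(seed=0, shape=(24, 24, 24), n_regions=12, n_hubs=2, n_patients=8)


class TestParcellation:
    def test_deterministic_and_nonempty(self):
        cfg = dataclasses.replace(SMALL, shape=(16, 16, 16), n_regions=4)
        p1 = generate_parcellation(cfg)
        p2 = generate_parcellation(cfg)
        assert np.array_equal(p1, p2)
        labels, counts = np.unique(p1[p1 > 0], return_counts=True)
        assert list(labels) == [1, 2, 3, 4]
        assert (counts > 0).all()

    def test_90_regions_on_default_grid(self):
        parc = generate_parcellation(SimulationConfig(seed=3))
        assert len(np.unique(parc[parc > 0])) == 90

    def test_regions_contiguous(self):
        parc = generate_parcellation(SMALL)
        for lab in np.unique(parc[parc > 0]):
            _, n_comp = ndimage.label(parc == lab)
            assert n_comp == 1

    def test_different_seeds_same_label_set(self):
        p1 = generate_parcellation(SMALL)
        p2 = generate_parcellation(dataclasses.replace(SMALL, seed=1))
        assert not np.array_equal(p1, p2)
        assert set(np.unique(p1)) == set(np.unique(p2))


class TestConnectome:
    def test_hubs_above_median_betweenness(self):
        cfg = dataclasses.replace(SMALL, n_regions=10, n_hubs=2)
        parc = generate_parcellation(cfg)
        conn = generate_connectome(cfg, parc)
        bc = betweenness_centrality(conn, weighted=True)
        top2 = bc.sort_values(ascending=False).index[:2]
        median = bc.median()
        # the two designated hubs dominate: at least two nodes above median
        assert all(bc[t] > median for t in top2)

    def test_deterministic(self):
        parc = generate_parcellation(SMALL)
        e1 = generate_connectome(SMALL, parc).to_edgelist_frame()
        e2 = generate_connectome(SMALL, parc).to_edgelist_frame()
        assert e1.equals(e2)

    def test_three_regions_gives_triangle(self):
        cfg = dataclasses.replace(SMALL, n_regions=3, n_hubs=1)
        conn = generate_connectome(cfg, generate_parcellation(cfg))
        assert conn.graph.number_of_edges() == 3
        bc = betweenness_centrality(conn, weighted=False)
        assert (bc == 0.0).all()

    def test_connected(self):
        import networkx as nx

        conn = generate_connectome(SMALL, generate_parcellation(SMALL))
        assert nx.is_connected(conn.graph)


class TestLesions:
    def test_voxel_count_near_target(self):
        cfg = dataclasses.replace(SimulationConfig(seed=5), n_patients=20)
        parc = generate_parcellation(cfg)
        lesions, scores, _ = generate_lesions(cfg, parc)
        from netimpact.synthetic import _volume_cap_ml

        cap = _volume_cap_ml(cfg)
        for pid, target in lesions.target_volumes_ml.items():
            got = len(lesions.voxel_indices[pid]) / 1000.0
            expected = min(target, cap)
            assert got == pytest.approx(expected, rel=0.05, abs=0.01)

    def test_median_volume_near_cohort_anchor(self):
        """Log-normal volume draw reproduces the 3.7 mL median (+-25%)."""
        cfg = dataclasses.replace(SimulationConfig(seed=6), n_patients=500)
        parc = generate_parcellation(cfg)
        lesions, _, _ = generate_lesions(cfg, parc)
        vols = np.array([len(v) for v in lesions.voxel_indices.values()]) / 1000.0
        assert 2.8 <= np.median(vols) <= 4.6

    def test_scores_and_exclusions_partition_patients(self):
        cfg = dataclasses.replace(SimulationConfig(seed=7), n_patients=60)
        parc = generate_parcellation(cfg)
        lesions, scores, exclusions = generate_lesions(cfg, parc)
        assert set(scores["patient_id"]) | set(exclusions["patient_id"]) == set(
            lesions.patient_ids()
        )
        assert np.isfinite(scores["log_score"]).all()


class TestOutcomes:
    def test_full_determinism_of_generation_chain(self):
        s1 = simulate_study(dataclasses.replace(SMALL, n_patients=15))
        s2 = simulate_study(dataclasses.replace(SMALL, n_patients=15))
        assert s1.scores.equals(s2.scores)
        assert s1.cohort.equals(s2.cohort)

    def test_cohort_passes_downstream_validation(self):
        cfg = dataclasses.replace(SimulationConfig(seed=8), n_patients=200)
        cohort, scores, _ = simulate_cohort_table(cfg)
        classified = classify_cohort(cohort)  # raises on any invalid record
        assert classified["psci_status"].isin(["PSCI", "no_PSCI", "indeterminate"]).all()
        assert (classified["days_post_stroke"] >= 0).all()

    def test_null_score_effect_independent_of_quartile(self):
        """With beta_score = 0, PSCI prevalence is flat across score quartiles."""
        from scipy.stats import chi2_contingency

        cfg = dataclasses.replace(
            SimulationConfig(seed=9), n_patients=2000, visits_fixed=1, beta_score=0.0
        )
        cohort, scores, _ = simulate_cohort_table(cfg)
        cls = classify_cohort(cohort).merge(scores[["patient_id", "log_score"]], on="patient_id")
        cls = cls.dropna(subset=["psci"])
        quart = np.asarray(
            np.digitize(cls["log_score"], np.quantile(cls["log_score"], [0.25, 0.5, 0.75]))
        )
        table = np.array(
            [[(cls["psci"][quart == q] == v).sum() for v in (0, 1)] for q in range(4)]
        )
        _, p, _, _ = chi2_contingency(table)
        assert p > 0.01

    def test_no_shared_term_gives_near_zero_working_correlation(self):
        cfg = dataclasses.replace(
            SimulationConfig(seed=10), n_patients=600, visits_fixed=3, sigma_subject=0.0
        )
        cohort, scores, _ = simulate_cohort_table(cfg)
        cls = classify_cohort(cohort).merge(scores[["patient_id", "log_score"]], on="patient_id")
        r = fit_gee_logistic(cls, ModelSpec(univariable=True))
        assert abs(r.working_corr) < 0.1

    def test_prevalence_in_observed_band(self):
        cohort, _, _ = simulate_cohort_table(
            dataclasses.replace(SimulationConfig(seed=11), n_patients=1500)
        )
        prev = classify_cohort(cohort)["psci"].mean()
        assert 0.28 <= prev <= 0.47

    def test_calibration_helper_hits_target(self):
        cfg = SimulationConfig(seed=12)
        b0 = calibrate_intercept(cfg, 0.35)
        cohort, _, _ = simulate_cohort_table(
            dataclasses.replace(cfg, n_patients=2500, beta_intercept=b0)
        )
        prev = classify_cohort(cohort)["psci"].mean()
        assert prev == pytest.approx(0.35, abs=0.04)

    def test_covariate_marginals(self):
        cov = generate_covariates(SimulationConfig(seed=13), [f"P{i}" for i in range(4000)])
        assert cov["age_years"].mean() == pytest.approx(66.7, abs=1.0)
        assert (cov["sex"] == "male").mean() == pytest.approx(0.598, abs=0.03)
        assert cov["prior_stroke"].mean() == pytest.approx(0.113, abs=0.02)
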