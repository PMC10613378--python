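"""Synthetic study generator: determinism, structural guarantees and the
sequential outcome process."""

import numpy as np
import pandas as pd
import pytest

from peernet.exceptions import ConfigurationError
from peernet.exposure import decompose, row_normalize, within_exposure
from peernet.metrics import subnetwork_density
from peernet.network import (
    attribute_physicians,
    binarize,
    build_encounter_matrix,
    project_shared_patients,
)
from peernet.simulate import (
    Coefficients,
    SimConfig,
    generate_encounters,
    generate_outcomes,
    generate_population,
    simulate_study,
)

from conftest import small_config


class TestConfigValidation:
    @pytest.mark.parametrize(
        "kwargs,match",
        [
            (dict(patients_per_hospital=(0, 5)), "patients_per_hospital"),
            (dict(multi_site_fraction=1.5), "multi_site_fraction"),
            (dict(tau=-0.1), "tau"),
            (dict(n_hospitals=0), "n_hospitals"),
            (dict(site_share_concentration=0.0), "site_share_concentration"),
            (dict(encounters_per_patient=(5, 2)), "encounters_per_patient"),
        ],
    )
    def test_invalid_fields_named(self, kwargs, match):
        with pytest.raises(ConfigurationError, match=match):
            SimConfig(**kwargs)


class TestPopulation:
    def test_balanced_steps_one_per_hospital(self):
        pop = generate_population(SimConfig(n_hospitals=5, n_steps=5, seed=2))
        assert sorted(pop.hospitals["step"]) == [1, 2, 3, 4, 5]

    def test_steps_balanced_generally(self):
        pop = generate_population(SimConfig(n_hospitals=12, n_steps=5, seed=2))
        counts = pop.hospitals["step"].value_counts()
        assert counts.max() - counts.min() <= 1

    def test_single_site_config_forces_share_one(self):
        pop = generate_population(small_config(multi_site_fraction=0.0))
        sites_per_phys = pop.affiliations.groupby("physician_id").size()
        assert (sites_per_phys == 1).all()
        assert (pop.affiliations["share"] == 1.0).all()

    def test_shares_sum_to_one(self):
        pop = generate_population(small_config(seed=9))
        sums = pop.affiliations.groupby("physician_id")["share"].sum()
        assert np.allclose(sums, 1.0)

    def test_determinism(self):
        a = generate_population(small_config(seed=4))
        b = generate_population(small_config(seed=4))
        pd.testing.assert_frame_equal(a.physicians, b.physicians)
        pd.testing.assert_frame_equal(a.affiliations, b.affiliations)
        pd.testing.assert_frame_equal(a.hospitals, b.hospitals)


class TestEncounters:
    def test_default_config_within_subnetworks_complete(self, default_study):
        billing = default_study.billing
        B = binarize(project_shared_patients(build_encounter_matrix(billing)), 0)
        attr = attribute_physicians(billing)
        out = subnetwork_density(B, attr)
        assert out.per_hospital.mean() > 0.98
        assert out.per_hospital.median() == 1.0

    def test_even_split_physician_bills_evenly(self):
        """A physician with equal shares at two otherwise-identical hospitals
        accrues encounter counts equal up to binomial sampling error."""
        config = SimConfig(
            n_hospitals=2,
            n_steps=2,
            physicians_per_hospital=(4, 4),
            patients_per_hospital=(200, 200),
            encounters_per_patient=(3, 3),
            multi_site_fraction=0.0,
            seed=8,
        )
        pop = generate_population(config)
        # graft an even 2-hospital affiliation onto the first physician
        target = pop.physicians["physician_id"].iloc[0]
        aff = pop.affiliations[pop.affiliations["physician_id"] != target]
        aff = pd.concat(
            [
                aff,
                pd.DataFrame(
                    {
                        "physician_id": [target, target],
                        "hospital_id": ["h01", "h02"],
                        "share": [0.5, 0.5],
                    }
                ),
            ],
            ignore_index=True,
        )
        pop.affiliations = aff
        billing = generate_encounters(pop, config)
        counts = (
            billing[billing["physician_id"] == target]
            .groupby("hospital_id")
            .size()
            .reindex(["h01", "h02"], fill_value=0)
        )
        total = counts.sum()
        # two-sided binomial z-check at ~4 sigma
        assert abs(counts.iloc[0] - total / 2) < 4 * np.sqrt(total * 0.25)

    def test_every_physician_bills(self):
        config = small_config(seed=3, patients_per_hospital=(5, 8))
        pop = generate_population(config)
        billing = generate_encounters(pop, config)
        assert set(pop.physicians["physician_id"]) <= set(billing["physician_id"])

    def test_determinism(self):
        config = small_config(seed=6)
        pop = generate_population(config)
        pd.testing.assert_frame_equal(
            generate_encounters(pop, config), generate_encounters(pop, config)
        )


class TestOutcomes:
    def test_null_model_near_half(self):
        config = SimConfig(
            n_hospitals=20,
            physicians_per_hospital=(12, 12),
            patients_per_hospital=(60, 80),
            beta=Coefficients(
                intercept=0.0, age=0.0, age_observed=0.0, sex_male=0.0,
                years_org=0.0, shannon=0.0, within=0.0, across=0.0,
                across_interaction=0.0,
            ),
            tau=0.0,
            seed=21,
        )
        study = simulate_study(config)
        rate = study.physicians["participated"].mean()
        n = len(study.physicians)
        assert abs(rate - 0.5) < 4 * np.sqrt(0.25 / n)

    def test_extreme_negative_intercept_kills_participation(self):
        config = small_config(
            seed=2, beta=Coefficients(intercept=-20.0, age_observed=0.0,
                                      years_org=0.0, shannon=0.0, within=0.0,
                                      across_interaction=0.0, age=0.0),
        )
        study = simulate_study(config)
        assert study.physicians["participated"].sum() == 0

    def test_adoption_order_covers_each_physician_once(self, small_study):
        order = small_study.truth.adoption_order
        assert sorted(order) == sorted(small_study.physicians["physician_id"])
        assert len(set(order)) == len(order)

    def test_order_respects_trial_steps(self, small_study):
        steps = small_study.hospitals.set_index("hospital_id")["step"]
        primary = small_study.truth.true_exposures["primary_hospital"]
        seq_steps = [steps[primary[p]] for p in small_study.truth.adoption_order]
        assert seq_steps == sorted(seq_steps)

    def test_exposure_bookkeeping_matches_exposure_module(self, small_study):
        """Every recorded decision-time exposure equals the exposure module's
        value computed on the already-decided peer set."""
        billing = small_study.billing
        B = binarize(project_shared_patients(build_encounter_matrix(billing)), 0)
        attr = attribute_physicians(billing)
        dec = decompose(B, attr)
        steps = small_study.hospitals.set_index("hospital_id")["step"]
        own_step = dec.primary.map(steps).to_numpy()
        y = (
            small_study.physicians.set_index("physician_id")["participated"]
            .reindex(B.physicians)
            .to_numpy(dtype=float)
        )
        pos = {p: i for i, p in enumerate(B.physicians)}
        decided = np.zeros(B.n, dtype=bool)
        truth = small_study.truth.true_exposures
        for pid in small_study.truth.adoption_order:
            i = pos[pid]
            masked_wi = dec.B_wi * decided[None, :]
            exp_wi, flags_wi = within_exposure(row_normalize(masked_wi), y)
            assert exp_wi[i] == pytest.approx(truth.loc[pid, "wy_wi"], abs=1e-9)
            assert bool(flags_wi[i]) == bool(truth.loc[pid, "wy_wi_undefined"])
            eligible = decided & (own_step <= own_step[i])
            masked_ac = dec.B_ac * eligible[None, :]
            W_ac = row_normalize(masked_ac)
            exp_ac = (W_ac.W @ y)[i]
            assert exp_ac == pytest.approx(truth.loc[pid, "wy_ac"], abs=1e-9)
            decided[i] = True

    def test_single_site_population_has_no_across_edges(self):
        config = small_config(seed=14, multi_site_fraction=0.0)
        study = simulate_study(config)
        B = binarize(
            project_shared_patients(build_encounter_matrix(study.billing)), 0
        )
        attr = attribute_physicians(study.billing)
        dec = decompose(B, attr)
        assert dec.B_ac.sum() == 0
        assert (study.truth.true_exposures["shannon"] == 0).all()

    def test_within_contagion_clusters_hospitals(self):
        """A strong within-hospital peer effect raises the between-hospital
        variance of participation rates relative to the no-peer-effect case."""
        base = dict(
            n_hospitals=12,
            physicians_per_hospital=(8, 8),
            patients_per_hospital=(30, 40),
            encounters_per_patient=(2, 3),
            tau=0.0,
        )
        null_beta = Coefficients(
            intercept=0.0, age=0.0, age_observed=0.0, sex_male=0.0,
            years_org=0.0, shannon=0.0, within=0.0, across=0.0,
            across_interaction=0.0,
        )
        peer_beta = Coefficients(
            intercept=-2.2, age=0.0, age_observed=0.0, sex_male=0.0,
            years_org=0.0, shannon=0.0, within=0.045, across=0.0,
            across_interaction=0.0,
        )
        diffs = []
        for seed in range(40):
            variances = {}
            for name, beta in (("null", null_beta), ("peer", peer_beta)):
                study = simulate_study(SimConfig(seed=seed, beta=beta, **base))
                phys = study.physicians
                rates = phys.groupby("primary_hospital_id")["participated"].mean()
                variances[name] = rates.var(ddof=1)
            diffs.append(variances["peer"] - variances["null"])
        assert np.mean(diffs) > 0

    def test_study_reproducible_end_to_end(self):
        a = simulate_study(small_config(seed=19))
        b = simulate_study(small_config(seed=19))
        pd.testing.assert_frame_equal(a.physicians, b.physicians)
        pd.testing.assert_frame_equal(a.billing, b.billing)
        pd.testing.assert_frame_equal(a.truth.true_exposures, b.truth.true_exposures)
        assert a.truth.adoption_order == b.truth.adoption_order


class TestTruthSerialization:
    def test_roundtrip(self, tmp_path, small_study):
        path = tmp_path / "truth.json"
        small_study.truth.to_json(path)
        from peernet.simulate import SimTruth

        loaded = SimTruth.from_json(path)
        assert loaded.adoption_order == small_study.truth.adoption_order
        assert loaded.beta == small_study.truth.beta
        pd.testing.assert_frame_equal(
            loaded.true_exposures, small_study.truth.true_exposures, check_dtype=False
        )
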