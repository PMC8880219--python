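"""Probabilistic sensitivity analysis: sampling, bootstrap, CEAC, NMB, plane."""
import dataclasses

import numpy as np
import pandas as pd
import pytest

import treecea as tc
from treecea.parameters import DistributionSpec
from treecea.uncertainty import (
    PSASample,
    bootstrap_patients,
    ceac,
    deltas,
    frame_to_samples,
    nmb_curve,
    patient_qalys,
    plane_summary,
    sample_psa,
    samples_to_frame,
)


def _settings(table1, **overrides):
    return dataclasses.replace(table1[1], **overrides)


def _fixed_arms(table1):
    """Both arms with every parameter pinned at its central value."""
    out = []
    for arm in table1[0]:
        fix = lambda s: DistributionSpec("fixed", s.central, min(s.range_low, s.central),
                                         max(s.range_high, s.central))
        branches = tuple(dataclasses.replace(b, cost=fix(b.cost), qaly=fix(b.qaly))
                         for b in arm.branches)
        out.append(dataclasses.replace(arm, p_survive=fix(arm.p_survive), branches=branches))
    return out


def _make_samples(dc_de_pairs):
    return [PSASample(i, "A", "B", {"A": 0.0, "B": 0.0}, {"A": 0.0, "B": 0.0}, dc, de)
            for i, (dc, de) in enumerate(dc_de_pairs)]


class TestSamplePsa:
    def test_deterministic_for_fixed_seed(self, table1):
        settings = _settings(table1, n_replications=50, rng_seed=99)
        a = sample_psa(table1[0], settings)
        b = sample_psa(table1[0], settings)
        assert a == b

    def test_replication_count_and_support(self, table1):
        settings = _settings(table1, n_replications=200)
        samples = sample_psa(table1[0], settings)
        assert len(samples) == 200
        for s in samples:
            for arm, draws in s.params.items():
                assert 0.0 <= draws["p_survive"] <= 1.0
                assert all(v >= 0 for v in draws.values())

    def test_all_fixed_specs_reproduce_base_case(self, table1):
        arms = _fixed_arms(table1)
        base = tc.compare(*arms)
        samples = sample_psa(arms, _settings(table1, n_replications=10))
        for s in samples:
            assert s.delta_cost == pytest.approx(base.delta_cost)
            assert s.delta_effect == pytest.approx(base.delta_effect)

    @pytest.mark.parametrize("seed", [1, 7, 12345])
    def test_mean_sampled_survival_probability(self, table1, seed):
        # Beta(42, 1): Monte-Carlo error of the mean over 1000 draws is ~0.001
        samples = sample_psa(table1[0], _settings(table1, rng_seed=seed))
        mean_p = np.mean([s.params["VTD"]["p_survive"] for s in samples])
        assert abs(mean_p - 0.9767) < 0.01

    def test_unfitted_spec_rejected(self, table1):
        vtd, vmp = table1[0]
        bad_branch = dataclasses.replace(
            vtd.branches[0],
            cost=DistributionSpec("gamma", 100.0, 0.0, 200.0, fitted_params=None))
        bad = dataclasses.replace(vtd, branches=(bad_branch, vtd.branches[1]))
        with pytest.raises(ValueError, match="unfitted"):
            sample_psa((bad, vmp), _settings(table1, n_replications=2))


class TestBootstrapPatients:
    def test_zero_variance_cohort(self, table1):
        rec = [tc.PatientRecord(f"{a}-{i}", a, 0, 365.25, 100.0, 50.0, 0.5)
               for a in ("VTD", "VMP") for i in range(2)]
        samples = bootstrap_patients(rec, _settings(table1, n_replications=20))
        for s in samples:
            assert s.delta_cost == 0.0 and s.delta_effect == 0.0

    def test_bootstrap_mean_near_plug_in_delta(self, small_cohort, table1):
        df = small_cohort
        samples = bootstrap_patients(df, _settings(table1, n_replications=1000))
        dc, de = deltas(samples)
        total = df["outpatient_cost"] + df["inpatient_cost"]
        plug_dc = (total[df["arm"] == "VTD"].mean() - total[df["arm"] == "VMP"].mean())
        q = patient_qalys(df)
        plug_de = q[df["arm"] == "VTD"].mean() - q[df["arm"] == "VMP"].mean()
        assert abs(dc.mean() - plug_dc) < 2 * dc.std(ddof=1)
        assert abs(de.mean() - plug_de) < 2 * de.std(ddof=1)

    def test_single_replicate_replays_rng_stream(self, small_cohort, table1):
        settings = _settings(table1, n_replications=1, rng_seed=4242)
        (sample,) = bootstrap_patients(small_cohort, settings)
        # independent replay of the documented stream: one child generator per
        # replicate, each arm resampled at its own size in reference order
        rng = np.random.default_rng(np.random.SeedSequence(4242).spawn(1)[0])
        df = small_cohort
        expected = {}
        for arm in ("VTD", "VMP"):
            ix = np.flatnonzero((df["arm"] == arm).to_numpy())
            take = rng.choice(ix, size=ix.size, replace=True)
            sub = df.iloc[take]
            expected[arm] = (
                float((sub["outpatient_cost"] + sub["inpatient_cost"]).mean()),
                float(patient_qalys(sub).mean()),
            )
        assert sample.delta_cost == pytest.approx(expected["VTD"][0] - expected["VMP"][0])
        assert sample.delta_effect == pytest.approx(expected["VTD"][1] - expected["VMP"][1])

    def test_small_arm_rejected(self, table1):
        rec = [tc.PatientRecord("a", "VTD", 0, 10, 1.0, 1.0, 0.5),
               tc.PatientRecord("b", "VTD", 0, 10, 1.0, 1.0, 0.5),
               tc.PatientRecord("c", "VMP", 0, 10, 1.0, 1.0, 0.5)]
        with pytest.raises(ValueError, match="fewer than 2"):
            bootstrap_patients(rec, _settings(table1, n_replications=2))


class TestCeac:
    def test_all_dominant_gives_probability_one_everywhere(self):
        samples = _make_samples([(-10.0, 1.0)] * 8)
        curve = ceac(samples, [0.0, 1.0, 100.0])
        assert curve.prob_acceptable == (1.0, 1.0, 1.0)

    def test_all_dominated_gives_zero_everywhere(self):
        samples = _make_samples([(10.0, -1.0)] * 8)
        curve = ceac(samples, [0.0, 1.0, 100.0])
        assert curve.prob_acceptable == (0.0, 0.0, 0.0)

    def test_half_acceptable_counts(self):
        # at wtp=10: inmb = 10*de - dc -> 5, 5, -5, -5
        samples = _make_samples([(5.0, 1.0), (-5.0, 0.0), (5.0, 0.0), (15.0, 1.0)])
        curve = ceac(samples, [10.0])
        assert curve.prob_acceptable == (0.5,)

    def test_complement_curve(self, table1):
        settings = _settings(table1, n_replications=300)
        samples = sample_psa(table1[0], settings)
        flipped = _make_samples([(-s.delta_cost, -s.delta_effect) for s in samples])
        grid = settings.grid_array()
        ours = np.array(ceac(samples, grid).prob_acceptable)
        theirs = np.array(ceac(flipped, grid).prob_acceptable)
        assert np.allclose(ours + theirs, 1.0)

    def test_limits(self, table1):
        settings = _settings(table1, n_replications=300)
        samples = sample_psa(table1[0], settings)
        dc, de = deltas(samples)
        at_zero = ceac(samples, [0.0]).prob_acceptable[0]
        assert at_zero == np.mean(dc < 0)
        at_huge = ceac(samples, [1e15]).prob_acceptable[0]
        assert at_huge == np.mean(de > 0)

    def test_exceeds_095_at_gdp_threshold(self, table1):
        for seed in (1, 2, 3):
            samples = sample_psa(table1[0], _settings(table1, rng_seed=seed))
            curve = ceac(samples, [table1[1].wtp_threshold_twd])
            assert curve.prob_acceptable[0] > 0.95

    def test_empty_grid_rejected(self):
        with pytest.raises(ValueError):
            ceac(_make_samples([(1.0, 1.0)]), [])


class TestNmbCurve:
    def test_hand_computed_two_sample_means(self):
        samples = _make_samples([(-10.0, 2.0), (30.0, 4.0)])
        curve = nmb_curve(samples, [0.0, 10.0, 100.0])
        # mean dc = 10, mean de = 3 -> mean inmb = wtp*3 - 10
        assert curve.mean_inmb == pytest.approx((-10.0, 20.0, 290.0))

    def test_zero_wtp_limit_and_slope(self, table1):
        settings = _settings(table1, n_replications=200)
        samples = sample_psa(table1[0], settings)
        dc, de = deltas(samples)
        curve = nmb_curve(samples, settings.grid_array())
        assert curve.mean_inmb[0] == pytest.approx(-dc.mean())
        grid = np.array(curve.wtp_grid)
        slopes = np.diff(curve.mean_inmb) / np.diff(grid)
        assert np.allclose(slopes, de.mean())
        assert de.mean() > 0 and np.all(np.diff(curve.mean_inmb) > 0)


class TestPlaneSummary:
    def test_point_mass_has_zero_width_region(self):
        summ = plane_summary(_make_samples([(5.0, 1.0)] * 25))
        assert summ.cost_interval == (5.0, 5.0)
        assert summ.effect_interval == (1.0, 1.0)
        assert summ.covariance == ((0.0, 0.0), (0.0, 0.0))

    def test_standard_normal_quantiles(self):
        rng = np.random.default_rng(2718)
        z = rng.standard_normal((100_000, 2))
        summ = plane_summary(_make_samples([tuple(row) for row in z]))
        for lo, hi in (summ.cost_interval, summ.effect_interval):
            assert abs(lo + 1.96) < 0.05 and abs(hi - 1.96) < 0.05

    def test_percentile_box_matches_order_statistic_oracle(self):
        rng = np.random.default_rng(11)
        pts = rng.normal(size=(20, 2))
        summ = plane_summary(_make_samples([tuple(row) for row in pts]))

        def quantile_oracle(values, q):
            # linear interpolation between order statistics at p = (i-1)/(n-1)
            xs = sorted(values)
            pos = q * (len(xs) - 1)
            i = int(np.floor(pos))
            frac = pos - i
            return xs[i] if frac == 0 else xs[i] * (1 - frac) + xs[i + 1] * frac

        assert summ.cost_interval[0] == pytest.approx(quantile_oracle(pts[:, 0], 0.025), abs=1e-10)
        assert summ.cost_interval[1] == pytest.approx(quantile_oracle(pts[:, 0], 0.975), abs=1e-10)
        assert summ.effect_interval[0] == pytest.approx(quantile_oracle(pts[:, 1], 0.025), abs=1e-10)

    def test_too_few_samples_rejected(self):
        with pytest.raises(ValueError, match="at least"):
            plane_summary(_make_samples([(1.0, 1.0)] * 5))


class TestSampleTableRoundTrip:
    def test_frame_round_trip(self, table1):
        samples = sample_psa(table1[0], _settings(table1, n_replications=10))
        df = samples_to_frame(samples)
        back = frame_to_samples(df)
        for a, b in zip(samples, back):
            assert a.delta_cost == b.delta_cost
            assert a.arm_cost == b.arm_cost

    def test_bootstrap_and_psa_share_the_downstream_contract(self, small_cohort, table1):
        settings = _settings(table1, n_replications=50)
        for samples in (sample_psa(table1[0], settings),
                        bootstrap_patients(small_cohort, settings)):
            curve = ceac(samples, settings.grid_array())
            assert all(0.0 <= p <= 1.0 for p in curve.prob_acceptable)
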