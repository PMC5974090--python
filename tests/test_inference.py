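"""Kd fitting, replicate statistics and assay quality scoring."""

import numpy as np
import pytest
from scipy import stats

from anisobind import (
    AnisotropyObservation,
    NoiseModel,
    PlateDesign,
    ProbeParams,
    aggregate_replicates,
    estimate_endpoints,
    fit_competition_kd,
    fit_direct_kd,
    simulate_direct_titration,
    simulate_displacement,
    zfactor,
)
from anisobind.inference import TitrationSeries, Well
from anisobind.synthetic import default_competitor_totals

NOISELESS = NoiseModel(sigma_r=0.0, sigma_I_rel=0.0, seed=0)


def obs(rs, its=None):
    its = its or [None] * len(rs)
    return [AnisotropyObservation(r, it) for r, it in zip(rs, its)]


class TestEndpointCalibration:
    def test_recovers_probe_parameters_from_controls(self):
        p = estimate_endpoints(
            obs([0.016, 0.016], [1.0, 1.0]),
            obs([0.245, 0.245], [3.1, 3.1]),
        )
        assert p.rf == pytest.approx(0.016)
        assert p.rb == pytest.approx(0.245)
        assert p.R == pytest.approx(3.1)

    def test_group_scatter_propagated(self):
        p = estimate_endpoints(
            obs([0.015, 0.016, 0.017], [1.0, 1.0, 1.0]),
            obs([0.240, 0.245, 0.250], [3.0, 3.1, 3.2]),
        )
        assert p.rf_sd == pytest.approx(np.std([0.015, 0.016, 0.017], ddof=1))
        assert p.rb_sd == pytest.approx(np.std([0.240, 0.245, 0.250], ddof=1))

    def test_indistinguishable_controls_rejected(self):
        with pytest.raises(ValueError, match="does not exceed"):
            estimate_endpoints(obs([0.1, 0.1]), obs([0.1, 0.1]))

    def test_unchanged_intensity_gives_unit_ratio(self):
        p = estimate_endpoints(
            obs([0.016, 0.016], [1.0, 1.0]), obs([0.245, 0.245], [1.0, 1.0])
        )
        assert p.R == pytest.approx(1.0)

    def test_missing_intensities_leave_ratio_unset(self, probe):
        p = estimate_endpoints(obs([0.016, 0.016]), obs([0.245, 0.245]))
        assert p.R is None


class TestDirectFit:
    def test_noiseless_recovery_of_generating_kd(self, probe):
        design = PlateDesign(mode="direct", n_replicates=3)
        series = simulate_direct_titration(design, probe, 6.8, NOISELESS)
        fit = fit_direct_kd(series)
        assert fit.converged
        assert fit.kd_mean == pytest.approx(6.8, rel=1e-6)
        assert fit.kd_sem == pytest.approx(0.0, abs=1e-6)
        assert fit.n_replicates == 3

    def test_no_binding_flags_nonconvergence(self, probe):
        wells = [
            Well(sites_total=s, probe_total=10.0, r=probe.rf, replicate_id=1)
            for s in [0.0, 10.0, 100.0, 400.0]
        ]
        series = TitrationSeries(mode="direct", wells=wells, probe=probe)
        fit = fit_direct_kd(series)
        assert not fit.converged
        assert fit.kd_mean is None

    def test_too_few_concentrations_rejected(self, probe):
        wells = [
            Well(sites_total=s, probe_total=10.0, r=0.1, replicate_id=1)
            for s in [0.0, 100.0, 400.0]
        ]
        series = TitrationSeries(mode="direct", wells=wells, probe=probe)
        with pytest.raises(ValueError, match=">=4"):
            fit_direct_kd(series)

    def test_requires_intensity_ratio(self):
        p = ProbeParams(rf=0.016, rb=0.245)
        wells = [
            Well(sites_total=s, probe_total=10.0, r=0.1, replicate_id=1)
            for s in [0.0, 10.0, 100.0, 400.0]
        ]
        series = TitrationSeries(mode="direct", wells=wells, probe=p)
        with pytest.raises(ValueError, match="intensity ratio"):
            fit_direct_kd(series)

    def test_wrong_mode_rejected(self, probe):
        series = TitrationSeries(mode="competition", wells=[], probe=probe)
        with pytest.raises(ValueError, match="direct"):
            fit_direct_kd(series)


class TestCompetitionFit:
    def fit_synthetic(self, probe, kd_true, n_replicates=1, noise=NOISELESS):
        design = PlateDesign(
            mode="competition", n_replicates=n_replicates,
            competitor_totals=tuple(default_competitor_totals(kd_true)),
        )
        series = simulate_displacement(design, probe, 6.8, kd_true, noise)
        return fit_competition_kd(series, probe_ka=1 / 6.8)

    def test_noiseless_recovery_of_generating_kd(self, probe):
        fit = self.fit_synthetic(probe, 15.0)
        assert fit.converged
        assert fit.kd_mean == pytest.approx(15.0, rel=1e-6)

    def test_noiseless_recovery_over_random_affinities(self, probe):
        # the probe's design (10 nM tracer, 4 nM sites) identifies any
        # competitor Kd across nearly four orders of magnitude
        rng = np.random.default_rng(11)
        for kd_true in 10 ** rng.uniform(0, np.log10(5000), 20):
            fit = self.fit_synthetic(probe, float(kd_true))
            assert fit.kd_mean == pytest.approx(kd_true, rel=1e-3)

    def test_self_consistency_with_unlabeled_parent(self, probe):
        # a competitor with the probe's own affinity must return it
        fit = self.fit_synthetic(probe, 6.8)
        assert fit.kd_mean == pytest.approx(6.8, rel=1e-6)

    def test_non_binder_yields_lower_bound_not_estimate(self, probe):
        wells = [
            Well(sites_total=4.0, probe_total=10.0, ligand_total=l,
                 r=0.0635, replicate_id=1)
            for l in [1.0, 10.0, 100.0, 1000.0, 10000.0]
        ]
        series = TitrationSeries(mode="competition", wells=wells, probe=probe)
        fit = fit_competition_kd(series, probe_ka=1 / 6.8)
        assert fit.is_lower_bound
        assert fit.kd_mean is None
        assert fit.kd_lower_bound == pytest.approx(10000.0)

    def test_sem_reflects_between_replicate_scatter(self, probe):
        fit = self.fit_synthetic(
            probe, 15.0, n_replicates=3,
            noise=NoiseModel(sigma_r=0.002, sigma_I_rel=0.0, seed=5),
        )
        assert fit.converged
        assert fit.kd_sem is not None and fit.kd_sem > 0
        assert fit.kd_mean == pytest.approx(15.0, rel=0.3)

    def test_replicate_mean_uncertainty_is_t_calibrated(self, probe):
        # with n = 3 replicates the statistic (mean - truth)/SEM should
        # follow Student's t with 2 degrees of freedom; a miscalibrated
        # SEM (wrong ddof, pooling bug) would shift the whole distribution
        kd_true = 15.0
        design = PlateDesign(
            mode="competition", n_replicates=3,
            competitor_totals=tuple(default_competitor_totals(kd_true)),
        )
        tstats = []
        for i in range(150):
            noise = NoiseModel(sigma_r=0.002, sigma_I_rel=0.0, seed=20_000 + i)
            series = simulate_displacement(design, probe, 6.8, kd_true, noise)
            fit = fit_competition_kd(series, probe_ka=1 / 6.8)
            tstats.append((fit.kd_mean - kd_true) / fit.kd_sem)
        _, p_value = stats.kstest(tstats, "t", args=(2,))
        assert p_value > 0.005


class TestZFactor:
    def test_noiseless_controls_give_unity(self):
        res = zfactor(obs([0.245] * 3), obs([0.016] * 3))
        assert res.z == pytest.approx(1.0)

    def test_inverse_construction(self):
        # three points m-s, m, m+s have sample SD exactly s; with
        # s = 0.001145 on both controls, 3*(sp+sn)/|dm| = 0.03 -> Z = 0.97
        s = 0.001145
        pos = obs([0.245 - s, 0.245, 0.245 + s])
        neg = obs([0.016 - s, 0.016, 0.016 + s])
        res = zfactor(pos, neg)
        assert res.z == pytest.approx(0.97, abs=1e-12)

    def test_overlapping_controls_give_negative_z(self):
        s = 0.05  # 3*(sp+sn) = 0.3 > the 0.229 window
        pos = obs([0.245 - s, 0.245, 0.245 + s])
        neg = obs([0.016 - s, 0.016, 0.016 + s])
        assert zfactor(pos, neg).z < 0

    @pytest.mark.parametrize("scale, offset", [(1000.0, 0.0), (2.5, 0.3), (0.1, -1.0)])
    def test_invariant_under_affine_rescaling(self, scale, offset):
        rng = np.random.default_rng(3)
        pos = rng.normal(0.245, 0.002, 8)
        neg = rng.normal(0.016, 0.002, 8)
        z0 = zfactor(obs(pos), obs(neg)).z
        z1 = zfactor(obs(pos * scale + offset), obs(neg * scale + offset)).z
        assert z1 == pytest.approx(z0, abs=1e-12)

    def test_identical_means_undefined(self):
        with pytest.raises(ValueError, match="identical"):
            zfactor(obs([0.1, 0.1, 0.1]), obs([0.1, 0.1, 0.1]))

    def test_requires_three_wells_per_group(self):
        with pytest.raises(ValueError, match=">=3"):
            zfactor(obs([0.245, 0.245]), obs([0.016, 0.016, 0.016]))


class TestReplicateAggregation:
    def test_identical_replicates_have_zero_sem(self):
        assert aggregate_replicates([10, 10, 10]) == (10, 0)

    def test_mean_and_sample_sem(self):
        mean, sem = aggregate_replicates([12, 15, 18])
        assert mean == pytest.approx(15.0)
        assert sem == pytest.approx(3 / np.sqrt(3))  # sample SD 3 over sqrt(n)

    def test_single_replicate_has_no_sem(self):
        assert aggregate_replicates([7.0]) == (7.0, None)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            aggregate_replicates([])
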