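import math

import numpy as np
import pytest
from scipy import stats

from radlesion.geometry import Domain
from radlesion.irradiation import (
    F1Spectrum,
    MicrodosimetrySpec,
    ProtractedIrradiation,
    ProtractedSpec,
    TrackModel,
    core_mass_fraction,
    generate_initial_damage,
    multi_event_distribution,
    p0_pmf,
    protracted_schedule,
    radial_cdf,
    sample_dose_event,
    sample_radial_offset,
    sample_track_count,
)


@pytest.fixture
def micro_default():
    """The printed scenario: D=10 Gy, z_F=0.04 Gy, kappa=50, lambda=0.5."""
    return MicrodosimetrySpec()


@pytest.fixture
def track_default():
    return TrackModel(r_core_um=0.01, r_penumbra_um=1.0)


class TestTrackCount:
    def test_zero_dose(self, rng):
        micro = MicrodosimetrySpec(dose_gy=0.0)
        assert all(sample_track_count(micro, rng) == 0 for _ in range(100))

    def test_poisson_mean(self, micro_default, rng):
        n = 10_000
        draws = np.array([sample_track_count(micro_default, rng) for _ in range(n)])
        mean = micro_default.mean_events  # D / z_F = 250
        se = np.sqrt(mean / n)
        assert abs(draws.mean() - mean) < 3 * se

    def test_equidispersion(self, micro_default, rng):
        draws = np.array([sample_track_count(micro_default, rng) for _ in range(10_000)])
        assert 0.95 < draws.var() / draws.mean() < 1.05


class TestRadialOffset:
    def test_support(self, track_default, rng):
        rho = sample_radial_offset(track_default, rng, size=10_000)
        assert (rho >= 0).all() and (rho <= track_default.r_penumbra_um).all()

    def test_core_mass_fraction(self, track_default, rng):
        # analytic: 0.5 / (0.5 + ln(R_p/R_c)) for the continuous profile
        analytic = 0.5 / (0.5 + math.log(100))
        assert core_mass_fraction(track_default) == pytest.approx(analytic)
        n = 100_000
        rho = sample_radial_offset(track_default, rng, size=n)
        frac = np.mean(rho <= track_default.r_core_um)
        se = np.sqrt(analytic * (1 - analytic) / n)
        assert abs(frac - analytic) < 3 * se

    def test_ks_against_analytic_cdf(self, track_default, rng):
        rho = sample_radial_offset(track_default, rng, size=20_000)
        res = stats.kstest(rho, lambda r: radial_cdf(track_default, r))
        assert res.pvalue > 0.001

    def test_invalid_radii_rejected(self):
        with pytest.raises(ValueError):
            TrackModel(r_core_um=1.0, r_penumbra_um=0.5)


class TestInitialDamage:
    def test_zero_yields_empty_state(self, disk5, track_default, rng):
        micro = MicrodosimetrySpec(kappa_per_gy=0.0, lambda_per_gy=0.0)
        s = generate_initial_damage(micro, track_default, disk5, rng)
        assert s.n_total == 0

    def test_mean_lesion_numbers(self, disk5, micro_default, track_default, rng):
        # E[N_X] = kappa * D = 500 and E[N_Y] = lambda * D = 5 in resample mode
        n = 200
        nx, ny = np.empty(n), np.empty(n)
        for k in range(n):
            s = generate_initial_damage(micro_default, track_default, disk5, rng)
            nx[k], ny[k] = s.n_x, s.n_y
        kd = micro_default.kappa_per_gy * micro_default.dose_gy
        ld = micro_default.lambda_per_gy * micro_default.dose_gy
        assert abs(nx.mean() - kd) < 3 * nx.std(ddof=1) / np.sqrt(n)
        assert abs(ny.mean() - ld) < 3 * ny.std(ddof=1) / np.sqrt(n)

    def test_positions_inside_and_track_ids(self, disk5, micro_default, track_default, rng):
        s, tids = generate_initial_damage(micro_default, track_default, disk5, rng,
                                          return_track_ids=True)
        assert disk5.contains(s.positions).all()
        assert len(tids) == s.n_total

    def test_discard_mode_drops_outside(self, disk5, track_default, rng):
        track = TrackModel(r_core_um=0.01, r_penumbra_um=1.0, boundary_mode="discard")
        micro = MicrodosimetrySpec()
        s = generate_initial_damage(micro, track, disk5, rng)
        assert disk5.contains(s.positions).all()


class TestMultiEventDistribution:
    def test_single_event_matches_f1_mean_and_mass(self):
        f1 = F1Spectrum("gamma", z_f_gy=0.05, shape=2.0)
        z = np.linspace(0.0, 1.0, 2001)
        out, atom = multi_event_distribution(f1, z, nu=1)
        dz = z[1] - z[0]
        assert atom == 0.0
        assert out.sum() * dz == pytest.approx(1.0, abs=1e-9)
        assert (out * z).sum() * dz == pytest.approx(0.05, rel=1e-4)
        # density shape agrees with the analytic pdf away from the edge
        pdf = f1.on_grid(z)
        assert np.max(np.abs(out[10:] - pdf[10:])) < 1e-3 * pdf.max()

    def test_convolution_mean_adds(self):
        f1 = F1Spectrum("gamma", z_f_gy=0.05, shape=2.0)
        z = np.linspace(0.0, 2.0, 8001)
        out, _ = multi_event_distribution(f1, z, nu=4)
        dz = z[1] - z[0]
        mean = (out * z).sum() * dz
        assert mean == pytest.approx(4 * 0.05, rel=1e-4)

    def test_dose_mixture_mean_is_dose(self):
        f1 = F1Spectrum("gamma", z_f_gy=0.1, shape=1.0)
        micro_dose = 1.0
        z = np.linspace(0.0, 8.0, 16001)
        mix, atom = multi_event_distribution(f1, z, dose=micro_dose)
        dz = z[1] - z[0]
        assert mix.sum() * dz + atom == pytest.approx(1.0, abs=1e-6)
        mean = (mix * z).sum() * dz
        assert mean == pytest.approx(micro_dose, rel=1e-4)

    def test_coarse_grid_rejected(self):
        f1 = F1Spectrum("gamma", z_f_gy=0.1, shape=1.0)
        z = np.linspace(0.0, 0.2, 11)  # cuts off most of the spectrum
        with pytest.raises(ValueError):
            multi_event_distribution(f1, z, nu=1)


class TestInitialCountPmf:
    """The microdosimetric Neyman-type law for the initial (x, y) counts."""

    def neyman_micro(self):
        return MicrodosimetrySpec(dose_gy=1.0, z_f_gy=0.1, kappa_per_gy=10.0,
                                  lambda_per_gy=0.0,
                                  f1=F1Spectrum("delta", z_f_gy=0.1))

    def test_mass_normalised(self):
        pmf, deficit = p0_pmf(self.neyman_micro(), x_max=80, y_max=0)
        assert pmf.sum() == pytest.approx(1.0, abs=1e-6)
        assert deficit < 1e-6

    def test_moments_match_compound_poisson_identities(self):
        # delta spectrum: x | nu ~ Poisson(nu * m2) with nu ~ Poisson(m1),
        # m1 = D/z_F, m2 = kappa z_F; tower property gives mean m1 m2 and
        # variance m1 m2 (1 + m2) -- the Neyman Type A moments
        micro = self.neyman_micro()
        pmf, _ = p0_pmf(micro, x_max=80, y_max=0)
        x = np.arange(81)
        px = pmf[:, 0]
        m1 = micro.dose_gy / micro.z_f_gy
        m2 = micro.kappa_per_gy * micro.z_f_gy
        mean = (x * px).sum()
        var = (x**2 * px).sum() - mean**2
        assert mean == pytest.approx(m1 * m2, rel=1e-4)
        assert var == pytest.approx(m1 * m2 * (1 + m2), rel=1e-3)

    def test_marginal_mean_kappa_dose_general_spectrum(self):
        micro = MicrodosimetrySpec(dose_gy=0.5, z_f_gy=0.05, kappa_per_gy=8.0,
                                   lambda_per_gy=1.0)
        pmf, _ = p0_pmf(micro, x_max=40, y_max=15)
        x = np.arange(41)
        mean_x = (x[:, None] * pmf).sum()
        assert mean_x == pytest.approx(micro.kappa_per_gy * micro.dose_gy, rel=1e-4)

    def test_sampler_agrees_with_pmf(self, disk5, rng):
        # marginalising generate_initial_damage over positions must
        # reproduce the analytic count pmf (chi-square goodness of fit)
        micro = MicrodosimetrySpec(dose_gy=0.2, z_f_gy=0.1, kappa_per_gy=10.0,
                                   lambda_per_gy=0.0,
                                   f1=F1Spectrum("delta", z_f_gy=0.1))
        track = TrackModel()
        n = 10_000
        draws = np.array([
            generate_initial_damage(micro, track, disk5, rng).n_x for k in range(n)
        ])
        pmf, _ = p0_pmf(micro, x_max=60, y_max=0)
        px = pmf[:, 0]
        # pool the tail so expected counts stay above 5
        kmax = int(np.searchsorted(np.cumsum(px), 1 - 5 / n))
        obs = np.bincount(np.minimum(draws, kmax), minlength=kmax + 1)
        exp = np.append(px[:kmax], px[kmax:].sum()) * n
        res = stats.chisquare(obs, exp)
        assert res.pvalue > 0.001


class TestProtracted:
    def test_zero_rate_empty(self, rng):
        assert len(protracted_schedule(ProtractedSpec(0.0, 1.0), rng)) == 0

    def test_times_sorted_within_window(self, rng):
        times = protracted_schedule(ProtractedSpec(100.0, 0.5), rng)
        assert (np.diff(times) >= 0).all()
        assert (times >= 0).all() and (times <= 0.5).all()

    def test_poisson_count_mean(self, rng):
        prot = ProtractedSpec(250.0, 1.0)
        counts = np.array([len(protracted_schedule(prot, rng)) for _ in range(1000)])
        se = np.sqrt(250 / 1000)
        assert abs(counts.mean() - 250) < 3 * se

    def test_rate_from_dose(self):
        prot = ProtractedSpec.from_dose(10.0, 1.0, 0.04)
        assert prot.dose_rate_events_per_h == pytest.approx(250.0)

    def test_single_event_yield(self, disk5, micro_default, track_default, rng):
        n = 10_000
        counts = np.array([
            len(sample_dose_event(micro_default, track_default, disk5, rng)[0])
            for _ in range(n)
        ])
        mean = micro_default.kappa_per_gy * micro_default.z_f_gy  # kappa z_F = 2
        assert abs(counts.mean() - mean) < 3 * counts.std(ddof=1) / np.sqrt(n)

    def test_dose_balance_under_protraction(self, disk5, rng):
        # with rate D/(T_irr z_F) the mean total X created over the window
        # equals kappa * D: protracted and instantaneous delivery agree
        micro = MicrodosimetrySpec(dose_gy=1.0, z_f_gy=0.05, kappa_per_gy=20.0,
                                   lambda_per_gy=0.0)
        track = TrackModel()
        prot = ProtractedSpec.from_dose(micro.dose_gy, 0.5, micro.z_f_gy)
        irr = ProtractedIrradiation(prot, micro, track)
        n = 500
        totals = np.empty(n)
        for k in range(n):
            times = irr.schedule(rng)
            totals[k] = sum(len(irr.sample_event(disk5, rng)[0]) for _ in times)
        expected = micro.kappa_per_gy * micro.dose_gy
        assert abs(totals.mean() - expected) < 3 * totals.std(ddof=1) / np.sqrt(n)


class TestSpecValidation:
    def test_tabulated_spectrum_checks(self):
        z = np.linspace(0.0, 1.0, 101)
        good = np.exp(-z / 0.1) / 0.1
        good /= np.trapezoid(good, z)
        mean = np.trapezoid(good * z, z)
        f1 = F1Spectrum("tabulated", z_f_gy=mean, z_grid=z, density=good)
        assert f1.kind == "tabulated"
        with pytest.raises(ValueError):
            F1Spectrum("tabulated", z_f_gy=0.5, z_grid=z, density=good)  # wrong mean

    def test_negative_dose_rejected(self):
        with pytest.raises(ValueError):
            MicrodosimetrySpec(dose_gy=-1.0)
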