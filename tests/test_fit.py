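"""Dose--response fitting, confidence band, saturation dose."""

import numpy as np
import pytest

from andgate import (
    DoseResponseSeries,
    confidence_band,
    fit_dose_response,
    hill_mean,
    predicted_saturation_dose,
)

DOSES = np.array([0.1, 1.0, 3.0, 10.0, 30.0, 100.0])
TRUTH = dict(background=10.0, amplitude=1000.0, k=10.0, h=2.0)


def make_series(doses=DOSES, noise_sd=0.0, seed=0, **truth):
    truth = {**TRUTH, **truth}
    y = hill_mean(doses, truth["background"], truth["amplitude"], truth["k"], truth["h"])
    if noise_sd:
        y = y + np.random.default_rng(seed).normal(0, noise_sd, len(doses))
    sd = np.full(len(doses), max(noise_sd, 1.0))
    return DoseResponseSeries(doses, y, sd, np.full(len(doses), 1000, dtype=int))


class TestFit:
    def test_exact_recovery_on_noise_free_data(self):
        f = fit_dose_response(make_series())
        assert f.converged
        assert f.k_hat == pytest.approx(10.0, rel=1e-4)
        assert f.h_hat == pytest.approx(2.0, rel=1e-4)
        assert f.amplitude_hat == pytest.approx(1000.0, rel=1e-4)
        assert f.background_hat == pytest.approx(10.0, rel=1e-3)

    def test_flat_series_does_not_converge(self):
        flat = DoseResponseSeries(DOSES, np.full(6, 55.0), np.ones(6), np.full(6, 10, int))
        f = fit_dose_response(flat)
        assert not f.converged and "flat" in f.message

    def test_unbracketed_doses_flagged(self):
        # all doses far below k: the rise is never seen
        f = fit_dose_response(make_series(doses=np.array([0.001, 0.002, 0.004, 0.008]), k=1e4))
        assert not f.converged

    def test_result_independent_of_dose_order(self):
        s = make_series(noise_sd=5.0)
        perm = np.random.default_rng(1).permutation(len(s.dose))
        s2 = DoseResponseSeries(s.dose[perm], s.mean[perm], s.sd[perm], s.n[perm])
        f1, f2 = fit_dose_response(s), fit_dose_response(s2)
        assert f1.k_hat == pytest.approx(f2.k_hat, rel=1e-6)
        assert f1.h_hat == pytest.approx(f2.h_hat, rel=1e-6)

    def test_noisy_recovery_over_replicates(self):
        # 1% multiplicative-scale noise: k and h within 10% in >= 90% of seeds
        ok = 0
        for seed in range(20):
            y = hill_mean(DOSES, **TRUTH)
            y = y * (1 + np.random.default_rng(seed).normal(0, 0.01, len(DOSES)))
            f = fit_dose_response(
                DoseResponseSeries(DOSES, y, np.ones(6), np.full(6, 100, int))
            )
            ok += (
                f.converged
                and abs(f.k_hat - 10) / 10 < 0.10
                and abs(f.h_hat - 2) / 2 < 0.10
            )
        assert ok >= 18

    def test_scale_equivariance(self):
        s = make_series(noise_sd=5.0)
        c = 7.5
        s2 = DoseResponseSeries(s.dose, c * s.mean, c * s.sd, s.n)
        f1, f2 = fit_dose_response(s), fit_dose_response(s2)
        assert f2.amplitude_hat == pytest.approx(c * f1.amplitude_hat, rel=1e-4)
        assert f2.background_hat == pytest.approx(c * f1.background_hat, rel=1e-3, abs=1e-2)
        assert f2.k_hat == pytest.approx(f1.k_hat, rel=1e-4)
        assert f2.h_hat == pytest.approx(f1.h_hat, rel=1e-4)

    def test_dose_unit_equivariance(self):
        s = make_series(noise_sd=5.0)
        c = 1000.0  # nM -> pM
        s2 = DoseResponseSeries(c * s.dose, s.mean, s.sd, s.n)
        f1, f2 = fit_dose_response(s), fit_dose_response(s2)
        assert f2.k_hat == pytest.approx(c * f1.k_hat, rel=1e-4)
        assert f2.h_hat == pytest.approx(f1.h_hat, rel=1e-4)

    def test_quasi_newton_matches_grid_search(self):
        # dense (k, h) grid with profiled linear parameters as the oracle;
        # background chosen large enough that its profile stays interior
        s = make_series(noise_sd=20.0, seed=4, background=80.0)
        f = fit_dose_response(s)
        ks = np.geomspace(2, 50, 160)
        hs = np.linspace(0.5, 5, 160)
        best = (np.inf, None, None)
        for k in ks:
            u = (s.dose / k) ** hs[:, None] / (1 + (s.dose / k) ** hs[:, None])
            for i, h in enumerate(hs):
                X = np.column_stack([np.ones(len(s.dose)), u[i]])
                beta, rss, *_ = np.linalg.lstsq(X, s.mean, rcond=None)
                r = float(((X @ beta - s.mean) ** 2).sum())
                if r < best[0]:
                    best = (r, k, h)
        assert f.k_hat == pytest.approx(best[1], rel=0.05)
        assert f.h_hat == pytest.approx(best[2], rel=0.05)
        assert f.residual_sum_of_squares <= best[0] * (1 + 1e-6)


class TestConfidenceBand:
    def test_noise_free_band_collapses(self):
        s = make_series()
        f = fit_dose_response(s)
        grid, lo, hi, _ = confidence_band(s, f, n_boot=100, seed=0)
        assert np.max(hi - lo) < 1e-3 * TRUTH["amplitude"]

    def test_band_reproducible_and_nested_in_level(self):
        s = make_series(noise_sd=10.0)
        f = fit_dose_response(s)
        g1, lo1, hi1, _ = confidence_band(s, f, level=0.5, n_boot=150, seed=2)
        g1b, lo1b, hi1b, _ = confidence_band(s, f, level=0.5, n_boot=150, seed=2)
        assert np.array_equal(lo1, lo1b) and np.array_equal(hi1, hi1b)
        _, lo2, hi2, _ = confidence_band(s, f, level=0.95, n_boot=150, seed=2)
        assert np.all(lo2 <= lo1 + 1e-9) and np.all(hi2 >= hi1 - 1e-9)

    def test_band_contains_point_fit(self):
        s = make_series(noise_sd=10.0, seed=3)
        f = fit_dose_response(s)
        grid, lo, hi, _ = confidence_band(s, f, n_boot=150, seed=5)
        point = hill_mean(grid, f.background_hat, f.amplitude_hat, f.k_hat, f.h_hat)
        assert np.all(lo <= point + 1e-9) and np.all(point <= hi + 1e-9)

    def test_requires_converged_fit(self):
        s = make_series()
        f = fit_dose_response(s)
        f.converged = False
        with pytest.raises(ValueError):
            confidence_band(s, f)


class TestSaturationDose:
    def test_half_max_is_k(self):
        f = fit_dose_response(make_series())
        assert predicted_saturation_dose(f, 0.5) == pytest.approx(f.k_hat)

    def test_closed_form_value(self):
        f = fit_dose_response(make_series())
        assert predicted_saturation_dose(f, 0.95) == pytest.approx(
            10 * np.sqrt(19), rel=1e-3
        )

    def test_monotone_and_domain(self):
        f = fit_dose_response(make_series())
        qs = [0.5, 0.8, 0.9, 0.99]
        ds = [predicted_saturation_dose(f, q) for q in qs]
        assert np.all(np.diff(ds) > 0)
        with pytest.raises(ValueError):
            predicted_saturation_dose(f, 1.0)


def test_series_csv_roundtrip(tmp_path):
    s = make_series(noise_sd=2.0)
    path = tmp_path / "dr.csv"
    s.to_csv(path)
    s2 = DoseResponseSeries.from_csv(path)
    assert np.allclose(s2.mean, s.mean) and np.allclose(s2.dose, s.dose)
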