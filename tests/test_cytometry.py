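"""Event I/O, gating, population summaries, histograms, trace utilities."""

import numpy as np
import pandas as pd
import pytest

from andgate import (
    CellTrace,
    EventTable,
    GateConfig,
    SyntheticConfig,
    apply_gates,
    default_gate_config,
    fluorescence_histogram,
    fold_activation,
    generate_condition,
    population_mean,
    read_events,
    smooth_trace,
    trace_background_correct,
    write_events,
)
from andgate.cytometry import is_bimodal


def make_table(n=100, fl=None, seed=0):
    rng = np.random.default_rng(seed)
    fl = np.full(n, 50.0) if fl is None else np.asarray(fl, dtype=float)
    n = len(fl)
    fsc = rng.lognormal(np.log(1e5), 0.1, n)
    return EventTable(
        pd.DataFrame(
            {
                "fsc_a": fsc,
                "ssc_a": rng.lognormal(np.log(5e4), 0.1, n),
                "fsc_h": 0.95 * fsc,
                "fl1": fl,
            }
        ),
        {"dose_nM": 1.0, "time_h": 20},
    )


class TestEventIO:
    def test_csv_roundtrip_preserves_channels_and_metadata(self, tmp_path):
        t = make_table(50)
        path = tmp_path / "events.csv"
        write_events(path, t)
        t2 = read_events(path)
        assert len(t2) == 50
        assert t2.metadata["dose_nM"] == 1.0
        for c in ("fsc_a", "ssc_a", "fsc_h", "fl1"):
            assert np.allclose(t2.data[c], t.data[c])

    def test_empty_file_is_an_error(self, tmp_path):
        p = tmp_path / "empty.csv"
        p.write_text("")
        with pytest.raises(ValueError):
            read_events(p)

    def test_missing_channels_reported(self, tmp_path):
        p = tmp_path / "bad.csv"
        p.write_text("a,b\n1,2\n")
        with pytest.raises(ValueError, match="available"):
            read_events(p)

    def test_channel_map_renames(self, tmp_path):
        p = tmp_path / "mapped.csv"
        p.write_text("FSC-A,SSC-A,FSC-H,FL1-A\n1,2,0.9,3\n")
        t = read_events(
            p,
            channel_map={"FSC-A": "fsc_a", "SSC-A": "ssc_a", "FSC-H": "fsc_h",
                         "FL1-A": "fl1"},
        )
        assert t.data["fl1"].iloc[0] == 3

    def test_generator_row_count(self):
        cfg = SyntheticConfig(n_cells_per_condition=1000, debris_fraction=0,
                              doublet_fraction=0, master_seed=1)
        assert len(generate_condition(1.0, cfg)) == 1000


class TestGating:
    def test_infinite_gates_are_identity(self):
        t = make_table(200)
        gated, rep = apply_gates(t, GateConfig())
        assert len(gated) == 200 and rep.n_kept == 200

    def test_contaminant_removal_on_labeled_fixture(self, default_config):
        table = generate_condition(5.0, default_config)
        gated, rep = apply_gates(table, default_gate_config())
        labels = table.data["label_truth"]
        kept_labels = gated.data["label_truth"]
        n_contam = (labels != "singlet").sum()
        n_contam_kept = (kept_labels != "singlet").sum()
        n_singlet = (labels == "singlet").sum()
        n_singlet_kept = (kept_labels == "singlet").sum()
        assert n_contam_kept <= 0.05 * n_contam
        assert n_singlet_kept >= 0.95 * n_singlet
        # report reconciles
        assert rep.n_kept + rep.n_removed_debris + rep.n_removed_doublets == rep.n_input

    def test_gating_is_idempotent(self, default_config):
        cfg = default_gate_config()
        once, _ = apply_gates(generate_condition(2.0, default_config), cfg)
        twice, rep = apply_gates(once, cfg)
        assert len(twice) == len(once)
        assert rep.n_removed_debris == 0 and rep.n_removed_doublets == 0

    def test_empty_survivors_flagged(self):
        t = make_table(10)
        _, rep = apply_gates(t, GateConfig(scatter_box=(0, 1, 0, 1)))
        assert rep.n_kept == 0 and rep.warning


class TestSummaries:
    def test_population_mean(self):
        assert population_mean(make_table(fl=[1, 2, 3])) == pytest.approx(2.0)
        with pytest.raises(ValueError):
            population_mean(EventTable(make_table(1).data.iloc[:0]))

    def test_fold_activation_basics(self):
        t = make_table(fl=np.full(100, 500.0))
        off = make_table(fl=np.full(100, 5.0))
        assert fold_activation(t, t) == pytest.approx(1.0)
        assert fold_activation(t, off) == pytest.approx(100.0)

    def test_fold_activation_scale_invariant(self):
        on = make_table(fl=np.random.default_rng(0).lognormal(6, 1, 500))
        off = make_table(fl=np.random.default_rng(1).lognormal(2, 1, 500))
        f1 = fold_activation(on, off)
        on2 = make_table(fl=3.3 * on.fl1)
        off2 = make_table(fl=3.3 * off.fl1)
        assert fold_activation(on2, off2) == pytest.approx(f1)

    def test_nonpositive_off_mean_raises(self):
        on = make_table(fl=np.ones(10))
        off = make_table(fl=np.zeros(10))
        with pytest.raises(ValueError, match="background"):
            fold_activation(on, off)


class TestHistogram:
    def test_mass_is_one_with_zero_bin(self):
        fl = np.concatenate([np.zeros(30), np.random.default_rng(0).lognormal(4, 1, 970)])
        h = fluorescence_histogram(fl, n_bins=32)
        assert h.total_mass() == pytest.approx(1.0)
        assert h.zero_mass == pytest.approx(0.03)

    def test_single_value_sample(self):
        h = fluorescence_histogram(np.full(10, 5.0), n_bins=8)
        assert h.total_mass() == pytest.approx(1.0)
        assert np.sum(h.mass > 0) == 1

    def test_two_seeds_give_compatible_histograms(self, params):
        from scipy import stats
        from andgate import StochasticSettings, simulate_population

        samples = []
        for seed in (1, 2):
            s = StochasticSettings(volume=3.0, t_end=10.0, n_cells=1500, seed=seed)
            samples.append(simulate_population(5.0, params, s))
        edges = np.histogram_bin_edges(np.concatenate(samples), bins=8)
        c1, _ = np.histogram(samples[0], bins=edges)
        c2, _ = np.histogram(samples[1], bins=edges)
        keep = (c1 + c2) >= 10
        _, pvalue, _, _ = stats.chi2_contingency(np.vstack([c1[keep], c2[keep]]))
        assert pvalue > 0.01

    def test_bimodality_detector_on_constructed_mixture(self):
        rng = np.random.default_rng(3)
        off = rng.lognormal(np.log(100), 0.3, 2000)
        on = rng.lognormal(np.log(5000), 0.4, 8000)
        assert is_bimodal(fluorescence_histogram(np.concatenate([off, on]), n_bins=24))
        assert not is_bimodal(fluorescence_histogram(on, n_bins=24))


class TestTraces:
    def test_smoothing_reference_values(self):
        tr = CellTrace(np.arange(5.0), np.array([1, 2, 3, 4, 5.0]))
        out = smooth_trace(tr, window=3)
        assert np.allclose(out.fluorescence, [1.5, 2, 3, 4, 4.5])

    def test_window_one_is_identity_and_even_rejected(self):
        tr = CellTrace(np.arange(4.0), np.array([3, 1, 4, 1.0]))
        assert np.array_equal(smooth_trace(tr, 1).fluorescence, tr.fluorescence)
        with pytest.raises(ValueError):
            smooth_trace(tr, 2)

    def test_constant_trace_unchanged(self):
        tr = CellTrace(np.arange(6.0), np.full(6, 2.5))
        assert np.allclose(smooth_trace(tr, 3).fluorescence, 2.5)

    def test_background_correction_anchors_reference_time(self):
        times = np.arange(0.0, 8.0)
        tr = CellTrace(times, 10.0 + times**1.5)
        bg = np.full(8, 2.0)
        out = trace_background_correct(tr, bg, reference_time=4.0)
        assert out.fluorescence[4] == pytest.approx(0.0)
        # affine: correcting the background itself gives all zeros
        flat = trace_background_correct(CellTrace(times, bg), bg, 4.0)
        assert np.allclose(flat.fluorescence, 0.0)

    def test_missing_reference_time_warns_and_uses_nearest(self):
        tr = CellTrace(np.arange(5.0), np.arange(5.0) * 2)
        with pytest.warns(UserWarning):
            out = trace_background_correct(tr, np.zeros(5), reference_time=2.4)
        assert out.fluorescence[2] == pytest.approx(0.0)
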