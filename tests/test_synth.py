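"""Generators: ground-truth structure, reproducibility, parameter checks."""

import numpy as np
import pytest

from cerebquant import spikestats
from cerebquant.exceptions import ParameterError
from cerebquant.synth import (
    BlinkSimParams,
    EyeSimParams,
    SpikeSimParams,
    TraceSimParams,
    TreeSimParams,
    generate_puncta_image,
    generate_tree,
    make_ss_template,
    render_trace,
    simulate_eye_session,
    simulate_eyeblink_session,
    simulate_spike_train,
)
from cerebquant.spiketrain import LabeledSpikeTrain


class TestSpikeTrainSim:
    def test_pure_ss_rate_and_count(self):
        train = simulate_spike_train(
            SpikeSimParams(ss_rate=50.0, ss_shape=1.0, cs_rate=0.0, duration=100.0, seed=42)
        )
        assert train.times_of("CS").size == 0
        n = train.times_of("SS").size
        se = np.sqrt(50.0 * 100.0)  # Poisson count SE
        assert abs(n - 5000) < 3 * se

    def test_pause_enforced_by_construction(self):
        train = simulate_spike_train(
            SpikeSimParams(ss_rate=80.0, cs_rate=1.0, cf_pause=0.050, duration=60.0, seed=0)
        )
        cs = train.times_of("CS")
        ss = train.times_of("SS")
        for c in cs:
            gap = ss[ss > c]
            if gap.size:
                assert gap[0] - c > 0.050

    def test_exponential_isis_mean_cv2_is_one(self):
        train = simulate_spike_train(
            SpikeSimParams(ss_rate=100.0, ss_shape=1.0, cs_rate=0.0, duration=101.0, seed=9)
        )
        isis = train.isis("SS")[:10_000]
        _, mean = spikestats.isi_cv2(isis)
        assert mean == pytest.approx(1.0, abs=0.02)

    def test_pause_deletion_thins_rate(self):
        # surviving SS rate -> ss_rate * (1 - cs_rate*cf_pause) for shape 1
        # (pause windows rarely overlap at these rates, so the linear
        # thinning formula and the exact exp(-cs_rate*cf_pause) agree)
        params = SpikeSimParams(
            ss_rate=60.0, ss_shape=1.0, cs_rate=1.0, cf_pause=0.020, duration=300.0, seed=5
        )
        train = simulate_spike_train(params)
        expected = 60.0 * (1 - 1.0 * 0.020)
        rate = spikestats.firing_rate(train, "SS")
        se = np.sqrt(expected / 300.0)
        assert abs(rate - expected) < 3 * se

    def test_reproducible(self):
        a = simulate_spike_train(SpikeSimParams(seed=3, duration=20.0))
        b = simulate_spike_train(SpikeSimParams(seed=3, duration=20.0))
        assert np.array_equal(a.times, b.times) and np.array_equal(a.labels, b.labels)

    @pytest.mark.parametrize(
        "kwargs",
        [
            {"ss_rate": -1.0},
            {"ss_shape": 0.0},
            {"cs_rate": -0.5},
            {"cs_rate": 2.0, "cf_pause": 0.6},
            {"duration": 0.0},
        ],
    )
    def test_invalid_params(self, kwargs):
        with pytest.raises(ParameterError):
            SpikeSimParams(**kwargs)


class TestTraceRendering:
    def test_empty_train_zero_noise_is_flat(self):
        train = LabeledSpikeTrain(np.empty(0), np.empty(0, dtype="U2"), 1.0)
        trace = render_trace(train, TraceSimParams(noise_sd=0.0))
        assert np.all(trace.samples == 0.0)

    def test_single_event_places_template_at_peak(self):
        fs = 50_000.0
        train = LabeledSpikeTrain(np.array([1.0]), np.array(["SS"]), 2.0)
        trace = render_trace(train, TraceSimParams(noise_sd=0.0))
        tpl = make_ss_template(fs)
        peak_idx = int(np.argmax(np.abs(trace.samples)))
        assert peak_idx == round(1.0 * fs)
        assert np.max(np.abs(trace.samples)) == pytest.approx(1.0)
        assert trace.samples[peak_idx] == pytest.approx(tpl[np.argmax(np.abs(tpl))])

    def test_overlap_warning(self):
        train = LabeledSpikeTrain(np.array([0.5, 0.5005]), np.array(["SS", "SS"]), 1.0)
        with pytest.warns(UserWarning, match="overlap"):
            render_trace(train, TraceSimParams(noise_sd=0.0))

    def test_template_normalization_enforced(self):
        with pytest.raises(ParameterError):
            TraceSimParams(ss_template=np.array([0.1, 0.5, 0.2]))


class TestTreeSim:
    def test_unbranched_path_length(self):
        tree = generate_tree(
            TreeSimParams(branch_prob=0.0, segment_len_mean=10.0, segment_len_sd=0.0, max_depth=10, seed=1)
        )
        assert tree.n_nodes == 11
        seg_lengths = [
            np.linalg.norm(tree.xyz[c] - tree.xyz[p]) for c, p in tree.segments()
        ]
        assert sum(seg_lengths) == pytest.approx(100.0)

    def test_full_binary_tree(self):
        tree = generate_tree(TreeSimParams(branch_prob=1.0, max_depth=3, seed=2))
        children = tree.children_of()
        leaves = [k for k, ch in children.items() if not ch]
        assert len(leaves) == 8  # 2^3

    def test_planar_growth_stays_in_plane(self):
        tree = generate_tree(TreeSimParams(planar=True, seed=3))
        assert np.all(tree.xyz[:, 2] == 0.0)
        tree3d = generate_tree(TreeSimParams(planar=False, branch_prob=0.5, max_depth=6, seed=3))
        assert np.any(tree3d.xyz[:, 2] != 0.0)

    def test_deterministic_under_seed(self, tmp_path):
        from cerebquant.morpho import write_swc

        a = generate_tree(TreeSimParams(seed=7))
        b = generate_tree(TreeSimParams(seed=7))
        pa, pb = tmp_path / "a.swc", tmp_path / "b.swc"
        write_swc(a, pa)
        write_swc(b, pb)
        assert pa.read_text() == pb.read_text()


class TestPunctaSim:
    def test_blank_above_soma_when_density_zero(self):
        image, truth = generate_puncta_image(100.0, 80.0, 0.0, um_per_px=0.5, seed=0)
        assert len(truth) == 0
        assert np.max(image.pixels) == pytest.approx(0.35)  # only the ML band

    def test_truth_band_height(self):
        image, truth = generate_puncta_image(100.0, 80.0, 0.05, size=(256, 512), um_per_px=0.5, seed=1)
        top = truth["y_um"].max() - image.soma_line_um
        assert top <= 80.0
        assert top > 78.0  # dense field reaches close to the band top

    def test_poisson_consistent_count(self):
        # 0.005/µm² over a 100x60 µm CF band -> lam = 30
        counts = [
            len(generate_puncta_image(80.0, 60.0, 0.005, size=(200, 200), um_per_px=0.5, seed=s)[1])
            for s in range(40)
        ]
        lam = 0.005 * 100.0 * 60.0
        assert abs(np.mean(counts) - lam) < 3 * np.sqrt(lam / 40)

    def test_cf_above_ml_rejected(self):
        with pytest.raises(ParameterError):
            generate_puncta_image(50.0, 60.0, 0.01)


class TestEyeSim:
    def test_zero_gain_flat_eye(self):
        trace = simulate_eye_session(EyeSimParams(true_gain=0.0, noise_sd=0.0, seed=0))
        assert np.allclose(trace.eye, 0.0)
        assert np.max(trace.stim) == pytest.approx(5.0, abs=1e-3)

    def test_ground_truth_round_trip(self):
        from cerebquant.eyemov import gain_phase

        trace = simulate_eye_session(
            EyeSimParams(true_gain=0.6, true_phase=20.0, noise_sd=0.0, seed=0)
        )
        gp = gain_phase(trace)
        assert gp.gain == pytest.approx(0.600, abs=1e-3)
        assert gp.phase == pytest.approx(20.0, abs=0.1)

    def test_five_cycle_minimum(self):
        with pytest.raises(ParameterError):
            EyeSimParams(frequency=0.1, duration=20.0)


class TestBlinkSim:
    def test_cr_prob_zero_no_crs(self):
        from cerebquant.eyeblink import cr_percentage

        ts = simulate_eyeblink_session(BlinkSimParams(cr_prob=0.0, noise_sd=0.0, seed=0))
        assert not ts.truth["has_cr"].any()
        assert cr_percentage(ts.trials) == 0.0

    def test_cr_prob_one_all_detected(self):
        from cerebquant.eyeblink import cr_percentage

        ts = simulate_eyeblink_session(BlinkSimParams(cr_prob=1.0, noise_sd=0.0, seed=1))
        assert cr_percentage(ts.trials) == 100.0

    def test_session_structure_follows_protocol(self):
        ts = simulate_eyeblink_session(BlinkSimParams(seed=2))
        types = ts.truth["type"].tolist()
        assert len(types) == 240
        assert types[:12] == ["us_only"] + ["paired"] * 10 + ["cs_only"]
        # US-only trials never carry a CR
        assert not ts.truth.loc[ts.truth.type == "us_only", "has_cr"].any()

    def test_reproducible(self):
        a = simulate_eyeblink_session(BlinkSimParams(seed=5))
        b = simulate_eyeblink_session(BlinkSimParams(seed=5))
        assert all(
            np.array_equal(x.fec, y.fec) for x, y in zip(a.trials[:20], b.trials[:20])
        )
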