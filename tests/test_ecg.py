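"""Synthetic ECG generator: waveform fidelity, rendering, preprocessing,
and patient-disjoint splitting."""

import numpy as np
import pandas as pd
import pytest
from scipy.signal import find_peaks

import cspanet as cn
from cspanet.ecg import FS, N_SAMPLES, LEAD_FACTORS
from cspanet.errors import InputError


def noiseless_cfg(**kw):
    return cn.SynthConfig(noise_sd_mv=0.0, wander_amp_mv=0.0, **kw)


def fixed_cfg(hr=75.0, **kw):
    """All sds zero: every patient draws exactly the configured means."""
    base = dict(heart_rate_bpm=(hr, 0.0), pr_interval_ms=(150.0, 0.0),
                p_amp_mv=(0.25, 0.0), p_width_ms=(90.0, 0.0),
                qrs_amp_mv=(1.1, 0.0), qrs_width_ms=(85.0, 0.0),
                t_amp_mv=(0.32, 0.0), t_width_ms=(160.0, 0.0))
    base.update(kw)
    return noiseless_cfg(**base)


def r_peak_indices(trace):
    peaks, _ = find_peaks(trace, height=0.5 * trace.max(), distance=int(0.3 * FS))
    return peaks


def measure_p_onset_to_r_ms(trace, p_amp):
    """Fiducial oracle: distance from the P-wave onset (5 %-amplitude
    crossing, which is exactly the onset under the generator's width
    convention) to the R peak. Analytically this equals
    PR interval + QRS width / 2, so PR offsets shift it one-to-one."""
    r_peaks = r_peak_indices(trace)
    vals = []
    for r in r_peaks[1:-1]:
        window = int(0.35 * FS)
        p_region = trace[r - window: r - int(0.1 * FS)]
        above = np.nonzero(p_region > 0.05 * p_amp)[0]
        if len(above) == 0:
            continue
        vals.append((window - above[0]) / FS * 1000.0)
    return float(np.median(vals))


class TestSynthesizeRecord:
    def test_noiseless_record_is_periodic_with_rr_lattice(self):
        cfg = fixed_cfg(hr=75.0)  # RR = 0.8 s = 400 samples exactly
        rec = cn.synthesize_record(0, cfg, np.random.default_rng(0))
        peaks = r_peak_indices(np.asarray(rec.leads["II"]))
        spacings = np.diff(peaks)
        assert np.all(spacings == round(FS * 60.0 / 75.0))

    def test_same_seed_bit_identical(self):
        cfg = cn.SynthConfig()
        a = cn.synthesize_record(1, cfg, np.random.default_rng(42))
        b = cn.synthesize_record(1, cfg, np.random.default_rng(42))
        for lead in cn.LEAD_NAMES:
            np.testing.assert_array_equal(a.leads[lead], b.leads[lead])
        assert a.generation_params == b.generation_params

    def test_structure_and_lead_scaling(self):
        cfg = fixed_cfg()
        rec = cn.synthesize_record(0, cfg, np.random.default_rng(0))
        assert set(rec.leads) == set(cn.LEAD_NAMES)
        assert all(len(rec.leads[l]) == N_SAMPLES for l in cn.LEAD_NAMES)
        # leads are scaled copies of one template trace
        ii = np.asarray(rec.leads["II"])
        np.testing.assert_allclose(rec.leads["aVR"],
                                   LEAD_FACTORS["aVR"] * ii, atol=1e-12)

    def test_cap_class_shifts_measured_pr_by_configured_offset(self):
        cfg = fixed_cfg()
        rng = np.random.default_rng(5)
        rec0 = cn.synthesize_record(0, cfg, rng)
        rec1 = cn.synthesize_record(1, cfg, rng)
        p = rec0.generation_params
        pr0 = measure_p_onset_to_r_ms(np.asarray(rec0.leads["II"]), p["p_amp_mv"])
        pr1 = measure_p_onset_to_r_ms(np.asarray(rec1.leads["II"]),
                                      rec1.generation_params["p_amp_mv"])
        assert pr0 - pr1 == pytest.approx(-cfg.cap_pr_offset_ms, abs=4.0)
        # absolute position: PR + QRS width / 2
        assert pr0 == pytest.approx(150.0 + 85.0 / 2, abs=4.0)

    def test_avnrt_class_scales_p_amplitude_and_heart_rate(self):
        cfg = fixed_cfg()
        rec2 = cn.synthesize_record(2, cfg, np.random.default_rng(0))
        assert rec2.heart_rate == pytest.approx(75.0 + cfg.avnrt_hr_offset_bpm)
        assert rec2.generation_params["p_amp_mv"] == pytest.approx(
            0.25 * cfg.avnrt_p_amp_factor)

    def test_out_of_range_parameters_clipped_with_warning(self):
        cfg = noiseless_cfg(heart_rate_bpm=(300.0, 0.0))
        with pytest.warns(RuntimeWarning, match="clipped"):
            rec = cn.synthesize_record(0, cfg, np.random.default_rng(0))
        assert rec.heart_rate == 200.0

    def test_invalid_label_rejected(self):
        with pytest.raises(InputError):
            cn.synthesize_record(3, cn.SynthConfig(), np.random.default_rng(0))


class TestRender:
    def test_flat_traces_render_twelve_horizontal_segments(self):
        cfg = noiseless_cfg(trace_thickness=1)
        rec = cn.synthesize_record(0, cfg, np.random.default_rng(0))
        for lead in cn.LEAD_NAMES:
            rec.leads[lead] = np.zeros(N_SAMPLES)
        img = cn.render_ecg_image(rec, cfg)
        ink_rows = np.nonzero((img == 0).any(axis=1))[0]
        assert len(ink_rows) == 3  # three row baselines
        segments = 0
        for r in ink_rows:
            cols = np.nonzero(img[r] == 0)[0]
            segments += 1 + int((np.diff(cols) > 1).sum())
        assert segments == 12

    def test_render_deterministic(self):
        cfg = cn.SynthConfig()
        rec = cn.synthesize_record(0, cfg, np.random.default_rng(3))
        np.testing.assert_array_equal(cn.render_ecg_image(rec, cfg),
                                      cn.render_ecg_image(rec, cfg))

    def test_doubling_amplitude_doubles_pixel_excursion(self):
        # small amplitudes so the doubled R peak stays inside its cell
        cfg = fixed_cfg(trace_thickness=1, qrs_amp_mv=(0.5, 0.0),
                        t_amp_mv=(0.15, 0.0), p_amp_mv=(0.12, 0.0))
        rec = cn.synthesize_record(0, cfg, np.random.default_rng(0))
        img1 = cn.render_ecg_image(rec, cfg)
        for lead in cn.LEAD_NAMES:
            rec.leads[lead] = 2.0 * np.asarray(rec.leads[lead])
        img2 = cn.render_ecg_image(rec, cfg)
        W, H = cfg.canvas_size
        ch = H // 3
        baseline = ch // 2  # lead II cell: column 0, row 1
        cell1 = img1[ch:2 * ch, : W // 4]
        cell2 = img2[ch:2 * ch, : W // 4]
        exc1 = baseline - np.nonzero((cell1 == 0).any(axis=1))[0][0]
        exc2 = baseline - np.nonzero((cell2 == 0).any(axis=1))[0][0]
        assert abs(exc2 - 2 * exc1) <= 2

    def test_canvas_too_small_rejected(self):
        cfg = noiseless_cfg(canvas_size=(32, 24))
        rec = cn.synthesize_record(0, cfg, np.random.default_rng(0))
        from cspanet.errors import ConfigurationError
        with pytest.raises(ConfigurationError):
            cn.render_ecg_image(rec, cfg)


class TestPreprocess:
    def test_two_by_two_bilinear_upscale_table(self):
        img = np.array([[0.0, 1.0], [1.0, 0.0]])
        out = cn.preprocess_image(img, (4, 4), margin=0.0, bg_threshold=1.5)
        # half-pixel centers: source coords (-0.25, .25, .75, 1.25) clamped
        expected = np.array([
            [0.00, 0.25, 0.75, 1.00],
            [0.25, 0.375, 0.625, 0.75],
            [0.75, 0.625, 0.375, 0.25],
            [1.00, 0.75, 0.25, 0.00],
        ])
        np.testing.assert_allclose(out, expected, atol=1e-6)

    def test_constant_interior_preserved(self):
        img = np.full((10, 14), 0.4)
        out = cn.preprocess_image(img, (7, 5), margin=0.0, bg_threshold=0.95)
        np.testing.assert_allclose(out, 0.4, atol=1e-6)

    def test_identity_when_already_tight_and_at_size(self):
        rng = np.random.default_rng(0)
        img = rng.random((8, 8)) * 0.5  # everything is foreground
        out = cn.preprocess_image(img, (8, 8), margin=0.0)
        np.testing.assert_allclose(out, img, atol=1e-6)

    def test_idempotent_at_zero_margin(self):
        cfg = cn.SynthConfig()
        rec = cn.synthesize_record(0, cfg, np.random.default_rng(1))
        img = cn.render_ecg_image(rec, cfg)
        once = cn.preprocess_image(img, (256, 128), margin=0.0)
        twice = cn.preprocess_image(once, (256, 128), margin=0.0)
        np.testing.assert_allclose(twice, once, atol=1e-6)

    def test_blank_image_rejected(self):
        with pytest.raises(InputError, match="foreground"):
            cn.preprocess_image(np.full((16, 16), 255, dtype=np.uint8), (8, 8))

    def test_uint8_range_normalized(self):
        img = np.full((6, 6), 128, dtype=np.uint8)
        out = cn.preprocess_image(img, (3, 3), margin=0.0)
        np.testing.assert_allclose(out, 128 / 255, atol=1e-6)


class TestSplit:
    @staticmethod
    def records(n_per_class, ecgs=1):
        recs = []
        for lab in range(3):
            for i in range(n_per_class):
                for j in range(ecgs):
                    recs.append(type("R", (), {"patient_id": f"C{lab}P{i}",
                                               "label": lab})())
        return recs

    def test_seven_three_counts_per_class(self):
        split = cn.split_patient_disjoint(self.records(10), ratio=0.7, seed=0)
        for part, n in ((split.train, 7), (split.test, 3)):
            for lab in range(3):
                assert sum(r.label == lab for r in part) == n

    def test_multi_record_patients_stay_together(self):
        split = cn.split_patient_disjoint(self.records(5, ecgs=3), ratio=0.7, seed=1)
        train_p = {r.patient_id for r in split.train}
        test_p = {r.patient_id for r in split.test}
        assert not train_p & test_p
        from collections import Counter
        for part in (split.train, split.test):
            for pid, k in Counter(r.patient_id for r in part).items():
                assert k == 3

    def test_disjoint_and_exhaustive_over_many_seeds(self):
        recs = self.records(9, ecgs=2)
        for seed in range(100):
            split = cn.split_patient_disjoint(recs, ratio=0.7, seed=seed)
            train_p = {r.patient_id for r in split.train}
            test_p = {r.patient_id for r in split.test}
            assert not train_p & test_p
            assert len(split.train) + len(split.test) == len(recs)
            for lab in range(3):
                n_train_pat = len({r.patient_id for r in split.train
                                   if r.label == lab})
                assert n_train_pat == round(0.7 * 9)

    def test_same_seed_reproducible_different_seed_varies(self):
        recs = self.records(10)
        a = cn.split_patient_disjoint(recs, seed=3)
        b = cn.split_patient_disjoint(recs, seed=3)
        assert [r.patient_id for r in a.train] == [r.patient_id for r in b.train]
        others = [cn.split_patient_disjoint(recs, seed=s).train for s in range(20)]
        assert any([r.patient_id for r in o] != [r.patient_id for r in a.train]
                   for o in others)

    def test_patient_in_two_classes_rejected(self):
        recs = self.records(5)
        recs[0].patient_id = recs[-1].patient_id
        with pytest.raises(InputError, match="multiple classes"):
            cn.split_patient_disjoint(recs)


class TestClassSeparability:
    @staticmethod
    def pr_values(cfg, label, n, seed):
        rng = np.random.default_rng(seed)
        vals = []
        for _ in range(n):
            rec = cn.synthesize_record(label, cfg, rng)
            vals.append(measure_p_onset_to_r_ms(
                np.asarray(rec.leads["II"]), rec.generation_params["p_amp_mv"]))
        return np.array(vals)

    def test_fiducial_classifier_chance_without_offsets_signal_with(self):
        # a PR-interval threshold separates CAP from controls only when the
        # class-effect offsets are active
        n = 25
        null_cfg = cn.SynthConfig(noise_sd_mv=0.0, wander_amp_mv=0.0,
                                  cap_pr_offset_ms=0.0, cap_p_width_offset_ms=0.0)
        cfg = cn.SynthConfig(noise_sd_mv=0.0, wander_amp_mv=0.0)

        def threshold_accuracy(c):
            a = self.pr_values(c, 0, n, seed=11)
            b = self.pr_values(c, 1, n, seed=22)
            thr = np.median(np.r_[a, b])
            return (np.sum(a > thr) + np.sum(b <= thr)) / (2 * n)

        assert threshold_accuracy(null_cfg) < 0.7
        assert threshold_accuracy(cfg) > 0.9


class TestGenerateDataset:
    def test_manifest_bookkeeping(self, tmp_path):
        cfg = cn.SynthConfig(n_patients=(4, 3, 3))
        man = cn.generate_dataset(cfg, tmp_path)
        assert len(man) == 10
        assert man["label"].value_counts().sort_index().tolist() == [4, 3, 3]
        for f in man["file"]:
            assert (tmp_path / f).exists()

    def test_regeneration_byte_identical(self, tmp_path):
        cfg = cn.SynthConfig(n_patients=(2, 2, 2))
        man1 = cn.generate_dataset(cfg, tmp_path / "a")
        man2 = cn.generate_dataset(cfg, tmp_path / "b")
        assert man1.equals(man2)
        for f in man1["file"]:
            assert (tmp_path / "a" / f).read_bytes() == \
                (tmp_path / "b" / f).read_bytes()

    def test_multi_ecg_patients_split_together(self, tmp_path):
        cfg = cn.SynthConfig(n_patients=(3, 3, 3), ecgs_per_patient=2)
        man = cn.generate_dataset(cfg, tmp_path)
        assert len(man) == 18
        sides = man.groupby("patient_id")["split"].nunique()
        assert (sides == 1).all()
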