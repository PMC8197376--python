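"""Augmentation: noise injection, time shifts, dynamic compression, plans."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import anurapam as ap
from anurapam.augment import AugmentationPlan


def _sine_clip(amplitude=0.1, freq=440.0, label="ec_standard"):
    t = np.arange(ap.CLIP_SAMPLES) / ap.SAMPLE_RATE
    return ap.AudioClip(amplitude * np.sin(2 * np.pi * freq * t),
                        label=label, origin_id="sine")


class TestPlan:
    def test_exactly_ten_recipes_with_distinct_tags(self):
        recipes = AugmentationPlan().recipes()
        assert len(recipes) == 10
        tags = [tag for tag, _, _ in recipes]
        assert len(set(tags)) == 10
        assert tags == ["noise_1", "noise_2", "shift_1.0", "shift_1.25",
                        "shift_1.75", "shift_2.0", "gain_+20", "gain_+40",
                        "gain_-20", "gain_-40"]

    def test_invalid_plans_rejected(self):
        with pytest.raises(ValueError):
            AugmentationPlan(noise_snrs_db=(20.0,))
        with pytest.raises(ValueError):
            AugmentationPlan(shifts_s=(1.0, 1.25, 1.75, 5.0))


class TestWhiteNoise:
    def test_infinite_snr_is_identity(self):
        clip = _sine_clip()
        out = ap.add_white_noise(clip, np.inf, seed=0)
        assert np.array_equal(out.samples, clip.samples)

    def test_noise_rms_matches_requested_snr(self):
        """At 0 dB SNR the added noise has the same RMS as the clip (1%)."""
        clip = _sine_clip(amplitude=0.1)
        out = ap.add_white_noise(clip, 0.0, seed=5)
        noise = out.samples - clip.samples
        clip_rms = np.sqrt(np.mean(clip.samples**2))
        noise_rms = np.sqrt(np.mean(noise**2))
        assert noise_rms == pytest.approx(clip_rms, rel=0.01)

    def test_deterministic_and_metadata_preserved(self):
        clip = _sine_clip()
        a = ap.add_white_noise(clip, 10.0, seed=7)
        b = ap.add_white_noise(clip, 10.0, seed=7)
        assert np.array_equal(a.samples, b.samples)
        assert a.origin_id == clip.origin_id
        assert a.variant_tag != "original"

    def test_zero_clip_rejected(self, zero_clip):
        with pytest.raises(ValueError):
            ap.add_white_noise(zero_clip, 20.0, seed=0)

    def test_nan_snr_rejected(self):
        with pytest.raises(ValueError):
            ap.add_white_noise(_sine_clip(), np.nan, seed=0)


class TestTimeShift:
    def test_zero_shift_identity(self):
        clip = _sine_clip()
        assert np.array_equal(ap.time_shift(clip, 0.0).samples, clip.samples)

    def test_impulse_moves_by_index_arithmetic(self):
        x = np.zeros(ap.CLIP_SAMPLES)
        x[0] = 1.0
        clip = ap.AudioClip(x, label="ec_standard")
        out = ap.time_shift(clip, 1.0)
        assert out.samples[44_100] == 1.0
        assert np.sum(out.samples != 0) == 1

    def test_out_of_range_rejected(self):
        clip = _sine_clip()
        with pytest.raises(ValueError):
            ap.time_shift(clip, 5.0)
        with pytest.raises(ValueError):
            ap.time_shift(clip, -0.5)

    @settings(derandomize=True, max_examples=20, deadline=None)
    @given(st.integers(min_value=0, max_value=220_499),
           st.integers(min_value=0, max_value=2**31 - 1))
    def test_energy_conserved_and_invertible(self, k, seed):
        """Circular shift conserves energy exactly and un-shifting by the
        complement restores the input bit-for-bit."""
        rng = np.random.default_rng(seed)
        x = rng.uniform(-1, 1, 4410)  # short clip: property is length-free
        clip = ap.AudioClip(x, label="ec_standard")
        shift_s = k % 4410 / ap.SAMPLE_RATE
        out = ap.time_shift(clip, shift_s)
        assert np.sum(out.samples**2) == pytest.approx(np.sum(x**2), rel=1e-12)
        back = ap.time_shift(out, (clip.duration - shift_s) % clip.duration)
        assert np.array_equal(back.samples, x)

    def test_pad_mode_zero_fills_head(self):
        x = np.zeros(ap.CLIP_SAMPLES)
        x[-1] = 0.5
        clip = ap.AudioClip(x, label="ec_standard")
        out = ap.time_shift(clip, 1.0, mode="pad")
        assert np.all(out.samples == 0)  # tail content discarded, head zeroed


class TestDynamicCompress:
    def test_zero_amount_identity(self):
        clip = _sine_clip()
        out = ap.dynamic_compress(clip, 0.0)
        assert np.array_equal(out.samples, clip.samples)

    def test_uniform_signal_fully_attenuated(self):
        """A constant-amplitude sinusoid is all-loud: -40% scales RMS by 0.6."""
        clip = _sine_clip(amplitude=0.5)
        out = ap.dynamic_compress(clip, -0.40)
        ratio = (np.sqrt(np.mean(out.samples**2))
                 / np.sqrt(np.mean(clip.samples**2)))
        assert ratio == pytest.approx(0.60, rel=0.02)

    def test_quiet_band_amplified_loud_band_untouched(self):
        """+20% lifts the quiet background ~20% and leaves the call alone."""
        sr = ap.SAMPLE_RATE
        rng = np.random.default_rng(0)
        x = 0.01 * rng.standard_normal(ap.CLIP_SAMPLES)
        t = np.arange(sr) / sr
        x[2 * sr: 3 * sr] += 0.6 * np.sin(2 * np.pi * 1000.0 * t)
        clip = ap.AudioClip(np.clip(x, -1, 1), label="ec_standard")
        out = ap.dynamic_compress(clip, 0.20)

        def seg_rms(a, lo_s, hi_s):
            return np.sqrt(np.mean(a[int(lo_s * sr): int(hi_s * sr)] ** 2))

        call_ratio = (seg_rms(out.samples, 2.1, 2.9)
                      / seg_rms(clip.samples, 2.1, 2.9))
        noise_ratio = (seg_rms(out.samples, 0.0, 1.9)
                       / seg_rms(clip.samples, 0.0, 1.9))
        assert call_ratio == pytest.approx(1.0, abs=0.02)
        assert noise_ratio == pytest.approx(1.20, abs=0.03)

    def test_amount_outside_set_needs_override(self):
        clip = _sine_clip()
        with pytest.raises(ValueError):
            ap.dynamic_compress(clip, -0.5)
        out = ap.dynamic_compress(clip, -0.5, allow_any_amount=True)
        assert out.samples.shape == clip.samples.shape


class TestAugmentClip:
    def test_ten_distinct_variants_same_origin(self):
        clip = ap.generate_clip("ec_standard", seed=1, origin_id="o1")
        variants = ap.augment_clip(clip, AugmentationPlan(rng_seed=0))
        assert len(variants) == 10
        assert len({v.variant_tag for v in variants}) == 10
        assert all(v.origin_id == "o1" for v in variants)
        assert all(v.label == clip.label for v in variants)
        # no variant duplicates another (or the original) bit-exactly
        arrays = [clip.samples] + [v.samples for v in variants]
        for i in range(len(arrays)):
            for j in range(i + 1, len(arrays)):
                assert not np.array_equal(arrays[i], arrays[j])

    def test_augmenting_a_variant_rejected(self):
        clip = ap.generate_clip("ec_standard", seed=1, origin_id="o1")
        noisy = ap.add_white_noise(clip, 20.0, seed=0)
        with pytest.raises(ValueError):
            ap.augment_clip(noisy, AugmentationPlan())


class TestAugmentDataset:
    def test_elevenfold_per_class(self):
        counts = {"ec_standard": 3, "ec_chorus": 2, "ao_distress": 1}
        m = ap.generate_dataset(counts, seed=0)
        aug = ap.augment_dataset(m, AugmentationPlan(rng_seed=0))
        assert len(aug) == 11 * len(m)
        got = aug.class_counts()
        assert got["ec_standard"] == 33
        assert got["ec_chorus"] == 22
        assert got["ao_distress"] == 11

    def test_empty_manifest(self):
        m = ap.generate_dataset({}, seed=0)
        assert len(ap.augment_dataset(m, AugmentationPlan())) == 0

    def test_already_augmented_rejected(self):
        m = ap.generate_dataset({"ec_standard": 1}, seed=0)
        aug = ap.augment_dataset(m, AugmentationPlan())
        with pytest.raises(ValueError):
            ap.augment_dataset(aug, AugmentationPlan())

    def test_duplicate_origins_rejected(self):
        import pandas as pd
        m = ap.generate_dataset({"ec_standard": 2}, seed=0)
        dup = ap.DatasetManifest(
            pd.concat([m.df, m.df.iloc[[0]]], ignore_index=True))
        with pytest.raises(ValueError):
            ap.augment_dataset(dup, AugmentationPlan())

    def test_lazy_rows_match_waveform_augmentation(self):
        """Rendering a manifest variant equals augmenting the rendered
        original directly (same derived seeds)."""
        m = ap.generate_dataset({"ao_standard": 1}, seed=4)
        plan = AugmentationPlan(rng_seed=4)
        aug = ap.augment_dataset(m, plan)
        direct = ap.augment_clip(m.render(0), plan)
        by_tag = {v.variant_tag: v for v in direct}
        for i in range(1, 11):
            rendered = aug.render(i)
            assert np.array_equal(rendered.samples,
                                  by_tag[rendered.variant_tag].samples)
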