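"""Signal-feature extraction: filtering, epoching, artifact rejection,
band power, coherence, aggregation, and within-subject normalization."""
import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from _oracles import dft_power_direct
from mweeg.bands import Band, BandScheme, KUBICKI_BANDS
from mweeg.exceptions import StructuralError
from mweeg.features import (Epoch, band_coherence, band_power, bandpass_notch,
                            build_feature_table, feature_columns,
                            feature_names, filter_frequency_response,
                            normalize_within_subject, power_spectrum,
                            reject_artifacts, segment_epochs)
from mweeg.simulate import Annotations, GeneratorConfig, Recording, generate_session


def _sine_recording(freq, sfreq=250.0, seconds=20, n_ch=2, amp=50.0):
    t = np.arange(int(seconds * sfreq)) / sfreq
    data = np.tile(amp * np.sin(2 * np.pi * freq * t), (n_ch, 1))
    return Recording(data=data, sfreq=sfreq, ch_names=tuple(f"c{i}" for i in range(n_ch)))


class TestBandScheme:
    def test_kubicki_bands_partition_bins_unambiguously(self):
        scheme = BandScheme()
        seen = set()
        for b in scheme:
            bins = scheme.bin_indices(b, 250, 250.0)
            assert len(bins) > 0
            assert not (set(bins) & seen)
            seen |= set(bins)
        assert 0 not in seen           # DC belongs to no band
        assert 31 not in seen and 34 not in seen   # 30-35 Hz gap

    def test_overlapping_bands_rejected(self):
        with pytest.raises(Exception):
            BandScheme((Band("a", 1.0, 5.0), Band("b", 4.0, 8.0)))


class TestFiltering:
    def test_notch_kills_50hz(self):
        rec = _sine_recording(50.0)
        out = bandpass_notch(rec)
        core = slice(500, -500)  # ignore filter edge transients
        ratio = (np.sqrt((out.data[:, core] ** 2).mean())
                 / np.sqrt((rec.data[:, core] ** 2).mean()))
        assert ratio <= 0.10

    def test_passband_preserves_10hz(self):
        rec = _sine_recording(10.0)
        out = bandpass_notch(rec)
        core = slice(500, -500)  # ignore filter edge transients
        ratio = (np.sqrt((out.data[:, core] ** 2).mean())
                 / np.sqrt((rec.data[:, core] ** 2).mean()))
        assert abs(ratio - 1.0) <= 0.05

    def test_stopband_attenuation_of_design(self):
        freqs = np.array([0.15, 50.0, 100.0])
        resp = filter_frequency_response(250.0, freqs)
        assert (10 * np.log10(resp) <= -20.0).all()

    def test_white_noise_spectrum_matches_designed_response(self, rng):
        n = 250 * 120
        x = rng.standard_normal(n)
        rec = Recording(data=x[None, :], sfreq=250.0, ch_names=("c0",))
        out = bandpass_notch(rec)
        f = np.fft.rfftfreq(n, 1 / 250.0)
        pxx = np.abs(np.fft.rfft(out.data[0])) ** 2
        resp = filter_frequency_response(250.0, f)
        # average over coarse bands in the passband interior; flat input PSD
        # E|X_k|^2 = n for unit-variance white noise
        for lo, hi in [(5, 20), (25, 45), (55, 65)]:
            sel = (f >= lo) & (f <= hi)
            measured = pxx[sel].mean() / n
            designed = resp[sel].mean()
            assert measured == pytest.approx(designed, rel=0.15)


class TestEpoching:
    def test_default_session_yields_840_one_second_epochs(self, default_session):
        rec, ann, _ = default_session
        epochs = segment_epochs(rec, ann)
        assert len(epochs) == 840
        assert all(ep.data.shape[1] == 250 for ep in epochs)
        assert all(np.sum([ep.section == s for ep in epochs]) == 20
                   for s in range(42))

    def test_truncated_recording_raises(self, default_session):
        rec, ann, _ = default_session
        cut = Recording(data=rec.data[:, :-100], sfreq=rec.sfreq,
                        ch_names=rec.ch_names)
        with pytest.raises(StructuralError, match="truncated"):
            segment_epochs(cut, ann)

    def test_misaligned_section_raises(self, default_session):
        rec, ann, _ = default_session
        bad = Annotations(section_onsets=ann.section_onsets + 0.5,
                          section_duration=ann.section_duration,
                          probe_answers=ann.probe_answers, rts=ann.rts)
        with pytest.raises(StructuralError):
            segment_epochs(rec, bad)


class TestArtifactRejection:
    def test_quiet_epochs_all_retained(self, rng):
        epochs = [Epoch(data=rng.normal(0, 10, (3, 250)), section=0, global_index=i)
                  for i in range(5)]
        assert not any(ep.artifact for ep in reject_artifacts(epochs))

    def test_transient_at_3x_threshold_flagged(self, rng):
        data = rng.normal(0, 10, (3, 250))
        data[1, 100:110] += 600.0   # 3x the 200 uV p2p threshold
        epochs = [Epoch(data=data, section=0, global_index=0)]
        assert reject_artifacts(epochs)[0].artifact

    def test_injected_artifacts_all_flagged_after_filtering(self):
        """Generator-injected transients survive the band-pass filter and are
        caught by the default thresholds (flagged set contains injected set)."""
        cfg = GeneratorConfig(artifact_rate=0.1, seed=9)
        rec, ann, _ = generate_session(cfg, 0)
        epochs = reject_artifacts(segment_epochs(bandpass_notch(rec), ann))
        flagged = {ep.global_index for ep in epochs if ep.artifact}
        assert set(rec.artifact_windows) <= flagged


class TestSpectra:
    def test_all_zero_epoch_has_zero_power(self):
        ep = Epoch(data=np.zeros((2, 250)), section=0, global_index=0)
        powers = band_power(ep, BandScheme(), 250.0)
        assert all((v == 0).all() for v in powers.values())

    def test_sine_concentrates_in_its_band(self):
        t = np.arange(250) / 250.0
        ep = Epoch(data=np.sin(2 * np.pi * 10 * t)[None, :], section=0,
                   global_index=0)
        powers = band_power(ep, BandScheme(), 250.0)
        assert powers["alpha1"][0] > 0
        assert powers["gamma"][0] <= 1e-6 * powers["alpha1"][0]

    def test_parseval_via_direct_dft(self, rng):
        """Sum of squared DFT magnitudes equals N * sum of squared samples;
        the one-sided bins returned by power_spectrum reconstruct the full sum."""
        x = rng.standard_normal(64)
        full = dft_power_direct(x)
        assert full.sum() == pytest.approx(64 * (x ** 2).sum(), rel=1e-9)
        one_sided = power_spectrum(x) * 64     # |X_k|^2 for k = 0..N/2
        recon = one_sided[0] + one_sided[-1] + 2 * one_sided[1:-1].sum()
        assert recon == pytest.approx(full.sum(), rel=1e-9)


class TestCoherence:
    def _epochs(self, data_list):
        return [Epoch(data=d, section=0, global_index=i)
                for i, d in enumerate(data_list)]

    def test_identical_signals_give_unit_coherence(self, rng):
        eps = self._epochs([np.tile(rng.normal(size=250), (2, 1))
                            for _ in range(10)])
        coh = band_coherence(eps, (0, 1), BandScheme(), 250.0)
        assert all(v == pytest.approx(1.0, abs=1e-9) for v in coh.values())

    def test_independent_noise_coherence_near_1_over_k(self, rng):
        """E[MSC] for independent Gaussian channels with K averaged segments
        is about 1/K; Monte-Carlo over realizations."""
        K = 20
        vals = []
        for _ in range(40):
            eps = self._epochs([rng.normal(size=(2, 250)) for _ in range(K)])
            coh = band_coherence(eps, (0, 1), BandScheme(), 250.0)
            vals.append(np.mean(list(coh.values())))
        assert np.mean(vals) == pytest.approx(1.0 / K, rel=0.25)

    def test_pure_delay_keeps_coherence_near_one(self, rng):
        x = rng.normal(size=250 + 3)
        eps = self._epochs([np.stack([x[3:], x[:-3]]) for _ in range(8)])
        coh = band_coherence(eps, (0, 1), BandScheme(), 250.0)
        assert all(v > 0.99 for v in coh.values())

    def test_requires_two_clean_epochs(self, rng):
        eps = self._epochs([rng.normal(size=(2, 250))])
        with pytest.raises(StructuralError):
            band_coherence(eps, (0, 1), BandScheme(), 250.0)


class TestAggregation:
    def test_feature_count_formula_17_electrodes(self, default_session):
        rec, ann, _ = default_session
        df = build_feature_table(rec, ann, subject=0)
        assert len(feature_columns(df)) == 1224

    @given(n_el=st.integers(2, 6), n_bands=st.integers(1, 4))
    @settings(max_examples=20, deadline=None)
    def test_feature_count_formula_generic(self, n_el, n_bands):
        montage = tuple(f"E{i}" for i in range(n_el))
        scheme = BandScheme(tuple(Band(f"b{i}", 1.5 + 3 * i, 3.0 + 3 * i)
                                  for i in range(n_bands)))
        names = feature_names(montage, scheme)
        assert len(names) == (n_el + n_el * (n_el - 1) // 2) * n_bands

    def test_columns_stable_across_subjects(self, small_config):
        dfs = [build_feature_table(*generate_session(small_config, i)[:2], i)
               for i in range(2)]
        assert list(dfs[0].columns) == list(dfs[1].columns)

    def test_coherence_in_unit_interval_and_power_nonnegative(self, small_session):
        rec, ann, _ = small_session
        df = build_feature_table(rec, ann, subject=0)
        coh_cols = [c for c in df.columns if c.startswith("coh_")]
        pow_cols = [c for c in df.columns if c.startswith("power_")]
        assert ((df[coh_cols] >= 0) & (df[coh_cols] <= 1)).all().all()
        assert (df[pow_cols] >= 0).all().all()


class TestNormalization:
    def test_zero_mean_unit_sd_per_subject(self, small_config):
        df = pd.concat([build_feature_table(*generate_session(small_config, i)[:2], i)
                        for i in range(2)], ignore_index=True)
        norm = normalize_within_subject(df)
        for _, block in norm.groupby("subject"):
            vals = block[feature_columns(norm) + ["response"]].to_numpy()
            assert np.abs(vals.mean(axis=0)).max() < 1e-9
            sds = vals.std(axis=0)
            assert np.abs(sds[sds > 0] - 1.0).max() < 1e-9

    def test_idempotent(self, small_config):
        df = build_feature_table(*generate_session(small_config, 0)[:2], 0)
        once = normalize_within_subject(df)
        twice = normalize_within_subject(once)
        pd.testing.assert_frame_equal(once, twice)

    def test_constant_column_zeroed_with_warning(self, small_config):
        import warnings as w
        df = build_feature_table(*generate_session(small_config, 0)[:2], 0)
        col = feature_columns(df)[0]
        df[col] = 3.14
        with w.catch_warnings(record=True) as caught:
            w.simplefilter("always")
            norm = normalize_within_subject(df)
        assert (norm[col] == 0).all()
        assert any("zero-variance" in str(c.message) for c in caught)
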