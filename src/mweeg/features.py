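"""From raw EEG to per-section feature rows.

Stages: zero-phase band-pass + notch filtering, 1-s epoching within sections,
amplitude/gradient artifact rejection, per-epoch DFT band power, per-section
magnitude-squared coherence (cross-spectra averaged over the section's clean
epochs), section averaging, and within-subject normalization.

Spectral conventions (documented here because the estimator admits several):

* each 1-s epoch is transformed with a plain rectangular-window DFT, giving
  1 Hz resolution (a Hann taper is available but off by default);
* per-bin power is |X_k|^2 / N; band power is the mean over the band's bins;
* magnitude-squared coherence is |S_xy|^2 / (S_xx S_yy) with auto/cross
  spectra averaged across the section's clean epochs, then averaged over the
  band's bins — per-epoch coherence would be identically 1.

Feature names follow the grammar ``power_<electrode>_<band>`` and
``coh_<el1>_<el2>_<band>`` with the electrode pair in montage order.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import signal

from .bands import BandScheme
from .exceptions import ConfigurationError, StructuralError
from .simulate import Annotations, Recording

__all__ = [
    "Epoch",
    "META_COLUMNS",
    "DEFAULT_P2P_THRESHOLD_UV",
    "DEFAULT_GRADIENT_THRESHOLD_UV",
    "DEFAULT_MIN_CLEAN_EPOCHS",
    "bandpass_notch",
    "filter_frequency_response",
    "segment_epochs",
    "reject_artifacts",
    "power_spectrum",
    "band_power",
    "band_coherence",
    "feature_names",
    "build_feature_table",
    "normalize_within_subject",
    "feature_columns",
]

#: non-predictor columns of a section-feature table
META_COLUMNS = ("subject", "section", "response", "n_clean_epochs")

DEFAULT_P2P_THRESHOLD_UV = 200.0        # peak-to-peak rejection threshold
DEFAULT_GRADIENT_THRESHOLD_UV = 150.0   # max sample-to-sample step
DEFAULT_MIN_CLEAN_EPOCHS = 4            # sections with fewer clean epochs are dropped

_BANDPASS = (0.3, 70.0)   # Hz
_NOTCH_FREQ = 50.0        # Hz
_NOTCH_Q = 30.0


@dataclass
class Epoch:
    """One 1-s channel x sample window belonging to exactly one section."""

    data: np.ndarray          # (n_channels, sfreq)
    section: int
    global_index: int         # 1-s window index from recording start
    artifact: bool = False


def _filter_sos(sfreq: float):
    if sfreq <= 2 * _BANDPASS[1]:
        raise ConfigurationError(
            "sampling_rate: too low for the 70 Hz band-pass edge")
    sos_bp = signal.butter(4, _BANDPASS, btype="bandpass", fs=sfreq, output="sos")
    b_n, a_n = signal.iirnotch(_NOTCH_FREQ, _NOTCH_Q, fs=sfreq)
    return sos_bp, (b_n, a_n)


def bandpass_notch(recording: Recording) -> Recording:
    """Zero-phase 0.3-70 Hz band-pass plus 50 Hz notch filtering."""
    sos_bp, (b_n, a_n) = _filter_sos(recording.sfreq)
    out = signal.sosfiltfilt(sos_bp, recording.data, axis=1)
    out = signal.filtfilt(b_n, a_n, out, axis=1)
    return Recording(data=out, sfreq=recording.sfreq, ch_names=recording.ch_names,
                     artifact_windows=recording.artifact_windows)


def filter_frequency_response(sfreq: float, freqs: np.ndarray) -> np.ndarray:
    """Power response of the zero-phase filter cascade at *freqs*.

    Each filter is applied forward and backward (filtfilt), so its amplitude
    gain is |h|^2 and the cascade's power gain is (|h_bp| |h_n|)^4.
    """
    sos_bp, (b_n, a_n) = _filter_sos(sfreq)
    _, h_bp = signal.sosfreqz(sos_bp, worN=freqs, fs=sfreq)
    _, h_n = signal.freqz(b_n, a_n, worN=freqs, fs=sfreq)
    return (np.abs(h_bp) * np.abs(h_n)) ** 4


def segment_epochs(recording: Recording, annotations: Annotations) -> list[Epoch]:
    """Cut the recording into 1-s epochs, respecting section boundaries.

    Only task time inside annotated sections is epoched (probe/instruction
    time, were it present between sections, is skipped).  A recording that
    ends mid-section raises rather than silently truncating.
    """
    fs = recording.sfreq
    n = int(round(fs))
    if annotations.section_duration % 1.0 != 0.0:
        raise StructuralError("section_duration must be a whole number of seconds")
    per_section = int(annotations.section_duration)
    epochs: list[Epoch] = []
    for s, onset in enumerate(annotations.section_onsets):
        if onset % 1.0 != 0.0:
            raise StructuralError(f"section {s} onset not aligned to a whole second")
        start = int(round(onset * fs))
        stop = start + per_section * n
        if stop > recording.n_samples:
            raise StructuralError(
                f"recording truncated mid-section (section {s})")
        for j in range(per_section):
            a = start + j * n
            epochs.append(Epoch(data=recording.data[:, a:a + n], section=s,
                                global_index=a // n))
    return epochs


def reject_artifacts(epochs: list[Epoch],
                     p2p_threshold: float = DEFAULT_P2P_THRESHOLD_UV,
                     gradient_threshold: float = DEFAULT_GRADIENT_THRESHOLD_UV,
                     ) -> list[Epoch]:
    """Flag epochs whose any channel exceeds the peak-to-peak or gradient threshold.

    Returns the same epochs with ``artifact`` set; flagged epochs are excluded
    from every downstream spectral estimate.
    """
    for ep in epochs:
        p2p = ep.data.max(axis=1) - ep.data.min(axis=1)
        grad = np.abs(np.diff(ep.data, axis=1)).max(axis=1) if ep.data.shape[1] > 1 \
            else np.zeros(ep.data.shape[0])
        ep.artifact = bool((p2p > p2p_threshold).any()
                           or (grad > gradient_threshold).any())
    return epochs


def _spectra(data: np.ndarray, taper: bool = False) -> np.ndarray:
    """One-sided DFT of (…, N) samples; rectangular window unless *taper*."""
    if taper:
        data = data * np.hanning(data.shape[-1])
    return np.fft.rfft(data, axis=-1)


def power_spectrum(data: np.ndarray, taper: bool = False) -> np.ndarray:
    """Per-bin power |X_k|^2 / N over the one-sided DFT bins of (…, N) samples."""
    n = data.shape[-1]
    return np.abs(_spectra(data, taper)) ** 2 / n


def band_power(epoch: Epoch, scheme: BandScheme, sfreq: float,
               taper: bool = False) -> dict[str, np.ndarray]:
    """Mean per-bin power of each band, per channel, for one epoch."""
    p = power_spectrum(epoch.data, taper)
    n = epoch.data.shape[-1]
    return {b.name: p[:, scheme.bin_indices(b, n, sfreq)].mean(axis=1)
            for b in scheme}


def _section_spectral(epoch_data: np.ndarray, taper: bool = False
                      ) -> tuple[np.ndarray, np.ndarray]:
    """Auto- and cross-spectra averaged over a section's clean epochs.

    epoch_data: (K, C, N).  Returns (S_auto (C, F), S_cross (C, C, F) complex).
    """
    fx = _spectra(epoch_data, taper)                      # (K, C, F)
    s_auto = (np.abs(fx) ** 2).mean(axis=0)               # (C, F)
    s_cross = np.einsum("kcf,kdf->cdf", fx, np.conj(fx)) / fx.shape[0]
    return s_auto, s_cross


def band_coherence(epochs_in_section: list[Epoch], pair: tuple[int, int],
                   scheme: BandScheme, sfreq: float,
                   taper: bool = False) -> dict[str, float]:
    """Magnitude-squared coherence of a channel pair over a section's clean epochs.

    Requires >= 2 clean epochs (single-segment coherence is identically 1).
    """
    clean = [ep for ep in epochs_in_section if not ep.artifact]
    if len(clean) < 2:
        raise StructuralError("band_coherence requires >= 2 clean epochs")
    i, j = pair
    stack = np.stack([ep.data[[i, j]] for ep in clean])   # (K, 2, N)
    s_auto, s_cross = _section_spectral(stack, taper)
    msc = np.abs(s_cross[0, 1]) ** 2 / (s_auto[0] * s_auto[1])
    n = stack.shape[-1]
    return {b.name: float(msc[scheme.bin_indices(b, n, sfreq)].mean())
            for b in scheme}


def feature_names(montage: tuple[str, ...], scheme: BandScheme) -> tuple[str, ...]:
    """Fixed column order: all power features, then all coherence features.

    Within each block, electrode (or montage-ordered pair) is the outer index
    and band the inner one, so the layout is stable across subjects and runs.
    """
    names = [f"power_{el}_{b.name}" for el in montage for b in scheme]
    names += [f"coh_{a}_{c}_{b.name}"
              for a, c in combinations(montage, 2) for b in scheme]
    return tuple(names)


def build_feature_table(recording: Recording, annotations: Annotations,
                        subject: str | int,
                        scheme: BandScheme | None = None,
                        p2p_threshold: float = DEFAULT_P2P_THRESHOLD_UV,
                        gradient_threshold: float = DEFAULT_GRADIENT_THRESHOLD_UV,
                        min_clean_epochs: int = DEFAULT_MIN_CLEAN_EPOCHS,
                        taper: bool = False,
                        prefiltered: bool = False) -> pd.DataFrame:
    """One subject's section-feature table (raw, pre-normalization).

    Runs filtering (unless *prefiltered*), epoching, artifact rejection, and
    per-section power/coherence aggregation.  The ``response`` column holds
    the raw 1-7 probe answer; sections with fewer than *min_clean_epochs*
    clean epochs are dropped.
    """
    scheme = scheme or BandScheme()
    min_clean_epochs = max(min_clean_epochs, 2)
    rec = recording if prefiltered else bandpass_notch(recording)
    epochs = reject_artifacts(segment_epochs(rec, annotations),
                              p2p_threshold, gradient_threshold)
    fs = rec.sfreq
    n = int(round(fs))
    montage = rec.ch_names
    cols = feature_names(montage, scheme)
    band_bins = {b.name: scheme.bin_indices(b, n, fs) for b in scheme}
    pair_idx = list(combinations(range(len(montage)), 2))

    rows = []
    for s in range(annotations.n_sections):
        clean = [ep for ep in epochs if ep.section == s and not ep.artifact]
        if len(clean) < min_clean_epochs:
            continue
        stack = np.stack([ep.data for ep in clean])       # (K, C, N)
        s_auto, s_cross = _section_spectral(stack, taper)
        power = s_auto / n                                # per-bin |X|^2/N, epoch-avg
        msc = (np.abs(s_cross) ** 2
               / (s_auto[:, None, :] * s_auto[None, :, :]))
        vals = {}
        for bname, bins in band_bins.items():
            p_band = power[:, bins].mean(axis=1)          # (C,)
            m_band = msc[:, :, bins].mean(axis=2)         # (C, C)
            for ci, el in enumerate(montage):
                vals[f"power_{el}_{bname}"] = float(p_band[ci])
            for ci, cj in pair_idx:
                vals[f"coh_{montage[ci]}_{montage[cj]}_{bname}"] = \
                    float(m_band[ci, cj])
        rows.append({"subject": subject, "section": s,
                     "response": int(annotations.probe_answers[s]),
                     "n_clean_epochs": len(clean), **vals})
    df = pd.DataFrame(rows, columns=list(META_COLUMNS) + list(cols))
    return df


def feature_columns(df: pd.DataFrame) -> list[str]:
    return [c for c in df.columns if c not in META_COLUMNS]


def normalize_within_subject(df: pd.DataFrame) -> pd.DataFrame:
    """Z-score every feature column and the response within each subject.

    Population-SD convention (divide by n).  Zero-variance columns are set to
    0 with a warning; subjects with fewer than 2 sections are excluded.
    Idempotent: normalizing an already-normalized table is a no-op.
    """
    cols = feature_columns(df) + ["response"]
    out = []
    for subject, block in df.groupby("subject", sort=False):
        if len(block) < 2:
            warnings.warn(f"subject {subject!r} has < 2 sections; excluded")
            continue
        block = block.copy()
        vals = block[cols].to_numpy(dtype=float)
        mu = vals.mean(axis=0)
        sd = vals.std(axis=0)          # population convention
        zero = sd == 0
        if zero.any():
            bad = [cols[i] for i in np.flatnonzero(zero)]
            warnings.warn(
                f"subject {subject!r}: zero-variance columns set to 0: {bad[:5]}"
                + ("..." if len(bad) > 5 else ""))
        sd_safe = np.where(zero, 1.0, sd)
        z = (vals - mu) / sd_safe
        z[:, zero] = 0.0
        block[cols] = z
        out.append(block)
    if not out:
        return df.iloc[0:0].copy()
    return pd.concat(out, ignore_index=True)
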