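"""Synthetic SART-style EEG cohort generator with a known latent mind-wandering process.

Each synthetic session mimics the study design the package targets: a subject
performs 42 sections of a sustained-attention task, each section 10 trials at
2-s intervals (20 s of task EEG) followed by a thought probe answered on a
1-7 Likert scale.  A latent per-section mind-wandering (MW) intensity follows
an AR(1) process and drives three planted, independently switchable pathways:

* ``effect_linear`` — a shared beta3-band (22-30 Hz) source mixed into Pz and
  O1 with MW-dependent gain (power-compensated, so band power stays flat),
  raising their magnitude-squared coherence monotonically with MW;
* ``effect_nonlinear`` — U-shaped modulations of band-limited 13-21 Hz power
  on the lateral-prefrontal channels F3/F4/F7/F8, each channel with its own
  vertex along the MW axis, so the MW -> beta-power links are curved and
  mutually complementary;
* ``rt_effect`` — per-section reaction-time dispersion growing with MW
  (lognormal per-trial RTs).

Everything is a pure function of ``(config, seed)``: the same configuration
regenerates a bit-identical cohort.
"""
from __future__ import annotations

import json
from dataclasses import dataclass
from functools import lru_cache
from pathlib import Path

import numpy as np
from scipy import signal

from .exceptions import ConfigurationError

__all__ = [
    "DEFAULT_MONTAGE",
    "GeneratorConfig",
    "Recording",
    "Annotations",
    "LatentTruth",
    "generate_session",
    "generate_cohort",
    "inject_artifacts",
    "save_session",
    "load_session",
]

DEFAULT_MONTAGE = (
    "F3", "F4", "F7", "F8", "Fz", "T3", "T4", "TP9", "TP10",
    "P5", "P6", "P9", "P10", "Pz", "O1", "O2", "Oz",
)

#: background white-noise standard deviation, microvolts
BACKGROUND_SD_UV = 15.0
#: between-subject log-amplitude scale SD (makes within-subject normalization matter)
SUBJECT_SCALE_LOG_SD = 0.15
#: number of broadband background sources shared across channels
N_SHARED_SOURCES = 3
#: fraction of background variance carried by shared sources (common-mode
#: activity seen by every channel under a common reference; gives scalp
#: channels the strong mutual correlation real EEG exhibits)
SHARED_VARIANCE_FRACTION = 0.5
#: per-section log-amplitude SD of each shared source (slow arousal-like
#: state drift, independent of MW; makes spectral features co-fluctuate
#: across sections the way real EEG features do)
SHARED_SECTION_LOG_SD = 0.4
#: electrodes carrying the linear (coherence) pathway, with relative source
#: gains; Pz-O1 receives the full gain and is the designated strongest pair,
#: the remaining occipital electrodes couple at reduced gain (parietal-midline
#: to occipital network coupling rather than a single isolated pair)
COHERENCE_GROUP = (("Pz", 1.0), ("O1", 1.0), ("O2", 0.5), ("Oz", 0.5))
COHERENCE_PAIR = ("Pz", "O1")
#: electrodes carrying the non-linear (power) pathway, each with the vertex
#: of its U-shaped MW -> beta-power link in standardized MW units; the
#: staggered vertices model graded engagement depths across the lateral
#: prefrontal cortex, so each channel's power is informative about a
#: different part of the MW axis and no single feature decodes MW well
PREFRONTAL = (("F3", -0.35), ("F4", -0.12), ("F7", 0.12), ("F8", 0.35))
#: injected transient peak amplitude, microvolts (2x the default rejection threshold)
ARTIFACT_PEAK_UV = 400.0
#: between-subject log-SD of each pathway's gain (subjects express the
#: MW pathways with different strength; drawn independently per pathway, so
#: a subject weak on one pathway may be strong on another — single-feature
#: models generalize worse across subjects than multivariate ones)
PATHWAY_HETEROGENEITY_LOG_SD = 0.35
#: between-subject log-SD of per-channel weights within a pathway group
CHANNEL_HETEROGENEITY_LOG_SD = 0.15


@dataclass(frozen=True)
class GeneratorConfig:
    """Study-design and effect-size parameters of the synthetic cohort.

    Defaults reproduce the target study design (42 sections x 10 trials x 2 s
    at 250 Hz on a 17-electrode montage).  Effect gains are dimensionless
    multiples of the background noise amplitude; see docs/methods.md for the
    calibration rationale.
    """

    n_subjects: int = 15
    n_sections: int = 42
    trials_per_section: int = 10
    trial_interval: float = 2.0          # seconds
    sampling_rate: float = 250.0         # Hz
    montage: tuple[str, ...] = DEFAULT_MONTAGE
    mw_ar_coef: float = 0.6              # AR(1) coefficient of the latent MW trace
    mw_innovation_sd: float = 1.0
    effect_linear: float = 0.25           # MW -> Pz-O1 beta3 shared-source mixing gain
    effect_nonlinear: float = 0.3       # MW -> lateral-prefrontal beta power (quadratic)
    rt_effect: float = 0.3               # MW -> per-trial RT dispersion gain
    artifact_rate: float = 0.05          # probability a 1-s window gets a transient
    likert_noise: float = 0.5            # SD of noise added before Likert rounding
    seed: int = 0

    def validate(self) -> None:
        for name in ("n_subjects", "n_sections", "trials_per_section"):
            if int(getattr(self, name)) < 1:
                raise ConfigurationError(f"{name}: must be >= 1")
        if self.trial_interval <= 0:
            raise ConfigurationError("trial_interval: must be > 0")
        if self.sampling_rate <= 2 * 44.0:
            raise ConfigurationError(
                "sampling_rate: must exceed twice the highest band edge (44 Hz)"
            )
        if not 0.0 <= self.artifact_rate < 1.0:
            raise ConfigurationError("artifact_rate: must lie in [0, 1)")
        if len(set(self.montage)) != len(self.montage):
            raise ConfigurationError("montage: electrode labels must be unique")
        if not -1.0 < self.mw_ar_coef < 1.0:
            raise ConfigurationError("mw_ar_coef: must lie in (-1, 1) for stationarity")
        if self.mw_innovation_sd <= 0:
            raise ConfigurationError("mw_innovation_sd: must be > 0")
        if self.likert_noise < 0:
            raise ConfigurationError("likert_noise: must be >= 0")

    @property
    def section_duration(self) -> float:
        return self.trials_per_section * self.trial_interval

    @property
    def session_duration(self) -> float:
        return self.n_sections * self.section_duration


@dataclass
class Recording:
    """Multichannel EEG as a (channels x samples) array in microvolts."""

    data: np.ndarray
    sfreq: float
    ch_names: tuple[str, ...]
    #: global indices of 1-s windows that received injected transients
    artifact_windows: tuple[int, ...] = ()

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def duration(self) -> float:
        return self.n_samples / self.sfreq


@dataclass
class Annotations:
    """Session structure: section boundaries, probe answers, and per-trial RTs."""

    section_onsets: np.ndarray    # seconds, one per section
    section_duration: float       # seconds
    probe_answers: np.ndarray     # int, 1..7, one per section
    rts: np.ndarray               # (n_sections, trials_per_section) seconds

    @property
    def n_sections(self) -> int:
        return len(self.section_onsets)


@dataclass
class LatentTruth:
    """Ground truth for recovery tests: the latent MW trace and planted features."""

    mw_trace: np.ndarray            # per-section latent MW intensity
    planted_features: tuple[str, ...]
    rt_sd_trace: np.ndarray         # per-section log-RT dispersion


def _ar1(rng: np.random.Generator, n: int, a: float, sd: float) -> np.ndarray:
    x = np.empty(n)
    x[0] = rng.normal(0.0, sd / np.sqrt(1.0 - a * a))
    for t in range(1, n):
        x[t] = a * x[t - 1] + rng.normal(0.0, sd)
    return x


def _zscore(x: np.ndarray) -> np.ndarray:
    s = x.std()
    return (x - x.mean()) / s if s > 0 else np.zeros_like(x)


@lru_cache(maxsize=16)
def _band_sos(low: float, high: float, sfreq: float) -> np.ndarray:
    return signal.butter(4, [low, high], btype="bandpass", fs=sfreq,
                         output="sos")


def _bandlimited_noise(rng: np.random.Generator, n: int, sfreq: float,
                       low: float, high: float) -> np.ndarray:
    """Unit-variance noise restricted to [low, high] Hz."""
    sos = _band_sos(low, high, sfreq)
    x = signal.sosfiltfilt(sos, rng.standard_normal(n + 2 * int(sfreq)))
    x = x[int(sfreq):n + int(sfreq)]
    s = x.std()
    return x / s if s > 0 else x


def _likert(rng: np.random.Generator, mw_z: np.ndarray, noise_sd: float) -> np.ndarray:
    noisy = mw_z + rng.normal(0.0, noise_sd, size=mw_z.shape)
    return np.clip(np.round(4.0 + 1.5 * noisy), 1, 7).astype(int)


def _planted_feature_names(config: GeneratorConfig) -> tuple[str, ...]:
    names: list[str] = []
    if config.effect_linear != 0:
        present = [e for e, _w in COHERENCE_GROUP if e in config.montage]
        pairs = [(a, b) for i, a in enumerate(present) for b in present[i + 1:]]
        for a, b in pairs:
            i, j = config.montage.index(a), config.montage.index(b)
            lo, hi = (a, b) if i < j else (b, a)
            names.append(f"coh_{lo}_{hi}_beta3")
    if config.effect_nonlinear != 0:
        for el, _v in PREFRONTAL:
            if el in config.montage:
                names.append(f"power_{el}_beta1")
                names.append(f"power_{el}_beta2")
    return tuple(names)


def generate_session(config: GeneratorConfig, subject_index: int
                     ) -> tuple[Recording, Annotations, LatentTruth]:
    """Generate one subject's session: EEG, annotations, and latent ground truth.

    Deterministic in ``(config, subject_index)``; different subjects receive
    independent sub-streams of ``config.seed`` plus an amplitude scale factor
    drawn per subject, so within-subject normalization downstream is
    consequential.
    """
    config.validate()
    if not 0 <= subject_index < config.n_subjects:
        raise ConfigurationError("subject_index: must be < n_subjects")

    rng = np.random.default_rng(np.random.SeedSequence([int(config.seed) & 0x7FFFFFFF,
                                                        subject_index]))
    fs = config.sampling_rate
    n_ch = len(config.montage)
    sec_len = int(round(config.section_duration * fs))
    n_samples = config.n_sections * sec_len

    mw = _ar1(rng, config.n_sections, config.mw_ar_coef, config.mw_innovation_sd)
    mw_z = _zscore(mw)

    subject_scale = float(np.exp(rng.normal(0.0, SUBJECT_SCALE_LOG_SD)))
    sigma = BACKGROUND_SD_UV

    # background: per-channel noise plus a few broadband sources shared by all
    # channels with per-subject random mixing weights (common-mode activity),
    # so channels are mutually correlated as real referenced EEG is
    rho = SHARED_VARIANCE_FRACTION
    mix = rng.standard_normal((n_ch, N_SHARED_SOURCES))
    mix *= sigma * np.sqrt(rho) / np.linalg.norm(mix, axis=1, keepdims=True)
    shared = rng.standard_normal((N_SHARED_SOURCES, n_samples))
    sec_amp = np.exp(rng.normal(0.0, SHARED_SECTION_LOG_SD,
                                (N_SHARED_SOURCES, config.n_sections)))
    shared *= np.repeat(sec_amp, sec_len, axis=1)
    data = mix @ shared + rng.normal(0.0, sigma * np.sqrt(1.0 - rho),
                                     size=(n_ch, n_samples))

    # linear pathway: shared beta3-band source in the parietal-occipital group
    # (full gain at Pz/O1, reduced at O2/Oz), gain monotone in MW.
    # Power-compensated mixing: each channel also receives an independent
    # same-band source at sqrt(g_max^2 - g^2), so total beta3 power stays flat
    # across sections and the planted effect is specifically coherence.
    # between-subject heterogeneity: each pathway's gain and each channel's
    # weight within a group vary across subjects (drawn independently)
    lin_het = float(np.exp(rng.normal(0.0, PATHWAY_HETEROGENEITY_LOG_SD)))
    nonlin_het = float(np.exp(rng.normal(0.0, PATHWAY_HETEROGENEITY_LOG_SD)))
    ch_het = np.exp(rng.normal(0.0, CHANNEL_HETEROGENEITY_LOG_SD,
                               size=len(COHERENCE_GROUP) + len(PREFRONTAL)))

    group = [(config.montage.index(e), w * ch_het[k])
             for k, (e, w) in enumerate(COHERENCE_GROUP) if e in config.montage]
    if config.effect_linear != 0 and len(group) >= 2:
        g_max = config.effect_linear * lin_het * sigma
        for s in range(config.n_sections):
            gain = config.effect_linear * lin_het * sigma \
                / (1.0 + np.exp(-mw_z[s]))
            src = _bandlimited_noise(rng, sec_len, fs, 22.0, 29.0)
            sl = slice(s * sec_len, (s + 1) * sec_len)
            for ch, w in group:
                own = _bandlimited_noise(rng, sec_len, fs, 22.0, 29.0)
                comp = w * np.sqrt(max(g_max ** 2 - gain ** 2, 0.0))
                data[ch, sl] += (w * gain) * src + comp * own

    # non-linear pathway: U-shaped MW -> prefrontal 13-21 Hz power, with a
    # channel-specific vertex so each channel tiles a different MW range
    if config.effect_nonlinear != 0:
        idx = [(config.montage.index(e), v, ch_het[len(COHERENCE_GROUP) + k])
               for k, (e, v) in enumerate(PREFRONTAL) if e in config.montage]
        for s in range(config.n_sections):
            sl = slice(s * sec_len, (s + 1) * sec_len)
            for ch, vertex, w in idx:
                amp = config.effect_nonlinear * nonlin_het * sigma * np.sqrt(
                    0.25 + (mw_z[s] - vertex) ** 2)
                data[ch, sl] += w * amp * _bandlimited_noise(rng, sec_len, fs,
                                                             13.0, 21.0)

    data *= subject_scale

    # behavior: lognormal per-trial RTs with MW-dependent dispersion
    base_log_sd = 0.10
    rt_sd = np.maximum(base_log_sd * (1.0 + config.rt_effect * mw_z), 0.02)
    rts = np.exp(np.log(0.45)
                 + rng.standard_normal((config.n_sections, config.trials_per_section))
                 * rt_sd[:, None])

    answers = _likert(rng, mw_z, config.likert_noise)

    recording = Recording(data=data, sfreq=fs, ch_names=tuple(config.montage))
    annotations = Annotations(
        section_onsets=np.arange(config.n_sections) * config.section_duration,
        section_duration=config.section_duration,
        probe_answers=answers,
        rts=rts,
    )
    truth = LatentTruth(mw_trace=mw, planted_features=_planted_feature_names(config),
                        rt_sd_trace=rt_sd)

    if config.artifact_rate > 0:
        art_seed = int(rng.integers(0, 2**31 - 1))
        recording = inject_artifacts(recording, annotations,
                                     config.artifact_rate, art_seed)
    return recording, annotations, truth


def generate_cohort(config: GeneratorConfig
                    ) -> list[tuple[Recording, Annotations, LatentTruth]]:
    """Generate all ``config.n_subjects`` sessions (deterministic sub-seeds)."""
    config.validate()
    return [generate_session(config, i) for i in range(config.n_subjects)]


def inject_artifacts(recording: Recording, annotations: Annotations,
                     rate: float, seed: int) -> Recording:
    """Add high-amplitude transients to randomly chosen 1-s windows.

    Each window is contaminated independently with probability ``rate`` by a
    raised-cosine burst (0.2 s, peak ARTIFACT_PEAK_UV, i.e. 2x the default
    peak-to-peak rejection threshold) on a random subset of channels.  The
    contaminated window indices are recorded on the returned Recording for
    test introspection; the input is not modified.
    """
    if not 0.0 <= rate < 1.0:
        raise ConfigurationError("rate: must lie in [0, 1)")
    if rate == 0.0:
        return recording
    rng = np.random.default_rng(seed)
    fs = recording.sfreq
    win = int(round(fs))
    n_windows = recording.n_samples // win
    hit = np.flatnonzero(rng.random(n_windows) < rate)

    data = recording.data.copy()
    burst_len = int(0.2 * fs)
    t = np.arange(burst_len)
    burst = 0.5 * (1.0 - np.cos(2.0 * np.pi * t / (burst_len - 1)))  # 0..1..0
    for w in hit:
        n_aff = rng.integers(2, min(5, data.shape[0]) + 1)
        chans = rng.choice(data.shape[0], size=n_aff, replace=False)
        start = w * win + int(rng.integers(0, win - burst_len))
        sign = rng.choice([-1.0, 1.0])
        for ch in chans:
            data[ch, start:start + burst_len] += sign * ARTIFACT_PEAK_UV * burst
    return Recording(data=data, sfreq=fs, ch_names=recording.ch_names,
                     artifact_windows=tuple(int(w) for w in hit))


def save_session(directory: str | Path, recording: Recording,
                 annotations: Annotations, truth: LatentTruth | None = None) -> None:
    """Write a session as an NPZ matrix container plus a JSON sidecar."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    np.savez(directory / "session.npz", data=recording.data,
             rts=annotations.rts,
             section_onsets=annotations.section_onsets,
             probe_answers=annotations.probe_answers,
             **({"mw_trace": truth.mw_trace, "rt_sd_trace": truth.rt_sd_trace}
                if truth is not None else {}))
    sidecar = {
        "sfreq": recording.sfreq,
        "ch_names": list(recording.ch_names),
        "artifact_windows": list(recording.artifact_windows),
        "section_duration": annotations.section_duration,
        "planted_features": list(truth.planted_features) if truth else None,
    }
    (directory / "session.json").write_text(json.dumps(sidecar, indent=1))


def load_session(directory: str | Path
                 ) -> tuple[Recording, Annotations, LatentTruth | None]:
    directory = Path(directory)
    sidecar = json.loads((directory / "session.json").read_text())
    arrays = np.load(directory / "session.npz")
    recording = Recording(data=arrays["data"], sfreq=sidecar["sfreq"],
                          ch_names=tuple(sidecar["ch_names"]),
                          artifact_windows=tuple(sidecar["artifact_windows"]))
    annotations = Annotations(section_onsets=arrays["section_onsets"],
                              section_duration=sidecar["section_duration"],
                              probe_answers=arrays["probe_answers"],
                              rts=arrays["rts"])
    truth = None
    if "mw_trace" in arrays:
        truth = LatentTruth(mw_trace=arrays["mw_trace"],
                            planted_features=tuple(sidecar["planted_features"] or ()),
                            rt_sd_trace=arrays["rt_sd_trace"])
    return recording, annotations, truth
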