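"""Synthetic multi-subject EEG+ECG studies with alert/drowsy structure.

The generator emulates the statistical signatures the analysis pipeline
assumes, so every downstream stage is testable without any recording
download:

* EEG: per channel, band-limited Gaussian noise whose relative power in the
  delta/theta/alpha/beta/gamma bands is set exactly by a :class:`BandProfile`
  (FFT-domain shaping).  Drowsy profiles raise delta/theta/alpha fractions on
  central/parietal/occipital channels; a *regularity* parameter narrows the
  alpha band so drowsy traces are also less complex (lower sample entropy).
* ECG: an integral-pulse-frequency-modulation (IPFM) beat generator - beats
  fire when the integral of an instantaneous heart rate, sinusoidally
  modulated at the LF (0.1 Hz) and HF (0.25 Hz) rhythms, crosses successive
  integers.  Drowsy profiles shift modulation power from LF toward HF,
  lowering the LF/HF ratio of the recovered tachogram.  QRS complexes are
  rendered as a fixed 80-ms biphasic template (1 mV) on a flat baseline.

One seeded generator drives everything; per-subject substreams are derived
from fixed seed offsets, so an identical :class:`SynthStudyConfig` yields a
bit-identical study.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .eeg import BAND_NAMES, BANDS
from .errors import ConfigurationError, ParameterError
from .io import CHANNEL_GROUPS, ECG_LABEL, EEG_1020, GROUP_OF_CHANNEL, Recording

ALPHA_CENTER_HZ = 10.0

# study protocol geometry (seconds): each event is preceded by >= 10 min of
# alert-state signal (5-min alert segment + 4-min HRV window context + 1 min
# spare) and followed by 6 min of drowsy-state signal.
PRE_EVENT_S = 600.0
POST_EVENT_S = 360.0


# ---------------------------------------------------------------------------
# Profiles
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class BandProfile:
    """Target relative band powers per scalp region plus a regularity knob.

    ``fractions[region][band]`` are non-negative and sum to one per region.
    ``regularity`` in [0, 1] narrows the effective alpha bandwidth (1 =
    narrow, rhythmic, low-entropy alpha); ``rms_uv`` sets each channel's
    overall RMS amplitude in microvolts.
    """

    fractions: dict
    regularity: float = 0.3
    rms_uv: float = 15.0

    def __post_init__(self):
        for region, fr in self.fractions.items():
            if set(fr) != set(BAND_NAMES):
                raise ConfigurationError(
                    f"region {region!r}: bands must be exactly {BAND_NAMES}"
                )
            vals = np.array([fr[b] for b in BAND_NAMES], dtype=float)
            if (vals < 0).any():
                raise ConfigurationError(
                    f"region {region!r}: negative band fraction"
                )
            if abs(vals.sum() - 1.0) > 1e-6:
                raise ConfigurationError(
                    f"region {region!r}: band fractions sum to "
                    f"{vals.sum():.6f}, not 1"
                )
        if not 0.0 <= self.regularity <= 1.0:
            raise ConfigurationError("regularity must lie in [0, 1]")
        if not self.rms_uv > 0:
            raise ConfigurationError("rms_uv must be positive")

    def fractions_for(self, channel: str) -> dict:
        region = GROUP_OF_CHANNEL.get(channel)
        if region is None or region not in self.fractions:
            raise ConfigurationError(
                f"no band profile for channel {channel!r}"
            )
        return self.fractions[region]

    @classmethod
    def alert_default(cls) -> "BandProfile":
        """Relaxed-wakefulness spectrum: posterior alpha moderate, broadband."""
        return cls(fractions={
            "frontal":   {"delta": 0.30, "theta": 0.22, "alpha": 0.18,
                          "beta": 0.20, "gamma": 0.10},
            "temporal":  {"delta": 0.28, "theta": 0.22, "alpha": 0.20,
                          "beta": 0.20, "gamma": 0.10},
            "central":   {"delta": 0.28, "theta": 0.22, "alpha": 0.20,
                          "beta": 0.20, "gamma": 0.10},
            "parietal":  {"delta": 0.25, "theta": 0.20, "alpha": 0.25,
                          "beta": 0.20, "gamma": 0.10},
            "occipital": {"delta": 0.22, "theta": 0.18, "alpha": 0.30,
                          "beta": 0.20, "gamma": 0.10},
        }, regularity=0.3)

    @classmethod
    def drowsy_default(cls) -> "BandProfile":
        """Drowsy spectrum: delta/theta/alpha up over central, parietal and
        occipital regions, fast activity down, alpha more rhythmic."""
        return cls(fractions={
            "frontal":   {"delta": 0.30, "theta": 0.22, "alpha": 0.18,
                          "beta": 0.20, "gamma": 0.10},
            "temporal":  {"delta": 0.28, "theta": 0.22, "alpha": 0.21,
                          "beta": 0.19, "gamma": 0.10},
            "central":   {"delta": 0.32, "theta": 0.24, "alpha": 0.24,
                          "beta": 0.13, "gamma": 0.07},
            "parietal":  {"delta": 0.28, "theta": 0.24, "alpha": 0.31,
                          "beta": 0.11, "gamma": 0.06},
            "occipital": {"delta": 0.25, "theta": 0.21, "alpha": 0.37,
                          "beta": 0.11, "gamma": 0.06},
        }, regularity=0.65)


@dataclass(frozen=True)
class HRVProfile:
    """IPFM heart-rate modulation: sinusoidal LF/HF (and slow VLF) rhythms
    plus broadband rate noise.

    Modulation depths are dimensionless fractions of the mean rate and must
    stay below 0.5 (larger risks non-physiologic RR intervals).
    """

    mean_hr_bpm: float = 72.0
    lf_depth: float = 0.09
    hf_depth: float = 0.05
    lf_freq_hz: float = 0.1
    hf_freq_hz: float = 0.25
    vlf_depth: float = 0.012
    vlf_freq_hz: float = 0.015
    noise_depth: float = 0.05

    def __post_init__(self):
        for name in ("lf_depth", "hf_depth", "vlf_depth", "noise_depth"):
            d = getattr(self, name)
            if not 0.0 <= d < 0.5:
                raise ConfigurationError(
                    f"{name}={d} outside [0, 0.5): risk of non-physiologic RR"
                )
        if not 30.0 < self.mean_hr_bpm < 200.0:
            raise ConfigurationError(
                f"mean HR {self.mean_hr_bpm} bpm outside (30, 200)"
            )

    @classmethod
    def alert_default(cls) -> "HRVProfile":
        """Sympathetically dominated: LF modulation exceeds HF."""
        return cls(mean_hr_bpm=72.0, lf_depth=0.095, hf_depth=0.045,
                   vlf_depth=0.012)

    @classmethod
    def drowsy_default(cls) -> "HRVProfile":
        """Vagally shifted: LF down, HF up (lower LF/HF ratio), VLF up."""
        return cls(mean_hr_bpm=69.0, lf_depth=0.060, hf_depth=0.072,
                   vlf_depth=0.02)


def interpolate_band_profiles(alert: BandProfile, drowsy: BandProfile,
                              s: float) -> BandProfile:
    """Linear interpolation on the band-fraction simplex; s=0 -> alert."""
    s = float(np.clip(s, 0.0, 1.0))
    fr = {
        region: {
            b: (1 - s) * alert.fractions[region][b]
            + s * drowsy.fractions[region][b]
            for b in BAND_NAMES
        }
        for region in alert.fractions
    }
    return BandProfile(
        fractions=fr,
        regularity=(1 - s) * alert.regularity + s * drowsy.regularity,
        rms_uv=(1 - s) * alert.rms_uv + s * drowsy.rms_uv,
    )


def interpolate_hrv_profiles(alert: HRVProfile, drowsy: HRVProfile,
                             s: float) -> HRVProfile:
    s = float(np.clip(s, 0.0, 1.0))

    def lerp(a, b):
        return (1 - s) * a + s * b

    return HRVProfile(
        mean_hr_bpm=lerp(alert.mean_hr_bpm, drowsy.mean_hr_bpm),
        lf_depth=lerp(alert.lf_depth, drowsy.lf_depth),
        hf_depth=lerp(alert.hf_depth, drowsy.hf_depth),
        lf_freq_hz=lerp(alert.lf_freq_hz, drowsy.lf_freq_hz),
        hf_freq_hz=lerp(alert.hf_freq_hz, drowsy.hf_freq_hz),
        vlf_depth=lerp(alert.vlf_depth, drowsy.vlf_depth),
        vlf_freq_hz=lerp(alert.vlf_freq_hz, drowsy.vlf_freq_hz),
        noise_depth=lerp(alert.noise_depth, drowsy.noise_depth),
    )


# ---------------------------------------------------------------------------
# EEG synthesis
# ---------------------------------------------------------------------------

def _as_rng(seed) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


def _band_masks(freqs: np.ndarray, regularity: float) -> dict:
    """Spectral masks per band; the alpha mask narrows with regularity."""
    masks = {}
    for band, (lo, hi) in BANDS.items():
        if band == "gamma":
            m = (freqs >= lo) & (freqs <= hi)
        else:
            m = (freqs >= lo) & (freqs < hi)
        if band == "alpha":
            half_width = 2.0 * (1.0 - 0.8 * regularity)
            m &= (np.abs(freqs - ALPHA_CENTER_HZ) <= half_width)
        masks[band] = m
    return masks


def generate_eeg_segment(profile: BandProfile, duration_s: float,
                         fs: float = 500.0, seed=None, state: str = "alert",
                         channels: list[str] | None = None) -> np.ndarray:
    """Generate a zero-mean multichannel EEG block matching ``profile``.

    Each channel is independent Gaussian noise shaped in the FFT domain so
    its relative band powers equal the profile's fractions for that
    channel's scalp region (exactly, at the synthesis resolution).

    Returns an array of shape ``(len(channels), duration_s * fs)`` in
    microvolts; ``channels`` defaults to the full 19-channel montage.
    """
    if duration_s < 2:
        raise ParameterError("duration_s must be >= 2 s")
    if fs < 100:
        raise ParameterError("fs must be >= 100 Hz")
    rng = _as_rng(seed)
    channels = list(channels) if channels is not None else list(EEG_1020)
    n = int(round(duration_s * fs))
    freqs = np.fft.rfftfreq(n, 1.0 / fs)
    masks = _band_masks(freqs, profile.regularity)

    out = np.empty((len(channels), n), dtype=np.float64)
    for ci, ch in enumerate(channels):
        fracs = profile.fractions_for(ch)
        spec = np.fft.rfft(rng.standard_normal(n))
        shaped = np.zeros_like(spec)
        for band, mask in masks.items():
            target = fracs[band]
            if target <= 0 or not mask.any():
                continue
            power = np.sum(np.abs(spec[mask]) ** 2)
            if power == 0:
                continue
            shaped[mask] = spec[mask] * math.sqrt(target / power)
        x = np.fft.irfft(shaped, n)
        sd = x.std()
        if sd > 0:
            x *= profile.rms_uv / sd
        out[ci] = x
    return out


# ---------------------------------------------------------------------------
# ECG synthesis (IPFM)
# ---------------------------------------------------------------------------

QRS_DURATION_S = 0.08
QRS_AMPLITUDE_UV = 1000.0  # 1 mV


def _qrs_template(fs: float) -> tuple[np.ndarray, int]:
    """Fixed biphasic 80-ms pulse; returns (template, peak offset)."""
    n = max(4, int(round(QRS_DURATION_S * fs)))
    t = np.arange(n) / n
    tpl = QRS_AMPLITUDE_UV * np.sin(2 * np.pi * t)
    return tpl, int(np.argmax(tpl))


def _smooth_noise(n: int, fs: float, rng: np.random.Generator) -> np.ndarray:
    """Unit-variance rate noise band-limited below ~1 Hz."""
    from scipy import signal as sp_signal

    w = rng.standard_normal(n)
    sos = sp_signal.butter(2, 1.0, btype="lowpass", fs=fs, output="sos")
    x = sp_signal.sosfiltfilt(sos, w)
    sd = x.std()
    return x / sd if sd > 0 else x


def _ipfm(spans: list[tuple[HRVProfile, float]], fs: float,
          rng: np.random.Generator) -> tuple[np.ndarray, np.ndarray]:
    """Run the IPFM beat generator over consecutive profile spans.

    The rate integrator runs continuously across span boundaries, so the
    beat train has no seam at state transitions.  Returns the rendered ECG
    (microvolts) and the beat times (seconds).
    """
    total_s = sum(d for _, d in spans)
    n_total = int(round(total_s * fs))
    t = np.arange(n_total) / fs
    rate = np.empty(n_total)

    phases = rng.uniform(0, 2 * np.pi, size=3)  # VLF, LF, HF - shared
    noise = _smooth_noise(n_total, fs, rng)

    start = 0
    for prof, dur in spans:
        stop = min(n_total, start + int(round(dur * fs)))
        tt = t[start:stop]
        mod = (
            prof.vlf_depth * np.sin(2 * np.pi * prof.vlf_freq_hz * tt
                                    + phases[0])
            + prof.lf_depth * np.sin(2 * np.pi * prof.lf_freq_hz * tt
                                     + phases[1])
            + prof.hf_depth * np.sin(2 * np.pi * prof.hf_freq_hz * tt
                                     + phases[2])
            + prof.noise_depth * noise[start:stop]
        )
        rate[start:stop] = (prof.mean_hr_bpm / 60.0) * (1.0 + mod)
        start = stop
    np.clip(rate, 0.1, None, out=rate)

    integral = np.cumsum(rate) / fs
    n_beats = int(np.floor(integral[-1]))
    targets = np.arange(1, n_beats + 1, dtype=np.float64)
    idx = np.searchsorted(integral, targets)
    idx = np.minimum(idx, n_total - 1)
    # sub-sample refinement by linear interpolation of the integral
    prev = np.maximum(idx - 1, 0)
    denom = integral[idx] - integral[prev]
    frac = np.where(denom > 0, (targets - integral[prev]) / denom, 0.0)
    beat_times = (prev + frac) / fs

    tpl, peak_off = _qrs_template(fs)
    ecg = np.zeros(n_total)
    starts = np.round(beat_times * fs).astype(int) - peak_off
    for s0 in starts:
        a, b = max(s0, 0), min(s0 + tpl.size, n_total)
        if b > a:
            ecg[a:b] += tpl[a - s0:b - s0]
    return ecg, beat_times


def generate_ecg(profile: HRVProfile, duration_s: float, fs: float = 500.0,
                 seed=None) -> np.ndarray:
    """Generate a single-lead ECG (microvolts) with IPFM-controlled beats.

    The RR tachogram recovered by R-peak detection carries LF and HF
    spectral peaks whose power ratio is monotone in the configured
    modulation-depth ratio.
    """
    if duration_s < 60:
        raise ParameterError("duration_s must be >= 60 s for HRV analysis")
    rng = _as_rng(seed)
    ecg, _ = _ipfm([(profile, duration_s)], fs, rng)
    return ecg


# ---------------------------------------------------------------------------
# Whole-study generation
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SynthStudyConfig:
    """Study-level knobs; the defaults emulate the drowsy-driver protocol:
    11 subjects, one drowsy event each, 5-min alert + 5-min drowsy spans.

    ``effect_scale`` in [0, 1] shrinks every alert-vs-drowsy contrast
    (0 = null study: both states drawn from identical distributions).
    Per-subject severity and spectral baselines are randomized so subjects
    differ, which is what makes leave-one-subject-out evaluation meaningful.
    """

    n_subjects: int = 11
    events_per_subject: int = 1
    alert_band: BandProfile = field(default_factory=BandProfile.alert_default)
    drowsy_band: BandProfile = field(
        default_factory=BandProfile.drowsy_default)
    alert_hrv: HRVProfile = field(default_factory=HRVProfile.alert_default)
    drowsy_hrv: HRVProfile = field(default_factory=HRVProfile.drowsy_default)
    fs: float = 500.0
    seed: int = 0
    effect_scale: float = 1.0
    channels: tuple = tuple(EEG_1020)
    subject_band_sigma: float = 0.18
    minute_band_sigma: float = 0.12
    subject_effect_mean: float = 0.55
    subject_effect_sigma: float = 0.3
    state_span_sigma: float = 0.06
    pre_event_s: float = PRE_EVENT_S
    post_event_s: float = POST_EVENT_S

    def __post_init__(self):
        if self.n_subjects < 1 or self.events_per_subject < 1:
            raise ConfigurationError("need >= 1 subject and >= 1 event")
        if not 0.0 <= self.effect_scale <= 1.0:
            raise ConfigurationError("effect_scale must lie in [0, 1]")
        if self.fs < 100:
            raise ConfigurationError("fs must be >= 100 Hz")
        if self.pre_event_s < 540.0:
            raise ConfigurationError(
                "pre_event_s must be >= 540 s (5-min alert segment plus "
                "4-min HRV window context): event too close to recording edge"
            )
        if self.post_event_s < 310.0:
            raise ConfigurationError(
                "post_event_s must be >= 310 s: event too close to "
                "recording edge"
            )
        unknown = [c for c in self.channels if c not in EEG_1020]
        if unknown:
            raise ConfigurationError(f"unknown EEG channels: {unknown}")

    @property
    def cycle_s(self) -> float:
        """Per-event block: alert run-up + drowsy aftermath."""
        return self.pre_event_s + self.post_event_s


def _jitter_fractions(profile: BandProfile, draws: dict,
                      sigma: float) -> BandProfile:
    """Multiplicative log-normal jitter of band fractions, renormalized."""
    fr = {}
    for region, fracs in profile.fractions.items():
        vals = np.array([fracs[b] for b in BAND_NAMES])
        vals = vals * np.exp(sigma * draws[region])
        vals = vals / vals.sum()
        fr[region] = dict(zip(BAND_NAMES, vals))
    return replace(profile, fractions=fr)


def _group_draws(rng: np.random.Generator) -> dict:
    return {g: rng.standard_normal(len(BAND_NAMES))
            for g in CHANNEL_GROUPS}


def subject_profiles(config: SynthStudyConfig, rng: np.random.Generator):
    """Draw one subject's alert/drowsy band and HRV profiles.

    A single baseline jitter is applied to both states (a subject trait),
    then the drowsy profile is pulled toward the drowsy target by the
    subject's drowsiness severity times the study effect scale.
    """
    baseline = _group_draws(rng)
    severity = rng.normal(config.subject_effect_mean,
                          config.subject_effect_sigma)
    severity = float(np.clip(severity, 0.05, 1.0))
    s = config.effect_scale * severity

    alert_band = _jitter_fractions(config.alert_band, baseline,
                                   config.subject_band_sigma)
    drowsy_target = _jitter_fractions(config.drowsy_band, baseline,
                                      config.subject_band_sigma)
    drowsy_band = interpolate_band_profiles(alert_band, drowsy_target, s)

    hr_shift = rng.normal(0.0, 5.0)
    depth_jit = np.exp(rng.normal(0.0, 0.18, size=2))

    def personalize(p: HRVProfile) -> HRVProfile:
        return HRVProfile(
            mean_hr_bpm=float(np.clip(p.mean_hr_bpm + hr_shift, 40, 150)),
            lf_depth=float(min(p.lf_depth * depth_jit[0], 0.45)),
            hf_depth=float(min(p.hf_depth * depth_jit[1], 0.45)),
            lf_freq_hz=p.lf_freq_hz, hf_freq_hz=p.hf_freq_hz,
            vlf_depth=p.vlf_depth, vlf_freq_hz=p.vlf_freq_hz,
            noise_depth=p.noise_depth,
        )

    alert_hrv = personalize(config.alert_hrv)
    drowsy_hrv = interpolate_hrv_profiles(
        alert_hrv, personalize(config.drowsy_hrv), s)
    return alert_band, drowsy_band, alert_hrv, drowsy_hrv


def generate_study(
    config: SynthStudyConfig,
) -> tuple[list[Recording], pd.DataFrame]:
    """Generate one Recording per subject plus the event annotation table.

    Each event sits ``pre_event_s`` into its block: the 5 minutes before the
    onset are drawn from the subject's alert profiles, the 5 minutes after
    from the drowsy profiles.  EEG is synthesized minute-by-minute with
    small per-minute profile jitter so instances within a subject-state are
    not duplicates.
    """
    recordings: list[Recording] = []
    events_rows = []
    minutes_per_pre = int(config.pre_event_s // 60)
    minutes_per_post = int(round(config.post_event_s / 60))
    if minutes_per_pre * 60 != config.pre_event_s or \
            minutes_per_post * 60 != config.post_event_s:
        raise ConfigurationError("pre/post event spans must be whole minutes")

    n_ch = len(config.channels)
    spm = int(round(60 * config.fs))  # samples per minute
    n_total = int(round(config.events_per_subject * config.cycle_s
                        * config.fs))

    for si in range(config.n_subjects):
        subject_id = f"S{si + 1:02d}"
        rng = np.random.default_rng([config.seed, 20170831, si])
        alert_band, drowsy_band, alert_hrv, drowsy_hrv = subject_profiles(
            config, rng)

        data = np.empty((n_ch + 1, n_total), dtype=np.float64)
        hrv_spans = []
        cursor = 0
        for ev in range(config.events_per_subject):
            for state_prof, hrv_prof, minutes in (
                    (alert_band, alert_hrv, minutes_per_pre),
                    (drowsy_band, drowsy_hrv, minutes_per_post)):
                # slow physiological drift: each state span gets its own
                # baseline offset on top of the subject profile
                span_prof = _jitter_fractions(
                    state_prof, _group_draws(rng), config.state_span_sigma)
                span_depth = np.exp(rng.normal(0.0, 0.10, size=2))
                for _ in range(minutes):
                    draws = _group_draws(rng)
                    minute_prof = _jitter_fractions(
                        span_prof, draws, config.minute_band_sigma)
                    data[:n_ch, cursor:cursor + spm] = generate_eeg_segment(
                        minute_prof, 60.0, config.fs, rng,
                        channels=list(config.channels))
                    cursor += spm
                hrv_spans.append((replace(
                    hrv_prof,
                    lf_depth=min(hrv_prof.lf_depth * span_depth[0], 0.45),
                    hf_depth=min(hrv_prof.hf_depth * span_depth[1], 0.45),
                ), config.pre_event_s if hrv_prof is alert_hrv
                    else config.post_event_s))
            events_rows.append({
                "subject_id": subject_id,
                "event_onset_s": config.pre_event_s + ev * config.cycle_s,
            })

        ecg, _ = _ipfm(hrv_spans, config.fs, rng)
        data[n_ch, :] = ecg
        recordings.append(Recording(
            subject_id=subject_id, fs=config.fs,
            labels=list(config.channels) + [ECG_LABEL], data=data,
        ))

    events = pd.DataFrame(events_rows)
    return recordings, events
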