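"""ECG processing: R-peak detection, RR tachogram filtering, and HRV
spectral features on sliding 5-min windows.

HRV band powers follow the standard split - VLF below 0.04 Hz, LF
0.04-0.15 Hz, HF 0.15-0.4 Hz.  LF and HF are reported in normalized units,

    P_LF = LF_abs / (P_total - VLF_abs),   P_HF = HF_abs / (P_total - VLF_abs),

with the LF/HF ratio as the sympathovagal balance index.  ``P_total`` is the
tachogram's total spectral power from 0.003 Hz up to the Nyquist of the
resampled series (not VLF+LF+HF, which would force P_LF + P_HF = 1).
Windows slide by one minute (80% overlap at the 5-min width), providing one
value per minute.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import interpolate as sp_interp
from scipy import signal as sp_signal

from .errors import EmptyDataError, ParameterError

HRV_BANDS = {
    "vlf": (0.003, 0.04),
    "lf": (0.04, 0.15),
    "hf": (0.15, 0.4),
}

RR_MIN_S = 0.3
RR_MAX_S = 2.0
RR_NEIGHBOR_TOL = 0.3  # max fractional deviation from local median
MIN_RR_PER_WINDOW = 30

RESAMPLE_HZ = 4.0
WELCH_SEGMENT_S = 120.0

WINDOW_S = 300.0  # 5-min HRV window
HOP_S = 60.0      # 80% overlap -> one value per minute


@dataclass(frozen=True)
class RRSeries:
    """Beat times with RR intervals (each interval timestamped at its later
    beat) and validity flags from outlier filtering."""

    beat_times: np.ndarray   # s, strictly increasing
    rr: np.ndarray           # s, len = len(beat_times) - 1
    rr_times: np.ndarray     # s, time of the later beat of each interval
    valid: np.ndarray        # bool, per interval


@dataclass(frozen=True)
class HRVWindow:
    """HRV features of one 5-min window.

    ``p_lf``/``p_hf`` are normalized units in [0, 1]; ``lf_hf_ratio`` is
    their quotient; ``p_vlf_abs`` is absolute VLF power in ms^2; ``hr`` is
    the mean heart rate (beats/min).  ``ok`` is False when the window had
    fewer than 30 valid RR intervals (features are NaN then).
    """

    start_s: float
    end_s: float
    p_vlf_abs: float
    p_lf: float
    p_hf: float
    lf_hf_ratio: float
    hr: float
    n_valid_rr: int
    ok: bool


# ---------------------------------------------------------------------------
# R-peak detection (Pan-Tompkins-style)
# ---------------------------------------------------------------------------

def detect_r_peaks(ecg: np.ndarray, fs: float) -> np.ndarray:
    """Detect R-peak times (seconds) in a single-lead ECG.

    Pipeline: 5-15 Hz band-pass, differentiation, squaring, 150-ms
    moving-window integration, adaptive signal/noise threshold with a
    200-ms refractory period, then refinement to the local maximum of the
    band-passed signal near each detection.
    """
    ecg = np.asarray(ecg, dtype=np.float64)
    if ecg.size < 10 * fs:
        raise ParameterError("need at least 10 s of ECG")
    sos = sp_signal.butter(2, [5.0, 15.0], btype="bandpass", fs=fs,
                           output="sos")
    filt = sp_signal.sosfiltfilt(sos, ecg)
    deriv = np.gradient(filt)
    squared = deriv ** 2
    win = max(1, int(round(0.15 * fs)))
    integrated = np.convolve(squared, np.ones(win) / win, mode="same")

    refractory = int(round(0.2 * fs))
    cand, _ = sp_signal.find_peaks(integrated, distance=refractory)
    if cand.size == 0 or integrated.max() <= 0:
        raise EmptyDataError("no R-peaks found (flat-line ECG?)")

    # adaptive running estimates of signal and noise peak levels
    init = integrated[:int(2 * fs)]
    spki = float(init.max()) * 0.5 if init.size else float(integrated.max())
    npki = float(np.mean(init)) * 0.5 if init.size else 0.0
    accepted = []
    for p in cand:
        thr = npki + 0.25 * (spki - npki)
        if integrated[p] > thr:
            accepted.append(p)
            spki = 0.125 * integrated[p] + 0.875 * spki
        else:
            npki = 0.125 * integrated[p] + 0.875 * npki
    if not accepted:
        raise EmptyDataError("no R-peaks exceeded the adaptive threshold")

    # refine to the filtered-signal maximum near each detection
    half = int(round(0.1 * fs))
    peaks = []
    for p in accepted:
        a, b = max(p - half, 0), min(p + half + 1, ecg.size)
        peaks.append(a + int(np.argmax(filt[a:b])))
    peaks = np.unique(peaks)
    # enforce refractory after refinement
    kept = [int(peaks[0])]
    for p in peaks[1:]:
        if p - kept[-1] >= refractory:
            kept.append(int(p))
    return np.asarray(kept, dtype=np.float64) / fs


# ---------------------------------------------------------------------------
# RR filtering
# ---------------------------------------------------------------------------

def rr_filter(beat_times: np.ndarray) -> RRSeries:
    """Build the RR series and flag physiologically implausible intervals.

    An interval is invalid if it lies outside (0.3, 2.0) s or deviates more
    than 30% from the median of its five nearest neighbours.  Invalid
    intervals are excluded from spectral analysis but keep their place in
    the series.
    """
    beat_times = np.asarray(beat_times, dtype=np.float64)
    if beat_times.size < 2:
        raise EmptyDataError("need at least 2 beats for an RR series")
    if np.any(np.diff(beat_times) <= 0):
        raise ParameterError("beat times must be strictly increasing")
    rr = np.diff(beat_times)
    rr_times = beat_times[1:]
    n = rr.size
    valid = (rr > RR_MIN_S) & (rr < RR_MAX_S)
    for i in range(n):
        lo = max(0, i - 2)
        hi = min(n, i + 3)
        neigh = np.concatenate([rr[lo:i], rr[i + 1:hi]])
        if neigh.size == 0:
            continue
        med = np.median(neigh)
        if med > 0 and abs(rr[i] - med) > RR_NEIGHBOR_TOL * med:
            valid[i] = False
    return RRSeries(beat_times=beat_times, rr=rr, rr_times=rr_times,
                    valid=valid)


# ---------------------------------------------------------------------------
# Spectral analysis
# ---------------------------------------------------------------------------

def hrv_spectrum(rr: RRSeries, start_s: float,
                 end_s: float) -> tuple[np.ndarray, np.ndarray]:
    """Welch PSD of the evenly resampled tachogram within one window.

    The valid RR intervals inside ``[start_s, end_s)`` are cubic-
    interpolated onto a 4 Hz grid, mean-detrended, and Welch-estimated with
    120-s segments at 50% overlap.  Returns ``(freqs, psd)`` with the PSD
    in s^2/Hz.
    """
    sel = (rr.rr_times >= start_s) & (rr.rr_times < end_s) & rr.valid
    if sel.sum() < MIN_RR_PER_WINDOW:
        raise EmptyDataError(
            f"window [{start_s}, {end_s}) s has only {int(sel.sum())} "
            f"valid RR intervals (< {MIN_RR_PER_WINDOW})"
        )
    t = rr.rr_times[sel]
    y = rr.rr[sel]
    interp = sp_interp.interp1d(t, y, kind="cubic", assume_sorted=True)
    grid = np.arange(t[0], t[-1], 1.0 / RESAMPLE_HZ)
    series = interp(grid)
    series = series - series.mean()
    nperseg = min(series.size, int(WELCH_SEGMENT_S * RESAMPLE_HZ))
    freqs, psd = sp_signal.welch(series, fs=RESAMPLE_HZ, nperseg=nperseg,
                                 noverlap=nperseg // 2, window="hann",
                                 detrend="constant")
    return freqs, psd


def _band_power(freqs: np.ndarray, psd: np.ndarray, lo: float,
                hi: float) -> float:
    df = freqs[1] - freqs[0]
    mask = (freqs >= lo) & (freqs < hi)
    return float(psd[mask].sum() * df)


def hrv_window(rr: RRSeries, start_s: float, end_s: float) -> HRVWindow:
    """Compute one window's HRV features; returns a flagged (NaN) window
    instead of raising when too few valid RR intervals remain."""
    sel = (rr.rr_times >= start_s) & (rr.rr_times < end_s) & rr.valid
    n_valid = int(sel.sum())
    try:
        freqs, psd = hrv_spectrum(rr, start_s, end_s)
    except EmptyDataError:
        nan = float("nan")
        return HRVWindow(start_s, end_s, nan, nan, nan, nan, nan,
                         n_valid, False)
    vlf = _band_power(freqs, psd, *HRV_BANDS["vlf"])
    lf = _band_power(freqs, psd, *HRV_BANDS["lf"])
    hf = _band_power(freqs, psd, *HRV_BANDS["hf"])
    total = _band_power(freqs, psd, HRV_BANDS["vlf"][0],
                        float(freqs[-1]) + 1e-12)
    denom = total - vlf
    p_lf = lf / denom if denom > 0 else float("nan")
    p_hf = hf / denom if denom > 0 else float("nan")
    ratio = p_lf / p_hf if p_hf and p_hf > 0 else float("nan")
    hr = 60.0 / float(np.mean(rr.rr[sel]))
    return HRVWindow(
        start_s=start_s, end_s=end_s, p_vlf_abs=vlf * 1e6,  # s^2 -> ms^2
        p_lf=p_lf, p_hf=p_hf, lf_hf_ratio=ratio, hr=hr,
        n_valid_rr=n_valid, ok=True,
    )


def hrv_features(rr: RRSeries, span_start_s: float, span_end_s: float,
                 window_s: float = WINDOW_S,
                 hop_s: float = HOP_S) -> list[HRVWindow]:
    """Slide 5-min windows (hop 1 min, i.e. 80% overlap) over a span.

    A 10-min span yields 6 windows (starts at minutes 0-5).  Windows with
    too few valid RR intervals are returned flagged, not dropped.
    """
    if span_end_s - span_start_s < window_s:
        raise ParameterError(
            f"span of {span_end_s - span_start_s} s shorter than one "
            f"{window_s} s window"
        )
    out = []
    start = span_start_s
    while start + window_s <= span_end_s + 1e-9:
        out.append(hrv_window(rr, start, start + window_s))
        start += hop_s
    return out


HRV_FEATURES = ("p_vlf_abs", "p_lf", "p_hf", "lf_hf_ratio", "hr")


def ecg_minute_features(rr: RRSeries, segments, fs: float) -> pd.DataFrame:
    """One HRV value per state-segment minute, in the tidy feature schema.

    Minute ``m`` of a segment is assigned the 5-min window *ending* at that
    minute's boundary, as the windows would fall in the continuous
    recording; windows for early drowsy minutes therefore straddle the
    event onset.  Requires 4 min of recording before each alert segment.
    """
    rows = []
    for pair in segments:
        for seg in pair:
            seg_start_s = seg.start / fs
            seg_end_s = seg.end / fs
            wins = hrv_features(rr, seg_start_s - (WINDOW_S - HOP_S),
                                seg_end_s)
            for m, w in enumerate(wins):
                if not w.ok:
                    continue  # flagged missing; excluded downstream
                for feat in HRV_FEATURES:
                    rows.append({
                        "subject_id": seg.subject_id, "state": seg.state,
                        "minute": m, "channel": "ECG", "feature": feat,
                        "value": getattr(w, feat),
                    })
    return pd.DataFrame(rows)
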