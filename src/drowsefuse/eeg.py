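"""Windowed EEG features: time-domain statistics, sample entropy, and
absolute/relative band powers, averaged to one value per minute.

The analysis window is 1000 samples (2 s at 500 Hz) with 50% overlap, so a
60-s trace yields 60 windows; every feature is then averaged across a
minute's windows, producing one value per channel, feature and minute.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from numba import njit
from numpy.lib.stride_tricks import sliding_window_view
from scipy.signal import get_window

from .errors import DegenerateInputError, EmptyDataError, ParameterError

BAND_NAMES = ("delta", "theta", "alpha", "beta", "gamma")

#: Analysis frequency bands (Hz).  The gamma band is capped at the 40 Hz
#: filter edge so the five bands are disjoint and exhaustive over 0.5-40 Hz;
#: pass a custom ``bands`` mapping to widen it.
BANDS = {
    "delta": (0.5, 4.0),
    "theta": (4.0, 8.0),
    "alpha": (8.0, 12.0),
    "beta": (12.0, 30.0),
    "gamma": (30.0, 40.0),
}

TOTAL_BAND = (0.5, 40.0)

#: Sentinel returned by :func:`sample_entropy` when no template match
#: extends to m+1 points (conditional probability 0, infinite entropy).
SAMPEN_INF = math.inf

TIME_FEATURES = ("mean", "var", "min", "max", "energy")


@dataclass(frozen=True)
class WindowingScheme:
    """Sliding-window layout: N samples per window with fractional overlap.

    The hop ``N * (1 - overlap)`` must be a whole number of samples.
    """

    n: int = 1000
    overlap: float = 0.5
    fs: float = 500.0

    def __post_init__(self):
        if self.n < 2:
            raise ParameterError("window length must be >= 2 samples")
        if not 0.0 <= self.overlap < 1.0:
            raise ParameterError("overlap must lie in [0, 1)")
        hop = self.n * (1.0 - self.overlap)
        if abs(hop - round(hop)) > 1e-9 or round(hop) < 1:
            raise ParameterError(
                f"hop {hop} is not a positive integer number of samples"
            )

    @property
    def hop(self) -> int:
        return int(round(self.n * (1.0 - self.overlap)))


@dataclass(frozen=True)
class SampleEntropyParams:
    """Sample-entropy settings: embedding dimension m and the tolerance
    factor multiplying each window's standard deviation to give r."""

    m: int = 2
    r_factor: float = 0.2

    def __post_init__(self):
        if self.m < 1:
            raise ParameterError("embedding dimension m must be >= 1")
        if not self.r_factor > 0:
            raise ParameterError("tolerance factor must be positive")


@dataclass(frozen=True)
class BandPowerSet:
    """Absolute band powers (uV^2), total 0.5-40 Hz power, and the relative
    powers (absolute / total) of the five disjoint bands."""

    abs_powers: dict
    total_power: float
    rel_powers: dict


def windows(segment: np.ndarray, scheme: WindowingScheme):
    """Yield ``(start, window)`` pairs over ``segment``.

    A window starts at every multiple of the hop that lies within the
    segment; the final window is truncated to the available samples when it
    would run past the end.  60 s at 500 Hz with N=1000/50% overlap yields
    exactly 60 windows.
    """
    segment = np.asarray(segment)
    n = segment.shape[0]
    if n < scheme.hop:
        raise EmptyDataError(
            f"segment of {n} samples is shorter than one hop ({scheme.hop})"
        )
    for start in range(0, n, scheme.hop):
        yield start, segment[start:start + scheme.n]


def time_stats(window: np.ndarray) -> dict:
    """Mean, population variance, min, max, and energy (sum of squared
    samples) of one window."""
    window = np.asarray(window, dtype=np.float64)
    if window.size == 0:
        raise EmptyDataError("empty window")
    return {
        "mean": float(window.mean()),
        "var": float(window.var()),  # population (1/N) variance
        "min": float(window.min()),
        "max": float(window.max()),
        "energy": float(np.sum(window ** 2)),
    }


@njit(cache=True)
def _sampen_counts(x: np.ndarray, order: np.ndarray, m: int,
                   r: float) -> tuple:
    """Count m-matches (B) and (m+1)-matches (A) under Chebyshev tolerance r.

    Only the N-m templates that can be extended to length m+1 are counted,
    self-matches excluded.  ``order`` sorts the template heads so inner
    scans stop once the first coordinate already exceeds r.
    """
    nt = x.shape[0] - m
    A = 0
    B = 0
    for a in range(nt - 1):
        i = order[a]
        xa = x[i]
        for b in range(a + 1, nt):
            j = order[b]
            if x[j] - xa > r:
                break
            ok = True
            for k in range(1, m):
                d = x[i + k] - x[j + k]
                if d < 0.0:
                    d = -d
                if d > r:
                    ok = False
                    break
            if ok:
                B += 1
                d = x[i + m] - x[j + m]
                if d < 0.0:
                    d = -d
                if d <= r:
                    A += 1
    return A, B


def sample_entropy(window: np.ndarray,
                   params: SampleEntropyParams = SampleEntropyParams()
                   ) -> float:
    """Sample entropy ``-ln(A/B)`` with tolerance ``r = r_factor * SD``.

    ``B`` counts template pairs matching for ``m`` points and ``A`` those
    still matching at ``m+1`` points, both under the Chebyshev distance with
    self-matches excluded.  Perfectly regular signals give 0; if no match
    extends (A = 0) the documented sentinel ``SAMPEN_INF`` is returned
    rather than raising.
    """
    x = np.ascontiguousarray(window, dtype=np.float64)
    m = params.m
    if x.shape[0] <= m + 1:
        raise ParameterError(
            f"window of {x.shape[0]} samples too short for m={m}"
        )
    sd = float(x.std())
    # constant windows can carry an O(eps) rounding std; treat as zero
    if sd <= 1e-12 * max(1.0, abs(float(x.mean()))):
        raise DegenerateInputError(
            "zero-variance window: tolerance r would be 0"
        )
    r = params.r_factor * sd
    order = np.argsort(x[:x.shape[0] - m], kind="stable").astype(np.int64)
    A, B = _sampen_counts(x, order, m, r)
    if A == 0:
        return SAMPEN_INF
    return float(-math.log(A / B))


# ---------------------------------------------------------------------------
# Band powers
# ---------------------------------------------------------------------------

def _band_mask(freqs: np.ndarray, lo: float, hi: float,
               hi_inclusive: bool) -> np.ndarray:
    if hi_inclusive:
        return (freqs >= lo) & (freqs <= hi)
    return (freqs >= lo) & (freqs < hi)


def _psd_hann(mat: np.ndarray, fs: float) -> tuple[np.ndarray, np.ndarray]:
    """One-sided Hann-tapered periodogram density of each row of ``mat``."""
    n = mat.shape[-1]
    w = get_window("hann", n)
    demeaned = mat - mat.mean(axis=-1, keepdims=True)
    spec = np.fft.rfft(demeaned * w, axis=-1)
    psd = (np.abs(spec) ** 2) / (fs * np.sum(w ** 2))
    psd[..., 1:] *= 2.0
    if n % 2 == 0:
        psd[..., -1] /= 2.0
    freqs = np.fft.rfftfreq(n, 1.0 / fs)
    return freqs, psd


def _integrate_bands(freqs: np.ndarray, psd: np.ndarray,
                     bands: dict) -> tuple[dict, np.ndarray]:
    df = freqs[1] - freqs[0]
    top = max(hi for _, hi in bands.values())
    abs_powers = {}
    for band, (lo, hi) in bands.items():
        mask = _band_mask(freqs, lo, hi, hi_inclusive=(hi >= top))
        abs_powers[band] = psd[..., mask].sum(axis=-1) * df
    total_mask = _band_mask(freqs, TOTAL_BAND[0], top, hi_inclusive=True)
    total = psd[..., total_mask].sum(axis=-1) * df
    return abs_powers, total


def band_powers(window: np.ndarray, fs: float,
                bands: dict = BANDS) -> BandPowerSet:
    """Absolute and relative band powers of one window.

    The PSD is a single Hann-tapered periodogram; band power integrates the
    density over each band, total power over 0.5-40 Hz, and relative powers
    divide absolute by total.
    """
    window = np.asarray(window, dtype=np.float64)
    if fs <= 2 * TOTAL_BAND[1]:
        raise ParameterError(
            f"fs={fs} Hz too low for the {TOTAL_BAND[1]} Hz analysis bound"
        )
    if window.size < 4:
        raise EmptyDataError("window too short for spectral analysis")
    freqs, psd = _psd_hann(window[np.newaxis, :], fs)
    abs_powers, total = _integrate_bands(freqs, psd, bands)
    abs_powers = {b: float(v[0]) for b, v in abs_powers.items()}
    total = float(total[0])
    rel = {b: (v / total if total > 0 else 0.0)
           for b, v in abs_powers.items()}
    return BandPowerSet(abs_powers=abs_powers, total_power=total,
                        rel_powers=rel)


# ---------------------------------------------------------------------------
# Per-minute aggregation
# ---------------------------------------------------------------------------

def eeg_minute_features(
    segment: np.ndarray,
    labels: list[str],
    fs: float,
    scheme: WindowingScheme | None = None,
    sampen_params: SampleEntropyParams = SampleEntropyParams(),
    mask: np.ndarray | None = None,
    feature_set: tuple = ("time", "sampen", "bandpower"),
    bands: dict = BANDS,
    min_valid_fraction: float = 0.5,
) -> pd.DataFrame:
    """Average every windowed feature across each minute of a state segment.

    Parameters
    ----------
    segment : ndarray, shape (n_channels, n_samples)
        One 5-min state segment (any whole number of minutes is accepted).
    labels : list of str
        Channel labels matching the rows of ``segment``.
    mask : boolean ndarray, optional
        Per-sample validity from artifact rejection; a window is valid only
        if all its samples are.  Minutes with fewer than
        ``min_valid_fraction`` valid windows are flagged missing and
        omitted.

    Returns a tidy frame with columns minute, channel, feature, value.
    With the 19-channel montage this yields 95 absolute-power features per
    minute (19 channels x 5 bands), mirrored for relative power, plus six
    time-domain features (five statistics and sample entropy) per channel.
    """
    if scheme is None:
        scheme = WindowingScheme(fs=fs)
    segment = np.atleast_2d(np.asarray(segment, dtype=np.float64))
    n_ch, n = segment.shape
    if n_ch != len(labels):
        raise ParameterError("labels do not match segment rows")
    spm = int(round(60 * fs))  # samples per minute
    if n < spm:
        raise EmptyDataError("segment shorter than one minute")

    starts = np.arange(0, n, scheme.hop)
    minute_of = (starts // spm).astype(int)
    full = starts + scheme.n <= n

    if mask is not None:
        mask = np.asarray(mask, dtype=bool)
        if mask.shape[0] != n:
            raise ParameterError("mask length does not match segment")
        valid = np.array([
            bool(mask[s:min(s + scheme.n, n)].all()) for s in starts
        ])
    else:
        valid = np.ones(starts.size, dtype=bool)
    if not valid.any():
        raise EmptyDataError(
            "no valid windows remain after artifact masking"
        )

    # per-minute validity gate
    minutes = np.unique(minute_of)
    minute_ok = {}
    for mi in minutes:
        in_min = minute_of == mi
        minute_ok[mi] = valid[in_min].sum() >= min_valid_fraction * in_min.sum()

    n_full = int(full.sum())
    full_starts = starts[full]
    rows_minute, rows_channel, rows_feature, rows_value = [], [], [], []

    def emit(mi, ch, feat, val):
        rows_minute.append(mi)
        rows_channel.append(ch)
        rows_feature.append(feat)
        rows_value.append(val)

    for ci, ch in enumerate(labels):
        x = segment[ci]
        wmat = sliding_window_view(x, scheme.n)[::scheme.hop][:n_full]
        assert wmat.shape[0] == n_full

        stats = {}
        if "time" in feature_set:
            stats["mean"] = wmat.mean(axis=1)
            stats["var"] = wmat.var(axis=1)
            stats["min"] = wmat.min(axis=1)
            stats["max"] = wmat.max(axis=1)
            stats["energy"] = np.sum(wmat ** 2, axis=1)
        if "bandpower" in feature_set:
            freqs, psd = _psd_hann(wmat, fs)
            abs_p, total = _integrate_bands(freqs, psd, bands)
            for b in bands:
                stats[f"p_abs_{b}"] = abs_p[b]
                with np.errstate(invalid="ignore", divide="ignore"):
                    stats[f"p_rel_{b}"] = np.where(
                        total > 0, abs_p[b] / total, 0.0)

        # truncated trailing windows: moments and band power only
        trunc = {}
        for s in starts[~full]:
            w = x[s:]
            entry = {}
            if "time" in feature_set:
                entry.update(time_stats(w))
            if "bandpower" in feature_set and w.size >= 4:
                bp = band_powers(w, fs, bands)
                for b in bands:
                    entry[f"p_abs_{b}"] = bp.abs_powers[b]
                    entry[f"p_rel_{b}"] = bp.rel_powers[b]
            trunc[s] = entry

        for mi in minutes:
            if not minute_ok[mi]:
                continue
            sel_full = (minute_of[:n_full] == mi) & valid[:n_full]
            for feat, col in stats.items():
                vals = list(col[sel_full])
                for s in starts[~full]:
                    if minute_of[np.searchsorted(starts, s)] == mi and \
                            valid[np.searchsorted(starts, s)] and \
                            feat in trunc[s]:
                        vals.append(trunc[s][feat])
                if vals:
                    emit(mi, ch, feat, float(np.mean(vals)))
            if "sampen" in feature_set:
                vals = []
                for wi in np.nonzero(sel_full)[0]:
                    try:
                        se = sample_entropy(wmat[wi], sampen_params)
                    except DegenerateInputError:
                        continue
                    if math.isfinite(se):
                        vals.append(se)
                if vals:
                    emit(mi, ch, "sampen", float(np.mean(vals)))

    return pd.DataFrame({
        "minute": rows_minute, "channel": rows_channel,
        "feature": rows_feature, "value": rows_value,
    })


def to_minute_vectors(tidy: pd.DataFrame) -> dict:
    """Pivot a tidy per-minute table into ``{minute: {(channel, feature):
    value}}`` maps."""
    out: dict = {}
    for row in tidy.itertuples(index=False):
        out.setdefault(int(row.minute), {})[(row.channel, row.feature)] = \
            row.value
    return out
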