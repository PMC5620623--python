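"""Recording container, EDF/CSV readers and writers, band-pass filtering,
automatic artifact rejection, and state-segment extraction.

A :class:`Recording` holds one driving session: 19 EEG channels on the 10-20
montage plus one ECG lead, all sampled at the same rate, in microvolts.
Drowsy-event annotations (subject id, onset in seconds) cut each recording
into paired 5-min *alert* (pre-event) and *drowsy* (post-event) segments; all
downstream features are computed inside those segments.

Sample coordinates are 0-based and windows are half-open ``[start, end)``
throughout.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import signal as sp_signal

from .errors import (
    AnnotationError,
    FormatError,
    ParameterError,
)

#: The 19 EEG labels of the reduced 10-20 montage, in canonical order.
EEG_1020 = [
    "Fp1", "Fp2", "F7", "F3", "Fz", "F4", "F8",
    "T7", "C3", "Cz", "C4", "T8",
    "P7", "P3", "Pz", "P4", "P8",
    "O1", "O2",
]

ECG_LABEL = "ECG"

#: Scalp region of each EEG electrode; the synthetic generator assigns one
#: spectral profile per region.
CHANNEL_GROUPS = {
    "frontal": ["Fp1", "Fp2", "F7", "F3", "Fz", "F4", "F8"],
    "temporal": ["T7", "T8"],
    "central": ["C3", "Cz", "C4"],
    "parietal": ["P7", "P3", "Pz", "P4", "P8"],
    "occipital": ["O1", "O2"],
}

GROUP_OF_CHANNEL = {
    ch: grp for grp, chans in CHANNEL_GROUPS.items() for ch in chans
}

SEGMENT_SECONDS = 300.0  # 5-min alert / drowsy spans


def _modality(label: str) -> str:
    if label in EEG_1020:
        return "eeg"
    if label.upper() == ECG_LABEL:
        return "ecg"
    return "unknown"


@dataclass
class Recording:
    """Synchronized multichannel EEG+ECG signal block.

    Parameters
    ----------
    subject_id : str
        Study-unique subject identifier.
    fs : float
        Sampling rate in Hz (> 80 so the 40 Hz analysis bound is below
        Nyquist).
    labels : list of str
        Ordered channel labels; 10-20 names for EEG plus ``"ECG"``.
    data : ndarray, shape (n_channels, n_samples)
        Signals in microvolts.
    """

    subject_id: str
    fs: float
    labels: list[str]
    data: np.ndarray
    modalities: list[str] = field(default_factory=list)

    def __post_init__(self):
        self.data = np.asarray(self.data, dtype=np.float64)
        if self.data.ndim != 2:
            raise FormatError(
                f"{self.subject_id}: signal block must be 2-D "
                f"(channels x samples), got ndim={self.data.ndim}"
            )
        if self.data.shape[0] != len(self.labels):
            raise FormatError(
                f"{self.subject_id}: {len(self.labels)} labels but "
                f"{self.data.shape[0]} signal rows"
            )
        if len(set(self.labels)) != len(self.labels):
            raise FormatError(
                f"{self.subject_id}: duplicate channel labels"
            )
        if not self.fs > 80:
            raise FormatError(
                f"{self.subject_id}: sampling rate must exceed 80 Hz, "
                f"got {self.fs}"
            )
        if not self.modalities:
            self.modalities = [_modality(lb) for lb in self.labels]
        unknown = [lb for lb, m in zip(self.labels, self.modalities)
                   if m == "unknown"]
        if unknown:
            warnings.warn(
                f"{self.subject_id}: unknown channel labels preserved but "
                f"flagged: {unknown}", stacklevel=2
            )

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.fs

    @property
    def eeg_labels(self) -> list[str]:
        return [lb for lb, m in zip(self.labels, self.modalities)
                if m == "eeg"]

    def channel(self, label: str) -> np.ndarray:
        try:
            i = self.labels.index(label)
        except ValueError:
            raise KeyError(f"no channel {label!r} in {self.subject_id}")
        return self.data[i]


@dataclass(frozen=True)
class StateSegment:
    """One 5-min alert or drowsy span, in sample coordinates.

    The alert segment ends exactly at the event onset; the drowsy segment
    starts there.
    """

    subject_id: str
    state: str  # "alert" | "drowsy"
    start: int  # inclusive, 0-based
    end: int    # exclusive
    event_onset_s: float

    def __post_init__(self):
        if self.state not in ("alert", "drowsy"):
            raise AnnotationError(f"unknown state {self.state!r}")
        if self.end <= self.start:
            raise AnnotationError("empty segment")


# ---------------------------------------------------------------------------
# EDF writing (16-bit EDF container) and reading (via mne)
# ---------------------------------------------------------------------------

def _edf_field(value, width: int) -> bytes:
    s = str(value)
    if len(s) > width:
        raise FormatError(f"EDF header field {s!r} exceeds {width} chars")
    return s.ljust(width).encode("ascii")


def write_edf(recording: Recording, path) -> Path:
    """Write a recording as a 16-bit EDF file, one data record per second.

    Physical units are microvolts; per-channel physical range is chosen
    symmetric around zero and rounded to 4 significant digits so that the
    8-character ASCII header field represents it exactly.
    """
    path = Path(path)
    fs = recording.fs
    if abs(fs - round(fs)) > 1e-9:
        raise FormatError("EDF export requires an integer sampling rate; "
                          "use the CSV dialect instead")
    spr = int(round(fs))  # samples per 1-s record, per channel
    n_records = recording.n_samples // spr
    if n_records * spr != recording.n_samples:
        raise FormatError("EDF export requires a whole number of seconds; "
                          "use the CSV dialect instead")
    ns = len(recording.labels)

    # physical range per channel, representable exactly in 8 ASCII chars
    pmaxs = []
    for row in recording.data:
        p = float(np.max(np.abs(row))) if row.size else 1.0
        p = max(p, 1e-3)
        q = float(f"{p:.4g}")
        if q < p:
            q = float(f"{p * 1.001:.4g}")
        pmaxs.append(q)

    hdr = b""
    hdr += _edf_field("0", 8)
    hdr += _edf_field(recording.subject_id, 80)
    hdr += _edf_field("drowsefuse synthetic/processed", 80)
    hdr += _edf_field("01.01.00", 8)
    hdr += _edf_field("00.00.00", 8)
    hdr += _edf_field(256 * (ns + 1), 8)
    hdr += _edf_field("", 44)
    hdr += _edf_field(n_records, 8)
    hdr += _edf_field(1, 8)
    hdr += _edf_field(ns, 4)
    # per-signal fields are stored field-major
    hdr += b"".join(_edf_field(lb, 16) for lb in recording.labels)
    hdr += b"".join(_edf_field("", 80) for _ in range(ns))
    hdr += b"".join(_edf_field("uV", 8) for _ in range(ns))
    hdr += b"".join(_edf_field(f"{-p:.4g}", 8) for p in pmaxs)
    hdr += b"".join(_edf_field(f"{p:.4g}", 8) for p in pmaxs)
    hdr += b"".join(_edf_field(-32767, 8) for _ in range(ns))
    hdr += b"".join(_edf_field(32767, 8) for _ in range(ns))
    hdr += b"".join(_edf_field("", 80) for _ in range(ns))
    hdr += b"".join(_edf_field(spr, 8) for _ in range(ns))
    hdr += b"".join(_edf_field("", 32) for _ in range(ns))
    assert len(hdr) == 256 * (ns + 1)

    digital = np.empty((ns, n_records * spr), dtype="<i2")
    for i, (row, p) in enumerate(zip(recording.data, pmaxs)):
        scaled = np.clip(np.round(row / (p / 32767.0)), -32767, 32767)
        digital[i] = scaled.astype("<i2")

    with open(path, "wb") as fh:
        fh.write(hdr)
        # record-major, then signal-major inside each record
        interleaved = (
            digital.reshape(ns, n_records, spr)
            .transpose(1, 0, 2)
        )
        fh.write(np.ascontiguousarray(interleaved).tobytes())
    return path


def _read_edf(path: Path) -> Recording:
    import mne

    with open(path, "rb") as fh:
        header = fh.read(88)
    if len(header) < 88:
        raise FormatError(f"{path}: truncated EDF header")
    subject_id = header[8:88].decode("ascii", "replace").strip() or path.stem

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        raw = mne.io.read_raw_edf(str(path), preload=True, verbose="error")
    fs = float(raw.info["sfreq"])
    labels = list(raw.ch_names)
    if len(set(labels)) != len(labels):
        raise FormatError(f"{path}: duplicate channel labels")
    data_uv = raw.get_data() * 1e6  # mne stores SI volts
    return Recording(subject_id=subject_id, fs=fs, labels=labels,
                     data=data_uv)


# ---------------------------------------------------------------------------
# CSV dialect: one row per sample, one column per channel, sidecar JSON
# ---------------------------------------------------------------------------

def write_csv(recording: Recording, path) -> Path:
    """Write the CSV dialect: header row of labels, one row per sample,
    with a ``.json`` sidecar carrying the sampling rate and subject id."""
    path = Path(path)
    df = pd.DataFrame(recording.data.T, columns=recording.labels)
    df.to_csv(path, index=False, float_format="%.6f")
    sidecar = {
        "subject_id": recording.subject_id,
        "sampling_rate_hz": recording.fs,
        "units": "uV",
    }
    path.with_suffix(".json").write_text(json.dumps(sidecar, indent=2))
    return path


def _read_csv(path: Path) -> Recording:
    sidecar_path = path.with_suffix(".json")
    if not sidecar_path.exists():
        raise FormatError(
            f"{path}: CSV dialect requires a {sidecar_path.name} sidecar "
            "declaring the sampling rate"
        )
    sidecar = json.loads(sidecar_path.read_text())
    if "sampling_rate_hz" not in sidecar:
        raise FormatError(f"{sidecar_path}: missing sampling_rate_hz")
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split(",")
    if len(set(header)) != len(header):
        raise FormatError(f"{path}: duplicate channel labels")
    df = pd.read_csv(path)
    return Recording(
        subject_id=str(sidecar.get("subject_id", path.stem)),
        fs=float(sidecar["sampling_rate_hz"]),
        labels=header,
        data=df.to_numpy(dtype=np.float64).T,
    )


def read_recording(path, dialect: str | None = None) -> Recording:
    """Read a recording from EDF or from the documented CSV dialect.

    ``dialect`` is ``"EDF"`` or ``"CSV"``; when omitted it is inferred from
    the file extension.
    """
    path = Path(path)
    if not path.exists():
        raise FormatError(f"no such file: {path}")
    if dialect is None:
        dialect = "EDF" if path.suffix.lower() == ".edf" else "CSV"
    dialect = dialect.upper()
    if dialect == "EDF":
        return _read_edf(path)
    if dialect == "CSV":
        return _read_csv(path)
    raise ParameterError(f"unknown dialect {dialect!r}")


def write_recording(recording: Recording, path, dialect: str = "EDF") -> Path:
    if dialect.upper() == "EDF":
        return write_edf(recording, path)
    if dialect.upper() == "CSV":
        return write_csv(recording, path)
    raise ParameterError(f"unknown dialect {dialect!r}")


def read_annotations(path) -> pd.DataFrame:
    """Read the event annotation table (columns subject_id, event_onset_s)."""
    df = pd.read_csv(path)
    required = {"subject_id", "event_onset_s"}
    if not required.issubset(df.columns):
        raise FormatError(
            f"{path}: annotation table must have columns {sorted(required)}"
        )
    df["subject_id"] = df["subject_id"].astype(str)
    return df


def write_annotations(events: pd.DataFrame, path) -> Path:
    path = Path(path)
    events[["subject_id", "event_onset_s"]].to_csv(path, index=False)
    return path


# ---------------------------------------------------------------------------
# Filtering
# ---------------------------------------------------------------------------

def bandpass(x: np.ndarray, fs: float, low: float = 0.5,
             high: float = 40.0) -> np.ndarray:
    """Zero-phase 0.5-40 Hz band-pass (4th-order Butterworth applied
    forward-backward), removing line noise and DC offset.

    Output has the input's length; the effective 8th-order response gives
    >= 40 dB attenuation one octave outside the pass-band.
    """
    x = np.asarray(x, dtype=np.float64)
    if not 0 < low < high:
        raise ParameterError(f"need 0 < low < high, got ({low}, {high})")
    if high >= fs / 2:
        raise ParameterError(
            f"upper edge {high} Hz not below Nyquist ({fs / 2} Hz)"
        )
    sos = sp_signal.butter(4, [low, high], btype="bandpass", fs=fs,
                           output="sos")
    return sp_signal.sosfiltfilt(sos, x)


def filter_recording(recording: Recording, low: float = 0.5,
                     high: float = 40.0) -> Recording:
    """Band-pass every channel (both modalities, as in the study protocol)."""
    if not 0 < low < high:
        raise ParameterError(f"need 0 < low < high, got ({low}, {high})")
    if high >= recording.fs / 2:
        raise ParameterError(
            f"upper edge {high} Hz not below Nyquist ({recording.fs / 2} Hz)"
        )
    sos = sp_signal.butter(4, [low, high], btype="bandpass",
                           fs=recording.fs, output="sos")
    filtered = sp_signal.sosfiltfilt(sos, recording.data, axis=1)
    return Recording(
        subject_id=recording.subject_id, fs=recording.fs,
        labels=list(recording.labels), data=filtered,
        modalities=list(recording.modalities),
    )


# ---------------------------------------------------------------------------
# Artifact rejection
# ---------------------------------------------------------------------------

def reject_artifacts(recording: Recording, amplitude_limit: float = 100.0,
                     window_s: float = 1.0) -> np.ndarray:
    """Automatic amplitude rule standing in for manual artifact screening.

    The recording is tiled into non-overlapping ``window_s`` windows; any
    window in which the peak absolute EEG amplitude (over all EEG channels)
    exceeds ``amplitude_limit`` microvolts is marked invalid.

    Returns a boolean per-sample validity mask (True = valid) of the
    recording's length.  Masked samples are excluded from feature averaging
    downstream.
    """
    if not amplitude_limit > 0:
        raise ParameterError("amplitude_limit must be positive")
    if not window_s > 0:
        raise ParameterError("window_s must be positive")
    n = recording.n_samples
    mask = np.ones(n, dtype=bool)
    eeg_rows = [i for i, m in enumerate(recording.modalities) if m == "eeg"]
    if not eeg_rows:
        return mask
    eeg = np.abs(recording.data[eeg_rows])
    step = int(round(window_s * recording.fs))
    for start in range(0, n, step):
        stop = min(start + step, n)
        if eeg[:, start:stop].max() > amplitude_limit:
            mask[start:stop] = False
    return mask


# ---------------------------------------------------------------------------
# Segment extraction (5-min alert before / 5-min drowsy after each event)
# ---------------------------------------------------------------------------

def extract_state_segments(
    recording: Recording, events: pd.DataFrame
) -> list[tuple[StateSegment, StateSegment]]:
    """Cut one (alert, drowsy) pair of exactly-5-min segments per event.

    The alert segment is the 5 minutes immediately before the event onset,
    the drowsy segment the 5 minutes immediately after; they abut at the
    onset sample.  Events whose expanded 5+5 min windows would leave the
    recording, or overlap each other, raise :class:`AnnotationError`.
    """
    fs = recording.fs
    half = int(round(SEGMENT_SECONDS * fs))
    own = events[events["subject_id"].astype(str) == recording.subject_id]
    own = own.sort_values("event_onset_s")
    pairs: list[tuple[StateSegment, StateSegment]] = []
    prev_end = None
    for _, row in own.iterrows():
        onset_s = float(row["event_onset_s"])
        onset = int(round(onset_s * fs))
        start, end = onset - half, onset + half
        if start < 0 or end > recording.n_samples:
            raise AnnotationError(
                f"subject {recording.subject_id}: event at {onset_s} s is "
                "within 5 min of a recording edge"
            )
        if prev_end is not None and start < prev_end:
            raise AnnotationError(
                f"subject {recording.subject_id}: events closer than 10 min "
                f"- 5+5 min windows overlap at {onset_s} s"
            )
        prev_end = end
        pairs.append((
            StateSegment(recording.subject_id, "alert", start, onset,
                         onset_s),
            StateSegment(recording.subject_id, "drowsy", onset, end,
                         onset_s),
        ))
    return pairs


def segments_to_frame(pairs, fs: float) -> pd.DataFrame:
    """Export segments as a BED-like table (subject, state, start_s, end_s)."""
    rows = []
    for pair in pairs:
        for seg in pair:
            rows.append({
                "subject_id": seg.subject_id, "state": seg.state,
                "start_s": seg.start / fs, "end_s": seg.end / fs,
            })
    return pd.DataFrame(rows)
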