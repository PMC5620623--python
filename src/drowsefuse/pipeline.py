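"""Pipeline orchestration: synthetic-or-real data -> preprocessing ->
features -> selection -> classification -> reports.

A single :class:`PipelineConfig` (loadable from YAML/JSON) drives the whole
run; one global seed fans out to named substreams (synthesis, KS Monte
Carlo), so a rerun with the same config reproduces every report byte for
byte.  The run manifest records the config hash, seeds and library
versions.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from scipy import signal as sp_signal

from . import __version__
from .classify import (
    KernelParams,
    channel_reduction,
    instance_matrix,
    loso_cv,
)
from .ecg import detect_r_peaks, ecg_minute_features, rr_filter
from .eeg import SampleEntropyParams, WindowingScheme, eeg_minute_features
from .errors import DrowseFuseError, EmptyDataError, PipelineError
from .io import (
    Recording,
    extract_state_segments,
    read_annotations,
    read_recording,
    reject_artifacts,
)
from .selection import SelectionReport, paired_t, select
from .synth import SynthStudyConfig, generate_study

logger = logging.getLogger("drowsefuse")

#: EEG channels most frequently carrying significant drowsiness contrasts
#: (posterior/central); default candidate set for channel reduction.
DEFAULT_CANDIDATE_CHANNELS = ("C3", "P4", "P7", "O1", "O2")


@dataclass
class PipelineConfig:
    """All pipeline knobs in one schema-validated block.

    ``data_dir`` switches the input source from the synthetic generator to
    a directory of EDF/CSV recordings plus an ``events.csv`` annotation
    table.
    """

    synth: SynthStudyConfig = field(default_factory=SynthStudyConfig)
    data_dir: str | None = None
    band_low_hz: float = 0.5
    band_high_hz: float = 40.0
    artifact_limit_uv: float = 100.0
    artifact_window_s: float = 1.0
    window_samples: int = 1000
    window_overlap: float = 0.5
    sampen_m: int = 2
    sampen_r_factor: float = 0.2
    feature_set: tuple = ("time", "sampen", "bandpower")
    alpha: float = 0.05
    correction: str = "none"
    svm_c: float = 1.0
    puk_omega: float = 1.0
    puk_sigma: float = 1.0
    candidate_channels: tuple = DEFAULT_CANDIDATE_CHANNELS
    channel_subset_max: int = 2
    seed: int = 0
    out_dir: str | None = None

    def __post_init__(self):
        # parameter blocks validate themselves; validate scalars up front
        if not 0 < self.band_low_hz < self.band_high_hz:
            raise DrowseFuseError("invalid band edges")
        if not 0.0 <= self.alpha <= 1.0:
            raise DrowseFuseError("alpha must lie in [0, 1]")
        WindowingScheme(n=self.window_samples, overlap=self.window_overlap)
        SampleEntropyParams(m=self.sampen_m, r_factor=self.sampen_r_factor)
        KernelParams(omega=self.puk_omega, sigma=self.puk_sigma)
        unknown = set(self.feature_set) - {"time", "sampen", "bandpower"}
        if unknown:
            raise DrowseFuseError(f"unknown feature families: {unknown}")

    @classmethod
    def from_dict(cls, payload: dict) -> "PipelineConfig":
        payload = dict(payload)
        synth_payload = payload.pop("synth", {})
        from .synth import BandProfile, HRVProfile
        kwargs = {}
        for key in ("alert_band", "drowsy_band"):
            if key in synth_payload:
                kwargs[key] = BandProfile(**synth_payload.pop(key))
        for key in ("alert_hrv", "drowsy_hrv"):
            if key in synth_payload:
                kwargs[key] = HRVProfile(**synth_payload.pop(key))
        synth = SynthStudyConfig(**synth_payload, **kwargs)
        for tup in ("feature_set", "candidate_channels"):
            if tup in payload and payload[tup] is not None:
                payload[tup] = tuple(payload[tup])
        return cls(synth=synth, **payload)

    @classmethod
    def from_file(cls, path) -> "PipelineConfig":
        text = Path(path).read_text()
        payload = yaml.safe_load(text)
        return cls.from_dict(payload or {})

    def to_dict(self) -> dict:
        d = asdict(self)
        d["synth"]["alert_band"] = asdict(self.synth.alert_band)
        d["synth"]["drowsy_band"] = asdict(self.synth.drowsy_band)
        return d

    def config_hash(self) -> str:
        payload = self.to_dict()
        payload.pop("out_dir", None)  # where reports land is not what ran
        blob = json.dumps(payload, sort_keys=True, default=list)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


@dataclass
class PipelineResult:
    """Bundle of everything one run produces."""

    features: pd.DataFrame
    selection: SelectionReport
    reports: dict            # label -> EvaluationReport
    channel_ranking: pd.DataFrame
    manifest: dict


def _load_recordings(config: PipelineConfig):
    if config.data_dir is None:
        # propagate the pipeline seed into the generator unless the synth
        # block pins its own
        synth = config.synth
        if synth.seed != config.seed:
            from dataclasses import replace
            synth = replace(synth, seed=config.seed)
        return generate_study(synth)
    data_dir = Path(config.data_dir)
    events = read_annotations(data_dir / "events.csv")
    recordings = []
    for path in sorted(data_dir.iterdir()):
        if path.suffix.lower() in (".edf", ".csv") and \
                path.name != "events.csv":
            recordings.append(read_recording(path))
    if not recordings:
        raise EmptyDataError(f"no recordings found in {data_dir}")
    return recordings, events


def extract_features(config: PipelineConfig, recordings,
                     events) -> pd.DataFrame:
    """Filter, mask, segment and featurize every recording into one tidy
    table (subject, state, minute, channel, feature, value)."""
    scheme = WindowingScheme(n=config.window_samples,
                             overlap=config.window_overlap)
    params = SampleEntropyParams(m=config.sampen_m,
                                 r_factor=config.sampen_r_factor)
    frames = []
    for rec in recordings:
        t0 = time.perf_counter()
        pairs = extract_state_segments(rec, events)
        eeg_rows = [i for i, m in enumerate(rec.modalities) if m == "eeg"]
        eeg_labels = [rec.labels[i] for i in eeg_rows]

        # band-pass only the span the state segments cover (plus a pad that
        # absorbs the filter's edge transient); other samples are never read
        pad = int(round(10 * rec.fs))
        a = max(0, min(seg.start for pair in pairs for seg in pair) - pad)
        b = min(rec.n_samples,
                max(seg.end for pair in pairs for seg in pair) + pad)
        filtered = np.zeros((len(eeg_rows), rec.n_samples))
        sos = sp_signal.butter(4, [config.band_low_hz, config.band_high_hz],
                               btype="bandpass", fs=rec.fs, output="sos")
        filtered[:, a:b] = sp_signal.sosfiltfilt(
            sos, rec.data[eeg_rows, a:b], axis=1)
        filtered_rec = Recording(
            subject_id=rec.subject_id, fs=rec.fs, labels=eeg_labels,
            data=filtered, modalities=["eeg"] * len(eeg_rows),
        )
        mask = reject_artifacts(filtered_rec, config.artifact_limit_uv,
                                config.artifact_window_s)
        for pair in pairs:
            for seg in pair:
                tidy = eeg_minute_features(
                    filtered[:, seg.start:seg.end],
                    eeg_labels, rec.fs, scheme, params,
                    mask=mask[seg.start:seg.end],
                    feature_set=config.feature_set,
                )
                tidy.insert(0, "state", seg.state)
                tidy.insert(0, "subject_id", seg.subject_id)
                frames.append(tidy)
        # the R-peak stage band-passes 5-15 Hz itself, a sub-band of the
        # analysis band, so detection runs on the raw ECG lead
        beats = detect_r_peaks(rec.channel("ECG"), rec.fs)
        rr = rr_filter(beats)
        frames.append(ecg_minute_features(rr, pairs, rec.fs))
        logger.info("featurized %s in %.1f s", rec.subject_id,
                    time.perf_counter() - t0)
    return pd.concat(frames, ignore_index=True)


def classify_features(config: PipelineConfig, features: pd.DataFrame,
                      report: SelectionReport):
    """Run the ECG-only / EEG-only / combined configurations plus the
    channel-reduction ranking."""
    params = KernelParams(omega=config.puk_omega, sigma=config.puk_sigma)
    pairs = report.significant_pairs()
    ecg_pairs = [p for p in pairs if p[0] == "ECG"]
    eeg_pairs = [p for p in pairs if p[0] != "ECG"]
    reports = {}
    for label, feats in (("ecg_only", ecg_pairs),
                         ("eeg_only", eeg_pairs),
                         ("combined", ecg_pairs + eeg_pairs)):
        if not feats:
            logger.warning("configuration %s has no significant features; "
                           "skipped", label)
            continue
        X, y, subjects, _ = instance_matrix(features, feats)
        reports[label] = loso_cv(X, y, subjects, params=params,
                                 C=config.svm_c, label=label)
    ranking = channel_reduction(
        features, pairs, list(config.candidate_channels),
        params=params, C=config.svm_c,
        max_subset_size=config.channel_subset_max,
    )
    return reports, ranking


def run_pipeline(config: PipelineConfig) -> PipelineResult:
    """Execute the full pipeline and (optionally) write the report bundle.

    Emits the selection report, the three modality evaluation reports, the
    channel-reduction ranking, the tidy feature CSV and a run manifest.
    Any stage failure aborts with the stage name attached.
    """
    stages = {}

    def run_stage(name, fn, *args):
        t0 = time.perf_counter()
        try:
            out = fn(*args)
        except DrowseFuseError as exc:
            raise PipelineError(name, str(exc)) from exc
        stages[name] = round(time.perf_counter() - t0, 2)
        logger.info("stage %s done in %.1f s", name, stages[name])
        return out

    recordings, events = run_stage("input", _load_recordings, config)
    features = run_stage("features", extract_features, config, recordings,
                         events)
    selection = run_stage(
        "selection",
        lambda: select(features, alpha=config.alpha,
                       correction=config.correction,
                       ks_seed=config.seed),
    )
    reports, ranking = run_stage(
        "classification", classify_features, config, features, selection)

    manifest = {
        "package_version": __version__,
        "config_hash": config.config_hash(),
        "seed": config.seed,
        "n_recordings": len(recordings),
        "n_instances": {
            label: rep.confusion.total for label, rep in reports.items()
        },
        "versions": _library_versions(),
    }

    result = PipelineResult(features=features, selection=selection,
                            reports=reports, channel_ranking=ranking,
                            manifest=manifest)
    if config.out_dir:
        _write_bundle(config, result, events)
    return result


def _library_versions() -> dict:
    import sklearn
    import scipy
    return {
        "numpy": np.__version__,
        "scipy": scipy.__version__,
        "pandas": pd.__version__,
        "scikit-learn": sklearn.__version__,
    }


def _write_bundle(config: PipelineConfig, result: PipelineResult,
                  events: pd.DataFrame) -> None:
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    result.features.to_csv(out / "features.csv", index=False,
                           float_format="%.10g")
    result.selection.to_csv(out / "selection.csv")
    result.channel_ranking.to_csv(out / "channel_ranking.csv", index=False,
                                  float_format="%.10g")
    events.to_csv(out / "events.csv", index=False)
    payload = {label: rep.to_dict() for label, rep in result.reports.items()}
    (out / "evaluation.json").write_text(json.dumps(payload, indent=2))
    (out / "manifest.json").write_text(
        json.dumps(result.manifest, indent=2))


# ---------------------------------------------------------------------------
# Subjective-rating comparison
# ---------------------------------------------------------------------------

def kss_compare(ratings: pd.DataFrame) -> dict:
    """Paired t-test of sleepiness self-ratings before vs after the
    monotonous drive, per group.

    ``ratings`` columns: subject_id, group, before, after.  A significant
    rise in *both* groups means the rating does not discriminate drowsy
    from alert drivers - that interpretation is attached to the result, not
    computed.
    """
    required = {"subject_id", "group", "before", "after"}
    if not required.issubset(ratings.columns):
        raise DrowseFuseError(
            f"ratings table needs columns {sorted(required)}"
        )
    results = {}
    for group, grp in ratings.groupby("group"):
        res = paired_t(grp["before"].to_numpy(), grp["after"].to_numpy())
        res["n"] = int(len(grp))
        res["significant"] = res["p"] < 0.05
        results[str(group)] = res
    sig = [g for g, r in results.items() if r["significant"]]
    if len(sig) == len(results) and len(results) > 1:
        note = ("rating rose significantly in every group, so it does not "
                "discriminate the drowsy group from the alert group")
    else:
        note = ""
    return {"groups": results, "note": note}
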