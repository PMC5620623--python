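"""Shared fixtures and independent oracles.

The brute-force sample-entropy oracle here counts template matches by full
pairwise enumeration (O(N^2) numpy broadcasting) and never touches the
package's optimized counting path.
"""

import math

import numpy as np
import pytest
from hypothesis import HealthCheck, settings
from numpy.lib.stride_tricks import sliding_window_view

from drowsefuse import PipelineConfig, SynthStudyConfig
from drowsefuse.pipeline import _load_recordings, extract_features

settings.register_profile(
    "ci", derandomize=True, max_examples=25,
    suppress_health_check=[HealthCheck.too_slow], deadline=None,
)
settings.load_profile("ci")


def sampen_bruteforce(x: np.ndarray, m: int, r: float) -> float:
    """Independent O(N^2) sample-entropy oracle (full template enumeration,
    Chebyshev distance, self-matches excluded, -ln(A/B))."""
    x = np.asarray(x, dtype=np.float64)
    nt = x.size - m  # templates that extend to length m+1
    tm = sliding_window_view(x, m)[:nt]
    tm1 = sliding_window_view(x, m + 1)[:nt]

    def count(templates):
        d = np.abs(templates[:, None, :] - templates[None, :, :]).max(axis=2)
        match = d <= r
        return (match.sum() - len(templates)) // 2  # i < j pairs

    B = count(tm)
    A = count(tm1)
    if A == 0:
        return math.inf
    return -math.log(A / B)


@pytest.fixture(scope="session")
def tiny_study():
    """3 subjects, 5 posterior/central channels - enough structure for the
    whole chain without full-montage cost."""
    cfg = SynthStudyConfig(
        n_subjects=3, seed=11, channels=("C3", "P4", "P7", "O1", "O2"),
    )
    recordings, events = _load_recordings(
        PipelineConfig(synth=cfg, seed=cfg.seed))
    return cfg, recordings, events


@pytest.fixture(scope="session")
def tiny_features(tiny_study):
    cfg, recordings, events = tiny_study
    pcfg = PipelineConfig(synth=cfg, seed=cfg.seed)
    return extract_features(pcfg, recordings, events)
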