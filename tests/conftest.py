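"""Shared fixtures: small synthetic corpora and reusable clean pulse trains.

Everything is generated programmatically with fixed seeds; nothing is read
from disk.
"""

from __future__ import annotations

import numpy as np
import pytest

from ppgvitals.synthetic import SynthConfig, generate_corpus, generate_segment


@pytest.fixture(scope="session")
def clean_segment():
    """Noise- and artifact-free 75 bpm segment with ground truth."""
    cfg = SynthConfig(hr_bpm=75.0, rr_bpm=15.0, spo2_pct=97.0,
                      noise_snr_db=None, artifact_rate_per_min=0.0, seed=11)
    return generate_segment(cfg)


@pytest.fixture(scope="session")
def noisy_segment():
    """Default-noise segment (25 dB SNR, artifacts possible)."""
    cfg = SynthConfig(hr_bpm=75.0, rr_bpm=15.0, spo2_pct=97.0, seed=12)
    return generate_segment(cfg)


@pytest.fixture(scope="session")
def small_corpus():
    """60 noisy segments with uniform RR/SpO2/HR draws, plus truths."""
    return generate_corpus(60, seed=21)


@pytest.fixture(scope="session")
def small_features(small_corpus):
    """Feature matrix of the small corpus (full preprocessing chain)."""
    from ppgvitals.pipeline import segments_to_features
    segments, _ = small_corpus
    return segments_to_features(segments)
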