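"""Shared fixtures: tiny synthetic corpora and pre-trained small models.

Everything is generated programmatically at test time; the heavier
fixtures (a trained regressor) are session-scoped so the cost is paid
once per run.
"""

from __future__ import annotations

import math

import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")

from caflex.features import FeatureMask, encode_protein
from caflex.model import ModelConfig, TrainConfig, train_model
from caflex.structures_io import ProteinRecord, ResidueSite
from caflex.synthetic_data import SyntheticConfig, generate_dataset


def make_record(
    coords: np.ndarray,
    b: np.ndarray,
    chain_ids=None,
    aa_codes=None,
    ss_labels=None,
    pid: str = "toy",
) -> ProteinRecord:
    """Assemble a ProteinRecord from arrays (test helper)."""
    n = len(b)
    chain_ids = chain_ids or ["A"] * n
    aa_codes = aa_codes or ["ALA"] * n
    ss_labels = ss_labels or ["coil"] * n
    sites = [
        ResidueSite(aa_codes[i], *map(float, coords[i]), float(b[i]),
                    chain_ids[i], ss_labels[i])
        for i in range(n)
    ]
    return ProteinRecord(pid, sites)


def helix_coords(n: int, rise: float = 1.5, twist_deg: float = 100.0,
                 bond: float = 3.8) -> np.ndarray:
    """Ideal α-helix Cα trace with exact virtual bond length."""
    tw = math.radians(twist_deg)
    radius = math.sqrt(bond**2 - rise**2) / (2 * math.sin(tw / 2))
    t = np.arange(n)
    return np.stack([radius * np.cos(tw * t), radius * np.sin(tw * t), rise * t], 1)


@pytest.fixture(scope="session")
def small_corpus():
    """30 short synthetic proteins with ground-truth caging law."""
    cfg = SyntheticConfig(n_min=40, n_max=80, seed=0)
    records, manifest = generate_dataset(cfg, 30, seed=202)
    return cfg, records, manifest


@pytest.fixture(scope="session")
def trained_small(small_corpus):
    """A small biLSTM regressor trained briefly on the small corpus."""
    _, records, _ = small_corpus
    encoded = [encode_protein(r) for r in records]
    cfg = ModelConfig(encoder_widths=(24,), lstm_hidden=24, lstm_layers=1,
                      decoder_widths=(24, 1))
    tc = TrainConfig(seeds=(0,), max_epochs=25, batch_size=8,
                     learning_rate=2e-3, early_stop_patience=25)
    model, hist = train_model(cfg, tc, encoded[:24], encoded[24:])
    return model, hist, records, encoded
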