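from __future__ import annotations

import numpy as np
import pytest
from hypothesis import settings

import rmethyl as rm

settings.register_profile("deterministic", derandomize=True)
settings.load_profile("deterministic")

AA = sorted("ACDEFGHIKLMNPQRSTVWY")


def random_window(rng: np.random.Generator, length: int = 11,
                  pad_left: int = 0, pad_right: int = 0) -> str:
    """An R-centered window with optional terminal padding."""
    inner = length - pad_left - pad_right
    codes = rng.integers(0, 20, size=inner)
    residues = list("X" * pad_left) + [AA[c] for c in codes] + list("X" * pad_right)
    residues[length // 2] = "R"
    return "".join(residues)


@pytest.fixture(scope="session")
def planted_dataset() -> rm.LabeledDataset:
    """The reference study conditions: 400 windows, strength 0.8, seed 42."""
    return rm.generate_windows(
        rm.SyntheticConfig(n_positive=200, n_negative=200, signal_strength=0.8, seed=42)
    )


@pytest.fixture(scope="session")
def planted_matrix(planted_dataset):
    df = rm.encode_dataset(planted_dataset)
    X, y, names = rm.split_matrix(df)
    return df, X, y, names


@pytest.fixture(scope="session")
def planted_model(planted_matrix) -> rm.TrainedModel:
    _, X, y, names = planted_matrix
    return rm.train(X, y, rm.ClassifierSpec(seed=42), feature_names=names)


@pytest.fixture()
def tiny_fasta(tmp_path):
    path = tmp_path / "proteins.fasta"
    path.write_text(">p1\nGGGGGRGGGGG\n>p2\nMARAGRKLRAA\n")
    return path
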