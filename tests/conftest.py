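"""Shared fixtures: small synthetic datasets generated once per session."""

from __future__ import annotations

import numpy as np
import pytest

from hicstack import matrix as mx
from hicstack import simulate as sim
from hicstack.genome import BinTable, ContactMatrix


@pytest.fixture(scope="session")
def small_spec() -> sim.SyntheticSpec:
    """8-Mb chromosome at 40 kb: fast, enough structure for recovery."""
    return sim.SyntheticSpec(
        length=8_000_000, resolution=40_000, library_size=1_500_000, seed=11
    )


@pytest.fixture(scope="session")
def small_dataset(small_spec):
    cm, truth = sim.generate_hic(small_spec)
    return {"spec": small_spec, "raw": cm, "truth": truth}


@pytest.fixture(scope="session")
def small_balanced(small_dataset):
    masked = mx.mask_low_coverage(small_dataset["raw"])
    return mx.ice_balance(masked)


@pytest.fixture(scope="session")
def loop_spec() -> sim.SyntheticSpec:
    """12-Mb chromosome at 10 kb for interaction-calling tests."""
    return sim.SyntheticSpec(
        length=12_000_000, resolution=10_000, library_size=3e6, seed=8
    )


@pytest.fixture(scope="session")
def loop_dataset(loop_spec):
    cm, truth = sim.generate_hic(loop_spec)
    bal = mx.ice_balance(mx.mask_low_coverage(cm))
    return {
        "spec": loop_spec,
        "raw": cm,
        "truth": truth,
        "balanced": bal,
        "tracks": sim.generate_tracks(truth, loop_spec),
    }


def toy_matrix(values: np.ndarray, resolution: int = 10_000) -> ContactMatrix:
    """Wrap a dense symmetric array as a raw ContactMatrix."""
    values = np.asarray(values, dtype=float)
    bins = BinTable("chrT", values.shape[0] * resolution, resolution)
    return ContactMatrix(bins, values)


def as_balanced(values: np.ndarray, resolution: int = 10_000) -> ContactMatrix:
    """Wrap a dense symmetric array as an already-balanced matrix with
    unit weights (for operations that require balanced state)."""
    values = np.asarray(values, dtype=float)
    bins = BinTable("chrT", values.shape[0] * resolution, resolution)
    return ContactMatrix(
        bins, values, weights=np.ones(values.shape[0]), state="balanced"
    )
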