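"""Shared fixtures: toy crystals, reflection sets, and the synthetic study."""

import numpy as np
import pytest

from msxref.assessment import FreeSetSpec
from msxref.crystal_core import AtomicState, ReflectionSet, SPACE_GROUPS, UnitCell
from msxref.synthetic_data import (SyntheticSpec, build_toy_native,
                                   full_hkl_set, simulate_datasets)


@pytest.fixture(scope="session")
def cubic_cell():
    return UnitCell(10.0, 10.0, 10.0)


@pytest.fixture(scope="session")
def p1():
    return SPACE_GROUPS["P1"]


@pytest.fixture(scope="session")
def small_state(p1):
    """Seeded 5-atom state in a 12 A cubic box (no topology)."""
    rng = np.random.default_rng(11)
    elements = ["C", "N", "O", "C", "S"]
    coords = rng.uniform(2.0, 10.0, size=(5, 3))
    return AtomicState(elements, coords, b_factors=np.full(5, 15.0))


@pytest.fixture(scope="session")
def small_refls(p1):
    cell = UnitCell(12.0, 12.0, 12.0)
    hkl = full_hkl_set(cell, p1, 3.0)
    rng = np.random.default_rng(4)
    return ReflectionSet(cell, p1, hkl, rng.uniform(1.0, 50.0, size=len(hkl)))


@pytest.fixture(scope="session")
def toy_study():
    """Noisy (sigma = 5%) 2-state 2-condition study at 2.5 A."""
    spec = SyntheticSpec(seed=3, d_min=2.5,
                         free_spec=FreeSetSpec(fraction=0.05, n_bins=10, seed=3))
    native, cell, ops, params = build_toy_native(spec)
    datasets = simulate_datasets(native, cell, ops, spec)
    return {"native": native, "cell": cell, "ops": ops, "params": params,
            "datasets": datasets, "spec": spec}


@pytest.fixture(scope="session")
def noiseless_study():
    """Same toy study with sigma = 0 (self-consistent amplitudes)."""
    spec = SyntheticSpec(seed=3, d_min=2.5, noise_sigma=0.0,
                         free_spec=FreeSetSpec(fraction=0.05, n_bins=10, seed=3))
    native, cell, ops, params = build_toy_native(spec)
    datasets = simulate_datasets(native, cell, ops, spec)
    return {"native": native, "cell": cell, "ops": ops, "params": params,
            "datasets": datasets, "spec": spec}


@pytest.fixture(scope="session")
def tiny_native():
    """2-residue 2-state native in a small padded box (fast scattering)."""
    spec = SyntheticSpec(n_residues=2, cell_padding=3.0, seed=1)
    native, cell, ops, params = build_toy_native(spec)
    return {"native": native, "cell": cell, "ops": ops, "params": params,
            "spec": spec}
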