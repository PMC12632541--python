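"""Synthetic benchmark generation: toy multi-state natives, simulated noisy
multi-condition reflection datasets, decoy sets, and the crystal-scattering
degeneracy experiment.

Everything the refinement method needs can be generated here, with no
downloads: a 2-state native whose states differ by small backbone and large
side-chain displacements, per-condition weight matrices, amplitudes with
relative Gaussian noise, and a shared per-resolution-bin free set.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .assessment import FreeSetSpec, assign_free_flags, rmsd_star
from .crystal_core import (AtomicState, MultiStateModel, ReflectionSet,
                           SPACE_GROUPS, UnitCell, WeightMatrix, reduce_to_asu)
from .forward_model import (DEFAULT_FORM_FACTORS, StateScattering,
                            multi_state_sf)
from .prior_ff import ForceFieldParameters, Topology, potential_energy

__all__ = [
    "SyntheticSpec",
    "build_toy_native",
    "toy_forcefield",
    "simulate_datasets",
    "generate_decoys",
    "degeneracy_experiment",
    "gridded_density",
    "full_hkl_set",
]


@dataclass
class SyntheticSpec:
    """Parameters of a synthetic study.

    Displacement magnitudes are RMS targets (angstrom) for the
    backbone-mimic (N, CA, C, O) and side-chain-mimic (CB, CG) atoms of
    state 2 relative to state 1.  noise_sigma is relative: the amplitude
    noise s.d. is noise_sigma * amplitude.
    """

    n_residues: int = 17
    backbone_disp: float = 0.3
    sidechain_disp: float = 1.5
    n_conditions: int = 2
    weights: np.ndarray = field(default_factory=lambda: np.array([[0.8, 0.3], [0.2, 0.7]]))
    d_min: float = 2.0
    noise_sigma: float = 0.05
    free_spec: FreeSetSpec = field(default_factory=FreeSetSpec)
    cell_padding: float = 5.0
    space_group: str = "P1"
    seed: int = 0

    def __post_init__(self):
        if self.d_min <= 0:
            raise ValueError("d_min must be positive")
        if self.noise_sigma < 0:
            raise ValueError("noise sigma must be non-negative")
        WeightMatrix(self.weights)


# ---------------------------------------------------------------------------
# Toy native
# ---------------------------------------------------------------------------

_RES_TYPES = ["NH1", "CT1", "C", "O", "CT2", "CT3"]  # N CA C O CB CG
_RES_ELEMENTS = ["N", "C", "C", "O", "C", "C"]
_BACKBONE = {0, 1, 2, 3}
_SIDECHAIN = {4, 5}


def _place(a, b, c, bond, angle_deg, torsion_deg):
    """NeRF placement of atom d from frame atoms a-b-c plus internal coordinates."""
    angle = math.radians(angle_deg)
    torsion = math.radians(torsion_deg)
    bc = c - b
    bc /= np.linalg.norm(bc)
    n = np.cross(b - a, bc)
    n /= max(np.linalg.norm(n), 1e-12)
    m = np.cross(n, bc)
    d_local = np.array([
        -bond * math.cos(angle),
        bond * math.sin(angle) * math.cos(torsion),
        bond * math.sin(angle) * math.sin(torsion),
    ])
    return c + d_local[0] * bc + d_local[1] * m + d_local[2] * n


def _build_chain(n_res: int) -> np.ndarray:
    """Helical poly-"GLU-lite" backbone with a 2-atom side chain per residue."""
    phi, psi, omega = -57.0, -47.0, 180.0
    coords = []
    # bootstrap residue 0
    n0 = np.array([0.0, 0.0, 0.0])
    ca0 = np.array([1.458, 0.0, 0.0])
    ang = math.radians(111.2)
    c0 = ca0 + 1.525 * np.array([-math.cos(ang), math.sin(ang), 0.0])
    prev = {"N": n0, "CA": ca0, "C": c0}
    for i in range(n_res):
        if i == 0:
            n, ca, c = n0, ca0, c0
        else:
            n = _place(prev["N"], prev["CA"], prev["C"], 1.329, 116.2, psi)
            ca = _place(prev["CA"], prev["C"], n, 1.458, 121.7, omega)
            c = _place(prev["C"], n, ca, 1.525, 111.2, phi)
        o = _place(n, ca, c, 1.231, 120.8, psi + 180.0)
        cb = _place(c, n, ca, 1.530, 110.5, -122.0)
        cg = _place(n, ca, cb, 1.520, 114.0, -60.0)
        coords.extend([n, ca, c, o, cb, cg])
        prev = {"N": n, "CA": ca, "C": c}
    return np.array(coords)


def _toy_topology(n_res: int) -> Topology:
    types = _RES_TYPES * n_res
    bonds, impropers = [], []
    for i in range(n_res):
        o = 6 * i
        bonds += [(o, o + 1), (o + 1, o + 2), (o + 2, o + 3), (o + 1, o + 4), (o + 4, o + 5)]
        if i + 1 < n_res:
            bonds.append((o + 2, o + 6))       # C(i) - N(i+1)
            impropers.append((o + 1, o + 6, o + 2, o + 3))  # CA, N+1, C, O planarity
    return Topology.from_bonds(types, bonds, impropers=impropers)


def toy_forcefield() -> ForceFieldParameters:
    """Minimal CHARMM-like parameter subset for the toy chain."""
    params = ForceFieldParameters(
        bonds={
            ("NH1", "CT1"): (320.0, 1.458),
            ("CT1", "C"): (250.0, 1.525),
            ("C", "O"): (620.0, 1.231),
            ("C", "NH1"): (370.0, 1.329),
            ("CT1", "CT2"): (222.0, 1.530),
            ("CT2", "CT3"): (222.0, 1.520),
        },
        angles={
            ("NH1", "CT1", "C"): (50.0, 111.2),
            ("CT1", "C", "O"): (80.0, 120.8),
            ("CT1", "C", "NH1"): (80.0, 116.2),
            ("C", "NH1", "CT1"): (50.0, 121.7),
            ("O", "C", "NH1"): (80.0, 123.0),
            ("NH1", "CT1", "CT2"): (70.0, 110.5),
            ("C", "CT1", "CT2"): (52.0, 110.1),
            ("CT1", "CT2", "CT3"): (58.0, 114.0),
        },
        dihedrals={
            ("X", "NH1", "CT1", "X"): [(0.2, 3, 0.0)],
            ("X", "CT1", "C", "X"): [(0.2, 3, 0.0)],
            ("X", "C", "NH1", "X"): [(2.5, 2, 180.0)],
            ("X", "CT1", "CT2", "X"): [(0.2, 3, 0.0)],
            ("X", "CT2", "CT3", "X"): [(0.16, 3, 0.0)],
        },
        impropers={("CT1", "NH1", "C", "O"): (20.0, 0.0)},
        nonbonded={
            "NH1": (0.20, 1.85),
            "CT1": (0.02, 2.275),
            "C": (0.11, 2.00),
            "O": (0.12, 1.70),
            "CT2": (0.055, 2.175),
            "CT3": (0.08, 2.06),
        },
    )
    return params


def _calibrate_improper(params: ForceFieldParameters, top: Topology, coords) -> None:
    # equilibrium improper value measured from the idealized template
    from .prior_ff import _dihedral_and_grad

    if not top.impropers:
        return
    vals = np.array([
        _dihedral_and_grad(coords[i], coords[j], coords[k], coords[l])[0]
        for i, j, k, l in top.impropers
    ])
    # circular mean (the planar value sits at +-180 deg)
    mean = math.atan2(float(np.sin(vals).mean()), float(np.cos(vals).mean()))
    params.impropers[("CT1", "NH1", "C", "O")] = (20.0, math.degrees(mean))


def _smooth_along_chain(noise: np.ndarray, window: int = 5) -> np.ndarray:
    window = min(window, len(noise))
    kernel = np.ones(window) / window
    out = np.empty_like(noise)
    for k in range(noise.shape[1]):
        out[:, k] = np.convolve(noise[:, k], kernel, mode="same")
    return out


def build_toy_native(spec: SyntheticSpec):
    """Build the 2-state toy native and its force field.

    State 2 is state 1 with a smooth low-frequency backbone displacement
    (rescaled to the requested backbone RMS) plus a rotamer-like rotation of
    each CG about its CA-CB axis sized so that the side-chain-mimic RMS hits
    its target.  B = 15 and occupancy = 1 everywhere; the default weight
    matrix makes state 1 dominant under condition 1 and state 2 dominant
    under condition 2.  Returns (MultiStateModel, UnitCell, SymmetryOps,
    ForceFieldParameters).
    """
    rng = np.random.default_rng(spec.seed)
    n_res = spec.n_residues
    coords1 = _build_chain(n_res)
    top = _toy_topology(n_res)
    params = toy_forcefield()
    _calibrate_improper(params, top, coords1)
    elements = _RES_ELEMENTS * n_res
    n_atoms = len(elements)
    backbone = np.array([i % 6 in _BACKBONE for i in range(n_atoms)])
    sidechain = ~backbone

    # smooth per-residue backbone displacement, applied to the whole residue
    res_noise = _smooth_along_chain(rng.normal(size=(n_res, 3)))
    disp = np.repeat(res_noise, 6, axis=0)
    rms = math.sqrt(float((disp[backbone] ** 2).sum(axis=1).mean()))
    disp *= spec.backbone_disp / max(rms, 1e-12)
    coords2 = coords1 + disp

    # rotamer-like CG rotation about the (displaced) CA-CB axis
    ms_bb = float((disp[backbone] ** 2).sum(axis=1).mean())
    ms_cb = ms_bb
    target = max(2.0 * spec.sidechain_disp**2 - ms_cb - ms_bb, 0.0)
    d_rot = math.sqrt(target)
    signs = rng.choice([-1.0, 1.0], size=n_res)
    for i in range(n_res):
        ca, cb, cg = 6 * i + 1, 6 * i + 4, 6 * i + 5
        axis = coords2[cb] - coords2[ca]
        axis /= np.linalg.norm(axis)
        rel = coords2[cg] - coords2[cb]
        r_perp = np.linalg.norm(rel - (rel @ axis) * axis)
        if r_perp < 1e-6 or d_rot == 0.0:
            continue
        mag = 2.0 * math.asin(min(1.0, d_rot / (2.0 * r_perp)))
        others = np.delete(np.arange(n_atoms), [cb, cg])

        def rotated(angle):
            k = axis
            return coords2[cb] + (rel * math.cos(angle) + np.cross(k, rel) * math.sin(angle)
                                  + k * (k @ rel) * (1.0 - math.cos(angle)))

        # pick the rotation sign with the larger clearance (clash avoidance);
        # both signs give the same displacement magnitude
        candidates = [rotated(s * mag) for s in (signs[i], -signs[i])]
        clearance = [np.linalg.norm(coords2[others] - c, axis=1).min() for c in candidates]
        coords2[cg] = candidates[int(np.argmax(clearance))]

    state1 = AtomicState(elements, coords1, topology=top)
    state2 = AtomicState(elements, coords2, topology=top)
    # center in a padded P1 box
    allc = np.vstack([coords1, coords2])
    span = allc.max(axis=0) - allc.min(axis=0) + 2.0 * spec.cell_padding
    shift = -allc.min(axis=0) + spec.cell_padding
    state1.coords += shift
    state2.coords += shift
    cell = UnitCell(*(float(round(x, 2)) for x in span))
    ops = SPACE_GROUPS[spec.space_group]
    model = MultiStateModel([state1, state2], WeightMatrix(spec.weights))
    return model, cell, ops, params


def interstate_rms(model: MultiStateModel, subset: str = "all") -> float:
    """Realized RMS deviation between states 1 and 2 over an atom subset."""
    n = model.n_atoms
    backbone = np.array([i % 6 in _BACKBONE for i in range(n)])
    mask = {"all": np.ones(n, bool), "backbone": backbone, "sidechain": ~backbone}[subset]
    d = model.states[1].coords[mask] - model.states[0].coords[mask]
    return float(np.sqrt((d**2).sum(axis=1).mean()))


# ---------------------------------------------------------------------------
# Simulated datasets
# ---------------------------------------------------------------------------

def full_hkl_set(cell: UnitCell, ops, d_min: float) -> np.ndarray:
    """Complete asymmetric-unit Miller index table to d_min (origin excluded)."""
    g = cell.reciprocal_metric
    hmax = [int(math.floor(length / d_min)) + 1 for length in (cell.a, cell.b, cell.c)]
    seen = {}
    for h in range(-hmax[0], hmax[0] + 1):
        for k in range(-hmax[1], hmax[1] + 1):
            for l in range(-hmax[2], hmax[2] + 1):
                if (h, k, l) == (0, 0, 0):
                    continue
                v = np.array([h, k, l], float)
                inv_d2 = float(v @ g @ v)
                if 1.0 / math.sqrt(inv_d2) < d_min:
                    continue
                rep = reduce_to_asu((h, k, l), ops)
                if rep not in seen and not ops.is_absent(rep):
                    seen[rep] = True
    return np.array(sorted(seen), dtype=int)


def simulate_datasets(native: MultiStateModel, cell: UnitCell, ops,
                      spec: SyntheticSpec):
    """Simulate one noisy ReflectionSet per condition from the native.

    Amplitudes are the multi-state forward model (k_total = 1, solvent off)
    with the native weight column of each condition; independent Gaussian
    noise with s.d. = noise_sigma * amplitude is added (negative results
    clamped to zero) and recorded in the sigma column; a shared free set is
    assigned per resolution bin.
    """
    rng = np.random.default_rng(spec.seed + 1)
    hkl = full_hkl_set(cell, ops, spec.d_min)
    base = ReflectionSet(cell, ops, hkl, np.zeros(len(hkl)))
    scattering = [StateScattering(s, base, DEFAULT_FORM_FACTORS) for s in native.states]
    f_states = [sc.F for sc in scattering]
    datasets = []
    for j in range(spec.n_conditions):
        amp = np.abs(multi_state_sf(f_states, native.weights.column(j)))
        sig = spec.noise_sigma * amp
        noisy = np.clip(amp + rng.normal(size=len(amp)) * sig, 0.0, None)
        datasets.append(ReflectionSet(cell, ops, hkl, noisy, sigma=sig,
                                      condition_id=f"cond{j + 1}"))
    return assign_free_flags(datasets, spec.free_spec)


# ---------------------------------------------------------------------------
# Decoys
# ---------------------------------------------------------------------------

def generate_decoys(native: MultiStateModel, datasets, n_decoys: int,
                    accuracy_range=(0.0, 1.0), rng=None, prior_params=None,
                    variant: str = "dynamics", temperatures=(400.0, 900.0, 1800.0, 3600.0),
                    n_bins: int = 10, max_bursts: int = 400, burst_steps: int = 150):
    """Decoy models spanning an RMSD*-to-native accuracy range.

    variant="dynamics" (default): short prior-only Langevin bursts from the
    native perturb the conformations (weights stay native); bursts cycle
    through a temperature ladder so snapshots reach the whole accuracy range,
    are binned by RMSD*, and sampled to approximately uniform bin coverage.
    variant="weights": native conformations with Dirichlet-random weights.
    """
    from .sampler import ACC, KB, _masses

    rng = rng or np.random.default_rng(0)
    lo, hi = accuracy_range
    if variant == "weights":
        out = []
        for _ in range(n_decoys):
            w = rng.dirichlet(np.ones(native.n_states), size=native.n_conditions).T
            out.append(MultiStateModel([s.copy() for s in native.states], WeightMatrix(w)))
        return out
    if variant != "dynamics":
        raise ValueError(f"unknown decoy variant {variant!r}")
    if hi <= lo:
        return [native.copy() for _ in range(n_decoys)]
    if prior_params is None:
        raise ValueError("dynamics decoys need force-field parameters")

    per_bin = int(math.ceil(n_decoys / n_bins))
    bins: list = [[] for _ in range(n_bins)]
    masses = _masses(native.states[0].elements)[:, None]
    dt = 1.0
    gamma = 1.0 / 1000.0
    c1 = math.exp(-gamma * dt)
    c2 = math.sqrt(1.0 - c1 * c1)

    def bin_of(acc):
        b = int((acc - lo) / (hi - lo) * n_bins)
        return b if 0 <= b < n_bins else None

    total = 0
    for burst in range(max_bursts):
        if total >= n_decoys:
            break
        temperature = temperatures[burst % len(temperatures)]
        sigma_v = np.sqrt(KB * temperature * ACC / masses)
        model = native.copy()
        vels = [rng.normal(size=(native.n_atoms, 3)) * sigma_v for _ in model.states]
        grads = [potential_energy(s, prior_params)[1] for s in model.states]
        for step in range(1, burst_steps + 1):
            for i, s in enumerate(model.states):
                v = vels[i] - 0.5 * dt * grads[i] / masses * ACC
                s.coords += 0.5 * dt * v
                v = c1 * v + c2 * sigma_v * rng.normal(size=v.shape)
                s.coords += 0.5 * dt * v
                grads[i] = potential_energy(s, prior_params)[1]
                vels[i] = v - 0.5 * dt * grads[i] / masses * ACC
            if step % 3 == 0:
                acc = rmsd_star(model, native)
                if acc > hi:
                    break
                b = bin_of(acc)
                if b is not None and len(bins[b]) < per_bin:
                    bins[b].append(model.copy())
                    total += 1
    empties = [i for i, b in enumerate(bins) if not b]
    if empties:
        warnings.warn(f"decoy bins with no members: {empties}")
    decoys = [m for b in bins for m in b][:n_decoys]
    return decoys


# ---------------------------------------------------------------------------
# Degeneracy experiment (finite-crystal scattering of mixed-state lattices)
# ---------------------------------------------------------------------------

def gridded_density(state: AtomicState, cell: UnitCell, shape,
                    table=DEFAULT_FORM_FACTORS, atom_subset=None) -> np.ndarray:
    """Electron density of a state sampled on a periodic fractional grid.

    Atoms are B-smeared sums of Gaussians (the 4-Gaussian + constant form
    factor transformed to real space); each is stamped locally with periodic
    wrap.
    """
    shape = tuple(shape)
    rho = np.zeros(shape)
    frac = cell.fractionalization
    ortho = cell.orthogonalization
    dims = np.array(shape)
    atoms = range(state.n_atoms) if atom_subset is None else atom_subset
    for a in atoms:
        el = state.elements[a]
        coeff_a, coeff_b, coeff_c = table.coefficients[el]
        b_iso = state.b_factors[a]
        gauss = [(ai, bi + b_iso) for ai, bi in zip(coeff_a, coeff_b)]
        if abs(coeff_c) > 0 and b_iso > 0:
            gauss.append((coeff_c, b_iso))
        p_min = min(4.0 * math.pi**2 / bp for _, bp in gauss if bp > 0)
        r_cut = math.sqrt(18.0 / p_min)
        xf = (frac @ state.coords[a]) % 1.0
        center = xf * dims
        span = [int(math.ceil(r_cut / (length / nd))) + 1
                for length, nd in zip((cell.a, cell.b, cell.c), dims)]
        idx = [np.arange(int(math.floor(center[k])) - span[k],
                         int(math.ceil(center[k])) + span[k] + 1) for k in range(3)]
        gi, gj, gk = np.meshgrid(*idx, indexing="ij")
        df = np.stack([gi / dims[0] - xf[0], gj / dims[1] - xf[1], gk / dims[2] - xf[2]],
                      axis=-1)
        df -= np.round(df)
        r2 = ((df @ ortho.T) ** 2).sum(axis=-1)
        dens = np.zeros_like(r2)
        for ai, bp in gauss:
            p = 4.0 * math.pi**2 / bp
            dens += ai * (p / math.pi) ** 1.5 * np.exp(-p * r2)
        dens *= state.occupancies[a]
        np.add.at(rho, (gi % dims[0], gj % dims[1], gk % dims[2]), dens)
    return rho


def density_transform(rho: np.ndarray, cell: UnitCell, hkl: np.ndarray) -> np.ndarray:
    """F(h) = (V/N) sum rho exp(+2 pi i h.x) evaluated at integer Miller indices."""
    fft = np.conj(np.fft.fftn(rho)) * (cell.volume / rho.size)
    dims = rho.shape
    h, k, l = np.asarray(hkl).T
    return fft[h % dims[0], k % dims[1], l % dims[2]]


def degeneracy_experiment(state1: AtomicState, state2: AtomicState, cell: UnitCell,
                          weights=(0.6, 0.4), n_cells=(2, 4, 8), grid=(32, 32, 32),
                          rng=None, h_max: int = 6, coherent_blocks: bool = True,
                          ref_floor: float = 1e-6, n_replicates: int = 16) -> pd.DataFrame:
    """Scattering error of five finite-crystal configurations vs crystal size.

    The five configurations of a two-state crystal:
      1. per-cell Bernoulli(w1) state assignment;
      2. two contiguous blocks with cell fractions w1/w2 ("two crystals");
      3. every cell the w1/w2 partial-occupancy mixture (the reference);
      4. configuration 1 with the state labels swapped (a pure relabeling:
         template list and weights swapped together);
      5. per-cell, per-atom independent state assignment.

    Structure factors at the reciprocal lattice points of the single-cell
    lattice are exact sums of per-cell single-cell DFTs (every inter-cell
    phase factor is 1 there), so each configuration reduces to counts of
    cells (or atoms) carrying each state; the counts are drawn per cell from
    the stated distribution.  The error at each lattice point is
    ||F - F_ref|| / ||F_ref|| against the infinite-crystal weighted sum
    (identical to configuration 3), summarized as the mean over points with
    non-negligible reference amplitude.

    With coherent_blocks=False configuration 2 adds the two blocks'
    intensities instead (two physically separate crystals); those amplitudes
    do not converge to the coherent reference and the option exists for
    comparison only.
    """
    rng = rng or np.random.default_rng(0)
    w1, w2 = float(weights[0]), float(weights[1])
    if abs(w1 + w2 - 1.0) > 1e-9:
        raise ValueError("weights must sum to 1")
    shape = tuple(grid)
    if any(s < 2 * h_max + 2 for s in shape):
        raise ValueError("grid incompatible with requested h_max")
    hs = np.arange(-h_max, h_max + 1)
    hkl = np.array([(h, k, l) for h in hs for k in hs for l in hs
                    if (h, k, l) != (0, 0, 0)], dtype=int)
    rho1 = gridded_density(state1, cell, shape)
    rho2 = gridded_density(state2, cell, shape)
    f1 = density_transform(rho1, cell, hkl)
    f2 = density_transform(rho2, cell, hkl)
    n_atoms = state1.n_atoms
    f1_atoms = np.stack([
        density_transform(gridded_density(state1, cell, shape, atom_subset=[a]), cell, hkl)
        for a in range(n_atoms)])
    f2_atoms = np.stack([
        density_transform(gridded_density(state2, cell, shape, atom_subset=[a]), cell, hkl)
        for a in range(n_atoms)])
    f_ref = w1 * f1 + w2 * f2
    good = np.abs(f_ref) > ref_floor * np.abs(f_ref).max()

    def mean_error(f):
        err = np.abs(f - f_ref) / np.abs(f_ref)
        return float(err[good].mean())

    rows = []
    for n in n_cells:
        if n < 1:
            raise ValueError("n_cells must be >= 1")
        total = n**3
        errs = {c: [] for c in (1, 2, 3, 4, 5)}
        for _ in range(max(1, n_replicates)):
            # 1: per-cell Bernoulli(w1)
            n1 = int(rng.binomial(total, w1))
            errs[1].append(mean_error((n1 * f1 + (total - n1) * f2) / total))
            # 2: contiguous blocks, deterministic split
            nb1 = int(round(w1 * total))
            if coherent_blocks:
                f_c2 = (nb1 * f1 + (total - nb1) * f2) / total
            else:
                f_c2 = np.sqrt((nb1 * np.abs(f1)**2 + (total - nb1) * np.abs(f2)**2) / total)
            errs[2].append(mean_error(f_c2))
            # 3: partial occupancy -- exact weighted sum in every cell
            errs[3].append(mean_error((total * f_ref) / total))
            # 4: relabeled configuration 1
            n1_swap = int(rng.binomial(total, w2))
            errs[4].append(mean_error((n1_swap * f2 + (total - n1_swap) * f1) / total))
            # 5: per-atom independent assignment
            m1 = rng.binomial(total, w1, size=n_atoms).astype(float)
            errs[5].append(mean_error((m1 @ f1_atoms + (total - m1) @ f2_atoms) / total))
        for config in (1, 2, 3, 4, 5):
            rows.append({"config": config, "n_cells": n,
                         "mean_error": float(np.mean(errs[config]))})
    return pd.DataFrame(rows)
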