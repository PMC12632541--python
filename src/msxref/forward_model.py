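"""Crystallographic forward model for multi-state structures.

Direct-summation structure factors per state, the weighted multi-state sum
F_C = sum_i w_i F_i, an optional flat-mask bulk-solvent term F_B, the total
scaled amplitude |F_M| = |k_total (F_C + k_mask F_B)|, nuisance-parameter
fitting, and analytic coordinate gradients for the sampler.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import scipy.ndimage

from .crystal_core import AtomicState, MultiStateModel, ReflectionSet, WeightMatrix

__all__ = [
    "FormFactorTable",
    "DEFAULT_FORM_FACTORS",
    "form_factor",
    "ModelStructureFactors",
    "NuisanceParameters",
    "single_state_sf",
    "multi_state_sf",
    "bulk_solvent_sf",
    "total_amplitude",
    "fit_nuisance",
    "amplitude_coordinate_gradients",
    "StateScattering",
    "resolution_shells",
]

# International Tables 4-Gaussian + constant scattering coefficients
# f(stol) = sum_i a_i exp(-b_i stol^2) + c, stol = sin(theta)/lambda in 1/A.
_IT92 = {
    "H": ([0.493002, 0.322912, 0.140191, 0.04081], [10.5109, 26.1257, 3.14236, 57.7997], 0.003038),
    "C": ([2.31, 1.02, 1.5886, 0.865], [20.8439, 10.2075, 0.5687, 51.6512], 0.2156),
    "N": ([12.2126, 3.1322, 2.0125, 1.1663], [0.0057, 9.8933, 28.9975, 0.5826], -11.529),
    "O": ([3.0485, 2.2868, 1.5463, 0.867], [13.2771, 5.7011, 0.3239, 32.9089], 0.2508),
    "S": ([6.9053, 5.2034, 1.4379, 1.5863], [1.4679, 22.2151, 0.2536, 56.172], 0.8669),
    "P": ([6.4345, 4.1791, 1.78, 1.4908], [1.9067, 27.157, 0.526, 68.1645], 1.1149),
    "Zn": ([14.0743, 7.0318, 5.1652, 2.41], [3.2655, 0.2333, 10.3163, 58.7097], 1.3041),
}

# van der Waals radii (A) used by the solvent mask
_VDW = {"H": 1.2, "C": 1.7, "N": 1.55, "O": 1.52, "S": 1.8, "P": 1.8, "Zn": 1.39}


class FormFactorTable:
    """Per-element 4-Gaussian + constant atomic scattering factors."""

    def __init__(self, coefficients=None):
        self.coefficients = dict(coefficients or _IT92)

    @classmethod
    def from_file(cls, path) -> "FormFactorTable":
        """Plain-text columns: element a1..a4 b1..b4 c (comments with #)."""
        coeffs = {}
        with open(path) as fh:
            for line in fh:
                line = line.split("#")[0].strip()
                if not line:
                    continue
                parts = line.split()
                if len(parts) != 10:
                    raise ValueError(f"expected 10 columns, got {len(parts)}: {line!r}")
                el = parts[0]
                vals = [float(x) for x in parts[1:]]
                coeffs[el] = (vals[0:4], vals[4:8], vals[8])
        table = cls(dict(_IT92))
        table.coefficients.update(coeffs)
        return table

    def f(self, element: str, stol) -> np.ndarray:
        if element not in self.coefficients:
            raise KeyError(f"no scattering coefficients for element {element!r}")
        a, b, c = self.coefficients[element]
        stol2 = np.asarray(stol, dtype=float) ** 2
        out = np.full_like(stol2, c, dtype=float)
        for ai, bi in zip(a, b):
            out += ai * np.exp(-bi * stol2)
        return out


DEFAULT_FORM_FACTORS = FormFactorTable()


def form_factor(element: str, stol) -> np.ndarray:
    """Atomic scattering factor f(sin(theta)/lambda) in electrons."""
    return DEFAULT_FORM_FACTORS.f(element, stol)


# ---------------------------------------------------------------------------
# Nuisance parameters and resolution shells
# ---------------------------------------------------------------------------

@dataclass
class NuisanceParameters:
    """Scaling/error parameters: k_total, k_mask, per-shell alpha and beta.

    Shell edges are d values, strictly decreasing (low to high resolution);
    shell s covers edges[s] >= d > edges[s+1].
    """

    k_total: float = 1.0
    k_mask: float = 0.0
    shell_edges: np.ndarray = field(default_factory=lambda: np.array([np.inf, 0.0]))
    alpha: np.ndarray = field(default_factory=lambda: np.array([1.0]))
    beta: np.ndarray = field(default_factory=lambda: np.array([1.0]))

    def __post_init__(self):
        self.shell_edges = np.asarray(self.shell_edges, dtype=float)
        self.alpha = np.atleast_1d(np.asarray(self.alpha, dtype=float))
        self.beta = np.atleast_1d(np.asarray(self.beta, dtype=float))
        if self.k_total <= 0:
            raise ValueError("k_total must be positive")
        if self.k_mask < 0:
            raise ValueError("k_mask must be non-negative")
        if np.any(np.diff(self.shell_edges) >= 0):
            raise ValueError("shell edges must be strictly decreasing in d")
        if np.any(self.beta <= 0):
            raise ValueError("beta must be positive in every shell")

    def shell_index(self, d) -> np.ndarray:
        d = np.asarray(d, dtype=float)
        idx = np.searchsorted(-self.shell_edges, -d, side="right") - 1
        return np.clip(idx, 0, len(self.alpha) - 1)

    def alpha_of(self, d) -> np.ndarray:
        return self.alpha[self.shell_index(d)]

    def beta_of(self, d) -> np.ndarray:
        return self.beta[self.shell_index(d)]


def resolution_shells(d, work_mask, n_shells: int, min_work: int = 20):
    """Equal-count shell edges in d; shells with < min_work work reflections merged."""
    d = np.asarray(d, dtype=float)
    dw = np.sort(d[work_mask])[::-1]
    if len(dw) == 0:
        raise ValueError("no work reflections")
    n_shells = max(1, min(n_shells, len(dw) // max(min_work, 1) or 1))
    edges = [np.inf]
    for s in range(1, n_shells):
        edges.append(dw[int(round(s * len(dw) / n_shells))])
    edges.append(0.0)
    edges = np.array(edges)
    # de-duplicate (ties in d)
    keep = [0]
    for i in range(1, len(edges)):
        if edges[i] < edges[keep[-1]]:
            keep.append(i)
    return edges[keep]


# ---------------------------------------------------------------------------
# Structure factors
# ---------------------------------------------------------------------------

class StateScattering:
    """Cached per-state scattering: contribution matrix T and phase gradients.

    F(h) = sum_ops sum_atoms T_op[r, a] with
    T_op[r, a] = occ_a f_a(stol_r) exp(-B_a stol_r^2) exp(2 pi i (h R) . x_a + 2 pi i h.t)
    dF/dX_a = sum_ops i * T_op[r, a] * gvec_op[r, :]  (Cartesian).
    """

    def __init__(self, state: AtomicState, refls: ReflectionSet,
                 table: FormFactorTable = DEFAULT_FORM_FACTORS):
        cell = refls.cell
        frac = cell.fractionalization
        x_frac = state.coords @ frac.T  # (A, 3)
        weight = self._atom_weights(state, refls, table)
        self.T_ops = []
        self.gvec_ops = []
        hkl = refls.hkl.astype(float)
        for rot, tr in refls.ops:
            h_rot = hkl @ rot  # row vector h^T R
            phase = 2.0 * np.pi * (h_rot @ x_frac.T + (hkl @ tr)[:, None])
            self.T_ops.append(weight * np.exp(1j * phase))
            self.gvec_ops.append(2.0 * np.pi * (h_rot @ frac))  # d(phase)/dX
        self.F = sum(t.sum(axis=1) for t in self.T_ops)

    @staticmethod
    def _atom_weights(state, refls, table):
        # occ * f(stol) * exp(-B stol^2) is coordinate-independent: cache on
        # the reflection set (B and occupancies are fixed during sampling)
        cache = getattr(refls, "_atom_weight_cache", None)
        if cache is None:
            cache = {}
            refls._atom_weight_cache = cache
        key = (id(table), tuple(state.elements), state.b_factors.tobytes(),
               state.occupancies.tobytes())
        weight = cache.get(key)
        if weight is not None:
            return weight
        stol = refls.stol
        stol2 = stol**2
        f_el = {el: table.f(el, stol) for el in set(state.elements)}
        weight = np.empty((len(refls), state.n_atoms))
        for a, el in enumerate(state.elements):
            weight[:, a] = state.occupancies[a] * f_el[el] * np.exp(-state.b_factors[a] * stol2)
        if len(cache) > 8:
            cache.pop(next(iter(cache)))
        cache[key] = weight
        return weight

    def gradient(self, coeff_complex: np.ndarray) -> np.ndarray:
        """Real gradient sum_r Re(coeff_r * i * dF_r/dX_a) as (A, 3)."""
        grad = np.zeros((self.T_ops[0].shape[1], 3))
        for t, g in zip(self.T_ops, self.gvec_ops):
            q = (1j * coeff_complex)[:, None] * g  # (n, 3)
            grad += np.real(t.T @ q)
        return grad


def single_state_sf(state: AtomicState, refls: ReflectionSet,
                    table: FormFactorTable = DEFAULT_FORM_FACTORS) -> np.ndarray:
    """Complex structure factors of one state by direct summation."""
    return StateScattering(state, refls, table).F


def multi_state_sf(per_state_f, weights) -> np.ndarray:
    """Weighted multi-state sum F_C(h) = sum_i w_i F_i(h)."""
    per_state_f = [np.asarray(f) for f in per_state_f]
    w = np.asarray(weights, dtype=float).ravel()
    if len(w) != len(per_state_f):
        raise ValueError(f"{len(w)} weights for {len(per_state_f)} states")
    return sum(wi * fi for wi, fi in zip(w, per_state_f))


# ---------------------------------------------------------------------------
# Bulk solvent (flat mask)
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SolventMaskParams:
    probe_radius: float = 1.1
    shrink_radius: float = 0.9
    grid_spacing: float | None = None  # default d_min/4


def bulk_solvent_sf(states, weights, refls: ReflectionSet,
                    mask_params: SolventMaskParams = SolventMaskParams()):
    """Flat-mask bulk-solvent structure factors of the weighted-average structure.

    The binary mask is 1 in solvent (outside atom-exclusion zones grown by the
    probe radius, then shrunk back), 0 inside; F_B is its DFT with unit density
    (the physical solvent density is absorbed by k_mask).  Returns (F_B,
    solvent volume fraction).
    """
    cell = refls.cell
    d_min = float(refls.d.min())
    spacing = mask_params.grid_spacing or d_min / 4.0
    if spacing > d_min / 2.0:
        raise ValueError("solvent mask grid too coarse (spacing > d_min/2)")
    dims = [max(4, int(math.ceil(length / spacing))) for length in (cell.a, cell.b, cell.c)]
    frac = cell.fractionalization
    ortho = cell.orthogonalization
    mask = np.ones(dims, dtype=bool)
    w = np.asarray(weights, dtype=float).ravel()
    avg = np.einsum("i,iak->ak", w, np.stack([s.coords for s in states]))
    elements = states[0].elements
    # voxel Cartesian offsets for a local stamp
    for a, el in enumerate(elements):
        r_cut = _VDW.get(el, 1.7) + mask_params.probe_radius
        xf = (frac @ avg[a]) % 1.0
        center = xf * dims
        span = [int(math.ceil(r_cut / (length / nd))) + 1
                for length, nd in ((cell.a, dims[0]), (cell.b, dims[1]), (cell.c, dims[2]))]
        idx = [np.arange(int(math.floor(center[k])) - span[k],
                         int(math.ceil(center[k])) + span[k] + 1) for k in range(3)]
        gi, gj, gk = np.meshgrid(*idx, indexing="ij")
        df = np.stack([gi / dims[0] - xf[0], gj / dims[1] - xf[1], gk / dims[2] - xf[2]], axis=-1)
        df -= np.round(df)
        cart = df @ ortho.T
        inside = (cart**2).sum(axis=-1) <= r_cut**2
        mask[gi % dims[0], gj % dims[1], gk % dims[2]] &= ~inside
    # shrink: dilate solvent back into the protein region by the shrink radius
    if mask_params.shrink_radius > 0:
        steps = [max(1, int(round(mask_params.shrink_radius / (length / nd))))
                 for length, nd in ((cell.a, dims[0]), (cell.b, dims[1]), (cell.c, dims[2]))]
        foot = np.ones((2 * steps[0] + 1, 2 * steps[1] + 1, 2 * steps[2] + 1), dtype=bool)
        mask = scipy.ndimage.grey_dilation(mask.astype(np.uint8), footprint=foot,
                                           mode="wrap").astype(bool)
    frac_solvent = mask.mean()
    fft = np.fft.fftn(mask.astype(float))
    h, k, l = refls.hkl.T
    f_b = np.conj(fft[h % dims[0], k % dims[1], l % dims[2]]) * (cell.volume / mask.size)
    return f_b, float(frac_solvent)


# ---------------------------------------------------------------------------
# Total amplitude and nuisance fitting
# ---------------------------------------------------------------------------

@dataclass
class ModelStructureFactors:
    """Forward-model output: per-state F_i, weighted F_C, solvent F_B, |F_M|, phase."""

    f_states: list
    f_calc: np.ndarray
    f_bulk: np.ndarray
    f_model_amp: np.ndarray
    phase: np.ndarray

    @property
    def f_model_complex(self) -> np.ndarray:
        return self.f_model_amp * np.exp(1j * self.phase)


def total_amplitude(f_calc, f_bulk, nuis: NuisanceParameters):
    """|F_M| and phase of F_M = k_total (F_C + k_mask F_B)."""
    f_m = nuis.k_total * (np.asarray(f_calc) + nuis.k_mask * np.asarray(f_bulk))
    return np.abs(f_m), np.angle(f_m)


def fit_nuisance(refls: ReflectionSet, f_calc, f_bulk=None, n_shells: int = 10,
                 beta_floor_scale: float = 1e-3) -> NuisanceParameters:
    """Fit k_total (and k_mask when solvent is present) by least squares on the
    work reflections, then set per-shell alpha/beta from the scaled residuals.

    alpha_s is initialized to 1; beta_s is the shell mean of
    (F_obs - |F_M|)^2 / epsilon, clamped from below at
    beta_floor_scale * <F_obs^2>.  Free reflections never enter the fit.
    """
    work = refls.work_mask
    if work.sum() == 0:
        raise ValueError("no work reflections to fit against")
    f_obs = refls.f_obs
    if not np.any(f_obs[work] > 0):
        raise ValueError("unscalable dataset: all F_obs are zero")
    f_calc = np.asarray(f_calc)

    def k_total_for(k_mask: float):
        amp = np.abs(f_calc + k_mask * f_bulk) if f_bulk is not None else np.abs(f_calc)
        denom = float((amp[work] ** 2).sum())
        if denom == 0:
            return 0.0, amp
        return float((f_obs[work] * amp[work]).sum() / denom), amp

    if f_bulk is None:
        k_mask = 0.0
        k_total, amp = k_total_for(0.0)
    else:
        f_bulk = np.asarray(f_bulk)

        def sse(k_mask):
            kt, amp = k_total_for(k_mask)
            r = f_obs[work] - kt * amp[work]
            return float((r * r).sum())

        from scipy.optimize import minimize_scalar

        res = minimize_scalar(sse, bounds=(0.0, 2.0), method="bounded",
                              options={"xatol": 1e-6})
        k_mask = max(0.0, float(res.x))
        k_total, amp = k_total_for(k_mask)
    if k_total <= 0:
        k_total = 1.0
    f_model = k_total * amp

    edges = resolution_shells(refls.d, work, n_shells)
    n_sh = len(edges) - 1
    idx = np.clip(np.searchsorted(-edges, -refls.d, side="right") - 1, 0, n_sh - 1)
    beta_floor = beta_floor_scale * float(np.mean(f_obs[work] ** 2))
    beta = np.full(n_sh, beta_floor)
    for s in range(n_sh):
        m = work & (idx == s)
        if m.sum() > 0:
            resid2 = (f_obs[m] - f_model[m]) ** 2 / refls.epsilon[m]
            beta[s] = max(float(resid2.mean()), beta_floor)
    return NuisanceParameters(k_total=k_total, k_mask=k_mask, shell_edges=edges,
                              alpha=np.ones(n_sh), beta=beta)


def shell_table(refls: ReflectionSet, nuis: NuisanceParameters):
    """Per-shell log row: (d_max, d_min, n_work, n_free, alpha, beta)."""
    import pandas as pd

    idx = nuis.shell_index(refls.d)
    rows = []
    for s in range(len(nuis.alpha)):
        m = idx == s
        rows.append({
            "d_max": float(refls.d[m].max()) if m.any() else float("nan"),
            "d_min": float(refls.d[m].min()) if m.any() else float("nan"),
            "n_work": int((m & refls.work_mask).sum()),
            "n_free": int((m & refls.free_flag).sum()),
            "alpha": float(nuis.alpha[s]),
            "beta": float(nuis.beta[s]),
        })
    return pd.DataFrame(rows)


def compute_msf(model: MultiStateModel, refls: ReflectionSet, j: int,
                nuis: NuisanceParameters | None = None, solvent: bool = False,
                mask_params: SolventMaskParams = SolventMaskParams(),
                n_shells: int = 10,
                scattering: list | None = None):
    """Full forward model for condition j: returns (ModelStructureFactors, nuisance).

    If `nuis` is None it is fitted to the work reflections.  `scattering` may
    carry precomputed StateScattering caches to reuse across conditions.
    """
    if scattering is None:
        scattering = [StateScattering(s, refls) for s in model.states]
    f_states = [sc.F for sc in scattering]
    w = model.weights.column(j)
    f_calc = multi_state_sf(f_states, w)
    if solvent:
        f_bulk, _ = bulk_solvent_sf(model.states, w, refls, mask_params)
    else:
        f_bulk = np.zeros_like(f_calc)
    if nuis is None:
        nuis = fit_nuisance(refls, f_calc, f_bulk if solvent else None, n_shells=n_shells)
    amp, phase = total_amplitude(f_calc, f_bulk, nuis)
    msf = ModelStructureFactors(f_states, f_calc, f_bulk, amp, phase)
    return msf, nuis


# ---------------------------------------------------------------------------
# Coordinate gradients
# ---------------------------------------------------------------------------

def amplitude_coordinate_gradients(model: MultiStateModel, refls: ReflectionSet,
                                   nuis: NuisanceParameters, dl_dfm: np.ndarray,
                                   j: int, msf: ModelStructureFactors,
                                   scattering: list) -> list:
    """Chain rule of a per-reflection loss through |F_M| to atom coordinates.

    Given dL/d|F_M| per reflection, returns a per-state list of (A, 3) Cartesian
    gradients for condition j.  The gradient on state i scales with w_ij, so a
    state carrying zero weight receives zero X-ray gradient.  The bulk-solvent
    mask is treated as fixed (standard practice).
    """
    safe_amp = np.where(msf.f_model_amp > 1e-30, msf.f_model_amp, 1.0)
    unit = np.where(msf.f_model_amp > 1e-30,
                    msf.f_model_complex / safe_amp, 0.0 + 0.0j)
    grads = []
    for i, sc in enumerate(scattering):
        w_ij = model.weights.w[i, j]
        if w_ij == 0.0:
            grads.append(np.zeros((model.n_atoms, 3)))
            continue
        coeff = dl_dfm * nuis.k_total * w_ij * np.conj(unit)
        grads.append(sc.gradient(coeff))
    return grads
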