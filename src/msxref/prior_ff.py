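"""Simplified molecular-mechanics prior: bonds, angles, dihedrals, impropers,
and Lennard-Jones nonbonded terms (no electrostatics).

E = sum_bond k_b (b - b0)^2 + sum_ang k_th (th - th0)^2
  + sum_dih k_phi [1 + cos(n phi - delta)] + sum_imp k_w (w - w0)^2
  + sum_nb eps [(Rmin/r)^12 - 2 (Rmin/r)^6]

conventions follow CHARMM: no 1/2 factors on the harmonic terms, pairwise
LJ parameters from Lorentz-Berthelot-style combination of per-type
(eps, Rmin/2), 1-2 and 1-3 pairs excluded, 1-4 pairs scaled, and a
switching function taking the LJ term smoothly to zero between r_on and the
cutoff.  States are treated as isolated molecules (no periodic images).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from itertools import combinations

import numpy as np

from .crystal_core import AtomicState

__all__ = [
    "Topology",
    "ForceFieldParameters",
    "potential_energy",
    "load_forcefield",
    "write_forcefield",
]


class Topology:
    """Bonded topology: per-atom types, bonds, angles, dihedrals, impropers.

    Angles and proper dihedrals can be enumerated from the bond graph;
    impropers must be listed explicitly (center atom first is not assumed --
    the four indices are used as an ordinary torsion).
    """

    def __init__(self, atom_types, bonds, angles=None, dihedrals=None, impropers=None):
        self.atom_types = list(atom_types)
        self.bonds = [tuple(sorted(b)) for b in bonds]
        self.angles = [tuple(a) for a in (angles or [])]
        self.dihedrals = [tuple(d) for d in (dihedrals or [])]
        self.impropers = [tuple(i) for i in (impropers or [])]
        self._exclusions = None

    @classmethod
    def from_bonds(cls, atom_types, bonds, impropers=None) -> "Topology":
        n = len(atom_types)
        adj = [set() for _ in range(n)]
        for i, j in bonds:
            adj[i].add(j)
            adj[j].add(i)
        angles = []
        for j in range(n):
            for i, k in combinations(sorted(adj[j]), 2):
                angles.append((i, j, k))
        dihedrals = []
        for j, k in (tuple(sorted(b)) for b in bonds):
            for i in adj[j] - {k}:
                for l in adj[k] - {j}:
                    if i != l:
                        dihedrals.append((i, j, k, l))
        return cls(atom_types, bonds, angles, dihedrals, impropers)

    @property
    def n_atoms(self) -> int:
        return len(self.atom_types)

    def exclusions(self):
        """(excluded 1-2/1-3 pair set, 1-4 pair set), pairs as sorted tuples."""
        if self._exclusions is None:
            p12 = {tuple(sorted(b)) for b in self.bonds}
            p13 = {tuple(sorted((a[0], a[2]))) for a in self.angles}
            p14 = {tuple(sorted((d[0], d[3]))) for d in self.dihedrals}
            p14 -= p12 | p13
            self._exclusions = (p12 | p13, p14)
        return self._exclusions


@dataclass
class ForceFieldParameters:
    """Parameter tables keyed by atom-type tuples (canonicalized on lookup)."""

    bonds: dict = field(default_factory=dict)       # (t1,t2) -> (kb, b0)
    angles: dict = field(default_factory=dict)      # (t1,t2,t3) -> (kth, th0_deg)
    dihedrals: dict = field(default_factory=dict)   # (t1..t4) -> [(kphi, n, delta_deg)]
    impropers: dict = field(default_factory=dict)   # (t1..t4) -> (kw, w0_deg)
    nonbonded: dict = field(default_factory=dict)   # type -> (eps, rmin_half)
    scale14: float = 1.0
    cutoff: float = 9.0
    switch_on: float = 7.5

    def __post_init__(self):
        for table in (self.bonds, self.angles, self.impropers):
            for key, val in table.items():
                if val[0] < 0:
                    raise ValueError(f"negative force constant for {key}")
        for key, terms in self.dihedrals.items():
            for kphi, n, delta in terms:
                if kphi < 0:
                    raise ValueError(f"negative force constant for {key}")
        for t, (eps, rmin_half) in self.nonbonded.items():
            if eps < 0 or rmin_half <= 0:
                raise ValueError(f"bad LJ parameters for type {t}")

    def bond_param(self, t1, t2):
        for key in ((t1, t2), (t2, t1)):
            if key in self.bonds:
                return self.bonds[key]
        raise KeyError(f"no bond parameters for type pair {t1}-{t2}")

    def angle_param(self, t1, t2, t3):
        for key in ((t1, t2, t3), (t3, t2, t1)):
            if key in self.angles:
                return self.angles[key]
        raise KeyError(f"no angle parameters for type triple {t1}-{t2}-{t3}")

    def dihedral_param(self, t1, t2, t3, t4):
        for key in ((t1, t2, t3, t4), (t4, t3, t2, t1),
                    ("X", t2, t3, "X"), ("X", t3, t2, "X")):
            if key in self.dihedrals:
                return self.dihedrals[key]
        raise KeyError(f"no dihedral parameters for {t1}-{t2}-{t3}-{t4}")

    def improper_param(self, t1, t2, t3, t4):
        for key in ((t1, t2, t3, t4), (t4, t3, t2, t1),
                    (t1, "X", "X", t4), (t4, "X", "X", t1)):
            if key in self.impropers:
                return self.impropers[key]
        raise KeyError(f"no improper parameters for {t1}-{t2}-{t3}-{t4}")

    def lj_pair(self, t1, t2):
        if t1 not in self.nonbonded:
            raise KeyError(f"no LJ parameters for type {t1}")
        if t2 not in self.nonbonded:
            raise KeyError(f"no LJ parameters for type {t2}")
        e1, r1 = self.nonbonded[t1]
        e2, r2 = self.nonbonded[t2]
        return math.sqrt(e1 * e2), r1 + r2


# ---------------------------------------------------------------------------
# Geometry helpers with analytic gradients
# ---------------------------------------------------------------------------

def _angle_and_grad(ri, rj, rk):
    rij = ri - rj
    rkj = rk - rj
    lij = np.linalg.norm(rij)
    lkj = np.linalg.norm(rkj)
    cos_t = np.clip(rij @ rkj / (lij * lkj), -1.0, 1.0)
    theta = math.acos(cos_t)
    sin_t = max(math.sqrt(1.0 - cos_t * cos_t), 1e-8)
    dci = rkj / (lij * lkj) - cos_t * rij / lij**2
    dck = rij / (lij * lkj) - cos_t * rkj / lkj**2
    gi = -dci / sin_t
    gk = -dck / sin_t
    return theta, gi, -(gi + gk), gk


def _dihedral_and_grad(p0, p1, p2, p3):
    b1 = p1 - p0
    b2 = p2 - p1
    b3 = p3 - p2
    n1 = np.cross(b1, b2)
    n2 = np.cross(b2, b3)
    lb2 = np.linalg.norm(b2)
    m1 = np.cross(n1, b2 / lb2)
    x = n1 @ n2
    y = m1 @ n2
    phi = math.atan2(y, x)
    n1sq = max(n1 @ n1, 1e-12)
    n2sq = max(n2 @ n2, 1e-12)
    g0 = lb2 / n1sq * n1
    g3 = -lb2 / n2sq * n2
    s12 = (b1 @ b2) / lb2**2
    s32 = (b3 @ b2) / lb2**2
    g1 = -(1.0 + s12) * g0 + s32 * g3
    g2 = s12 * g0 - (1.0 + s32) * g3
    return phi, g0, g1, g2, g3


def _wrap(angle):
    return (angle + math.pi) % (2.0 * math.pi) - math.pi


# ---------------------------------------------------------------------------
# Potential energy
# ---------------------------------------------------------------------------

_BONDED_CACHE: dict = {}


def _bonded_tables(top: Topology, params: ForceFieldParameters):
    """Index/parameter arrays for vectorized bonded evaluation, cached."""
    key = (id(top), id(params))
    cached = _BONDED_CACHE.get(key)
    if cached is not None:
        return cached
    t = top.atom_types
    bond_idx = np.array(top.bonds, dtype=int).reshape(-1, 2)
    bond_p = np.array([params.bond_param(t[i], t[j]) for i, j in top.bonds]).reshape(-1, 2)
    ang_idx = np.array(top.angles, dtype=int).reshape(-1, 3)
    ang_p = np.array([params.angle_param(t[i], t[j], t[k])
                      for i, j, k in top.angles]).reshape(-1, 2)
    dih_idx, dih_p = [], []
    for d in top.dihedrals:
        for kphi, n, delta in params.dihedral_param(*(t[a] for a in d)):
            dih_idx.append(d)
            dih_p.append((kphi, n, math.radians(delta)))
    imp_idx = np.array(top.impropers, dtype=int).reshape(-1, 4)
    imp_p = np.array([[kw, math.radians(w0)] for kw, w0 in
                      (params.improper_param(*(t[a] for a in d)) for d in top.impropers)
                      ]).reshape(-1, 2)
    tables = (bond_idx, bond_p, ang_idx, np.column_stack([ang_p[:, 0],
                                                          np.radians(ang_p[:, 1])]),
              np.array(dih_idx, dtype=int).reshape(-1, 4),
              np.array(dih_p).reshape(-1, 3), imp_idx, imp_p)
    _BONDED_CACHE[key] = tables
    if len(_BONDED_CACHE) > 64:
        _BONDED_CACHE.pop(next(iter(_BONDED_CACHE)))
    return tables


def _angles_vec(x, idx):
    ri, rj, rk = x[idx[:, 0]], x[idx[:, 1]], x[idx[:, 2]]
    rij = ri - rj
    rkj = rk - rj
    lij = np.linalg.norm(rij, axis=1)
    lkj = np.linalg.norm(rkj, axis=1)
    cos_t = np.clip(np.einsum("nk,nk->n", rij, rkj) / (lij * lkj), -1.0, 1.0)
    theta = np.arccos(cos_t)
    sin_t = np.maximum(np.sqrt(1.0 - cos_t**2), 1e-8)
    dci = rkj / (lij * lkj)[:, None] - cos_t[:, None] * rij / (lij**2)[:, None]
    dck = rij / (lij * lkj)[:, None] - cos_t[:, None] * rkj / (lkj**2)[:, None]
    gi = -dci / sin_t[:, None]
    gk = -dck / sin_t[:, None]
    return theta, gi, -(gi + gk), gk


def _dihedrals_vec(x, idx):
    p0, p1, p2, p3 = (x[idx[:, a]] for a in range(4))
    b1 = p1 - p0
    b2 = p2 - p1
    b3 = p3 - p2
    n1 = np.cross(b1, b2)
    n2 = np.cross(b2, b3)
    lb2 = np.linalg.norm(b2, axis=1)
    m1 = np.cross(n1, b2 / lb2[:, None])
    phi = np.arctan2(np.einsum("nk,nk->n", m1, n2), np.einsum("nk,nk->n", n1, n2))
    n1sq = np.maximum(np.einsum("nk,nk->n", n1, n1), 1e-12)
    n2sq = np.maximum(np.einsum("nk,nk->n", n2, n2), 1e-12)
    g0 = (lb2 / n1sq)[:, None] * n1
    g3 = -(lb2 / n2sq)[:, None] * n2
    s12 = (np.einsum("nk,nk->n", b1, b2) / lb2**2)[:, None]
    s32 = (np.einsum("nk,nk->n", b3, b2) / lb2**2)[:, None]
    g1 = -(1.0 + s12) * g0 + s32 * g3
    g2 = s12 * g0 - (1.0 + s32) * g3
    return phi, g0, g1, g2, g3


def potential_energy(state: AtomicState, params: ForceFieldParameters):
    """Total prior energy (kcal/mol) and analytic per-atom gradient (kcal/mol/A)."""
    top = state.topology
    if top is None:
        raise ValueError("state has no bonded topology")
    x = state.coords
    types = top.atom_types
    bond_idx, bond_p, ang_idx, ang_p, dih_idx, dih_p, imp_idx, imp_p = \
        _bonded_tables(top, params)
    energy = 0.0
    grad = np.zeros_like(x)

    if len(bond_idx):
        rij = x[bond_idx[:, 0]] - x[bond_idx[:, 1]]
        b = np.linalg.norm(rij, axis=1)
        db = b - bond_p[:, 1]
        energy += float((bond_p[:, 0] * db**2).sum())
        g = (2.0 * bond_p[:, 0] * db / b)[:, None] * rij
        np.add.at(grad, bond_idx[:, 0], g)
        np.add.at(grad, bond_idx[:, 1], -g)

    if len(ang_idx):
        theta, gi, gj, gk = _angles_vec(x, ang_idx)
        dt = theta - ang_p[:, 1]
        energy += float((ang_p[:, 0] * dt**2).sum())
        c = (2.0 * ang_p[:, 0] * dt)[:, None]
        np.add.at(grad, ang_idx[:, 0], c * gi)
        np.add.at(grad, ang_idx[:, 1], c * gj)
        np.add.at(grad, ang_idx[:, 2], c * gk)

    if len(dih_idx):
        phi, g0, g1, g2, g3 = _dihedrals_vec(x, dih_idx)
        kphi, n, delta = dih_p.T
        energy += float((kphi * (1.0 + np.cos(n * phi - delta))).sum())
        c = (-kphi * n * np.sin(n * phi - delta))[:, None]
        for col, g in enumerate((g0, g1, g2, g3)):
            np.add.at(grad, dih_idx[:, col], c * g)

    if len(imp_idx):
        w, g0, g1, g2, g3 = _dihedrals_vec(x, imp_idx)
        dw = _wrap(w - imp_p[:, 1])
        energy += float((imp_p[:, 0] * dw**2).sum())
        c = (2.0 * imp_p[:, 0] * dw)[:, None]
        for col, g in enumerate((g0, g1, g2, g3)):
            np.add.at(grad, imp_idx[:, col], c * g)

    e_nb, g_nb = _lj_energy(x, types, top, params)
    return energy + e_nb, grad + g_nb


def _switch_arrays(u, u_on, u_off):
    """CHARMM switching function of u = r^2 and its d/du, vectorized."""
    s = np.ones_like(u)
    ds = np.zeros_like(u)
    mid = (u > u_on) & (u < u_off)
    off = u >= u_off
    denom = (u_off - u_on) ** 3
    a = u_off - u[mid]
    b = u_off + 2.0 * u[mid] - 3.0 * u_on
    s[mid] = a * a * b / denom
    ds[mid] = (2.0 * a * a - 2.0 * a * b) / denom
    s[off] = 0.0
    return s, ds


_LJ_CACHE: dict = {}


def _lj_tables(types, top: Topology, params: ForceFieldParameters):
    """Pairwise (eps, rmin, scale) upper-triangle tables, cached per topology."""
    key = (id(top), id(params))
    cached = _LJ_CACHE.get(key)
    if cached is not None:
        return cached
    n = len(types)
    eps_t = np.empty(n)
    rmh_t = np.empty(n)
    for a, t in enumerate(types):
        if t not in params.nonbonded:
            raise KeyError(f"no LJ parameters for type {t}")
        eps_t[a], rmh_t[a] = params.nonbonded[t]
    eps = np.sqrt(np.outer(eps_t, eps_t))
    rmin = rmh_t[:, None] + rmh_t[None, :]
    scale = np.ones((n, n))
    excl, pairs14 = top.exclusions()
    for i, j in excl:
        scale[i, j] = scale[j, i] = 0.0
    for i, j in pairs14:
        scale[i, j] = scale[j, i] = params.scale14
    scale[np.diag_indices(n)] = 0.0
    iu, ju = np.triu_indices(n, k=1)
    tables = (iu, ju, eps[iu, ju], rmin[iu, ju], scale[iu, ju])
    _LJ_CACHE[key] = tables
    if len(_LJ_CACHE) > 64:
        _LJ_CACHE.pop(next(iter(_LJ_CACHE)))
    return tables


def _lj_energy(x, types, top: Topology, params: ForceFieldParameters):
    iu, ju, eps, rmin, scale = _lj_tables(types, top, params)
    diff = x[iu] - x[ju]
    u = np.einsum("pk,pk->p", diff, diff)
    cutoff2 = params.cutoff**2
    active = (scale > 0) & (eps > 0) & (u < cutoff2)
    if np.any(u[active] < 1e-12):
        p = int(np.flatnonzero(active & (u < 1e-12))[0])
        raise ValueError(f"singular contact between atoms {iu[p]} and {ju[p]}")
    ua = u[active]
    q6 = (rmin[active] ** 2 / ua) ** 3
    e_lj = eps[active] * (q6 * q6 - 2.0 * q6)
    de_du = 6.0 * eps[active] * (q6 - q6 * q6) / ua
    s, ds_du = _switch_arrays(ua, params.switch_on**2, cutoff2)
    energy = float((scale[active] * s * e_lj).sum())
    c = scale[active] * (s * de_du + ds_du * e_lj)
    g = 2.0 * c[:, None] * diff[active]
    grad = np.zeros_like(x)
    np.add.at(grad, iu[active], g)
    np.add.at(grad, ju[active], -g)
    return energy, grad


# ---------------------------------------------------------------------------
# Parameter file I/O
# ---------------------------------------------------------------------------

_SECTIONS = ("BONDS", "ANGLES", "DIHEDRALS", "IMPROPERS", "NONBONDED")


def load_forcefield(path) -> ForceFieldParameters:
    """Read a sectioned plain-text parameter file (CHARMM-like layout).

    BONDS:      t1 t2 kb b0
    ANGLES:     t1 t2 t3 kth th0_deg
    DIHEDRALS:  t1 t2 t3 t4 kphi n delta_deg      (X = wildcard; repeatable)
    IMPROPERS:  t1 t2 t3 t4 kw w0_deg
    NONBONDED:  t eps rmin_half
    """
    params = ForceFieldParameters()
    section = None
    with open(path) as fh:
        for raw in fh:
            line = raw.split("!")[0].split("#")[0].strip()
            if not line:
                continue
            if line.upper() in _SECTIONS:
                section = line.upper()
                continue
            parts = line.split()
            try:
                if section == "BONDS":
                    params.bonds[(parts[0], parts[1])] = (float(parts[2]), float(parts[3]))
                elif section == "ANGLES":
                    params.angles[tuple(parts[:3])] = (float(parts[3]), float(parts[4]))
                elif section == "DIHEDRALS":
                    key = tuple(parts[:4])
                    params.dihedrals.setdefault(key, []).append(
                        (float(parts[4]), int(parts[5]), float(parts[6])))
                elif section == "IMPROPERS":
                    params.impropers[tuple(parts[:4])] = (float(parts[4]), float(parts[5]))
                elif section == "NONBONDED":
                    params.nonbonded[parts[0]] = (float(parts[1]), float(parts[2]))
                else:
                    raise ValueError(f"data line outside any section: {line!r}")
            except (IndexError, ValueError) as exc:
                raise ValueError(f"malformed parameter line {line!r}: {exc}") from exc
    params.__post_init__()
    return params


def write_forcefield(params: ForceFieldParameters, path) -> None:
    with open(path, "w") as fh:
        fh.write("BONDS\n")
        for (t1, t2), (kb, b0) in params.bonds.items():
            fh.write(f"{t1} {t2} {kb!r} {b0!r}\n")
        fh.write("ANGLES\n")
        for key, (kt, t0) in params.angles.items():
            fh.write(f"{' '.join(key)} {kt!r} {t0!r}\n")
        fh.write("DIHEDRALS\n")
        for key, terms in params.dihedrals.items():
            for kphi, n, delta in terms:
                fh.write(f"{' '.join(key)} {kphi!r} {n} {delta!r}\n")
        fh.write("IMPROPERS\n")
        for key, (kw, w0) in params.impropers.items():
            fh.write(f"{' '.join(key)} {kw!r} {w0!r}\n")
        fh.write("NONBONDED\n")
        for t, (eps, rmin_half) in params.nonbonded.items():
            fh.write(f"{t} {eps!r} {rmin_half!r}\n")


def validate_parameterization(top: Topology, params: ForceFieldParameters) -> None:
    """Raise (naming the term) if any topology term lacks parameters."""
    t = top.atom_types
    for i, j in top.bonds:
        params.bond_param(t[i], t[j])
    for i, j, k in top.angles:
        params.angle_param(t[i], t[j], t[k])
    for d in top.dihedrals:
        params.dihedral_param(*(t[a] for a in d))
    for d in top.impropers:
        params.improper_param(*(t[a] for a in d))
    for ty in set(t):
        if ty not in params.nonbonded:
            raise KeyError(f"no LJ parameters for type {ty}")
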