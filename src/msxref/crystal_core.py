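"""Unit-cell geometry, symmetry classification, and shared domain types.

Conventions: Miller indices are integers, fractional translations are in cell
fractions, phases use exp(+2*pi*i h.x), and coordinates are stored Cartesian
(angstrom) -- fractionalization happens only inside the forward model.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "UnitCell",
    "SymmetryOps",
    "SPACE_GROUPS",
    "Reflection",
    "ReflectionSet",
    "AtomicState",
    "WeightMatrix",
    "MultiStateModel",
    "resolution_of",
    "classify_reflection",
    "orthogonalization_matrix",
    "reduce_to_asu",
]


# ---------------------------------------------------------------------------
# Unit cell
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class UnitCell:
    """Triclinic unit cell: lengths in angstrom, angles in degrees."""

    a: float
    b: float
    c: float
    alpha: float = 90.0
    beta: float = 90.0
    gamma: float = 90.0

    def __post_init__(self) -> None:
        if min(self.a, self.b, self.c) <= 0:
            raise ValueError("unit-cell lengths must be positive")
        for ang in (self.alpha, self.beta, self.gamma):
            if not 0.0 < ang < 180.0:
                raise ValueError("unit-cell angles must lie in (0, 180)")
        if self.volume <= 0:
            raise ValueError("degenerate unit cell (non-positive volume)")

    @property
    def volume(self) -> float:
        ca, cb, cg = (math.cos(math.radians(x)) for x in (self.alpha, self.beta, self.gamma))
        arg = 1.0 - ca * ca - cb * cb - cg * cg + 2.0 * ca * cb * cg
        if arg <= 0:
            return 0.0
        return self.a * self.b * self.c * math.sqrt(arg)

    @property
    def orthogonalization(self) -> np.ndarray:
        return orthogonalization_matrix(self)

    @property
    def fractionalization(self) -> np.ndarray:
        return np.linalg.inv(self.orthogonalization)

    @property
    def reciprocal_metric(self) -> np.ndarray:
        """G* = (A^T A)^-1 where A is the orthogonalization matrix."""
        a_mat = self.orthogonalization
        return np.linalg.inv(a_mat.T @ a_mat)


def orthogonalization_matrix(cell: UnitCell) -> np.ndarray:
    """Fractional -> Cartesian matrix (standard crystallographic convention).

    a along x; b in the xy plane.  Columns are the cell vectors in Cartesian
    angstrom.  The round trip fractional -> Cartesian -> fractional is the
    identity to machine precision.
    """
    a, b, c = cell.a, cell.b, cell.c
    ca, cb, cg = (math.cos(math.radians(x)) for x in (cell.alpha, cell.beta, cell.gamma))
    sg = math.sin(math.radians(cell.gamma))
    v = cell.volume
    if v <= 0 or sg == 0:
        raise ValueError("degenerate unit cell")
    return np.array(
        [
            [a, b * cg, c * cb],
            [0.0, b * sg, c * (ca - cb * cg) / sg],
            [0.0, 0.0, v / (a * b * sg)],
        ]
    )


def resolution_of(hkl, cell: UnitCell) -> float:
    """d-spacing (angstrom) of Miller index hkl from the reciprocal metric tensor."""
    h = np.asarray(hkl, dtype=float)
    if h.shape[-1] != 3:
        raise ValueError("hkl must have 3 components")
    inv_d2 = np.einsum("...i,ij,...j->...", h, cell.reciprocal_metric, h)
    if np.any(inv_d2 <= 0):
        raise ValueError("undefined resolution for hkl = (0,0,0)")
    return float(1.0 / math.sqrt(inv_d2)) if np.isscalar(inv_d2) or inv_d2.ndim == 0 else 1.0 / np.sqrt(inv_d2)


# ---------------------------------------------------------------------------
# Symmetry
# ---------------------------------------------------------------------------

class SymmetryOps:
    """Explicit list of (3x3 integer rotation, fractional translation) operators.

    The list must contain the identity and be closed under composition modulo
    lattice translations; both are checked at construction.
    """

    def __init__(self, ops, name: str = "custom"):
        self.name = name
        self.rotations = [np.asarray(r, dtype=int).reshape(3, 3) for r, _ in ops]
        self.translations = [np.asarray(t, dtype=float).reshape(3) % 1.0 for _, t in ops]
        self._validate()

    def __len__(self) -> int:
        return len(self.rotations)

    def __iter__(self):
        return iter(zip(self.rotations, self.translations))

    def _key(self, rot, tr):
        return (tuple(rot.ravel()), tuple(np.round(np.asarray(tr) % 1.0, 9)))

    def _validate(self) -> None:
        keys = {self._key(r, t) for r, t in self}
        ident = self._key(np.eye(3, dtype=int), np.zeros(3))
        if ident not in keys:
            raise ValueError("symmetry operator list lacks the identity")
        if len(keys) != len(self.rotations):
            raise ValueError("duplicate symmetry operators")
        for r1, t1 in self:
            for r2, t2 in self:
                r = r1 @ r2
                t = (r1 @ t2 + t1) % 1.0
                if self._key(r, t) not in keys:
                    raise ValueError(f"operator list not closed under composition ({self.name})")

    @property
    def n_centering(self) -> int:
        """Number of operators with identity rotation (pure lattice centerings)."""
        return sum(1 for r in self.rotations if np.array_equal(r, np.eye(3, dtype=int)))

    def equivalents(self, hkl) -> set:
        """All symmetry- and Friedel-equivalent Miller indices of hkl."""
        h = np.asarray(hkl, dtype=int)
        out = set()
        for rot in self.rotations:
            e = tuple(int(x) for x in rot.T @ h)
            out.add(e)
            out.add(tuple(-x for x in e))
        return out

    def is_absent(self, hkl) -> bool:
        """Systematically absent: some op fixes h but shifts its phase."""
        h = np.asarray(hkl, dtype=int)
        for rot, tr in self:
            if np.array_equal(rot.T @ h, h):
                phase = float(np.dot(h, tr))
                if abs(phase - round(phase)) > 1e-9:
                    return True
        return False


def _ops(*triplets):
    return [(np.array(r, dtype=int), np.array(t, dtype=float)) for r, t in triplets]


_I = np.eye(3, dtype=int)
_INV = -np.eye(3, dtype=int)
_TWO_B = np.diag([-1, 1, -1])  # 2-fold along b
_TWO_A = np.diag([1, -1, -1])
_TWO_C = np.diag([-1, -1, 1])

SPACE_GROUPS = {
    "P1": SymmetryOps(_ops((_I, (0, 0, 0))), name="P1"),
    "P-1": SymmetryOps(_ops((_I, (0, 0, 0)), (_INV, (0, 0, 0))), name="P-1"),
    "P2": SymmetryOps(_ops((_I, (0, 0, 0)), (_TWO_B, (0, 0, 0))), name="P2"),
    "P212121": SymmetryOps(
        _ops(
            (_I, (0, 0, 0)),
            (_TWO_A, (0.5, 0.5, 0)),
            (_TWO_B, (0, 0.5, 0.5)),
            (_TWO_C, (0.5, 0, 0.5)),
        ),
        name="P212121",
    ),
    "C2": SymmetryOps(
        _ops(
            (_I, (0, 0, 0)),
            (_TWO_B, (0, 0, 0)),
            (_I, (0.5, 0.5, 0)),
            (_TWO_B, (0.5, 0.5, 0)),
        ),
        name="C2",
    ),
}


def classify_reflection(hkl, ops: SymmetryOps):
    """(centric flag, epsilon) of a Miller index under a symmetry group.

    A reflection is centric iff some rotation maps h to -h; epsilon is the
    count of rotations fixing h, normalized by the lattice-centering
    multiplicity so that a general reflection has epsilon = 1.
    """
    h = np.asarray(hkl, dtype=int)
    centric = False
    n_fix = 0
    for rot in ops.rotations:
        rh = rot.T @ h
        if np.array_equal(rh, -h):
            centric = True
        if np.array_equal(rh, h):
            n_fix += 1
    epsilon = n_fix // ops.n_centering
    return centric, max(epsilon, 1)


def reduce_to_asu(hkl, ops: SymmetryOps):
    """Representative Miller index: lexicographically largest equivalent."""
    return max(ops.equivalents(hkl))


# ---------------------------------------------------------------------------
# Reflections
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Reflection:
    h: int
    k: int
    l: int
    d: float
    centric: bool
    epsilon: int

    def __post_init__(self):
        if self.d <= 0:
            raise ValueError("d must be positive")
        if self.epsilon < 1:
            raise ValueError("epsilon must be >= 1")

    @property
    def hkl(self):
        return (self.h, self.k, self.l)


class ReflectionSet:
    """Asymmetric-unit-reduced amplitudes for one experimental condition.

    Stores columnar numpy arrays; `reflections` yields Reflection records.
    Free flags mark reflections withheld from refinement (cross-validation);
    one study shares a single free set across all conditions.
    """

    def __init__(self, cell, ops, hkl, f_obs, sigma=None, free_flag=None,
                 condition_id="cond"):
        self.cell = cell
        self.ops = ops
        hkl = np.asarray(hkl, dtype=int).reshape(-1, 3)
        self.hkl = hkl
        self.condition_id = condition_id
        n = len(hkl)
        f_obs = np.asarray(f_obs, dtype=float)
        if f_obs.shape != (n,):
            raise ValueError("f_obs length mismatch")
        if np.any(f_obs < 0):
            raise ValueError("F_obs must be non-negative")
        self.f_obs = f_obs
        self.sigma = np.zeros(n) if sigma is None else np.asarray(sigma, dtype=float)
        self.free_flag = (
            np.zeros(n, dtype=bool) if free_flag is None else np.asarray(free_flag, dtype=bool)
        )
        # annotate
        reduced = [reduce_to_asu(h, ops) for h in hkl]
        if len(set(reduced)) != n:
            raise ValueError("duplicate (h,k,l) after symmetry reduction")
        cent_eps = [classify_reflection(h, ops) for h in hkl]
        self.centric = np.array([c for c, _ in cent_eps], dtype=bool)
        self.epsilon = np.array([e for _, e in cent_eps], dtype=int)
        g = cell.reciprocal_metric
        inv_d2 = np.einsum("ni,ij,nj->n", hkl.astype(float), g, hkl.astype(float))
        if np.any(inv_d2 <= 0):
            raise ValueError("undefined resolution for hkl = (0,0,0)")
        self.d = 1.0 / np.sqrt(inv_d2)

    def __len__(self) -> int:
        return len(self.hkl)

    @property
    def stol(self) -> np.ndarray:
        """sin(theta)/lambda = 1/(2d) per reflection."""
        return 1.0 / (2.0 * self.d)

    @property
    def work_mask(self) -> np.ndarray:
        return ~self.free_flag

    @property
    def reflections(self):
        return [
            Reflection(int(h), int(k), int(l), float(d), bool(c), int(e))
            for (h, k, l), d, c, e in zip(self.hkl, self.d, self.centric, self.epsilon)
        ]

    def copy(self) -> "ReflectionSet":
        return ReflectionSet(
            self.cell, self.ops, self.hkl.copy(), self.f_obs.copy(),
            self.sigma.copy(), self.free_flag.copy(), self.condition_id,
        )


# ---------------------------------------------------------------------------
# Atomic states, weights, multi-state model
# ---------------------------------------------------------------------------

class AtomicState:
    """One conformational state: elements, Cartesian coordinates, B, occupancy.

    Under the default representation all B-factors are 15 and occupancies 1
    (discrete states carry the heterogeneity, not the displacement model).
    """

    def __init__(self, elements, coords, b_factors=None, occupancies=None, topology=None):
        self.elements = list(elements)
        coords = np.asarray(coords, dtype=float)
        if coords.shape != (len(self.elements), 3):
            raise ValueError("coords must be (n_atoms, 3)")
        if not np.all(np.isfinite(coords)):
            raise ValueError("non-finite coordinates")
        self.coords = coords
        n = len(self.elements)
        self.b_factors = np.full(n, 15.0) if b_factors is None else np.asarray(b_factors, dtype=float)
        self.occupancies = np.ones(n) if occupancies is None else np.asarray(occupancies, dtype=float)
        if np.any(self.b_factors < 0):
            raise ValueError("negative B-factor")
        self.topology = topology

    @property
    def n_atoms(self) -> int:
        return len(self.elements)

    def copy(self) -> "AtomicState":
        return AtomicState(self.elements, self.coords.copy(), self.b_factors.copy(),
                           self.occupancies.copy(), self.topology)


class WeightMatrix:
    """N x J matrix of state weights; each column (condition) sums to 1."""

    COLUMN_TOL = 1e-12

    def __init__(self, w):
        w = np.atleast_2d(np.asarray(w, dtype=float))
        if np.any(w < -1e-15) or np.any(w > 1 + 1e-15):
            raise ValueError("weights must lie in [0, 1]")
        col = w.sum(axis=0)
        if np.any(np.abs(col - 1.0) > 1e-9):
            raise ValueError("weight columns must sum to 1")
        self.w = np.clip(w, 0.0, 1.0)
        self.w /= self.w.sum(axis=0, keepdims=True)

    @property
    def n_states(self) -> int:
        return self.w.shape[0]

    @property
    def n_conditions(self) -> int:
        return self.w.shape[1]

    def column(self, j: int) -> np.ndarray:
        return self.w[:, j]

    def permuted_states(self, perm) -> "WeightMatrix":
        return WeightMatrix(self.w[list(perm), :])

    def copy(self) -> "WeightMatrix":
        return WeightMatrix(self.w.copy())


class MultiStateModel:
    """N atomic states of identical composition plus the N x J weight matrix."""

    def __init__(self, states, weights):
        if len(states) < 1:
            raise ValueError("need at least one state")
        ref = states[0]
        for s in states[1:]:
            if s.elements != ref.elements:
                for i, (e1, e2) in enumerate(zip(s.elements, ref.elements)):
                    if e1 != e2:
                        raise ValueError(f"state composition mismatch at atom {i}: {e1} vs {e2}")
                raise ValueError("state atom-count mismatch")
        weights = weights if isinstance(weights, WeightMatrix) else WeightMatrix(weights)
        if weights.n_states != len(states):
            raise ValueError("weight rows must match state count")
        self.states = list(states)
        self.weights = weights

    @property
    def n_states(self) -> int:
        return len(self.states)

    @property
    def n_conditions(self) -> int:
        return self.weights.n_conditions

    @property
    def n_atoms(self) -> int:
        return self.states[0].n_atoms

    def weighted_average_coords(self, j: int) -> np.ndarray:
        """Per-atom weighted-average position under condition j."""
        w = self.weights.column(j)
        return np.einsum("i,iak->ak", w, np.stack([s.coords for s in self.states]))

    def copy(self) -> "MultiStateModel":
        return MultiStateModel([s.copy() for s in self.states], self.weights.copy())

    def permuted(self, perm) -> "MultiStateModel":
        """Relabel states (with the matching weight-row permutation)."""
        return MultiStateModel([self.states[i].copy() for i in perm],
                               self.weights.permuted_states(perm))
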