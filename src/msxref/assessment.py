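"""Cross-validation bookkeeping and model assessment.

Shared free-reflection sets (the same flags withheld from every condition of
a study), Rwork/Rfree, best-model selection, the RMSD* model-difference
metric (condition-averaged RMSD between weighted-average structures),
convergence curves, and decoy-landscape tables.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .crystal_core import MultiStateModel, ReflectionSet

__all__ = [
    "FreeSetSpec",
    "assign_free_flags",
    "r_factor",
    "rmsd_star",
    "select_best",
    "convergence_curve",
    "decoy_landscape",
]


@dataclass(frozen=True)
class FreeSetSpec:
    fraction: float = 0.05
    n_bins: int = 10
    seed: int = 0

    def __post_init__(self):
        if not 0.0 <= self.fraction < 0.5:
            raise ValueError("free fraction must lie in [0, 0.5)")
        if self.n_bins < 1:
            raise ValueError("need at least one resolution bin")


def assign_free_flags(datasets, spec: FreeSetSpec):
    """Assign one shared free set across all datasets, per resolution bin.

    Within each of `n_bins` equal-count resolution bins of the hkl union,
    round(fraction * n_bin) reflections are drawn uniformly at random
    (seeded) and flagged free in EVERY dataset.  Returns new ReflectionSets.
    """
    import warnings

    union: dict = {}
    for ds in datasets:
        for hkl, d in zip(map(tuple, ds.hkl), ds.d):
            union.setdefault(hkl, d)
    keys = sorted(union)
    d_vals = np.array([union[k] for k in keys])
    order = np.argsort(-d_vals, kind="stable")
    n = len(keys)
    rng = np.random.default_rng(spec.seed)
    free_keys = set()
    n_bins = min(spec.n_bins, n)
    bounds = [int(round(b * n / n_bins)) for b in range(n_bins + 1)]
    any_free = False
    for b in range(n_bins):
        members = order[bounds[b]:bounds[b + 1]]
        n_free = int(round(spec.fraction * len(members)))
        if n_free > 0:
            any_free = True
            chosen = rng.choice(members, size=n_free, replace=False)
            free_keys.update(keys[i] for i in chosen)
    if spec.fraction > 0 and not any_free:
        warnings.warn("free fraction too small for every bin; zero free set")
    out = []
    for ds in datasets:
        new = ds.copy()
        new.free_flag = np.array([tuple(h) in free_keys for h in ds.hkl])
        out.append(new)
    return out


def r_factor(f_obs, f_model_amp, subset_mask=None) -> float:
    """R = sum |F_obs - |F_M|| / sum F_obs over the given subset."""
    f_obs = np.asarray(f_obs, dtype=float)
    f_model_amp = np.asarray(f_model_amp, dtype=float)
    if subset_mask is not None:
        mask = np.asarray(subset_mask, dtype=bool)
        f_obs, f_model_amp = f_obs[mask], f_model_amp[mask]
    if len(f_obs) == 0:
        raise ValueError("empty reflection subset")
    return float(np.abs(f_obs - f_model_amp).sum() / f_obs.sum())


def rmsd_star(a: MultiStateModel, b: MultiStateModel, superpose: bool = False) -> float:
    """Condition-averaged RMSD between weighted-average structures (angstrom).

    For each condition j the weighted average position of atom k is
    sum_i w_ij x_ik; the RMSD between the two averages is computed on raw
    coordinates (no superposition by default: the metric lives in the crystal
    frame), then averaged over conditions.  The state counts of the two
    models may differ; compositions must match.
    """
    if a.states[0].elements != b.states[0].elements:
        raise ValueError("model compositions differ")
    if a.n_conditions != b.n_conditions:
        raise ValueError("models must share the number of conditions")
    total = 0.0
    for j in range(a.n_conditions):
        xa = a.weighted_average_coords(j)
        xb = b.weighted_average_coords(j)
        if superpose:
            xa = xa - xa.mean(axis=0)
            xb = xb - xb.mean(axis=0)
            # Kabsch rotation
            u, _, vt = np.linalg.svd(xa.T @ xb)
            sign = np.sign(np.linalg.det(u @ vt))
            rot = u @ np.diag([1.0, 1.0, sign]) @ vt
            xa = xa @ rot
        total += float(np.sqrt(((xa - xb) ** 2).sum(axis=1).mean()))
    return total / a.n_conditions


def select_best(sample, dataset_id, criterion: str = "rfree"):
    """Record minimizing Rfree (or total score) for one dataset.

    Ties break by lower total score, then earlier trajectory id.
    """
    if len(sample) == 0:
        raise ValueError("empty sample")

    def key(rec):
        if criterion == "rfree":
            primary = rec.rfree[dataset_id]
        elif criterion == "score":
            primary = rec.score.total
        else:
            raise ValueError(f"unknown criterion {criterion!r}")
        return (primary, rec.score.total, rec.trajectory_id, rec.step)

    return min(sample, key=key)


def convergence_curve(sample, subsample_sizes, n_resamples, rng,
                      dataset_id=0, criterion: str = "score",
                      accuracy_of=None) -> pd.DataFrame:
    """Best criterion value in random trajectory subsets of increasing size.

    For each size s, draws `n_resamples` subsets of s distinct trajectories
    and records the best (lowest) criterion among their records; reports the
    mean and standard deviation per size.  With `accuracy_of` (a callable
    mapping a record to an accuracy), the accuracy of the best-scoring record
    is tracked as well.
    """
    by_traj: dict = {}
    for rec in sample:
        by_traj.setdefault(rec.trajectory_id, []).append(rec)
    traj_ids = sorted(by_traj)
    rows = []
    for s in subsample_sizes:
        if s > len(traj_ids):
            raise ValueError(f"subsample size {s} exceeds trajectory count {len(traj_ids)}")
        bests, accs = [], []
        exhaustive = s == len(traj_ids)
        for _ in range(1 if exhaustive else n_resamples):
            chosen = traj_ids if exhaustive else [
                traj_ids[i] for i in rng.choice(len(traj_ids), size=s, replace=False)
            ]
            recs = [r for t in chosen for r in by_traj[t]]
            best = select_best(recs, dataset_id, criterion=criterion)
            bests.append(best.score.total if criterion == "score" else best.rfree[dataset_id])
            if accuracy_of is not None:
                accs.append(accuracy_of(best))
        row = {"size": s, "mean_best": float(np.mean(bests)), "sd_best": float(np.std(bests))}
        if accuracy_of is not None:
            row["mean_accuracy"] = float(np.mean(accs))
            row["sd_accuracy"] = float(np.std(accs))
        rows.append(row)
    return pd.DataFrame(rows)


def decoy_landscape(decoys, native: MultiStateModel, datasets,
                    include_prior: bool = False, prior_params=None,
                    n_shells: int = 10) -> pd.DataFrame:
    """Score-vs-accuracy table over a decoy set.

    Each row holds the decoy's RMSD* to the native and its joint score
    (negative log-likelihood by default, the full posterior score when
    include_prior=True); the native's own row is appended with
    is_native=True, and `better_than_native` counts decoys scoring strictly
    below the native.
    """
    from .likelihood import total_score

    def score_of(model):
        sb = total_score(model, datasets, prior_params if include_prior else None,
                         n_shells=n_shells)
        return float(sb.neg_log_likelihoods.sum() + (sb.prior_energies.sum()
                                                     if include_prior else 0.0))

    rows = []
    for i, decoy in enumerate(decoys):
        rows.append({"model": f"decoy_{i}", "accuracy": rmsd_star(decoy, native),
                     "score": score_of(decoy), "is_native": False})
    native_score = score_of(native)
    rows.append({"model": "native", "accuracy": 0.0, "score": native_score,
                 "is_native": True})
    table = pd.DataFrame(rows)
    table.attrs["better_than_native"] = int(
        (table.loc[~table.is_native, "score"] < native_score).sum())
    return table
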