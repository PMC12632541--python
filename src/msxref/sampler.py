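"""Posterior sampling: biased Langevin dynamics plus conjugate-gradient polish.

The sampler draws a sample from the posterior over multi-state
multi-condition models.  Coordinates evolve under a biased force

    F = w_xray * w_auto * (-grad NLL) + (-grad E_prior)

where w_auto rescales the likelihood gradient so its average atomic magnitude
matches the prior's, and w_xray (swept over {1.0, 0.5, 0.25} by default)
deliberately under-weights the data term to aid exploration.  Weights are
drawn once per trajectory from the flat Dirichlet; dynamics run hot
(default "temperature" 5000 K) under a Langevin thermostat, nuisance
parameters and the quadratic likelihood approximation are refreshed every
macro-cycle, and every final snapshot is polished by conjugate gradients.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np

from .assessment import r_factor
from .crystal_core import MultiStateModel, WeightMatrix
from .forward_model import StateScattering, compute_msf, amplitude_coordinate_gradients
from .likelihood import (ScoreBreakdown, dataset_neg_log_likelihood,
                         quadratic_gradient_weights)
from .prior_ff import potential_energy

__all__ = [
    "SamplerConfig",
    "SampleRecord",
    "compute_wauto",
    "biased_force",
    "sample_weight_matrix",
    "run_trajectory",
    "cg_polish",
    "sampling_protocol",
    "PosteriorEngine",
]

KB = 0.0019872041          # kcal/mol/K
ACC = 4.184e-4             # (kcal/mol/A)/amu -> A/fs^2
_MASSES = {"H": 1.008, "C": 12.011, "N": 14.007, "O": 15.999, "S": 32.06,
           "P": 30.974, "Zn": 65.38}


@dataclass
class SamplerConfig:
    temperature: float = 5000.0       # sampling "temperature" (K)
    w_xray_sweep: tuple = (1.0, 0.5, 0.25)
    n_steps: int = 200
    timestep_fs: float = 1.0
    friction_ps: float = 1.0
    macro_cycle: int = 100            # steps between nuisance/w_auto refresh
    n_trajectories: int = 8
    seed: int = 0
    n_shells: int = 10
    solvent: bool = False
    sample_weights: bool = True       # draw W at trajectory start
    resample_weights_every: int = 0   # macro-cycles; 0 = never mid-trajectory
    exact_likelihood_gradient: bool = False
    wauto_max: float = 1e6
    sync_state_noise: bool = False    # identical noise stream for every state
    polish_max_iter: int = 500
    polish_tol: float = 1e-3

    def __post_init__(self):
        if self.temperature <= 0:
            raise ValueError("temperature must be positive")
        if self.n_steps < 0:
            raise ValueError("steps must be >= 0")
        if any(w <= 0 for w in self.w_xray_sweep):
            raise ValueError("w_xray must be positive")


@dataclass
class SampleRecord:
    trajectory_id: str
    step: int
    model: MultiStateModel
    score: ScoreBreakdown
    rwork: np.ndarray
    rfree: np.ndarray
    w_xray: float = 1.0
    flags: list = field(default_factory=list)


def compute_wauto(likelihood_grads, prior_grads, wauto_max: float = 1e6) -> float:
    """w_auto = mean atomic |prior gradient| / mean atomic |likelihood gradient|.

    After scaling the likelihood gradient by w_auto the two average magnitudes
    coincide.  A vanishing likelihood gradient clamps w_auto to wauto_max.
    """
    lik = np.concatenate([np.linalg.norm(g, axis=1) for g in likelihood_grads])
    pri = np.concatenate([np.linalg.norm(g, axis=1) for g in prior_grads])
    mean_lik = float(lik.mean())
    mean_pri = float(pri.mean())
    if mean_lik <= 0.0:
        warnings.warn("zero likelihood gradient; w_auto clamped")
        return wauto_max
    return min(mean_pri / mean_lik, wauto_max)


def sample_weight_matrix(n_states: int, n_conditions: int, rng) -> WeightMatrix:
    """Each column drawn independently from the uniform (flat Dirichlet) simplex."""
    w = rng.dirichlet(np.ones(n_states), size=n_conditions).T
    return WeightMatrix(w)


class PosteriorEngine:
    """Caches everything the biased force needs between macro-cycle refreshes.

    Holds per-dataset nuisance parameters and frozen quadratic likelihood
    approximations; `refresh` refits them (and w_auto) at the current
    coordinates, `force` evaluates the biased force cheaply in between.
    Datasets sharing an identical hkl table reuse one scattering computation
    per state.
    """

    def __init__(self, datasets, prior_params, cfg: SamplerConfig):
        self.datasets = datasets
        self.prior_params = prior_params
        self.cfg = cfg
        self.nuisances = [None] * len(datasets)
        self.quads = [None] * len(datasets)
        self.wauto = 1.0
        self._shared = [0] * len(datasets)
        for j in range(1, len(datasets)):
            d0, dj = datasets[0], datasets[j]
            if np.array_equal(dj.hkl, d0.hkl) and dj.cell == d0.cell:
                self._shared[j] = 0
            else:
                self._shared[j] = j

    def _scattering(self, model):
        cache = {}
        out = []
        for j in range(len(self.datasets)):
            key = self._shared[j]
            if key not in cache:
                cache[key] = [StateScattering(s, self.datasets[key]) for s in model.states]
            out.append(cache[key])
        return out

    def _likelihood_grads(self, model, scattering, fit: bool):
        """Per-state grad of sum_j NLL_j; optionally refit nuisance/quadratics."""
        grads = [np.zeros((model.n_atoms, 3)) for _ in model.states]
        nlls = np.zeros(len(self.datasets))
        for j, refls in enumerate(self.datasets):
            nuis = None if fit else self.nuisances[j]
            msf, nuis = compute_msf(model, refls, j, nuis=nuis, solvent=self.cfg.solvent,
                                    n_shells=self.cfg.n_shells, scattering=scattering[j])
            if fit:
                self.nuisances[j] = nuis
                self.quads[j] = quadratic_gradient_weights(refls, msf, nuis)
            if self.cfg.exact_likelihood_gradient:
                from .likelihood import neg_log_p_derivative

                dl = neg_log_p_derivative(refls.f_obs, msf.f_model_amp,
                                          nuis.alpha_of(refls.d), nuis.beta_of(refls.d),
                                          refls.epsilon, refls.centric)
            else:
                dl = self.quads[j].gradient(msf.f_model_amp)
            dl = np.where(refls.work_mask, dl, 0.0)
            gj = amplitude_coordinate_gradients(model, refls, nuis, dl, j, msf,
                                                scattering[j])
            for i in range(model.n_states):
                grads[i] += gj[i]
            nlls[j] = dataset_neg_log_likelihood(refls, msf, nuis)
        return grads, nlls

    def refresh(self, model):
        """Macro-cycle refresh: nuisance fits, quadratic approximations, w_auto.

        Returns (ScoreBreakdown, rwork, rfree) at the refreshed parameters.
        """
        scattering = self._scattering(model)
        lik_grads, nlls = self._likelihood_grads(model, scattering, fit=True)
        prior = [potential_energy(s, self.prior_params) for s in model.states]
        prior_e = np.array([p[0] for p in prior])
        prior_g = [p[1] for p in prior]
        self.wauto = compute_wauto(lik_grads, prior_g, self.cfg.wauto_max)
        rwork, rfree = self.r_factors(model, scattering)
        return ScoreBreakdown(nlls, prior_e), rwork, rfree

    def r_factors(self, model, scattering=None):
        if scattering is None:
            scattering = self._scattering(model)
        rwork = np.zeros(len(self.datasets))
        rfree = np.zeros(len(self.datasets))
        for j, refls in enumerate(self.datasets):
            msf, _ = compute_msf(model, refls, j, nuis=self.nuisances[j],
                                 solvent=self.cfg.solvent, n_shells=self.cfg.n_shells,
                                 scattering=scattering[j])
            rwork[j] = r_factor(refls.f_obs, msf.f_model_amp, refls.work_mask)
            if refls.free_flag.sum() > 0:
                rfree[j] = r_factor(refls.f_obs, msf.f_model_amp, refls.free_flag)
            else:
                rfree[j] = np.nan
        return rwork, rfree

    def force(self, model, w_xray: float):
        """Biased per-state forces at the current coordinates."""
        scattering = self._scattering(model)
        lik_grads, _ = self._likelihood_grads(model, scattering, fit=False)
        forces = []
        for i, state in enumerate(model.states):
            _, pg = potential_energy(state, self.prior_params)
            forces.append(-(w_xray * self.wauto * lik_grads[i]) - pg)
        return forces


def biased_force(model: MultiStateModel, datasets, prior_params, w_xray: float,
                 w_auto: float, nuisances=None, quads=None,
                 cfg: SamplerConfig | None = None):
    """One-shot biased force F = w_xray w_auto (-grad NLL) + (-grad E_prior).

    Convenience wrapper over PosteriorEngine for a single evaluation; the
    X-ray term on state i sums contributions from all datasets weighted by
    w_ij, so the force is affine in w_xray and a zero-weight state feels only
    the prior.
    """
    engine = PosteriorEngine(datasets, prior_params, cfg or SamplerConfig())
    scattering = engine._scattering(model)
    if nuisances is None:
        engine._likelihood_grads(model, scattering, fit=True)
    else:
        engine.nuisances = list(nuisances)
        engine.quads = list(quads)
    engine.wauto = w_auto
    return engine.force(model, w_xray)


def _masses(elements) -> np.ndarray:
    try:
        return np.array([_MASSES[e] for e in elements])
    except KeyError as exc:
        raise KeyError(f"no atomic mass for element {exc.args[0]}") from exc


def run_trajectory(start: MultiStateModel, datasets, cfg: SamplerConfig, rng,
                   prior_params, trajectory_id: str = "t0", w_xray: float = 1.0):
    """BAOAB Langevin dynamics under the biased force; returns SampleRecords.

    Velocities initialize from the Maxwell-Boltzmann distribution at the
    sampling temperature; the weight matrix is drawn once at trajectory start
    (flat Dirichlet per column) and held fixed unless mid-trajectory
    resampling is enabled.  Snapshots and scores are recorded at every
    macro-cycle boundary.  Identical (seed, config, inputs) reproduce the
    trajectory bit for bit; a coordinate blow-up truncates the trajectory
    with a flag instead of failing the batch.
    """
    model = start.copy()
    if cfg.sample_weights:
        model = MultiStateModel(
            model.states, sample_weight_matrix(model.n_states, len(datasets), rng))
    engine = PosteriorEngine(datasets, prior_params, cfg)
    masses = _masses(model.states[0].elements)
    dt = cfg.timestep_fs
    gamma = cfg.friction_ps / 1000.0
    c1 = np.exp(-gamma * dt)
    c2 = np.sqrt(max(0.0, 1.0 - c1 * c1))
    sigma_v = np.sqrt(KB * cfg.temperature * ACC / masses)[:, None]

    if cfg.sync_state_noise:
        seed = int(rng.integers(2**31))
        state_rngs = [np.random.default_rng(seed) for _ in model.states]
    else:
        state_rngs = [rng] * model.n_states
    vels = [state_rngs[i].normal(size=(model.n_atoms, 3)) * sigma_v
            for i in range(model.n_states)]

    records = []

    def record(step):
        score, rwork, rfree = engine.refresh(model)
        records.append(SampleRecord(trajectory_id, step, model.copy(), score,
                                    rwork, rfree, w_xray=w_xray))

    record(0)
    if cfg.n_steps == 0:
        return records

    forces = engine.force(model, w_xray)
    step = 0
    macro_count = 0
    truncated = False
    while step < cfg.n_steps:
        chunk = min(cfg.macro_cycle, cfg.n_steps - step)
        for _ in range(chunk):
            for i, state in enumerate(model.states):
                a = forces[i] / masses[:, None] * ACC
                v = vels[i] + 0.5 * dt * a
                state.coords += 0.5 * dt * v
                noise = state_rngs[i].normal(size=v.shape)
                v = c1 * v + c2 * sigma_v * noise
                state.coords += 0.5 * dt * v
                vels[i] = v
            if not all(np.all(np.isfinite(s.coords)) for s in model.states):
                truncated = True
                break
            forces = engine.force(model, w_xray)
            for i in range(model.n_states):
                vels[i] += 0.5 * dt * forces[i] / masses[:, None] * ACC
        if truncated:
            if records:
                records[-1].flags.append("truncated")
            break
        step += chunk
        macro_count += 1
        if (cfg.resample_weights_every and
                macro_count % cfg.resample_weights_every == 0 and step < cfg.n_steps):
            model.weights = sample_weight_matrix(model.n_states, len(datasets), rng)
        record(step)
        if step < cfg.n_steps:
            forces = engine.force(model, w_xray)  # pick up refreshed parameters
    return records


# ---------------------------------------------------------------------------
# Conjugate-gradient polish
# ---------------------------------------------------------------------------

def cg_polish(model: MultiStateModel, datasets, prior_params,
              cfg: SamplerConfig | None = None,
              max_iter: int | None = None, tol: float | None = None):
    """Polak-Ribiere conjugate-gradient minimization of the score S (w_xray=1).

    Nuisance parameters are fitted once at entry and frozen so the objective
    is well defined; the likelihood gradient is exact.  Iterates until the
    gradient RMS falls below `tol` (force units, kcal/mol/A) or `max_iter`;
    the score never increases (Armijo backtracking; a failed line search
    returns the best point reached, flagged).  Returns (model, records_flags).
    """
    cfg = replace(cfg or SamplerConfig(), exact_likelihood_gradient=True)
    max_iter = cfg.polish_max_iter if max_iter is None else max_iter
    tol = cfg.polish_tol if tol is None else tol
    engine = PosteriorEngine(datasets, prior_params, cfg)
    model = model.copy()
    n, a3 = model.n_states, model.n_atoms * 3

    def unpack(x):
        for i, s in enumerate(model.states):
            s.coords = x[i * a3:(i + 1) * a3].reshape(-1, 3)

    def pack():
        return np.concatenate([s.coords.ravel() for s in model.states])

    def objective(refit: bool = False):
        scattering = engine._scattering(model)
        if refit:
            _, nlls = engine._likelihood_grads(model, scattering, fit=True)
        else:
            nlls = np.zeros(len(datasets))
            for j, refls in enumerate(datasets):
                msf, _ = compute_msf(model, refls, j, nuis=engine.nuisances[j],
                                     solvent=cfg.solvent, n_shells=cfg.n_shells,
                                     scattering=scattering[j])
                nlls[j] = dataset_neg_log_likelihood(refls, msf, engine.nuisances[j])
        prior = sum(potential_energy(s, engine.prior_params)[0] for s in model.states)
        return float(nlls.sum() + prior)

    def gradient():
        scattering = engine._scattering(model)
        lik_grads, _ = engine._likelihood_grads(model, scattering, fit=False)
        return np.concatenate([
            (lik_grads[i] + potential_energy(model.states[i], engine.prior_params)[1]).ravel()
            for i in range(n)])

    flags = []
    x = pack()
    f = objective(refit=True)
    g = gradient()
    d = -g
    alpha = 1e-3
    for _ in range(max_iter):
        grms = float(np.sqrt((g * g).mean()))
        if grms < tol:
            break
        gd = float(g @ d)
        if gd >= 0:
            d = -g
            gd = float(g @ d)
        alpha = min(alpha * 4.0, 1.0 / max(1.0, float(np.abs(d).max())))
        success = False
        for _ in range(40):
            unpack(x + alpha * d)
            try:
                f_new = objective()
            except (ValueError, FloatingPointError):
                f_new = np.inf
            if np.isfinite(f_new) and f_new <= f + 1e-4 * alpha * gd:
                success = True
                break
            alpha *= 0.5
        if not success:
            unpack(x)
            flags.append("line_search_failed")
            break
        assert f_new <= f + 1e-9, "CG polish must never increase the score"
        x = x + alpha * d
        g_new = gradient()
        beta = max(0.0, float(g_new @ (g_new - g)) / max(float(g @ g), 1e-30))
        d = -g_new + beta * d
        f, g = f_new, g_new
    unpack(x)
    return model, flags


def sampling_protocol(start: MultiStateModel, datasets, cfg: SamplerConfig,
                      prior_params):
    """Full workflow: n_trajectories per w_xray value, each final snapshot polished.

    Seeds for individual trajectories derive deterministically from cfg.seed.
    Returns the merged sample (polished final models appended as extra records).
    """
    sample = []
    ss = np.random.SeedSequence(cfg.seed)
    children = ss.spawn(len(cfg.w_xray_sweep) * cfg.n_trajectories)
    idx = 0
    for w_xray in cfg.w_xray_sweep:
        for t in range(cfg.n_trajectories):
            rng = np.random.default_rng(children[idx])
            idx += 1
            tid = f"wx{w_xray:g}-t{t}"
            recs = run_trajectory(start, datasets, cfg, rng, prior_params,
                                  trajectory_id=tid, w_xray=w_xray)
            sample.extend(recs)
            final = recs[-1]
            polished, flags = cg_polish(final.model, datasets, prior_params, cfg)
            engine = PosteriorEngine(datasets, prior_params, cfg)
            score, rwork, rfree = engine.refresh(polished)
            sample.append(SampleRecord(tid, final.step + 1, polished, score,
                                       rwork, rfree, w_xray=w_xray,
                                       flags=final.flags + flags + ["polished"]))
    return sample
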