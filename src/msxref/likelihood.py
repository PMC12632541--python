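"""Rice/Woolfson amplitude likelihood and the total Bayesian score.

Each observed amplitude F_O is scored against the model amplitude F_M with a
Rice density (acentric reflections; 2-D Gaussian of the complex structure
factor with variance eps*beta/2 per component and scale alpha) or a Woolfson
density (centric; folded 1-D Gaussian with variance eps*beta).  The total
score S is the joint negative log-likelihood over all conditions plus the
molecular-mechanics prior energy of every state.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.special import i0e, i1e

from .crystal_core import MultiStateModel, ReflectionSet
from .forward_model import (ModelStructureFactors, NuisanceParameters,
                            SolventMaskParams, StateScattering, compute_msf)

__all__ = [
    "log_p_amplitude",
    "neg_log_p_derivative",
    "dataset_neg_log_likelihood",
    "joint_neg_log_likelihood",
    "quadratic_gradient_weights",
    "QuadraticApprox",
    "ScoreBreakdown",
    "total_score",
]


def _log_i0(x):
    # log I0(x) = log(i0e(x)) + |x|; exact and overflow-safe for any argument
    x = np.abs(np.asarray(x, dtype=float))
    return np.log(i0e(x)) + x


def _log_cosh(x):
    x = np.abs(np.asarray(x, dtype=float))
    return x + np.log1p(np.exp(-2.0 * x)) - np.log(2.0)


def log_p_amplitude(f_obs, f_model, alpha, beta, epsilon, centric):
    """Log-density of an observed amplitude given the model amplitude.

    Acentric (Rice):
        log p = log(2 F_O / (eps beta)) - (F_O^2 + a^2 F_M^2)/(eps beta)
                + log I0(2 a F_O F_M / (eps beta))
    Centric (Woolfson):
        log p = 0.5 log(2/(pi eps beta)) - (F_O^2 + a^2 F_M^2)/(2 eps beta)
                + log cosh(a F_O F_M / (eps beta))

    All arguments broadcast; evaluated fully in log space (no overflow up to
    Bessel/cosh arguments of 1e6 and beyond).
    """
    f_obs = np.asarray(f_obs, dtype=float)
    f_model = np.asarray(f_model, dtype=float)
    alpha = np.asarray(alpha, dtype=float)
    beta = np.asarray(beta, dtype=float)
    epsilon = np.asarray(epsilon, dtype=float)
    centric = np.asarray(centric, dtype=bool)
    if np.any(beta <= 0):
        raise ValueError("beta must be positive")
    eb = epsilon * beta
    nu = alpha * f_model
    with np.errstate(divide="ignore"):
        log_fo = np.log(np.where(f_obs > 0, f_obs, 1.0))
        log_fo = np.where(f_obs > 0, log_fo, -np.inf)
    acentric = (np.log(2.0) + log_fo - np.log(eb)
                - (f_obs**2 + nu**2) / eb + _log_i0(2.0 * f_obs * nu / eb))
    cent = (0.5 * (np.log(2.0) - np.log(np.pi * eb))
            - (f_obs**2 + nu**2) / (2.0 * eb) + _log_cosh(f_obs * nu / eb))
    return np.where(centric, cent, acentric)


def neg_log_p_derivative(f_obs, f_model, alpha, beta, epsilon, centric):
    """Exact d(-log p)/dF_M.

    Acentric: 2 a^2 F_M/(eps beta) - (2 a F_O/(eps beta)) I1/I0(2 a F_O F_M/(eps beta))
    Centric:    a^2 F_M/(eps beta) - (a F_O/(eps beta)) tanh(a F_O F_M/(eps beta))
    Positive when F_M exceeds the per-reflection optimum.
    """
    f_obs = np.asarray(f_obs, dtype=float)
    f_model = np.asarray(f_model, dtype=float)
    alpha = np.asarray(alpha, dtype=float)
    beta = np.asarray(beta, dtype=float)
    epsilon = np.asarray(epsilon, dtype=float)
    centric = np.asarray(centric, dtype=bool)
    eb = epsilon * beta
    z_ac = 2.0 * alpha * f_obs * f_model / eb
    ratio = np.where(z_ac != 0, i1e(np.abs(z_ac)) / i0e(np.abs(z_ac)), 0.0) * np.sign(z_ac)
    d_ac = 2.0 * alpha**2 * f_model / eb - (2.0 * alpha * f_obs / eb) * ratio
    z_c = alpha * f_obs * f_model / eb
    d_c = alpha**2 * f_model / eb - (alpha * f_obs / eb) * np.tanh(z_c)
    return np.where(centric, d_c, d_ac)


# ---------------------------------------------------------------------------
# Dataset and joint likelihoods
# ---------------------------------------------------------------------------

def _per_reflection_log_p(refls: ReflectionSet, f_model_amp, nuis: NuisanceParameters):
    return log_p_amplitude(refls.f_obs, f_model_amp, nuis.alpha_of(refls.d),
                           nuis.beta_of(refls.d), refls.epsilon, refls.centric)


def dataset_neg_log_likelihood(refls: ReflectionSet, msf: ModelStructureFactors,
                               nuis: NuisanceParameters) -> float:
    """-sum(log p) over the WORK reflections only (free set is held out)."""
    work = refls.work_mask
    if work.sum() == 0:
        raise ValueError("empty work set")
    lp = _per_reflection_log_p(refls, msf.f_model_amp, nuis)
    return float(-lp[work].sum())


def joint_neg_log_likelihood(model: MultiStateModel, datasets, solvent: bool = False,
                             n_shells: int = 10, nuisances=None):
    """Per-dataset negative log-likelihoods and their total.

    Dataset j is scored with weight column j of the model.  Nuisance
    parameters are fitted per dataset on its work reflections unless supplied.
    """
    if model.n_conditions != len(datasets):
        raise ValueError(f"{len(datasets)} datasets but {model.n_conditions} weight columns")
    per = []
    scattering_cache = {}
    for j, refls in enumerate(datasets):
        key = id(refls)
        # states scatter identically for every condition sharing the hkl set
        sc = scattering_cache.get(key)
        if sc is None and scattering_cache:
            first = next(iter(scattering_cache.values()))
            if np.array_equal(refls.hkl, datasets[0].hkl) and refls.cell == datasets[0].cell:
                sc = first
        if sc is None:
            sc = [StateScattering(s, refls) for s in model.states]
        scattering_cache[key] = sc
        nuis = None if nuisances is None else nuisances[j]
        msf, nuis = compute_msf(model, refls, j, nuis=nuis, solvent=solvent,
                                n_shells=n_shells, scattering=sc)
        per.append(dataset_neg_log_likelihood(refls, msf, nuis))
    return np.array(per), float(sum(per))


# ---------------------------------------------------------------------------
# Quadratic approximation for gradients
# ---------------------------------------------------------------------------

@dataclass
class QuadraticApprox:
    """Frozen second-order Taylor expansion of -log p around |F_M| = f0.

    Between macro-cycle refreshes the per-reflection gradient is evaluated as
    g(F) = g0 + c0 (F - f0); at the refresh point it equals the exact
    derivative by construction.
    """

    f0: np.ndarray
    g0: np.ndarray
    c0: np.ndarray

    def gradient(self, f_model_amp) -> np.ndarray:
        return self.g0 + self.c0 * (np.asarray(f_model_amp) - self.f0)


def quadratic_gradient_weights(refls: ReflectionSet, msf: ModelStructureFactors,
                               nuis: NuisanceParameters):
    """Per-reflection d(-log p)/d|F_M| (work reflections; free get weight 0).

    Returns a QuadraticApprox frozen at the current |F_M|: the exact first
    derivative at the expansion point plus a curvature term (a small central
    difference of the exact first derivative), so the frozen gradient and
    the exact one agree at the refresh point.
    """
    f0 = msf.f_model_amp.copy()
    args = (refls.f_obs, f0, nuis.alpha_of(refls.d), nuis.beta_of(refls.d),
            refls.epsilon, refls.centric)
    g0 = neg_log_p_derivative(*args)
    h = np.maximum(1e-3 * np.abs(f0), 1e-6)
    gp = neg_log_p_derivative(refls.f_obs, f0 + h, *args[2:])
    gm = neg_log_p_derivative(refls.f_obs, np.maximum(f0 - h, 0.0), *args[2:])
    c0 = (gp - gm) / (h + np.minimum(f0, h))
    work = refls.work_mask
    g0 = np.where(work, g0, 0.0)
    c0 = np.where(work, c0, 0.0)
    return QuadraticApprox(f0=f0, g0=g0, c0=c0)


# ---------------------------------------------------------------------------
# Total score
# ---------------------------------------------------------------------------

@dataclass
class ScoreBreakdown:
    """S = sum_j(-log L_j) + sum_i E_prior(M_i), with per-part bookkeeping."""

    neg_log_likelihoods: np.ndarray
    prior_energies: np.ndarray
    dl_dfm: list = field(default_factory=list, repr=False)

    @property
    def total(self) -> float:
        return float(self.neg_log_likelihoods.sum() + self.prior_energies.sum())


def total_score(model: MultiStateModel, datasets, prior_params=None,
                solvent: bool = False, n_shells: int = 10, nuisances=None) -> ScoreBreakdown:
    """Negative log-posterior S (additive constants and the partition function dropped)."""
    if len(datasets) > 0:
        nll, _ = joint_neg_log_likelihood(model, datasets, solvent=solvent,
                                          n_shells=n_shells, nuisances=nuisances)
    else:
        nll = np.zeros(0)
    if prior_params is not None:
        from .prior_ff import potential_energy

        prior = np.array([potential_energy(s, prior_params)[0] for s in model.states])
    else:
        prior = np.zeros(model.n_states)
    if not np.all(np.isfinite(nll)) or not np.all(np.isfinite(prior)):
        raise ValueError("non-finite score component")
    return ScoreBreakdown(neg_log_likelihoods=nll, prior_energies=prior)
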