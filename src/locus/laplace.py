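"""Laplace-approximation Bayesian inversion (variational Laplace).

One subject's dataset is inverted under a generative model by damped Newton
ascent on the log-joint

    J(kappa) = log p(data | kappa) + log N(kappa; 0, C0),

with the prior a zero-mean Gaussian of spherical covariance C0 = (1/8) I in
the unconstrained parameter space.  The posterior is approximated as Gaussian
at the mode with covariance equal to the inverse negative Hessian, and the
Laplace free energy

    F = J(mode) + (d/2) ln 2*pi + (1/2) ln det(posterior covariance)

approximates the log model evidence.  With no data, the posterior is the
prior and F is exactly zero, so F measures evidence relative to an empty
experiment.

Derivatives of the likelihood term are taken by central finite differences
(the models are smooth and low-dimensional); the prior's contribution is
added analytically, so an empty dataset inverts exactly.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable

import numpy as np

from .laplace_opts import FitOptions
from .models import ModelSpec, ObservationSet, dataset_loglik, transform_params

__all__ = ["PriorSpec", "PosteriorFit", "FitOptions", "laplace_fit",
           "fit_model", "free_energy", "DegenerateFitError"]

_LOG_2PI = math.log(2.0 * math.pi)

#: Prior variance of every unconstrained parameter.
PRIOR_VARIANCE = 1.0 / 8.0


class DegenerateFitError(RuntimeError):
    """The negative Hessian could not be rendered positive definite."""


@dataclass(frozen=True)
class PriorSpec:
    """Zero-mean Gaussian prior with spherical covariance."""

    dim: int
    variance: float = PRIOR_VARIANCE

    @property
    def mean(self) -> np.ndarray:
        return np.zeros(self.dim)

    @property
    def covariance(self) -> np.ndarray:
        return self.variance * np.eye(self.dim)

    def logpdf(self, kappa: np.ndarray) -> float:
        k = np.asarray(kappa, dtype=float)
        return float(-0.5 * self.dim * (_LOG_2PI + math.log(self.variance))
                     - 0.5 * k @ k / self.variance)


@dataclass
class PosteriorFit:
    """Laplace posterior for one subject under one model."""

    subject_id: object
    model_id: int
    mode: np.ndarray
    covariance: np.ndarray
    free_energy: float
    n_iterations: int
    converged: bool
    param_names: tuple[str, ...] = field(default=())

    @property
    def variances(self) -> np.ndarray:
        return np.diag(self.covariance)


def free_energy(log_joint_at_mode: float, posterior_covariance: np.ndarray,
                dim: int) -> float:
    """Laplace free energy from the log-joint at the mode and the posterior."""
    cov = np.asarray(posterior_covariance)
    try:
        chol = np.linalg.cholesky(cov)
    except np.linalg.LinAlgError as err:
        raise ValueError("posterior covariance must be positive definite") from err
    logdet = 2.0 * float(np.log(np.diag(chol)).sum())
    return float(log_joint_at_mode + 0.5 * dim * _LOG_2PI + 0.5 * logdet)


def _fd_gradient_hessian(f: Callable[[np.ndarray], float], x: np.ndarray,
                         step: float) -> tuple[float, np.ndarray, np.ndarray]:
    """Value, gradient and Hessian of f at x by central finite differences."""
    d = len(x)
    f0 = f(x)
    grad = np.empty(d)
    hess = np.empty((d, d))
    fp = np.empty(d)
    fm = np.empty(d)
    for i in range(d):
        e = np.zeros(d)
        e[i] = step
        fp[i] = f(x + e)
        fm[i] = f(x - e)
        grad[i] = (fp[i] - fm[i]) / (2.0 * step)
        hess[i, i] = (fp[i] - 2.0 * f0 + fm[i]) / step**2
    for i in range(d):
        for j in range(i + 1, d):
            ei = np.zeros(d)
            ej = np.zeros(d)
            ei[i] = step
            ej[j] = step
            hij = (f(x + ei + ej) - f(x + ei - ej)
                   - f(x - ei + ej) + f(x - ei - ej)) / (4.0 * step**2)
            hess[i, j] = hess[j, i] = hij
    return f0, grad, hess


def _spd_inverse(neg_hess: np.ndarray, max_jitter: float = 1e4):
    """Invert a (nearly) SPD matrix, adding diagonal jitter if needed."""
    jitter = 0.0
    eye = np.eye(len(neg_hess))
    while True:
        try:
            chol = np.linalg.cholesky(neg_hess + jitter * eye)
        except np.linalg.LinAlgError:
            jitter = max(2.0 * jitter, 1e-8)
            if jitter > max_jitter:
                raise DegenerateFitError(
                    "negative Hessian not positive definite after maximum damping")
            continue
        inv_chol = np.linalg.inv(chol)
        return inv_chol.T @ inv_chol


def laplace_fit(loglik: Callable[[np.ndarray], float], prior: PriorSpec,
                opts: FitOptions | None = None, subject_id=None,
                model_id: int = 0, param_names: tuple[str, ...] = (),
                x0: np.ndarray | None = None) -> PosteriorFit:
    """Invert an arbitrary log-likelihood function under a Gaussian prior.

    The likelihood derivatives come from finite differences; the prior's
    gradient ``-kappa / v`` and Hessian ``-(1/v) I`` are exact.  A
    Levenberg-Marquardt damping term is doubled whenever a Newton step fails
    to increase the free energy, and halved after each success.  Iteration is
    deterministic, starting from the prior mean unless ``x0`` overrides it.
    """
    opts = opts or FitOptions()
    d = prior.dim
    prior_prec = 1.0 / prior.variance
    eye = np.eye(d)

    def stats_at(x: np.ndarray):
        ll0, g_ll, h_ll = _fd_gradient_hessian(loglik, x, opts.fd_step)
        joint = ll0 + prior.logpdf(x)
        grad = g_ll - prior_prec * x
        hess = h_ll - prior_prec * eye
        cov = _spd_inverse(-hess)
        return joint, grad, hess, cov, free_energy(joint, cov, d)

    x = prior.mean.copy() if x0 is None else np.asarray(x0, dtype=float).copy()
    if not math.isfinite(loglik(x)):
        raise ValueError("log-likelihood is non-finite at the starting point")
    joint, grad, hess, cov, f_cur = stats_at(x)
    lam = opts.initial_damping
    converged = False
    it = 0
    for it in range(1, opts.max_iterations + 1):
        improved = False
        for _ in range(opts.max_damping_doublings):
            try:
                step = np.linalg.solve(-hess + lam * eye, grad)
                cand = x + step
                joint_c, grad_c, hess_c, cov_c, f_c = stats_at(cand)
            except (np.linalg.LinAlgError, FloatingPointError,
                    DegenerateFitError, ValueError):
                lam *= 2.0
                continue
            if f_c > f_cur:
                gain = f_c - f_cur
                x, joint, grad, hess, cov, f_cur = (cand, joint_c, grad_c,
                                                    hess_c, cov_c, f_c)
                lam = max(lam / 2.0, opts.min_damping)
                improved = True
                if gain < opts.tolerance:
                    converged = True
                break
            lam *= 2.0
        if converged or not improved:
            converged = converged or not improved
            break

    return PosteriorFit(subject_id=subject_id, model_id=model_id, mode=x,
                        covariance=cov, free_energy=f_cur, n_iterations=it,
                        converged=converged, param_names=tuple(param_names))


def fit_model(spec: ModelSpec, dataset: ObservationSet,
              prior: PriorSpec | None = None, opts: FitOptions | None = None,
              subject_id=None, x0: np.ndarray | None = None) -> PosteriorFit:
    """Fit one generative model to one subject's normalised trials."""
    prior = prior or PriorSpec(dim=spec.n_params)
    if prior.dim != spec.n_params:
        raise ValueError("prior dimension does not match the model")

    def loglik(kappa: np.ndarray) -> float:
        return dataset_loglik(spec, transform_params(kappa, spec), dataset)

    return laplace_fit(loglik, prior, opts, subject_id=subject_id,
                       model_id=spec.model_id, param_names=spec.param_names,
                       x0=x0)
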