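"""Weighted REML variance components for GRM-structured mixed models.

The models are of the form

    dEBV = mu + Z a + (W b) + e,   a ~ N(0, G_SNP sigma_g^2),
                                   b ~ N(0, G_CNV sigma_c^2),
                                   e ~ N(0, D^-1 sigma_e^2)

with D the diagonal matrix of Garrick weights.  Internally the model is
premultiplied by D^{1/2}, which leaves every variance component
untouched and makes the residual covariance the identity; the restricted
log-likelihood reported is that of the transformed model, so likelihood
*differences* between models fitted to the same data and weights are
exact.

The maximizer is average-information REML with a monotone EM fallback:
an AI step that leaves the non-negative orthant or decreases the
restricted log-likelihood is replaced by the EM update (step-halved if
numerics ever make it non-monotone).  Variance components pinned at the
lower floor are reported as boundary solutions.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import stats
from scipy.linalg import cho_factor, cho_solve

logger = logging.getLogger(__name__)

_FLOOR_FRAC = 1e-8  # variance floor as a fraction of var(y)


@dataclass
class MixedModelSpec:
    """Response, weights, and one GRM per random effect (plus residual)."""

    y: np.ndarray
    grms: list[tuple[str, np.ndarray]]
    weights: np.ndarray | None = None
    fixed: np.ndarray | None = None  # fixed-effect design; default intercept

    def __post_init__(self) -> None:
        self.y = np.asarray(self.y, float).ravel()
        n = self.y.size
        if n < 30:
            raise ValueError("need at least 30 observations for REML")
        if self.weights is None:
            self.weights = np.ones(n)
        self.weights = np.asarray(self.weights, float).ravel()
        if self.weights.size != n or (self.weights <= 0).any():
            raise ValueError("weights must be a strictly positive vector matching y")
        if self.fixed is None:
            self.fixed = np.ones((n, 1))
        else:
            self.fixed = np.asarray(self.fixed, float)
            if self.fixed.ndim == 1:
                self.fixed = self.fixed[:, None]
            if self.fixed.shape[0] != n:
                raise ValueError("fixed-effect design does not match y")
        for name, g in self.grms:
            if np.asarray(g).shape != (n, n):
                raise ValueError(f"GRM '{name}' does not match n={n}")


@dataclass
class VarCompFit:
    variances: dict[str, float]
    intercept: float
    loglik: float
    converged: bool
    n_iter: int
    boundary: list[str] = field(default_factory=list)
    proportions: dict[str, float] = field(default_factory=dict)
    proportions_unweighted: dict[str, float] = field(default_factory=dict)
    trace: list[float] = field(default_factory=list)
    fixed_effects: np.ndarray | None = None


def _stabilize(k: np.ndarray, name: str) -> np.ndarray:
    evmin = float(np.linalg.eigvalsh(k).min())
    if evmin < 1e-8:
        k = k + np.eye(k.shape[0]) * 1e-6
        logger.info("GRM '%s': smallest eigenvalue %.2e; added 1e-6 to diagonal", name, evmin)
        if evmin < -1e-4:
            raise ValueError(f"GRM '{name}' is not PSD after stabilization (eigmin {evmin:.2e})")
    return k


class _RemlProblem:
    """Transformed problem: V = sum_k sigma_k^2 K_k + sigma_e^2 I."""

    def __init__(self, spec: MixedModelSpec):
        s = np.sqrt(spec.weights)
        self.n = spec.y.size
        self.y = s * spec.y
        self.x = s[:, None] * spec.fixed  # fixed design after premultiplication
        self.ks = [
            _stabilize(s[:, None] * np.asarray(g, float) * s[None, :], name)
            for name, g in spec.grms
        ]
        self.names = [name for name, _ in spec.grms]
        self.s = s

    def loglik_parts(self, theta: np.ndarray):
        """Return (logL, Py, P, Vinv) at theta = (sigma_1^2.., sigma_e^2)."""
        v = theta[-1] * np.eye(self.n)
        for t, k in zip(theta[:-1], self.ks):
            v += t * k
        try:
            c, low = cho_factor(v, lower=True)
        except np.linalg.LinAlgError:
            return None
        logdet_v = 2.0 * float(np.sum(np.log(np.diag(c))))
        vinv = cho_solve((c, low), np.eye(self.n))
        u = vinv @ self.x  # (n, p)
        xvx = self.x.T @ u
        sign, logdet_xvx = np.linalg.slogdet(xvx)
        if sign <= 0:
            return None
        p = vinv - u @ np.linalg.solve(xvx, u.T)
        py = p @ self.y
        ypy = float(self.y @ py)
        logl = -0.5 * (logdet_v + logdet_xvx + ypy)
        return logl, py, p, vinv


def _clamped_ai_step(theta, grads, ai, floor):
    """Newton-like AI proposal with components that would go negative
    clamped at the floor and the step re-solved over the free set."""
    k = theta.size
    fixed = np.zeros(k, bool)
    for _ in range(k):
        free = ~fixed
        if not free.any():
            break
        sub = ai[np.ix_(free, free)] + 1e-12 * np.eye(int(free.sum()))
        try:
            delta = np.linalg.solve(sub, grads[free])
        except np.linalg.LinAlgError:
            return None
        cand = theta.copy()
        cand[free] = theta[free] + delta
        cand[fixed] = floor
        neg = cand < floor
        if not neg.any():
            return cand
        fixed |= neg
    cand = np.full(k, floor)
    return cand


def _em_update(theta, py, p, ks, n):
    new = theta.copy()
    for k_idx, k in enumerate(ks):
        t = theta[k_idx]
        kpy = k @ py
        new[k_idx] = t + (t * t / n) * (float(py @ kpy) - float(np.sum(p * k)))
    t = theta[-1]
    new[-1] = t + (t * t / n) * (float(py @ py) - float(np.trace(p)))
    return new


def fit_reml(
    spec: MixedModelSpec,
    max_iter: int = 200,
    tol: float = 1e-8,
    start: np.ndarray | None = None,
) -> VarCompFit:
    """Maximize the restricted likelihood over the non-negative orthant.

    Raises on a non-PSD covariance; non-convergence within ``max_iter``
    is flagged on the returned fit, never silent.
    """
    prob = _RemlProblem(spec)
    n, m = prob.n, len(prob.ks)
    vary = float(np.var(prob.y))
    floor = max(_FLOOR_FRAC * vary, 1e-12)
    theta = (
        np.asarray(start, float).copy()
        if start is not None
        else np.full(m + 1, vary / (m + 1))
    )
    theta = np.maximum(theta, floor)

    parts = prob.loglik_parts(theta)
    if parts is None:
        raise ValueError("initial covariance not positive definite")
    logl, py, p, _ = parts
    trace = [logl]
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        # score and average-information matrix over (components, residual)
        kpys = [k @ py for k in prob.ks] + [py]
        grads = np.empty(m + 1)
        for j in range(m):
            grads[j] = -0.5 * (float(np.sum(p * prob.ks[j])) - float(py @ kpys[j]))
        grads[m] = -0.5 * (float(np.trace(p)) - float(py @ py))
        pk = [p @ v for v in kpys]
        ai = 0.5 * np.array([[float(kpys[i] @ pk[j]) for j in range(m + 1)] for i in range(m + 1)])

        accepted = False
        cand = _clamped_ai_step(theta, grads, ai, floor)
        if cand is not None:
            step = 1.0
            for _ in range(12):
                trial = theta + step * (cand - theta)
                trial_parts = prob.loglik_parts(trial)
                if trial_parts is not None and trial_parts[0] >= logl - 1e-10:
                    cand, cand_parts, accepted = trial, trial_parts, True
                    break
                step /= 2.0
        if not accepted:
            cand = np.maximum(_em_update(theta, py, p, prob.ks, n), floor)
            cand_parts = prob.loglik_parts(cand)
            step = 1.0
            while (cand_parts is None or cand_parts[0] < logl - 1e-10) and step > 1e-4:
                step /= 2.0
                cand = np.maximum(theta + step * (cand - theta), floor)
                cand_parts = prob.loglik_parts(cand)
            if cand_parts is None or cand_parts[0] < logl - 1e-10:
                converged = True  # no ascent direction left: stationary at theta
                break
        new_logl = cand_parts[0]
        rel = abs(new_logl - logl) / max(1.0, abs(logl))
        theta, (logl, py, p, _) = cand, cand_parts
        trace.append(logl)
        if rel < tol:
            converged = True
            break
    if not converged and it >= max_iter:
        logger.warning("REML did not converge in %d iterations (rel change %.1e)", max_iter, rel)

    # fixed effects via GLS at the final covariance
    _, py, p, vinv = prob.loglik_parts(theta)
    u = vinv @ prob.x
    coef = np.linalg.solve(prob.x.T @ u, u.T @ prob.y)
    mu = float(coef[0])

    names = prob.names + ["residual"]
    boundary = [nm for nm, t in zip(names, theta) if t <= floor * 1.01]
    variances = {nm: float(t) for nm, t in zip(names, theta)}
    fixed_effects = np.asarray(coef, float)
    hm = n / float(spec.weights.sum())  # harmonic mean of 1/w
    denom_w = sum(variances[nm] for nm in prob.names) + variances["residual"] * hm
    denom_u = sum(variances.values())
    props = {nm: variances[nm] / denom_w for nm in prob.names}
    props_u = {nm: variances[nm] / denom_u for nm in prob.names}
    return VarCompFit(
        variances=variances,
        intercept=mu,
        loglik=float(logl),
        converged=converged,
        n_iter=it,
        boundary=boundary,
        proportions=props,
        proportions_unweighted=props_u,
        trace=trace,
        fixed_effects=fixed_effects,
    )


def likelihood_ratio_test(
    full: VarCompFit, reduced: VarCompFit, boundary_mixture: bool = True
) -> tuple[float, float]:
    """2*(logL_full - logL_reduced), floored at 0, with its p-value.

    The default reference is the 0.5*chi2_0 + 0.5*chi2_1 mixture
    appropriate for one variance component tested on its boundary;
    ``boundary_mixture=False`` gives the plain chi2_1 p-value.
    """
    stat = 2.0 * (full.loglik - reduced.loglik)
    if stat < -1e-4:
        raise ValueError(
            f"full-model logL below reduced-model logL by {-stat / 2:.2e}: optimizer failure"
        )
    stat = max(stat, 0.0)
    tail = float(stats.chi2.sf(stat, df=1))
    if boundary_mixture:
        p = 0.5 * tail if stat > 0 else 1.0
    else:
        p = tail if stat > 0 else 1.0
    return stat, p


def blup_random_effect(
    spec: MixedModelSpec, fit: VarCompFit, component: str | None = None
) -> np.ndarray:
    """BLUP of one GRM-structured random effect at the fitted variances."""
    names = [nm for nm, _ in spec.grms]
    component = component or names[0]
    g = dict(spec.grms)[component]
    n = spec.y.size
    v = np.diag(fit.variances["residual"] / spec.weights)
    for nm, gk in spec.grms:
        v += fit.variances[nm] * np.asarray(gk, float)
    c, low = cho_factor(v, lower=True)
    fixed_part = (
        spec.fixed @ fit.fixed_effects if fit.fixed_effects is not None else fit.intercept
    )
    resid = spec.y - fixed_part
    return fit.variances[component] * (np.asarray(g, float) @ cho_solve((c, low), resid))


def two_step_cnv_variance(
    spec_snp: MixedModelSpec, g_cnv: np.ndarray, **reml_kwargs
) -> tuple[VarCompFit, VarCompFit]:
    """Two-step estimate of the CNV variance after removing the SNP signal.

    Step 1 fits the SNP-GRM model; the dependent variable of step 2 is
    E = residual + intercept = y - BLUP(a), modelled with the CNV GRM and
    the same weights.  Returns (step-1 fit, step-2 fit); the step-2 GRM
    component is the CNV variance net of the SNP-tracked signal.
    """
    fit1 = fit_reml(spec_snp, **reml_kwargs)
    if not fit1.converged:
        logger.warning("step-1 REML flagged non-converged; two-step estimate may be unstable")
    a_hat = blup_random_effect(spec_snp, fit1)
    e_dep = spec_snp.y - a_hat
    spec2 = MixedModelSpec(y=e_dep, grms=[("cnv", g_cnv)], weights=spec_snp.weights)
    fit2 = fit_reml(spec2, **reml_kwargs)
    return fit1, fit2


def draw_polygenic(g: np.ndarray, variance: float, rng: np.random.Generator) -> np.ndarray:
    """Draw a ~ N(0, G * variance) via the eigen square root (negative
    eigenvalues clipped at 0)."""
    if variance == 0:
        return np.zeros(g.shape[0])
    evals, evecs = np.linalg.eigh(np.asarray(g, float))
    root = evecs * np.sqrt(np.clip(evals, 0.0, None))
    return root @ rng.standard_normal(g.shape[0]) * np.sqrt(variance)
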