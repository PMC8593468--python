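"""Joint SNP+CNV association: LASSO selection, relaxed refit, and the
single-variant mixed-model t-test.

The selection model regresses weighted deregressed EBVs on the full set
of SNP and CNV columns plus the top principal components of the SNP and
CNV GRMs and an intercept, minimising

    (1/2N) ||y - X beta||^2 + lambda * sum_{j penalized} |beta_j|

by cyclic coordinate descent.  The intercept and PC columns are
unpenalized adjustments; marker columns are standardized and their
coefficients soft-thresholded.  lambda is chosen by k-fold
cross-validation.  Selected markers are then refitted jointly by
ordinary (weighted) least squares without the penalty - the relaxed
LASSO - giving debiased allele-substitution effects a_i, from which each
CNV's share of the genetic variance is 2 p_i (1 - p_i) a_i^2 / sigma_g^2
with p_i the carrier proportion of the collapsed class.

Weights enter by premultiplying y and every column of X by sqrt(w_i), so
the unpenalized part of the objective is the weighted least-squares
criterion.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .cnv import CnvLocus, DELETION_CLASSES, DUPLICATION_CLASSES
from .qc import SnpPanel

logger = logging.getLogger(__name__)

KKT_TOL = 1e-6


@dataclass
class DesignMatrix:
    x: np.ndarray  # sqrt(w)-weighted, marker columns standardized
    y: np.ndarray  # sqrt(w) * dEBV
    col_names: list[str]
    col_types: list[str]  # intercept | pc | snp | cnv
    penalty_mask: np.ndarray  # 1 for marker columns, 0 otherwise
    col_scale: np.ndarray  # std of the weighted marker columns (1 elsewhere)
    col_center: np.ndarray
    marker_freq: dict[str, float] = field(default_factory=dict)  # p_i per marker

    @property
    def n(self) -> int:
        return self.x.shape[0]


@dataclass
class LassoFit:
    lam: float
    beta: np.ndarray  # on the standardized design
    selected: list[str]
    cv_lambdas: np.ndarray
    cv_errors: np.ndarray
    seed: int


@dataclass
class AssocResult:
    variant_id: str
    variant_type: str  # snp | cnv
    effect: float  # debiased allele-substitution effect, original scale
    se: float
    freq: float  # allele frequency (snp) or carrier proportion (cnv)
    lasso_beta: float
    t_stat: float = np.nan
    p_value: float = np.nan
    var_fraction: float = np.nan


def cnv_design_columns(
    loci: list[CnvLocus], animal_ids: np.ndarray
) -> tuple[np.ndarray, list[str], dict[str, float]]:
    """Carrier-indicator columns per (collapsed) locus.

    Pure deletion/duplication loci contribute one 0/1 carrier column;
    mixed loci contribute a deletion column and a duplication column.
    Returns (matrix, names, carrier proportion per column).
    """
    cols, names, freqs = [], [], {}
    n = len(animal_ids)
    for locus in loci:
        parts = []
        if locus.cnv_type in ("deletion", "mixed"):
            parts.append((f"{locus.locus_id}:del" if locus.cnv_type == "mixed" else locus.locus_id,
                          DELETION_CLASSES))
        if locus.cnv_type in ("duplication", "mixed"):
            parts.append((f"{locus.locus_id}:dup" if locus.cnv_type == "mixed" else locus.locus_id,
                          DUPLICATION_CLASSES))
        for name, classes in parts:
            col = np.array(
                [1.0 if locus.class_of(str(a)) in classes else 0.0 for a in animal_ids]
            )
            cols.append(col)
            names.append(name)
            freqs[name] = float(col.mean())
    m = np.column_stack(cols) if cols else np.empty((n, 0))
    return m, names, freqs


def build_design(
    panel: SnpPanel,
    loci: list[CnvLocus],
    pcs_snp: np.ndarray | None,
    pcs_cnv: np.ndarray | None,
    traits: pd.DataFrame,
    k_pcs: int = 10,
) -> DesignMatrix:
    """Assemble the weighted, standardized selection design.

    ``traits`` must carry animal_id, debv and weight, ordered like the
    panel.  Zero-variance marker columns are dropped with a warning.
    """
    order = panel.animal_index(traits["animal_id"])
    if not np.array_equal(order, np.arange(panel.n_animals)):
        raise ValueError("trait table must be ordered like the panel")
    if np.isnan(panel.geno).any():
        raise ValueError("impute missing genotypes before building the design")
    w = traits["weight"].to_numpy(float)
    sw = np.sqrt(w)
    y = sw * traits["debv"].to_numpy(float)

    blocks, names, types = [np.ones(panel.n_animals)], ["intercept"], ["intercept"]
    for tag, pcs in (("snp", pcs_snp), ("cnv", pcs_cnv)):
        if pcs is not None and k_pcs > 0:
            k = min(k_pcs, pcs.shape[1])
            blocks.append(pcs[:, :k])
            names += [f"pc_{tag}{j + 1}" for j in range(k)]
            types += ["pc"] * k
    snp_block = panel.geno
    blocks.append(snp_block)
    names += list(panel.snp_map["snp_id"])
    types += ["snp"] * panel.n_snps
    cnv_block, cnv_names, cnv_freqs = cnv_design_columns(loci, panel.animal_ids)
    blocks.append(cnv_block)
    names += cnv_names
    types += ["cnv"] * len(cnv_names)

    x = np.column_stack([b if b.ndim == 2 else b[:, None] for b in blocks])
    x = x * sw[:, None]

    penalty = np.array([1.0 if t in ("snp", "cnv") else 0.0 for t in types])
    center = np.zeros(x.shape[1])
    scale = np.ones(x.shape[1])
    keep = np.ones(x.shape[1], bool)
    marker = penalty == 1.0
    mu = x[:, marker].mean(axis=0)
    sd = x[:, marker].std(axis=0)
    zero = sd == 0
    if zero.any():
        dropped = [n for n, z in zip(np.array(names, object)[marker], zero) if z]
        logger.warning("dropping %d zero-variance marker columns: %s", len(dropped), dropped[:5])
    center[marker] = mu
    scale[marker] = np.where(zero, 1.0, sd)
    x = (x - center) / scale
    x[:, ~marker] = x[:, ~marker] * scale[~marker] + center[~marker]  # untouched
    keep[np.flatnonzero(marker)[zero]] = False

    freqs = dict(cnv_freqs)
    snp_p = panel.geno.mean(axis=0) / 2.0
    freqs.update({n: float(p) for n, p in zip(panel.snp_map["snp_id"], snp_p)})
    sel = np.flatnonzero(keep)
    return DesignMatrix(
        x=x[:, sel],
        y=y,
        col_names=[names[i] for i in sel],
        col_types=[types[i] for i in sel],
        penalty_mask=penalty[sel],
        col_scale=scale[sel],
        col_center=center[sel],
        marker_freq=freqs,
    )


# --- coordinate descent --------------------------------------------------

try:  # compiled kernel; the pure-Python twin below is the fallback
    from numba import njit as _njit
except ImportError:  # pragma: no cover
    _njit = None


def _cd_sweeps(xt, y, penalty, lam, beta, xx, tol, max_sweeps):
    """Cyclic coordinate sweeps; returns when no coefficient moves more
    than tol.  ``xt`` is the transposed design (one contiguous row per
    column of X)."""
    p, n = xt.shape
    r = y - xt.T @ beta
    for _ in range(max_sweeps):
        move = 0.0
        for j in range(p):
            if xx[j] == 0.0:
                continue
            b_old = beta[j]
            z = np.dot(xt[j], r) / n + xx[j] * b_old
            if penalty[j] != 0.0:
                az = abs(z) - lam
                b_new = (np.sign(z) * az if az > 0.0 else 0.0) / xx[j]
            else:
                b_new = z / xx[j]
            d = b_new - b_old
            if d != 0.0:
                beta[j] = b_new
                for i in range(n):
                    r[i] -= d * xt[j, i]
                mv = abs(d) * np.sqrt(xx[j])
                if mv > move:
                    move = mv
        if move < tol:
            break
    return beta


if _njit is not None:
    _cd_sweeps = _njit(cache=True)(_cd_sweeps)


def _cd_solve(
    x: np.ndarray,
    y: np.ndarray,
    penalty: np.ndarray,
    lam: float,
    beta0: np.ndarray | None = None,
    tol: float = 1e-9,
    max_sweeps: int = 2000,
) -> np.ndarray:
    """Cyclic coordinate descent on (1/2N)||y-Xb||^2 + lam * sum m_j |b_j|."""
    xt = np.ascontiguousarray(np.asarray(x, np.float64).T)
    p = xt.shape[0]
    xx = (xt * xt).sum(axis=1) / xt.shape[1]
    beta = np.zeros(p) if beta0 is None else np.asarray(beta0, np.float64).copy()
    return _cd_sweeps(
        xt, np.ascontiguousarray(y, np.float64), np.asarray(penalty, np.float64),
        float(lam), beta, xx, float(tol), int(max_sweeps),
    )


def kkt_violation(x: np.ndarray, y: np.ndarray, beta: np.ndarray, penalty: np.ndarray, lam: float) -> float:
    """Largest KKT violation: for zero penalized coefficients
    |x_j'r/N| - lam, for the rest |x_j'r/N - lam*sign(b_j)| (unpenalized:
    |x_j'r/N|).  Non-positive (within tolerance) at an exact solution."""
    n = x.shape[0]
    grad = x.T @ (y - x @ beta) / n
    viol = 0.0
    for j in range(x.shape[1]):
        if penalty[j] == 0:
            viol = max(viol, abs(grad[j]))
        elif beta[j] == 0:
            viol = max(viol, abs(grad[j]) - lam)
        else:
            viol = max(viol, abs(grad[j] - lam * np.sign(beta[j])))
    return viol


def lambda_max(design: DesignMatrix) -> float:
    """Smallest lambda at which every penalized coefficient is zero,
    accounting for the unpenalized columns (their fit is profiled out)."""
    free = design.penalty_mask == 0
    y = design.y
    if free.any():
        xf = design.x[:, free]
        coef, *_ = np.linalg.lstsq(xf, y, rcond=None)
        y = y - xf @ coef
    pen = design.x[:, design.penalty_mask == 1]
    return float(np.abs(pen.T @ y).max() / design.n)


def fit_lasso(
    design: DesignMatrix,
    lambda_grid: np.ndarray | None = None,
    cv_folds: int = 10,
    seed: int = 0,
    lambda_rule: str = "min",
    n_lambda: int = 40,
) -> LassoFit:
    """Cross-validated LASSO on the selection design.

    The lambda path runs from lambda_max down two decades (warm starts);
    lambda is chosen at the minimum mean CV prediction error, or by the
    one-standard-error rule with ``lambda_rule='1se'``.
    """
    n = design.n
    if cv_folds > n:
        raise ValueError("more folds than animals")
    if lambda_grid is None:
        lmax = lambda_max(design) * 1.001
        lambda_grid = np.geomspace(lmax, lmax * 1e-2, n_lambda)
    lambda_grid = np.sort(np.asarray(lambda_grid, float))[::-1]

    rng = np.random.default_rng(seed)
    fold_of = np.repeat(np.arange(cv_folds), int(np.ceil(n / cv_folds)))[:n]
    rng.shuffle(fold_of)
    errs = np.zeros((cv_folds, lambda_grid.size))
    for f in range(cv_folds):
        tr, va = fold_of != f, fold_of == f
        xtr = np.asfortranarray(design.x[tr])
        ytr = design.y[tr]
        cv_tol = 1e-6 * max(float(np.std(ytr)), 1e-12)
        beta = None
        for li, lam in enumerate(lambda_grid):
            beta = _cd_solve(xtr, ytr, design.penalty_mask, lam, beta, tol=cv_tol)
            resid = design.y[va] - design.x[va] @ beta
            errs[f, li] = float(resid @ resid) / va.sum()
    mean_err = errs.mean(axis=0)
    if lambda_rule == "1se":
        se = errs.std(axis=0, ddof=1) / np.sqrt(cv_folds)
        best = int(np.argmin(mean_err))
        ok = np.flatnonzero(mean_err <= mean_err[best] + se[best])
        pick = int(ok[0])  # largest lambda within one SE (grid is descending)
    else:
        pick = int(np.argmin(mean_err))
    lam = float(lambda_grid[pick])

    xf = np.asfortranarray(design.x)
    beta = None
    for li in range(pick + 1):
        beta = _cd_solve(xf, design.y, design.penalty_mask, lambda_grid[li], beta)
    viol = kkt_violation(design.x, design.y, beta, design.penalty_mask, lam)
    if viol > KKT_TOL:
        beta = _cd_solve(xf, design.y, design.penalty_mask, lam, beta, tol=1e-12)
        viol = kkt_violation(design.x, design.y, beta, design.penalty_mask, lam)
        if viol > KKT_TOL:
            raise RuntimeError(f"LASSO KKT violation {viol:.2e} exceeds tolerance")
    selected = [
        name
        for name, b, m in zip(design.col_names, beta, design.penalty_mask)
        if m == 1 and b != 0.0
    ]
    return LassoFit(lam, beta, selected, lambda_grid, mean_err, seed)


def relaxed_refit(design: DesignMatrix, fit: LassoFit) -> list[AssocResult]:
    """Unpenalized joint WLS refit of the selected markers (relaxed LASSO).

    Aliased columns within the selected set are dropped (logged); the
    refit falls back to a ridge-stabilized solve when the selected set is
    not smaller than the sample size.  Effects are returned on the
    original marker scale.
    """
    if not fit.selected:
        return []
    names = np.array(design.col_names, object)
    free_idx = np.flatnonzero(design.penalty_mask == 0)
    sel_idx = np.array([design.col_names.index(s) for s in fit.selected])
    cols = np.concatenate([free_idx, sel_idx])
    x = design.x[:, cols]
    ridge = x.shape[1] >= design.n
    if ridge:
        logger.warning("selected set size %d >= n=%d: ridge-stabilized refit", x.shape[1], design.n)
        xtx = x.T @ x + 1e-6 * np.eye(x.shape[1])
        coef = np.linalg.solve(xtx, x.T @ design.y)
        rank = x.shape[1]
        kept = np.arange(x.shape[1])
    else:
        q, r, piv = _qr_pivot(x)
        diag = np.abs(np.diag(r))
        rank = int((diag > diag.max() * 1e-10).sum()) if diag.size else 0
        kept = np.sort(piv[:rank])
        if rank < x.shape[1]:
            logger.info("dropping aliased columns in refit: %s", list(names[cols[np.sort(piv[rank:])]]))
        x = x[:, kept]
        coef, *_ = np.linalg.lstsq(x, design.y, rcond=None)
    resid = design.y - x @ coef
    dof = max(design.n - x.shape[1], 1)
    sigma2 = float(resid @ resid) / dof
    xtx_inv = np.linalg.pinv(x.T @ x)
    ses = np.sqrt(sigma2 * np.diag(xtx_inv))

    results = []
    kept_orig = cols[kept]
    for local, orig in enumerate(kept_orig):
        if design.penalty_mask[orig] != 1:
            continue
        name = design.col_names[orig]
        scale = design.col_scale[orig]
        results.append(
            AssocResult(
                variant_id=name,
                variant_type=design.col_types[orig],
                effect=float(coef[local] / scale),
                se=float(ses[local] / scale),
                freq=design.marker_freq.get(name, np.nan),
                lasso_beta=float(fit.beta[orig] / scale),
            )
        )
    return results


def _qr_pivot(x: np.ndarray):
    from scipy.linalg import qr

    q, r, piv = qr(x, mode="economic", pivoting=True)
    return q, r, piv


def variance_explained(result: AssocResult, sigma_g2: float) -> float:
    """Fraction of the genetic variance attributed to one variant:
    2 p (1 - p) a^2 / sigma_g^2."""
    if sigma_g2 <= 0:
        raise ValueError("sigma_g2 must be positive")
    p = result.freq
    if not 0.0 < p < 1.0:
        raise ValueError(f"variant frequency must be in (0,1), got {p}")
    frac = 2.0 * p * (1.0 - p) * result.effect**2 / sigma_g2
    result.var_fraction = frac
    return frac


def single_marker_mlm(
    marker: np.ndarray,
    g_snp: np.ndarray,
    debv: np.ndarray,
    weights: np.ndarray,
    sigma_g2: float,
    sigma_e2: float,
) -> tuple[float, float, float]:
    """GLS effect and t-test of one variant under V = G sigma_g^2 + D^-1 sigma_e^2.

    The null-model variance components are estimated once and reused
    across markers (population-parameters-previously-determined); pass
    per-marker REML estimates for the exact variant-specific test.
    """
    marker = np.asarray(marker, float)
    if marker.std() == 0:
        raise ValueError("zero-variance marker")
    n = marker.size
    v = sigma_g2 * np.asarray(g_snp, float) + np.diag(sigma_e2 / np.asarray(weights, float))
    from scipy.linalg import cholesky, solve_triangular

    l = cholesky(v, lower=True)
    x = np.column_stack([np.ones(n), marker])
    xw = solve_triangular(l, x, lower=True)
    yw = solve_triangular(l, np.asarray(debv, float), lower=True)
    xtx = xw.T @ xw
    coef = np.linalg.solve(xtx, xw.T @ yw)
    resid = yw - xw @ coef
    sigma2 = float(resid @ resid) / (n - 2)
    cov = sigma2 * np.linalg.inv(xtx)
    se = float(np.sqrt(cov[1, 1]))
    t = float(coef[1] / se)
    p = 2.0 * float(stats.t.sf(abs(t), df=n - 2))
    return float(coef[1]), t, p


def results_table(results: list[AssocResult]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "variant": [r.variant_id for r in results],
            "type": [r.variant_type for r in results],
            "lasso_beta": [r.lasso_beta for r in results],
            "debiased_beta": [r.effect for r in results],
            "se": [r.se for r in results],
            "freq": [r.freq for r in results],
            "t": [r.t_stat for r in results],
            "p": [r.p_value for r in results],
            "var_fraction": [r.var_fraction for r in results],
        }
    )
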