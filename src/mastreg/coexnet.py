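"""Per-cohort coexpression networks from shrinkage partial correlations.

The sample correlation matrix is shrunk toward the identity with the
analytic intensity

    lambda* = sum_{i<j} Var^(r_ij) / sum_{i<j} r_ij^2,

(the Schafer-Strimmer target-to-identity estimator, clipped to [0, 1]),
guaranteeing a positive-definite matrix that can be inverted into
partial correlations even when genes outnumber samples.  Each TF-target
partial correlation is tested against an empirical null density

    f0(r; kappa) = (1 - r^2)^((kappa - 3) / 2) / B(1/2, (kappa - 1)/2),

whose effective degree-of-freedom parameter ``kappa`` is fitted to the
central mass of the observed partial correlations (fdrtool-style
empirical null).  With no shrinkage and ``kappa = n - 1`` this reduces
to the classical test of a sample correlation on ``n`` observations.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import linalg, optimize, stats
from statsmodels.stats.multitest import multipletests

from .containers import ExpressionMatrix

logger = logging.getLogger(__name__)


@dataclass
class ShrinkageFit:
    """Shrinkage intensity and empirical-null parameters for one cohort."""

    lambda_star: float
    kappa: float | None = None
    eta0: float = 1.0

    def __post_init__(self) -> None:
        if not 0.0 <= self.lambda_star <= 1.0:
            raise ValueError("lambda_star must lie in [0, 1]")


def shrink_correlation(
    mat: ExpressionMatrix | pd.DataFrame,
    lambda_star: float | None = None,
) -> tuple[pd.DataFrame, ShrinkageFit]:
    """Shrunk correlation matrix R* = lambda* I + (1 - lambda*) R^.

    ``lambda_star`` may be forced (e.g. 0 for the plain sample
    correlation); otherwise the analytic estimate is used, with the
    pairwise variance term computed from the unbiased w-moment
    estimator ``Var^(r_ij) = n / (n-1)^3 * sum_k (w_kij - w_ij)^2``
    on standardized data.
    """
    values = mat.values if isinstance(mat, ExpressionMatrix) else mat
    X = values.to_numpy(dtype=float)
    p, n = X.shape
    if n < 3:
        raise ValueError("need >=3 samples")
    if p < 2:
        raise ValueError("need >=2 genes")
    sd = X.std(axis=1, ddof=1)
    constant = (X.max(axis=1) - X.min(axis=1) == 0) | (sd == 0)
    if np.any(constant):
        bad = values.index[constant].tolist()
        raise ValueError(f"constant gene(s): {bad[:5]}")
    Xs = (X - X.mean(axis=1, keepdims=True)) / sd[:, None]
    R = (Xs @ Xs.T) / (n - 1)
    np.fill_diagonal(R, 1.0)
    if lambda_star is None:
        # sum over k of w^2 and (sum w)^2 for every pair, done as matrix products
        S = Xs @ Xs.T  # sum_k w_kij
        M2 = (Xs**2) @ (Xs**2).T  # sum_k w_kij^2
        var_r = n / (n - 1.0) ** 3 * (M2 - S**2 / n)
        iu = np.triu_indices(p, k=1)
        denom = float(np.sum(R[iu] ** 2))
        num = float(np.sum(var_r[iu]))
        lam = 1.0 if denom == 0 else num / denom
        lam = min(1.0, max(0.0, lam))
    else:
        lam = float(lambda_star)
        if not 0.0 <= lam <= 1.0:
            raise ValueError("lambda_star must lie in [0, 1]")
    R_star = lam * np.eye(p) + (1.0 - lam) * R
    out = pd.DataFrame(R_star, index=values.index.copy(), columns=values.index.copy())
    return out, ShrinkageFit(lambda_star=lam)


def partial_correlations(R_star: pd.DataFrame) -> pd.DataFrame:
    """Partial correlations from the concentration matrix of R*.

    With Omega = (R*)^-1, ``pcor(i, j) = -Omega_ij / sqrt(Omega_ii *
    Omega_jj)``; the diagonal is set to 1 by convention.
    """
    A = R_star.to_numpy(dtype=float)
    try:
        cho = linalg.cho_factor(A)
        omega = linalg.cho_solve(cho, np.eye(A.shape[0]))
    except linalg.LinAlgError as exc:
        raise ValueError("shrunk correlation matrix is singular; use lambda_star > 0") from exc
    d = np.sqrt(np.diag(omega))
    P = -omega / np.outer(d, d)
    np.fill_diagonal(P, 1.0)
    P = np.clip((P + P.T) / 2.0, -1.0, 1.0)
    np.fill_diagonal(P, 1.0)
    return pd.DataFrame(P, index=R_star.index.copy(), columns=R_star.columns.copy())


def null_pvalue(r, kappa: float) -> np.ndarray:
    """Two-sided tail probability of |R| >= |r| under f0(r; kappa).

    Uses the exact monotone transform ``t = r * sqrt(kappa - 1) /
    sqrt(1 - r^2) ~ Student-t(kappa - 1)``.
    """
    if kappa <= 1:
        raise ValueError("kappa must exceed 1")
    r = np.clip(np.asarray(r, dtype=float), -1.0, 1.0)
    with np.errstate(divide="ignore"):
        t = np.abs(r) * math.sqrt(kappa - 1.0) / np.sqrt(1.0 - r**2)
    t = np.where(np.abs(r) >= 1.0, np.inf, t)
    return np.minimum(1.0, 2.0 * stats.t.sf(t, kappa - 1.0))


def fit_kappa(r_values: np.ndarray, band: float = 0.95) -> float:
    """Fit the null df ``kappa`` to the central mass of partial correlations.

    Maximizes the truncated f0 likelihood over observations inside the
    central ``band`` quantile range (default the 2.5th-97.5th
    percentile).  The band excludes the extreme tails where true edges
    live; keeping the shoulders in the fit matters because the null
    distribution of shrunk partial correlations is slightly
    heavier-tailed than f0, and a narrower band would understate the
    null spread and inflate the far-tail p-values.  Raises
    ``RuntimeError`` when no informative fit is possible.
    """
    r = np.asarray(r_values, dtype=float)
    r = r[np.isfinite(r)]
    r = r[np.abs(r) < 1.0]
    if r.size < 10:
        raise RuntimeError("too few partial correlations to fit kappa")
    lo, hi = np.quantile(r, [(1 - band) / 2, 1 - (1 - band) / 2])
    sel = r[(r >= lo) & (r <= hi)]
    if sel.size < 10 or np.allclose(sel, 0.0):
        raise RuntimeError("degenerate central band; cannot fit kappa")
    log1mr2 = np.log1p(-np.clip(sel**2, 0.0, 1.0 - 1e-15))
    m = sel.size

    def nll(log_kappa: float) -> float:
        kappa = math.exp(log_kappa) + 3.0
        # normalizing constant of f0 truncated to [lo, hi]
        mass = stats.beta.cdf((hi + 1) / 2, (kappa - 1) / 2, (kappa - 1) / 2) - stats.beta.cdf(
            (lo + 1) / 2, (kappa - 1) / 2, (kappa - 1) / 2
        )
        if mass <= 0:
            return np.inf
        log_const = (
            math.lgamma(kappa / 2.0)
            - math.lgamma((kappa - 1.0) / 2.0)
            - 0.5 * math.log(math.pi)
        )
        ll = m * (log_const - math.log(mass)) + (kappa - 3.0) / 2.0 * float(np.sum(log1mr2))
        return -ll

    res = optimize.minimize_scalar(nll, bounds=(math.log(0.5), math.log(1e7)), method="bounded")
    if not res.success or not np.isfinite(res.fun):
        raise RuntimeError("kappa likelihood optimization failed")
    kappa = math.exp(res.x) + 3.0
    if kappa > 5e6:
        raise RuntimeError("kappa fit diverged (no variance in null band)")
    return float(kappa)


def edge_significance(
    pcor: pd.DataFrame,
    tf_list,
    n_samples: int,
    fit: ShrinkageFit | None = None,
    fdr_threshold: float = 0.05,
    kappa: float | None = None,
    cohort_id: str = "cohort",
) -> tuple[pd.DataFrame, ShrinkageFit]:
    """Empirical-null p/q-values for every TF-incident partial correlation.

    Only TF-target pairs (TF from ``tf_list`` against every other gene)
    are tested and emitted.  ``kappa`` may be supplied; otherwise it is
    fitted to the central mass of the TF-incident partial correlations,
    falling back to ``n_samples - 1`` with a warning when the fit fails.
    q-values are Benjamini-Hochberg over the emitted pairs;
    ``significant = (q < fdr_threshold)``.
    """
    genes = pcor.index
    tfs = [tf for tf in tf_list if tf in genes]
    if not tfs:
        raise ValueError("no TF from tf_list present in the matrix")
    P = pcor.to_numpy(dtype=float)
    gene_pos = {g: i for i, g in enumerate(genes)}
    tf_rows = np.array([gene_pos[tf] for tf in tfs])

    rows_tf, rows_target, rows_r = [], [], []
    seen = set()
    for tf, i in zip(tfs, tf_rows):
        for j, target in enumerate(genes):
            if j == i:
                continue
            key = (min(i, j), max(i, j))
            if target in tfs and key in seen:
                continue  # one row per unordered TF-TF pair
            seen.add(key)
            rows_tf.append(tf)
            rows_target.append(target)
            rows_r.append(P[i, j])
    r = np.asarray(rows_r, dtype=float)
    if r.size < 20:
        logger.warning("only %d TF-target pairs; kappa estimation is unstable", r.size)

    if kappa is None:
        try:
            kappa = fit_kappa(r)
        except RuntimeError as exc:
            kappa = float(n_samples - 1)
            logger.warning("kappa fit failed (%s); falling back to n - 1 = %g", exc, kappa)
    p = null_pvalue(r, kappa)
    p = np.clip(p, np.finfo(float).tiny, 1.0)
    reject, q, _, _ = multipletests(p, alpha=fdr_threshold, method="fdr_bh")[:4]
    significant = q < fdr_threshold

    fit = fit or ShrinkageFit(lambda_star=0.0)
    fit.kappa = float(kappa)
    fit.eta0 = float(min(1.0, 2.0 * np.mean(p > 0.5))) if p.size else 1.0

    edges = pd.DataFrame(
        {
            "cohort": cohort_id,
            "n_samples": int(n_samples),
            "tf": rows_tf,
            "target": rows_target,
            "r_partial": r,
            "p": p,
            "q": q,
            "significant": significant,
        }
    )
    return edges, fit


def infer_network(
    mat: ExpressionMatrix,
    tf_list,
    fdr_threshold: float = 0.05,
    lambda_star: float | None = None,
    kappa: float | None = None,
    cohort_id: str | None = None,
) -> tuple[pd.DataFrame, ShrinkageFit]:
    """One-shot per-cohort network: shrink, invert, test, BH-correct."""
    cohort_id = cohort_id or str(mat.sample_meta["cohort"].iloc[0])
    R_star, fit = shrink_correlation(mat, lambda_star=lambda_star)
    pcor = partial_correlations(R_star)
    edges, fit = edge_significance(
        pcor,
        tf_list,
        n_samples=mat.n_samples,
        fit=fit,
        fdr_threshold=fdr_threshold,
        kappa=kappa,
        cohort_id=cohort_id,
    )
    return edges, fit
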