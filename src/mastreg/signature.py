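"""Perturbation signatures: moderated t, DEG calls, ortholog projection.

The treated-vs-control signature is the per-gene log2 fold-change with
an empirical-Bayes moderated t-statistic: gene-wise sample variances
``s_g^2`` (residual df ``d_g``) are shrunk toward a prior variance
``s0^2`` with prior df ``d0``,

    s~_g^2 = (d0 * s0^2 + d_g * s_g^2) / (d0 + d_g),

where ``(d0, s0^2)`` are fitted by matching moments of ``log s_g^2``
against the scaled-F sampling model.  The moderated t uses
``d0 + d_g`` degrees of freedom, borrowing strength across genes when
replicates are few.  Differentially expressed genes (DEGs) are called
with strict volcano thresholds |log2FC| > 1 and p < 0.05 on raw
p-values.
"""

from __future__ import annotations

import logging
import math

import numpy as np
import pandas as pd
from scipy import special, stats

from .containers import ExpressionMatrix

logger = logging.getLogger(__name__)

LFC_THRESHOLD = 1.0
P_THRESHOLD = 0.05

SIGNATURE_COLUMNS = ("log2fc", "t", "p", "deg_call")


class DegenerateVarianceError(ValueError):
    """Raised when every gene has zero variance and no prior is available."""


def _trigamma_inverse(y: float) -> float:
    """Solve trigamma(x) = y for x > 0 by damped Newton iteration."""
    if y <= 0:
        return math.inf
    if y > 1e7:
        return 1.0 / math.sqrt(y)
    x = 0.5 + 1.0 / y
    for _ in range(50):
        tri = special.polygamma(1, x)
        dif = tri * (1.0 - tri / y) / special.polygamma(2, x)
        x += dif
        if x <= 0:
            x = 1e-8
        if abs(dif) < 1e-10 * x:
            break
    return float(x)


def fit_variance_prior(s2: np.ndarray, df: float) -> tuple[float, float]:
    """Fit (d0, s0^2) of the scaled-F model by moments of log s_g^2.

    Zero variances are excluded from the fit.  Returns ``d0 = 0`` (no
    moderation) when fewer than two positive variances are available,
    and ``d0 = inf`` (complete shrinkage to s0^2) when the observed
    spread of log-variances is no larger than its sampling expectation.
    """
    s2 = np.asarray(s2, dtype=float)
    pos = s2[s2 > 0]
    if pos.size < 2:
        logger.warning("variance-prior fit needs >=2 positive variances; using ordinary t")
        return 0.0, float(np.mean(pos)) if pos.size else 0.0
    z = np.log(pos)
    e = z - special.digamma(df / 2.0) + math.log(df / 2.0)
    emean = float(np.mean(e))
    evar = float(np.var(e, ddof=1)) - float(special.polygamma(1, df / 2.0))
    if evar <= 0:
        s0_2 = math.exp(emean)
        return math.inf, s0_2
    d0 = 2.0 * _trigamma_inverse(evar)
    s0_2 = math.exp(emean + special.digamma(d0 / 2.0) - math.log(d0 / 2.0))
    return d0, s0_2


def _deg_calls(log2fc: np.ndarray, p: np.ndarray) -> np.ndarray:
    call = np.full(log2fc.shape, "none", dtype=object)
    call[(log2fc > LFC_THRESHOLD) & (p < P_THRESHOLD)] = "up"
    call[(log2fc < -LFC_THRESHOLD) & (p < P_THRESHOLD)] = "down"
    return call


def moderated_t_signature(
    mat: ExpressionMatrix,
    group_a: str = "treated",
    group_b: str = "control",
    prior_df: float | None = None,
) -> pd.DataFrame:
    """Per-gene log2FC, moderated t and two-sided p for group_a vs group_b.

    Parameters
    ----------
    prior_df
        Override the fitted prior df ``d0``; ``0`` gives the ordinary
        pooled-variance two-sample t.

    Returns a DataFrame indexed by gene with columns ``log2fc``, ``t``,
    ``p``, ``deg_call``.
    """
    groups = set(mat.sample_meta["group"])
    for g in (group_a, group_b):
        if g not in groups:
            raise ValueError(f"unknown group label {g!r}; available: {sorted(groups)}")
    a_ids = mat.samples_in_group(group_a)
    b_ids = mat.samples_in_group(group_b)
    if len(a_ids) < 2 or len(b_ids) < 2:
        raise ValueError("need >=2 samples per group")
    A = mat.values[a_ids].to_numpy(dtype=float)
    B = mat.values[b_ids].to_numpy(dtype=float)
    n_a, n_b = A.shape[1], B.shape[1]
    log2fc = A.mean(axis=1) - B.mean(axis=1)
    d_g = n_a + n_b - 2
    ss = A.var(axis=1, ddof=1) * (n_a - 1) + B.var(axis=1, ddof=1) * (n_b - 1)
    s2 = ss / d_g
    c = math.sqrt(1.0 / n_a + 1.0 / n_b)

    if prior_df is None:
        d0, s0_2 = fit_variance_prior(s2, d_g)
    else:
        d0 = float(prior_df)
        _, s0_2 = fit_variance_prior(s2, d_g) if d0 > 0 else (0.0, 0.0)

    if d0 == 0 and not np.any(s2 > 0):
        raise DegenerateVarianceError(
            "all genes have zero variance and the prior df is 0; t undefined"
        )

    if math.isinf(d0):
        s2_post = np.full_like(s2, s0_2)
        df_total = math.inf
    else:
        s2_post = (d0 * s0_2 + d_g * s2) / (d0 + d_g)
        df_total = d0 + d_g

    with np.errstate(divide="ignore", invalid="ignore"):
        t = log2fc / (np.sqrt(s2_post) * c)
    t = np.where(np.isnan(t), 0.0, t)  # 0/0 -> no evidence
    if math.isinf(df_total):
        p = 2.0 * stats.norm.sf(np.abs(t))
    else:
        p = 2.0 * stats.t.sf(np.abs(t), df_total)
    p = np.clip(p, np.finfo(float).tiny, 1.0)

    return pd.DataFrame(
        {"log2fc": log2fc, "t": t, "p": p, "deg_call": _deg_calls(log2fc, p)},
        index=mat.gene_ids.copy(),
    )


def call_degs(sig: pd.DataFrame) -> tuple[int, int]:
    """Counts of (up, down) DEGs under the strict volcano thresholds."""
    for col in SIGNATURE_COLUMNS[:3]:
        if col not in sig.columns:
            raise ValueError(f"signature missing column {col!r}")
    call = _deg_calls(sig["log2fc"].to_numpy(float), sig["p"].to_numpy(float))
    return int(np.sum(call == "up")), int(np.sum(call == "down"))


def map_orthologs(
    sig: pd.DataFrame,
    ortholog_map: pd.DataFrame,
    ambiguity: str = "drop",
) -> pd.DataFrame:
    """Project a gene-indexed table into the ortholog target namespace.

    Genes without a partner in the map are eliminated.  Ambiguous
    mappings (a source with several targets, or several sources sharing
    one target) are dropped under the default policy, or resolved to the
    first listed pair with ``ambiguity="first"``.  Statistics carry over
    unchanged.
    """
    if ortholog_map.empty:
        raise ValueError("empty ortholog map")
    if ambiguity not in ("drop", "first"):
        raise ValueError(f"unknown ambiguity policy {ambiguity!r}")
    m = ortholog_map.drop_duplicates()
    if ambiguity == "drop":
        m = m[~m["source"].duplicated(keep=False)]
        m = m[~m["target"].duplicated(keep=False)]
    else:
        m = m.drop_duplicates(subset="source", keep="first")
        m = m.drop_duplicates(subset="target", keep="first")
    lut = dict(zip(m["source"], m["target"]))
    keep = [g for g in sig.index if g in lut]
    out = sig.loc[keep].copy()
    out.index = pd.Index([lut[g] for g in keep], name=sig.index.name)
    return out


def batch_adjust(mat: ExpressionMatrix) -> ExpressionMatrix:
    """Location-scale batch adjustment toward pooled per-gene moments.

    Per gene, each batch is standardized by its own mean and SD, then
    rescaled to the pooled (all-sample) mean and SD — a ComBat-style
    correction without empirical-Bayes shrinkage of the batch
    parameters.  After adjustment the per-gene batch means coincide.
    Batches with zero variance for a gene are shifted only.
    """
    batches = mat.sample_meta["batch"]
    labels = sorted(batches.unique())
    if len(labels) < 2:
        raise ValueError("batch adjustment needs >=2 batches")
    counts = batches.value_counts()
    small = counts[counts < 2]
    if not small.empty:
        raise ValueError(f"single-sample batch(es): {sorted(small.index)}; cannot estimate scale")
    X = mat.values.to_numpy(dtype=float)
    pooled_mean = X.mean(axis=1)
    pooled_sd = X.std(axis=1, ddof=1)
    out = X.copy()
    for label in labels:
        cols = (batches == label).to_numpy()
        sub = X[:, cols]
        mu = sub.mean(axis=1)
        sd = sub.std(axis=1, ddof=1)
        z = np.where(sd[:, None] > 0, (sub - mu[:, None]) / np.where(sd == 0, 1.0, sd)[:, None],
                     sub - mu[:, None])
        out[:, cols] = pooled_mean[:, None] + pooled_sd[:, None] * z
    values = pd.DataFrame(out, index=mat.gene_ids.copy(), columns=mat.sample_ids.copy())
    return ExpressionMatrix(values, mat.sample_meta.copy())


def combine_replicate_signatures(signatures: list[pd.DataFrame]) -> pd.DataFrame:
    """Summarize replicate signatures into one via a one-sample moderated t.

    The per-replicate log2 fold-changes are treated as repeated
    measurements per gene; the combined statistic is the moderated
    one-sample t of their mean against zero (the multi-sample mode
    consumed by master-regulator scoring).  Only genes present in every
    replicate are kept.
    """
    if len(signatures) < 2:
        raise ValueError("need >=2 replicate signatures to combine")
    common = signatures[0].index
    for sig in signatures[1:]:
        common = common.intersection(sig.index)
    if common.empty:
        raise ValueError("replicate signatures share no genes")
    stack = np.column_stack([sig.loc[common, "log2fc"].to_numpy(float) for sig in signatures])
    k = stack.shape[1]
    mean = stack.mean(axis=1)
    s2 = stack.var(axis=1, ddof=1)
    d_g = k - 1
    d0, s0_2 = fit_variance_prior(s2, d_g)
    if math.isinf(d0):
        s2_post = np.full_like(s2, s0_2)
        df_total = math.inf
    else:
        s2_post = (d0 * s0_2 + d_g * s2) / (d0 + d_g)
        df_total = d0 + d_g
    with np.errstate(divide="ignore", invalid="ignore"):
        t = mean / np.sqrt(s2_post / k)
    t = np.where(np.isnan(t), 0.0, t)
    if math.isinf(df_total):
        p = 2.0 * stats.norm.sf(np.abs(t))
    else:
        p = 2.0 * stats.t.sf(np.abs(t), df_total)
    p = np.clip(p, np.finfo(float).tiny, 1.0)
    return pd.DataFrame(
        {"log2fc": mean, "t": t, "p": p, "deg_call": _deg_calls(mean, p)}, index=common.copy()
    )
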