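"""Master-regulator scoring: aREA-style regulon enrichment (msVIPER).

A signature (per-gene t-statistic) is rank-transformed onto normal
quantile grids: a one-tail quantile ``q2 = Phi^-1((rank(s) - 0.5)/N)``
capturing direction, and a two-tail quantile ``q1 = Phi^-1(0.5 +
(rank(|s|) - 0.5)/(2N))`` capturing magnitude only.  Each regulon
target contributes

    x_t = mor_t * q2_t + (1 - |mor_t|) * q1_t,

so fully signed targets use the directional quantile and unsigned
targets the magnitude quantile.  The enrichment score is the
likelihood-weighted mean of ``x_t`` and the normalized score

    NES = ES * sum(w) / sqrt(sum(w^2))

is approximately standard normal when targets are drawn at random from
the signature, giving analytic two-sided p-values; a gene-permutation
null is available as a check for small regulons.  A TF is called a
master regulon when its (raw) p-value falls below the threshold
(default 0.01).
"""

from __future__ import annotations

import logging
import math

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .containers import Regulon
from .signature import combine_replicate_signatures

logger = logging.getLogger(__name__)

DEFAULT_MASTER_P = 0.01
DEFAULT_MIN_TARGETS = 10

ACTIVITY_COLUMNS = ("tf", "es", "nes", "p", "fdr", "direction", "master_call", "n_targets_used")


def rank_transform(sig: pd.DataFrame | pd.Series) -> pd.DataFrame:
    """Normal-quantile rank transform of a signature.

    Accepts a signature DataFrame (uses its ``t`` column) or a Series of
    per-gene scores.  Ties receive average ranks.  Returns a DataFrame
    indexed by gene with columns ``s``, ``q1`` (two-tail, >= 0) and
    ``q2`` (one-tail, signed).
    """
    if isinstance(sig, pd.DataFrame):
        if "t" not in sig.columns:
            raise ValueError("signature DataFrame must carry a 't' column")
        s = sig["t"].astype(float)
    else:
        s = sig.astype(float)
    if len(s) < 2:
        raise ValueError("need >=2 genes")
    values = s.to_numpy()
    if np.allclose(values, values[0]):
        raise ValueError("degenerate signature: all scores identical")
    n = len(values)
    r2 = stats.rankdata(values, method="average")
    q2 = stats.norm.ppf((r2 - 0.5) / n)
    r1 = stats.rankdata(np.abs(values), method="average")
    q1 = stats.norm.ppf(0.5 + (r1 - 0.5) / (2.0 * n))
    return pd.DataFrame({"s": values, "q1": q1, "q2": q2}, index=s.index.copy())


def area_score(
    regulon: Regulon,
    rsig: pd.DataFrame,
    min_targets: int = DEFAULT_MIN_TARGETS,
) -> tuple[float, float, int]:
    """Enrichment score and NES of one regulon against a ranked signature.

    Targets absent from the signature are dropped (logged); fewer than
    ``min_targets`` remaining raises ``ValueError``.
    Returns ``(es, nes, n_targets_used)``.
    """
    present = regulon.targets.index.intersection(rsig.index)
    n_dropped = regulon.size - len(present)
    if n_dropped:
        logger.info("regulon %s: %d targets absent from signature", regulon.tf, n_dropped)
    if len(present) < min_targets:
        raise ValueError(
            f"regulon {regulon.tf}: only {len(present)} targets overlap the signature "
            f"(< {min_targets})"
        )
    tab = regulon.targets.loc[present]
    mor = tab["mor"].to_numpy(dtype=float)
    w = tab["likelihood"].to_numpy(dtype=float)
    q1 = rsig.loc[present, "q1"].to_numpy(dtype=float)
    q2 = rsig.loc[present, "q2"].to_numpy(dtype=float)
    x = mor * q2 + (1.0 - np.abs(mor)) * q1
    sw = float(np.sum(w))
    es = float(np.sum(w * x) / sw)
    nes = es * sw / math.sqrt(float(np.sum(w**2)))
    return es, nes, int(len(present))


def nes_pvalue(
    nes: float,
    null_model: str = "analytic",
    regulon: Regulon | None = None,
    rsig: pd.DataFrame | None = None,
    n_perm: int = 1000,
    seed: int | None = None,
    min_targets: int = DEFAULT_MIN_TARGETS,
) -> float:
    """Two-sided p-value of a NES.

    ``analytic``: standard-normal tail ``2 * (1 - Phi(|NES|))``.
    ``permutation``: shuffle the gene labels of the ranked signature
    ``n_perm`` times (requires ``regulon``, ``rsig`` and ``seed``) and
    report ``(1 + #{|NES_perm| >= |NES|}) / (1 + n_perm)``.
    """
    if null_model == "analytic":
        return float(2.0 * stats.norm.sf(abs(nes)))
    if null_model != "permutation":
        raise ValueError(f"unknown null model {null_model!r}")
    if regulon is None or rsig is None:
        raise ValueError("permutation null requires the regulon and ranked signature")
    if n_perm < 100:
        raise ValueError("permutation null requires n_perm >= 100")
    if seed is None:
        raise ValueError("permutation null requires a seed")
    rng = np.random.default_rng(seed)
    present = regulon.targets.index.intersection(rsig.index)
    if len(present) < min_targets:
        raise ValueError(f"regulon {regulon.tf}: insufficient signature overlap")
    tab = regulon.targets.loc[present]
    mor = tab["mor"].to_numpy(dtype=float)
    w = tab["likelihood"].to_numpy(dtype=float)
    q1 = rsig["q1"].to_numpy(dtype=float)
    q2 = rsig["q2"].to_numpy(dtype=float)
    norm = math.sqrt(float(np.sum(w**2)))
    k, n_genes = len(present), len(rsig)
    count = 0
    # shuffling gene labels == assigning k distinct random genes to the targets
    for _ in range(n_perm):
        idx = rng.choice(n_genes, size=k, replace=False)
        x = mor * q2[idx] + (1.0 - np.abs(mor)) * q1[idx]
        if abs(float(np.sum(w * x)) / norm) >= abs(nes):
            count += 1
    return (1.0 + count) / (1.0 + n_perm)


def msviper(
    signatures: pd.DataFrame | list[pd.DataFrame],
    regulons: list[Regulon],
    master_p_threshold: float = DEFAULT_MASTER_P,
    null_model: str = "analytic",
    min_targets: int = DEFAULT_MIN_TARGETS,
    n_perm: int = 1000,
    seed: int | None = None,
) -> pd.DataFrame:
    """Score every regulon against a (possibly replicated) signature.

    A list of replicate signatures is first summarized by the per-gene
    moderated t across replicates.  Returns a DataFrame sorted by NES
    descending with columns ``tf``, ``es``, ``nes``, ``p``, ``fdr``
    (BH), ``direction`` and ``master_call`` (raw p below the threshold).
    TFs with insufficient signature overlap are skipped with a logged
    reason.
    """
    if not regulons:
        raise ValueError("no regulons given")
    if isinstance(signatures, list):
        sig = signatures[0] if len(signatures) == 1 else combine_replicate_signatures(signatures)
    else:
        sig = signatures
    rsig = rank_transform(sig)
    sig_genes = set(rsig.index)
    all_targets = set()
    for reg in regulons:
        all_targets.update(reg.targets.index)
    if not (all_targets & sig_genes):
        raise ValueError(
            "signature and regulon namespaces are disjoint: signature IDs look like "
            f"{sorted(sig_genes)[:3]}, regulon target IDs like {sorted(all_targets)[:3]}"
        )
    rows = []
    for reg in regulons:
        try:
            es, nes, n_used = area_score(reg, rsig, min_targets=min_targets)
        except ValueError as exc:
            logger.warning("skipping TF %s: %s", reg.tf, exc)
            continue
        p = nes_pvalue(
            nes,
            null_model=null_model,
            regulon=reg,
            rsig=rsig,
            n_perm=n_perm,
            seed=seed,
            min_targets=min_targets,
        )
        rows.append((reg.tf, es, nes, p, nes > 0, n_used))
    if not rows:
        raise ValueError("no regulon had sufficient overlap with the signature")
    out = pd.DataFrame(rows, columns=["tf", "es", "nes", "p", "_act", "n_targets_used"])
    out["fdr"] = multipletests(out["p"].to_numpy(), method="fdr_bh")[1]
    out["direction"] = np.where(out["_act"], "activated", "repressed")
    out["master_call"] = out["p"] < master_p_threshold
    out = out.sort_values("nes", ascending=False, kind="mergesort").reset_index(drop=True)
    return out[list(ACTIVITY_COLUMNS)]
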