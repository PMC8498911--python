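"""Meta-network: Stouffer combination of per-cohort edges and regulons.

Per-cohort edge p-values are turned into signed Z-scores,
``Z = sign(r) * Phi^-1(1 - p/2)``, and combined across cohorts with
sample-size weights ``w_i = sqrt(n_i)``:

    Z_meta = sum_i w_i Z_i / sqrt(sum_i w_i^2).

Edges whose correlation sign disagrees between cohorts are discarded by
a coherence filter; retained edges (coherent and |Z_meta| above a
threshold) are grouped per TF into regulons with a bounded mode of
regulation ``mor = tanh(Z_meta / z_scale)`` and a confidence weight
``likelihood = |Z_meta| / max |Z_meta|`` within the regulon.
"""

from __future__ import annotations

import logging
import math

import numpy as np
import pandas as pd
from scipy import stats

from .containers import Regulon

logger = logging.getLogger(__name__)

DEFAULT_Z_THRESHOLD = float(stats.norm.ppf(1.0 - 0.025))  # two-sided 5% retention cut
DEFAULT_Z_SCALE = 3.0
DEFAULT_MIN_REGULON_SIZE = 10

META_COLUMNS = (
    "tf",
    "target",
    "z_combined",
    "n_cohorts_observed",
    "n_cohorts_significant",
    "coherent",
    "retained",
)


def signed_z(p, r_partial) -> np.ndarray:
    """Signed Z-score of a two-sided p-value: sign(r) * Phi^-1(1 - p/2)."""
    p = np.asarray(p, dtype=float)
    r = np.asarray(r_partial, dtype=float)
    if np.any(p > 1) or np.any(p < 0):
        raise ValueError("p-values must lie in [0, 1]")
    if np.any(p == 0):
        logger.warning("p = 0 clamped to the smallest positive float")
        p = np.maximum(p, np.finfo(float).tiny)
    z = stats.norm.isf(p / 2.0)
    return np.sign(r) * z


def stouffer_combine(z_list, n_list) -> float:
    """Sample-size-weighted Stouffer combination with w_i = sqrt(n_i)."""
    z = np.asarray(z_list, dtype=float)
    n = np.asarray(n_list, dtype=float)
    if z.size == 0 or z.shape != n.shape:
        raise ValueError("z_list and n_list must be equal-length and non-empty")
    if np.any(n < 3):
        raise ValueError("every cohort size must be >= 3")
    w = np.sqrt(n)
    return float(np.sum(w * z) / math.sqrt(float(np.sum(w**2))))


def combine_edge_tables(edge_tables: list[pd.DataFrame]) -> pd.DataFrame:
    """Combine per-cohort edge tables into a raw meta-edge table.

    Each (tf, target) pair observed in at least one cohort receives the
    weighted Z over the cohorts where it was observed, plus bookkeeping
    counts.  Coherence/retention flags are added by
    :func:`coherence_filter`.
    """
    if not edge_tables:
        raise ValueError("no edge tables given")
    stacked = pd.concat(edge_tables, ignore_index=True)
    required = {"cohort", "n_samples", "tf", "target", "r_partial", "p", "significant"}
    missing = required - set(stacked.columns)
    if missing:
        raise ValueError(f"edge tables missing columns: {sorted(missing)}")
    if np.any(stacked["n_samples"].to_numpy(dtype=float) < 3):
        raise ValueError("every cohort size must be >= 3")
    stacked = stacked.copy()
    stacked["z"] = signed_z(stacked["p"].to_numpy(), stacked["r_partial"].to_numpy())
    w = np.sqrt(stacked["n_samples"].to_numpy(dtype=float))
    stacked["_wz"] = w * stacked["z"].to_numpy()
    stacked["_w2"] = w**2
    stacked["_sig"] = stacked["significant"].astype(int)
    agg = stacked.groupby(["tf", "target"], sort=True).agg(
        _wz=("_wz", "sum"), _w2=("_w2", "sum"), n_cohorts_observed=("z", "size"),
        n_cohorts_significant=("_sig", "sum"),
    )
    agg["z_combined"] = agg["_wz"] / np.sqrt(agg["_w2"])
    out = agg.reset_index()[
        ["tf", "target", "z_combined", "n_cohorts_observed", "n_cohorts_significant"]
    ]
    out["n_cohorts_observed"] = out["n_cohorts_observed"].astype(int)
    out["n_cohorts_significant"] = out["n_cohorts_significant"].astype(int)
    return out


def coherence_filter(
    meta: pd.DataFrame,
    edge_tables: list[pd.DataFrame],
    z_threshold: float = DEFAULT_Z_THRESHOLD,
    mode: str = "significant-only",
) -> pd.DataFrame:
    """Flag cross-cohort sign coherence and retention.

    ``mode="significant-only"`` (default): an edge is coherent when its
    correlation sign agrees across all cohorts in which it passed
    per-cohort significance; cohorts where it was absent or
    non-significant do not veto.  ``mode="strict"``: signs must agree
    across every cohort in which the edge was observed at all.
    ``retained = coherent and n_cohorts_significant >= 1 and
    |z_combined| >= z_threshold`` — every retained edge must trace back
    to at least one cohort where its partial correlation passed the
    per-cohort FDR, so the combined network never contains edges built
    purely from sub-threshold evidence.
    """
    if mode not in ("significant-only", "strict"):
        raise ValueError(f"unknown coherence mode {mode!r}")
    stacked = pd.concat(edge_tables, ignore_index=True)
    if mode == "significant-only":
        pool = stacked[stacked["significant"].astype(bool)]
    else:
        pool = stacked
    sign = np.sign(pool["r_partial"].to_numpy(dtype=float))
    agg = (
        pool.assign(_sign=sign)
        .groupby(["tf", "target"], sort=False)["_sign"]
        .agg(["min", "max"])
    )
    incoherent = set(agg.index[(agg["min"] < 0) & (agg["max"] > 0)])
    out = meta.copy()
    keys = list(zip(out["tf"], out["target"]))
    out["coherent"] = [k not in incoherent for k in keys]
    out["retained"] = (
        out["coherent"]
        & (out["n_cohorts_significant"] >= 1)
        & (out["z_combined"].abs() >= z_threshold)
    )
    return out[list(META_COLUMNS)]


def build_meta_network(
    edge_tables: list[pd.DataFrame],
    z_threshold: float = DEFAULT_Z_THRESHOLD,
    coherence: str = "significant-only",
) -> pd.DataFrame:
    """Combine cohort edge tables and apply the coherence filter."""
    meta = combine_edge_tables(edge_tables)
    return coherence_filter(meta, edge_tables, z_threshold=z_threshold, mode=coherence)


def build_regulons(
    meta: pd.DataFrame,
    min_regulon_size: int = DEFAULT_MIN_REGULON_SIZE,
    z_scale: float = DEFAULT_Z_SCALE,
) -> list[Regulon]:
    """Regulons from retained meta-edges.

    ``mor = tanh(z_combined / z_scale)`` bounds the mode of regulation
    in (-1, 1); ``likelihood`` normalizes |z_combined| to (0, 1] within
    each regulon.  TFs with fewer than ``min_regulon_size`` retained
    targets are dropped and logged.
    """
    kept = meta[meta["retained"].astype(bool)]
    if kept.empty:
        raise ValueError("no retained meta-edges; cannot build regulons")
    regulons: list[Regulon] = []
    for tf, grp in kept.groupby("tf", sort=True):
        grp = grp[grp["target"] != tf]
        if len(grp) < min_regulon_size:
            logger.info("dropping TF %s: %d retained targets < %d", tf, len(grp), min_regulon_size)
            continue
        z = grp["z_combined"].to_numpy(dtype=float)
        mor = np.tanh(z / z_scale)
        likelihood = np.abs(z) / np.max(np.abs(z))
        tab = pd.DataFrame(
            {"mor": mor, "likelihood": likelihood},
            index=pd.Index(grp["target"].to_numpy(), name="target"),
        )
        regulons.append(Regulon(tf=str(tf), targets=tab))
    if not regulons:
        raise ValueError(
            f"no TF retained >= {min_regulon_size} targets; relax thresholds or check inputs"
        )
    return regulons
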