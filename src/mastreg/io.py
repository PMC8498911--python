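"""Plain-text (TSV) readers and writers for every pipeline table.

All tables are tab-separated with a header row so that each stage can be
re-run independently from files on disk.  Dialects:

- expression: first column ``gene``, remaining columns are sample IDs
- sample metadata: columns ``sample``, ``group``, ``batch``, ``cohort``
- signature: ``gene``, ``log2fc``, ``t``, ``p``, ``deg_call``
- edges (per cohort): ``cohort``, ``n_samples``, ``tf``, ``target``,
  ``r_partial``, ``p``, ``q``, ``significant``
- meta edges: ``tf``, ``target``, ``z_combined``, ``n_cohorts_observed``,
  ``n_cohorts_significant``, ``coherent``, ``retained``
- regulons: ``tf``, ``target``, ``mor``, ``likelihood``
- activity: ``tf``, ``es``, ``nes``, ``p``, ``fdr``, ``direction``,
  ``master_call``, ``n_targets_used``
- ortholog map: two headered columns (source, target)
- TF list: one identifier per line
- gene sets: GMT (name, description, genes...)
"""

from __future__ import annotations

import logging
from pathlib import Path

import pandas as pd

from .containers import ExpressionMatrix, Regulon

logger = logging.getLogger(__name__)

_FLOAT_FMT = "%.10g"


def read_expression(expr_path, meta_path=None) -> ExpressionMatrix:
    """Load an expression TSV (and optional sample-metadata TSV).

    Genes with any missing value are dropped and logged; the matrix must
    be fully observed downstream.
    """
    df = pd.read_csv(expr_path, sep="\t", index_col=0)
    df.index = df.index.astype(str)
    df.index.name = "gene"
    n_missing = int(df.isna().any(axis=1).sum())
    if n_missing:
        logger.warning("dropping %d genes with missing values from %s", n_missing, expr_path)
        df = df.dropna(axis=0)
    meta = None
    if meta_path is not None:
        meta = pd.read_csv(meta_path, sep="\t", index_col=0, dtype=str)
        meta.index = meta.index.astype(str)
    return ExpressionMatrix(df.astype(float), meta)


def write_expression(mat: ExpressionMatrix, expr_path, meta_path=None) -> None:
    out = mat.values.copy()
    out.index.name = "gene"
    out.to_csv(expr_path, sep="\t", float_format=_FLOAT_FMT)
    if meta_path is not None:
        meta = mat.sample_meta.copy()
        meta.index.name = "sample"
        meta.to_csv(meta_path, sep="\t")


def read_signature(path) -> pd.DataFrame:
    sig = pd.read_csv(path, sep="\t", index_col=0)
    sig.index = sig.index.astype(str)
    return sig


def write_signature(sig: pd.DataFrame, path) -> None:
    out = sig.copy()
    out.index.name = "gene"
    out.to_csv(path, sep="\t", float_format=_FLOAT_FMT)


def read_tf_list(path) -> list[str]:
    tfs = [line.strip() for line in Path(path).read_text().splitlines() if line.strip()]
    if not tfs:
        raise ValueError(f"empty TF list: {path}")
    return tfs


def write_tf_list(tfs, path) -> None:
    Path(path).write_text("\n".join(tfs) + "\n")


def read_ortholog_map(path) -> pd.DataFrame:
    m = pd.read_csv(path, sep="\t", dtype=str)
    if m.shape[1] != 2:
        raise ValueError(f"ortholog map must have exactly 2 columns, got {m.shape[1]}")
    m.columns = ["source", "target"]
    return m.dropna()


def read_edges(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", dtype={"tf": str, "target": str, "cohort": str})


def write_edges(edges: pd.DataFrame, path) -> None:
    edges.to_csv(path, sep="\t", index=False, float_format=_FLOAT_FMT)


def read_meta_edges(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", dtype={"tf": str, "target": str})


def write_meta_edges(meta: pd.DataFrame, path) -> None:
    meta.to_csv(path, sep="\t", index=False, float_format=_FLOAT_FMT)


def read_regulons(path) -> list[Regulon]:
    df = pd.read_csv(path, sep="\t", dtype={"tf": str, "target": str})
    regs = []
    for tf, grp in df.groupby("tf", sort=True):
        tab = grp.set_index("target")[["mor", "likelihood"]].astype(float)
        regs.append(Regulon(tf=str(tf), targets=tab))
    return regs


def write_regulons(regulons, path) -> None:
    rows = []
    for reg in regulons:
        for target, row in reg.targets.iterrows():
            rows.append((reg.tf, target, row["mor"], row["likelihood"]))
    pd.DataFrame(rows, columns=["tf", "target", "mor", "likelihood"]).to_csv(
        path, sep="\t", index=False, float_format=_FLOAT_FMT
    )


def read_activity(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", dtype={"tf": str})


def write_activity(act: pd.DataFrame, path) -> None:
    act.to_csv(path, sep="\t", index=False, float_format=_FLOAT_FMT)


def read_gmt(path) -> dict[str, set[str]]:
    """Read a GMT gene-set collection: name, description, genes..."""
    sets: dict[str, set[str]] = {}
    for line in Path(path).read_text().splitlines():
        if not line.strip():
            continue
        parts = line.rstrip("\n").split("\t")
        if len(parts) < 3:
            raise ValueError(f"malformed GMT row (need name, description, >=1 gene): {line[:60]}")
        name = parts[0]
        if name in sets:
            raise ValueError(f"duplicate gene-set name: {name}")
        genes = {g for g in parts[2:] if g}
        if not genes:
            raise ValueError(f"empty gene set: {name}")
        sets[name] = genes
    return sets


def write_gmt(collection: dict[str, set[str]], path, descriptions=None) -> None:
    lines = []
    for name in collection:
        desc = (descriptions or {}).get(name, "na")
        lines.append("\t".join([name, desc, *sorted(collection[name])]))
    Path(path).write_text("\n".join(lines) + "\n")
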