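"""End-to-end orchestration: signature -> networks -> meta -> MRA -> structure.

A single YAML config drives the whole two-stage analysis.  Every
intermediate table is written in the module TSV dialects so each stage
can be re-run independently, and a machine-readable manifest records
parameters, seeds, package version and input checksums.  Outputs are a
pure function of (config, input files), so re-running a config
reproduces the run directory byte for byte.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import __version__, coexnet, io, metanet, mra, netstruct, signature as sigmod

logger = logging.getLogger(__name__)


class PipelineError(RuntimeError):
    """A stage failed; the message names the stage and offending input."""


@dataclass
class PipelineConfig:
    """Validated configuration for :func:`run_all`.

    ``signatures`` entries: name, expr, meta, group_a, group_b.
    ``cohorts`` entries: expr (and optional meta).  All stage
    parameters carry the module defaults.
    """

    signatures: list[dict]
    cohorts: list[dict]
    tf_list: str
    ortholog_map: str | None = None
    ortholog_ambiguity: str = "drop"
    batch_adjust: bool = False
    gmt: str | None = None
    fdr_threshold: float = 0.05
    z_threshold: float = metanet.DEFAULT_Z_THRESHOLD
    coherence: str = "significant-only"
    min_regulon_size: int = metanet.DEFAULT_MIN_REGULON_SIZE
    z_scale: float = metanet.DEFAULT_Z_SCALE
    master_p_threshold: float = mra.DEFAULT_MASTER_P
    min_targets: int = mra.DEFAULT_MIN_TARGETS
    null_model: str = "analytic"
    n_perm: int = 1000
    seed: int = 0
    weighted_communities: bool = False
    base_dir: Path = field(default_factory=Path)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        path = Path(path)
        raw = yaml.safe_load(path.read_text())
        known = {f for f in cls.__dataclass_fields__ if f != "base_dir"}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(base_dir=path.parent, **raw)

    def _resolve(self, p) -> Path:
        p = Path(p)
        return p if p.is_absolute() else self.base_dir / p

    def validate(self) -> None:
        if not self.signatures:
            raise ValueError("config needs >=1 signature entry")
        if not self.cohorts:
            raise ValueError("config needs >=1 cohort entry")
        for entry in self.signatures:
            for key in ("name", "expr", "meta"):
                if key not in entry:
                    raise ValueError(f"signature entry missing {key!r}: {entry}")
        paths = [self.tf_list]
        paths += [e["expr"] for e in self.signatures] + [e["meta"] for e in self.signatures]
        paths += [e["expr"] for e in self.cohorts]
        paths += [e["meta"] for e in self.cohorts if e.get("meta")]
        if self.ortholog_map:
            paths.append(self.ortholog_map)
        if self.gmt:
            paths.append(self.gmt)
        for p in paths:
            if not self._resolve(p).exists():
                raise FileNotFoundError(f"config references missing path: {p}")
        if not 0 < self.fdr_threshold < 1:
            raise ValueError("fdr_threshold must lie in (0, 1)")
        if not 0 < self.master_p_threshold < 1:
            raise ValueError("master_p_threshold must lie in (0, 1)")
        if self.z_threshold < 0:
            raise ValueError("z_threshold must be >= 0")
        if self.coherence not in ("significant-only", "strict"):
            raise ValueError(f"unknown coherence mode {self.coherence!r}")
        if self.null_model not in ("analytic", "permutation"):
            raise ValueError(f"unknown null model {self.null_model!r}")


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def intersect_masters(results: dict[str, pd.DataFrame]) -> pd.DataFrame:
    """TFs called master regulons in every signature's activity table.

    Returns one row per shared TF with per-signature NES and direction
    columns (``nes_<name>``, ``direction_<name>``), sorted by the mean
    NES descending.
    """
    if len(results) < 2:
        raise ValueError("need >=2 activity tables to intersect")
    master_sets = []
    for name, tab in results.items():
        master_sets.append(set(tab.loc[tab["master_call"].astype(bool), "tf"]))
    shared = sorted(set.intersection(*master_sets)) if master_sets else []
    rows = []
    for tf in shared:
        row: dict = {"tf": tf}
        for name, tab in results.items():
            sub = tab[tab["tf"] == tf].iloc[0]
            row[f"nes_{name}"] = float(sub["nes"])
            row[f"direction_{name}"] = sub["direction"]
        rows.append(row)
    out = pd.DataFrame(rows)
    if not out.empty:
        nes_cols = [c for c in out.columns if c.startswith("nes_")]
        out = out.iloc[out[nes_cols].mean(axis=1).to_numpy().argsort()[::-1]]
        out = out.reset_index(drop=True)
    return out


def _stage(name: str, detail: str = ""):
    def wrap(exc: Exception) -> PipelineError:
        suffix = f" ({detail})" if detail else ""
        return PipelineError(f"stage {name!r} failed{suffix}: {exc}")

    return wrap


def run_all(config: PipelineConfig, outdir) -> Path:
    """Execute the full two-stage analysis and write a run directory."""
    config.validate()
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    tf_list = io.read_tf_list(config._resolve(config.tf_list))
    ortho = (
        io.read_ortholog_map(config._resolve(config.ortholog_map))
        if config.ortholog_map
        else None
    )

    # --- signatures -------------------------------------------------
    signatures: dict[str, pd.DataFrame] = {}
    for entry in config.signatures:
        name = entry["name"]
        try:
            mat = io.read_expression(
                config._resolve(entry["expr"]), config._resolve(entry["meta"])
            )
            if config.batch_adjust and mat.sample_meta["batch"].nunique() > 1:
                mat = sigmod.batch_adjust(mat)
            sig = sigmod.moderated_t_signature(
                mat, entry.get("group_a", "treated"), entry.get("group_b", "control")
            )
            if ortho is not None:
                sig = sigmod.map_orthologs(sig, ortho, ambiguity=config.ortholog_ambiguity)
            io.write_signature(sig, outdir / f"signature_{name}.tsv")
            signatures[name] = sig
        except Exception as exc:  # noqa: BLE001 - rewrap with stage context
            raise _stage("signature", entry["expr"])(exc) from exc

    # --- per-cohort networks ----------------------------------------
    edge_tables = []
    fits = {}
    for idx, entry in enumerate(config.cohorts, start=1):
        try:
            mat = io.read_expression(
                config._resolve(entry["expr"]),
                config._resolve(entry["meta"]) if entry.get("meta") else None,
            )
            if config.batch_adjust and mat.sample_meta["batch"].nunique() > 1:
                mat = sigmod.batch_adjust(mat)
            edges, fit = coexnet.infer_network(
                mat, tf_list, fdr_threshold=config.fdr_threshold, cohort_id=f"cohort{idx}"
            )
            io.write_edges(edges, outdir / f"edges_cohort{idx}.tsv")
            edge_tables.append(edges)
            fits[f"cohort{idx}"] = {
                "lambda_star": fit.lambda_star,
                "kappa": fit.kappa,
                "eta0": fit.eta0,
                "n_samples": int(mat.n_samples),
            }
        except Exception as exc:  # noqa: BLE001
            raise _stage("coexnet", entry["expr"])(exc) from exc

    # --- meta-network and regulons ----------------------------------
    try:
        meta = metanet.build_meta_network(
            edge_tables, z_threshold=config.z_threshold, coherence=config.coherence
        )
        io.write_meta_edges(meta, outdir / "meta_edges.tsv")
        regulons = metanet.build_regulons(
            meta, min_regulon_size=config.min_regulon_size, z_scale=config.z_scale
        )
        io.write_regulons(regulons, outdir / "regulons.tsv")
    except Exception as exc:  # noqa: BLE001
        raise _stage("metanet")(exc) from exc

    # --- master-regulator scoring -----------------------------------
    activities: dict[str, pd.DataFrame] = {}
    for name, sig in signatures.items():
        try:
            act = mra.msviper(
                sig,
                regulons,
                master_p_threshold=config.master_p_threshold,
                null_model=config.null_model,
                min_targets=config.min_targets,
                n_perm=config.n_perm,
                seed=config.seed,
            )
            io.write_activity(act, outdir / f"activity_{name}.tsv")
            activities[name] = act
        except Exception as exc:  # noqa: BLE001
            raise _stage("mra", name)(exc) from exc

    if len(activities) >= 2:
        shared = intersect_masters(activities)
        shared.to_csv(outdir / "shared_masters.tsv", sep="\t", index=False,
                      float_format="%.10g")

    # --- network structure ------------------------------------------
    try:
        master_tfs = set().union(
            *(set(a.loc[a["master_call"].astype(bool), "tf"]) for a in activities.values())
        )
        master_regs = [r for r in regulons if r.tf in master_tfs] or regulons
        graph = netstruct.build_graph(
            master_regs, meta=meta, weighted=config.weighted_communities
        )
        partition, q = netstruct.greedy_communities(
            graph, weighted=config.weighted_communities
        )
        part_df = partition.rename_axis("node").reset_index()
        part_df.to_csv(outdir / "communities.tsv", sep="\t", index=False)
        enrichment = None
        if config.gmt:
            collection = io.read_gmt(config._resolve(config.gmt))
            enrichment = netstruct.enrich_communities(partition, collection)
            enrichment.to_csv(outdir / "enrichment.tsv", sep="\t", index=False,
                              float_format="%.10g")
    except Exception as exc:  # noqa: BLE001
        raise _stage("netstruct")(exc) from exc

    # --- manifest ----------------------------------------------------
    input_paths = sorted(
        {
            str(config._resolve(p))
            for p in (
                [config.tf_list]
                + [e["expr"] for e in config.signatures]
                + [e["meta"] for e in config.signatures]
                + [e["expr"] for e in config.cohorts]
                + [e["meta"] for e in config.cohorts if e.get("meta")]
                + ([config.ortholog_map] if config.ortholog_map else [])
                + ([config.gmt] if config.gmt else [])
            )
        }
    )
    manifest = {
        "package": "mastreg",
        "version": __version__,
        "parameters": {
            "fdr_threshold": config.fdr_threshold,
            "z_threshold": config.z_threshold,
            "coherence": config.coherence,
            "min_regulon_size": config.min_regulon_size,
            "z_scale": config.z_scale,
            "master_p_threshold": config.master_p_threshold,
            "min_targets": config.min_targets,
            "null_model": config.null_model,
            "n_perm": config.n_perm,
            "batch_adjust": config.batch_adjust,
            "ortholog_ambiguity": config.ortholog_ambiguity,
            "weighted_communities": config.weighted_communities,
        },
        "seed": config.seed,
        "network_fits": fits,
        "modularity_q": q,
        "n_communities": int(partition.nunique()),
        "inputs": {p: _sha256(Path(p)) for p in input_paths},
    }
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
    return outdir
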