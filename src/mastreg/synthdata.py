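"""Synthetic multi-cohort expression data with planted TF regulons.

The generator follows a linear-Gaussian latent-activity factor model:
each transcription factor (TF) carries a latent per-sample activity
``a_s``; each of its targets responds linearly, ``x_gs = baseline +
sum_TF a_s(TF) * mor * strength + eps`` with Gaussian noise.  Under
"treatment" the activity of selected TFs is shifted by an effect size
``delta``, which moves target expression without moving the TF's own
transcript — mirroring post-transcriptionally activated regulators whose
mRNA stays flat while their regulon responds.  Cohort matrices draw
activities independently per sample so TF-target coexpression exists,
and the TF transcript is included as a noisy readout of its activity
(correlation ``r_tf``).  Additive per-(batch, gene) offsets emulate
platform/batch structure.

Every quantity is a pure function of ``(config, truth, seed)``;
per-cohort RNG substreams are spawned deterministically from the single
seed so output is bit-reproducible.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .containers import GROUP_CONTROL, GROUP_TREATED, GROUP_UNLABELED, ExpressionMatrix

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class SimConfig:
    """Study-design parameters for the synthetic generator.

    Defaults describe a compact study: 300 genes, 10 TFs with 20 targets
    each, log2-scale noise SD 0.5 (a typical residual SD for array
    data), 10 treated vs 10 control replicates for signatures, and three
    cohorts of 200 samples for network inference.  ``r_tf`` is the
    correlation between a TF's transcript and its latent activity.
    """

    n_genes: int = 300
    n_tfs: int = 10
    targets_per_tf: int = 20
    noise_sd: float = 0.5
    n_treated: int = 10
    n_control: int = 10
    n_cohorts: int = 3
    seed: int = 0
    r_tf: float = 0.9
    baseline: float = 7.0
    strength_range: tuple[float, float] = (0.5, 1.0)
    frac_repressed: float = 0.25
    batch_sd: float = 1.0

    def __post_init__(self) -> None:
        for name in ("n_genes", "n_tfs", "targets_per_tf", "n_treated", "n_control", "n_cohorts"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.noise_sd <= 0:
            raise ValueError("noise_sd must be > 0")
        if not 0 < self.r_tf <= 1:
            raise ValueError("r_tf must lie in (0, 1]")
        lo, hi = self.strength_range
        if not (0 < lo <= hi <= 1):
            raise ValueError("strength_range must satisfy 0 < lo <= hi <= 1")
        if self.n_genes < self.n_tfs * (1 + self.targets_per_tf):
            raise ValueError(
                "n_genes too small to host disjoint regulons: need at least "
                f"{self.n_tfs * (1 + self.targets_per_tf)}"
            )


@dataclass
class GroundTruth:
    """Planted structure the generator embeds and tests recover.

    ``regulons`` maps TF -> DataFrame (index target, columns ``mor`` in
    {-1, +1} and ``strength`` in (0, 1]).  ``activity_shift`` maps TF ->
    effect size delta applied to treated samples.  ``batch_offsets``
    maps batch label -> per-gene additive offset Series.
    """

    gene_ids: list[str]
    tf_ids: list[str]
    regulons: dict[str, pd.DataFrame]
    activity_shift: dict[str, float] = field(default_factory=dict)
    batch_offsets: dict[str, pd.Series] = field(default_factory=dict)
    cohort_sizes: tuple[int, ...] = (200, 200, 200)

    def __post_init__(self) -> None:
        if len(set(self.gene_ids)) != len(self.gene_ids):
            raise ValueError("duplicate gene IDs in universe")
        universe = set(self.gene_ids)
        for tf, tab in self.regulons.items():
            if tf not in universe:
                raise ValueError(f"regulon TF {tf} not in gene universe")
            missing = set(tab.index) - universe
            if missing:
                raise ValueError(f"regulon targets outside gene universe: {sorted(missing)[:5]}")
            strength = tab["strength"].to_numpy(dtype=float)
            if np.any(strength <= 0) or np.any(strength > 1):
                raise ValueError(f"strengths must lie in (0, 1] for TF {tf}")
        unknown = set(self.activity_shift) - set(self.tf_ids)
        if unknown:
            raise ValueError(f"activity_shift given for unknown TFs: {sorted(unknown)}")
        if any(n < 3 for n in self.cohort_sizes):
            raise ValueError("every cohort size must be >= 3")

    def targets_of(self, tf: str) -> list[str]:
        return list(self.regulons.get(tf, pd.DataFrame()).index)


def make_ground_truth(
    config: SimConfig,
    activity_shift: dict[str, float] | None = None,
    cohort_sizes: tuple[int, ...] | None = None,
    batch_labels: tuple[str, ...] = (),
) -> GroundTruth:
    """Draw a random ground truth consistent with ``config``.

    TF target sets are disjoint (drawn without replacement from the
    non-TF genes) so recovery metrics are unambiguous.  Signs are +1
    with probability ``1 - frac_repressed``, else -1; strengths are
    uniform over ``strength_range``.
    """
    rng = np.random.default_rng(np.random.SeedSequence([int(config.seed), 0xA11CE]))
    tf_ids = [f"TF{i + 1:03d}" for i in range(config.n_tfs)]
    n_other = config.n_genes - config.n_tfs
    other = [f"G{i + 1:04d}" for i in range(n_other)]
    pool = rng.permutation(np.array(other))
    regulons: dict[str, pd.DataFrame] = {}
    k = config.targets_per_tf
    for i, tf in enumerate(tf_ids):
        targets = pool[i * k : (i + 1) * k]
        mor = np.where(rng.random(k) < config.frac_repressed, -1.0, 1.0)
        lo, hi = config.strength_range
        strength = rng.uniform(lo, hi, size=k)
        regulons[tf] = pd.DataFrame(
            {"mor": mor, "strength": strength}, index=pd.Index(targets, name="target")
        )
    if cohort_sizes is None:
        cohort_sizes = tuple([200] * config.n_cohorts)
    batch_offsets = {
        label: pd.Series(
            rng.normal(0.0, config.batch_sd, size=config.n_genes),
            index=tf_ids + other,
        )
        for label in batch_labels
    }
    return GroundTruth(
        gene_ids=tf_ids + other,
        tf_ids=tf_ids,
        regulons=regulons,
        activity_shift=dict(activity_shift or {}),
        batch_offsets=batch_offsets,
        cohort_sizes=tuple(cohort_sizes),
    )


def _target_loadings(truth: GroundTruth) -> np.ndarray:
    """Genes x TFs loading matrix L with L[g, t] = mor * strength."""
    gene_index = pd.Index(truth.gene_ids)
    L = np.zeros((len(gene_index), len(truth.tf_ids)))
    for j, tf in enumerate(truth.tf_ids):
        tab = truth.regulons.get(tf)
        if tab is None or tab.empty:
            continue
        rows = gene_index.get_indexer(tab.index)
        L[rows, j] = tab["mor"].to_numpy() * tab["strength"].to_numpy()
    return L


def _expression_from_activity(
    truth: GroundTruth,
    activity: np.ndarray,
    rng: np.random.Generator,
    config: SimConfig,
) -> np.ndarray:
    """Assemble genes x samples values from a TFs x samples activity matrix."""
    n_genes = len(truth.gene_ids)
    n_samples = activity.shape[1]
    L = _target_loadings(truth)
    x = config.baseline + L @ activity
    x += rng.normal(0.0, config.noise_sd, size=(n_genes, n_samples))
    return x


def simulate_signature_study(
    config: SimConfig, truth: GroundTruth
) -> tuple[ExpressionMatrix, GroundTruth]:
    """Treated-vs-control replicate matrix with shifted TF activities.

    Each TF's activity is its base level (zero) plus ``delta`` in
    treated samples for TFs appearing in ``truth.activity_shift``;
    replicate-to-replicate variation is measurement noise.  The TF's
    own transcript is baseline plus noise only: the treatment changes
    activity, not TF expression.
    """
    rng = np.random.default_rng(np.random.SeedSequence([int(config.seed), 1]))
    n_t, n_c = config.n_treated, config.n_control
    sample_ids = [f"T{i + 1:02d}" for i in range(n_t)] + [f"C{i + 1:02d}" for i in range(n_c)]
    treated = np.array([1.0] * n_t + [0.0] * n_c)

    n_tfs = len(truth.tf_ids)
    activity = np.zeros((n_tfs, n_t + n_c))
    for j, tf in enumerate(truth.tf_ids):
        delta = truth.activity_shift.get(tf, 0.0)
        if delta:
            activity[j] += delta * treated

    x = _expression_from_activity(truth, activity, rng, config)
    # TF transcript rows: activity-independent (noise around baseline)
    gene_index = pd.Index(truth.gene_ids)
    tf_rows = gene_index.get_indexer(truth.tf_ids)
    x[tf_rows] = config.baseline + rng.normal(
        0.0, config.noise_sd, size=(n_tfs, n_t + n_c)
    )

    values = pd.DataFrame(x, index=gene_index.copy(), columns=sample_ids)
    meta = pd.DataFrame(
        {
            "group": [GROUP_TREATED] * n_t + [GROUP_CONTROL] * n_c,
            "batch": "batch0",
            "cohort": "signature",
        },
        index=pd.Index(sample_ids, name="sample"),
    )
    return ExpressionMatrix(values, meta), truth


def simulate_cohorts(
    config: SimConfig,
    truth: GroundTruth,
    batch_cohorts: tuple[int, ...] = (),
) -> list[ExpressionMatrix]:
    """One expression matrix per cohort with continuous latent activities.

    TF activities are ``N(0, 1)`` per sample and surface in the TF's
    own transcript, ``x_tf = baseline + r_tf * a + sqrt(1 - r_tf^2) * z``
    (so the transcript-activity correlation is ~``r_tf``).  Targets
    respond to the TF's transcript deviation — transcription-level
    regulation, the premise that lets coexpression reverse-engineer
    TF-target edges — so each planted edge is a genuine conditional
    dependence between measured variables.  Cohorts listed in
    ``batch_cohorts`` are split into two batches receiving the additive
    per-gene offsets stored in ``truth.batch_offsets`` (labels
    ``batchA`` / ``batchB``; missing labels mean zero offset).
    """
    if config.n_cohorts != len(truth.cohort_sizes):
        raise ValueError(
            f"n_cohorts ({config.n_cohorts}) != len(cohort_sizes) ({len(truth.cohort_sizes)})"
        )
    if any(n < 3 for n in truth.cohort_sizes):
        raise ValueError("every cohort size must be >= 3")
    streams = np.random.SeedSequence([int(config.seed), 2]).spawn(config.n_cohorts)
    gene_index = pd.Index(truth.gene_ids)
    tf_rows = gene_index.get_indexer(truth.tf_ids)
    cohorts: list[ExpressionMatrix] = []
    for c, (n_samples, stream) in enumerate(zip(truth.cohort_sizes, streams)):
        rng = np.random.default_rng(stream)
        activity = rng.normal(0.0, 1.0, size=(len(truth.tf_ids), n_samples))
        noise = rng.normal(0.0, 1.0, size=activity.shape)
        # unit-variance transcript signal carrying the activity at corr r_tf
        transcript = config.r_tf * activity + np.sqrt(1.0 - config.r_tf**2) * noise
        x = _expression_from_activity(truth, transcript, rng, config)
        x[tf_rows] = config.baseline + transcript
        sample_ids = [f"c{c + 1}s{i + 1:03d}" for i in range(n_samples)]
        batch = np.array(["batch0"] * n_samples, dtype=object)
        if c in batch_cohorts:
            half = n_samples // 2
            batch[:half] = "batchA"
            batch[half:] = "batchB"
            for label in ("batchA", "batchB"):
                offs = truth.batch_offsets.get(label)
                if offs is not None:
                    cols = batch == label
                    x[:, cols] += offs.reindex(gene_index).fillna(0.0).to_numpy()[:, None]
        values = pd.DataFrame(x, index=gene_index.copy(), columns=sample_ids)
        meta = pd.DataFrame(
            {
                "group": GROUP_UNLABELED,
                "batch": batch,
                "cohort": f"cohort{c + 1}",
            },
            index=pd.Index(sample_ids, name="sample"),
        )
        cohorts.append(ExpressionMatrix(values, meta))
    return cohorts


def true_regulon_table(truth: GroundTruth) -> pd.DataFrame:
    """Truth as a regulon TSV table (tf, target, mor, likelihood=strength)."""
    rows = []
    for tf in truth.tf_ids:
        tab = truth.regulons.get(tf)
        if tab is None:
            continue
        for target, row in tab.iterrows():
            rows.append((tf, target, row["mor"], row["strength"]))
    return pd.DataFrame(rows, columns=["tf", "target", "mor", "likelihood"])
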