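"""Combine per-cohort networks into one meta-network and build regulons.

Per-cohort edge p-values become signed Z-scores and are combined with
sqrt(n)-weighted Stouffer Z so larger cohorts count more; edges whose
correlation sign flips between significant cohorts are discarded.  Each
retained TF-target edge contributes a mode of regulation
mor = tanh(Z/3) and a confidence weight |Z| / max|Z| to the TF's regulon.
"""

from mastreg.coexnet import infer_network
from mastreg.metanet import build_meta_network, build_regulons
from mastreg.synthdata import SimConfig, make_ground_truth, simulate_cohorts

config = SimConfig(
    n_genes=300, n_tfs=10, targets_per_tf=20, seed=7,
    strength_range=(0.8, 0.8), n_cohorts=3,
)
truth = make_ground_truth(config, cohort_sizes=(200, 150, 100))

tables = [infer_network(c, truth.tf_ids)[0] for c in simulate_cohorts(config, truth)]
meta = build_meta_network(tables)
print(f"{len(meta)} candidate edges, {int(meta['retained'].sum())} retained "
      f"({int((~meta['coherent']).sum())} rejected as sign-incoherent)")

regulons = build_regulons(meta, min_regulon_size=10)
print(f"\n{len(regulons)} regulons assembled; overlap with the planted truth:")
for reg in regulons:
    true_targets = set(truth.regulons[reg.tf].index)
    rec = set(reg.targets.index)
    jaccard = len(true_targets & rec) / len(true_targets | rec)
    print(f"  {reg.tf}: {reg.size} targets, Jaccard vs truth = {jaccard:.2f}")
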