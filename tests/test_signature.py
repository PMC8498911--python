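"""Signature extraction: moderated t, DEG calls, orthologs, batch adjustment."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from mastreg.signature import (
    DegenerateVarianceError,
    batch_adjust,
    call_degs,
    combine_replicate_signatures,
    fit_variance_prior,
    map_orthologs,
    moderated_t_signature,
)
from mastreg.coexnet import infer_network
from mastreg.synthdata import SimConfig, make_ground_truth, simulate_cohorts

from .conftest import make_matrix


class TestModeratedT:
    def test_identical_groups_give_null_gene(self, rng):
        values = rng.normal(size=(5, 8))
        values[0] = np.tile([1.0, 2.0, 3.0, 4.0], 2)  # same values in both groups
        mat = make_matrix(values, groups=["treated"] * 4 + ["control"] * 4)
        sig = moderated_t_signature(mat)
        assert sig.loc["g0", "log2fc"] == 0.0
        assert sig.loc["g0", "deg_call"] == "none"

    def test_prior_zero_equals_pooled_t(self, two_group_matrix):
        """d0 = 0 reduces the moderated t to the ordinary pooled-variance t."""
        sig = moderated_t_signature(two_group_matrix, prior_df=0)
        a = two_group_matrix.values.iloc[:, :6].to_numpy()
        b = two_group_matrix.values.iloc[:, 6:].to_numpy()
        t_ref, p_ref = stats.ttest_ind(a, b, axis=1)
        np.testing.assert_allclose(sig["t"].to_numpy(), t_ref, rtol=1e-12)
        np.testing.assert_allclose(sig["p"].to_numpy(), p_ref, rtol=1e-12)

    def test_worked_example_gene(self):
        """a=(5.0,5.1,4.9) vs b=(2.0,2.1,1.9): log2FC 3, pooled t = 3/(0.1*sqrt(2/3))."""
        mat = make_matrix(
            [[5.0, 5.1, 4.9, 2.0, 2.1, 1.9], [1.0, 1.2, 0.8, 1.1, 0.9, 1.0]],
            groups=["treated"] * 3 + ["control"] * 3,
        )
        sig = moderated_t_signature(mat, prior_df=0)
        t_oracle = 3.0 / (0.1 * math.sqrt(2.0 / 3.0))
        assert sig.loc["g0", "log2fc"] == pytest.approx(3.0, abs=1e-12)
        assert sig.loc["g0", "t"] == pytest.approx(t_oracle, rel=1e-10)
        assert sig.loc["g0", "p"] == pytest.approx(2 * stats.t.sf(t_oracle, 4), rel=1e-10)
        assert sig.loc["g0", "p"] < 0.05
        assert sig.loc["g0", "deg_call"] == "up"

    def test_unknown_group_rejected(self, two_group_matrix):
        with pytest.raises(ValueError, match="unknown group"):
            moderated_t_signature(two_group_matrix, "treated", "sham")

    def test_degenerate_variance_error(self):
        values = np.tile([[1.0, 1.0, 1.0, 2.0, 2.0, 2.0]], (3, 1))
        mat = make_matrix(values, groups=["treated"] * 3 + ["control"] * 3)
        with pytest.raises(DegenerateVarianceError):
            moderated_t_signature(mat, prior_df=0)

    @settings(deadline=None, max_examples=25, derandomize=True)
    @given(st.integers(0, 10_000))
    def test_antisymmetry_under_group_swap(self, seed):
        rng = np.random.default_rng(seed)
        values = rng.normal(0, 1, size=(12, 10))
        mat = make_matrix(values, groups=["treated"] * 5 + ["control"] * 5)
        fwd = moderated_t_signature(mat, "treated", "control")
        rev = moderated_t_signature(mat, "control", "treated")
        np.testing.assert_allclose(fwd["log2fc"], -rev["log2fc"], atol=1e-12)
        np.testing.assert_allclose(fwd["t"], -rev["t"], atol=1e-10)
        np.testing.assert_allclose(fwd["p"], rev["p"], rtol=1e-10)

    def test_order_invariance(self, two_group_matrix):
        sig = moderated_t_signature(two_group_matrix)
        perm_genes = two_group_matrix.values.sample(frac=1, random_state=1).index
        shuffled = make_matrix(
            two_group_matrix.values.loc[perm_genes].to_numpy(),
            gene_ids=list(perm_genes),
            groups=list(two_group_matrix.sample_meta["group"]),
        )
        sig2 = moderated_t_signature(shuffled)
        pd.testing.assert_frame_equal(sig.loc[perm_genes], sig2, check_like=True)


class TestVariancePrior:
    def test_posterior_between_sample_and_prior(self, rng):
        """Moderated variances always lie between s_g^2 and s0^2."""
        s2 = stats.chi2.rvs(4, size=200, random_state=rng) / 4 * np.exp(
            rng.normal(0, 0.8, 200)
        )
        d0, s0_2 = fit_variance_prior(s2, df=4)
        assert d0 > 0 and s0_2 > 0
        s2_post = (d0 * s0_2 + 4 * s2) / (d0 + 4)
        lo, hi = np.minimum(s2, s0_2), np.maximum(s2, s0_2)
        assert np.all(s2_post >= lo - 1e-12) and np.all(s2_post <= hi + 1e-12)

    def test_homogeneous_variances_give_heavy_prior(self, rng):
        """When variances share one scale, the prior df dominates the data df."""
        s2 = stats.chi2.rvs(40, size=300, random_state=rng) / 40
        d0, s0_2 = fit_variance_prior(s2, df=40)
        assert d0 > 40 or math.isinf(d0)
        assert s0_2 == pytest.approx(1.0, rel=0.1)


class TestDegCalls:
    @pytest.mark.parametrize(
        "log2fc,p,expected",
        [
            (1.5, 0.01, "up"),
            (-1.5, 0.01, "down"),
            (1.0, 0.001, "none"),  # boundary log2FC is excluded (strict >)
            (-1.0, 0.001, "none"),
            (1.5, 0.05, "none"),  # boundary p is excluded (strict <)
            (0.2, 0.0001, "none"),
        ],
    )
    def test_threshold_boundaries(self, log2fc, p, expected):
        sig = pd.DataFrame(
            {"log2fc": [log2fc], "t": [1.0], "p": [p], "deg_call": ["none"]},
            index=["g"],
        )
        n_up, n_down = call_degs(sig)
        assert {"up": (1, 0), "down": (0, 1), "none": (0, 0)}[expected] == (n_up, n_down)

    def test_counts_match_enumeration(self, rng):
        log2fc = rng.uniform(-3, 3, 10)
        p = rng.uniform(0, 0.2, 10)
        sig = pd.DataFrame({"log2fc": log2fc, "t": log2fc, "p": p}, index=[f"g{i}" for i in range(10)])
        expected_up = int(np.sum((log2fc > 1) & (p < 0.05)))
        expected_down = int(np.sum((log2fc < -1) & (p < 0.05)))
        assert call_degs(sig) == (expected_up, expected_down)


class TestOrthologs:
    def sig(self, genes):
        return pd.DataFrame(
            {"log2fc": np.arange(len(genes), dtype=float), "t": 1.0, "p": 0.5},
            index=pd.Index(genes, name="gene"),
        )

    def test_identity_map(self):
        sig = self.sig(["a", "b", "c"])
        m = pd.DataFrame({"source": ["a", "b", "c"], "target": ["a", "b", "c"]})
        out = map_orthologs(sig, m)
        pd.testing.assert_frame_equal(out, sig)

    def test_unmapped_genes_eliminated(self):
        sig = self.sig(["a", "b", "c", "d", "e"])
        m = pd.DataFrame({"source": ["a", "b", "c"], "target": ["A", "B", "C"]})
        out = map_orthologs(sig, m)
        assert list(out.index) == ["A", "B", "C"]
        assert len(out) == 3
        np.testing.assert_array_equal(out["log2fc"], [0.0, 1.0, 2.0])

    def test_ambiguous_source_dropped_by_default(self):
        sig = self.sig(["a", "b"])
        m = pd.DataFrame({"source": ["a", "a", "b"], "target": ["A1", "A2", "B"]})
        out = map_orthologs(sig, m)
        assert list(out.index) == ["B"]
        out_first = map_orthologs(sig, m, ambiguity="first")
        assert list(out_first.index) == ["A1", "B"]

    def test_empty_map_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            map_orthologs(self.sig(["a"]), pd.DataFrame(columns=["source", "target"]))


class TestBatchAdjust:
    def test_batch_means_equalized(self, rng):
        values = rng.normal(5, 1, size=(10, 12))
        values[:, 6:] += rng.normal(0, 3, size=(10, 1))  # per-gene offset on batch B
        mat = make_matrix(values, batches=["A"] * 6 + ["B"] * 6)
        adj = batch_adjust(mat)
        a = adj.values.iloc[:, :6].mean(axis=1)
        b = adj.values.iloc[:, 6:].mean(axis=1)
        np.testing.assert_allclose(a, b, atol=1e-10)

    def test_plus_minus_offset_removed(self, rng):
        base = rng.normal(0, 1, size=(5, 8))
        values = base.copy()
        values[:, :4] += 2.0
        values[:, 4:] -= 2.0
        mat = make_matrix(values, batches=["A"] * 4 + ["B"] * 4)
        adj = batch_adjust(mat)
        diff = adj.values.iloc[:, :4].mean(axis=1) - adj.values.iloc[:, 4:].mean(axis=1)
        np.testing.assert_allclose(diff, 0.0, atol=1e-10)

    def test_single_sample_batch_rejected(self, rng):
        mat = make_matrix(rng.normal(size=(4, 5)), batches=["A"] * 4 + ["B"])
        with pytest.raises(ValueError, match="single-sample batch"):
            batch_adjust(mat)

    def test_planted_edges_recovered_after_adjustment(self):
        """Edges survive a strong additive batch effect once it is adjusted out."""
        recovered = 0
        n_seeds = 40
        for seed in range(n_seeds):
            cfg = SimConfig(
                n_genes=40, n_tfs=2, targets_per_tf=4, seed=seed, n_cohorts=1,
                strength_range=(0.8, 0.8), batch_sd=3.0,
            )
            truth = make_ground_truth(
                cfg, batch_labels=("batchA", "batchB"), cohort_sizes=(300,)
            )
            mat = simulate_cohorts(cfg, truth, batch_cohorts=(0,))[0]
            edges, _ = infer_network(batch_adjust(mat), truth.tf_ids)
            true_edges = {
                (tf, t) for tf in truth.tf_ids for t in truth.regulons[tf].index
            }
            found = set(zip(*edges.loc[edges["significant"], ["tf", "target"]].T.values)) if edges["significant"].any() else set()
            sens = len(found & true_edges) / len(true_edges)
            recovered += sens >= 0.75
        assert recovered >= 0.9 * n_seeds


class TestReplicateCombination:
    def test_needs_two_replicates(self):
        sig = pd.DataFrame({"log2fc": [1.0], "t": [1.0], "p": [0.5]}, index=["g"])
        with pytest.raises(ValueError, match=">=2"):
            combine_replicate_signatures([sig])

    def test_consistent_replicates_reinforce(self, rng):
        genes = [f"g{i}" for i in range(50)]
        reps = []
        shift = np.where(np.arange(50) < 5, 2.0, 0.0)
        for _ in range(4):
            lfc = shift + rng.normal(0, 0.3, 50)
            reps.append(pd.DataFrame({"log2fc": lfc, "t": lfc, "p": 0.5}, index=genes))
        combined = combine_replicate_signatures(reps)
        assert (combined.loc[genes[:5], "t"] > 3).all()
        assert combined.loc[genes[5:], "t"].abs().mean() < 2
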