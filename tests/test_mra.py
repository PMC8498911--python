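"""aREA rank enrichment, NES calibration and master-regulon calling."""

import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from mastreg.mra import area_score, msviper, nes_pvalue, rank_transform
from mastreg.signature import moderated_t_signature
from mastreg.synthdata import SimConfig, make_ground_truth, simulate_signature_study

from .conftest import make_regulon


def series(values, prefix="g"):
    return pd.Series(np.asarray(values, float), index=[f"{prefix}{i}" for i in range(len(values))])


class TestRankTransform:
    def test_three_gene_quantiles(self):
        rsig = rank_transform(series([-2.0, 0.0, 5.0]))
        expected = stats.norm.ppf([1 / 6, 3 / 6, 5 / 6])
        np.testing.assert_allclose(rsig["q2"], expected, atol=1e-6)
        assert rsig["q2"].iloc[1] == pytest.approx(0.0, abs=1e-12)

    def test_negation_flips_q2_keeps_q1(self):
        s = series([-1.3, 0.2, 0.9, 2.5, -0.4])
        a, b = rank_transform(s), rank_transform(-s)
        np.testing.assert_allclose(a["q2"], -b["q2"], atol=1e-12)
        np.testing.assert_allclose(a["q1"], b["q1"], atol=1e-12)

    def test_ties_share_quantiles(self):
        rsig = rank_transform(series([1.0, 1.0, 3.0, -2.0]))
        assert rsig["q2"].iloc[0] == rsig["q2"].iloc[1]

    def test_degenerate_signature_rejected(self):
        with pytest.raises(ValueError, match="degenerate"):
            rank_transform(series([2.0, 2.0, 2.0]))

    def test_uses_t_column_of_signature(self):
        sig = pd.DataFrame(
            {"log2fc": [0.0, 0.0], "t": [1.0, -1.0], "p": [0.5, 0.5]},
            index=["a", "b"],
        )
        rsig = rank_transform(sig)
        assert rsig.loc["a", "q2"] > 0 > rsig.loc["b", "q2"]


class TestAreaScore:
    def test_top_k_closed_form(self):
        """All-positive equal-weight regulon at the top k ranks: ES is the
        mean of the k largest q2 grid values; NES = sqrt(k) * ES."""
        n, k = 100, 10
        s = series(np.arange(n, dtype=float))
        rsig = rank_transform(s)
        top = s.nlargest(k).index
        reg = make_regulon("tf", top, [1.0] * k, [1.0] * k)
        es, nes, used = area_score(reg, rsig)
        grid = stats.norm.ppf((np.arange(1, n + 1) - 0.5) / n)
        assert used == k
        assert es == pytest.approx(grid[-k:].mean(), abs=1e-12)
        assert nes == pytest.approx(math.sqrt(k) * es, abs=1e-12)

    def test_weight_scale_invariance(self, rng):
        s = series(rng.normal(size=200))
        rsig = rank_transform(s)
        targets = s.index[:20]
        mor = rng.choice([-1.0, 1.0], 20)
        w = rng.uniform(0.5, 1.0, 20)
        es1, nes1, _ = area_score(make_regulon("tf", targets, mor, w), rsig)
        es2, nes2, _ = area_score(make_regulon("tf", targets, mor, w / 2), rsig)
        assert es1 == pytest.approx(es2, abs=1e-12)
        assert nes1 == pytest.approx(nes2, abs=1e-12)

    def test_signature_negation_negates_nes(self, rng):
        s = series(rng.normal(size=150))
        targets = s.index[10:40]
        reg = make_regulon("tf", targets, [1.0] * 30, rng.uniform(0.3, 1, 30))
        _, nes_pos, _ = area_score(reg, rank_transform(s))
        _, nes_neg, _ = area_score(reg, rank_transform(-s))
        assert nes_pos == pytest.approx(-nes_neg, abs=1e-10)

    def test_nes_scales_with_sqrt_regulon_size(self):
        """Fixed mean target quantile: NES grows ~sqrt(k) across 10/40/160."""
        n = 2000
        s = series(np.arange(n, dtype=float))
        rsig = rank_transform(s)
        nes_by_size = []
        for k in (10, 40, 160):
            pos = np.round(np.linspace(0, 499, k)).astype(int)
            targets = s.nlargest(500).index[pos]  # same quantile band
            _, nes, _ = area_score(make_regulon("tf", targets, [1.0] * k, [1.0] * k), rsig)
            nes_by_size.append(nes)
        for small, big in zip(nes_by_size, nes_by_size[1:]):
            assert big / small == pytest.approx(2.0, rel=0.15)  # 4x size ~ 2x NES

    def test_insufficient_overlap_raises(self):
        rsig = rank_transform(series(np.arange(30.0)))
        reg = make_regulon("tf", ["x0", "x1"], [1.0, 1.0], [1.0, 1.0])
        with pytest.raises(ValueError, match="overlap"):
            area_score(reg, rsig)


class TestNesPvalue:
    def test_zero_nes_gives_one(self):
        assert nes_pvalue(0.0) == pytest.approx(1.0)

    def test_master_cut_boundary_value(self):
        """NES = 2.575829 sits exactly at the two-sided p = 0.01 cut."""
        assert nes_pvalue(2.575829) == pytest.approx(0.01, abs=1e-6)

    def test_permutation_deterministic(self, rng):
        s = series(rng.normal(size=300))
        rsig = rank_transform(s)
        reg = make_regulon("tf", s.index[:15], [1.0] * 15, [1.0] * 15)
        _, nes, _ = area_score(reg, rsig)
        p1 = nes_pvalue(nes, "permutation", regulon=reg, rsig=rsig, n_perm=200, seed=42)
        p2 = nes_pvalue(nes, "permutation", regulon=reg, rsig=rsig, n_perm=200, seed=42)
        assert p1 == p2
        with pytest.raises(ValueError, match="seed"):
            nes_pvalue(nes, "permutation", regulon=reg, rsig=rsig, n_perm=200)

    def test_permutation_agrees_with_analytic(self, rng):
        """Gene-label shuffling p matches the normal tail within binomial CI."""
        n_perm = 2000
        for trial in range(5):
            s = series(rng.normal(size=400))
            rsig = rank_transform(s)
            idx = rng.choice(400, 20, replace=False)
            reg = make_regulon(
                "tf", s.index[idx], rng.choice([-1.0, 1.0], 20), rng.uniform(0.3, 1, 20)
            )
            _, nes, _ = area_score(reg, rsig)
            p_a = nes_pvalue(nes)
            p_p = nes_pvalue(
                nes, "permutation", regulon=reg, rsig=rsig, n_perm=n_perm, seed=trial
            )
            count = p_p * (1 + n_perm) - 1
            lo, hi = stats.binom.interval(0.99, n_perm, max(p_a, 1e-6))
            assert lo / n_perm <= max(count, 0.5) / n_perm <= hi / n_perm * 1.5 + 0.01


class TestMsviper:
    def run_planted(self, seed, delta):
        cfg = SimConfig(n_genes=700, n_tfs=30, targets_per_tf=20, seed=seed)
        truth = make_ground_truth(cfg, activity_shift={"TF001": delta})
        mat, _ = simulate_signature_study(cfg, truth)
        sig = moderated_t_signature(mat)
        regulons = [
            make_regulon(
                tf,
                truth.regulons[tf].index,
                truth.regulons[tf]["mor"],
                truth.regulons[tf]["strength"],
            )
            for tf in truth.tf_ids
        ]
        return msviper(sig, regulons), truth

    def test_planted_activated_tf_recovered(self):
        """delta=3 TF among 29 nulls ranks first with master_call (>=95/100)."""
        hits = 0
        for seed in range(100):
            act, _ = self.run_planted(seed, 3.0)
            top = act.iloc[0]
            hits += top["tf"] == "TF001" and bool(top["master_call"])
        assert hits >= 95

    def test_planted_repressed_tf_direction(self):
        """delta=-3 TF gets NES < 0 and direction 'repressed' (>=95/100)."""
        hits = 0
        for seed in range(100):
            act, _ = self.run_planted(seed, -3.0)
            row = act[act["tf"] == "TF001"].iloc[0]
            hits += row["nes"] < 0 and row["direction"] == "repressed"
        assert hits >= 95

    def test_master_call_strict_threshold(self):
        """master_call is p < threshold, strictly: the observed p itself fails."""
        cfg = SimConfig(n_genes=700, n_tfs=30, targets_per_tf=20, seed=0)
        truth = make_ground_truth(cfg)
        mat, _ = simulate_signature_study(cfg, truth)
        sig = moderated_t_signature(mat)
        regulons = [
            make_regulon(
                tf, truth.regulons[tf].index,
                truth.regulons[tf]["mor"], truth.regulons[tf]["strength"],
            )
            for tf in truth.tf_ids
        ]
        act = msviper(sig, regulons)
        p = float(act.iloc[0]["p"])
        just_above = msviper(sig, regulons, master_p_threshold=p * (1 + 1e-9))
        at_p = msviper(sig, regulons, master_p_threshold=p)
        assert bool(just_above.iloc[0]["master_call"])
        assert not bool(at_p.iloc[0]["master_call"])

    def test_disjoint_namespaces_error(self, rng):
        sig = pd.DataFrame(
            {"log2fc": rng.normal(size=30), "t": rng.normal(size=30), "p": 0.5},
            index=[f"h{i}" for i in range(30)],
        )
        reg = make_regulon("tf", [f"m{i}" for i in range(15)], [1.0] * 15, [1.0] * 15)
        with pytest.raises(ValueError, match="disjoint"):
            msviper(sig, [reg])

    def test_null_nes_calibration(self, rng):
        """Random regulons vs a random signature: NES ~ Normal(0,1)."""
        s = series(rng.normal(size=2000))
        rsig = rank_transform(s)
        nes_values = []
        for _ in range(500):
            idx = rng.choice(2000, 25, replace=False)
            reg = make_regulon(
                "tf", s.index[idx], rng.choice([-1.0, 1.0], 25), rng.uniform(0.2, 1, 25)
            )
            nes_values.append(area_score(reg, rsig)[1])
        nes_values = np.asarray(nes_values)
        assert abs(nes_values.mean()) < 0.1
        assert 0.85 < nes_values.std(ddof=1) < 1.15
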