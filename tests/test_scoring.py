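"""Scoring operations against independent brute-force oracles."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from g0kit import (
    ExpressionMatrix,
    G0,
    GeneSignature,
    HousekeepingSet,
    PROLIFERATING,
    PurityVector,
    ScoreVector,
    StateLabels,
    ValidationError,
    batch_adjust,
    call_states,
    combined_zscore,
    evaluate_auc,
    kmeans_high_low,
    mean_scaled_score,
    proportion_arrested,
    purity_adjust,
    rank_score,
    zscore_transform,
)


# ---------------------------------------------------------------------------
# Independent oracles (explicit loops, no shared code with the implementation)
# ---------------------------------------------------------------------------

def oracle_combined_z(expr, sig):
    """Loop-based combined Z-score: sum z/sqrt(n) per direction, subtract."""
    out = []
    for j, _ in enumerate(expr.samples):
        parts = {}
        for direction, genes in (("up", sig.up), ("down", sig.down)):
            zs = []
            for g in genes:
                if g not in expr.genes:
                    continue
                row = expr.values[expr.genes.index(g), :]
                sd = row.std(ddof=1)
                if sd == 0:
                    continue
                zs.append((row[j] - row.mean()) / sd)
            parts[direction] = sum(zs) / np.sqrt(len(zs)) if zs else 0.0
        out.append(parts["up"] - parts["down"])
    return np.array(out)


def oracle_rank(expr, sig):
    out = []
    n = len(expr.genes)
    for j in range(len(expr.samples)):
        col = expr.values[:, j]
        order = np.argsort(col, kind="stable")
        ranks = np.empty(n)
        i = 0
        while i < n:  # mid-ranks for ties
            k = i
            while k + 1 < n and col[order[k + 1]] == col[order[i]]:
                k += 1
            ranks[order[i:k + 1]] = (i + k) / 2 + 1
            i = k + 1
        norm = (ranks - 1) / (n - 1)
        up = [norm[expr.genes.index(g)] for g in sig.up if g in expr.genes]
        down = [norm[expr.genes.index(g)] for g in sig.down if g in expr.genes]
        score = (np.mean(up) if up else 0.0) - (np.mean(down) if down else 0.0)
        out.append(score)
    return np.array(out)


def oracle_auc_threshold_sweep(score, is_pos):
    """Trapezoidal ROC AUC from an explicit threshold sweep."""
    thresholds = np.concatenate([[np.inf], np.sort(np.unique(score))[::-1], [-np.inf]])
    tpr, fpr = [], []
    n_pos, n_neg = is_pos.sum(), (~is_pos).sum()
    for t in thresholds:
        called = score >= t
        tpr.append((called & is_pos).sum() / n_pos)
        fpr.append((called & ~is_pos).sum() / n_neg)
    return float(np.trapezoid(tpr, fpr))


# ---------------------------------------------------------------------------
# zscore_transform / combined_zscore
# ---------------------------------------------------------------------------

class TestZScore:
    def test_two_sample_row(self):
        expr = ExpressionMatrix(genes=["g"], samples=["a", "b"], values=[[0.0, 2.0]])
        z = zscore_transform(expr)
        np.testing.assert_allclose(z.values[0], [-0.70710678, 0.70710678])

    def test_constant_row_zeroed(self):
        expr = ExpressionMatrix(genes=["g"], samples=["a", "b"], values=[[3.0, 3.0]])
        np.testing.assert_array_equal(zscore_transform(expr).values, [[0.0, 0.0]])

    def test_row_moments(self, rng):
        expr = ExpressionMatrix(
            genes=[f"g{i}" for i in range(5)],
            samples=[f"s{i}" for i in range(4)],
            values=rng.normal(size=(5, 4)),
        )
        z = zscore_transform(expr)
        np.testing.assert_allclose(z.values.mean(axis=1), 0, atol=1e-12)
        np.testing.assert_allclose(z.values.std(axis=1, ddof=1), 1, atol=1e-12)

    def test_single_sample_rejected(self):
        expr = ExpressionMatrix(genes=["g"], samples=["a"], values=[[1.0]])
        with pytest.raises(ValidationError):
            zscore_transform(expr)


class TestCombinedZScore:
    def test_symmetric_up_down_cancel(self):
        expr = ExpressionMatrix(
            genes=["U1", "D1"], samples=["a", "b"], values=[[0, 2], [0, 2]]
        )
        sig = GeneSignature(name="s", up=["U1"], down=["D1"])
        np.testing.assert_allclose(combined_zscore(expr, sig).score, [0.0, 0.0], atol=1e-12)

    def test_single_direction_reduces_to_z(self):
        expr = ExpressionMatrix(genes=["U1"], samples=["a", "b"], values=[[0, 2]])
        sig = GeneSignature(name="s", up=["U1"])
        np.testing.assert_allclose(
            combined_zscore(expr, sig).score, [-0.70710678, 0.70710678]
        )

    def test_matches_brute_force_oracle(self, seeded_matrix, small_sig):
        sv = combined_zscore(seeded_matrix, small_sig)
        np.testing.assert_allclose(sv.score, oracle_combined_z(seeded_matrix, small_sig),
                                   atol=1e-9)

    def test_dropout_counted(self, seeded_matrix):
        sig = GeneSignature(name="s", up=["U1", "ABSENT"], down=["D1"])
        sv = combined_zscore(seeded_matrix, sig)
        assert sv.n_up_used == 1 and sv.n_down_used == 1

    def test_no_signature_genes_rejected(self, seeded_matrix):
        sig = GeneSignature(name="s", up=["NOPE"])
        with pytest.raises(ValidationError):
            combined_zscore(seeded_matrix, sig)

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(st.integers(min_value=0, max_value=2**31 - 1))
    def test_invariant_under_genewise_positive_affine(self, seed):
        """z-scores are unchanged by x -> a_i*x + b_i with a_i > 0."""
        r = np.random.default_rng(seed)
        genes = ["U1", "U2", "D1", "N1"]
        expr = ExpressionMatrix(
            genes=genes, samples=[f"s{i}" for i in range(5)],
            values=r.normal(size=(4, 5)),
        )
        sig = GeneSignature(name="s", up=["U1", "U2"], down=["D1"])
        a = r.uniform(0.1, 5.0, size=(4, 1))
        b = r.normal(size=(4, 1))
        transformed = ExpressionMatrix(
            genes=genes, samples=expr.samples, values=a * expr.values + b
        )
        np.testing.assert_allclose(
            combined_zscore(expr, sig).score,
            combined_zscore(transformed, sig).score,
            atol=1e-9,
        )

    def test_monotone_in_up_gene_value(self, rng):
        """Raising an up gene in one sample raises that sample's score rank."""
        genes = ["U1", "D1", "N1"]
        base = rng.normal(5, 1, size=(3, 6))
        sig = GeneSignature(name="s", up=["U1"], down=["D1"])
        expr = ExpressionMatrix(genes=genes, samples=[f"s{i}" for i in range(6)], values=base)
        bumped_vals = base.copy()
        bumped_vals[0, 2] += 2.0
        bumped = ExpressionMatrix(genes=genes, samples=expr.samples, values=bumped_vals)
        before = combined_zscore(expr, sig).score
        after = combined_zscore(bumped, sig).score
        assert (after[2] - after.mean()) >= (before[2] - before.mean()) - 1e-12


class TestMeanScaled:
    def _matrix(self):
        return ExpressionMatrix(
            genes=["U1", "D1", "H1"],
            samples=["a"],
            values=[[2.0], [1.0], [1.0]],
            log_scale=False,
        )

    def test_direct_formula(self):
        sv = mean_scaled_score(self._matrix(), GeneSignature(name="s", up=["U1"], down=["D1"]),
                               HousekeepingSet(genes=["H1"]))
        np.testing.assert_allclose(sv.score, [1.0])

    def test_zero_numerator(self):
        expr = ExpressionMatrix(genes=["U1", "D1", "H1"], samples=["a"],
                                values=[[1.5], [1.5], [7.0]], log_scale=False)
        sv = mean_scaled_score(expr, GeneSignature(name="s", up=["U1"], down=["D1"]),
                               HousekeepingSet(genes=["H1"]))
        np.testing.assert_allclose(sv.score, [0.0])

    def test_global_rescale_invariance(self, rng):
        genes = ["U1", "U2", "D1", "H1", "H2"]
        vals = rng.uniform(1, 10, size=(5, 4))
        sig = GeneSignature(name="s", up=["U1", "U2"], down=["D1"])
        hk = HousekeepingSet(genes=["H1", "H2"])
        e1 = ExpressionMatrix(genes=genes, samples=list("abcd"), values=vals, log_scale=False)
        e2 = ExpressionMatrix(genes=genes, samples=list("abcd"), values=3.7 * vals,
                              log_scale=False)
        np.testing.assert_allclose(
            mean_scaled_score(e1, sig, hk).score, mean_scaled_score(e2, sig, hk).score
        )

    def test_zero_housekeeping_mean_names_sample(self):
        expr = ExpressionMatrix(genes=["U1", "D1", "H1"], samples=["bad"],
                                values=[[2.0], [1.0], [0.0]], log_scale=False)
        with pytest.raises(ValidationError, match="bad"):
            mean_scaled_score(expr, GeneSignature(name="s", up=["U1"], down=["D1"]),
                              HousekeepingSet(genes=["H1"]))


class TestRankScore:
    def test_extreme_ranks(self):
        expr = ExpressionMatrix(
            genes=["UP", "MID1", "MID2", "DOWN"], samples=["a"],
            values=[[9.0], [5.0], [4.0], [1.0]],
        )
        sig = GeneSignature(name="s", up=["UP"], down=["DOWN"])
        np.testing.assert_allclose(rank_score(expr, sig).score, [1.0])

    def test_tied_values_zero(self):
        expr = ExpressionMatrix(genes=["U1", "D1", "N1"], samples=["a"],
                                values=[[2.0], [2.0], [5.0]])
        sig = GeneSignature(name="s", up=["U1"], down=["D1"])
        np.testing.assert_allclose(rank_score(expr, sig).score, [0.0])

    def test_matches_sort_oracle(self, rng):
        genes = [f"g{i}" for i in range(20)]
        expr = ExpressionMatrix(genes=genes, samples=[f"s{i}" for i in range(5)],
                                values=rng.normal(size=(20, 5)))
        sig = GeneSignature(name="s", up=genes[:4], down=genes[4:7])
        np.testing.assert_allclose(rank_score(expr, sig).score, oracle_rank(expr, sig),
                                   atol=1e-12)


class TestPurityAdjust:
    def test_low_purity_sample_removed(self):
        expr = ExpressionMatrix(genes=["g"], samples=["keep", "drop"],
                                values=[[1.0, 1.0]])
        purity = PurityVector(samples=["keep", "drop"], purity=[0.5, 0.29])
        out = purity_adjust(expr, purity, min_purity=0.30)
        assert out.samples == ["keep"]

    def test_full_purity_identity(self):
        expr = ExpressionMatrix(genes=["g"], samples=["a", "b"], values=[[2.0, 3.0]])
        out = purity_adjust(expr, PurityVector(samples=["a", "b"], purity=[1.0, 1.0]))
        np.testing.assert_allclose(out.values, expr.values)

    def test_linear_division(self):
        expr = ExpressionMatrix(genes=["g"], samples=["a"], values=[[10.0]],
                                log_scale=False)
        out = purity_adjust(expr, PurityVector(samples=["a"], purity=[0.5]))
        np.testing.assert_allclose(out.values, [[20.0]])

    def test_log_scale_equivalence(self):
        """Adjusting on log2 scale equals dividing on linear scale."""
        linear = ExpressionMatrix(genes=["g"], samples=["a"], values=[[10.0]],
                                  log_scale=False)
        logged = ExpressionMatrix(genes=["g"], samples=["a"],
                                  values=np.log2([[10.0]]), log_scale=True)
        p = PurityVector(samples=["a"], purity=[0.4])
        np.testing.assert_allclose(
            np.exp2(purity_adjust(logged, p).values), purity_adjust(linear, p).values
        )

    def test_missing_purity_rejected(self):
        expr = ExpressionMatrix(genes=["g"], samples=["a", "b"], values=[[1.0, 2.0]])
        with pytest.raises(ValidationError, match="b"):
            purity_adjust(expr, PurityVector(samples=["a"], purity=[0.8]))


class TestCallsAndProportions:
    def test_strict_threshold_boundary(self):
        sv = ScoreVector(samples=["a", "b", "c"], score=[-1.0, 0.0, 2.0], method="z")
        assert call_states(sv).states == [PROLIFERATING, PROLIFERATING, G0]

    def test_all_above_threshold(self):
        sv = ScoreVector(samples=["a", "b"], score=[1.0, 2.0], method="z")
        labels = call_states(sv)
        assert proportion_arrested(labels)["fraction_G0"].iloc[0] == 1.0

    def test_fraction_and_partition(self):
        labels = StateLabels(
            samples=list("abcdefg"),
            states=[G0, G0, G0, PROLIFERATING, G0, PROLIFERATING, PROLIFERATING],
            group=["t1"] * 4 + ["t2"] * 3,
        )
        table = proportion_arrested(labels)
        assert table["n"].sum() == 7
        t1 = table.set_index("group").loc["t1"]
        assert t1["fraction_G0"] == 0.75


class TestAUC:
    def test_perfect_separation(self):
        sv = ScoreVector(samples=list("abcd"), score=[1, 2, 8, 9], method="z")
        truth = StateLabels(samples=list("abcd"),
                            states=[PROLIFERATING, PROLIFERATING, G0, G0])
        assert evaluate_auc(sv, truth) == 1.0

    def test_all_ties_half(self):
        sv = ScoreVector(samples=list("abcd"), score=[1, 1, 1, 1], method="z")
        truth = StateLabels(samples=list("abcd"),
                            states=[PROLIFERATING, PROLIFERATING, G0, G0])
        assert evaluate_auc(sv, truth) == 0.5

    def test_single_inversion_eight_ninths(self):
        sv = ScoreVector(samples=list("abcdef"), score=[1, 2, 3, 4, 5, 6], method="z")
        truth = StateLabels(
            samples=list("abcdef"),
            states=[PROLIFERATING, PROLIFERATING, G0, PROLIFERATING, G0, G0],
        )
        np.testing.assert_allclose(evaluate_auc(sv, truth), 8 / 9)

    def test_single_class_rejected(self):
        sv = ScoreVector(samples=["a", "b"], score=[1, 2], method="z")
        with pytest.raises(ValidationError):
            evaluate_auc(sv, StateLabels(samples=["a", "b"], states=[G0, G0]))

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(st.integers(min_value=0, max_value=2**31 - 1))
    def test_equals_threshold_sweep_oracle(self, seed):
        r = np.random.default_rng(seed)
        n = 30
        score = np.round(r.normal(size=n), 1)  # rounding forces ties
        is_pos = r.random(n) < 0.4
        if is_pos.all() or not is_pos.any():
            is_pos[0] = ~is_pos[0]
        sv = ScoreVector(samples=[f"s{i}" for i in range(n)], score=score, method="z")
        truth = StateLabels(samples=sv.samples,
                            states=[G0 if p else PROLIFERATING for p in is_pos])
        np.testing.assert_allclose(
            evaluate_auc(sv, truth), oracle_auc_threshold_sweep(score, is_pos), atol=1e-12
        )


class TestKMeansHighLow:
    def _planted(self, rng, batch_offset=0.0):
        genes = [f"U{i}" for i in range(8)] + [f"N{i}" for i in range(12)]
        sig = GeneSignature(name="s", up=[f"U{i}" for i in range(8)])
        n = 40
        vals = rng.normal(5, 1, size=(20, n))
        high = np.arange(n) < n // 2
        vals[:8, high] += 3.0
        batch = ["b1" if j % 2 == 0 else "b2" for j in range(n)]
        if batch_offset:
            vals[:, np.array(batch) == "b2"] += batch_offset
        expr = ExpressionMatrix(genes=genes, samples=[f"s{j}" for j in range(n)],
                                values=vals)
        return expr, sig, high, batch

    def test_recovers_planted_split(self, rng):
        expr, sig, high, batch = self._planted(rng)
        labels = kmeans_high_low(expr, sig, batch=batch, seed=1)
        assert [s == "high" for s in labels.states] == list(high)

    def test_batch_offset_removed(self, rng):
        expr, sig, high, batch = self._planted(rng, batch_offset=5.0)
        labels = kmeans_high_low(expr, sig, batch=batch, seed=1)
        assert [s == "high" for s in labels.states] == list(high)

    def test_high_cluster_has_higher_score(self, rng):
        expr, sig, _, batch = self._planted(rng)
        labels = kmeans_high_low(expr, sig, batch=batch, seed=3)
        score = combined_zscore(expr, sig).score
        hi = np.array([s == "high" for s in labels.states])
        assert score[hi].mean() > score[~hi].mean()


class TestBatchAdjust:
    def test_pure_location_offset_removed(self, rng):
        vals = rng.normal(0, 1, size=(5, 20))
        genes = [f"g{i}" for i in range(5)]
        samples = [f"s{j}" for j in range(20)]
        batch = ["a"] * 10 + ["b"] * 10
        shifted = vals.copy()
        shifted[:, 10:] += 7.0
        adj = batch_adjust(
            ExpressionMatrix(genes=genes, samples=samples, values=shifted), batch
        )
        means_a = adj.values[:, :10].mean(axis=1)
        means_b = adj.values[:, 10:].mean(axis=1)
        np.testing.assert_allclose(means_a, means_b, atol=1e-9)
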