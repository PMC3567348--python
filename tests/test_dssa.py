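"""Differential strain sensitivity analysis: each stage against oracles."""

import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

from fitscreen.dssa import (
    ArrayExperiment,
    PairOutlierResult,
    binomial_tail,
    build_pairs,
    detect_outliers,
    fitness_scores,
    gene_binomial_calls,
    normalize_pair,
    preprocess_arrays,
    select_effective_pairs,
    summarize_conditions,
)


def make_experiment(columns, n_genes, n_nulls, meta, ceiling=60000.0):
    probes = pd.DataFrame(
        {
            "gene_id": [f"G{i}" for i in range(n_genes)] + [""] * n_nulls,
            "is_null_feature": [False] * n_genes + [True] * n_nulls,
        },
        index=[f"P{i}" for i in range(n_genes)] + [f"N{i}" for i in range(n_nulls)],
    )
    return ArrayExperiment(
        intensities=pd.DataFrame(columns, index=probes.index),
        probes=probes,
        arrays=pd.DataFrame(meta).set_index("array_id"),
        saturation_ceiling=ceiling,
    )


class TestPreprocess:
    def test_exact_medians_give_adjusted_two(self):
        cols = {"A1": np.array([2.0 ** 12] * 3 + [2.0 ** 10] * 3)}
        meta = [{"array_id": "A1", "dose_uM": 0.0, "generations": 5,
                 "arm": "control", "replicate": 1}]
        exp = make_experiment(cols, 3, 3, meta)
        adj = preprocess_arrays(exp, pseudocount=0.0)
        assert np.allclose(adj.gene_matrix()["A1"], 2.0)

    def test_null_median_is_zero_after_adjustment(self, tiny_array_experiment):
        adj = preprocess_arrays(tiny_array_experiment)
        nulls = adj.log2.loc[tiny_array_experiment.null_probes]
        assert np.all(np.abs(nulls.median(axis=0)) < 1e-9)

    def test_saturated_probes_winsorized_and_flagged(self):
        cols = {"A1": np.array([3 * 1000.0, 500.0, 400.0, 100.0, 110.0, 120.0])}
        meta = [{"array_id": "A1", "dose_uM": 0.0, "generations": 5,
                 "arm": "control", "replicate": 1}]
        exp = make_experiment(cols, 3, 3, meta, ceiling=1000.0)
        adj = preprocess_arrays(exp)
        assert adj.saturated.loc["P0", "A1"]
        assert adj.log2.loc["P0", "A1"] <= np.log2(1001.0)

    def test_background_location_matches_median_oracle(self, rng):
        nulls = rng.lognormal(6, 0.8, 200)
        genes = rng.lognormal(9, 0.5, 50)
        cols = {"A1": np.concatenate([genes, nulls])}
        meta = [{"array_id": "A1", "dose_uM": 0.0, "generations": 5,
                 "arm": "control", "replicate": 1}]
        exp = make_experiment(cols, 50, 200, meta)
        adj = preprocess_arrays(exp, pseudocount=1.0)
        oracle_loc = float(np.median(np.log2(sorted(nulls) + np.ones(200))))
        recovered = np.log2(genes + 1.0) - adj.gene_matrix()["A1"].to_numpy()
        assert np.allclose(recovered, oracle_loc)
        oracle_scale = 1.4826 * np.median(
            np.abs(np.log2(nulls + 1.0) - oracle_loc)
        )
        assert adj.background_scale["A1"] == pytest.approx(oracle_scale, rel=1e-12)

    def test_all_zero_array_rejected(self):
        cols = {"A1": np.zeros(6), "A2": np.ones(6)}
        meta = [
            {"array_id": a, "dose_uM": 0.0, "generations": 5, "arm": "control",
             "replicate": i}
            for i, a in enumerate(["A1", "A2"], 1)
        ]
        exp = make_experiment(cols, 3, 3, meta)
        with pytest.raises(ValueError, match="all-zero"):
            preprocess_arrays(exp)


class TestBuildPairs:
    @pytest.mark.parametrize("n_t,n_c,expected", [(3, 12, 36), (1, 1, 1), (2, 5, 10)])
    def test_cartesian_pairing(self, n_t, n_c, expected, rng):
        cols, meta = {}, []
        for i in range(n_t):
            cols[f"T{i}"] = rng.uniform(1, 10, 4)
            meta.append({"array_id": f"T{i}", "dose_uM": 330.0, "generations": 5,
                         "arm": "treatment", "replicate": i})
        for i in range(n_c):
            cols[f"C{i}"] = rng.uniform(1, 10, 4)
            meta.append({"array_id": f"C{i}", "dose_uM": 0.0, "generations": 5,
                         "arm": "control", "replicate": i})
        exp = make_experiment(cols, 2, 2, meta)
        pairs = build_pairs(exp)
        assert len(pairs) == expected
        assert len({(t, c) for t, c, _ in pairs}) == expected  # all distinct
        oracle = {(f"T{i}", f"C{j}") for i in range(n_t) for j in range(n_c)}
        assert {(t, c) for t, c, _ in pairs} == oracle

    def test_missing_generation_arm_errors(self, rng):
        cols = {"T0": rng.uniform(1, 10, 4), "C0": rng.uniform(1, 10, 4)}
        meta = [
            {"array_id": "T0", "dose_uM": 330.0, "generations": 15,
             "arm": "treatment", "replicate": 1},
            {"array_id": "C0", "dose_uM": 0.0, "generations": 5,
             "arm": "control", "replicate": 1},
        ]
        exp = make_experiment(cols, 2, 2, meta)
        with pytest.raises(ValueError, match="generation arm"):
            build_pairs(exp)
        assert len(build_pairs(exp, allow_arm_mismatch=True)) == 1


class TestNormalizePair:
    def test_identical_arrays_give_exact_zero(self, rng):
        x = pd.Series(rng.normal(5, 1, 200), index=[f"G{i}" for i in range(200)])
        m, skipped = normalize_pair(x, x)
        assert not skipped
        assert np.all(m == 0.0)

    def test_constant_offset_removed(self, rng):
        x = pd.Series(rng.normal(5, 1, 200), index=[f"G{i}" for i in range(200)])
        m, _ = normalize_pair(x + 1.0, x)
        assert np.allclose(m, 0.0, atol=1e-6)

    def test_small_gene_set_falls_back_to_median(self, rng):
        x = pd.Series(rng.normal(5, 1, 10), index=[f"G{i}" for i in range(10)])
        m, skipped = normalize_pair(x + 0.7, x)
        assert skipped
        assert np.allclose(m, 0.0, atol=1e-12)

    def test_planted_intensity_trend_flattened_per_decile(self, rng):
        n = 2000
        a = rng.uniform(2, 12, n)
        trend = 0.5 * np.sin(a / 2.0) + 0.05 * a
        noise = rng.normal(0, 0.05, n)
        idx = [f"G{i}" for i in range(n)]
        t = pd.Series(a + (trend + noise) / 2.0, index=idx)
        c = pd.Series(a - (trend + noise) / 2.0, index=idx)
        m, _ = normalize_pair(t, c)
        deciles = pd.qcut(a, 10, labels=False)
        binned = pd.Series(m.to_numpy()).groupby(deciles).mean()
        assert np.all(np.abs(binned.to_numpy()) <= 0.05)


class TestDetectOutliers:
    def test_all_equal_gives_no_calls(self):
        m = pd.Series(np.full(200, 0.3), index=[f"G{i}" for i in range(200)])
        out = detect_outliers(m)
        assert (out["q_value"] == 1.0).all()
        assert not out["outlier"].any()

    def test_planted_twenty_sigma_outlier_called(self, rng):
        vals = rng.normal(0, 0.1, 4000)
        vals[123] = 2.0
        m = pd.Series(vals, index=[f"G{i}" for i in range(4000)])
        out = detect_outliers(m)
        assert out.iloc[123]["outlier"]
        assert out.iloc[123]["q_value"] <= 0.05
        assert out.iloc[123]["sign"] == 1

    def test_null_calibration_mean_call_count(self):
        r = np.random.default_rng(99)
        n_genes, runs = 1000, 200
        counts = []
        for _ in range(runs):
            m = pd.Series(r.normal(0, 0.2, n_genes))
            counts.append(int(detect_outliers(m)["outlier"].sum()))
        # under the global null BH makes any rejection with prob <= alpha
        assert np.mean(counts) <= 0.05 * n_genes
        assert np.mean(counts) <= 2.0  # no systematic inflation

    def test_q_values_monotone_in_abs_residual(self, rng):
        m = pd.Series(rng.normal(0, 0.3, 500))
        out = detect_outliers(m)
        center = np.median(m)
        order = np.argsort(-np.abs(m.to_numpy() - center))
        q_sorted = out["q_value"].to_numpy()[order]
        assert np.all(np.diff(q_sorted) >= -1e-12)


def make_pair(pid, var, m_values=None, signs=None, qs=None, cond=(330.0, 5)):
    n = 5 if m_values is None else len(m_values)
    m = np.zeros(n) if m_values is None else np.asarray(m_values, float)
    return PairOutlierResult(
        pair_id=pid,
        treatment="T",
        control="C",
        condition=cond,
        genes=np.array([f"G{i}" for i in range(n)]),
        m_value=m,
        q_value=np.ones(n) if qs is None else np.asarray(qs, float),
        sign=np.sign(m).astype(int) if signs is None else np.asarray(signs, int),
        residual_variance=var,
    )


class TestSelectEffectivePairs:
    def test_equal_variance_all_effective(self):
        pairs = [make_pair(f"p{i}", 0.01) for i in range(36)]
        eff, report = select_effective_pairs(pairs)
        assert len(eff) == 36
        assert report["effective"].all()

    def test_gross_outlier_pair_excluded(self):
        pairs = [make_pair(f"p{i}", 0.01) for i in range(35)]
        pairs.append(make_pair("bad", 1.0))
        eff, _ = select_effective_pairs(pairs)
        assert len(eff) == 35
        assert all(p.pair_id != "bad" for p in eff)

    def test_matches_tukey_fence_oracle(self):
        r = np.random.default_rng(5)
        var = 0.02 * r.chisquare(4, 30) / 4
        pairs = [make_pair(f"p{i}", v) for i, v in enumerate(var)]
        eff, _ = select_effective_pairs(pairs)
        q1, q3 = np.percentile(var, [25, 75])
        fence = q3 + 1.5 * (q3 - q1)
        oracle = {f"p{i}" for i, v in enumerate(var) if v <= fence}
        assert {p.pair_id for p in eff} == oracle


def binom_tail_enumeration(k, m, pi0):
    """Exhaustive 2^m outcome-vector enumeration of P(X >= k)."""
    total = 0.0
    for outcome in itertools.product([0, 1], repeat=m):
        s = sum(outcome)
        if s >= k:
            total += pi0 ** s * (1 - pi0) ** (m - s)
    return total


class TestGeneBinomialCalls:
    def test_zero_successes_give_p_one(self):
        pairs = [make_pair(f"p{i}", 0.01, m_values=[0.1] * 5) for i in range(6)]
        calls = gene_binomial_calls(pairs)
        assert (calls["p"] == 1.0).all()
        assert not calls["called"].any()

    def test_full_success_closed_form(self):
        # all 36 pairs significant with the same sign: p = 0.05^36
        pairs = [
            make_pair(f"p{i}", 0.01, m_values=[1.0] * 3, qs=[0.01] * 3)
            for i in range(36)
        ]
        calls = gene_binomial_calls(pairs, pi0=0.05)
        assert np.allclose(calls["p"], 0.05 ** 36, rtol=1e-9)
        assert calls["called"].all()

    @pytest.mark.parametrize("pi0", [0.05, 0.2, 0.5])
    def test_tail_matches_exhaustive_enumeration(self, pi0):
        m = 6
        for k in range(m + 1):
            assert binomial_tail(k, m, pi0) == pytest.approx(
                binom_tail_enumeration(k, m, pi0), rel=1e-12
            )

    def test_tail_nonincreasing_in_k(self):
        ps = [binomial_tail(k, 10, 0.3) for k in range(11)]
        assert all(a >= b for a, b in zip(ps, ps[1:]))

    def test_sign_tie_yields_no_call(self):
        pairs = [
            make_pair("p0", 0.01, m_values=[1.0], qs=[0.001]),
            make_pair("p1", 0.01, m_values=[-1.0], qs=[0.001]),
        ]
        calls = gene_binomial_calls(pairs, strict=False)
        assert not calls["called"].any()
        assert (calls["sign"] == 0).all()

    def test_strict_mode_requires_all_pairs(self):
        # significant in 3 of 4 pairs: strict rejects, non-strict may call
        pairs = [
            make_pair(f"p{i}", 0.01, m_values=[2.0] * 2, qs=[0.001] * 2)
            for i in range(3)
        ] + [make_pair("p3", 0.01, m_values=[2.0] * 2, qs=[0.9] * 2)]
        strict = gene_binomial_calls(pairs, strict=True)
        loose = gene_binomial_calls(pairs, strict=False)
        assert not strict["called"].any()
        assert loose["called"].all()


class TestFitnessScores:
    def test_equal_arms_give_zero(self, tiny_array_experiment):
        exp = tiny_array_experiment
        # make treatment arrays copies of a control array
        exp.intensities["T1"] = exp.intensities["C1"]
        exp.intensities["T2"] = exp.intensities["C1"]
        exp.intensities["C2"] = exp.intensities["C1"]
        exp.intensities["C3"] = exp.intensities["C1"]
        adj = preprocess_arrays(exp)
        scores = fitness_scores(adj, exp, (330.0, 5))
        assert np.allclose(scores, 0.0)

    def test_antisymmetry_under_arm_relabel(self, tiny_array_experiment):
        exp = tiny_array_experiment
        adj = preprocess_arrays(exp)
        fwd = fitness_scores(adj, exp, (330.0, 5))
        swapped = exp.arrays.copy()
        swapped["arm"] = swapped["arm"].map(
            {"treatment": "control", "control": "treatment"}
        )
        swapped["dose_uM"] = np.where(swapped["arm"] == "treatment", 330.0, 0.0)
        exp2 = ArrayExperiment(
            intensities=exp.intensities,
            probes=exp.probes,
            arrays=swapped,
            saturation_ceiling=exp.saturation_ceiling,
        )
        rev = fitness_scores(preprocess_arrays(exp2), exp2, (330.0, 5))
        assert np.allclose(fwd.to_numpy(), -rev.to_numpy())


class TestSummarize:
    def _calls(self, rows):
        return pd.DataFrame(
            rows, columns=["gene", "condition", "k", "m", "p", "q", "called",
                           "sign", "fitness_score", "label"]
        )

    def test_empty_calls(self):
        calls = self._calls([])
        out = summarize_conditions(calls)
        assert out["union_counts"] == {"sensitive": 0, "resistant": 0}

    def test_disjoint_sets_union_is_sum(self):
        rows = [
            ["A", "c1", 3, 3, 0.0, 0.0, True, -1, -1.0, "sensitive"],
            ["B", "c2", 3, 3, 0.0, 0.0, True, -1, -1.0, "sensitive"],
        ]
        out = summarize_conditions(self._calls(rows))
        assert out["union_counts"]["sensitive"] == 2
        assert out["recurrent"]["sensitive"] == []

    def test_counts_match_set_algebra_oracle(self):
        r = np.random.default_rng(3)
        genes = [f"G{i}" for i in range(40)]
        conds = ["c1", "c2", "c3", "c4"]
        rows, member = [], {}
        for g in genes:
            for c in conds:
                if r.random() < 0.3:
                    rows.append([g, c, 3, 3, 0.0, 0.0, True, -1, -1.0, "sensitive"])
                    member.setdefault(g, set()).add(c)
        out = summarize_conditions(self._calls(rows), min_conditions=3)
        assert out["union_counts"]["sensitive"] == len(member)
        oracle = sorted(g for g, cs in member.items() if len(cs) >= 3)
        assert out["recurrent"]["sensitive"] == oracle
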