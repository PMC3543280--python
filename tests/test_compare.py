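"""Overlap statistics: Fisher, Monte-Carlo hub nulls, DE rankings, ORA, SNPs."""

import itertools
import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

import adiponet as a
from helpers import make_expr


class TestHarmonizeGenes:
    def _gene_expr(self, symbols, rng):
        return make_expr(rng.standard_normal((len(symbols), 6)),
                         feature_ids=symbols, kind="gene")

    def test_identical_and_partial_symbol_sets(self, rng):
        e1 = self._gene_expr(["A", "B", "C"], rng)
        e2 = self._gene_expr(["B", "C", "D"], rng)
        aligned, shared = a.harmonize_genes([e1, e2], [None, None])
        assert shared == ["B", "C"]
        assert [m.feature_ids for m in aligned] == [["B", "C"], ["B", "C"]]
        same, shared_same = a.harmonize_genes([e1, e1], [None, None])
        assert shared_same == ["A", "B", "C"]

    def test_three_cohorts_match_set_intersection(self, rng):
        pool = [f"G{i}" for i in range(30)]
        subsets = [sorted(rng.choice(pool, 20, replace=False)) for _ in range(3)]
        exprs = [self._gene_expr(s, rng) for s in subsets]
        _, shared = a.harmonize_genes(exprs, [None] * 3)
        assert shared == sorted(set(subsets[0]) & set(subsets[1]) & set(subsets[2]))

    def test_empty_intersection_errors(self, rng):
        e1 = self._gene_expr(["A"], rng)
        e2 = self._gene_expr(["B"], rng)
        with pytest.raises(a.EmptyResultError):
            a.harmonize_genes([e1, e2], [None, None])


class TestFisherOverlap:
    def test_printed_overlap_percentage(self):
        """115 of 123 genes shared gives the headline 93.5% overlap."""
        background = [f"G{i}" for i in range(14000)]
        set_a = background[:320]
        set_b = background[:115] + background[320:328]
        res = a.fisher_module_overlap(set_a, set_b, background)
        assert res.shared_count == 115 and res.set_b_size == 123
        assert res.percentage == pytest.approx(93.5, abs=0.05)
        assert res.fisher_p < 1e-100

    def test_matches_exhaustive_enumeration(self):
        """p equals full enumeration over all C(10,5) placements of set B."""
        background = list("ABCDEFGHIJ")
        set_a = list("ABCD")
        set_b = list("ABCE F".replace(" ", ""))
        res = a.fisher_module_overlap(set_a, set_b, background)
        observed_shared = len(set(set_a) & set(set_b))
        # enumerate every possible 5-subset as B; two-sided Fisher sums the
        # probabilities of tables as or less probable than the observed one
        counts = {}
        for combo in itertools.combinations(background, 5):
            k = len(set(combo) & set(set_a))
            counts[k] = counts.get(k, 0) + 1
        total = math.comb(10, 5)
        probs = {k: c / total for k, c in counts.items()}
        p_obs = probs[observed_shared]
        expected = sum(p for p in probs.values() if p <= p_obs + 1e-12)
        assert res.fisher_p == pytest.approx(expected, rel=1e-9)

    def test_disjoint_sets_degenerate_tails(self):
        background = [f"g{i}" for i in range(10)]
        res = a.fisher_module_overlap(background[:4], background[4:10], background,
                                      sidedness="greater")
        assert res.shared_count == 0
        assert res.fisher_p == pytest.approx(1.0)

    def test_p_symmetric_in_sets_percentage_is_not(self, rng):
        background = [f"g{i}" for i in range(40)]
        set_a = list(rng.choice(background, 12, replace=False))
        set_b = list(rng.choice(background, 7, replace=False))
        r_ab = a.fisher_module_overlap(set_a, set_b, background)
        r_ba = a.fisher_module_overlap(set_b, set_a, background)
        assert r_ab.fisher_p == pytest.approx(r_ba.fisher_p, rel=1e-12)
        assert r_ab.percentage == pytest.approx(100 * r_ab.shared_count / 7)
        assert r_ba.percentage == pytest.approx(100 * r_ab.shared_count / 12)

    def test_element_outside_background_named(self):
        with pytest.raises(a.PipelineError, match="stray"):
            a.fisher_module_overlap(["stray"], ["g1"], ["g1", "g2"])


class TestEmpiricalHubOverlap:
    def _kmes(self, sizes, rng, candidates=()):
        out = []
        for d, m in enumerate(sizes):
            genes = [f"G{i}" for i in range(m)]
            out.append(pd.Series(rng.uniform(0.2, 0.95, m), index=genes))
        return out

    def test_observed_zero_gives_p_one(self, rng):
        kmes = self._kmes((30, 30), rng)
        spec = a.HubOverlapSpec("top_fraction", 0.5, trials=10_000, seed=1)
        res = a.empirical_hub_overlap(kmes, spec, ["G0", "G1"], 0)
        assert res.empirical_p == pytest.approx(1.0)

    @staticmethod
    def exact_joint_overlap_tail(module_size, draw, n_candidates, observed,
                                 n_datasets=3):
        """Closed-form tail of the joint hub count under without-replacement draws.

        Chains hypergeometrics: per dataset the draw captures
        H ~ Hypergeom(module, candidates, draw) candidates, and the running
        intersection of size s shrinks as Hypergeom(candidates, s, H).
        """
        hd = stats.hypergeom(module_size, n_candidates, draw)
        hprobs = [(h, hd.pmf(h)) for h in range(n_candidates + 1) if hd.pmf(h) > 0]
        dist = {n_candidates: 1.0}
        for _ in range(n_datasets):
            new: dict[int, float] = {}
            for s, ps in dist.items():
                for h, ph in hprobs:
                    inner = stats.hypergeom(n_candidates, s, h)
                    for k in range(max(0, s + h - n_candidates), min(s, h) + 1):
                        new[k] = new.get(k, 0.0) + ps * ph * inner.pmf(k)
            dist = new
        return sum(p for k, p in dist.items() if k >= observed)

    def test_matches_exact_hypergeometric_chain_oracle(self, rng):
        """Three modules of 100, top 50% each: 34 candidates, observed 7."""
        kmes = self._kmes((100, 100, 100), rng)
        candidates = [f"G{i}" for i in range(34)]  # members everywhere
        spec = a.HubOverlapSpec("top_fraction", 0.5, trials=100_000, seed=7)
        res = a.empirical_hub_overlap(kmes, spec, candidates, 7)
        exact = self.exact_joint_overlap_tail(100, 50, 34, 7)
        mc_se = math.sqrt(exact * (1 - exact) / spec.trials)
        assert res.empirical_p == pytest.approx(exact, abs=3 * mc_se)

    def test_matches_binomial_tail_in_sparse_candidate_limit(self, rng):
        """With candidates ≪ module, joint inclusion is ≈ independent Bin(34, 0.125)."""
        kmes = self._kmes((2000, 2000, 2000), rng)
        candidates = [f"G{i}" for i in range(34)]
        spec = a.HubOverlapSpec("top_fraction", 0.5, trials=100_000, seed=7)
        res = a.empirical_hub_overlap(kmes, spec, candidates, 7, chunk=5000)
        exact = stats.binom.sf(6, 34, 0.125)
        mc_se = math.sqrt(exact * (1 - exact) / spec.trials)
        assert res.empirical_p == pytest.approx(exact, abs=3 * mc_se)

    def test_impossible_observation_guarded(self, rng):
        kmes = [pd.Series(np.full(20, 0.5), index=[f"G{i}" for i in range(20)])]
        spec = a.HubOverlapSpec("kme_above", 0.9, trials=10_000, seed=0)
        with pytest.raises(a.PipelineError, match="attainable"):
            a.empirical_hub_overlap(kmes, spec, ["G0"], 1)
        res = a.empirical_hub_overlap(kmes, spec, ["G0"], 0)
        assert res.empirical_p == pytest.approx(1.0)

    def test_super_uniform_under_own_null(self):
        """Null-generated observations yield P(p <= 0.05) <= 0.05 + 3 MC se."""
        rng = np.random.default_rng(99)
        sizes = (40, 40, 40)
        candidates = [f"G{i}" for i in range(20)]
        spec_proto = dict(criterion="top_fraction", parameter=0.5, trials=10_000)
        draws = 200
        hits = 0
        kmes = [pd.Series(rng.uniform(0.2, 0.9, m), index=[f"G{i}" for i in range(m)])
                for m in sizes]
        for t in range(draws):
            # generate an observation from the null itself
            joint = np.ones(len(candidates), dtype=bool)
            for m in sizes:
                drawn = rng.choice(m, m // 2, replace=False)
                joint &= np.isin(np.arange(len(candidates)), drawn)
            observed = int(joint.sum())
            spec = a.HubOverlapSpec(seed=int(rng.integers(2**31)), **spec_proto)
            p = a.empirical_hub_overlap(kmes, spec, candidates, observed).empirical_p
            hits += p <= 0.05
        rate = hits / draws
        assert rate <= 0.05 + 3 * math.sqrt(0.05 * 0.95 / draws)

    def test_deterministic_given_seed(self, rng):
        kmes = self._kmes((50, 50), rng)
        spec = a.HubOverlapSpec("top_rank", 10, trials=10_000, seed=5)
        r1 = a.empirical_hub_overlap(kmes, spec, ["G0", "G1", "G2"], 1)
        r2 = a.empirical_hub_overlap(kmes, spec, ["G0", "G1", "G2"], 1)
        assert r1.empirical_p == r2.empirical_p

    def test_criterion_exceeding_module_size_errors(self, rng):
        kmes = self._kmes((5,), rng)
        with pytest.raises(a.PipelineError, match="exceeds"):
            spec = a.HubOverlapSpec("top_rank", 10, trials=10_000, seed=0)
            a.empirical_hub_overlap(kmes, spec, ["G0"], 0)


class TestKmeCrossCorrelation:
    def test_identity_and_negation(self, rng):
        genes = [f"G{i}" for i in range(10)]
        k = pd.Series(rng.uniform(0.2, 0.9, 10), index=genes)
        r, _ = a.kme_cross_correlation(k, k, genes)
        assert r == pytest.approx(1.0)
        r_neg, _ = a.kme_cross_correlation(k, -k, genes)
        assert r_neg == pytest.approx(-1.0)

    def test_attenuation_matches_closed_form(self):
        """Shared loadings + independent noise attenuate r to var(λ)/(var(λ)+σ²)."""
        sigma = 0.2
        genes = [f"G{i}" for i in range(115)]
        lam_lo, lam_hi = 0.1, 0.95
        var_lam = (lam_hi - lam_lo) ** 2 / 12
        expected_r = var_lam / (var_lam + sigma**2)
        in_range, rs = 0, []
        reps = 20
        for seed in range(reps):
            rng = np.random.default_rng(seed)
            lam = rng.uniform(lam_lo, lam_hi, 115)
            ka = pd.Series(lam + sigma * rng.standard_normal(115), index=genes)
            kb = pd.Series(lam + sigma * rng.standard_normal(115), index=genes)
            r, _ = a.kme_cross_correlation(ka, kb, genes)
            rs.append(r)
            in_range += 0.5 <= r <= 0.9
        assert in_range >= 0.9 * reps
        assert np.mean(rs) == pytest.approx(expected_r, abs=0.05)

    def test_constant_vector_errors(self):
        genes = ["G0", "G1", "G2"]
        flat = pd.Series([0.5, 0.5, 0.5], index=genes)
        vary = pd.Series([0.1, 0.5, 0.9], index=genes)
        with pytest.raises(a.PipelineError, match="constant"):
            a.kme_cross_correlation(flat, vary, genes)


class TestDifferentialExpression:
    def _labels(self, n1, n2):
        ids = [f"s{j}" for j in range(n1 + n2)]
        return ids, pd.Series(["case"] * n1 + ["control"] * n2, index=ids)

    def test_null_gene_ranked_last(self, rng):
        ids, labels = self._labels(8, 8)
        X = rng.standard_normal((5, 16))
        X[2, :8] = X[2, 8:]  # identical class values -> t = 0, p = 1
        ranked = a.rank_differential_expression(make_expr(X, sample_ids=ids), labels)
        assert ranked["gene"].iloc[-1] == "g2"
        assert ranked["p"].iloc[-1] == pytest.approx(1.0)

    def test_planted_de_gene_dominates_ranking(self):
        # Δ = 2 sd at n = 10+10 gives t ≈ 4.5 (p ≈ 3e-4); against the minimum
        # of 500 null p-values the top-rank probability calibrates to ~0.75,
        # and the top-10 probability to ~0.95.
        first, top10, reps = 0, 0, 40
        for seed in range(reps):
            rng = np.random.default_rng(seed)
            ids, labels = self._labels(10, 10)
            X = rng.standard_normal((501, 20))
            X[0, :10] += 2.0  # Δ = 2 sd
            ranked = a.rank_differential_expression(make_expr(X, sample_ids=ids), labels)
            pos = int(ranked.index[ranked["gene"] == "g0"][0])
            first += pos == 0
            top10 += pos < 10
        assert first >= 0.55 * reps
        assert top10 >= 0.85 * reps

    def test_matches_hand_computed_welch_ordering(self):
        ids, labels = self._labels(3, 3)
        X = np.array([
            [1.0, 2.0, 3.0, 4.0, 5.0, 6.0],
            [1.0, 1.1, 0.9, 5.0, 5.2, 4.9],
            [2.0, 2.5, 1.5, 2.1, 2.4, 1.8],
        ])
        ranked = a.rank_differential_expression(make_expr(X, sample_ids=ids), labels)

        def welch_t(x1, x2):
            v1, v2 = np.var(x1, ddof=1), np.var(x2, ddof=1)
            return (np.mean(x1) - np.mean(x2)) / math.sqrt(v1 / len(x1) + v2 / len(x2))

        ts = [abs(welch_t(row[:3], row[3:])) for row in X]
        expected_order = [f"g{i}" for i in np.argsort(ts)[::-1]]
        assert ranked["gene"].tolist() == expected_order

    def test_small_class_errors(self, rng):
        ids = [f"s{j}" for j in range(5)]
        labels = pd.Series(["case"] + ["control"] * 4, index=ids)
        with pytest.raises(a.PipelineError, match="2 samples"):
            a.rank_differential_expression(
                make_expr(rng.standard_normal((3, 5)), sample_ids=ids), labels)


class TestTopNOverlap:
    def _ranking(self, genes):
        return pd.DataFrame({"gene": genes})

    def test_identical_and_reversed_rankings(self):
        genes = [f"g{i}" for i in range(200)]
        res = a.top_n_overlap(self._ranking(genes), self._ranking(genes), 100, genes)
        assert res.shared_count == 100
        rev = a.top_n_overlap(self._ranking(genes), self._ranking(genes[::-1]),
                              100, genes)
        assert rev.shared_count == 0

    def test_independent_rankings_match_hypergeometric_expectation(self):
        N, n, reps = 1000, 100, 200
        genes = [f"g{i}" for i in range(N)]
        overlaps = []
        for seed in range(reps):
            rng = np.random.default_rng(seed)
            ra = list(rng.permutation(genes))
            rb = list(rng.permutation(genes))
            overlaps.append(len(set(ra[:n]) & set(rb[:n])))
        expected = n * n / N
        sd = math.sqrt(n * (n / N) * (1 - n / N) * (N - n) / (N - 1))
        assert np.mean(overlaps) == pytest.approx(expected, abs=3 * sd / math.sqrt(reps))

    def test_p_nonincreasing_in_n_for_identical_rankings(self, rng):
        genes = [f"g{i}" for i in range(120)]
        ranking = self._ranking(list(rng.permutation(genes)))
        ps = [a.top_n_overlap(ranking, ranking, n, genes).fisher_p
              for n in (5, 10, 20, 40)]
        assert all(p2 <= p1 + 1e-15 for p1, p2 in zip(ps, ps[1:]))

    def test_n_exceeding_ranking_errors(self):
        genes = ["g0", "g1"]
        with pytest.raises(a.PipelineError, match="exceeds"):
            a.top_n_overlap(self._ranking(genes), self._ranking(genes), 5, genes)


class TestOraEnrichment:
    def test_worked_toy_equals_inverse_binomial_coefficient(self):
        background = [f"g{i}" for i in range(20)]
        gene_sets = {"setA": background[:5]}
        res = a.ora_enrichment(background[:5], gene_sets, background)
        assert res.table["p"].iloc[0] == pytest.approx(1 / math.comb(20, 5), rel=1e-9)
        assert res.table["bonferroni_p"].iloc[0] == res.table["p"].iloc[0]

    def test_disjoint_query_gives_p_one(self):
        background = [f"g{i}" for i in range(20)]
        res = a.ora_enrichment(background[10:], {"s": background[:5]}, background)
        assert res.table["p"].iloc[0] == pytest.approx(1.0)

    @settings(deadline=None, max_examples=60, derandomize=True)
    @given(data=st.data())
    def test_matches_exact_enumeration_small_backgrounds(self, data):
        N = data.draw(st.integers(5, 25))
        K = data.draw(st.integers(1, N))
        nq = data.draw(st.integers(1, N))
        background = [f"g{i}" for i in range(N)]
        gene_set = background[:K]
        query = background[N - nq:]
        overlap = len(set(gene_set) & set(query))
        res = a.ora_enrichment(query, {"s": gene_set}, background)
        # exact integer-arithmetic enumeration of the hypergeometric upper tail
        exact = sum(
            math.comb(K, k) * math.comb(N - K, nq - k)
            for k in range(overlap, min(K, nq) + 1)
        ) / math.comb(N, nq)
        assert res.table["p"].iloc[0] == pytest.approx(exact, rel=1e-9)

    def test_empty_query_errors(self):
        with pytest.raises(a.PipelineError, match="empty"):
            a.ora_enrichment([], {"s": ["g1"]}, ["g1"])


class TestSnpAssociation:
    def _dosage(self, rng, n):
        ids = [f"s{j}" for j in range(n)]
        return pd.Series(rng.binomial(2, 0.3, n).astype(float), index=ids)

    def test_perfect_and_null_association(self, rng):
        g = self._dosage(rng, 30)
        r, p = a.snp_association(g, g.copy())
        assert r == pytest.approx(1.0)
        nulls = 0
        reps = 20
        for seed in range(reps):
            rng2 = np.random.default_rng(seed)
            g2 = self._dosage(rng2, 1000)
            t = pd.Series(rng2.standard_normal(1000), index=g2.index)
            r2, _ = a.snp_association(g2, t)
            nulls += abs(r2) < 0.1
        assert nulls >= 0.95 * reps

    def test_power_matches_noncentral_t_oracle(self):
        """Planted eQTL (slope 0.5, σ=1, n=20): empirical power ≈ noncentral-t power."""
        rng = np.random.default_rng(1)
        n = 20
        g = self._dosage(rng, n)
        while g.std() == 0:
            g = self._dosage(rng, n)
        b, sigma = 0.5, 1.0
        sxx = float(((g - g.mean()) ** 2).sum())
        ncp = b * math.sqrt(sxx) / sigma
        tcrit = stats.t.ppf(0.975, df=n - 2)
        power = stats.nct.sf(tcrit, n - 2, ncp) + stats.nct.cdf(-tcrit, n - 2, ncp)
        reps, hits = 400, 0
        for seed in range(reps):
            rng2 = np.random.default_rng(10_000 + seed)
            target = pd.Series(b * g.to_numpy() + sigma * rng2.standard_normal(n),
                               index=g.index)
            _, p = a.snp_association(g, target)
            hits += p < 0.05
        se = math.sqrt(power * (1 - power) / reps)
        assert hits / reps == pytest.approx(power, abs=3.5 * se)

    def test_constant_genotype_errors(self, rng):
        ids = [f"s{j}" for j in range(5)]
        g = pd.Series(np.ones(5), index=ids)
        t = pd.Series(rng.standard_normal(5), index=ids)
        with pytest.raises(a.PipelineError, match="constant"):
            a.snp_association(g, t)
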