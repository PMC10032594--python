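"""Frequencies, biallelization, Hudson F_ST, pruning, Bayes factors, overlap test."""

import numpy as np
import pandas as pd
import pytest

from strhab.genotypes import StrGenotypeMatrix
from strhab.popgen import (
    biallelize,
    env_bayes_factor,
    estimate_covariance,
    fst_scan,
    hudson_fst,
    ld_prune,
    overlap_permutation_test,
    subpop_allele_frequencies,
)
from strhab.envspace import decompose, subpop_mean_env
from strhab.synth import CohortSpec, PlantedEffect, generate_cohort


def _geno(calls):
    """calls: {accession: [(a1, a2) per locus]}"""
    acc = sorted(calls)
    n_loci = len(next(iter(calls.values())))
    a1 = np.array([[calls[a][j][0] for j in range(n_loci)] for a in acc])
    a2 = np.array([[calls[a][j][1] for j in range(n_loci)] for a in acc])
    return StrGenotypeMatrix(acc, [f"L{j}" for j in range(n_loci)], a1, a2)


class TestFrequencies:
    def test_simple_count(self):
        g = _geno({"a": [(7, 7)], "b": [(7, 4)]})
        sp = pd.Series({"a": "x", "b": "x"})
        out = subpop_allele_frequencies(g, sp)
        spectrum, n = out["L0"]["x"]
        assert n == 4
        assert spectrum == {7: 0.75, 4: 0.25}

    def test_identical_homozygotes(self):
        g = _geno({"a": [(9, 9)], "b": [(9, 9)]})
        sp = pd.Series({"a": "x", "b": "x"})
        spectrum, n = subpop_allele_frequencies(g, sp)["L0"]["x"]
        assert spectrum == {9: 1.0}

    def test_matches_brute_force_tally(self, small_cohort):
        g, sp = small_cohort["geno"], small_cohort["subpops"]
        out = subpop_allele_frequencies(g, sp)
        rng = np.random.default_rng(0)
        for j in rng.choice(g.n_loci, size=5, replace=False):
            locus = g.loci[j]
            for pop in sp.unique():
                rows = [i for i, a in enumerate(g.accessions) if sp[a] == pop]
                alleles = [g.a1[i, j] for i in rows] + [g.a2[i, j] for i in rows]
                spectrum, n = out[locus][pop]
                assert n == len(alleles)
                for v in set(alleles):
                    assert spectrum[v] == pytest.approx(alleles.count(v) / n)

    def test_missing_calls_excluded(self):
        g = _geno({"a": [(7, 7)], "b": [(-1, -1)]})
        sp = pd.Series({"a": "x", "b": "x"})
        spectrum, n = subpop_allele_frequencies(g, sp)["L0"]["x"]
        assert n == 2 and spectrum == {7: 1.0}


class TestBiallelize:
    def test_major_allele_definition(self):
        freqs = {
            "L0": {
                "x": ({7: 0.5, 4: 0.3, 9: 0.2}, 10),
                "y": ({7: 0.1, 4: 0.9}, 10),
            }
        }
        view = biallelize(freqs)
        # pooled chromosomes: allele 4 has 0.3*10 + 0.9*10 = 12 of 20 -> major
        assert view.major_allele[0] == 4
        assert np.allclose(view.p[0], [0.3, 0.9])
        freqs2 = {"L0": {"x": ({7: 0.9, 4: 0.1}, 10), "y": ({7: 0.8, 4: 0.2}, 10)}}
        view2 = biallelize(freqs2)
        assert view2.major_allele[0] == 7
        assert np.allclose(view2.p[0], [0.9, 0.8])

    def test_monomorphic(self):
        view = biallelize({"L0": {"x": ({5: 1.0}, 8), "y": ({5: 1.0}, 6)}})
        assert np.allclose(view.p[0], 1.0)

    def test_tie_smaller_unit_wins(self):
        view = biallelize({"L0": {"x": ({4: 0.5, 9: 0.5}, 10)}})
        assert view.major_allele[0] == 4

    def test_mass_conserved(self, small_cohort):
        """Major frequency plus pooled remainder is 1 per subpopulation."""
        freqs = subpop_allele_frequencies(small_cohort["geno"], small_cohort["subpops"])
        view = biallelize(freqs)
        for i, locus in enumerate(view.loci):
            for k, pop in enumerate(view.subpops):
                if np.isnan(view.p[i, k]):
                    continue
                spectrum, _ = freqs[locus][pop]
                pooled_rest = sum(f for a, f in spectrum.items() if a != view.major_allele[i])
                assert view.p[i, k] + pooled_rest == pytest.approx(1.0, abs=1e-9)


class TestHudsonFst:
    def test_fixed_difference(self):
        assert hudson_fst(1.0, 0.0, 20, 20) == pytest.approx(1.0)

    def test_worked_half_half_n11(self):
        """(0.5, 0.5, n=11): (0 - 0.025 - 0.025) / 0.5 = -0.1."""
        assert hudson_fst(0.5, 0.5, 11, 11) == pytest.approx(-0.1)

    def test_both_fixed_same_allele_undefined(self):
        assert np.isnan(hudson_fst(1.0, 1.0, 10, 10))

    def test_symmetry(self):
        rng = np.random.default_rng(1)
        for _ in range(100):
            p1, p2 = rng.uniform(size=2)
            n1, n2 = rng.integers(2, 100, size=2)
            assert hudson_fst(p1, p2, n1, n2) == pytest.approx(hudson_fst(p2, p1, n2, n1))

    def test_small_n_raises(self):
        with pytest.raises(ValueError):
            hudson_fst(0.5, 0.5, 1, 10)


class TestFstScan:
    def test_pair_count_ten_subpops(self):
        spec = CohortSpec(n_accessions=60, n_subpops=10, n_str_loci=5, n_snps=20, n_env_vars=8, seed=2)
        g, _, _, sp, _ = generate_cohort(spec)
        view = biallelize(subpop_allele_frequencies(g, sp))
        pairs, summary = fst_scan(view)
        assert len(pairs) == 5 * 45
        assert set(summary["n_pairs_defined"]) <= set(range(46))

    def test_no_divergence_fst_near_zero(self):
        vals = []
        for rep in range(5):
            spec = CohortSpec(
                n_accessions=100, n_subpops=5, n_str_loci=30, n_snps=20,
                n_env_vars=8, drift_scale=0.0, seed=60 + rep,
            )
            g, _, _, sp, _ = generate_cohort(spec)
            view = biallelize(subpop_allele_frequencies(g, sp))
            _, summary = fst_scan(view)
            vals.append(summary["fst_mean"].mean())
        assert abs(np.mean(vals)) < 0.02

    def test_outlier_rate_definitional(self):
        spec = CohortSpec(n_accessions=100, n_subpops=5, n_str_loci=100, n_snps=20, n_env_vars=8, seed=3)
        g, _, _, sp, _ = generate_cohort(spec)
        view = biallelize(subpop_allele_frequencies(g, sp))
        _, summary = fst_scan(view)
        frac = summary["outlier"].mean()
        assert 0.02 <= frac <= 0.06  # ~5% by the percentile rule

    def test_fst_monotone_in_drift(self):
        """Mean F_ST rises with the drift scale (rank correlation over a grid)."""
        from scipy.stats import spearmanr

        grid = (0.0, 0.5, 1.0, 2.0, 4.0)
        means = []
        for ds in grid:
            vals = []
            for rep in range(4):
                spec = CohortSpec(
                    n_accessions=100, n_subpops=5, n_str_loci=25, n_snps=20,
                    n_env_vars=8, drift_scale=ds, seed=70 + rep,
                )
                g, _, _, sp, _ = generate_cohort(spec)
                view = biallelize(subpop_allele_frequencies(g, sp))
                _, summary = fst_scan(view)
                vals.append(summary["fst_mean"].mean())
            means.append(np.mean(vals))
        rho, _ = spearmanr(grid, means)
        assert rho > 0.9

    def test_planted_divergent_locus_flagged(self):
        hits = 0
        for rep in range(20):
            spec = CohortSpec(
                n_accessions=120, n_subpops=6, n_str_loci=40, n_snps=20,
                n_env_vars=8, seed=700 + rep, n_divergent_loci=1,
            )
            g, _, _, sp, truth = generate_cohort(spec)
            view = biallelize(subpop_allele_frequencies(g, sp))
            _, summary = fst_scan(view)
            hits += bool(summary.set_index("locus").loc[truth.divergent_loci[0], "outlier"])
        assert hits >= 19


class TestLdPrune:
    def test_duplicates_pruned(self):
        rng = np.random.default_rng(4)
        x = rng.normal(size=(50, 1))
        X = np.hstack([x, x, rng.normal(size=(50, 1))])
        kept = ld_prune(X, size=10, step=5, threshold=0.1)
        assert list(kept) == [0, 2]

    def test_independent_retained(self):
        rng = np.random.default_rng(5)
        X = rng.normal(size=(500, 8))
        kept = ld_prune(X, size=8, step=4, threshold=0.1)
        assert list(kept) == list(range(8))

    def test_zero_variance_dropped(self):
        X = np.ones((20, 3))
        X[:, 1] = np.arange(20)
        kept = ld_prune(X, size=3, step=1, threshold=0.1)
        assert list(kept) == [1]

    def test_matches_exhaustive_oracle_within_window(self):
        """Greedy pruning equals a brute-force pairwise-r^2 filter when one
        window covers all columns."""
        rng = np.random.default_rng(6)
        for _ in range(20):
            base = rng.normal(size=(80, 4))
            cols = [base[:, i % 4] + rng.normal(scale=rng.uniform(0.1, 3), size=80) for i in range(12)]
            X = np.column_stack(cols)
            kept = ld_prune(X, size=12, step=12, threshold=0.1)
            # oracle: scan columns left to right, keep unless r^2 with a kept
            # earlier column exceeds the threshold
            oracle = []
            for j in range(12):
                ok = True
                for i in oracle:
                    r = np.corrcoef(X[:, i], X[:, j])[0, 1]
                    if r * r > 0.1:
                        ok = False
                        break
                if ok:
                    oracle.append(j)
            assert list(kept) == oracle


class TestCovariance:
    def test_two_subpop_hand_computed(self):
        from strhab.popgen import BiallelicView

        p = np.array([[0.2, 0.4], [0.5, 0.9], [0.3, 0.1], [0.8, 0.6]])
        view = BiallelicView(
            loci=[f"L{i}" for i in range(4)], subpops=["x", "y"],
            p=p, n=np.full((4, 2), 20), major_allele=np.array([7, 7, 7, 7]),
        )
        cov = estimate_covariance(view)
        x = np.arcsin(np.sqrt(p))
        want = np.cov(x, rowvar=False)
        assert np.allclose(cov.to_numpy(), want)

    def test_structure_recovered(self):
        """The covariance top axis correlates with the generator's subpop structure."""
        spec = CohortSpec(
            n_accessions=200, n_subpops=10, n_str_loci=150, n_snps=20,
            n_env_vars=8, drift_scale=2.0, seed=8,
        )
        g, _, _, sp, _ = generate_cohort(spec)
        view = biallelize(subpop_allele_frequencies(g, sp))
        cov = estimate_covariance(view)
        # diagonal dominates (per-subpop drift variance) and is positive
        assert np.all(np.diag(cov) > 0)
        assert np.mean(np.diag(cov)) > abs(np.mean(cov.to_numpy()[~np.eye(10, dtype=bool)]))

    def test_too_few_loci_raises(self):
        from strhab.popgen import BiallelicView

        view = BiallelicView(["L0"], ["x", "y"], np.array([[0.5, 0.5]]), np.full((1, 2), 10), np.array([7]))
        with pytest.raises(ValueError):
            estimate_covariance(view)


class TestBayesFactor:
    def _setup(self, spec):
        g, _, env, sp, truth = generate_cohort(spec)
        view = biallelize(subpop_allele_frequencies(g, sp))
        pruned = ld_prune(np.nan_to_num(view.p.T), size=10, step=1, threshold=0.1)
        cov = estimate_covariance(view, pruned)
        sub_pca = decompose(subpop_mean_env(env, sp), rule="per_axis_min:0.01")
        return view, cov, sub_pca, truth

    def test_constant_environment_gives_unit_bf(self):
        spec = CohortSpec(n_accessions=100, n_subpops=5, n_str_loci=30, n_snps=20, n_env_vars=8, seed=9)
        view, cov, sub_pca, _ = self._setup(spec)
        const = pd.DataFrame({"flat": np.ones(5)}, index=sub_pca.scores.index)
        bf = env_bayes_factor(view, const, cov)
        assert np.abs(bf["log10_bf"]).max() < 1e-9

    def test_prior_collapse_to_null(self):
        """prior_sd -> 0 collapses every Bayes factor to 1."""
        spec = CohortSpec(n_accessions=100, n_subpops=5, n_str_loci=30, n_snps=20, n_env_vars=8, seed=10)
        view, cov, sub_pca, _ = self._setup(spec)
        bf = env_bayes_factor(view, sub_pca.scores, cov, prior_sd=1e-9)
        assert np.abs(bf["log10_bf"]).max() < 1e-6

    def test_null_median_below_strong_evidence(self):
        spec = CohortSpec(n_accessions=200, n_subpops=10, n_str_loci=200, n_snps=20, n_env_vars=20, seed=11)
        view, cov, sub_pca, _ = self._setup(spec)
        bf = env_bayes_factor(view, sub_pca.scores, cov, prior_sd=1.0)
        assert bf["log10_bf"].median() < 1.0

    def test_planted_gradient_recovered(self):
        """A strong frequency cline yields log10 BF > 1 in >= 90% of replicates."""
        hits = 0
        for rep in range(20):
            spec = CohortSpec(
                n_accessions=200, n_subpops=10, n_str_loci=60, n_snps=20, n_env_vars=88,
                confound_strength=0.8, seed=900 + rep,
                planted_effects=(PlantedEffect("L0010", env_axis=0, beta=2.5, shape="cline"),),
            )
            view, cov, sub_pca, _ = self._setup(spec)
            bf = env_bayes_factor(view, sub_pca.scores, cov, prior_sd=1.0)
            hits += bf.loc[bf["locus"] == "L0010", "log10_bf"].max() > 1
        assert hits >= 18


class TestOverlap:
    def test_identical_sets(self):
        s = set(range(10))
        res = overlap_permutation_test([s, s, s], set(range(50)), n_draws=200, seed=0)
        assert res.observed == 10
        assert res.p < 0.05

    def test_disjoint_sets(self):
        uni = set(range(60))
        res = overlap_permutation_test(
            [set(range(20)), set(range(20, 40)), set(range(40, 60))], uni, n_draws=200, seed=1
        )
        assert res.observed == 0
        assert res.p > 0.5

    def test_null_mean_matches_closed_form(self):
        """E[overlap] for independent draws = N * prod(k_i / N)."""
        uni = set(range(100))
        rng = np.random.default_rng(2)
        sets = [set(rng.choice(100, size=20, replace=False)) for _ in range(3)]
        res = overlap_permutation_test(sets, uni, n_draws=4000, seed=3)
        expect = 100 * (20 / 100) ** 3
        se = np.sqrt(expect / 4000) * 3  # generous: Poisson-scale error
        assert abs(res.null_mean - expect) < max(3 * se, 0.1)

    def test_at_least_two_rule(self):
        sets = [{1, 2}, {2, 3}, {4}]
        res = overlap_permutation_test(sets, set(range(10)), n_draws=50, seed=4, overlap_rule="at_least_two")
        assert res.observed == 1

    def test_oversized_set_rejected(self):
        with pytest.raises(ValueError):
            overlap_permutation_test([{1, 99}], {1, 2, 3}, n_draws=10, seed=0)

    def test_seeded_determinism(self):
        uni = set(range(40))
        sets = [set(range(8)), set(range(5, 14)), set(range(10, 20))]
        r1 = overlap_permutation_test(sets, uni, n_draws=300, seed=9)
        r2 = overlap_permutation_test(sets, uni, n_draws=300, seed=9)
        assert (r1.null_mean, r1.p) == (r2.null_mean, r2.p)
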