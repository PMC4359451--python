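"""Haplotype-copying HMM: forward-backward oracle, refinement, R-hat-squared."""

import itertools

import numpy as np
import pytest

from exocall.ldc import (
    HmmConfig,
    estimate_rsq,
    merge_scaffold,
    mix_matrix,
    refine_callset,
    sample_individual,
)


def enumerate_marginals(templates, gl3, eps, rho):
    """Independent oracle: exact pair-state marginals by summing over every
    path of the K^2-state chain (feasible for <=3 markers, K<=3)."""
    K, M = templates.shape
    mix = mix_matrix(eps)
    states = list(itertools.product(range(K), repeat=2))

    def emis(m, j, l):
        d = templates[j, m] + templates[l, m]
        return float(mix[d] @ gl3[m])

    def trans(a, b):
        return ((1 - rho) * (a == b) + rho / K)

    gamma = np.zeros((M, K, K))
    total = 0.0
    for path in itertools.product(states, repeat=M):
        p = 1.0 / K**2 * emis(0, *path[0])
        for m in range(1, M):
            (j0, l0), (j1, l1) = path[m - 1], path[m]
            p *= trans(j0, j1) * trans(l0, l1) * emis(m, j1, l1)
        total += p
        for m, (j, l) in enumerate(path):
            gamma[m, j, l] += p
    return gamma / total


def genotype_posterior_from_gamma(gamma, templates, gl3, eps):
    """Genotype triplet implied by state marginals."""
    K, M = templates.shape
    mix = mix_matrix(eps)
    post = np.zeros((M, 3))
    for m in range(M):
        for j in range(K):
            for l in range(K):
                d = templates[j, m] + templates[l, m]
                w = mix[d] * gl3[m]
                post[m] += gamma[m, j, l] * w / w.sum()
    return post


class TestForwardBackwardOracle:
    @pytest.mark.parametrize("seed", range(6))
    def test_marginals_match_enumeration(self, seed):
        r = np.random.default_rng(seed)
        K = int(r.integers(1, 4))
        M = int(r.integers(1, 4))
        templates = r.integers(0, 2, (K, M)).astype(np.int8)
        gl3 = r.uniform(0.05, 1.0, (M, 3))
        eps = float(r.uniform(0.005, 0.2))
        rho = float(r.uniform(0.01, 0.4))
        cfg = HmmConfig(n_iterations=2, burn_in=1, seed=seed)
        res = sample_individual(
            templates, gl3, cfg, np.random.default_rng(0), rho=rho, eps=eps,
            return_gamma=True,
        )
        ref_gamma = enumerate_marginals(templates, gl3, eps, rho)
        np.testing.assert_allclose(res["gamma"], ref_gamma, atol=1e-10)
        ref_post = genotype_posterior_from_gamma(ref_gamma, templates, gl3, eps)
        np.testing.assert_allclose(res["post3"], ref_post, atol=1e-10)

    def test_forced_copy_single_template(self):
        """K=1, tiny rates, no read data: the posterior concentrates on the
        template's implied genotype."""
        templates = np.array([[1, 0, 1]], dtype=np.int8)
        gl3 = np.ones((3, 3))
        cfg = HmmConfig(n_iterations=2, burn_in=1)
        res = sample_individual(
            templates, gl3, cfg, np.random.default_rng(0), rho=1e-6, eps=1e-4
        )
        assert res["post3"][0].argmax() == 2  # template dosage 1+1
        assert res["post3"][1].argmax() == 0
        assert res["post3"][0, 2] > 0.99

    def test_strong_reads_dominate_templates(self):
        """Overwhelming het evidence wins regardless of the panel."""
        templates = np.zeros((3, 1), dtype=np.int8)
        gl3 = np.array([[1e-12, 1.0, 1e-12]])
        cfg = HmmConfig()
        res = sample_individual(templates, gl3, cfg, np.random.default_rng(0), eps=0.01)
        assert res["post3"][0, 1] > 0.99

    def test_zero_templates_rejected(self):
        with pytest.raises(ValueError):
            sample_individual(
                np.zeros((0, 2), dtype=np.int8), np.ones((2, 3)), HmmConfig(),
                np.random.default_rng(0),
            )


class TestRsq:
    def test_identical_dosages_zero(self):
        assert estimate_rsq(np.full(10, 1.0)) == 0.0

    def test_hand_computed(self):
        """{0,0,1,1}: Var=0.25, 2f(1-f)=0.375 -> 2/3."""
        assert estimate_rsq(np.array([0, 0, 1, 1.0])) == pytest.approx(2 / 3)

    def test_hard_hwe_dosages_near_one(self, rng):
        f = 0.3
        hap = rng.random((2, 500)) < f
        dos = hap.sum(axis=0).astype(float)
        assert estimate_rsq(dos) > 0.9

    def test_few_samples_rejected(self):
        with pytest.raises(ValueError):
            estimate_rsq(np.array([1.0]))


class TestMergeScaffold:
    def _callset(self):
        import pandas as pd

        from exocall.callset import CallSet

        sites = pd.DataFrame(
            {
                "chrom": ["chr1"] * 2,
                "pos": [1000, 2000],
                "ref": [0, 1],
                "alts": [(2,), (3,)],
                "qual": [50.0, 50.0],
            }
        )
        z = np.zeros((2, 3), dtype=np.int8)
        return CallSet("pbc", list("abc"), sites, z, z.copy(), z.astype(float), z.astype(np.int32))

    def test_empty_scaffold(self):
        mm = merge_scaffold(self._callset(), None, None, [(900, 2500)])
        assert (mm["source"] == "sequence").all()
        assert len(mm) == 2

    def test_window_rule(self):
        import pandas as pd

        scaffold = pd.DataFrame(
            {"chrom": ["chr1"] * 2, "pos": [400_000, 700_000], "ref": [0, 0],
             "alt": [2, 2], "on_target": [False, False]}
        )
        mm = merge_scaffold(self._callset(), scaffold, None, [(900, 2500)], window=500_000)
        assert 400_000 in mm["pos"].values  # within 500 kb
        assert 700_000 not in mm["pos"].values  # beyond the window

    def test_masked_inside_target(self):
        import pandas as pd

        scaffold = pd.DataFrame(
            {"chrom": ["chr1"], "pos": [1500], "ref": [0], "alt": [2],
             "on_target": [True]}
        )
        mm = merge_scaffold(self._callset(), scaffold, None, [(900, 2500)])
        row = mm[mm["pos"] == 1500].iloc[0]
        assert bool(row["masked"])

    def test_allele_mismatch_rejected(self):
        import pandas as pd

        scaffold = pd.DataFrame(
            {"chrom": ["chr1"], "pos": [1000], "ref": [0], "alt": [3],
             "on_target": [True]}
        )
        with pytest.raises(ValueError):
            merge_scaffold(self._callset(), scaffold, None, [(900, 2500)])


class TestRefinement:
    def test_single_sample_returns_input_posteriors(self):
        import pandas as pd

        from exocall.callset import CallSet

        sites = pd.DataFrame(
            {"chrom": ["chr1"], "pos": [1000], "ref": [0], "alts": [(2,)],
             "qual": [50.0], "f_hat": [0.2]}
        )
        gl3 = np.array([[[0.1, 1.0, 0.1]]])
        z = np.zeros((1, 1), dtype=np.int8)
        cs = CallSet("pbc", ["only"], sites, z, z.copy(), z.astype(float),
                     z.astype(np.int32), gl3=gl3)
        out = refine_callset(cs, [(900, 2000)], cfg=HmmConfig(n_iterations=2, burn_in=1))
        prior = np.array([0.64, 0.32, 0.04])
        expected = gl3[0, 0] * prior
        expected /= expected.sum()
        np.testing.assert_allclose(out.post3[0, 0], expected, atol=1e-12)

    def test_determinism_under_seed(self, small_data):
        from exocall.pbc import call_pbc

        cs = call_pbc(
            small_data.loglik, small_data.depth, small_data.refs,
            small_data.positions, small_data.cohort.samples,
            reads=small_data.read_tuple,
        )
        cfg = dict(n_iterations=4, n_reference_haplotypes=8, burn_in=2, seed=5)
        a = refine_callset(cs, small_data.cohort.targets, cfg=HmmConfig(**cfg))
        b = refine_callset(cs, small_data.cohort.targets, cfg=HmmConfig(**cfg))
        np.testing.assert_array_equal(a.a1, b.a1)
        np.testing.assert_allclose(a.post3, b.post3)
        np.testing.assert_allclose(a.sites["rsq"], b.sites["rsq"])

    def test_site_set_unchanged_and_triplets_normalized(self, small_data):
        from exocall.pbc import call_pbc

        cs = call_pbc(
            small_data.loglik, small_data.depth, small_data.refs,
            small_data.positions, small_data.cohort.samples,
            reads=small_data.read_tuple,
        )
        out = refine_callset(
            cs, small_data.cohort.targets,
            scaffold_sites=small_data.cohort.scaffold_sites,
            scaffold_gt=small_data.cohort.scaffold_gt,
            cfg=HmmConfig(n_iterations=4, n_reference_haplotypes=8, burn_in=2, seed=3),
        )
        assert out.n_sites == cs.n_sites
        assert (out.sites["pos"].to_numpy() == cs.sites["pos"].to_numpy()).all()
        np.testing.assert_allclose(out.post3.sum(axis=2), 1.0, atol=1e-9)
        assert np.all((out.dosage >= 0) & (out.dosage <= 2))
        assert np.all((out.sites["rsq"] >= 0) & (out.sites["rsq"] <= 1))


def test_ld_partner_imputation():
    """Two perfectly LD'd markers: a sample with no data at marker 2 is
    imputed to match its marker-1 genotype in nearly all seeds."""
    n_ok = 0
    for seed in range(10):
        r = np.random.default_rng(seed)
        n = 30
        hap1 = r.integers(0, 2, 2 * n).astype(np.int8)
        haps = np.stack([hap1, hap1], axis=1)  # (2n, 2 markers), perfect LD
        g = haps[0::2] + haps[1::2]
        import pandas as pd

        from exocall.callset import CallSet

        sites = pd.DataFrame(
            {"chrom": ["chr1"] * 2, "pos": [1000, 1100], "ref": [0, 0],
             "alts": [(2,), (2,)], "qual": [50.0] * 2,
             "f_hat": [hap1.mean()] * 2}
        )
        gl3 = np.zeros((2, n, 3))
        for m in range(2):
            for s in range(n):
                gl3[m, s] = 1e-6
                gl3[m, s, g[s, m]] = 1.0
        gl3[1, 0] = 1.0  # sample 0 has no information at marker 2
        a1 = (g.T >= 1).astype(np.int8)
        a2 = (g.T == 2).astype(np.int8)
        cs = CallSet("pbc", [f"s{i}" for i in range(n)], sites, a1, a2,
                     np.full((2, n), 40.0), np.full((2, n), 10, dtype=np.int32),
                     gl3=gl3)
        out = refine_callset(
            cs, [(900, 1200)],
            cfg=HmmConfig(n_iterations=6, n_reference_haplotypes=12, burn_in=2, seed=seed),
        )
        if out.post3[1, 0].argmax() == g[0, 0]:
            n_ok += 1
    assert n_ok >= 9
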