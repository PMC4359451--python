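"""Population-based caller: polymorphism prior, EM frequencies, genotypes."""

import numpy as np
import pytest

from exocall.model import ModelParams
from exocall.pbc import (
    MISSING,
    call_genotypes_pbc,
    choose_alt,
    estimate_f_em,
    polymorphism_prior,
    variant_posterior,
)


def grid_search_f(gl3, step=1e-4):
    """Independent oracle: maximize the HWE-mixture likelihood on a grid
    over the admissible frequency interval [1/2n, 1 - 1/2n]."""
    n2 = 2 * gl3.shape[0]
    fs = np.arange(step, 1.0, step)
    fs = fs[(fs >= 1 / n2 - 1e-12) & (fs <= 1 - 1 / n2 + 1e-12)]
    prior = np.stack([(1 - fs) ** 2, 2 * fs * (1 - fs), fs * fs], axis=1)
    ll = np.log(np.einsum("sk,fk->fs", gl3, prior)).sum(axis=1)
    return float(fs[int(np.argmax(ll))])


class TestPolymorphismPrior:
    def test_two_chromosomes(self):
        assert polymorphism_prior(2) == pytest.approx(0.001)

    def test_four_chromosomes(self):
        assert polymorphism_prior(4) == pytest.approx(0.0018333, rel=1e-4)

    def test_cohort_scale(self):
        """theta * H_{n-1} at the full-cohort chromosome count."""
        assert polymorphism_prior(15684) == pytest.approx(0.010238, rel=1e-4)

    def test_capped(self):
        assert polymorphism_prior(10, theta=0.4) == 0.5

    def test_small_n_rejected(self):
        with pytest.raises(ValueError):
            polymorphism_prior(1)


class TestChooseAlt:
    def test_majority(self):
        bases = np.array([2] * 5 + [3], dtype=np.int8)
        assert choose_alt(bases, np.full(6, 30), ref=0) == 2

    def test_tie_breaks_by_base_order(self):
        bases = np.array([2, 2, 2, 3, 3, 3], dtype=np.int8)
        assert choose_alt(bases, np.full(6, 30), ref=0) == 2

    def test_single_alt_read(self):
        assert choose_alt(np.array([3], dtype=np.int8), np.array([20]), ref=0) == 3

    def test_no_alt_returns_none(self):
        assert choose_alt(np.array([0, 0], dtype=np.int8), np.array([30, 30]), ref=0) is None


class TestEstimateF:
    def test_degenerate_closed_form(self):
        """One AA, one RR, one RA sample: 3 alt alleles / 6 chromosomes."""
        gl3 = np.array([[0, 0, 1], [1, 0, 0], [0, 1, 0]], dtype=float)
        assert estimate_f_em(gl3) == pytest.approx(0.5, abs=1e-6)

    def test_no_alt_evidence_floors(self):
        eps = 1e-12
        gl3 = np.tile([1.0, eps, eps], (10, 1))
        assert estimate_f_em(gl3) == pytest.approx(1 / 20, abs=1e-6)

    def test_matches_grid_search(self):
        """EM argmax equals a 1e-4-step grid search on random cohorts."""
        rng = np.random.default_rng(2024)
        for _ in range(20):
            n = int(rng.integers(2, 11))
            gl3 = rng.uniform(0.01, 1.0, (n, 3))
            f_em = estimate_f_em(gl3)
            f_grid = grid_search_f(gl3)
            assert f_em == pytest.approx(f_grid, abs=1.5e-4)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            estimate_f_em(np.zeros((0, 3)))

    def test_vectorized_matches_scalar(self, rng):
        from exocall.pbc import _estimate_f_em_many

        gl3 = rng.uniform(0.01, 1.0, (8, 6, 3))
        f0 = np.full(8, 0.1)
        many = _estimate_f_em_many(gl3, f0)
        for m in range(8):
            assert many[m] == pytest.approx(estimate_f_em(gl3[m], f0=0.1), abs=1e-5)


class TestVariantPosterior:
    def test_evidence_against(self):
        """Strong hom-ref cohort: posterior below the prior."""
        gl3 = np.tile([1.0, 1e-8, 1e-12], (20, 1))
        prior = polymorphism_prior(40)
        _, _, p = variant_posterior(gl3, 1 / 40, prior)
        assert p < prior

    def test_equal_likelihoods_return_prior(self):
        """Flat triplets make L1 == L0, so the posterior equals the prior."""
        gl3 = np.tile([1.0, 1.0, 1.0], (5, 1))
        _, _, p = variant_posterior(gl3, 0.2, 0.01)
        assert p == pytest.approx(0.01, rel=1e-9)

    def test_clean_het_carrier_detected(self):
        """One 5+5 Q20 carrier among ten 10x hom-ref samples is a variant."""
        from exocall.model import SampleObservations, genotype_likelihoods
        from exocall.pbc import triplet_indices

        idx = list(triplet_indices(0, 2))
        rows = []
        carrier = genotype_likelihoods(
            SampleObservations.from_strings("AAAAAGGGGG", [20] * 10)
        )
        rows.append(np.exp(carrier.loglik[idx]))
        for _ in range(9):
            gl = genotype_likelihoods(
                SampleObservations.from_strings("A" * 10, [20] * 10)
            )
            rows.append(np.exp(gl.loglik[idx]))
        gl3 = np.array(rows)
        f = estimate_f_em(gl3)
        is_var, qual, _ = variant_posterior(gl3, f, polymorphism_prior(20))
        assert is_var
        assert qual > 20


class TestGenotypeCalls:
    def test_zero_reads_missing_at_f_001(self):
        """(1-f)^2 = 0.9801 < 0.99 at f=0.01: no call without reads."""
        gt, _gq, pm = call_genotypes_pbc(np.array([[1.0, 1.0, 1.0]]), 0.01)
        assert gt[0] == MISSING
        assert pm[0] == pytest.approx(0.9801, abs=1e-4)

    def test_zero_reads_called_at_f_0001(self):
        """(1-f)^2 = 0.998 >= 0.99 at f=0.001: hom-ref called from the prior
        alone — the source of PBC's low missingness."""
        gt, _gq, pm = call_genotypes_pbc(np.array([[1.0, 1.0, 1.0]]), 0.001)
        assert gt[0] == 0
        assert pm[0] == pytest.approx(0.998, abs=1e-4)

    def test_clean_alt_sample_called_hom_alt(self):
        """12 clean alt reads overcome the HWE prior at a common frequency.

        (At rare frequencies the hom-alt prior penalty ~2/f demands far more
        reads; brute-force posterior checks the boundary.)"""
        from exocall.model import SampleObservations, genotype_likelihoods
        from exocall.pbc import triplet_indices

        gl = genotype_likelihoods(SampleObservations.from_strings("G" * 12, [25] * 12))
        gl3 = np.exp(gl.loglik[list(triplet_indices(0, 2))])[None, :]
        gt, _, pm = call_genotypes_pbc(gl3, 0.3)
        # independent check: direct posterior arithmetic
        prior = np.array([0.49, 0.42, 0.09])
        direct = gl3[0] * prior
        direct /= direct.sum()
        assert pm[0] == pytest.approx(direct[2])
        assert direct[2] > 0.99
        assert gt[0] == 2


def test_singleton_prior_effect():
    """For fixed carrier reads, P(polymorphic) shrinks as reference-only
    samples are added to the cohort."""
    from exocall.model import SampleObservations, genotype_likelihoods
    from exocall.pbc import triplet_indices

    idx = list(triplet_indices(0, 2))
    carrier = np.exp(
        genotype_likelihoods(
            SampleObservations.from_strings("AAAGG", [22] * 5)
        ).loglik[idx]
    )
    ref_row = np.exp(
        genotype_likelihoods(
            SampleObservations.from_strings("A" * 12, [30] * 12)
        ).loglik[idx]
    )
    last = None
    for n in (10, 50, 200):
        gl3 = np.vstack([carrier[None, :], np.tile(ref_row, (n - 1, 1))])
        f = estimate_f_em(gl3)
        _, _, p = variant_posterior(gl3, f, polymorphism_prior(2 * n))
        if last is not None:
            assert p < last
        last = p


def test_call_pbc_biallelic_only(small_data):
    from exocall.pbc import call_pbc

    cs = call_pbc(
        small_data.loglik,
        small_data.depth,
        small_data.refs,
        small_data.positions,
        small_data.cohort.samples,
        reads=small_data.read_tuple,
    )
    assert cs.n_sites > 0
    assert all(len(a) == 1 for a in cs.sites["alts"])
    # every emitted site carries its ML frequency within [floor, 1-floor]
    n2 = 2 * len(small_data.cohort.samples)
    f = cs.sites["f_hat"].to_numpy()
    assert np.all((f >= 1 / n2 - 1e-12) & (f <= 1 - 1 / n2 + 1e-12))


def test_sample_subset_restricts_cohort(small_data):
    from exocall.pbc import call_pbc

    subset = np.arange(10)
    cs = call_pbc(
        small_data.loglik,
        small_data.depth,
        small_data.refs,
        small_data.positions,
        small_data.cohort.samples,
        reads=small_data.read_tuple,
        sample_subset=subset,
    )
    assert cs.n_samples == 10
    assert cs.samples == small_data.cohort.samples[:10]
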