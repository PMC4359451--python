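"""Comparison statistics: Ts/Tv, h_e, audits, Fisher, down-sampling."""

import itertools
from math import comb

import numpy as np
import pandas as pd
import pytest

from exocall.callset import CallSet
from exocall.evaluate import (
    additional_het_audit,
    downsampling_experiment,
    fisher_exact_2x2,
    het_mismatch,
    missingness,
    replicate_concordance,
    site_list_overlap,
    singleton_summary,
    tstv,
    validation_rate,
)


def fisher_oracle(table):
    """Independent oracle: two-sided p by explicit hypergeometric
    enumeration, summing tables no more probable than the observed one."""
    (a, b), (c, d) = table
    r1, r2 = a + b, c + d
    c1 = a + c
    n = r1 + r2

    def prob(x):
        return comb(r1, x) * comb(r2, c1 - x) / comb(n, c1)

    p_obs = prob(a)
    total = 0.0
    for x in range(max(0, c1 - r2), min(r1, c1) + 1):
        p = prob(x)
        if p <= p_obs * (1 + 1e-7):
            total += p
    return total


def dosage_callset(gt_rows, caller="a", pos0=100, refs=None):
    """Build a biallelic call set from a dosage matrix (-1 missing)."""
    gt = np.array(gt_rows)
    n_sites, n_samples = gt.shape
    refs = refs if refs is not None else [0] * n_sites
    sites = pd.DataFrame(
        {
            "chrom": ["chr1"] * n_sites,
            "pos": np.arange(pos0, pos0 + n_sites),
            "ref": refs,
            "alts": [(2,)] * n_sites,
            "qual": [50.0] * n_sites,
        }
    )
    a1 = np.where(gt >= 0, (gt >= 1).astype(np.int8), -1).astype(np.int8)
    a2 = np.where(gt >= 0, (gt == 2).astype(np.int8), -1).astype(np.int8)
    return CallSet(caller, [f"s{i}" for i in range(n_samples)], sites, a1, a2,
                   np.full(gt.shape, 40.0), np.full(gt.shape, 20, dtype=np.int32))


class TestTsTv:
    def test_two_to_one(self):
        sites = pd.DataFrame({"ref": [0, 1, 0], "alt": [2, 3, 1]})  # AG, CT, AC
        r = tstv(sites)
        assert (r.n_ts, r.n_tv) == (2, 1)
        assert r.ratio == pytest.approx(2.0)

    def test_zero_transversions_flagged(self):
        r = tstv(pd.DataFrame({"ref": [0], "alt": [2]}))
        assert not r.defined
        assert np.isnan(r.ratio)

    def test_strand_complement_invariant(self):
        rng = np.random.default_rng(0)
        ref = rng.integers(0, 4, 50)
        alt = (ref + rng.integers(1, 4, 50)) % 4
        comp = {0: 3, 1: 2, 2: 1, 3: 0}  # A<->T, C<->G
        r1 = tstv(pd.DataFrame({"ref": ref, "alt": alt}))
        r2 = tstv(pd.DataFrame({"ref": [comp[x] for x in ref],
                                "alt": [comp[x] for x in alt]}))
        assert r1.ratio == pytest.approx(r2.ratio)

    def test_multiallelic_counts_each_alt(self):
        sites = pd.DataFrame({"ref": [0], "alts": [(2, 1)]})  # A->G (ts), A->C (tv)
        r = tstv(sites)
        assert (r.n_ts, r.n_tv) == (1, 1)


class TestHetMismatch:
    def test_identical_sets_zero(self):
        a = dosage_callset([[1, 1, 0]])
        assert het_mismatch(a, a).h_e == 0.0

    def test_printed_definition(self):
        """A: {s1 het, s2 het}; B: {s1 het, s2 hom} -> 1/(2+1)."""
        a = dosage_callset([[1, 1]])
        b = dosage_callset([[1, 0]], caller="b")
        rep = het_mismatch(a, b)
        assert rep.n_het_a == 2 and rep.n_het_b == 1 and rep.n_mismatch == 1
        assert rep.h_e == pytest.approx(1 / 3)

    def test_opposite_hets(self):
        a = dosage_callset([[1, 0]])
        b = dosage_callset([[0, 1]], caller="b")
        assert het_mismatch(a, b).h_e == pytest.approx(1.0)

    def test_symmetric(self):
        a = dosage_callset([[1, 0, 2], [0, 1, 1]])
        b = dosage_callset([[1, 1, 0], [0, 0, 1]], caller="b")
        assert het_mismatch(a, b).h_e == pytest.approx(het_mismatch(b, a).h_e)

    def test_missing_cells_excluded(self):
        a = dosage_callset([[1, -1]])
        b = dosage_callset([[0, 1]], caller="b")
        rep = het_mismatch(a, b)
        assert rep.n_het_a + rep.n_het_b == 1
        assert rep.n_mismatch == 1

    def test_no_shared_sites_rejected(self):
        a = dosage_callset([[1]])
        b = dosage_callset([[1]], pos0=999, caller="b")
        with pytest.raises(ValueError):
            het_mismatch(a, b)


class TestReplicateConcordance:
    def test_identical_members_zero(self):
        cs = dosage_callset([[1, 1, 0, 0], [2, 2, 1, 1]])
        rep = replicate_concordance(cs, cs, [("s0", "s1"), ("s2", "s3")])
        assert rep.h_e == 0.0

    def test_het_hom_pair(self):
        cs = dosage_callset([[1, 0]])
        rep = replicate_concordance(cs, cs, [("s0", "s1")])
        assert rep.n_mismatch == 1
        assert rep.h_e == pytest.approx(1.0)

    def test_both_hom_sites_excluded(self):
        cs = dosage_callset([[0, 0], [2, 2], [1, 1]])
        rep = replicate_concordance(cs, cs, [("s0", "s1")])
        assert rep.n_het_a + rep.n_het_b == 2  # only the het site counts
        assert rep.h_e == 0.0

    def test_unknown_member_rejected(self):
        cs = dosage_callset([[1, 0]])
        with pytest.raises(ValueError):
            replicate_concordance(cs, cs, [("s0", "zz")])


class TestAdditionalHets:
    def test_identical_no_extras(self):
        cs = dosage_callset([[1, 0]])
        truth = dosage_callset([[1, 0]], caller="truth")
        assert additional_het_audit(cs, cs, truth) == (0, 0.0)

    def test_true_extra_het_clean(self):
        simple = dosage_callset([[-1, 0]])
        complex_ = dosage_callset([[1, 0]], caller="b")
        truth = dosage_callset([[1, 0]], caller="truth")
        n, he = additional_het_audit(simple, complex_, truth)
        assert n == 1 and he == 0.0

    def test_false_extra_het_counted(self):
        simple = dosage_callset([[-1, 0]])
        complex_ = dosage_callset([[1, 0]], caller="b")
        truth = dosage_callset([[0, 0]], caller="truth")
        n, he = additional_het_audit(simple, complex_, truth)
        assert n == 1 and he == pytest.approx(1.0)


class TestMissingness:
    def test_zero(self):
        assert missingness(dosage_callset([[0, 1], [2, 0]])) == 0.0

    def test_fraction(self):
        gt = np.zeros((100, 2), dtype=int)
        gt[0, 0] = -1
        assert missingness(dosage_callset(gt)) == pytest.approx(1 / 200)

    def test_filters_only_increase(self):
        from exocall.qc import apply_genotype_filters

        cs = dosage_callset(np.array([[1, 0, 2, -1]]), caller="pbc")
        cs.gq[0, 0] = 5.0
        before = missingness(cs)
        after, _ = apply_genotype_filters(cs)
        assert missingness(after) >= before


class TestSingletons:
    def test_identical_sets_nothing_specific(self):
        cs = dosage_callset([[1, 0]])
        s = singleton_summary(cs, cs)
        assert s.n_specific == 0

    def test_specific_singleton_found(self):
        a = dosage_callset([[1, 0, 0], [1, 1, 0]])
        b = dosage_callset([[1, 0, 0]], caller="b")
        s = singleton_summary(a, b)
        assert s.n_specific == 1
        assert s.n_specific_singletons == 0  # the specific site has 2 carriers
        a2 = dosage_callset([[1, 0, 0], [0, 1, 0]])
        s2 = singleton_summary(a2, b)
        assert s2.n_specific_singletons == 1

    def test_validation_against_truth(self):
        a = dosage_callset([[1, 0], [0, 1]])
        b = dosage_callset([[1, 0]], pos0=999, caller="b")  # shares nothing
        truth = dosage_callset([[1, 0], [0, 0]], caller="truth")
        s = singleton_summary(a, b, truth)
        assert s.n_specific_singletons == 2
        assert s.validation_rate == pytest.approx(0.5)


class TestOverlap:
    def test_empty_list(self):
        cs = dosage_callset([[1, 0]])
        known = pd.DataFrame({"chrom": [], "pos": []})
        assert site_list_overlap(cs, known) == 0.0

    def test_all_listed(self):
        cs = dosage_callset([[1, 0], [0, 1]])
        known = pd.DataFrame({"chrom": ["chr1", "chr1"], "pos": [100, 101]})
        assert site_list_overlap(cs, known) == 1.0

    def test_half_listed(self):
        cs = dosage_callset([[1, 0], [0, 1]])
        known = pd.DataFrame({"chrom": ["chr1"], "pos": [100]})
        assert site_list_overlap(cs, known) == 0.5


class TestFisher:
    @pytest.mark.parametrize(
        "table,expected",
        [
            ([[5, 5], [5, 5]], 1.0),
            ([[1, 0], [0, 1]], 1.0),
        ],
    )
    def test_symmetric_tables(self, table, expected):
        assert fisher_exact_2x2(table) == pytest.approx(expected)

    def test_matches_enumeration_oracle(self):
        rng = np.random.default_rng(5)
        for _ in range(25):
            t = rng.integers(0, 12, (2, 2))
            if t.sum() == 0:
                continue
            assert fisher_exact_2x2(t) == pytest.approx(fisher_oracle(t), rel=1e-9)

    def test_all_zero_rejected(self):
        with pytest.raises(ValueError):
            fisher_exact_2x2([[0, 0], [0, 0]])

    def test_negative_rejected(self):
        with pytest.raises(ValueError):
            fisher_exact_2x2([[1, -1], [0, 1]])


class TestValidationRate:
    def test_rounding(self):
        assert validation_rate(38, 41) == 92.68
        assert validation_rate(30, 30) == 100.0

    def test_zero_tested_rejected(self):
        with pytest.raises(ValueError):
            validation_rate(0, 0)


class TestDownsampling:
    def test_deterministic_under_seed(self, small_data):
        c = small_data.cohort
        singles = np.array([0, 1, 2])
        carriers = np.array([0, 1, 2])
        kw = dict(
            sizes=[5, 10], n_reps=2, seed=9, reads=small_data.read_tuple
        )
        r1 = downsampling_experiment(
            small_data.loglik, small_data.depth, small_data.refs,
            small_data.positions, c.samples, singles, carriers, **kw
        )
        r2 = downsampling_experiment(
            small_data.loglik, small_data.depth, small_data.refs,
            small_data.positions, c.samples, singles, carriers, **kw
        )
        np.testing.assert_array_equal(r1.recovered_called, r2.recovered_called)
        np.testing.assert_array_equal(r1.mean_qual, r2.mean_qual)

    def test_oversize_rejected(self, small_data):
        with pytest.raises(ValueError):
            downsampling_experiment(
                small_data.loglik, small_data.depth, small_data.refs,
                small_data.positions, small_data.cohort.samples,
                np.array([0]), np.array([0]), sizes=[10_000],
            )
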