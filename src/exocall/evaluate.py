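"""Call-set comparison statistics.

Implements the quality readouts used to compare calling strategies:
transition/transversion ratio, the pairwise heterozygote mismatch rate h_e
(hets in one set that are homozygous in the other, over all hets in both
sets), replicate-pair concordance, the additional-heterozygote audit between
a simpler and a more complex caller, genotype missingness, singleton and
caller-specific site characterization, known-site (dbSNP-like) overlap, the
two-sided Fisher exact test, and the down-sampling singleton-recovery
experiment.
"""

from __future__ import annotations

import dataclasses
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .callset import CallSet
from .model import TRANSITION_PARTNER, ModelParams
from .pbc import call_pbc

MISSING = -1


# ---------------------------------------------------------------------------
# Ts/Tv
# ---------------------------------------------------------------------------

@dataclasses.dataclass(frozen=True)
class TsTvResult:
    n_ts: int
    n_tv: int

    @property
    def defined(self) -> bool:
        return self.n_tv > 0

    @property
    def ratio(self) -> float:
        return self.n_ts / self.n_tv if self.defined else float("nan")


def tstv(sites: pd.DataFrame) -> TsTvResult:
    """Transition/transversion ratio of a site table.

    Multi-allelic sites contribute one ref-alt substitution per alternate
    allele.  With zero transversions the ratio is flagged undefined (NaN).
    """
    n_ts = n_tv = 0
    if "alts" in sites.columns:
        pairs = (
            (int(r), int(a)) for r, alts in zip(sites["ref"], sites["alts"]) for a in alts
        )
    else:
        pairs = ((int(r), int(a)) for r, a in zip(sites["ref"], sites["alt"]))
    for r, a in pairs:
        if TRANSITION_PARTNER[r] == a:
            n_ts += 1
        else:
            n_tv += 1
    return TsTvResult(n_ts, n_tv)


# ---------------------------------------------------------------------------
# heterozygote mismatch
# ---------------------------------------------------------------------------

@dataclasses.dataclass(frozen=True)
class ConcordanceReport:
    n_het_a: int
    n_het_b: int
    n_mismatch: int
    stratum: str = "all"

    @property
    def h_e(self) -> float:
        total = self.n_het_a + self.n_het_b
        return self.n_mismatch / total if total else 0.0


def _shared_site_indices(a: CallSet, b: CallSet) -> tuple[np.ndarray, np.ndarray]:
    key_a = {(c, int(p)): i for i, (c, p) in enumerate(zip(a.sites["chrom"], a.sites["pos"]))}
    ia, ib = [], []
    for j, (c, p) in enumerate(zip(b.sites["chrom"], b.sites["pos"])):
        i = key_a.get((c, int(p)))
        if i is not None:
            if int(a.sites["ref"].iloc[i]) != int(b.sites["ref"].iloc[j]):
                continue
            ia.append(i)
            ib.append(j)
    return np.array(ia, dtype=int), np.array(ib, dtype=int)


def _shared_sample_indices(a: CallSet, b: CallSet) -> tuple[np.ndarray, np.ndarray]:
    pos_b = {s: j for j, s in enumerate(b.samples)}
    sa, sb = [], []
    for i, s in enumerate(a.samples):
        if s in pos_b:
            sa.append(i)
            sb.append(pos_b[s])
    return np.array(sa, dtype=int), np.array(sb, dtype=int)


def het_mismatch(
    a: CallSet,
    b: CallSet,
    site_idx: Optional[tuple[np.ndarray, np.ndarray]] = None,
    sample_idx: Optional[tuple[np.ndarray, np.ndarray]] = None,
    stratum: str = "all",
) -> ConcordanceReport:
    """Heterozygote mismatch rate h_e between two call sets.

    Genotype cells missing in either set are excluded; h_e is the number of
    het-in-one/hom-in-other cells divided by the total het calls of both
    sets over the compared cells.  Symmetric in its two arguments.
    """
    ia, ib = site_idx if site_idx is not None else _shared_site_indices(a, b)
    if ia.size == 0:
        raise ValueError("no shared sites between the call sets")
    sa, sb = sample_idx if sample_idx is not None else _shared_sample_indices(a, b)
    if sa.size == 0:
        raise ValueError("no shared samples between the call sets")
    het_a = a.is_het[np.ix_(ia, sa)]
    het_b = b.is_het[np.ix_(ib, sb)]
    ok = (a.a1[np.ix_(ia, sa)] >= 0) & (b.a1[np.ix_(ib, sb)] >= 0)
    mism = ok & (het_a != het_b)
    return ConcordanceReport(
        int((het_a & ok).sum()), int((het_b & ok).sum()), int(mism.sum()), stratum
    )


def replicate_concordance(
    a: CallSet,
    b: CallSet,
    pairs: Sequence[tuple[str, str]],
) -> ConcordanceReport:
    """h_e between replicate pairs, at sites where at least one member of a
    pair is heterozygous.

    ``a`` and ``b`` are the call sets containing the first and second member
    of each pair (they may be the same object when both members were called
    in one run).
    """
    ia, ib = _shared_site_indices(a, b)
    if ia.size == 0:
        raise ValueError("no shared sites between the replicate call runs")
    idx_a = {s: i for i, s in enumerate(a.samples)}
    idx_b = {s: i for i, s in enumerate(b.samples)}
    n_het = n_mm = 0
    for s1, s2 in pairs:
        if s1 not in idx_a or s2 not in idx_b:
            raise ValueError(f"replicate pair ({s1}, {s2}) missing from call sets")
        g1_het = a.is_het[ia, idx_a[s1]]
        g2_het = b.is_het[ib, idx_b[s2]]
        ok = (a.a1[ia, idx_a[s1]] >= 0) & (b.a1[ib, idx_b[s2]] >= 0)
        use = ok & (g1_het | g2_het)
        n_het += int((g1_het & use).sum() + (g2_het & use).sum())
        n_mm += int((use & (g1_het != g2_het)).sum())
    return ConcordanceReport(n_het // 2, n_het - n_het // 2, n_mm, "replicates")


def additional_het_audit(
    simple: CallSet, complex_: CallSet, truth: CallSet
) -> tuple[int, float]:
    """Audit heterozygotes the complex caller adds over the simple one.

    Counts genotype cells (at sites shared by all three sets) that are
    non-missing het in the complex set but missing in the simple set, and
    returns their mismatch rate against truth: cells where truth is
    homozygous, over the extra hets plus the truth hets among those cells.
    """
    isc, icc = _shared_site_indices(simple, complex_)
    ict, itt = _shared_site_indices(complex_, truth)
    both = np.intersect1d(icc, ict)
    if both.size == 0:
        return 0, 0.0
    map_s = dict(zip(icc, isc))
    map_t = dict(zip(ict, itt))
    rows_c = both
    rows_s = np.array([map_s[i] for i in both])
    rows_t = np.array([map_t[i] for i in both])
    sa, sc = _shared_sample_indices(simple, complex_)
    _, st = _shared_sample_indices(simple, truth)
    extra = (
        complex_.is_het[np.ix_(rows_c, sc)]
        & (simple.a1[np.ix_(rows_s, sa)] < 0)
        & (truth.a1[np.ix_(rows_t, st)] >= 0)
    )
    n_extra = int(extra.sum())
    if n_extra == 0:
        return 0, 0.0
    truth_het = truth.is_het[np.ix_(rows_t, st)]
    n_mm = int((extra & ~truth_het).sum())
    n_truth_het = int((extra & truth_het).sum())
    return n_extra, n_mm / (n_extra + n_truth_het)


def missingness(callset: CallSet) -> float:
    """Fraction of missing genotype cells over the fixed site set."""
    return callset.missingness()


# ---------------------------------------------------------------------------
# singletons & caller-specific sites
# ---------------------------------------------------------------------------

@dataclasses.dataclass
class SingletonSummary:
    n_specific: int
    n_specific_singletons: int
    tstv_specific: TsTvResult
    carrier_depth: np.ndarray  # depth at the singleton carrier, per singleton
    validation_rate: Optional[float]  # fraction of specific singletons true


def singleton_summary(
    a: CallSet, b: CallSet, truth: Optional[CallSet] = None
) -> SingletonSummary:
    """Characterize sites specific to call set ``a`` relative to ``b``.

    Reports their count, how many are singletons (minor allele count 1 on
    non-missing genotypes), their Ts/Tv, the read depth at each singleton's
    carrier, and — when truth is supplied — the fraction of the specific
    singletons that are true variants with a truth-het carrier.
    """
    key_b = set(zip(b.sites["chrom"], b.sites["pos"].astype(int)))
    specific = np.array(
        [
            i
            for i, (c, p) in enumerate(zip(a.sites["chrom"], a.sites["pos"].astype(int)))
            if (c, p) not in key_b
        ],
        dtype=int,
    )
    singl = a.is_singleton()
    spec_singl = [i for i in specific if singl[i]]
    depths = []
    valid = []
    truth_lookup = None
    if truth is not None:
        ia, it = _shared_site_indices(a, truth)
        truth_lookup = dict(zip(ia, it))
        _, s_t = _shared_sample_indices(a, truth)
    for i in spec_singl:
        carriers = np.where(a.is_het[i] | ((a.a1[i] > 0) & (a.a1[i] == a.a2[i])))[0]
        if carriers.size == 0:
            continue
        c = int(carriers[0])
        depths.append(int(a.dp[i, c]))
        if truth_lookup is not None:
            t = truth_lookup.get(i)
            valid.append(bool(t is not None and truth.is_het[t, s_t[c]]))
    sub = a.sites.iloc[specific] if specific.size else a.sites.iloc[[]]
    rate = (float(np.mean(valid)) if valid else None) if truth is not None else None
    return SingletonSummary(
        n_specific=int(specific.size),
        n_specific_singletons=len(spec_singl),
        tstv_specific=tstv(sub),
        carrier_depth=np.array(depths, dtype=int),
        validation_rate=rate,
    )


def site_list_overlap(callset: CallSet, known: pd.DataFrame) -> float:
    """Fraction of call-set sites present in a known-site list."""
    if callset.n_sites == 0:
        return 0.0
    key = set(zip(known["chrom"], known["pos"].astype(int)))
    hits = sum(
        1
        for c, p in zip(callset.sites["chrom"], callset.sites["pos"].astype(int))
        if (c, p) in key
    )
    return hits / callset.n_sites


# ---------------------------------------------------------------------------
# Fisher exact test & validation rates
# ---------------------------------------------------------------------------

def fisher_exact_2x2(table) -> float:
    """Two-sided Fisher exact p-value (minimum-likelihood summation)."""
    t = np.asarray(table, dtype=int)
    if t.shape != (2, 2) or (t < 0).any():
        raise ValueError("need a non-negative 2x2 integer table")
    if t.sum() == 0:
        raise ValueError("all-zero table")
    return float(stats.fisher_exact(t, alternative="two-sided")[1])


def validation_rate(n_confirmed: int, n_tested: int) -> float:
    """Percentage of validated calls, as printed (e.g. 92.68)."""
    if n_tested <= 0:
        raise ValueError("need at least one tested call")
    return round(100.0 * n_confirmed / n_tested, 2)


# ---------------------------------------------------------------------------
# down-sampling experiment
# ---------------------------------------------------------------------------

@dataclasses.dataclass
class DownsamplingResult:
    sizes: list[int]
    recovered_called: np.ndarray  # (n_rep, n_sizes) fraction, carrier het called
    recovered_emitted: np.ndarray  # (n_rep, n_sizes) fraction, site emitted only
    mean_qual: np.ndarray  # (n_rep, n_sizes) mean site quality of recovered
    n_reps: int
    seed: int

    def mean_recovery(self) -> np.ndarray:
        return self.recovered_called.mean(axis=0)


def downsampling_experiment(
    loglik: np.ndarray,
    depth: np.ndarray,
    refs: np.ndarray,
    positions: np.ndarray,
    samples: list[str],
    singleton_sites: np.ndarray,
    singleton_carriers: np.ndarray,
    sizes: Sequence[int],
    n_reps: int = 10,
    seed: int = 0,
    params: ModelParams | None = None,
    reads: Optional[tuple] = None,
) -> DownsamplingResult:
    """Recovery of reference singletons by population-based calling in
    nested random sub-cohorts.

    ``singleton_sites``/``singleton_carriers`` give, per reference singleton
    (typically from a full-cohort individual-based call), the site row and
    the carrier's column in the cohort arrays.  Sub-cohorts are built by
    sequential addition (nested across sizes within a replicate); a
    singleton counts as recovered when its carrier is in the sub-cohort, the
    site is emitted as variant, and the carrier genotype is called het
    (non-missing).  The emitted-only fraction is also reported.
    """
    sizes = list(sizes)
    n_samples = depth.shape[1]
    if max(sizes) > n_samples:
        raise ValueError("sub-cohort size exceeds the cohort")
    rng = np.random.default_rng(seed)
    rec_c = np.zeros((n_reps, len(sizes)))
    rec_e = np.zeros((n_reps, len(sizes)))
    mq = np.zeros((n_reps, len(sizes)))
    for rep in range(n_reps):
        order = rng.permutation(n_samples)
        for k, size in enumerate(sizes):
            subset = order[:size]
            cs = call_pbc(
                loglik,
                depth,
                refs,
                positions,
                samples,
                reads=reads,
                params=params,
                sample_subset=subset,
                candidate_sites=singleton_sites,
            )
            emitted = {
                (int(p)): i for i, p in enumerate(cs.sites["pos"].astype(int))
            }
            col_of = {int(c): j for j, c in enumerate(subset)}
            n_in = n_called = n_emit = 0
            quals = []
            for site, carrier in zip(singleton_sites, singleton_carriers):
                if int(carrier) not in col_of:
                    continue
                n_in += 1
                row = emitted.get(int(positions[site]))
                if row is None:
                    continue
                n_emit += 1
                j = col_of[int(carrier)]
                if cs.is_het[row, j]:
                    n_called += 1
                    quals.append(float(cs.sites["qual"].iloc[row]))
            rec_c[rep, k] = n_called / n_in if n_in else 0.0
            rec_e[rep, k] = n_emit / n_in if n_in else 0.0
            mq[rep, k] = float(np.mean(quals)) if quals else 0.0
    return DownsamplingResult(sizes, rec_c, rec_e, mq, n_reps, seed)
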