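"""Quality-control ladder: genotype filters, site features, ranking, selection.

The pipeline mirrors large-scale sequencing practice: per-site summary
features feed a linear classifier trained on labelled good/bad sites; the
site score ranks variants and a fixed-size top-K call set (positive scores
only) is selected; finally per-genotype hard filters discard genotypes with
more than ~1% estimated error — for individual-based calls GQ < 20 or depth
< 7, for population-based calls GQ < 20, and for LD-refined calls a
best:second posterior ratio below 99:1.  LD-refined call sets additionally
drop sites with imputation quality R-hat-squared < 0.7 before ranking.

Filters only ever add missing marks or remove sites; they never alter a
called genotype.
"""

from __future__ import annotations

import dataclasses
from typing import Optional

import numpy as np
import pandas as pd
from sklearn.preprocessing import StandardScaler
from sklearn.svm import LinearSVC

from .callset import CallSet
from .simulate import ReadBlock

MISSING = -1


@dataclasses.dataclass(frozen=True)
class GenotypeFilterPolicy:
    caller: str
    min_gq: float = 20.0
    min_depth: Optional[int] = None  # IBC only
    min_posterior_ratio: Optional[float] = None  # LDC only


POLICIES = {
    "ibc": GenotypeFilterPolicy("ibc", min_gq=20.0, min_depth=7),
    "pbc": GenotypeFilterPolicy("pbc", min_gq=20.0),
    "ldc": GenotypeFilterPolicy("ldc", min_gq=None, min_posterior_ratio=99.0),
    "ldc+f": GenotypeFilterPolicy("ldc+f", min_gq=None, min_posterior_ratio=99.0),
}


def apply_genotype_filters(
    callset: CallSet, policy: GenotypeFilterPolicy | None = None
) -> tuple[CallSet, int]:
    """Mark genotypes failing the caller's hard filters as missing.

    Returns the filtered call set and the number of newly missing genotypes.
    """
    if policy is None:
        if callset.caller not in POLICIES:
            raise ValueError(f"unknown caller kind {callset.caller!r}")
        policy = POLICIES[callset.caller]
    out = callset.copy()
    bad = np.zeros(out.a1.shape, dtype=bool)
    if policy.min_gq is not None:
        bad |= out.gq < policy.min_gq
    if policy.min_depth is not None:
        bad |= out.dp < policy.min_depth
    if policy.min_posterior_ratio is not None:
        if out.posterior_ratio is None:
            raise ValueError("posterior-ratio filter needs an LD-refined call set")
        bad |= out.posterior_ratio < policy.min_posterior_ratio
    newly = int((bad & (out.a1 >= 0)).sum())
    out.a1 = np.where(bad, MISSING, out.a1).astype(np.int8)
    out.a2 = np.where(bad, MISSING, out.a2).astype(np.int8)
    return out, newly


def excess_het_statistic(n_rr: int, n_ra: int, n_aa: int) -> float:
    """Signed z statistic for heterozygote excess relative to HWE.

    Positive values mean more heterozygotes than the Hardy-Weinberg
    expectation at the sample allele frequency; monomorphic sites give 0.
    """
    n = n_rr + n_ra + n_aa
    if n <= 0:
        raise ValueError("need at least one genotype")
    f = (n_ra + 2 * n_aa) / (2.0 * n)
    if f <= 0.0 or f >= 1.0:
        return 0.0
    p_het = 2.0 * f * (1.0 - f)
    exp_het = n * p_het
    var = n * p_het * (1.0 - p_het)
    return float((n_ra - exp_het) / np.sqrt(var))


def compute_site_features(callset: CallSet, reads: ReadBlock | None = None,
                          site_map: np.ndarray | None = None) -> pd.DataFrame:
    """Per-site feature vector for ranking.

    Features (all from non-missing genotypes): quality-weighted allele
    balance deviation among het carriers, mean depth, mean GQ, call rate,
    excess-heterozygosity z, and the site quality.  ``site_map`` gives, for
    each call-set site, its row in the read block's site indexing (needed
    for the allele-balance feature); without reads the balance feature is 0.
    """
    n_sites, n_samples = callset.a1.shape
    called = callset.a1 >= 0
    het = callset.is_het
    feats = pd.DataFrame(index=np.arange(n_sites))
    with np.errstate(invalid="ignore"):
        feats["mean_depth"] = np.where(
            called.any(axis=1), (callset.dp * called).sum(axis=1) / called.sum(axis=1), 0.0
        )
        feats["mean_gq"] = np.where(
            called.any(axis=1), (callset.gq * called).sum(axis=1) / called.sum(axis=1), 0.0
        )
    feats["call_rate"] = called.mean(axis=1)
    hetz = np.zeros(n_sites)
    for m in range(n_sites):
        n_called = int(called[m].sum())
        if n_called == 0:
            continue
        n_het = int(het[m].sum())
        n_hom_alt = int(((callset.a1[m] > 0) & (callset.a1[m] == callset.a2[m])).sum())
        hetz[m] = excess_het_statistic(n_called - n_het - n_hom_alt, n_het, n_hom_alt)
    feats["excess_het_z"] = hetz
    feats["site_qual"] = callset.sites["qual"].to_numpy(dtype=float)

    ab_dev = np.zeros(n_sites)
    if reads is not None and site_map is not None:
        refs = callset.sites["ref"].to_numpy()
        w = 1.0 - np.minimum(10.0 ** (-reads.qual.astype(float) / 10.0), 0.75)
        n_read_sites = reads.depth.shape[0]
        ref_of_read = np.full(n_read_sites, -1, dtype=np.int8)
        row_of = np.full(n_read_sites, -1, dtype=np.int64)
        row_of[site_map] = np.arange(n_sites)
        ref_of_read[site_map] = refs
        sel = row_of[reads.site_idx] >= 0
        rrow = row_of[reads.site_idx[sel]]
        rsamp = reads.sample_idx[sel]
        is_ref_read = reads.base[sel] == ref_of_read[reads.site_idx[sel]]
        het_cell = het[rrow, rsamp]
        flat = rrow * n_samples + rsamp
        wsel = w[sel]
        num = np.bincount(flat[het_cell], weights=(wsel * ~is_ref_read)[het_cell],
                          minlength=n_sites * n_samples)
        den = np.bincount(flat[het_cell], weights=wsel[het_cell],
                          minlength=n_sites * n_samples)
        num = num.reshape(n_sites, n_samples).sum(axis=1)
        den = den.reshape(n_sites, n_samples).sum(axis=1)
        with np.errstate(invalid="ignore", divide="ignore"):
            frac = np.where(den > 0, num / den, 0.5)
        ab_dev = np.abs(frac - 0.5)
    feats["allele_balance_dev"] = ab_dev
    return feats


def rank_sites(
    features: pd.DataFrame,
    good_idx: np.ndarray,
    bad_idx: np.ndarray,
    seed: int = 0,
) -> np.ndarray:
    """Linear-classifier site score (signed margin; higher is better).

    Trained on labelled good/bad site rows of the feature table; the two
    training sets must be non-empty and disjoint.
    """
    good_idx = np.asarray(good_idx)
    bad_idx = np.asarray(bad_idx)
    if good_idx.size == 0 or bad_idx.size == 0:
        raise ValueError("training sets must be non-empty")
    if np.intersect1d(good_idx, bad_idx).size:
        raise ValueError("training sets must be disjoint")
    x = features.to_numpy(dtype=float)
    scaler = StandardScaler().fit(x)
    xs = scaler.transform(x)
    xt = np.concatenate([xs[good_idx], xs[bad_idx]])
    yt = np.concatenate([np.ones(good_idx.size), -np.ones(bad_idx.size)])
    clf = LinearSVC(dual=False, C=1.0, random_state=seed).fit(xt, yt)
    return clf.decision_function(xs)


def select_top_k(
    scores: np.ndarray, k: int, positions: np.ndarray
) -> tuple[np.ndarray, bool]:
    """Top-K sites by score among positive scores; ties by genomic order.

    Returns (selected site indices in genomic order, truncated flag set when
    fewer than K sites had positive scores).
    """
    if k <= 0:
        raise ValueError("K must be positive")
    scores = np.asarray(scores, dtype=float)
    if k > scores.size:
        raise ValueError("K exceeds the number of sites")
    positive = np.where(scores > 0)[0]
    order = positive[np.lexsort((positions[positive], -scores[positive]))]
    truncated = order.size < k
    chosen = order[:k]
    return np.sort(chosen), truncated


def rsq_filter(callset: CallSet, threshold: float = 0.7) -> np.ndarray:
    """Site indices passing the imputation-quality filter (LD-refined only)."""
    if not callset.caller.startswith("ldc"):
        raise ValueError("R-hat-squared filter applies to LD-refined call sets only")
    if "rsq" not in callset.sites.columns:
        raise ValueError("call set has no rsq column")
    rsq = callset.sites["rsq"].to_numpy(dtype=float)
    return np.where(rsq >= threshold)[0]
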