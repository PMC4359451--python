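"""Individual-based single-marker caller (IBC).

Each sample at each site is genotyped independently: the 10-genotype read
likelihood is combined with a reference-anchored prior in which each allele
differs from the reference with per-bp heterozygosity theta, and the most
likely genotype is emitted when its posterior reaches the 99% threshold
(otherwise the genotype is missing).  The prior is uniform over transitions
and transversions so the transition/transversion ratio of the call set is an
unbiased quality readout.

Two prior parameterizations are provided:

``dependent`` (default)
    P(het ref/X) = theta/3 per specific alternate X, P(hom X/X) = theta/6,
    P(X/Y) = 2*(theta/3)^2 per non-reference pair, P(ref/ref) = remainder.
    This is the parameterization used by the consensus-caller family: the
    hom-alt prior scales with theta rather than theta^2, so genuine hom-alt
    genotypes are callable at moderate depth.

``independent``
    A literal two-independent-alleles reading: P(ref/ref) = (1-theta)^2,
    P(het ref/X) = 2(1-theta)theta/3, P(X/X) = (theta/3)^2,
    P(X/Y) = 2(theta/3)^2.  Retained as an option; it requires ~18x of clean
    reads to call a hom-alt genotype.

The union call set across samples keeps every site where at least one
non-missing called genotype carries a non-reference allele; the site allele
list is the reference plus the union of called alternates, so sites with two
or three alternate alleles are representable.
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd

from .callset import CallSet
from .model import (
    GENOTYPES,
    GT_PAIR_A1,
    GT_PAIR_A2,
    GenotypeLikelihoods,
    ModelParams,
    N_GENOTYPES,
    gq_from_posterior,
)

MISSING = -1


@dataclasses.dataclass(frozen=True)
class IbcPrior:
    mode: str
    ref: int
    probs: np.ndarray  # (10,) sums to 1

    @property
    def log_probs(self) -> np.ndarray:
        return np.log(self.probs)


@dataclasses.dataclass(frozen=True)
class IbcGenotypeCall:
    genotype: int  # genotype index 0..9, or MISSING
    gq: float
    depth: int
    posterior_max: float


def ibc_prior(ref: int, params: ModelParams | None = None, mode: str = "dependent") -> IbcPrior:
    """Reference-anchored genotype prior for the individual-based caller."""
    params = params or ModelParams()
    th = params.theta
    probs = np.zeros(N_GENOTYPES)
    for k, (a1, a2) in enumerate(GENOTYPES):
        n_ref = (a1 == ref) + (a2 == ref)
        if mode == "independent":
            if n_ref == 2:
                probs[k] = (1.0 - th) ** 2
            elif n_ref == 1:
                probs[k] = 2.0 * (1.0 - th) * th / 3.0
            elif a1 == a2:
                probs[k] = (th / 3.0) ** 2
            else:
                probs[k] = 2.0 * (th / 3.0) ** 2
        elif mode == "dependent":
            if n_ref == 2:
                continue  # filled with the remainder below
            elif n_ref == 1:
                probs[k] = th / 3.0
            elif a1 == a2:
                probs[k] = th / 6.0
            else:
                probs[k] = 2.0 * (th / 3.0) ** 2
        else:
            raise ValueError(f"unknown prior mode {mode!r}")
    if mode == "dependent":
        rest = 1.0 - probs.sum()
        if rest <= 0:
            raise ValueError("theta too large: hom-ref prior would be <= 0")
        probs[GENOTYPES.index((ref, ref))] = rest
    if probs[GENOTYPES.index((ref, ref))] <= 0:
        raise ValueError("theta too large: hom-ref prior would be <= 0")
    return IbcPrior(mode, ref, probs)


def call_genotype_ibc(
    gl: GenotypeLikelihoods, prior: IbcPrior, params: ModelParams | None = None
) -> IbcGenotypeCall:
    """Argmax-posterior call with the 99% threshold; ties break alphabetically."""
    params = params or ModelParams()
    w = gl.loglik + prior.log_probs
    w -= w.max()
    p = np.exp(w)
    p /= p.sum()
    best = int(np.argmax(p))  # np.argmax returns the first (alphabetical) max
    pmax = float(p[best])
    if pmax < params.posterior_threshold:
        return IbcGenotypeCall(MISSING, gq_from_posterior(pmax), gl.depth, pmax)
    return IbcGenotypeCall(best, gq_from_posterior(pmax), gl.depth, pmax)


def call_cohort_ibc(
    loglik: np.ndarray,
    depth: np.ndarray,
    refs: np.ndarray,
    params: ModelParams | None = None,
    mode: str = "dependent",
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Vectorized per-cell IBC calls.

    Parameters
    ----------
    loglik : (n_sites, n_samples, 10) renormalized log-likelihoods
    depth : (n_sites, n_samples)
    refs : (n_sites,) reference allele index per site

    Returns
    -------
    gt : (n_sites, n_samples) int8 genotype index, -1 missing
    post_max : posterior of the best genotype
    gq : PHRED genotype quality
    """
    params = params or ModelParams()
    logpriors = np.stack(
        [ibc_prior(r, params, mode).log_probs for r in range(4)]
    )  # (4, 10)
    w = loglik + logpriors[refs][:, None, :]
    w -= w.max(axis=2, keepdims=True)
    p = np.exp(w)
    p /= p.sum(axis=2, keepdims=True)
    best = p.argmax(axis=2)
    pmax = np.take_along_axis(p, best[..., None], axis=2)[..., 0]
    gt = np.where(pmax >= params.posterior_threshold, best, MISSING).astype(np.int8)
    return gt, pmax, gq_from_posterior(pmax)


def build_union_callset(
    gt: np.ndarray,
    gq: np.ndarray,
    depth: np.ndarray,
    refs: np.ndarray,
    positions: np.ndarray,
    samples: list[str],
    chrom: str = "chr1",
) -> CallSet:
    """Union of variant sites and genotypes across all individuals.

    A site enters the call set iff at least one non-missing called genotype
    carries a non-reference allele.  The site allele list is the reference
    plus the union of called alternates (ordered by called allele count,
    ties by base order), supporting tri- and tetra-allelic sites.
    """
    n_sites, n_samples = gt.shape
    a1_base = np.where(gt >= 0, GT_PAIR_A1[np.maximum(gt, 0)], -1)
    a2_base = np.where(gt >= 0, GT_PAIR_A2[np.maximum(gt, 0)], -1)

    keep: list[int] = []
    rows = []
    a1_list, a2_list = [], []
    for m in range(n_sites):
        ref = int(refs[m])
        called = gt[m] >= 0
        carries_alt = called & ((a1_base[m] != ref) | (a2_base[m] != ref))
        if not carries_alt.any():
            continue
        # called alternate allele counts
        counts = np.zeros(4, dtype=int)
        for arr in (a1_base[m], a2_base[m]):
            v = arr[called]
            counts += np.bincount(v[v != ref], minlength=4) if (v != ref).any() else 0
        alts = [b for b in np.argsort(-counts, kind="stable") if counts[b] > 0]
        allele_of = {ref: 0}
        for j, b in enumerate(alts):
            allele_of[int(b)] = j + 1
        remap = np.full(4, -1, dtype=np.int8)
        for b, j in allele_of.items():
            remap[b] = j
        keep.append(m)
        rows.append(
            {
                "chrom": chrom,
                "pos": int(positions[m]),
                "ref": ref,
                "alts": tuple(int(b) for b in alts),
                "qual": float(np.max(gq[m][carries_alt])) if carries_alt.any() else 0.0,
            }
        )
        a1_list.append(np.where(called, remap[np.maximum(a1_base[m], 0)], MISSING))
        a2_list.append(np.where(called, remap[np.maximum(a2_base[m], 0)], MISSING))

    if not keep:
        sites = pd.DataFrame(columns=["chrom", "pos", "ref", "alts", "qual"])
        empty = np.zeros((0, n_samples), dtype=np.int8)
        return CallSet("ibc", samples, sites, empty, empty.copy(),
                       np.zeros((0, n_samples)), np.zeros((0, n_samples), dtype=np.int32))
    keep_arr = np.array(keep)
    return CallSet(
        caller="ibc",
        samples=samples,
        sites=pd.DataFrame(rows),
        a1=np.array(a1_list, dtype=np.int8),
        a2=np.array(a2_list, dtype=np.int8),
        gq=gq[keep_arr].astype(float),
        dp=depth[keep_arr].astype(np.int32),
    )


def call_ibc(
    loglik: np.ndarray,
    depth: np.ndarray,
    refs: np.ndarray,
    positions: np.ndarray,
    samples: list[str],
    chrom: str = "chr1",
    params: ModelParams | None = None,
    mode: str = "dependent",
) -> CallSet:
    """End-to-end IBC: per-cell calls then union call-set assembly."""
    gt, _pmax, gq = call_cohort_ibc(loglik, depth, refs, params, mode)
    return build_union_callset(gt, gq, depth, refs, positions, samples, chrom)
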