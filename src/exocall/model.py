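"""Genotype-likelihood model shared by all callers.

A diploid genotype at a biallelic-or-worse SNV site is an unordered pair of
the four nucleotides, giving 10 possible genotypes.  For a single sample at a
single site, the probability of the observed read bases given each candidate
genotype is the product over reads of a per-base emission term: a read base
matches a template allele with probability 1 - e and is misread as any
specific other base with probability e/3, where e is the PHRED-derived
per-base error probability.  A heterozygous template emits each of its two
alleles with probability 1/2.

All likelihood math is carried in natural-log space, renormalized per sample
so the best genotype has log-likelihood 0; this keeps depths of several
hundred reads numerically safe.
"""

from __future__ import annotations

import dataclasses
from typing import Iterable, Mapping

import numpy as np

BASES = "ACGT"
BASE_INDEX: dict[str, int] = {b: i for i, b in enumerate(BASES)}

#: the 10 unordered diploid genotypes in fixed alphabetical order
GENOTYPES: tuple[tuple[int, int], ...] = (
    (0, 0), (0, 1), (0, 2), (0, 3),
    (1, 1), (1, 2), (1, 3),
    (2, 2), (2, 3),
    (3, 3),
)
GENOTYPE_NAMES: tuple[str, ...] = tuple(BASES[i] + BASES[j] for i, j in GENOTYPES)
N_GENOTYPES = len(GENOTYPES)

#: lookup from an (ordered or unordered) allele pair to the genotype index
GT_INDEX: dict[tuple[int, int], int] = {}
for _k, (_i, _j) in enumerate(GENOTYPES):
    GT_INDEX[(_i, _j)] = _k
    GT_INDEX[(_j, _i)] = _k

#: GT_PAIR_A1[k], GT_PAIR_A2[k]: allele indices of genotype k
GT_PAIR_A1 = np.array([p[0] for p in GENOTYPES], dtype=np.int8)
GT_PAIR_A2 = np.array([p[1] for p in GENOTYPES], dtype=np.int8)

#: transition partner of each base (A<->G, C<->T)
TRANSITION_PARTNER = np.array([2, 3, 0, 1], dtype=np.int8)


@dataclasses.dataclass(frozen=True)
class ModelParams:
    """Global calling parameters.

    theta
        Per-bp heterozygosity of the individual-based prior and of the
        neutral-model polymorphism prior (default 0.001).
    posterior_threshold
        Minimum posterior probability required to emit a genotype call
        rather than a missing genotype (default 0.99).
    error_floor_cap
        Per-base error probabilities are capped at this value so that a
        quality-0 base never carries an (improper) error probability of 1.
    """

    theta: float = 0.001
    posterior_threshold: float = 0.99
    error_floor_cap: float = 0.75

    def __post_init__(self) -> None:
        if not 0.0 < self.theta < 1.0:
            raise ValueError(f"theta must be in (0, 1), got {self.theta}")
        if not 0.5 < self.posterior_threshold < 1.0:
            raise ValueError(
                f"posterior_threshold must be in (0.5, 1), got {self.posterior_threshold}"
            )
        if not 0.0 < self.error_floor_cap <= 1.0:
            raise ValueError("error_floor_cap must be in (0, 1]")


@dataclasses.dataclass
class SampleObservations:
    """Read bases and PHRED qualities for one sample at one site."""

    bases: np.ndarray  # int8 allele indices into BASES
    quals: np.ndarray  # integer PHRED scores

    def __post_init__(self) -> None:
        self.bases = np.asarray(self.bases, dtype=np.int8)
        self.quals = np.asarray(self.quals)
        if self.bases.shape != self.quals.shape:
            raise ValueError("bases and quals must have the same length")
        if self.depth and self.quals.min() < 0:
            raise ValueError("PHRED qualities must be non-negative")

    @property
    def depth(self) -> int:
        return int(self.bases.size)

    @classmethod
    def from_strings(cls, bases: str, quals: Iterable[int]) -> "SampleObservations":
        return cls(
            np.array([BASE_INDEX[b] for b in bases], dtype=np.int8),
            np.asarray(list(quals)),
        )


@dataclasses.dataclass
class PileupColumn:
    """One reference position with per-sample observations."""

    chrom: str
    pos: int  # 1-based
    ref: int  # allele index
    obs: dict[str, SampleObservations]

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise ValueError("pos is 1-based and must be >= 1")
        if not 0 <= self.ref < 4:
            raise ValueError("ref must be an A/C/G/T allele index")


@dataclasses.dataclass
class GenotypeLikelihoods:
    """Log-likelihood over the 10 genotypes for one sample at one site.

    Renormalized so the maximum entry is 0; ``depth == 0`` implies a flat
    vector.
    """

    loglik: np.ndarray  # shape (10,)
    depth: int

    def __post_init__(self) -> None:
        self.loglik = np.asarray(self.loglik, dtype=float)
        if self.loglik.shape != (N_GENOTYPES,):
            raise ValueError("loglik must have one entry per genotype")
        if not np.all(np.isfinite(self.loglik)):
            raise ValueError("loglik must be finite")


def phred_to_error(q, cap: float = 0.75):
    """PHRED score -> per-base error probability, capped at ``cap``."""
    q = np.asarray(q)
    if np.any(q < 0):
        raise ValueError("PHRED scores must be non-negative")
    e = np.minimum(10.0 ** (-q / 10.0), cap)
    return float(e) if e.ndim == 0 else e


def base_emission(b: int, g: tuple[int, int] | int, e: float) -> float:
    """P(read base b | genotype g) with error probability e.

    ``g`` may be a genotype index or an allele-index pair.  The emission is
    symmetric in the two alleles of the genotype.
    """
    if not 0.0 < e < 1.0:
        raise ValueError("error probability must be in (0, 1)")
    if isinstance(g, (int, np.integer)):
        a1, a2 = GENOTYPES[int(g)]
    else:
        a1, a2 = g
    p1 = 1.0 - e if b == a1 else e / 3.0
    p2 = 1.0 - e if b == a2 else e / 3.0
    return 0.5 * (p1 + p2)


def genotype_likelihoods(
    obs: SampleObservations, params: ModelParams | None = None
) -> GenotypeLikelihoods:
    """Compute the 10-genotype log-likelihood vector for one sample/site."""
    params = params or ModelParams()
    if obs.depth == 0:
        return GenotypeLikelihoods(np.zeros(N_GENOTYPES), 0)
    e = phred_to_error(obs.quals, cap=params.error_floor_cap)
    e = np.atleast_1d(np.asarray(e, dtype=float))
    # (reads, 4): per-read probability of the base given each template allele
    p_allele = np.where(
        obs.bases[:, None] == np.arange(4)[None, :], 1.0 - e[:, None], e[:, None] / 3.0
    )
    # (reads, 10): half-sum over the two alleles of each genotype
    p_geno = 0.5 * (p_allele[:, GT_PAIR_A1] + p_allele[:, GT_PAIR_A2])
    loglik = np.log(p_geno).sum(axis=0)
    loglik -= loglik.max()
    return GenotypeLikelihoods(loglik, obs.depth)


def loglik_matrix(
    site_idx: np.ndarray,
    sample_idx: np.ndarray,
    base_idx: np.ndarray,
    qual: np.ndarray,
    n_sites: int,
    n_samples: int,
    params: ModelParams | None = None,
    chunk: int = 2_000_000,
) -> tuple[np.ndarray, np.ndarray]:
    """Vectorized cohort-scale genotype likelihoods.

    Takes flattened read arrays (one entry per read) and scatter-adds the
    per-read log emission into a dense ``(n_sites, n_samples, 10)`` array.
    Returns ``(loglik, depth)`` with ``loglik`` renormalized so the per-cell
    maximum is 0 (zero-depth cells are exactly flat).
    """
    params = params or ModelParams()
    ncell = n_sites * n_samples
    flat = site_idx.astype(np.int64) * n_samples + sample_idx.astype(np.int64)
    acc = np.zeros((ncell, N_GENOTYPES))
    for lo in range(0, flat.size, chunk):
        hi = min(lo + chunk, flat.size)
        e = np.minimum(
            10.0 ** (-qual[lo:hi].astype(float) / 10.0), params.error_floor_cap
        )
        p_allele = np.where(
            base_idx[lo:hi, None] == np.arange(4)[None, :],
            1.0 - e[:, None],
            e[:, None] / 3.0,
        )
        logem = np.log(0.5 * (p_allele[:, GT_PAIR_A1] + p_allele[:, GT_PAIR_A2]))
        for g in range(N_GENOTYPES):
            acc[:, g] += np.bincount(flat[lo:hi], weights=logem[:, g], minlength=ncell)
    depth = np.bincount(flat, minlength=ncell).reshape(n_sites, n_samples)
    loglik = acc.reshape(n_sites, n_samples, N_GENOTYPES)
    loglik -= loglik.max(axis=2, keepdims=True)
    return loglik, depth.astype(np.int32)


def posterior(
    loglik: GenotypeLikelihoods | np.ndarray,
    logprior: Mapping[int, float] | np.ndarray,
) -> np.ndarray:
    """Posterior over the 10 genotypes from log-likelihood and log-prior.

    The prior must be normalized (sum of exp(logprior) == 1).  Computed in
    log space with max-subtraction; the result sums to 1 within 1e-12.
    """
    ll = loglik.loglik if isinstance(loglik, GenotypeLikelihoods) else np.asarray(loglik)
    if isinstance(logprior, Mapping):
        lp = np.full(N_GENOTYPES, -np.inf)
        for g, v in logprior.items():
            lp[g] = v
    else:
        lp = np.asarray(logprior, dtype=float)
    total = np.exp(lp[np.isfinite(lp)]).sum()
    if abs(total - 1.0) > 1e-8:
        raise ValueError(f"prior is not normalized (sums to {total})")
    w = ll + lp
    w -= w.max()
    p = np.exp(w)
    return p / p.sum()


def gq_from_posterior(post_max, cap: float = 100.0):
    """PHRED-scaled genotype quality -10*log10(1 - posterior), capped."""
    post_max = np.asarray(post_max, dtype=float)
    with np.errstate(divide="ignore"):
        gq = -10.0 * np.log10(np.maximum(1.0 - post_max, 1e-300))
    gq = np.minimum(gq, cap)
    return float(gq) if gq.ndim == 0 else gq
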