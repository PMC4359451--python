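"""Population-based single-marker caller (PBC).

Variant discovery and genotyping proceed in two steps.  Upon observing at
least one non-reference read in the cohort, the site is tested for
polymorphism: the prior probability that a site segregates in n sampled
chromosomes is the Watterson expectation theta * sum_{i<n} 1/i (capped at
0.5), and the evidence is the ratio of the cohort likelihood under a
biallelic Hardy-Weinberg model at the ML allele frequency to the likelihood
of everyone being reference-homozygous.  For emitted sites, per-sample
genotype posteriors combine the individual read likelihoods with the
HWE genotype prior {(1-f)^2, 2f(1-f), f^2} at the estimated frequency; the
best genotype is called when its posterior reaches 99%, else missing.

The allele-frequency estimate maximizes the cohort likelihood by EM on the
HWE mixture, started from the quality-weighted non-reference read fraction
and floored at one allele in the sampled chromosomes.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .callset import CallSet
from .model import GT_INDEX, ModelParams, gq_from_posterior

MISSING = -1


def polymorphism_prior(n_chromosomes: int, theta: float = 0.001) -> float:
    """Watterson probability that a site segregates among n chromosomes.

    theta * H_{n-1}, capped at 0.5 to remain a proper prior for large n.
    """
    if n_chromosomes < 2:
        raise ValueError("need at least 2 chromosomes")
    harmonic = np.sum(1.0 / np.arange(1, n_chromosomes))
    return float(min(0.5, theta * harmonic))


def choose_alt(
    base_idx: np.ndarray, qual: np.ndarray, ref: int, cap: float = 0.75
) -> int | None:
    """Pick the alternate allele with the highest quality-weighted read count.

    Each read is weighted by its probability of being correct (1 - e).
    Returns None when no non-reference base was observed (site skipped).
    Ties break by base order (A < C < G < T).
    """
    base_idx = np.asarray(base_idx)
    if base_idx.size == 0:
        return None
    w = 1.0 - np.minimum(10.0 ** (-np.asarray(qual, dtype=float) / 10.0), cap)
    weights = np.bincount(base_idx, weights=w, minlength=4)
    weights[ref] = -1.0
    if np.all(weights <= 0):
        return None
    return int(np.argmax(weights))  # argmax returns the first max: base order


def estimate_f_em(
    gl3: np.ndarray,
    f0: float | None = None,
    tol: float = 1e-6,
    max_iter: int = 100,
) -> float:
    """ML alternate-allele frequency under HWE by EM for one site.

    gl3 : (n_samples, 3) likelihoods (any scale) for (RR, RA, AA).

    The mixture likelihood can be multimodal for very small cohorts, so EM
    runs from several starting frequencies and the run with the highest
    final likelihood wins; the result is floored at one allele in the
    sampled chromosomes.
    """
    gl3 = np.asarray(gl3, dtype=float)
    if gl3.ndim != 2 or gl3.shape[0] == 0:
        raise ValueError("need a (n_samples, 3) likelihood array")
    if np.any(gl3.max(axis=1) <= 0):
        raise ValueError("each sample needs at least one positive likelihood")
    f = _estimate_f_em_many(
        gl3[None, :, :],
        np.array([f0 if f0 is not None else 1.0 / (2 * gl3.shape[0])]),
        tol,
        max_iter,
    )
    return float(f[0])


_EXTRA_STARTS = (0.05, 0.5, 0.95)


def _mixture_loglik(gl3: np.ndarray, f: np.ndarray) -> np.ndarray:
    prior = np.stack([(1 - f) ** 2, 2 * f * (1 - f), f * f], axis=1)
    return np.log(
        np.maximum(np.einsum("msk,mk->ms", gl3, prior), 1e-300)
    ).sum(axis=1)


def _em_single_start(gl3, f0, tol, max_iter):
    n_sites, n_samples, _ = gl3.shape
    n2 = 2.0 * n_samples
    floor = 1.0 / n2
    f = np.clip(f0.astype(float), floor, 1.0 - floor)
    active = np.ones(n_sites, dtype=bool)
    for _ in range(max_iter):
        if not active.any():
            break
        fa = f[active]
        prior = np.stack([(1 - fa) ** 2, 2 * fa * (1 - fa), fa * fa], axis=1)
        post = gl3[active] * prior[:, None, :]
        post /= post.sum(axis=2, keepdims=True)
        f_new = (post[:, :, 1] + 2.0 * post[:, :, 2]).sum(axis=1) / n2
        done = np.abs(f_new - fa) < tol
        f[active] = f_new
        active[np.where(active)[0][done]] = False
    return np.clip(f, floor, 1.0 - floor)


def _estimate_f_em_many(
    gl3: np.ndarray, f0: np.ndarray, tol: float = 1e-6, max_iter: int = 100
) -> np.ndarray:
    """Vectorized multi-start EM across sites; gl3 is (n_sites, n_samples, 3)."""
    best_f = _em_single_start(gl3, f0, tol, max_iter)
    best_ll = _mixture_loglik(gl3, best_f)
    for start in _EXTRA_STARTS:
        f = _em_single_start(gl3, np.full(gl3.shape[0], start), tol, max_iter)
        ll = _mixture_loglik(gl3, f)
        better = ll > best_ll + 1e-12
        best_f = np.where(better, f, best_f)
        best_ll = np.maximum(ll, best_ll)
    return best_f


def variant_posterior(
    gl3: np.ndarray, f_hat: float, prior_poly: float
) -> tuple[bool, float, float]:
    """Posterior probability of polymorphism and the PHRED site quality.

    Returns (is_variant at the default threshold P > 0.5, site_qual capped at
    255, P(poly|data)).
    """
    gl3 = np.asarray(gl3, dtype=float)
    prior = np.array([(1 - f_hat) ** 2, 2 * f_hat * (1 - f_hat), f_hat**2])
    tiny = 1e-300  # guards exact-zero likelihoods from deep-coverage underflow
    log_l1 = np.log(np.maximum((gl3 * prior).sum(axis=1), tiny)).sum()
    log_l0 = np.log(np.maximum(gl3[:, 0], tiny)).sum()
    # P = prior*L1 / (prior*L1 + (1-prior)*L0), in log space
    a = np.log(prior_poly) + log_l1
    b = np.log1p(-prior_poly) + log_l0
    p_poly = float(1.0 / (1.0 + np.exp(b - a)))
    qual = float(min(255.0, -10.0 * np.log10(max(1.0 - p_poly, 1e-300))))
    return p_poly > 0.5, qual, p_poly


def call_genotypes_pbc(
    gl3: np.ndarray, f_hat: float, params: ModelParams | None = None
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Per-sample biallelic genotype calls with the HWE(f_hat) prior.

    Returns (dosage in {0,1,2} or -1 missing, gq, posterior max).
    """
    params = params or ModelParams()
    gl3 = np.asarray(gl3, dtype=float)
    prior = np.array([(1 - f_hat) ** 2, 2 * f_hat * (1 - f_hat), f_hat**2])
    post = gl3 * prior
    post /= post.sum(axis=1, keepdims=True)
    best = post.argmax(axis=1)
    pmax = np.take_along_axis(post, best[:, None], axis=1)[:, 0]
    gt = np.where(pmax >= params.posterior_threshold, best, MISSING).astype(np.int8)
    return gt, gq_from_posterior(pmax), pmax


def triplet_indices(ref: int, alt: int) -> tuple[int, int, int]:
    """Genotype-vector indices of (ref/ref, ref/alt, alt/alt)."""
    return GT_INDEX[(ref, ref)], GT_INDEX[(ref, alt)], GT_INDEX[(alt, alt)]


def call_pbc(
    loglik: np.ndarray,
    depth: np.ndarray,
    refs: np.ndarray,
    positions: np.ndarray,
    samples: list[str],
    reads: tuple[np.ndarray, np.ndarray, np.ndarray] | None = None,
    chrom: str = "chr1",
    params: ModelParams | None = None,
    emit_qual: float = 3.0,
    sample_subset: np.ndarray | None = None,
    candidate_sites: np.ndarray | None = None,
) -> CallSet:
    """End-to-end population-based calling over a cohort.

    Parameters
    ----------
    loglik : (n_sites, n_samples, 10) renormalized genotype log-likelihoods
    reads : optional (site_idx, sample_idx, base_idx, qual) flattened read
        arrays used to pick the alternate allele by quality-weighted count
        (restricted to the sample subset if one is given); when omitted the
        alternate is chosen by summed likelihood evidence.
    emit_qual : site quality (PHRED) above which a site is emitted as
        variant; the default 3 corresponds to P(polymorphic) > 0.5 — the
        real selection is done downstream by ranking.
    sample_subset : optional integer indices restricting the cohort (used for
        split replicate runs and down-sampling analyses).
    candidate_sites : optional integer site indices to evaluate (defaults to
        all sites with any non-reference evidence).
    """
    params = params or ModelParams()
    if sample_subset is not None:
        sample_subset = np.asarray(sample_subset)
        loglik = loglik[:, sample_subset]
        depth = depth[:, sample_subset]
        samples = [samples[i] for i in sample_subset]
        if reads is not None:
            site_idx, samp_idx, base_idx, qual = reads
            keep = np.isin(samp_idx, sample_subset)
            reads = (site_idx[keep], samp_idx[keep], base_idx[keep], qual[keep])
    n_sites, n_samples = depth.shape
    prior_poly = polymorphism_prior(2 * n_samples, params.theta)

    # choose the alternate allele per site
    alt = np.full(n_sites, -1, dtype=np.int8)
    w_alt_frac = np.zeros(n_sites)
    if reads is not None:
        site_idx, _samp_idx, base_idx, qual = reads
        w = 1.0 - np.minimum(
            10.0 ** (-qual.astype(float) / 10.0), params.error_floor_cap
        )
        wsum = np.zeros((n_sites, 4))
        for b in range(4):
            sel = base_idx == b
            wsum[:, b] = np.bincount(site_idx[sel], weights=w[sel], minlength=n_sites)
        total = wsum.sum(axis=1)
        wsum[np.arange(n_sites), refs] = -1.0
        best = wsum.argmax(axis=1)
        has_alt = wsum[np.arange(n_sites), best] > 0
        alt[has_alt] = best[has_alt]
        with np.errstate(invalid="ignore", divide="ignore"):
            w_alt_frac = np.where(
                total > 0, np.maximum(wsum[np.arange(n_sites), best], 0.0) / total, 0.0
            )
    else:
        # likelihood fallback: hom-alt loglik summed over samples
        hom_idx = np.array([GT_INDEX[(b, b)] for b in range(4)])
        evidence = loglik[:, :, hom_idx].sum(axis=1)  # (n_sites, 4)
        evidence[np.arange(n_sites), refs] = -np.inf
        alt = evidence.argmax(axis=1).astype(np.int8)
        w_alt_frac = np.full(n_sites, 0.01)

    cand = np.where(alt >= 0)[0]
    if candidate_sites is not None:
        cand = np.intersect1d(cand, np.asarray(candidate_sites))

    rows = []
    keep = []
    gt_rows, gq_rows, gl3_rows, fh = [], [], [], []
    if cand.size:
        i_rr = np.array([GT_INDEX[(int(r), int(r))] for r in refs[cand]])
        i_ra = np.array([GT_INDEX[(int(r), int(a))] for r, a in zip(refs[cand], alt[cand])])
        i_aa = np.array([GT_INDEX[(int(a), int(a))] for a in alt[cand]])
        idx3 = np.stack([i_rr, i_ra, i_aa], axis=1)  # (n_cand, 3)
        ll3 = np.take_along_axis(loglik[cand], idx3[:, None, :], axis=2)
        ll3 = ll3 - ll3.max(axis=2, keepdims=True)
        gl3 = np.exp(ll3)  # (n_cand, n_samples, 3)
        f0 = np.maximum(w_alt_frac[cand], 1.0 / (2 * n_samples))
        f_hat = _estimate_f_em_many(gl3, f0)
        for j, m in enumerate(cand):
            is_var, qual, _p = variant_posterior(gl3[j], f_hat[j], prior_poly)
            if qual <= emit_qual:
                continue
            gt, gq, _pm = call_genotypes_pbc(gl3[j], f_hat[j], params)
            keep.append(m)
            rows.append(
                {
                    "chrom": chrom,
                    "pos": int(positions[m]),
                    "ref": int(refs[m]),
                    "alts": (int(alt[m]),),
                    "qual": qual,
                    "f_hat": f_hat[j],
                }
            )
            gt_rows.append(gt)
            gq_rows.append(gq)
            gl3_rows.append(gl3[j])
            fh.append(f_hat[j])

    if not keep:
        sites = pd.DataFrame(columns=["chrom", "pos", "ref", "alts", "qual", "f_hat"])
        empty = np.zeros((0, n_samples), dtype=np.int8)
        return CallSet("pbc", samples, sites, empty, empty.copy(),
                       np.zeros((0, n_samples)), np.zeros((0, n_samples), dtype=np.int32))

    keep_arr = np.array(keep)
    gt = np.array(gt_rows, dtype=np.int8)
    a1 = np.where(gt >= 0, (gt >= 1).astype(np.int8), MISSING)
    a2 = np.where(gt >= 0, (gt == 2).astype(np.int8), MISSING)
    return CallSet(
        caller="pbc",
        samples=samples,
        sites=pd.DataFrame(rows),
        a1=a1.astype(np.int8),
        a2=a2.astype(np.int8),
        gq=np.array(gq_rows, dtype=float),
        dp=depth[keep_arr].astype(np.int32),
        gl3=np.array(gl3_rows, dtype=float),
    )
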