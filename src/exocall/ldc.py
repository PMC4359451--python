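"""LD-aware genotype refinement via a haplotype-copying HMM.

Starting from a population-based call set, each individual's pair of
haplotypes is modelled as an imperfect mosaic of K template haplotypes
sampled from the rest of the cohort (the Li-Stephens model).  The hidden
state at each marker is the ordered pair of templates being copied; each
haplotype switches template between adjacent markers with probability rho
(jumping to a uniformly chosen template), and the copied allele differs from
the template allele with per-allele error rate epsilon.  The emission at a
sequence marker is the read-genotype likelihood mixed over copying errors;
at an unmasked scaffold marker it is the chip-genotype likelihood with a
small chip error rate; masked or missing markers emit flat.

Each iteration visits every sample in random order, runs an exact
forward-backward over the K^2 pair states against a fresh random panel of K
haplotypes from the other samples, samples a new haplotype pair from the
posterior, and re-estimates epsilon and rho from the sampled mismatch and
switch counts (stochastic EM in the MACH tradition).  After a burn-in, the
exact per-marker genotype posteriors are averaged across iterations; the
consensus gives the refined genotype, the dosage (expected alternate-allele
count), and the per-site imputation quality R-hat-squared
Var(dosage) / (2 f (1-f)).

Refinement never adds or removes sites; it only updates genotypes at the
sites of the input call set.  Processing is per target region (the target
interval plus its scaffold flanks), so distant regions stay independent.
"""

from __future__ import annotations

import dataclasses
from typing import Optional

import numpy as np
import pandas as pd
from numba import njit

from .callset import CallSet

MISSING = -1


@dataclasses.dataclass
class HmmConfig:
    n_iterations: int = 30
    n_reference_haplotypes: int = 200
    burn_in: int = 10
    error_rate: float = 0.01  # per-allele copying error, re-estimated
    crossover_rate: float = 0.01  # per-interval switch probability, re-estimated
    chip_error_rate: float = 0.002
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.burn_in < self.n_iterations:
            raise ValueError("burn_in must be < n_iterations")
        if self.n_reference_haplotypes < 1:
            raise ValueError("need at least one reference haplotype")
        for r in (self.error_rate, self.crossover_rate):
            if not 0.0 < r < 0.5:
                raise ValueError("rates must be in (0, 0.5)")


def mix_matrix(eps: float) -> np.ndarray:
    """P(copied genotype g | template dosage d) under per-allele error eps."""
    stay, flip = 1.0 - eps, eps
    m = np.empty((3, 3))
    m[0] = [stay * stay, 2 * stay * flip, flip * flip]
    m[1] = [stay * flip, stay * stay + flip * flip, stay * flip]
    m[2] = [flip * flip, 2 * stay * flip, stay * stay]
    return m


@njit(cache=True)
def _pair_fb(H, L3, eps, rho, u_path, u_allele, want_gamma):  # pragma: no cover
    """Forward-backward + posterior path sampling for one individual.

    H : (K, M) int8 template haplotypes
    L3 : (M, 3) per-marker genotype likelihoods (flat rows for no data)
    eps : (M,) per-marker copying-error rate
    rho : (M-1,) per-interval switch probabilities
    u_path, u_allele : (M,) uniforms for path / allele sampling
    want_gamma : if True, also return the (M, K, K) state marginals

    Returns (post3, hap1, hap2, n_switch, mismatch counts per marker, gamma).
    """
    K, M = H.shape
    KK = K * K
    alpha = np.empty((M, K, K))
    emis = np.empty((M, 3))
    mix = np.empty((M, 3, 3))
    for m in range(M):
        stay = 1.0 - eps[m]
        flip = eps[m]
        mix[m, 0, 0] = stay * stay
        mix[m, 0, 1] = 2 * stay * flip
        mix[m, 0, 2] = flip * flip
        mix[m, 1, 0] = stay * flip
        mix[m, 1, 1] = stay * stay + flip * flip
        mix[m, 1, 2] = stay * flip
        mix[m, 2, 0] = flip * flip
        mix[m, 2, 1] = 2 * stay * flip
        mix[m, 2, 2] = stay * stay
        for d in range(3):
            emis[m, d] = (
                mix[m, d, 0] * L3[m, 0]
                + mix[m, d, 1] * L3[m, 1]
                + mix[m, d, 2] * L3[m, 2]
            )
    # forward
    s = 0.0
    for j in range(K):
        for l in range(K):
            v = emis[0, H[j, 0] + H[l, 0]] / KK
            alpha[0, j, l] = v
            s += v
    for j in range(K):
        for l in range(K):
            alpha[0, j, l] /= s
    for m in range(1, M):
        q = rho[m - 1]
        stay = 1.0 - q
        jump = q / K
        row = np.zeros(K)
        col = np.zeros(K)
        tot = 0.0
        for j in range(K):
            for l in range(K):
                v = alpha[m - 1, j, l]
                row[j] += v
                col[l] += v
                tot += v
        s = 0.0
        for j in range(K):
            for l in range(K):
                v = (
                    stay * stay * alpha[m - 1, j, l]
                    + stay * jump * (row[j] + col[l])
                    + jump * jump * tot
                ) * emis[m, H[j, m] + H[l, m]]
                alpha[m, j, l] = v
                s += v
        for j in range(K):
            for l in range(K):
                alpha[m, j, l] /= s

    # backward + genotype posteriors
    post3 = np.zeros((M, 3))
    beta = np.ones((K, K))
    gamma_out = np.empty((M, K, K)) if want_gamma else np.empty((1, 1, 1))
    bwork = np.empty((K, K))
    for m in range(M - 1, -1, -1):
        # gamma at m
        s = 0.0
        for j in range(K):
            for l in range(K):
                v = alpha[m, j, l] * beta[j, l]
                bwork[j, l] = v
                s += v
        for j in range(K):
            for l in range(K):
                g = bwork[j, l] / s
                if want_gamma:
                    gamma_out[m, j, l] = g
                d = H[j, m] + H[l, m]
                e = emis[m, d]
                post3[m, 0] += g * mix[m, d, 0] * L3[m, 0] / e
                post3[m, 1] += g * mix[m, d, 1] * L3[m, 1] / e
                post3[m, 2] += g * mix[m, d, 2] * L3[m, 2] / e
        if m > 0:
            q = rho[m - 1]
            stay = 1.0 - q
            jump = q / K
            row = np.zeros(K)
            col = np.zeros(K)
            tot = 0.0
            for j in range(K):
                for l in range(K):
                    v = emis[m, H[j, m] + H[l, m]] * beta[j, l]
                    bwork[j, l] = v
                    row[j] += v
                    col[l] += v
                    tot += v
            mx = 0.0
            for j in range(K):
                for l in range(K):
                    v = (
                        stay * stay * bwork[j, l]
                        + stay * jump * (row[j] + col[l])
                        + jump * jump * tot
                    )
                    beta[j, l] = v
                    if v > mx:
                        mx = v
            for j in range(K):
                for l in range(K):
                    beta[j, l] /= mx
    for m in range(M):
        s = post3[m, 0] + post3[m, 1] + post3[m, 2]
        post3[m, 0] /= s
        post3[m, 1] /= s
        post3[m, 2] /= s

    # posterior path sampling (forward-filter backward-sample)
    path_j = np.empty(M, dtype=np.int64)
    path_l = np.empty(M, dtype=np.int64)
    u = u_path[M - 1]
    acc = 0.0
    jj = K - 1
    ll = K - 1
    done = False
    # last state ~ alpha (beta folded in: use alpha*beta == gamma at M-1)
    s = 0.0
    for j in range(K):
        for l in range(K):
            s += alpha[M - 1, j, l]
    for j in range(K):
        if done:
            break
        for l in range(K):
            acc += alpha[M - 1, j, l] / s
            if u <= acc:
                jj, ll = j, l
                done = True
                break
    path_j[M - 1], path_l[M - 1] = jj, ll
    n_switch = 0
    for m in range(M - 2, -1, -1):
        q = rho[m]
        stay = 1.0 - q
        jump = q / K
        s = 0.0
        for j in range(K):
            for l in range(K):
                tj = stay + jump if j == jj else jump
                tl = stay + jump if l == ll else jump
                bwork[j, l] = alpha[m, j, l] * tj * tl
                s += bwork[j, l]
        u = u_path[m]
        acc = 0.0
        done = False
        nj, nl = K - 1, K - 1
        for j in range(K):
            if done:
                break
            for l in range(K):
                acc += bwork[j, l] / s
                if u <= acc:
                    nj, nl = j, l
                    done = True
                    break
        if nj != jj:
            n_switch += 1
        if nl != ll:
            n_switch += 1
        jj, ll = nj, nl
        path_j[m], path_l[m] = jj, ll

    # allele sampling along the path
    hap1 = np.empty(M, dtype=np.int8)
    hap2 = np.empty(M, dtype=np.int8)
    n_mismatch = np.zeros(M, dtype=np.int64)
    for m in range(M):
        t1 = H[path_j[m], m]
        t2 = H[path_l[m], m]
        em = eps[m]
        w = np.empty(4)
        idx = 0
        s = 0.0
        for a1 in range(2):
            for a2 in range(2):
                p1 = 1.0 - em if a1 == t1 else em
                p2 = 1.0 - em if a2 == t2 else em
                v = L3[m, a1 + a2] * p1 * p2
                w[idx] = v
                s += v
                idx += 1
        u = u_allele[m] * s
        acc = 0.0
        pick = 3
        for idx in range(4):
            acc += w[idx]
            if u <= acc:
                pick = idx
                break
        a1 = pick // 2
        a2 = pick % 2
        hap1[m] = a1
        hap2[m] = a2
        if a1 != t1:
            n_mismatch[m] += 1
        if a2 != t2:
            n_mismatch[m] += 1
    return post3, hap1, hap2, n_switch, n_mismatch, gamma_out


def sample_individual(
    templates: np.ndarray,
    gl3: np.ndarray,
    cfg: HmmConfig,
    rng: np.random.Generator,
    rho: float | None = None,
    eps: float | None = None,
    return_gamma: bool = False,
):
    """Run the pair HMM for one individual against K template haplotypes.

    Returns a dict with exact marginal posterior triplets (``post3``), one
    sampled haplotype pair, the sampled switch/mismatch counts, and (on
    request) the per-marker pair-state marginals for oracle checks.
    """
    templates = np.ascontiguousarray(templates, dtype=np.int8)
    if templates.shape[0] < 1:
        raise ValueError("need at least one reference haplotype (K >= 1)")
    gl3 = np.ascontiguousarray(gl3, dtype=float)
    m = gl3.shape[0]
    rho = cfg.crossover_rate if rho is None else rho
    eps = cfg.error_rate if eps is None else eps
    eps_vec = np.ascontiguousarray(np.broadcast_to(np.asarray(eps, float), (m,)))
    rho_vec = np.ascontiguousarray(
        np.broadcast_to(np.asarray(rho, float), (max(m - 1, 0),))
    )
    post3, h1, h2, nsw, nmm, gamma = _pair_fb(
        templates,
        gl3,
        eps_vec,
        rho_vec,
        rng.random(m),
        rng.random(m),
        return_gamma,
    )
    out = {
        "post3": post3,
        "hap1": h1,
        "hap2": h2,
        "n_switch": int(nsw),
        "n_mismatch": int(nmm.sum()),
    }
    if return_gamma:
        out["gamma"] = gamma
    return out


# ---------------------------------------------------------------------------
# marker map / scaffold merging
# ---------------------------------------------------------------------------

def merge_scaffold(
    callset: CallSet,
    scaffold_sites: Optional[pd.DataFrame],
    scaffold_gt: Optional[np.ndarray],
    targets: list[tuple[int, int]],
    window: int = 500_000,
) -> pd.DataFrame:
    """Build the ordered marker map of sequence + scaffold markers.

    Scaffold markers within ``window`` bp of a target interval are included;
    those inside a target are masked (chip genotype not used as emission).
    A scaffold marker at the position of a sequence marker is reconciled
    when ref/alt agree (single marker; chip masked there) and rejected
    otherwise.  Returns a DataFrame with columns pos, source, masked,
    seq_idx, chip_idx sorted by position.
    """
    seq_pos = callset.sites["pos"].to_numpy()
    rows = [
        {"pos": int(p), "source": "sequence", "masked": False, "seq_idx": i, "chip_idx": -1}
        for i, p in enumerate(seq_pos)
    ]
    if scaffold_sites is not None and len(scaffold_sites):
        seq_by_pos = {int(p): i for i, p in enumerate(seq_pos)}
        in_target = np.zeros(len(scaffold_sites), dtype=bool)
        pos = scaffold_sites["pos"].to_numpy()
        near = np.zeros(len(scaffold_sites), dtype=bool)
        for start, end in targets:
            in_target |= (pos >= start) & (pos <= end)
            near |= (pos >= start - window) & (pos <= end + window)
        for c in range(len(scaffold_sites)):
            if not near[c]:
                continue
            p = int(pos[c])
            if p in seq_by_pos:
                i = seq_by_pos[p]
                srow = scaffold_sites.iloc[c]
                site = callset.sites.iloc[i]
                alts = site["alts"]
                if int(srow["ref"]) != int(site["ref"]) or (
                    len(alts) and int(srow["alt"]) != int(alts[0])
                ):
                    raise ValueError(
                        f"allele mismatch between scaffold and call set at pos {p}"
                    )
                # reconciled: the sequence marker absorbs it; chip is masked
                # inside targets, usable as emission outside
                rows[i]["chip_idx"] = c
                rows[i]["masked"] = bool(in_target[c])
            else:
                rows.append(
                    {
                        "pos": p,
                        "source": "scaffold",
                        "masked": bool(in_target[c]),
                        "seq_idx": -1,
                        "chip_idx": c,
                    }
                )
    out = pd.DataFrame(rows).sort_values("pos", kind="stable").reset_index(drop=True)
    if out["pos"].duplicated().any():
        raise ValueError("duplicate marker positions after scaffold merge")
    return out


def estimate_rsq(dosages: np.ndarray) -> float:
    """Imputation quality R-hat-squared = Var(dosage) / (2 f (1-f)).

    f is the dosage-implied allele frequency; monomorphic dosages give 0.
    """
    dosages = np.asarray(dosages, dtype=float)
    if dosages.size < 2:
        raise ValueError("need at least 2 samples")
    fbar = dosages.mean() / 2.0
    denom = 2.0 * fbar * (1.0 - fbar)
    if denom <= 0:
        return 0.0
    return float(np.clip(dosages.var() / denom, 0.0, 1.0))


# ---------------------------------------------------------------------------
# full refinement driver
# ---------------------------------------------------------------------------

def refine_callset(
    callset: CallSet,
    targets: list[tuple[int, int]],
    scaffold_sites: Optional[pd.DataFrame] = None,
    scaffold_gt: Optional[np.ndarray] = None,
    cfg: HmmConfig | None = None,
    window: int = 500_000,
) -> CallSet:
    """Iterative LD-aware refinement of a population-based call set.

    Returns a call set over the same sites with refined genotypes, averaged
    posterior triplets, dosages, best:second posterior ratios and per-site
    R-hat-squared.  With a single-sample cohort there are no reference
    haplotypes, and the input genotype posteriors are returned unchanged.
    """
    cfg = cfg or HmmConfig()
    if callset.gl3 is None:
        raise ValueError("refinement needs the biallelic likelihood triplets (gl3)")
    n_sites, n_samples = callset.a1.shape
    out = callset.copy()
    out = dataclasses.replace(
        out,
        caller="ldc" if scaffold_sites is None or not len(scaffold_sites) else "ldc+f",
    )
    post3 = np.zeros((n_sites, n_samples, 3))
    if n_samples < 2 or n_sites == 0:
        # degenerate: no panel to copy from; keep the input HWE posteriors
        f = callset.sites["f_hat"].to_numpy() if "f_hat" in callset.sites else np.full(n_sites, 0.05)
        prior = np.stack([(1 - f) ** 2, 2 * f * (1 - f), f * f], axis=1)
        post3 = callset.gl3 * prior[:, None, :]
        post3 /= post3.sum(axis=2, keepdims=True)
    else:
        rng = np.random.default_rng(cfg.seed)
        mmap = merge_scaffold(callset, scaffold_sites, scaffold_gt, targets, window)
        # assign each marker to a target region (nearest midpoint)
        mids = np.array([(s + e) / 2 for s, e in targets])
        region = np.argmin(
            np.abs(mmap["pos"].to_numpy()[:, None] - mids[None, :]), axis=1
        )
        for g in np.unique(region):
            sel = np.where(region == g)[0]
            sub = mmap.iloc[sel].reset_index(drop=True)
            _refine_region(callset, sub, scaffold_gt, cfg, rng, post3)

    dosage = post3[:, :, 1] + 2.0 * post3[:, :, 2]
    best2 = np.sort(post3, axis=2)[:, :, ::-1]
    with np.errstate(divide="ignore"):
        ratio = best2[:, :, 0] / np.maximum(best2[:, :, 1], 1e-300)
    gt = post3.argmax(axis=2).astype(np.int8)
    out.a1 = (gt >= 1).astype(np.int8)
    out.a2 = (gt == 2).astype(np.int8)
    pmax = best2[:, :, 0]
    with np.errstate(divide="ignore"):
        out.gq = np.minimum(-10.0 * np.log10(np.maximum(1 - pmax, 1e-300)), 100.0)
    out.post3 = post3
    out.dosage = dosage
    out.posterior_ratio = ratio
    rsq = np.array([
        estimate_rsq(dosage[m]) if n_samples >= 2 else 0.0 for m in range(n_sites)
    ])
    out.sites = out.sites.copy()
    out.sites["rsq"] = rsq
    return out


def _refine_region(
    callset: CallSet,
    mmap: pd.DataFrame,
    scaffold_gt: Optional[np.ndarray],
    cfg: HmmConfig,
    rng: np.random.Generator,
    post3_out: np.ndarray,
) -> None:
    """Run the iterative HMM over one target region, accumulating averaged
    posteriors into ``post3_out`` at the region's sequence markers."""
    n_samples = callset.n_samples
    m = len(mmap)
    seq_idx = mmap["seq_idx"].to_numpy()
    chip_idx = mmap["chip_idx"].to_numpy()
    masked = mmap["masked"].to_numpy()

    # per-sample per-marker likelihood triplets
    L = np.ones((n_samples, m, 3))
    is_seq = seq_idx >= 0
    L[:, is_seq, :] = np.transpose(callset.gl3[seq_idx[is_seq]], (1, 0, 2))
    use_chip = (chip_idx >= 0) & ~masked & ~is_seq
    if scaffold_gt is not None and use_chip.any():
        ce = cfg.chip_error_rate
        chip = scaffold_gt[chip_idx[use_chip]]  # (m_chip, n_samples)
        trip = np.full((chip.shape[0], n_samples, 3), ce / 2.0)
        for g in range(3):
            trip[:, :, g] = np.where(chip == g, 1.0 - ce, ce / 2.0)
        trip[chip < 0] = 1.0  # chip no-call: flat
        L[:, use_chip, :] = np.transpose(trip, (1, 0, 2))

    # initial haplotypes: random phase of the best-guess genotypes
    f0 = np.full(m, 0.05)
    if "f_hat" in callset.sites.columns:
        f_seq = callset.sites["f_hat"].to_numpy()
        f0[is_seq] = f_seq[seq_idx[is_seq]]
    g_best = L.argmax(axis=2)  # (n_samples, m)
    flat = np.abs(L.max(axis=2) - L.min(axis=2)) < 1e-12
    g_best = np.where(flat, -1, g_best)
    h1 = np.zeros((n_samples, m), dtype=np.int8)
    h2 = np.zeros((n_samples, m), dtype=np.int8)
    bern = (rng.random((n_samples, m)) < f0[None, :]).astype(np.int8)
    h1[:] = np.where(g_best == 2, 1, np.where(g_best == -1, bern, 0))
    bern2 = (rng.random((n_samples, m)) < f0[None, :]).astype(np.int8)
    h2[:] = np.where(g_best == 2, 1, np.where(g_best == -1, bern2, 0))
    het = g_best == 1
    coin = rng.random((n_samples, m)) < 0.5
    h1[het] = np.where(coin[het], 1, 0)
    h2[het] = np.where(coin[het], 0, 1)

    haps = np.empty((2 * n_samples, m), dtype=np.int8)
    haps[0::2] = h1
    haps[1::2] = h2

    k = min(cfg.n_reference_haplotypes, 2 * (n_samples - 1))
    # switch probability scales with inter-marker distance: rho_interval =
    # 1 - exp(-r * d_kb) with a region-wide rate r per kb, re-estimated
    gaps_kb = np.maximum(np.diff(mmap["pos"].to_numpy().astype(float)), 1.0) / 1000.0
    total_kb = float(gaps_kb.sum())
    r_kb = cfg.crossover_rate
    eps = np.full(m, cfg.error_rate)
    acc: list[np.ndarray] = []  # per-iteration marginals after burn-in
    cur = None
    for it in range(cfg.n_iterations):
        rho_vec = np.clip(1.0 - np.exp(-r_kb * gaps_kb), 1e-6, 0.45)
        sw_tot = 0
        mm_marker = np.zeros(m, dtype=np.int64)
        if it >= cfg.burn_in:
            cur = np.empty((n_samples, m, 3))
            acc.append(cur)
        for s in rng.permutation(n_samples):
            pool = np.concatenate(
                [np.arange(0, 2 * s), np.arange(2 * s + 2, 2 * n_samples)]
            )
            panel = haps[rng.choice(pool, size=k, replace=False)]
            p3, nh1, nh2, nsw, nmm, _ = _pair_fb(
                np.ascontiguousarray(panel),
                np.ascontiguousarray(L[s]),
                eps,
                np.ascontiguousarray(rho_vec),
                rng.random(m),
                rng.random(m),
                False,
            )
            haps[2 * s] = nh1
            haps[2 * s + 1] = nh2
            sw_tot += nsw
            mm_marker += nmm
            if cur is not None:
                cur[s] = p3
        # stochastic-EM parameter updates from the sampled paths; the
        # copying-error rate is per marker so that non-imputable rare
        # variants do not degrade emission confidence everywhere
        r_kb = float(
            np.clip(sw_tot / (2.0 * n_samples * max(total_kb, 1e-3)), 1e-5, 10.0)
        )
        eps = np.clip(mm_marker / (2.0 * n_samples), 1e-4, 0.2)
    # robust consensus: per-cell median of per-iteration marginals, so the
    # occasional iteration whose random panel misses a sample's haplotype
    # background cannot contaminate an otherwise well-determined genotype
    cons = np.median(np.stack(acc), axis=0)
    cons /= cons.sum(axis=2, keepdims=True)
    sel = np.where(is_seq)[0]
    post3_out[seq_idx[sel]] = np.transpose(cons[:, sel, :], (1, 0, 2))
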