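"""Synthetic targeted-sequencing cohorts with known truth.

The generator reproduces the statistical structure that the caller
comparison exercises, without modelling reads at the alignment level:

* **Site frequency spectrum.**  True alternate-allele counts are drawn from
  P(count = i) proportional to i**(-alpha) over 1..2n-1.  alpha = 1 is the
  stationary neutral spectrum; the cohort default alpha = 2 skews toward
  rare alleles, emulating the strong singleton excess that population growth
  and purifying selection produce in human exons (well over half of
  discovered exonic SNVs are singletons in large cohorts).
* **Linkage disequilibrium.**  Common variants and chip markers live on a
  small set of founder haplotypes; each sample haplotype is a founder mosaic
  with a per-kb switch rate, so nearby markers are strongly correlated while
  distant target regions are independent.  Rare variants are placed directly
  on sample chromosomes (recent mutations carry little LD).
* **Capture-coverage heterogeneity.**  Per-cell depth is Poisson with mean
  ``mean_depth * a_sample * b_site`` where the two factors are unit-mean
  gamma variables; per-site capture efficiency varies much more than
  per-sample library size, giving depths from 0 to several times the mean.
* **Replicate pairs.**  A subset of individuals receives a second,
  independently re-sequenced read column with identical truth genotypes.
* **Chip scaffold.**  Genotypes at common on-target markers and at flanking
  markers within 500 kb of each target region, perturbed at the chip error
  rate.
* **Artifact sites.**  Optional non-variant sites where a random subset of
  samples shows a systematic non-reference read fraction, producing the
  excess-heterozygosity failure mode that site ranking must learn to reject.

Everything is driven by a single integer seed and is deterministic.
"""

from __future__ import annotations

import dataclasses
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .model import TRANSITION_PARTNER


@dataclasses.dataclass
class SimConfig:
    n_samples: int = 300
    n_target_sites: int = 2000
    n_flank_markers: int = 480  # ~1 chip marker per 16 kb of flank
    n_targets: int = 8  # number of target regions ("genes")
    target_length: int = 4000  # bp per target region
    target_spacing: int = 1_200_000  # bp between target starts
    flank_window: int = 500_000  # scaffold window each side of a target

    n_founders: int = 6
    switch_rate: float = 0.01  # founder-mosaic switches per kb

    mean_depth: float = 24.0
    sample_gamma_shape: float = 10.0  # per-sample depth factor dispersion
    site_gamma_shape: float = 2.0  # per-site capture-efficiency dispersion
    qual_values: tuple[int, ...] = (20, 25, 30, 35)
    qual_probs: tuple[float, ...] = (0.1, 0.2, 0.4, 0.3)

    chip_error: float = 0.002
    chip_freq_threshold: float = 0.05  # chips type common on-target markers
    n_replicate_pairs: Optional[int] = None  # default: 80 scaled by n/7842

    ts_bias: float = 0.67  # P(transition | mutation) -> true Ts/Tv ~ 2
    sfs_alpha: float = 2.0  # rare-excess exponent; 1.0 = neutral 1/i
    common_ld_threshold: float = 0.02  # frequency above which sites ride founders

    artifact_rate: float = 0.05  # artifact sites per target site
    artifact_sample_frac: float = 0.3  # fraction of samples affected per artifact
    artifact_alt_frac: float = 0.35  # non-reference read fraction when affected

    known_freq_threshold: float = 0.01  # dbSNP-like known-site list cutoff
    site_freqs: Optional[np.ndarray] = None  # override: fixed true frequencies
    seed: int = 0

    @property
    def replicate_pairs(self) -> int:
        if self.n_replicate_pairs is not None:
            return self.n_replicate_pairs
        return max(2, round(80 * self.n_samples / 7842))


@dataclasses.dataclass
class ReadBlock:
    """Flattened per-read arrays for the sequenced markers."""

    site_idx: np.ndarray
    sample_idx: np.ndarray
    base: np.ndarray  # int8 allele index A/C/G/T
    qual: np.ndarray
    depth: np.ndarray  # (n_sites, n_columns)


@dataclasses.dataclass
class TruthSet:
    genotypes: np.ndarray  # (n_seq_sites, n_columns) true alt dosage (0 at artifacts)
    freqs: np.ndarray  # realized alternate frequency per sequenced site
    is_artifact: np.ndarray  # bool per sequenced site
    pairs: list[tuple[int, int]]  # column-index pairs (original, replicate)
    haplotypes: np.ndarray  # (2*n_samples, n_hap_markers) 0/1
    hap_positions: np.ndarray  # positions of haplotype markers (targets + flanks)


@dataclasses.dataclass
class SimulatedCohort:
    cfg: SimConfig
    samples: list[str]  # sequencing columns, replicates included
    sites: pd.DataFrame  # sequenced markers: chrom,pos,ref,alt,is_artifact,true_f
    reads: ReadBlock
    truth: TruthSet
    scaffold_sites: pd.DataFrame  # chip markers: chrom,pos,ref,alt,on_target
    scaffold_gt: np.ndarray  # (n_chip, n_columns) chip dosage with errors, -1 missing
    known_sites: pd.DataFrame  # chrom,pos,ref,alt
    targets: list[tuple[int, int]]  # 1-based inclusive target intervals

    @property
    def refs(self) -> np.ndarray:
        return self.sites["ref"].to_numpy()

    @property
    def positions(self) -> np.ndarray:
        return self.sites["pos"].to_numpy()


def sfs_frequency_draw(n_chromosomes: int, rng: np.random.Generator,
                       alpha: float = 1.0, size: int | None = None):
    """Draw alternate-allele counts with P(count=i) proportional to i**-alpha."""
    if n_chromosomes < 2:
        raise ValueError("need at least 2 chromosomes")
    i = np.arange(1, n_chromosomes)
    p = i.astype(float) ** (-alpha)
    p /= p.sum()
    draw = rng.choice(i, size=size if size is not None else 1, p=p)
    return draw if size is not None else int(draw[0])


def _mutate(ref: np.ndarray, rng: np.random.Generator, ts_bias: float) -> np.ndarray:
    """Alternate alleles: transition with probability ts_bias, else a random
    transversion."""
    n = ref.size
    is_ts = rng.random(n) < ts_bias
    alt = TRANSITION_PARTNER[ref].astype(np.int8)
    # transversion partners: the two bases that are neither ref nor its ts partner
    for b in range(4):
        tv = np.array([x for x in range(4) if x != b and x != TRANSITION_PARTNER[b]], dtype=np.int8)
        sel = (~is_ts) & (ref == b)
        alt[sel] = tv[rng.integers(0, 2, size=int(sel.sum()))]
    return alt


def _unique_positions(rng: np.random.Generator, lo: int, hi: int, n: int,
                      taken: set[int]) -> np.ndarray:
    """n distinct random integer positions in [lo, hi] avoiding ``taken``."""
    out: list[int] = []
    while len(out) < n:
        cand = rng.integers(lo, hi + 1, size=2 * (n - len(out)))
        for p in cand:
            p = int(p)
            if p not in taken:
                taken.add(p)
                out.append(p)
                if len(out) == n:
                    break
    return np.array(sorted(out))


def simulate_haplotypes(cfg: SimConfig, rng: np.random.Generator):
    """Founder-mosaic haplotypes over target sites and flanking markers.

    Returns (hap matrix (2n, M) int8, marker position array, marker table
    with ref/alt/is_flank, target interval list).
    """
    if cfg.n_founders < 2:
        raise ValueError("need at least 2 founder haplotypes")
    n = cfg.n_samples
    n2 = 2 * n
    taken: set[int] = set()
    targets = []
    tpos_all, fpos_all = [], []
    per_gene_t = np.full(cfg.n_targets, cfg.n_target_sites // cfg.n_targets)
    per_gene_t[: cfg.n_target_sites % cfg.n_targets] += 1
    per_gene_f = np.full(cfg.n_targets, cfg.n_flank_markers // cfg.n_targets)
    per_gene_f[: cfg.n_flank_markers % cfg.n_targets] += 1
    for k in range(cfg.n_targets):
        start = cfg.flank_window + 10_000 + k * cfg.target_spacing
        end = start + cfg.target_length - 1
        targets.append((start, end))
        tpos_all.append(_unique_positions(rng, start, end, int(per_gene_t[k]), taken))
        half = int(per_gene_f[k]) // 2
        left = _unique_positions(rng, start - cfg.flank_window, start - 1, half, taken)
        right = _unique_positions(
            rng, end + 1, end + cfg.flank_window, int(per_gene_f[k]) - half, taken
        )
        fpos_all.append(np.concatenate([left, right]))
    tpos = np.concatenate(tpos_all)
    fpos = np.concatenate(fpos_all)
    pos = np.concatenate([tpos, fpos])
    is_flank = np.concatenate([np.zeros(tpos.size, bool), np.ones(fpos.size, bool)])
    order = np.argsort(pos)
    pos, is_flank = pos[order], is_flank[order]
    m = pos.size

    ref = rng.integers(0, 4, size=m).astype(np.int8)
    alt = _mutate(ref, rng, cfg.ts_bias)

    # --- allele counts / founder assignment -------------------------------
    founders = np.zeros((cfg.n_founders, m), dtype=np.int8)
    direct_counts = np.zeros(m, dtype=np.int64)  # rare variants placed directly
    t_order = np.where(~is_flank)[0]
    if cfg.site_freqs is not None:
        freqs = np.broadcast_to(np.asarray(cfg.site_freqs, float), t_order.shape)
        counts = np.clip(np.round(freqs * n2).astype(int), 1, n2 - 1)
        direct_counts[t_order] = counts
    else:
        counts = sfs_frequency_draw(n2, rng, cfg.sfs_alpha, size=t_order.size)
        for j, mm in enumerate(t_order):
            f = counts[j] / n2
            if f >= cfg.common_ld_threshold:
                fc = int(np.clip(round(f * cfg.n_founders), 1, cfg.n_founders - 1))
                founders[rng.choice(cfg.n_founders, fc, replace=False), mm] = 1
            else:
                direct_counts[mm] = counts[j]
    f_order = np.where(is_flank)[0]
    for mm in f_order:
        fc = int(rng.integers(max(1, cfg.n_founders // 10),
                              max(2, (9 * cfg.n_founders) // 10) + 1))
        founders[rng.choice(cfg.n_founders, fc, replace=False), mm] = 1

    # --- founder mosaics --------------------------------------------------
    gap_kb = np.diff(pos) / 1000.0
    p_switch = 1.0 - np.exp(-cfg.switch_rate * gap_kb)
    switch = rng.random((n2, m - 1)) < p_switch[None, :]
    cand = rng.integers(0, cfg.n_founders, size=(n2, m))
    # index of the most recent founder draw per haplotype
    key = np.zeros((n2, m), dtype=np.int64)
    key[:, 1:] = np.where(switch, np.arange(1, m)[None, :], 0)
    key = np.maximum.accumulate(key, axis=1)
    path = np.take_along_axis(cand, key, axis=1)
    hap = founders[path, np.arange(m)[None, :]]

    # --- direct placement of rare variants --------------------------------
    # A rare variant is a single recent mutation: all carrier chromosomes
    # share the founder background at the site (identity by descent), so
    # nearby markers remain informative about carriership.
    for mm in np.where(direct_counts > 0)[0]:
        i = int(direct_counts[mm])
        origin = path[int(rng.integers(0, n2)), mm]
        same = np.where(path[:, mm] == origin)[0]
        if same.size >= i:
            carriers = rng.choice(same, i, replace=False)
        else:
            other = np.setdiff1d(np.arange(n2), same)
            carriers = np.concatenate(
                [same, rng.choice(other, i - same.size, replace=False)]
            )
        hap[carriers, mm] = 1

    table = pd.DataFrame(
        {"chrom": "chr1", "pos": pos, "ref": ref, "alt": alt, "is_flank": is_flank}
    )
    return hap.astype(np.int8), pos, table, targets


def simulate_reads(
    p_alt: np.ndarray, cfg: SimConfig, rng: np.random.Generator,
    refs: np.ndarray, alts: np.ndarray,
) -> ReadBlock:
    """Draw per-cell depths and per-read bases/qualities.

    p_alt : (n_sites, n_columns) probability that a read carries the
        alternate allele before sequencing error (genotype/2 for true
        genotypes, an arbitrary contamination fraction at artifact sites).
    """
    m, s = p_alt.shape
    a = rng.gamma(cfg.sample_gamma_shape, 1.0 / cfg.sample_gamma_shape, size=s)
    b = rng.gamma(cfg.site_gamma_shape, 1.0 / cfg.site_gamma_shape, size=m)
    depth = rng.poisson(cfg.mean_depth * b[:, None] * a[None, :]).astype(np.int32)
    total = int(depth.sum())
    cell = np.repeat(np.arange(m * s, dtype=np.int64), depth.ravel())
    site_idx = (cell // s).astype(np.int32)
    sample_idx = (cell % s).astype(np.int32)
    is_alt = rng.random(total) < np.repeat(p_alt.ravel(), depth.ravel())
    base = np.where(is_alt, alts[site_idx], refs[site_idx]).astype(np.int8)
    qual = rng.choice(
        np.asarray(cfg.qual_values), size=total, p=np.asarray(cfg.qual_probs)
    ).astype(np.int16)
    err = rng.random(total) < 10.0 ** (-qual / 10.0)
    shift = rng.integers(1, 4, size=total).astype(np.int8)
    base = np.where(err, (base + shift) % 4, base).astype(np.int8)
    return ReadBlock(site_idx, sample_idx, base, qual, depth)


def simulate_cohort(cfg: SimConfig) -> SimulatedCohort:
    """Compose haplotypes, reads, scaffold, known sites and truth tracking."""
    rng = np.random.default_rng(cfg.seed)
    n = cfg.n_samples
    hap, hap_pos, hap_table, targets = simulate_haplotypes(cfg, rng)
    geno = hap[0::2] + hap[1::2]  # (n, M_hap) per individual
    geno = geno.T  # (M_hap, n)

    # replicate columns duplicate an individual's truth
    r = cfg.replicate_pairs
    if r > n:
        raise ValueError("more replicate pairs than samples")
    rep_of = np.arange(r)
    samples = [f"S{i:04d}" for i in range(n)] + [f"S{i:04d}r" for i in rep_of]
    col_individual = np.concatenate([np.arange(n), rep_of])
    pairs = [(int(i), int(n + j)) for j, i in enumerate(rep_of)]

    # sequenced markers: on-target sites plus artifact sites
    is_target = ~hap_table["is_flank"].to_numpy()
    t_idx = np.where(is_target)[0]
    taken = set(int(p) for p in hap_pos)
    n_art = int(round(cfg.artifact_rate * cfg.n_target_sites))
    art_pos = []
    for k, (start, end) in enumerate(targets):
        n_here = n_art // len(targets) + (1 if k < n_art % len(targets) else 0)
        art_pos.append(_unique_positions(rng, start, end, n_here, taken))
    art_pos = np.concatenate(art_pos) if n_art else np.array([], dtype=int)
    art_ref = rng.integers(0, 4, size=art_pos.size).astype(np.int8)
    art_alt = _mutate(art_ref, rng, cfg.ts_bias)

    seq_pos = np.concatenate([hap_pos[t_idx], art_pos])
    seq_ref = np.concatenate([hap_table["ref"].to_numpy()[t_idx], art_ref])
    seq_alt = np.concatenate([hap_table["alt"].to_numpy()[t_idx], art_alt])
    seq_art = np.concatenate(
        [np.zeros(t_idx.size, bool), np.ones(art_pos.size, bool)]
    )
    order = np.argsort(seq_pos)
    seq_pos, seq_ref, seq_alt, seq_art = (
        seq_pos[order], seq_ref[order], seq_alt[order], seq_art[order]
    )
    # truth genotypes on sequencing columns (0 at artifact sites)
    g_target = geno[t_idx][:, col_individual]  # (n_target, n_cols)
    g_seq = np.zeros((seq_pos.size, len(samples)), dtype=np.int8)
    g_seq[np.where(~seq_art)[0]] = g_target

    # per-read alternate probability, with artifact contamination
    p_alt = g_seq.astype(float) / 2.0
    art_rows = np.where(seq_art)[0]
    if art_rows.size:
        affected = rng.random((art_rows.size, len(samples))) < cfg.artifact_sample_frac
        p_alt[art_rows] = np.where(affected, cfg.artifact_alt_frac, 0.0)

    reads = simulate_reads(p_alt, cfg, rng, seq_ref.astype(np.int8), seq_alt.astype(np.int8))

    f_target = hap[:, t_idx].mean(axis=0)
    true_f = np.zeros(seq_pos.size)
    true_f[np.where(~seq_art)[0]] = f_target

    sites = pd.DataFrame(
        {
            "chrom": "chr1",
            "pos": seq_pos,
            "ref": seq_ref.astype(np.int8),
            "alt": seq_alt.astype(np.int8),
            "is_artifact": seq_art,
            "true_f": true_f,
        }
    )

    # --- chip scaffold ----------------------------------------------------
    f_hapmarkers = hap.mean(axis=0)
    chip_mask = hap_table["is_flank"].to_numpy() | (
        is_target & (f_hapmarkers >= cfg.chip_freq_threshold)
    )
    chip_idx = np.where(chip_mask)[0]
    chip_truth = geno[chip_idx][:, col_individual].astype(np.int8)
    chip_gt = chip_truth.copy()
    err = rng.random((chip_idx.size, n)) < cfg.chip_error
    if err.any():
        # one perturbation draw per individual, copied to its replicate column
        shift = rng.integers(1, 3, size=(chip_idx.size, n)).astype(np.int8)
        pert = np.where(err, (chip_truth[:, :n] + shift) % 3, chip_truth[:, :n])
        chip_gt[:, :n] = pert
        chip_gt[:, n:] = pert[:, rep_of]
    scaffold_sites = pd.DataFrame(
        {
            "chrom": "chr1",
            "pos": hap_pos[chip_idx],
            "ref": hap_table["ref"].to_numpy()[chip_idx].astype(np.int8),
            "alt": hap_table["alt"].to_numpy()[chip_idx].astype(np.int8),
            "on_target": is_target[chip_idx],
        }
    )

    known_mask = (~seq_art) & (true_f >= cfg.known_freq_threshold)
    known_sites = sites.loc[known_mask, ["chrom", "pos", "ref", "alt"]].reset_index(
        drop=True
    )

    truth = TruthSet(
        genotypes=g_seq,
        freqs=true_f,
        is_artifact=seq_art,
        pairs=pairs,
        haplotypes=hap,
        hap_positions=hap_pos,
    )
    return SimulatedCohort(
        cfg=cfg,
        samples=samples,
        sites=sites,
        reads=reads,
        truth=truth,
        scaffold_sites=scaffold_sites,
        scaffold_gt=chip_gt,
        known_sites=known_sites,
        targets=targets,
    )
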