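"""End-to-end pipelines: call a synthetic cohort with every strategy, run
the QC ladder, and compute the comparison statistics.

These drivers are what the acceptance script, the example scripts and the
qualitative-pattern tests share.  Problem sizes default to desk scale
(hundreds of samples, a few thousand sites) so a full three-caller
comparison runs in about a minute.
"""

from __future__ import annotations

import dataclasses
from typing import Optional

import numpy as np
import pandas as pd

from . import evaluate, qc
from .callset import CallSet
from .ibc import call_ibc
from .ldc import HmmConfig, refine_callset
from .model import ModelParams, loglik_matrix
from .pbc import call_pbc
from .simulate import SimConfig, SimulatedCohort, simulate_cohort
from .vcfio import callset_from_dosage

#: HMM budget used by the desk-scale comparison trials: a reduced panel and
#: iteration count that keeps a full cohort refinement around a minute.
TRIAL_HMM = dict(n_iterations=10, n_reference_haplotypes=20, burn_in=3)


@dataclasses.dataclass
class CohortData:
    """A simulated cohort plus the shared genotype-likelihood arrays."""

    cohort: SimulatedCohort
    loglik: np.ndarray  # (n_sites, n_cols, 10)
    depth: np.ndarray

    @property
    def refs(self) -> np.ndarray:
        return self.cohort.refs

    @property
    def positions(self) -> np.ndarray:
        return self.cohort.positions

    @property
    def read_tuple(self):
        r = self.cohort.reads
        return (r.site_idx, r.sample_idx, r.base, r.qual)


def prepare(cfg: SimConfig, params: ModelParams | None = None) -> CohortData:
    cohort = simulate_cohort(cfg)
    loglik, depth = loglik_matrix(
        cohort.reads.site_idx,
        cohort.reads.sample_idx,
        cohort.reads.base,
        cohort.reads.qual,
        len(cohort.sites),
        len(cohort.samples),
        params,
    )
    return CohortData(cohort, loglik, depth)


def truth_callset(cohort: SimulatedCohort) -> CallSet:
    """Truth genotypes at the true (non-artifact, segregating) sites."""
    mask = (~cohort.truth.is_artifact) & (cohort.truth.freqs > 0)
    idx = np.where(mask)[0]
    sites = cohort.sites.iloc[idx][["chrom", "pos", "ref", "alt"]].reset_index(drop=True)
    return callset_from_dosage(sites, cohort.truth.genotypes[idx], cohort.samples)


def chip_callset(cohort: SimulatedCohort, on_target_only: bool = False) -> CallSet:
    sel = np.arange(len(cohort.scaffold_sites))
    if on_target_only:
        sel = np.where(cohort.scaffold_sites["on_target"].to_numpy())[0]
    sites = cohort.scaffold_sites.iloc[sel][["chrom", "pos", "ref", "alt"]].reset_index(drop=True)
    return callset_from_dosage(sites, cohort.scaffold_gt[sel], cohort.samples, "chip")


def run_callers(
    data: CohortData,
    params: ModelParams | None = None,
    hmm: Optional[dict] = None,
    seed: int = 0,
    with_flank: bool = True,
    with_noflank: bool = False,
) -> dict[str, CallSet]:
    """IBC, PBC and LD-refined call sets for a prepared cohort."""
    cohort = data.cohort
    out: dict[str, CallSet] = {}
    out["ibc"] = call_ibc(
        data.loglik, data.depth, data.refs, data.positions, cohort.samples, params=params
    )
    out["pbc"] = call_pbc(
        data.loglik,
        data.depth,
        data.refs,
        data.positions,
        cohort.samples,
        reads=data.read_tuple,
        params=params,
    )
    hmm = dict(hmm or TRIAL_HMM)
    hmm.setdefault("seed", seed)
    if with_flank:
        out["ldc+f"] = refine_callset(
            out["pbc"],
            cohort.targets,
            scaffold_sites=cohort.scaffold_sites,
            scaffold_gt=cohort.scaffold_gt,
            cfg=HmmConfig(**hmm),
        )
    if with_noflank:
        out["ldc"] = refine_callset(out["pbc"], cohort.targets, cfg=HmmConfig(**hmm))
    return out


def qc_select(
    callset: CallSet,
    data: CohortData,
    k: int,
    seed: int = 0,
    apply_filters: bool = True,
) -> CallSet:
    """R-hat-squared filter (LD sets), rank, select top-K, genotype-filter."""
    cohort = data.cohort
    cs = callset
    if cs.caller.startswith("ldc"):
        cs = cs.take_sites(qc.rsq_filter(cs))
    # map call-set rows onto cohort site rows for the allele-balance feature
    pos_to_row = {int(p): i for i, p in enumerate(cohort.positions)}
    site_map = np.array([pos_to_row.get(int(p), -1) for p in cs.sites["pos"]])
    known = site_map >= 0
    feats = qc.compute_site_features(cs, cohort.reads, np.where(known, site_map, 0))
    is_art = np.zeros(len(cs.sites), dtype=bool)
    is_true = np.zeros(len(cs.sites), dtype=bool)
    art = cohort.truth.is_artifact
    tf = cohort.truth.freqs
    for i, r in enumerate(site_map):
        if r >= 0:
            is_art[i] = art[r]
            is_true[i] = (not art[r]) and tf[r] > 0
    good = np.where(is_true)[0]
    bad = np.where(is_art)[0]
    if good.size and bad.size:
        scores = qc.rank_sites(feats, good, bad, seed=seed)
        sel, _trunc = qc.select_top_k(scores, min(k, len(scores)), cs.sites["pos"].to_numpy())
        cs = cs.take_sites(sel)
    if apply_filters:
        cs, _ = qc.apply_genotype_filters(cs)
    return cs


# ---------------------------------------------------------------------------
# the qualitative comparison trial
# ---------------------------------------------------------------------------

def run_trial(
    seed: int,
    sim: Optional[SimConfig] = None,
    hmm: Optional[dict] = None,
    select_k: int = 1400,
    downsample_sizes=(25, 50, 100, 200),
    downsample_reps: int = 2,
    with_noflank: bool = False,
) -> dict:
    """One full comparison on a synthetic cohort; returns summary statistics.

    The returned dict carries per-caller missingness, truth heterozygote
    mismatch at common sites, low-coverage singleton calling counts, the
    PBC recovery curve of IBC singletons across nested sub-cohorts, Ts/Tv
    and singleton fractions of the selected call sets.
    """
    sim = sim or SimConfig(seed=seed)
    if sim.seed != seed:
        sim = dataclasses.replace(sim, seed=seed)
    params = ModelParams()
    data = prepare(sim, params)
    cohort = data.cohort
    raw = run_callers(data, params, hmm, seed=seed, with_noflank=with_noflank)
    selected = {
        name: qc_select(cs, data, select_k, seed=seed) for name, cs in raw.items()
    }
    truth = truth_callset(cohort)
    res: dict = {"seed": seed}

    for name, cs in selected.items():
        key = name.replace("+", "")
        res[f"missing_{key}"] = cs.missingness()
        res[f"n_sites_{key}"] = cs.n_sites
        t = evaluate.tstv(cs.sites)
        res[f"tstv_{key}"] = t.ratio
        singl = cs.is_singleton()
        res[f"singleton_frac_{key}"] = float(singl.mean()) if cs.n_sites else 0.0
        res[f"known_overlap_{key}"] = evaluate.site_list_overlap(cs, cohort.known_sites)

    # truth h_e at common sites shared by all selected sets
    common_pos = None
    for cs in selected.values():
        here = set(int(p) for p in cs.sites["pos"])
        common_pos = here if common_pos is None else (common_pos & here)
    tf_by_pos = dict(zip(cohort.positions.astype(int), cohort.truth.freqs))
    common_pos = {p for p in common_pos if tf_by_pos.get(p, 0.0) >= 0.05}
    for name, cs in selected.items():
        key = name.replace("+", "")
        idx = [i for i, p in enumerate(cs.sites["pos"].astype(int)) if p in common_pos]
        if idx:
            rep = evaluate.het_mismatch(cs.take_sites(idx), truth)
            res[f"he_truth_{key}"] = rep.h_e
            res[f"n_common_{key}"] = len(idx)
        else:
            res[f"he_truth_{key}"] = float("nan")
            res[f"n_common_{key}"] = 0

    # replicate-pair h_e on the joint call sets
    pair_names = [
        (cohort.samples[i], cohort.samples[j]) for i, j in cohort.truth.pairs
    ]
    for name, cs in selected.items():
        key = name.replace("+", "")
        try:
            res[f"he_rep_{key}"] = evaluate.replicate_concordance(cs, cs, pair_names).h_e
        except ValueError:
            res[f"he_rep_{key}"] = float("nan")

    # audit of heterozygotes the refiners add over the single-marker caller
    if "ldc" in selected:
        for name in ("ldc", "ldc+f"):
            n_extra, he = evaluate.additional_het_audit(
                selected["pbc"], selected[name], truth
            )
            key = name.replace("+", "")
            res[f"extra_hets_{key}"] = n_extra
            res[f"he_extra_hets_{key}"] = he

    # low-coverage true-singleton calling (gq filter only, per-caller)
    res.update(_lowdepth_singletons(data, raw, selected))

    # PBC recovery of IBC singletons across nested sub-cohort sizes
    ibc_sel = selected["ibc"]
    singl = ibc_sel.is_singleton()
    pos_to_row = {int(p): i for i, p in enumerate(cohort.positions)}
    sites, carriers = [], []
    for i in np.where(singl)[0]:
        row = pos_to_row.get(int(ibc_sel.sites["pos"].iloc[i]), -1)
        if row < 0:
            continue
        c = np.where(ibc_sel.is_het[i])[0]
        if c.size != 1:
            continue
        sites.append(row)
        carriers.append(int(c[0]))
    downsample_sizes = [s for s in downsample_sizes if s <= sim.n_samples]
    if sites and downsample_sizes:
        ds = evaluate.downsampling_experiment(
            data.loglik,
            data.depth,
            data.refs,
            data.positions,
            cohort.samples,
            np.array(sites),
            np.array(carriers),
            downsample_sizes,
            n_reps=downsample_reps,
            seed=seed,
            params=params,
            reads=data.read_tuple,
        )
        res["recovery_sizes"] = list(downsample_sizes)
        res["recovery"] = ds.mean_recovery().tolist()
        res["recovery_qual"] = ds.mean_qual.mean(axis=0).tolist()
    return res


def _lowdepth_singletons(data: CohortData, raw, selected) -> dict:
    """Count true singletons with carrier depth < 10x called het by each
    caller (genotype-quality filter only, no depth filter)."""
    cohort = data.cohort
    n_ind = cohort.cfg.n_samples
    g = cohort.truth.genotypes[:, :n_ind]
    alt_count = g.sum(axis=1)
    het_count = (g == 1).sum(axis=1)
    true_singleton = (~cohort.truth.is_artifact) & (alt_count == 1) & (het_count == 1)
    rows = np.where(true_singleton)[0]
    carriers = np.argmax(cohort.truth.genotypes[rows, :n_ind] == 1, axis=1)
    lowdepth = data.depth[rows, carriers] < 10
    rows, carriers = rows[lowdepth], carriers[lowdepth]
    out = {"n_true_lowdepth_singletons": int(rows.size)}
    for name in ("ibc", "pbc"):
        cs = raw[name]  # pre-filter calls; the quality rule is applied below
        pos_of = {int(p): i for i, p in enumerate(cs.sites["pos"].astype(int))}
        n_called = 0
        for row, c in zip(rows, carriers):
            i = pos_of.get(int(cohort.positions[row]))
            if i is None:
                continue
            # gq>=20 corresponds to the 99% posterior rule; no depth filter
            a1 = cs.a1[i, c]
            if a1 >= 0 and cs.a1[i, c] != cs.a2[i, c] and cs.gq[i, c] >= 20:
                n_called += 1
        out[f"n_lowdepth_singletons_{name}"] = n_called
    return out
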