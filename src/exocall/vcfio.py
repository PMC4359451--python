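"""VCF v4.2 serialization of call sets (via pysam).

Per-genotype FORMAT fields are GT/GQ/DP and, for LD-refined sets, DS
(alternate-allele dosage).  INFO carries AF (per alternate), NS and, for
LD-refined sets, R2.  Missing genotypes round-trip as ``./.``; multi-allelic
ALT lists are preserved.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import pysam

from .callset import CallSet
from .model import BASES, BASE_INDEX

MISSING = -1


def _header(samples: list[str], chroms: list[str]) -> pysam.VariantHeader:
    h = pysam.VariantHeader()
    for c in chroms:
        h.contigs.add(c, length=2_000_000_000)
    h.info.add("AF", "A", "Float", "Alternate allele frequency")
    h.info.add("NS", 1, "Integer", "Number of samples with called genotypes")
    h.info.add("R2", 1, "Float", "Estimated imputation quality R-hat-squared")
    h.info.add("CALLER", 1, "String", "Calling strategy that produced the record")
    h.formats.add("GT", 1, "String", "Genotype")
    h.formats.add("GQ", 1, "Integer", "PHRED genotype quality")
    h.formats.add("DP", 1, "Integer", "Read depth")
    h.formats.add("DS", 1, "Float", "Alternate allele dosage")
    for s in samples:
        h.add_sample(s)
    return h


def write_vcf(callset: CallSet, path: str) -> None:
    chroms = list(dict.fromkeys(callset.sites["chrom"])) or ["chr1"]
    header = _header(callset.samples, chroms)
    with pysam.VariantFile(path, "w", header=header) as vf:
        for m in range(callset.n_sites):
            row = callset.sites.iloc[m]
            rec = vf.new_record()
            rec.chrom = str(row["chrom"])
            rec.pos = int(row["pos"])
            rec.ref = BASES[int(row["ref"])]
            alts = tuple(BASES[int(a)] for a in row["alts"]) or ("N",)
            rec.alts = alts
            rec.qual = float(row["qual"])
            called = callset.a1[m] >= 0
            an = 2 * int(called.sum())
            afs = []
            for j in range(1, len(alts) + 1):
                ac = int(((callset.a1[m] == j) & called).sum()) + int(
                    ((callset.a2[m] == j) & called).sum()
                )
                afs.append(ac / an if an else 0.0)
            rec.info["AF"] = tuple(afs)
            rec.info["NS"] = int(called.sum())
            rec.info["CALLER"] = callset.caller
            if "rsq" in callset.sites.columns:
                rec.info["R2"] = round(float(row["rsq"]), 4)
            for s, name in enumerate(callset.samples):
                smp = rec.samples[name]
                if callset.a1[m, s] < 0:
                    smp["GT"] = (None, None)
                else:
                    smp["GT"] = (int(callset.a1[m, s]), int(callset.a2[m, s]))
                smp["GQ"] = int(round(min(float(callset.gq[m, s]), 99.0)))
                smp["DP"] = int(callset.dp[m, s])
                if callset.dosage is not None:
                    smp["DS"] = round(float(callset.dosage[m, s]), 4)
            vf.write(rec)


def read_vcf(path: str, caller: str | None = None) -> CallSet:
    rows = []
    a1_rows, a2_rows, gq_rows, dp_rows, ds_rows = [], [], [], [], []
    has_ds = False
    with pysam.VariantFile(path) as vf:
        samples = list(vf.header.samples)
        for rec in vf:
            alts = tuple(BASE_INDEX[a] for a in (rec.alts or ()) if a in BASE_INDEX)
            row = {
                "chrom": rec.chrom,
                "pos": rec.pos,
                "ref": BASE_INDEX[rec.ref],
                "alts": alts,
                "qual": float(rec.qual if rec.qual is not None else 0.0),
            }
            if "R2" in rec.info:
                row["rsq"] = float(rec.info["R2"])
            if caller is None and "CALLER" in rec.info:
                caller = str(rec.info["CALLER"])
            rows.append(row)
            a1r, a2r, gqr, dpr, dsr = [], [], [], [], []
            for name in samples:
                smp = rec.samples[name]
                gt = smp.get("GT")
                if gt is None or gt[0] is None:
                    a1r.append(MISSING)
                    a2r.append(MISSING)
                else:
                    a1r.append(int(gt[0]))
                    a2r.append(int(gt[1]))
                gqr.append(int(smp.get("GQ") or 0))
                dpr.append(int(smp.get("DP") or 0))
                ds = smp.get("DS")
                if ds is not None:
                    has_ds = True
                    dsr.append(float(ds))
                else:
                    dsr.append(0.0)
            a1_rows.append(a1r)
            a2_rows.append(a2r)
            gq_rows.append(gqr)
            dp_rows.append(dpr)
            ds_rows.append(dsr)
    n = len(rows)
    sites = pd.DataFrame(rows) if rows else pd.DataFrame(
        columns=["chrom", "pos", "ref", "alts", "qual"]
    )
    shape = (n, len(samples))
    return CallSet(
        caller=caller or "unknown",
        samples=samples,
        sites=sites,
        a1=np.array(a1_rows, dtype=np.int8).reshape(shape),
        a2=np.array(a2_rows, dtype=np.int8).reshape(shape),
        gq=np.array(gq_rows, dtype=float).reshape(shape),
        dp=np.array(dp_rows, dtype=np.int32).reshape(shape),
        dosage=np.array(ds_rows, dtype=float).reshape(shape) if has_ds else None,
    )


def write_genotype_vcf(
    sites: pd.DataFrame, gt: np.ndarray, samples: list[str], path: str,
    caller: str = "truth",
) -> None:
    """Write a plain dosage-coded genotype matrix (truth or chip) as VCF.

    ``sites`` needs chrom/pos/ref/alt columns; ``gt`` holds alternate-allele
    dosages 0/1/2 with -1 for missing.
    """
    cs = callset_from_dosage(sites, gt, samples, caller)
    write_vcf(cs, path)


def callset_from_dosage(
    sites: pd.DataFrame, gt: np.ndarray, samples: list[str], caller: str = "truth"
) -> CallSet:
    """Wrap a dosage matrix (0/1/2, -1 missing) as a CallSet."""
    n = len(sites)
    tab = pd.DataFrame(
        {
            "chrom": sites["chrom"].to_numpy(),
            "pos": sites["pos"].to_numpy(),
            "ref": sites["ref"].to_numpy(),
            "alts": [(int(a),) for a in sites["alt"]],
            "qual": np.zeros(n),
        }
    )
    a1 = np.where(gt >= 0, (gt >= 1).astype(np.int8), MISSING).astype(np.int8)
    a2 = np.where(gt >= 0, (gt == 2).astype(np.int8), MISSING).astype(np.int8)
    return CallSet(
        caller=caller,
        samples=list(samples),
        sites=tab,
        a1=a1,
        a2=a2,
        gq=np.full(gt.shape, 99.0),
        dp=np.zeros(gt.shape, dtype=np.int32),
    )
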