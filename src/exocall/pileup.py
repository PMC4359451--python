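"""Reader/writer for a samtools-mpileup-style text dialect.

One line per reference position: ``chrom  pos  ref`` followed by three
columns per sample (depth, base string, quality string).  Supported base
tokens: ``.``/``,`` for a reference match, ``ACGTacgt`` for a mismatch,
``^X`` read-start (the mapping-quality character is stripped), ``$`` read
end, ``*``/``N`` placeholders (their quality character is consumed and the
read dropped), and ``+N<seq>``/``-N<seq>`` indel tokens which are skipped
and counted.  Qualities are ASCII PHRED+33.  Zero-depth samples are written
``0 * *``.

All positions are 1-based.  Target intervals travel separately as BED
(0-based half-open) and are converted at the boundary.
"""

from __future__ import annotations

import re
from typing import Iterator

import numpy as np

from .model import BASE_INDEX, BASES, PileupColumn, SampleObservations
from .simulate import SimulatedCohort

_INDEL = re.compile(r"[+-](\d+)")


def write_pileup(cohort: SimulatedCohort, path: str) -> None:
    """Serialize a simulated cohort's reads to the pileup dialect."""
    reads = cohort.reads
    n_sites, n_cols = reads.depth.shape
    refs = cohort.refs
    positions = cohort.positions
    order = np.lexsort((reads.sample_idx, reads.site_idx))
    site_sorted = reads.site_idx[order]
    samp_sorted = reads.sample_idx[order]
    base_sorted = reads.base[order]
    qual_sorted = reads.qual[order]
    starts = np.searchsorted(site_sorted, np.arange(n_sites + 1))
    with open(path, "w") as fh:
        fh.write("##exocall-pileup\n")
        fh.write("#samples\t" + "\t".join(cohort.samples) + "\n")
        for m in range(n_sites):
            lo, hi = starts[m], starts[m + 1]
            srow = samp_sorted[lo:hi]
            brow = base_sorted[lo:hi]
            qrow = qual_sorted[lo:hi]
            cuts = np.searchsorted(srow, np.arange(n_cols + 1))
            cols = [cohort.sites["chrom"].iloc[m], str(int(positions[m])), BASES[int(refs[m])]]
            ref = int(refs[m])
            for s in range(n_cols):
                a, b = cuts[s], cuts[s + 1]
                if a == b:
                    cols += ["0", "*", "*"]
                    continue
                bases = "".join(
                    "." if int(x) == ref else BASES[int(x)] for x in brow[a:b]
                )
                quals = "".join(chr(int(q) + 33) for q in qrow[a:b])
                cols += [str(b - a), bases, quals]
            fh.write("\t".join(cols) + "\n")


def _parse_bases(token: str, ref: int, line_no: int) -> tuple[list[int], list[bool]]:
    """Expand a base-column token into allele indices.

    Returns (allele index per qual-consuming symbol, keep flag per symbol);
    dropped symbols (* and N placeholders) still consume a quality char.
    """
    out: list[int] = []
    keep: list[bool] = []
    i = 0
    n = len(token)
    while i < n:
        c = token[i]
        if c == "^":
            i += 2  # skip the mapping-quality character
            continue
        if c == "$":
            i += 1
            continue
        if c in "+-":
            m = _INDEL.match(token, i)
            if not m:
                raise ValueError(f"malformed indel token at line {line_no}")
            i = m.end() + int(m.group(1))
            continue
        if c in ".,":
            out.append(ref)
            keep.append(True)
        elif c.upper() in BASE_INDEX:
            out.append(BASE_INDEX[c.upper()])
            keep.append(True)
        elif c in "*Nn><":
            out.append(0)
            keep.append(False)
        else:
            raise ValueError(f"unsupported pileup symbol {c!r} at line {line_no}")
        i += 1
    return out, keep


def read_pileup(path: str) -> Iterator[PileupColumn]:
    """Stream PileupColumns from the dialect written by :func:`write_pileup`.

    The sample roster comes from the ``#samples`` header line.
    """
    samples: list[str] | None = None
    with open(path) as fh:
        for line_no, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("##"):
                continue
            if line.startswith("#samples"):
                samples = line.split("\t")[1:]
                continue
            fields = line.split("\t")
            if samples is None:
                n_cols = (len(fields) - 3) // 3
                samples = [f"S{i:04d}" for i in range(n_cols)]
            if len(fields) != 3 + 3 * len(samples):
                raise ValueError(f"malformed pileup column at line {line_no}")
            chrom, pos, refbase = fields[0], int(fields[1]), fields[2]
            ref = BASE_INDEX[refbase.upper()]
            obs: dict[str, SampleObservations] = {}
            for s, name in enumerate(samples):
                depth = int(fields[3 + 3 * s])
                btok = fields[4 + 3 * s]
                qtok = fields[5 + 3 * s]
                if depth == 0:
                    obs[name] = SampleObservations(
                        np.zeros(0, np.int8), np.zeros(0, int)
                    )
                    continue
                alleles, keep = _parse_bases(btok, ref, line_no)
                if len(alleles) != len(qtok):
                    raise ValueError(
                        f"base/quality length mismatch at line {line_no}, sample {name}"
                    )
                quals = np.array([ord(c) - 33 for c in qtok])
                mask = np.array(keep, dtype=bool)
                obs[name] = SampleObservations(
                    np.array(alleles, np.int8)[mask], quals[mask]
                )
            yield PileupColumn(chrom, pos, ref, obs)


def read_pileup_arrays(path: str):
    """Load a pileup file into the flattened cohort arrays.

    Returns (samples, positions, refs, (site_idx, sample_idx, base, qual),
    depth matrix).
    """
    samples: list[str] = []
    positions, refs = [], []
    si, pi, bi, qi = [], [], [], []
    depths = []
    for m, col in enumerate(read_pileup(path)):
        if not samples:
            samples = list(col.obs.keys())
        positions.append(col.pos)
        refs.append(col.ref)
        drow = []
        for s, name in enumerate(samples):
            o = col.obs[name]
            drow.append(o.depth)
            si.extend([m] * o.depth)
            pi.extend([s] * o.depth)
            bi.extend(o.bases.tolist())
            qi.extend(o.quals.tolist())
        depths.append(drow)
    return (
        samples,
        np.array(positions, dtype=np.int64),
        np.array(refs, dtype=np.int8),
        (
            np.array(si, dtype=np.int32),
            np.array(pi, dtype=np.int32),
            np.array(bi, dtype=np.int8),
            np.array(qi, dtype=np.int16),
        ),
        np.array(depths, dtype=np.int32),
    )


def read_bed(path: str) -> list[tuple[int, int]]:
    """BED intervals (0-based half-open) -> 1-based inclusive tuples."""
    out = []
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith(("#", "track")):
                continue
            f = line.split()
            out.append((int(f[1]) + 1, int(f[2])))
    return out


def write_bed(targets: list[tuple[int, int]], path: str, chrom: str = "chr1") -> None:
    with open(path, "w") as fh:
        for start, end in targets:
            fh.write(f"{chrom}\t{start - 1}\t{end}\n")
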