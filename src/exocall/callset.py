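"""The CallSet container: sites x samples genotype matrix with metadata.

Genotypes are stored as two allele-index arrays ``a1``/``a2`` (indices into
the per-site allele list, 0 = reference, 1 = first alternate, ...; -1 marks a
missing genotype).  Per-genotype quality (GQ) and depth (DP) ride along, and
callers attach what they additionally know: the population frequency and
biallelic likelihood triplets for the population-based caller, averaged
posterior triplets / dosages / R-hat-squared for the LD refiner.
"""

from __future__ import annotations

import dataclasses
from typing import Optional

import numpy as np
import pandas as pd

from .model import BASES


@dataclasses.dataclass
class CallSet:
    caller: str
    samples: list[str]
    sites: pd.DataFrame
    """Per-site table with columns chrom, pos, ref, alts (tuple of allele
    index ints), qual; callers may add f_hat, rsq."""
    a1: np.ndarray  # (n_sites, n_samples) int8, -1 missing
    a2: np.ndarray
    gq: np.ndarray  # (n_sites, n_samples) float
    dp: np.ndarray  # (n_sites, n_samples) int
    gl3: Optional[np.ndarray] = None  # (n_sites, n_samples, 3) linear scale
    post3: Optional[np.ndarray] = None  # averaged posterior triplets (LDC)
    dosage: Optional[np.ndarray] = None  # (n_sites, n_samples) expected alt count
    posterior_ratio: Optional[np.ndarray] = None  # best:second posterior ratio

    def __post_init__(self) -> None:
        n_sites, n_samples = self.a1.shape
        if len(self.sites) != n_sites or len(self.samples) != n_samples:
            raise ValueError("shape mismatch between sites/samples and genotypes")
        if self.a2.shape != self.a1.shape:
            raise ValueError("a1/a2 shape mismatch")

    # ------------------------------------------------------------------
    @property
    def n_sites(self) -> int:
        return self.a1.shape[0]

    @property
    def n_samples(self) -> int:
        return self.a1.shape[1]

    @property
    def missing(self) -> np.ndarray:
        return self.a1 < 0

    @property
    def is_het(self) -> np.ndarray:
        """Boolean matrix: called and heterozygous."""
        return (self.a1 >= 0) & (self.a1 != self.a2)

    @property
    def alt_dosage(self) -> np.ndarray:
        """Called non-reference allele count per cell (any alternate); -1 missing."""
        d = (self.a1 > 0).astype(np.int8) + (self.a2 > 0).astype(np.int8)
        return np.where(self.a1 < 0, -1, d)

    def site_key(self) -> pd.Index:
        return pd.MultiIndex.from_arrays(
            [self.sites["chrom"], self.sites["pos"]], names=["chrom", "pos"]
        )

    # ------------------------------------------------------------------
    def allele_counts(self) -> tuple[np.ndarray, np.ndarray]:
        """(non-missing chromosome count, alternate allele count) per site.

        The alternate count sums every non-reference allele across the two
        called alleles, so multi-allelic sites report total non-ref alleles.
        """
        called = self.a1 >= 0
        an = 2 * called.sum(axis=1)
        ac = np.where(called, (self.a1 > 0).astype(int) + (self.a2 > 0).astype(int), 0).sum(axis=1)
        return an, ac

    def minor_allele_count(self) -> np.ndarray:
        an, ac = self.allele_counts()
        return np.minimum(ac, an - ac)

    def is_singleton(self) -> np.ndarray:
        return self.minor_allele_count() == 1

    def missingness(self) -> float:
        """Fraction of missing genotype cells."""
        if self.a1.size == 0:
            return 0.0
        return float(self.missing.mean())

    # ------------------------------------------------------------------
    def take_sites(self, idx) -> "CallSet":
        idx = np.asarray(idx)
        return dataclasses.replace(
            self,
            sites=self.sites.iloc[idx].reset_index(drop=True),
            a1=self.a1[idx],
            a2=self.a2[idx],
            gq=self.gq[idx],
            dp=self.dp[idx],
            gl3=None if self.gl3 is None else self.gl3[idx],
            post3=None if self.post3 is None else self.post3[idx],
            dosage=None if self.dosage is None else self.dosage[idx],
            posterior_ratio=None
            if self.posterior_ratio is None
            else self.posterior_ratio[idx],
        )

    def take_samples(self, idx) -> "CallSet":
        idx = np.asarray(idx)
        return dataclasses.replace(
            self,
            samples=[self.samples[i] for i in idx],
            a1=self.a1[:, idx],
            a2=self.a2[:, idx],
            gq=self.gq[:, idx],
            dp=self.dp[:, idx],
            gl3=None if self.gl3 is None else self.gl3[:, idx],
            post3=None if self.post3 is None else self.post3[:, idx],
            dosage=None if self.dosage is None else self.dosage[:, idx],
            posterior_ratio=None
            if self.posterior_ratio is None
            else self.posterior_ratio[:, idx],
        )

    def copy(self) -> "CallSet":
        return dataclasses.replace(
            self,
            sites=self.sites.copy(),
            a1=self.a1.copy(),
            a2=self.a2.copy(),
            gq=self.gq.copy(),
            dp=self.dp.copy(),
        )


def allele_name(site_row, allele_index: int) -> str:
    """Human-readable base for an allele index of a site row."""
    if allele_index == 0:
        return BASES[int(site_row.ref)]
    return BASES[int(site_row.alts[allele_index - 1])]
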