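"""Simulate a small targeted-sequencing cohort and call variants two ways.

Builds a 100-sample cohort with heterogeneous 24x capture coverage, runs the
individual-based caller (per-sample Bayesian genotypes, 99% posterior
threshold) and the population-based caller (Watterson polymorphism prior +
HWE allele-frequency estimation), and prints what each finds.
"""

import numpy as np

from exocall.evaluate import tstv
from exocall.experiments import prepare, run_callers
from exocall.simulate import SimConfig

data = prepare(SimConfig(n_samples=100, n_target_sites=500, seed=42))
callers = run_callers(data, with_flank=False, seed=42)

truth_variants = int(((~data.cohort.truth.is_artifact)
                      & (data.cohort.truth.freqs > 0)).sum())
print(f"cohort: 100 samples, {len(data.cohort.sites)} sequenced sites "
      f"({truth_variants} true variants), mean depth "
      f"{data.depth.mean():.1f}x (range {data.depth.min()}-{data.depth.max()}x)")

for name, cs in callers.items():
    singl = cs.is_singleton().mean()
    print(f"{name.upper():4s}: {cs.n_sites} variant sites, "
          f"{100 * singl:.1f}% singletons, Ts/Tv {tstv(cs.sites).ratio:.2f}")

print("Singleton fractions near 60% reflect the rare-skewed site-frequency "
      "spectrum; Ts/Tv near 2 reflects the 2:1 transition bias of true "
      "variants, diluted by false calls. Genotype-level quality differences "
      "between the callers appear after the per-genotype filters "
      "(see example 02 and the QC ladder).")
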