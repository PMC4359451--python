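"""Down-sampling: how population-based singleton recovery depends on n.

Reference singletons come from a full-cohort individual-based call; the
population-based caller is then re-run on nested random sub-cohorts, and we
measure the fraction of those singletons it recovers (carrier present, site
emitted, carrier het called).
"""

import numpy as np

from exocall.evaluate import downsampling_experiment
from exocall.experiments import prepare, run_callers
from exocall.simulate import SimConfig

data = prepare(SimConfig(n_samples=200, n_target_sites=600, seed=5))
ibc = run_callers(data, with_flank=False, seed=5)["ibc"]

singl = ibc.is_singleton()
pos_to_row = {int(p): i for i, p in enumerate(data.positions)}
sites, carriers = [], []
for i in np.where(singl)[0]:
    c = np.where(ibc.is_het[i])[0]
    if c.size == 1:
        sites.append(pos_to_row[int(ibc.sites["pos"].iloc[i])])
        carriers.append(int(c[0]))
print(f"reference set: {len(sites)} IBC singletons from the full cohort")

res = downsampling_experiment(
    data.loglik, data.depth, data.refs, data.positions, data.cohort.samples,
    np.array(sites), np.array(carriers), sizes=[25, 50, 100, 200],
    n_reps=5, seed=5, reads=data.read_tuple,
)
print("size   recovered%   mean site qual")
for k, size in enumerate(res.sizes):
    print(f"{size:4d}   {100 * res.recovered_called[:, k].mean():8.1f}   "
          f"{res.mean_qual[:, k].mean():10.1f}")
print("Recovery does not increase with sample size: in bigger cohorts the "
      "singleton's frequency prior weakens, so borderline-evidence carriers "
      "stop reaching the 99% genotype threshold.")
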