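"""Positional arrangement of pore-lining protomers around the hexameric ring.

Under independence, a ring arrangement (necklace class) with k pore-lining
protomers and orbit size m has probability m p^k (1-p)^(6-k). This example
counts arrangements in coupled and uncoupled synthetic data, runs the
goodness-of-fit test and the adjacency permutation test.
"""

import gjctools as gj
import numpy as np

for J in (0.0, 0.8):
    table, _ = gj.simulate_metadata(
        gj.MetadataSimConfig(n_particles=5000, p_pln=0.57, coupling_J=J, seed=7)
    )
    comps, _ = gj.group_by_particle(table)
    classes, p_used = gj.arrangement_distribution(comps)

    print(f"\n=== nearest-neighbour coupling J = {J} (p_hat = {p_used:.3f}) ===")
    print(" ring      k  orbit  observed  expected")
    for a in classes:
        print(f" {a.canonical}  {a.k_pln}   {a.orbit_size}    "
              f"{a.observed:6d}   {a.expected:8.1f}")

    obs = np.array([a.observed for a in classes], dtype=float)
    exp = np.array([a.expected for a in classes], dtype=float)
    res = gj.independence_test(obs, exp, p_estimated=True)
    print(f"independence test: stat={res.statistic:.1f}, df={res.df}, "
          f"p={res.p_value:.2g}  ({res.pooled_bins})")

    stat, p_perm = gj.adjacency_coupling_stat(comps, n_perm=2000, seed=1)
    print(f"mean adjacent same-state pairs: {stat:.3f}, "
          f"permutation p={p_perm:.3g}")
    print("p << 0.05 flags positional clustering of like states beyond "
          "what ring compositions alone produce."
          if p_perm < 0.05 else
          "No evidence of neighbour coupling: arrangements look random.")
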