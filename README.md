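# gjctools

Statistical analysis tools for gap-junction channel (GJC) structure and
permeation. A GJC is a dodecamer: two hexameric connexin hemichannels docked
end to end, and each of the 12 protomers can hold its N-terminal helix either
inside the pore (pore-lining, **PLN** — open) or out of it (flexible, **FN**
— occluded). `gjctools` answers three questions that come up when such
channels are studied by cryo-EM and simulation:

1. **How are protomer conformations distributed over particles?** Starting
   from symmetry-expanded, subunit-classified particle metadata (RELION-3.1
   STAR tables), the package traces every expanded copy back to its parent
   particle, counts the 13 possible FN:PLN compositions (0:12 … 12:0), and
   tests them against the random-placement null: if protomers switch
   independently with probability *p* of being pore-lining, compositions are
   Binomial(12, *p*) and a hexameric ring arrangement (a binary necklace
   class with *k* pore-lining sites and rotational orbit size *m*) has
   probability *m·pᵏ(1−p)⁶⁻ᵏ*. Departures indicate neighbour coupling,
   which a ring-Ising simulator and permutation test quantify.
2. **What current does the open pore carry?** From per-frame ion
   coordinates, crossing events through a two-plane gate give the current
   *I = q·e·n_net/T*, the conductance *g = I/V* (1 nA / 1 mV = 10⁶ pS), and a
   viscosity-corrected *g/3* accounting for the ~3× too-fast diffusion of
   standard simulation water. Axial concentration profiles and 3D
   density–flux maps localise where ions accumulate and flow.
3. **What fits through the pore?** An inscribed-sphere (HOLE-style) profiler
   reports the pore radius along the axis of a PDB/mmCIF model and the
   solvent-accessible diameter at the constriction.

Every analysis has a synthetic generator with exact ground truth
(`gjctools.simulate`): ring-Ising classification metadata, overdamped
drift–diffusion ion trajectories with a constant-field Nernst–Planck
closed-form current, and toy pore structures with known geometry.

## Worked example

```python
import gjctools as gj

# 5,000 dodecamers, protomers independently pore-lining with p = 0.57
table, _ = gj.simulate_metadata(gj.MetadataSimConfig(n_particles=5000, p_pln=0.57, seed=42))
table = gj.assign_states(table, gj.ClassStateMap.default_protomer_map())
est = gj.estimate_state_fraction(table)
comps, report = gj.group_by_particle(table)
dist = gj.composition_distribution(comps)
expected = gj.binomial_expectation(est.p_hat, 12, dist.n_particles)
res = gj.independence_test(dist.counts, expected, p_estimated=True)
print(est.p_hat, res.p_value)

# conductance arithmetic from a measured current
print(gj.conductance(0.007, 200.0).g_pS)          # 35.0 pS at 200 mV
print(gj.conductance(0.007, 200.0).g_corrected_pS) # 11.67 pS after /3
```

Running `examples/composition_analysis.py` prints the full composition
table; the run above gives a pore-lining fraction of 0.569 (Wilson 95% CI
0.566–0.573), a 13-bin histogram matching the binomial prediction
(χ² = 2.84, df = 10, p = 0.985 — no evidence against independent switching),
and 3 hetero-junctional particles (an all-PLN ring docked onto an all-FN
ring, the configuration expected ~0.06% of the time at this *p*).
`examples/ring_arrangements.py`, `examples/ion_current.py` and
`examples/pore_profiling.py` walk through the other capabilities; on the toy
two-ring channel the profiler reports a constriction diameter of 8.60 Å,
exactly 2·(6.0 − 1.7) Å.

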