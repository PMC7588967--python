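# ksbind

Analysis tools for studying how type II polyketide synthase ketoreductases
(KRs) recognise their poly-β-ketone substrates, built around four pieces of
post-processing that MD and docking studies of these enzymes need:

1. **A framewise native-contact stability score (SS).** The native pair set is
   every receptor–ligand heavy-atom pair within 7 Å in the initial frame of a
   trajectory. For frame *t*,

   SS(*t*) = |{native pairs with *d* ≤ 7 Å at *t*}| / |native pairs|,

   so SS of the initial frame is always 1, SS ≈ 1 means the ligand holds its
   starting pose, and SS ≈ 0 means it has left the binding site. Ligand exit
   is detected as the first sustained window of SS below a threshold.
2. **Binding-patch classification of docking poses.** KRs present two
   entrances to the substrate channel — a front patch of arginines
   (R38/R65/R93 in ActKR numbering) that grips the phosphate of the
   phosphopantetheine arm, and a back patch (Q149/R220/N260). Poses are
   assigned front / back / other by the distance from a reference point
   (the phosphorus atom when present, else the heavy-atom centroid) to each
   patch centroid, and tabulated as one-decimal percentages.
3. **MM-PBSA decomposition and framewise correlation.** Per-frame tables of
   VDWAALS / EEL / EPB / ENPOLAR terms are decomposed into
   ΔG<sub>vdw</sub> = VDWAALS + ENPOLAR, ΔG<sub>ele</sub> = EEL + EPB and
   ΔG<sub>total</sub> = ΔG<sub>vdw</sub> + ΔG<sub>ele</sub>, and each
   component is correlated framewise (Pearson) with the total. A
   Lennard-Jones + Coulomb cross-term calculator (10 Å truncation,
   Lorentz–Berthelot combining, k = 332.0637 kcal·Å/(mol·e²)) supports
   desk-scale exercises; solvation terms are parsed, never computed.
4. **Grouped statistics.** Production-window values (by default the last half
   of each trajectory, i.e. the last 100 ns of a 200 ns run sampled every
   1 ns) are compared with Welch's two-sided t-test, with the star scheme
   ns (p > 0.05), \* (p ≤ 0.05), \*\* (p ≤ 0.01), \*\*\* (p ≤ 0.001),
   \*\*\*\* (p ≤ 0.0001). Replicate trajectories are represented by the one
   with the highest mean SS.

A synthetic-data module generates bound and unbinding trajectories, energy
tables with controlled component–total correlations, and docking pose clouds,
so the whole pipeline is testable without MD engines, docking software or
deposited structures. See `docs/methods.md` for the model details and
assumptions.

## Worked example

```python
import ksbind
from ksbind import SyntheticSpec

complex_ = ksbind.make_toy_complex(30, 5, seed=1)
spec = SyntheticSpec(seed=1, exit_frame=50)          # ligand starts drifting at frame 50
traj = ksbind.simulate_unbinding_trajectory(complex_, spec)
pairs = ksbind.native_pairs(traj, complex_.receptor_indices, complex_.ligand_indices)
series = ksbind.stability_series(traj, pairs)
print("native pairs:", len(pairs))
print("SS frame 0:", series.values[0])
print("mean SS (all 200 frames):", round(series.values.mean(), 3))
window = ksbind.production_window(series)            # last 100 of 200 frames
print("mean SS (production window):", round(ksbind.mean_ss(window), 3))
print("ligand exit detected at frame:", ksbind.detect_exit(series))

energy = ksbind.simulate_energy_table(SyntheticSpec(seed=1, n_frames=200))
decomp = ksbind.decompose(energy)
r_vdw, p_vdw = ksbind.framewise_correlation(decomp.component("dG_total"),
                                            decomp.component("dG_vdw"))
r_ele, p_ele = ksbind.framewise_correlation(decomp.component("dG_total"),
                                            decomp.component("dG_ele"))
print(f"corr(dG_total, dG_vdw) = {r_vdw:.3f} (p = {p_vdw:.2e})")
print(f"corr(dG_total, dG_ele) = {r_ele:.3f} (p = {p_ele:.2e})")
```

Output:

```
native pairs: 16
SS frame 0: 1.0
mean SS (all 200 frames): 0.24
mean SS (production window): 0.0
ligand exit detected at frame: 55
corr(dG_total, dG_vdw) = 0.980 (p = 3.80e-141)
corr(dG_total, dG_ele) = 0.030 (p = 6.72e-01)
```

The 16 native pairs are intact at frame 0 (SS = 1 by construction). Because
the ligand starts drifting at frame 50, the production window is fully
post-exit (mean SS 0.0) and exit detection fires at frame 55, a few frames
after the switch once enough contacts have broken. In the energy table, the
van der Waals component dominates the variance of the total
(r = 0.98 vs 0.03), the packing-over-electrostatics pattern the correlation
analysis is designed to expose.

The same operations are available as a CLI:

```bash
ksbind simulate trajectory --seed 1 --out-dir demo/
ksbind ss --topology demo/topology.pdb --frames demo/trajectory.pdb \
       --receptor protein --ligand "resname LIG" --out demo/ss.csv
ksbind run --seed 1 --out-dir demo_run/   # full synthetic pipeline + manifest
```

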