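# Methods

## The stability score

For a receptor–ligand trajectory, the native pair set is the set of
receptor × ligand heavy-atom pairs (element ≠ H/D/T) whose Euclidean distance
is ≤ 7 Å in the reference frame (by default the first frame of the analysed
trajectory). For each frame, SS is the fraction of native pairs still within
7 Å. Consequences of the definition: SS of the reference frame is exactly 1
whenever the native set is non-empty; every SS lies in [0, 1]; and SS is
invariant under any rigid transform applied to the whole system, because it
depends only on pairwise distances.

Two choices are deliberate. First, only intermolecular (cross) pairs enter
the native set: the score measures the stability of the receptor–ligand
interface, and intra-molecular pairs — which survive almost any motion —
would dilute the signal toward 1. Second, the distance comparison is closed
(≤ 7 Å) on both the reference and subsequent frames; the open alternative
differs only on a measure-zero set of configurations.

The implementation evaluates exact distances for the explicit pair list with
vectorised numpy; no neighbour lists or periodic imaging. Inputs are assumed
to be imaged, whole molecules. A guard computes the intra-ligand
nearest-neighbour distances in the first frame and warns when any exceeds
3 Å, the signature of a molecule split across a periodic box.

**Production window.** All grouped statistics use the suffix of each series
starting at ⌊start_fraction · n⌋ with start_fraction = 0.5, which on a
200-frame trajectory sampled every 1 ns is the last 100 ns — the equilibrated
portion in the emulated protocol. The fraction is configurable for
trajectories with different equilibration behaviour.

**Exit detection.** "The ligand left the pocket" is operationalised as the
first frame index f with SS < 0.1 for every frame in [f, f + 10). The
10-frame sustain requirement makes transient contact losses (which occur even
in stably bound systems) not count as exits; a terminal dip shorter than the
sustain window is also not an exit, because the evidence is censored. Both
thresholds are parameters; the defaults were chosen as a conservative reading
of "exited the binding pocket" given 1 ns sampling.

## Patch classification

The front patch (R38/R65/R93) and back patch (Q149/R220/N260), in
crystal-structure residue numbering, are each summarised by the unweighted
centroid of their residues' heavy atoms (optionally side-chain atoms only).
A pose's reference point is its first phosphorus atom when one exists —
the phosphate is the moiety the front patch is seen to grip — otherwise the
heavy-atom centroid, with a logged warning. The pose is labelled with the
nearer patch if that distance is ≤ 8 Å, "other" if both are farther or if the
two distances tie within 1e-6 Å. The 8 Å acceptance threshold is a
reproducible surrogate for by-eye assignment in a molecular viewer: it is on
the scale of one binding-site radius, and the classification is insensitive
to it as long as it is well below the inter-patch separation. Shrinking the
threshold can only move poses into "other", never between patches.
Percentages are reported to one decimal place.

## Energy decomposition and correlation

ΔG_vdw = VDWAALS + ENPOLAR and ΔG_ele = EEL + EPB per frame, with
ΔG_total their sum; these identities are definitions, so the pipeline
enforces them to 1e-9 and ignores any TOTAL column present in input tables.
Tables are kcal/mol as emitted by MM-PBSA-style post-processors; no unit
conversion. Framewise Pearson correlations of each component with the total
are tested two-sided against the t-distribution with n − 2 df (scipy).
Correlations are computed over the same production window as the t-tests,
keeping the two analyses consistent. Among replicate trajectories of one
system, energy analysis uses the replicate with the highest mean SS over the
production window; exact ties resolve to the lowest index with a log message.

The in-repo Lennard-Jones + Coulomb calculator provides only the
molecular-mechanics cross terms: over receptor × ligand pairs within 10 Å,
ε_ij[(r_min,ij/r)¹² − 2(r_min,ij/r)⁶] with Lorentz–Berthelot combining, and
332.0637·q_iq_j/r with vacuum dielectric. Hard truncation at the cutoff, no
switching function, and a hard error below 0.1 Å (an atomic clash would
otherwise overflow the r⁻¹² term). Poisson–Boltzmann and nonpolar solvation
are out of scope by design: EPB and ENPOLAR are parsed from tables produced
by external tools. The internal dielectric of 4 that such tools use for
highly charged binding sites is recorded in the run config for provenance but
is never used in computation here.

## Grouped statistics

Welch's unequal-variance, two-sided, unpaired t-test is the default test
family (a pooled-variance Student variant is available behind a flag):
replicate windows have no natural pairing and no reason to share variance.
The star scheme is ns (p > 0.05), \* (p ≤ 0.05), \*\* (p ≤ 0.01),
\*\*\* (p ≤ 0.001), \*\*\*\* (p ≤ 0.0001), with inclusive boundaries —
p = 0.05 earns a star. Degenerate inputs: two constant samples with equal
means return p = 1 by convention; constant samples with different means are
rejected as degenerate rather than reported as infinitely significant.

Framewise values within one trajectory are autocorrelated, so treating
frames as independent observations overstates the effective n. The default
reproduces that convention (it is what the emulated analyses do); an
optional block-averaging pre-step (configurable block size, trailing partial
block dropped) is provided for users who want honest effective sample sizes.
No multiple-testing correction is applied by default, matching per-panel
star reporting; a Benjamini–Hochberg option exists.

Comparison cells are formed by three groupings: per ligand front-vs-back
windows; per ligand all pairs of KR types; and per KR type and ketide body,
pantetheine (-p) vs phosphopantetheine (-pp) arms, using the ligand
nomenclature parser ([m-]{tet|oct}[-{p|pp}], prefix m = isoxazole mimic).
Cells with fewer than two values are skipped with a warning. When replicates
are present, the default pools production-window frames across replicates
within a cell.

## Synthetic data

The generators emulate the statistical structure of the study conditions —
200-frame trajectories at 1 ns per frame in triplicate — not the physics:

- **Toy complexes**: receptor heavy atoms on a jittered cubic lattice (3 Å
  spacing), ligand a short chain placed 4 Å off the receptor surface, so at
  least one native pair exists by construction.
- **Bound trajectories**: rigid receptor; each ligand atom displaced by a
  fresh isotropic Gaussian (σ = 0.3 Å default) every frame; frame 0 is the
  initial pose exactly. Internal protein dynamics are irrelevant to the
  statistics implemented here, so they are not modelled.
- **Unbinding trajectories**: bound behaviour until the exit frame, then the
  ligand is additionally translated by drift · (frame − exit) along a fixed
  random unit vector (default 1 Å/frame). Since every native pair starts
  ≤ 7 Å, a 15 Å displacement guarantees SS = 0 regardless of direction.
- **Energy tables**: (ΔG_vdw, ΔG_ele) drawn from a bivariate normal. The raw
  terms are back-filled through fixed splits — VDWAALS:ENPOLAR = 9:1 of
  ΔG_vdw; EEL = −ΔG_ele and EPB = 2·ΔG_ele, sign-opposing as in typical
  charged systems — so component standard deviations derive from the
  4-vector of term sds through the split coefficients (defaults (9, 2, 4, 1)
  → component sds (10, 2)), and parsing + decomposition round-trips the
  drawn sums exactly. When component–total correlation targets are given,
  the single free correlation parameter of the bivariate normal is fitted by
  least squares; targets outside the achievable set (residual > 0.1, or an
  implied covariance that is not positive definite) raise an error reporting
  the covariance determinant. With the default sds the vdw component
  dominates the variance of the total, so corr(total, vdw) ≫ corr(total,
  ele) — the regime the correlation analysis is meant to detect.
- **Pose clouds**: the front/back/other composition is apportioned from the
  weights by largest remainder, so the generated composition equals the
  weights exactly at any seed, then the order is shuffled; per-pose geometry
  is stochastic. Patch poses scatter isotropically with σ = 1.5 Å — a
  realistic spread for a docking cluster within one motif (~1–2 Å) and small
  enough relative to the 8 Å threshold that label flips are negligible
  (P ≈ 3·10⁻⁶ per pose). "Other" poses land uniformly in a shell 15–30 Å
  from both centroids. A separability guard requires the centroids to be at
  least 4σ apart.

All generators are deterministic given (spec, seed). What passing tests on
these fixtures show: the analysis layer computes its definitions correctly
and recovers constructed effects. What they do not show: anything about
force-field accuracy, real pose distributions, or real energy distributions —
the generators have none of the anharmonicity, correlated collective motion
or heavy-tailed energetics of real MD output.

## Numerical and interface choices

- Canonical trajectory/pose dialect is multi-model PDB (self-contained,
  text, round-trippable at PDB's 1e-3 Å precision); binary formats pass
  through mdtraj when available. PDB reading uses Bio.PDB (strict mode;
  element inferred from the atom name when the element column is blank);
  writing emits fixed-column records directly so per-model score REMARKs can
  accompany pose sets.
- Residue numbering is preserved exactly as printed — patch definitions cite
  crystal-structure numbering, so renumbering would corrupt them. Hydrogens
  are read and retained; heavy-atom filtering happens in the analysis layer.
- Atom selections use a deliberately small grammar (`protein`, `resname`,
  `chain`, `resid` with ranges, `not protein`, `and`); anything more belongs
  to a full trajectory toolkit, and callables are accepted for arbitrary
  predicates.
- The pipeline runner writes a manifest (config, config hash, seeds, package
  version, per-stage timings) so any run is reproducible bit-for-bit from
  the manifest alone; results go only to disk, logs only to stderr.
- Problem sizes in the test suite and acceptance script (complexes of tens
  of atoms, 100–200-frame trajectories, 100–1000 statistical replications)
  were chosen so that each property is decided by construction or by
  comfortable statistical margins at small scale.

## Known limitations

- SS uses raw pair counts; there is no soft switching, so a pair oscillating
  across the 7 Å boundary contributes bang-bang noise. The sustain window in
  exit detection absorbs this for the exit question but not for SS itself.
- The classifier assigns by centroid distance only; a pose threading the
  channel between patches is assigned to the nearer entrance rather than
  recognised as a distinct mode.
- Frame-level t-tests inherit the autocorrelation caveat above; block
  averaging mitigates but does not model it.
- The LJ/Coulomb calculator is a truncated vacuum calculator for exercising
  the decomposition pipeline; its absolute values are not comparable to
  solvated MM-PBSA components.
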