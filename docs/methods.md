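# Methods note

Conventions, parameter defaults and numerical choices used throughout
`coilkit`. Units are Å for lengths, Å² for areas, degrees for angles,
°C for temperatures, and the titration concentration unit is carried as
a tag (`nM` by default) and checked at fit time.

## Register and heptad rows

A register assignment maps residue numbers to heptad letters a–g. The
text format is `START-END:a..g[,phase=X]` segments joined by `;`, where
`a..g` propagates cyclically from the phase letter and any other string
is a literal letter run (e.g. `79-82:abcd` is the classic stutter
insert). Discontinuities are detected by walking the letters cyclically:
a break that skips `k` letters is an insert of `(7 − k) mod 7` residues
(4 = stutter, 3 = stammer, 1 = skip).

`enumerate_heptads` emits one row per a-position that has a following
a-position. In regular repeats the row is (a, a+7, a+3). A row that
spans an insert keeps a′ = a+7 — the start of the next heptad on the
*regular extrapolation* — with d the d-lettered residue of the insert,
so a stutter row still reads (a, a+7, a+3) even though the next assigned
a sits at a+11. Because that arithmetic shape is indistinguishable from
a regular row, regularity is stored as an explicit flag on the row. For
the NEMO register (stutter at 79–82) this reproduces the published
table: rows at a = 23, 30, …, 72, then the stutter row (79, 86, 82),
then 83, 90, …, 132.

## Interhelical spacing

For a row (a, a′, d) and chain pair (1, 2): da = |Cα(d, chain 1) −
Cα(a, chain 2)|, da′ = |Cα(d, chain 1) − Cα(a′, chain 2)|, and the
reported value is (da + da′)/2. By default the measure is symmetrized
over the two chain orderings (averaging the d-on-1 and d-on-2 values),
which makes it invariant to chain labeling; `symmetrize=False` gives
the one-directional value. Missing residues propagate `None` ("NA" in
TSV output) rather than being silently dropped.

## Superposition and RMSD

Kabsch superposition via SVD with the determinant correction that
forbids improper rotations. `region_rmsd` matches atoms by (mapped
chain, residue number, atom name) over a declarative selection
(`all-heavy`, `backbone`, `calpha`, or a named set); `chain_map="auto"`
evaluates both dimer pairings and returns the minimum, which is the
convention used for all homodimer comparisons. Tests verify the optimum
against an independent quaternion-sampling rotation search to 1e-3 Å.

## Helix axes

A chain-region axis is the principal component of 4-residue sliding-
window Cα centroids, oriented N→C. Interaxis angles are reported on
[0°, 90°] by default (line–line angle); `oriented=True` distinguishes
antiparallel. At least 7 residues are required; fewer raises `AxisError`.

## SASA

Shrake–Rupley with the package-canonical single-element radii C 1.70,
N 1.55, O 1.52, S 1.80 Å (unknown elements fall back to 1.70 with a
warning), probe 1.4 Å, 960 quasi-uniform (golden-section spiral) sphere
points per atom. Hydrogens, waters and heteroatoms are excluded; a
`chains=` filter strips bound ligands before computing exposure. A point
exactly on a neighbor sphere counts as buried (relative epsilon 1e-9),
so duplicated atoms are fully buried. An isolated atom evaluates to
exactly 4π(r + 1.4)²; agreement with an independent implementation
(biotite, same radii/point count) is within 2% on a full dimer. Because
the point set is fixed in the lab frame, per-residue values vary at the
~1% quadrature level under rotation; totals are stable to 0.1%.

## Packing detections

* **Knobs-into-holes** (simplified, not all-atom SOCKET): a residue is a
  knob when its side-chain centroid lies within 7.0 Å (configurable) of
  ≥ 4 partner-chain side-chain centroids; the 4 nearest form the hole.
  Glycines (no side chain) are skipped. Chain-terminal a/d residues can
  lack a complete hole diamond, so the a/d knob fraction on an ideal
  dimer is slightly below 1 (0.94 at 117 residues/chain).
* **Salt bridges**: cross-chain acidic (Glu OE1/OE2, Asp OD1/OD2) vs
  basic (Lys NZ, Arg NH1/NH2/NE; His ND1/NE2 only on request) heavy-atom
  minimum distance ≤ 4.0 Å. Distance-only — the target crystal
  structures carry no hydrogens.
* **Polar core contacts**: symmetric a–a′ Asn pairs and a-Lys/g′-Glu
  pairs (|Δresidue| ≤ 2) within 3.5 Å.
* **Underwound flagging**: heptads whose mean spacing exceeds a baseline
  (median of the profile by default) + 0.5 Å, grouped into contiguous
  (first_a, last_a′) regions.

## Flexibility

Per-residue B is the mean of heavy-atom B-factors. With B_ave and B_std
(sample SD) over all N residues of the structure and n the residues of
the examined chain, the normalized value is

    BN′ = (B − B_ave) / ((B_std/√n) · √((N − n)/(N − 1)))

reported both raw and averaged over a 3-residue moving window that
shrinks to 2 at the termini. Degenerate inputs (n = N, constant B,
missing chain, N < 2) raise `DegenerateVarianceError` rather than
returning infinities. Ensemble RMSF superposes every frame onto the
ensemble mean (two refinement passes), making it invariant to arbitrary
per-frame rigid motion to ~1e-3 Å. Per-heptad spacing fluctuation is the
mean and sample SD of (da + da′)/2 over frames, indexed by the heptad's
d residue.

## Binding and melts

The titration model is the exact ligand-depletion solution: bound
fraction = (L + K_D + P − √((L + K_D + P)² − 4LP)) / 2L, required when
the reporter concentration L is comparable to K_D. Fits are unweighted
least squares with K_D log-parameterized; 95% bounds come from the
linearized covariance with a t-quantile (K_D bounds exponentiated), and
case-resampling bootstrap intervals are available with an explicit seed.
Constant FA, fewer than 4 points, or unit mismatches raise errors;
titrations that do not span half-saturation trigger a warning.

Tm is the temperature of the maximum |dθ/dT| after moving-average
smoothing (window 5), refined by 3-point parabolic interpolation and
reported at 0.1 °C resolution. The cooperativity score — peak slope over
mean slope (amplitude/span) — is ~1 for a linear ramp and large for a
sharp two-state transition; curves scoring below 2.0 (or with negligible
amplitude) report no transition instead of a meaningless Tm.

## Synthetic generator

Chain A Cα positions follow a minor helix of radius R1 = 2.26 Å wound
around a superhelical circle of radius R0 = 4.9 Å with rise 1.51
Å/residue and 3.62 residues/turn; the supercoil frequency is
w0 = w1 − 4π/7 so the a/d interface phase advances exactly two minor
turns per heptad (left-handed supercoil, pitch ≈ 159 Å). Chain B is a C2
rotation of chain A about the superhelical axis (parallel dimer). Each
residue gets a CA and a CB stub 1.5 Å outward along the minor radial
direction — a usable side-chain centroid for packing analyses — with
LEU at a/d positions and ALA elsewhere. The default length is 117
residues/chain, matching the studied NEMO construct (numbering 23–139).

A stutter is realized as (i) a permanent interface-phase correction that
undoes the +4-residue register shift, ramped across the insert, plus
(ii) a transient triangular extra lag (`local_unwind`, default 20°) over
the insert ± 4 residues. This elevates the spacing at the stutter row by
~2 Å over the 7.76 Å baseline and returns to baseline within one heptad
— the qualitative signature of real stutters — without modeling the
true backbone physics. The generator emulates *ideal* geometry for
testing and demonstration; it is not a structure predictor, and
perturbed ensembles (isotropic Gaussian noise, optional per-frame random
rigid motion) stand in for MD trajectories only statistically.

## Determinism

All generators are pure functions of (parameters, seed); report
generation with a fixed config and seed is byte-identical across reruns.
Bootstrap and ensemble routines require explicit seeds.

## Known limitations

* Parallel homodimers only; no antiparallel or higher-order oligomers.
* Knob detection is centroid-based, not packing-angle-classified
  (no parallel/perpendicular knob types).
* SASA uses a single-element radii table; published areas computed with
  other radii sets can differ by several percent (the acceptance checks
  use a ±10% tolerance for this reason).
* Helix-axis angles depend on the axis definition; published values are
  matched with a ±1.5° tolerance.
* The deposited-structure comparisons require user-downloaded PDB files
  (see README); the corresponding tests fail with instructions when the
  files are absent.
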