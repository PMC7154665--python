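# Methods

This note documents the models, conventions and numerical choices behind
cmphelix, and what the synthetic-data generator does and does not emulate.

## Torsion conventions and circular statistics

Backbone dihedrals follow the IUPAC right-hand convention and are reported
in degrees on [−180, 180): φ(i) = C(i−1)-N-Cα-C, ψ(i) = N-Cα-C-N(i+1), and
ω(i) = Cα(i)-C(i)-N(i+1)-Cα(i+1), i.e. ω belongs to the peptide bond
*following* residue i, so a trans amide reports ω ≈ ±180°. Chain termini and
residues with missing backbone atoms yield undefined entries with a recorded
reason — never interpolated values.

Triplet profiles pool the selected triplets of all chains and use
directional statistics: the mean is the argument of the summed unit vectors
and the SD is √(−2 ln R̄) in degrees. For collagen torsions, which cluster
within a few degrees, this is numerically identical to arithmetic averaging
(the package asserts agreement to millidegrees on tight clusters), but it is
exact across the ±180° wrap where ω lives. An alternative per-chain
averaging mode (mean of chain means) is exposed as a flag; pooling is the
default. A sample whose resultant vanishes (uniform angles) has no defined
mean and raises instead of returning a number.

"Central n triplets" selects, per chain, the n consecutive triplets whose
window is farthest from both termini; when the two candidate windows tie
(e.g. 9 of 10 triplets), the N-terminal window is taken. The choice is a
convention — published tables do not state their window bounds — and the
profile records the selection used.

## Preorganization

A dipeptide module is compared against the (PPG)₁₀ reference means
(φ_Xxx = −75°, ψ_Xxx = 164°, φ_Yyy = −60°, ψ_Yyy = 152°) by absolute
circular difference per angle. The module counts as main-chain preorganized
when the maximum deviation stays below 15°; the threshold is a parameter
with that default. The report is symmetric in its two arguments.

## Ring pucker

The discrete Cγ-endo/exo call uses the signed perpendicular displacement of
Cγ from the N-Cα-Cδ ring base plane, with the side carrying the residue's
carbonyl carbon defined as positive: endo means Cγ and carbonyl on the same
side. Displacements below 0.1 Å are called ambiguous — flatter rings are not
reliably callable at crystallographic precision. This displacement
convention was chosen over a phase-window rule on the pseudorotation circle
because the downstream analysis only consumes the binary label; the full
Cremer–Pople phase and total amplitude Q (ring order N-Cα-Cβ-Cγ-Cδ) are
still computed and reported for diagnostics. Only residues whose five-ring
actually closes (Cδ-N < 1.8 Å) enter the per-position tallies, which keeps
arginine and other open side chains out without a residue-name whitelist.

Ring-flip energies of candidate modules are user-supplied fixtures in
kJ/mol with the convention that negative values indicate exo preference;
`flip_preference_label` turns them into exo-preferring / balanced /
endo-preferring with a ±1 kJ/mol dead band by default. The package never
recomputes such energies — they come from quantum-chemical calculations
outside its scope.

## The helix builder (synthetic-data generator)

Strands are grown residue by residue from internal coordinates (sequential
NeRF placement) with fixed standard bond lengths and angles (N-Cα 1.458 Å,
Cα-C 1.525 Å, C-N 1.329 Å; N-Cα-C 111.2°, Cα-C-N 116.2°, C-N-Cα 121.7°).
Backbone torsions are exactly the specified per-position values, so the
builder↔analyzer round trip is exact to numerical precision; Gaussian
angular noise (SD in degrees, seeded) can be injected per angle to emulate
the variability seen across a crystal. Torsion presets cover the rounded
(PPG)₁₀ means, the full (PPG)₁₀ crystal profile, and the crystal profile of
the bridged-diproline CMP.

Proline rings are attached from two precomputed closed-ring templates, one
per pucker state. The template fixes χ1 = ±30° with ring bond angles of 102°
and solves the one-dimensional ring-closure problem in χ2 (bracketed root
finding on |Cδ−N| − 1.473 Å, choosing the closure branch with the
pyrrolidine-like Cδ-N-Cα angle). Each template is labelled by running the
pucker classifier on it, so builder and classifier agree by construction;
the resulting total puckering amplitude (≈0.37 Å) and Cγ displacement
(≈0.39 Å) sit in the range typical of pyrrolidines. L-configuration at Cα is
fixed by the improper dihedral N-C-Cα-Cβ = +120°, verified against an
independently embedded L-proline reference. 4R-hydroxyproline is built as
proline plus a hydroxyl on Cγ placed at χ(Cδ) − 120°.

Three-stranded helices are assembled by rigid placement only: each strand is
kept rigid, displaced 7.3 Å radially from a common axis parallel to the
strand's own screw axis, and the three copies are related by exact 120°
rotations plus (by default) a one-residue axial stagger of one third of the
per-triplet rise (~2.9 Å). The radial distance and the azimuthal face
orientation (40°) were fixed once so that all torsion presets assemble with
closest inter-strand contacts of ≈3.2 Å — realistic van-der-Waals packing
with zero clashes at the 0.4 Å overlap criterion. This is deliberately an
idealized generator: no energy model, no interstrand hydrogen-bond
optimization, no supercoiling of the strand around the common axis. A
strand rebuilt from mean torsions does not reproduce the supertwist of a
real crystal (helical twist is exquisitely sensitive to bond angles and to
the small per-triplet torsion variations that mean values erase), so the
assembly uses the strand's own measured screw only for the stagger rise and
axis direction. Consequences for testing: passing round-trip and
clash-freedom tests on builder output validates the measurement pipeline
and the generator's internal consistency, not the fine packing geometry of
deposited crystal structures.

## Superposition and clash screening

Rigid superposition is the Kabsch SVD solution with the determinant
correction, requiring at least three non-collinear pairs; the test suite
cross-checks it against an independent Horn quaternion implementation to
1e-9 Å. Fragment-to-helix alignment matches the N/Cα/C atoms of the
fragment's Xxx and Yyy residues to the chosen helix triplet.

Clash detection uses Bondi van-der-Waals radii and flags a posed-atom /
environment-atom pair when its distance falls below r₁ + r₂ − t with
t = 0.4 Å by default (a common crystallographic overlap criterion). Pairs
within three covalent bonds are excluded; since coordinate files may lack
connectivity records, bonds are inferred by distance (<1.9 Å heavy-heavy,
<1.3 Å to hydrogen) over the combined system. Reports carry the environment
chain of each contact so same-strand and neighboring-strand counts can be
read off. The detector is validated against a brute-force all-pairs oracle
on small instances and is invariant under rigid motion of the whole system.

## Suitability scoring

Four categories — main-chain preorganization, Yyy ring-flip preference,
adaptability, steric toleration — each carry a mark from {+, o, −}. The
quantitative mapping defaults are: main chain "+" below 10° maximum
deviation, "o" below 15°, "−" otherwise; ring flip from the preference
label; sterics "−" for any neighboring-strand clash; adaptability is a
pass-through mark because no quantitative definition of it exists — it
encodes whether the fused ring system can follow thermal main-chain
fluctuations, a property the package cannot compute from a static
structure. All thresholds are parameters.

The summed score S uses integer weights per (category, mark). A plain
±1/0 sum cannot reproduce the published score column: three
linker-functionalized modules print "−" where the naive sum gives 0. The
shipped default weighting keeps ±1/0 everywhere except that "−" in the
main-chain and sterics categories counts −2 — the minimal asymmetry that
reproduces all thirteen published S symbols, and a chemically sensible one
(a badly preorganized main chain or a steric collision is more damaging
than a suboptimal ring-flip bias). The test suite verifies that no weighting
shared across categories can reproduce the full column, so the asymmetry is
necessary, not decorative. Symbols map from the sum as ≥2 → "++", 1 → "+",
0 → "o", ≤−1 → "−" (the bands are configurable; "−−" is reachable only
under custom bands). Score–stability association is summarized by the
Spearman rank correlation of S with Tm, ties mid-ranked; on the published
thirteen-row table the default weights give ρ ≈ 0.89.

## Melt-curve fitting

Two model families share linear folded/unfolded baselines and differ in the
folded-fraction function: an empirical Boltzmann sigmoid
x(T) = 1/(1+exp((T−Tm)/k)), and a two-state trimer ⇌ 3·monomer van't Hoff
model in which x solves (1−x)³/x = 0.25·exp[(ΔH/R)(1/Tm_K − 1/T_K)] (the
0.25 makes x(Tm) = 0.5 exactly). In both families Tm is defined as the
folded-fraction-0.5 midpoint, so the reported quantity is model-agnostic;
with the generator's default sharpness (ΔH = 800 kJ/mol, k = 1.5 °C — a
cooperative transition spanning a few degrees, matching the steep CMP melts
the rubric is calibrated against) cross-family fits agree on Tm to well
within the ±1 °C reproducibility of the experiment. Temperatures are °C
throughout; the van't Hoff model converts to kelvin internally.

Fitting is plain nonlinear least squares (no smoothing, no outlier
rejection) with automatic initialization: Tm from the extremum of the
numerical derivative, baselines from the edge segments. A fit is reported
as non-converged — never with a fabricated Tm — when the optimizer fails,
when the fitted transition amplitude at the midpoint drops below five times
the residual noise (flat curves), or when the midpoint lands on the edge of
the scanned range. Jittered re-initializations agree to <0.05 °C on
converging fits, and Tm is invariant under affine rescaling of the signal.

Synthetic melts default to 101 points over 20–70 °C (a reading every
0.5 °C, ordinary for CD melt protocols) with seeded Gaussian noise. Under
the validation conditions (200 curves, Tm ∈ [35, 50] °C, noise 3% of the
transition amplitude) the matched-model fit recovers Tm with a median error
of ≈0.1 °C and a 95th percentile well under 1 °C. The generator emulates
only the two-state signal shape with white noise; it does not model scan-
rate hysteresis, concentration dependence, baseline curvature or
correlated instrument drift, so melt-fit validation speaks to estimator
correctness, not to every systematic a real melt can carry.

## Degenerate inputs and error behavior

Dihedrals of coincident or collinear points, circular means of empty or
uniform samples, superposition of collinear point sets, registration of
chains where no reading frame places ≥80% glycines correctly, melt curves
with non-monotone temperature grids, and atom names that overflow the PDB
field all raise typed domain errors; the command-line layer maps them to
exit status 1 (usage errors exit 2). PDB coordinates are written at the
format's fixed three-decimal precision, which perturbs re-measured torsions
by at most a few hundredths of a degree — round-trip tests assert at that
precision, not tighter.

## Known limitations

* The triple-helix assembly is idealized rigid packing; it does not
  reproduce crystallographic supercoiling or interstrand hydrogen-bond
  geometry, and quantitative clash analysis of real deposited structures
  should treat the builder only as a source of controlled test geometry.
* Bridged diproline modules enter the analysis through their printed
  torsions, marks and flip energies; their tricyclic 3-D geometry is not
  constructed.
* The adaptability category is not computable from static coordinates and
  remains an input.
* No correction is applied for finite heating-rate non-equilibrium in melt
  data.
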