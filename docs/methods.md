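# Methods

This note documents the models implemented in `memallo`, the defaults that
matter, the synthetic-data generators used for validation, and the limits
of what the validation shows. Units are Å and ns everywhere inside the
package; nm/ps formats (XTC) are converted at the I/O boundary.

## Perturbation response scanning (`memallo.prs`)

The protein is reduced to its Cα atoms. The 3N×3N positional covariance

    C = ⟨(x − ⟨x⟩)(x − ⟨x⟩)ᵀ⟩

is estimated after rigid-body superposition of every frame onto an
iteratively refined mean structure (two iterations by default — enough for
equilibrium fluctuation ensembles; configurable). The denominator is the
frame count n, not n−1; the choice is immaterial to overlap scores, which
are scale-invariant, and is stated for reproducibility.

Linear response theory gives the expected displacement under a constant
point force **F** at one node as **ΔR** = C·**F**. The thermal prefactor
1/kT is deliberately omitted: the overlap score is invariant to any
positive scaling of C, **ΔS**, or the force magnitude (a property-tested
invariant), so the prefactor only matters for absolute displacements,
which this package does not report.

The overlap between a response and the target conformational change is the
**absolute** cosine, |ΔR·ΔS|/(|ΔR||ΔS|). The absolute value is taken
because the sign of a probe force is arbitrary — ±F carry identical
information. Per node the scan samples 1000 uniform unit directions
(normalized 3D standard normals — exactly uniform on the sphere) per
repeat, 5 repeats, and records the best overlap across all repeats; the
mean-over-repeats aggregate is available as an option. Nodes with best
overlap ≥ 0.6 are reported as hotspots, ranked descending with ties broken
by ascending residue number.

A closed-form optimum accompanies the scan: with Cᵢ the node's 3N×3 column
block, B = CᵢᵀCᵢ and a = CᵢᵀΔS, the unit force maximizing |cos| is
f\* ∝ B⁻¹a (pseudo-inverse when B is singular) with achieved overlap
√(aᵀB⁻¹a)/|ΔS|. The random scan can approach but never exceed it, which
makes it both a per-node upper bound and the convergence oracle: at 10⁴
sampled directions the median per-node gap is below 10⁻³ in practice.

Target displacements are built by Kabsch-superposing the target structure
onto the initial one over the node selection, removing the arbitrary
rigid-body component. When a PRS start frame is not given explicitly, the
first frame of the *converged interval* is used — the longest trajectory
suffix whose Cα RMSD to the final frame stays below a bound (default 1 Å).

Out of scope by design: steered-MD follow-up of candidate residues,
elastic-network covariances as the production path (the network builder
exists only in the synthetic module), and mode decompositions.

## Occupancy grids (`memallo.density`)

Voxel value = fraction of frames in which ≥1 selected particle falls in the
voxel (occupancy, not mass-weighted density, and no Gaussian smearing).
Binning is half-open, `floor((x − origin)/spacing)`, with particles wrapped
into the box by minimum image first; the origin is the box minimum corner
and the default spacing 1 Å. The reporting filter zeroes voxels below 0.5
(inclusive keep at exactly 0.5).

The published criterion — "reported where lipid and protein were in contact
in ≥50 % of frames" — is ambiguous between voxel occupancy and
protein-contact occupancy. The implementation brackets both readings:
plain voxel occupancy, plus an optional protein-proximity mask (default on
in the CLI, 6 Å from any protein particle) applied multiplicatively.
Grids export to OpenDX via GridDataFormats for VMD/PyMOL display.

## Contact events and binding sites (`memallo.sites`)

Contacts use dual-cutoff hysteresis per (lipid molecule, protein residue):
an event opens at the first frame with minimum interparticle distance
< r_on and closes at the first frame > r_off. Defaults r_on = 4.75 Å,
r_off = 7.0 Å mirror common coarse-grained practice and are fully
configurable. Events separated by ≤1 frame are stitched (configurable, 0
disables). An event still open at the last frame is closed there
(right-censored). The last frame inherits the previous frame's time credit
so durations are well-defined on irregularly spaced trajectories.

Residence time is 1/k from an equally weighted least-squares fit of
log S(t) over the empirical survival curve of event durations; below 5
events the estimator falls back to the mean duration, as a one- or
two-event "fit" is noise. On planted exponential durations (500 events,
mean 50 ns) the fit lands within a few percent of truth. No bi-exponential
model and no bootstrap CIs — deliberately simpler than PyLipID, which this
module re-implements in reduced form.

Sites are connected components (≥2 residues) of a co-occurrence graph:
edge (i, j) when, among frames where either residue touches any lipid, the
same lipid touches both in ≥50 %. Thresholded components were chosen over
community detection: deterministic, order-independent (tested), and
adequate for planted-truth validation. Site-level kinetics are computed
over maximal segments in which one lipid contacts ≥2 site residues
simultaneously; the representative pose is the midpoint frame of the
longest such segment (ties → earliest). The 3 µs "long-lived" flag is pure
reporting: it never changes the site list.

## Atomistic interactions (`memallo.interactions`)

Hydrogen bonds: donor-heavy-atom-to-acceptor distance ≤ 3.5 Å **and**
D–H–A angle ≥ 130°. The distance is the published screening cutoff; the
angle follows common fingerprinting defaults and is configurable. Donor
hydrogens are resolved geometrically (same residue, ≤1.25 Å from the donor
heavy atom); donors without one are skipped with a logged count.
Hydrophobic contacts: any carbon/sulfur atom pair ≤ 4.5 Å, reported at
residue level. π–π and cation–π classes are omitted: cholesterol has
neither aromatic rings nor formal charges. All cutoffs are inclusive with
a 10⁻⁹ numeric guard so fixtures built exactly at a boundary classify as
inside it; all distances are minimum-image.

Fingerprints aggregate per-frame booleans into per-residue frequencies for
three classes (protein donates, ligand donates, hydrophobic); replicas are
pooled by frame-weighted mean. Distance series report per-frame
minimum-image distances with population mean ± SD, per ligand copy and
pooled — matching how multi-subunit receptors are usually reported.

The pore profile is a deliberate simplification of curved-pathway channel
annotators: a straight axis through the centroid of the pore-lining
selection, directed along the principal axis of the coordinate set (an
explicit axis can be given for squat test geometries), 1 Å slabs, radius =
min over slab atoms of (distance to axis − Bondi vdW radius), atoms
outside a 15 Å search cylinder ignored, empty slabs flagged undefined
(NaN), never zero-filled.

## Synthetic data (`memallo.synthetic`)

**Gaussian ensembles** sample i.i.d. frames from N(mean, C) with C built
isotropically (σ²I), with a planted rank-one spike (σ²I + λuuᵀ), or from a
distance-cutoff elastic network. The exact C is returned alongside the
trajectory so estimators can be validated against truth (sample covariance
converges within 10 % Frobenius error at 10⁴ frames for N ≤ 30 — tested).
Frames are temporally uncorrelated; real MD is autocorrelated, so
convergence rates measured here are optimistic relative to real data.
Validation on these ensembles demonstrates estimator correctness, not
sampling adequacy of any particular simulation.

**Lipid walks** move point lipids by isotropic Gaussian steps (per-axis σ
scaled so the mean 3D step length equals `diffusion_step`) inside a
reflecting orthorhombic box around a fixed toy protein. Entering within
`r_bind` of a site center freezes the lipid **at the center** (it settles
into the pose) for Exponential(mean_dwell) ns, quantized up to whole
frames; it then resumes walking and cannot rebind until it has diffused
beyond `r_release` (default 2.5 × r_bind). The escape shell exists because
an unbiased 3D walker released at the capture boundary re-enters with high
probability before its contacts break, which would merge adjacent planted
dwells at the detection level and bias residence times upward — with the
shell, detected site durations track the planted exponential (KS test at
α = 0.01 on ≥500 events, fixed seed). One seeded generator drives
placement, steps, and dwell draws in a fixed order, so runs are
bit-reproducible. The walk has no lipid shape, no force field, no
leaflets, and bound lipids are rigidly immobile — the simplest kinetics
whose residence-time distribution equals the planted one. Conclusions
about detection and estimation transfer to real data; conclusions about
lipid physics do not.

The default validation conditions — 50 ns mean dwell, 1 ns frames, 4 Å
capture radius, 2 Å mean step, a four-residue site ring of radius 2 Å,
80 lipids × 20 000 frames where ≥200 events are needed (40 × 4 000 for the
fast pipeline demo) — were chosen once as a regime where arrival is
diffusion-limited but events are plentiful, and are fixed in the
configuration defaults.

**H-bond fixtures** place a serine O–H donor and a sterol hydroxyl
acceptor at an exactly prescribed donor–acceptor distance and D–H–A angle
(CHARMM naming: SER/OG/HG1, CHL1/O3/C3), giving the detectors constructive
boundary cases.

**Leaflet mole percents** are computed from integer lipid counts and
rounded half-away-from-zero to one decimal. Published composition tables
are sometimes internally inconsistent in their last digit between table
and prose; the calculator reports from counts only and the shipped
reference compositions are validated against the self-consistent entries.

## Numerical choices

* Kabsch superposition via SVD with a determinant sign fix guarantees a
  proper rotation; degenerate (collinear, N < 3) references raise rather
  than returning a garbage frame.
* Covariance PSD tolerance: eigenvalues ≥ −10⁻⁸ × the largest are treated
  as round-off and clipped to zero (the elastic-network pseudo-inverse
  produces them).
* `analytic_best_force` falls back to the pseudo-inverse when the 3×3 Gram
  block is singular, and reports overlap 0 with a flagged arbitrary
  direction when the node cannot produce any response along the target.
* Hysteresis contact states are computed by forward-filling a three-state
  code over frames, which is exactly the sequential state machine but
  vectorized over all (lipid, residue) pairs.
* Ties are always broken deterministically (earlier frame, smaller residue
  number), and clustering output is independent of event ordering.

## Known limitations

* Orthorhombic boxes only; triclinic input errors out at the reader.
* No PBC re-wrapping of broken molecules — inputs are assumed whole.
* The PDB reader rejects insertion codes instead of merging them.
* The straight-axis pore profile understates the radius of curved pores.
* Single-exponential residence times misrepresent genuinely multi-modal
  unbinding; inspect the survival curves (returned with every residue
  stat) before trusting 1/k.
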