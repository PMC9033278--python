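# Methods

This note records the models behind each analysis arm, the synthetic data
they are validated against, the tunable parameters that matter, and the
numerical choices made where the design was genuinely open.

## 1. Spin-label (3pESEEM) solvent accessibility

### Signal model

A three-pulse stimulated-echo experiment (π/2–τ–π/2–T–π/2) on a nitroxide
label records the integrated echo V(T) as the second delay T is stepped
(by convention from 400 ns in 12 ns steps).  Weakly hyperfine-coupled
deuterium nuclei of D₂O modulate the envelope.  The simulator, and therefore
the fit convention, uses a single effective deuterium line:

    V(T) = B(T) · [ 1 − (k/4)·(1 − cos 2πν_Dτ)·(1 − cos 2πν_D(T+τ))·e^(−T/τ_d) ] + ε(T)

* `B(T) = B₀·exp(−(T/T_bg)^β)` — stretched-exponential echo decay,
* `k ∈ [0,1]` — total deuterium modulation depth; the accessibility proxy,
* `ν_D` — effective deuterium Larmor frequency (MHz),
* `(1 − cos 2πν_Dτ)` — the blind-spot factor: at τ = m/ν_D the deuterium
  modulation vanishes identically,
* `τ_d` — modulation damping time,
* `ε` — white Gaussian noise, σ expressed as a fraction of B₀.

Deuterium quadrupole splitting and combination lines are deliberately
omitted: the analysis fits a damped harmonic oscillation, and a simulator
with the same effective-line structure makes depth recovery exact and
round-trippable.  Modulation depth is taken as linear in accessibility
(depth ∝ number/proximity of coupled solvent deuterons).

### Background deconvolution

`correct_background` fits `B(T)` to the oscillation-free upper envelope by
two-pass iterative masking — fit all points, then refit on the points at or
above the first fit, exploiting that deuterium modulation only ever dips
*below* the envelope — followed by a joint background × modulation
refinement.  The joint pass is what makes noiseless round trips exact
(depth error < 10⁻³): without it the masked envelope fit retains an O(0.3 %)
bias from discrete sampling of the cosine tops.  A cubic-in-log-amplitude
background is available as a fallback (`model="poly3"`).  The modulation
function is `V/B − 1`, so it is invariant to overall trace scaling.

The contract that the modulation tail (last 10 % of the grid) should average
to ~0 is recorded as a `tail_converged` diagnostic rather than enforced:
for large depths with slow damping, the decaying offset −A·e^(−T/τ_d)
legitimately exceeds 3σ at the end of a 12.7 µs trace.

### Depth fit and FT route

`fit_modulation` fits m(T) = −A·e^(−T/τ_d)·[1 − cos(2πν(T+τ)+φ)] + c
(weighted by B(T)/B₀, since dividing by a decaying background amplifies
noise late in the trace) and converts A to k by the blind-spot factor.
Initialisation matters and is automated: ν from the magnitude-FT peak of
the detrended modulation (a moving-average detrend over ~one period removes
the slowly decaying offset, which otherwise biases the peak), φ from a
quadrature projection at that frequency, and five damping starts log-spaced
over the trace duration; the best χ² wins.  The fitted damping is bounded
below by one oscillation period — anything faster only ever fits individual
noise spikes.  `relative_sd` is the covariance-derived σ(A)/A.  Traces whose
peak-to-peak modulation is below 3× the noise floor return depth 0 with a
`"no deuterium modulation"` flag.

The FT route Hamming-apodizes the mean-subtracted modulation, zero-fills
≥ 4×, and integrates the magnitude spectrum over a window (default ±0.75 MHz)
around the deuterium line.  Both routes estimate the same quantity; the
test suite requires Pearson r > 0.99 across a simulated panel and agreement
within the 5-point error bars after normalisation.

### Panels, normalisation, state comparison

Panels are normalised so the most accessible residue reads 100 % (an
explicit reference label is supported).  Uncertainties propagate in
quadrature and are floored at 5 percentage points — a conservative
convention covering relaxation and non-solvent-proton differences between
labelled mutants that the fit covariance cannot see.  Two states are each
normalised on their own scale and compared per residue; `no_change` when
|Δ| ≤ the combined (≥ √2·5-point) uncertainty, otherwise
deprotected/protected by sign.  Per-state normalisation is the default
because each state's panel is internally referenced; joint normalisation is
available by normalising a concatenated panel explicitly.

### Generator defaults (the simulated study conditions)

| parameter | default | rationale |
|---|---|---|
| grid | 400 + 12·i ns, 1024 points | stimulated-echo convention; ~12.7 µs trace |
| τ | 200 ns | proton-blind-spot-like value at X band |
| ν_D | 2.25 MHz | deuterium Larmor frequency at ~0.34 T (X band); a declared default, recorded in the fixture manifest |
| τ_d | 8 µs | slow deuterium-modulation damping typical of frozen (80 K) nitroxide samples |
| T_bg, β | 20 µs, 1.0 | slow stimulated-echo decay at 80 K |
| noise σ | 0.5 % of B₀ | realistic averaged-trace noise |

With these conditions a 26-trace panel spanning depths 0.05–0.9 yields a
maximum covariance-derived relative SD of the depth parameter just under
2 % — the fit-precision level the generator is calibrated to emulate; the
acceptance script recomputes this number from scratch.

## 2. Differential HDX-MS

### Uptake model

Residue-level exchange with a uniform intrinsic rate k_int and per-residue
protection factor P: D_r(t) = 1 − exp(−k_int·t/P_r).  A peptide's uptake is
the sum over its exchangeable residues — all but the peptide's first residue
and prolines (standard HDX bookkeeping; sequence-dependent intrinsic rates
are out of scope, as only *differential* behaviour is analysed).  State B
equals state A except in planted regions where P is divided by a fold
change.  Replicate noise is i.i.d. Gaussian in Da.  Uptake is relative
throughout; no back-exchange correction is applied or needed for
differences.

Defaults: 125 residues, exposures 0.5/1/2/10/60 min, 3 replicates,
k_int = 60 min⁻¹, P = 600 (so k_obs = 0.1 min⁻¹ and the exposure ladder
spans ~5–100 % exchange), noise 0.05 Da.

### Significance

Per peptide: Δ_t = ū_B(t) − ū_A(t) and ΣΔ = Σ_t Δ_t.  The global threshold
pools replicate variances per timepoint across all peptides (df-weighted)
and applies a Student-t critical value:

    threshold = t(1 − α/2, n_A + n_B − 2) · sqrt( Σ_t ( s²_A,t/n_A + s²_B,t/n_B ) )

with α = 0.01 by default.  Classes follow the sign of ΣΔ beyond the
threshold.  A `hybrid` mode additionally requires at least one per-timepoint
Welch test at p < α; summed-only is the default.  The df choice (replicates,
not timepoints × replicates) is deliberately conservative; null simulations
show a significant fraction far below 2α.

### Residue mapping

The digest is modelled as a cut-site fragment map (sites every 3 residues
plus termini, every run of 1–3 intervals a peptide), giving the nested
short fragments and ~6× redundancy of a well-behaved proteolytic digest.
The residue-level consensus is conservative: a residue is classed
deprotected (protected) only when **every** peptide covering it is
significant with that sign.  A covering non-significant peptide — direct
evidence that the change does not localise to that residue — vetoes, as do
overlapping contradictory peptides.  With an overlapping digest this
resolves region boundaries to roughly the inter-cut-site spacing (±2
residues in the tests) and keeps the residue-level false-positive rate
near zero; a plain majority vote over significant peptides would bleed each
region outward by a peptide length and merge regions separated by less than
one peptide, because every straddling peptide containing even one
deprotected residue is (correctly) significant at the peptide level.
The cost is that sub-peptide regions covered only by long peptides are
reported at peptide granularity, never sharper — which is honest.

## 3. MD structural metrics

All coordinates are Å internally; thicknesses are reported in nm.  Systems
load from single- or multi-model PDB via MDAnalysis; an optional CSV
parameter table attaches per-(resname, atom) σ (Å), ε (kJ/mol), charge (e)
and vdW radius; element-guessed radii (H 1.2, C 1.7, N 1.55, O 1.52,
P/S 1.8 Å) fill gaps for geometry metrics, while energies require explicit
parameters and fail loudly otherwise.

* **RMSD** — Kabsch superposition via SVD, with the determinant correction
  against improper rotations; validated against a brute-force rotation
  search to 10⁻⁶ Å.
* **Helix tilt** — principal axis of the Cα trace versus the membrane
  normal, folded into [0°, 90°].  The Cα coordinates are smoothed with a
  4-residue moving average first: the ~3.6-residue helical wobble otherwise
  biases the principal axis of a short helix by 1–2°.
* **Membrane thickness** — mean upper- minus mean lower-leaflet phosphate
  z, leaflets split by sign about the phosphate midplane; per frame.
* **Pore profile** — largest-sphere radius per z-slice,
  r(z) = max over in-plane (x,y) of min_i(|p − a_i| − R_i), maximised by
  Nelder-Mead seeded from the previous slice centre (with a fallback seed
  on the nominal axis and a bound on how far the maximiser may wander).
  Slices classify as sub_water (< 1.15 Å), intermediate, or open (> 2.3 Å)
  — the water-passage thresholds.  The axis defaults to the selection
  centroid; pass `axis_xy` explicitly for off-centre assemblies.  Matches
  dense stochastic sampling oracles within 0.1 Å on cylinder/cone/hourglass
  fixtures.
* **Solvent density** — water count per z-bin inside an axial cylinder,
  converted to nm⁻³; bulk calibrated from bins outside the membrane span
  (phosphate z-range by default).  `hydrated` overall iff every in-membrane
  bin is ≥ 0.2× bulk (configurable); a dewetted vapor lock drops to ~0.
* **Lipid contacts** — heavy-atom pairs within 4.0 Å (configurable,
  reported), summed per protein residue, averaged over frames.  The
  two-condition difference is reported three ways: absolute, per-residue
  relative (C_t − C_r)/max(C_r, 1) with zero-reference rows flagged, and
  normalised to the panel's maximum reference count — the two plausible
  normalisations of a "relative contact difference".
* **Order parameters** — S_CD = ⟨(3cos²θ − 1)/2⟩ for each chain carbon's
  C–H bonds versus the normal, averaged over hydrogens, lipids and frames;
  carbons without resolvable hydrogens are omitted with a warning.
  Closed-form anchors: vertical all-trans chains give exactly −0.5; chains
  tilted by t with azimuthally distributed C–H give (3·sin²t/2 − 1)/2, so
  horizontal chains give +0.25 and |S_CD| always shrinks on tension-style
  reorientation.
* **Pocket SASA** — Shrake–Rupley with a deterministic golden-spiral point
  set (960 points/atom, probe 1.4 Å); all atoms occlude, area accumulates
  over the pocket residues only.  The pocket residue set is a required user
  input — there is no universal definition of a pocket surface.
* **Pairwise energies** — E_LJ = Σ 4ε_ij[(σ_ij/r)¹² − (σ_ij/r)⁶] with
  Lorentz–Berthelot combining and E_C = f·q_iq_j/r with
  f = e²/4πε₀ = 138.935458 kJ·mol⁻¹·nm, over a plain 12 Å cutoff (no
  force-switching — reproducing a specific simulation engine's switching
  scheme is out of scope and matters only at the few-percent level for the
  pocket-scale groups analysed here); mean ± sd over the chosen frame
  window.

## 4. Toy-system generator

`build_toy_structure` emits pseudo-atoms whose ground truth is exact by
construction: leaflet phosphates at z = ±thickness/2; acyl pseudo-chains of
8 carbons with explicit hydrogen pairs perpendicular to the chain axis,
chain azimuths golden-angle-distributed so tilted chains sample azimuth
uniformly; pore-lining sphere rings (36/ring, 0.5 Å z-spacing) whose centres
sit at free_radius + vdW from the axis, realising cylinder/cone/hourglass
free-radius profiles; an ideal α-helix Cα trace (2.3 Å radius, 1.5 Å rise,
100°/residue) rotated by the requested tilt; and seeded uniform waters in
the pore and optional bulk slabs.  Components are ordered so residue ids
increase monotonically through the file (PDB readers interpret a resid drop
as 10000-overflow).  What the toys do **not** emulate: thermal disorder,
realistic lipid conformations, protein side chains, periodic boundary
effects.  Passing geometry tests therefore certifies the *metric
implementations*, not force-field realism — which is exactly their job.

## 5. Pipeline & reporting

One YAML config with per-arm sections; each arm writes CSV/JSON artifacts
plus a manifest with SHA-256 hashes (fixed seed ⇒ byte-identical outputs).
Arm failures are recorded and isolated.  The report merges on residue
number: spin-label comparison classes (residue parsed from the label), HDX
residue classes from the region map, MD summaries as per-task means.
Agreement is flagged `concordant-<class>`; a residue called deprotected by
one arm and protected by the other is flagged a conflict, never resolved —
the two observables (accessibility vs hydrogen bonding + accessibility) can
genuinely diverge.  Residues absent from every arm never appear.

## 6. Problem sizes and limitations

The test suite and acceptance script use 26-trace panels (1024-point
traces), 123-peptide two-state HDX datasets with 200-replicate-experiment
null calibrations, and toy systems of ~3–5 k atoms — sizes chosen so the
full suite completes in well under a minute of CPU per arm while every
statistical claim still has adequate resolution.  Known limitations:
single-effective-line ESEEM (no quadrupole/combination structure, no
absolute water-count calibration); uniform intrinsic HDX rates and no EX1
analysis; pore search assumes a roughly z-aligned channel; energies use
plain cutoffs and no periodic images.
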