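# Methods

## Plan and dose model

Plans are ordered control-point sequences per beam: two 60-leaf banks, X/Y
jaw pairs, and a fractional MU weight per control point (weights sum to 1
per beam; the control-point model is agnostic to step-and-shoot vs
sliding-window semantics — a control point is simply one weighted aperture
instant). All geometry is expressed in cm at the isocenter plane (IEC
61217: leaves travel along X, stack along Y), dose in Gy, and these
conventions are enforced once at the IO boundary. Voxel grids are
node-centred (`world = origin + index·spacing`) with half-open voxel
membership for masks, which makes volumes exact multiples of the voxel
volume. The JSON plan schema is canonical; DICOM-RT Plan/Dose readers are
adapters that normalize into it (mm→cm, cumulative meterset → per-interval
fractional MU). DICOM-RT Structure Sets are not imported; masks travel as
NRRD.

## Aperture geometry and complexity

The open aperture of a control point is the union of per-leaf-pair
rectangles clipped to the jaw rectangle. A leaf-pair gap narrower than
0.05 cm is treated as closed (dosimetric leaf-gap noise would otherwise
make EAM unstable), and pairs outside the Y-jaw window are excluded. Area
and perimeter are computed exactly by a row sweep; edges shared between
vertically adjacent rectangles are interior, jaw-cut edges count as real
field boundary (this is precisely why locking the jaws onto a sub-window
reduces EAM). Disjoint components are summed into a single A and P before
forming `EAM = P²/(4πA)`; the per-aperture definition does not distinguish
components, and this totals convention is the recorded choice.

`EAM_plan` is the MU-weighted mean over all apertures with positive MU and
nonzero area; zero-MU control points and empty apertures are
dose-irrelevant and excluded. Jaw-locked plans additionally report per
segment (cervical/thoracic window) aggregates.

For MCS, the qualitative definitions of AAV and LSV are fixed as:

* `AAV(cp) = Σ (b_i − a_i)⁺ / Σ max_beam gap_i` over leaf pairs whose band
  intersects the Y-jaw window (the same row set the aperture uses), with
  the denominator the per-pair maximum gap attained anywhere in the beam's
  sequence. Raw leaf gaps are used, not X-jaw-clipped gaps.
* `LSV` is the product over the two banks of
  `Σ_{n<N} (pos_max − |pos_n − pos_{n+1}|) / ((N−1)·pos_max)` with
  `pos_max = max − min` of the bank's in-jaw positions, defined as 1 when
  the bank is perfectly aligned (`pos_max = 0`) or has a single in-jaw pair.

Both lie in [0, 1]; MCS averages adjacent control-point intervals
(`(X_{i-1}+X_i)/2`, the first point pairing with itself so ΣMU is
conserved) and pools beams MU-weighted. MU-weighted pooling (rather than
unweighted beam averaging) was chosen for consistency with the plan EAM;
the alternative changes plan values only through beam-weight imbalance.

## DVH and dosimetric indices

DVHs are exact voxel-counting histograms at a fixed 0.05 Gy bin width; each
bin's representative dose is the mean voxel dose within the bin, so the
DVH mean equals the voxel mean exactly (and EUD with a = 1 reproduces MLD
exactly). D₂%/D₉₈% interpolate the cumulative curve linearly — the
treatment-planning convention — rather than taking raw voxel percentiles;
at 0.05 Gy bins the two differ by at most half a bin.

`CI = V_RI/V_PTV` measures V_RI over the whole grid, the literal ratio
definition; it can exceed 1 when the prescription isodose spills outside
the target. `GM` is computed as the maximum Euclidean distance from any
voxel on the 50%-prescription isodose surface to the target centroid,
minus the equivalent-sphere radius `R_PTV = (3V/4π)^{1/3}`. The
radial-from-centroid reading is the one that makes the defining
subtraction meaningful and reproduces the closed-form sphere case
(isodose r = 5, target r = 3 → GM = 2) and the coincident-surface limit
(GM → 0); surfaces are extracted as face-connected boundary voxels.

## Radiobiology

`EUD = (Σ v_i D_i^a)^{1/a}` on physical DVH doses — no EQD2/fractionation
correction, matching the plain logistic formulation used here. For a < 0,
zero-dose bins are floored at ε = 0.01 Gy (configurable); without a floor
any empty bin collapses the generalized mean to zero. TCP and NTCP use the
logistic form with exponent `4·γ50`. Shipped parameters: esophageal tumor
TCD50 = 49.09 Gy, γ50 = 2.16, a = −8; lung TD50 = 34 Gy, γ50 = 0.9, a = 3;
cord TD50 = 68.6 Gy, γ50 = 1.9, a = 13. TCP is reported for both PTV and
CTV (the generator carves a CTV as a one-voxel erosion of the PTV).

## γ analysis

Criteria default to 3% of the global reference maximum, 3 mm, and a 10%
low-dose threshold; points below threshold are NaN and never enter the
passing-rate denominator. The evaluated distribution is resampled once
onto a global fine lattice whose step divides the stored spacing and is
≤ dist_tol/10, so the stored samples are a sub-lattice — identical
distributions therefore score γ ≡ 0 exactly. Each reference point searches
a window of radius 2·dist_tol on that lattice; γ beyond the window is
represented by the boundary value, which only matters above γ ≈ 2. The
729-chamber array is emulated as pure 10-mm-pitch decimation, with no
chamber volume averaging. Verification planes are composed at gantry 0
and 5 cm depth from the plan's own fluence through the forward model's
penumbra/scatter/attenuation chain.

## Synthetic paired cohort

The generator's defaults are the study conditions: 40 patients, 50 Gy in
25 fractions, paired arms sharing one anatomy per patient, every artifact
a pure function of (spec, seed).

**Anatomy.** A 0.5-cm grid over 35×25×30 cm. The target is an elongated
tube (length drawn 20–24 cm) blending from a wide, flat
cervical-supraclavicular cross-section (half-widths ~3.5–5 × 1.5–2 cm)
into a tighter thoracic tube, with the thoracic inlet at the isocenter
plane z = 0. Two ellipsoidal lungs flank the target caudal to the inlet;
a 0.55-cm-radius cord runs posteriorly. Patient-to-patient jitter on all
semi-axes provides the between-subject variance the Wilcoxon analysis
needs.

**Plans.** Beams get conformal per-row openings (projected target extent
+0.6 cm margin; margin rows extend past the target ends so the field-edge
penumbra falls outside the target). Modulation draws per control point:
half-normal edge retractions (σ = 0.7 cm for EF, uncorrelated across rows;
σ = 0.25 cm for SJL, smoothed across rows) and occasional row collapse to
a narrow notch (probability 0.12 EF / 0.03 SJL) — the extended field is
jagged and notched, the jaw-locked windows smooth, which is the mechanism
under test, encoded as priors. EF uses 10 control points per beam, SJL 6.
Posterior beams (traversing the cord first) carry reduced MU, as planners
weight them.

**Dose.** Per beam, the MU-weighted fluence (open = 1, leaf-shielded
inside the jaws = 2% MLC transmission) is blurred with a σ = 0.4 cm
penumbra kernel, projected along the gantry direction with exponential
attenuation (μ = 0.055 cm⁻¹) inside an elliptical body contour, and
summed; a wide 3-D scatter kernel (σ = 3 cm, 10% amplitude) spreads the
summed dose, creating the low-dose bath. Jaw-locked segments are feathered
with complementary linear fluence ramps across the 2-cm overlap, inset
0.5 cm from the window edges so the jaw penumbra acts on already-zero
fluence; the ramps then sum to exactly 1 through the blur. Two
optimizer-emulation steps replace what inverse planning would do: each
segment is scaled so its near-junction target dose matches the
prescription and the slice-mean profile across the overlap is pulled
(≤ ±10%) onto the line joining its neighbourhood; extended-field plans get
the analogous longitudinal flattening toward their profile median. Every
plan is finally renormalized so target D₉₅% = 95% of the prescription,
which makes V₉₅% ≥ 95% coverage true by construction.

**What the generator does *not* emulate.** No inverse optimization beyond
the longitudinal corrections above (so transverse inhomogeneity in the
extended-field arm is exaggerated: D₂% ≈ 63 Gy rather than ~52 Gy, and CI
and HI differences between arms come out significant where a clinical
cohort found none); no tongue-and-groove or interleaf transmission beyond
the uniform 2% factor; no heterogeneity, build-up, or inverse-square; no
respiratory motion or imaging. Cord sparing via transverse modulation is
not modelled, so the jaw-locked arm's butterfly beams give it a *higher*
cord D_max than the extended field — the opposite of an optimized clinical
plan — and target TCP follows the extended arm's hot spots upward. Passing
cohort tests therefore demonstrates the analysis pipeline and the
geometric mechanism (window confinement + feathering), not dose-engine
fidelity; absolute metric magnitudes are scaled-down caricatures, and only
the paired orderings of complexity and lung metrics are meaningful.

## Statistics

Zero differences are dropped before ranking (the classical treatment),
tied magnitudes get midranks. For n ≤ 25 the two-tailed p is exact:
doubling midranks makes them integers, and the permutation distribution of
the positive-rank sum is built by generating-function convolution, so ties
cost nothing; beyond 25 a normal approximation with tie and continuity
corrections is used (the two agree within 0.01 at the crossover sizes).
Raw p-values are reported with no multiplicity correction; significance is
flagged at both 0.01 (primary) and 0.05 (secondary) so the reader can
apply either threshold.

## Numerical choices

* Aperture closure tolerance 0.05 cm; aperture row adjacency at 1e-9;
  exact perimeter by row sweep (rasterization and polygon-union oracles in
  the test suite).
* DVH bin width 0.05 Gy, fixed for reproducibility.
* EUD zero-dose floor 0.01 Gy for negative exponents.
* γ fine-lattice step ≤ dist_tol/10 and dividing the grid spacing; search
  radius 2·dist_tol; boundary passes (γ = 1) count as passing with a 1e-9
  guard.
* Wilcoxon exact/normal crossover at n = 25.
* Cohort problem sizes — a 0.5-cm grid, 6–10 control points per beam and a
  40-patient default — were chosen as the smallest sizes at which the
  paired contrasts and junction behaviour are stable and well-resolved.
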