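# Methods

## Volumetry

Cells in suspension, embedded sparsely in agarose, are close to ellipsoidal,
so the volumetry stage treats segmentation as a per-channel global problem
with no touching-cell splitting (watershed is out of scope by design).

**Segmentation.** Each channel is thresholded globally (3D Otsu by default,
with an optional absolute floor for channels whose histogram is dominated by
background), hole-filled slice-wise, closed with a 3×3×3 structuring element
and hole-filled again in 3D, then labelled by 26-connectivity connected
components. The binary volume is padded (edge mode) around the closing so
that the erosion half of the closing cannot shave voxels off objects at the
stack faces — otherwise an object truncated by the field of view would escape
the border-exclusion rule. Objects below a minimum volume (default 0.05 pL)
are removed as debris; objects touching the stack border are removed when
border exclusion is on (default), since a truncated cell under-reports its
volume. Volumes are voxel counts times the voxel volume, with no sub-voxel
surface correction; voxel indices are 0-based and a voxel belongs to a region
if its centre lies inside the analytic surface. At lateral voxel sizes
≤ 0.25 µm this voxelization error stays within 3 % for cell-sized objects,
which is the recovery bound the tests enforce on zero-noise phantoms.

**Cross-channel matching.** A cell is a Calcein object containing exactly one
Hoechst-object centroid; the DiI object is found by containment of the
Calcein centroid. Nuclei with no enclosing Calcein object are orphans
(reported, excluded); Calcein objects with two or more nuclei are flagged as
dividing candidates and excluded from the statistics rather than split.

**Compartments.** The three markers nest: Hoechst marks the nucleus, Calcein
the viable cytoplasm including the nuclear region, and DiI the membrane plus
near-membrane cytoplasm, so the filled DiI object is the whole cell. Hence
nuclei = V(Hoechst), cytosol = V(Calcein) − V(Hoechst), membrane-outer
cytoplasm = V(DiI) − V(Calcein), and the parts sum to V(DiI) exactly. A
record violating V(DiI) ≥ V(Calcein) ≥ V(Hoechst) is a hard error, not
clamped: negative compartments indicate segmentation failure and should
surface, not be absorbed into statistics.

**Dividing/non-dividing split.** DNA replication roughly doubles nuclear
volume while cells maintain their nuclear-to-cell ratio, so the Hoechst axis
carries the split. Cells below the 75th Hoechst percentile seed the
non-dividing (ND) population; cells above `cutoff_factor` (default 1.5, the
midpoint between the 1× and 2× modes) times the ND median are labelled
dividing (D), and the median/label step is iterated once. Both constants are
exposed. The rule is sharp for hoechst CVs up to ~0.2 and degrades as the two
lognormal modes overlap (at CV 0.25 it overcalls D by a few percentage
points); the D/ND volume-ratio statistic is far more robust to that
contamination than the D fraction itself, because misclassified cells sit
near the cutoff. Ordinary least squares supplies the Calcein-on-Hoechst fit
statistics reported for the whole table and the ND subset. Below 10 cells no
split is attempted (all ND, with a warning).

## Concentrations

The whole-cell chain per protein and cell line: standard lanes of known
recombinant mass give an ordinary-least-squares line of intensity on mass
(free intercept by default — forcing through the origin is a flag, not the
default, since blot backgrounds are rarely zero). Sample lanes are inverted
through the line (sub-background intensities clamp to 0 ng with a warning;
masses outside the standards' range carry an extrapolation flag), divided by
the total protein loaded, averaged over replicates, scaled by the total
protein content of one cell (BCA + cell count), divided by the molecular
weight and converted with Avogadro's number and the resting cell volume. The
resting volume is the *non-dividing DiI* (whole-cell) mean — the one choice
that makes the converted concentrations match the printed whole-cell values —
and molecular weights are configuration, not constants, since the proteins
involved (notably truncated APC, quantified as the single "APC" quantity with
an `apc_truncated` flag) vary by cell line. The SEM over replicate lanes
propagates linearly through the purely multiplicative remainder of the chain.
All molecule↔molarity conversions go through one pair of functions
(`molecules_to_nM` / `nM_to_molecules`, N_A = 6.02214×10²³) to keep units
from drifting; every concentration record checks its own
molecules-vs-nM consistency to 1 part in 10⁶ on construction.

Sub-cellular fractions follow the same arithmetic per fraction, scaling each
loaded aliquot back to the full fraction volume and dividing by the number of
cells fractionated; recovery is the summed compartment concentration as a
percentage of the whole-cell value, warned below 90 % (fractionation loss).
Active-epitope blots are mapped onto the total-protein mass scale by the
ratio of standard-curve slopes fitted on identical standard sets.

## The Wnt model and its calibration

The model is the complete Lee (2003) reaction network — 15 species: the
Dishevelled pair, the axin/APC/GSK3β degradation-complex cycle with its
phosphorylated forms, free and phosphorylated β-catenin, and the TCF and APC
sinks — integrated *without* the rapid-equilibrium reduction of the original
paper, because there is no guarantee the reduction's assumptions carry over
to parameter regimes far from Xenopus egg extract. Rate constants, synthesis
fluxes (v12 for β-catenin, v14 for axin) and the reference totals live in
`data/lee2003.yaml`, transcribed from the Lee 2003 reference state (units nM,
min). The four fast binding steps (axin+APC, β-catenin+phospho-complex,
β-catenin+TCF, β-catenin+APC) are specified there only by dissociation
constants; the unreduced model needs explicit on/off rates, so a common
forward rate (default 100 /nM·min, the diffusion-limited scale) is applied
with each reverse rate equal to forward × K. Steady-state results change by
~1 % as this forward rate varies over 100–10 000 /nM·min; well below the
diffusion limit the effective K of the β-catenin binding step inflates by
k₉/k_on and retention rises, which is why the default sits at the diffusion
limit and the value is versioned rather than hard-coded. Wnt activity W
multiplies only the Dishevelled activation step, and W = 0 throughout the
calibration.

**Two-phase calibration.** Measured totals enter as free species (the choice
is immaterial — see pathway independence). Phase A integrates the *closed*
system (v12, v14 and the three degradation steps off) to steady state,
redistributing each conserved total among its complexes; note the closed
system still runs the irreversible phosphorylation/release cycle, so β-catenin
accumulates as free phospho-β-catenin — the β-catenin *moiety* is exactly
conserved. Phase B continues from that state with all fluxes on. A model that
is steady-state calibrated for the given totals retains each protein's total
through Phase B; the I∶SS ratio per protein quantifies the failure to do so.
Every calibration also runs the open system directly from the initial state
and flags `pathway_independent` when both open steady states agree to 0.1 %
relative on all six protein totals — they do, for all parameterizations
tested, confirming the redistribution path does not matter. APC, GSK3β, Dsh
and TCF have no synthesis/degradation fluxes, so their totals are invariants
even in the open system (retention exactly 1). Dsh and TCF totals are not
normally measured; mammalian runs default them to the Xenopus reference
values (100 and 15 nM) and reports carry a `dsh_tcf_assumed` flag. Truncated
APC is fed to the model as APC — the network has a single APC species — which
is a caveat, not a claim about ΔAPC function.

**Steady-state numerics.** The system is stiff (binding rates up to ~10⁶/min
against an axin synthesis flux of 8×10⁻⁵ nM/min). Integration runs over
geometrically expanding time windows (LSODA, rtol 10⁻⁸, atol 10⁻¹¹ nM, BDF
retry on the rare LSODA stall, max step capped per window because scipy's
step-size control can grow the step without bound once the trajectory sits on
the steady state). When the derivative norm falls below 10⁻⁶ nM/min the state
is polished by Levenberg–Marquardt root-finding on the derivative function —
LM tolerates the Jacobian rank deficiency the conservation laws create — and
the polished root is accepted only if it stays non-negative, preserves the
mode's conserved totals to 10⁻⁶ relative, and reaches the convergence
threshold of 10⁻¹⁰ nM/min on max |dẋ|; otherwise integration continues, up to
t_max = 10⁶ min (axin relaxes on a ~6 min timescale but β-catenin rebuild
after Phase A takes ~10⁴–10⁵ min at mammalian concentrations).
Non-convergence is returned as a flag, never silently. Halving the threshold
moves reported retentions by < 0.1 % (tested). Negative solver excursions
beyond −10⁻⁹ nM are an error; smaller ones are clamped to zero.

Reported per-protein totals sum the free species and every complex containing
the protein, including the phosphorylated forms — membership is checked in
the tests against an oracle that parses the species names independently.

## Synthetic data

The generators encode the study conditions rather than convenient ones:
the population generator defaults to n = 469 cells with dividing fraction
0.085 and a joint D/ND scale factor of 2.0; non-dividing marker means default
to the pooled five-line values (1.51, 0.53, 1.89 pL for Calcein, Hoechst,
DiI); the lognormal size CV defaults to 0.25 and the per-cell marker-ratio
relative SD to 0.2, matching the spread of the measured volume tables (the
Hoechst CV sets the size axis; the cytoplasmic markers inherit it plus ratio
noise, reproducing their larger marginal CVs). Volumes are lognormal because
they are positive and right-skewed. Phantoms are ellipsoids rendered by the
voxel-centre rule with analytic ground-truth volumes; the DiI shell has
finite thickness (default 1 µm) because the membrane stain marks
near-membrane cytoplasm, not the bilayer. Voxel dimensions default to
0.2×0.2×0.5 µm (a typical confocal setting; the acquisitions being emulated
do not state theirs). Blot simulation is a straight line plus additive
Gaussian noise. What the generators deliberately omit: optics beyond an
optional Gaussian blur (no PSF model, photobleaching or spectral
bleed-through), touching cells, saturating or nonlinear blot response, and
correlated lane noise. Passing recovery tests on these phantoms therefore
validates the measurement arithmetic and the segmentation/matching logic,
not robustness to real microscope or blot artefacts.

## Problem sizes

The test suite and the acceptance script run at the sizes the analyses call
for: population tables of ~300–500 cells, phantom stacks of ~10⁵–10⁶ voxels
(one or two cells per stack), 200-replicate Monte-Carlo checks for the
blot estimators, and all six model parameterizations (five mammalian lines
plus Xenopus), each a 15-species stiff ODE solve that converges in well under
a second.

## Known limitations

- The ND/D cutoff rule stands in for an unpublished selection protocol; its
  constants are exposed and its breakdown regime (size CV ≳ 0.25) documented
  above.
- Whether the whole-cell "Total" statistics of the emulated tables include
  partially imaged or orphaned cells is unknowable from the published
  material; this implementation excludes them.
- The Xenopus parameterization retains ~101 % of initial β-catenin rather
  than the ~97 % sometimes quoted: with the Lee reference constants the open
  steady state reproduces the 35 nM measured total by construction (v12 and
  k13 were fitted to it), so retention is ~100 % up to the binding-rate
  choice; no accounting variant of the total yields 97 %.
- ΔAPC-as-APC and the assumed Dsh/TCF totals (above) are the two untestable
  modelling choices in the mammalian runs; the SW480APC retention sits within
  ~2 percentage points of the 75 % mark and is the value most sensitive to
  them.
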