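# Methods

This note documents the models implemented in `corona_thermo`, the
conventions and defaults they rely on, what the synthetic-data generators do
and do not emulate, and the numerical choices made where the design was
genuinely open.

## System and scope

The package targets the binding of human serum albumin (HSA, 585 residues,
single tryptophan W214) to nanomicelles self-assembled from an amphiphilic
dendrimer (AD): two C18 tails and a PAMAM dendron head, aggregation number
N_agg = 17 monomers per micelle, CMC in the 3.2–5.7 µM range. Four
independent experimental windows onto the same binding event are analysed:
tryptophan-quenching fluorescence, isothermal titration calorimetry, far-UV
circular dichroism, and molecular-dynamics trajectories of the
six-protein corona complex. The package implements the *analysis* of each
window; instrument control, force-field parameterization and the MD engine
itself are out of scope.

## Fluorescence quenching

The Stern–Volmer fit is ordinary least squares of F₀/F on quencher
concentration; the intercept is reported, not constrained to 1, so a
departure from unity is visible as a diagnostic. F₀ is taken from the
zero-quencher row when the table contains one, otherwise supplied
explicitly, because in practice it is measured in a separate scan. No
inner-filter correction is applied.

The modified Stern–Volmer fit regresses log₁₀((F₀−F)/F) on
log₁₀([AD] − (F₀−F)[HSA]/F₀) — the second term is the free-titrant
concentration under the single-site assumption — and reports
K_D = 10^(−intercept). The slope is left free (expected ≈ 1) rather than
fixed; base-10 logarithms follow the convention of the double-log plot.
Points with F ≥ F₀ or a non-positive free-titrant term cannot enter the
logarithms and are excluded with a warning and a count. Because K_D comes
from an extrapolated intercept, single noisy replicates scatter noticeably
(tens of percent); recovery statements are therefore made on medians over
replicates.

Excitation–emission peak location masks the first-order Rayleigh band
|λ_em − λ_ex| ≤ 10 nm (configurable) and returns local maxima exceeding
mean + 3 SD of the unmasked cells, sorted by intensity.

## ITC with micelle mass conservation

Above the CMC the amphiphile partitions by mass conservation,
[AD_tot] = [AD_mon] + N_agg·[AD_mic]: the monomer pool is pinned at the CMC
and the excess is micellar. The CMC default is 4.5 µM, the midpoint of the
measured 3.2–5.7 µM range, and is configurable because the exact value
entering the transform is not pinned down by the source characterization.
The syringe concentration (900 µM ≫ CMC) is converted to a micelle
concentration once; monomer re-equilibration in the cell is ignored since
the titrant stays above the CMC throughout.

The micelle is the macromolecular species carrying n independent identical
protein sites (default 6), and ΔH is per mole of protein bound. This
reproduces both the 1:1 site-level "one set of sites" algebra and the ~6:1
protein:micelle stoichiometry. Per injection i of volume dV into the
overflow (perfusion) cell of volume V₀ = 208 µL, previously present species
are diluted by (1 − dV/V₀) and the fresh aliquot contributes dV·c_syr/V₀;
bound complex follows the mass-action quadratic
[HS] = ((H+S+K_d) − √((H+S+K_d)² − 4HS))/2, the cell heat content is
Q_i = [HS]_i·ΔH·V₀, and the measured heat is
δQ_i = Q_i − Q_{i−1} + (dV/V₀)(Q_i+Q_{i−1})/2 (displaced-volume
correction). The overflow convention is the de-facto standard for this
instrument class.

Fitting is nonlinear least squares over (log₁₀K_d, ΔH, n), multi-started
from 8 log-spaced K_d values spanning 1e-9–1e-3 M; the best SSE wins.
n can be fixed, the first injection optionally discarded (off by default),
and a constant heat offset optionally floated — control-heat subtraction is
assumed done upstream. Standard errors come from the Gauss–Newton
covariance scaled by reduced χ². ΔG = RT·ln K_d (standard state 1 M,
R = 1.9872×10⁻³ kcal mol⁻¹ K⁻¹) and −TΔS = ΔG − ΔH close to 1e-9 by
construction. The default analysis temperature is 298.15 K (25 °C): with
K_d = 13.4 µM this gives ΔG = −6.648 kcal/mol, consistent to two decimals
with the reference decomposition (−6.65, −4.02, −2.63 kcal/mol).

At this design the Wiseman c-parameter is ≈ 2, so the isotherm is a gentle
sigmoid and K_d is the most weakly identified parameter; additive
integration noise of 0.1 µcal is enough to skew single-replicate estimates
low by ~10 % in the median even when the optimizer provably reaches the
global SSE minimum. Recovery experiments therefore quote medians over 100
replicates at 1 % multiplicative noise.

## Circular dichroism

MRE normalization divides observed mdeg at 208 nm (linear interpolation
between bracketing samples, no smoothing) by 10·C_p·n·l. The helicity map
is linear between the pure-helix (−33,000 deg cm² dmol⁻¹) and coil/β
(−4,000) references at 208 nm; out-of-range results are clamped to
[0, 100] with a flag rather than raised, because noisy spectra legitimately
overshoot. The default path length is 0.1 cm — the value tied to the
helicity formula — although instrument records for such measurements
sometimes carry 0.2 cm; the parameter is explicit in `CDParams` and every
call logs the value used.

Melting curves at 222 nm are fitted with the two-state sigmoid
θ(T) = θ_F + (θ_U − θ_F)/(1 + exp((T_M − T)/w)) with
temperature-independent baselines (sloped baselines behind a flag). T_M is
initialized at the finite-difference maximum of |dθ/dT| and the baselines
from the first/last 10 % of points; a derivative maximal at the scan edge
raises "no transition" instead of returning a boundary artefact.

## Synthetic-data generators

Each generator is the exact forward model of its paired analysis, so at
zero noise every fit inverts its generator to ≤ 1e-6 relative error (tested
for quenching, ITC, CD helicity and melting). Defaults are the reference
experimental conditions: quencher ladder 2–20 µM with [HSA] = 2 µM,
the 208 µL / 30 µM / 900 µM / 19×2 µL ITC design, CD at C_p = 2 µM,
n = 585, l = 0.1 cm on a 200–260 nm grid, melts sampled every 1 °C over
25–95 °C. Noise is 1 % multiplicative Gaussian (fluorescence error scales
with signal); the ITC generator additionally offers a 0.1 µcal additive
baseline term mimicking integration noise. F₀ is fixed at 100 a.u. — an
arbitrary scale, since both fits are scale-invariant.

The CD bases are synthetic Gaussians (negative bands at 208/222 nm for
helix, a broad shallow coil feature) calibrated *only* at 208 nm, where the
helicity formula reads the spectrum; band shapes elsewhere are cosmetic and
not suitable for multivariate deconvolution.

The toy complex is bead-scale, not atomistic: a 17-amphiphile micelle with
tail/linker/head beads at 14/24/33 Å from the centre (R_g ≈ 25 Å),
cationic heads on a quasi-uniform (golden-spiral) lattice so planted
contacts can only bridge to their own head, and six ~50-bead protein chains
on a 37.6–43.4 Å shell whose floor sits 4.6 Å above the heads — close
enough to register incidental contacts at the 6.5 Å cutoff (emulating
protein interpenetration into the polar-head region) but outside the 4 Å
salt-bridge criterion, so bridge occupancies are exactly the planted ones.
Planted pairs place an anionic protein bead 3 Å from its head in
⌈occupancy·n_frames⌉ frames and 12 Å away otherwise. The trajectory
operators depend only on coordinates and labels, so bead scale suffices for
validating them; passing these tests says nothing about force-field
accuracy or sampling of real trajectories, only that the measurement
operators are correct.

Backbone fixtures for secondary structure are built from ideal internal
coordinates (NeRF chaining): an α-helix at φ=−57°, ψ=−47°, an extended
chain at φ=ψ=180°, and a parallel two-strand pair displaced 4.8 Å along
the carbonyl direction where the inter-strand H-bond ladder forms.

## Trajectory analysis conventions

* Distances in Å; residue indices 1-based (PDB convention); COM and R_g
  mass-weighted by default with a geometric option.
* Contact: minimum residue–micelle atom distance < 6.5 Å in a frame;
  frequencies are per (chain, residue) with the full min-distance trace
  retained.
* Salt bridge: minimum charged-atom distance ≤ 4.0 Å — the field-standard
  N–O criterion, supplied here because only the 50 % persistence threshold
  is pinned by the reference analysis; both are configurable. The analysis
  window (which frames enter) is the caller's choice via the trajectory
  slice.
* Gyration-tensor semi-axes default to a_i = √(5λ_i) (uniform solid
  ellipsoid). The literal √λ convention is available behind a flag, but the
  √5 scaling is the one consistent with the published complex values: the
  printed semi-axes (81.8, 80.2, 71.4 Å) close with the printed
  R_g = 60.01 Å through √((a²+b²+c²)/5) within 1 %.
* RDF: histogram of target-atom distances from the per-frame reference COM,
  frame-averaged; `g` mode normalizes by shell volume and a number density
  (supplied, or estimated from a sphere of radius r_max), `counts` mode
  returns raw shell counts for visual parity with unnormalized published
  distributions.
* SASA: in-package Shrake–Rupley with 960 golden-spiral points per atom
  (configurable) and probe 1.4 Å; radii from an element lookup or a
  per-atom array for bead models. Verified against the two-sphere
  spherical-cap closed form (2 %), rotation invariance (0.5 %), and
  biotite's independent implementation (2 %).
* Secondary structure: Kabsch–Sander H-bond energies
  E = 0.084·332·(1/r_ON + 1/r_CH − 1/r_OH − 1/r_CN) kcal/mol with the amide
  H rebuilt 1 Å from N anti-parallel to the preceding C=O; bond if
  E < −0.5 kcal/mol. Four classes only (H from paired i→i+4 bonds, E from
  parallel/antiparallel bridge rules, T from i→i+3 turns, C otherwise) —
  the fractions reported for this system need no finer classes. Residues
  with missing backbone atoms are labelled C with a warning.

## Problem sizes

Recovery experiments use 100 replicates; the toy complex defaults to 6
proteins × 50 beads and 20 frames; brute-force oracle comparisons run on
50–60-atom frames; uniform-sphere/ellipsoid moment checks use 10–20 k
points. These sizes make every statistical claim in the test suite
reproducible on a laptop in minutes.

## Known limitations

* The ITC model is single-site-class only; sequential or multi-site models,
  ΔCp analysis and raw power-trace integration are not implemented.
* Helicity uses the single-wavelength 208 nm calibration; full-spectrum
  secondary-structure deconvolution is out of scope.
* The melting fit reports an apparent T_M; no van 't Hoff enthalpy is
  derived.
* PDB is the only trajectory format (multi-model, text); binary formats
  (DCD/XTC) and mmCIF are not read.
* Electrostatic potentials, ζ-potentials and per-residue energy
  decompositions are not computed; the contact fingerprint is geometric.
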