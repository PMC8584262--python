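# Methods

This note records the models, estimators, conventions and numerical choices
behind each analysis stage, what the synthetic generators do and do not
emulate, and the known limitations.

## Units and constants

Coordinates are in Å, time in ns, temperature in K, moduli in J, surface
pressure and compressibility in mN/m, diffusion in µm²/s, molar free
energies in J/mol.  All conversion factors live in `membramech.units`
(1 J/Å² = 10²³ mN/m; 1 µm²/s = 0.1 Å²/ns; 1 Å²·mN/m = 10⁻²³ J, hence
N_A Å²·mN/m ≈ 6.022 J/mol) and are covered by tests, since unit slips are
the dominant failure mode of this kind of pipeline.  Two temperatures are
deliberately distinct: 303.15 K for trajectory analyses and 295.15 K for
flicker spectroscopy, matching the conditions under which each kind of data
is typically acquired.

## Frames, topology, leaflets

A `FrameSeries` holds orthorhombic periodic frames; all distances use the
minimum-image convention, and triclinic boxes are out of scope.  Per
species, a topology declares headgroup atoms (everything down to and
including the glycerol C2), acyl-chain atoms, the P/C2 reference pair
(sterols use their C3/C2/C1 surrogates), terminal chain carbons, van der
Waals radii and optional masses (absent masses default to 1, which leaves
mass-ratio quantities such as the interdigitation integrand unchanged for
single-species systems).

The lipid *head point* is the P–C2 midpoint, the *tail point* the midpoint
of the terminal carbons; midpoints are computed from minimum-image
displacements so molecules split across a boundary are handled.  Leaflets
are assigned by the sign of head-point z against the midplane of the first
analyzed frame (the mean head z); the midplane is then held fixed, and a
lipid whose head later crosses it is flagged but not reassigned — flip-flop
is rare on the ~10 ns windows this analysis targets, and silently
reassigning would corrupt per-leaflet statistics.

Readers: multi-frame PDB/GRO/XYZ are delegated to MDAnalysis (XYZ boxes are
taken from a `box Lx Ly Lz` comment line and lipids recovered by matching
runs of atom names against the declared topologies).  A documented
plain-text native format (`write_native_frames`) lets the synthetic
generators produce inputs without third-party writers.

## Area per lipid

Head points are projected onto xy and tessellated per leaflet and frame
with scipy's Voronoi on a 3×3 tiling of periodic images; only primary-image
cells are kept.  This reproduces the periodic tessellation exactly — the
cell areas partition the box cross-section to ~1e-12 relative — without a
periodic-tessellation dependency.  Coincident or degenerate seeds are
jittered by 1e-6 Å and retried once.  The system APL is the mean of a
least-squares Gaussian fitted to the pooled cell-area histogram
(Freedman–Diaconis binning); if the fit degenerates (e.g. noise-free
lattices produce a delta-like histogram) the sample mean ± sd is reported
with a warning.  Per-species values are arithmetic means.  Note that
Voronoi cell-area distributions are right-skewed at finite positional
disorder, so the Gaussian mean tracks the mode and can sit a few percent
below the arithmetic mean; both are reported.

## Thickness, diffusion, interdigitation

Thickness is the difference of mean tag-atom z between leaflets, per frame,
reported as mean ± sd over frames in nm.

Diffusion: head-point xy tracks are unwrapped by accumulating minimum-image
steps (valid while per-frame displacements stay below half a box length),
per-leaflet center-of-mass motion is subtracted (the two leaflets can
drift antisymmetrically in MD; whole-system COM removal would leave that
in), and the MSD is averaged over lipids and all time origins.  D is
slope/4 of a straight line on the default 10–50 % lag window — early lags
are ballistic/noise-dominated in real data, late lags have few independent
origins.

Interdigitation: per frame, leaflet mass-density profiles on 100 z-bins
spanning the box; the overlap width is w = ∫4ρ_uρ_l/(ρ_u+ρ_l)² dz, which is
the support length where the profiles coincide and 0 where they are
disjoint.  The z-bin count trades resolution against counting noise at the
~650-lipid scale and is configurable.

## Real-space-fluctuation mechanics

Directors run from head point to tail point; the tilt θ is the angle to the
inward leaflet normal (∓z).  Neighbor pairs come from the same periodic
Voronoi adjacency used for APL.  The splay of a pair is the projected
finite-difference divergence S = (d_j⊥ − d_i⊥)·ê_ij/|r_ij| with d⊥ the
in-plane director components and r_ij the minimum-image head separation.
"Weakly correlated" pairs are selected by a window — head separation within
[5, 12] Å and director angle below 60° — because strongly collective
(peristaltic) pairs violate the independent-fluctuation assumption of the
method; rejection counts are logged so the filter's bite is visible.

PMFs are estimated from histograms (default bin count ~√n/2, capped to
[20, 200]); the fit range is all populated bins within 2 k_BT of the PMF
minimum (at least 5 bins), which restricts the fit to the quadratic basin.
Fits are Poisson-weighted least squares; uncertainties come from the fit
covariance.  The tilt PMF removes the sin θ Jacobian before inversion so
the small-angle form is quadratic.  The splay PMF keeps a linear term as a
symmetry diagnostic; the curvature χ is taken numerically as the monolayer
modulus on a 1-Å² patch (S carries 1/Å, so χ carries J·Å²; this package and
its generators share that normalization, and the tabulated bilayer value is
κ = 2χ).  The `apl` argument of the splay fit is recorded as metadata for
provenance.

Area compressibility follows the thickness-fluctuation route: relative
deviations x = (t₀ − t)/t₀ (t₀ defaults to the series mean) are binned, the
PMF −(2k_BT/a₀) ln p(x) is fitted with K_A x² + C′ over the same
2-k_BT-window rule, and K_A converted from J/Å² to mN/m.  For Gaussian x of
variance σ² this reduces to the closed form K_A = k_BT/(a₀σ²), which the
tests verify.  The quadratic-in-x form is the dimensionally consistent
reading of the method; the result is reported as a whole-membrane value
with the per-leaflet-vs-whole ambiguity flagged in the result's `scope`
field, since the literature has used both conventions.

## Hydrophobic defects

Each leaflet of each frame is rasterized on a grid as close to 0.5 Å as box
divisibility allows.  Atoms are painted from the midplane outward (the
outermost covering atom labels each cell; ties break toward larger vdW
radius, then lower atom index, for determinism), with the disc of the full
vdW radius as footprint.  Cells covered by no atom stay *empty*; they count
in denominators and block probes — counting vacuum as defect would inflate
the curves.  F_exp is the tail-cell fraction of the whole map.

The sphere-probe analysis is a morphological opening of the tail mask with
a periodic disc footprint: centers whose whole neighborhood within the
probe radius is tail survive the erosion, and the defect set is the union
of their probe discs (dilation).  It is implemented with wrap-mode
min/max filters; the tests compare it bit-for-bit against an independent
shift-accumulate implementation and check that the defect fraction never
increases with probe radius.  Radii below the grid spacing degrade to
F_exp with a warning.

## Langmuir isotherms

Isotherm records are sorted by decreasing area with duplicate areas
averaged; fewer than 10 points is an error and non-monotone pressure only a
warning (kinks can be genuine transitions).  APL at a target pressure is
linear interpolation.  Surface elasticity: with smoothing off (the
default), dA/dπ comes from central differences, so analytic records are
differentiated essentially exactly; with smoothing on, a Savitzky–Golay
local polynomial (window 7, order 2 by default) smooths A and supplies the
derivative, which keeps noisy experimental records usable.  Both the
compressibility C_s = −(1/A)dA/dπ and the reciprocal modulus −A dπ/dA are
returned; the modulus (mN/m) is the headline value, matching how such
tables are conventionally printed.  A vanishing derivative at the target
raises a "phase transition plateau" error rather than reporting an infinite
modulus.

Mixing: the ideal reference is the mole-fraction-weighted area on the
merged pressure grid of the components; ΔG_m^ex is the cumulative
trapezoidal integral of (A_mix − A_ideal) from the lift-off pressure π₀
(first point above 0.5 mN/m, configurable — the integral's lower limit is
otherwise undefined on records that start at zero pressure) up to the
target, times N_A with the Å²·mN/m → J/mol conversion.  Replicate
deviations propagate linearly as the summed area deviations times
N_A(π−π₀), a deliberate simple convention.  ΔG_m^ex vanishes identically
for ideal mixtures and is additive over pressure intervals; both are
tested.

## Flicker-noise spectroscopy

Model: a quasi-spherical vesicle with spherical-harmonic amplitude
variances ⟨|u_lm|²⟩ = k_BT/[κ(l−1)(l+2)(l(l+1)+σ̄)] (Milner–Safran), σ̄ the
dimensionless reduced tension.  Two consequences drive the estimators:

- the equatorial angular autocorrelation of u = (r−R)/R is
  ξ̃(γ) = Σ_l (2l+1)/(4π) ⟨|u_l|²⟩ P_l(cos γ) (addition theorem);
- an equatorial Fourier mode m mixes all degrees l ≥ m:
  ⟨|c_m|²⟩ = Σ_{l≥m} |Y_lm(π/2)|² ⟨|u_l|²⟩.

*Contour extraction*: per frame, the center is refined iteratively with an
intensity-weighted least-squares circle through the detected rim (robust to
partial arcs when the initial guess is far off); along each ray the rim is
the radial intensity maximum — fluorescence rims are bright, so peak
detection beats gradient edges here — with 3-point parabolic subpixel
refinement.  Rays whose peak falls below 30 % of the frame maximum, or at
the search limits, are marked missing; frames with >10 % missing rays are
dropped and logged.

*Average-based approach*: the autocorrelation is computed by circular FFT
(pairwise-complete masked products when rays are missing).  Because the
autocorrelation on the uniform angle grid is exactly a cosine series and
each P_l(cos γ) has the exact equatorial cosine expansion
4π/(2l+1)|Y_lm(π/2)|², the Legendre coefficients B_l are obtained by
back-substitution of that triangular system — equivalent to the
orthogonality integral but exact for band-limited data, which matters
because high-mode amplitudes are ~10⁻⁷ of the low-mode ones and naive
quadrature noise swamps them.  Then ⟨|u_l|²⟩ = 4πB_l/(2l+1) and the direct
per-degree model is fitted.

*Statistical approach*: per frame, Fourier coefficients of u; per mode, the
squared amplitudes are histogrammed (binned up to the 98th percentile —
sparse tail bins carry asymmetric log-count noise) and the mode's
mean-square amplitude is the decay constant of a Poisson-weighted
straight-line fit to the log-counts, since the equilibrium distribution of
a mode's power is exponential.  This histogram-based estimate is more
robust than the raw mean to heavy-tailed artifacts (e.g. transient buds);
with fewer than 50 frames, or a degenerate histogram, it falls back to the
raw mean with a warning.  The fit then uses the degree-summed equatorial
model above, truncated at l_max = 30 by default (amplitudes decay as l⁻⁴,
so higher degrees are below realistic noise floors); the truncation degree
is a parameter.

*Rigidity fit*: log-amplitude least squares over modes 3–20 (modes 0–2 are
size/translation/tension-dominated, higher modes pixel-noise-dominated) in
(ln κ, σ̄), which keeps κ positive; errors from the Gauss–Newton
covariance.  No finite-integration-time correction is applied — video
integration over ~150–190 ms damps high modes; the mode window is the
mitigation, and this is a documented limitation for real recordings.

## Synthetic data

Generators are deterministic under a fixed seed and emit exactly the
containers the analyses consume.

- `make_lattice_membrane`: jittered hexagonal leaflets of minimal
  three-atom lipids (P, C2, terminal carbon — the smallest structure that
  exercises every reference-point, leaflet, grid and director rule).  The
  lattice constant realizes the requested APL exactly; P planes sit at
  ±thickness/2 so the generated MT_P-P equals the request; xy positions
  follow a 2D random walk with per-step variance 4DΔt; z jitter and
  director angle jitter are optional.  Defaults follow the bulk
  study conditions (324 lipids per leaflet, 60.7 Å², 3.78 nm, 303.15 K).
  It deliberately has no inter-lipid forces: positions of different lipids
  are independent, so Voronoi-area correlations, collective undulations and
  anomalous subdiffusion of real membranes are *not* emulated, and passing
  recovery tests demonstrates estimator correctness under the estimators'
  own assumptions, not robustness to those real-data features.
- `sample_tilt_splay`: θ rejection-sampled from sin θ·exp(−κ_tilt
  θ²/2k_BT) via a Rayleigh proposal; S Gaussian with variance k_BT/χ,
  χ = κ/2 per the mechanics convention.
- `sample_thickness_series`: Gaussian relative deviations with variance
  k_BT/(a₀K_A).
- `make_isotherm` / `make_mixed_isotherm`: exponential, linear or tabulated
  A(π) with optional Gaussian area noise (monotonicity restored by a
  running minimum); mixtures are the ideal mean plus a deviation δ(π) so
  ΔG_m^ex has a closed form.
- `make_fluctuating_vesicle`: per-frame independent (equilibrium,
  temporally uncorrelated) spherical-harmonic amplitudes up to l_max = 30,
  assembled directly in equatorial Fourier space; optional rendering as a
  bright rim of Gaussian radial cross-section over a dark background with
  Poisson counting noise.  Frame-to-frame correlation of real video, point
  spread anisotropy and photobleaching are not emulated.

## Problem sizes in tests

The test suite and the acceptance script use desk-scale sizes chosen to
keep the full run in tens of seconds while leaving comfortable statistical
margins: 10⁵ tilt/splay samples and 20 seeds for the modulus recoveries,
10⁴ thickness samples, a 200-lipid × 500-frame walk for diffusion, 1200
contour frames × 10 seeds for flicker, 50 random grids for the defect
oracle, and a 648-lipid membrane over 10 frames for the Voronoi
conservation and APL/MT recovery checks.

## Known limitations

- Orthorhombic boxes only; no trajectory alignment beyond the fixed
  z-midplane convention; flip-flop is flagged, never followed.
- The splay modulus normalization absorbs the Å² of S² (see above); when
  comparing against other implementations, check their per-pair area
  convention.
- K_A is reported whole-membrane; halve for a per-leaflet reading.
- The defect probe works on the 2D projected map, not the 3D cavity
  structure; per-defect shape statistics are out of scope.
- Flicker analysis assumes quasi-spherical vesicles and equatorial
  sections; strongly deflated or tubulated vesicles violate the model.
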