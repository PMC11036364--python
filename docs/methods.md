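# Methods

This note documents the models, conventions, numerical choices and known
limitations of `crystalsizer`.

## Template geometry and conventions

The crystal outline is the intersection of six half-planes
{x : nₖ·(x − c) ≤ dₖ} grouped into three parallel pairs.  Pair i has unit
normal n(φᵢ) with φ₁ = θ₁ and φ₂,₃ = θ₁ + rel_angles; the relative angles
are frozen at their crystallographic values during fitting.  For β-LGA,
the printed interior angles (108° between the capping faces at the needle
tip, 126° between capping and prismatic faces) imply normals at ±54° from
the prismatic normal; `CrystalAngles` makes these configurable per
compound and checks the hexagon closure identity
2·108 + 4·126 = 720.

Pixel centres sit at integer (x = column, y = row); angles are measured
counterclockwise in the (x, −y) frame so reported orientations follow the
usual mathematical convention.  This is stated explicitly because image
work mixes both conventions freely.

Two exact parameter symmetries matter when comparing fits:

* **half turn** — θ₁ ↦ θ₁ + 180° with the ± distances swapped describes
  the same hexagon; orientations are therefore only defined modulo 180°.
* **centre gauge** — moving the centre by δ while adding −nᵢ·δ / +nᵢ·δ to
  the paired distances leaves all six face lines unchanged.  The data term
  of the fit is exactly flat along this 2-dof direction; the symmetry
  regularizer (below) anchors it.  `geometry.recenter` and
  `hexfit.template_errors` express a fit in a reference gauge so per-face
  distances are comparable; paired distances d⁺ᵢ + d⁻ᵢ are
  gauge-invariant, which is why the growth analysis uses them.

`width_to_normal_distance` applies the out-of-plane correction for the
prismatic pair: with the crystal resting on its largest {010} face the
{021}/(02-1) faces are tilted symmetrically out of the viewing plane by
half their 3D interfacial angle (78° for β-LGA), so the normal distance is
the projected width times sin(angle/2).  This trigonometric construction
is the package's own reading of the projection geometry and should be
confirmed against an independent 3D habit model before quantitative use on
a new compound.

## Soft rasterisation and the fitting loss

The differentiable mask is the product of six logistic factors
σ(s·(dₖ − nₖ·(x − c))) with sharpness s in 1/px.  The 0.5 level set of
each factor coincides with the face line for any s, so distance estimates
are not biased by the softness; s = 1.5/px (default) spreads the gradient
over ≈ 2 px, which is enough basin width for Adam while keeping
sub-pixel localisation.  Rendering and all gradients are closed-form; the
analytic gradients are verified against central finite differences to
1e-4 relative error in the test suite.

Total loss per frame:

    w_mse · mean((m − t)²) + w_sum · Σ d + w_sym · Σᵢ (d⁺ᵢ − d⁻ᵢ)²
                           + w_temp · Σ (d − d_prev)²

with defaults (1, 1e-6, 1e-6, 1e-5).  The scale rationale: the MSE is
normalised by the full-frame pixel count N, so moving one face line by
1 px changes it by roughly L/N (edge length L ≈ 50 px, N = 65536 gives
≈ 8e-4).  Regularizer weights are chosen two to three orders below that
so they perturb noiseless recovery by far less than 0.5 px, while still
(i) anchoring the centre gauge (any ε > 0 suffices, as the data term is
exactly flat there), (ii) pulling grown-out faces down to a minimal
bounding polygon, and (iii) damping frame-to-frame jitter.  Measured
noiseless recovery with these defaults: ≤ 0.11 px per face, ≤ 0.07°.

## Optimisation

Parameters (centre, θ₁, six distances; 9 dof) are optimised with Adam,
starting from a batch of candidates: centres at the mask centroid, θ₁ on
a uniform grid over [0°, 180°) (n = 12 by default; half a turn covers all
orientations by the flip symmetry), distances initialised from the mask's
maximal signed projections along each candidate's normals.  All candidates
run a short prescreen stage (80 iterations on a 3-stride pixel subsample);
the best two by loss are refined at full resolution under the
decay-on-plateau schedule: every `plateau_patience` = 20 iterations the
relative loss improvement is checked against `tol` = 1e-4, the learning
rate (initial 0.5) is halved on a plateau, and convergence is declared
after four decays.  The best-so-far parameters are tracked at plateau
checkpoints, so the reported loss trace is non-increasing by construction.
Distances are clipped at zero after each step (projected gradient).
Refining only the top candidates rather than running every candidate to
convergence is a CPU-cost choice; `refine_top = n_candidates` restores the
exhaustive behaviour.

Sequences are fitted sequentially from the selected frame, forward then
backward, each frame seeded with the previous centre (segmentation
prompt) and the previous template (optimiser init, plus a fresh
projection-initialised candidate at the same orientation), with the
temporal term anchoring to the previous distances.  Sequential tracking
with a previous-frame anchor was chosen over whole-sequence joint
optimisation because it matches the frame-by-frame tracking behaviour and
keeps failures local; the temporal weight is small enough that a second
joint pass adds nothing measurable on linear synthetic sequences.

## Segmentation

The default backend thresholds at the global inter-class-variance optimum
(Otsu), orients the threshold so the prompted point's side is foreground,
fills holes, and keeps the single 4-connected component containing the
prompt.  The same post-processing applies to every backend, so any
point-promptable segmenter (e.g. a foundation model) can be registered
behind the identical interface; the package deliberately keeps such
models optional so it is fully functional offline.  On the synthetic
scenes the default backend reaches IoU ≥ 0.95 against ground truth.

## Growth rates

Paired distances are converted to physical units with the calibrated
pixel size; the early linear stage is the longest prefix (≥ 5 points)
whose ordinary-least-squares fit reaches R² ≥ 0.99 (configurable), with a
flagged 5-point fallback when nothing qualifies.  The longest-qualifying-
prefix rule is a reproducible operationalisation of "use the early-stage
data before solute depletion bends the curve"; on a hard linear-then-
plateau series the 0.99 threshold admits about five plateau points, so
the window ends within a few frames of the true breakpoint.  The facet
rate is half the paired-distance slope, exported in m s⁻¹.  The prismatic
width correction, when enabled, is applied to distances before the slope
(the operations commute for linear series, but the order is fixed for
definiteness).  Repeat experiments aggregate to mean ± sample SD
(n − 1 denominator; SD = 0 for a single run).

## Interface kinetics

Growth is modelled as a driving force over two serial resistances,
G = σ/(R_MT + R_SI).  The mass-transfer resistance follows from a
stagnant-film balance: molar flux k_mt·C_e·σ and face velocity
flux·MW_s/ρ_s give R_MT = ρ_s/(k_mt·MW_s·C_e(σ)) with
C_e = C₀/(1 + σ); R_MT grows with σ because the solubility reference
falls.  This algebra is isolated in one function
(`kinetics.mass_transfer_resistance`) so a different film-model
convention is a one-line change.  With the L-glutamic-acid constants
(MW 147.13 g/mol, ρ 1.54 g/cm³, C₀ 237.88 mol/m³) the formula yields
resistances on the 1e6–1e8 s/m scale for k_mt in the physically expected
1e-6–1e-5 m/s range, which is the consistency check behind the default
synthetic conditions.

The three interface mechanisms are the canonical forms (power law
k_G σ^r; Birth & Spread A₁ σ^{5/6} e^{−A₂/σ}; BCF A₁ σ² tanh(A₂/σ)), all
with G_SI(0) = 0.  Fitting is damped Gauss–Newton (Levenberg–Marquardt)
in log-parameter space (all parameters positive by construction) from a
deterministic multi-start grid — A₁ over six decades around the data
scale, A₂ ∈ {0.05…5}, k_mt over six decades around the value at which MT
alone would carry the largest observed rate — prescreened by sum of
squares with the best eight starts refined.  R² = 1 − SS_res/SS_tot about
the mean of G.  An optional per-point spread weights the residuals.

**Plausibility gate.**  Ranked model selection goes by R² among plausible
fits; a fit is implausible when a parameter leaves its mechanistic range.
For the power-law exponent that range is [1e-3, 2]: r = 1 is rough
interface growth and r = 2 the parabolic low-σ limit of spiral growth, so
an exponent collapsing to ~0 or exceeding 2 marks a degenerate fit, not a
mechanism.  The upper bound does real work: a free-exponent power law
with r ≈ 2.1 plus a mass-transfer bend can mimic a BCF curve over a
4× range of σ to within 1 − R² ≈ 1e-4, so without the gate
noisy-replicate model identification degrades to roughly a coin toss
weighted 4:1.  With it, the generating mechanism is recovered in ≥ 98/100
seeded 1%-noise replicates for both Birth & Spread and BCF under the
default study conditions.

**Dead zone.**  The combined models are strictly positive for σ > 0, so a
literal G = 0 crossing sits at σ = 0; operationally the dead zone ends
where growth becomes measurable.  σ_c is the smallest σ at which the
fitted curve reaches a detectability threshold, default 1% of the largest
observed rate, found by 100-step bisection on [0, σ_max] (the curves are
monotone in σ); a curve that never reaches the threshold returns σ_max
with a flag.  The threshold is configurable because mechanisms differ in
dynamic range: an exponential nucleation barrier (B&S) produces a genuine
sharp onset, whereas BCF is at most quadratic, so its 1%-threshold σ_c is
necessarily small — reproducing a large prismatic-face dead zone requires
either a higher detectability threshold or a barrier-type mechanism.

## Synthetic data

The scene generator renders the hard polygon raster (foreground over
background, defaults 0.75/0.30 on a [0,1] intensity scale), adds a linear
illumination gradient, Gaussian optical blur (σ = 1.2 px) and seeded
additive Gaussian sensor noise (sd 0.03); the ground-truth mask is the
clean raster.  Growth sequences advance each of the six distances
linearly (clipped at zero), which makes the half-distance convention
exact: the recovered facet rate equals rateᵢ · pixel_size / interval
analytically in the noiseless case.  The default 20-frame 256×256
sequence is a needle-habit crystal (short prismatic pair ~21 px, long
capping pairs ~60 px) growing anisotropically (capping ≈ 1.1 px/frame
per face, prismatic ≈ 0.11), the anisotropy pattern of β-LGA.

Kinetics datasets evaluate a chosen mechanism on the nine-point σ grid
1.21…0.28 used in growth-cell studies of β-LGA and apply multiplicative
Gaussian noise (the minimal structure that exercises the estimators; real
repeat-to-repeat scatter also carries systematic components).  The
per-face default conditions (`KINETICS_FACE_DEFAULTS`) are anchored to
the measured β-LGA resistance scales: k_mt chosen so R_MT(0.75) matches
the reported MT resistances (9.8e6 s/m capping, 7.8e7 prismatic), A₁ so
R_SI(0.75) matches the reported GSI resistances, the capping A₂ so the 1%
dead zone sits at σ_c = 0.23, and the prismatic A₂ = 1.0 placed in the
tanh transition band where the spiral mechanism is identifiable on this
grid at the study noise level (a design choice made by a power-analysis
style scan, since BCF cannot express the large reported prismatic dead
zone under a 1% threshold — see above).

What passing synthetic tests does **not** show: robustness to defocus,
motion, occlusion, secondary nucleation, non-convex or multi-crystal
scenes, texture inside the crystal, or non-linear late-stage growth; the
generator's noise is pixel-independent and Gaussian.  Real-image use
should validate segmentation quality (the fitting stage consumes only the
mask, so mask IoU is the single sufficient statistic to check).

## Problem sizes used in validation

Accuracy figures quoted here and checked in the test suite use: 20-frame
256×256 sequences for the end-to-end pipeline (max paired-distance error
≈ 0.3% of truth); 20 random noiseless 256×256 masks with distances
30–80 px for parameter recovery (median per-face error ≤ 0.5 px, max
≤ 1 px, θ₁ ≤ 1°); 100 seeded replicates for noisy kinetics selection and
recovery studies.  These sizes were chosen so the full validation runs
comfortably on a single CPU core.

## Known limitations

* The template is 2D; the vertical {010} direction is not measured.
* One crystal per sequence; instance segmentation is out of scope.
* The centre reported by the fit is the symmetry-anchored gauge choice,
  not a physical nucleation centre; only face lines and paired distances
  are physically meaningful.
* Model selection on nine points distinguishes mechanisms only when the
  supersaturation range straddles the mechanism's curvature signature;
  outside that band the R² ranking ties and the plausibility gate is the
  deciding evidence, as it is for real data.
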