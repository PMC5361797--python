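# Methods

## Signal model and quantification chain

A CHESS acquisition excites fat and water protons separately and records
one magnitude stack per channel. We model the noise-free object signal
per voxel as proportional to its fat (or water) proton content: a voxel
of fat fraction *f* emits fat signal *f·T* and water signal *(1−f)·T*,
with *T* the tissue proton signal level. The scanner applies a
per-channel receiver gain *RG* and adds complex Gaussian noise before
magnitude detection, so a recorded voxel is

    M = sqrt((RG·S + n1)^2 + n2^2),   n1, n2 ~ N(0, sigma^2),

the Rician model standard for magnitude MR images. At S = 0 this is
Rayleigh with mean σ·sqrt(π/2) and second moment 2σ².

The chain (noise estimation → power subtraction → gain normalisation →
fat fraction → volume/mass integration) is described in the README. Two
choices deserve justification:

**Fat fraction convention.** "Fat–water ratio" is implemented as the fat
signal fraction F/(F+W), which is bounded in [0, 1] and is the standard
quantity in fat-fraction mapping; F/W diverges where the water signal
vanishes (inside pure adipose tissue). The two are monotonically related
(r = f/(1−f)) and the F/W view is exposed on the fraction map and in the
CLI's `--ratio fw` export.

**Foreground threshold k = 6.** A voxel enters the integral when its
de-biased total signal exceeds k·max(σ̂_F, σ̂_W). Power subtraction
zeroes ~63% of pure-noise voxels but leaves a heavy-tailed residual: the
corrected two-channel sum exceeds 3σ with probability ≈ 4×10⁻², and in a
field of view that is ~85% air those survivors carry fat fraction ≈ 0.5
and would dominate the fat integral. At 6σ the exceedance probability is
≈ 9×10⁻⁵ (Monte-Carlo, 10⁷ draws), making the spurious air contribution
negligible (< 0.5 mm³ on the default grid) while 6σ remains far below
any tissue total signal (≥ T at the default noise levels). k is a
parameter of every user-facing entry point.

**Volume→mass conversion** uses a triglyceride density of 0.9 mg/mm³
(adipose lipid is essentially triglyceride at 0.9 g/cm³); configurable
everywhere it appears.

## The digital phantom

The generator emulates the study's acquisition: a sacrificed adult
zebrafish embedded in 2% low-melting agarose (10% NaCl) inside a tube,
imaged axially. Defaults, chosen once as realistic values where the
protocol prints none:

| parameter | default | rationale |
|---|---|---|
| geometry | 16×16 mm FOV, 128×128, 50 × 0.5 mm slices | the published protocol; the slice stack spans 25 mm (the printed 250 mm FOV depth is inconsistent with 50 × 0.5 mm slices and is not used) |
| body | ellipsoid, semi-axes 2.8 × 3.2 × 11 mm | obese adult male AB zebrafish (~22 mm imaged trunk span, deep belly) |
| tube inner radius | 3.5 mm | an 8 mm NMR tube with ~0.5 mm wall, snug around the fish |
| depots | subcutaneous shell (outer 15% of the body radius), visceral ellipsoid, fat fraction 0.90 | adipose tissue is predominantly lipid; hepatic (0.40) and intramuscular labels are supported |
| lean fat fraction | 0.05 | low intramyocellular lipid of lean fish muscle |
| tissue / agarose signal | 1.0 / 1.3 | agarose gel is nearly pure water vs ~75% tissue water content |
| receiver gains | fat 180, water 125 | autogain-consistent: gain × peak channel signal matched across channels (162 vs 162.5) |
| fat density | 0.9 mg/mm³ | triglyceride |

Ground truth is exact by construction: the true fat volume is the sum of
per-voxel fat fractions times the voxel volume, with per-depot masses
tracked separately. Cohorts are designed by scaling depot linear
dimensions (ellipsoids isotropically, shells by thickness) with a
per-animal factor found by bisection on the voxelised true mass, so the
cohort's ground-truth masses increase linearly across a requested range
(default 40–220 mg, a 5.5-fold span) up to voxelisation error.

The reference readout emulates a quantitative-NMR analyser as
mass × (1 + e), e ~ N(0, cv²), cv = 0.02 by default — multiplicative
because QMR precision scales with the measured mass.

What the phantom does **not** model: k-space acquisition, pulse profiles
and slice cross-talk, B0/B1 inhomogeneity, chemical-shift displacement,
multi-peak fat spectra, T1/T2 weighting differences between tissues, and
partial-volume mixing at compartment boundaries (each voxel is assigned
the fat fraction of the compartment containing its center). Passing
recovery tests therefore demonstrate correctness of the processing chain
under the stated noise model, not robustness to these physical effects
in real acquisitions.

## Noise-floor bias of the chain (known limitation)

Power subtraction is unbiased in the squared intensity but not in the
magnitude: a pure-noise voxel retains E[M̃] = 0.461σ. Two systematic
effects follow at finite SNR:

- over the water-only agarose compartment the fat channel contributes a
  spurious fraction ≈ 0.461σ/A per voxel (A the agarose signal), adding
  ≈ +4% of the true fat volume at peak SNR 20 on the default phantom;
- inside high-fat depots the per-voxel ratio F/(F+W) is convex in W, so
  water-channel noise biases the fraction slightly upward (~+2.5%
  relative on depot voxels), partly offset by a small negative bias over
  lean tissue.

The net effect measured by the recovery experiment (10 seeds, peak SNR
20) is ≈ +5.4% mean fat-mass error; it shrinks roughly linearly with σ
and vanishes in the noise-free limit (recovery is exact to machine
precision at σ = 0). Because the bias is nearly constant across animals
of a cohort it barely affects method-comparison correlation (R² ≈ 0.998
against the reference readout). Mitigations outside the present chain —
an explicit fish mask, fat-channel significance thresholding, or
conditional-expectation (rather than power-subtraction) de-biasing —
would reduce the absolute bias and are natural extensions.

## Morphometry

BMI is weight/length² (g/cm²) and Fulton's condition index
K = 100·W/L³ (W in g, L in cm standard length), the conventions of the
fish obesity literature. Body fat percentage is 100·(fat mass in g)/
(body weight in g). Adipocyte areas are shoelace polygon areas of traced
outlines (validated as simple polygons via shapely) scaled by the
squared pixel size; summaries (count per field of view, mean/median
area) are exact aggregations, invariant to how outlines are partitioned
among fields. Ration energies use Atwater factors 9/4/4 kcal/g for
fat/protein/carbohydrate by default; with these factors the
normal-fat-overfeeding ration (60 mg artemia, 0.2628 kcal) exceeds the
high-fat ration (5 mg artemia + 30 mg egg yolk, 0.2220 kcal) by ~18%,
so no energy-equality assertion is made — the factors are configurable
for users who wish to explore coefficient sets under which the rations
match.

## Numerical choices

- Bisection for cohort design runs 30 iterations on the depot scale
  factor; achieved masses match targets to well under a voxel-quantum
  per depot-boundary crossing (< 1% on the default grid).
- The power-subtraction boundary M² − 2σ² is snapped to zero within a
  1e-12 relative band so that M = σ·sqrt(2) maps to exactly 0 despite
  floating-point rounding.
- Noise estimation requires ≥ 100 background voxels and uses the four
  in-plane corner blocks (⌈n/8⌉ pixels square) of every slice in "auto"
  mode; per-channel sigmas are estimated independently since the two
  excitations may differ in gain and noise.
- Seeds: all simulation entry points accept explicit seeds;
  cohort/experiment helpers derive per-animal and per-replicate streams
  via `numpy.random.SeedSequence` spawning, so results are reproducible
  and independent of execution order.
- Problem sizes: unit tests run on a down-scaled 32×32×12 grid; the
  recovery and cohort experiments run on the full 128×128×50 grid with
  10 and 100 noise realisations respectively, and the acceptance script
  uses 40 cohort realisations.
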