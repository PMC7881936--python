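# Methods

## The measurement model

On an anteroposterior radiograph, axial rotation of a vertebra displaces the
shadow of one pedicle toward the vertebral midline. The Raimondi method
quantifies this with two lengths: the projected vertebral-body width `D` and
the distance `d` from the centre of the migrated pedicle's shadow to a
vertebral-body edge. Ideally all (D, d) pairs at a given rotation are
proportional, so the rotation is a function of the dimensionless ratio
`x = D/d` alone. `avrot` models that function as a degree-(2,2) rational:

    AVR(x) = (a + b·x + c·x²) / (1 + d·x + e·x²)

with the published coefficient set a = 20.22483, b = −330.5077,
c = 33.46082, d = −3.93825, e = −1.322272 (stored and evaluated at full
printed precision, never rounded internally). Key properties, all asserted
in the test suite:

- On the validity interval x ∈ [1.14359, 8.87897] the function decreases
  strictly from 60° to 2°; the single denominator root (x ≈ 0.2353) lies
  well outside it.
- The interval is *defined* by numerical inversion at 2° and 60° (Brent's
  method on the bracket [0.5, 20], |ΔAVR| ≤ 1e−9), not hard-coded, so it is
  consistent for any monotone model the pipeline produces.
- Outside the interval the fit is unvalidated extrapolation. The default
  policy evaluates anyway and flags `in_domain=False`; `clamp` projects onto
  the interval; `strict` raises. Real images routinely produce rotations
  below 2°, and silently trusting extrapolation there would be wrong — but
  so would refusing to return anything.

The model is a least-squares fit to 30 representative (D/d, AVR) pairs, one
per rotation 2°–60° step 2° (bundled as `data/table4.csv`). Its residuals
on those pairs are not zero: max |residual| ≈ 0.0134° at the 2° row,
residual SD ≈ 6.24e−3°. Consequently the numerical inverse at 2° is
8.87897, about 5.8e−3 below the tabulated representative ratio 8.8848 —
a property of the published fit itself, visible in the round-trip tests.

## Landmark geometry

`d` is computed as a *projection*: the pedicle centre (arithmetic midpoint
of the two marked shadow-edge points) is orthogonally projected onto the
line through the two body-edge points, and the distance from the projection
to the edge named by `reference_side` is taken. Compared to a raw
point-to-point distance this is exactly invariant under rigid motion of the
image and insensitive to where along the pedicle shadow's vertical extent
the operator clicks. The operator must name `reference_side`; inferring
which pedicle has migrated is an anatomical judgement the software does not
attempt. A pedicle centre projecting outside the body segment by more than
10% of D warns (likely digitization error) but still returns a value.

All geometry is unit-agnostic. Millimetres are required only by the
discrete-table path (`avrot.tables`), which inherits the physical-scale
assumption of the printed tables (20 ≤ D ≤ 70 mm).

## The table-modelling pipeline

`run_pipeline` re-derives a rational model from a Raimondi-style table in
five stages, mirroring how the published model was obtained:

1. **Column fits.** Each width column's (d, AVR) pairs are fitted with
   AVR(d) = (a + b·d)/(1 + c·d + d₂·d²) by Levenberg–Marquardt least
   squares. Initial values come from the denominator-cleared linear system
   (multiply through by the denominator and solve the resulting linear
   least-squares problem); a singular solve falls back to unit coefficients
   with a warning. Convergence uses relative tolerances at machine level
   with a 2000-evaluation cap; non-convergence raises, carrying the best
   iterate.
2. **Inversion.** Each fitted column curve is root-found at each grid
   rotation and the d values rounded to exactly five decimals — the one
   place (with the ratio cells below) where rounding is applied, matching
   how the tables were tabulated.
3. **Ratio table.** cell(AVR, D) = D/d̂, entered to five decimals. Rows
   whose cells spread beyond 10% of the row mean warn.
4. **Row representatives.** Per row, an OLS line ratio = α + β·D is fitted
   and read at the central width D = 45 mm. By default the D = 60 and
   70 mm columns are omitted from every row regression — the empirical
   tables lose regularity at those widths — and the omission set is
   configurable per row (`omit_config`), since the original choice is not
   recorded column-by-column.
5. **Final fit.** The 30 (representative ratio, AVR) pairs are fitted with
   the five-coefficient rational model, same initialization and optimizer.

Fit statistics follow the common nonlinear-regression conventions:
pseudo-R² = 1 − SSE/SST (SST about the response mean); df = n − p with p
the coefficient count; AICc = n·ln(SSE/n) + 2k + 2k(k+1)/(n−k−1) with
k = p + 1 (coefficients plus the residual-variance parameter). With those
conventions the final fit on the bundled 30 pairs reproduces the published
statistics block (SSE 9.722e−4, df 25, AICc −294.46) to printed precision.

### What the pipeline can and cannot recover

An important numerical fact shapes the tests: the exact column function
implied by the adimensional model is quadratic-over-quadratic in d, while
the column form fitted in stage 1 is linear-over-quadratic. The column fits
therefore carry a small intrinsic smoothing residual (max ≈ 0.009° on
model-generated columns), which propagates to ≈ 0.01 mm in the inverted d
values and ≈ 3e−3 in the high-ratio cells. The end-to-end pipeline still
reproduces the generator's *predictions* to < 0.01° everywhere on the
validity interval (< 0.012° with 0.1 mm cell quantization).

The *coefficients*, however, are not individually identifiable: the rational
parameterization is ill-conditioned, with near-flat directions along which
very different coefficient sets give near-identical curves. Pipeline
self-consistency is therefore asserted in prediction space. Coefficient
recovery to ~1e−6 relative is asserted only where the data pin them down —
refitting the model's own 30-pair source data, or noise-free synthetic
columns generated from the same four-coefficient family being fitted.

## Discrete tables and lookup

`generate_table` builds cell(AVR, D) = round(D/ratio(AVR), quantum) with a
0.1 mm default quantum matching the printed tables (an analytic 1e−5 quantum
and exact quantum 0 are available). Whether the historical tables were
rounded or truncated at 0.1 mm is not recoverable; rounding is used. Lookup
emulates manual use: nearest column in D, then nearest cell in d, ties
breaking toward the lower width and lower rotation (the conservative
reading). No interpolation between cells is offered — the continuous model
is precisely the replacement for that. Reconstructed cells track the
printed empirical fragment to within 10% relative; the largest deviations
sit on the D = 70 column, consistent with the irregularity that motivates
omitting it from the row regressions.

## Synthetic data

The generator runs the model in reverse and adds the simplest
well-understood error model — independent Gaussian noise — since the error
sources in real measurements (projection of a 3-D structure, image noise,
observer variability, vertebral morphology, patient positioning) are known
qualitatively but without published distributions:

- **Tables:** cells d = D/ratio(AVR) + N(0, σ_d), then quantized. Defaults
  mirror the source tables: 51 columns (20–70 mm step 1), rotations 2°–60°
  step 2°, 0.1 mm cells, no noise.
- **Landmarks:** body edges D pixels apart, pedicle centre placed so a
  perfect measurement returns the requested rotation exactly, optional
  rigid tilt, then per-coordinate N(0, σ) pixel noise. The default body
  width of 450 px represents a vertebra digitized at typical radiograph
  resolution. With 1 px noise at 450 px width, 200 replicates at a true
  20° give a mean recovery bias well under 0.5° (asserted); the empirical
  SD is reported by the test run, not assumed.

All randomness flows from one integer seed through
`numpy.random.default_rng`; identical seeds give identical fixtures. What
passing these tests does *not* show: robustness to the projective geometry
of real cone-beam images, correlated observer error, or deformed vertebral
anatomy — the generator works in measurement space, not image space, and
its noise is independent by construction.

## Numerical choices and limitations

- Root finding: Brent's method with xtol 1e−14; monotonicity over the
  bracket is verified on a coarse grid first, and ambiguity raises rather
  than returning an arbitrary root.
- Denominator magnitudes below 1e−12 raise a singularity error instead of
  returning huge values.
- Problem sizes are those of the source material itself (51 columns × 30
  rows, 30-pair final fits); the full pipeline runs in well under a second,
  and the whole test suite in a few seconds.
- Landmark detection, image handling (DICOM/TIFF), and alternative rotation
  methods (Perdriolle, Nash–Moe, CT-based) are out of scope: coordinates
  arrive already digitized.
- No uncertainty quantification (e.g. bootstrap confidence intervals on
  coefficients) is provided.
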