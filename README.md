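# avrot — scale-free axial vertebral rotation measurement

`avrot` measures **axial vertebral rotation (AVR)** — the rotation of a
vertebra about its longitudinal axis, a key severity and progression
parameter in idiopathic scoliosis — on digital anteroposterior spine
radiographs, using the Raimondi pedicle method in closed form.

Traditionally AVR is read off printed Raimondi lookup tables: for a
vertebral-body width *D* (20–70 mm) and the distance *d* from the centre of
the migrated pedicle's shadow to the vertebral-body edge, the tables give a
rotation on a 2° grid. That requires the image scale in millimetres, which
digital images often lack. `avrot` instead evaluates the adimensional
rational model

```
            a + b·(D/d) + c·(D/d)²
AVR(D/d) = ------------------------ ,   a = 20.22483,  b = −330.5077,
            1 + d·(D/d) + e·(D/d)²      c = 33.46082,  d = −3.93825,
                                        e = −1.322272
```

which depends only on the dimensionless ratio *D/d*, so pixel coordinates
are sufficient — no scale needed. On its validity interval
*D/d* ∈ [1.1436, 8.8790] the function decreases strictly from 60° to 2° and
is inverted by bracketed (Brent) root finding.

The package is aimed at people building or validating computer-aided
diagnosis (CADx) measurement software, and at anyone who wants to audit how
such a closed-form model is derived from empirical lookup tables: the whole
derivation pipeline is included and testable against synthetic tables with
known ground truth.

## What's inside

- **`avrot.model`** — evaluate/invert the rational model, validity-interval
  handling, JSON (de)serialization, bundled published coefficients.
- **`avrot.geometry`** — from four digitized landmark points (two lateral
  body-edge points, two pedicle-shadow edge points) to *D*, *d*, *D/d* and an
  AVR; exactly invariant under image scaling and rigid motion.
- **`avrot.pipeline`** — the table-modelling derivation: per-width-column
  rational fits AVR = (a+b·d)/(1+c·d+d₂·d²), inversion to a five-decimal
  *D/d* table, per-row regression read at the central width D = 45 mm, and
  the final five-coefficient fit with full statistics (SSE, MSE, residual
  SD, df, AICc, pseudo-R²).
- **`avrot.tables`** — generate discrete Raimondi-style tables from a model
  and emulate manual nearest-cell lookup.
- **`avrot.synthetic`** — seeded generators for tables and landmark sets
  with known ground truth.
- **`avrot.cli`** — the `avrot` command: `measure`, `avr`, `refit`, `table`,
  `lookup`, `simulate`.

## Worked example

```python
>>> from avrot import published_model, evaluate_avr, VertebralLandmarks, measure_avr
>>> model = published_model()
>>> evaluate_avr(model, 2.9495).avr_degrees     # representative ratio for 30°
29.997393361509896
>>> lm = VertebralLandmarks(
...     body_edge_left=(0.0, 0.0), body_edge_right=(45.0, 0.0),
...     pedicle_edge_1=(13.3, 2.0), pedicle_edge_2=(17.3, 2.0),
...     reference_side="left")
>>> r = measure_avr(lm, model)
>>> r.ratio, r.avr_degrees, r.in_domain
(2.941176470588235, 30.0799385200872, True)
```

The pedicle centre (15.3, 2.0) projects 15.3 units from the left body edge,
so *D/d* = 45/15.3 ≈ 2.941 — a rotation of about 30.1°. The same numbers
come out for any scaled, rotated or translated copy of those four points.

From the shell, refit the model to the bundled 30 representative
(*D/d*, AVR) pairs and print the fit statistics:

```
$ avrot refit --table src/avrot/data/table4.csv
a = 20.2247
b = -330.508
c = 33.4609
d = -3.93826
e = -1.32227
SSE = 0.000972176
...
df = 25
```

recovering the published coefficients to five significant figures. An
out-of-domain measurement is flagged rather than trusted:

```
$ avrot avr --D 45 --d 45
64.9737
warning: ratio 1 outside validity interval [1.14359, 8.87897] (extrapolated)
```

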