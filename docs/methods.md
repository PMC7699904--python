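# Methods

## The model

`hypoxalert` scores the risk that a patient is developing a hypoxemic
episode (arterial oxygen deficit) by combining two concurrent expert
systems:

* **Technical risk** `RT` — a Mamdani fuzzy inference over objective vitals:
  blood oxygen saturation (SpO2, 70–100 %), heart rate (15–180 bpm) and
  body temperature (33–41 °C).
* **Expert risk** `RE` — a second Mamdani inference over three 0–10
  assessments issued by the healthcare team: their reading of the sensor
  measurements, the patient's history, and any other risk factors
  (occupation, exposure, comorbidities).

Both risks live on the scale [10, 100]. They are coupled by the **decision
factor** `f(RT, RE)`, a piecewise surface in the technical risk:

    f(RT, RE) = f1(RT)^(RE − f2(RT)) + 10          for RT ≤ 50
    f(RT, RE) = f3(RT)·ln(RE) + f4(RT)             for RT > 50

    f1(RT) = −0.0015·RT + 1.1391
    f2(RT) = −0.0085·RT² + 0.5092·RT + 57.247
    f3(RT) = 215.3·RT^−1.005
    f4(RT) = −0.0048·RT + 0.7849

and the **global hypoxemic risk** is

    RG = RT · f(RT, RE) / 10,   capped at 100.

The shape encodes a clinical stance: when the objective picture is
reassuring (RT ≤ 50) the expert must push hard (exponential growth in RE)
to raise a global alert; when it is alarming (RT > 50) even moderate expert
scores produce high global risk (logarithmic), and a dissenting low expert
score needs justification. At the floor RT = 10 the global risk equals the
decision factor — the objective data abstain and the expert side decides
alone. The coefficient functions f1–f4 are fixed fitted constants of the
model; refitting them is out of scope.

Alert states follow half-open bands: Wait on [0, 60), Warning on [60, 80),
Emergency on [80, 100]. For binary evaluation an emergency is declared at
`RG ≥ limit` (default limit 60, i.e. warnings count as emergencies).

## Corrections

Three expert overrides are implemented; whenever several risk values are
available the **highest prevails** (capped at 100), and every applied
correction is logged as an audit trail.

1. **Linear growth (exponential zone, RT ≤ 50).** From an anchor expert
   risk `a` upward the factor follows `f(RT, a) + rate·(RE − a)`. The legal
   rate bracket at a given RT is `[f(RT, a+1) − f(RT, a),
   (f(RT, 100) − f(RT, a)) / (100 − a)]`; at the maximum rate the line
   interpolates the surface at both `RE = a` and `RE = 100`.
2. **Security (logarithmic zone, RT > 50).** Triggered when the global risk
   undercuts the technical risk by more than a threshold
   (`100·(RT − RG)/RT > 15 %` by default). The factor is divided by the
   declared security fraction, so 100 % confidence is the identity and
   lower confidence raises RG back toward the technical alert. The source
   description of this correction is ambiguous about multiply-vs-divide;
   division is the only reading under which reduced confidence counteracts
   the undervaluation the correction exists to catch, so that is the
   adopted semantics.
3. **Ramp (transition zone).** Between two technical-risk bounds
   `25 ≤ rt1 < 50 < rt2 ≤ 75` the surface is replaced by the linear
   interpolation, at fixed RE, of its values at the bounds — smoothing the
   exponential/logarithmic seam. It is continuous at both ends and exactly
   linear inside.

## The fuzzy engine

Classical Mamdani pipeline: trapezoidal memberships (four knots
`a ≤ b ≤ c ≤ d`, degenerate triangles allowed), AND = minimum over
antecedents with `is not` as the standard complement `1 − μ`, MIN
implication (consequents truncated at the rule activation), MAX
aggregation, centroid defuzzification on a uniform sample of the output
universe (default 1001 points, endpoints inclusive). Doubling the
resolution moves the centroid by well under 0.1 output units on all shipped
configurations, and the engine agrees with an independent dense-sampling
integration to 0.05 on randomized systems (tested).

Numerical/edge choices:

* Inputs outside the declared universe are clamped to the nearest bound
  with a logged warning — pulse-oximeters can read below the 70 % floor of
  their reliable range (the packaged cohort contains such a reading).
* If no rule fires the engine raises instead of returning a default: a
  silently invented risk is unsafe in this domain. Input variables must
  therefore cover their universe; output variables may leave gaps between
  consequent sets (aggregation handles that naturally).
* Configurations are plain JSON (YAML accepted): variables with ranges and
  labelled knots, rules as `{"if": {"var": "label" | "!label" | "*"},
  "then": "label"}`, plus the defuzzification resolution.

## The default risk systems

The published structure fixes both systems (trapezoidal labels, MIN/MAX,
centroid, input universes, 45 and 29 rules, and a printed subset of rules)
but not the membership knots, which are shown only as unreadable figure
panels. The defaults are therefore the package's own, anchored as follows:

* **SpO2**: Normal plateaus at 97–100 % (97–99 % is a normal reading),
  Low spans the ~80–90 % band where supplementary oxygen may be required,
  Very_Low sits below the 75–80 % reliability floor of a pulse-oximeter.
* **Heart rate**: Normal plateau 65–95 bpm inside the resting 60–100 band,
  flanked by Low/High and by Very_Low/Very_High beyond ~35/150 bpm.
* **Temperature**: Normal plateau 36–36.5 °C; Low below ~35 °C; High
  saturating near 38.2 °C.
* **Output**: five ranks R1–R5 on [0, 100] centred at 10, 30, 50, 70, 90.
  The boundary ranks are rectangular and the interior ones symmetric, so
  MIN-truncation never shifts a rank's own centroid: a saturated R1 (R5)
  inference defuzzifies to exactly 10 (90) at any activation level, and
  mixed inferences interpolate monotonically between rank centres. This is
  what makes the grid monotonicity properties below hold exactly.

Rule bases are full combination tables with consequents assigned by a
max-of-severities completion, overridden where the printed rules dictate:
any non-Very_Low SpO2 with normal temperature and normal-or-high heart rate
maps to the lowest rank, Very_Low SpO2 maps to the highest, and in the
expert system a Medium sensor assessment with Low history and Low other
factors maps to the lowest rank. The technical table has 3×3×5 = 45 rules
(the printed patterns are implied by the combinations); the expert table
has 27 combinations plus the two printed rules verbatim, 29 in all —
matching the published counts.

**Calibration.** The free temperature ramp edges are fixed by a coarse grid
search (`scripts/calibrate_fis.py`, part of the repository) against the
published worked example: RT(92 %, 80 bpm, 37.0 °C) = 43.33 and
RE(3, 7, 10) = 90. The expert anchor is structural (those scores saturate
R5, whose centroid is 90 by construction); the technical anchor is carried
by how much a borderline 37.0 °C reading activates the High temperature
label. This is a consequence of the printed rules: they pin any
non-Very_Low saturation with normal temperature and heart rate to the
lowest rank, so SpO2 = 92 % alone cannot produce a mid-scale risk — the
borderline temperature must. Both memberships at 37.0 °C are kept below the
0.5 label-crossover level so that membership dips of the other inputs can
never modulate them. The shipped configurations reproduce both anchors to
three decimals; the calibration script reports any deviation rather than
hiding it.

**Monotonicity.** On a 5×5×5 grid of each system's inputs the default
technical risk is non-increasing in SpO2 and non-decreasing in temperature
and heart-rate deviation (checked per side of the normal band), and the
expert risk is non-decreasing in each score. Strict pointwise monotonicity
of Mamdani centroids is not a theorem: between two label plateaus the
maximum membership dips to the crossover level, and truncating an
asymmetric consequent there can ripple the centroid by a fraction of a risk
unit. The shipped output-label geometry eliminates this on the test grid;
off-grid ripples below ~0.1 risk units may remain in mixed-consequent
regions and are considered irrelevant at the 20-unit width of the alert
bands.

## Case-study reproduction

The packaged fixtures carry the published 30-patient cohort: the raw
patient table and the results table (printed RT, RE, RG, recommended and
actual states). Recomputing RG from the printed risk pairs reproduces the
printed value within ±0.05 on 27 of 30 rows. The three exceptions are
recorded as a fixture exclusion set and treated as print anomalies: one row
prints RG identical to RE, one prints 87.74 where the formulas give ≈80.7,
and one prints 97.70 where the four other rows with the identical (90, 90)
pair print ≈97.9 (which the formulas match).

At the default emergency limit 60 the pipeline reproduces the published
confusion matrix (16, 7, 6, 1) exactly, hence accuracy 76.67 %,
sensitivity 94.12 %, specificity 53.85 %, Youden 0.4797 and Cohen's kappa
0.502. Sweeping the limit over 1–100 in unit steps, both Youden and kappa
reach their maximum (0.746 / 0.733) on a plateau of limits — re-binarizing
a 30-patient cohort only changes at observed risk values, so the maximizing
limit is an interval, here 81–87, which contains the published optimum 85.
The sweep therefore reports the full maximizing set together with a scalar
argmax tie-broken toward the lowest limit (earlier alerts are safer).

## Synthetic cohorts

The seeded generator emulates the case-study conditions for testing: SpO2
as a mixture of a healthy mode (truncated normal, 94–100 %, centred 97.5 %)
and a hypoxemic tail (truncated normal below 90 %, centred 84 %) with
default weight 0.5 (the published cohort has 17/30 actual emergencies);
heart rate ~N(75, 15²) on [40, 150]; temperature ~N(36.7, 0.5²) on
[35, 40] with a +0.8 °C shift for hypoxemic patients; and the three expert
scores as a stated monotone severity map of the vitals (weights 0.6 SpO2
deficit, 0.25 temperature deviation, 0.15 heart-rate deviation, scaled to
0–10) plus unit-variance noise. What it does **not** emulate: temporal
structure (repeated readings, trends), sensor artefacts, correlations
between history and vitals beyond the severity map, and the free-text
richness a real expert would assess. Passing tests on synthetic cohorts
demonstrate the pipeline's internal consistency and calibration, not
clinical validity on real patients.

## Known limitations

* The published uncertainty-supervision metric of the technical system is
  described but given no formula; it is not implemented.
* Membership knots are package defaults calibrated to a single worked
  example; a deployment would re-derive them from local clinical practice
  (the configs are plain JSON and fully overridable).
* The cohort is 30 patients from a single study; the evaluation layer
  reports no confidence intervals (out of scope) and the sweep optimum is
  correspondingly coarse — an interval of limits, not a point.
* Problem sizes in the test suite (grids of a few hundred points, cohorts
  up to 1000) are chosen to keep the whole suite under a few seconds while
  leaving the numerical tolerances comfortably resolved.
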