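# hypoxalert

Early detection of hypoxemic risk with concurrent fuzzy expert systems.

`hypoxalert` is a clinical decision-support toolkit that scores the risk of
a blood-oxygen-saturation deficit by combining two Mamdani-type fuzzy
inference systems running concurrently: a **technical risk** `RT` inferred
from pulse-oximeter vitals (SpO2 %, heart rate bpm, temperature °C) and an
**expert risk** `RE` inferred from three 0–10 assessments by the healthcare
team (measurements, history, other risk factors). Both live on [10, 100]
and are coupled into the **global hypoxemic risk**

    RG = RT · f(RT, RE) / 10    (capped at 100)

through a piecewise *decision factor*: exponential in RE when the
technical picture is reassuring (RT ≤ 50, so the expert must push hard to
raise an alert) and logarithmic when it is alarming (RT > 50, so the alert
prevails unless the expert justifies otherwise),

    f = f1(RT)^(RE − f2(RT)) + 10          RT ≤ 50
    f = f3(RT)·ln(RE) + f4(RT)             RT > 50.

RG drives a three-state alert — Wait [0, 60), Warning [60, 80), Emergency
[80, 100] — plus expert correction procedures (linear-growth override,
security/confidence division, transition ramp; the highest corrected risk
prevails) and a diagnostic-evaluation layer: confusion counts,
sensitivity/specificity, Youden index, Cohen's kappa, and emergency-limit
sweeps. It is aimed at researchers and engineers building or auditing
rule-based triage/monitoring pipelines; it is not a certified medical
device.

## Worked example

The packaged default inference systems are calibrated so that the
case-study patient — SpO2 92 %, heart rate 80 bpm, temperature 37.0 °C,
expert scores (3, 7, 10) — scores RT = 43.33 and RE = 90. From the library:

```python
from hypoxalert import decision_factor, global_risk, classify_alert

f = decision_factor(43.33, 90)        # 16.72, exponential zone
rg = global_risk(43.33, 90).rg_final  # 72.45
classify_alert(rg)                    # <AlertLevel.WARNING: 'Warning'>
```

or from the command line, with the first-level correction (anchor 30,
maximum growth rate) and a second-level ramp on [40, 70]:

```sh
$ hypoxalert assess --rt 43.33 --re 90 --exp-correction 30,max --ramp 40,70
{
  "technical_risk": 43.33,
  "expert_risk": 90.0,
  "decision_factor": 21.7853,
  "rg_uncorrected": 72.4454,
  "rg_corrected": {
    "linear_growth": 94.3956,
    "ramp": 72.1446
  },
  "rg_final": 94.3956,
  "corrections_applied": ["linear_growth", "ramp"],
  "alert": "Emergency"
}
```

Uncorrected, the patient sits in the Warning band (RG 72.45). The
linear-growth correction replaces the exponential tail above expert risk 30
by its maximum-rate chord, lifting the factor from 16.72 to 21.79 and the
global risk to 94.4 — an Emergency, which prevails over the lower ramp
value (72.14).

Evaluating the packaged 30-patient results table at the default emergency
limit of 60:

```sh
$ hypoxalert evaluate src/hypoxalert/data/table6_results.csv
```

reports the confusion counts tp=16, tn=7, fp=6, fn=1 — accuracy 76.67 %,
sensitivity 94.12 %, specificity 53.85 %, Youden 0.4797, kappa 0.502 — and
a unit-step sweep of the emergency limit on which both agreement metrics
peak at 0.7466 / 0.7333 over the limit plateau 81–87 (which contains the
conventional optimum 85). `hypoxalert surface` exports the RG surface as a
grid, and `hypoxalert simulate` writes seeded synthetic cohorts.

Other entry points: `hypoxalert assess --cohort <csv>` scores a whole
cohort (vitals + scores per row), `--technical-fis/--expert-fis` swap in
your own JSON system configurations, and `scripts/calibrate_fis.py`
regenerates the shipped defaults from the calibration anchors.

See `docs/methods.md` for the model, the calibration of the default
membership functions, and known limitations.

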