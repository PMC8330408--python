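# swallowkit

Quantitative analysis of videofluoroscopic swallow studies (VFSS): from
dual-rater per-bolus annotations to anatomically scaled swallowing
parameters, inter-rater agreement statistics, and hierarchical
age/sex/sip-volume regression — plus a calibrated synthetic-cohort
generator that makes the whole pipeline verifiable without any recorded
patient data.

## Who this is for

Deglutition researchers and speech-language pathology labs that measure
swallowing physiology from lateral-view fluoroscopy using a standardized
event/kinematics/timing protocol (ASPEKT-style), and want a tested,
scriptable implementation of the measurement and statistics stages.
The package does **not** process video: frame numbers, pixel tracks and
contours annotated by human raters are its inputs.

## The measurements

For each bolus, two blinded raters annotate:

* event frames (bolus past the mandibular ramus, hyoid burst onset, UES
  opening/closure, laryngeal vestibule closure onset/offset, maximum UES
  opening, maximum pharyngeal constriction, swallow rest),
* a frame-by-frame hyoid pixel track, pharynx/residue contours, a UES
  diameter segment, and the anterior-inferior corners of C2 and C4,
* sip volume, swallow count, Penetration–Aspiration Scale (PAS) scores and
  LVC integrity.

From a consensus annotation the package derives 19 parameters per bolus.
Durations use the ceiling convention `ceil((end − start)·1000/fps)`; at
30 fps every duration falls on the grid {0, 34, 67, 100, 134, …} ms.
Distances and areas are anatomically scaled: with L = |C2AI − C4AI| in
pixels, a length d maps to `100·d/L` %(C2–4) and an area A to `100·A/L²`
%(C2–4)², which removes fluoroscopic magnification and body-size effects.
Hyoid kinematics use the radial position `r(t) = ‖(x(t), y(t))‖` in the
anatomical frame (origin C4AI, Y superior along the spine, X anterior):
peak XY position is `max r(t)` over the swallow, and hyoid speed is
`(r_peak − r_min)/Δt` over the hyoid burst.

Pre-consensus agreement is summarized per item as percent absolute
agreement, mean absolute difference and ICC(2,1) (two-way random effects,
absolute agreement, single measures); disagreements above configurable
thresholds (±3 frames, ±4 %(C2–4) for UES diameter, ±10 %(C2–4)² for
areas, ±1 %(C2–4)² for residue, exact match for categorical items) are
flagged and must be resolved before consensus merging.

The statistical stage computes participant means, medians/IQRs, a Pearson
correlation screen (report threshold |r| > 0.25), Bonferroni family alphas
`round(0.05/m, 3)`, hierarchical OLS per outcome (stage 1: age; stage 2:
+ sex; stage 3: + sip volume, skipped for rest measures) with R² and ΔR²
per stage, a bolus-level logistic model for multiple swallows per bolus,
and a 2×2 odds ratio for sips dichotomized at 16 ml (Woolf CI,
Haldane–Anscombe correction for zero cells).

## Worked example

```python
from swallowkit import PipelineConfig, run_pipeline

result = run_pipeline(PipelineConfig(seed=11))
print(result.regression_summary[
    ["outcome", "family_alpha", "age_effect", "age_coef"]
].head(6).to_string(index=False))
o = result.sip_odds_ratio
print(f"multiple-swallow OR (sip > 16 ml): {o.odds_ratio:.2f} "
      f"[{o.ci_low:.2f}, {o.ci_high:.2f}]")
```

This simulates a sex-balanced cohort of 76 adults aged 21–82 (3 thin-liquid
boluses each), rates every bolus with two noisy synthetic raters, merges
them by consensus, measures all parameters, and runs the statistics. It
prints:

```
              outcome  family_alpha  age_effect  age_coef
           sip_volume         0.050       False  0.026866
swallow_reaction_time         0.050        True  3.787268
          hyb_to_ueso         0.017       False -0.039270
        ueso_duration         0.010        True  1.739597
          time_to_lvc         0.017       False -0.795290
         lvc_duration         0.010        True  3.061027
multiple-swallow OR (sip > 16 ml): 1.67 [0.93, 3.00]
```

Read: on this simulated cohort, swallow reaction time lengthens by
~3.8 ms per year of age (significant at α = 0.05) and UES opening duration
by ~1.7 ms/year (significant at its family α = 0.01), while the
hyoid-burst-to-UES-opening interval and time-to-LVC show no age effect —
the pattern the generator is calibrated to produce.

A CLI wraps the same library:

```bash
swallowkit simulate --seed 5 --out sim/           # annotation bundles + truth
swallowkit measure  --annotations sim/annotations_truth.json --out records.csv
swallowkit agree    --rater-a sim/annotations_rater_a.json \
                    --rater-b sim/annotations_rater_b.json --out agree/
swallowkit analyze  --records records.csv --covariates sim/participants.csv --out stats/
swallowkit pipeline --seed 5 --out out/           # everything end to end
```

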