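# luxsense

Light-sensitivity assessment for children with autism spectrum disorder
(ASD), computed from interaction logs of an illuminated bubble-tube device
used in multi-sensory (Snoezelen) rooms. The package is aimed at clinical
practitioners and researchers who want an objective, reproducible
alternative to manual video coding for deciding whether a child is
**hypo-sensitive** (drawn to bright light), **hyper-sensitive** (averse to
it), or **normal**.

The device runs two protocols, logged as plain CSV:

* **CCM** (child control mode) — the child picks colors and illumination
  levels; each record is a chosen stimulus with its dwell duration.
* **SCM** (system control mode) — stimuli change automatically every 5 s;
  each record carries the child's emotional response, coded positive
  (joy, surprise) or negative (anger, fear, sadness, neutrality).

Illumination is binarized at 100 lux (measured at 1 m) into LI/HI classes.

## Method

For each child, Apriori-style *supports* are mined from the pooled records:
in CCM the HI/LI selection supports `HI_S`, `LI_S` and total dwell durations
`HI_D`, `LI_D`; in SCM the four (illumination, response) pair supports
`HI_PR`, `HI_NR`, `LI_PR`, `LI_NR`. Contrasts use the symmetric percentage
difference

```
pd(A, B) = |A − B| / ((A + B) / 2) × 100   ∈ [0, 200]
```

and a child is classified with a ≥ 40 % threshold:

* **hypo-sensitive** (CCM): `pd(HI_S, LI_S) ≥ 40` and `pd(HI_D, LI_D) ≥ 40`
  with `HI_S > LI_S` and `HI_D > LI_D`; (SCM): both response differences
  ≥ 40 with positives concentrated under HI and negatives under LI;
* **hyper-sensitive**: the HI↔LI mirror of the above;
* **normal**: everything else (balanced, sub-threshold, or mixed-direction).

System labels are audited against practitioner assessments as a simple
per-child agreement rate. A session simulator generates protocol-faithful
synthetic cohorts (180-s sessions, 3 per mode, 5-s SCM intervals) from
per-class behavioral profiles, so the whole pipeline can be validated by
parameter recovery without hardware.

## Worked example

```python
from luxsense import parse_log, ccm_summary, classify_ccm, Mode

log = parse_log("""date_time,color,illumination,duration_s
2024-07-23 14:35:10,B,HI,60
2024-07-23 14:36:50,R,LI,40
2024-07-23 14:38:15,G,LI,30
""", Mode.CCM)

s = ccm_summary(log)
print(s.support_hi, s.support_li, s.total_hi_duration_s, s.total_li_duration_s)
d = classify_ccm(s)
print(d.label.display, round(d.hls_diff, 1), round(d.hld_diff, 1))
```

prints

```
1/3 2/3 60 70
Normal 66.7 15.4
```

The child chose HI in 1 of 3 interactions (support 33.3 %) for 60 s total.
The support difference (66.7 %) crosses the 40 % threshold toward LI, but
the dwell-duration difference (15.4 %) does not, so the directions are not
jointly significant and the child is classified Normal.

The same pipeline from the shell, on a simulated cohort:

```
luxsense simulate --n-children 20 --seed 7 --out cohort/
luxsense classify --logs cohort/ccm --mode CCM --out ccm_labels.csv
luxsense audit --system ccm_labels.csv --practitioner cohort/truth.csv
```

The package also ships the published 20-child field-evaluation label
tables (practitioner, CCM, SCM) under `luxsense.datasets`; auditing them
reproduces the reported agreement rates — CCM 95 % (one mismatch, child
016) and SCM 90 % (children 004 and 014).

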