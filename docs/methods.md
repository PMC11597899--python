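# Methods

## Data model

Interaction logs are per-child, per-mode CSV files. A CCM record is one
child-chosen stimulus `(timestamp, color ∈ {R,G,B,Y,W}, illumination ∈
{LI,HI}, duration_s)`; an SCM record is one system-presented stimulus with
the child's valence-coded response `(timestamp, color, illumination,
response ∈ {P,N})`. Timestamps are accepted at minute or second precision
and stored at second precision (minutes padded with `:00`). Raw six-emotion
words (joy, surprise, anger, fear, sadness, neutrality) are accepted in the
SCM response column and mapped to valence at parse time: joy and surprise
are positive, the other four negative — neutrality is coded negative
because it reflects absence of positive engagement rather than comfort.

An optional 1-based `session` column groups records into sessions (the
field protocol runs three 180-s sessions per mode); without it, a file is
one session. Sessions are pooled before mining, so each child gets one
summary and one classification per mode; per-session summaries are exposed
for diagnostics only. One representational limit: a trailing *empty*
session in a multi-session log cannot be expressed in the CSV (the session
column exists only on record rows), so round-trip identity holds for logs
whose sessions are non-empty plus the single-empty-session case.

Illumination is binarized at 100 lux measured at 1 m from the tube: below
100 is LI, at or above is HI. The boundary value itself is assigned to HI
to keep the map total; the defining inequalities are strict on both sides
and leave 100 lux unassigned, so this is an explicit package decision.
A point-source inverse-square helper converts the 1-m reference illuminance
to other viewing distances (half a meter → 4× the 1-m value).

## Mining

Support is the Apriori notion restricted to what the classifier consumes:
single items (illumination classes; colors, descriptively) and the four
fixed (illumination, response) pairs. No candidate-generation lattice,
confidence or lift is computed — the downstream rules need exactly these
supports. Counts are integers and supports exact `Fraction`s; floats
appear only in serialized output and report renderings. This makes audits
bit-for-bit reproducible and keeps normalization identities (`HI_S + LI_S
= 1`; the four SCM supports sum to 1) exact rather than approximate.
Color supports are mined for descriptive reports but never enter
classification.

## Classification

The contrast metric is the symmetric percentage difference
`pd(A,B) = |A−B| / ((A+B)/2) × 100`, bounded in [0, 200], symmetric, and
invariant under common rescaling — hence identical on supports and raw
counts, which is why the SCM rule can be stated on either. At `A = B = 0`
the expression is 0/0; it is defined as 0 (the limit of equal values) so an
entirely absent response class can never trigger a rule.

The decision threshold defaults to 40 (percent), compared with `≥`, and is
configurable. CCM: hypo-sensitive requires both the support and duration
differences to reach the threshold *and* both quantities to point toward
HI; hyper-sensitive is the exact LI mirror; everything else — balanced,
sub-threshold, or mixed directions (e.g. support favoring HI while dwell
favors LI) — is normal, because the hypo/hyper rules are conjunctions and
normal is the residual class. SCM is analogous on `pd(HI_PR, LI_PR)` and
`pd(HI_NR, LI_NR)` with the direction conjunction `HI_PR > LI_PR ∧ HI_NR <
LI_NR` (mirrored for hyper). The construction guarantees exactly one label,
HI↔LI mirror symmetry (swapping HI and LI quantities exchanges hypo and
hyper and fixes normal), and threshold monotonicity (raising the threshold
can only move labels toward normal).

Labels are rendered `Hypo-sensitive` / `Hyper-sensitive` / `Normal` and
compared case-, hyphen- and whitespace-insensitively, since published
tables mix casings.

## Reports and audits

Report tables carry supports as percentages (one CCM row per child:
`HI_S %, LI_S %, HI_D s, LI_D s`, label; one SCM row: the four response
supports, label), rendered to one decimal place in CSV/text. Agreement
audits compare normalized labels computed from exact supports, never
rounded renderings, and list mismatches in child-id order with both labels.

The package bundles the 20-child field-evaluation label tables
(practitioner, CCM, SCM) as its only real data; the raw logs behind them
were never deposited. Auditing them yields CCM 95 % (19/20; child 016:
practitioner hypo-sensitive, system normal) and SCM 90 % (18/20; children
004 and 014: practitioner normal, system hyper-sensitive). The prose
accompanying the published tables describes both mismatch directions the
other way around; the package treats the tables as ground truth and
surfaces directions explicitly rather than resolving the inconsistency.

## Simulator

The simulator emulates the assessment protocol — five colors, nine device
levels (default lux map: L1–L4 = 20/40/60/80 lux below the LI/HI boundary,
L5–L9 = 110/140/180/230/290 above; per-level photometry is
hardware-dependent and configurable), 180-s sessions, three per mode, SCM
stimuli every 5 s — and child behavior via per-class profiles:

| parameter | hypo | hyper | normal | meaning |
|---|---|---|---|---|
| `p_hi_select` | 0.85 | 0.15 | 0.5 | P(CCM selection is HI) |
| `dwell_hi_mean_s` | 25 | 10 | 15 | mean dwell on HI stimuli (s) |
| `dwell_li_mean_s` | 10 | 25 | 15 | mean dwell on LI stimuli (s) |
| `p_pos_given_hi` | 0.8 | 0.2 | 0.5 | P(positive response to HI) |
| `p_pos_given_li` | 0.2 | 0.8 | 0.5 | P(positive response to LI) |

The hyper template is the exact HI↔LI mirror of hypo; normal is balanced
(expected percentage differences of 0). These defaults encode the
qualitative behavioral premises behind the rules — light-seeking children
select and dwell on bright stimuli and respond to them positively — with
contrasts strong enough that the rule conjunctions hold in expectation.
A `contrast ∈ [0,1]` knob interpolates every parameter toward the balanced
template for sensitivity studies.

Design choices where the protocol description left the design open:

* **Dwell distribution** (CCM): geometric on whole seconds with the class
  mean (memoryless, integer-valued — a reasonable null model for hold
  times); the final dwell is truncated at the session boundary, so each
  session's dwell total is exactly the session length.
* **SCM schedule**: the device "systematically varies" stimuli without a
  stated order. The simulator alternates deterministically between the LI
  sub-grid (L1–L4 × colors) and HI sub-grid (L5–L9 × colors), cycling
  levels then colors within each, giving exactly 18 HI and 18 LI exposures
  per 36-record session. Balance makes the support contrasts directly
  interpretable; a straight cycle over all 45 level×color combinations
  would give a 5:4 HI:LI imbalance.
* **One response per stimulus window**, matching the one-row-per-stimulus
  log structure.
* **Seeding**: per-child streams derive from the master seed plus a CRC-32
  of the child id and a mode tag, so cohorts are byte-reproducible and
  independent of generation order; identical profile+seed gives identical
  logs.
* **No idle gaps** in CCM sessions (the child is always engaged) and no
  habituation/fatigue across sessions.

What the simulator does *not* emulate: facial images or the emotion
recognizer (responses are sampled valences, so recognizer error is absorbed
into `p_pos_given_*`), color-specific preferences (colors are uniform),
idle time, and drift across sessions. Passing recovery tests therefore
show that the mining + classification rules invert the assumed behavioral
model at protocol sample sizes — not that real children behave like the
model.

## Parameter recovery

A recovery experiment simulates cohorts with known true classes (default
composition 9 hypo : 5 hyper : 6 normal of 20, matching the field cohort;
largest-remainder apportionment for other sizes), runs mining and
classification in both modes, and audits against truth. With the default
strong profiles, 50 replicates of 20 children give mean accuracy ≈ 95 %
(CCM) and ≈ 98 % (SCM); residual errors are almost entirely normal
children whose ~36-record CCM sample crosses the 40 % threshold by chance.
Accuracy is monotone non-decreasing in profile contrast, collapsing to the
normal-class base rate at zero contrast. These sizes (20 children, 50
replicates, 3×180-s sessions) mirror the field protocol and keep the whole
experiment under a few seconds.

## Numerical notes

* Supports and percentage differences are exact rationals end-to-end;
  equality assertions in tests are exact, not tolerance-based.
* `percentage_difference` raises on negative input; classification
  comparisons use strict `>` for direction and `≥ threshold` for
  significance, so ties in either quantity fall to normal.
* Parsing rejects, with the 1-based row and field named: unknown color or
  illumination codes, negative durations, responses outside {P, N} ∪ the
  six emotion words, malformed timestamps, bad session numbers, and
  out-of-order timestamps within a session.
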