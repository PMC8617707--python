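# Methods

## Model

`madmsg` implements a weighted-sum multi-attribute decision model over a
message × attribute matrix of mean scores. Twelve candidate messages in
a 2 (risk content: harms / addiction) × 3 (theme: alone / flavors /
social) factorial design are evaluated on seven attributes: four
self-report constructs measured in a between-subjects crowdsourced arm
(each participant rates one message) and three psychophysiological
measures from a within-subjects lab arm (each participant views all
twelve messages in random order).

All seven attributes are treated as higher-is-better, including negative
emotion: in a fear-appeal framing, stronger reported
frightened/anxious/nervous/worried responses indicate a more effective
risk message. The direction is configurable per attribute for reuse with
other instruments.

### Attribute summaries

* **Self-report constructs.** A participant's construct score is the
  arithmetic mean of the construct's items (receptivity 9 items on 1–7,
  engagement 3 on 1–7, positive attitude 9 on 1–7, negative emotion 4 on
  1–4); per-message attribute values are means of participant scores.
  Standard errors use the sample (n−1) standard deviation over
  participants; with a single participant the SE is undefined and
  reported as NaN. Records with missing items are rejected, not
  prorated: silent prorating would shift means invisibly. Scale bounds
  are validated, never clamped — an out-of-range response is a data
  error. Cronbach's alpha, `α = k/(k−1)·(1 − Σ var_i / var(Σ items))`,
  is provided as a quality-control utility.
* **Heart-rate deceleration.** Per exposure second, the last pre-message
  baseline second's BPM is subtracted; deviations are folded to absolute
  values and averaged over the exposure. The fold means acceleration
  seconds also inflate the score — a property of the change-score
  definition itself, acceptable when message content predominantly
  decelerates the heart and per-second noise is small relative to the
  effect. Traces of different lengths are scored over whatever seconds
  exist and averaged unweighted across participants.
* **Recognition accuracy.** Hit rate on target fragments (two per
  message out of a 24-target + 24-foil task). Hit proportions are
  computed per participant and then averaged — identical to pooling when
  target counts are balanced, robust when trials are dropped. Foils
  never enter the rate.
* **Visual attention.** Mean of the three AOI dwell durations (sentence
  1, sentence 2, hashtag) per participant-message, then an unweighted
  mean across participants, in absolute milliseconds. An AOI without a
  recorded fixation counts as 0 ms: absence of fixation is informative
  non-attention, and dropping it would bias dwell upward.

### Ranking and scenarios

Within each attribute, messages receive **competition ("minimum")
ranks**: the highest mean ranks 1, tied values share the minimum rank,
and the next distinct value skips by the tie-group size. This tie rule
is load-bearing — dense or fractional ranking does not reproduce the
reference tables (`Σ ranks ≤ n(n+1)/2`, with equality iff no ties, is
tested as the characteristic property). Ranks are summed per study arm
into rank totals, and the totals are themselves competition-ranked
(smaller total = better).

A weighting scenario is a list of components — attribute rank columns or
study total-rank columns — with non-negative weights; the summary score
is the weighted mean of component ranks and messages are
competition-ranked on unrounded scores, with ties flagged. The four
presets: equal attribute weights (7 components), equal study weights (2
study-total ranks), prefer self-report (4 self-report attribute ranks +
lab total rank), prefer lab (self-report total rank + 3 lab attribute
ranks). Scores are rendered to 1 decimal (2 for prefer-lab, whose
4-component means land on quarters) purely for display.

**Published-total reproduction mode.** The published lab total-rank
column is not the rank of the published lab rank sums — it coincides
with the visual-attention ranks — yet it is demonstrably the column the
published scenario table consumed for the equal-study and
prefer-self-report scenarios. Whether that column is a transcription
artifact or intentional cannot be determined from the source text, so
the engine computes rank-of-sums by default and accepts an explicit
override column for bit-for-bit reproduction of the published table.
Both paths are tested; neither is asserted as the "true" method.

**Consensus** returns the messages ranked ≤ ⌊n/2⌋ in every supplied
scenario. **Weight sweep** generalizes the fixed scenarios: weight
vectors sampled uniformly on the 7-simplex (Dirichlet(1)), reporting the
fraction of samples in which each message attains rank 1 (all members of
a tie win); deterministic given a seed.

The model performs no statistical inference on rank differences; that is
an explicit non-goal.

## Synthetic cohorts

The generator emulates both study arms with planted per-message truths
(defaulting to the bundled reference means) and default cohort sizes of
713 crowdsourced and 120 lab participants, mirroring the two arms. One
root seed spawns independent child streams per arm, so either arm
regenerates identically on its own.

* **Self-report arm** (between-subjects, round-robin balanced
  assignment): items are a latent participant value (planted mean +
  normal participant effect) plus item noise, rounded to the nearest
  scale point and clipped to the bounds. The item-noise sd is derived
  from a target Cronbach's alpha (default 0.9) via the Spearman–Brown
  relation `ρ = α/(k − α(k−1))`, `σ_e = σ_p·√((1−ρ)/ρ)`. Default
  participant sds: 0.9 on the 7-point scales, 0.6 on the 4-point
  negative-emotion scale (its narrower range implies less
  between-person spread). Rounding and clipping pull raw means toward
  the scale centre (up to ≈0.09 points near a bound at these sds), so
  the latent location is calibrated by root-finding on the closed-form
  discretized-normal mean so that the *generated* population mean equals
  the planted mean exactly; the discretized mean is strictly increasing
  in the latent mean, making the calibration unique.
* **Lab arm** (within-subjects): per participant a baseline BPM
  ~ N(72, 8²) (floored at 40), per message a 15 s exposure (configurable)
  with BPM = baseline − (planted deceleration + N(0, 0.45²)) + per-second
  N(0, 0.3²). The per-second noise default is deliberately small: the
  absolute-value fold in the change score turns zero-mean per-second
  noise into a positive bias of ≈ 2σφ(δ/σ) − 2δΦ(−δ/σ), negligible only
  when σ ≪ δ (δ ranges 1.5–3 BPM here). The 0.45 BPM trace-level sd
  reproduces the observed participant-level spread of deceleration
  scores (≈0.5 BPM). Recognition: 2 targets per message with hit
  probability = planted accuracy, 24 foils with a 0.2 false-alarm rate
  (foils affect nothing downstream; the rate just makes the task
  realistic). Dwell: a participant-message mean ~ N(planted, 780²) ms
  (the observed between-participant spread), split into three AOI values
  with 150 ms within-message jitter, clipped at 0 — the clip shifts
  generated dwell means up by ≈15–20 ms at these settings, which is well
  inside sampling error at the cohort sizes used and is accounted for in
  the recovery tests.
* **Deterministic mode** is the operational noise-free limit: construct
  scores equal planted means exactly (no discretization), traces
  decelerate exactly, dwells equal planted means, and recognition hits
  are assigned by quota (`round(p·2n)` of the `2n` cohort target trials),
  the only way a Bernoulli rate can be realized exactly. With the lab
  cohort at its default n = 120 the quota resolution (1/240) separates
  hit rates 0.005 apart, and the full pipeline then reproduces the
  reference rank matrix and the recomputed-rank scenarios exactly; this
  is verified end-to-end in the tests.

### What the generator does and does not emulate

It produces balanced designs, symmetric unimodal latent distributions,
i.i.d. per-second heart-rate noise, and no within-person correlation
across the twelve messages beyond a shared baseline (the magnitude of
any such correlation is not identifiable from the source aggregates).
Real data have dropout, skewed and multimodal response styles,
autocorrelated cardiac dynamics, and fatigue/order effects. Passing
recovery tests therefore demonstrates that the *pipeline arithmetic* is
unbiased and convergent under the stated generative model — not that the
field instruments are unbiased.

### Problem sizes in the recovery tests

Construct-mean recovery uses n = 5000 crowdsourced participants (≈417
per message, 3-SE criterion per cell); lab recovery uses the study's own
n = 120; rank-ordering recovery uses n = 5000 / 2000 with planted values
in the reference rank order spaced evenly at ≈5 standard errors of a
difference of recovered means — the printed means themselves are spaced
as closely as 0.01 points (engagement), which no realistic cohort could
resolve, so ordering recovery is checked on separated truths, with
planted-tie cells excluded (a noisy cohort cannot reproduce an exact
tie, and under competition ranking a tie's resolution leaves all other
cells' ranks unchanged). The convergence check compares mean absolute
recovery error at n = 50 versus n = 5000 on fixed seeds.

## Numerical choices and degenerate inputs

* Ranking delegates to `scipy.stats.rankdata(method="min")` on negated
  values; a brute-force counting oracle (`1 + #{strictly greater}`)
  guards it in the tests.
* Scenario ranking always uses full-precision scores; display rounding
  is presentation-only.
* Empty item lists, empty exposure series, messages without target
  trials or AOI records, missing decision-matrix cells (named
  message/attribute), duplicate message ids, negative weights, and empty
  component lists all raise a validation error (CLI exit code 2).
* Alpha requires ≥2 items, ≥2 participants and nonzero total-score
  variance; it may legitimately be ≤0 for discordant items.
* Weight-sweep tie detection uses a 1e-12 absolute slack on the sample
  minimum to keep exact rank ties counted as joint wins despite
  floating-point summation order.

## Known limitations

* The change-score fold (absolute values) cannot distinguish sustained
  acceleration from deceleration; interpretation as "deceleration"
  relies on the domain expectation that message exposure slows heart
  rate.
* The published lab total-rank ambiguity (above) is surfaced, not
  resolved; downstream numbers exist for both readings.
* Consensus uses the floor of n/2; with odd message counts the "top
  half" is the strict minority side.
* The generator's within-person correlation structure in the lab arm is
  a free design choice (shared baseline only), not an estimate.
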