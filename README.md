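# madmsg

Multi-attribute decision-making (MADM) for health risk-communication
message testing.

## The problem

Formative message testing for public-health campaigns (here: the risks of
waterpipe/hookah tobacco smoking for young adults) typically collects two
very different kinds of evidence about each candidate message:

* **self-report constructs** from a crowdsourced survey arm — receptivity
  (9 items, 1–7), engagement (3 items, 1–7), positive attitude (9 items,
  1–7) and negative emotion (4 items, 1–4); and
* **psychophysiological measures** from a lab arm — heart-rate
  deceleration during exposure (more deceleration = more cognitive
  resources allocated to encoding), recognition-memory hit rate for
  message fragments, and eye-tracking dwell time on areas of interest
  (AOIs).

These arms rarely agree on which message is "best". `madmsg` integrates
them with a weighted-sum MADM model over a decision matrix
`X ∈ R^(m×k)` of per-message attribute means (m = 12 messages, k = 7
attributes). Within each attribute the messages receive **competition
ranks** `r_ij = 1 + #{i' : x_i'j > x_ij}` (highest mean → rank 1; ties
share the minimum rank and the next distinct value skips by the tie-group
size). Attribute ranks are summed per study arm into rank totals
`T_i^(s) = Σ_{j∈s} r_ij`, and a weighting scenario with components
`c ∈ C` (attribute ranks or study-total ranks) and weights `w_c` gives
each message the summary score

```
S_i = Σ_c w_c · rank_c(i) / Σ_c w_c
```

with messages finally competition-ranked on `S_i` (smaller = better).
Four preset scenarios are built in: equal attribute weights, equal study
weights, prefer self-report, and prefer lab. The model deliberately does
no hypothesis testing — it is a transparent aggregation device for
decision making.

The package also ships a synthetic-cohort generator for both arms with
planted per-message effects, so the complete pipeline (item scoring →
signal summaries → decision matrix → scenarios → consensus) is testable
end-to-end without any participant data.

## Worked example

The bundled fixture `table1` is the published decision matrix of printed
per-message means. Evaluating the four scenarios in reproduction mode
(the published lab total-rank column substituted where a scenario
consumes a study total):

```
$ madmsg scenarios --published-totals --out table2.csv
           equal_attributes_score equal_attributes_rank equal_studies_score equal_studies_rank prefer_self_report_score prefer_self_report_rank prefer_lab_score prefer_lab_rank
message_id
H1                            4.0                     3                 6.5                5 *                      4.4                       4             4.75             4 *
H2                            4.4                     4                 3.0                1 *                      3.6                       3             4.75             4 *
HS1                           5.7                     5                 7.0                7 *                      5.0                     5 *             7.25             7 *
HS2                           3.6                   1 *                 3.5                  3                      3.2                     1 *             4.00               2
HF1                           6.6                     7                 7.5                  9                      6.4                       7             7.25             7 *
HF2                           3.6                   1 *                 3.0                1 *                      3.2                     1 *             3.75               1
A1                            5.9                     6                 5.0                  4                      5.0                     5 *             6.50               6
A2                            7.7                     9                 8.5                 10                      8.4                       8             7.25             7 *
AS1                           9.6                    11                 7.0                7 *                      8.8                     9 *             9.25              11
AS2                           9.1                    10                 9.5                 11                     10.2                      12             8.00              10
AF1                           7.0                     8                 6.5                5 *                      8.8                     9 *             4.50               3
AF2                          10.0                    12                10.0                 12                     10.0                      11            10.00              12

* denotes tied ranking.
```

Reading the HF2 row: its seven attribute ranks average to 3.6, tied for
best with HS2 under equal attribute weights (the `*` marks the tie), and
it is the single best message (3.75) when the lab measures are
preferred. Exactly five messages sit in the top half (rank ≤ 6) of every
scenario — the robust choices across weighting philosophies:

```
$ madmsg consensus --published-totals
A1
H1
H2
HF2
HS2
```

Other verbs: `simulate` (synthetic cohorts for both arms), `score` /
`physio` (summarize participant-level CSVs per arm), `rank` (decision
matrix → rank table with study totals), `sweep` (win frequency of each
message over weight vectors sampled uniformly on the simplex), and
`reproduce` (regenerate the bundled reference tables and verify them
against the golden copies). The same functionality is available as a
library, e.g.:

```python
from madmsg import load_decision_matrix, evaluate_scenarios, consensus_top_half

dm = load_decision_matrix("table1")
results = evaluate_scenarios(dm)          # computed total ranks throughout
consensus_top_half(results.values())      # ['A1', 'H1', 'H2', 'HF2', 'HS2']
```

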