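# Methods

## The scoring model

The MRF tool is an explicit, additive falls-risk score over a fixed catalog of
medication classes. Each class carries one of three tiers with the point values
high = 3, moderate = 2, low = 1; this label→score mapping is total and
hard-coded (`mrf.catalog.TIER_SCORES`), and a catalog file that states a
contradictory per-class score fails validation. A medication belonging to more
than one class contributes the *maximum* of the class scores — a deliberate
worst-case rule, so combination exposure is never under-counted — and the
patient total is the plain sum of contributions over distinct medications.
There are no interaction terms: the tier definitions mention risk "especially
in combination", but the instrument's arithmetic is a sum, and we implement
exactly that.

Assumptions worth making explicit:

* **Medications, not prescription lines.** Lists are deduplicated by
  normalized generic name before summation, so a drug supplied as two products
  counts once.
* **Combination products** (e.g. an ACE inhibitor + thiazide tablet) are one
  list entry; if that entry's generic resolves to several classes the max rule
  applies. Clinically this may under-count a true two-drug exposure; callers
  who disagree can list the components separately.
* **No dose, duration, route or renal-function adjustment** — outside the
  instrument's scope.
* **Referral flag**: true iff any resolved medication is high- or
  moderate-tier. No numeric threshold on the total is built in, because the
  interpretation and risk threshold of the summed score have not been
  established; the CLI's `--threshold` is an explicit user choice, not a
  recommendation.

## Drug-name normalization

Lookup is deterministic and fully offline: case-fold, trim, then strip
*trailing* tokens that are doses/strengths (`40mg`, `10mg/5ml`, `%`),
pharmaceutical forms (`tablets`, `m/r`, `solution`, …) and common salt
suffixes (`hydrochloride`, `tartrate`, …). Leading tokens are never stripped,
so `sodium valproate` is preserved and resolved through the catalog's synonym
table, which is also the only place brand names live. There is no external
terminology service (no ATC/RxNorm/SNOMED); anything the catalog does not
know stays `unresolved`, contributes 0, and is surfaced with a warning rather
than dropped — unresolved items are expected on real lists and form part of
the audit trail. Normalization is idempotent, so lookups agree on raw and
pre-normalized spellings.

## The packaged catalog and its provenance

The shipped file `src/mrf/data/mrf_catalog_v1_synthetic.json` has 19 classes
partitioned 10 high / 8 moderate / 1 low. The published description of the
final tool pins the ten high-risk classes and five of the moderate-risk
classes by name; the remaining three moderate classes (opioids, nitrates,
sulfonylureas) and the single low-risk class (cardiac glycosides) are
*reconstructions* chosen once on mechanism-of-action grounds, as are all
member drug lists — hence the `synthetic` in the filename and the explicit
`provenance` field. Two consequences:

* the catalog's *structure* (counts, tiers of the named classes, absence of
  the non-consensus classes such as SSRIs, SNRIs, selective alpha-blockers,
  prochlorperazine, cyclizine, dopaminergics and eye preparations) is
  faithful and tested;
* individual membership beyond the named classes should be reviewed before
  clinical use. The catalog is deliberately a human-editable JSON file with
  `version`/`provenance` fields so it can be amended without code changes.

The "antidepressants" high-risk class is implemented as *tricyclic and
related* antidepressants: a generic antidepressant class would contradict the
explicit exclusion of SSRIs and SNRIs from the final instrument.

## Delphi consensus engine

Raters score each item on the 5-point Likert scale (Strongly agree = 5 …
Strongly disagree = 1). Per item we report the number of responses, the
percentage agreeing (responses ≥ 4), the median, P₂₅, P₇₅ and the IQR. Missing
responses are excluded from both the numerator and denominator of the
agreement percentage and from the quantiles — the statistics describe
respondents, not the panel roster — and an all-missing item is an error naming
the item. Nothing is rounded internally; display rounding is one decimal, half
away from zero (the convention matched by every published panel percentage,
e.g. 7/22 → 31.8, 14/22 → 63.6).

**Quantile convention.** No interpolation method is attached to the published
rules. The default here is weighted-average interpolation at position (n+1)p —
the default of the commercial statistics package named in the study's analysis
description — with the method exposed as an option (`linear`, `hazen`,
`nearest` map onto the corresponding numpy conventions). The study's printed
P₂₅ = 3.8 for a 22-rater item is *not* reconstructible from integer responses
under any of these conventions (position (n+1)/4 = 5.75 yields values on a
0.25-grid, e.g. 3.75); we therefore treat 3.8 as a rounded or differently
computed figure and do not force agreement — the decision rule only needs
P₂₅ < 4, which is robust to that ambiguity.

**Decision rules.** Exactly one verdict per item:

1. retain iff median ≥ 4 and P₂₅ ≥ 4;
2. exclude if median ≤ 3 (any round);
3. otherwise modify and carry forward — except in the final round, where
   every non-retained item is excluded.

Two edges the three stated clauses do not address: an even respondent count
can produce a median of 4.5 (retained — the rule is implemented as median ≥ 4)
or a median strictly between 3 and 4 (treated conservatively: modify in
non-final rounds, exclude in the final round, since only the stated inclusion
clause can retain). The per-item `rule_trace` records when either edge fires.

The "at least 75% agreeing or strongly agreeing" phrasing is a gloss on the
P₂₅ rule, not an independent criterion: agreement % is reported descriptively
only. Exhaustive enumeration of all 1286 integer response multisets up to
n = 8 finds 83 vectors where the two tests disagree under the default
interpolation — always with agreement ≥ 75% but P₂₅ < 4 (e.g. [3,4,4,4]:
agreement 75%, P₂₅ = 3.25) — so the operative P₂₅ rule is strictly stricter.

**Rounds.** `run_round` decides every open item, carries forward the modified
items plus any `new_items` (criteria distilled from free-text comments — a
manual research-team input, not a computation), and errors if an item already
retained or excluded in a prior round reappears. Feedback mirrors the
controlled-feedback design: a group summary per item and a per-panellist table
of own response against the group median and agreement.

## Synthetic data

No raw panel responses were ever published, so the generators define the test
conditions. `generate_responses` draws each (item, panellist) cell
independently from a categorical distribution over 1–5 — independence mirrors
an anonymous panel; rater correlation, learning across rounds and attrition
are deliberately not modelled. A profile can be given as explicit
probabilities or via a target agreement probability `p_agree` (the defaults,
22 panellists and p_agree = 0.77, are the study's panel size and its reported
typical agreement level), with the agreeing mass split evenly between 4 and 5
and the remainder spread 20/30/50 over 1/2/3 — expert panels drift toward
Neutral rather than strong disagreement. Missingness is an independent
Bernoulli mask, with one response per item kept so statistics stay defined. A
single `numpy` Generator keyed by the seed drives each call, so fixtures are
bit-reproducible.

`generate_med_list` draws tier counts multinomially from the requested mix
over {high, moderate, low, unknown} and samples distinct generic names without
replacement within each tier ("unknown" draws from a fixed pool of common
drugs outside the catalog). A realized list therefore scores exactly
3·n_high + 2·n_moderate + n_low, and the expectation has the closed form
n·(3p_h + 2p_m + p_l) used by the law-of-large-numbers test. Because sampling
is without replacement, a tier cannot supply more drugs than its distinct
pool (the packaged low tier has two members); over-asking is an error rather
than silent replacement.

What passing tests on these generators do *not* show: anything about real
panels' correlation structure, real prescriptions' co-occurrence patterns
(e.g. polypharmacy clusters), or the clinical validity of the tiers
themselves — content validity is the instrument's claim, predictive validity
remains future work.

## Numerical and interface choices

* Percentile computation delegates to `numpy.percentile`; the independent
  test oracle re-implements (n+1)p interpolation by hand.
* Problem sizes in tests and the acceptance script — rule enumeration to
  n = 8 (1286 multisets × 2 round types), 300–500 simulated items,
  400 simulated patients — were chosen to put sampling error well inside the
  asserted bounds while keeping runs quick.
* Exit codes: 0 success, 2 validation failure (bad inputs, failed catalog
  checks, all-missing items), 1 unexpected — for scriptability in pharmacy
  pipelines.
* JSON reports are rendered with sorted keys so repeated runs are
  byte-identical.

## Known limitations

* Catalog membership beyond the explicitly named classes is a reconstruction
  (see above) — review before any clinical use.
* No dose/duration/route adjustment; no interaction modelling beyond the max
  rule; no score-threshold interpretation.
* The Delphi engine decides from statistics alone; turning comments into new
  survey items is human work supplied via `new_items`.
* Quantile-convention ambiguity means borderline P₂₅ values near 4 can change
  verdicts across methods; the method is therefore configurable and recorded
  in output.
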