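# mrf-tool — Medication-Related Fall screening and scoring

Falls are a leading cause of injury in older people, and medication use is an
established, modifiable risk factor. Fall-risk-increasing drugs (FRIDs) span
many therapeutic classes — sedatives, antihypertensives, diuretics,
anti-epileptics — and clinicians reviewing long medication lists need a fast
way to rank which patients most need a medication review.

This package implements the **Medication-Related Fall (MRF) screening and
scoring tool** for clinical pharmacists, geriatricians and researchers in
medicines optimisation, together with the **Delphi consensus engine** used to
validate such instruments and **seeded synthetic-data generators** for testing
both.

## The model

The MRF catalog assigns each of 19 medication classes a falls-risk tier with a
fixed point value:

| tier | definition | points |
|---|---|---|
| high (10 classes) | may commonly cause or contribute to falling risk, alone or in combination | 3 |
| moderate (8 classes) | may cause falls, especially in combination | 2 |
| low (1 class) | possibly cause falls, particularly in combination | 1 |

For a patient on medications *m₁ … mₖ* (deduplicated by generic name), each
medication contributes the score of the highest-risk class it belongs to,

```
contribution(m) = max{ s(c) : m ∈ c },   s ∈ {3, 2, 1},  0 if m is in no class
MRF total       = Σ contribution(mᵢ)
```

and any high- or moderate-risk medication raises a referral flag for a
medication review with fall-prevention strategies.

The Delphi engine computes, per rated item, the agreement percentage
(responses ≥ 4 on the 5-point Likert scale), the median and the quartiles
(weighted-average interpolation at position (n+1)p by default), then applies
the consensus rules: **retain** iff median ≥ 4 and P₂₅ ≥ 4; **exclude** if
median ≤ 3; otherwise **modify** and re-rate in the next round — except in the
final round, where every non-retained item is excluded.

> **Note on the packaged catalog.** The published final tool's full class table
> is not reproducible from the text available here; the shipped catalog
> (`mrf/data/mrf_catalog_v1_synthetic.json`) fixes the 12 classes and tiers the
> publication names explicitly and reconstructs the remainder (see the file's
> `provenance` field and `docs/methods.md`). Edit or replace it with
> `--catalog` — the file is plain JSON by design.

## Worked example

```bash
$ cat meds.txt
FUROSEMIDE 40mg tablets
bisoprolol 2.5mg
Amlodipine
digoxin 62.5 mcg
ascorbic acid
$ mrf score --meds meds.txt
Medication-related falls risk report
====================================
  FUROSEMIDE 40mg tablets: loop diuretics [high] -> 3 point(s)
      mechanism: Hypovolaemia and orthostatic hypotension; urinary urgency prompting rushed mobilisation.
  bisoprolol 2.5mg: beta-blockers [moderate] -> 2 point(s)
      mechanism: Bradycardia and hypotension; falls risk considered patient-specific, chiefly with orthostatic hypotension.
  Amlodipine: dihydropyridine calcium channel blockers [moderate] -> 2 point(s)
      mechanism: Vasodilation and hypotension, particularly in combination with other antihypertensives.
  digoxin 62.5 mcg: cardiac glycosides (digoxin) [low] -> 1 point(s)
      mechanism: Bradycardia and arrhythmia possibly contributing to syncope, particularly in combination; direct published evidence of increased falls risk is lacking.
  ascorbic acid: WARNING not in catalog (unresolved) -> 0 points
------------------------------------
Total MRF score: 8
Tier breakdown: high=1, moderate=2, low=1
Unresolved medications: 1
Referral: patient is taking high- or moderate-risk medication(s); refer for medication review and fall prevention strategies.
```

Dose, formulation and salt tokens are stripped and brand names resolved before
lookup (`FUROSEMIDE 40mg tablets` → `furosemide`); drugs outside the catalog
score 0 but are flagged, never dropped. The total of 8 = 3 + 2 + 2 + 1.

Other entry points:

```bash
mrf catalog validate packaged            # 19 classes, tier counts, index checks
mrf delphi analyze --responses r1.csv --round 1 --max-rounds 3
mrf simulate responses --items 500 --panellists 22 --p-agree 0.77 --seed 1 --out r.csv
mrf simulate meds --n 8 --mix high=0.4,moderate=0.4,low=0.1,unknown=0.1 --seed 1 --out meds.txt
```

The same operations are available as a library (`mrf.score_patient`,
`mrf.run_round`, `mrf.generate_responses`, …).

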