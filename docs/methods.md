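# Methods

This note documents the models and procedures implemented in `varpheno`,
the parameters that matter, the design choices made where the design was
genuinely open, and the limits of what the synthetic evaluation shows.

## Variant classification

### Evidence model

A variant's evidence is a set of activated criteria drawn from the 28
ACMG/AMP items: 1 pathogenic very strong (PVS1), 4 strong (PS1–4), 6
moderate (PM1–6), 5 supporting (PP1–5); 1 benign stand-alone (BA1), 4
strong (BS1–4), 7 supporting (BP1–7). Each criterion is activatable at most
once and always at its default strength — strength modulation (e.g. PM6
used at strong level, Bayesian point systems, gene-specific ClinGen VCEP
rules) is out of scope. Evidence is user-asserted through the
questionnaire; the package performs no automated evidence derivation from
VCFs, population databases, or in-silico predictors.

### Stage 1 — combination rules

The ACMG/AMP 2015 combination table is stored as data
(`varpheno.acmg.COMBINATION_RULES`): 8 pathogenic, 6 likely-pathogenic, 2
benign, 2 likely-benign rows, each a set of inclusive (min, max) count
constraints per strength category. All satisfied rules on both sides are
reported, not just the first; the tentative class is the strongest tier on
a side when exactly one side fires. Count constraints are minimums except
"1 PS + 1–2 PM", which is a bounded range (three or more moderates with a
strong criterion satisfy the corresponding Pathogenic row instead). The
engine's stage-1 outcome is verified against an independently written
literal transcription of the table over all
2·5·7·6·2·5·8 = 33,600 admissible count vectors.

### Stage 2 — conflict resolution

When both sides satisfy rules, a deterministic ladder applies, in order:

1. both sides hold strong-or-above evidence (PVS1/PS vs BA1/BS) → VUS
   (comparable strength);
2. the pathogenic side holds PVS1 or PS and the benign side lacks BA1/BS →
   the pathogenic-side tier;
3. the benign side holds BA1 or BS and the pathogenic side lacks PVS1/PS →
   the benign-side tier;
4. the pathogenic side has ≥2 PM and the benign side lacks BS → the
   pathogenic-side tier;
5. otherwise VUS.

The ladder depends only on the activated set, never on input order.

### Stage 3 — conditional VUS overrides

Activated only when no combination rule fired **and** the profile holds no
strong-or-above evidence (no PVS1, no PS, no BS; BA1 alone would already
have classified at stage 1). Any one of five incomplete-evidence conditions
forces VUS, and every triggering condition is named in the rationale:
functional studies not done; variant not located in a known mutational
hotspot or critical domain; assumed de novo without confirmed parentage;
observed in healthy individuals in a genotype inconsistent with the
disease; alternate molecular basis for disease in the case. The "any of"
reading (rather than requiring several conditions jointly) is a design
choice: each condition alone already marks the evidence as incomplete.

### Stage 4 — weighted score

For profiles still unclassified, the score is the sum of fixed per-category
weights — BA1 = 1, BS = 2, BP = 3, PP = 4, PM = 8, PS = 16, PVS1 = 32 —
over all activated criteria, mapped through fixed bands:

| score | class |
|-------|-------|
| 0–2   | LB    |
| 3–8   | B     |
| 9–16  | VUS   |
| 17–25 | VUS   |
| 26–48 | LP    |
| ≥49   | P     |

Numerical choices here: the published band description leaves 9–16 unmapped
and gives the Pathogenic band an open top; the gap defaults to VUS (the
safe class for intermediate evidence) and the P band is open-ended (the
maximum achievable score, all 28 criteria, is 194). The LB-below-B ordering
is implemented literally — it follows the weight gradient (BA1 = 1 lands in
the LB band) — and every score-decided benign-side report carries a note
flagging it. One special case: a profile with **zero** activated criteria
returns VUS, never the LB that a literal score of 0 would give — absence of
evidence is not benign evidence. The score is computed for every result as
an informational quantity but decides the class only at this stage.

### Questionnaire

The question set and its answer→criterion mapping are data (a YAML
definition shipped in `varpheno/data/questionnaire.yaml`, replaceable per
site). Twenty questions cover all 28 criteria and every context flag across
the seven standard evidence areas. Mutually exclusive activations are
enforced by single multiple-choice questions: de novo status (confirmed →
PS2, assumed → PM6) and population frequency (>5% → BA1, above disease
expectation → BS1, absent/extremely rare → PM2). Unanswered questions are
conservatively treated as "No" and activate nothing. The shipped wording is
this package's own; only the criterion definitions behind it are standard.

## Phenotype screen and prioritization

The screen computes `100·k/N` for `k` present indicators out of a panel of
`N` (default 24) and labels the patient positive at or above the threshold
(default 30%, a parameter so the boundary rule is testable at any panel
size). The displayed percentage is rounded half-up to one decimal (10/24 →
41.7); the threshold comparison uses the unrounded value.

Prioritization validates input symptoms against the knowledgebase index —
matching is exact after normalization (trim, case-fold, collapse internal
whitespace); no fuzzy or ontology-aware matching — deduplicates them,
reports unrecognized names without failing, and scores each condition by
its column sum over the validated rows. Ranking is by score descending with
ties broken by knowledgebase column order (stable); all co-maximal
conditions are reported as the top recommendation. Symptom weighting by
specificity is a known omission, as is HPO term resolution.

The default screening panel contains the ten documented core indicators
plus fourteen synthetic, clinically plausible placeholders; the packaged
example knowledgebase (`data/example_kb_synthetic.csv`, 21 symptoms × 8
conditions) is likewise a synthetic stand-in whose dystroglycanopathy
column carries the eight hallmark symptoms of the worked example. Both are
replaceable through files at the CLI and API level.

## Synthetic fixtures and what they show

`generate_synthetic_knowledgebase` draws i.i.d. Bernoulli(density)
associations (defaults 141 symptoms × 34 conditions, density 0.15, matching
the scale of the curated knowledgebase) and guarantees each condition at
least one symptom. Real knowledgebases have correlated, block-structured
associations and heavy-tailed symptom frequencies; the generator does not
emulate those, so passing tests demonstrate algorithmic correctness (score
arithmetic, ranking, tie handling), not clinical retrieval performance.

`generate_synthetic_gene_table` (default 747 records) emulates the curated
gene collection's schema — symbol, chromosome, locus, diseases, inheritance
modes, external identifiers — with uniform random content, enough to
exercise parsing, per-row error reporting, and the chromosome × inheritance
summary.

`generate_synthetic_evidence_profiles` draws criteria per category from
class-specific activation probabilities and random contexts, labels each
(profile, context) with `oracle_classify_counts` — a self-contained,
branch-written reference classifier deliberately independent of the
data-driven engine — and rejection-samples to a balanced request (default
100 profiles, 20 per class; bounded attempts, seeded, byte-reproducible).
The balanced evaluation classifies these end to end and scores concordance
against the oracle labels. This is a desk-scale substitute for an external
100-variant comparison against curated databases, which requires manually
curated evidence answers per variant; perfect concordance here shows the
engine implements its specification exactly, not that it would agree with
any external curator.

The concordance evaluator reports both exact-label and merged-category
({P, LP} / {VUS} / {LB, B}) percent agreement side by side, because
published comparisons mix the two readings; references may contain an
`unknown` label (kept in an extra confusion-matrix row, discordant under
both modes). Percentages are displayed to one decimal, rounded half-up.

## Problem sizes and determinism

The rule-table equivalence enumerates all 33,600 count vectors (seconds on
one CPU). Prioritizer equivalence uses 100 seeded random knowledgebases of
30 × 10 at density 0.25 — small enough to brute-force, large enough to hit
ties and zero rows. All generators are pure functions of their spec,
including the seed; the CLI logs input digests and the package version to
standard error so runs are attributable, and no subcommand mutates its
inputs.

## Known limitations

- Evidence quality is the user's responsibility: the classifier formalizes
  combination logic, it does not validate the underlying assertions.
- No criterion strength modulation, gene-specific rule specifications, or
  quantitative Bayesian frameworks.
- HGVS strings are carried as free text (non-empty is the only check).
- The phenotype engine treats symptoms as exchangeable binary features; two
  conditions sharing a symptom count are indistinguishable regardless of
  how specific the matched symptoms are.
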