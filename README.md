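# varpheno

Variant classification and phenotype-driven disease prioritization for
neuromuscular genetic disorders (NMGDs), as a tested, scriptable Python
package with a `varpheno` command-line interface.

NMGDs — inherited diseases of peripheral nerve, motor neuron, neuromuscular
junction, or skeletal muscle — involve over 700 genes with strongly
overlapping clinical presentations, so diagnosis hinges on two coupled
tasks: narrowing the differential diagnosis from a patient's phenotype, and
classifying the sequence variants found by testing. `varpheno` implements
one engine for each, aimed at clinicians, genetic counselors, and
laboratory scientists who need reproducible, auditable versions of both
steps.

## The two engines

### ACMG/AMP variant classifier

A four-stage hierarchical decision system over the 28 standard ACMG/AMP
evidence criteria (PVS1; PS1–4; PM1–6; PP1–5; BA1; BS1–4; BP1–7), fed by a
structured questionnaire (YAML/JSON answer files or an interactive prompt
session):

1. **Combination rules** — the canonical ACMG/AMP 2015 criterion-combination
   table (e.g. PVS1 + ≥1 PS ⇒ Pathogenic, PVS1 + 1 PM ⇒ Likely Pathogenic,
   BA1 ⇒ Benign), stored as data so it can be enumerated and audited. If
   rules fire on exactly one side, the strongest tier wins.
2. **Conflict resolution** — when pathogenic- and benign-side rules fire
   simultaneously, a deterministic ladder weighs strong-or-above evidence
   (PVS/PS vs BA1/BS); comparable strength defaults to VUS.
3. **Conditional VUS overrides** — with no rule satisfied and no strong
   evidence, incomplete-evidence conditions (functional studies not done,
   variant not in a known hotspot, assumed de novo without confirmed
   parentage, observed in healthy individuals with an inconsistent
   genotype, alternate molecular basis) force VUS.
4. **Weighted score fallback** — the quantitative score
   `S = Σ w(c)` over activated criteria with
   `w = {BA1: 1, BS: 2, BP: 3, PP: 4, PM: 8, PS: 16, PVS1: 32}`, mapped
   through fixed bands (0–2 LB, 3–8 B, 9–25 VUS, 26–48 LP, ≥49 P).

The result is one of the five standard tiers — Pathogenic (P), Likely
Pathogenic (LP), Uncertain Significance (VUS), Likely Benign (LB), Benign
(B) — with the deciding stage, satisfied rules, per-strength criterion
counts, total score, and rationale in a machine- and human-readable report.

### Phenotype screen and prioritizer

* **Screen** — a panel of binary clinical indicators (default 24, each worth
  one point) gives `score = 100 · k / N` percent; at or above the 30%
  threshold the patient is flagged "NMGD likely Positive".
* **Prioritize** — patient symptoms are validated against the symptom index
  of a binary symptom × condition knowledgebase `M` and each condition `c`
  scores `Σ_s M[s, c]` over the validated symptoms `s`; conditions are
  ranked by score descending, and all co-maximal conditions are reported as
  the top recommendation, with a nested condition → matched-symptom summary
  for sunburst-style visualisation.

The package ships a small synthetic example knowledgebase; real
knowledgebases load from CSV/TSV (`+`/empty cells). Seeded generators
produce synthetic knowledgebases, gene tables, and oracle-labelled evidence
profiles for evaluation, and a concordance evaluator compares two
classification sources (5×5 confusion matrix, percent agreement at
exact-label and merged-category resolution).

## Worked example

Classify a hemizygous null variant absent from population databases:

```sh
cat > answers.yaml <<EOF
variant_name: NM_004006.3:c.9568C>T
condition: Duchenne muscular dystrophy
zygosity: hemizygous
inheritance: x_linked
answers:
  variant_type: null_variant
  population_frequency: absent_or_extremely_rare
EOF
varpheno classify --answers answers.yaml
```

prints

```
Variant   : NM_004006.3:c.9568C>T
Condition : Duchenne muscular dystrophy
Class     : LP
Rationale : PVS1 + PM2
Stage     : combination_rule
Counts    : PVS:1 PS:0 PM:1 PP:0 BA1:0 BS:0 BP:0
Score     : 40
Criteria  :
  PVS: PVS1
  PM: PM2
```

i.e. the null-variant answer activates PVS1, the frequency answer PM2, and
the combination rule PVS1 + 1 PM classifies the variant Likely Pathogenic at
stage 1; the informational weighted score is 32 + 8 = 40.

Screen and prioritize:

```sh
varpheno screen -p "muscle weakness" -p "frequent falls" \
  -p "breathing difficulties" -p "cardiac involvement" \
  -p "difficulty in swallowing" -p "difficulty in climbing stairs" \
  -p "toe walking" -p "joint contractures" \
  -p "cognitive impairment" -p "impaired vision"
```

```
Indicators present : 10 / 24
Screening score    : 41.7%
Result             : NMGD likely Positive
```

```sh
varpheno prioritize -s ophthalmoplegia -s "facial muscle weakness" \
  -s hypotonia -s "white matter signal abnormalities" -s dysmorphism \
  -s "growth failure" -s spasticity -s "spastic paralysis of legs"
```

```
Validated symptoms : 8
Top recommendation : Dystroglycanopathy
Ranking:
   1. Dystroglycanopathy  (matched symptoms: 8)
   2. Nemaline myopathy  (matched symptoms: 2)
   3. Mitochondrial myopathy  (matched symptoms: 2)
   ...
```

All eight symptoms match the dystroglycanopathy column of the example
knowledgebase, so it ranks first with score 8.

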