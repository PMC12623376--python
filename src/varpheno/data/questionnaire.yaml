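# Default evidence-intake questionnaire.
#
# Each question maps answers onto ACMG criteria and/or variant-context
# flags.  `criteria` entries activate a criterion when the answer equals
# `when` (yes/no questions activate on `true`); `context` entries set a
# VariantContext field from the answer through `map`.
#
# The question set spans the seven evidence areas of a standard variant
# intake: variant type, population frequency, computational predictions,
# functional assays, segregation/de novo, cis-trans configuration, and
# prior reports from reputable sources.
questions:
  - id: variant_type
    text: >-
      What type of variant is this?  "Null" covers nonsense, frameshift,
      canonical splice-site, initiation-codon and single/multi-exon
      deletion variants in a gene where loss of function is a known disease
      mechanism.
    kind: multiple_choice
    choices:
      - null_variant
      - missense
      - synonymous_no_predicted_splice_impact
      - in_frame_indel_in_repeat_region
      - other
    criteria:
      - code: PVS1
        when: null_variant
      - code: BP7
        when: synonymous_no_predicted_splice_impact
      - code: BP3
        when: in_frame_indel_in_repeat_region

  - id: population_frequency
    text: >-
      What does population-database (e.g. gnomAD) allele frequency show for
      this variant?
    kind: multiple_choice
    choices:
      - greater_than_5_percent
      - above_expectation_for_disease
      - absent_or_extremely_rare
      - present_but_uninformative
    criteria:
      - code: BA1
        when: greater_than_5_percent
      - code: BS1
        when: above_expectation_for_disease
      - code: PM2
        when: absent_or_extremely_rare

  - id: same_amino_acid_change_as_pathogenic
    text: >-
      Does the variant produce the same amino-acid change as a previously
      established pathogenic variant (different nucleotide change)?
    kind: yes_no
    criteria:
      - code: PS1

  - id: de_novo_status
    text: De novo status of the variant in the proband.
    kind: multiple_choice
    choices:
      - confirmed
      - assumed
      - not_applicable
    criteria:
      - code: PS2
        when: confirmed
      - code: PM6
        when: assumed
    context:
      - field: de_novo_status
        map:
          confirmed: confirmed
          assumed: assumed
          not_applicable: not_applicable

  - id: functional_assay
    text: What do well-established functional studies show?
    kind: multiple_choice
    choices:
      - damaging
      - benign
      - not_done
    criteria:
      - code: PS3
        when: damaging
      - code: BS3
        when: benign
    context:
      - field: functional_studies_done
        map:
          damaging: true
          benign: true
          not_done: false

  - id: case_control_enrichment
    text: >-
      Is the prevalence of the variant in affected individuals significantly
      increased over controls?
    kind: yes_no
    criteria:
      - code: PS4

  - id: in_hotspot_or_critical_domain
    text: >-
      Is the variant located in a mutational hotspot or a critical,
      well-established functional domain without benign variation?
    kind: yes_no
    criteria:
      - code: PM1
    context:
      - field: in_hotspot_or_critical_domain
        map:
          true: true
          false: false

  - id: in_trans_with_pathogenic
    text: >-
      For a recessive disorder, is the variant detected in trans with a
      pathogenic variant?
    kind: yes_no
    criteria:
      - code: PM3

  - id: protein_length_change
    text: >-
      Does the variant change protein length (in-frame indel in a
      non-repeat region, or stop-loss)?
    kind: yes_no
    criteria:
      - code: PM4

  - id: novel_missense_at_pathogenic_residue
    text: >-
      Is this a novel missense change at an amino-acid residue where a
      different pathogenic missense change has been seen before?
    kind: yes_no
    criteria:
      - code: PM5

  - id: cosegregation
    text: >-
      Does the variant cosegregate with disease in multiple affected family
      members?
    kind: yes_no
    criteria:
      - code: PP1

  - id: missense_in_constrained_gene
    text: >-
      Is this a missense variant in a gene with a low rate of benign
      missense variation where missense is a common disease mechanism?
    kind: yes_no
    criteria:
      - code: PP2

  - id: computational_predictions
    text: Do multiple lines of computational evidence agree?
    kind: multiple_choice
    choices:
      - concordant_damaging
      - concordant_benign
      - conflicting
      - not_available
    criteria:
      - code: PP3
        when: concordant_damaging
      - code: BP4
        when: concordant_benign

  - id: phenotype_specific_for_gene
    text: >-
      Is the patient's phenotype or family history highly specific for a
      disease with a single genetic etiology in this gene?
    kind: yes_no
    criteria:
      - code: PP4

  - id: reputable_report
    text: >-
      Has a reputable source recently reported the variant, without
      accessible primary evidence?
    kind: multiple_choice
    choices:
      - reported_pathogenic
      - reported_benign
      - none
    criteria:
      - code: PP5
        when: reported_pathogenic
      - code: BP6
        when: reported_benign

  - id: observed_healthy_inconsistent_genotype
    text: >-
      Has the variant been observed in a healthy adult with a genotype
      (homozygous, hemizygous, or heterozygous for a dominant condition)
      inconsistent with the disease?
    kind: yes_no
    criteria:
      - code: BS2
    context:
      - field: observed_healthy_inconsistent_genotype
        map:
          true: true
          false: false

  - id: non_segregation
    text: Does the variant fail to segregate with disease in affected family members?
    kind: yes_no
    criteria:
      - code: BS4

  - id: missense_where_only_truncating_pathogenic
    text: >-
      Is this a missense variant in a gene where primarily truncating
      variants cause disease?
    kind: yes_no
    criteria:
      - code: BP1

  - id: in_cis_with_pathogenic
    text: Is the variant observed in cis with a pathogenic variant?
    kind: yes_no
    criteria:
      - code: BP2

  - id: alternate_molecular_basis
    text: Was the variant found in a case with an alternate molecular basis for disease?
    kind: yes_no
    criteria:
      - code: BP5
    context:
      - field: alternate_molecular_basis
        map:
          true: true
          false: false
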