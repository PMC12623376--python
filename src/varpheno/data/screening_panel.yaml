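# Default 24-indicator neuromuscular screening panel.
#
# The first ten indicators are the documented core screen; the remaining
# fourteen are synthetic, clinically plausible placeholders for the full
# curated panel.  Replace with `--panel` / load_panel for a site-specific
# panel.
indicators:
  - muscle weakness
  - frequent falls
  - breathing difficulties
  - cardiac involvement
  - difficulty in swallowing
  - difficulty in climbing stairs
  - toe walking
  - joint contractures
  - cognitive impairment
  - impaired vision
  - delayed motor milestones
  - hypotonia
  - muscle cramps
  - exercise intolerance
  - calf hypertrophy
  - scapular winging
  - foot drop
  - ptosis
  - facial weakness
  - scoliosis
  - tongue fasciculations
  - elevated creatine kinase
  - family history of neuromuscular disease
  - sensory disturbances
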