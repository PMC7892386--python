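# Default mapping from intervention descriptions to the direction of effect
# on protein product/activity. Edit or extend, then pass the file to
# read_observations(..., intervention_map=load_intervention_map(path)).
# Matching is case-insensitive on the whole intervention string.
decrease:
  - knockout
  - knockdown
  - knock-down
  - sirna
  - shrna
  - antisense
  - antibody
  - inhibitor
  - haploinsufficiency
  - dominant negative
  - neutralisation
increase:
  - overexpression
  - knockin
  - knock-in
  - transgenic
  - protein
  - agonist
  - activator
  - recombinant protein
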