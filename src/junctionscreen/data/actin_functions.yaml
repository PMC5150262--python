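# Vocabulary of manually curated actin-remodelling function classes.
# These names are data, not code: replace this file with your own curation
# to use a different ontology. The pipeline only requires that every
# annotation row uses a name from this list.
functions:
  - polymerization
  - bundling
  - capping
  - severing_depolymerization
  - cross_linking
  - branching
  - trafficking
  - contraction
  - adhesion_regulation
  - filament_stabilization
  - nucleation
  - scaffolding
  - motor_activity
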