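# Ordered NOVA classification rules (first match wins).  A food's descriptor
# flags are matched against require_flags; the first rule whose flags are all
# present assigns the processing level.  Foods matching no rule default to
# level 4 (ultra-processed) with a warning.
rules:
  - level: 4
    require_flags: [ultra_processed]
  - level: 4
    require_flags: [soft_drink]
  - level: 2
    require_flags: [culinary_ingredient]
  - level: 3
    require_flags: [processed]
  - level: 1
    require_flags: [raw_vegetable]
  - level: 1
    require_flags: [fresh_fruit]
  - level: 1
    require_flags: [raw]
  - level: 1
    require_flags: [fresh]
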