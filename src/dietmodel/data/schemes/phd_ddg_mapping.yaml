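# Food-group correspondence between the Planetary Health Diet and the Dutch
# Dietary Guidelines (after the red-meat and cheese merges applied by
# load_phd()/load_ddg()).  Matching is by food nature and is explicit
# configuration: added sugars (PHD) and drinks (DDG) have no equivalent in
# the other scheme and are deliberately absent from the pair list.
pairs:
  - [whole_grains, bread]
  - [tubers, cereal_potatoes]
  - [vegetables, vegetables]
  - [fruits, fruits]
  - [dairy, dairy]
  - [red_meat, meat]
  - [poultry, poultry]
  - [eggs, eggs]
  - [fish, fish]
  - [legumes, legumes]
  - [nuts, nuts]
  - [added_fats, fats]
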