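# Default structure-name normalization rules for the ten organs at risk
# tracked by the registry. Patterns are case-insensitive globs matched against
# raw planning-system labels; the first matching rule wins.
- pattern: ["heart*", "*coeur*"]
  canonical: heart
- pattern: ["l*lung*", "lung*l*", "*left*lung*", "*lung*left*"]
  canonical: left_lung
- pattern: ["r*lung*", "lung*r*", "*right*lung*", "*lung*right*"]
  canonical: right_lung
- pattern: ["l*kidney*", "kidney*l*", "*left*kidney*", "*kidney*left*", "l*ren*"]
  canonical: left_kidney
- pattern: ["r*kidney*", "kidney*r*", "*right*kidney*", "*kidney*right*", "r*ren*"]
  canonical: right_kidney
- pattern: ["liver*", "*hepat*"]
  canonical: liver
- pattern: ["stomach*", "*gastr*"]
  canonical: stomach
- pattern: ["esophagus*", "oesophagus*", "*esoph*"]
  canonical: esophagus
- pattern: ["trachea*"]
  canonical: trachea
- pattern: ["thyroid*", "*thyroid*"]
  canonical: thyroid
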