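{
  "_comment": "Synthetic default keyword/regex baseline written for this package; not a published ruleset. Edit freely: each category lists ordered include/exclude patterns. An include match is suppressed when an exclude pattern matches within +/-5 words of the matched span. Patterns are case-insensitive and matched against normalized text (lowercase words joined by single spaces).",
  "adenoma": [
    {"pattern": "adenoma", "polarity": "include"},
    {"pattern": "(sessile serrated|traditional serrated|serrated) adenoma", "polarity": "exclude"}
  ],
  "serrated": [
    {"pattern": "sessile serrated|traditional serrated", "polarity": "include"}
  ],
  "advanced": [
    {"pattern": "adenocarcinoma", "polarity": "include"},
    {"pattern": "high.?grade dysplasia", "polarity": "include"},
    {"pattern": "villous", "polarity": "include"},
    {"pattern": "\\b(1[0-9]|[2-9][0-9]) ?mm\\b", "polarity": "include"}
  ]
}
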