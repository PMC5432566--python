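# Cyclic-lipopeptide family templates.
#
# Each position is a list of allowed residue symbols (merged "Leu/Ile" for the
# isobaric pair), or null for a position the template does not constrain.
# A template with any null position is treated as incomplete (a stub): it is
# kept in the registry but never matched during classification.
#
# Surfactin: heptapeptide Glu1-Leu/Ile2-Leu3-Val4-Asp5-Leu6-Leu/Ile7 closed
# into a lactone with a beta-hydroxy fatty acid (position "R", reported as a
# carbon count n). Positions 3 and 6 are Leu and position 5 is Asp in the
# canonical family definition; at unit mass resolution Leu is reported as the
# merged Leu/Ile label.
surfactin:
  positions:
    - [Glu]
    - [Leu/Ile]
    - [Leu/Ile]
    - [Val]
    - [Asp]
    - [Leu/Ile]
    - [Leu/Ile]
  lipid_range: [10, 17]
  cyclic: true

# Stubs for the other Bacillus lipopeptide families. Fill in the positions to
# enable them; incomplete templates are skipped by the classifier.
iturin:
  positions: [[Asn], null, null, null, null, null, null]
  lipid_range: [13, 17]
  cyclic: true
fengycin:
  positions: [[Glu], null, null, null, null, null, null, null, null, null]
  lipid_range: [13, 19]
  cyclic: true
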