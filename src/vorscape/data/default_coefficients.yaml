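# Default VORS coefficient tables for the six-class land-use legend
#   1 cropland, 2 forest, 3 grassland, 4 water, 5 built-up, 6 unused
#
# These are documented, replaceable defaults in the spirit of the
# expert-knowledge coefficient tables used by regional ecosystem-health
# assessments (natural vegetated classes resilient and service-rich,
# built-up land at the bottom).  Supply your own table for real studies.
class_names:
  1: cropland
  2: forest
  3: grassland
  4: water
  5: builtup
  6: unused

# ecosystem resilience coefficient per class, in [0, 1]
erc:
  1: 0.50
  2: 0.90
  3: 0.80
  4: 0.75
  5: 0.20
  6: 0.30

# ecosystem service coefficient per class, in [0, 1]
esc:
  1: 0.45
  2: 0.85
  3: 0.65
  4: 0.90
  5: 0.05
  6: 0.15

# spatial-neighbour effect, percent adjustment applied per adjacent cell:
# sne[a][b] is added to SNE_j (in percent) for each neighbour of class b
# around a pixel of class a.  Positive: the neighbour enhances the
# pixel's services; negative: it suppresses them.
sne:
  1: {1: 0.2, 2: 0.5, 3: 0.3, 4: 0.6, 5: -0.6, 6: -0.2}
  2: {1: 0.1, 2: 0.8, 3: 0.4, 4: 0.6, 5: -0.8, 6: -0.3}
  3: {1: 0.1, 2: 0.5, 3: 0.6, 4: 0.5, 5: -0.6, 6: -0.3}
  4: {1: 0.0, 2: 0.6, 3: 0.4, 4: 0.8, 5: -1.0, 6: -0.4}
  5: {1: 0.1, 2: 0.4, 3: 0.3, 4: 0.4, 5: -0.2, 6: -0.1}
  6: {1: 0.1, 2: 0.3, 3: 0.3, 4: 0.4, 5: -0.3, 6: 0.0}
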