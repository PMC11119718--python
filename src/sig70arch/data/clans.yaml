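# Clan registry: letter -> set of essential domains and canonical core pattern
# (each essential domain exactly once, in canonical N->C rank order).
# Z is the miscellaneous clan with undetermined core patterns; every core
# pattern routed to Z is treated as non-canonical (families Z.5+, Z.9+, ...).
clans:
  A: {essential: [r1_2, r2, r3, r4], canonical: [r1_2, r2, r3, r4]}
  B: {essential: [r1_2, r2, r4], canonical: [r1_2, r2, r4]}
  C: {essential: [r2, r3, r4], canonical: [r2, r3, r4]}
  D: {essential: [r2, r3, r4_2], canonical: [r2, r3, r4_2]}
  E: {essential: [r2, r4], canonical: [r2, r4]}
  F: {essential: [r2, r4_2], canonical: [r2, r4_2]}
  G: {essential: [r1_2], canonical: [r1_2]}
  H: {essential: [r2], canonical: [r2]}
  I: {essential: [r3], canonical: [r3]}
  J: {essential: [r4], canonical: [r4]}
  K: {essential: [r4_2], canonical: [r4_2]}
  L: {essential: [ECF], canonical: [ECF]}
# Registered non-canonical core patterns, per clan, in registration order:
# the k-th pattern owns family indices 4k+1 .. 4k+4.
noncanonical:
  A:
    - [r1_2, r3, r2, r3, r4]
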