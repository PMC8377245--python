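# Per-residue disorder propensity, rescaled to [0, 1].
# Derived from a published disorder/order discriminating scale (TOP-IDP-type
# ranking) by a linear map of the raw values onto [0, 1]: disorder-promoting
# residues (P, E, K, S, Q, R, G, D) score high; order-promoting aromatic and
# hydrophobic residues (W, F, Y, I, M, L, V, C) score low.
name: topidp-rescaled
values:
  A: 0.505
  C: 0.462
  D: 0.575
  E: 0.866
  F: 0.100
  G: 0.561
  H: 0.634
  I: 0.213
  K: 0.786
  L: 0.298
  M: 0.260
  N: 0.476
  P: 1.000
  Q: 0.642
  R: 0.569
  S: 0.655
  T: 0.504
  V: 0.408
  W: 0.000
  Y: 0.200
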