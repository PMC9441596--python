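# Example condition file for an anaerobic (fully fermentative) batch state on
# an ecYeastGEM-style model: oxygen removed, physiological caps on the
# overflow-product exchanges, and the mitochondrial-to-cytosolic serine
# transport blocked.  Reaction identifiers must match the loaded model;
# adjust biomass/maintenance parameterization through additional bound
# overrides as required by the model version in use.
name: anaerobic_batch
bounds:
  r_1992_REV: [null, 0.0]        # oxygen uptake closed
  r_2033: [null, 0.05]           # pyruvate exchange, physiological cap
  r_1631: [null, 0.05]           # acetaldehyde exchange
  r_1549: [null, 0.05]           # (R,R)-2,3-butanediol exchange
  r_1810: [null, 0.05]           # glycine exchange
blocked:
  - r_2045_REV                   # L-serine transport, mitochondrion -> cytosol
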