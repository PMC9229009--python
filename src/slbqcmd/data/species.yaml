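# Packaged lipid species constants.
# mw: average molecular weight (g/mol); v_tail: hydrophobic tail volume
# (nm^3/molecule).  Egg-derived PG and PC are acyl-chain mixtures treated as
# single species with average constants; LPG carries one chain.
PG:  {mw: 782.0, v_tail: 0.96}
LPG: {mw: 506.0, v_tail: 0.46}
PC:  {mw: 770.0, v_tail: 0.96}
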