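# Built-in gapped signature motifs of the IL-12 family.
#
# The three fn3-domain signatures of the beta-subunit C-terminus, written as
# ordered anchors separated by intervals of one or more residues ("-"), plus
# the contiguous WSXWS hallmark of class-I cytokine receptors.
# Anchor syntax: a literal residue string, or alternatives joined by "/".
signatures:
  - motif_id: F-I-KPDPP
    anchors: [F, I, KPDPP]
  - motif_id: W-P-W-P-F-L-K/F
    anchors: [W, P, W, P, F, L, K/F]
  - motif_id: V-A-S-WS
    anchors: [V, A, S, WS]
wsxws:
  motif_id: WSXWS
  pattern: WS.WS
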