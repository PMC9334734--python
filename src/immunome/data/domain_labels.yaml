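# Canonical label map: signature accession -> domain label, seeded from the
# signatures used for the TLR domain-architecture heatmap. LRR subtypes from
# the member databases (typical, bacterial, sds22-like, BspA, ribonuclease-
# inhibitor-like) all collapse onto the LRR label; the cysteine-rich
# C-terminal flanking cap keeps its own label so "LRR with CT flank" remains
# detectable. Phobius signal-peptide / transmembrane calls use the literal
# signature strings Phobius emits.
labels:
  TIR:
    - IPR000157
  LRR:
    - IPR001611      # single leucine-rich repeat
    - IPR032675      # LRR domain superfamily
    - IPR003591      # typical subtype
    - SM00369
    - SM00364        # bacterial type
    - SM00365        # sds22-like
    - IPR026906      # BspA type
    - "G3DSA:3.80.10.10"  # ribonuclease-inhibitor-like fold
  LRR_CT:
    - IPR000483      # cysteine-rich flanking region, C-terminal
    - SM00082
  ROC:
    - IPR020859
  COR:
    - IPR032171
  MBT:
    - IPR004092
  EF:
    - IPR002048
  CARD:
    - IPR031964      # RIG-I/MAVS-type CARD
    - IPR001315
  DEATH:
    - IPR000488
  RLR_CTD:
    - IPR038557      # RIG-I-like receptor C-terminal regulatory domain
    - IPR011545
    - IPR021673
  ARM:
    - IPR000225
    - IPR016024
  EGF:
    - IPR000742
  SP:
    - SIGNAL_PEPTIDE
    - SIGNAL_PEPTIDE_N_REGION
    - SIGNAL_PEPTIDE_H_REGION
    - SIGNAL_PEPTIDE_C_REGION
  TM:
    - TRANSMEMBRANE
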