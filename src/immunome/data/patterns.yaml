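# Declarative architecture patterns over merged domain intervals.
# required: label -> minimum number of merged intervals; forbidden: labels
# that must be absent for the flag to fire.
patterns:
  - name: dual_TIR
    required: {TIR: 2}
  - name: ROCO
    required: {ROC: 1, COR: 1}
  - name: LRR_CT_flank
    required: {LRR: 1, LRR_CT: 1}
  - name: CARD_present
    required: {CARD: 1}
  - name: CARD_absent_RLR
    required: {RLR_CTD: 1}
    forbidden: [CARD]
  - name: Mbt_accessory
    required: {MBT: 1, TIR: 1}
  - name: EF_hand_accessory
    required: {EF: 1, TIR: 1}
  - name: multi_TM
    required: {TM: 2}
  - name: SP_present
    required: {SP: 1}
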