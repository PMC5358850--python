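# 20-gene lymph-node-metastasis expression signature (qRT-PCR assay panel).
# Direction labels record behaviour in lymph-node-positive tumors; only the
# eight directions documented for the published signature are filled in —
# the remaining twelve are unspecified and must be set before scoring.
genes:
  - TOX3
  - SLC11A2
  - FAM36A/COX20
  - LIMCH1
  - RAB15
  - AVL9
  - PCMTD2
  - PTHLH
  - DPP4
  - PCDHGA10
  - MT1E
  - MAP4K4
  - SLC16A1
  - BST2
  - MMP14
  - IFI27
  - NCLN
  - HLA G
  - RRBP1
  - ICAM1
direction:
  AVL9: up_in_pos
  PCMTD2: up_in_pos
  FAM36A/COX20: up_in_pos
  LIMCH1: up_in_pos
  RAB15: up_in_pos
  NCLN: down_in_pos
  MAP4K4: down_in_pos
  MMP14: down_in_pos
housekeeping: [ACTB, HPRT]
reference_genes: [ACTB]
ct_ceiling: 35.0
aliases:
  FAM36A: FAM36A/COX20
  COX20: FAM36A/COX20
  HLA-G: HLA G
  HLA_G: HLA G
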