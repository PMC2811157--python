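# Default kinase-consensus and docking-motif library.
# Each motif: a set of allowed central phospho-acceptors and required
# residues at offsets relative to the phospho-residue (-5..+5).
# ATM/ATR ([S/T]Q) and Plk1 ([D/E]X[S/T]) follow the canonical consensus
# strings; the CDK, Chk1/2 and PBD-docking entries follow Scansite-style
# consensus definitions from the motif literature and may be edited here.
motifs:
  - name: ATM/ATR
    kinase: ATM/ATR
    central: [S, T]
    required:
      "+1": [Q]
  - name: CDK-minimal
    kinase: CDK1/2
    central: [S, T]
    required:
      "+1": [P]
  - name: CDK-strict
    kinase: CDK1/2
    central: [S, T]
    required:
      "+1": [P]
      "+3": [K, R]
  - name: Plk1
    kinase: PLK1
    central: [S, T]
    required:
      "-2": [D, E]
  - name: PBD-docking
    kinase: null
    central: [S, T]
    required:
      "-1": [S]
      "+1": [P]
  - name: Chk1/2
    kinase: CHK1/2
    central: [S, T]
    required:
      "-3": [R]
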