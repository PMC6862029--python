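# High-activity guideline rules distilled from the decision-tree analysis.
#
# PROVENANCE NOTE: only the atom-count cap (107.5) and the HBD cap (5) are
# published thresholds. The remaining cutoffs (minimum double bonds, minimum
# rotatable bonds, MR lower bound, TPSA cap) have no published values; the
# numbers below are conservative named placeholders consistent with the
# reported per-class distributions, and are exposed here precisely so they
# can be edited. They are not validated quantities.
rules:
  - label: rule1
    clauses:
      - [a_count, "<=", 107.5]
      - [HBD, "<=", 5]
      - [b_double, ">=", 4]     # placeholder
      - [b_RotN, ">=", 8]       # placeholder
      - [MR, ">=", 40]          # placeholder
  - label: rule2
    clauses:
      - [a_count, "<=", 107.5]
      - [TPSA, "<=", 180]       # placeholder cap ("limited TPSA" branch)
      - [b_double, ">=", 4]     # placeholder
      - [b_RotN, ">=", 8]       # placeholder
      - [MR, ">=", 40]          # placeholder
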