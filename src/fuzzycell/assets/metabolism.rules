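# AMPK/mTORC1 metabolism-control module of T CD4 lymphocytes.
# Eight synchronous update rules over the metabolic core; the five inputs
# (CD25, AKT, CA, FOXP3, IL4E) are the signals the enclosing activation
# network supplies.  AMP_ATP stands for the AMP/ATP ratio (the slash is not
# a legal identifier character).

input CD25
input AKT
input CA
input FOXP3
input IL4E

MTOR       = CD25 or AKT
MTORC1     = MTOR and not AMPK
MTORC2     = (MTOR and AMPK) or (MTOR and IL4E)
LKB1       = AKT and AMP_ATP
AMPK       = (LKB1 and not MTORC1) or (CA and AMP_ATP and not MTORC1) or (AKT and AMP_ATP and not MTORC1) or FOXP3
GLYCOLYSIS = MTORC1 and not AMP_ATP
OXPHOS     = AMPK
AMP_ATP    = GLYCOLYSIS and not OXPHOS
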