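# SYNTHETIC RECONSTRUCTION of the 51-node T CD4 activation/metabolism network.
#
# The original rule set is distributed as supplementary material of the
# source publication and in the authors' public repository; neither could be
# obtained when this package was assembled.  This file is therefore a
# reconstruction: the 8-rule metabolism module is copied verbatim from the
# published table, and the remaining 36 rules were rebuilt from the
# publication's text, figure captions and network diagram, using canonical
# T-cell signaling biology for the interactions the text leaves implicit.
# Node count (51), the input set (MHC-antigen, CD80/86, five exogenous
# cytokines), and the qualitative dynamical repertoire (sustained /
# regulated / no activation, anergy under incomplete stimulation, Th1, Th2,
# Th17 and Treg differentiation with their metabolic polarities) reproduce
# the published description; individual rules need not match the original
# supplementary file clause for clause.
#
# Recommended sigmoid gain for this reconstruction: beta = 10 (the value the
# loader applies; the publication does not print its beta).
#
# 7 inputs + 44 regulated nodes = 51.

# ---- inputs: antigen presentation, co-stimulation, exogenous cytokines ----
input MHC_A      # MHC-antigen complex; avidity follows the step input
input CD8086     # CD80/86 co-stimulatory ligands; avidity follows the step input
input IL4E       # exogenous IL-4
input IFNGE      # exogenous IFN-gamma
input IL10E      # exogenous IL-10
input TGFBE      # exogenous TGF-beta
input IL21E      # exogenous IL-21

# ---- TCR-proximal signaling -----------------------------------------------
TCR    = MHC_A
ZAP70  = TCR
LAT    = ZAP70 and TCR and not CTLA4      # LAT-Gads-SLP-76 complex; dephosphorylated under CTLA-4 engagement
PLCG   = (LAT and ZAP70) or JAK3          # IL-2R signaling sustains PLC-gamma once the autocrine loop closes
CA     = PLCG                             # calcium release
CALCIN = CA                               # calcineurin
NFAT   = CALCIN
RAS    = LAT or JAK3
ERK    = RAS
PKCTH  = PLCG                             # PKC-theta
NFKB   = PKCTH
JNK    = PKCTH and (CD28 or JAK3)         # JNK arm of AP-1 needs co-stimulation (or IL-2R relay)
AP1    = ERK and JNK

# ---- co-stimulation, checkpoint, anergy -----------------------------------
CD28   = CD8086 and not CTLA4             # CTLA-4 displaces CD28 at CD80/86
CTLA4  = (NFAT and STAT5 and TCR) or FOXP3   # late activation-induced expression; constitutive in Treg
NDRG1  = TCR and not AKT                  # anergy factor, suppressed by AKT
PI3K   = (CD28 or JAK3) and not CTLA4
PDK1   = PI3K
AKT    = PI3K and PDK1

# ---- IL-2 autocrine loop ---------------------------------------------------
IL2G   = NFAT and AP1 and NFKB and not NDRG1    # IL-2 gene
CD25   = NFKB or STAT5                    # high-affinity IL-2 receptor chain
JAK3   = IL2G and CD25 and not CTLA4
STAT5  = JAK3

# ---- metabolism module (verbatim) ------------------------------------------
MTOR       = CD25 or AKT
MTORC1     = MTOR and not AMPK
MTORC2     = (MTOR and AMPK) or (MTOR and IL4E)
LKB1       = AKT and AMP_ATP
AMPK       = (LKB1 and not MTORC1) or (CA and AMP_ATP and not MTORC1) or (AKT and AMP_ATP and not MTORC1) or FOXP3
GLYCOLYSIS = MTORC1 and not AMP_ATP
OXPHOS     = AMPK
AMP_ATP    = GLYCOLYSIS and not OXPHOS

# ---- differentiation modules -----------------------------------------------
STAT1  = IFNGE or IFNG
TBET   = STAT1 and NFAT and not GATA3
IFNG   = TBET
STAT6  = IL4E or IL4
GATA3  = STAT6 and STAT5 and not TBET
IL4    = GATA3
STAT3  = IL21E or IL21
RORGT  = (TGFBE or TGFB) and STAT3 and NFAT and not FOXP3
IL17   = RORGT
IL21   = RORGT
FOXP3  = (TGFBE or TGFB) and NFAT and (STAT5 or IL10E) and not STAT3
IL10   = FOXP3
TGFB   = FOXP3
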