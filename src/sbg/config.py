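"""Pipeline-wide constants and default parameter sets.

Coordinates are 1-based base pairs everywhere inside the pipeline; the only
0-based format touched is BED, converted at the read boundary.  Chromosome
labels are opaque strings; the autosome set below is the horse (EquCab2)
default and is only used where an operation needs to know what counts as
autosomal.
"""

from __future__ import annotations

#: Length of the equine autosomal genome (EquCab2), in kb.  Denominator of
#: F_ROH.
L_AUTO_KB: float = 2_242_960.0

#: Horse autosome labels.
AUTOSOMES: tuple[str, ...] = tuple(str(i) for i in range(1, 32))

#: Missing-genotype code in call matrices (dtype int8).
MISSING: int = -1

# --- QC defaults (strictly-greater thresholds) ------------------------------
CALL_RATE_MIN: float = 0.95     # keep samples/SNPs with call rate > this
MAF_MIN: float = 0.05           # keep SNPs with MAF > this
MAF_MIN_MERGED: float = 0.01    # final pass on a merged multi-population set
PIHAT_MAX: float = 0.25         # relatedness exclusion threshold

# --- LD pruning defaults (PLINK --indep style) ------------------------------
PRUNE_WINDOW_SNPS: int = 50
PRUNE_STEP_SNPS: int = 5
PRUNE_VIF_MAX: float = 50.0

# --- ROH scan defaults (PLINK --homozyg style) ------------------------------
ROH_MIN_KB: float = 1000.0
ROH_MIN_KB_LONG: float = 5000.0     # ">5 Mb" scan for recent inbreeding
ROH_MIN_SNPS: int = 30
ROH_MAX_GAP_KB: float = 1000.0
ROH_MAX_DENSITY_KB_PER_SNP: float = 1000.0
ROH_WINDOW_SNPS: int = 30
ROH_WINDOW_HET: int = 1
ROH_WINDOW_MISSING: int = 2
ROH_HIT_FRACTION: float = 0.05

# --- CSS defaults -----------------------------------------------------------
CSS_SMOOTH_WINDOW_KB: float = 1000.0
CSS_TOP_FRACTION: float = 0.01
CSS_REGION_MIN_SNPS: int = 5
CSS_REGION_MAX_GAP_KB: float = 1000.0
CSS_GENE_FLANK_KB: float = 500.0
XPEHH_EHH_FLOOR: float = 0.05

# --- PCA / Ne defaults ------------------------------------------------------
PCA_OUTLIER_SIGMA: float = 10.0
NE_MAF_MIN: float = 0.05
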