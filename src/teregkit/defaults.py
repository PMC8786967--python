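"""Shipped default thresholds for every pipeline stage.

Each constant is the analysis cut-off applied by the corresponding module;
they are collected here so a run's configuration is auditable in one place.
"""

# Differential expression (te_expression)
DETE_FOLD_THRESHOLD = 4.0          # minimum fold change for a differential TE copy
DEG_FOLD_THRESHOLD = 1.5           # minimum fold change for a differential gene
FDR_THRESHOLD = 0.05               # BH-adjusted FDR cut-off for DETE/DEG calls
EXPRESSED_RPKM_THRESHOLD = 1.0     # group-mean RPKM must strictly exceed this
SUBFAMILY_MIN_COPIES = 80          # subfamily ranking: minimum total copies
SUBFAMILY_MIN_DETE = 8             # subfamily ranking: minimum DETE copies
TOP_VARIANCE_K = 200               # subfamilies kept in the variance heatmap
NB_PSEUDOCOUNT = 0.5               # pseudo-count on group means for log2FC
NB_DISPERSION_FLOOR = 1e-8         # lower bound on the NB dispersion

# Solo/proviral LTR classification
SOLO_LTR_MAX_DISTANCE_ERVK = 100   # bp; LTR within this of an ERVK internal = proviral
SOLO_LTR_MAX_DISTANCE_ERVH = 10    # bp; LTR7-type threshold

# Open-chromatin enrichment (chromatin_enrichment)
PEAK_MIN_FOLD_ENRICHMENT = 4.0     # strict > filter on peak fold enrichment
OR_MIN_LENGTH = 100                # bp; exclusive open regions shorter are discarded
N_SHUFFLES = 10_000                # stratified shuffles for the enrichment null
MOTIF_PSEUDOCOUNT = 1.0            # pseudo-occurrence in motif enrichment ratios
MOTIF_TOP_K = 50                   # motifs reported by enrichment ratio

# Genome partition (genome_intervals)
PROMOTER_WINDOW = 1000             # bp each side of the TSS
TTS_WINDOW = 1000                  # bp each side of the TES
PROXIMAL_DISTANCE = 10_000         # bp; gene-proximal shell
DISTAL_DISTANCE = 100_000          # bp; 10-100 kb distal shell outer bound

# Methylation (methylation)
MIN_CG_COVERAGE = 3                # reads; CG sites below are dropped
DMR_BIN_SIZE = 200                 # bp; fixed-phase DMR bins
DMR_MIN_CG = 4                     # qualifying CG sites per tested bin
DMR_MIN_DIFF = 0.2                 # minimum absolute pooled methylation difference
DMR_MERGE_GAP = 100                # bp; same-direction DMRs within this are merged
METAPROFILE_FLANK = 2000           # bp flanks in metaprofiles
METAPROFILE_BODY_BINS = 50
METAPROFILE_FLANK_BINS = 20

# Guide scanning (guide_scan)
GUIDE_MAX_MISMATCHES = 3           # Hamming budget over non-degenerate positions

# RAD analysis (rad_association)
RAD_EXTENSIONS = (0, 200_000, 400_000, 600_000, 800_000, 1_000_000)  # bp

# TE class vocabulary accepted by the TE-table reader
TE_CLASSES = ("LTR", "LINE", "SINE", "SVA", "DNA", "other")
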