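"""Canonical feature lists used by the five TME views.

These are the cell-type and pathway vocabularies the framework is normally
instantiated with; all view functions accept arbitrary lists, so these are
defaults rather than hard requirements.
"""

# The ten immune cell types quantified by deconvolution.  "CD4" denotes
# non-regulatory CD4+ T cells; after deconvolution it is reported as the sum
# of non-regulatory CD4+ T cells and Tregs, with Tregs kept as a separate
# column too.  Adding the unclassified remainder ("Other") yields 11
# cellular features.
IMMUNE_CELL_TYPES = (
    "B",
    "M1",
    "M2",
    "Monocyte",
    "Neutrophil",
    "NK",
    "CD4",
    "CD8",
    "Treg",
    "DC",
)

OTHER_CELLS_LABEL = "Other"

# The 14 signaling pathways scored by the perturbation-response model.
PATHWAYS = (
    "Androgen",
    "EGFR",
    "Estrogen",
    "Hypoxia",
    "JAK-STAT",
    "MAPK",
    "NFkB",
    "p53",
    "PI3K",
    "TGFb",
    "TNFa",
    "Trail",
    "VEGF",
    "WNT",
)

# Twelve aggregated TME cell types plus one pan-cancer cell type.  Ordered
# sender -> receiver pairs over these 13 types (autocrine included) give the
# 169 cell-cell interaction features.
AGGREGATED_CELL_TYPES = (
    "Adipocytes",
    "B cells",
    "CD4 T cells",
    "CD8 T cells",
    "Dendritic cells",
    "Endothelial cells",
    "Fibroblasts",
    "Macrophages",
    "Mast cells",
    "Monocytes",
    "Neutrophils",
    "NK cells",
    "Cancer cells",
)

# Default TPM threshold for calling a ligand or receptor expressed.
LR_TPM_THRESHOLD = 10.0
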