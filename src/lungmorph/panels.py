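"""Gene panels shared across the genetic-feature modules.

The panel is the set of genes recurrently mutated in both lung adenocarcinoma
and lung squamous cell carcinoma for which CNV, SNV and mRNA features are
carried.  The CNV and mRNA sub-panels default to the published factor-schema
sizes (15 and 26); their membership is a configuration input, with the leading
genes of the panel used by default.
"""

GENES: tuple[str, ...] = (
    "TP53", "MUC16", "CSMD3", "LRP1B", "FAT3", "KEAP1", "CDH10", "FAT4",
    "FAM135B", "CNTNAP2", "CTNND2", "CTNNA2", "FAT1", "KRAS", "PTPRD",
    "STK11", "SETBP1", "FAM47C", "ZNF521", "COL3A1", "KMT2D", "CDKN2A",
    "NFE2L2", "PIK3CA", "KMT2C", "PTEN", "NF1",
)

#: genes with a CNV factor (default sub-panel of size 15)
CNV_PANEL: tuple[str, ...] = GENES[:15]

#: genes with an SNV factor (all 27)
SNV_PANEL: tuple[str, ...] = GENES

#: genes with an mRNA-expression factor (default sub-panel of size 26)
MRNA_PANEL: tuple[str, ...] = GENES[:26]
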