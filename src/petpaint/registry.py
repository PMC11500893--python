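"""Frozen catalogue of the 46 radiomic indices.

The catalogue follows LIFEx-style naming: conventional SUV statistics, shape
of the segmented volume, intensity-histogram statistics, and the four 3-D
texture families (co-occurrence, run-length, neighbourhood-difference,
zone-length). Volume appears once, as SHAPE_Volume_mL; it doubles as the
metabolically active tumour volume (MATV).
"""

FEATURE_NAMES: tuple[str, ...] = (
    "CONV_SUVmin",
    "CONV_SUVmean",
    "CONV_SUVstd",
    "CONV_SUVmax",
    "CONV_SUVpeak",
    "CONV_TLG",
    "SHAPE_Volume_mL",
    "SHAPE_Sphericity",
    "SHAPE_Compacity",
    "HISTO_Skewness",
    "HISTO_Kurtosis",
    "HISTO_Entropy_log10",
    "HISTO_Entropy_log2",
    "HISTO_Energy",
    "GLCM_Homogeneity",
    "GLCM_Energy",
    "GLCM_Contrast",
    "GLCM_Correlation",
    "GLCM_Entropy_log10",
    "GLCM_Entropy_log2",
    "GLCM_Dissimilarity",
    "GLRLM_SRE",
    "GLRLM_LRE",
    "GLRLM_LGRE",
    "GLRLM_HGRE",
    "GLRLM_SRLGE",
    "GLRLM_SRHGE",
    "GLRLM_LRLGE",
    "GLRLM_LRHGE",
    "GLRLM_GLNU",
    "GLRLM_RLNU",
    "GLRLM_RP",
    "NGLDM_Coarseness",
    "NGLDM_Contrast",
    "NGLDM_Busyness",
    "GLZLM_SZE",
    "GLZLM_LZE",
    "GLZLM_LGZE",
    "GLZLM_HGZE",
    "GLZLM_SZLGE",
    "GLZLM_SZHGE",
    "GLZLM_LZLGE",
    "GLZLM_LZHGE",
    "GLZLM_GLNU",
    "GLZLM_ZLNU",
    "GLZLM_ZP",
)

assert len(FEATURE_NAMES) == 46

#: Indices unaffected by grey-level discretization (intensity- and shape-based).
DISCRETIZATION_INDEPENDENT: tuple[str, ...] = tuple(
    n for n in FEATURE_NAMES if n.startswith(("CONV_", "SHAPE_"))
)


def family(name: str) -> str:
    """Feature family prefix, e.g. ``GLZLM`` for ``GLZLM_SZE``."""
    return name.split("_", 1)[0]
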