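"""Published reference inputs for the SCRiP family.

The 24 publicly documented SCRiP query sequences (UniProt-reviewed plus
NCBI-predicted) with their cysteine-framework descriptors, the published
per-subfamily replicate global-omega values, and the headline dataset
counts.  These are inputs to the report layer - the descriptors drive
framework matching, the replicate tables drive the replicate-mean
summaries - not outputs of this package.
"""

from __future__ import annotations

# (toxin name, species, order, preprotein length aa, framework descriptor)
QUERY_FRAMEWORKS: tuple[tuple[str, str, str, int, str], ...] = (
    ("Amil_SCRiP1", "Acropora millepora", "Scleractinia", 89, "C_(6)_C_(6)_C_(7)_C_(5)_C_(6)_CCC_(12)_"),
    ("Amil_SCRiP2", "Acropora millepora", "Scleractinia", 79, "C_(6)_C_(6)_CP_(5)_C_(6)_C_(6)_CCC_(2)_"),
    ("Amil_SCRiP3", "Acropora millepora", "Scleractinia", 83, "C_(6)_C_(6)_CP_(5)_C_(5)_C_(6)_CCC_(2)_"),
    ("Ofav_SCRiP1", "Orbicella faveolata", "Scleractinia", 79, "C_(6)_C_(4)_CP_(5)_C_(6)_C_(6)_CCC_(2)_"),
    ("Ofav_SCRiP2", "Orbicella faveolata", "Scleractinia", 68, "C_(6)_C_(6)_CP_(6)_C_(5)_C_(6)_CCC_(2)_"),
    ("Ofav_SCRiP4", "Orbicella faveolata", "Scleractinia", 81, "C_(7)_C_(5)_CP_(5)_C_(4)_C_(6)_CCC_(4)_"),
    ("Ofav_SCRiP5", "Orbicella faveolata", "Scleractinia", 68, "C_(6)_C_(6)_CP_(6)_C_(5)_C_(6)_CCC_(2)_"),
    ("Ofav_SCRiP6", "Orbicella faveolata", "Scleractinia", 81, "C_(7)_C_(6)_CP_(5)_C_(5)_C_(5)_CCC_(5)_"),
    ("Ofav_SCRiP8", "Orbicella faveolata", "Scleractinia", 74, "C_(6)_C_(6)_CP_(3)_C_(4)_C_(6)_CCC_(2)_"),
    ("Mcap_SCRiP1a", "Montipora capitata", "Scleractinia", 81, "C_(6)_C_(6)_CP_(5)_C_(4)_C_(5)_CCC_(2)_"),
    ("Mcap_SCRiP1b", "Montipora capitata", "Scleractinia", 81, "C_(6)_C_(6)_CP_(5)_C_(4)_C_(5)_CCC_(2)_"),
    ("Msen_SCRiP", "Metridium senile", "Actiniaria", 69, "C_(6)_C_(6)_CP_(5)_C_(5)_C_(7)_CCC_(3)_"),
    ("Aten_SCRiP", "Actinia tenebrosa", "Actiniaria", 98, "C_(6)_C_(6)_C_(6)_C_(5)_C_(6)_CCC_(7)_"),
    ("Amil_SCRiP3like", "Acropora millepora", "Scleractinia", 84, "C_(6)_C_(6)_C_(6)_C_(5)_C_(5)_CCC_(4)_"),
    ("Amil_SCRiP1like", "Acropora millepora", "Scleractinia", 89, "C_(6)_C_(6)_C_(7)_C_(5)_C_(6)_CCC_(12)_"),
    ("Spis_SCRiP1like", "Stylophora pistillata", "Scleractinia", 89, "C_(6)_C_(6)_C_(7)_C_(5)_C_(6)_CCC_(12)_"),
    ("Ofav_SCRiP8like2", "Orbicella faveolata", "Scleractinia", 87, "C_(6)_C_(6)_CP_(3)_C_(4)_C_(6)_CCC_(6)_"),
    ("Ofav_SCRiP6like2", "Orbicella faveolata", "Scleractinia", 80, "C_(8)_C_(6)_CP_(5)_C_(3)_C_(5)_CCC_(6)_"),
    ("Adig_SCRiP3like1", "Acropora digitifera", "Scleractinia", 84, "C_(6)_C_(6)_C_(6)_C_(5)_C_(5)_CCC_(4)_"),
    ("Adig_SCRiP3like2.1", "Acropora digitifera", "Scleractinia", 84, "C_(6)_C_(6)_C_(6)_C_(5)_C_(5)_CCC_(4)_"),
    ("Adig_SCRiP3like2.2", "Acropora digitifera", "Scleractinia", 84, "C_(6)_C_(6)_C_(6)_C_(5)_C_(5)_CCC_(4)_"),
    ("Adig_SCRiP1", "Acropora digitifera", "Scleractinia", 89, "C_(6)_C_(6)_C_(7)_C_(5)_C_(6)_CCC_(12)_"),
    ("Adig_SCRiP3", "Acropora digitifera", "Scleractinia", 83, "C_(6)_C_(6)_CP_(5)_C_(5)_C_(6)_CCC_(2)_"),
    ("Adig_SCRiP3like3", "Acropora digitifera", "Scleractinia", 89, "C_(6)_C_(6)_C_(6)_C_(4)_C_(5)_CCC_(10)_"),
)

# Published replicate global-omega values per subfamily (three paralog
# subsampling replicates each).
PUBLISHED_REPLICATE_OMEGAS: dict[str, tuple[float, float, float]] = {
    "alpha": (1.36, 1.28, 1.26),
    "beta": (0.647, 0.595, 0.673),
    "gamma": (0.688, 0.599, 0.569),
    "delta": (0.605, 0.577, 0.545),
}

# Headline dataset counts: 168 newly annotated sequences plus 24 queries.
DATASET_COUNTS = {
    "novel_total": 168,
    "novel_complete": 106,
    "novel_partial": 62,
    "phylogeny_total": 192,  # novel + 24 queries
    "stony_coral_sequences": 173,
    "sea_anemone_sequences": 19,
}

# Example subfamily compositions used by the report layer's worked
# examples: (subfamily size, count of the named taxon group).
COMPOSITION_EXAMPLES = {
    "delta_sea_anemones": (31, 19),     # printed as 61.3%
    "beta_merulinidae": (45, 23),       # printed as 51.11%
}
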