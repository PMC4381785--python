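"""Printed worked-example inputs for the ranking validation.

Gene-level expression intensities of reference genes with known tissue
laterality: Schwann-cell genes (spinal-cord-enriched) vs synaptic genes
(brain-enriched) for the adult brain / spinal cord ranking, and
migration/synaptogenesis genes for the adult / fetal brain ranking.
Values are raw atlas intensities; ratios are computed, never stored.
"""

from __future__ import annotations

from .expression import ReferenceGene, TissueRatioTable

# gene -> (adult brain, spinal cord)
BRAIN_VS_SPINAL_CORD: dict[str, tuple[float, float]] = {
    "PMP22": (720.55, 2516.35),
    "MPZ": (5.5, 181.5),
    "BSN": (56.7, 3.45),
    "GRIA2": (355.1, 11.55),
}

# gene -> (adult brain, fetal brain)
ADULT_VS_FETAL_BRAIN: dict[str, tuple[float, float]] = {
    "RELN": (34.85, 93.35),
    "DCX": (10.55, 2577.0),
    "NRXN1": (72.1, 143.15),
    "NLGN1": (7.5, 24.7),
    "CAMK2B": (818.15, 321.25),
    "MUNC13": (26.3, 9.75),
    "MECP2": (818.15, 321.25),
    "PSD95": (362.1, 12.7),
    "PACSIN1": (90.8, 20.1),
}

# validation thresholds: Schwann-cell genes sit below 0.3, synaptic genes above 15
BRAIN_VS_SPINAL_CORD_REFS: list[ReferenceGene] = [
    ReferenceGene("MPZ", "low", 0.3),
    ReferenceGene("PMP22", "low", 0.3),
    ReferenceGene("BSN", "high", 15.0),
    ReferenceGene("GRIA2", "high", 15.0),
]


def brain_vs_spinal_cord_table() -> TissueRatioTable:
    genes = list(BRAIN_VS_SPINAL_CORD)
    a = [BRAIN_VS_SPINAL_CORD[g][0] for g in genes]
    b = [BRAIN_VS_SPINAL_CORD[g][1] for g in genes]
    return TissueRatioTable.from_values(genes, a, b, "adult brain", "spinal cord")


def adult_vs_fetal_table() -> TissueRatioTable:
    genes = list(ADULT_VS_FETAL_BRAIN)
    a = [ADULT_VS_FETAL_BRAIN[g][0] for g in genes]
    b = [ADULT_VS_FETAL_BRAIN[g][1] for g in genes]
    return TissueRatioTable.from_values(genes, a, b, "adult brain", "fetal brain")
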