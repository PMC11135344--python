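"""Region-name references for the biomarker panels.

The canonical per-biomarker region counts are enforced at load time; region
identities are free strings, but the 68-region Desikan-Killiany cortical
parcellation names are shipped here for the thickness/volume/amyloid panels
that use them.
"""

from __future__ import annotations

#: Canonical number of regions per biomarker panel.  VGM/ATH: 68 cortical
#: regions; SA: 70 cortical and subcortical; VWM: 45; the four DTI scalars
#: (FA, MD, RD, LD): 57 tracts/regions; amyloid-beta PET: 109 cortical and
#: subcortical regions.
CANONICAL_REGION_COUNTS: dict[str, int] = {
    "VGM": 68,
    "ATH": 68,
    "SA": 70,
    "VWM": 45,
    "FA": 57,
    "MD": 57,
    "RD": 57,
    "LD": 57,
    "ABETA": 109,
}

_DK_BASE = [
    "bankssts",
    "caudalanteriorcingulate",
    "caudalmiddlefrontal",
    "cuneus",
    "entorhinal",
    "fusiform",
    "inferiorparietal",
    "inferiortemporal",
    "isthmuscingulate",
    "lateraloccipital",
    "lateralorbitofrontal",
    "lingual",
    "medialorbitofrontal",
    "middletemporal",
    "parahippocampal",
    "paracentral",
    "parsopercularis",
    "parsorbitalis",
    "parstriangularis",
    "pericalcarine",
    "postcentral",
    "posteriorcingulate",
    "precentral",
    "precuneus",
    "rostralanteriorcingulate",
    "rostralmiddlefrontal",
    "superiorfrontal",
    "superiorparietal",
    "superiortemporal",
    "supramarginal",
    "frontalpole",
    "temporalpole",
    "transversetemporal",
    "insula",
]

#: The 68 Desikan-Killiany cortical region names (34 per hemisphere).
DESIKAN_KILLIANY_68: list[str] = [f"lh_{r}" for r in _DK_BASE] + [
    f"rh_{r}" for r in _DK_BASE
]


def default_region_names(biomarker: str, n_regions: int) -> list[str]:
    """Region names for a simulated panel: DK names where they apply."""
    if n_regions == 68 and biomarker.upper() in {"VGM", "ATH"}:
        return list(DESIKAN_KILLIANY_68)
    return [f"{biomarker.lower()}_region_{i:03d}" for i in range(n_regions)]
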