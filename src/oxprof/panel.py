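"""Marker panel constants: subunits, complexes, representative subunits.

Eight OxPhos subunits spanning complexes I-V, the VDAC1 mass marker, a
dopaminergic marker (TH), a nuclear marker (Histone H3) and the
Ir-intercalator channel that highlights nuclei/neuromelanin.
"""

from __future__ import annotations

# Subunit -> respiratory-chain complex
SUBUNIT_COMPLEX: dict[str, str] = {
    "NDUFB8": "CI",
    "NDUFA13": "CI",
    "SDHA": "CII",
    "UqCRC2": "CIII",
    "MTCO1": "CIV",
    "COX4+4L2": "CIV",
    "ATP5B": "CV",
    "OSCP": "CV",
}

SUBUNITS: tuple[str, ...] = tuple(SUBUNIT_COMPLEX)

COMPLEXES: tuple[str, ...] = ("CI", "CII", "CIII", "CIV", "CV")

# One subunit drives the complex-level call for multi-subunit complexes.
REPRESENTATIVE_SUBUNITS: dict[str, str] = {
    "CI": "NDUFA13",
    "CII": "SDHA",
    "CIII": "UqCRC2",
    "CIV": "MTCO1",
    "CV": "ATP5B",
}

MASS_TARGET = "VDAC1"
NEURONAL_TARGET = "TH"
NUCLEAR_TARGET = "HistoneH3"
INTERCALATOR_TARGET = "Ir"

# Channels excluded from the cytoplasmic mean by default (nucleus + NM).
DEFAULT_EXCLUSION_TARGETS: tuple[str, ...] = (NUCLEAR_TARGET, INTERCALATOR_TARGET)
DEFAULT_EXCLUSION_THRESHOLD = 5.0

# role labels used in panel sidecar files
ROLE_BY_TARGET: dict[str, str] = {
    **{s: "oxphos_subunit" for s in SUBUNITS},
    MASS_TARGET: "mass",
    NEURONAL_TARGET: "neuronal",
    NUCLEAR_TARGET: "nuclear",
    INTERCALATOR_TARGET: "intercalator",
}

# default channel order for rendered synthetic stacks (12 channels)
DEFAULT_TARGET_ORDER: tuple[str, ...] = SUBUNITS + (
    MASS_TARGET,
    NEURONAL_TARGET,
    NUCLEAR_TARGET,
    INTERCALATOR_TARGET,
)

METAL_TAGS: dict[str, str] = {
    "NDUFB8": "160Gd",
    "NDUFA13": "164Dy",
    "SDHA": "153Eu",
    "UqCRC2": "174Yb",
    "MTCO1": "158Yb",
    "COX4+4L2": "168Er",
    "ATP5B": "170Yb",
    "OSCP": "161Dy",
    "VDAC1": "166Er",
    "TH": "176Yb",
    "HistoneH3": "171Yb",
    "Ir": "193Ir",
}


def complex_of(subunit: str) -> str:
    try:
        return SUBUNIT_COMPLEX[subunit]
    except KeyError:
        raise KeyError(f"unknown OxPhos subunit: {subunit!r}") from None
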