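"""AAL-90 cerebral parcellation codes and the default node scheme.

The 90 cortical and subcortical regions (45 per hemisphere) of the Automated
Anatomical Labeling atlas define the connectome nodes. Odd table positions are
left-hemisphere (.L), even positions right (.R), in the atlas' canonical order;
label value k in a parcellation volume maps to ``AAL90_CODES[k - 1]`` (label 0
is background).
"""

from __future__ import annotations

AAL90_CODES: tuple[str, ...] = (
    "PreCG.L", "PreCG.R", "SFGdor.L", "SFGdor.R", "ORBsup.L", "ORBsup.R",
    "MFG.L", "MFG.R", "ORBmid.L", "ORBmid.R", "IFGoperc.L", "IFGoperc.R",
    "IFGtriang.L", "IFGtriang.R", "ORBinf.L", "ORBinf.R", "ROL.L", "ROL.R",
    "SMA.L", "SMA.R", "OLF.L", "OLF.R", "SFGmed.L", "SFGmed.R",
    "ORBsupmed.L", "ORBsupmed.R", "REC.L", "REC.R", "INS.L", "INS.R",
    "ACG.L", "ACG.R", "DCG.L", "DCG.R", "PCG.L", "PCG.R", "HIP.L", "HIP.R",
    "PHG.L", "PHG.R", "AMYG.L", "AMYG.R", "CAL.L", "CAL.R", "CUN.L", "CUN.R",
    "LING.L", "LING.R", "SOG.L", "SOG.R", "MOG.L", "MOG.R", "IOG.L", "IOG.R",
    "FFG.L", "FFG.R", "PoCG.L", "PoCG.R", "SPG.L", "SPG.R", "IPL.L", "IPL.R",
    "SMG.L", "SMG.R", "ANG.L", "ANG.R", "PCUN.L", "PCUN.R", "PCL.L", "PCL.R",
    "CAU.L", "CAU.R", "PUT.L", "PUT.R", "PAL.L", "PAL.R", "THA.L", "THA.R",
    "HES.L", "HES.R", "STG.L", "STG.R", "TPOsup.L", "TPOsup.R",
    "MTG.L", "MTG.R", "TPOmid.L", "TPOmid.R", "ITG.L", "ITG.R",
)

assert len(AAL90_CODES) == 90


def code_index(code: str) -> int:
    """0-based node index of a region code (e.g. ``'THA.L'`` -> 76)."""
    return AAL90_CODES.index(code)


# Fronto-subcortical / limbic node set used as the default planted-subnetwork
# fixture: bilateral orbitofrontal regions, left thalamus, hippocampus and
# postcentral gyrus. A 7-edge spanning tree over these 8 nodes, with THA.L as
# the local hub, is the default group-difference support in synthetic cohorts.
PLANTED_NODES: tuple[str, ...] = (
    "ORBmid.L", "ORBsup.L", "ORBsupmed.L", "THA.L",
    "HIP.L", "PoCG.L", "REC.R", "ORBinf.R",
)

PLANTED_EDGES: tuple[tuple[int, int], ...] = tuple(
    (min(code_index(a), code_index(b)), max(code_index(a), code_index(b)))
    for a, b in (
        ("THA.L", "PoCG.L"),
        ("THA.L", "HIP.L"),
        ("THA.L", "ORBmid.L"),
        ("ORBmid.L", "ORBsup.L"),
        ("ORBsup.L", "ORBsupmed.L"),
        ("ORBsupmed.L", "REC.R"),
        ("REC.R", "ORBinf.R"),
    )
)
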