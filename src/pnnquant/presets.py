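"""Bundled per-hole marker-occupancy profiles.

Each preset is a mutually exclusive partition of PNN-hole contents over a
marker panel, transcribed from the reported cohort percentages for cortical
fast-spiking neurons (astrocytic reporter AldheGFP; astrocytic channel and
transporters Kir4.1, GLT1, GAT3; presynaptic vesicular transporters vGlut1
and vGAT).  They parameterise the synthetic cohort generator so the full
detection/classification pipeline can be benchmarked against known truth.

For the three-channel panel only the synaptic-combination marginals, the
astrocytic marginal and the overall "any" occupancy are pinned by the
reported numbers; astrocytic presence is allocated proportionally across the
synaptic categories (see docs/methods.md).
"""

from __future__ import annotations

from .synth import OccupancyProfile

__all__ = ["OCCUPANCY_PRESETS", "get_preset"]


def _p(channels, probs):
    return OccupancyProfile.from_dict(channels, probs)


OCCUPANCY_PRESETS: dict[str, OccupancyProfile] = {
    # AldheGFP 63 %, Kir4.1 71 %, both 62 %
    "aldhegfp_kir41": _p(
        ["AldheGFP", "Kir4.1"],
        {
            ("AldheGFP", "Kir4.1"): 0.62,
            ("AldheGFP",): 0.01,
            ("Kir4.1",): 0.09,
            (): 0.28,
        },
    ),
    # AldheGFP 59 %, GLT1 70 %, both 56 %
    "aldhegfp_glt1": _p(
        ["AldheGFP", "GLT1"],
        {
            ("AldheGFP", "GLT1"): 0.56,
            ("AldheGFP",): 0.03,
            ("GLT1",): 0.14,
            (): 0.27,
        },
    ),
    # vGlut1 71 %, AldheGFP 53 %, both 44 %, any ~80 %
    "aldhegfp_vglut1": _p(
        ["AldheGFP", "vGlut1"],
        {
            ("AldheGFP", "vGlut1"): 0.44,
            ("AldheGFP",): 0.09,
            ("vGlut1",): 0.27,
            (): 0.20,
        },
    ),
    # both 33 %, any 80 %, 58 % of vGAT-occupied holes astro-contacted
    "aldhegfp_vgat": _p(
        ["AldheGFP", "vGAT"],
        {
            ("AldheGFP", "vGAT"): 0.33,
            ("AldheGFP",): 0.23,
            ("vGAT",): 0.24,
            (): 0.20,
        },
    ),
    # vGlut1∧GLT1 47 %; 75 % of vGlut1 holes carry GLT1
    "vglut1_glt1": _p(
        ["GLT1", "vGlut1"],
        {
            ("GLT1", "vGlut1"): 0.47,
            ("vGlut1",): 0.16,
            ("GLT1",): 0.23,
            (): 0.14,
        },
    ),
    # vGAT∧GAT3 35 %; 67 % of vGAT holes carry GAT3
    "vgat_gat3": _p(
        ["GAT3", "vGAT"],
        {
            ("GAT3", "vGAT"): 0.35,
            ("vGAT",): 0.17,
            ("GAT3",): 0.35,
            (): 0.13,
        },
    ),
    # three-channel panel: vGlut1∧vGAT 37 %, vGlut1-only 33 %, vGAT-only 19 %,
    # AldheGFP marginal 64 %, any 95 % (astro allocated proportionally)
    "aldhegfp_vglut1_vgat": _p(
        ["AldheGFP", "vGAT", "vGlut1"],
        {
            ("AldheGFP", "vGAT", "vGlut1"): 0.2411,
            ("AldheGFP", "vGlut1"): 0.2151,
            ("AldheGFP", "vGAT"): 0.1238,
            ("vGAT", "vGlut1"): 0.1289,
            ("vGlut1",): 0.1149,
            ("vGAT",): 0.0662,
            ("AldheGFP",): 0.06,
            (): 0.05,
        },
    ),
}


def get_preset(name: str) -> OccupancyProfile:
    try:
        return OCCUPANCY_PRESETS[name]
    except KeyError:
        raise KeyError(
            f"unknown occupancy preset {name!r}; available: {sorted(OCCUPANCY_PRESETS)}"
        ) from None
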