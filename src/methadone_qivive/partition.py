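"""Tissue:plasma partition coefficients from tissue composition.

Implements the tissue-composition partitioning scheme of Berezhkovskiy
(a refinement of the Poulin-Theil method): a compound distributes between
tissue water, neutral lipid and phospholipid according to its octanol:water
partitioning, with ionisation of the basic species (Henderson-Hasselbalch at
pH 7.4) suppressing partitioning into adipose neutral lipid, and with the
tissue interstitial protein binding taken as half the plasma binding for
non-adipose tissues.  Tissue:blood coefficients follow by dividing by the
blood/plasma concentration ratio.
"""

from __future__ import annotations

import math

#: fractional tissue composition: water, neutral lipid, phospholipid
TISSUE_COMPOSITION: dict[str, dict[str, float]] = {
    "liver":  {"water": 0.751, "nlipid": 0.0348, "plipid": 0.0252},
    "heart":  {"water": 0.758, "nlipid": 0.0115, "plipid": 0.0166},
    "fat":    {"water": 0.180, "nlipid": 0.7900, "plipid": 0.0020},
    "richly": {"water": 0.783, "nlipid": 0.0207, "plipid": 0.0162},
    "slowly": {"water": 0.760, "nlipid": 0.0238, "plipid": 0.0072},
}

PLASMA_COMPOSITION: dict[str, float] = {
    "water": 0.96, "nlipid": 0.00147, "plipid": 0.00083,
}


def _lipid_water_term(p_ow: float, comp: dict[str, float]) -> float:
    # phospholipid behaves 30% lipid-like, 70% water-like
    return (p_ow * (comp["nlipid"] + 0.3 * comp["plipid"])
            + (comp["water"] + 0.7 * comp["plipid"]))


def ionisation_corrected_pow(logp: float, pka: float, ph: float = 7.4) -> float:
    """Apparent (distribution) octanol:water ratio of a monoprotic base.

    Only the neutral fraction 1/(1+10^(pKa-pH)) partitions into neutral
    lipid, so P is scaled down accordingly (vegetable-oil:water surrogate).
    """
    return 10.0 ** logp / (1.0 + 10.0 ** (pka - ph))


def estimate_partition_coefficients(
    logp: float, pka: float, fu_p: float, *, ph: float = 7.4
) -> dict[str, float]:
    """Tissue:plasma partition coefficients for a monoprotic base.

    Parameters
    ----------
    logp
        log10 octanol:water partition coefficient of the neutral species.
    pka
        basic pKa; ionisation is evaluated at ``ph``.
    fu_p
        fraction unbound in plasma, in (0, 1].

    Returns
    -------
    dict mapping tissue name (liver, heart, fat, richly, slowly) to the
    tissue:plasma coefficient.
    """
    if not 0.0 < fu_p <= 1.0:
        raise ValueError(f"fu_p must be in (0, 1], got {fu_p}")
    p_ow = 10.0 ** logp
    d_ow = ionisation_corrected_pow(logp, pka, ph)
    # interstitial/tissue protein binding ~ half of plasma binding
    fu_t = 1.0 / (1.0 + 0.5 * (1.0 - fu_p) / fu_p)
    out: dict[str, float] = {}
    for tissue, comp in TISSUE_COMPOSITION.items():
        if tissue == "fat":
            num = _lipid_water_term(d_ow, comp)
            den = _lipid_water_term(d_ow, PLASMA_COMPOSITION)
            out[tissue] = num / den * fu_p  # fu_fat taken as 1
        else:
            num = _lipid_water_term(p_ow, comp)
            den = _lipid_water_term(p_ow, PLASMA_COMPOSITION)
            out[tissue] = num / den * fu_p / fu_t
    return out


def tissue_blood_partition(p_tissue_plasma: float, bp_ratio: float) -> float:
    """Convert a tissue:plasma coefficient to tissue:blood."""
    if bp_ratio <= 0:
        raise ValueError("blood/plasma ratio must be positive")
    return p_tissue_plasma / bp_ratio


def partition_coefficients_blood(
    logp: float, pka: float, fu_p: float, bp_ratio: float
) -> dict[str, float]:
    """Tissue:blood coefficients for all PBK compartments."""
    kp = estimate_partition_coefficients(logp, pka, fu_p)
    return {t: tissue_blood_partition(v, bp_ratio) for t, v in kp.items()}


def sanity_neutral_limit(tissue: str) -> float:
    """Composition-ratio limit of Kp for P_ow=1, fu_p=1 (used in tests)."""
    comp = TISSUE_COMPOSITION[tissue]
    return _lipid_water_term(1.0, comp) / _lipid_water_term(1.0, PLASMA_COMPOSITION)


def log_spaced_check(logp_values: list[float], pka: float, fu_p: float) -> list[float]:
    """P_fat across increasing logP (strictly increasing; property check)."""
    return [
        estimate_partition_coefficients(lp, pka, fu_p)["fat"] for lp in logp_values
    ]


def henderson_hasselbalch_neutral_fraction(pka: float, ph: float = 7.4) -> float:
    """Neutral fraction of a monoprotic base at the given pH."""
    return 1.0 / (1.0 + math.pow(10.0, pka - ph))
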