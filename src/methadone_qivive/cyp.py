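"""Scaling of recombinant-CYP kinetics to the liver-microsome scale.

Recombinant (Supersome) Vmax values, expressed per pmol of CYP, are scaled
to microsomal Vmax via the isoform-specific inter-system extrapolation
factor (ISEF) and the hepatic CYP abundance:

    Vmax_HLM = Vmax_CYP * ISEF * abundance

and the ISEF itself derives from the measured total microsomal intrinsic
clearance, the isoform's fractional contribution f_m,CYP and the
recombinant intrinsic clearance:

    ISEF = (CLint_HLM * f_m,CYP) / (CLint_CYP * abundance)

The packaged ISEF constants are used for modelling by default;
`compute_isef` is provided for audit, because the packaged values stem from
a clearance source that the packaged summary inputs do not exactly
reproduce.
"""

from __future__ import annotations

from dataclasses import dataclass

from .datasets import cyp_data

ISOFORMS = ("CYP2B6", "CYP2C19", "CYP3A4")


@dataclass(frozen=True)
class CypIsoformKinetics:
    """Recombinant kinetic constants of one CYP isoform."""

    isoform: str
    vmax_cyp: float  # pmol/min/pmol CYP
    km_cyp: float    # uM (reported Ks used as Km)

    def __post_init__(self):
        if self.vmax_cyp <= 0 or self.km_cyp <= 0:
            raise ValueError("kinetic constants must be positive")

    @property
    def clint_cyp(self) -> float:
        """Recombinant intrinsic clearance, uL/min/pmol CYP."""
        return self.vmax_cyp / self.km_cyp


@dataclass(frozen=True)
class AbundanceDistribution:
    """Lognormal hepatic abundance of one isoform for one phenotype."""

    isoform: str
    phenotype: str          # EM, PM or general
    frequency: float        # phenotype frequency in the population
    mean_abundance: float   # pmol/mg microsomal protein
    cv: float               # fraction

    def __post_init__(self):
        if not 0 < self.frequency <= 1:
            raise ValueError("frequency must be in (0, 1]")
        if self.mean_abundance <= 0:
            raise ValueError("mean_abundance must be positive")
        if self.cv < 0:
            raise ValueError("cv must be non-negative")


def compute_isef(clint_hlm_total: float, fm_cyp: float,
                 clint_cyp: float, abundance: float) -> float:
    """ISEF from total microsomal clearance and isoform contribution.

    Units: clint_hlm_total in uL/min/mg protein, clint_cyp in
    uL/min/pmol CYP, abundance in pmol/mg protein; the result is
    dimensionless.
    """
    if min(clint_hlm_total, fm_cyp, clint_cyp, abundance) <= 0:
        raise ValueError("all inputs must be positive")
    return clint_hlm_total * fm_cyp / (clint_cyp * abundance)


def scale_vmax_to_hlm(vmax_cyp: float, isef: float, abundance: float) -> float:
    """Microsomal-scale Vmax in pmol/min/mg protein (divide by 1000 for
    nmol/min/mg)."""
    if min(vmax_cyp, isef, abundance) <= 0:
        raise ValueError("all inputs must be positive")
    return vmax_cyp * isef * abundance


def phenotype_weighted_abundance(dists: list[AbundanceDistribution]) -> float:
    """Frequency-weighted mean abundance across phenotypes of one isoform."""
    total = sum(d.frequency for d in dists)
    if abs(total - 1.0) > 1e-6:
        raise ValueError(f"phenotype frequencies must sum to 1, got {total}")
    return sum(d.frequency * d.mean_abundance for d in dists)


def isoform_kinetics(enantiomer: str, isoform: str) -> CypIsoformKinetics:
    """Packaged recombinant kinetics for one enantiomer x isoform."""
    k = cyp_data()["isoform_kinetics"][enantiomer][isoform]
    return CypIsoformKinetics(
        isoform=isoform, vmax_cyp=k["vmax_pmol_min_pmol"], km_cyp=k["km_um"],
    )


def packaged_isef(population: str, enantiomer: str, isoform: str) -> float:
    """Packaged ISEF constant."""
    return cyp_data()["isef"][population][enantiomer][isoform]


def abundance_distributions(population: str, isoform: str) -> list[AbundanceDistribution]:
    """Packaged abundance distributions (all phenotypes) of one isoform."""
    return [
        AbundanceDistribution(
            isoform=isoform, phenotype=e["phenotype"], frequency=e["frequency"],
            mean_abundance=e["mean_pmol_mg"], cv=e["cv"],
        )
        for e in cyp_data()["abundances"][population][isoform]
    ]


def fm_cyp(enantiomer: str, isoform: str) -> float:
    """Fraction of total in vitro metabolic clearance carried by an isoform.

    Caucasian-derived values; also applied to the Chinese population.
    """
    return cyp_data()["fm_cyp"][enantiomer][isoform]


def rcyp_metabolism_spec(population: str, enantiomer: str,
                         abundances: dict[str, float] | None = None):
    """Metabolism spec with one MM term per isoform at the HLM scale.

    ``abundances`` overrides the phenotype-weighted packaged means, e.g.
    with Monte Carlo draws.
    """
    from .pbk import MetabolismSpec

    entries = []
    for iso in ISOFORMS:
        kin = isoform_kinetics(enantiomer, iso)
        ab = (abundances[iso] if abundances is not None
              else phenotype_weighted_abundance(abundance_distributions(population, iso)))
        entries.append({
            "isoform": iso, "vmax_cyp": kin.vmax_cyp, "km_cyp": kin.km_cyp,
            "isef": packaged_isef(population, enantiomer, iso), "abundance": ab,
        })
    return MetabolismSpec(mode="rcyp_mm", isoforms=entries)
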