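"""Synthetic data generators mirroring the statistical structure of the study.

Three generators cover the pipeline's external inputs: (1) per-individual
microsomal incubation tables with lognormal inter-individual (Vmax, Km)
variation calibrated to the packaged 25-donor descriptive statistics and
multiplicative measurement noise on rates; (2) sigmoidal in vitro FPDc
concentration-response curves with known ground truth; (3) simulated blood
concentration-time series with multiplicative noise, standing in for
digitised clinical observations in model-evaluation exercises.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import pbk
from .datasets import hlm_data, invitro_curve_data, compound_data
from .dosimetry import ConcResponseCurve, _hill
from .kinetics import ENANTIOMER_CONCS_UM, michaelis_menten
from .population import lognormal_params, sample_truncated


@dataclass
class PopulationKineticsProfile:
    """Lognormal (Vmax, Km) population profile for one enantiomer.

    Defaults reproduce the packaged incubation-study means and CVs; Vmax
    and Km are drawn independently (no correlation is reported).
    """

    population: str
    enantiomer: str
    mean_vmax: float
    cv_vmax: float
    mean_km: float
    cv_km: float
    n_individuals: int = 25
    noise_cv: float = 0.1       # multiplicative lognormal noise on rates
    n_replicates: int = 2
    concentrations: tuple = field(default=ENANTIOMER_CONCS_UM)

    def __post_init__(self):
        if min(self.mean_vmax, self.mean_km) <= 0:
            raise ValueError("means must be positive")
        if min(self.cv_vmax, self.cv_km, self.noise_cv) < 0:
            raise ValueError("CVs must be non-negative")


def profile_from_reference(population: str, enantiomer: str,
                           **overrides) -> PopulationKineticsProfile:
    """Profile calibrated to the packaged 25-donor summary statistics."""
    s = hlm_data()["summaries"][population][enantiomer]
    kw = dict(
        population=population, enantiomer=enantiomer,
        mean_vmax=s["mean_vmax"], cv_vmax=s["sd_vmax"] / s["mean_vmax"],
        mean_km=s["mean_km"], cv_km=s["sd_km"] / s["mean_km"],
        n_individuals=hlm_data()["n_individuals"],
    )
    kw.update(overrides)
    return PopulationKineticsProfile(**kw)


def generate_incubation_dataset(
    profile: PopulationKineticsProfile, seed: int
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Synthetic per-individual incubation table plus ground truth.

    Per individual, (Vmax, Km) are drawn from truncated lognormals
    (+/- 3 SD on the untransformed scale), Michaelis-Menten rates are
    evaluated at the seven enantiomer concentrations of the racemate
    design, and multiplicative lognormal noise is applied per replicate.

    Returns (data, truth): ``data`` in the tidy schema read by the fitting
    stage (individual_id, population, enantiomer, substrate_conc_uM,
    rate_nmol_min_mg, replicate), ``truth`` with the drawn constants.
    """
    rng = np.random.default_rng(seed)
    vmax = sample_truncated(
        lognormal_params(profile.mean_vmax, profile.cv_vmax),
        profile.n_individuals, rng)
    km = sample_truncated(
        lognormal_params(profile.mean_km, profile.cv_km),
        profile.n_individuals, rng)
    conc = np.asarray(profile.concentrations, float)
    rows = []
    for i in range(profile.n_individuals):
        clean = michaelis_menten(conc, vmax[i], km[i])
        for rep in range(profile.n_replicates):
            if profile.noise_cv > 0:
                spec = lognormal_params(1.0, profile.noise_cv)
                noise = rng.lognormal(spec.mu_omega, spec.sigma_omega, conc.size)
            else:
                noise = 1.0
            rates = clean * noise
            for c, r in zip(conc, rates):
                rows.append({
                    "individual_id": f"{profile.population[:4]}-{i + 1:02d}",
                    "population": profile.population,
                    "enantiomer": profile.enantiomer,
                    "substrate_conc_uM": c,
                    "rate_nmol_min_mg": r,
                    "replicate": rep + 1,
                })
    truth = pd.DataFrame({
        "individual_id": [f"{profile.population[:4]}-{i + 1:02d}"
                          for i in range(profile.n_individuals)],
        "vmax": vmax, "km": km,
        "catalytic_efficiency": vmax / km * 1000.0,
    })
    return pd.DataFrame(rows), truth


def generate_invitro_curve(
    hill: dict | None = None,
    concentrations: np.ndarray | None = None,
    *,
    noise_cv: float = 0.0,
    seed: int = 0,
) -> tuple[ConcResponseCurve, dict]:
    """Synthetic rac FPDc concentration-response curve with known truth.

    ``hill`` holds emax_pct, ec50_um and n (packaged defaults when None);
    optional multiplicative noise on the effect values.
    """
    d = invitro_curve_data()
    hill = dict(d["hill"]) if hill is None else dict(hill)
    if hill["n"] <= 0:
        raise ValueError("Hill slope must be positive")
    conc = np.asarray(
        d["concentrations_um"] if concentrations is None else concentrations,
        float)
    effect = _hill(conc, hill["emax_pct"], hill["ec50_um"], hill["n"])
    if noise_cv > 0:
        rng = np.random.default_rng(seed)
        spec = lognormal_params(1.0, noise_cv)
        effect = effect * rng.lognormal(spec.mu_omega, spec.sigma_omega, conc.size)
    curve = ConcResponseCurve(
        conc, effect, fu_medium=compound_data()["fu_medium"], compound="rac",
    )
    return curve, hill


def generate_invivo_profile(
    params: pbk.PBKParameters,
    dose_mg_per_day: float,
    *,
    n_days: int = 30,
    noise_cv: float = 0.1,
    seed: int = 0,
    last_hours: float = 24.0,
) -> pd.DataFrame:
    """Noisy observed-like venous blood concentration series.

    Simulates the model, keeps the final ``last_hours`` window and applies
    multiplicative lognormal noise, emulating digitised clinical data on
    the blood basis.
    """
    res = pbk.simulate(params, dose_mg_per_day, n_days, rtol=1e-6, atol=1e-8)
    t_end = n_days * 24.0
    m = res.window(t_end - last_hours, t_end)
    t = res.t[m] - (t_end - last_hours)
    conc = res.conc_venous_um[m]
    if noise_cv > 0:
        rng = np.random.default_rng(seed)
        spec = lognormal_params(1.0, noise_cv)
        conc = conc * rng.lognormal(spec.mu_omega, spec.sigma_omega, conc.size)
    return pd.DataFrame({
        "time_h": t, "conc_uM": conc, "conc_ug_l": conc * res.coeffs.mw,
    })
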