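"""Reverse dosimetry and benchmark-dose analysis of FPDc prolongation.

The in vitro rac-methadone concentration-response curve (FPDc prolongation
in hiPSC-cardiomyocytes) is split into enantiomer curves using the 1:3.5
R:S hERG-block potency ratio, converted to unbound medium concentrations
(fu_medium), and each effect level is mapped to the external daily dose at
which the PBK model predicts the same unbound steady-state Cmax in heart
venous blood.  Curves for sensitive individuals divide the doses by the
CSAF.  The benchmark dose at 10% effect (BMD10) is read from the best
fitting of a Hill and an exponential dose-response family and BMDL10 is
BMD10/3.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import brentq, curve_fit

from . import pbk
from .datasets import compound_data, invitro_curve_data


@dataclass
class ConcResponseCurve:
    """In vitro concentration-response points (nominal medium conc)."""

    conc_um: np.ndarray
    effect_pct: np.ndarray
    fu_medium: float = 0.79
    compound: str = "rac"  # rac, R or S

    def __post_init__(self):
        self.conc_um = np.asarray(self.conc_um, float)
        self.effect_pct = np.asarray(self.effect_pct, float)
        if np.any(self.conc_um <= 0):
            raise ValueError("concentrations must be positive")
        if not 0 < self.fu_medium <= 1:
            raise ValueError("fu_medium must be in (0, 1]")

    @property
    def unbound_conc_um(self) -> np.ndarray:
        return self.conc_um * self.fu_medium


@dataclass
class DoseResponseCurve:
    """Predicted in vivo dose-response points for one enantiomer."""

    dose_mg_day: np.ndarray
    effect_pct: np.ndarray
    population: str
    enantiomer: str
    variant: str = "average"  # average or sensitive
    csaf: float = 1.0

    def __post_init__(self):
        self.dose_mg_day = np.asarray(self.dose_mg_day, float)
        self.effect_pct = np.asarray(self.effect_pct, float)
        if np.any(self.dose_mg_day <= 0):
            raise ValueError("doses must be positive")
        if np.any(np.diff(self.dose_mg_day) <= 0):
            raise ValueError("doses must be strictly increasing")


@dataclass
class BmdResult:
    """Benchmark dose at 10% effect and its /3 lower bound."""

    bmd10: float
    model: str
    diagnostics: dict = field(default_factory=dict)

    @property
    def bmdl10(self) -> float:
        return self.bmd10 / 3.0


def split_rac_response(
    rac: ConcResponseCurve, potency_ratio: float = 3.5
) -> tuple[ConcResponseCurve, ConcResponseCurve]:
    """Distribute the racemate response over the enantiomers.

    At each rac point the enantiomer concentration is half the nominal rac
    concentration (1:1 racemate) and the effect is split proportionally
    1 : potency_ratio between R and S, so the enantiomer effects sum back
    to the rac effect exactly.
    """
    if potency_ratio <= 0:
        raise ValueError("potency_ratio must be positive")
    conc = rac.conc_um / 2.0
    r = ConcResponseCurve(conc, rac.effect_pct / (1.0 + potency_ratio),
                          fu_medium=rac.fu_medium, compound="R")
    s = ConcResponseCurve(conc, rac.effect_pct * potency_ratio / (1.0 + potency_ratio),
                          fu_medium=rac.fu_medium, compound="S")
    return r, s


def concentration_to_dose(
    params: pbk.PBKParameters,
    target_unbound_um: float,
    *,
    n_days: int = 30,
    rtol_dose: float = 1e-4,
    dose_bracket: tuple[float, float] = (1e-3, 1e4),
    sim_rtol: float = 1e-6,
) -> float:
    """External daily dose whose unbound steady-state Cmax equals the target.

    Secant iteration starting from the linear-kinetics estimate obtained at
    a 30 mg/day probe simulation; because metabolism saturates only mildly
    at therapeutic exposures, convergence takes a handful of simulations.
    """
    if target_unbound_um <= 0:
        raise ValueError("target must be positive")

    def unbound(dose: float) -> float:
        res = pbk.simulate(params, dose, n_days, rtol=sim_rtol,
                           atol=sim_rtol * 1e-2)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", pbk.SteadyStateWarning)
            _, u = pbk.steady_state_cmax(res)
        return u

    lo, hi = dose_bracket
    d0 = 30.0
    u0 = unbound(d0)
    d1 = float(np.clip(d0 * target_unbound_um / u0, lo, hi))
    if not lo <= d1 <= hi:
        raise ValueError("target unreachable within dose bracket")
    for _ in range(30):
        u1 = unbound(d1)
        if abs(u1 - target_unbound_um) <= rtol_dose * target_unbound_um:
            return d1
        # secant step on the (nearly linear) dose -> Cmax map
        if u1 == u0 or d1 == d0:
            break
        d2 = d1 - (u1 - target_unbound_um) * (d1 - d0) / (u1 - u0)
        if not np.isfinite(d2) or d2 <= 0:
            d2 = d1 * target_unbound_um / u1
        d0, u0, d1 = d1, u1, float(np.clip(d2, lo, hi))
    raise RuntimeError("dose search did not converge")


def build_dose_response(
    curve: ConcResponseCurve,
    params: pbk.PBKParameters,
    csaf: float = 1.0,
    *,
    n_days: int = 30,
) -> DoseResponseCurve:
    """Reverse dosimetry of each in vitro effect level.

    The unbound in vitro concentration (nominal x fu_medium) is equated to
    the unbound steady-state Cmax in heart venous blood; doses for the
    sensitive variant are the average-population doses divided by the CSAF.
    Effect values carry over unchanged.
    """
    if curve.compound not in ("R", "S"):
        raise ValueError("reverse dosimetry needs an enantiomer curve")
    if curve.compound != params.compound.enantiomer:
        raise ValueError("curve and model enantiomer differ")
    doses = np.array([
        concentration_to_dose(params, u, n_days=n_days)
        for u in curve.unbound_conc_um
    ])
    doses = doses / csaf
    if np.any(np.diff(doses) <= 0):
        warnings.warn("resulting dose-response curve is not monotone")
    return DoseResponseCurve(
        dose_mg_day=doses, effect_pct=curve.effect_pct,
        population=params.physiology.population,
        enantiomer=curve.compound,
        variant="average" if csaf == 1.0 else "sensitive", csaf=csaf,
    )


# -- dose-response families --------------------------------------------------

def _hill(d, emax, ed50, n):
    return emax * d ** n / (ed50 ** n + d ** n)


def _expo(d, a, b, c):
    return a * (1.0 - np.exp(-((d / b) ** c)))


_FAMILIES = {
    "hill": (_hill, ([1.0, 1.0, 1.0], ([1e-6, 1e-6, 0.1], [1e4, 1e6, 15.0]))),
    "exponential": (_expo, ([1.0, 1.0, 1.0], ([1e-6, 1e-6, 0.1], [1e4, 1e6, 15.0]))),
}


def bmd10(curve: DoseResponseCurve, bmr_pct: float = 10.0) -> BmdResult:
    """Benchmark dose at ``bmr_pct`` FPDc prolongation.

    Fits the Hill and exponential families by least squares, keeps the
    lowest-AIC fit and inverts it for the dose at the benchmark response
    (background response is zero by construction of the in vitro split).
    """
    d, e = curve.dose_mg_day, curve.effect_pct
    if e.max() < bmr_pct:
        raise ValueError("extrapolation required: 10% effect outside observed range")
    results = {}
    for name, (fn, (p0, bounds)) in _FAMILIES.items():
        p0 = [e.max(), float(np.median(d)), 1.0]
        try:
            popt, _ = curve_fit(fn, d, e, p0=p0, bounds=bounds, maxfev=20000)
        except RuntimeError:
            continue
        rss = float(np.sum((fn(d, *popt) - e) ** 2))
        n = len(d)
        aic = n * np.log(max(rss, 1e-300) / n) + 2 * len(popt)
        results[name] = (popt, rss, aic)
    if not results:
        raise RuntimeError("no dose-response family converged")
    best = min(results, key=lambda k: results[k][2])
    popt, rss, aic = results[best]
    fn = _FAMILIES[best][0]

    def f(x):
        return fn(x, *popt) - bmr_pct

    lo, hi = d.min() / 100.0, d.max() * 10.0
    if f(lo) > 0 or f(hi) < 0:
        raise ValueError("extrapolation required: 10% effect outside fitted range")
    bmd = brentq(f, lo, hi, xtol=1e-10, rtol=1e-10)
    return BmdResult(
        bmd10=float(bmd), model=best,
        diagnostics={"rss": rss, "aic": aic,
                     "params": [float(v) for v in popt],
                     "candidates": {k: v[2] for k, v in results.items()}},
    )


def margin_of_safety(bmdl10_sensitive: float, therapeutic_dose_mg_day: float) -> float:
    """MOS = sensitive-population BMDL10 / therapeutic rac dose."""
    if bmdl10_sensitive <= 0 or therapeutic_dose_mg_day <= 0:
        raise ValueError("inputs must be positive")
    return bmdl10_sensitive / therapeutic_dose_mg_day


def packaged_rac_curve() -> ConcResponseCurve:
    """The packaged synthetic rac FPDc concentration-response curve."""
    d = invitro_curve_data()
    h = d["hill"]
    conc = np.asarray(d["concentrations_um"], float)
    effect = _hill(conc, h["emax_pct"], h["ec50_um"], h["n"])
    return ConcResponseCurve(
        conc, effect, fu_medium=compound_data()["fu_medium"], compound="rac",
    )
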