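"""Local one-at-a-time sensitivity analysis of steady-state Cmax.

Each model parameter is increased by 1% (forward difference) and the
normalized sensitivity coefficient

    SC = (C' - C) / (P' - P) * P / C

is evaluated on the predicted steady-state Cmax of the enantiomer in heart
venous blood.  SC is dimensionless and invariant to parameter rescaling.
Parameters with |SC| > 0.1 are conventionally reported as influential.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

from . import pbk

INFLUENTIAL_THRESHOLD = 0.1


@dataclass(frozen=True)
class SensitivityResult:
    parameter: str
    sc: float
    dose_mg_per_day: float
    population: str
    enantiomer: str

    @property
    def influential(self) -> bool:
        return abs(self.sc) > INFLUENTIAL_THRESHOLD


def _scale_metabolism(m: pbk.MetabolismSpec, vmax_f=1.0, km_f=1.0) -> pbk.MetabolismSpec:
    if m.mode == "hlm_mm":
        return pbk.MetabolismSpec(mode=m.mode, vmax=m.vmax * vmax_f, km=m.km * km_f)
    isoforms = [
        {**iso, "vmax_cyp": iso["vmax_cyp"] * vmax_f, "km_cyp": iso["km_cyp"] * km_f}
        for iso in m.isoforms
    ]
    return pbk.MetabolismSpec(mode=m.mode, isoforms=isoforms)


def _scale_vf(phys: pbk.PhysiologyParams, tissue: str, f: float) -> pbk.PhysiologyParams:
    vf = dict(phys.volume_fractions)
    vf[tissue] *= f
    return replace(phys, volume_fractions=vf)


def _perturbations(params: pbk.PBKParameters, f: float) -> dict[str, pbk.PBKParameters]:
    """Fresh parameter sets with one value scaled by ``f``.

    Partition coefficients are re-derived whenever an input of the
    partitioning step (fu_p, blood/plasma ratio) changes.
    """
    c, ph, m = params.compound, params.physiology, params.metabolism

    def build(compound=None, physiology=None, metabolism=None):
        return pbk.PBKParameters(
            compound=compound or c, physiology=physiology or ph,
            metabolism=metabolism or m,
        )

    return {
        "Fa": build(compound=replace(c, fa=min(c.fa * f, 1.0))),
        "BW": build(physiology=replace(ph, bw=ph.bw * f)),
        "VLc": build(physiology=_scale_vf(ph, "liver", f)),
        "MPPGL": build(physiology=replace(ph, mppgl=ph.mppgl * f)),
        "Vmax": build(metabolism=_scale_metabolism(m, vmax_f=f)),
        "Km": build(metabolism=_scale_metabolism(m, km_f=f)),
        "ka": build(compound=replace(c, ka=c.ka * f)),
        "RCL": build(compound=replace(c, rcl=c.rcl * f)),
        "fu_p": build(compound=replace(c, fu_p=min(c.fu_p * f, 1.0))),
        "B:P": build(compound=replace(c, bp_ratio=c.bp_ratio * f)),
        "QCC": build(physiology=replace(ph, co_coeff=ph.co_coeff * f)),
        "VHc": build(physiology=_scale_vf(ph, "heart", f)),
    }


def _cmax(params: pbk.PBKParameters, dose: float, n_days: int, rtol: float) -> float:
    res = pbk.simulate(params, dose, n_days, rtol=rtol, atol=rtol * 1e-2)
    total, _ = pbk.steady_state_cmax(res)
    return total


def sensitivity_coefficients(
    params: pbk.PBKParameters,
    dose_mg_per_day: float,
    *,
    parameters: list[str] | None = None,
    delta: float = 0.01,
    n_days: int = 30,
    rtol: float = 1e-8,
) -> list[SensitivityResult]:
    """Normalized sensitivity coefficients for a 1% forward perturbation.

    Returns one result per parameter, sorted by |SC| descending.  The
    baseline Cmax must be positive (dose > 0).
    """
    base = _cmax(params, dose_mg_per_day, n_days, rtol)
    if base <= 0:
        raise ValueError("baseline Cmax must be positive (is the dose zero?)")
    perturbed = _perturbations(params, 1.0 + delta)
    names = parameters if parameters is not None else list(perturbed)
    out = []
    for name in names:
        c_new = _cmax(perturbed[name], dose_mg_per_day, n_days, rtol)
        sc = (c_new - base) / base / delta
        out.append(SensitivityResult(
            parameter=name, sc=sc, dose_mg_per_day=dose_mg_per_day,
            population=params.physiology.population,
            enantiomer=params.compound.enantiomer,
        ))
    return sorted(out, key=lambda r: abs(r.sc), reverse=True)
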