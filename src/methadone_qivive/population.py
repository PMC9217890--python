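"""Population variability of internal exposure and CSAF derivation.

Inter-individual variability in the unbound steady-state Cmax of each
enantiomer in heart venous blood is propagated in two ways: (a) one PBK
model per microsome donor (individual models), and (b) Monte Carlo
sampling of lognormally distributed hepatic CYP abundances - stratified by
CYP2B6 phenotype (extensive/poor metabolisers) - optionally together with
body weight, oral fraction absorbed and plasma unbound fraction.  Draws
more than three standard deviations from the mean (untransformed scale)
are rejected and redrawn.  Chemical-specific adjustment factors (CSAF) are
upper-percentile-to-geometric-mean ratios of the resulting distributions.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from . import cyp, pbk
from .cyp import ISOFORMS


@dataclass(frozen=True)
class LognormalSpec:
    """Lognormal variable given its untransformed mean and CV.

    mu_omega and sigma_omega are the mean and SD of the log-transformed
    variable: mu_omega = ln(mu_x/sqrt(1+CV^2)), sigma_omega^2 = ln(1+CV^2).
    """

    mu_x: float
    cv_x: float

    def __post_init__(self):
        if self.mu_x <= 0:
            raise ValueError("mu_x must be positive")
        if self.cv_x < 0:
            raise ValueError("cv_x must be non-negative")

    @property
    def mu_omega(self) -> float:
        return math.log(self.mu_x / math.sqrt(1.0 + self.cv_x ** 2))

    @property
    def sigma_omega(self) -> float:
        return math.sqrt(math.log(1.0 + self.cv_x ** 2))


def lognormal_params(mu_x: float, cv_x: float) -> LognormalSpec:
    """Log-scale parameters of a lognormal with given mean and CV."""
    return LognormalSpec(mu_x=mu_x, cv_x=cv_x)


def sample_truncated(spec: LognormalSpec, n: int,
                     rng: np.random.Generator | int) -> np.ndarray:
    """Lognormal draws with +/- 3 SD truncation on the untransformed scale.

    SD = mu_x * CV; draws outside [mu_x - 3 SD, mu_x + 3 SD] are rejected
    and redrawn.  Reproducible for a given generator state.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(rng) if isinstance(rng, (int, np.integer)) else rng
    if spec.cv_x == 0:
        return np.full(n, spec.mu_x)
    lo = spec.mu_x * (1.0 - 3.0 * spec.cv_x)
    hi = spec.mu_x * (1.0 + 3.0 * spec.cv_x)
    out = rng.lognormal(spec.mu_omega, spec.sigma_omega, size=n)
    bad = (out < lo) | (out > hi)
    first_reject = bad.mean()
    if first_reject > 0.5:
        raise ValueError(
            f"rejection rate {first_reject:.0%} > 50%: degenerate spec")
    while bad.any():
        out[bad] = rng.lognormal(spec.mu_omega, spec.sigma_omega, size=bad.sum())
        bad = (out < lo) | (out > hi)
    return out


def _weighted_quantile(x: np.ndarray, w: np.ndarray, q: float) -> float:
    order = np.argsort(x)
    x, w = x[order], w[order]
    cdf = np.cumsum(w) - 0.5 * w
    cdf /= w.sum()
    return float(np.interp(q, cdf, x))


@dataclass
class PopulationDistribution:
    """Sample of unbound Cmax (uM) with weights and summary statistics."""

    samples: np.ndarray
    weights: np.ndarray
    scenario: str
    population: str
    enantiomer: str
    strata: dict = field(default_factory=dict)  # phenotype -> (n, frequency)
    n_redrawn: int = 0

    def __post_init__(self):
        if len(self.samples) == 0:
            raise ValueError("empty distribution")
        self.weights = np.asarray(self.weights, float)
        self.weights = self.weights / self.weights.sum()

    @property
    def n(self) -> int:
        return len(self.samples)

    @property
    def gm(self) -> float:
        """Geometric mean, exp(weighted mean of ln samples)."""
        return float(np.exp(np.sum(self.weights * np.log(self.samples))))

    @property
    def gcv(self) -> float:
        """Geometric CV, sqrt(exp(var(ln samples)) - 1)."""
        lx = np.log(self.samples)
        mu = np.sum(self.weights * lx)
        var = np.sum(self.weights * (lx - mu) ** 2)
        return float(np.sqrt(np.expm1(var)))

    def percentile(self, q: float) -> float:
        """Weighted percentile of the pooled sample (q in [0, 100])."""
        return _weighted_quantile(self.samples, self.weights, q / 100.0)

    @property
    def p95(self) -> float:
        return self.percentile(95.0)

    @property
    def p99(self) -> float:
        return self.percentile(99.0)

    def percentile_parameter_weighted(self, q: float) -> float:
        """Percentile reconstructed from frequency-weighted lognormal
        parameters of the phenotype strata (alternative pooling mode)."""
        from scipy.stats import norm

        if not self.strata:
            return self.percentile(q)
        mus, sigmas, freqs = [], [], []
        start = 0
        for pheno, (n_s, freq) in self.strata.items():
            lx = np.log(self.samples[start:start + n_s])
            mus.append(lx.mean())
            sigmas.append(lx.std(ddof=1) if n_s > 1 else 0.0)
            freqs.append(freq)
            start += n_s
        freqs = np.array(freqs) / np.sum(freqs)
        mu = float(np.dot(freqs, mus))
        sigma = float(np.dot(freqs, sigmas))
        return float(np.exp(mu + norm.ppf(q / 100.0) * sigma))


@dataclass(frozen=True)
class CsafResult:
    """Percentile-over-reference-GM ratio under a named scenario."""

    enantiomer: str
    scenario: str
    basis: str       # within_caucasian, within_chinese or combined
    percentile: int  # 95 or 99
    csaf: float

    @property
    def exceeds_ipcs_default(self) -> bool:
        """True when the CSAF exceeds the default kinetic subfactor 3.16."""
        return self.csaf > 3.16


def derive_csaf(
    dist: PopulationDistribution,
    percentile: int,
    reference: PopulationDistribution | None = None,
    *,
    basis: str | None = None,
) -> CsafResult:
    """CSAF = percentile(dist) / GM(reference); within-population when the
    distribution is its own reference."""
    if percentile not in (95, 99):
        raise ValueError("percentile must be 95 or 99")
    ref = reference if reference is not None else dist
    if basis is None:
        basis = ("within_" + dist.population.lower() if ref is dist
                 else "combined")
    return CsafResult(
        enantiomer=dist.enantiomer, scenario=dist.scenario, basis=basis,
        percentile=percentile, csaf=dist.percentile(percentile) / ref.gm,
    )


# ---------------------------------------------------------------------------
# Monte Carlo over CYP abundances (and optional multifactor variation)
# ---------------------------------------------------------------------------

VARIED_CV = 0.3  # CV for body weight, Fa and fu_p in the multifactor scenario


def _stratum_draws(population: str, enantiomer: str, phenotype_dist,
                   scenario: str, n: int, rng: np.random.Generator):
    """Sample per-draw abundances (all isoforms) and multifactor variates."""
    draws = {}
    for iso in ISOFORMS:
        dists = cyp.abundance_distributions(population, iso)
        if iso == "CYP2B6":
            d = phenotype_dist
        else:
            d = dists[0]  # single (general or EM) distribution
        draws[iso] = sample_truncated(
            lognormal_params(d.mean_abundance, d.cv), n, rng)
    comp = pbk.default_compound(enantiomer)
    phys = pbk.default_physiology(population)
    if scenario == "multifactor":
        bw = sample_truncated(lognormal_params(phys.bw, VARIED_CV), n, rng)
        fa = np.minimum(
            sample_truncated(lognormal_params(comp.fa, VARIED_CV), n, rng), 1.0)
        fu_p = np.minimum(
            sample_truncated(lognormal_params(comp.fu_p, VARIED_CV), n, rng), 1.0)
    else:
        bw = np.full(n, phys.bw)
        fa = np.full(n, comp.fa)
        fu_p = np.full(n, comp.fu_p)
    return draws, bw, fa, fu_p


def _stratum_cmax(population: str, enantiomer: str, phenotype_dist,
                  scenario: str, n: int, rng: np.random.Generator,
                  dose_mg_per_day: float, n_days: int) -> tuple[np.ndarray, int]:
    draws, bw, fa, fu_p = _stratum_draws(
        population, enantiomer, phenotype_dist, scenario, n, rng)
    comp = pbk.default_compound(enantiomer)
    phys = pbk.default_physiology(population)
    part = pbk.PBKParameters(
        compound=comp, physiology=phys,
        metabolism=pbk.MetabolismSpec(mode="hlm_mm", vmax=1.0, km=100.0),
    ).partition_blood  # partitions at the mean fu_p (not re-derived per draw)

    vf, qf = phys.volume_fractions, phys.flow_fractions
    V = np.outer(bw, [vf[t] for t in pbk.TISSUES] + [vf["arterial"], vf["venous"]])
    q_tot = phys.co_coeff * bw ** 0.74
    Q = np.outer(q_tot, [qf[t] for t in pbk.TISSUES])
    P = np.tile([part[t] for t in pbk.TISSUES], (n, 1))
    liver_g = vf["liver"] * bw * 1000.0
    vmax_vivo = np.empty((n, len(ISOFORMS)))
    km = np.empty((n, len(ISOFORMS)))
    for j, iso in enumerate(ISOFORMS):
        kin = cyp.isoform_kinetics(enantiomer, iso)
        isef = cyp.packaged_isef(population, enantiomer, iso)
        micro = kin.vmax_cyp * isef * draws[iso] / 1000.0  # nmol/min/mg
        vmax_vivo[:, j] = micro * phys.mppgl * liver_g * 60.0 / 1000.0
        km[:, j] = kin.km_cyp
    out = pbk.batch_unbound_cmax(
        V, Q, P, q_tot, np.full(n, comp.ka), fa, np.full(n, comp.rcl),
        fu_p / comp.bp_ratio, vmax_vivo, km,
        dose_mg_per_day, n_days, comp.mw,
    )
    samples = out["cmax_unbound_um"]
    bad = ~np.isfinite(samples) | (samples <= 0)
    n_bad = int(bad.sum())
    if n_bad:
        redo, _ = _stratum_cmax(population, enantiomer, phenotype_dist,
                                scenario, n_bad, rng, dose_mg_per_day, n_days)
        samples[bad] = redo
    return samples, n_bad


def monte_carlo_cmax(
    population: str,
    enantiomer: str,
    scenario: str = "multifactor",
    n_per_stratum: int = 15000,
    seed: int = 1,
    *,
    dose_mg_per_day: float = 30.0,
    n_days: int = 30,
) -> PopulationDistribution:
    """Monte Carlo distribution of unbound steady-state Cmax.

    One simulation batch per CYP2B6 phenotype stratum; strata are pooled as
    a frequency-weighted mixture.  Parameters vary independently.  The
    default stratum size matches the reference analysis (15,000); smaller
    sizes are appropriate for exploratory runs.
    """
    if scenario not in ("metabolism_only", "multifactor"):
        raise ValueError(f"unknown scenario {scenario!r}")
    ss = np.random.SeedSequence([seed, {"R": 0, "S": 1}[enantiomer],
                                 {"Caucasian": 0, "Chinese": 1}[population],
                                 {"metabolism_only": 0, "multifactor": 1}[scenario]])
    phenos = cyp.abundance_distributions(population, "CYP2B6")
    children = ss.spawn(len(phenos))
    samples, weights, strata = [], [], {}
    n_redrawn = 0
    for child, dist in zip(children, phenos):
        rng = np.random.default_rng(child)
        s, n_bad = _stratum_cmax(population, enantiomer, dist, scenario,
                                 n_per_stratum, rng, dose_mg_per_day, n_days)
        samples.append(s)
        weights.append(np.full(len(s), dist.frequency / len(s)))
        strata[dist.phenotype] = (len(s), dist.frequency)
        n_redrawn += n_bad
    return PopulationDistribution(
        samples=np.concatenate(samples), weights=np.concatenate(weights),
        scenario=scenario, population=population, enantiomer=enantiomer,
        strata=strata, n_redrawn=n_redrawn,
    )


def individual_models_cmax(
    fits,
    population: str,
    enantiomer: str,
    *,
    dose_mg_per_day: float = 30.0,
    n_days: int = 30,
) -> PopulationDistribution:
    """One PBK model per microsome donor (microsomal MM metabolism).

    ``fits`` is a sequence of objects with vmax (nmol/min/mg) and km (uM)
    attributes, one per individual.
    """
    fits = list(fits)
    if len(fits) < 2:
        raise ValueError("need at least 2 individuals")
    comp = pbk.default_compound(enantiomer)
    phys = pbk.default_physiology(population)
    n = len(fits)
    base = pbk.build_coeffs(pbk.PBKParameters(
        compound=comp, physiology=phys,
        metabolism=pbk.MetabolismSpec(mode="hlm_mm", vmax=1.0, km=100.0),
    ))
    V = np.tile(base.V, (n, 1))
    Q = np.tile(base.Q, (n, 1))
    P = np.tile(base.P, (n, 1))
    vmax_micro = np.array([f.vmax for f in fits])
    km = np.array([[f.km] for f in fits])
    vmax_vivo = (vmax_micro * phys.mppgl * phys.liver_g * 60.0 / 1000.0)[:, None]
    out = pbk.batch_unbound_cmax(
        V, Q, P, np.full(n, base.q_tot), np.full(n, base.ka),
        np.full(n, base.fa), np.full(n, base.rcl), np.full(n, base.fu_b),
        vmax_vivo, km, dose_mg_per_day, n_days, base.mw,
    )
    return PopulationDistribution(
        samples=out["cmax_unbound_um"], weights=np.full(n, 1.0 / n),
        scenario="individual_models", population=population,
        enantiomer=enantiomer,
    )
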