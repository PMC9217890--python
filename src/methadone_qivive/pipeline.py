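"""End-to-end pipeline: kinetics -> scaling -> Monte Carlo -> CSAF ->
reverse dosimetry -> BMD -> margin of safety.

Writes result tables shaped like the study's summary tables (population
kinetics, CSAFs, BMDL10, MOS) plus a provenance manifest (config hash,
seed, package version).
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import pandas as pd

from . import __version__, cyp, dosimetry, kinetics, pbk, population
from .config import StudyConfig
from .datasets import reference_data

log = logging.getLogger("methadone_qivive.pipeline")


def kinetics_table(config: StudyConfig) -> pd.DataFrame:
    """Population kinetic summaries and inter-ethnic ratios."""
    rows = []
    for pop in config.populations:
        for en in config.enantiomers:
            s = kinetics.summary_from_reference(pop, en)
            rows.append({
                "population": pop, "enantiomer": en,
                "mean_vmax": s.mean_vmax, "cv_vmax_pct": s.cv_vmax_pct,
                "mean_km": s.mean_km, "cv_km_pct": s.cv_km_pct,
                "mean_eff": s.mean_eff, "cv_eff_pct": s.cv_eff_pct,
                "fold_eff": s.fold_range_eff, "n": s.n_individuals,
            })
    return pd.DataFrame(rows)


def abundance_table(config: StudyConfig) -> pd.DataFrame:
    """Phenotype-weighted CYP abundances per population."""
    rows = []
    for pop in config.populations:
        for iso in cyp.ISOFORMS:
            dists = cyp.abundance_distributions(pop, iso)
            rows.append({
                "population": pop, "isoform": iso,
                "weighted_abundance_pmol_mg": cyp.phenotype_weighted_abundance(dists),
                "phenotypes": ";".join(
                    f"{d.phenotype}({d.frequency:g})x{d.mean_abundance:g}"
                    for d in dists),
            })
    return pd.DataFrame(rows)


def monte_carlo_tables(config: StudyConfig) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Distribution summaries and the CSAF table.

    CSAFs are computed within each population and for the combined basis
    (Chinese upper percentile over the Caucasian geometric mean).
    """
    dists = {}
    summary_rows = []
    for scenario in config.monte_carlo.scenarios:
        for pop in config.populations:
            for en in config.enantiomers:
                log.info("Monte Carlo: %s %s %s", pop, en, scenario)
                d = population.monte_carlo_cmax(
                    pop, en, scenario,
                    n_per_stratum=config.monte_carlo.n_per_stratum,
                    seed=config.monte_carlo.seed,
                    dose_mg_per_day=config.dose_mg_per_day,
                    n_days=config.n_days,
                )
                dists[(scenario, pop, en)] = d
                summary_rows.append({
                    "scenario": scenario, "population": pop, "enantiomer": en,
                    "gm_unbound_cmax_uM": d.gm, "gcv": d.gcv,
                    "p95_uM": d.p95, "p99_uM": d.p99, "n": d.n,
                    "n_redrawn": d.n_redrawn,
                })
    csaf_rows = []
    for (scenario, pop, en), d in dists.items():
        for p in config.csaf_percentiles:
            r = population.derive_csaf(d, p)
            csaf_rows.append({
                "scenario": scenario, "enantiomer": en, "basis": r.basis,
                "percentile": p, "csaf": r.csaf,
                "exceeds_ipcs_default": r.exceeds_ipcs_default,
            })
    if {"Caucasian", "Chinese"} <= set(config.populations):
        for scenario in config.monte_carlo.scenarios:
            for en in config.enantiomers:
                chin = dists[(scenario, "Chinese", en)]
                cauc = dists[(scenario, "Caucasian", en)]
                for p in config.csaf_percentiles:
                    r = population.derive_csaf(chin, p, reference=cauc)
                    csaf_rows.append({
                        "scenario": scenario, "enantiomer": en,
                        "basis": "combined", "percentile": p, "csaf": r.csaf,
                        "exceeds_ipcs_default": r.exceeds_ipcs_default,
                    })
    return pd.DataFrame(summary_rows), pd.DataFrame(csaf_rows)


def dose_response_tables(
    config: StudyConfig, csaf_df: pd.DataFrame | None
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """BMD/BMDL table via reverse dosimetry and the MOS table.

    Sensitive-population curves apply the 99th-percentile multifactor CSAF
    of the respective population (computed ones when available, packaged
    reference values otherwise).
    """
    ref = reference_data()
    rac = dosimetry.packaged_rac_curve()
    curve_r, curve_s = dosimetry.split_rac_response(rac)
    curves = {"R": curve_r, "S": curve_s}
    bmd_rows, mos_rows = [], []
    for pop in config.populations:
        for en in config.enantiomers:
            csaf = None
            if csaf_df is not None:
                sel = csaf_df[
                    (csaf_df.scenario == "multifactor")
                    & (csaf_df.enantiomer == en)
                    & (csaf_df.basis == f"within_{pop.lower()}")
                    & (csaf_df.percentile == 99)
                ]
                if len(sel):
                    csaf = float(sel.csaf.iloc[0])
            if csaf is None:
                csaf = ref["csaf"][en][pop.lower()]["p99"]
            params = pbk.default_parameters(pop, en)
            avg = dosimetry.build_dose_response(curves[en], params,
                                                n_days=config.n_days)
            bmd_avg = dosimetry.bmd10(avg, config.bmr_pct)
            sens = dosimetry.DoseResponseCurve(
                dose_mg_day=avg.dose_mg_day / csaf, effect_pct=avg.effect_pct,
                population=pop, enantiomer=en, variant="sensitive", csaf=csaf,
            )
            bmd_sens = dosimetry.bmd10(sens, config.bmr_pct)
            bmd_rows.append({
                "population": pop, "enantiomer": en, "csaf_p99": csaf,
                "bmd10_average": bmd_avg.bmd10, "bmdl10_average": bmd_avg.bmdl10,
                "bmd10_sensitive": bmd_sens.bmd10,
                "bmdl10_sensitive": bmd_sens.bmdl10,
                "model": bmd_avg.model,
            })
            for stage, dose in config.therapeutic_doses_mg_day.items():
                mos_rows.append({
                    "population": pop, "enantiomer": en, "stage": stage,
                    "therapeutic_dose_mg_day": dose,
                    "toxic_dose_mg_day": bmd_sens.bmdl10,
                    "mos": dosimetry.margin_of_safety(bmd_sens.bmdl10, dose),
                })
    return pd.DataFrame(bmd_rows), pd.DataFrame(mos_rows)


def run_pipeline(config: StudyConfig, outdir: str | Path) -> dict:
    """Execute all stages and write CSV tables plus a manifest.

    Returns the result bundle as a dict of DataFrames.  Stage failures
    abort with a stage-tagged error; tables written before the failure are
    retained.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    bundle: dict[str, pd.DataFrame] = {}

    stages = [
        ("kinetics", lambda: {"kinetics_summary": kinetics_table(config)}),
        ("abundances", lambda: {"cyp_abundances": abundance_table(config)}),
    ]

    def mc_stage():
        summary, csaf = monte_carlo_tables(config)
        return {"population_distributions": summary, "csaf": csaf}

    stages.append(("monte_carlo", mc_stage))
    if config.run_reverse_dosimetry:
        stages.append(("reverse_dosimetry", lambda: dict(zip(
            ("bmd", "mos"), dose_response_tables(config, bundle.get("csaf"))))))

    for name, fn in stages:
        try:
            tables = fn()
        except Exception as exc:  # noqa: BLE001 - re-tag and abort
            raise RuntimeError(f"pipeline stage {name!r} failed: {exc}") from exc
        for key, df in tables.items():
            df.to_csv(outdir / f"{key}.csv", index=False)
            bundle[key] = df
        log.info("stage %s complete", name)

    manifest = {
        "package_version": __version__,
        "config_hash": config.digest(),
        "seed": config.monte_carlo.seed,
        "config": config.model_dump(),
        "tables": sorted(bundle),
    }
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2))
    bundle["manifest"] = manifest
    return bundle
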