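"""End-to-end orchestration: climate indices -> homoclimatic zones ->
vulnerability index, with disease-incidence stratification.

Stages:

1. reduce daily series to the seven extreme indices and quintile-code them;
2. fit the Grade of Membership model, classify regions into membership
   tiers and reclassify mixed tiers into their dominant extreme zone;
3. assemble the indicator panel (computed exposure indices + social
   indicators), apply deprivation cutoffs on the pooled study area, and
   compute the population-weighted adjusted index overall, by zone, and
   by zone x disease-incidence stratum, with decompositions;
4. cutoff diagnostics over the k_p grid (sensitivity curves, the
   forward-local-variance optimum, the CH/DI intersection advisory).

Disease stratification uses hospitalization rates per 100,000 (5-year
mean counts over the reference population) cut into quintiles: the first
quintile is the low-incidence stratum, the fourth and fifth the
high-incidence stratum; the middle quintiles are excluded from the
stratified comparison (an all-strata mode is available).
"""

from __future__ import annotations

import dataclasses
import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .climate import ClimateConfig, categorize_quantiles, compute_extreme_indices
from .ecvi import (
    apply_deprivation_cutoffs,
    compute_ecvi,
    decompose_by_dimension,
    decompose_by_indicator,
    decompose_by_subgroup,
    default_schema,
    weighted_score,
)
from .gom import GoMConfig, classify_profiles, fit_gom
from .kp import default_grid, kp_report, sensitivity_curve
from .synthetic import GeneratorConfig, generate_study

__all__ = ["RunConfig", "disease_rate", "incidence_strata", "name_profiles", "run_pipeline"]


@dataclass(frozen=True)
class RunConfig:
    """One reproducible run: inputs, cutoff, sampler and SE settings."""

    k_p: float = 0.25
    gom: GoMConfig = field(default_factory=GoMConfig)
    climate: ClimateConfig = field(default_factory=ClimateConfig)
    generator: GeneratorConfig | None = None  # synthetic mode when set
    climate_csv: str | None = None
    panel_csv: str | None = None
    counts_csv: str | None = None
    se_method: str = "bootstrap"
    n_bootstrap: int = 1000
    kp_grid_step: float = 0.05
    kp_window: int = 3
    include_middle_stratum: bool = False
    income_threshold: float = 296.8
    output_dir: str | None = None
    seed: int = 0

    def inputs_exist(self) -> None:
        if self.generator is not None:
            return
        for name in ("climate_csv", "panel_csv", "counts_csv"):
            path = getattr(self, name)
            if path is None or not Path(path).exists():
                raise FileNotFoundError(f"{name} missing or not found: {path}")


def disease_rate(annual_counts, population: float) -> float:
    """Hospitalization rate per 100,000: 5-year mean count over the
    reference population."""
    counts = np.asarray(annual_counts, dtype=float)
    if counts.size != 5:
        raise ValueError("exactly 5 annual counts are required")
    if (counts < 0).any():
        raise ValueError("negative counts")
    if population <= 0:
        raise ValueError("population must be positive")
    return float(counts.mean() / population * 1e5)


def incidence_strata(rates: pd.Series) -> pd.Series:
    """Quintile-based strata: Q1 = low, Q4+Q5 = high, Q2+Q3 = middle.

    Quintiles are cut on the cross-region rate distribution; ties that
    collapse a quintile fall back to rank order with a stable tie-break
    (warning); all-equal rates land everyone in Q1 (low), with warning.
    """
    if len(rates) < 5:
        raise ValueError("need at least 5 regions to form quintiles")
    tbl = pd.DataFrame({"region_id": rates.index, "rate": rates.to_numpy(dtype=float)})
    cats = categorize_quantiles(tbl, n_categories=5, items=["rate"])
    cat = cats.set_index("region_id")["category"]
    stratum = pd.Series("middle", index=cat.index, name="stratum")
    stratum[cat == 1] = "low"
    stratum[cat >= 4] = "high"
    return stratum.reindex(rates.index)


def name_profiles(fit) -> tuple[str, ...]:
    """Label latent profiles by their climate signature.

    The profile whose dry-spell (cdd) response mass sits in higher
    categories is the drought/heat zone ('ED-HT'); the other is the
    rain-extreme zone ('ER').  Falls back to the extremely-wet-days
    index (reversed) and then to positional names.
    """
    K = fit.config.K
    if K != 2:
        return tuple(f"profile_{k + 1}" for k in range(K))
    lam = fit.lambda_means
    L = lam.shape[2]
    cats = np.arange(1, L + 1)
    if "cdd" in fit.item_ids:
        j = fit.item_ids.index("cdd")
        expected = lam[:, j, :] @ cats
        order = np.argsort(expected)  # low cdd first -> ER
    elif "r99p" in fit.item_ids:
        j = fit.item_ids.index("r99p")
        expected = lam[:, j, :] @ cats
        order = np.argsort(-expected)  # high r99p first -> ER
    else:
        return ("profile_1", "profile_2")
    names = [""] * 2
    names[order[0]] = "ER"
    names[order[1]] = "ED-HT"
    return tuple(names)


def _stage(name: str):
    class _StageContext:
        def __enter__(self):
            return self

        def __exit__(self, exc_type, exc, tb):
            if exc is not None:
                raise RuntimeError(f"pipeline stage '{name}' failed: {exc}") from exc
            return False

    return _StageContext()


def run_pipeline(config: RunConfig) -> dict:
    """Execute every stage and return (and optionally write) the bundle.

    Returns a dict with the index table, categorical matrix, GoM fit,
    zone assignment, assembled panel, ECVI tables (overall/zone and
    zone x incidence stratum), decomposition tables, the k_p report and
    a run manifest.  With ``output_dir`` set, CSV/JSON outputs are
    written; identical config and seed give identical bytes.
    """
    config.inputs_exist()
    log: list[str] = []

    with _stage("inputs"):
        if config.generator is not None:
            gen = dataclasses.replace(config.generator, seed=config.seed)
            study = generate_study(gen)
            climate_df = study["daily_climate"]
            panel_social = study["indicator_panel"]
            counts = study["disease_counts"]
        else:
            climate_df = pd.read_csv(config.climate_csv, parse_dates=["date"])
            panel_social = pd.read_csv(config.panel_csv)
            counts = pd.read_csv(config.counts_csv)
        log.append(f"inputs: {climate_df['region_id'].nunique()} regions, "
                   f"{len(climate_df)} daily rows")

    with _stage("climate_indices"):
        indices = compute_extreme_indices(climate_df, config.climate)
        matrix = categorize_quantiles(indices)
        log.append(f"climate_indices: {len(indices)} regions x 7 indices")

    with _stage("gom"):
        gom_cfg = dataclasses.replace(config.gom, seed=config.seed)
        fit = fit_gom(matrix, gom_cfg)
        names = name_profiles(fit)
        zones = classify_profiles(fit, profile_names=names)
        log.append(f"gom: K={gom_cfg.K}, PSRF={fit.psrf_loglik:.3f}")

    with _stage("panel"):
        schema = default_schema(config.income_threshold)
        exposure_cols = [c for c in indices.columns if c != "region_id"]
        social = panel_social.drop(columns=exposure_cols, errors="ignore")
        panel = social.merge(indices, on="region_id", validate="1:1")
        panel = panel.merge(
            zones[["region_id", "zone_binary"]], on="region_id", validate="1:1"
        )
        rates = (
            counts.groupby("region_id")["count"]
            .apply(lambda s: s.mean())
            .to_frame("mean_count")
            .join(panel.set_index("region_id")["population"])
        )
        panel["disease_rate"] = (
            rates["mean_count"] / rates["population"] * 1e5
        ).reindex(panel["region_id"]).to_numpy()
        panel["stratum"] = incidence_strata(
            panel.set_index("region_id")["disease_rate"]
        ).to_numpy()
        log.append(f"panel: {len(panel)} regions, strata "
                   f"{panel['stratum'].value_counts().to_dict()}")

    with _stage("ecvi"):
        flags = apply_deprivation_cutoffs(panel, schema)
        c = weighted_score(flags, schema)
        pop = panel.set_index("region_id")["population"].reindex(flags.index)
        zone = panel.set_index("region_id")["zone_binary"].reindex(flags.index)
        stratum = panel.set_index("region_id")["stratum"].reindex(flags.index)

        results = [
            compute_ecvi(c, pop, config.k_p, "overall", config.se_method,
                         config.n_bootstrap, config.seed)
        ]
        for zname in sorted(zone.unique()):
            mask = (zone == zname).to_numpy()
            results.append(
                compute_ecvi(c[mask], pop[mask], config.k_p, zname,
                             config.se_method, config.n_bootstrap, config.seed)
            )
        strata_keep = ["low", "high"] + (["middle"] if config.include_middle_stratum else [])
        stratified = []
        for sname in strata_keep:
            smask = (stratum == sname).to_numpy()
            if smask.sum() == 0:
                continue
            stratified.append(
                compute_ecvi(c[smask], pop[smask], config.k_p, f"overall/{sname}",
                             config.se_method, config.n_bootstrap, config.seed)
            )
            for zname in sorted(zone.unique()):
                mask = smask & (zone == zname).to_numpy()
                if mask.sum() == 0:
                    continue
                stratified.append(
                    compute_ecvi(c[mask], pop[mask], config.k_p, f"{zname}/{sname}",
                                 config.se_method, config.n_bootstrap, config.seed)
                )
        ecvi_table = pd.DataFrame([r.as_dict() for r in results])
        strata_table = pd.DataFrame([r.as_dict() for r in stratified])

        subgroup = decompose_by_subgroup(c.to_numpy(), pop.to_numpy(),
                                         zone.to_numpy(), config.k_p)
        indicator = decompose_by_indicator(flags, schema, pop.to_numpy(), config.k_p)
        dimension = decompose_by_dimension(indicator)
        log.append(f"ecvi: overall {results[0].ecvi:.4f} at k_p={config.k_p}")

    with _stage("kp_diagnostics"):
        grid = default_grid(step=config.kp_grid_step)
        curves = pd.concat(
            [
                sensitivity_curve(c.to_numpy(), pop.to_numpy(), stat, grid)
                for stat in ("ECVI", "CH", "DI")
            ],
            ignore_index=True,
        )
        report = kp_report(
            c.to_numpy(), pop.to_numpy(), grid, config.kp_window,
            config.k_p, groups=zone.to_numpy(),
        )

    manifest = {
        "package_version": __version__,
        "seed": config.seed,
        "k_p": config.k_p,
        "config": _config_dict(config),
        "n_regions": int(len(panel)),
        "profiles": list(names),
        "stratified_cutoffs": "pooled study area",
        "log": log,
    }

    bundle = {
        "indices": indices,
        "categorical_matrix": matrix,
        "gom_fit": fit,
        "zones": zones,
        "panel": panel,
        "flags": flags,
        "scores": c,
        "ecvi": ecvi_table,
        "ecvi_by_stratum": strata_table,
        "decomposition_subgroup": subgroup,
        "decomposition_indicator": indicator,
        "decomposition_dimension": dimension,
        "kp_curves": curves,
        "kp_report": report,
        "manifest": manifest,
    }
    if config.output_dir is not None:
        _write_outputs(bundle, config.output_dir, fit)
    return bundle


def _config_dict(config: RunConfig) -> dict:
    def convert(obj):
        if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
            return {k: convert(v) for k, v in dataclasses.asdict(obj).items()}
        if isinstance(obj, (np.floating, np.integer)):
            return obj.item()
        if isinstance(obj, tuple):
            return list(obj)
        return obj

    # the destination path is not part of the reproducible run identity
    return {
        k: convert(v)
        for k, v in dataclasses.asdict(config).items()
        if k != "output_dir"
    }


def _write_outputs(bundle: dict, output_dir: str, fit) -> None:
    out = Path(output_dir)
    out.mkdir(parents=True, exist_ok=True)
    bundle["indices"].to_csv(out / "extreme_indices.csv", index=False)
    bundle["categorical_matrix"].to_csv(out / "categorical_matrix.csv", index=False)
    bundle["zones"].to_csv(out / "zones.csv", index=False)
    bundle["panel"].to_csv(out / "panel.csv", index=False)
    bundle["ecvi"].to_csv(out / "ecvi.csv", index=False)
    bundle["ecvi_by_stratum"].to_csv(out / "ecvi_by_stratum.csv", index=False)
    bundle["decomposition_subgroup"].to_csv(out / "decomposition_subgroup.csv", index=False)
    bundle["decomposition_indicator"].to_csv(out / "decomposition_indicator.csv", index=False)
    bundle["decomposition_dimension"].to_csv(out / "decomposition_dimension.csv", index=False)
    bundle["kp_curves"].to_csv(out / "kp_curves.csv", index=False)
    with open(out / "kp_report.json", "w") as fh:
        json.dump(bundle["kp_report"], fh, indent=2, sort_keys=True)
    with open(out / "gom_summary.json", "w") as fh:
        json.dump(fit.summary(), fh, indent=2, sort_keys=True)
    with open(out / "manifest.json", "w") as fh:
        json.dump(bundle["manifest"], fh, indent=2, sort_keys=True)
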