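"""Weighted Alkire-Foster Extreme Climate Vulnerability Index (ECVI).

The index follows the dual-cutoff counting approach.  Each region i is
flagged deprived (0/1) in each of I indicators by a per-indicator cutoff
(a cross-region quartile bound or an absolute threshold); the weighted
deprivation score is c_i = sum_i w_i * flag_i with weights summing to 1.
A region is multidimensionally vulnerable when c_i >= k_p (the
multidimensional cutoff expressed as a share of weighted deprivations).

With population weights p_i:

    CH   = sum_i p_i [c_i >= k_p] / sum_i p_i          (censored headcount)
    DI   = sum_i p_i c_i [c_i >= k_p] / sum_i p_i [c_i >= k_p]
                                                       (deprivation intensity)
    ECVI = CH * DI                                     (adjusted headcount)

ECVI decomposes exactly by population subgroup,

    ECVI(y) = sum_g (n_g / n) * ECVI(y_g),

and by indicator, ECVI(y) = sum_i w_i * CH_i with CH_i the censored
(post-cutoff) headcount of indicator i; dimension contributions are sums
over member indicators.  Standard errors come from a nonparametric
bootstrap over regions or a Taylor linearization.

The default 18-indicator schema spans three equally weighted dimensions:
exposure (7 extreme-climate indices, w = 1/21 each), susceptibility
(5 sociodemographic indicators, w = 1/15) and adaptive capacity
(6 infrastructure / health-supply indicators, w = 1/18).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from importlib import resources

import numpy as np
import pandas as pd
import yaml

__all__ = [
    "Indicator",
    "IndicatorSchema",
    "default_schema",
    "load_schema",
    "apply_deprivation_cutoffs",
    "weighted_score",
    "ECVIResult",
    "adjusted_index",
    "compute_ecvi",
    "decompose_by_subgroup",
    "decompose_by_indicator",
    "estimate_se",
    "af_statistics",
    "DIMENSIONS",
]

DIMENSIONS = ("exposure", "susceptibility", "adaptive_capacity")
RULES = ("upper_quartile", "lower_quartile", "below_absolute")


@dataclass(frozen=True)
class Indicator:
    """One deprivation indicator: id, dimension, cutoff rule, weight.

    rule: 'upper_quartile'  -> deprived iff value >= cross-region Q3
          'lower_quartile'  -> deprived iff value <= cross-region Q1
          'below_absolute'  -> deprived iff value <  threshold
    """

    indicator_id: str
    dimension: str
    rule: str
    weight: float
    threshold: float | None = None

    def __post_init__(self) -> None:
        if self.rule not in RULES:
            raise ValueError(f"unknown rule {self.rule!r}")
        if self.rule == "below_absolute" and self.threshold is None:
            raise ValueError(f"{self.indicator_id}: absolute rule needs a threshold")


class IndicatorSchema:
    """Ordered set of indicators; weights must sum to 1."""

    def __init__(self, indicators: list[Indicator]):
        if not indicators:
            raise ValueError("empty schema")
        total = sum(ind.weight for ind in indicators)
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"indicator weights sum to {total!r}, not 1")
        self.indicators = list(indicators)

    @property
    def ids(self) -> list[str]:
        return [ind.indicator_id for ind in self.indicators]

    @property
    def weights(self) -> np.ndarray:
        return np.array([ind.weight for ind in self.indicators])

    @property
    def dimensions(self) -> list[str]:
        return [ind.dimension for ind in self.indicators]

    def __len__(self) -> int:
        return len(self.indicators)

    def __iter__(self):
        return iter(self.indicators)


def load_schema(source) -> IndicatorSchema:
    """Load a schema from a YAML file path or mapping.

    Expected structure: ``indicators: [{id, dimension, rule, weight,
    threshold?}, ...]``; weights may be given as strings like '1/21'.
    """
    if isinstance(source, dict):
        spec = source
    else:
        with open(source) as fh:
            spec = yaml.safe_load(fh)
    indicators = []
    for entry in spec["indicators"]:
        w = entry["weight"]
        if isinstance(w, str) and "/" in w:
            num, den = w.split("/")
            w = float(num) / float(den)
        indicators.append(
            Indicator(
                indicator_id=entry["id"],
                dimension=entry["dimension"],
                rule=entry["rule"],
                weight=float(w),
                threshold=entry.get("threshold"),
            )
        )
    return IndicatorSchema(indicators)


def default_schema(income_threshold: float = 296.8) -> IndicatorSchema:
    """The packaged 18-indicator schema (equal dimension weights of 1/3;
    equal indicator weights within a dimension).

    ``income_threshold`` is the absolute per-capita income deprivation
    line (default R$296.8; R$255.00 — half the 2010 minimum wage — is a
    documented alternative preset).
    """
    text = resources.files("climvuln").joinpath("data/default_schema.yaml").read_text()
    spec = yaml.safe_load(text)
    for entry in spec["indicators"]:
        if entry["rule"] == "below_absolute" and entry["id"] == "income_per_capita":
            entry["threshold"] = income_threshold
    return load_schema(spec)


def apply_deprivation_cutoffs(
    panel: pd.DataFrame, schema: IndicatorSchema
) -> pd.DataFrame:
    """Deprivation flags per (region, indicator) from the schema rules.

    Quartile bounds (linear-interpolation percentiles) are computed over
    the full panel — the whole study area — never per subgroup, so that
    subgroup decompositions remain exact.  Returns a 0/1 DataFrame
    indexed by region_id with one column per indicator.
    """
    if len(panel) < 4:
        raise ValueError("need at least 4 regions to define quartile cutoffs")
    idx = panel["region_id"] if "region_id" in panel.columns else panel.index
    flags = pd.DataFrame(index=pd.Index(idx, name="region_id"))
    for ind in schema:
        if ind.indicator_id not in panel.columns:
            raise ValueError(f"panel lacks indicator {ind.indicator_id!r}")
        vals = panel[ind.indicator_id].to_numpy(dtype=float)
        if np.isnan(vals).any():
            bad = np.asarray(idx)[np.isnan(vals)][0]
            raise ValueError(f"missing value for {ind.indicator_id!r} in region {bad!r}")
        if ind.rule == "upper_quartile":
            bound = np.percentile(vals, 75)
            flag = vals >= bound
            if np.all(vals == vals[0]):
                warnings.warn(f"{ind.indicator_id}: degenerate distribution, all flagged")
        elif ind.rule == "lower_quartile":
            bound = np.percentile(vals, 25)
            flag = vals <= bound
            if np.all(vals == vals[0]):
                warnings.warn(f"{ind.indicator_id}: degenerate distribution, all flagged")
        else:  # below_absolute, strict '<'
            flag = vals < float(ind.threshold)
        flags[ind.indicator_id] = flag.astype(int)
    return flags


def weighted_score(flags: pd.DataFrame, schema: IndicatorSchema) -> pd.Series:
    """Weighted deprivation score c_i = sum_i w_i * flag_i, in [0, 1]."""
    w = schema.weights
    if abs(w.sum() - 1.0) > 1e-9:
        raise ValueError("schema weights do not sum to 1")
    mat = flags[schema.ids].to_numpy(dtype=float)
    return pd.Series(mat @ w, index=flags.index, name="c")


@dataclass(frozen=True)
class ECVIResult:
    """Censored headcount, deprivation intensity and their product."""

    ch: float
    di: float
    ecvi: float
    k_p: float
    group: str = "overall"
    se_ch: float | None = None
    se_di: float | None = None
    se_ecvi: float | None = None

    def as_dict(self) -> dict:
        return {
            "group": self.group,
            "k_p": self.k_p,
            "ECVI": self.ecvi,
            "CH": self.ch,
            "DI": self.di,
            "SE_ECVI": self.se_ecvi,
            "SE_CH": self.se_ch,
            "SE_DI": self.se_di,
        }


def adjusted_index(ch: float, di: float) -> float:
    """The adjusted-headcount identity ECVI = CH * DI."""
    if not (0 <= ch <= 1 and 0 <= di <= 1):
        raise ValueError("CH and DI must lie in [0, 1]")
    return ch * di


def af_statistics(
    c: np.ndarray, populations: np.ndarray | None, k_p: float
) -> tuple[float, float, float]:
    """Core dual-cutoff statistics (CH, DI, ECVI) on scores c.

    ``populations`` of None gives the unweighted (region-counting)
    variant.  DI is 0 when no region is vulnerable.
    """
    c = np.asarray(c, dtype=float)
    if c.size == 0:
        raise ValueError("no regions")
    if not 0 < k_p <= 1:
        raise ValueError("k_p must lie in (0, 1]")
    if populations is None:
        p = np.ones_like(c)
    else:
        p = np.asarray(populations, dtype=float)
        if (p <= 0).any():
            raise ValueError("populations must be positive")
    vulnerable = c >= k_p
    total = p.sum()
    ch = float(p[vulnerable].sum() / total)
    if ch > 0:
        di = float((p * c * vulnerable).sum() / (p * vulnerable).sum())
    else:
        di = 0.0
    return ch, di, ch * di


def compute_ecvi(
    c,
    populations=None,
    k_p: float = 0.25,
    group: str = "overall",
    se_method: str | None = None,
    n_bootstrap: int = 1000,
    seed: int = 0,
) -> ECVIResult:
    """ECVI, CH and DI for one group of regions.

    ``c`` are weighted deprivation scores; ``populations`` weight the
    regions (None = unweighted).  ``se_method`` in {'bootstrap',
    'linearization', None} attaches standard errors.
    """
    c = np.asarray(c, dtype=float)
    pop = None if populations is None else np.asarray(populations, dtype=float)
    ch, di, ecvi = af_statistics(c, pop, k_p)
    se = {"se_ch": None, "se_di": None, "se_ecvi": None}
    if se_method is not None and c.size < 2:
        warnings.warn(f"group {group!r} has a single region; SEs undefined")
        se = {"se_ch": np.nan, "se_di": np.nan, "se_ecvi": np.nan}
    elif se_method is not None:
        se_ch, se_di, se_ecvi = estimate_se(
            c, pop, k_p, method=se_method, n_bootstrap=n_bootstrap, seed=seed
        )
        se = {"se_ch": se_ch, "se_di": se_di, "se_ecvi": se_ecvi}
    return ECVIResult(ch=ch, di=di, ecvi=ecvi, k_p=k_p, group=group, **se)


def estimate_se(
    c,
    populations=None,
    k_p: float = 0.25,
    method: str = "bootstrap",
    n_bootstrap: int = 1000,
    seed: int = 0,
) -> tuple[float, float, float]:
    """Standard errors for (CH, DI, ECVI).

    'bootstrap': resample regions with replacement (with their
    populations), recompute all three statistics, report the SD across
    replicates.  'linearization': Taylor expansion treating CH and ECVI
    as population-weighted means of [c >= k_p] and c*[c >= k_p], and DI
    as their ratio (delta method).
    """
    c = np.asarray(c, dtype=float)
    n = c.size
    if n < 2:
        raise ValueError("need at least 2 regions for a standard error")
    pop = np.ones(n) if populations is None else np.asarray(populations, dtype=float)
    if method == "bootstrap":
        if n_bootstrap < 50:
            warnings.warn("fewer than 50 bootstrap replicates; SEs will be noisy")
        rng = np.random.default_rng(seed)
        stats = np.empty((n_bootstrap, 3))
        for b in range(n_bootstrap):
            idx = rng.integers(0, n, size=n)
            stats[b] = af_statistics(c[idx], pop[idx], k_p)
        return tuple(float(s) for s in stats.std(axis=0, ddof=1))
    if method == "linearization":
        w = pop / pop.sum()
        vuln = (c >= k_p).astype(float)
        x = c * vuln
        ch = float(w @ vuln)
        ecvi = float(w @ x)
        var_ch = float((w**2 * (vuln - ch) ** 2).sum())
        var_e = float((w**2 * (x - ecvi) ** 2).sum())
        cov = float((w**2 * (vuln - ch) * (x - ecvi)).sum())
        if ch > 0:
            di = ecvi / ch
            var_di = (var_e + di**2 * var_ch - 2 * di * cov) / ch**2
        else:
            var_di = 0.0
        return float(np.sqrt(var_ch)), float(np.sqrt(max(var_di, 0.0))), float(np.sqrt(var_e))
    raise ValueError(f"unknown SE method {method!r}")


def decompose_by_subgroup(
    c, populations, groups, k_p: float = 0.25
) -> pd.DataFrame:
    """Exact population-share decomposition of ECVI across a partition.

    Each subgroup's ECVI uses the deprivation flags already cut on the
    full study area.  contribution_g = (n_g/n) * ECVI_g / ECVI; the
    shares sum to 1 whenever the pooled ECVI is positive (reported as
    NaN otherwise).
    """
    c = np.asarray(c, dtype=float)
    pop = np.ones_like(c) if populations is None else np.asarray(populations, dtype=float)
    groups = np.asarray(groups)
    if groups.shape != c.shape:
        raise ValueError("groups must label every region exactly once")
    _, _, pooled = af_statistics(c, pop, k_p)
    if pooled == 0:
        warnings.warn("pooled ECVI is 0: subgroup contributions undefined")
    total_pop = pop.sum()
    rows = []
    for gname in pd.unique(groups):
        mask = groups == gname
        ch_g, di_g, ecvi_g = af_statistics(c[mask], pop[mask], k_p)
        share = pop[mask].sum() / total_pop
        rows.append(
            {
                "subgroup": gname,
                "population_share": share,
                "CH": ch_g,
                "DI": di_g,
                "ECVI": ecvi_g,
                "weighted_ECVI": share * ecvi_g,
                "contribution": share * ecvi_g / pooled if pooled > 0 else np.nan,
            }
        )
    return pd.DataFrame(rows)


def decompose_by_indicator(
    flags: pd.DataFrame,
    schema: IndicatorSchema,
    populations=None,
    k_p: float = 0.25,
) -> pd.DataFrame:
    """Exact indicator decomposition ECVI = sum_i w_i * CH_i.

    CH_i is the population-weighted share of regions that are both
    vulnerable (c >= k_p) and deprived in indicator i; the contribution
    of indicator i is w_i * CH_i / ECVI.  A ``dimension`` column allows
    rolling contributions up to dimensions by summation.
    """
    c = weighted_score(flags, schema).to_numpy()
    n = len(c)
    pop = np.ones(n) if populations is None else np.asarray(populations, dtype=float)
    vuln = (c >= k_p).astype(float)
    wpop = pop / pop.sum()
    ecvi = float(wpop @ (c * vuln))
    if ecvi == 0:
        warnings.warn("ECVI is 0: indicator contributions undefined")
    rows = []
    for ind in schema:
        f = flags[ind.indicator_id].to_numpy(dtype=float)
        ch_i = float(wpop @ (f * vuln))
        rows.append(
            {
                "indicator_id": ind.indicator_id,
                "dimension": ind.dimension,
                "weight": ind.weight,
                "censored_headcount": ch_i,
                "contribution": ind.weight * ch_i / ecvi if ecvi > 0 else np.nan,
            }
        )
    return pd.DataFrame(rows)


def decompose_by_dimension(indicator_table: pd.DataFrame) -> pd.DataFrame:
    """Sum indicator contributions within each dimension."""
    return (
        indicator_table.groupby("dimension", sort=False)["contribution"]
        .sum()
        .reset_index()
    )
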