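"""Synthetic study generator with known ground truth.

Emulates the structure of the real inputs — daily gridded meteorology,
census-style region indicators, and hospitalization counts — so every
pipeline stage can be exercised and validated without external data:

* region memberships g_i over two latent climate regimes drawn from a
  Dirichlet(alpha0 * xi) (low alpha0 => regions near the pure profiles);
* daily weather per region as a membership-weighted mixture of a
  rain-extreme regime (ER-like: frequent wet days, heavy-tail events,
  cooler maxima) and a drought/heat regime (ED-HT-like: long dry runs,
  hot maxima, wide diurnal range): precipitation from a two-state
  wet/dry Markov chain with gamma wet-day amounts plus rare heavy
  events, temperatures from a seasonal sinusoid plus regime shift and
  noise;
* sociodemographic / infrastructure indicators as baseline + effect
  * (dominant-profile indicator) + noise, signed so the drought/heat
  zone is worse off (except primary-care coverage, worse in the
  rain-extreme zone), with log-normal populations;
* annual infectious-disease counts Poisson(pop * rate / 1e5) over five
  years with log rate linear in the region's weighted deprivation score.

The default configuration matches the study scale (62 regions, 34 years
of daily data); the ``fast`` profile (30 regions, 3 years) keeps test
runs small.  A fixed master seed makes every output bit-identical.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from . import ecvi

__all__ = [
    "RegimeParams",
    "GeneratorConfig",
    "generate_memberships",
    "generate_daily_climate",
    "generate_indicator_panel",
    "generate_disease_counts",
    "generate_categorical_matrix",
    "well_separated_lambda",
    "generate_study",
]


@dataclass(frozen=True)
class RegimeParams:
    """Daily-weather parameters of one pure climate regime."""

    wet_to_wet: float  # P(wet tomorrow | wet today)
    dry_to_wet: float  # P(wet tomorrow | dry today)
    gamma_shape: float  # wet-day amount ~ 1 mm + Gamma(shape, scale)
    gamma_scale: float  # mm
    heavy_prob: float  # chance a wet day carries an extra heavy event
    heavy_scale: float  # mean of the exponential heavy-event addition, mm
    tmax_mean: float  # degC
    diurnal_range: float  # mean tmax - tmin, degC


ER_REGIME = RegimeParams(
    wet_to_wet=0.70, dry_to_wet=0.45, gamma_shape=1.2, gamma_scale=10.0,
    heavy_prob=0.012, heavy_scale=60.0, tmax_mean=31.0, diurnal_range=8.0,
)
EDHT_REGIME = RegimeParams(
    wet_to_wet=0.45, dry_to_wet=0.06, gamma_shape=1.0, gamma_scale=6.0,
    heavy_prob=0.001, heavy_scale=40.0, tmax_mean=36.5, diurnal_range=12.0,
)

# indicator -> (baseline, effect added when the dominant profile is the
# drought/heat regime, noise sd); signs make that zone worse off except
# primary care, which is scarcer in the rain-extreme zone.
SOCIAL_INDICATORS: dict[str, tuple[float, float, float]] = {
    "prop_elderly": (0.085, +0.020, 0.008),
    "prop_children": (0.095, +0.015, 0.007),
    "income_per_capita": (420.0, -140.0, 45.0),
    "prop_poor": (0.32, +0.14, 0.04),
    "prop_literate": (0.84, -0.07, 0.02),
    "prop_sewage": (0.45, -0.15, 0.06),
    "prop_water": (0.78, -0.10, 0.05),
    "prop_garbage": (0.72, -0.16, 0.05),
    "urbanization": (0.62, -0.13, 0.06),
    "primary_care_coverage": (0.62, +0.08, 0.06),
    "hospital_beds_per_100k": (190.0, -45.0, 25.0),
}

# exposure proxies used only when a panel is generated without a daily
# climate pass (baseline, drought/heat effect, noise sd)
EXPOSURE_PROXIES: dict[str, tuple[float, float, float]] = {
    "txx": (32.0, +5.0, 0.8),
    "tnx": (24.0, +2.0, 0.6),
    "tx90p": (10.0, +4.0, 1.0),
    "tn90p": (10.0, +4.0, 1.0),
    "dtr": (8.0, +4.0, 0.5),
    "cdd": (15.0, +45.0, 5.0),
    "r99p": (150.0, -110.0, 20.0),
}

PROFILE_NAMES = ("ER", "ED-HT")


@dataclass(frozen=True)
class GeneratorConfig:
    """Knobs of the synthetic study; defaults are study-scale."""

    n_regions: int = 62
    n_years: int = 34
    start_year: int = 1980
    alpha0: float = 0.5
    xi: tuple[float, float] = (0.5, 0.5)
    er: RegimeParams = ER_REGIME
    edht: RegimeParams = EDHT_REGIME
    seasonal_amplitude: float = 3.0
    temp_noise_sd: float = 1.5
    dtr_noise_sd: float = 0.8
    indicator_effect_scale: float = 1.0  # 0 silences zone effects
    pop_log_mean: float = 13.1  # log persons (median ~ 490k)
    pop_log_sd: float = 0.7
    disease_base_rate: float = 300.0  # per 100,000 at zero deprivation
    disease_coef: float = 2.5  # log-rate slope in the deprivation score
    disease_years: int = 5
    seed: int = 0

    @classmethod
    def fast(cls, seed: int = 0, **overrides) -> "GeneratorConfig":
        """Small profile for tests: 30 regions, 3 years of daily data."""
        return cls(n_regions=30, n_years=3, seed=seed, **overrides)

    def rng(self) -> np.random.Generator:
        return np.random.default_rng(self.seed)


def generate_memberships(
    config: GeneratorConfig, rng: np.random.Generator | None = None
) -> np.ndarray:
    """True memberships g_i ~ Dirichlet(alpha0 * xi), shape (n, 2)."""
    rng = config.rng() if rng is None else rng
    alpha = config.alpha0 * np.asarray(config.xi, dtype=float)
    return rng.dirichlet(alpha, size=config.n_regions)


def _mix(g_row: np.ndarray, attr: str, config: GeneratorConfig) -> float:
    """Membership-weighted mixture of a regime parameter."""
    return float(
        g_row[0] * getattr(config.er, attr) + g_row[1] * getattr(config.edht, attr)
    )


def generate_daily_climate(
    config: GeneratorConfig,
    memberships: np.ndarray,
    rng: np.random.Generator | None = None,
) -> pd.DataFrame:
    """Daily tmax/tmin/precip per region over the configured years."""
    rng = config.rng() if rng is None else rng
    dates = pd.date_range(
        f"{config.start_year}-01-01",
        f"{config.start_year + config.n_years - 1}-12-31",
        freq="D",
    )
    n_days = len(dates)
    doy = dates.dayofyear.to_numpy()
    season = config.seasonal_amplitude * np.cos(2 * np.pi * (doy - 15) / 365.25)
    frames = []
    for i, g_row in enumerate(np.asarray(memberships, dtype=float)):
        p_ww = _mix(g_row, "wet_to_wet", config)
        p_dw = _mix(g_row, "dry_to_wet", config)
        shape = _mix(g_row, "gamma_shape", config)
        scale = _mix(g_row, "gamma_scale", config)
        heavy_p = _mix(g_row, "heavy_prob", config)
        heavy_s = _mix(g_row, "heavy_scale", config)

        u = rng.random(n_days)
        wet = np.zeros(n_days, dtype=bool)
        state = False  # start dry
        for d in range(n_days):
            prob = p_ww if state else p_dw
            state = u[d] < prob
            wet[d] = state
        precip = np.zeros(n_days)
        n_wet = int(wet.sum())
        if n_wet and shape > 0:
            amounts = 1.0 + rng.gamma(shape, scale, size=n_wet)
            heavy = rng.random(n_wet) < heavy_p
            amounts[heavy] += rng.exponential(heavy_s, size=int(heavy.sum()))
            precip[wet] = amounts

        tmax = (
            _mix(g_row, "tmax_mean", config)
            + season
            + config.temp_noise_sd * rng.standard_normal(n_days)
        )
        dtr = np.maximum(
            0.3,
            _mix(g_row, "diurnal_range", config)
            + config.dtr_noise_sd * rng.standard_normal(n_days),
        )
        frames.append(
            pd.DataFrame(
                {
                    "region_id": f"R{i + 1:03d}",
                    "date": dates,
                    "tmax": tmax,
                    "tmin": tmax - dtr,
                    "precip": precip,
                }
            )
        )
    return pd.concat(frames, ignore_index=True)


def generate_indicator_panel(
    config: GeneratorConfig,
    memberships: np.ndarray,
    rng: np.random.Generator | None = None,
    extreme_indices: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Region panel: population, 18 indicators, and the true profile.

    Exposure columns come from ``extreme_indices`` (as computed by the
    climate stage) when given; otherwise regime-linked proxies are
    synthesized directly.  Social indicators are baseline + effect *
    1[dominant profile is drought/heat] + noise.
    """
    rng = config.rng() if rng is None else rng
    g = np.asarray(memberships, dtype=float)
    n = g.shape[0]
    region_ids = [f"R{i + 1:03d}" for i in range(n)]
    dominant = g.argmax(axis=1)
    is_edht = (dominant == 1).astype(float)

    panel = pd.DataFrame({"region_id": region_ids})
    panel["population"] = np.round(
        np.exp(config.pop_log_mean + config.pop_log_sd * rng.standard_normal(n))
    ).astype(int)
    panel["true_profile"] = [PROFILE_NAMES[k] for k in dominant]
    panel["true_g_dominant"] = g.max(axis=1)

    scale = config.indicator_effect_scale
    for name, (base, effect, sd) in SOCIAL_INDICATORS.items():
        vals = base + scale * effect * is_edht + sd * rng.standard_normal(n)
        if name.startswith("prop_") or name in ("urbanization", "primary_care_coverage"):
            vals = np.clip(vals, 0.01, 0.99)
        else:
            vals = np.maximum(vals, 10.0)
        panel[name] = vals

    if extreme_indices is not None:
        panel = panel.merge(extreme_indices, on="region_id", validate="1:1")
    else:
        for name, (base, effect, sd) in EXPOSURE_PROXIES.items():
            vals = base + scale * effect * is_edht + sd * rng.standard_normal(n)
            if name in ("tx90p", "tn90p", "cdd", "r99p"):
                vals = np.maximum(vals, 0.0)
            panel[name] = vals
    return panel


def generate_disease_counts(
    config: GeneratorConfig,
    panel: pd.DataFrame,
    rng: np.random.Generator | None = None,
    schema: ecvi.IndicatorSchema | None = None,
) -> pd.DataFrame:
    """Annual hospitalization counts per region over five years.

    counts ~ Poisson(pop * rate / 1e5) with log rate = log(base) +
    coef * c_i, where c_i is the region's weighted deprivation score
    under the default schema — more deprived regions are sicker.
    """
    rng = config.rng() if rng is None else rng
    schema = ecvi.default_schema() if schema is None else schema
    flags = ecvi.apply_deprivation_cutoffs(panel, schema)
    c = ecvi.weighted_score(flags, schema).to_numpy()
    rate = config.disease_base_rate * np.exp(config.disease_coef * c)
    pop = panel["population"].to_numpy(dtype=float)
    years = np.arange(config.disease_years)
    rows = []
    for i, region in enumerate(panel["region_id"]):
        mean = pop[i] * rate[i] / 1e5
        counts = rng.poisson(mean, size=len(years))
        for y, cnt in zip(years, counts):
            rows.append({"region_id": region, "year": int(y + 1), "count": int(cnt)})
    return pd.DataFrame(rows)


def well_separated_lambda(J: int = 7, L: int = 5) -> np.ndarray:
    """Two profiles concentrated on disjoint category ranges."""
    low = np.array([0.70, 0.20, 0.05, 0.03, 0.02])
    if L != 5:
        low = np.full(L, 0.1 / max(L - 1, 1))
        low[0] = 0.9
        low /= low.sum()
    lam = np.empty((2, J, L))
    lam[0] = np.tile(low, (J, 1))
    lam[1] = np.tile(low[::-1], (J, 1))
    return lam


def generate_categorical_matrix(
    memberships: np.ndarray,
    lam: np.ndarray,
    rng: np.random.Generator,
    item_ids: list[str] | None = None,
) -> pd.DataFrame:
    """Sample Y_ij ~ Categorical(sum_k g_ik lambda_kj.) as a long table."""
    g = np.asarray(memberships, dtype=float)
    K, J, L = lam.shape
    if g.shape[1] != K:
        raise ValueError("membership and lambda profile counts differ")
    item_ids = item_ids or [f"item{j + 1}" for j in range(J)]
    probs = np.einsum("ik,kjl->ijl", g, lam)
    u = rng.random((g.shape[0], J))
    cats = (np.cumsum(probs, axis=2) < u[:, :, None]).sum(axis=2)
    rows = []
    for i in range(g.shape[0]):
        for j in range(J):
            rows.append(
                {
                    "region_id": f"R{i + 1:03d}",
                    "item_id": item_ids[j],
                    "category": int(cats[i, j] + 1),
                }
            )
    return pd.DataFrame(rows)


def generate_study(config: GeneratorConfig = GeneratorConfig()) -> dict:
    """Full synthetic study: memberships, daily climate, panel, counts.

    One master seed drives all stages in a fixed order, so identical
    configs give bit-identical outputs.
    """
    rng = config.rng()
    g = generate_memberships(config, rng)
    climate = generate_daily_climate(config, g, rng)
    panel = generate_indicator_panel(config, g, rng, extreme_indices=None)
    counts = generate_disease_counts(config, panel, rng)
    return {
        "config": config,
        "memberships": g,
        "daily_climate": climate,
        "indicator_panel": panel,
        "disease_counts": counts,
    }
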