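"""Bayesian Grade of Membership (GoM) model for categorical item responses.

Each region i holds a membership vector g_i = (g_i1..g_iK) on the simplex
(g_ik >= 0, sum_k g_ik = 1) over K latent extreme profiles; each profile k
carries multinomial response probabilities lambda_kjl over the L categories
of item j (sum_l lambda_kjl = 1).  The marginal cell probability is

    P(Y_ijl = 1) = sum_k g_ik * lambda_kjl

with g_i ~ Dirichlet(alpha), reparameterized as alpha = alpha0 * xi where
xi_k = alpha_k / alpha0 are expected profile proportions and alpha0 governs
the spread of memberships (lower alpha0 => memberships closer to the
simplex vertices, i.e. sharper extreme profiles).

Estimation is a conjugate Gibbs sampler over per-(region, item) latent
profile indicators z_ij:

    z_ij | g, lambda  ~ Categorical ∝ g_ik * lambda_{k j y_ij}
    g_i  | z, alpha   ~ Dirichlet(alpha + counts_i.)
    lambda_kj | z     ~ Dirichlet(1 + counts_kj.)
    alpha             : log-random-walk Metropolis under independent
                        Gamma(1, rate) priors on each alpha_k, which
                        factorize into xi ~ Dirichlet(1,..,1) and a
                        diffuse Gamma(K, rate) prior on alpha0.

Mixture label switching is resolved post hoc by permuting each draw's
labels to best match a reference draw (`align_labels`).
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import gammaln

__all__ = [
    "GoMConfig",
    "GoMFit",
    "fit_gom",
    "align_labels",
    "classify_profiles",
    "characterize_profiles",
    "matrix_to_array",
    "DEFAULT_CUTOFFS",
]

DEFAULT_CUTOFFS = (0.90, 0.75, 0.50)
TIER_NAMES = ("extreme", "high-mixed", "medium-mixed")


@dataclass(frozen=True)
class GoMConfig:
    """Sampler settings.

    n_iterations is the number of retained post-burn-in draws (the study
    convention: 5,000 draws after a 2,500 burn-in); alpha_prior_rate is
    the rate of the Gamma(1, rate) prior on each Dirichlet parameter
    alpha_k; mh_step is the log-random-walk scale of the Metropolis
    update for alpha.
    """

    K: int = 2
    n_iterations: int = 5000
    burn_in: int = 2500
    seed: int = 0
    alpha_prior_rate: float = 0.1
    mh_step: float = 0.3
    alpha_init: float = 1.0
    g_thin: int = 5

    def __post_init__(self) -> None:
        if self.K < 1:
            raise ValueError("K must be >= 1")
        if self.n_iterations < 1 or self.burn_in < 0:
            raise ValueError("need n_iterations >= 1 and burn_in >= 0")


@dataclass
class GoMFit:
    """Posterior draws and summaries of a fitted GoM model."""

    config: GoMConfig
    region_ids: list
    item_ids: list
    lambda_draws: np.ndarray  # (n_draws, K, J, L)
    g_draws: np.ndarray  # (n_draws // g_thin, n, K)
    g_means: np.ndarray  # (n, K)
    xi_draws: np.ndarray  # (n_draws, K)
    alpha0_draws: np.ndarray  # (n_draws,)
    loglik_trace: np.ndarray  # (n_draws,)
    mh_acceptance: float
    psrf_loglik: float

    @property
    def lambda_means(self) -> np.ndarray:
        return self.lambda_draws.mean(axis=0)

    @property
    def xi_mean(self) -> np.ndarray:
        return self.xi_draws.mean(axis=0)

    @property
    def alpha0_mean(self) -> float:
        return float(self.alpha0_draws.mean())

    def summary(self) -> dict:
        lo, hi = np.percentile(self.lambda_draws, [2.5, 97.5], axis=0)
        return {
            "K": self.config.K,
            "n_iterations": self.config.n_iterations,
            "burn_in": self.config.burn_in,
            "lambda_mean": self.lambda_means.tolist(),
            "lambda_ci_low": lo.tolist(),
            "lambda_ci_high": hi.tolist(),
            "xi_mean": self.xi_mean.tolist(),
            "alpha0_mean": self.alpha0_mean,
            "alpha0_ci": np.percentile(self.alpha0_draws, [2.5, 97.5]).tolist(),
            "psrf_loglik": self.psrf_loglik,
            "mh_acceptance": self.mh_acceptance,
        }

    def memberships(self) -> pd.DataFrame:
        cols = {f"g{k + 1}": self.g_means[:, k] for k in range(self.config.K)}
        return pd.DataFrame({"region_id": self.region_ids, **cols})


def matrix_to_array(matrix: pd.DataFrame) -> tuple[np.ndarray, list, list, int]:
    """Long categorical matrix -> dense (n, J) zero-based category array."""
    required = {"region_id", "item_id", "category"}
    if not required <= set(matrix.columns):
        raise ValueError(f"categorical matrix needs columns {sorted(required)}")
    wide = matrix.pivot(index="region_id", columns="item_id", values="category")
    if wide.isna().any().any():
        raise ValueError("categorical matrix has missing (region, item) cells")
    wide = wide.sort_index()
    L = int(matrix["category"].max())
    if matrix["category"].min() < 1:
        raise ValueError("categories must be 1-based")
    Y = wide.to_numpy(dtype=int) - 1
    return Y, list(wide.index), list(wide.columns), L


def _dirichlet_logpdf_sum(g: np.ndarray, alpha: np.ndarray, logg_sums: np.ndarray) -> float:
    n = g.shape[0]
    return float(
        n * (gammaln(alpha.sum()) - gammaln(alpha).sum()) + ((alpha - 1.0) * logg_sums).sum()
    )


def _observed_loglik(Y: np.ndarray, g: np.ndarray, lam: np.ndarray) -> float:
    J = Y.shape[1]
    lamY = lam[:, np.arange(J)[None, :], Y]  # (K, n, J)
    p = np.einsum("ik,kij->ij", g, lamY)
    return float(np.log(np.clip(p, 1e-300, None)).sum())


def _split_psrf(trace: np.ndarray) -> float:
    """Potential scale reduction on the first/second half of one chain."""
    m = len(trace) // 2
    if m < 2:
        return np.nan
    chains = np.stack([trace[:m], trace[m : 2 * m]])
    w = chains.var(axis=1, ddof=1).mean()
    b = m * chains.mean(axis=1).var(ddof=1)
    if w == 0:
        return 1.0
    var_plus = (m - 1) / m * w + b / m
    return float(np.sqrt(var_plus / w))


def fit_gom(matrix: pd.DataFrame, config: GoMConfig = GoMConfig()) -> GoMFit:
    """Fit the GoM model by Gibbs sampling on a complete categorical matrix.

    Returns post-burn-in draws with mixture labels aligned.  Identical
    config (including seed) and data give bit-identical draws.
    """
    Y, region_ids, item_ids, L = matrix_to_array(matrix)
    n, J = Y.shape
    K = config.K
    if K > n:
        raise ValueError("K cannot exceed the number of regions")
    for j, item in enumerate(item_ids):
        if len(np.unique(Y[:, j])) < 2 and K > 1:
            raise ValueError(f"degenerate item {item!r}: single observed category")

    rng = np.random.default_rng(config.seed)
    rows = np.broadcast_to(np.arange(n)[:, None], (n, J))
    cols = np.broadcast_to(np.arange(J)[None, :], (n, J))

    alpha = np.full(K, config.alpha_init, dtype=float)
    g = rng.dirichlet(np.ones(K), size=n)
    lam = rng.dirichlet(np.ones(L), size=(K, J))

    total = config.burn_in + config.n_iterations
    keep = config.n_iterations
    lambda_draws = np.empty((keep, K, J, L))
    g_kept = []
    g_sum = np.zeros((n, K))
    xi_draws = np.empty((keep, K))
    alpha0_draws = np.empty(keep)
    loglik = np.empty(keep)
    accept = 0

    for it in range(total):
        # z | g, lambda
        lamY = lam[:, cols, Y]  # (K, n, J)
        p = g[:, :, None].transpose(1, 0, 2) * lamY  # (K, n, J)
        p /= p.sum(axis=0, keepdims=True)
        u = rng.random((n, J))
        z = (np.cumsum(p, axis=0) < u[None, :, :]).sum(axis=0)

        # g | z, alpha
        Nik = np.zeros((n, K))
        np.add.at(Nik, (rows.ravel(), z.ravel()), 1.0)
        gam = rng.gamma(alpha[None, :] + Nik)
        g = gam / gam.sum(axis=1, keepdims=True)

        # lambda | z
        Ckjl = np.zeros((K, J, L))
        np.add.at(Ckjl, (z.ravel(), cols.ravel(), Y.ravel()), 1.0)
        gam = rng.gamma(1.0 + Ckjl)
        lam = gam / gam.sum(axis=2, keepdims=True)

        # alpha | g : log random walk Metropolis, Gamma(1, rate) priors
        logg_sums = np.log(np.clip(g, 1e-300, None)).sum(axis=0)
        prop = alpha * np.exp(config.mh_step * rng.standard_normal(K))
        log_ratio = (
            _dirichlet_logpdf_sum(g, prop, logg_sums)
            - _dirichlet_logpdf_sum(g, alpha, logg_sums)
            + config.alpha_prior_rate * (alpha.sum() - prop.sum())
            + (np.log(prop) - np.log(alpha)).sum()  # prior Gamma(1) log-density + Jacobian
        )
        if np.log(rng.random()) < log_ratio:
            alpha = prop
            accept += 1

        if it >= config.burn_in:
            d = it - config.burn_in
            lambda_draws[d] = lam
            xi_draws[d] = alpha / alpha.sum()
            alpha0_draws[d] = alpha.sum()
            loglik[d] = _observed_loglik(Y, g, lam)
            g_sum += g
            if d % config.g_thin == 0:
                g_kept.append(g.copy())

    g_draws = np.array(g_kept)
    if K > 1:
        lambda_draws, g_draws, xi_draws, g_sum_aligned = align_labels(
            lambda_draws, g_draws, xi_draws, g_thin=config.g_thin
        )
        g_means = g_sum_aligned if g_sum_aligned is not None else g_draws.mean(axis=0)
    else:
        g_means = g_sum / keep

    psrf = _split_psrf(loglik)
    if np.isfinite(psrf) and psrf > 1.1:
        warnings.warn(f"possible non-convergence: split-chain PSRF on loglik = {psrf:.3f}")

    return GoMFit(
        config=config,
        region_ids=region_ids,
        item_ids=item_ids,
        lambda_draws=lambda_draws,
        g_draws=g_draws,
        g_means=g_means,
        xi_draws=xi_draws,
        alpha0_draws=alpha0_draws,
        loglik_trace=loglik,
        mh_acceptance=accept / total,
        psrf_loglik=psrf,
    )


def align_labels(
    lambda_draws: np.ndarray,
    g_draws: np.ndarray | None = None,
    xi_draws: np.ndarray | None = None,
    g_thin: int = 1,
):
    """Undo mixture label switching by per-draw relabeling.

    Each draw's profile labels are permuted to minimize the squared
    distance of its lambda to a reference (the draw closest to the
    element-wise median of the chain); deterministic given the draws.
    Returns (lambda, g, xi, g_mean) with g/xi permuted consistently
    (g draws are assumed thinned by ``g_thin`` relative to lambda).
    """
    lambda_draws = np.asarray(lambda_draws)
    n_draws, K = lambda_draws.shape[:2]
    if K == 1 or n_draws < 2:
        g_mean = g_draws.mean(axis=0) if g_draws is not None else None
        return lambda_draws, g_draws, xi_draws, g_mean

    med = np.median(lambda_draws, axis=0)
    ref_idx = int(np.argmin(((lambda_draws - med) ** 2).sum(axis=(1, 2, 3))))
    ref = lambda_draws[ref_idx]
    perms = list(itertools.permutations(range(K)))
    lam_out = lambda_draws.copy()
    g_out = g_draws.copy() if g_draws is not None else None
    xi_out = xi_draws.copy() if xi_draws is not None else None
    g_sum = None
    for d in range(n_draws):
        costs = [((lambda_draws[d][list(p)] - ref) ** 2).sum() for p in perms]
        p = list(perms[int(np.argmin(costs))])
        lam_out[d] = lambda_draws[d][p]
        if xi_out is not None:
            xi_out[d] = xi_draws[d][p]
        if g_out is not None and d % g_thin == 0 and d // g_thin < len(g_out):
            g_out[d // g_thin] = g_draws[d // g_thin][:, p]
    if g_out is not None and len(g_out):
        g_sum = g_out.mean(axis=0)
    return lam_out, g_out, xi_out, g_sum


def classify_profiles(
    fit_or_g, cutoffs: tuple[float, float, float] = DEFAULT_CUTOFFS,
    profile_names: tuple[str, ...] | None = None,
) -> pd.DataFrame:
    """Assign each region its dominant profile and membership tier.

    The dominant profile is argmax_k of the posterior mean membership;
    the tier is the first cutoff the dominant membership meets (extreme
    >= 0.90, high-mixed >= 0.75, medium-mixed >= 0.50 by default).  The
    binary zone reclassifies mixed tiers into their dominant extreme
    profile.  Exact ties go to the lower profile index with a warning.
    """
    if isinstance(fit_or_g, GoMFit):
        g = fit_or_g.g_means
        region_ids = fit_or_g.region_ids
        K = fit_or_g.config.K
    else:
        g = np.asarray(fit_or_g["g"] if isinstance(fit_or_g, dict) else fit_or_g)
        region_ids = list(range(len(g)))
        K = g.shape[1]
    if K < 2:
        raise ValueError("profile classification requires K >= 2")
    if profile_names is None:
        profile_names = tuple(f"profile_{k + 1}" for k in range(K))
    cutoffs = tuple(sorted(cutoffs, reverse=True))
    dominant = g.argmax(axis=1)
    top = g.max(axis=1)
    ties = (g == top[:, None]).sum(axis=1) > 1
    if ties.any():
        warnings.warn(f"{int(ties.sum())} region(s) with tied dominant membership; lower index kept")
    tiers = []
    for value in top:
        tier = TIER_NAMES[-1]
        for name, cut in zip(TIER_NAMES, cutoffs):
            if value >= cut:
                tier = name
                break
        tiers.append(tier)
    return pd.DataFrame(
        {
            "region_id": region_ids,
            "profile": dominant + 1,
            "dominant_membership": top,
            "tier": tiers,
            "zone_binary": [profile_names[k] for k in dominant],
        }
    )


def characterize_profiles(
    fit: GoMFit, matrix: pd.DataFrame, ratio_threshold: float = 1.2
) -> pd.DataFrame:
    """Salient (item, category) pairs per profile.

    A cell is salient for profile k when its posterior mean response
    probability is at least ``ratio_threshold`` times the overall
    marginal frequency of that category in the study region (the "at
    least 20% higher than overall" rule at the default 1.2).
    """
    Y, _, item_ids, L = matrix_to_array(matrix)
    n, J = Y.shape
    marginal = np.zeros((J, L))
    for j in range(J):
        counts = np.bincount(Y[:, j], minlength=L)
        marginal[j] = counts / n
    lam = fit.lambda_means
    rows = []
    for k in range(fit.config.K):
        for j, item in enumerate(item_ids):
            for l in range(L):
                if marginal[j, l] > 0 and lam[k, j, l] >= ratio_threshold * marginal[j, l]:
                    rows.append(
                        {
                            "profile": k + 1,
                            "item_id": item,
                            "category": l + 1,
                            "lambda_mean": lam[k, j, l],
                            "marginal_freq": marginal[j, l],
                            "ratio": lam[k, j, l] / marginal[j, l],
                        }
                    )
    return pd.DataFrame(rows, columns=["profile", "item_id", "category", "lambda_mean", "marginal_freq", "ratio"])
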