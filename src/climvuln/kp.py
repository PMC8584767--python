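"""Choosing the multidimensional cutoff k_p: sensitivity curves,
forward-local-variance optimization, intersection and dominance checks.

The adjusted index and its components are recomputed over a grid of
cutoffs; ECVI and CH are nonincreasing in k_p by construction.  The
automated selector picks the grid point whose next ``t`` curve values
have minimal variance (the flattest forward window); when several groups
are compared, window variances are averaged across the group curves.
The selector is advisory: the vulnerable share at the suggested cutoff
is always reported so a too-censoring optimum can be overridden, and the
grid point where |CH - DI| is smallest is reported as a second advisory
(the intersection rule).
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .ecvi import af_statistics

__all__ = [
    "default_grid",
    "sensitivity_curve",
    "forward_local_variance_optimum",
    "grouped_optimum",
    "dominance_check",
    "intersection_point",
    "vulnerable_share",
    "kp_report",
]

STATISTICS = ("ECVI", "CH", "DI")


def default_grid(start: float = 0.05, stop: float = 1.0, step: float = 0.05) -> np.ndarray:
    grid = np.round(np.arange(start, stop + step / 2, step), 10)
    return grid[(grid > 0) & (grid <= 1)]


def sensitivity_curve(
    c,
    populations=None,
    statistic: str = "ECVI",
    grid: np.ndarray | None = None,
    group: str = "overall",
) -> pd.DataFrame:
    """Evaluate ECVI/CH/DI at every cutoff of the grid."""
    if statistic not in STATISTICS:
        raise ValueError(f"statistic must be one of {STATISTICS}")
    grid = default_grid() if grid is None else np.asarray(grid, dtype=float)
    if len(grid) == 0 or not np.all(np.diff(grid) > 0):
        raise ValueError("grid must be strictly increasing and nonempty")
    values = []
    for kp in grid:
        ch, di, ecvi = af_statistics(c, populations, float(kp))
        values.append({"ECVI": ecvi, "CH": ch, "DI": di}[statistic])
    return pd.DataFrame({"k_p": grid, "value": values, "statistic": statistic, "group": group})


def _window_variances(values: np.ndarray, t: int) -> np.ndarray:
    """Population variance of each forward window of length t."""
    n = len(values)
    if t < 2:
        raise ValueError("window length t must be >= 2")
    if n <= t:
        raise ValueError("grid must be longer than the window")
    return np.array([np.var(values[p : p + t]) for p in range(n - t + 1)])


def _first_minimum(variances: np.ndarray, grid: np.ndarray) -> float:
    # ties (within floating noise) break to the smallest cutoff
    vmin = variances.min()
    idx = int(np.argmax(variances <= vmin + 1e-12))
    return float(grid[idx])


def forward_local_variance_optimum(curve: pd.DataFrame, t: int = 3) -> float:
    """Grid point whose t forward curve values have minimal variance.

    Ties break to the smallest k_p (np.argmin takes the first minimum on
    an ascending grid).
    """
    values = curve["value"].to_numpy(dtype=float)
    grid = curve["k_p"].to_numpy(dtype=float)
    return _first_minimum(_window_variances(values, t), grid)


def grouped_optimum(curves: dict[str, pd.DataFrame], t: int = 3) -> float:
    """Minimize the forward window variance averaged across group curves."""
    if not curves:
        raise ValueError("no curves supplied")
    grids = [cv["k_p"].to_numpy(dtype=float) for cv in curves.values()]
    for g in grids[1:]:
        if len(g) != len(grids[0]) or not np.allclose(g, grids[0]):
            raise ValueError("group curves must share the same grid")
    stacked = np.mean(
        [_window_variances(cv["value"].to_numpy(dtype=float), t) for cv in curves.values()],
        axis=0,
    )
    return _first_minimum(stacked, grids[0])


def dominance_check(curves: dict[str, pd.DataFrame], tol: float = 0.0) -> pd.DataFrame:
    """Weak dominance between each ordered pair of group curves.

    Group A dominates B when A >= B (within tol) at every grid point
    where either curve is positive; otherwise the violating grid points
    are listed.
    """
    names = list(curves)
    rows = []
    for a in names:
        for b in names:
            if a == b:
                continue
            ga = curves[a]["k_p"].to_numpy(dtype=float)
            gb = curves[b]["k_p"].to_numpy(dtype=float)
            if len(ga) != len(gb) or not np.allclose(ga, gb):
                raise ValueError("group curves must share the same grid")
            va = curves[a]["value"].to_numpy(dtype=float)
            vb = curves[b]["value"].to_numpy(dtype=float)
            active = (va > 0) | (vb > 0)
            violations = ga[active & (va < vb - tol)]
            rows.append(
                {
                    "dominant": a,
                    "dominated": b,
                    "dominates": len(violations) == 0,
                    "violating_k_p": list(violations),
                }
            )
    return pd.DataFrame(rows)


def intersection_point(c, populations=None, grid: np.ndarray | None = None) -> float:
    """Grid point where |CH - DI| is smallest (the intersection rule)."""
    grid = default_grid() if grid is None else np.asarray(grid, dtype=float)
    gaps = []
    for kp in grid:
        ch, di, _ = af_statistics(c, populations, float(kp))
        gaps.append(abs(ch - di))
    return float(grid[int(np.argmin(gaps))])


def vulnerable_share(c, populations=None, k_p: float = 0.25) -> float:
    """Population share of regions with c >= k_p (the censored headcount)."""
    ch, _, _ = af_statistics(c, populations, k_p)
    return ch


def kp_report(
    c,
    populations=None,
    grid: np.ndarray | None = None,
    t: int = 3,
    chosen_kp: float = 0.25,
    groups=None,
) -> dict:
    """Advisory report: criterion optimum, intersection point, chosen
    cutoff, and the vulnerable share at each (flagging over-censoring)."""
    grid = default_grid() if grid is None else np.asarray(grid, dtype=float)
    if groups is None:
        curve = sensitivity_curve(c, populations, "ECVI", grid)
        optimum = forward_local_variance_optimum(curve, t)
    else:
        groups = np.asarray(groups)
        pop = None if populations is None else np.asarray(populations, dtype=float)
        curves = {}
        for gname in pd.unique(groups):
            mask = groups == gname
            curves[str(gname)] = sensitivity_curve(
                np.asarray(c)[mask], None if pop is None else pop[mask], "ECVI", grid, str(gname)
            )
        optimum = grouped_optimum(curves, t)
    report = {
        "grid": [float(x) for x in grid],
        "t": t,
        "criterion_optimum": optimum,
        "intersection_point": intersection_point(c, populations, grid),
        "chosen_kp": chosen_kp,
        "vulnerable_share_at_optimum": vulnerable_share(c, populations, optimum),
        "vulnerable_share_at_chosen": vulnerable_share(c, populations, chosen_kp),
    }
    report["optimum_overcensors"] = report["vulnerable_share_at_optimum"] < 0.05
    return report
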