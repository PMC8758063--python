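"""Posterior reporting: fixed-effect tables, smooth-effect curves with
credible bands, district spatial-effect summaries and convergence
diagnostics.

All intervals are equal-tail 95% (2.5% / 97.5% posterior quantiles); a
coefficient is flagged significant when that interval excludes zero, and
exp(mean) is reported as the odds ratio against the reference level.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .mcmc import ChainResult

__all__ = [
    "summarize_fixed",
    "smooth_effect_curve",
    "spatial_effect_summary",
    "diagnostics",
    "autocorrelation",
]

_Q = (2.5, 50.0, 97.5)


def _summary_rows(draws: np.ndarray, names) -> pd.DataFrame:
    q = np.percentile(draws, _Q, axis=0)
    mean = draws.mean(axis=0)
    return pd.DataFrame(
        {
            "variable": list(names),
            "mean": mean,
            "sd": draws.std(axis=0, ddof=1),
            "q2.5": q[0],
            "median": q[1],
            "q97.5": q[2],
            "significant": (q[0] > 0) | (q[2] < 0),
            "odds_ratio": np.exp(mean),
        }
    )


def summarize_fixed(chain: ChainResult) -> pd.DataFrame:
    """Fixed-effect posterior table: mean, SD, quantiles, significance, OR."""
    return _summary_rows(chain.fixed, chain.fixed_labels)


def smooth_effect_curve(
    chain: ChainResult, name: str, grid=None, n_grid: int = 100
) -> pd.DataFrame:
    """Pointwise posterior summary of one centered smooth on a grid.

    The grid defaults to ``n_grid`` equispaced points across the term's knot
    range (the observed covariate range); points outside that range raise.
    Columns: grid, mean, lo, hi (2.5%/97.5% bands on the log-odds scale).
    """
    if name not in chain.smooth_terms:
        raise KeyError(f"{name!r} is not a smooth term of this model")
    term = chain.smooth_terms[name]
    lo_k = term.knots[term.degree]
    hi_k = term.knots[-term.degree - 1]
    if grid is None:
        grid = np.linspace(lo_k, hi_k, n_grid)
    grid = np.asarray(grid, dtype=float)
    if grid.min() < lo_k - 1e-12 or grid.max() > hi_k + 1e-12:
        raise ValueError("evaluation grid outside the observed covariate range")
    Bg = term.basis_at(grid)  # (g, k) in the centered parameterisation
    curves = chain.smooth_coefs[name] @ Bg.T  # (M, g)
    q = np.percentile(curves, (2.5, 97.5), axis=0)
    return pd.DataFrame(
        {"grid": grid, "mean": curves.mean(axis=0), "lo": q[0], "hi": q[1]}
    )


def spatial_effect_summary(chain: ChainResult) -> tuple[pd.DataFrame, dict]:
    """Per-district posterior means/bands of both spatial fields + headline stats.

    Returns ``(table, stats)``.  ``table`` has one row per district with
    mean/lo/hi and a sign-significance flag per field.  ``stats`` reports
    each field's min-max range of posterior means and the empirical SD of
    those means — the dominance diagnostic separating neighbour-shared from
    district-local residual variation.
    """
    if chain.f_structured is None and chain.f_unstructured is None:
        raise ValueError("model has no spatial terms")
    labels = chain.district_labels
    table = pd.DataFrame({"district_id": labels})
    stats = {}
    for field_name, draws in (
        ("f_struct", chain.f_structured),
        ("f_unstruct", chain.f_unstructured),
    ):
        if draws is None:
            continue
        q = np.percentile(draws, (2.5, 97.5), axis=0)
        means = draws.mean(axis=0)
        table[f"{field_name}_mean"] = means
        table[f"{field_name}_lo"] = q[0]
        table[f"{field_name}_hi"] = q[1]
        table[f"{field_name}_significant"] = (q[0] > 0) | (q[1] < 0)
        stats[field_name] = {
            "range": (float(means.min()), float(means.max())),
            "sd": float(means.std(ddof=0)),
        }
    return table, stats


def autocorrelation(series: np.ndarray, max_lag: int = 50) -> np.ndarray:
    """Empirical lag-1..max_lag autocorrelation; NaN for constant series."""
    x = np.asarray(series, dtype=float)
    n = len(x)
    x = x - x.mean()
    denom = float(x @ x)
    if denom == 0.0:
        return np.full(min(max_lag, n - 1), np.nan)
    lags = range(1, min(max_lag, n - 1) + 1)
    return np.array([float(x[k:] @ x[:-k]) / denom for k in lags])


def diagnostics(chain: ChainResult, max_lag: int = 50) -> tuple[pd.DataFrame, dict]:
    """Convergence diagnostics: autocorrelations + sampling-path traces.

    Returns ``(acf_table, traces)`` where ``acf_table`` has one row per
    monitored scalar (each fixed effect and each variance) with lag-1/5/10
    autocorrelations, and ``traces`` maps the same names to their stored
    draw series for sampling-path export/plotting.
    """
    traces: dict[str, np.ndarray] = {}
    for j, lab in enumerate(chain.fixed_labels):
        traces[lab] = chain.fixed[:, j]
    for name, v in chain.variances.items():
        traces[name] = v
    traces["deviance"] = chain.deviance
    rows = []
    for name, series in traces.items():
        acf = autocorrelation(series, max_lag)
        take = {f"acf_lag{k}": (acf[k - 1] if len(acf) >= k else np.nan) for k in (1, 5, 10)}
        rows.append({"parameter": name, **take})
    return pd.DataFrame(rows), traces


def export_spatial_geojson(table: pd.DataFrame, polygons: dict, path) -> None:
    """Write the spatial summary as GeoJSON properties on the district polygons."""
    from .spatial import write_geojson

    props = {
        row["district_id"]: {
            k: (bool(v) if isinstance(v, (bool, np.bool_)) else float(v))
            for k, v in row.items()
            if k != "district_id"
        }
        for _, row in table.iterrows()
    }
    write_geojson({k: polygons[k] for k in props}, path, properties=props)


def plot_smooth(curve: pd.DataFrame, ax=None, **kwargs):
    """Optional matplotlib helper: posterior mean curve with credible band."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    ax.fill_between(curve["grid"], curve["lo"], curve["hi"], alpha=0.3, **kwargs)
    ax.plot(curve["grid"], curve["mean"])
    ax.axhline(0.0, lw=0.5, color="k")
    return ax
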