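"""Gradient statistics: Pearson correlation screens and simple regressions.

Links the ordination site scores (and index totals) to chemical health
indicators and landscape covariates: simple linear regression of each NMDS
axis on each log-transformed indicator, and a Pearson correlation screen with
a p < alpha significance mask.  No multiple-testing correction is applied by
default (raw p-values are reported per cell); a Holm option is available.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats


@dataclass
class RegressionResult:
    predictor: str
    response: str
    slope: float
    intercept: float
    r2: float
    p_value: float
    n: int
    stderr: float = float("nan")

    def confidence_band(self, x_grid, x, y, level: float = 0.95):
        """Pointwise confidence band for the fitted mean at x_grid."""
        x = np.asarray(x, float)
        y = np.asarray(y, float)
        n = len(x)
        yhat = self.intercept + self.slope * x
        mse = float(np.sum((y - yhat) ** 2) / (n - 2))
        xbar = x.mean()
        sxx = float(np.sum((x - xbar) ** 2))
        tcrit = stats.t.ppf(0.5 + level / 2, n - 2)
        xg = np.asarray(x_grid, float)
        se = np.sqrt(mse * (1.0 / n + (xg - xbar) ** 2 / sxx))
        center = self.intercept + self.slope * xg
        return center - tcrit * se, center + tcrit * se


def _pairwise_complete(x, y):
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    mask = np.isfinite(x) & np.isfinite(y)
    return x[mask], y[mask]


def pearson(x, y) -> tuple[float, float]:
    """Pearson r and its two-sided p (t distribution, n-2 df).

    Missing entries are dropped pairwise-complete; zero variance in either
    variable makes r undefined and raises.
    """
    xs, ys = _pairwise_complete(x, y)
    n = len(xs)
    if n < 3:
        raise ValueError(f"Pearson correlation needs n >= 3 complete pairs, got {n}")
    if np.std(xs) == 0 or np.std(ys) == 0:
        raise ValueError("Pearson correlation undefined for zero-variance input")
    r, p = stats.pearsonr(xs, ys)
    return float(r), float(p)


def ols_simple(x, y, predictor: str = "x", response: str = "y") -> RegressionResult:
    """Simple least-squares regression y = a + b x with R^2 and slope p.

    For one predictor, R^2 is identically the squared Pearson r of (x, y);
    the slope p-value is the two-sided t test with n-2 df.
    """
    xs, ys = _pairwise_complete(x, y)
    n = len(xs)
    if n < 3:
        raise ValueError(f"regression needs n >= 3 complete pairs, got {n}")
    if np.std(xs) == 0:
        raise ValueError("regression undefined: predictor has zero variance")
    if np.std(ys) == 0:
        # constant response: flat fit, no explained variance
        return RegressionResult(
            predictor=predictor, response=response, slope=0.0,
            intercept=float(ys[0]), r2=0.0, p_value=1.0, n=n, stderr=0.0,
        )
    res = stats.linregress(xs, ys)
    return RegressionResult(
        predictor=predictor,
        response=response,
        slope=float(res.slope),
        intercept=float(res.intercept),
        r2=float(res.rvalue**2),
        p_value=float(res.pvalue),
        n=n,
        stderr=float(res.stderr),
    )


def _sig_tier(p: float) -> str:
    if p < 0.001:
        return "p<0.001"
    if p < 0.05:
        return "p<0.05"
    return "ns"


def regress_axes_on_indicators(
    scores: pd.DataFrame,
    chem: pd.DataFrame,
    indicators: list[str],
    log_transform: bool = True,
) -> pd.DataFrame:
    """Regress each ordination axis on each chemical indicator.

    Indicators are log10-transformed first (zero-safe offset as in the
    clustering stage) — the convention for right-skewed water chemistry —
    and the transform is recorded per row so it is applied exactly once.
    """
    from .clustering import log_transform_chem

    shared = scores.index.intersection(chem.index)
    if len(shared) < 3:
        raise ValueError("axis and chemistry tables share fewer than 3 sites")
    chem_sub = chem.loc[shared, indicators]
    x_table = log_transform_chem(chem_sub) if log_transform else chem_sub
    rows = []
    for axis in scores.columns:
        for ind in indicators:
            res = ols_simple(
                x_table[ind], scores.loc[shared, axis], predictor=ind, response=axis
            )
            rows.append(
                {
                    "axis": axis,
                    "indicator": ind,
                    "slope": res.slope,
                    "intercept": res.intercept,
                    "R2": res.r2,
                    "p": res.p_value,
                    "n": res.n,
                    "transform": "log10" if log_transform else "none",
                    "significance": _sig_tier(res.p_value),
                }
            )
    return pd.DataFrame(rows)


def environment_screen(
    table: pd.DataFrame, alpha: float = 0.05, holm: bool = False
) -> pd.DataFrame:
    """Pearson correlation screen over all column pairs of ``table``.

    Returns a long DataFrame (var1, var2, r, p, n, significant) with
    pairwise-complete handling; constant columns are excluded with a
    warning.  ``holm=True`` applies a Holm step-down correction across the
    off-diagonal pairs (off by default; raw p-values are the reported
    convention).
    """
    cols = []
    for c in table.columns:
        vals = table[c].to_numpy(dtype=float)
        finite = vals[np.isfinite(vals)]
        if finite.size == 0 or np.std(finite) == 0:
            warnings.warn(f"excluding constant/empty column {c!r} from screen")
            continue
        cols.append(c)
    rows = []
    for i, a in enumerate(cols):
        for b in cols[i + 1 :]:
            xs, ys = _pairwise_complete(table[a], table[b])
            if len(xs) < 3 or np.std(xs) == 0 or np.std(ys) == 0:
                continue
            r, p = stats.pearsonr(xs, ys)
            rows.append({"var1": a, "var2": b, "r": float(r), "p": float(p), "n": len(xs)})
    out = pd.DataFrame(rows)
    if out.empty:
        return out.assign(significant=pd.Series(dtype=bool))
    if holm:
        order = np.argsort(out["p"].to_numpy())
        m = len(out)
        adj = np.empty(m)
        running = 0.0
        for rank, idx in enumerate(order):
            val = (m - rank) * out["p"].iloc[idx]
            running = max(running, val)
            adj[idx] = min(running, 1.0)
        out["p_adj"] = adj
        out["significant"] = out["p_adj"] < alpha
    else:
        out["significant"] = out["p"] < alpha
    return out


def screen_matrix(screen: pd.DataFrame, columns: list[str]) -> pd.DataFrame:
    """Pivot a long screen into a square r matrix (NaN where not significant)."""
    mat = pd.DataFrame(np.nan, index=columns, columns=columns)
    np.fill_diagonal(mat.values, 1.0)
    for _, row in screen.iterrows():
        if row["significant"]:
            mat.loc[row["var1"], row["var2"]] = row["r"]
            mat.loc[row["var2"], row["var1"]] = row["r"]
    return mat
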