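"""Evaluation statistics: indirect-light proportion, MAPE, band shares,
quantiles, paired t-tests and grouped aggregation.

Two paired comparisons drive the analysis:

* runs with vs. without multiple reflections give the indirect-light
  proportion  eta = 1 - E_without / E_with  of any tally;
* runs with the Phong BRDF vs. the spectrally equivalent diffuse model
  give the mean absolute percentage error

      MAPE = 100/n * sum |phi_phong - phi_diffuse| / phi_diffuse ,

  whose absolute value keeps opposite deviations from cancelling.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "indirect_fraction",
    "mape",
    "mape_frame",
    "band_fraction",
    "quantiles",
    "paired_t",
    "aggregate",
]


def indirect_fraction(e_without, e_with):
    """eta = 1 - E_without/E_with (elementwise; may be slightly negative
    under Monte-Carlo noise — values are reported unclamped)."""
    e_w = np.asarray(e_with, dtype=float)
    e_wo = np.asarray(e_without, dtype=float)
    if np.any(e_w <= 0):
        raise ValueError("the with-reflections tally must be positive")
    if np.any(e_wo < 0):
        raise ValueError("the without-reflections tally must be >= 0")
    return 1.0 - e_wo / e_w


def mape(phong, diffuse) -> float:
    """Mean absolute percentage error (percent) of paired values."""
    a = np.asarray(phong, dtype=float).ravel()
    b = np.asarray(diffuse, dtype=float).ravel()
    if a.size == 0:
        raise ValueError("empty comparison")
    if a.shape != b.shape:
        raise ValueError("pairs must align")
    if np.any(b <= 0):
        raise ValueError("diffuse reference values must be positive")
    return float(100.0 * np.mean(np.abs(a - b) / b))


def mape_frame(pairs: pd.DataFrame, group_by,
               value_a: str = "phong", value_b: str = "diffuse",
               drop_zero: bool = True) -> pd.DataFrame:
    """Grouped MAPE over an aligned comparison table.

    Zero-reference records (e.g. fully shaded sensors) make the relative
    error undefined; they are dropped and counted in ``n_dropped``.
    """
    need = {value_a, value_b}
    if not need.issubset(pairs.columns):
        raise ValueError(f"need columns {sorted(need)}")
    if pairs[[value_a, value_b]].isna().any().any():
        raise ValueError("comparison pairs must be complete")
    df = pairs
    n_total = len(df)
    if drop_zero:
        df = df[df[value_b] > 0]
    rows = []
    for key, sub in df.groupby(group_by):
        rel = np.abs(sub[value_a] - sub[value_b]) / sub[value_b]
        rows.append(dict(zip(np.atleast_1d(group_by).tolist()
                             if not isinstance(group_by, str) else [group_by],
                             np.atleast_1d(key)),
                         mape_pct=100.0 * rel.mean(),
                         se_pct=100.0 * rel.std(ddof=1) / np.sqrt(len(rel))
                         if len(rel) > 1 else np.nan,
                         n=len(rel)))
    out = pd.DataFrame(rows)
    out.attrs["n_dropped"] = n_total - len(df)
    return out


def band_fraction(band_values: np.ndarray) -> np.ndarray:
    """Share of each band in the total over the last axis (sums to 1)."""
    v = np.asarray(band_values, dtype=float)
    tot = v.sum(axis=-1, keepdims=True)
    if np.any(tot <= 0):
        raise ValueError("total flux must be positive")
    return v / tot


def quantiles(values, probs=(0.25, 0.5, 0.9)) -> np.ndarray:
    """Linear-interpolation (type 7) quantiles."""
    v = np.asarray(values, dtype=float)
    if v.size == 0:
        raise ValueError("empty input")
    return np.quantile(v, probs)


def paired_t(a, b):
    """Paired two-sided t-test; returns (t, df, p)."""
    a = np.asarray(a, dtype=float).ravel()
    b = np.asarray(b, dtype=float).ravel()
    if a.size < 2 or a.shape != b.shape:
        raise ValueError("need >= 2 aligned pairs")
    d = a - b
    if np.allclose(d.std(ddof=1), 0.0):
        raise ValueError("zero-variance differences: t undefined")
    res = stats.ttest_rel(a, b)
    return float(res.statistic), int(a.size - 1), float(res.pvalue)


_DIMENSIONS = ("leaf_order", "q_direct", "altitude", "side", "arrangement")


def aggregate(results: pd.DataFrame, dimension: str, value: str = "value",
              central_only: bool = False) -> pd.DataFrame:
    """Group means with standard errors along one study dimension.

    ``central_only`` restricts to centrally positioned plants (column
    ``central`` must be present and boolean).
    """
    if dimension not in _DIMENSIONS:
        raise ValueError(f"dimension must be one of {_DIMENSIONS}")
    df = results
    if central_only:
        df = df[df["central"]]
    g = df.groupby(dimension)[value]
    out = g.agg(mean="mean", sd="std", n="count").reset_index()
    out["se"] = out["sd"] / np.sqrt(out["n"])
    return out.drop(columns="sd")
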