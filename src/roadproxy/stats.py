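"""Spearman rank correlation between proxies and PM2.5.

rho is the Pearson correlation of mid-ranks (ties get the mean rank). The
two-sided p-value uses the t approximation
``t = rho * sqrt((n-2) / (1-rho^2))`` with n-2 degrees of freedom for
n >= 10, and the exact permutation distribution of rho for n < 10.
Constant inputs yield rho = 0, p = 1 with a flag rather than an error.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import permutations
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

PROXY_COLUMNS = {"WRND": "wrnd_kmkm2", "EM": "em_km", "EH": "eh_km"}

FLAG_CONSTANT = "constant-input"
FLAG_UNDEFINED = "undefined"

_T_APPROX_MIN_N = 10


@dataclass
class CorrelationResult:
    proxy_name: str
    stratum: str
    n: int
    rho: float
    p_value: float
    flags: set[str] = field(default_factory=set)

    @property
    def stars(self) -> str:
        if not np.isfinite(self.p_value):
            return ""
        if self.p_value < 0.001:
            return "***"
        if self.p_value < 0.01:
            return "**"
        if self.p_value < 0.05:
            return "*"
        return ""


def _rank_corr(x: np.ndarray, y: np.ndarray) -> float:
    rx = sps.rankdata(x)  # average ranks for ties
    ry = sps.rankdata(y)
    rx = rx - rx.mean()
    ry = ry - ry.mean()
    denom = np.sqrt((rx**2).sum() * (ry**2).sum())
    return float((rx * ry).sum() / denom)


def spearman(
    x: Sequence[float], y: Sequence[float],
    proxy_name: str = "x", stratum: str = "global",
) -> CorrelationResult:
    """Spearman rho with a two-sided p-value (complete-case)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-D sequences of equal length")
    keep = np.isfinite(x) & np.isfinite(y)
    x, y = x[keep], y[keep]
    n = x.size
    if n < 3:
        raise ValueError(f"spearman requires n >= 3 complete pairs (got {n})")
    if np.all(x == x[0]) or np.all(y == y[0]):
        return CorrelationResult(proxy_name, stratum, n, 0.0, 1.0, {FLAG_CONSTANT})
    rho = _rank_corr(x, y)
    if n >= _T_APPROX_MIN_N:
        if abs(rho) >= 1.0 - 1e-15:
            p = 0.0
        else:
            t = rho * np.sqrt((n - 2) / (1 - rho**2))
            p = float(2 * sps.t.sf(abs(t), df=n - 2))
    else:
        p = _exact_permutation_p(x, y, rho)
    return CorrelationResult(proxy_name, stratum, n, rho, min(p, 1.0))


def _exact_permutation_p(x: np.ndarray, y: np.ndarray, rho_obs: float) -> float:
    """Two-sided p from the full permutation distribution of rho (n < 10)."""
    rx = sps.rankdata(x)
    ry = sps.rankdata(y)
    rx = rx - rx.mean()
    denom_x = np.sqrt((rx**2).sum())
    count = 0
    total = 0
    ry_c = ry - ry.mean()
    denom_y = np.sqrt((ry_c**2).sum())
    for perm in permutations(range(x.size)):
        r = float((rx * ry_c[list(perm)]).sum() / (denom_x * denom_y))
        if abs(r) >= abs(rho_obs) - 1e-12:
            count += 1
        total += 1
    return count / total


def correlation_matrix(
    proxy_table: pd.DataFrame,
    exposure_table: pd.DataFrame,
    strata: Mapping[str, str] | None = None,
) -> list[CorrelationResult]:
    """One CorrelationResult per (proxy x stratum) plus pooled "global".

    ``proxy_table`` carries village_id, wrnd_kmkm2, em_km, eh_km;
    ``exposure_table`` carries village_id, pm25. ``strata`` maps
    village_id -> stratum label (omit for a single pooled stratum).
    Strata with fewer than 3 complete pairs are flagged undefined.
    """
    merged = proxy_table.merge(exposure_table, on="village_id", how="inner")
    if strata:
        merged["stratum"] = [strata.get(v, "unknown") for v in merged["village_id"]]
        labels = sorted(set(merged["stratum"])) + ["global"]
    else:
        labels = ["global"]
    results = []
    for label in labels:
        sub = merged if label == "global" else merged[merged["stratum"] == label]
        for proxy, col in PROXY_COLUMNS.items():
            x = np.asarray(sub[col], dtype=float)
            y = np.asarray(sub["pm25"], dtype=float)
            n_ok = int((np.isfinite(x) & np.isfinite(y)).sum())
            if n_ok < 3:
                results.append(CorrelationResult(proxy, label, n_ok, float("nan"),
                                                 float("nan"), {FLAG_UNDEFINED}))
                continue
            results.append(spearman(x, y, proxy_name=proxy, stratum=label))
    return results


def correlation_table(results: Sequence[CorrelationResult]) -> pd.DataFrame:
    return pd.DataFrame(
        [(r.proxy_name, r.stratum, r.n, r.rho, r.p_value, r.stars,
          ";".join(sorted(r.flags))) for r in results],
        columns=["proxy", "stratum", "n", "rho", "p", "stars", "flags"],
    )
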