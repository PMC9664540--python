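"""Statistical toolbox: one-way ANOVA with Tukey HSD, Spearman correlation
with banded strength categories, paired and two-sample t-tests, and a
Kolmogorov-Smirnov normality pre-check.

Significance threshold alpha = 0.05 throughout.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

log = logging.getLogger(__name__)

ALPHA = 0.05

#: |rho| bands, inclusive lower bound.  The source table stops at 0.8;
#: "very strong" for |rho| >= 0.8 is an explicit extension.
SPEARMAN_BANDS = (
    (0.0, "little"),
    (0.2, "weak"),
    (0.4, "moderate"),
    (0.6, "strong"),
    (0.8, "very strong"),
)


def spearman_category(rho: float) -> str:
    if np.isnan(rho):
        raise ValueError("rho is undefined")
    mag = abs(rho)
    label = SPEARMAN_BANDS[0][1]
    for lo, name in SPEARMAN_BANDS:
        if mag >= lo:
            label = name
    return label


@dataclass
class SpearmanResult:
    rho: float
    p_value: float
    category: str
    ks_p_x: float
    ks_p_y: float
    ks_caveat: str = (
        "KS normality computed with estimated mean/SD (Lilliefors-type bias)"
    )


def ks_normality(x: np.ndarray) -> float:
    """KS test against a normal with estimated parameters.

    Estimating the parameters from the data biases the p-value upward
    (Lilliefors); the caveat is carried in :class:`SpearmanResult`.
    """
    x = np.asarray(x, dtype=float)
    sd = x.std(ddof=1)
    if sd == 0:
        return 0.0
    return float(stats.kstest(x, "norm", args=(x.mean(), sd)).pvalue)


def spearman_with_category(x, y) -> SpearmanResult:
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y) or len(x) < 4:
        raise ValueError("need paired samples with n >= 4")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("constant input: Spearman rho undefined")
    rho, p = stats.spearmanr(x, y)
    return SpearmanResult(
        rho=float(rho),
        p_value=float(p),
        category=spearman_category(float(rho)),
        ks_p_x=ks_normality(x),
        ks_p_y=ks_normality(y),
    )


def anova_tukey(groups: dict[str, np.ndarray] | list[np.ndarray]) -> pd.DataFrame:
    """One-way ANOVA followed by Tukey's HSD.

    Returns a table with one 'anova' row (F, p) and one row per group pair
    (Tukey-adjusted p, mean difference).
    """
    if isinstance(groups, dict):
        names = list(groups)
        data = [np.asarray(groups[k], dtype=float) for k in names]
    else:
        data = [np.asarray(g, dtype=float) for g in groups]
        names = [f"g{i}" for i in range(len(data))]
    if len(data) < 2:
        raise ValueError("need at least 2 groups")
    for name, g in zip(names, data):
        if len(g) < 2:
            raise ValueError(f"group {name!r} has fewer than 2 observations")

    grand = np.concatenate(data)
    if np.ptp(grand) == 0:  # all observations identical everywhere
        F, p = 0.0, 1.0
    else:
        means = [g.mean() for g in data]
        if max(means) == min(means) and all(np.ptp(g) == 0 for g in data):
            F, p = 0.0, 1.0
        else:
            F, p = stats.f_oneway(*data)
    rows = [
        {"comparison": "anova", "statistic": float(F), "p_value": float(p), "mean_diff": np.nan}
    ]
    tk = stats.tukey_hsd(*data)
    for i in range(len(data)):
        for j in range(i + 1, len(data)):
            rows.append(
                {
                    "comparison": f"{names[i]} vs {names[j]}",
                    "statistic": float(tk.statistic[i, j]),
                    "p_value": float(tk.pvalue[i, j]),
                    "mean_diff": float(data[i].mean() - data[j].mean()),
                }
            )
    return pd.DataFrame(rows)


def paired_t(x, y) -> tuple[float, float]:
    """Paired t-test for a corresponding two-group comparison."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y):
        raise ValueError("paired test requires equal lengths")
    if len(x) < 2:
        raise ValueError("need n >= 2 pairs")
    if np.ptp(x - y) == 0:
        return 0.0, 1.0
    t, p = stats.ttest_rel(x, y)
    return float(t), float(p)


def run_pipeline(config: dict, out_dir) -> dict:
    """End-to-end orchestration; see :func:`nodule4d.pipeline.run_pipeline`."""
    from .pipeline import run_pipeline as _run  # deferred: pipeline imports this module

    return _run(config, out_dir)


def two_sample_t(x, y) -> tuple[float, float]:
    """Two-sample (equal-variance) t-test for uncorresponding groups."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) < 2 or len(y) < 2:
        raise ValueError("need n >= 2 per group")
    t, p = stats.ttest_ind(x, y, equal_var=True)
    return float(t), float(p)
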