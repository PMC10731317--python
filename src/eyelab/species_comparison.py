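"""Two-sample wolf/dog comparison of contrast values.

Welch's t with Satterthwaite degrees of freedom, a 95% CI for the mean
difference on the same df, and Cohen's d (pooled SD) with a
normal-approximation CI.  No multiplicity adjustment across channels.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from ._exceptions import DegenerateDataError, GroupingError, SampleSizeError

__all__ = ["WelchResult", "welch_t", "cohens_d", "compare_species"]

logger = logging.getLogger(__name__)

CONTRAST_COLUMNS = {"L": "c_L", "A": "c_A", "B": "c_B"}


@dataclass(frozen=True)
class WelchResult:
    t: float
    df: float
    p: float
    ci: tuple[float, float]
    d: float
    d_ci: tuple[float, float]
    n_a: int
    n_b: int


def _clean(group: np.ndarray, label: str) -> np.ndarray:
    group = np.asarray(group, dtype=float)
    finite = np.isfinite(group)
    dropped = group.size - int(finite.sum())
    if dropped:
        logger.info("dropped %d non-finite values from group %s", dropped, label)
    group = group[finite]
    if group.size < 2:
        raise SampleSizeError(f"group {label} has {group.size} values; need >= 2")
    return group


def welch_t(
    group_a: np.ndarray, group_b: np.ndarray, conf_level: float = 0.95
) -> WelchResult:
    """Welch's two-sample t-test of ``group_a`` minus ``group_b``."""
    a = _clean(group_a, "a")
    b = _clean(group_b, "b")
    if a.var(ddof=1) == 0 and b.var(ddof=1) == 0:
        raise DegenerateDataError("both groups have zero variance")

    n1, n2 = a.size, b.size
    v1, v2 = a.var(ddof=1), b.var(ddof=1)
    se2 = v1 / n1 + v2 / n2
    t = (a.mean() - b.mean()) / np.sqrt(se2)
    # Welch–Satterthwaite
    df = se2**2 / ((v1 / n1) ** 2 / (n1 - 1) + (v2 / n2) ** 2 / (n2 - 1))
    p = 2.0 * stats.t.sf(abs(t), df)
    half = stats.t.ppf(0.5 + conf_level / 2, df) * np.sqrt(se2)
    diff = a.mean() - b.mean()
    d, d_ci = cohens_d(a, b, conf_level=conf_level)
    return WelchResult(
        t=float(t),
        df=float(df),
        p=float(p),
        ci=(float(diff - half), float(diff + half)),
        d=d,
        d_ci=d_ci,
        n_a=n1,
        n_b=n2,
    )


def cohens_d(
    group_a: np.ndarray,
    group_b: np.ndarray,
    conf_level: float = 0.95,
    ci_method: str = "normal",
) -> tuple[float, tuple[float, float]]:
    """Cohen's d with pooled SD and a normal-approximation CI.

    The CI uses the large-sample standard error
    sqrt((n1+n2)/(n1*n2) + d^2 / (2*(n1+n2-2))).
    """
    a = _clean(group_a, "a")
    b = _clean(group_b, "b")
    n1, n2 = a.size, b.size
    pooled_var = ((n1 - 1) * a.var(ddof=1) + (n2 - 1) * b.var(ddof=1)) / (
        n1 + n2 - 2
    )
    if pooled_var == 0:
        raise DegenerateDataError("pooled SD is zero")
    d = (a.mean() - b.mean()) / np.sqrt(pooled_var)
    if ci_method != "normal":
        raise ValueError(f"unknown d CI method {ci_method!r}")
    se = np.sqrt((n1 + n2) / (n1 * n2) + d**2 / (2 * (n1 + n2 - 2)))
    z = stats.norm.ppf(0.5 + conf_level / 2)
    return float(d), (float(d - se * z), float(d + se * z))


def compare_species(
    table: pd.DataFrame,
    species_col: str = "species",
    group_a: str = "dog",
    group_b: str = "wolf",
) -> tuple[pd.DataFrame, dict[str, WelchResult]]:
    """Per-channel Welch comparison (group_a minus group_b) of a contrast table.

    Flagged/missing contrast values are dropped listwise per channel with a
    logged count.  Returns a tidy one-row-per-channel report plus the raw
    :class:`WelchResult` objects keyed by channel.
    """
    present = set(table[species_col].unique())
    for label in (group_a, group_b):
        if label not in present:
            raise GroupingError(f"species {label!r} absent from the table")

    results: dict[str, WelchResult] = {}
    rows = []
    for channel, col in CONTRAST_COLUMNS.items():
        sub = table[[species_col, col]].copy()
        sub[col] = pd.to_numeric(sub[col], errors="coerce")
        n_missing = int(sub[col].isna().sum())
        if n_missing:
            logger.info("channel %s: excluded %d flagged/missing values",
                        channel, n_missing)
        a = sub.loc[sub[species_col] == group_a, col].dropna().to_numpy()
        b = sub.loc[sub[species_col] == group_b, col].dropna().to_numpy()
        res = welch_t(a, b)
        results[channel] = res
        rows.append(
            {
                "channel": channel,
                f"n_{group_a}": res.n_a,
                f"n_{group_b}": res.n_b,
                "n_excluded": n_missing,
                "t": res.t,
                "df": res.df,
                "p": res.p,
                "ci_low": res.ci[0],
                "ci_high": res.ci[1],
                "d": res.d,
                "d_ci_low": res.d_ci[0],
                "d_ci_high": res.d_ci[1],
            }
        )
    return pd.DataFrame(rows), results
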