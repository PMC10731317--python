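"""Factor structure of the ten personality items and scale-score construction.

Parallel analysis (Horn's criterion against eigenvalues of random normal
data of identical shape), maximum-likelihood factor extraction with a
Kaiser-normalized varimax rotation, item→scale assignment by loading
threshold, and reverse-keyed scale scoring.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from statsmodels.multivariate.factor import Factor
from statsmodels.multivariate.factor_rotation import rotate_factors

from ._exceptions import (
    CoverageError,
    CrossLoadingError,
    DegenerateItemError,
    HeywoodWarning,
)

__all__ = [
    "PERSONALITY_ITEMS",
    "FRIENDLINESS_MARKERS",
    "FactorSolution",
    "parallel_analysis",
    "ml_factor_analysis",
    "assign_items",
    "scale_scores",
    "rater_scale_scores",
]

logger = logging.getLogger(__name__)

PERSONALITY_ITEMS = (
    "aggressive",
    "easygoing",
    "friendly",
    "kind",
    "sociable",
    "confident",
    "independent",
    "intelligent",
    "mature",
    "trustworthy",
)

#: items whose shared factor is labelled "friendliness"
FRIENDLINESS_MARKERS = ("sociable", "kind", "friendly")

ITEM_SCALE_MAX = 5


@dataclass
class FactorSolution:
    """Varimax-rotated orthogonal loadings plus the derived summaries."""

    n_factors: int
    loadings: pd.DataFrame  # items × factors
    communalities: pd.Series  # row sums of squared loadings
    ss_loadings: pd.Series  # column sums of squared loadings
    variance_explained: float  # total ss_loadings / n items
    heywood: bool = False


def _as_item_matrix(data) -> pd.DataFrame:
    df = pd.DataFrame(data)
    if df.shape[1] < 3:
        raise ValueError("need at least 3 items")
    constant = df.columns[df.std(ddof=1) == 0]
    if len(constant):
        raise DegenerateItemError(f"constant items: {list(constant)}")
    return df


def parallel_analysis(
    data,
    n_random: int = 100,
    criterion: str = "mean",
    seed: int | None = None,
) -> int:
    """Number of factors retained by Horn's parallel analysis.

    Observed correlation-matrix eigenvalues are compared position by
    position with the ``criterion`` summary ("mean" or "p95") of
    eigenvalues from ``n_random`` i.i.d. standard-normal data sets of the
    same shape; counting stops at the first eigenvalue that fails.
    """
    df = _as_item_matrix(data)
    n, p = df.shape
    if n < 3 * p:
        raise ValueError(f"need >= {3 * p} rows for {p} items, got {n}")
    obs = np.sort(np.linalg.eigvalsh(df.corr().to_numpy()))[::-1]

    rng = np.random.default_rng(seed)
    rand = np.empty((n_random, p))
    for i in range(n_random):
        x = rng.standard_normal((n, p))
        rand[i] = np.sort(np.linalg.eigvalsh(np.corrcoef(x, rowvar=False)))[::-1]
    if criterion == "mean":
        ref = rand.mean(axis=0)
    elif criterion == "p95":
        ref = np.percentile(rand, 95, axis=0)
    else:
        raise ValueError(f"unknown criterion {criterion!r}")

    n_factors = 0
    for o, r in zip(obs, ref):
        if o > r:
            n_factors += 1
        else:
            break
    return n_factors


def _kaiser_varimax(loadings: np.ndarray) -> np.ndarray:
    """Varimax rotation with Kaiser row normalization."""
    h = np.sqrt((loadings**2).sum(axis=1))
    h = np.where(h > 0, h, 1.0)
    rotated, _ = rotate_factors(loadings / h[:, None], "varimax")
    return rotated * h[:, None]


def ml_factor_analysis(data, n_factors: int) -> FactorSolution:
    """Maximum-likelihood factor extraction with varimax rotation.

    Factors are ordered by descending sum of squared loadings, and each
    factor's sign is fixed so its largest-magnitude loading is positive.
    A Heywood case (communality ≥ 1) emits a warning but still returns
    the solution.
    """
    df = _as_item_matrix(data)
    model = Factor(df.to_numpy(dtype=float), n_factor=n_factors, method="ml")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # optimizer chatter
        fit = model.fit()
    raw = np.asarray(fit.loadings)
    rotated = _kaiser_varimax(raw) if n_factors > 1 else raw.copy()

    # order by explained variance, fix signs
    ss = (rotated**2).sum(axis=0)
    order = np.argsort(ss)[::-1]
    rotated = rotated[:, order]
    for j in range(rotated.shape[1]):
        if rotated[np.argmax(np.abs(rotated[:, j])), j] < 0:
            rotated[:, j] = -rotated[:, j]

    factor_names = [f"factor{i + 1}" for i in range(n_factors)]
    loadings = pd.DataFrame(rotated, index=df.columns, columns=factor_names)
    communalities = (loadings**2).sum(axis=1)
    heywood = bool((communalities >= 1.0 - 1e-12).any())
    if heywood:
        warnings.warn(
            f"Heywood case: communalities >= 1 for "
            f"{list(communalities.index[communalities >= 1.0 - 1e-12])}",
            HeywoodWarning,
            stacklevel=2,
        )
    ss_loadings = (loadings**2).sum(axis=0)
    return FactorSolution(
        n_factors=n_factors,
        loadings=loadings,
        communalities=communalities,
        ss_loadings=ss_loadings,
        variance_explained=float(ss_loadings.sum() / len(df.columns)),
        heywood=heywood,
    )


def assign_items(
    solution: FactorSolution, threshold: float = 0.4
) -> dict[str, tuple[str, int]]:
    """Map each item to its scale with a keying direction.

    Returns ``{item: (scale, key)}`` where ``key`` is the sign of the
    qualifying loading.  The factor holding the sociable/kind/friendly
    block is labelled "friendliness", the other "maturity".
    """
    if solution.n_factors != 2:
        raise ValueError("item assignment requires a 2-factor solution")
    load = solution.loadings
    above = load.abs() >= threshold
    cross = list(load.index[above.sum(axis=1) > 1])
    if cross:
        raise CrossLoadingError(cross)

    assignment: dict[str, tuple[str, int]] = {}
    for item in load.index:
        hits = [c for c in load.columns if above.loc[item, c]]
        if hits:
            col = hits[0]
            assignment[item] = (col, 1 if load.loc[item, col] > 0 else -1)
    if not assignment:
        raise CoverageError("no item loads above the threshold on any factor")

    marker_votes = {c: 0 for c in load.columns}
    for marker in FRIENDLINESS_MARKERS:
        if marker in assignment:
            marker_votes[assignment[marker][0]] += 1
    friendly_col = max(marker_votes, key=marker_votes.get)
    labels = {
        c: ("friendliness" if c == friendly_col else "maturity")
        for c in load.columns
    }
    return {item: (labels[col], key) for item, (col, key) in assignment.items()}


def rater_scale_scores(
    ratings: pd.DataFrame, mapping: dict[str, tuple[str, int]]
) -> pd.DataFrame:
    """Per-row friendliness/maturity scores (reverse-keyed items flipped)."""
    missing = set(PERSONALITY_ITEMS) - set(mapping)
    if missing:
        raise CoverageError(f"mapping does not cover items: {sorted(missing)}")
    out = ratings.copy()
    for scale in ("friendliness", "maturity"):
        items = [it for it, (s, _) in mapping.items() if s == scale]
        cols = []
        for it in items:
            key = mapping[it][1]
            col = ratings[it] if key > 0 else ITEM_SCALE_MAX - ratings[it]
            cols.append(col)
        out[scale] = pd.concat(cols, axis=1).mean(axis=1)
    reversed_items = sorted(it for it, (_, k) in mapping.items() if k < 0)
    if reversed_items:
        logger.info("reverse-keyed before averaging: %s", reversed_items)
    return out


def scale_scores(
    ratings: pd.DataFrame, mapping: dict[str, tuple[str, int]]
) -> pd.DataFrame:
    """Mean friendliness/maturity per (image_id, eye_colour) across raters."""
    scored = rater_scale_scores(ratings, mapping)
    grouped = (
        scored.groupby(["image_id", "eye_colour"], observed=True)
        .agg(
            friendliness=("friendliness", "mean"),
            maturity=("maturity", "mean"),
            n_raters=("participant_id", "nunique"),
        )
        .reset_index()
    )
    if (grouped["n_raters"] == 0).any():
        raise CoverageError("stimulus with zero raters")
    return grouped
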