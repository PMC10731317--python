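"""Eye-colour effect tests and mixed-model analysis of acceptance attitudes.

Paired t-tests of the 12 dark/light stimulus pairs, a one-way MANOVA of
the ten items on eye colour (Pillai's trace with unadjusted univariate
follow-ups), and Gaussian linear mixed models of the two acceptance
responses with a random intercept per dog image and Type III Wald χ²
tests of the fixed terms.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
import statsmodels.formula.api as smf
from statsmodels.multivariate.manova import MANOVA

from ._exceptions import (
    DegenerateDataError,
    GroupingError,
    PairingError,
    RankError,
    SingularFitWarning,
)
from .psychometrics import PERSONALITY_ITEMS

__all__ = [
    "PairedTestResult",
    "ManovaResult",
    "LmmTermResult",
    "paired_eye_colour_test",
    "item_manova",
    "fit_acceptance_lmm",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class PairedTestResult:
    t: float
    df: int
    p: float
    ci: tuple[float, float]
    d: float
    d_ci: tuple[float, float]


@dataclass
class ManovaResult:
    pillai: float
    f: float
    df_num: float
    df_den: float
    p: float
    univariate: pd.DataFrame  # item, F, p


@dataclass(frozen=True)
class LmmTermResult:
    term: str
    beta: float
    ci: tuple[float, float]
    wald_chi2: float
    df: int
    p: float


def paired_eye_colour_test(
    scale_table: pd.DataFrame,
    scale: str,
    conf_level: float = 0.95,
) -> PairedTestResult:
    """Paired t-test of dark minus light per-image scale scores.

    ``scale_table`` is the per-(image_id, eye_colour) score table; each
    image must appear in both eye colours.
    """
    wide = scale_table.pivot(index="image_id", columns="eye_colour", values=scale)
    incomplete = wide.index[wide.isna().any(axis=1)]
    if len(incomplete) or wide.shape[1] != 2:
        raise PairingError(list(incomplete) or list(wide.index))
    diff = (wide["dark"] - wide["light"]).to_numpy(dtype=float)
    n = diff.size
    sd = diff.std(ddof=1)
    if sd == 0:
        if (diff == 0).all():  # exact identity: no effect, by convention
            return PairedTestResult(
                t=0.0, df=n - 1, p=1.0, ci=(0.0, 0.0), d=0.0, d_ci=(0.0, 0.0)
            )
        raise DegenerateDataError("zero variance of paired differences")
    t = diff.mean() / (sd / np.sqrt(n))
    df = n - 1
    p = 2.0 * stats.t.sf(abs(t), df)
    half = stats.t.ppf(0.5 + conf_level / 2, df) * sd / np.sqrt(n)
    d = diff.mean() / sd
    se_d = np.sqrt(1.0 / n + d**2 / (2.0 * n))
    z = stats.norm.ppf(0.5 + conf_level / 2)
    return PairedTestResult(
        t=float(t),
        df=int(df),
        p=float(p),
        ci=(float(diff.mean() - half), float(diff.mean() + half)),
        d=float(d),
        d_ci=(float(d - z * se_d), float(d + z * se_d)),
    )


def item_manova(
    ratings: pd.DataFrame, items: tuple[str, ...] = PERSONALITY_ITEMS
) -> ManovaResult:
    """One-way MANOVA of the items on eye colour (Pillai's trace)."""
    groups = set(ratings["eye_colour"].unique())
    if not {"dark", "light"} <= groups:
        raise GroupingError("both eye-colour groups must be present")
    if len(ratings) < len(items) + 2:
        raise ValueError("too few rows for a MANOVA on this many items")

    y = ratings[list(items)].to_numpy(dtype=float)
    for label in ("dark", "light"):
        sub = y[(ratings["eye_colour"] == label).to_numpy()]
        cov = np.cov(sub, rowvar=False)
        if np.linalg.matrix_rank(cov) < len(items):
            raise RankError(
                f"singular within-group covariance in {label!r} group; "
                "consider removing collinear items"
            )

    uni_rows = []
    for item in items:
        dark = ratings.loc[ratings["eye_colour"] == "dark", item]
        light = ratings.loc[ratings["eye_colour"] == "light", item]
        f, p = stats.f_oneway(dark, light)
        uni_rows.append({"item": item, "F": float(f), "p": float(p)})

    if len(items) == 1:
        # degenerate multivariate case: Pillai reduces to eta², F to ANOVA F
        values = y[:, 0]
        grand = values.mean()
        ssb = sum(
            len(g) * (g.mean() - grand) ** 2
            for _, g in ratings.groupby("eye_colour")[items[0]]
        )
        sst = ((values - grand) ** 2).sum()
        pillai = float(ssb / sst)
        df_den = len(values) - 2
        f = pillai / (1 - pillai) * df_den
        return ManovaResult(
            pillai=pillai,
            f=float(f),
            df_num=1.0,
            df_den=float(df_den),
            p=float(stats.f.sf(f, 1, df_den)),
            univariate=pd.DataFrame(uni_rows),
        )

    # exactly coincident group means: the hypothesis matrix is zero and the
    # generalized eigenproblem degenerates; the answer is the null identity
    group_means = ratings.groupby("eye_colour")[list(items)].mean()
    if np.abs(group_means.diff().iloc[1]).max() < 1e-12:
        n = len(ratings)
        return ManovaResult(
            pillai=0.0,
            f=0.0,
            df_num=float(len(items)),
            df_den=float(n - 1 - len(items)),
            p=1.0,
            univariate=pd.DataFrame(uni_rows),
        )

    formula = " + ".join(items) + " ~ C(eye_colour)"
    mv = MANOVA.from_formula(formula, data=ratings)
    table = mv.mv_test().results["C(eye_colour)"]["stat"]
    row = table.loc["Pillai's trace"]
    return ManovaResult(
        pillai=float(row["Value"]),
        f=float(row["F Value"]),
        df_num=float(row["Num DF"]),
        df_den=float(row["Den DF"]),
        p=float(row["Pr > F"]),
        univariate=pd.DataFrame(uni_rows),
    )


def fit_acceptance_lmm(
    ratings: pd.DataFrame,
    response: str,
    conf_level: float = 0.95,
    covariate_level: str = "rater",
) -> tuple[list[LmmTermResult], object]:
    """Gaussian LMM of an acceptance response with image random intercepts.

    Fixed effects: eye colour plus friendliness and maturity scale scores.
    With ``covariate_level="rater"`` (default) each row carries that
    rater's own scale scores; "stimulus" replaces them with per-stimulus
    means across raters.  Returns per-term Type III Wald χ² results (1 df
    terms) and the fitted statsmodels results object.
    """
    data = ratings.copy()
    if covariate_level == "stimulus":
        means = data.groupby(["image_id", "eye_colour"], observed=True)[
            ["friendliness", "maturity"]
        ].transform("mean")
        data[["friendliness", "maturity"]] = means
    elif covariate_level != "rater":
        raise ValueError(f"unknown covariate level {covariate_level!r}")
    logger.info("LMM covariates entered at the %s level", covariate_level)

    formula = f"{response} ~ C(eye_colour, Treatment('light')) + friendliness + maturity"
    model = smf.mixedlm(formula, data=data, groups=data["image_id"])
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        fit = model.fit(reml=True)
    re_var = float(np.asarray(fit.cov_re).ravel()[0])
    k = len(fit.fe_params)
    params = fit.fe_params
    cov = np.asarray(fit.cov_params())[:k, :k]
    if re_var < 1e-8:
        # profiled boundary solution (variance 0) is exactly GLS with
        # V = σ²I, i.e. ordinary least squares — use it verbatim
        warnings.warn(
            "random-intercept variance estimated at the boundary (~0); "
            "falling back to the ordinary-least-squares solution",
            SingularFitWarning,
            stacklevel=2,
        )
        logger.info("singular LMM fit for %s: variance fixed at 0", response)
        ols = smf.ols(formula, data=data).fit()
        params = ols.params
        cov = np.asarray(ols.cov_params())
    z = stats.norm.ppf(0.5 + conf_level / 2)

    pretty = {
        "C(eye_colour, Treatment('light'))[T.dark]": "eye_colour",
        "friendliness": "friendliness",
        "maturity": "maturity",
        "Intercept": "intercept",
    }
    results = []
    for i, name in enumerate(params.index):
        beta = float(params.iloc[i])
        se = float(np.sqrt(cov[i, i]))
        chi2 = (beta / se) ** 2
        results.append(
            LmmTermResult(
                term=pretty.get(name, name),
                beta=beta,
                ci=(beta - z * se, beta + z * se),
                wald_chi2=float(chi2),
                df=1,
                p=float(stats.chi2.sf(chi2, 1)),
            )
        )
    return results, fit
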