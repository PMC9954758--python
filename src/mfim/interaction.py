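"""Moderation GLMs: outcome ~ predictor + OF + predictor x OF, with one-tailed inference.

The scientific prediction is directional: a NEGATIVE interaction coefficient,
i.e. the effect of a single cognitive predictor on reading is amplified when the
remaining factors (the OF index) are collectively low.  One-tailed p-values are
therefore lower-tail by default, with an explicit flag to flip the direction.

Variables enter the product term uncentered: predictors are z-scores and the OF
index is a weighted sum of z-scores, and simple-slopes output handles
interpretation at mean / +-1 SD of the focal predictor.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Literal

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .ofindex import OFSeries

__all__ = [
    "InteractionFit",
    "SimpleSlopes",
    "fit_interaction",
    "summarize_t_p",
    "count_significant",
    "simple_slopes",
]

Direction = Literal["negative", "positive"]

_TERMS = ("intercept", "x", "of", "x_of")


@dataclass(frozen=True)
class InteractionFit:
    """One fitted interaction model.

    ``coef`` and ``se`` are keyed by term: intercept, x (focal predictor),
    of (other-factors index), x_of (their product).  ``df = n - 4``.
    """

    predictor: str
    outcome: str
    n: int
    coef: dict[str, float]
    se: dict[str, float]
    df: int
    t_interaction: float
    p_one_tailed: float
    direction: Direction = "negative"
    x_mean: float = float("nan")
    x_sd: float = float("nan")

    @property
    def estimate(self) -> float:
        """The interaction coefficient b3."""
        return self.coef["x_of"]

    @property
    def se_interaction(self) -> float:
        return self.se["x_of"]


@dataclass(frozen=True)
class SimpleSlopes:
    """Regression lines of outcome on OF at fixed levels of the focal predictor.

    ``levels`` maps a label ("mean-1sd", "mean", "mean+1sd") to
    (level value, intercept, slope) where intercept = b0 + b1*L and
    slope = b2 + b3*L.
    """

    predictor: str
    outcome: str
    levels: dict[str, tuple[float, float, float]]


def summarize_t_p(
    estimate: float,
    se: float,
    df: int,
    direction: Direction = "negative",
) -> tuple[float, float]:
    """t = estimate/se and its one-tailed p under Student t with *df* df.

    ``direction="negative"`` gives the lower-tail probability (the predicted sign
    of the interaction is negative); ``"positive"`` gives the upper tail.
    """
    if se <= 0:
        raise ValueError(f"standard error must be positive, got {se}")
    if df < 1:
        raise ValueError(f"degrees of freedom must be >= 1, got {df}")
    t = estimate / se
    if direction == "negative":
        p = float(stats.t.cdf(t, df))
    else:
        p = float(stats.t.sf(t, df))
    return float(t), p


def fit_interaction(
    y: pd.Series,
    x: pd.Series,
    of: OFSeries | pd.Series,
    direction: Direction = "negative",
    predictor: str = "x",
    outcome: str = "y",
) -> InteractionFit:
    """OLS fit of ``y = b0 + b1 x + b2 of + b3 (x*of) + e`` with listwise deletion.

    Standard errors use the unbiased residual variance and the inverse
    cross-product matrix (plain OLS); the interaction t and its one-tailed p
    follow :func:`summarize_t_p`.
    """
    of_values = of.values if isinstance(of, OFSeries) else of
    frame = pd.concat(
        {"y": y, "x": x, "of": of_values}, axis=1, join="inner"
    ).dropna()
    n = len(frame)
    if n <= 4:
        raise ValueError(f"need at least 5 complete cases, got {n}")

    xv = frame["x"].to_numpy()
    ofv = frame["of"].to_numpy()
    design = np.column_stack([np.ones(n), xv, ofv, xv * ofv])
    if np.linalg.matrix_rank(design) < 4:
        raise ValueError(
            f"rank-deficient design for predictor {predictor!r} "
            "(focal predictor collinear with the OF index?)"
        )

    res = sm.OLS(frame["y"].to_numpy(), design).fit()
    coef = dict(zip(_TERMS, map(float, res.params)))
    se = dict(zip(_TERMS, map(float, res.bse)))
    df = int(res.df_resid)
    t, p = summarize_t_p(coef["x_of"], se["x_of"], df, direction)
    return InteractionFit(
        predictor=predictor,
        outcome=outcome,
        n=n,
        coef=coef,
        se=se,
        df=df,
        t_interaction=t,
        p_one_tailed=p,
        direction=direction,
        x_mean=float(np.mean(xv)),
        x_sd=float(np.std(xv, ddof=1)),
    )


def count_significant(
    fits: Iterable[InteractionFit | float],
    alpha: float,
) -> int:
    """Number of fits with one-tailed p < alpha; no multiple-comparison correction.

    The interaction is predicted in every test (not "in at least one"), so no
    familywise adjustment is applied.  Accepts fitted objects or bare p-values.
    """
    ps = [f.p_one_tailed if isinstance(f, InteractionFit) else float(f) for f in fits]
    if not ps:
        raise ValueError("no fits supplied")
    return int(sum(p < alpha for p in ps))


def simple_slopes(fit: InteractionFit, x_mean: float | None = None,
                  x_sd: float | None = None) -> SimpleSlopes:
    """Lines of outcome on OF at the focal predictor's mean and mean +- 1 SD.

    Defaults to the mean/SD of the complete cases used in the fit.
    """
    mean = fit.x_mean if x_mean is None else x_mean
    sd = fit.x_sd if x_sd is None else x_sd
    if not np.isfinite(mean) or not np.isfinite(sd):
        raise ValueError("x mean/sd unavailable; pass them explicitly")
    if sd <= 0:
        raise ValueError(f"x_sd must be positive, got {sd}")
    b0, b1, b2, b3 = (fit.coef[k] for k in _TERMS)
    levels = {}
    for label, level in (("mean-1sd", mean - sd), ("mean", mean), ("mean+1sd", mean + sd)):
        levels[label] = (level, b0 + b1 * level, b2 + b3 * level)
    return SimpleSlopes(predictor=fit.predictor, outcome=fit.outcome, levels=levels)
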