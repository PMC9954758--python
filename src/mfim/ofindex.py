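"""Correlation-weighted "other factors" (OF) index construction.

Each candidate predictor is weighted by its Pearson correlation with a reading
outcome, estimated on the largest available (weighting) sample with pairwise
deletion.  The OF index for a singled-out predictor is the weighted sum of the
z-scores of every *other* predictor, computed on the (typically smaller)
analysis sample.  With no predictor singled out, the same weighted sum over all
predictors is the full multifactor (MFi) index, exposed for descriptive use.

Weights are plain correlations — not renormalized, shrunk, or regression-based.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import pandas as pd

from .cohort import CohortTable, _pairwise_pearson

__all__ = ["WeightVector", "OFSeries", "compute_weights", "compute_of"]


@dataclass(frozen=True)
class WeightVector:
    """Per-predictor correlation weights against one reading outcome."""

    outcome: str
    weights: dict[str, float]
    n_pairwise: dict[str, int] | None = None

    def to_csv(self, path: str | Path) -> None:
        """Export as a two-column (predictor, weight) comma-separated file."""
        pd.Series(self.weights, name="weight").rename_axis("predictor").to_csv(path)


@dataclass(frozen=True)
class OFSeries:
    """Weighted-sum index over the predictors other than ``singled_out``.

    ``singled_out`` is ``None`` for the full MFi index (no exclusion).
    Values are missing wherever any contributing predictor is missing.
    """

    singled_out: str | None
    outcome: str
    values: pd.Series

    @property
    def contributors(self) -> list[str]:
        return list(self.values.attrs.get("contributors", []))


def compute_weights(
    weighting_table: CohortTable,
    predictors: list[str],
    outcome: str,
) -> WeightVector:
    """Pearson correlation of each predictor with *outcome*, pairwise-complete.

    The weighting table is intentionally a separate argument from the analysis
    table: weights come from the largest sample on which each predictor/outcome
    pair is jointly observed, while model fitting later happens on complete cases.
    """
    if outcome not in weighting_table.data.columns:
        raise KeyError(f"unknown outcome column {outcome!r}")
    weights: dict[str, float] = {}
    ns: dict[str, int] = {}
    for pred in predictors:
        if pred not in weighting_table.data.columns:
            raise KeyError(f"unknown predictor column {pred!r}")
        col = weighting_table.data[pred].dropna()
        if len(col) and col.nunique() == 1:
            raise ValueError(f"predictor {pred!r} is constant (zero variance)")
        r, n = _pairwise_pearson(weighting_table.data[pred], weighting_table.data[outcome])
        if pd.isna(r):
            raise ValueError(
                f"cannot weight predictor {pred!r}: fewer than 3 pairwise-complete "
                f"observations with {outcome!r} (n={n}) or zero variance"
            )
        weights[pred] = r
        ns[pred] = n
    return WeightVector(outcome=outcome, weights=weights, n_pairwise=ns)


def compute_of(
    analysis_table: CohortTable,
    weights: WeightVector,
    singled_out: str | None,
) -> OFSeries:
    """Per-child OF index: sum of weight x z-score over the non-singled-out predictors.

    Missing wherever any contributor is missing (NaN propagates through the sum).
    """
    if singled_out is not None and singled_out not in weights.weights:
        raise KeyError(f"singled-out predictor {singled_out!r} has no weight")
    contributors = [p for p in weights.weights if p != singled_out]
    if not contributors:
        raise ValueError("no contributing predictors remain after exclusion")
    for p in contributors:
        if p not in analysis_table.data.columns:
            raise KeyError(f"contributor {p!r} missing from analysis table")
    values = sum(
        weights.weights[p] * analysis_table.data[p] for p in contributors
    )
    name = "mfi_index" if singled_out is None else f"of_excl_{singled_out}"
    values = values.rename(name)
    values.attrs["contributors"] = contributors
    return OFSeries(singled_out=singled_out, outcome=weights.outcome, values=values)
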