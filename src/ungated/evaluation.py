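"""Replicate evaluation: rmse, the rmse < mean/3 success rule, and the
continuous-vs-gated binomial sign test.

A health measure counts as *successfully predicted* when the replicate-mean
validation rmse is strictly less than one third of the measure's cohort
mean — an rmse near or above the mean is what a no-information predictor
produces.  Across measures, the two model arms are compared by an exact
one-sided binomial sign test on the number of measures for which one arm's
rmse is lower, under a null success probability of 1/2.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .models import TrainedReplicate


def rmse(observed: np.ndarray, predicted: np.ndarray) -> float:
    """Root mean squared error, sqrt(mean((observed - predicted)^2))."""
    observed = np.asarray(observed, dtype=float).ravel()
    predicted = np.asarray(predicted, dtype=float).ravel()
    if observed.size == 0:
        raise ValueError("rmse of empty vectors is undefined")
    if observed.shape != predicted.shape:
        raise ValueError("observed and predicted must have equal length")
    return float(np.sqrt(np.mean((observed - predicted) ** 2)))


def apply_success_rule(rmse_value: float, outcome_mean: float) -> bool:
    """True iff rmse is strictly below one third of the outcome mean."""
    if not outcome_mean > 0:
        raise ValueError(
            f"success rule undefined for non-positive outcome mean {outcome_mean}"
        )
    return rmse_value < outcome_mean / 3.0


@dataclass(frozen=True)
class EvaluationSummary:
    """Replicate-aggregated rmse for one (outcome, model) pair."""

    outcome: str
    model_kind: str
    rmse_mean: float
    rmse_std: float       # sample (n-1) standard deviation over replicates
    outcome_mean: float
    n_replicates: int

    @property
    def success(self) -> bool:
        return apply_success_rule(self.rmse_mean, self.outcome_mean)


def summarize_replicates(replicate_rmses: dict[tuple[str, str], list[float]],
                         outcome_means: dict[str, float]) -> list[EvaluationSummary]:
    """Aggregate per-(outcome, model) replicate rmses into summaries.

    ``replicate_rmses`` maps (outcome, model_kind) to the list of validation
    rmses of its replicates.  A single-replicate entry reports std 0 with a
    warning (spread is undefined there, not zero).
    """
    out = []
    for (outcome, kind), values in replicate_rmses.items():
        values = [float(v) for v in values]
        if len(values) == 0:
            raise ValueError(f"no replicates for ({outcome}, {kind})")
        if len(values) == 1:
            warnings.warn(f"single replicate for ({outcome}, {kind}); "
                          "rmse_std reported as 0", stacklevel=2)
            std = 0.0
        else:
            std = float(np.std(values, ddof=1))
        out.append(EvaluationSummary(
            outcome=outcome, model_kind=kind,
            rmse_mean=float(np.mean(values)), rmse_std=std,
            outcome_mean=float(outcome_means[outcome]),
            n_replicates=len(values),
        ))
    return out


def summaries_to_frame(summaries: list[EvaluationSummary]) -> pd.DataFrame:
    """Wide table mirroring the published layout: one row per outcome,
    continuous and gated rmse mean/std side by side, outcome mean, flags."""
    by_outcome: dict[str, dict] = {}
    for s in summaries:
        row = by_outcome.setdefault(s.outcome, {"outcome": s.outcome,
                                                "mean": s.outcome_mean})
        row[f"{s.model_kind}_rmse"] = s.rmse_mean
        row[f"{s.model_kind}_rmse_std"] = s.rmse_std
        row[f"{s.model_kind}_success"] = s.success
    return pd.DataFrame(list(by_outcome.values())).set_index("outcome")


@dataclass(frozen=True)
class SignTestResult:
    n_outcomes: int
    k_lower: int          # outcomes where the first arm's rmse is lower
    p_value: float        # one-sided exact binomial tail at p = 1/2
    ties_dropped: int = 0


def binomial_tail(k: int, n: int) -> float:
    """P(K >= k) for K ~ Binomial(n, 1/2), by exact pmf summation."""
    if not 0 <= k <= n:
        raise ValueError("need 0 <= k <= n")
    return sum(math.comb(n, j) for j in range(k, n + 1)) / 2.0 ** n


def sign_test(first_rmse: dict[str, float] | pd.Series,
              second_rmse: dict[str, float] | pd.Series) -> SignTestResult:
    """Exact one-sided sign test: is the first arm's rmse lower more often
    than chance?  Ties are dropped with a warning and n reduced."""
    a = pd.Series(first_rmse, dtype=float)
    b = pd.Series(second_rmse, dtype=float)
    if set(a.index) != set(b.index):
        raise ValueError("the two arms must cover the same outcome set")
    b = b.reindex(a.index)
    diffs = a - b
    ties = int((diffs == 0).sum())
    if ties:
        warnings.warn(f"{ties} tied outcome(s) dropped from the sign test",
                      stacklevel=2)
        diffs = diffs[diffs != 0]
    n = int(diffs.size)
    if n == 0:
        raise ValueError("no untied outcomes left for the sign test")
    k = int((diffs < 0).sum())
    return SignTestResult(n_outcomes=n, k_lower=k,
                          p_value=binomial_tail(k, n), ties_dropped=ties)


def export_error_distributions(
        replicates: dict[tuple[str, str], list[TrainedReplicate]],
        validation_ids: list[str] | None = None) -> pd.DataFrame:
    """Long-format per-individual prediction errors for external plotting.

    One row per (outcome, model, replicate, validation individual) with the
    signed error ``observed - predicted``; per-model medians and violin/
    scatter summaries are computable downstream.
    """
    records = []
    for (outcome, kind), reps in replicates.items():
        for r_idx, rep in enumerate(reps):
            if rep.predictions_val is None or rep.observed_val is None:
                raise ValueError(
                    f"replicate {r_idx} of ({outcome}, {kind}) lacks validation predictions"
                )
            errors = rep.observed_val - rep.predictions_val
            ids = (validation_ids if validation_ids is not None
                   else [str(i) for i in range(errors.size)])
            for iid, err in zip(ids, errors):
                records.append((outcome, kind, r_idx, iid, float(err)))
    return pd.DataFrame.from_records(
        records, columns=["outcome", "model", "replicate", "individual_id", "error"]
    )
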