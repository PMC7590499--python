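"""Population-level validation: CSMF vectors and their accuracy.

Cause-specific mortality fractions (CSMFs) are the shares of deaths
attributed to each cause.  The gold standard contributes one certain
cause per death; the coder contributes *partial likelihoods*: each
reported cause is credited with its likelihood, and per-death residual
mass accrues to the non-conclusive category.

CSMF accuracy compares an estimated composition with the true one,

    CSMFA = 1 - sum_j |est_j - true_j| / (2 * (1 - min_j true_j)),

which is 1 iff the compositions coincide and 0 at the worst possible
misallocation given the truth.  The chance-corrected version rescales it
so that allocating deaths uniformly at random scores 0 on average.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .data_model import (
    NON_CONCLUSIVE,
    CauseDictionary,
    DataValidationError,
)

#: Large-K analytic limit of the random-allocation baseline.
ANALYTIC_BASELINE = 1.0 - 1.0 / np.e


class DegenerateCompositionError(ValueError):
    """The true composition is concentrated on a single cause.

    The CSMF-accuracy denominator is zero for such a truth; exclude the
    draw and resample instead of scoring it.
    """


@dataclass(frozen=True)
class AccuracyResult:
    """CSMF accuracy together with its chance-corrected version."""

    csmfa: float
    cccsmfa: float
    baseline: float


def cda_csmf(records: Sequence, dictionary: CauseDictionary) -> pd.Series:
    """Gold-standard CSMF vector: fraction of deaths per cause (NC included)."""
    if not records:
        raise DataValidationError("empty cohort")
    groups = {r.group for r in records}
    if len(groups) != 1:
        raise DataValidationError("CSMFs are computed within a single study group")
    causes = dictionary.for_group(next(iter(groups)))
    counts = pd.Series(0.0, index=list(causes))
    for r in records:
        counts[r.cda_cause] += 1.0
    return counts / len(records)


def model_csmf(
    outputs: Sequence,
    causes: Sequence,
    max_causes_used: int = 2,
) -> pd.Series:
    """Partial-likelihood CSMF vector from coder outputs.

    Each death's first ``max_causes_used`` reported causes are credited
    with their likelihoods; the remaining per-death mass (including the
    coder's own residual) accrues to non-conclusive.  The vector sums
    to 1 by construction.
    """
    if not outputs:
        raise DataValidationError("empty cohort")
    if NON_CONCLUSIVE not in causes:
        raise DataValidationError(f"cause list must include {NON_CONCLUSIVE!r}")
    acc = pd.Series(0.0, index=list(causes))
    for out in outputs:
        used = 0.0
        for cause, lik in out.assigned[:max_causes_used]:
            if cause not in acc.index:
                raise DataValidationError(f"cause {cause!r} not in cause list")
            acc[cause] += lik
            used += lik
        acc[NON_CONCLUSIVE] += 1.0 - used
    return acc / len(outputs)


def csmf_accuracy(true_csmf: pd.Series, est_csmf: pd.Series) -> float:
    """CSMF accuracy of an estimated composition against the truth.

    Both vectors must share the same cause support.  The result lies in
    [0, 1]; tiny negative values from floating-point cancellation are
    clamped to 0.
    """
    if list(true_csmf.index) != list(est_csmf.index):
        raise DataValidationError("true and estimated CSMF must share cause support")
    t = true_csmf.to_numpy(dtype=float)
    e = est_csmf.to_numpy(dtype=float)
    denom = 2.0 * (1.0 - t.min())
    if denom <= 0.0:
        raise DegenerateCompositionError(
            "true composition is degenerate at a single cause; exclude this draw"
        )
    return float(np.clip(1.0 - np.abs(e - t).sum() / denom, 0.0, 1.0))


def chance_corrected_csmfa(csmfa: float, baseline: float) -> float:
    """Rescale a CSMF accuracy so the random-allocation baseline scores 0.

    (csmfa - baseline) / (1 - baseline); negative values mean worse than
    random allocation.
    """
    if not (0.0 < baseline < 1.0):
        raise DataValidationError("baseline must lie strictly between 0 and 1")
    return (csmfa - baseline) / (1.0 - baseline)


def random_allocation_baseline(
    n_causes: int,
    n: int,
    n_draws: int = 500,
    *,
    seed=None,
    rng: np.random.Generator | None = None,
    alpha: float = 1.0,
) -> float:
    """Median CSMF accuracy of uniform random allocation.

    For each draw the true composition is a symmetric Dirichlet(alpha)
    sample over ``n_causes`` causes and the estimate allocates each of
    ``n`` deaths to a cause uniformly at random.  The median accuracy
    over draws is the empirical chance baseline used by the corrected
    metric.  Strictly between 0 and 1.
    """
    if n_causes < 2:
        raise DataValidationError("need at least 2 causes")
    if n < 1 or n_draws < 1:
        raise DataValidationError("n and n_draws must be >= 1")
    if rng is None:
        rng = np.random.default_rng(seed)
    true = rng.dirichlet(np.full(n_causes, alpha), size=n_draws)
    est = rng.multinomial(n, np.full(n_causes, 1.0 / n_causes), size=n_draws) / n
    denom = 2.0 * (1.0 - true.min(axis=1))
    acc = np.clip(1.0 - np.abs(est - true).sum(axis=1) / denom, 0.0, 1.0)
    return float(np.median(acc))


def accuracy_result(
    true_csmf: pd.Series,
    est_csmf: pd.Series,
    baseline: float,
) -> AccuracyResult:
    """Bundle CSMFA and its chance-corrected value against a baseline."""
    a = csmf_accuracy(true_csmf, est_csmf)
    return AccuracyResult(
        csmfa=a, cccsmfa=chance_corrected_csmfa(a, baseline), baseline=baseline
    )
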