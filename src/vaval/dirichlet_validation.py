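"""Resampling harness: metric stability across Dirichlet cause compositions.

A single observed cohort fixes one cause composition; to characterise the
coder across many, the harness draws symmetric-Dirichlet cause
compositions, resamples the cohort (with replacement, stratified by
gold-standard cause) to match each composition, recomputes the
chance-corrected concordance and CSMF accuracy on every resampled cohort,
and summarises them by the median.  Kappa and the per-cause confusion
table are computed once on the observed data, whose integer counts are
raw-data quantities.

Records and coder outputs are resampled jointly: the coder is
deterministic per death, so its output travels with the record.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .data_model import (
    NON_CONCLUSIVE,
    CauseDictionary,
    DataValidationError,
    DeathRecord,
)
from .individual_metrics import (
    ccc_per_cause,
    cohen_kappa,
    confusion_matrix,
    metrics_table,
    top_cause,
)
from .population_metrics import (
    ANALYTIC_BASELINE,
    chance_corrected_csmfa,
    random_allocation_baseline,
)

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class ValidationConfig:
    """Settings for the Dirichlet resampling validation.

    ``alpha=1`` is the uninformative (uniform) symmetric Dirichlet.
    ``max_causes_used`` caps how many reported causes enter the
    partial-likelihood CSMF.  ``baseline_mode`` selects the empirical
    random-allocation baseline (default) or the analytic large-K constant
    1 - 1/e.
    """

    n_draws: int = 500
    alpha: float = 1.0
    seed: int = 0
    max_causes_used: int = 2
    baseline_mode: str = "empirical"

    def __post_init__(self):
        if self.n_draws < 1:
            raise DataValidationError("n_draws must be >= 1")
        if self.alpha <= 0:
            raise DataValidationError("alpha must be > 0")
        if self.baseline_mode not in ("empirical", "analytic"):
            raise DataValidationError("baseline_mode must be 'empirical' or 'analytic'")


@dataclass(frozen=True)
class GroupValidationSummary:
    """Validation results for one study group."""

    group: str
    n: int
    kappa: float
    median_ccc: float
    median_csmfa: float
    median_cccsmfa: float
    baseline: float
    per_cause: pd.DataFrame
    draws: pd.DataFrame


def draw_compositions(n_causes: int, config: ValidationConfig) -> np.ndarray:
    """``n_draws`` symmetric-Dirichlet compositions over ``n_causes`` causes."""
    if n_causes < 2:
        raise DataValidationError("need at least 2 causes")
    rng = np.random.default_rng(config.seed)
    return rng.dirichlet(np.full(n_causes, config.alpha), size=config.n_draws)


def resample_to_composition(
    records: Sequence,
    composition: Sequence,
    seed=None,
    *,
    causes: Sequence | None = None,
    rng: np.random.Generator | None = None,
) -> list:
    """Resample a cohort (with replacement) to a target cause composition.

    Cause counts come from a multinomial over ``composition``; within each
    cause, records are drawn with replacement from the observed records of
    that gold cause.  A positive-weight cause with no observed records
    triggers renormalisation over the observed causes with a warning.
    The resampled cohort has the same size as the input.
    """
    if rng is None:
        rng = np.random.default_rng(seed)
    if causes is None:
        causes = _observed_causes(records)
    composition = np.asarray(composition, dtype=float)
    if composition.shape != (len(causes),):
        raise DataValidationError("composition length must match cause list")
    pools = {c: [i for i, r in enumerate(records) if r.cda_cause == c] for c in causes}
    empty = [c for c, w in zip(causes, composition) if w > 0 and not pools[c]]
    if empty:
        logger.warning(
            "renormalising composition: no observed records for %s", empty
        )
        keep = np.array([bool(pools[c]) for c in causes])
        composition = np.where(keep, composition, 0.0)
        composition = composition / composition.sum()
    idx = _resample_indices(
        [pools[c] for c in causes], composition, len(records), rng
    )
    return [records[i] for i in idx]


def _observed_causes(records: Sequence) -> tuple:
    seen = []
    for r in records:
        if r.cda_cause not in seen:
            seen.append(r.cda_cause)
    return tuple(seen)


def _resample_indices(
    pools: Sequence, composition: np.ndarray, n: int, rng: np.random.Generator
) -> np.ndarray:
    counts = rng.multinomial(n, composition)
    chosen = []
    for pool, k in zip(pools, counts):
        if k == 0:
            continue
        chosen.append(rng.choice(np.asarray(pool), size=k, replace=True))
    return np.concatenate(chosen) if chosen else np.empty(0, dtype=int)


def validate_group(
    records: Sequence,
    outputs: Sequence,
    dictionary: CauseDictionary,
    config: ValidationConfig,
) -> GroupValidationSummary:
    """Full validation of one study group across Dirichlet draws.

    Per draw, a composition over the observed gold causes is sampled, the
    (record, output) pairs are resampled to it, and CCC / CSMFA /
    chance-corrected CSMFA are recomputed.  CSMFA compares the
    partial-likelihood estimate with the realised gold composition of the
    resampled cohort; its denominator uses the drawn (continuous)
    composition, which is never degenerate.  Kappa and the per-cause
    table come from the observed cohort.
    """
    if len(records) != len(outputs):
        raise DataValidationError("records and outputs must have equal length")
    if not records:
        raise DataValidationError("empty cohort")
    group = records[0].group
    causes = dictionary.for_group(group)
    substantive = dictionary.substantive(group)
    n_causes = dictionary.n_substantive(group)
    if n_causes < 2:
        raise DataValidationError("need at least 2 substantive causes")
    n = len(records)

    cause_index = {c: i for i, c in enumerate(causes)}
    gold_idx = np.array([cause_index[r.cda_cause] for r in records])
    pred_idx = np.array([cause_index[top_cause(o)] for o in outputs])
    substantive_idx = np.array([cause_index[c] for c in substantive])

    # Per-record partial-likelihood contribution vectors (residual -> NC).
    contrib = np.zeros((n, len(causes)))
    for i, out in enumerate(outputs):
        used = 0.0
        for cause, lik in out.assigned[: config.max_causes_used]:
            contrib[i, cause_index[cause]] += lik
            used += lik
        contrib[i, cause_index[NON_CONCLUSIVE]] += 1.0 - used

    observed = [c for c in causes if any(r.cda_cause == c for r in records)]
    observed_idx = [cause_index[c] for c in observed]
    pools = [np.flatnonzero(gold_idx == j) for j in observed_idx]

    comps = draw_compositions(len(observed), config) if len(observed) >= 2 else None
    if comps is None:
        raise DataValidationError("fewer than 2 observed gold causes; cannot resample")

    if config.baseline_mode == "analytic":
        baseline = ANALYTIC_BASELINE
    else:
        baseline = random_allocation_baseline(
            len(observed), n, config.n_draws,
            rng=np.random.default_rng(np.random.SeedSequence(config.seed).spawn(1)[0]),
            alpha=config.alpha,
        )

    draw_seeds = np.random.SeedSequence(config.seed).spawn(config.n_draws + 1)[1:]
    rows = []
    for d in range(config.n_draws):
        rng = np.random.default_rng(draw_seeds[d])
        idx = _resample_indices(pools, comps[d], n, rng)
        g, p = gold_idx[idx], pred_idx[idx]

        ccc_vals = []
        for j in substantive_idx:
            n_j = int((g == j).sum())
            if n_j == 0:
                continue
            tp = int(((g == j) & (p == j)).sum())
            ccc_vals.append(ccc_per_cause(tp / n_j, n_causes))
        ccc = float(np.mean(ccc_vals)) if ccc_vals else float("nan")

        est = contrib[idx].mean(axis=0)
        realized = np.bincount(g, minlength=len(causes)) / n
        denom = 2.0 * (1.0 - comps[d].min())
        csmfa = float(np.clip(1.0 - np.abs(est - realized).sum() / denom, 0.0, 1.0))
        rows.append(
            {
                "draw": d,
                "ccc": ccc,
                "csmfa": csmfa,
                "cccsmfa": chance_corrected_csmfa(csmfa, baseline),
                "composition": ";".join(f"{w:.6f}" for w in comps[d]),
            }
        )
    draws = pd.DataFrame(rows)

    per_cause = metrics_table(
        [r.cda_cause for r in records], [top_cause(o) for o in outputs], causes
    )
    kappa = cohen_kappa(confusion_matrix(records, outputs, dictionary))

    return GroupValidationSummary(
        group=group.value,
        n=n,
        kappa=float(kappa),
        median_ccc=float(draws["ccc"].median()),
        median_csmfa=float(draws["csmfa"].median()),
        median_cccsmfa=float(draws["cccsmfa"].median()),
        baseline=float(baseline),
        per_cause=per_cause,
        draws=draws,
    )
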