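"""Individual-level agreement between coder and gold-standard causes.

Comparison is between the gold-standard cause and the coder's *top* cause;
an empty coder report counts as non-conclusive.  From the resulting
cross-tabulation the module derives per-cause confusion counts,
sensitivity / specificity / predictive values, Cohen's kappa and the
chance-corrected concordance (CCC), plus a first/second-cause agreement
summary.

Percentages are carried at full double precision; the integer display
values use round-half-to-even.
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
    DeathRecord,
    VAOutput,
)


def top_cause(output: VAOutput) -> str:
    """The coder's most probable cause; non-conclusive if nothing was reported."""
    return output.assigned[0][0] if output.assigned else NON_CONCLUSIVE


def round_half_even(x: float) -> int:
    """Round to the nearest integer, ties to the even neighbour."""
    return int(round(x))


@dataclass(frozen=True)
class ConfusionCounts:
    """Per-cause one-vs-rest confusion counts; TP+TN+FP+FN equals cohort size."""

    cause: str
    tp: int
    tn: int
    fp: int
    fn: int

    @property
    def n(self) -> int:
        """Number of gold-standard deaths from this cause."""
        return self.tp + self.fn

    @property
    def total(self) -> int:
        return self.tp + self.tn + self.fp + self.fn


@dataclass(frozen=True)
class BinaryMetrics:
    """Sensitivity/specificity/PPV/NPV as percentages (None where undefined)."""

    sensitivity: float | None
    specificity: float | None
    ppv: float | None
    npv: float | None

    def display(self) -> dict:
        """Integer display values (round-half-to-even), 'N/A' where undefined."""
        return {
            name: ("N/A" if v is None else round_half_even(v))
            for name, v in (
                ("sensitivity", self.sensitivity),
                ("specificity", self.specificity),
                ("ppv", self.ppv),
                ("npv", self.npv),
            )
        }


@dataclass(frozen=True)
class AgreementSummary:
    """How often the coder's first or second cause matched the gold standard."""

    n_first_match: int
    n_second_match: int
    mean_second_likelihood: float  # nan when there are no second-cause matches


def confusion_matrix(
    records: Sequence,
    outputs: Sequence,
    dictionary: CauseDictionary,
) -> pd.DataFrame:
    """K x K cross-tabulation: rows gold cause, columns predicted top cause.

    The cause axis is the group-scoped dictionary order with
    non-conclusive included as a first-class category.
    """
    if len(records) != len(outputs):
        raise DataValidationError("records and outputs must have equal length")
    group = _single_group(records)
    causes = dictionary.for_group(group)
    index = {c: i for i, c in enumerate(causes)}
    mat = np.zeros((len(causes), len(causes)), dtype=int)
    for rec, out in zip(records, outputs):
        pred = top_cause(out)
        if pred not in index:
            raise DataValidationError(
                f"record {rec.id!r}: predicted cause {pred!r} not reportable "
                f"in group {group.value!r}"
            )
        mat[index[rec.cda_cause], index[pred]] += 1
    return pd.DataFrame(mat, index=list(causes), columns=list(causes))


def confusion_from_labels(
    gold: Sequence, predicted: Sequence, causes: Sequence
) -> pd.DataFrame:
    """Cross-tabulation over an explicit cause list (generic label version)."""
    if len(gold) != len(predicted):
        raise DataValidationError("gold and predicted must have equal length")
    index = {c: i for i, c in enumerate(causes)}
    mat = np.zeros((len(causes), len(causes)), dtype=int)
    for g, p in zip(gold, predicted):
        mat[index[g], index[p]] += 1
    return pd.DataFrame(mat, index=list(causes), columns=list(causes))


def confusion_by_cause(
    records: Sequence,
    outputs: Sequence,
    dictionary: CauseDictionary,
) -> list:
    """One-vs-rest confusion counts for every cause in the group dictionary."""
    matrix = confusion_matrix(records, outputs, dictionary)
    return counts_from_matrix(matrix)


def counts_from_matrix(matrix: pd.DataFrame) -> list:
    """Split a K x K cross-tabulation into per-cause one-vs-rest counts."""
    total = int(matrix.to_numpy().sum())
    out = []
    for cause in matrix.index:
        tp = int(matrix.loc[cause, cause])
        fn = int(matrix.loc[cause].sum()) - tp
        fp = int(matrix[cause].sum()) - tp
        out.append(
            ConfusionCounts(cause=cause, tp=tp, tn=total - tp - fn - fp, fp=fp, fn=fn)
        )
    return out


def binary_metrics(counts: ConfusionCounts) -> BinaryMetrics:
    """Sensitivity, specificity, PPV and NPV from one-vs-rest counts.

    Each is 100 * a ratio of counts; a zero denominator yields None
    (reported as 'N/A').
    """

    def ratio(num: int, den: int) -> float | None:
        return None if den == 0 else 100.0 * num / den

    return BinaryMetrics(
        sensitivity=ratio(counts.tp, counts.tp + counts.fn),
        specificity=ratio(counts.tn, counts.tn + counts.fp),
        ppv=ratio(counts.tp, counts.tp + counts.fp),
        npv=ratio(counts.tn, counts.tn + counts.fn),
    )


def cohen_kappa(matrix: pd.DataFrame | np.ndarray) -> float:
    """Cohen's kappa of a square cross-tabulation.

    kappa = (p_o - p_e) / (1 - p_e) with p_o the diagonal fraction and
    p_e the expected agreement under independent margins.  Returns nan
    when p_e == 1 (both axes degenerate on a single category).
    """
    m = np.asarray(matrix, dtype=float)
    if m.ndim != 2 or m.shape[0] != m.shape[1]:
        raise DataValidationError("confusion matrix must be square")
    total = m.sum()
    if total <= 0:
        raise DataValidationError("confusion matrix must have positive total")
    p_o = np.trace(m) / total
    p_e = float((m.sum(axis=1) * m.sum(axis=0)).sum()) / total**2
    if p_e >= 1.0 - 1e-15:
        return float("nan")
    return (p_o - p_e) / (1.0 - p_e)


def ccc_per_cause(sensitivity: float, n_causes: int) -> float:
    """Chance-corrected concordance for one cause.

    Rescales a sensitivity (fraction in [0, 1]) so that random guessing
    among ``n_causes`` causes scores 0 and perfect detection scores 1:
    (sens - 1/K) / (1 - 1/K).  May be negative.
    """
    if n_causes < 2:
        raise DataValidationError("chance correction requires at least 2 causes")
    chance = 1.0 / n_causes
    return (sensitivity - chance) / (1.0 - chance)


def overall_ccc(
    records: Sequence,
    outputs: Sequence,
    dictionary: CauseDictionary,
) -> float:
    """Unweighted mean CCC over substantive causes with observed deaths.

    K is the number of substantive causes in the group's dictionary; causes
    with no gold-standard death are not averaged (their sensitivity is
    undefined).
    """
    group = _single_group(records)
    gold = [r.cda_cause for r in records]
    pred = [top_cause(o) for o in outputs]
    return ccc_from_labels(
        gold, pred,
        substantive=dictionary.substantive(group),
        n_causes=dictionary.n_substantive(group),
    )


def ccc_from_labels(
    gold: Sequence,
    predicted: Sequence,
    substantive: Sequence,
    n_causes: int,
) -> float:
    """Overall CCC from parallel gold/predicted label sequences."""
    vals = []
    for cause in substantive:
        n_j = sum(1 for g in gold if g == cause)
        if n_j == 0:
            continue
        tp = sum(1 for g, p in zip(gold, predicted) if g == cause and p == cause)
        vals.append(ccc_per_cause(tp / n_j, n_causes))
    if not vals:
        raise DataValidationError("no substantive cause has an observed death")
    return float(np.mean(vals))


def agreement_summary(records: Sequence, outputs: Sequence) -> AgreementSummary:
    """Count first-cause matches, then second-cause matches among the rest.

    A death contributes to at most one counter: a first-cause match is
    never also counted as a second-cause match.
    """
    if len(records) != len(outputs):
        raise DataValidationError("records and outputs must have equal length")
    n_first = 0
    second_liks = []
    for rec, out in zip(records, outputs):
        if out.assigned and out.assigned[0][0] == rec.cda_cause:
            n_first += 1
        elif len(out.assigned) >= 2 and out.assigned[1][0] == rec.cda_cause:
            second_liks.append(out.assigned[1][1])
    return AgreementSummary(
        n_first_match=n_first,
        n_second_match=len(second_liks),
        mean_second_likelihood=float(np.mean(second_liks)) if second_liks else float("nan"),
    )


def metrics_table(
    gold: Sequence,
    predicted: Sequence,
    causes: Sequence,
    report_causes: Sequence | None = None,
) -> pd.DataFrame:
    """Per-cause confusion counts and derived percentages, one row per cause.

    ``causes`` is the full category list used for cross-tabulation;
    ``report_causes`` optionally restricts which rows appear in the table
    (e.g. only infection sub-categories, not the terminal categories).
    Display percentages use round-half-to-even; undefined entries are 'N/A'.
    """
    matrix = confusion_from_labels(gold, predicted, causes)
    rows = []
    for counts in counts_from_matrix(matrix):
        if report_causes is not None and counts.cause not in report_causes:
            continue
        disp = binary_metrics(counts).display()
        rows.append(
            {
                "cause": counts.cause,
                "n": counts.n,
                "TP": counts.tp,
                "TN": counts.tn,
                "FP": counts.fp,
                "FN": counts.fn,
                **disp,
            }
        )
    return pd.DataFrame(rows)


def _single_group(records: Sequence):
    if not records:
        raise DataValidationError("empty cohort")
    groups = {r.group for r in records}
    if len(groups) != 1:
        raise DataValidationError(
            f"records span multiple study groups: {sorted(g.value for g in groups)}"
        )
    return next(iter(groups))
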