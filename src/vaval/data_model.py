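"""Domain types and tabular I/O for verbal-autopsy validation datasets.

The central objects are the cause dictionary (a closed, group-scoped list of
broad cause-of-death categories with a reserved terminal ``non_conclusive``
category), individual death records carrying a gold-standard cause and a
vector of three-valued symptom indicators, and the probabilistic coder's
per-death output (up to three causes with likelihoods plus a residual
non-conclusive mass).

Files are plain CSV.  Indicator responses are coded ``Y`` / ``N`` / ``.``
(yes / no / not recorded); internally they are an ``int8`` vector with
values ``1`` / ``0`` / ``-1``.  The distinction between "no" and "not
recorded" matters because the coder only uses affirmative responses.
"""

from __future__ import annotations

import enum
import logging
from collections import Counter
from dataclasses import dataclass, field, replace
from importlib import resources
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: Reserved cause code for the residual / undetermined category.
NON_CONCLUSIVE = "non_conclusive"

#: Indicator response codes (internal int8 values).
YES, NO, MISSING = 1, 0, -1

_INDICATOR_SYMBOLS = {"Y": YES, "N": NO, ".": MISSING}
_INDICATOR_CHARS = {YES: "Y", NO: "N", MISSING: "."}


class DataValidationError(ValueError):
    """A dataset or record violates a structural invariant."""


class UnmappedCodeError(KeyError):
    """An ICD-10 code has no matching prefix in the mapping table."""


class StudyGroup(str, enum.Enum):
    """The five age/condition strata in which deaths are analysed."""

    STILLBIRTH = "stillbirth"
    NEONATE = "neonate"
    CHILD = "child"
    MATERNAL = "maternal"
    OTHER_ADULT = "other_adult"

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.value


ALL_GROUPS: tuple[StudyGroup, ...] = tuple(StudyGroup)


@dataclass(frozen=True)
class Cause:
    """One cause-of-death category with the groups in which it is reportable."""

    code: str
    label: str
    groups: frozenset


@dataclass(frozen=True)
class CauseDictionary:
    """Ordered, group-scoped cause list with ``non_conclusive`` last.

    ``for_group`` returns the causes reportable in one study group (the
    non-conclusive category always comes last); ``n_substantive`` is the
    per-group K used by chance-corrected concordance.
    """

    causes: tuple

    def __post_init__(self):
        codes = [c.code for c in self.causes]
        if len(set(codes)) != len(codes):
            raise DataValidationError("cause codes must be unique")
        if codes.count(NON_CONCLUSIVE) != 1 or codes[-1] != NON_CONCLUSIVE:
            raise DataValidationError(
                f"dictionary must contain {NON_CONCLUSIVE!r} exactly once, as the last entry"
            )
        for g in self.groups():
            if len(self.for_group(g)) < 2:
                raise DataValidationError(f"group {g.value!r} has fewer than 2 causes")

    def codes(self) -> tuple:
        return tuple(c.code for c in self.causes)

    def groups(self) -> tuple:
        seen = set()
        for c in self.causes:
            seen |= c.groups
        return tuple(g for g in ALL_GROUPS if g in seen)

    def __contains__(self, code: str) -> bool:
        return any(c.code == code for c in self.causes)

    def cause(self, code: str) -> Cause:
        for c in self.causes:
            if c.code == code:
                return c
        raise KeyError(code)

    def for_group(self, group: StudyGroup) -> tuple:
        """Cause codes reportable in ``group``, dictionary order, NC last."""
        return tuple(c.code for c in self.causes if group in c.groups)

    def substantive(self, group: StudyGroup | None = None) -> tuple:
        """Cause codes excluding ``non_conclusive`` (optionally group-scoped)."""
        if group is None:
            return tuple(c.code for c in self.causes if c.code != NON_CONCLUSIVE)
        return tuple(c for c in self.for_group(group) if c != NON_CONCLUSIVE)

    def n_substantive(self, group: StudyGroup) -> int:
        return len(self.substantive(group))


def load_cause_dictionary(path) -> CauseDictionary:
    """Read a cause dictionary CSV with columns ``code,label,groups``.

    ``groups`` is a semicolon-separated list of study-group names.
    """
    df = pd.read_csv(path, dtype=str)
    causes = []
    for _, row in df.iterrows():
        groups = frozenset(StudyGroup(g) for g in str(row["groups"]).split(";") if g)
        causes.append(Cause(code=row["code"], label=row["label"], groups=groups))
    return CauseDictionary(causes=tuple(causes))


def default_cause_dictionary() -> CauseDictionary:
    """The broad-category dictionary shipped with the package.

    Group scopes: 6 stillbirth, 6 neonate, 5 child, 7 maternal and 4
    other-adult categories, each including non-conclusive.
    """
    with resources.files("vaval.data").joinpath("cause_dictionary.csv").open() as fh:
        return load_cause_dictionary(fh)


#: Infection sub-categories used by the pooled infectious-death analysis.
INFECTION_CATEGORIES: tuple = (
    "disseminated_infections",
    "pneumonia",
    "meningitis",
    "tuberculosis",
    "diarrhoea",
    "hiv_aids_related",
    "malaria",
    "other_infections",
)

#: Terminal categories a prediction may fall into at the infection level.
NON_INFECTIOUS = "non_infectious"


@dataclass(frozen=True, eq=False)
class DeathRecord:
    """One deceased individual.

    ``cda_cause`` is the gold-standard broad category established by the
    complete diagnostic autopsy; its likelihood is 1 by definition (a single
    certain diagnosis).  ``indicators`` is an int8 vector with values
    1 (yes), 0 (no), -1 (not recorded).  ``fine_cause`` optionally carries
    the infection sub-category for deaths of infectious origin.
    """

    id: str
    group: StudyGroup
    cda_cause: str
    indicators: np.ndarray
    cda_likelihood: float = 1.0
    fine_cause: str | None = None

    def __post_init__(self):
        object.__setattr__(
            self, "indicators", np.asarray(self.indicators, dtype=np.int8)
        )


def validate_record(
    record: DeathRecord,
    dictionary: CauseDictionary,
    n_indicators: int | None = None,
) -> None:
    """Raise :class:`DataValidationError` if ``record`` breaks an invariant."""
    if record.cda_cause not in dictionary:
        raise DataValidationError(
            f"record {record.id!r}: cause {record.cda_cause!r} not in dictionary"
        )
    if record.cda_cause not in dictionary.for_group(record.group):
        raise DataValidationError(
            f"record {record.id!r}: cause {record.cda_cause!r} not reportable "
            f"in group {record.group.value!r}"
        )
    if record.cda_likelihood != 1.0:
        raise DataValidationError(
            f"record {record.id!r}: gold-standard likelihood must be 1"
        )
    if n_indicators is not None and record.indicators.shape != (n_indicators,):
        raise DataValidationError(
            f"record {record.id!r}: expected {n_indicators} indicators, "
            f"got {record.indicators.shape[0]}"
        )
    bad = set(np.unique(record.indicators)) - {YES, NO, MISSING}
    if bad:
        raise DataValidationError(
            f"record {record.id!r}: invalid indicator values {sorted(bad)}"
        )


@dataclass(frozen=True)
class VAOutput:
    """Coder output for one death: up to three (cause, likelihood) pairs.

    Likelihoods are non-increasing and, together with the residual
    ``nonconclusive_mass``, sum to 1.  An empty report (all mass
    non-conclusive) is valid.
    """

    assigned: tuple = ()
    nonconclusive_mass: float = 1.0

    def __post_init__(self):
        object.__setattr__(
            self,
            "assigned",
            tuple((str(c), float(l)) for c, l in self.assigned),
        )
        self.validate()

    def validate(self) -> None:
        if len(self.assigned) > 3:
            raise DataValidationError("at most three causes may be reported")
        liks = [l for _, l in self.assigned]
        if any(not (0.0 <= l <= 1.0) for l in liks):
            raise DataValidationError("likelihoods must lie in [0, 1]")
        if any(b > a + 1e-12 for a, b in zip(liks, liks[1:])):
            raise DataValidationError("likelihoods must be non-increasing")
        total = sum(liks) + self.nonconclusive_mass
        if abs(total - 1.0) > 1e-9:
            raise DataValidationError(
                f"likelihoods + non-conclusive mass must sum to 1 (got {total!r})"
            )


@dataclass(frozen=True)
class Icd10Map:
    """Longest-prefix ICD-10 to broad-category mapping table.

    Rows are ``(prefix, group-or-None, category)``; ``None`` matches any
    study group.  At equal prefix length a group-specific row beats an
    ``any`` row.  An empty prefix acts as a per-group catch-all.
    """

    rows: tuple

    def categories(self) -> set:
        return {cat for _, _, cat in self.rows}


def load_icd10_map(path) -> Icd10Map:
    df = pd.read_csv(path, dtype=str).fillna("")
    rows = []
    for _, r in df.iterrows():
        group = None if r["group"] in ("", "any") else StudyGroup(r["group"])
        rows.append((r["prefix"], group, r["category"]))
    return Icd10Map(rows=tuple(rows))


def default_icd10_map() -> Icd10Map:
    """Illustrative default ICD-10 to broad-category map.

    The source study never published its full code-to-category table; this
    default covers the shipped dictionary's categories and common codes and
    is meant to be edited for real deployments.
    """
    with resources.files("vaval.data").joinpath("icd10_map.csv").open() as fh:
        return load_icd10_map(fh)


def default_icd10_infection_map() -> Icd10Map:
    """ICD-10 to infection sub-category map (pooled infectious-death analysis)."""
    with resources.files("vaval.data").joinpath("icd10_infection_map.csv").open() as fh:
        return load_icd10_map(fh)


def map_icd10(code: str, group: StudyGroup, icd10_map: Icd10Map) -> str:
    """Map an ICD-10 code to a cause category by longest matching prefix.

    Only rows whose group is ``group`` or "any" are considered.  An
    unmapped code raises :class:`UnmappedCodeError` rather than silently
    falling back to non-conclusive.
    """
    if not code:
        raise UnmappedCodeError("empty ICD-10 code")
    candidates = [
        (len(prefix), g is not None, cat)
        for prefix, g, cat in icd10_map.rows
        if (g is None or g == group) and code.startswith(prefix)
    ]
    if not candidates:
        raise UnmappedCodeError(f"no mapping for ICD-10 code {code!r} in group {group.value!r}")
    candidates.sort(reverse=True)
    best_len, best_specific, best_cat = candidates[0]
    ties = {
        cat
        for length, specific, cat in candidates
        if (length, specific) == (best_len, best_specific)
    }
    if len(ties) > 1:
        raise DataValidationError(
            f"ambiguous ICD-10 mapping for {code!r}: {sorted(ties)}"
        )
    return best_cat


# ---------------------------------------------------------------------------
# Records CSV I/O
# ---------------------------------------------------------------------------

_RESERVED_COLUMNS = ("id", "group", "cda_cause", "fine_cause")


def load_records(path, dictionary: CauseDictionary) -> list:
    """Read and validate a death-records CSV.

    Expected header: ``id,group,cda_cause[,fine_cause],i_0001,...``; indicator
    cells are ``Y`` / ``N`` / ``.``.  Every record is validated against the
    dictionary and the per-group cause scope; errors name the offending row.
    """
    df = pd.read_csv(path, dtype=str).fillna(".")
    indicator_cols = [c for c in df.columns if c not in _RESERVED_COLUMNS]
    has_fine = "fine_cause" in df.columns
    records = []
    for _, row in df.iterrows():
        rid = str(row["id"])
        try:
            group = StudyGroup(row["group"])
        except ValueError:
            raise DataValidationError(
                f"record {rid!r}: unknown study group {row['group']!r}"
            ) from None
        try:
            indicators = np.array(
                [_INDICATOR_SYMBOLS[row[c]] for c in indicator_cols], dtype=np.int8
            )
        except KeyError as exc:
            raise DataValidationError(
                f"record {rid!r}: invalid indicator symbol {exc.args[0]!r}"
            ) from None
        fine = row["fine_cause"] if has_fine and row["fine_cause"] != "." else None
        rec = DeathRecord(
            id=rid,
            group=group,
            cda_cause=row["cda_cause"],
            indicators=indicators,
            fine_cause=fine,
        )
        validate_record(rec, dictionary, n_indicators=len(indicator_cols))
        records.append(rec)
    tally = Counter(r.group.value for r in records)
    logger.info(
        "loaded %d records (%s) with %d indicators",
        len(records),
        ", ".join(f"{g}={n}" for g, n in sorted(tally.items())),
        len(indicator_cols),
    )
    return records


def write_records(records: Sequence, path) -> None:
    """Write records to CSV in the dialect read by :func:`load_records`."""
    if not records:
        raise DataValidationError("cannot write an empty record set")
    n_ind = records[0].indicators.shape[0]
    cols = ["id", "group", "cda_cause", "fine_cause"] + [
        f"i_{k + 1:04d}" for k in range(n_ind)
    ]
    rows = []
    for r in records:
        rows.append(
            [r.id, r.group.value, r.cda_cause, r.fine_cause or "."]
            + [_INDICATOR_CHARS[int(v)] for v in r.indicators]
        )
    pd.DataFrame(rows, columns=cols).to_csv(path, index=False)


# ---------------------------------------------------------------------------
# Coder-output CSV I/O
# ---------------------------------------------------------------------------


def write_va_outputs(outputs: Sequence, path, ids: Sequence | None = None) -> None:
    """Write coder outputs to CSV.

    Columns: ``id,cause1,lik1,cause2,lik2,cause3,lik3,nonconclusive``.
    Likelihoods are written with 12 significant digits so a read-back
    reproduces the inputs at that precision.
    """
    if ids is None:
        ids = [f"r{i:05d}" for i in range(len(outputs))]
    if len(ids) != len(outputs):
        raise DataValidationError("ids and outputs must have equal length")
    rows = []
    for rid, out in zip(ids, outputs):
        row = [str(rid)]
        for k in range(3):
            if k < len(out.assigned):
                cause, lik = out.assigned[k]
                row += [cause, f"{lik:.12g}"]
            else:
                row += ["", ""]
        row.append(f"{out.nonconclusive_mass:.12g}")
        rows.append(row)
    cols = [
        "id",
        "cause1", "lik1", "cause2", "lik2", "cause3", "lik3",
        "nonconclusive",
    ]
    pd.DataFrame(rows, columns=cols).to_csv(path, index=False)


def load_va_outputs(path) -> tuple:
    """Read a coder-output CSV; returns ``(ids, outputs)``."""
    df = pd.read_csv(path, dtype=str).fillna("")
    ids, outputs = [], []
    for _, row in df.iterrows():
        assigned = []
        for k in (1, 2, 3):
            cause, lik = row[f"cause{k}"], row[f"lik{k}"]
            if cause:
                assigned.append((cause, float(lik)))
        ids.append(str(row["id"]))
        outputs.append(
            VAOutput(
                assigned=tuple(assigned),
                nonconclusive_mass=float(row["nonconclusive"]),
            )
        )
    return ids, outputs
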