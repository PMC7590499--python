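"""Probbase-driven Bayesian cause-of-death assignment.

The coder follows the InterVA family of models: a prior probability for
each cause is combined, via Bayes' theorem under conditional independence,
with the conditional probabilities of the symptom indicators answered
"yes".  Negative and unrecorded indicators contribute nothing to the
likelihood, which makes structurally unavailable indicators well defined.
Accumulation is done in the log domain so long indicator vectors cannot
underflow.

Reporting mirrors the up-to-three-causes convention: the top posterior
cause is reported only if it clears an absolute threshold, subsequent
causes only if they clear a fraction of the top posterior; whatever
posterior mass is not reported becomes the non-conclusive residual.
"""

from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .data_model import (
    DeathRecord,
    VAOutput,
    YES,
    DataValidationError,
)

logger = logging.getLogger(__name__)

#: Conditional probabilities are clamped inside this open interval at load
#: time so a sparse probbase can never annihilate a cause outright.
PROB_FLOOR = 1e-6


@dataclass(frozen=True, eq=False)
class ProbBase:
    """Prior vector and indicator-given-cause conditional matrix.

    ``causes`` excludes the non-conclusive category: the coder only ever
    distributes posterior mass over substantive causes, and the residual
    arises from the reporting rule, not from the probbase.
    ``prevalence_tags`` flags the causes whose priors are rescaled by the
    malaria / HIV prevalence setting.
    """

    causes: tuple
    indicators: tuple
    prior: np.ndarray
    conditional: np.ndarray
    prevalence_tags: Mapping = field(default_factory=dict)

    def __post_init__(self):
        prior = np.asarray(self.prior, dtype=float)
        cond = np.asarray(self.conditional, dtype=float)
        if prior.shape != (len(self.causes),):
            raise DataValidationError("prior length must match cause count")
        if cond.shape != (len(self.causes), len(self.indicators)):
            raise DataValidationError(
                f"conditional matrix must be {len(self.causes)}x{len(self.indicators)}"
            )
        if np.any(prior < 0) or prior.sum() <= 0:
            raise DataValidationError("prior must be non-negative with positive sum")
        object.__setattr__(self, "prior", prior / prior.sum())
        object.__setattr__(
            self, "conditional", np.clip(cond, PROB_FLOOR, 1.0 - PROB_FLOOR)
        )
        for tag, codes in self.prevalence_tags.items():
            unknown = set(codes) - set(self.causes)
            if unknown:
                raise DataValidationError(
                    f"prevalence tag {tag!r} references unknown causes {sorted(unknown)}"
                )

    @property
    def n_indicators(self) -> int:
        return len(self.indicators)

    def restrict(self, causes: Sequence) -> "ProbBase":
        """Probbase conditioned on a subset of causes (prior renormalised).

        Used to scope the coder to the causes reportable in one study
        group, analogous to conditioning on age/sex eligibility.
        """
        idx = [self.causes.index(c) for c in causes]
        tags = {
            tag: frozenset(c for c in codes if c in causes)
            for tag, codes in self.prevalence_tags.items()
        }
        return ProbBase(
            causes=tuple(causes),
            indicators=self.indicators,
            prior=self.prior[idx],
            conditional=self.conditional[idx, :],
            prevalence_tags=tags,
        )


@dataclass(frozen=True)
class PrevalenceSetting:
    """Epidemiological context: malaria and HIV prevalence levels.

    Each level multiplies the priors of the causes carrying the matching
    tag before renormalisation; prevalence is prior information about
    cause frequency, so conditionals are untouched.
    """

    malaria: str = "low"
    hiv: str = "high"
    level_factors: Mapping = field(
        default_factory=lambda: {"high": 1.0, "low": 0.1, "very_low": 0.01}
    )

    def factor(self, level: str) -> float:
        f = self.level_factors[level]
        if f <= 0:
            raise DataValidationError(f"prevalence factor for {level!r} must be > 0")
        return f


@dataclass(frozen=True)
class ReportingRule:
    """Thresholds controlling how much of the posterior is reported.

    ``top_threshold``: minimum posterior for any cause to be reported at
    all; ``relative_threshold``: fraction of the top posterior that each
    subsequent cause must reach; ``max_causes``: cap on reported causes.
    """

    top_threshold: float = 0.4
    relative_threshold: float = 0.5
    max_causes: int = 3

    def __post_init__(self):
        if not (0.0 < self.top_threshold < 1.0):
            raise DataValidationError("top_threshold must be in (0, 1)")
        if not (0.0 < self.relative_threshold <= 1.0):
            raise DataValidationError("relative_threshold must be in (0, 1]")
        if self.max_causes < 1:
            raise DataValidationError("max_causes must be >= 1")


def apply_prevalence(probbase: ProbBase, setting: PrevalenceSetting) -> ProbBase:
    """Rescale the priors of malaria/HIV-tagged causes and renormalise."""
    prior = probbase.prior.copy()
    for tag, level in (("malaria", setting.malaria), ("hiv", setting.hiv)):
        codes = probbase.prevalence_tags.get(tag, ())
        f = setting.factor(level)
        for code in codes:
            prior[probbase.causes.index(code)] *= f
    return replace(probbase, prior=prior)


def compute_posterior(record: DeathRecord, probbase: ProbBase) -> np.ndarray:
    """Posterior over substantive causes given the record's "yes" indicators.

    posterior(c) is proportional to prior(c) times the product over
    indicators answered yes of P(indicator | c); accumulated in the log
    domain and normalised to sum to 1.
    """
    if record.indicators.shape[0] != probbase.n_indicators:
        raise DataValidationError(
            f"record {record.id!r} has {record.indicators.shape[0]} indicators, "
            f"probbase expects {probbase.n_indicators}"
        )
    yes = record.indicators == YES
    logpost = np.log(probbase.prior)
    if yes.any():
        logpost = logpost + np.log(probbase.conditional[:, yes]).sum(axis=1)
    logpost -= logpost.max()
    post = np.exp(logpost)
    total = post.sum()
    if not np.isfinite(total) or total <= 0.0:
        raise FloatingPointError(
            "posterior mass vanished; accumulate in the log domain"
        )
    return post / total


def rank_causes(
    posterior: np.ndarray,
    *,
    tie_break: str = "dictionary",
    rng: np.random.Generator | None = None,
) -> np.ndarray:
    """Indices of causes by decreasing posterior.

    Exact ties are broken by dictionary (index) order by default, which
    keeps the coder fully deterministic; ``tie_break="random"`` breaks
    them uniformly with the supplied generator, which is the right choice
    when a zero-information posterior must not collapse onto the first
    cause (e.g. chance-calibration runs).
    """
    n = posterior.shape[0]
    if tie_break == "dictionary":
        order = np.lexsort((np.arange(n), -posterior))
    elif tie_break == "random":
        if rng is None:
            raise ValueError("random tie-breaking requires an rng")
        jitter = rng.permutation(n)
        order = np.lexsort((jitter, -posterior))
    else:
        raise ValueError(f"unknown tie_break {tie_break!r}")
    return order


def report_causes(
    posterior: np.ndarray,
    rule: ReportingRule,
    causes: Sequence,
    *,
    tie_break: str = "dictionary",
    rng: np.random.Generator | None = None,
) -> VAOutput:
    """Turn a posterior vector into an up-to-three-cause report.

    The top cause is reported iff its posterior reaches
    ``rule.top_threshold``; each subsequent cause iff it reaches
    ``rule.relative_threshold`` times the top posterior, up to
    ``rule.max_causes`` causes.  Unreported mass is non-conclusive.  An
    empty report (non-conclusive mass 1) is valid.
    """
    posterior = np.asarray(posterior, dtype=float)
    if abs(posterior.sum() - 1.0) > 1e-9:
        raise DataValidationError("posterior must sum to 1")
    order = rank_causes(posterior, tie_break=tie_break, rng=rng)
    top = posterior[order[0]]
    assigned = []
    if top >= rule.top_threshold:
        cutoff = rule.relative_threshold * top
        for idx in order[: min(rule.max_causes, 3)]:
            if posterior[idx] >= cutoff:
                assigned.append((causes[idx], float(posterior[idx])))
            else:
                break
    mass = 1.0 - sum(l for _, l in assigned)
    return VAOutput(assigned=tuple(assigned), nonconclusive_mass=mass)


def code_death(
    record: DeathRecord,
    probbase: ProbBase,
    setting: PrevalenceSetting | None = None,
    rule: ReportingRule | None = None,
    *,
    tie_break: str = "dictionary",
    rng: np.random.Generator | None = None,
) -> VAOutput:
    """Code one death: prevalence adjustment, posterior, reporting."""
    if setting is not None:
        probbase = apply_prevalence(probbase, setting)
    posterior = compute_posterior(record, probbase)
    return report_causes(
        posterior, rule or ReportingRule(), probbase.causes,
        tie_break=tie_break, rng=rng,
    )


def code_cohort(
    records: Sequence,
    probbase: ProbBase,
    setting: PrevalenceSetting | None = None,
    rule: ReportingRule | None = None,
    *,
    tie_break: str = "dictionary",
    rng: np.random.Generator | None = None,
) -> list:
    """Code every record, preserving order, and log the cause-count shape."""
    if setting is not None:
        probbase = apply_prevalence(probbase, setting)
        setting = None
    rule = rule or ReportingRule()
    outputs = [
        code_death(r, probbase, setting, rule, tie_break=tie_break, rng=rng)
        for r in records
    ]
    hist = Counter(len(o.assigned) for o in outputs)
    logger.info(
        "coded %d deaths: %s",
        len(outputs),
        ", ".join(f"{hist.get(k, 0)} with {k} cause(s)" for k in (1, 2, 3, 0)),
    )
    return outputs


# ---------------------------------------------------------------------------
# Probbase CSV I/O
# ---------------------------------------------------------------------------


def write_probbase(probbase: ProbBase, path) -> None:
    """Write a probbase CSV: cause, prior, then one column per indicator."""
    df = pd.DataFrame(probbase.conditional, columns=list(probbase.indicators))
    df.insert(0, "prior", probbase.prior)
    df.insert(0, "cause", list(probbase.causes))
    df.to_csv(path, index=False, float_format="%.12g")


def load_probbase(path, prevalence_tags: Mapping | None = None) -> ProbBase:
    """Read a probbase CSV written by :func:`write_probbase`."""
    df = pd.read_csv(path)
    indicators = tuple(c for c in df.columns if c not in ("cause", "prior"))
    return ProbBase(
        causes=tuple(df["cause"].astype(str)),
        indicators=indicators,
        prior=df["prior"].to_numpy(dtype=float),
        conditional=df[list(indicators)].to_numpy(dtype=float),
        prevalence_tags=prevalence_tags or {},
    )
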