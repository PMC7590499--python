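"""Published per-cause classification counts from the source validation study.

The hospital autopsy validation study that motivates this package
published, for every study group and broad cause (and for infection
sub-categories pooled over groups), the one-vs-rest classification counts
of the coder's top cause against the gold standard, together with the
derived integer percentages.  Those printed counts are shipped here as
reference data: they are the worked examples for
:func:`vaval.individual_metrics.binary_metrics` and the inputs to the
reproduction checks.

Columns: ``table`` ("broad" per-group or "infection" pooled), ``group``,
``cause``, ``tp``, ``tn``, ``fp``, ``fn``, and the printed
``sensitivity`` / ``specificity`` / ``ppv`` / ``npv`` percentages
(``N/A`` where the denominator is zero).
"""

from __future__ import annotations

from importlib import resources

import pandas as pd


def load_study_confusion_counts() -> pd.DataFrame:
    """The study's published confusion counts and printed percentages."""
    with resources.files("vaval.data").joinpath("study_confusion_counts.csv").open() as fh:
        # keep_default_na: the literal string "N/A" marks undefined metrics
        df = pd.read_csv(
            fh,
            dtype={"tp": int, "tn": int, "fp": int, "fn": int},
            keep_default_na=False,
        )
    return df
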