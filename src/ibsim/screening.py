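"""Subject exclusion pipeline.

Applies the paradigm's standard screening rules to a cohort: underage
subjects; bounce counts off by more than 50% (strictly) of the true count
on two or more trials; vision correction needed but not worn; technical
problems; prior experience with inattentional blindness tasks; and, for
the colour-report experiment only, a Farnsworth D-15 confusion index
strictly greater than 1.78. A subject may be flagged by several rules but
is removed once; the per-rule accounting therefore may sum to more than
the number excluded.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .d15 import exceeds_d15_threshold, score_d15

__all__ = [
    "RULE_ORDER",
    "bounce_error_rule",
    "d15_rule",
    "ExclusionReport",
    "apply_exclusions",
]

#: Report row order (matches the conventional exclusion-table layout).
RULE_ORDER = (
    "bounce_error",
    "underage",
    "vision_uncorrected",
    "technical_problem",
    "prior_experience",
    "d15",
)


def bounce_error_rule(true_counts, reported_counts) -> bool:
    """True when the subject miscounted by more than 50% on >= 2 trials.

    Per trial the flag is |reported - true| > 0.5 * true, with the strict
    inequality keeping an exactly-50% error unflagged. A zero true count
    with any nonzero report counts as a flagged trial (the limit of the
    relative error).
    """
    true = np.asarray(true_counts, dtype=float)
    rep = np.asarray(reported_counts, dtype=float)
    err = np.abs(rep - true)
    with np.errstate(invalid="ignore"):
        flagged = np.where(true > 0, err > 0.5 * true, rep > 0)
    return bool(flagged.sum() >= 2)


def _bounce_flags(cohort: pd.DataFrame) -> pd.Series:
    true = cohort[["true_bounces_1", "true_bounces_2", "true_bounces_3"]].to_numpy(float)
    rep = cohort[
        ["reported_bounces_1", "reported_bounces_2", "reported_bounces_3"]
    ].to_numpy(float)
    err = np.abs(rep - true)
    per_trial = np.where(true > 0, err > 0.5 * true, rep > 0)
    return pd.Series(per_trial.sum(axis=1) >= 2, index=cohort.index)


def d15_rule(arrangement_str: str | None) -> bool:
    """True when a serialised arrangement ('1-2-...-15') fails the D-15
    screen; missing arrangements never flag."""
    if arrangement_str is None or (isinstance(arrangement_str, float) and np.isnan(arrangement_str)):
        return False
    caps = [int(c) for c in str(arrangement_str).split("-")]
    return exceeds_d15_threshold(score_d15(caps))


@dataclass
class ExclusionReport:
    """Per-rule exclusion accounting for one cohort."""

    counts: dict[str, int]
    total_excluded: int
    total_retained: int
    total_recruited: int
    retained_ids: list[str] = field(default_factory=list, repr=False)

    def to_frame(self) -> pd.DataFrame:
        rows = [{"exclusion_rule": r, "n_excluded": self.counts[r]} for r in RULE_ORDER]
        rows += [
            {"exclusion_rule": "total excluded", "n_excluded": self.total_excluded},
            {"exclusion_rule": "total retained", "n_excluded": self.total_retained},
            {"exclusion_rule": "total recruited", "n_excluded": self.total_recruited},
        ]
        return pd.DataFrame(rows)

    def to_json(self) -> str:
        return json.dumps(
            {
                "counts": self.counts,
                "total_excluded": self.total_excluded,
                "total_retained": self.total_retained,
                "total_recruited": self.total_recruited,
            },
            indent=2,
        )


def apply_exclusions(
    cohort: pd.DataFrame, experiment: str | None = None
) -> tuple[pd.DataFrame, ExclusionReport]:
    """Apply every screening rule and return (retained cohort, report).

    The D-15 rule runs only for E3 cohorts (those carry arrangements).
    Rule order does not affect the retained set; subjects flagged by
    several rules appear in each rule's count but are excluded once.
    """
    experiment = experiment or (
        str(cohort["experiment"].iloc[0]) if len(cohort) else "E1"
    )
    flags = pd.DataFrame(index=cohort.index)
    flags["bounce_error"] = _bounce_flags(cohort) if len(cohort) else []
    flags["underage"] = ~cohort["age_ok"].astype(bool)
    flags["vision_uncorrected"] = ~cohort["vision_corrected_ok"].astype(bool)
    flags["technical_problem"] = cohort["technical_problem"].astype(bool)
    flags["prior_experience"] = cohort["prior_ib_experience"].astype(bool)
    if experiment == "E3" and "d15_arrangement" in cohort:
        flags["d15"] = cohort["d15_arrangement"].map(d15_rule).astype(bool)
    else:
        flags["d15"] = False

    any_flag = flags.any(axis=1)
    retained = cohort.loc[~any_flag].copy()
    report = ExclusionReport(
        counts={r: int(flags[r].sum()) for r in RULE_ORDER},
        total_excluded=int(any_flag.sum()),
        total_retained=int((~any_flag).sum()),
        total_recruited=int(len(cohort)),
        retained_ids=list(retained.get("subject_id", pd.Series(dtype=str))),
    )
    return retained, report
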