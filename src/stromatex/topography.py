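"""CD8+ immune-topography phenotyping of matched tumor triplets.

A tumor compartment (stroma or cancer-cell area) is called INFILTRATED
when more than 2% of its cells are CD8+ T cells (strict inequality;
exactly 2% is NOT_INFILTRATED by the package's documented boundary
convention).  The (stroma, cancer) status pair maps bijectively onto four
phenotypes:

=========  ==================  ==================
phenotype  stroma              cancer
=========  ==================  ==================
HOT        infiltrated         infiltrated
EXCLUDED   infiltrated         not infiltrated
HOT_CANCER not infiltrated     infiltrated
COLD       not infiltrated     not infiltrated
=========  ==================  ==================

Across matched primary / metastasis / recurrence triplets the module
tallies ordered infiltration patterns (2^3 status patterns per
compartment, or 4^3 phenotype patterns).
"""

from __future__ import annotations

import enum
import logging
from collections import Counter
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .synthetic import SAMPLE_LABELS

__all__ = [
    "InfiltrationStatus",
    "TumorImmunePhenotype",
    "DEFAULT_THRESHOLD",
    "call_infiltration",
    "phenotype",
    "tumor_phenotypes",
    "cohort_patterns",
    "PatternTally",
]

log = logging.getLogger(__name__)

DEFAULT_THRESHOLD = 2.0  # percent CD8+ cells


class InfiltrationStatus(enum.Enum):
    INFILTRATED = "INFILTRATED"
    NOT_INFILTRATED = "NOT_INFILTRATED"


class TumorImmunePhenotype(enum.Enum):
    HOT = "HOT"
    COLD = "COLD"
    EXCLUDED = "EXCLUDED"
    HOT_CANCER = "HOT_CANCER"


def call_infiltration(cd8_percent: float, threshold: float = DEFAULT_THRESHOLD) -> InfiltrationStatus:
    """Strictly-greater-than-threshold infiltration call."""
    if not 0.0 <= cd8_percent <= 100.0:
        raise ValueError(f"cd8_percent {cd8_percent} outside [0, 100]")
    return (
        InfiltrationStatus.INFILTRATED
        if cd8_percent > threshold
        else InfiltrationStatus.NOT_INFILTRATED
    )


_PHENOTYPE_MAP = {
    (InfiltrationStatus.INFILTRATED, InfiltrationStatus.INFILTRATED): TumorImmunePhenotype.HOT,
    (InfiltrationStatus.INFILTRATED, InfiltrationStatus.NOT_INFILTRATED): TumorImmunePhenotype.EXCLUDED,
    (InfiltrationStatus.NOT_INFILTRATED, InfiltrationStatus.INFILTRATED): TumorImmunePhenotype.HOT_CANCER,
    (InfiltrationStatus.NOT_INFILTRATED, InfiltrationStatus.NOT_INFILTRATED): TumorImmunePhenotype.COLD,
}


def phenotype(stroma: InfiltrationStatus, cancer: InfiltrationStatus) -> TumorImmunePhenotype:
    """Map a (stroma, cancer) status pair to the four-way phenotype."""
    return _PHENOTYPE_MAP[(stroma, cancer)]


def tumor_phenotypes(tumor_df: pd.DataFrame, threshold: float = DEFAULT_THRESHOLD) -> pd.DataFrame:
    """Per-tumor infiltration statuses and phenotype.

    Expects the tumor summary table from :func:`stromatex.cores.summarize_cohort`
    (columns ``pct_cd8_stroma`` / ``pct_cd8_cancer``; tumor-level medians
    over triplicate cores).  Tumors with a missing CD8 percentage get
    missing statuses/phenotype.
    """
    out = tumor_df.copy()

    def _status(p):
        return call_infiltration(p, threshold).value if not np.isnan(p) else None

    out["stroma_status"] = out["pct_cd8_stroma"].map(_status)
    out["cancer_status"] = out["pct_cd8_cancer"].map(_status)
    out["phenotype"] = [
        phenotype(InfiltrationStatus(s), InfiltrationStatus(c)).value if s and c else None
        for s, c in zip(out["stroma_status"], out["cancer_status"])
    ]
    return out


@dataclass
class PatternTally:
    """Ordered (primary, metastasis, recurrence) pattern counts."""

    mode: str
    counts: Counter = field(default_factory=Counter)
    n_patients: int = 0
    excluded_patients: list[str] = field(default_factory=list)

    @property
    def all_infiltrated(self) -> int:
        return self.counts.get(("INFILTRATED",) * 3, 0)

    @property
    def all_not_infiltrated(self) -> int:
        return self.counts.get(("NOT_INFILTRATED",) * 3, 0)

    def as_dict(self) -> dict:
        return {
            "mode": self.mode,
            "n_patients": self.n_patients,
            "excluded_patients": list(self.excluded_patients),
            "patterns": {"|".join(k): v for k, v in sorted(self.counts.items())},
        }


def cohort_patterns(
    tumor_df: pd.DataFrame,
    mode: str = "stroma",
    threshold: float = DEFAULT_THRESHOLD,
    sample_order: tuple[str, ...] = SAMPLE_LABELS,
) -> PatternTally:
    """Tally ordered infiltration patterns across matched triplets.

    ``mode`` is ``"stroma"`` or ``"cancer"`` (2^3 = 8 possible status
    patterns) or ``"phenotype"`` (4^3 = 64 possible patterns).  Patients
    missing any sample of the triplet, or whose required value is missing
    (e.g., no valid core for a compartment), are excluded and listed in
    ``excluded_patients``; counts always sum to ``n_patients``.
    """
    if mode not in ("stroma", "cancer", "phenotype"):
        raise ValueError(f"unknown mode {mode!r}")
    pheno = tumor_phenotypes(tumor_df, threshold)
    col = {"stroma": "stroma_status", "cancer": "cancer_status", "phenotype": "phenotype"}[mode]

    tally = PatternTally(mode=mode)
    for patient, grp in pheno.groupby("patient_id", sort=True):
        by_sample = grp.set_index("sample_label")[col]
        if any(lab not in by_sample.index or by_sample[lab] is None for lab in sample_order):
            tally.excluded_patients.append(patient)
            log.info("patient %s excluded from topography (incomplete triplet)", patient)
            continue
        pattern = tuple(by_sample[lab] for lab in sample_order)
        tally.counts[pattern] += 1
        tally.n_patients += 1
    return tally
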