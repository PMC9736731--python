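"""Core-, tumor- and patient-level quantification of per-cell tables.

Consumes the per-cell CSV export of a cell-detection tool (one table per
TMA core; columns documented in :mod:`stromatex.synthetic`) and derives:

* per-core percentages of fibroblasts / epithelial cancer cells / immune
  cells;
* CAF-subset percentages -- the share of fibroblasts whose mean DAB
  optical density for COL11A1, alpha-SMA or PDPN exceeds a configured
  threshold;
* CD8+ percentages computed separately within the stroma and cancer
  compartments;
* a validity flag implementing the quality rule that cores with fewer
  than 200 epithelial cancer cells are excluded from statistics;
* tumor-level medians over the valid triplicate cores.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, asdict

import numpy as np
import pandas as pd

from . import stats as group_stats

__all__ = [
    "MarkerThresholds",
    "CoreSummary",
    "MIN_EPITHELIAL_CELLS",
    "summarize_core",
    "aggregate_tumor",
    "summarize_cohort",
    "group_compare",
    "TUMOR_QUANTITIES",
]

MIN_EPITHELIAL_CELLS = 200

#: Quantities carried from cores to tumor level (percent units).
TUMOR_QUANTITIES = [
    "pct_fibroblast", "pct_epithelial", "pct_immune",
    "pct_caf_col11a1", "pct_caf_asma", "pct_caf_pdpn",
    "pct_cd8_stroma", "pct_cd8_cancer",
]


@dataclass(frozen=True)
class MarkerThresholds:
    """Mean-DAB-OD cutoffs calling a fibroblast positive for each marker."""

    col11a1: float = 0.3
    asma: float = 0.3
    pdpn: float = 0.3

    def __post_init__(self) -> None:
        if min(self.col11a1, self.asma, self.pdpn) < 0:
            raise ValueError("marker thresholds must be >= 0")


@dataclass
class CoreSummary:
    core_id: str
    n_cells: int
    n_fibroblast: int
    n_epithelial: int
    n_immune: int
    pct_fibroblast: float
    pct_epithelial: float
    pct_immune: float
    pct_caf_col11a1: float  # NaN when the core has no fibroblasts
    pct_caf_asma: float
    pct_caf_pdpn: float
    pct_cd8_stroma: float  # NaN when the compartment is empty
    pct_cd8_cancer: float
    valid: bool

    def as_dict(self) -> dict:
        return asdict(self)


def summarize_core(
    cells: pd.DataFrame,
    thresholds: MarkerThresholds = MarkerThresholds(),
    core_id: str = "",
    min_epithelial: int = MIN_EPITHELIAL_CELLS,
) -> CoreSummary:
    """Quantify one core's cell table.

    CAF-subset percentages are the marker-positive share among all
    fibroblasts; with zero fibroblasts they are reported as NaN (missing),
    never as 0.  CD8+ percentages use per-compartment denominators.
    ``valid`` is False when the epithelial count falls below
    ``min_epithelial``.
    """
    n = len(cells)
    counts = {t: 0 for t in ("FIBROBLAST", "EPITHELIAL", "IMMUNE")}
    if n:
        counts.update(cells["cell_type"].value_counts().to_dict())
    n_fib, n_epi, n_imm = counts["FIBROBLAST"], counts["EPITHELIAL"], counts["IMMUNE"]

    def pct(a: int, b: int) -> float:
        return 100.0 * a / b if b else math.nan

    caf = {}
    fib = cells[cells["cell_type"] == "FIBROBLAST"] if n else cells
    for marker, tau in (("col11a1", thresholds.col11a1), ("asma", thresholds.asma), ("pdpn", thresholds.pdpn)):
        caf[marker] = pct(int((fib[f"dab_{marker}"] > tau).sum()), n_fib) if n_fib else math.nan

    cd8 = {}
    for comp in ("STROMA", "CANCER"):
        sub = cells[cells["compartment"] == comp] if n else cells
        cd8[comp] = pct(int(sub["cd8_positive"].sum()), len(sub)) if len(sub) else math.nan

    return CoreSummary(
        core_id=core_id,
        n_cells=n,
        n_fibroblast=n_fib,
        n_epithelial=n_epi,
        n_immune=n_imm,
        pct_fibroblast=pct(n_fib, n) if n else 0.0,
        pct_epithelial=pct(n_epi, n) if n else 0.0,
        pct_immune=pct(n_imm, n) if n else 0.0,
        pct_caf_col11a1=caf["col11a1"],
        pct_caf_asma=caf["asma"],
        pct_caf_pdpn=caf["pdpn"],
        pct_cd8_stroma=cd8["STROMA"],
        pct_cd8_cancer=cd8["CANCER"],
        valid=bool(n_epi >= min_epithelial),
    )


def aggregate_tumor(cores: list[CoreSummary]) -> dict:
    """Median over the tumor's valid cores, per quantity.

    Invalid cores (the <200-epithelial-cell rule) are excluded entirely;
    per-core NaN values are skipped quantity by quantity.  A tumor with no
    valid core reports NaN for every quantity and ``n_valid_cores = 0``.
    An even number of contributing cores yields the midpoint median.
    """
    if not cores:
        raise ValueError("aggregate_tumor needs at least one core summary")
    valid = [c for c in cores if c.valid]
    out: dict = {"n_cores": len(cores), "n_valid_cores": len(valid)}
    for q in TUMOR_QUANTITIES:
        vals = np.array([getattr(c, q) for c in valid], dtype=float)
        vals = vals[~np.isnan(vals)]
        out[q] = float(np.median(vals)) if vals.size else math.nan
    return out


def summarize_cohort(
    tables: dict[str, pd.DataFrame],
    manifest: pd.DataFrame,
    thresholds: MarkerThresholds = MarkerThresholds(),
    min_epithelial: int = MIN_EPITHELIAL_CELLS,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Summarize every core and aggregate to (patient, sample) tumors.

    Returns ``(core_df, tumor_df)``; ``tumor_df`` is keyed by
    (patient_id, sample_label) and carries the median quantities plus
    core-count bookkeeping.
    """
    missing = [cid for cid in manifest["core_id"] if cid not in tables]
    if missing:
        raise KeyError(f"manifest cores without cell tables: {missing[:5]} (n={len(missing)})")
    summaries = {
        cid: summarize_core(tables[cid], thresholds, core_id=cid, min_epithelial=min_epithelial)
        for cid in manifest["core_id"]
    }
    core_df = pd.DataFrame([s.as_dict() for s in summaries.values()]).set_index("core_id")
    core_df = core_df.join(manifest.set_index("core_id")[["patient_id", "sample_label", "slide"]])

    rows = []
    for (patient, sample), grp in manifest.groupby(["patient_id", "sample_label"], sort=True):
        agg = aggregate_tumor([summaries[cid] for cid in grp["core_id"]])
        rows.append({"patient_id": patient, "sample_label": sample, **agg})
    tumor_df = pd.DataFrame(rows)
    return core_df, tumor_df


def group_compare(
    tumor_df: pd.DataFrame,
    quantities: list[str] | None = None,
    group_col: str = "sample_label",
    alpha: float = 0.05,
) -> pd.DataFrame:
    """ANOVA + Tukey-Kramer across sample groups for each quantity.

    Tumors with a missing value for a quantity are dropped from that
    quantity's test.  Returns one row per quantity with F, p and the
    pairwise significance flags.
    """
    quantities = quantities or TUMOR_QUANTITIES
    labels = sorted(tumor_df[group_col].unique().tolist())
    if len(labels) < 2:
        raise ValueError("group_compare needs >= 2 groups")
    rows = []
    for q in quantities:
        groups = [
            tumor_df.loc[tumor_df[group_col] == lab, q].dropna().to_numpy() for lab in labels
        ]
        if any(len(g) < 2 for g in groups):
            rows.append({"quantity": q, "F": math.nan, "p": math.nan})
            continue
        f, p = group_stats.anova_oneway(groups)
        row = {"quantity": q, "F": f, "p": p, "significant": p < alpha}
        tk = group_stats.tukey_kramer(groups, alpha=alpha)
        for (i, j), res in tk.items():
            row[f"tukey_{labels[i]}_vs_{labels[j]}"] = res["significant"]
        rows.append(row)
    return pd.DataFrame(rows).set_index("quantity")
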