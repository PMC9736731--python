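"""Differential-feature screening: z-score, one-way ANOVA, Tukey-Kramer.

The screening protocol: features are pooled-z-scored, each is tested by
classical one-way ANOVA across the groups, significance is declared at a
Bonferroni-corrected level alpha0 / m (m = number of testable features,
212 for the full panel -> per-test threshold ~2.36e-4), and
ANOVA-significant features are followed up with Tukey-Kramer pairwise
comparisons (studentized-range critical value; Kramer's harmonic
adjustment makes unequal group sizes valid).
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "zscore_features",
    "anova_oneway",
    "tukey_kramer",
    "differential_screen",
    "DifferentialResult",
]

log = logging.getLogger(__name__)


def zscore_features(table: pd.DataFrame) -> tuple[pd.DataFrame, list[str]]:
    """Pooled z-scoring of every numeric column (ddof = 1).

    Returns the standardized table and the list of zero-variance columns,
    which are dropped rather than propagated as NaN.  Pooling across all
    observations (not per group) preserves every ANOVA F statistic.
    """
    if len(table) < 2:
        raise ValueError("need at least 2 observations to z-score")
    sd = table.std(ddof=1)
    degenerate = list(sd.index[(sd == 0) | sd.isna()])
    if degenerate:
        log.warning("excluding %d zero-variance features: %s", len(degenerate), degenerate[:5])
    kept = table.drop(columns=degenerate)
    return (kept - kept.mean()) / kept.std(ddof=1), degenerate


def anova_oneway(groups: list[np.ndarray]) -> tuple[float, float]:
    """Classical one-way ANOVA; returns (F, p) with (k-1, N-k) df."""
    if len(groups) < 2 or any(len(g) < 2 for g in groups):
        raise ValueError("need >= 2 groups with >= 2 values each")
    import warnings

    with warnings.catch_warnings():
        warnings.simplefilter("ignore", sps.ConstantInputWarning)
        res = sps.f_oneway(*groups)
    f = float(res.statistic)
    p = float(res.pvalue)
    if np.isnan(f):  # all groups constant and equal
        return 0.0, 1.0
    return f, p


def tukey_kramer(groups: list[np.ndarray], alpha: float = 0.05) -> dict[tuple[int, int], dict]:
    """Tukey-Kramer pairwise comparisons.

    Pair (i, j) is flagged when |mean_i - mean_j| exceeds
    q(alpha, k, N-k) * sqrt(MSW/2 * (1/n_i + 1/n_j)), where q is the
    studentized-range critical value.  Returns per-pair dicts with the
    mean difference, the q statistic and the significance flag; keys are
    ordered index pairs (i < j) and flags are symmetric by construction.
    """
    if len(groups) < 2 or any(len(g) < 2 for g in groups):
        raise ValueError("need >= 2 groups with >= 2 values each")
    groups = [np.asarray(g, dtype=float) for g in groups]
    k = len(groups)
    ns = np.array([len(g) for g in groups])
    n_total = int(ns.sum())
    means = np.array([g.mean() for g in groups])
    ssw = float(sum(((g - g.mean()) ** 2).sum() for g in groups))
    df_w = n_total - k
    msw = ssw / df_w
    q_crit = float(sps.studentized_range.ppf(1.0 - alpha, k, df_w))
    out = {}
    for i, j in itertools.combinations(range(k), 2):
        se = np.sqrt(msw / 2.0 * (1.0 / ns[i] + 1.0 / ns[j]))
        diff = means[i] - means[j]
        q_stat = np.abs(diff) / se if se > 0 else (np.inf if diff != 0 else 0.0)
        out[(i, j)] = {
            "diff": float(diff),
            "q": float(q_stat),
            "q_crit": q_crit,
            "significant": bool(q_stat > q_crit),
        }
    return out


@dataclass
class DifferentialResult:
    """Outcome of a Bonferroni-gated differential screen.

    ``per_feature`` has one row per testable feature (F, p, significant);
    ``pairwise`` maps each ANOVA-significant feature to its Tukey-Kramer
    flags keyed by group-label pair; ``venn`` counts significant features
    per pairwise contrast (populated for 3-group screens).
    """

    per_feature: pd.DataFrame
    alpha_per_test: float
    m: int
    group_labels: list[str]
    excluded: list[str] = field(default_factory=list)
    pairwise: dict = field(default_factory=dict)
    venn: dict = field(default_factory=dict)

    @property
    def significant_features(self) -> list[str]:
        return list(self.per_feature.index[self.per_feature["significant"]])


def differential_screen(
    table: pd.DataFrame,
    groups: pd.Series | np.ndarray,
    alpha0: float = 0.05,
    alpha_pairwise: float = 0.05,
    gatekeep: bool = True,
    zscore: bool = True,
) -> DifferentialResult:
    """Screen every feature for group differences.

    Parameters
    ----------
    table : DataFrame
        Observations x features.
    groups : array-like
        Group label per observation (2 or 3 groups typical).
    alpha0 : float
        Family-wise level; each feature is tested at ``alpha0 / m``.
    gatekeep : bool
        When True (default) Tukey-Kramer runs only on ANOVA-significant
        features, mirroring the ANOVA-then-post-hoc protocol.
    """
    groups = pd.Series(np.asarray(groups), index=table.index, name="group")
    labels = sorted(groups.unique().tolist())
    if len(labels) < 2:
        raise ValueError("need >= 2 groups")
    if zscore:
        table, excluded = zscore_features(table)
    else:
        sd = table.std(ddof=1)
        excluded = list(sd.index[(sd == 0) | sd.isna()])
        table = table.drop(columns=excluded)
    m = table.shape[1]
    if m == 0:
        raise ValueError("no testable features after degenerate exclusion")
    alpha_per_test = alpha0 / m

    rows = []
    by_group = {lab: table[groups.values == lab] for lab in labels}
    for feat in table.columns:
        vals = [by_group[lab][feat].to_numpy() for lab in labels]
        f, p = anova_oneway(vals)
        rows.append({"feature": feat, "F": f, "p": p, "significant": p < alpha_per_test})
    per_feature = pd.DataFrame(rows).set_index("feature")

    pairwise: dict[str, dict] = {}
    candidates = per_feature.index[per_feature["significant"]] if gatekeep else per_feature.index
    for feat in candidates:
        vals = [by_group[lab][feat].to_numpy() for lab in labels]
        tk = tukey_kramer(vals, alpha=alpha_pairwise)
        pairwise[feat] = {
            (labels[i], labels[j]): res["significant"] for (i, j), res in tk.items()
        }

    venn: dict[tuple[str, str], int] = {}
    for i, j in itertools.combinations(range(len(labels)), 2):
        key = (labels[i], labels[j])
        venn[key] = sum(flags.get(key, False) for flags in pairwise.values())

    return DifferentialResult(
        per_feature=per_feature,
        alpha_per_test=alpha_per_test,
        m=m,
        group_labels=labels,
        excluded=excluded,
        pairwise=pairwise,
        venn=venn,
    )
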