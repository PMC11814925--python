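"""Normality-gated group comparisons and report assembly.

Test selection mirrors the field's standard recipe: every group's sample is
screened with the Shapiro-Wilk test at alpha = 0.05; if all groups pass,
parametric tests are used (one-way ANOVA, t tests), otherwise the
nonparametric family (Kruskal-Wallis, Mann-Whitney U). Off-the-shelf tests
are delegated to scipy.stats; this module owns only the gating, pairing and
correction bookkeeping.
"""

from __future__ import annotations

import itertools
import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "normality_gate",
    "PairedComparison",
    "paired_compare",
    "PairwiseResult",
    "ComparisonResult",
    "compare_groups",
    "build_report",
]

logger = logging.getLogger(__name__)

ALPHA_DEFAULT = 0.05


def normality_gate(samples: dict[str, np.ndarray] | list[np.ndarray],
                   alpha: float = ALPHA_DEFAULT) -> str:
    """Choose the test family: ``"parametric"`` iff every group passes
    Shapiro-Wilk at ``alpha``.

    Degenerate groups (n < 3 or zero variance) cannot be screened and force
    the nonparametric family with a warning — the conservative choice.
    """
    groups = samples.values() if isinstance(samples, dict) else samples
    for g in groups:
        g = np.asarray(g, dtype=float)
        if g.size < 3 or np.ptp(g) == 0:
            logger.warning("degenerate sample (n=%d); using nonparametric tests",
                           g.size)
            return "nonparametric"
        if sps.shapiro(g).pvalue < alpha:
            return "nonparametric"
    return "parametric"


@dataclass
class PairedComparison:
    """Paired two-condition location test with its normality gate."""

    statistic: float
    p_value: float
    family: str
    test_name: str
    n: int
    mean_diff: float


def paired_compare(a: np.ndarray, b: np.ndarray,
                   alpha: float = ALPHA_DEFAULT) -> PairedComparison:
    """Paired location test on matched per-cell values.

    NaN pairs (cells undefined in either condition) are dropped. The
    Shapiro-Wilk gate runs on the paired differences: paired t test if they
    look normal, Wilcoxon signed-rank otherwise.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("paired samples must have equal length")
    keep = np.isfinite(a) & np.isfinite(b)
    a, b = a[keep], b[keep]
    d = a - b
    if d.size < 3 or np.ptp(d) == 0:
        logger.warning("paired comparison degenerate (n=%d)", d.size)
        return PairedComparison(float("nan"), 1.0, "nonparametric",
                                "degenerate", int(d.size), float(np.mean(d)) if d.size else float("nan"))
    family = normality_gate([d], alpha=alpha)
    if family == "parametric":
        res = sps.ttest_rel(a, b)
        name = "paired t"
    else:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = sps.wilcoxon(a, b, zero_method="wilcox")
        name = "Wilcoxon signed-rank"
    return PairedComparison(float(res.statistic), float(res.pvalue), family,
                            name, int(d.size), float(np.mean(d)))


@dataclass
class PairwiseResult:
    group_a: str
    group_b: str
    statistic: float
    p_value: float
    p_corrected: float
    test_name: str


@dataclass
class ComparisonResult:
    """Omnibus + pairwise comparison of >= 2 groups for one metric."""

    family: str
    omnibus_test: str
    omnibus_statistic: float
    omnibus_p: float
    pairwise: list[PairwiseResult] = field(default_factory=list)
    alpha: float = ALPHA_DEFAULT
    posthoc: str = "none"

    @property
    def significant(self) -> bool:
        return self.omnibus_p < self.alpha


def compare_groups(samples: dict[str, np.ndarray],
                   family: str | None = None,
                   alpha: float = ALPHA_DEFAULT,
                   posthoc: str = "none") -> ComparisonResult:
    """Gated omnibus and pairwise comparison of labelled groups.

    With ``family=None`` the Shapiro-Wilk gate picks the family. Three or
    more groups get a one-way ANOVA or Kruskal-Wallis omnibus followed by
    all pairwise t / Mann-Whitney tests; two groups get the pairwise test
    directly (reported as the omnibus as well). ``posthoc="bonferroni"``
    multiplies pairwise p values by the number of comparisons.
    """
    if len(samples) < 2:
        raise ValueError("need at least two groups")
    clean = {k: np.asarray(v, dtype=float)[np.isfinite(np.asarray(v, dtype=float))]
             for k, v in samples.items()}
    if family is None:
        family = normality_gate(clean, alpha=alpha)
    if family not in ("parametric", "nonparametric"):
        raise ValueError(f"unknown family {family!r}")
    arrays = list(clean.values())

    if family == "parametric":
        omni_name, pair_name = "one-way ANOVA", "t test"
        omni = sps.f_oneway(*arrays)
        def pair_test(x, y):
            return sps.ttest_ind(x, y)
    else:
        omni_name, pair_name = "Kruskal-Wallis", "Mann-Whitney U"
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            omni = sps.kruskal(*arrays)
        def pair_test(x, y):
            return sps.mannwhitneyu(x, y, alternative="two-sided")

    combos = list(itertools.combinations(clean.keys(), 2))
    m = len(combos)
    pairwise = []
    for ka, kb in combos:
        try:
            res = pair_test(clean[ka], clean[kb])
            stat, p = float(res.statistic), float(res.pvalue)
        except ValueError:  # e.g. all-identical inputs
            stat, p = float("nan"), 1.0
        p_corr = min(1.0, p * m) if posthoc == "bonferroni" else p
        pairwise.append(PairwiseResult(ka, kb, stat, p, p_corr, pair_name))

    omni_stat, omni_p = float(omni.statistic), float(omni.pvalue)
    if not np.isfinite(omni_p):   # exact ties across all groups
        omni_stat, omni_p = float("nan"), 1.0
    if len(clean) == 2:
        omni_name = pair_name
        omni_stat, omni_p = pairwise[0].statistic, pairwise[0].p_value
    return ComparisonResult(family=family, omnibus_test=omni_name,
                            omnibus_statistic=omni_stat, omnibus_p=omni_p,
                            pairwise=pairwise, alpha=alpha, posthoc=posthoc)


REPORT_COLUMNS = [
    "metric", "session", "family", "omnibus_test", "omnibus_statistic",
    "omnibus_p", "significant", "group_a", "group_b", "pairwise_test",
    "pairwise_statistic", "pairwise_p", "pairwise_p_corrected",
]


def build_report(comparisons: dict[tuple[str, str], ComparisonResult | None],
                 ) -> pd.DataFrame:
    """Flatten (metric, session) -> comparison results into one table.

    Missing comparisons (value ``None``) are listed with empty test fields
    rather than silently dropped, so the report always documents the full
    metric x session grid it was asked for.
    """
    rows = []
    for (metric, session), comp in comparisons.items():
        if comp is None:
            rows.append({c: "" for c in REPORT_COLUMNS}
                        | {"metric": metric, "session": session,
                           "omnibus_test": "ABSENT"})
            continue
        base = {
            "metric": metric, "session": session, "family": comp.family,
            "omnibus_test": comp.omnibus_test,
            "omnibus_statistic": comp.omnibus_statistic,
            "omnibus_p": comp.omnibus_p, "significant": comp.significant,
        }
        if not comp.pairwise:
            rows.append(base | {"group_a": "", "group_b": "",
                                "pairwise_test": "", "pairwise_statistic": "",
                                "pairwise_p": "", "pairwise_p_corrected": ""})
        for pw in comp.pairwise:
            rows.append(base | {
                "group_a": pw.group_a, "group_b": pw.group_b,
                "pairwise_test": pw.test_name,
                "pairwise_statistic": pw.statistic,
                "pairwise_p": pw.p_value,
                "pairwise_p_corrected": pw.p_corrected,
            })
    return pd.DataFrame(rows, columns=REPORT_COLUMNS)
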