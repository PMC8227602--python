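"""Concordance of electrophoresis-based MSI calls with immunohistochemistry.

IHC reads mismatch-repair protein expression and therefore only separates
MSI-H from MSS — it cannot recognise MSI-L.  Samples the electrophoresis
method calls MSI-L are consequently excluded before computing percent
agreement; the exclusion is method-specific (the marker-count rule and the
MSI-score tiers can call different samples MSI-L).

Also provides per-tier sample counts and a nonparametric comparison of MSI
scores across subgroups (Kruskal-Wallis, with a two-group t-test utility).
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
from scipy import stats

from .classify import SampleResult
from .trace_io import MSI_L, IhcLabel

NCI = "nci"
SCORE = "score"
ALL_GROUPS = "all"


@dataclass(frozen=True)
class ConcordanceReport:
    """Agreement with IHC for one method within one subgroup (or overall)."""

    method: str
    group: str
    n_total: int
    n_excluded_msil: int
    n_evaluated: int
    n_concordant: int
    pct_concordant: int | None  # None when nothing is evaluable

    def __post_init__(self) -> None:
        assert self.n_evaluated == self.n_total - self.n_excluded_msil
        assert self.n_concordant <= self.n_evaluated


def _method_status(result: SampleResult, method: str) -> str:
    if method == NCI:
        return result.nci_status
    if method == SCORE:
        return result.score_status
    raise ValueError(f"method must be {NCI!r} or {SCORE!r}, got {method!r}")


def _match_labels(
    results: Sequence[SampleResult], labels: Mapping[str, IhcLabel]
) -> list[tuple[SampleResult, IhcLabel]]:
    unmatched = [r.sample_id for r in results if r.sample_id not in labels]
    if unmatched:
        raise ValueError(f"no IHC label for sample(s): {unmatched}")
    return [(r, labels[r.sample_id]) for r in results]


def concordance(
    results: Sequence[SampleResult],
    labels: Mapping[str, IhcLabel],
    method: str = NCI,
    group: str | None = None,
) -> ConcordanceReport:
    """Percent agreement between one method's calls and the IHC labels.

    ``group`` restricts to samples whose label carries that subgroup;
    ``None`` pools everything.  Method-called MSI-L samples are excluded
    first; the percentage is rounded to the nearest integer and is ``None``
    when no sample remains evaluable.
    """
    pairs = _match_labels(results, labels)
    if group is not None:
        pairs = [(r, l) for r, l in pairs if l.subgroup == group]
    statuses = [(_method_status(r, method), l.status) for r, l in pairs]
    evaluated = [(c, i) for c, i in statuses if c != MSI_L]
    n_conc = sum(1 for c, i in evaluated if c == i)
    pct = round(100.0 * n_conc / len(evaluated)) if evaluated else None
    return ConcordanceReport(
        method=method,
        group=group if group is not None else ALL_GROUPS,
        n_total=len(statuses),
        n_excluded_msil=len(statuses) - len(evaluated),
        n_evaluated=len(evaluated),
        n_concordant=n_conc,
        pct_concordant=pct,
    )


def concordance_by_group(
    results: Sequence[SampleResult],
    labels: Mapping[str, IhcLabel],
    method: str = NCI,
) -> list[ConcordanceReport]:
    """One report per subgroup present in the labels, plus the pooled total."""
    groups = sorted({l.subgroup for l in labels.values() if l.subgroup is not None})
    reports = [concordance(results, labels, method, g) for g in groups]
    reports.append(concordance(results, labels, method, None))
    return reports


def tier_counts(results: Sequence[SampleResult]) -> dict[str, Counter]:
    """Counts of MSS/MSI-L/MSI-H calls for each classification method."""
    return {
        NCI: Counter(r.nci_status for r in results),
        SCORE: Counter(r.score_status for r in results),
    }


@dataclass(frozen=True)
class GroupScoreTest:
    """Kruskal-Wallis comparison of MSI scores across subgroups."""

    groups: tuple[str, ...]
    n_per_group: tuple[int, ...]
    mean_per_group: tuple[float, ...]
    median_per_group: tuple[float, ...]
    statistic: float
    p_value: float


def group_score_test(
    results: Sequence[SampleResult], labels: Mapping[str, IhcLabel]
) -> GroupScoreTest:
    """Compare MSI scores across subgroups with the Kruskal-Wallis H test.

    Ties receive average ranks; the p-value is the chi-square approximation
    with (k - 1) degrees of freedom.  Per-group mean and median scores are
    reported alongside.
    """
    by_group: dict[str, list[float]] = {}
    for r, l in _match_labels(results, labels):
        if r.msi_score is None:
            continue
        by_group.setdefault(l.subgroup or "unlabelled", []).append(r.msi_score)
    groups = sorted(by_group)
    if len(groups) < 2:
        raise ValueError("need at least two subgroups with scores")
    for g in groups:
        if not by_group[g]:
            raise ValueError(f"subgroup {g!r} has no samples")
    samples = [by_group[g] for g in groups]
    if all(len(set(s)) == 1 for s in samples) and len({s[0] for s in samples}) == 1:
        # scipy raises on all-identical data; the null answer is exact here
        h, p = 0.0, 1.0
    else:
        h, p = stats.kruskal(*samples)
    return GroupScoreTest(
        groups=tuple(groups),
        n_per_group=tuple(len(s) for s in samples),
        mean_per_group=tuple(float(np.mean(s)) for s in samples),
        median_per_group=tuple(float(np.median(s)) for s in samples),
        statistic=float(h),
        p_value=float(p),
    )


def two_group_t_test(scores_a: Sequence[float], scores_b: Sequence[float]) -> tuple[float, float]:
    """Welch t-test on mean MSI score between two groups (utility)."""
    t, p = stats.ttest_ind(list(scores_a), list(scores_b), equal_var=False)
    return float(t), float(p)


def report_frame(reports: Sequence[ConcordanceReport]):
    """Concordance reports as a tidy DataFrame (for TSV/JSON output)."""
    import pandas as pd

    return pd.DataFrame(
        [
            {
                "method": r.method,
                "group": r.group,
                "n_total": r.n_total,
                "n_excluded_msil": r.n_excluded_msil,
                "n_evaluated": r.n_evaluated,
                "n_concordant": r.n_concordant,
                "pct_concordant": r.pct_concordant,
            }
            for r in reports
        ]
    )
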