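"""Group-comparison conventions for per-cell readouts.

Per-cell measurements (class counts, peripheral fractions, Pearson
coefficients) are the statistical unit.  Values are normalized to the
mean of a reference group (young / untreated control), summarized as
mean +/- SEM, and compared with a two-tailed unpaired Student's t-test
(two groups) or one-way ANOVA followed by a multiple-comparisons test
(Tukey HSD by default, Bonferroni optional).  Significance markers
follow the convention *P < 0.05, **P <= 0.01.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "GroupResult",
    "DoseResponseSummary",
    "sem",
    "normalize_to_reference",
    "compare_two_groups",
    "compare_many_groups",
    "significance_marker",
    "significance_letters",
    "summarize_dose_response",
]


def sem(values) -> float:
    """Standard error of the mean: sd(ddof=1) / sqrt(n)."""
    v = np.asarray(values, dtype=float)
    if v.size < 2:
        raise ValueError("SEM needs at least two values")
    return float(v.std(ddof=1) / np.sqrt(v.size))


def normalize_to_reference(
    values_by_group: Mapping[str, Sequence[float]], reference: str
) -> dict[str, np.ndarray]:
    """Divide every value by the reference group's mean.

    The reference group then has normalized mean exactly 1.  Raises if
    the reference group is absent or has zero mean.
    """
    if reference not in values_by_group:
        raise ValueError(f"reference group {reference!r} not present")
    ref_mean = float(np.mean(values_by_group[reference]))
    if ref_mean == 0:
        raise ValueError("reference group mean is zero; cannot normalize")
    return {
        g: np.asarray(v, dtype=float) / ref_mean for g, v in values_by_group.items()
    }


@dataclass
class GroupResult:
    """Summary and test result for one metric across groups."""

    groups: list[str]
    n: dict[str, int]
    mean: dict[str, float]
    sem: dict[str, float]
    normalized_mean: dict[str, float]
    test: str
    statistic: float
    p_value: float
    reference: str
    posthoc: pd.DataFrame | None = None
    letters: dict[str, str] | None = None

    def marker(self) -> str:
        return significance_marker(self.p_value)

    def summary_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "group": self.groups,
                "n": [self.n[g] for g in self.groups],
                "mean": [self.mean[g] for g in self.groups],
                "sem": [self.sem[g] for g in self.groups],
                "normalized_mean": [self.normalized_mean[g] for g in self.groups],
            }
        )


def significance_marker(p: float) -> str:
    """'**' for P <= 0.01, '*' for P < 0.05, else 'ns'."""
    if p <= 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return "ns"


def _summaries(groups: Mapping[str, Sequence[float]], reference: str):
    names = list(groups)
    arrays = {g: np.asarray(v, dtype=float) for g, v in groups.items()}
    norm = normalize_to_reference(arrays, reference)
    return (
        names,
        {g: int(a.size) for g, a in arrays.items()},
        {g: float(a.mean()) for g, a in arrays.items()},
        {g: sem(a) for g, a in arrays.items()},
        {g: float(v.mean()) for g, v in norm.items()},
        arrays,
    )


def compare_two_groups(
    a: Sequence[float],
    b: Sequence[float],
    labels: tuple[str, str] = ("control", "treated"),
    reference: str | None = None,
    equal_var: bool = True,
) -> GroupResult:
    """Two-tailed unpaired Student's t-test between two groups.

    Equal-variance by default (the classical Student form); set
    ``equal_var=False`` for the Welch variant.  Each group needs n >= 2.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each group needs at least two values")
    reference = reference or labels[0]
    names, n, mean, sems, norm, _ = _summaries(
        {labels[0]: a, labels[1]: b}, reference
    )
    res = sps.ttest_ind(a, b, equal_var=equal_var)
    return GroupResult(
        groups=names,
        n=n,
        mean=mean,
        sem=sems,
        normalized_mean=norm,
        test="t_test" if equal_var else "welch_t_test",
        statistic=float(res.statistic),
        p_value=float(res.pvalue),
        reference=reference,
    )


def compare_many_groups(
    groups: Mapping[str, Sequence[float]],
    reference: str | None = None,
    posthoc: str = "tukey",
    alpha: float = 0.05,
) -> GroupResult:
    """One-way ANOVA with a multiple-comparisons follow-up.

    ``posthoc`` is ``"tukey"`` (Tukey HSD) or ``"bonferroni"``
    (pairwise t-tests with Bonferroni-adjusted p-values).  Significance
    letters are assigned so groups sharing no letter differ at
    ``alpha`` in the post-hoc test.  Needs >= 2 groups, each n >= 2
    (>= 3 groups is the intended use; 2 groups reduce to F = t^2).
    """
    if len(groups) < 2:
        raise ValueError("need at least two groups")
    arrays = {g: np.asarray(v, dtype=float) for g, v in groups.items()}
    if any(a.size < 2 for a in arrays.values()):
        raise ValueError("each group needs at least two values")
    reference = reference or next(iter(groups))
    names, n, mean, sems, norm, arrays = _summaries(arrays, reference)
    f_res = sps.f_oneway(*arrays.values())

    pairs = list(itertools.combinations(names, 2))
    if posthoc == "tukey":
        t_res = sps.tukey_hsd(*[arrays[g] for g in names])
        pvals = {
            (g1, g2): float(t_res.pvalue[names.index(g1), names.index(g2)])
            for g1, g2 in pairs
        }
    elif posthoc == "bonferroni":
        m = len(pairs)
        pvals = {
            (g1, g2): min(
                1.0, float(sps.ttest_ind(arrays[g1], arrays[g2]).pvalue) * m
            )
            for g1, g2 in pairs
        }
    else:
        raise ValueError(f"unknown posthoc {posthoc!r}")
    posthoc_df = pd.DataFrame(
        {
            "group1": [p[0] for p in pairs],
            "group2": [p[1] for p in pairs],
            "p_adj": [pvals[p] for p in pairs],
            "reject": [pvals[p] < alpha for p in pairs],
        }
    )
    letters = significance_letters(names, pvals, alpha=alpha)
    return GroupResult(
        groups=names,
        n=n,
        mean=mean,
        sem=sems,
        normalized_mean=norm,
        test="anova",
        statistic=float(f_res.statistic),
        p_value=float(f_res.pvalue),
        reference=reference,
        posthoc=posthoc_df,
        letters=letters,
    )


def significance_letters(
    names: Sequence[str],
    pairwise_p: Mapping[tuple[str, str], float],
    alpha: float = 0.05,
) -> dict[str, str]:
    """Compact letter display from pairwise p-values.

    Groups sharing a letter are not significantly different.  Greedy
    assignment: each group joins every existing letter whose members it
    does not differ from; otherwise it starts a new letter.
    """

    def differs(g1: str, g2: str) -> bool:
        p = pairwise_p.get((g1, g2), pairwise_p.get((g2, g1), 1.0))
        return p < alpha

    letter_sets: list[set[str]] = []
    for g in names:
        placed = False
        for s in letter_sets:
            if all(not differs(g, other) for other in s):
                s.add(g)
                placed = True
        if not placed:
            letter_sets.append({g})
    alphabet = "abcdefghijklmnopqrstuvwxyz"
    out = {g: "" for g in names}
    for letter, s in zip(alphabet, letter_sets):
        for g in names:
            if g in s:
                out[g] += letter
    return out


@dataclass
class DoseResponseSummary:
    """Per-dose summaries with explicit exclusions.

    Doses whose viability falls below ``viability_min`` are excluded
    from statistics with a recorded reason (toxicity), mirroring how a
    dose-response trial drops a lethal top dose rather than analysing
    it.
    """

    doses: list[float]
    mean_area: dict[float, float]
    mean_count: dict[float, float]
    viability: dict[float, float]
    excluded: dict[float, str] = field(default_factory=dict)
    anova: GroupResult | None = None


def summarize_dose_response(
    per_cell: pd.DataFrame,
    viability: Mapping[float, float],
    metric: str = "mean_area_um2",
    viability_min: float = 0.5,
    reference_dose: float = 0.0,
) -> DoseResponseSummary:
    """Summarize a dose-response trial from per-cell measurements.

    ``per_cell`` needs columns ``dose``, ``mean_area_um2`` and
    ``n_puncta`` (one row per cell).  Viability is a fraction in [0, 1]
    per dose; doses below ``viability_min`` are excluded from the ANOVA
    with a reason string.
    """
    for v in viability.values():
        if not 0 <= v <= 1:
            raise ValueError("viability must lie in [0, 1]")
    doses = sorted(per_cell["dose"].unique())
    mean_area = {
        d: float(per_cell.loc[per_cell["dose"] == d, "mean_area_um2"].mean())
        for d in doses
    }
    mean_count = {
        d: float(per_cell.loc[per_cell["dose"] == d, "n_puncta"].mean())
        for d in doses
    }
    excluded = {
        d: f"viability {viability[d]:.0%} below {viability_min:.0%} (toxicity)"
        for d in doses
        if viability.get(d, 1.0) < viability_min
    }
    kept = [d for d in doses if d not in excluded]
    anova = None
    if len(kept) >= 3:
        groups = {
            f"{float(d):g}": per_cell.loc[per_cell["dose"] == d, metric].to_numpy()
            for d in kept
        }
        anova = compare_many_groups(groups, reference=f"{float(reference_dose):g}")
    return DoseResponseSummary(
        doses=list(doses),
        mean_area=mean_area,
        mean_count=mean_count,
        viability={d: float(viability.get(d, np.nan)) for d in doses},
        excluded=excluded,
        anova=anova,
    )
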