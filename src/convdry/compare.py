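"""Treatment comparison: percent change, one-way ANOVA, and Tukey HSD with
a compact letter display.

Dried-product quality properties (fiber fractions, techno-functional
attributes, bioactive contents) are measured in replicate per treatment
(drying temperature or freeze-dried control).  Differences among treatment
means are screened by one-way ANOVA and resolved pairwise by Tukey's
honestly-significant-difference test at level alpha; the outcome is
summarized as a compact letter display in which treatments sharing no
letter differ significantly, with the highest mean lettered "a".

Unequal group sizes are handled by the Tukey–Kramer standard error.
Shapiro–Wilk (per-group normality) and Levene (variance homogeneity)
screens are attached as advisory flags only — they do not gate the
analysis.
"""

from __future__ import annotations

import itertools
import string
from dataclasses import dataclass
from typing import Dict, List, Mapping, Sequence, Tuple

import numpy as np
from scipy import stats

from .errors import DegenerateSeriesError, InvalidInputError

__all__ = [
    "GroupTable",
    "AnovaResult",
    "TukeyOutcome",
    "percent_change",
    "pooled_mean",
    "anova_oneway",
    "tukey_letters",
]


@dataclass(frozen=True)
class GroupTable:
    """Replicate measurements of one property across treatments."""

    groups: Dict[str, np.ndarray]  # treatment label -> replicate values
    property_name: str = ""
    units: str = ""

    def __post_init__(self) -> None:
        if len(self.groups) < 2:
            raise InvalidInputError("need at least 2 treatments")
        clean = {}
        for label, values in self.groups.items():
            arr = np.asarray(values, dtype=float)
            if arr.ndim != 1 or len(arr) < 2:
                raise InvalidInputError(
                    f"treatment {label!r} needs >= 2 replicate values"
                )
            if not np.all(np.isfinite(arr)):
                raise InvalidInputError(f"treatment {label!r} has non-finite values")
            clean[str(label)] = arr
        object.__setattr__(self, "groups", clean)

    @property
    def labels(self) -> List[str]:
        return list(self.groups)

    def means(self) -> Dict[str, float]:
        return {k: float(v.mean()) for k, v in self.groups.items()}


@dataclass(frozen=True)
class AnovaResult:
    f_statistic: float
    p_value: float
    df_between: int
    df_within: int
    ms_within: float
    shapiro_p: Dict[str, float]   # advisory per-group normality screen
    levene_p: float               # advisory homogeneity screen


@dataclass(frozen=True)
class TukeyOutcome:
    """Pairwise Tukey HSD results plus the compact letter display."""

    alpha: float
    mean_diffs: Dict[Tuple[str, str], float]
    critical_ranges: Dict[Tuple[str, str], float]
    significant: Dict[Tuple[str, str], bool]
    letters: Dict[str, str]       # treatment -> letter string, "a" = highest mean
    q_critical: float


def percent_change(reference: float, observed: float) -> float:
    """Signed percent change of ``observed`` relative to ``reference``.

    100·(observed − reference)/reference.  Round to 2 decimals when
    reporting.
    """
    if reference == 0:
        raise InvalidInputError("reference value must be non-zero")
    return 100.0 * (observed - reference) / reference


def pooled_mean(table: GroupTable, labels: Sequence[str]) -> float:
    """Mean of the selected treatments' group means (equal treatment weight).

    Used for cross-temperature summaries such as a property averaged over
    a temperature band before a percent-change comparison.
    """
    missing = [l for l in labels if l not in table.groups]
    if missing:
        raise InvalidInputError(f"unknown treatments {missing}")
    return float(np.mean([table.groups[l].mean() for l in labels]))


def _sums_of_squares(table: GroupTable):
    all_values = np.concatenate(list(table.groups.values()))
    grand = all_values.mean()
    ss_between = sum(
        len(v) * (v.mean() - grand) ** 2 for v in table.groups.values()
    )
    ss_within = sum(float(np.sum((v - v.mean()) ** 2)) for v in table.groups.values())
    df_between = len(table.groups) - 1
    df_within = len(all_values) - len(table.groups)
    return ss_between, ss_within, df_between, df_within


def anova_oneway(table: GroupTable) -> AnovaResult:
    """Classical one-way ANOVA via the textbook sums-of-squares decomposition.

    Raises
    ------
    DegenerateSeriesError
        If every group has zero within-group variance (F undefined).
    """
    ss_b, ss_w, df_b, df_w = _sums_of_squares(table)
    if ss_w == 0.0:
        raise DegenerateSeriesError(
            "zero within-group variance in every treatment; ANOVA undefined"
        )
    ms_b = ss_b / df_b
    ms_w = ss_w / df_w
    f_stat = ms_b / ms_w
    p = float(stats.f.sf(f_stat, df_b, df_w))
    shapiro = {}
    for label, v in table.groups.items():
        # Shapiro needs n >= 3 and some spread
        if len(v) >= 3 and np.ptp(v) > 0:
            shapiro[label] = float(stats.shapiro(v).pvalue)
        else:
            shapiro[label] = float("nan")
    try:
        levene_p = float(stats.levene(*table.groups.values()).pvalue)
    except Exception:
        levene_p = float("nan")
    return AnovaResult(
        f_statistic=float(f_stat),
        p_value=p,
        df_between=df_b,
        df_within=df_w,
        ms_within=float(ms_w),
        shapiro_p=shapiro,
        levene_p=levene_p,
    )


def _compact_letters(
    labels_desc: List[str], significant: Mapping[Tuple[str, str], bool]
) -> Dict[str, str]:
    """Insert-and-absorb compact letter display.

    ``labels_desc`` must be ordered by descending group mean so the first
    letter ("a") attaches to the highest mean.
    """
    letter_sets: List[set] = [set(labels_desc)]
    for pair, sig in significant.items():
        if not sig:
            continue
        i, j = pair
        for s in [s for s in letter_sets if i in s and j in s]:
            letter_sets.remove(s)
            letter_sets.append(s - {i})
            letter_sets.append(s - {j})
        # absorb: drop any set contained in another
        letter_sets = [
            s for s in letter_sets
            if s and not any(s < other for other in letter_sets)
        ]
    # order letters by the rank of their best (highest-mean) member
    rank = {label: idx for idx, label in enumerate(labels_desc)}
    letter_sets.sort(key=lambda s: (min(rank[l] for l in s), -len(s)))
    alphabet = string.ascii_lowercase
    letters: Dict[str, List[str]] = {label: [] for label in labels_desc}
    for pos, s in enumerate(letter_sets):
        char = alphabet[pos] if pos < 26 else f"z{pos}"
        for label in labels_desc:
            if label in s:
                letters[label].append(char)
    return {label: "".join(chars) for label, chars in letters.items()}


def tukey_letters(table: GroupTable, alpha: float = 0.05) -> TukeyOutcome:
    """Tukey HSD pairwise comparisons with a compact letter display.

    Pair (i, j) is significant when |mean_i − mean_j| exceeds the critical
    range q(1−alpha; k, df_w)·√(MS_w/2·(1/n_i + 1/n_j)) (Tukey–Kramer form,
    which reduces to q·√(MS_w/n) for balanced groups).
    """
    if not 0.0 < alpha < 1.0:
        raise InvalidInputError("alpha must lie in (0, 1)")
    anova = anova_oneway(table)
    k = len(table.groups)
    q_crit = float(stats.studentized_range.ppf(1.0 - alpha, k, anova.df_within))
    means = table.means()
    labels_desc = sorted(means, key=means.get, reverse=True)

    mean_diffs: Dict[Tuple[str, str], float] = {}
    crit: Dict[Tuple[str, str], float] = {}
    sig: Dict[Tuple[str, str], bool] = {}
    for i, j in itertools.combinations(labels_desc, 2):
        ni, nj = len(table.groups[i]), len(table.groups[j])
        se = np.sqrt(anova.ms_within / 2.0 * (1.0 / ni + 1.0 / nj))
        diff = means[i] - means[j]
        mean_diffs[(i, j)] = float(diff)
        crit[(i, j)] = float(q_crit * se)
        sig[(i, j)] = abs(diff) > q_crit * se

    letters = _compact_letters(labels_desc, sig)
    return TukeyOutcome(
        alpha=alpha,
        mean_diffs=mean_diffs,
        critical_ranges=crit,
        significant=sig,
        letters=letters,
        q_critical=q_crit,
    )
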