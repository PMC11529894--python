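"""Population-level group statistics: Kruskal–Wallis, pairwise rank-sum
post hoc tests with Holm adjustment, and compact letter displays."""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, List, Sequence, Tuple

import numpy as np
from scipy import stats as sps

__all__ = [
    "GroupComparison",
    "compare_groups",
    "assign_group_letters",
    "verify_letter_axioms",
    "holm_adjust",
]

NAN = float("nan")


@dataclass
class GroupComparison:
    statistic_name: str
    h: float
    df: int
    p: float
    groups: List[str]
    pairwise_p: Dict[Tuple[str, str], float]
    letters: Dict[str, str]
    alpha: float


def holm_adjust(p_values: Sequence[float]) -> List[float]:
    """Holm step-down adjustment (monotone, clipped at 1)."""
    m = len(p_values)
    order = np.argsort(p_values)
    adjusted = [0.0] * m
    running = 0.0
    for rank, idx in enumerate(order):
        value = min(1.0, (m - rank) * p_values[idx])
        running = max(running, value)
        adjusted[idx] = running
    return adjusted


def compare_groups(
    values: Dict[str, Sequence[float]],
    statistic_name: str = "statistic",
    alpha: float = 0.05,
) -> GroupComparison:
    """Kruskal–Wallis H (tie-corrected) plus Holm-adjusted pairwise
    two-sided rank-sum post hoc tests and a compact letter display.

    NA values are dropped per group; a group left empty (or with fewer than
    two values) is an error naming the group.
    """
    if len(values) < 2:
        raise ValueError("need at least two groups")
    cleaned: Dict[str, np.ndarray] = {}
    for name, series in values.items():
        arr = np.asarray(list(series), dtype=float)
        arr = arr[~np.isnan(arr)]
        if arr.size < 2:
            raise ValueError(f"group {name!r} has fewer than 2 non-NA values")
        cleaned[name] = arr
    names = sorted(cleaned)
    h, p = sps.kruskal(*(cleaned[n] for n in names))
    pairs = [(a, b) for i, a in enumerate(names) for b in names[i + 1:]]
    raw = [
        sps.mannwhitneyu(cleaned[a], cleaned[b], alternative="two-sided").pvalue
        for a, b in pairs
    ]
    adjusted = holm_adjust(raw)
    pairwise = {pair: adj for pair, adj in zip(pairs, adjusted)}
    k = len(names)
    significant = np.zeros((k, k), dtype=bool)
    for (a, b), adj in pairwise.items():
        i, j = names.index(a), names.index(b)
        significant[i, j] = significant[j, i] = adj < alpha
    letters = assign_group_letters(significant)
    return GroupComparison(
        statistic_name=statistic_name,
        h=float(h),
        df=k - 1,
        p=float(p),
        groups=names,
        pairwise_p=pairwise,
        letters={name: letters[i] for i, name in enumerate(names)},
        alpha=alpha,
    )


def assign_group_letters(significant: np.ndarray) -> List[str]:
    """Insert-and-absorb compact letter display.

    ``significant[i, j]`` is True when groups i and j differ. Groups that do
    NOT differ share at least one letter; groups that differ share none.
    """
    significant = np.asarray(significant, dtype=bool)
    k = significant.shape[0]
    if significant.shape != (k, k):
        raise ValueError("significance matrix must be square")
    if not np.array_equal(significant, significant.T):
        raise ValueError("significance matrix must be symmetric")
    if significant.diagonal().any():
        raise ValueError("a group cannot differ from itself")
    # letter classes as sets of group indices; start with one class of all
    classes: List[set] = [set(range(k))]
    for i in range(k):
        for j in range(i + 1, k):
            if not significant[i, j]:
                continue
            for cls in [c for c in classes if i in c and j in c]:
                classes.remove(cls)
                classes.append(cls - {i})
                classes.append(cls - {j})
            # absorb: drop classes contained in another
            classes = [
                c for c in classes
                if c and not any(c < other for other in classes if other is not c)
            ]
    # every non-differing pair must still share a class; add singletons for
    # groups that lost all letters
    for i in range(k):
        if not any(i in c for c in classes):
            classes.append({i})
    classes.sort(key=lambda c: (min(c), -len(c)))
    alphabet = "abcdefghijklmnopqrstuvwxyz"
    letters = ["" for _ in range(k)]
    for li, cls in enumerate(classes):
        symbol = alphabet[li] if li < len(alphabet) else f"<{li}>"
        for i in sorted(cls):
            letters[i] += symbol
    return letters


def verify_letter_axioms(significant: np.ndarray, letters: Sequence[str]) -> bool:
    """Exhaustively check both CLD axioms for an emitted lettering."""
    k = len(letters)
    for i in range(k):
        if not letters[i]:
            return False
        for j in range(i + 1, k):
            shared = set(letters[i]) & set(letters[j])
            if significant[i][j] and shared:
                return False
            if not significant[i][j] and not shared:
                return False
    return True
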