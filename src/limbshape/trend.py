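"""Ancestor-descendant change extraction and the 50:50 change-frequency test.

Given ancestral character estimates on a time tree, every node of a named
clade contributes one change: its value minus its parent's value (the
clade's basal node is compared against its parent in the full tree when one
exists).  Counting strictly positive against strictly negative changes and
testing the counts against a 50:50 null with a chi-square goodness-of-fit
statistic is the classical change-frequency test for a directional
(Cope's-rule-like) trend.
"""

from __future__ import annotations

import dataclasses

import numpy as np
from scipy import stats

from .trees import TimeTree, TreeError, _subtree_tips
from .comparative import AncestralStates


class TrendError(ValueError):
    pass


@dataclasses.dataclass
class ChangeSummary:
    """Per-clade change statistics with the 50:50 chi-square test.

    ``n`` counts clade nodes (internal + tips) even when the number of
    strictly directional changes is smaller; ``mean`` is sum / n for
    consistency with that convention.
    """

    clade: str
    mean: float
    sum: float
    median: float
    skew: float
    n: int
    positive_changes: int
    negative_changes: int
    chi2: float | None = None
    p: float | None = None


def branch_changes(tree: TimeTree, states: AncestralStates,
                   clade) -> list[float]:
    """One ancestor-descendant change per clade member node.

    ``clade`` is an annotated clade name, a tip-label set, or a node.
    Every node of the clade (its basal node included) is compared against
    its parent; the basal node's parent lies outside the clade and is used
    when it exists (i.e. unless the clade is the whole tree).
    """
    if isinstance(clade, str):
        node = tree.clade_node(clade)
    elif isinstance(clade, (set, frozenset)):
        node = tree.mrca(clade)
    else:
        node = clade
    changes = []
    stack = [node]
    while stack:
        cur = stack.pop()
        if cur.parent is not None:
            changes.append(states.estimates[cur.id]
                           - states.estimates[cur.parent.id])
        stack.extend(cur.children)
    return changes


def clade_node_count(tree: TimeTree, clade) -> int:
    """Number of clade nodes, internal nodes plus tips, basal node included."""
    if isinstance(clade, str):
        node = tree.clade_node(clade)
    elif isinstance(clade, (set, frozenset)):
        node = tree.mrca(clade)
    else:
        node = clade
    count = 0
    stack = [node]
    while stack:
        cur = stack.pop()
        count += 1
        stack.extend(cur.children)
    return count


def summarize_changes(changes, clade: str = "", n: int | None = None,
                      test: bool = True) -> ChangeSummary:
    """Mean, sum, median, skewness and directional counts of a change list.

    Exactly-zero changes are excluded from the positive/negative counts and
    from the chi-square test (they are non-directional); ``n`` defaults to
    the number of changes.
    """
    ch = np.asarray(list(changes), float)
    if ch.size == 0:
        raise TrendError("empty change list")
    n = int(n) if n is not None else ch.size
    pos = int(np.sum(ch > 0))
    neg = int(np.sum(ch < 0))
    skew = float(stats.skew(ch, bias=True)) if ch.size > 2 else 0.0
    chi2 = p = None
    if test and pos + neg > 0:
        chi2, p = chi2_5050(pos, neg)
    return ChangeSummary(
        clade=clade, mean=float(ch.sum() / n), sum=float(ch.sum()),
        median=float(np.median(ch)), skew=skew, n=n,
        positive_changes=pos, negative_changes=neg, chi2=chi2, p=p)


def chi2_5050(positive: int, negative: int) -> tuple[float, float]:
    """Chi-square goodness of fit of directional change counts to 50:50.

    With m = positive + negative and expected m/2 in each direction,
    chi^2 = (positive - negative)^2 / m on 1 df, no continuity correction.
    """
    m = positive + negative
    if m == 0:
        raise TrendError("no directional changes")
    chi2 = (positive - negative) ** 2 / m
    return float(chi2), float(stats.chi2.sf(chi2, 1))


def clade_change_summary(tree: TimeTree, states: AncestralStates,
                         clade_name: str) -> ChangeSummary:
    """Changes, summary statistics and 50:50 test for one annotated clade."""
    changes = branch_changes(tree, states, clade_name)
    n = clade_node_count(tree, clade_name)
    return summarize_changes(changes, clade=clade_name, n=n)
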