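"""Composite susceptibility/resistance score and its classification.

The score for a group is

    S = 1 / mean(−log10 p_i)

over the slope p-values of the measured dose responses (by default IL-4,
IL-13, CCL7 and CCL11).  Strong dose responses give small p-values, a large
mean −log10 p, and hence a *small* score: lower S = more susceptible.  The
classification cutoff is the score a group would get if every response sat
exactly at the significance threshold alpha:

    cutoff = 1 / (−log10 alpha)        (0.77 at alpha = 0.05, to 2 d.p.)

Groups below the cutoff are labelled susceptible, groups above it resistant.
A one-dimensional Euclidean agglomerative clustering of the group scores
summarizes which groups behave alike.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Iterable, Literal, Sequence

import numpy as np
from scipy.cluster import hierarchy

from .dose_response import SlopeFit
from .exceptions import InputValidationError, MissingDataError

__all__ = [
    "DEFAULT_ANALYTES",
    "IFNG",
    "CLAMP_FLOOR",
    "ScoreResult",
    "Dendrogram",
    "composite_score",
    "classification_cutoff",
    "classify",
    "score_groups",
    "cluster_scores",
]

logger = logging.getLogger(__name__)

#: Analytes entering the default score (IFN-gamma is available behind a flag;
#: its inclusion only shrinks the separation between groups).
DEFAULT_ANALYTES: tuple[str, ...] = ("IL-4", "IL-13", "CCL7", "CCL11")
IFNG = "IFN-g"

#: p-values are clamped into [CLAMP_FLOOR, 1] so that an exact-fit p = 0
#: yields a finite (tiny) score instead of a division by infinity.
CLAMP_FLOOR = 1e-300

Label = Literal["susceptible", "resistant"]


@dataclass(frozen=True)
class ScoreResult:
    """Composite score and classification for one group."""

    group: str
    analytes_used: tuple[str, ...]
    p_values: tuple[float, ...]
    score: float
    alpha: float
    cutoff: float
    label: Label


def composite_score(p_values: Iterable[float], clamp_floor: float = CLAMP_FLOOR) -> float:
    """1 / mean(−log10 p) over the supplied slope p-values.

    p-values are clamped into ``[clamp_floor, 1]`` (an exact-fit p of 0 maps
    to the floor, i.e. maximal susceptibility).  If every p equals 1 the mean
    log is 0 and ``+inf`` is returned — an unambiguous "resistant" sentinel.
    """
    ps = [float(p) for p in p_values]
    if not ps:
        raise InputValidationError("composite_score needs at least one p-value")
    for p in ps:
        if math.isnan(p) or p < 0 or p > 1:
            raise InputValidationError(f"p-value {p!r} outside [0, 1]")
    neglogs = [-math.log10(min(max(p, clamp_floor), 1.0)) for p in ps]
    if all(v == neglogs[0] for v in neglogs):
        # exact replication invariance: score({p,...,p}) == score({p}) without
        # the rounding that sum/len would introduce at the alpha boundary
        mean = neglogs[0]
    else:
        mean = sum(neglogs) / len(neglogs)
    if mean == 0.0:
        return math.inf
    return 1.0 / mean


def classification_cutoff(alpha: float = 0.05) -> float:
    """Score value separating susceptible from resistant: 1/(−log10 alpha)."""
    alpha = float(alpha)
    if not 0.0 < alpha < 1.0:
        raise InputValidationError(f"alpha must lie in (0, 1), got {alpha!r}")
    return 1.0 / (-math.log10(alpha))


def classify(score: float, cutoff: float) -> Label:
    """"susceptible" below the cutoff, "resistant" at or above it.

    Equality is resolved to resistant (the conservative, non-disease call;
    the boundary score corresponds to every p sitting exactly at alpha).
    """
    if math.isnan(score) or score < 0:
        raise InputValidationError(f"score must be a non-negative number, got {score!r}")
    if not cutoff > 0:
        raise InputValidationError(f"cutoff must be positive, got {cutoff!r}")
    return "susceptible" if score < cutoff else "resistant"


def score_groups(
    fits: Iterable[SlopeFit],
    analytes: Sequence[str] = DEFAULT_ANALYTES,
    alpha: float = 0.05,
    include_ifng: bool = False,
    clamp_floor: float = CLAMP_FLOOR,
) -> list[ScoreResult]:
    """One :class:`ScoreResult` per group from its per-analyte slope fits.

    Exactly the requested ``analytes`` are used (append IFN-gamma via
    ``include_ifng``); a group missing any of them raises
    :class:`MissingDataError`.  Results are ordered by group name.
    """
    analytes = tuple(analytes)
    if include_ifng and IFNG not in analytes:
        analytes = analytes + (IFNG,)
    if not analytes:
        raise InputValidationError("analytes must be non-empty")
    cutoff = classification_cutoff(alpha)
    by_group: dict[str, dict[str, SlopeFit]] = {}
    for f in fits:
        by_group.setdefault(f.group, {})[f.analyte] = f
    results = []
    for group in sorted(by_group):
        cell = by_group[group]
        missing = [a for a in analytes if a not in cell]
        if missing:
            raise MissingDataError(f"group {group!r} has no slope fit for {', '.join(missing)}")
        ps = tuple(cell[a].p_value for a in analytes)
        s = composite_score(ps, clamp_floor=clamp_floor)
        results.append(
            ScoreResult(
                group=group,
                analytes_used=analytes,
                p_values=ps,
                score=s,
                alpha=alpha,
                cutoff=cutoff,
                label=classify(s, cutoff),
            )
        )
    return results


@dataclass(frozen=True)
class Dendrogram:
    """Agglomerative hierarchy over group scores.

    ``linkage_matrix`` is in scipy's standard (n−1) x 4 format; ``heights``
    are the merge distances.  ``scores`` are the (sentinel-replaced) values
    actually clustered, in ``labels`` order.
    """

    labels: tuple[str, ...]
    scores: tuple[float, ...]
    linkage_matrix: np.ndarray = field(repr=False)
    method: str = "average"

    @property
    def heights(self) -> tuple[float, ...]:
        return tuple(float(h) for h in self.linkage_matrix[:, 2])

    def merge_order(self) -> list[tuple[frozenset[str], frozenset[str], float]]:
        """The two leaf-sets united at each merge, with the merge height."""
        n = len(self.labels)
        clusters: dict[int, frozenset[str]] = {i: frozenset([lab]) for i, lab in enumerate(self.labels)}
        merges = []
        for step, (i, j, h, _) in enumerate(self.linkage_matrix):
            a, b = clusters[int(i)], clusters[int(j)]
            merges.append((a, b, float(h)))
            clusters[n + step] = a | b
        return merges

    def to_newick(self) -> str:
        """Serialize as a rooted Newick tree, branch lengths = height differences."""
        tree = hierarchy.to_tree(self.linkage_matrix)

        def render(node, parent_height: float) -> str:
            length = parent_height - node.dist
            if node.is_leaf():
                label = self.labels[node.id].replace(" ", "_").replace(",", "").replace("(", "").replace(")", "").replace(":", "").replace(";", "")
                return f"{label}:{length:.10g}"
            inner = ",".join(render(c, node.dist) for c in (node.left, node.right))
            return f"({inner}):{length:.10g}"

        root_children = ",".join(render(c, tree.dist) for c in (tree.left, tree.right))
        return f"({root_children});"


def cluster_scores(
    results: Iterable[ScoreResult] | dict[str, float],
    linkage: str = "average",
) -> Dendrogram:
    """Euclidean agglomerative clustering of the (scalar) group scores.

    An infinite score (the all-p=1 sentinel) is replaced by the maximum
    finite score plus 1 so the geometry stays well defined; the replacement
    is logged.  UPGMA (average) linkage is the default; on scalar inputs the
    topology is insensitive to the linkage for well separated scores.
    """
    if isinstance(results, dict):
        items = list(results.items())
    else:
        items = [(r.group, r.score) for r in results]
    if len(items) < 2:
        raise InputValidationError("clustering needs at least 2 groups")
    labels = tuple(name for name, _ in items)
    scores = [float(s) for _, s in items]
    finite = [s for s in scores if math.isfinite(s)]
    if len(finite) < len(scores):
        replacement = (max(finite) if finite else 0.0) + 1.0
        logger.warning(
            "replacing %d infinite score(s) with %.6g for clustering",
            len(scores) - len(finite),
            replacement,
        )
        scores = [s if math.isfinite(s) else replacement for s in scores]
    Z = hierarchy.linkage(np.asarray(scores, dtype=float).reshape(-1, 1), method=linkage, metric="euclidean")
    return Dendrogram(labels=labels, scores=tuple(scores), linkage_matrix=Z, method=linkage)
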