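"""Scoring predicted complex catalogs against a reference.

Matching uses the overlapping score OS(P, K) = |P & K|^2 / (|P| * |K|); a
predicted complex matches a known one when OS >= 0.2 (OS = 1 exactly when
the sets are identical — a "perfect" match).  Sensitivity, specificity and
F-measure follow the usual complex-detection convention: TP counts matched
predictions, FN unmatched known complexes, FP unmatched predictions.
Functional enrichment of a complex is the hypergeometric tail probability of
drawing at least k members of a functional group of size F in |C| draws from
a network of N proteins; complexes with p < 0.01 are conventionally called
significant.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

from scipy.stats import hypergeom

logger = logging.getLogger(__name__)

MATCH_OS_THRESHOLD = 0.2
SIGNIFICANCE_LEVEL = 0.01

__all__ = [
    "MATCH_OS_THRESHOLD",
    "SIGNIFICANCE_LEVEL",
    "MatchResult",
    "EnrichmentQuery",
    "overlapping_score",
    "match_catalogs",
    "hypergeom_pvalue",
    "enrich_complex",
]


@dataclass
class MatchResult:
    """Catalog-level match counts and derived scores.

    pc/mpc/mkc/perfect: predicted, matched-predicted, matched-known and
    perfectly matched complex counts.
    """

    tp: int
    fn: int
    fp: int
    sn: float
    sp: float
    f_measure: float
    pc: int
    mpc: int
    mkc: int
    perfect: int


@dataclass(frozen=True)
class EnrichmentQuery:
    """One hypergeometric enrichment question.

    k: group members inside the complex; n_total: network size; c_size:
    complex size; f_size: functional-group size.
    """

    k: int
    n_total: int
    c_size: int
    f_size: int

    def __post_init__(self) -> None:
        ok = (
            0 <= self.k <= min(self.c_size, self.f_size)
            and self.f_size <= self.n_total
            and 0 < self.c_size <= self.n_total
        )
        if not ok:
            raise ValueError(f"combinatorially invalid enrichment query: {self}")


def overlapping_score(p: frozenset | set, k: frozenset | set) -> float:
    """|P & K|^2 / (|P| * |K|); symmetric, 1 iff identical, 0 iff disjoint."""
    if not p or not k:
        raise ValueError("overlapping_score: empty protein set")
    inter = len(p & k)
    return inter * inter / (len(p) * len(k))


def _safe_ratio(num: int, den: int, label: str) -> float:
    if den == 0:
        logger.warning("match_catalogs: %s is 0/0, reported as 0", label)
        return 0.0
    return num / den


def match_catalogs(predicted, reference, os_threshold: float = MATCH_OS_THRESHOLD) -> MatchResult:
    """Count matches between two catalogs at the given overlap-score cutoff.

    A predicted complex may match several known complexes but counts once in
    TP; likewise each known complex counts once in MKC.
    """
    if not 0.0 < os_threshold <= 1.0:
        raise ValueError("os_threshold must be in (0, 1]")
    pred = list(predicted)
    ref = list(reference)
    tp = 0
    perfect = 0
    matched_ref: set[int] = set()
    for p in pred:
        hit = False
        for j, k in enumerate(ref):
            if overlapping_score(p, k) >= os_threshold:
                hit = True
                matched_ref.add(j)
            if p == k:
                perfect += 1
        if hit:
            tp += 1
    fp = len(pred) - tp
    fn = len(ref) - len(matched_ref)
    sn = _safe_ratio(tp, tp + fn, "sensitivity")
    sp = _safe_ratio(tp, tp + fp, "specificity")
    f = 2.0 * sn * sp / (sn + sp) if (sn + sp) > 0 else 0.0
    return MatchResult(
        tp=tp, fn=fn, fp=fp, sn=sn, sp=sp, f_measure=f,
        pc=len(pred), mpc=tp, mkc=len(matched_ref), perfect=perfect,
    )


def hypergeom_pvalue(query: EnrichmentQuery) -> float:
    """Exact upper-tail probability of >= k group members in the complex.

    p = 1 - sum_{i=0}^{k-1} C(F, i) C(N-F, C-i) / C(N, C); k = 0 gives 1.
    """
    if query.k == 0:
        return 1.0
    p = float(
        hypergeom.sf(query.k - 1, query.n_total, query.f_size, query.c_size)
    )
    return min(max(p, 0.0), 1.0)


def enrich_complex(
    members: frozenset | set,
    groups: dict[str, set[str]],
    n_total: int,
) -> list[tuple[str, int, float]]:
    """Per-group enrichment of one complex: (group, k, p-value), best p first.

    `groups` maps a functional-group label to its protein set; groups with no
    member in the complex are skipped.
    """
    rows = []
    for label in sorted(groups):
        grp = groups[label]
        k = len(members & grp)
        if k == 0:
            continue
        q = EnrichmentQuery(k=k, n_total=n_total, c_size=len(members), f_size=len(grp))
        rows.append((label, k, hypergeom_pvalue(q)))
    rows.sort(key=lambda r: (r[2], r[0]))
    return rows
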