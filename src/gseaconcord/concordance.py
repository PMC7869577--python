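"""Concordance of enriched pathways between two markers.

Given two enrichment result lists over the same gene set collection (one per
proliferation marker), this module partitions significant pathways
(``fdr_q < threshold``, strict) into common and marker-specific groups,
stratifies them by the sign of the enrichment score, and intersects the
leading-edge gene unions of the commonly enriched pathways — within a sample
group and across groups.

"Common" is by pathway name regardless of ES sign; sign agreement over the
common pathways is reported as an auxiliary count, since two markers can
enrich the same pathway from opposite ends of the ranking.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import pandas as pd

from .gsea import EnrichmentResult

__all__ = [
    "ConcordanceReport",
    "LeadingEdgeOverlap",
    "significant_sets",
    "summarize_concordance",
    "leading_edge_overlap",
    "cross_group_overlap",
]


@dataclass
class ConcordanceReport:
    """Common / marker-specific enriched-pathway counts, split by sign.

    Satisfies, by construction, the set identities
    ``n_enriched_x = n_pos_x + n_neg_x``,
    ``n_specific_a = n_enriched_a - n_common`` (and symmetrically for b) and
    ``|A ∪ B| = n_enriched_a + n_enriched_b - n_common``.
    """

    marker_a_name: str
    marker_b_name: str
    n_enriched_a: int
    n_pos_a: int
    n_neg_a: int
    n_enriched_b: int
    n_pos_b: int
    n_neg_b: int
    n_common: int
    n_specific_a: int
    n_specific_b: int
    common_set_names: tuple[str, ...]
    specific_a_names: tuple[str, ...]
    specific_b_names: tuple[str, ...]
    n_common_sign_agree: int
    fdr_threshold: float

    def to_series(self) -> pd.Series:
        d = {
            "marker_a": self.marker_a_name,
            "marker_b": self.marker_b_name,
            "fdr_threshold": self.fdr_threshold,
            "n_enriched_a": self.n_enriched_a,
            "n_pos_a": self.n_pos_a,
            "n_neg_a": self.n_neg_a,
            "n_enriched_b": self.n_enriched_b,
            "n_pos_b": self.n_pos_b,
            "n_neg_b": self.n_neg_b,
            "n_common": self.n_common,
            "n_specific_a": self.n_specific_a,
            "n_specific_b": self.n_specific_b,
            "n_common_sign_agree": self.n_common_sign_agree,
        }
        return pd.Series(d)


@dataclass
class LeadingEdgeOverlap:
    """Leading-edge gene unions over common pathways, per marker."""

    group_name: str
    le_union_a: frozenset[str]
    le_union_b: frozenset[str]

    @property
    def n_intersection(self) -> int:
        return len(self.le_union_a & self.le_union_b)

    @property
    def n_a_only(self) -> int:
        return len(self.le_union_a - self.le_union_b)

    @property
    def n_b_only(self) -> int:
        return len(self.le_union_b - self.le_union_a)

    def to_series(self) -> pd.Series:
        return pd.Series(
            {
                "group": self.group_name,
                "n_union_a": len(self.le_union_a),
                "n_union_b": len(self.le_union_b),
                "n_intersection": self.n_intersection,
                "n_a_only": self.n_a_only,
                "n_b_only": self.n_b_only,
            }
        )


def significant_sets(
    results: Sequence[EnrichmentResult], threshold: float
) -> tuple[list[str], list[str]]:
    """Set names with ``fdr_q < threshold``, partitioned by ES sign.

    Each list is ordered by (q, name) for determinism.
    """
    if not (0 < threshold < 1):
        raise ValueError("threshold must lie in (0, 1)")
    sig = [r for r in results if r.fdr_q < threshold]
    sig.sort(key=lambda r: (r.fdr_q, r.set_name))
    pos = [r.set_name for r in sig if r.es >= 0]
    neg = [r.set_name for r in sig if r.es < 0]
    return pos, neg


def summarize_concordance(
    results_a: Sequence[EnrichmentResult],
    results_b: Sequence[EnrichmentResult],
    threshold: float,
    marker_a_name: str = "marker_a",
    marker_b_name: str = "marker_b",
) -> ConcordanceReport:
    """Compare the significant pathway sets of two markers.

    Both result lists must cover the same gene set collection. Common
    pathways are intersected by name regardless of sign; sign agreement is
    reported separately in ``n_common_sign_agree``.
    """
    names_a = {r.set_name for r in results_a}
    names_b = {r.set_name for r in results_b}
    if names_a != names_b:
        raise ValueError("result lists cover different gene set collections")
    pos_a, neg_a = significant_sets(results_a, threshold)
    pos_b, neg_b = significant_sets(results_b, threshold)
    sig_a = set(pos_a) | set(neg_a)
    sig_b = set(pos_b) | set(neg_b)
    common = sig_a & sig_b
    sign_a = {r.set_name: r.sign for r in results_a}
    sign_b = {r.set_name: r.sign for r in results_b}
    return ConcordanceReport(
        marker_a_name=marker_a_name,
        marker_b_name=marker_b_name,
        n_enriched_a=len(sig_a),
        n_pos_a=len(pos_a),
        n_neg_a=len(neg_a),
        n_enriched_b=len(sig_b),
        n_pos_b=len(pos_b),
        n_neg_b=len(neg_b),
        n_common=len(common),
        n_specific_a=len(sig_a) - len(common),
        n_specific_b=len(sig_b) - len(common),
        common_set_names=tuple(sorted(common)),
        specific_a_names=tuple(sorted(sig_a - common)),
        specific_b_names=tuple(sorted(sig_b - common)),
        n_common_sign_agree=sum(1 for n in common if sign_a[n] == sign_b[n]),
        fdr_threshold=threshold,
    )


def leading_edge_overlap(
    results_a: Sequence[EnrichmentResult],
    results_b: Sequence[EnrichmentResult],
    common_names: Sequence[str],
    group_name: str = "all",
) -> LeadingEdgeOverlap:
    """Union leading-edge genes over common pathways and intersect them.

    For each marker, the leading-edge genes of every commonly enriched
    pathway are pooled into one union set; the report carries the
    intersection and the marker-exclusive counts.
    """
    by_name_a = {r.set_name: r for r in results_a}
    by_name_b = {r.set_name: r for r in results_b}
    union_a: set[str] = set()
    union_b: set[str] = set()
    for name in common_names:
        if name not in by_name_a or name not in by_name_b:
            raise KeyError(f"common pathway {name!r} missing from a result list")
        union_a.update(by_name_a[name].leading_edge)
        union_b.update(by_name_b[name].leading_edge)
    return LeadingEdgeOverlap(
        group_name=group_name,
        le_union_a=frozenset(union_a),
        le_union_b=frozenset(union_b),
    )


def cross_group_overlap(overlaps: Sequence[LeadingEdgeOverlap]) -> pd.DataFrame:
    """Tabulate per-group leading-edge counts and pairwise group overlaps.

    A group's pooled set is the union of its two marker unions. The output
    has one row per group with the within-group counts, plus, for every
    group pair, the size of the intersection of their pooled sets.
    """
    if len(overlaps) < 1:
        raise ValueError("need at least one group")
    names = [o.group_name for o in overlaps]
    if len(set(names)) != len(names):
        raise ValueError(f"duplicate group names: {names}")
    rows = [o.to_series() for o in overlaps]
    table = pd.DataFrame(rows).set_index("group")
    pooled = {o.group_name: o.le_union_a | o.le_union_b for o in overlaps}
    table["n_pooled"] = [len(pooled[g]) for g in table.index]
    for i, gi in enumerate(names):
        for gj in names[i + 1 :]:
            table.loc[gi, f"n_shared_with_{gj}"] = len(pooled[gi] & pooled[gj])
    return table
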