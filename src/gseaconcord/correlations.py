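"""Gene-level concordance of two continuous proliferation markers.

Every gene's expression is correlated with each marker by Spearman's rho
(average ranks for ties), yielding one correlation profile per marker. Genes
are then ranked by correlation *strength* (descending |rho|), and a
rank-shift table over a focal gene set quantifies how differently the two
markers order those genes: ``delta_rank = |rank_a - rank_b|`` and
``delta_rho = |rho_a - rho_b|``.

Signed rho values are retained alongside the strength ranks so callers can
re-rank by their own convention. Genes with constant expression over the
analyzed samples have no defined rank correlation; they are flagged invalid
and excluded from ranking rather than being assigned rho = 0.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .io import ExpressionMatrix, PhenotypeTable

__all__ = [
    "CorrelationProfile",
    "RankShiftTable",
    "marker_correlation",
    "gene_marker_correlations",
    "top_k_genes",
    "rank_shift_table",
]


@dataclass
class CorrelationProfile:
    """Per-gene Spearman correlations with one marker.

    ``table`` is indexed by gene id with columns:

    rho
        Spearman correlation with the marker (NaN when invalid).
    valid
        False for genes whose expression is constant across the analyzed
        samples (correlation undefined).
    strength_rank
        1 = largest |rho| among valid genes; ties broken by gene id.
        <NA> for invalid genes.
    """

    marker_name: str
    table: pd.DataFrame
    n_samples: int

    @property
    def valid_table(self) -> pd.DataFrame:
        return self.table[self.table["valid"]]

    def rho(self, gene: str) -> float:
        return float(self.table.at[gene, "rho"])


@dataclass
class RankShiftTable:
    """Rank shifts of focal genes between two marker profiles.

    ``table`` columns: rank_a, rank_b, rho_a, rho_b, delta_rank, delta_rho;
    sorted by delta_rank descending (ties: delta_rho descending, gene id).
    """

    marker_a: str
    marker_b: str
    table: pd.DataFrame

    @property
    def max_delta_rho(self) -> float:
        return float(self.table["delta_rho"].max())

    @property
    def min_delta_rho(self) -> float:
        return float(self.table["delta_rho"].min())


def _resolve_samples(
    available: Sequence[str], sample_subset: Iterable[str] | None
) -> list[str]:
    if sample_subset is None:
        return list(available)
    subset = set(sample_subset)
    missing = subset - set(available)
    if missing:
        raise KeyError(f"sample_subset contains unknown sample ids: {sorted(missing)}")
    return [s for s in available if s in subset]


def marker_correlation(
    pheno: PhenotypeTable,
    marker_a: str,
    marker_b: str,
    sample_subset: Iterable[str] | None = None,
) -> float:
    """Spearman correlation between two marker columns of the phenotype table.

    Average ranks are used for ties. Requires at least 3 samples after
    subsetting and non-constant columns.
    """
    samples = _resolve_samples(pheno.sample_ids, sample_subset)
    if len(samples) < 3:
        raise ValueError(f"need >= 3 samples for a correlation, got {len(samples)}")
    a = pheno.marker(marker_a).loc[samples].to_numpy(dtype=float)
    b = pheno.marker(marker_b).loc[samples].to_numpy(dtype=float)
    for name, v in ((marker_a, a), (marker_b, b)):
        if np.ptp(v) == 0:
            raise ValueError(f"marker column {name!r} is constant on the selected samples")
    rho = stats.spearmanr(a, b).statistic
    return float(rho)


def _spearman_vectorized(values: np.ndarray, target: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Spearman rho of each row of ``values`` against ``target``.

    Computed as the Pearson correlation of mid-ranks (exact for ties).
    Returns (rho, valid) where constant rows are invalid with rho NaN.
    """
    row_ranks = stats.rankdata(values, axis=1)
    t_rank = stats.rankdata(target)
    rr = row_ranks - row_ranks.mean(axis=1, keepdims=True)
    tr = t_rank - t_rank.mean()
    num = rr @ tr
    den = np.sqrt((rr**2).sum(axis=1) * (tr**2).sum())
    valid = np.ptp(values, axis=1) > 0
    rho = np.full(values.shape[0], np.nan)
    np.divide(num, den, out=rho, where=valid & (den > 0))
    return rho, valid


def gene_marker_correlations(
    expr: ExpressionMatrix,
    pheno: PhenotypeTable,
    marker: str,
    sample_subset: Iterable[str] | None = None,
) -> CorrelationProfile:
    """Per-gene Spearman correlation profile against one marker.

    Samples are the (ordered) intersection of the expression and phenotype
    sample ids, optionally restricted to ``sample_subset``; at least 3
    overlapping samples are required. Constant-expression genes are flagged
    ``valid=False`` and excluded from strength ranking.
    """
    overlap = [s for s in expr.sample_ids if s in set(pheno.sample_ids)]
    samples = _resolve_samples(overlap, sample_subset)
    if len(samples) < 3:
        raise ValueError(
            f"expression and phenotype tables share only {len(samples)} sample(s); need >= 3"
        )
    target = pheno.marker(marker).loc[samples].to_numpy(dtype=float)
    if np.ptp(target) == 0:
        raise ValueError(f"marker column {marker!r} is constant on the selected samples")
    values = expr.data[samples].to_numpy(dtype=float)
    rho, valid = _spearman_vectorized(values, target)

    table = pd.DataFrame(
        {"rho": rho, "valid": valid}, index=pd.Index(expr.gene_ids, name="gene_id")
    )
    # strength rank: descending |rho|, deterministic lexicographic tie-break
    vt = table[table["valid"]]
    order = sorted(vt.index, key=lambda g: (-abs(vt.at[g, "rho"]), g))
    ranks = pd.Series(np.arange(1, len(order) + 1), index=order, dtype="Int64")
    table["strength_rank"] = ranks.reindex(table.index)
    return CorrelationProfile(marker_name=marker, table=table, n_samples=len(samples))


def top_k_genes(profile: CorrelationProfile, k: int, direction: str) -> list[str]:
    """The k most positively (or negatively) correlated valid genes.

    ``direction='positive'`` sorts by rho descending, ``'negative'`` by rho
    ascending; ties broken by gene id. If fewer than k valid genes exist the
    list is truncated with a warning.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    if direction not in ("positive", "negative"):
        raise ValueError(f"direction must be 'positive' or 'negative', got {direction!r}")
    vt = profile.valid_table
    sign = -1.0 if direction == "positive" else 1.0
    order = sorted(vt.index, key=lambda g: (sign * vt.at[g, "rho"], g))
    if k > len(order):
        warnings.warn(
            f"requested top {k} genes but only {len(order)} valid genes exist; truncating",
            stacklevel=2,
        )
    return order[:k]


def rank_shift_table(
    profile_a: CorrelationProfile,
    profile_b: CorrelationProfile,
    focal: Iterable[str],
) -> RankShiftTable:
    """Rank-shift analysis of a focal gene set between two marker profiles.

    Restricted to focal genes valid in both profiles. Both profiles must be
    computed over the same gene universe.
    """
    if list(profile_a.table.index) != list(profile_b.table.index):
        raise ValueError("profiles were computed over different gene universes")
    focal = set(focal)
    genes = [
        g
        for g in profile_a.table.index
        if g in focal and profile_a.table.at[g, "valid"] and profile_b.table.at[g, "valid"]
    ]
    if not genes:
        raise ValueError("no focal gene is valid in both profiles")
    ta = profile_a.table.loc[genes]
    tb = profile_b.table.loc[genes]
    out = pd.DataFrame(
        {
            "rank_a": ta["strength_rank"].astype(int),
            "rank_b": tb["strength_rank"].astype(int),
            "rho_a": ta["rho"],
            "rho_b": tb["rho"],
        },
        index=pd.Index(genes, name="gene_id"),
    )
    out["delta_rank"] = (out["rank_a"] - out["rank_b"]).abs()
    out["delta_rho"] = (out["rho_a"] - out["rho_b"]).abs()
    out = out.sort_values(
        by=["delta_rank", "delta_rho", "gene_id"],
        ascending=[False, False, True],
        kind="mergesort",
    )
    return RankShiftTable(
        marker_a=profile_a.marker_name, marker_b=profile_b.marker_name, table=out
    )
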