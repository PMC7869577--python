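"""The full two-marker concordance analysis as a model/results pair.

:class:`ProliferationConcordance` is built from an expression matrix, a
phenotype table and a gene set collection; :meth:`fit` runs, for the whole
cohort and for each sample group (by default the histological subtypes):

1. the marker–marker Spearman correlation,
2. per-gene correlation profiles against both markers,
3. a rank-shift table over the focal gene sets (when present),
4. one GSEA run per marker (permutation null, BH FDR),
5. the pathway-concordance report and the leading-edge gene overlap,

and finally the cross-group leading-edge comparison. The returned
:class:`ConcordanceResults` carries every intermediate table, prints a
``summary()`` and can ``save()`` itself as a tree of TSV files with a run
manifest (seed, parameters, input checksums) for byte-reproducible reruns.
"""

from __future__ import annotations

import hashlib
import io as _stdio
import logging
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Mapping

import pandas as pd
import yaml

from .concordance import (
    ConcordanceReport,
    LeadingEdgeOverlap,
    cross_group_overlap,
    leading_edge_overlap,
    summarize_concordance,
)
from .correlations import (
    CorrelationProfile,
    RankShiftTable,
    gene_marker_correlations,
    marker_correlation,
    rank_shift_table,
)
from .gsea import EnrichmentResult, GseaParams, results_to_frame, run_gsea
from .io import (
    ExpressionMatrix,
    GeneSetCollection,
    PhenotypeTable,
    read_expression_tsv,
    read_gmt,
    read_phenotype_tsv,
)

__all__ = [
    "ProliferationConcordance",
    "ConcordanceResults",
    "GroupResult",
    "AnalysisConfig",
    "run_full_analysis",
]

logger = logging.getLogger(__name__)

FLOAT_FMT = "%.12g"


@dataclass
class GroupResult:
    """All per-group outputs of one fitted analysis."""

    group: str
    sample_ids: tuple[str, ...]
    marker_rho: float
    profile_a: CorrelationProfile
    profile_b: CorrelationProfile
    rank_shift: RankShiftTable | None
    results_a: list[EnrichmentResult]
    results_b: list[EnrichmentResult]
    report: ConcordanceReport
    le_overlap: LeadingEdgeOverlap

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)


def _sha256_of_frame(df: pd.DataFrame) -> str:
    buf = _stdio.StringIO()
    df.to_csv(buf, sep="\t", float_format=FLOAT_FMT, lineterminator="\n")
    return hashlib.sha256(buf.getvalue().encode()).hexdigest()


class ProliferationConcordance:
    """Concordance of two continuous proliferation markers on one cohort.

    Parameters
    ----------
    expression, phenotypes, gene_sets
        The cohort data (log2(TPM+1) expression, per-sample markers, GMT
        collection).
    marker_a, marker_b
        Phenotype columns to compare (defaults: ``mitotic_rate``, ``ki67``).
    group_column, groups
        Optional stratification. With the default ``subtype`` column and
        ``groups=None``, every distinct subtype value becomes a group next
        to the whole-cohort ``all`` analysis. Groups with fewer than 3
        samples are skipped with a warning.
    focal_genes
        Genes for the rank-shift analysis; defaults to the union over the
        collection's focal sets (skipped when empty).
    params
        :class:`~gseaconcord.gsea.GseaParams`; each (group, marker) GSEA
        run gets its own sub-seed derived from ``params.seed``.
    """

    def __init__(
        self,
        expression: ExpressionMatrix,
        phenotypes: PhenotypeTable,
        gene_sets: GeneSetCollection,
        marker_a: str = "mitotic_rate",
        marker_b: str = "ki67",
        group_column: str | None = "subtype",
        groups: list[str] | None = None,
        focal_genes: set[str] | None = None,
        params: GseaParams | None = None,
    ) -> None:
        self.expression = expression
        self.phenotypes = phenotypes
        self.gene_sets = gene_sets
        self.marker_a = marker_a
        self.marker_b = marker_b
        self.group_column = group_column
        self.params = params if params is not None else GseaParams()
        for m in (marker_a, marker_b):
            if m not in phenotypes.data.columns:
                raise ValueError(f"marker column {m!r} not in the phenotype table")
        if group_column is not None:
            if group_column not in phenotypes.data.columns:
                raise ValueError(f"group column {group_column!r} not in the phenotype table")
            present = list(dict.fromkeys(phenotypes.data[group_column]))
            if groups is None:
                groups = present
            else:
                unknown = set(groups) - set(present)
                if unknown:
                    raise ValueError(f"group values not present in the table: {sorted(unknown)}")
        self.groups = groups if group_column is not None else []
        self.focal_genes = (
            focal_genes if focal_genes is not None else gene_sets.focal_genes()
        )

    @classmethod
    def from_files(
        cls,
        expression_path: str | Path,
        phenotype_path: str | Path,
        gmt_path: str | Path,
        already_log: bool = True,
        **kwargs,
    ) -> "ProliferationConcordance":
        return cls(
            expression=read_expression_tsv(expression_path, already_log=already_log),
            phenotypes=read_phenotype_tsv(phenotype_path),
            gene_sets=read_gmt(gmt_path),
            **kwargs,
        )

    # -- fitting ---------------------------------------------------------

    def _group_samples(self, group: str | None) -> list[str]:
        in_both = [
            s for s in self.expression.sample_ids if s in set(self.phenotypes.sample_ids)
        ]
        if group is None:
            return in_both
        col = self.phenotypes.data[self.group_column]
        keep = set(col.index[col == group])
        return [s for s in in_both if s in keep]

    def _sub_seed(self, group_index: int, marker_index: int) -> int:
        return (self.params.seed * 1_000_003 + 7919 * group_index + marker_index) % 2**31

    def _fit_group(self, name: str, samples: list[str], group_index: int) -> GroupResult:
        subset = None if name == "all" else samples
        rho = marker_correlation(self.phenotypes, self.marker_a, self.marker_b, samples)
        prof_a = gene_marker_correlations(self.expression, self.phenotypes, self.marker_a, subset)
        prof_b = gene_marker_correlations(self.expression, self.phenotypes, self.marker_b, subset)
        shift = None
        focal_valid = [
            g for g in self.focal_genes
            if g in prof_a.table.index
            and prof_a.table.at[g, "valid"] and prof_b.table.at[g, "valid"]
        ]
        if focal_valid:
            shift = rank_shift_table(prof_a, prof_b, focal_valid)
        elif self.focal_genes:
            logger.warning("group %s: no focal gene valid in both profiles; rank-shift skipped", name)
        res_a = run_gsea(
            self.expression, self.phenotypes, self.marker_a, self.gene_sets,
            replace(self.params, seed=self._sub_seed(group_index, 0)), subset,
        )
        res_b = run_gsea(
            self.expression, self.phenotypes, self.marker_b, self.gene_sets,
            replace(self.params, seed=self._sub_seed(group_index, 1)), subset,
        )
        report = summarize_concordance(
            res_a, res_b, self.params.fdr_threshold, self.marker_a, self.marker_b
        )
        le = leading_edge_overlap(res_a, res_b, report.common_set_names, group_name=name)
        return GroupResult(
            group=name,
            sample_ids=tuple(samples),
            marker_rho=rho,
            profile_a=prof_a,
            profile_b=prof_b,
            rank_shift=shift,
            results_a=res_a,
            results_b=res_b,
            report=report,
            le_overlap=le,
        )

    def fit(self) -> "ConcordanceResults":
        """Run the full analysis for the whole cohort and each group."""
        group_results: dict[str, GroupResult] = {}
        plan: list[tuple[str, str | None]] = [("all", None)]
        plan += [(g, g) for g in self.groups]
        for gi, (name, group_value) in enumerate(plan):
            samples = self._group_samples(group_value)
            if len(samples) < 3:
                logger.warning(
                    "group %r has %d sample(s) (< 3); skipped", name, len(samples)
                )
                continue
            group_results[name] = self._fit_group(name, samples, gi)
        if not group_results:
            raise ValueError("no group has the >= 3 samples needed for the analysis")
        cross = cross_group_overlap([gr.le_overlap for gr in group_results.values()])
        return ConcordanceResults(model=self, groups=group_results, cross_group=cross)


@dataclass
class ConcordanceResults:
    """Fitted output of :class:`ProliferationConcordance`."""

    model: ProliferationConcordance
    groups: Mapping[str, GroupResult]
    cross_group: pd.DataFrame

    def summary(self) -> str:
        """Human-readable run summary across all sample groups."""
        m = self.model
        lines = [
            "Proliferation-marker concordance analysis",
            "=" * 57,
            f"markers: {m.marker_a} (A) vs {m.marker_b} (B)",
            f"genes: {m.expression.n_genes}   gene sets: {len(m.gene_sets.set_names)}",
            f"GSEA: p={m.params.weight_exponent:g}, {m.params.n_permutations} "
            f"{m.params.permutation_mode}-permutations, FDR < {m.params.fdr_threshold:g}",
            "",
            f"{'group':<12}{'n':>4}{'rho(A,B)':>10}{'enr A':>7}{'enr B':>7}"
            f"{'common':>8}{'spec A':>8}{'spec B':>8}{'LE∩':>6}",
            "-" * 70,
        ]
        for name, gr in self.groups.items():
            r = gr.report
            lines.append(
                f"{name:<12}{gr.n_samples:>4}{gr.marker_rho:>10.3f}"
                f"{r.n_enriched_a:>7}{r.n_enriched_b:>7}{r.n_common:>8}"
                f"{r.n_specific_a:>8}{r.n_specific_b:>8}{gr.le_overlap.n_intersection:>6}"
            )
        return "\n".join(lines)

    # -- persistence -----------------------------------------------------

    def save(self, outdir: str | Path) -> Path:
        """Write every table plus a run manifest under ``outdir``."""
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        m = self.model
        for name, gr in self.groups.items():
            gdir = outdir / name
            gdir.mkdir(exist_ok=True)
            for marker, prof in ((m.marker_a, gr.profile_a), (m.marker_b, gr.profile_b)):
                prof.table.to_csv(
                    gdir / f"profile_{marker}.tsv", sep="\t",
                    float_format=FLOAT_FMT, lineterminator="\n",
                )
            if gr.rank_shift is not None:
                gr.rank_shift.table.to_csv(
                    gdir / "rank_shift.tsv", sep="\t",
                    float_format=FLOAT_FMT, lineterminator="\n",
                )
            for marker, res in ((m.marker_a, gr.results_a), (m.marker_b, gr.results_b)):
                results_to_frame(res).to_csv(
                    gdir / f"gsea_{marker}.tsv", sep="\t",
                    float_format=FLOAT_FMT, lineterminator="\n",
                )
            report = gr.report.to_series()
            report["marker_rho"] = gr.marker_rho
            report["n_samples"] = gr.n_samples
            report.to_csv(gdir / "concordance.tsv", sep="\t", header=False, lineterminator="\n")
            with open(gdir / "common_pathways.txt", "w", encoding="utf-8", newline="\n") as fh:
                fh.write("\n".join(gr.report.common_set_names) + "\n")
            gr.le_overlap.to_series().to_csv(
                gdir / "leading_edge_overlap.tsv", sep="\t", header=False, lineterminator="\n"
            )
        self.cross_group.to_csv(
            outdir / "cross_group_overlap.tsv", sep="\t",
            float_format=FLOAT_FMT, lineterminator="\n",
        )
        with open(outdir / "venn_counts.txt", "w", encoding="utf-8", newline="\n") as fh:
            for name, gr in self.groups.items():
                o = gr.le_overlap
                fh.write(
                    f"{name}\tA_only={o.n_a_only}\tintersection={o.n_intersection}"
                    f"\tB_only={o.n_b_only}\n"
                )
        manifest = {
            "marker_a": m.marker_a,
            "marker_b": m.marker_b,
            "group_column": m.group_column,
            "groups_analyzed": list(self.groups),
            "seed": m.params.seed,
            "weight_exponent": m.params.weight_exponent,
            "n_permutations": m.params.n_permutations,
            "permutation_mode": m.params.permutation_mode,
            "fdr_threshold": m.params.fdr_threshold,
            "sha256_expression": _sha256_of_frame(m.expression.data),
            "sha256_phenotypes": _sha256_of_frame(m.phenotypes.data),
        }
        with open(outdir / "run_manifest.yaml", "w", encoding="utf-8", newline="\n") as fh:
            yaml.safe_dump(manifest, fh, sort_keys=True)
        with open(outdir / "summary.txt", "w", encoding="utf-8", newline="\n") as fh:
            fh.write(self.summary() + "\n")
        return outdir


# ---------------------------------------------------------------------------
# config-file driven entry point
# ---------------------------------------------------------------------------

@dataclass
class AnalysisConfig:
    """Flat key-value run configuration (YAML mapping on disk)."""

    expression: str
    phenotypes: str
    gene_sets: str
    output: str
    marker_a: str = "mitotic_rate"
    marker_b: str = "ki67"
    group_column: str | None = "subtype"
    focal_sets: list[str] | None = None
    already_log: bool = True
    weight_exponent: float = 1.0
    n_permutations: int = 10000
    permutation_mode: str = "gene"
    fdr_threshold: float = 0.10
    min_set_size: int = 1
    max_set_size: int | None = None
    seed: int = 0

    @classmethod
    def from_yaml(cls, path: str | Path) -> "AnalysisConfig":
        with open(path, encoding="utf-8") as fh:
            raw = yaml.safe_load(fh)
        if not isinstance(raw, dict):
            raise ValueError(f"{path}: config must be a flat key-value mapping")
        return cls(**raw)

    def gsea_params(self) -> GseaParams:
        return GseaParams(
            weight_exponent=self.weight_exponent,
            n_permutations=self.n_permutations,
            permutation_mode=self.permutation_mode,
            min_set_size=self.min_set_size,
            max_set_size=self.max_set_size,
            fdr_threshold=self.fdr_threshold,
            seed=self.seed,
        )


def run_full_analysis(config: AnalysisConfig) -> Path:
    """Load inputs, fit the concordance model, save all outputs.

    Returns the output directory; rerunning with the same config and seed
    reproduces the output tree byte for byte.
    """
    for path in (config.expression, config.phenotypes, config.gene_sets):
        if not Path(path).exists():
            raise FileNotFoundError(f"input file not found: {path}")
    collection = read_gmt(config.gene_sets)
    focal_genes = None
    if config.focal_sets:
        missing = set(config.focal_sets) - set(collection.set_names)
        if missing:
            raise ValueError(f"focal sets not in the collection: {sorted(missing)}")
        focal_genes = {
            g for name in config.focal_sets for g in collection.genes_of(name)
        }
    else:
        logger.info("no focal set configured; rank-shift stage will be skipped")
    model = ProliferationConcordance(
        expression=read_expression_tsv(config.expression, already_log=config.already_log),
        phenotypes=read_phenotype_tsv(config.phenotypes),
        gene_sets=collection,
        marker_a=config.marker_a,
        marker_b=config.marker_b,
        group_column=config.group_column,
        focal_genes=focal_genes,
        params=config.gsea_params(),
    )
    return model.fit().save(config.output)
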