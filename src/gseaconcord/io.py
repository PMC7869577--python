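"""Data containers and file formats.

The pipeline works on three tabular inputs, all plain UTF-8 text:

* an expression matrix (TSV, genes in rows, samples in columns, first header
  cell ``gene_id``), stored internally as log2(TPM+1);
* a per-sample phenotype table (TSV) carrying the two continuous
  proliferation markers — mitotic rate per 2 mm² and Ki-67 percentage — plus
  a histological subtype label and an optional necrosis flag;
* gene set collections in the standard MSigDB GMT dialect
  (``name<TAB>description<TAB>gene<TAB>gene...``).

Readers validate rather than repair: duplicate identifiers, non-numeric or
negative expression cells and out-of-range phenotype values are hard errors.
The only silent-ish repair is de-duplication of repeated genes within a GMT
line, which is reported through a warning.

Also here: gene-level TPM aggregation (summing transcript TPM per gene) and
the WHO mitotic-count grading rule for lung neuroendocrine tumors.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

__all__ = [
    "ExpressionMatrix",
    "TranscriptMatrix",
    "PhenotypeTable",
    "GeneSet",
    "GeneSetCollection",
    "WhoGrade",
    "read_expression_tsv",
    "write_expression_tsv",
    "read_phenotype_tsv",
    "write_phenotype_tsv",
    "aggregate_transcripts_to_genes",
    "read_gmt",
    "write_gmt",
    "grade_by_who",
]

#: formatting used for all numeric TSV output; >= 10 significant digits so
#: write -> read round-trips reproduce values to within 1 ulp-ish precision.
FLOAT_FMT = "%.12g"

SUBTYPES = ("typical_carcinoid", "atypical_carcinoid", "carcinoid", "LCNEC", "other")


def _check_unique(ids: Iterable[str], what: str) -> None:
    seen: set[str] = set()
    for x in ids:
        if x in seen:
            raise ValueError(f"duplicate {what}: {x!r}")
        seen.add(x)


@dataclass
class ExpressionMatrix:
    """Genes x samples matrix of log2(TPM+1) expression values.

    ``data`` is a float DataFrame indexed by gene id with sample ids as
    columns. Values must be finite and non-negative; both axes must carry
    unique identifiers.
    """

    data: pd.DataFrame

    def __post_init__(self) -> None:
        if self.data.shape[0] == 0 or self.data.shape[1] == 0:
            raise ValueError("expression matrix must have at least one gene and one sample")
        _check_unique(self.data.index, "gene id")
        _check_unique(self.data.columns, "sample id")
        values = self.data.to_numpy()
        if not np.issubdtype(values.dtype, np.number):
            raise ValueError("expression matrix contains non-numeric values")
        if not np.isfinite(values).all():
            bad = np.argwhere(~np.isfinite(values))[0]
            raise ValueError(
                f"non-finite expression value at gene {self.data.index[bad[0]]!r}, "
                f"sample {self.data.columns[bad[1]]!r}"
            )
        if (values < 0).any():
            bad = np.argwhere(values < 0)[0]
            raise ValueError(
                f"negative expression value at gene {self.data.index[bad[0]]!r}, "
                f"sample {self.data.columns[bad[1]]!r}"
            )

    @property
    def gene_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.columns)

    @property
    def n_genes(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    def equals(self, other: "ExpressionMatrix", atol: float = 1e-9) -> bool:
        return (
            self.gene_ids == other.gene_ids
            and self.sample_ids == other.sample_ids
            and np.allclose(self.data.to_numpy(), other.data.to_numpy(), atol=atol, rtol=1e-9)
        )


@dataclass
class TranscriptMatrix:
    """Transcripts x samples matrix of TPM values (pre log-transform)."""

    data: pd.DataFrame

    def __post_init__(self) -> None:
        _check_unique(self.data.index, "transcript id")
        _check_unique(self.data.columns, "sample id")
        values = self.data.to_numpy()
        if not np.isfinite(values).all():
            raise ValueError("transcript matrix contains non-finite values")
        if (values < 0).any():
            raise ValueError("transcript matrix contains negative TPM values")


@dataclass
class PhenotypeTable:
    """Per-sample phenotypes: mitotic rate, Ki-67 index, subtype, necrosis.

    ``data`` is indexed by sample id with columns ``mitotic_rate`` (mitoses
    per 2 mm², >= 0), ``ki67`` (percent, in [0, 100]), ``subtype`` (one of
    typical_carcinoid / atypical_carcinoid / carcinoid / LCNEC / other) and
    optionally ``necrosis`` (boolean).
    """

    data: pd.DataFrame

    def __post_init__(self) -> None:
        _check_unique(self.data.index, "sample id")
        for col in ("mitotic_rate", "ki67", "subtype"):
            if col not in self.data.columns:
                raise ValueError(f"phenotype table missing required column {col!r}")
        mr = self.data["mitotic_rate"].to_numpy(dtype=float)
        ki = self.data["ki67"].to_numpy(dtype=float)
        if not np.isfinite(mr).all() or (mr < 0).any():
            raise ValueError("mitotic_rate must be finite and >= 0")
        if not np.isfinite(ki).all() or (ki < 0).any() or (ki > 100).any():
            raise ValueError("ki67 must lie in [0, 100]")
        bad = set(self.data["subtype"]) - set(SUBTYPES)
        if bad:
            raise ValueError(f"unknown subtype labels: {sorted(bad)}")

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.index)

    def marker(self, name: str) -> pd.Series:
        """Return a numeric marker column (e.g. ``mitotic_rate`` or ``ki67``)."""
        if name not in self.data.columns:
            raise KeyError(f"phenotype table has no column {name!r}")
        return pd.to_numeric(self.data[name])


@dataclass
class GeneSet:
    description: str
    genes: tuple[str, ...]


@dataclass
class GeneSetCollection:
    """Named gene sets, plus an optional focal subset of set names.

    The focal subset marks sets of special interest for rank-shift analysis
    (in the motivating study: the cell-cycle pathways).
    """

    sets: dict[str, GeneSet]
    focal_set_names: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        for name, gs in self.sets.items():
            _check_unique(gs.genes, f"gene in set {name!r}")
        for name in self.focal_set_names:
            if name not in self.sets:
                raise ValueError(f"focal set {name!r} not present in collection")

    @property
    def set_names(self) -> list[str]:
        return list(self.sets)

    def genes_of(self, name: str) -> tuple[str, ...]:
        return self.sets[name].genes

    def focal_genes(self) -> set[str]:
        """Union of genes over the focal sets."""
        out: set[str] = set()
        for name in self.focal_set_names:
            out.update(self.sets[name].genes)
        return out

    def subset(self, names: Iterable[str]) -> "GeneSetCollection":
        names = list(names)
        return GeneSetCollection(
            sets={n: self.sets[n] for n in names},
            focal_set_names=[n for n in self.focal_set_names if n in names],
        )


# ---------------------------------------------------------------------------
# expression TSV
# ---------------------------------------------------------------------------

def read_expression_tsv(path: str | Path, already_log: bool = False) -> ExpressionMatrix:
    """Read a genes-x-samples TSV into an :class:`ExpressionMatrix`.

    The first column holds gene ids, the header row sample ids. Values are
    interpreted as TPM and transformed by ``log2(x + 1)`` unless
    ``already_log`` is true, in which case they are taken to be log2(TPM+1)
    already.
    """
    path = Path(path)
    df = pd.read_csv(path, sep="\t", index_col=0, dtype=str)
    df.index = df.index.astype(str)
    if df.index.duplicated().any():
        dup = df.index[df.index.duplicated()][0]
        raise ValueError(f"{path}: duplicate gene id {dup!r}")
    if pd.Index(df.columns).duplicated().any():
        dup = pd.Index(df.columns)[pd.Index(df.columns).duplicated()][0]
        raise ValueError(f"{path}: duplicate sample id {dup!r}")
    numeric = df.apply(pd.to_numeric, errors="coerce")
    if numeric.isna().to_numpy().any():
        gi, si = np.argwhere(numeric.isna().to_numpy())[0]
        raise ValueError(
            f"{path}: non-numeric or missing value at gene {df.index[gi]!r}, "
            f"sample {df.columns[si]!r}"
        )
    values = numeric.astype(float)
    if (values.to_numpy() < 0).any():
        gi, si = np.argwhere(values.to_numpy() < 0)[0]
        raise ValueError(
            f"{path}: negative value at gene {df.index[gi]!r}, sample {df.columns[si]!r}"
        )
    if not already_log:
        values = np.log2(values + 1.0)
    return ExpressionMatrix(values)


def write_expression_tsv(matrix: ExpressionMatrix, path: str | Path) -> None:
    """Write an expression matrix as TSV (first header cell ``gene_id``)."""
    path = Path(path)
    df = matrix.data.copy()
    df.index.name = "gene_id"
    df.to_csv(path, sep="\t", float_format=FLOAT_FMT, lineterminator="\n")


# ---------------------------------------------------------------------------
# phenotype TSV
# ---------------------------------------------------------------------------

def read_phenotype_tsv(path: str | Path) -> PhenotypeTable:
    """Read a per-sample phenotype TSV (first column ``sample_id``)."""
    path = Path(path)
    df = pd.read_csv(path, sep="\t", index_col=0, dtype={0: str})
    df.index = df.index.astype(str)
    if "necrosis" in df.columns:
        df["necrosis"] = df["necrosis"].map(
            {"True": True, "False": False, True: True, False: False, 1: True, 0: False}
        )
        if df["necrosis"].isna().any():
            raise ValueError(f"{path}: necrosis column must be boolean (True/False)")
        df["necrosis"] = df["necrosis"].astype(bool)
    return PhenotypeTable(df)


def write_phenotype_tsv(pheno: PhenotypeTable, path: str | Path) -> None:
    df = pheno.data.copy()
    df.index.name = "sample_id"
    df.to_csv(path, sep="\t", float_format=FLOAT_FMT, lineterminator="\n")


# ---------------------------------------------------------------------------
# transcript -> gene aggregation
# ---------------------------------------------------------------------------

def aggregate_transcripts_to_genes(
    tx: TranscriptMatrix, tx2gene: Mapping[str, str]
) -> pd.DataFrame:
    """Sum transcript-level TPM into gene-level TPM.

    Per sample, a gene's TPM is the sum of the TPM of its transcripts, which
    keeps the per-sample TPM mass of mapped transcripts intact. Transcripts
    absent from ``tx2gene`` are dropped (a warning reports how many). The
    returned DataFrame is gene x sample TPM in lexicographic gene order.
    """
    mapped = tx.data.index.to_series().map(dict(tx2gene))
    n_dropped = int(mapped.isna().sum())
    if n_dropped == len(mapped):
        raise ValueError("no transcript maps to any gene")
    if n_dropped:
        warnings.warn(
            f"{n_dropped} transcript(s) absent from tx2gene map were dropped",
            stacklevel=2,
        )
    kept = tx.data.loc[mapped.notna()]
    gene_tpm = kept.groupby(mapped.dropna().to_numpy()).sum()
    gene_tpm = gene_tpm.sort_index()
    gene_tpm.index.name = "gene_id"
    return gene_tpm


# ---------------------------------------------------------------------------
# GMT
# ---------------------------------------------------------------------------

def read_gmt(path: str | Path) -> GeneSetCollection:
    """Parse a GMT file: one gene set per line, ``name\\tdesc\\tgene...``."""
    path = Path(path)
    sets: dict[str, GeneSet] = {}
    n_dup_genes = 0
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(
                    f"{path}: line {lineno}: expected >= 3 tab-separated fields, "
                    f"got {len(fields)}"
                )
            name, desc, *genes = fields
            if name in sets:
                raise ValueError(f"{path}: line {lineno}: duplicate set name {name!r}")
            uniq = list(dict.fromkeys(genes))
            n_dup_genes += len(genes) - len(uniq)
            sets[name] = GeneSet(description=desc, genes=tuple(uniq))
    if n_dup_genes:
        warnings.warn(
            f"{n_dup_genes} duplicated gene entr(ies) within GMT lines were de-duplicated",
            stacklevel=2,
        )
    return GeneSetCollection(sets=sets)


def write_gmt(collection: GeneSetCollection, path: str | Path) -> None:
    """Write a collection in the GMT dialect read by :func:`read_gmt`."""
    if not collection.sets:
        raise ValueError("refusing to write an empty gene set collection")
    path = Path(path)
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        for name, gs in collection.sets.items():
            for token in (name, gs.description, *gs.genes):
                if "\t" in token or "\n" in token:
                    raise ValueError(
                        f"GMT cannot represent tab/newline inside field {token!r} "
                        f"(set {name!r})"
                    )
            fh.write("\t".join((name, gs.description, *gs.genes)) + "\n")


# ---------------------------------------------------------------------------
# WHO mitotic-count grading
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class WhoGrade:
    """Grading outcome: a grade label plus a morphology-review flag.

    ``review`` is only ever set under the modified scheme, for mitotic rates
    in (10, 20] — tumors in that band may show carcinoid-like morphology and
    warrant pathology review, but reclassification needs evidence (morphology,
    IHC, transcriptome) that a mitotic count alone cannot provide.
    """

    grade: str
    review: bool = False


def grade_by_who(mitotic_rate: float, necrosis: bool, modified: bool = False) -> WhoGrade:
    """Grade a lung NET by its WHO mitotic-count criterion.

    Typical carcinoid: < 2 mitoses per 2 mm² without necrosis. Atypical
    carcinoid: 2–10 mitoses per 2 mm² and/or necrosis (at < 2 mitoses).
    High grade: > 10 mitoses per 2 mm². With ``modified=True``, rates in
    (10, 20] additionally carry ``review=True`` ("possible carcinoid")
    without changing the grade.
    """
    if not np.isfinite(mitotic_rate) or mitotic_rate < 0:
        raise ValueError(f"mitotic_rate must be finite and >= 0, got {mitotic_rate!r}")
    if mitotic_rate > 10:
        review = bool(modified and mitotic_rate <= 20)
        return WhoGrade("high_grade", review=review)
    if mitotic_rate >= 2 or necrosis:
        return WhoGrade("atypical_carcinoid")
    return WhoGrade("typical_carcinoid")
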