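"""Containers and TSV readers/writers for multi-study labelled expression data.

The on-disk dialect is plain tab-delimited text, UTF-8, "." decimal point:

* expression table — header ``gene_id\t<sample_1>\t...\t<sample_n>``, one row
  per gene, numeric body (log-scale expression values);
* sample metadata — header ``sample_id\tstudy_id\tphenotype``, one row per
  sample.

Values are assumed to be already log-transformed and normalized; no
normalization is performed here.  Sample matching between the two tables is
strict: any mismatch is an error, never a silent intersection.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "DataFormatError",
    "ExpressionMatrix",
    "SampleAnnotation",
    "MultiStudyDataset",
    "read_expression",
    "write_expression",
    "read_annotations",
    "write_annotations",
    "assemble",
    "subset",
]


class DataFormatError(ValueError):
    """An on-disk table or in-memory container violates the expected layout."""


def _find_duplicates(items: Iterable[str]) -> list[str]:
    seen: set[str] = set()
    dups: list[str] = []
    for it in items:
        if it in seen and it not in dups:
            dups.append(it)
        seen.add(it)
    return dups


@dataclass(frozen=True, eq=False)
class ExpressionMatrix:
    """A genes x samples matrix of log-scale expression values.

    Gene and sample identifiers are ordered and unique; the value matrix is
    dense, finite and aligned with them (rows = genes, columns = samples).
    """

    gene_ids: tuple[str, ...]
    sample_ids: tuple[str, ...]
    values: np.ndarray

    def __post_init__(self) -> None:
        object.__setattr__(self, "gene_ids", tuple(str(g) for g in self.gene_ids))
        object.__setattr__(self, "sample_ids", tuple(str(s) for s in self.sample_ids))
        vals = np.asarray(self.values, dtype=np.float64)
        if vals.ndim != 2:
            raise DataFormatError("expression values must be a 2-D matrix")
        object.__setattr__(self, "values", vals)
        dup_g = _find_duplicates(self.gene_ids)
        if dup_g:
            raise DataFormatError(f"duplicate gene id(s): {', '.join(dup_g)}")
        dup_s = _find_duplicates(self.sample_ids)
        if dup_s:
            raise DataFormatError(f"duplicate sample id(s): {', '.join(dup_s)}")
        if vals.shape != (len(self.gene_ids), len(self.sample_ids)):
            raise DataFormatError(
                f"value matrix shape {vals.shape} does not match "
                f"{len(self.gene_ids)} genes x {len(self.sample_ids)} samples"
            )
        if vals.size and not np.all(np.isfinite(vals)):
            bad = np.argwhere(~np.isfinite(vals))[0]
            raise DataFormatError(
                f"non-finite value at gene '{self.gene_ids[bad[0]]}', "
                f"sample '{self.sample_ids[bad[1]]}'"
            )
        if not self.gene_ids or not self.sample_ids:
            raise DataFormatError("expression matrix must have >=1 gene and >=1 sample")

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    def sample_index(self) -> dict[str, int]:
        return {s: i for i, s in enumerate(self.sample_ids)}

    def gene_index(self) -> dict[str, int]:
        return {g: i for i, g in enumerate(self.gene_ids)}

    def restrict_samples(self, sample_ids: Sequence[str]) -> "ExpressionMatrix":
        """Column subset, in the order given; unknown ids are an error."""
        idx = self.sample_index()
        try:
            cols = [idx[s] for s in sample_ids]
        except KeyError as exc:
            raise DataFormatError(f"unknown sample id: {exc.args[0]}") from None
        return ExpressionMatrix(self.gene_ids, tuple(sample_ids), self.values[:, cols])

    def restrict_genes(self, gene_ids: Sequence[str]) -> "ExpressionMatrix":
        idx = self.gene_index()
        try:
            rows = [idx[g] for g in gene_ids]
        except KeyError as exc:
            raise DataFormatError(f"unknown gene id: {exc.args[0]}") from None
        return ExpressionMatrix(tuple(gene_ids), self.sample_ids, self.values[rows, :])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.values, index=list(self.gene_ids), columns=list(self.sample_ids)
        )

    def equals(self, other: "ExpressionMatrix") -> bool:
        return (
            self.gene_ids == other.gene_ids
            and self.sample_ids == other.sample_ids
            and np.array_equal(self.values, other.values)
        )


@dataclass(frozen=True)
class SampleAnnotation:
    """Study and phenotype labels for one sample."""

    sample_id: str
    study_id: str
    phenotype: str

    def __post_init__(self) -> None:
        for fld in ("sample_id", "study_id", "phenotype"):
            v = getattr(self, fld)
            if not isinstance(v, str) or not v:
                raise DataFormatError(
                    f"annotation field '{fld}' must be a non-empty string "
                    f"(sample '{self.sample_id}')"
                )


class MultiStudyDataset:
    """An expression matrix plus per-sample study and phenotype labels.

    Invariants: annotation sample ids match the matrix sample ids exactly
    (as sets); at least two distinct studies and two distinct phenotypes;
    every study holds at least one sample.  A (study, phenotype) cell may be
    empty — studies are allowed to lack phenotypes.
    """

    def __init__(
        self, matrix: ExpressionMatrix, annotations: Sequence[SampleAnnotation]
    ) -> None:
        ann_ids = [a.sample_id for a in annotations]
        dup = _find_duplicates(ann_ids)
        if dup:
            raise DataFormatError(f"duplicate annotation sample id(s): {', '.join(dup)}")
        if set(ann_ids) != set(matrix.sample_ids):
            only_m = sorted(set(matrix.sample_ids) - set(ann_ids))
            only_a = sorted(set(ann_ids) - set(matrix.sample_ids))
            raise DataFormatError(
                "sample sets of matrix and annotations differ; "
                f"only in matrix: {only_m}; only in annotations: {only_a}"
            )
        by_id = {a.sample_id: a for a in annotations}
        self.matrix = matrix
        # annotations stored in matrix column order
        self.annotations: tuple[SampleAnnotation, ...] = tuple(
            by_id[s] for s in matrix.sample_ids
        )
        self.study_of: dict[str, str] = {a.sample_id: a.study_id for a in self.annotations}
        self.phenotype_of: dict[str, str] = {
            a.sample_id: a.phenotype for a in self.annotations
        }
        self.studies: tuple[str, ...] = tuple(sorted({a.study_id for a in self.annotations}))
        self.phenotypes: tuple[str, ...] = tuple(
            sorted({a.phenotype for a in self.annotations})
        )
        if len(self.studies) < 2:
            raise DataFormatError(
                f"dataset must contain >=2 studies (got {list(self.studies)})"
            )
        if len(self.phenotypes) < 2:
            raise DataFormatError(
                f"dataset must contain >=2 phenotypes (got {list(self.phenotypes)})"
            )

    # -- accessors -------------------------------------------------------

    @property
    def sample_ids(self) -> tuple[str, ...]:
        return self.matrix.sample_ids

    @property
    def gene_ids(self) -> tuple[str, ...]:
        return self.matrix.gene_ids

    def samples_of_study(self, study_id: str) -> tuple[str, ...]:
        return tuple(s for s in self.sample_ids if self.study_of[s] == study_id)

    def samples_of_phenotype(self, phenotype: str) -> tuple[str, ...]:
        return tuple(s for s in self.sample_ids if self.phenotype_of[s] == phenotype)

    def phenotype_labels(self) -> np.ndarray:
        """Phenotype label per sample, aligned with matrix columns."""
        return np.array([self.phenotype_of[s] for s in self.sample_ids], dtype=object)

    def study_labels(self) -> np.ndarray:
        return np.array([self.study_of[s] for s in self.sample_ids], dtype=object)

    def studies_with_phenotype(self, phenotype: str) -> tuple[str, ...]:
        return tuple(
            st
            for st in self.studies
            if any(self.phenotype_of[s] == phenotype for s in self.samples_of_study(st))
        )

    def counts(self) -> pd.DataFrame:
        """Study x phenotype sample-count table (zeros for empty cells)."""
        df = pd.DataFrame(
            {"study_id": self.study_labels(), "phenotype": self.phenotype_labels()}
        )
        return (
            df.groupby(["study_id", "phenotype"], sort=True)
            .size()
            .unstack(fill_value=0)
            .reindex(index=list(self.studies), columns=list(self.phenotypes), fill_value=0)
        )

    def subset(self, keep_studies: Iterable[str]) -> "MultiStudyDataset":
        """Restrict to the given studies; gene set and sample order preserved."""
        keep = set(keep_studies)
        unknown = sorted(keep - set(self.studies))
        if unknown:
            raise DataFormatError(f"unknown study id(s): {', '.join(unknown)}")
        kept_samples = [s for s in self.sample_ids if self.study_of[s] in keep]
        matrix = self.matrix.restrict_samples(kept_samples)
        anns = [a for a in self.annotations if a.study_id in keep]
        return MultiStudyDataset(matrix, anns)

    def equals(self, other: "MultiStudyDataset") -> bool:
        return self.matrix.equals(other.matrix) and self.annotations == other.annotations


# -- readers / writers ---------------------------------------------------


def _check_numeric(frame: pd.DataFrame, path: Path) -> np.ndarray:
    """Convert the body to float64, locating the first offending cell."""
    try:
        return frame.to_numpy(dtype=np.float64)
    except (ValueError, TypeError):
        pass
    for j, col in enumerate(frame.columns):
        for i, v in enumerate(frame.iloc[:, j]):
            try:
                float(v)
            except (ValueError, TypeError):
                raise DataFormatError(
                    f"{path}: non-numeric value {v!r} at gene '{frame.index[i]}', "
                    f"sample '{col}' (row {i + 2}, column {j + 2})"
                ) from None
    raise DataFormatError(f"{path}: could not parse numeric body")  # pragma: no cover


def read_expression(path: str | Path) -> ExpressionMatrix:
    """Read a gene x sample expression TSV (first column gene ids, header
    row sample ids).  Row and column order are preserved from the file."""
    path = Path(path)
    with open(path, encoding="utf-8") as fh:
        header = fh.readline()
    if not header.strip():
        raise DataFormatError(f"{path}: empty file")
    header_ids = header.rstrip("\n").split("\t")[1:]
    dup = _find_duplicates(header_ids)
    if dup:
        raise DataFormatError(f"{path}: duplicate sample id(s) in header: {', '.join(dup)}")
    try:
        frame = pd.read_csv(path, sep="\t", index_col=0, dtype=str, keep_default_na=False)
    except pd.errors.EmptyDataError:
        raise DataFormatError(f"{path}: empty file") from None
    if frame.shape[0] == 0 or frame.shape[1] == 0:
        raise DataFormatError(f"{path}: expression table has no data rows or columns")
    gene_ids = [str(g) for g in frame.index]
    dup = _find_duplicates(gene_ids)
    if dup:
        raise DataFormatError(f"{path}: duplicate gene id(s): {', '.join(dup)}")
    values = _check_numeric(frame, path)
    return ExpressionMatrix(tuple(gene_ids), tuple(header_ids), values)


def write_expression(matrix: ExpressionMatrix, path: str | Path) -> None:
    """Write the expression TSV.  Floats use shortest round-trip formatting,
    so write/read cycles preserve values bit-exactly."""
    matrix.to_frame().to_csv(path, sep="\t", index_label="gene_id", lineterminator="\n")


_ANNOTATION_COLUMNS = ("sample_id", "study_id", "phenotype")


def read_annotations(path: str | Path) -> list[SampleAnnotation]:
    """Read the sample metadata TSV (columns sample_id, study_id, phenotype)."""
    path = Path(path)
    try:
        frame = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    except pd.errors.EmptyDataError:
        raise DataFormatError(f"{path}: empty file") from None
    missing = [c for c in _ANNOTATION_COLUMNS if c not in frame.columns]
    if missing:
        raise DataFormatError(f"{path}: missing column(s): {', '.join(missing)}")
    dup = _find_duplicates(list(frame["sample_id"]))
    if dup:
        raise DataFormatError(f"{path}: duplicate sample id(s): {', '.join(dup)}")
    anns = []
    for i, row in frame.iterrows():
        for col in _ANNOTATION_COLUMNS:
            if not row[col]:
                raise DataFormatError(
                    f"{path}: empty '{col}' in row {int(i) + 2}"
                )
        anns.append(
            SampleAnnotation(row["sample_id"], row["study_id"], row["phenotype"])
        )
    return anns


def write_annotations(annotations: Sequence[SampleAnnotation], path: str | Path) -> None:
    pd.DataFrame(
        {
            "sample_id": [a.sample_id for a in annotations],
            "study_id": [a.study_id for a in annotations],
            "phenotype": [a.phenotype for a in annotations],
        }
    ).to_csv(path, sep="\t", index=False, lineterminator="\n")


def assemble(
    matrix: ExpressionMatrix, annotations: Sequence[SampleAnnotation]
) -> MultiStudyDataset:
    """Join matrix and annotations into a dataset; any sample present in one
    input but not the other is a hard error (no silent intersection)."""
    m_ids = set(matrix.sample_ids)
    a_ids = {a.sample_id for a in annotations}
    if m_ids != a_ids:
        only_m = sorted(m_ids - a_ids)
        only_a = sorted(a_ids - m_ids)
        parts = []
        if only_m:
            parts.append(f"samples only in expression matrix: {', '.join(only_m)}")
        if only_a:
            parts.append(f"samples only in annotations: {', '.join(only_a)}")
        raise DataFormatError("; ".join(parts))
    return MultiStudyDataset(matrix, annotations)


def subset(ds: MultiStudyDataset, keep_studies: Iterable[str]) -> MultiStudyDataset:
    """Functional form of :meth:`MultiStudyDataset.subset`."""
    return ds.subset(keep_studies)
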