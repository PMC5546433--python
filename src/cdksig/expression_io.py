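"""Readers, writers and validated domain containers for every on-disk artifact.

All tabular formats are tab-separated UTF-8 text with a header row; gene
lists are newline-delimited identifiers with ``#`` comments; derived results
are emitted as JSON elsewhere in the package.  Gene and sample identifiers
are opaque strings compared by exact equality.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "FormatError",
    "ExpressionMatrix",
    "SampleAnnotation",
    "SurvivalRecord",
    "SurvivalTable",
    "EssentialityTable",
    "RB_STATUSES",
    "AGENTS",
    "CONTEXTS",
    "read_expression_matrix",
    "write_expression_matrix",
    "read_sample_annotation",
    "write_sample_annotation",
    "read_gene_list",
    "write_gene_list",
    "read_survival_table",
    "write_survival_table",
    "read_essentiality_table",
    "write_essentiality_table",
]

RB_STATUSES = ("proficient", "deficient")
AGENTS = ("vehicle", "PD", "LY")
CONTEXTS = ("cell_line", "xenograft")

ANNOTATION_COLUMNS = (
    "sample_id",
    "model",
    "rb_status",
    "agent",
    "dose_nM",
    "context",
    "replicate",
)


class FormatError(ValueError):
    """A file violated its format contract; the message names the offender."""


def _check_unique(ids: Sequence[str], kind: str) -> None:
    seen: set[str] = set()
    for x in ids:
        if x in seen:
            raise FormatError(f"duplicate {kind} id: {x!r}")
        seen.add(x)


@dataclass(frozen=True)
class ExpressionMatrix:
    """Genes x samples matrix of log2 intensities.

    ``values`` is a dense float array with genes as rows, in the order of
    ``gene_ids``; columns follow ``sample_ids``.  All values must be finite
    and identifiers unique.
    """

    gene_ids: tuple[str, ...]
    sample_ids: tuple[str, ...]
    values: np.ndarray

    def __post_init__(self) -> None:
        _check_unique(self.gene_ids, "gene")
        _check_unique(self.sample_ids, "sample")
        vals = np.asarray(self.values, dtype=float)
        if vals.shape != (len(self.gene_ids), len(self.sample_ids)):
            raise FormatError(
                f"matrix shape {vals.shape} does not match "
                f"{len(self.gene_ids)} genes x {len(self.sample_ids)} samples"
            )
        if not np.all(np.isfinite(vals)):
            g, s = np.argwhere(~np.isfinite(vals))[0]
            raise FormatError(
                f"non-finite value at gene {self.gene_ids[g]!r}, "
                f"sample {self.sample_ids[s]!r}"
            )
        object.__setattr__(self, "values", vals)

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.values, index=list(self.gene_ids), columns=list(self.sample_ids)
        )

    @classmethod
    def from_frame(cls, frame: pd.DataFrame) -> "ExpressionMatrix":
        return cls(
            gene_ids=tuple(str(g) for g in frame.index),
            sample_ids=tuple(str(s) for s in frame.columns),
            values=frame.to_numpy(dtype=float),
        )

    def column(self, sample_id: str) -> np.ndarray:
        try:
            j = self.sample_ids.index(sample_id)
        except ValueError:
            raise KeyError(f"sample {sample_id!r} not in matrix") from None
        return self.values[:, j]

    def subset_samples(self, sample_ids: Iterable[str]) -> "ExpressionMatrix":
        wanted = list(sample_ids)
        missing = [s for s in wanted if s not in self.sample_ids]
        if missing:
            raise KeyError(f"samples not in matrix: {missing}")
        idx = [self.sample_ids.index(s) for s in wanted]
        return ExpressionMatrix(self.gene_ids, tuple(wanted), self.values[:, idx])

    def subset_genes(self, gene_ids: Iterable[str]) -> "ExpressionMatrix":
        wanted = list(gene_ids)
        missing = [g for g in wanted if g not in set(self.gene_ids)]
        if missing:
            raise KeyError(f"genes not in matrix: {missing}")
        pos = {g: i for i, g in enumerate(self.gene_ids)}
        idx = [pos[g] for g in wanted]
        return ExpressionMatrix(tuple(wanted), self.sample_ids, self.values[idx, :])


@dataclass(frozen=True)
class SampleAnnotation:
    """Per-sample experimental design: model, RB status, agent, dose, context."""

    table: pd.DataFrame = field(repr=False)

    def __post_init__(self) -> None:
        t = self.table
        missing = [c for c in ANNOTATION_COLUMNS if c not in t.columns]
        if missing:
            raise FormatError(f"annotation missing required columns: {missing}")
        _check_unique(list(t["sample_id"].astype(str)), "sample")
        for i, row in t.iterrows():
            sid = row["sample_id"]
            if row["rb_status"] not in RB_STATUSES:
                raise FormatError(
                    f"sample {sid!r}: unknown rb_status {row['rb_status']!r}"
                )
            if row["agent"] not in AGENTS:
                raise FormatError(f"sample {sid!r}: unknown agent {row['agent']!r}")
            if row["context"] not in CONTEXTS:
                raise FormatError(
                    f"sample {sid!r}: unknown context {row['context']!r}"
                )
            dose = float(row["dose_nM"])
            if dose < 0:
                raise FormatError(f"sample {sid!r}: negative dose {dose}")
            if (row["agent"] == "vehicle") != (dose == 0):
                raise FormatError(
                    f"sample {sid!r}: vehicle arms must have dose 0 and "
                    f"treated arms dose > 0 (agent={row['agent']!r}, dose={dose})"
                )
            if int(row["replicate"]) < 1:
                raise FormatError(
                    f"sample {sid!r}: replicate must be a positive integer"
                )

    @property
    def sample_ids(self) -> tuple[str, ...]:
        return tuple(self.table["sample_id"].astype(str))

    def select(self, **criteria) -> tuple[str, ...]:
        """Sample ids matching all given column=value criteria."""
        mask = pd.Series(True, index=self.table.index)
        for col, val in criteria.items():
            if col not in self.table.columns:
                raise KeyError(f"unknown annotation column {col!r}")
            mask &= self.table[col] == val
        return tuple(self.table.loc[mask, "sample_id"].astype(str))

    def row(self, sample_id: str) -> pd.Series:
        hit = self.table[self.table["sample_id"] == sample_id]
        if hit.empty:
            raise KeyError(f"sample {sample_id!r} not annotated")
        return hit.iloc[0]


@dataclass(frozen=True)
class SurvivalRecord:
    case_id: str
    time: float
    event: int

    def __post_init__(self) -> None:
        if not self.time > 0:
            raise FormatError(f"case {self.case_id!r}: time must be > 0, got {self.time}")
        if self.event not in (0, 1):
            raise FormatError(
                f"case {self.case_id!r}: event must be 0 or 1, got {self.event}"
            )


@dataclass(frozen=True)
class SurvivalTable:
    """Complete survival records plus the count of incomplete rows dropped."""

    records: tuple[SurvivalRecord, ...]
    n_dropped: int = 0

    @property
    def case_ids(self) -> tuple[str, ...]:
        return tuple(r.case_id for r in self.records)

    @property
    def times(self) -> np.ndarray:
        return np.array([r.time for r in self.records], dtype=float)

    @property
    def events(self) -> np.ndarray:
        return np.array([r.event for r in self.records], dtype=int)


@dataclass(frozen=True)
class EssentialityTable:
    """Per-gene, per-cell-line viability-screen p-values; NaN marks missing."""

    gene_ids: tuple[str, ...]
    cell_line_ids: tuple[str, ...]
    pvalues: np.ndarray

    def __post_init__(self) -> None:
        _check_unique(self.gene_ids, "gene")
        _check_unique(self.cell_line_ids, "cell line")
        p = np.asarray(self.pvalues, dtype=float)
        if p.shape != (len(self.gene_ids), len(self.cell_line_ids)):
            raise FormatError("essentiality p-value matrix shape mismatch")
        bad = np.argwhere((p < 0) | (p > 1))
        if bad.size:
            g, c = bad[0]
            raise FormatError(
                f"p-value out of [0,1] for gene {self.gene_ids[g]!r}, "
                f"cell line {self.cell_line_ids[c]!r}: {p[g, c]}"
            )
        object.__setattr__(self, "pvalues", p)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.pvalues, index=list(self.gene_ids), columns=list(self.cell_line_ids)
        )


# ---------------------------------------------------------------------------
# readers / writers


def read_expression_matrix(path: str | Path) -> ExpressionMatrix:
    """Parse a genes-x-samples TSV of log2 intensities.

    The header row carries sample ids; the first column carries gene ids.
    Row and column order are preserved as on disk.  Duplicate identifiers
    and non-numeric or missing cells are rejected with the offender named.
    """
    frame = pd.read_csv(path, sep="\t", index_col=0, dtype=str)
    gene_ids = [str(g) for g in frame.index]
    sample_ids = [str(s) for s in frame.columns]
    _check_unique(gene_ids, "gene")
    _check_unique(sample_ids, "sample")
    values = np.empty(frame.shape, dtype=float)
    raw = frame.to_numpy()
    for j, sid in enumerate(sample_ids):
        col = pd.to_numeric(pd.Series(raw[:, j]), errors="coerce")
        bad = np.flatnonzero(col.isna().to_numpy())
        if bad.size:
            raise FormatError(
                f"non-numeric or missing value at gene {gene_ids[bad[0]]!r}, "
                f"sample {sid!r}"
            )
        values[:, j] = col.to_numpy()
    return ExpressionMatrix(tuple(gene_ids), tuple(sample_ids), values)


def write_expression_matrix(matrix: ExpressionMatrix, path: str | Path) -> None:
    matrix.to_frame().to_csv(path, sep="\t", index_label="gene_id", float_format="%.6f")


def read_sample_annotation(path: str | Path) -> SampleAnnotation:
    """Parse and validate a sample-annotation TSV (one row per sample)."""
    t = pd.read_csv(path, sep="\t", dtype={"sample_id": str, "model": str})
    return SampleAnnotation(t)


def write_sample_annotation(annotation: SampleAnnotation, path: str | Path) -> None:
    annotation.table.to_csv(path, sep="\t", index=False)


def read_gene_list(path: str | Path) -> tuple[str, ...]:
    """One identifier per line; ``#`` starts a comment; order is preserved."""
    out: list[str] = []
    seen: set[str] = set()
    text = Path(path).read_text(encoding="utf-8")
    for lineno, line in enumerate(text.splitlines(), start=1):
        entry = line.split("#", 1)[0].strip()
        if not entry:
            continue
        if entry in seen:
            raise FormatError(f"duplicate gene list entry {entry!r} at line {lineno}")
        seen.add(entry)
        out.append(entry)
    return tuple(out)


def write_gene_list(genes: Iterable[str], path: str | Path) -> None:
    genes = list(genes)
    _check_unique(genes, "gene")
    Path(path).write_text("".join(f"{g}\n" for g in genes), encoding="utf-8")


def read_survival_table(path: str | Path) -> SurvivalTable:
    """Parse a case_id/time/event TSV.

    Rows with a missing time or event are dropped and counted (mirroring the
    exclusion of cases lacking survival or relapse data); a negative or zero
    time, or a non-binary event, on a complete row is an error.
    """
    t = pd.read_csv(path, sep="\t", dtype={"case_id": str})
    for col in ("case_id", "time", "event"):
        if col not in t.columns:
            raise FormatError(f"survival table missing required column {col!r}")
    complete = t["time"].notna() & t["event"].notna()
    n_dropped = int((~complete).sum())
    records = tuple(
        SurvivalRecord(str(r.case_id), float(r.time), int(r.event))
        for r in t[complete].itertuples()
    )
    return SurvivalTable(records=records, n_dropped=n_dropped)


def write_survival_table(table: SurvivalTable, path: str | Path) -> None:
    pd.DataFrame(
        {
            "case_id": [r.case_id for r in table.records],
            "time": [r.time for r in table.records],
            "event": [r.event for r in table.records],
        }
    ).to_csv(path, sep="\t", index=False, float_format="%.6f")


def read_essentiality_table(path: str | Path) -> EssentialityTable:
    """Parse a gene_id + one-p-value-column-per-cell-line TSV; blanks allowed."""
    t = pd.read_csv(path, sep="\t", index_col=0)
    return EssentialityTable(
        gene_ids=tuple(str(g) for g in t.index),
        cell_line_ids=tuple(str(c) for c in t.columns),
        pvalues=t.to_numpy(dtype=float),
    )


def write_essentiality_table(table: EssentialityTable, path: str | Path) -> None:
    table.to_frame().to_csv(
        path, sep="\t", index_label="gene_id", float_format="%.6g", na_rep=""
    )
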