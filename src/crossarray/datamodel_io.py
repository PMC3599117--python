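"""Core data types and tab-delimited readers/writers.

Every table the pipeline touches is plain UTF-8 tab-delimited text:

* expression tables — header row of sample IDs, first column of feature IDs,
  missing values encoded as the literal ``NA``;
* annotation maps — two columns, platform probe ID -> common identifier;
* sample-info tables — ``Array.name  Sample.name  Batch  Covariate ...``
  (a leading index column in input is tolerated and ignored).

Identifiers are case-sensitive throughout; decimal point only, scientific
notation accepted.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .exceptions import ValidationError

__all__ = [
    "ExpressionDataset",
    "AnnotationMap",
    "SampleInfoTable",
    "BatchProvenance",
    "MergedDataset",
    "ALLOWED_SCALES",
    "ALLOWED_PRECISIONS",
    "read_expression_table",
    "write_expression_table",
    "read_annotation_map",
    "read_sample_info",
    "write_sample_info",
    "create_sample_info_template",
    "write_merged",
    "read_merged",
]

ALLOWED_SCALES = ("linear", "log2", "log10")
ALLOWED_PRECISIONS = (12, 14, 16, 20)

MISSING_TOKEN = "NA"

SAMPLE_INFO_COLUMNS = ("Array.name", "Sample.name", "Batch")


def _check_unique(ids: Sequence[str], what: str) -> None:
    index = pd.Index(ids)
    if index.has_duplicates:
        dupes = sorted(set(index[index.duplicated()]))
        raise ValidationError(f"duplicate {what}: {', '.join(map(str, dupes))}")


@dataclass
class ExpressionDataset:
    """A feature x sample intensity matrix from one batch / platform.

    ``values`` is a float DataFrame whose index holds feature IDs and whose
    columns hold sample IDs.  ``scale`` is one of ``linear``/``log2``/
    ``log10`` or ``None`` when unknown; ``precision_bits`` is the scanner
    A/D-converter depth (12/14/16/20) or ``None`` when unknown.
    ``annotation_name`` names the identifier namespace currently on the rows
    (the platform's probe namespace until :func:`annotate_features` runs).
    """

    values: pd.DataFrame
    scale: str | None = None
    precision_bits: int | None = None
    batch: str = ""
    annotation_name: str = "probe"
    #: feature count before annotation/collapsing, for provenance reporting
    original_features: int | None = None
    #: set by annotate_features: duplicated IDs are legal until collapsed
    allow_duplicate_features: bool = False

    def __post_init__(self) -> None:
        if not isinstance(self.values, pd.DataFrame):
            self.values = pd.DataFrame(self.values)
        if self.values.shape[0] == 0 or self.values.shape[1] == 0:
            raise ValidationError("expression matrix is empty")
        if self.scale is not None and self.scale not in ALLOWED_SCALES:
            raise ValidationError(
                f"unknown scale {self.scale!r}; expected one of {ALLOWED_SCALES}"
            )
        if self.precision_bits is not None and self.precision_bits not in ALLOWED_PRECISIONS:
            raise ValidationError(
                f"precision_bits must be one of {ALLOWED_PRECISIONS}, got {self.precision_bits}"
            )
        if not self.allow_duplicate_features:
            _check_unique(self.values.index, "feature IDs")
        _check_unique(self.values.columns, "sample IDs")
        arr = self.values.to_numpy()
        if np.isinf(arr).any():
            raise ValidationError("expression matrix contains infinite values")

    @property
    def feature_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)

    @property
    def n_features(self) -> int:
        return self.values.shape[0]

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]

    def with_values(self, values: pd.DataFrame, **changes) -> "ExpressionDataset":
        return replace(self, values=values, **changes)


@dataclass
class AnnotationMap:
    """Many-to-one map from platform probe IDs to a common identifier.

    A probe maps to at most one common identifier; a common identifier may be
    targeted by many probes.  Probes without a mapping are simply absent.
    """

    namespace: str
    entries: dict[str, str]
    n_skipped: int = 0

    def __post_init__(self) -> None:
        if not self.namespace:
            raise ValidationError("annotation namespace must be non-empty")
        for probe, common in self.entries.items():
            if not common:
                raise ValidationError(f"empty common identifier for probe {probe!r}")

    def __len__(self) -> int:
        return len(self.entries)

    @property
    def common_ids(self) -> set[str]:
        return set(self.entries.values())


@dataclass
class SampleInfoTable:
    """Per-sample batch and covariate assignments.

    Stored as a DataFrame with columns ``Array.name``, ``Sample.name``,
    ``Batch`` and zero or more covariate columns (all strings).
    """

    table: pd.DataFrame

    def __post_init__(self) -> None:
        cols = list(self.table.columns)
        if cols[:3] != list(SAMPLE_INFO_COLUMNS):
            raise ValidationError(
                f"sample_info columns must start with {SAMPLE_INFO_COLUMNS}, got {cols[:3]}"
            )
        self.table = self.table.astype(str)
        _check_unique(self.table["Sample.name"], "sample names in sample_info")
        empty_batch = self.table["Batch"].isin(["", "nan"])
        if empty_batch.any():
            bad = self.table.loc[empty_batch, "Sample.name"].tolist()
            raise ValidationError(f"missing batch for samples: {', '.join(bad)}")
        for col in self.covariate_columns:
            blank = self.table[col].isin([""])
            if blank.any():
                bad = self.table.loc[blank, "Sample.name"].tolist()
                raise ValidationError(
                    f"ragged covariate column {col!r}: empty for samples {', '.join(bad)}"
                )

    @property
    def sample_names(self) -> list[str]:
        return list(self.table["Sample.name"])

    @property
    def covariate_columns(self) -> list[str]:
        return [c for c in self.table.columns if c not in SAMPLE_INFO_COLUMNS]

    def batch_of(self) -> pd.Series:
        return pd.Series(
            self.table["Batch"].to_numpy(), index=self.table["Sample.name"].to_numpy()
        )

    def subset(self, sample_ids: Sequence[str]) -> "SampleInfoTable":
        missing = [s for s in sample_ids if s not in set(self.sample_names)]
        if missing:
            raise ValidationError(
                f"samples absent from sample_info: {', '.join(missing)}"
            )
        t = self.table.set_index("Sample.name", drop=False).loc[list(sample_ids)]
        return SampleInfoTable(t.reset_index(drop=True))


@dataclass
class BatchProvenance:
    original_features: int
    collapsed_features: int

    def __post_init__(self) -> None:
        if self.collapsed_features > self.original_features:
            raise ValidationError(
                "collapsed feature count exceeds original feature count"
            )


@dataclass
class MergedDataset:
    """Intersected multi-batch expression matrix with per-sample batch labels."""

    values: pd.DataFrame
    batch_of_sample: pd.Series
    sample_info: SampleInfoTable | None = None
    provenance: dict[str, BatchProvenance] = field(default_factory=dict)
    scale: str | None = "log2"
    precision_bits: int | None = None
    annotation_name: str = ""
    #: True once a discretizing correction (QD/NorDi) has replaced intensities
    discretized: bool = False

    def __post_init__(self) -> None:
        _check_unique(self.values.index, "feature IDs")
        _check_unique(self.values.columns, "sample IDs")
        if list(self.batch_of_sample.index) != list(self.values.columns):
            raise ValidationError("batch_of_sample index must equal the sample columns")
        merged = self.merged_features
        for batch, prov in self.provenance.items():
            if merged > prov.collapsed_features:
                raise ValidationError(
                    f"merged feature count {merged} exceeds collapsed count "
                    f"{prov.collapsed_features} for batch {batch!r}"
                )

    @property
    def feature_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)

    @property
    def merged_features(self) -> int:
        return self.values.shape[0]

    @property
    def batches(self) -> list[str]:
        seen: list[str] = []
        for b in self.batch_of_sample:
            if b not in seen:
                seen.append(b)
        return seen

    def with_values(self, values: pd.DataFrame, **changes) -> "MergedDataset":
        return replace(self, values=values, **changes)


# ---------------------------------------------------------------------------
# readers / writers
# ---------------------------------------------------------------------------


def _read_header(path: Path) -> list[str]:
    with open(path, encoding="utf-8") as fh:
        first = fh.readline().rstrip("\n")
    if not first:
        raise ValidationError(f"{path}: empty table")
    return first.split("\t")


def read_expression_table(
    path: str | Path,
    scale_hint: str | None = None,
    precision_hint: int | None = None,
    batch_label: str | None = None,
) -> ExpressionDataset:
    """Read a feature x sample expression table.

    The header row holds sample IDs (the first header cell names the feature
    column and is ignored); the first column holds feature IDs.  ``NA`` marks
    a missing value.  Duplicated feature or sample IDs and non-numeric cells
    are hard errors that name the offender.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"expression table not found: {path}")
    header = _read_header(path)
    sample_ids = header[1:]
    if not sample_ids:
        raise ValidationError(f"{path}: no sample columns")
    _check_unique(sample_ids, f"sample IDs in {path.name}")

    raw = pd.read_csv(
        path, sep="\t", index_col=0, dtype=str, keep_default_na=False, encoding="utf-8"
    )
    if raw.shape[0] == 0:
        raise ValidationError(f"{path}: table has no feature rows")
    raw.index = raw.index.astype(str)
    _check_unique(raw.index, f"feature IDs in {path.name}")

    # astype(float) is correctly rounded (bit-exact round trips); to_numeric is not
    def _convert(col: pd.Series) -> pd.Series:
        col = col.replace(MISSING_TOKEN, np.nan)
        try:
            return col.astype(float)
        except (ValueError, TypeError):
            return pd.to_numeric(col, errors="coerce")

    values = raw.apply(_convert)
    bad = values.isna() & (raw != MISSING_TOKEN)
    if bad.to_numpy().any():
        rows, cols = np.nonzero(bad.to_numpy())
        where = ", ".join(
            f"(row {raw.index[r]!r}, column {raw.columns[c]!r})"
            for r, c in list(zip(rows, cols))[:5]
        )
        raise ValidationError(f"{path}: non-numeric cells at {where}")
    values.columns = sample_ids

    return ExpressionDataset(
        values=values.astype(float),
        scale=scale_hint,
        precision_bits=precision_hint,
        batch=batch_label if batch_label is not None else path.stem,
    )


def write_expression_table(values: pd.DataFrame, path: str | Path) -> Path:
    path = Path(path)
    values.to_csv(path, sep="\t", na_rep=MISSING_TOKEN, index_label="ID")
    return path


def read_annotation_map(path: str | Path, namespace: str = "SYMBOL") -> AnnotationMap:
    """Read a two-column probe -> common-identifier map.

    An optional header row is detected (and dropped) when its second field
    matches the namespace name or common header words.  Rows with an empty
    common identifier are skipped and counted; a probe appearing with two
    different common identifiers is an ambiguity error.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"annotation map not found: {path}")
    entries: dict[str, str] = {}
    skipped = 0
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) < 2:
                parts = parts + [""]
            probe, common = parts[0], parts[1]
            if lineno == 1 and common and (
                common.upper() in {"SYMBOL", "ENTREZID", "UNIGENE", "ENSEMBL", "ID", "GENE"}
                or common == namespace
            ) and probe.lower() in {"probe", "probe_id", "probeid", "id", ""}:
                continue  # header row
            if not common or common == MISSING_TOKEN:
                skipped += 1
                continue
            if probe in entries and entries[probe] != common:
                raise ValidationError(
                    f"{path}: ambiguous annotation for probe {probe!r}: "
                    f"{entries[probe]!r} vs {common!r}"
                )
            entries[probe] = common
    return AnnotationMap(namespace=namespace, entries=entries, n_skipped=skipped)


def read_sample_info(path: str | Path) -> SampleInfoTable:
    """Read a sample-info table (Array.name / Sample.name / Batch / covariates).

    A leading unnamed index column is tolerated and dropped.  Column names
    beyond the first three are kept as covariate names; unnamed positions get
    ``Covariate``, ``Covariate.2``, ...
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"sample_info file not found: {path}")
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False, encoding="utf-8")
    if df.shape[0] == 0:
        raise ValidationError(f"{path}: sample_info has no rows")
    first = str(df.columns[0])
    if first == "" or first.startswith("Unnamed"):
        df = df.iloc[:, 1:]
    if df.shape[1] < 3:
        raise ValidationError(
            f"{path}: sample_info needs at least 3 columns (array, sample, batch)"
        )
    names = list(SAMPLE_INFO_COLUMNS)
    for k in range(3, df.shape[1]):
        names.append(str(df.columns[k]) if str(df.columns[k]) else _covariate_name(k - 3))
    # ensure covariate names unique
    seen: dict[str, int] = {}
    uniq = []
    for n in names:
        if n in seen:
            seen[n] += 1
            uniq.append(f"{n}.{seen[n]}")
        else:
            seen[n] = 1
            uniq.append(n)
    df.columns = uniq
    return SampleInfoTable(df.reset_index(drop=True))


def _covariate_name(i: int) -> str:
    return "Covariate" if i == 0 else f"Covariate.{i + 1}"


def write_sample_info(info: SampleInfoTable, path: str | Path) -> Path:
    path = Path(path)
    info.table.to_csv(path, sep="\t", index=False)
    return path


def create_sample_info_template(
    datasets: Sequence[ExpressionDataset], path: str | Path
) -> Path:
    """Write a sample-info template: one row per sample, batch taken from the
    dataset's label, and the covariate column pre-filled with running numbers
    for the user to replace with group names."""
    if not datasets:
        raise ValidationError("no datasets given for sample_info template")
    rows = []
    counter = 1
    for ds in datasets:
        for sample in ds.sample_ids:
            rows.append((sample, sample, ds.batch, str(counter)))
            counter += 1
    df = pd.DataFrame(rows, columns=list(SAMPLE_INFO_COLUMNS) + ["Covariate"])
    info = SampleInfoTable(df)
    return write_sample_info(info, path)


def write_merged(merged: MergedDataset, path_prefix: str | Path) -> dict[str, Path]:
    """Write a merged dataset as three tab-delimited files.

    ``<prefix>_expression.tsv`` (features sorted lexicographically),
    ``<prefix>_sample_info.txt`` and ``<prefix>_coverage.tsv`` (one row per
    batch plus a merged-count row).  Returns the paths written.
    """
    from .annotate_merge import coverage_report  # local import to avoid a cycle

    prefix = Path(path_prefix)
    prefix.parent.mkdir(parents=True, exist_ok=True)
    expr_path = prefix.parent / (prefix.name + "_expression.tsv")
    info_path = prefix.parent / (prefix.name + "_sample_info.txt")
    cov_path = prefix.parent / (prefix.name + "_coverage.tsv")

    write_expression_table(merged.values.sort_index(), expr_path)

    if merged.sample_info is not None:
        info = merged.sample_info.subset(merged.sample_ids)
    else:
        rows = [
            (s, s, merged.batch_of_sample[s]) for s in merged.sample_ids
        ]
        info = SampleInfoTable(pd.DataFrame(rows, columns=list(SAMPLE_INFO_COLUMNS)))
    write_sample_info(info, info_path)

    if merged.provenance:
        report = coverage_report(merged)
        table = report.to_dataframe()
    else:
        table = pd.DataFrame(
            columns=["Batch", "Original feat. num.", "Collapsed feat. num.",
                     "Merged feat. num.", "Overlap"]
        )
    with open(cov_path, "w", encoding="utf-8") as fh:
        table.to_csv(fh, sep="\t", index=False)
        fh.write(f"merged\t\t\t{merged.merged_features}\t\n")
    return {"expression": expr_path, "sample_info": info_path, "coverage": cov_path}


def read_merged(
    expression_path: str | Path,
    sample_info_path: str | Path | None = None,
    scale: str | None = "log2",
    precision_bits: int | None = None,
    annotation_name: str = "",
) -> MergedDataset:
    """Re-assemble a MergedDataset from a written expression table and
    sample-info file (batch labels come from the sample_info Batch column;
    without a sample_info file, all samples fall into one batch)."""
    ds = read_expression_table(expression_path, scale_hint=scale,
                               precision_hint=precision_bits, batch_label="merged")
    if sample_info_path is not None:
        info = read_sample_info(sample_info_path).subset(ds.sample_ids)
        batch = pd.Series(
            info.batch_of().loc[ds.sample_ids].to_numpy(), index=ds.sample_ids
        )
    else:
        info = None
        batch = pd.Series(["merged"] * ds.n_samples, index=ds.sample_ids)
    return MergedDataset(
        values=ds.values,
        batch_of_sample=batch,
        sample_info=info,
        scale=scale,
        precision_bits=precision_bits,
        annotation_name=annotation_name,
    )
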