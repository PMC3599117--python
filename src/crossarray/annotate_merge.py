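"""Re-annotation, probe collapsing, intersection and coverage statistics.

The cross-platform merge rests on three steps: translate each platform's
probe IDs into a common identifier namespace (gene symbols by default),
collapse probes targeting the same identifier to a single row (median by
default, mean and Tukey median polish also supported), and keep only the
identifiers present on every platform.  Coverage statistics record, per
batch, the original and collapsed feature counts and the fraction of
collapsed features that survive the intersection.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np
import pandas as pd

from .datamodel_io import (
    AnnotationMap,
    BatchProvenance,
    ExpressionDataset,
    MergedDataset,
    SampleInfoTable,
)
from .exceptions import ValidationError

__all__ = [
    "annotate_features",
    "collapse_features",
    "intersect_and_merge",
    "CoverageReport",
    "coverage_report",
    "median_polish_summary",
]


def annotate_features(ds: ExpressionDataset, mapping: AnnotationMap) -> ExpressionDataset:
    """Replace probe IDs by common identifiers; drop unmapped probes.

    The result may contain duplicated feature IDs (several probes per gene)
    and must be collapsed before merging.
    """
    common = ds.values.index.map(lambda p: mapping.entries.get(p))
    keep = np.asarray(pd.notna(common))
    n_mapped = int(keep.sum())
    if n_mapped == 0:
        raise ValidationError(
            f"no probes of batch {ds.batch!r} found in the {mapping.namespace} map; "
            "wrong annotation map supplied?"
        )
    values = ds.values.loc[keep].copy()
    values.index = pd.Index(common[keep], name=mapping.namespace)
    return ds.with_values(
        values,
        annotation_name=mapping.namespace,
        original_features=ds.original_features or ds.n_features,
        allow_duplicate_features=True,
    )


def median_polish_summary(mat: np.ndarray, max_iter: int = 10, tol: float = 1e-6) -> np.ndarray:
    """Tukey median polish of a probe x sample block; returns the fitted
    overall + column effects as the collapsed row (NaN-aware)."""
    resid = np.array(mat, dtype=float)
    nrow, ncol = resid.shape
    overall = 0.0
    row_eff = np.zeros(nrow)
    col_eff = np.zeros(ncol)
    last = np.inf
    for _ in range(max_iter):
        rmed = np.nanmedian(resid, axis=1)
        rmed = np.where(np.isnan(rmed), 0.0, rmed)
        resid -= rmed[:, None]
        row_eff += rmed
        shift = np.median(row_eff)
        row_eff -= shift
        overall += shift
        cmed = np.nanmedian(resid, axis=0)
        cmed = np.where(np.isnan(cmed), 0.0, cmed)
        resid -= cmed[None, :]
        col_eff += cmed
        shift = np.median(col_eff)
        col_eff -= shift
        overall += shift
        total = np.nansum(np.abs(resid))
        if abs(last - total) <= tol * max(total, 1.0):
            break
        last = total
    return overall + col_eff


def collapse_features(
    ds: ExpressionDataset,
    method: str | Callable[[np.ndarray], np.ndarray] = "median",
) -> ExpressionDataset:
    """Collapse redundant rows sharing one identifier to a single row.

    ``method`` is ``"median"`` (default), ``"mean"``, ``"medpolish"`` or a
    callable mapping a probe x sample block (2-D array, possibly with NaN) to
    one row of per-sample values.  Missing values are excluded per cell;
    identifiers whose collapsed row is entirely missing are dropped.  The
    output has unique, lexicographically sorted feature IDs.
    """
    if ds.n_features == 0:
        raise ValidationError("cannot collapse an empty dataset")
    if isinstance(method, str):
        if method == "median":
            collapsed = ds.values.groupby(level=0, sort=True).median()
        elif method == "mean":
            collapsed = ds.values.groupby(level=0, sort=True).mean()
        elif method == "medpolish":
            collapsed = _collapse_by_block(ds.values, median_polish_summary)
        else:
            raise ValidationError(
                f"unknown collapse method {method!r}; use median, mean, medpolish or a callable"
            )
    elif callable(method):
        collapsed = _collapse_by_block(ds.values, method)
    else:
        raise ValidationError("collapse method must be a string or callable")
    collapsed = collapsed.loc[~collapsed.isna().all(axis=1)]
    if collapsed.shape[0] == 0:
        raise ValidationError("all identifiers are entirely missing after collapse")
    collapsed = collapsed.sort_index()
    return ds.with_values(collapsed, allow_duplicate_features=False)


def _collapse_by_block(values: pd.DataFrame, fn: Callable[[np.ndarray], np.ndarray]) -> pd.DataFrame:
    out: dict[str, np.ndarray] = {}
    for ident, block in values.groupby(level=0, sort=True):
        mat = block.to_numpy(dtype=float)
        if mat.shape[0] == 1:
            out[ident] = mat[0]
        else:
            row = np.asarray(fn(mat), dtype=float)
            if row.shape != (mat.shape[1],):
                raise ValidationError(
                    "collapse callable must return one value per sample"
                )
            out[ident] = row
    return pd.DataFrame.from_dict(out, orient="index", columns=values.columns)


def intersect_and_merge(
    datasets: Sequence[ExpressionDataset],
    sample_info: SampleInfoTable | None = None,
) -> MergedDataset:
    """Build the merged matrix over the identifiers present in all datasets.

    Non-matching rows are discarded; features come out sorted
    lexicographically and sample columns are concatenated in input-list
    order, each sample carrying its dataset's batch label.
    """
    if len(datasets) < 2:
        raise ValidationError("need at least two datasets to merge")
    ref = datasets[0]
    for ds in datasets:
        if ds.allow_duplicate_features or pd.Index(ds.feature_ids).has_duplicates:
            raise ValidationError(
                f"batch {ds.batch!r} still has duplicate feature IDs; collapse first"
            )
        if ds.annotation_name != ref.annotation_name:
            raise ValidationError(
                f"annotation namespace mismatch: {ds.annotation_name!r} vs {ref.annotation_name!r}"
            )
        if ds.scale != ref.scale:
            raise ValidationError(f"scale mismatch: {ds.scale!r} vs {ref.scale!r}")
        if ds.precision_bits != ref.precision_bits:
            raise ValidationError(
                f"precision mismatch: {ds.precision_bits} vs {ref.precision_bits} bits"
            )
    all_samples = [s for ds in datasets for s in ds.sample_ids]
    if len(set(all_samples)) != len(all_samples):
        dupes = sorted({s for s in all_samples if all_samples.count(s) > 1})
        raise ValidationError(f"duplicate sample IDs across datasets: {', '.join(dupes)}")

    common = set(datasets[0].feature_ids)
    for ds in datasets[1:]:
        common &= set(ds.feature_ids)
    if not common:
        raise ValidationError("empty intersection: no identifier is present in all datasets")
    features = sorted(common)

    blocks = [ds.values.loc[features] for ds in datasets]
    values = pd.concat(blocks, axis=1)
    batch = pd.Series(
        [ds.batch for ds in datasets for _ in ds.sample_ids], index=all_samples
    )
    provenance = {
        ds.batch: BatchProvenance(
            original_features=ds.original_features or ds.n_features,
            collapsed_features=ds.n_features,
        )
        for ds in datasets
    }
    if sample_info is not None:
        sample_info = sample_info.subset(all_samples)
        declared = sample_info.batch_of()
        for s in all_samples:
            if declared[s] != batch[s]:
                raise ValidationError(
                    f"sample {s!r}: sample_info batch {declared[s]!r} does not match "
                    f"dataset batch {batch[s]!r}"
                )
    return MergedDataset(
        values=values,
        batch_of_sample=batch,
        sample_info=sample_info,
        provenance=provenance,
        scale=ref.scale,
        precision_bits=ref.precision_bits,
        annotation_name=ref.annotation_name,
    )


@dataclass
class CoverageReport:
    """Per-batch feature coverage through the pipeline.

    ``rows`` holds (batch, original, collapsed, merged, overlap_percent);
    overlap = merged / collapsed, reported as percent rounded to one decimal.
    """

    rows: list[tuple[str, int, int, int, float]]

    @classmethod
    def from_counts(
        cls, counts: dict[str, tuple[int, int]], merged_features: int
    ) -> "CoverageReport":
        """Build a report from per-batch (original, collapsed) counts and the
        global merged feature count."""
        rows = []
        for batch, (original, collapsed) in counts.items():
            rows.append(
                (batch, original, collapsed, merged_features,
                 overlap_percent(merged_features, collapsed))
            )
        return cls(rows)

    def to_dataframe(self) -> pd.DataFrame:
        df = pd.DataFrame(
            self.rows,
            columns=["Batch", "Original feat. num.", "Collapsed feat. num.",
                     "Merged feat. num.", "Overlap"],
        )
        df["Overlap"] = df["Overlap"].map(lambda p: f"{p:.1f}%")
        return df

    def overlap_of(self, batch: str) -> float:
        for row in self.rows:
            if row[0] == batch:
                return row[4]
        raise KeyError(batch)


def overlap_percent(merged: int, collapsed: int) -> float:
    if not 0 < merged <= collapsed:
        raise ValidationError(
            f"invalid counts: merged={merged} must lie in (0, collapsed={collapsed}]"
        )
    return round(100.0 * merged / collapsed, 1)


def coverage_report(merged: MergedDataset) -> CoverageReport:
    """Coverage statistics of a merged dataset from its provenance counts."""
    if not merged.provenance:
        raise ValidationError("merged dataset has no provenance counts")
    counts = {
        b: (p.original_features, p.collapsed_features)
        for b, p in merged.provenance.items()
    }
    return CoverageReport.from_counts(counts, merged.merged_features)
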