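"""Scale and precision harmonization.

Datasets from different scanners arrive on different scales (linear, log2,
log10) and different analog-digital-converter depths (12/14/16/20 bit; a
16-bit scanner reports 0..65535, a 20-bit scanner 0..1048575).  Before any
cross-platform merge every dataset is brought to log2 scale and one common
bit depth.  Precision rescaling multiplies log2 values by the ratio of
target to source bits, so a 20-bit log2 value of 20.0 becomes 16.0 at a
16-bit target; the operation is exactly invertible.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .datamodel_io import ALLOWED_PRECISIONS, ExpressionDataset
from .exceptions import NumericalError, ValidationError

__all__ = ["PrecisionSpec", "to_log2", "rescale_precision", "detect_precision", "harmonize_dataset"]

_LOG2_10 = math.log2(10.0)


@dataclass(frozen=True)
class PrecisionSpec:
    bits: int

    def __post_init__(self) -> None:
        if self.bits not in ALLOWED_PRECISIONS:
            raise ValidationError(
                f"precision must be one of {ALLOWED_PRECISIONS}, got {self.bits}"
            )

    @property
    def max_intensity(self) -> int:
        return 2 ** self.bits - 1


def to_log2(ds: ExpressionDataset) -> ExpressionDataset:
    """Return the dataset on log2 scale (identity if already log2)."""
    if ds.scale == "log2":
        return ds
    if ds.scale == "linear":
        arr = ds.values.to_numpy()
        n_bad = int(np.sum(arr[np.isfinite(arr)] <= 0))
        if n_bad:
            raise NumericalError(
                f"cannot log2-transform linear data: {n_bad} cells are <= 0"
            )
        return ds.with_values(np.log2(ds.values), scale="log2")
    if ds.scale == "log10":
        return ds.with_values(ds.values * _LOG2_10, scale="log2")
    raise ValidationError(
        "dataset scale is unknown; supply a scale hint (linear, log2 or log10)"
    )


def rescale_precision(ds: ExpressionDataset, target: PrecisionSpec | int) -> ExpressionDataset:
    """Rescale log2 values from the source bit depth to ``target`` bits.

    Each log2 value x becomes x * target_bits / source_bits; e.g. data from a
    20-bit scanner are divided by 20 and multiplied by 16 for a 16-bit target.
    """
    if isinstance(target, int):
        target = PrecisionSpec(target)
    if ds.scale != "log2":
        raise ValidationError("rescale_precision requires log2-scale data; run to_log2 first")
    if ds.precision_bits is None:
        raise ValidationError(
            "source precision unknown; use detect_precision or supply a hint"
        )
    if ds.precision_bits == target.bits:
        return ds
    # literal divide-then-multiply so e.g. 20-bit data become x / 20 * 16
    rescaled = ds.values / ds.precision_bits * target.bits
    return ds.with_values(rescaled, precision_bits=target.bits)


def detect_precision(ds: ExpressionDataset) -> PrecisionSpec:
    """Empirically determine the bit depth from the data's dynamic range.

    Returns the smallest allowed depth b such that the maximum linear-scale
    intensity fits in 0 .. 2^b - 1.
    """
    if ds.scale is None:
        raise ValidationError("detect_precision requires a known scale")
    arr = ds.values.to_numpy()
    finite = arr[np.isfinite(arr)]
    if finite.size == 0:
        raise ValidationError("cannot detect precision: all values are missing")
    peak = float(finite.max())
    if ds.scale == "log2":
        linear_peak = 2.0 ** peak
    elif ds.scale == "log10":
        linear_peak = 10.0 ** peak
    else:
        linear_peak = peak
    for bits in ALLOWED_PRECISIONS:
        if linear_peak <= 2 ** bits - 1:
            return PrecisionSpec(bits)
    raise NumericalError(
        f"maximum linear intensity {linear_peak:.6g} exceeds the 20-bit range"
    )


def harmonize_dataset(
    ds: ExpressionDataset, target_bits: int = 16
) -> ExpressionDataset:
    """Convenience: detect precision if unknown, go to log2, rescale to target."""
    if ds.precision_bits is None:
        ds = ds.with_values(ds.values, precision_bits=detect_precision(ds).bits)
    ds = to_log2(ds)
    return rescale_precision(ds, PrecisionSpec(target_bits))
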