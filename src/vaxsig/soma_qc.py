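"""SomaScan plate calibration and acceptance gates.

Each plate carries replicate wells of a pooled calibrator serum and of a
pooled QC serum. Calibration compares the plate's per-SOMAmer calibrator
median with a stored reference: the per-feature ratio
``reference / plate_median`` is the Calibration Scale Factor, and the
median of those ratios is the Plate Scale Factor. After applying the
per-feature factors, plate calibrator medians equal the reference exactly.

Acceptance requires the Plate Scale Factor within [0.4, 2.5] and at
least 85% of per-SOMAmer QC ratios (QC reference / plate QC median)
within [0.8, 1.2]; both intervals closed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .datatypes import ValidationError

PLATE_SCALE_RANGE = (0.4, 2.5)
QC_RATIO_RANGE = (0.8, 1.2)
QC_FRACTION_MIN = 0.85


@dataclass
class PlateCalibration:
    per_feature_scale: pd.Series  # feature -> reference / plate calibrator median
    plate_scale_factor: float
    qc_ratios: pd.Series | None = None
    notes: list[str] = field(default_factory=list)


def calibrate_plate(
    calibrator_replicates: pd.DataFrame,
    calibrator_reference: pd.Series,
    qc_replicates: pd.DataFrame | None = None,
    qc_reference: pd.Series | None = None,
) -> PlateCalibration:
    """Derive per-feature calibration scale factors for one plate.

    ``calibrator_replicates`` is features x replicate wells;
    ``calibrator_reference`` the stored per-feature reference RFU. QC
    tables, when given, produce the post-calibration accuracy ratios the
    acceptance gate inspects.
    """
    if calibrator_replicates.shape[1] < 1:
        raise ValidationError("need at least one calibrator replicate")
    missing = calibrator_replicates.index.difference(calibrator_reference.index)
    if len(missing):
        raise ValidationError(f"reference lacks features: {missing.tolist()[:5]}")
    ref = calibrator_reference.loc[calibrator_replicates.index].astype(float)
    med = calibrator_replicates.median(axis=1).astype(float)
    if (med <= 0).any():
        bad = med.index[med <= 0].tolist()
        raise ValidationError(f"non-positive calibrator median for: {bad[:5]}")
    scale = ref / med
    psf = float(scale.median())
    qc_ratios = None
    if qc_replicates is not None:
        if qc_reference is None:
            raise ValidationError("qc_replicates given without qc_reference")
        qc_med = qc_replicates.median(axis=1).astype(float)
        # QC accuracy is assessed after applying the calibration scale
        qc_scaled = qc_med * scale.reindex(qc_med.index)
        qc_ratios = qc_reference.loc[qc_med.index].astype(float) / qc_scaled
    return PlateCalibration(
        per_feature_scale=scale, plate_scale_factor=psf, qc_ratios=qc_ratios
    )


def apply_calibration(values: pd.DataFrame, calibration: PlateCalibration) -> pd.DataFrame:
    """Multiply each feature row by its Calibration Scale Factor."""
    scale = calibration.per_feature_scale.reindex(values.index)
    if scale.isna().any():
        raise ValidationError("calibration lacks scale factors for some features")
    return values.mul(scale, axis=0)


@dataclass
class QCReport:
    passed: bool
    plate_scale_factor: float
    qc_fraction_in_range: float | None
    diagnostics: list[str]


def qc_gate(calibration: PlateCalibration) -> QCReport:
    """Plate acceptance: scale factor in [0.4, 2.5] and >= 85% of QC
    ratios in [0.8, 1.2]. Diagnostics name each failing criterion."""
    diags: list[str] = []
    psf = calibration.plate_scale_factor
    lo, hi = PLATE_SCALE_RANGE
    if not lo <= psf <= hi:
        diags.append(f"plate scale factor {psf:.4g} outside [{lo}, {hi}]")
    frac = None
    if calibration.qc_ratios is not None and len(calibration.qc_ratios):
        r = calibration.qc_ratios.to_numpy(dtype=float)
        qlo, qhi = QC_RATIO_RANGE
        frac = float(((r >= qlo) & (r <= qhi)).mean())
        if frac < QC_FRACTION_MIN:
            diags.append(
                f"only {frac:.1%} of QC ratios within [{qlo}, {qhi}] "
                f"(need >= {QC_FRACTION_MIN:.0%})"
            )
    return QCReport(
        passed=not diags,
        plate_scale_factor=psf,
        qc_fraction_in_range=frac,
        diagnostics=diags,
    )
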