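"""Absolute RT-qPCR quantification via per-assay standard curves.

Each miRNA assay is calibrated with a dilution series of a synthetic
oligonucleotide of known concentration (typically decade steps over
1 fM – 1e5 fM).  The threshold cycle Cq is linear in log10 concentration,

    Cq = intercept + slope * log10(conc),

with slope close to -1/log10(2) = -3.32 for perfect doubling per cycle.
Fitting that line (OLS) and inverting it converts measured Cq values into
absolute concentrations.  Because stable endogenous reference species are
degraded in serum, quantities are normalized to serum volume rather than
to a housekeeping gene.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from .errors import DataError, ParameterError

__all__ = [
    "StandardCurve",
    "QuantResult",
    "fit_standard_curve",
    "cq_to_concentration",
    "quantify_samples",
    "MAX_CYCLES",
    "EFFICIENCY_SLOPE_RANGE",
    "REPLICATE_SPREAD_MAX",
]

#: qPCR run length; wells with no Cq by this cycle are "non-amplified".
MAX_CYCLES = 40.0

#: Advisory slope band corresponding to ~80-115% amplification efficiency.
EFFICIENCY_SLOPE_RANGE = (-3.9, -3.0)

#: Replicate Cq range (max - min) above which a spread warning is raised.
REPLICATE_SPREAD_MAX = 1.0


@dataclass(frozen=True)
class StandardCurve:
    """Linear Cq-vs-log10(concentration) calibration for one miRNA assay.

    ``intercept`` is the Cq at 1 fM (log10 conc = 0); ``slope`` is the Cq
    change per decade of concentration and must be negative.  ``conc_range``
    records the calibrated span; inversions outside it are extrapolations.
    """

    mirna_id: str
    intercept: float
    slope: float
    r_squared: float = 1.0
    conc_range: tuple[float, float] = (1.0, 1e5)
    efficiency_warning: bool = False

    def __post_init__(self) -> None:
        if not self.slope < 0:
            raise ParameterError(
                f"standard curve for {self.mirna_id!r}: slope must be < 0, "
                f"got {self.slope}"
            )
        if not self.conc_range[0] > 0:
            raise ParameterError(
                f"standard curve for {self.mirna_id!r}: conc_range.min must be > 0"
            )

    @property
    def amplification_efficiency(self) -> float:
        """Per-cycle efficiency implied by the slope (1.0 == perfect doubling)."""
        return 10.0 ** (-1.0 / self.slope) - 1.0


def fit_standard_curve(
    known_concs: Iterable[float],
    cq_values: Iterable[float],
    mirna_id: str = "",
) -> StandardCurve:
    """Fit the calibration line Cq = intercept + slope*log10(conc) by OLS.

    Requires at least three distinct positive concentrations.  Sets an
    advisory ``efficiency_warning`` if the slope falls outside
    ``EFFICIENCY_SLOPE_RANGE`` (never fatal).
    """
    conc = np.asarray(list(known_concs), dtype=float)
    cq = np.asarray(list(cq_values), dtype=float)
    if conc.shape != cq.shape:
        raise DataError("known_concs and cq_values must have equal length")
    if np.any(conc <= 0):
        raise DataError("standard-curve concentrations must be > 0")
    if np.unique(conc).size < 3:
        raise DataError(
            f"standard curve needs >= 3 distinct concentrations, "
            f"got {np.unique(conc).size}"
        )
    if not np.all(np.isfinite(cq)):
        raise DataError("standard-curve Cq values must be finite")

    x = np.log10(conc)
    slope, intercept = np.polyfit(x, cq, 1)
    fitted = intercept + slope * x
    ss_res = float(np.sum((cq - fitted) ** 2))
    ss_tot = float(np.sum((cq - cq.mean()) ** 2))
    r2 = 1.0 if ss_tot == 0 else max(0.0, 1.0 - ss_res / ss_tot)
    lo, hi = EFFICIENCY_SLOPE_RANGE
    return StandardCurve(
        mirna_id=mirna_id,
        intercept=float(intercept),
        slope=float(slope),
        r_squared=min(r2, 1.0),
        conc_range=(float(conc.min()), float(conc.max())),
        efficiency_warning=not (lo <= slope <= hi),
    )


def cq_to_concentration(cq, curve: StandardCurve):
    """Invert the standard curve: concentration = 10**((cq - intercept)/slope).

    Accepts a scalar or array of Cq values; extrapolations beyond the
    calibrated range are returned as-is (callers flag them, see
    :func:`quantify_samples`).
    """
    arr = np.asarray(cq, dtype=float)
    if not np.all(np.isfinite(arr)):
        raise DataError("Cq values must be finite")
    conc = 10.0 ** ((arr - curve.intercept) / curve.slope)
    if np.isscalar(cq) or arr.ndim == 0:
        return float(conc)
    return conc


def is_extrapolated(cq, curve: StandardCurve):
    """True where the inverted concentration lies outside the calibrated range."""
    conc = np.asarray(cq_to_concentration(cq, curve))
    lo, hi = curve.conc_range
    return (conc < lo) | (conc > hi)


@dataclass
class QuantResult:
    """Output of :func:`quantify_samples`.

    ``concentration`` is a samples x miRNAs matrix in fM per ml of serum;
    ``flags`` is a long table (sample_id, mirna_id) with the replicate-spread,
    non-amplification and extrapolation warnings.
    """

    concentration: pd.DataFrame
    flags: pd.DataFrame
    serum_volume_ml: float
    curve_ids: list[str] = field(default_factory=list)


def quantify_samples(
    measurements: pd.DataFrame,
    curves: Mapping[str, StandardCurve],
    serum_volume_ml: float,
    max_cycles: float = MAX_CYCLES,
) -> QuantResult:
    """Aggregate replicate Cq values and convert to volume-normalized amounts.

    ``measurements`` is a long table with columns sample_id, mirna_id,
    replicate, cq; an empty/NaN cq cell marks a non-amplified well.  The
    aggregation contract is mean-of-Cq-then-invert (geometric mean of
    concentrations).  If every replicate of a well group failed to amplify,
    the concentration is imputed at the curve's Cq = ``max_cycles`` value
    (the limit of detection) and flagged — a zero would break log-scale
    statistics downstream.  The final matrix is divided by
    ``serum_volume_ml``.
    """
    if serum_volume_ml <= 0:
        raise ParameterError(f"serum_volume_ml must be > 0, got {serum_volume_ml}")
    required = {"sample_id", "mirna_id", "cq"}
    missing_cols = required - set(measurements.columns)
    if missing_cols:
        raise DataError(f"measurement table missing columns: {sorted(missing_cols)}")
    mirnas = list(pd.unique(measurements["mirna_id"]))
    for m in mirnas:
        if m not in curves:
            raise DataError(f"no standard curve for miRNA {m!r}")

    work = measurements[["sample_id", "mirna_id", "cq"]].copy()
    work["cq"] = pd.to_numeric(work["cq"], errors="coerce")
    agg = (
        work.groupby(["sample_id", "mirna_id"], sort=False)["cq"]
        .agg(mean_cq="mean", n_amplified="count", cq_min="min", cq_max="max")
        .reset_index()
    )
    non_amp = agg["n_amplified"] == 0
    agg["spread_warning"] = (agg["cq_max"] - agg["cq_min"] > REPLICATE_SPREAD_MAX) & ~non_amp
    agg.loc[non_amp, "mean_cq"] = max_cycles
    agg["non_amplified"] = non_amp

    intercept = agg["mirna_id"].map({m: curves[m].intercept for m in mirnas})
    slope = agg["mirna_id"].map({m: curves[m].slope for m in mirnas})
    lo = agg["mirna_id"].map({m: curves[m].conc_range[0] for m in mirnas})
    hi = agg["mirna_id"].map({m: curves[m].conc_range[1] for m in mirnas})
    conc = 10.0 ** ((agg["mean_cq"] - intercept) / slope)
    agg["extrapolated"] = (conc < lo) | (conc > hi)
    agg["conc"] = conc / serum_volume_ml

    matrix = agg.pivot(index="sample_id", columns="mirna_id", values="conc")
    matrix = matrix.reindex(index=pd.unique(agg["sample_id"]), columns=mirnas)
    matrix.columns.name = None
    matrix.index.name = "sample_id"
    if matrix.isna().any().any():
        missing = int(matrix.isna().sum().sum())
        raise DataError(f"incomplete measurement table: {missing} sample x miRNA "
                        "cells have no wells")
    flag_cols = ["sample_id", "mirna_id", "mean_cq", "n_amplified",
                 "spread_warning", "non_amplified", "extrapolated"]
    return QuantResult(
        concentration=matrix,
        flags=agg[flag_cols].copy(),
        serum_volume_ml=serum_volume_ml,
        curve_ids=mirnas,
    )
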