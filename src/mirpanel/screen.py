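"""Genome-wide sequencing screen of pooled serum small-RNA libraries.

The screening stage works on a per-miRNA read-count table from two
pooled libraries (patient pool vs control pool).  Two operations mirror
the screen reported for such designs: a detection tally (how many
miRNAs are seen per pool) and the candidate filter — a miRNA is carried
forward when the patient pool holds at least ``min_copies`` raw reads
and the depth-adjusted fold change between pools is at least
``min_fold`` in either direction.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import DataError, ParameterError

__all__ = ["DetectionSummary", "detect_mirnas", "screen_filter", "validate_count_table"]


@dataclass
class DetectionSummary:
    """Per-pool detection tallies from :func:`detect_mirnas`."""

    n_case: int
    n_control: int
    n_union: int
    ids_case: list[str]
    ids_control: list[str]


def validate_count_table(table: pd.DataFrame) -> pd.DataFrame:
    required = {"mirna_id", "count_case", "count_control"}
    missing = required - set(table.columns)
    if missing:
        raise DataError(f"count table missing columns: {sorted(missing)}")
    if len(table) == 0:
        raise DataError("empty count table")
    if table["mirna_id"].duplicated().any():
        dup = table.loc[table["mirna_id"].duplicated(), "mirna_id"].iloc[0]
        raise DataError(f"duplicate miRNA id {dup!r} in count table")
    counts = table[["count_case", "count_control"]].to_numpy()
    if np.any(counts < 0):
        raise DataError("read counts must be non-negative")
    return table


def detect_mirnas(table: pd.DataFrame, detection_min: int = 1) -> DetectionSummary:
    """Tally which miRNAs are detected (count >= ``detection_min``) per pool."""
    table = validate_count_table(table)
    if detection_min < 1:
        raise ParameterError(f"detection_min must be >= 1, got {detection_min}")
    case_mask = table["count_case"] >= detection_min
    ctrl_mask = table["count_control"] >= detection_min
    ids_case = list(table.loc[case_mask, "mirna_id"])
    ids_control = list(table.loc[ctrl_mask, "mirna_id"])
    return DetectionSummary(
        n_case=len(ids_case),
        n_control=len(ids_control),
        n_union=int((case_mask | ctrl_mask).sum()),
        ids_case=ids_case,
        ids_control=ids_control,
    )


def screen_filter(
    table: pd.DataFrame,
    min_copies: int = 1000,
    min_fold: float = 5.0,
    pseudocount: float = 1.0,
    library_size_case: float | None = None,
    library_size_control: float | None = None,
    depth_normalize: bool = True,
) -> pd.DataFrame:
    """Copy-number + fold-change candidate filter on the pooled counts.

    The copy-number rule uses RAW patient-pool counts (``count_case >=
    min_copies``).  The fold change is computed on counts scaled to the
    mean of the two library depths (``depth_normalize=True``; library
    sizes default to the column sums), with ``pseudocount`` added to both
    pools so a zero control count yields a finite ratio.  A miRNA passes
    when both rules hold; "min_fold-fold difference" is bidirectional
    (>= min_fold or <= 1/min_fold), with the direction recorded so callers
    can restrict to up-regulated candidates.  Results are sorted by
    descending fold change.
    """
    table = validate_count_table(table)
    if min_copies < 0:
        raise ParameterError(f"min_copies must be >= 0, got {min_copies}")
    if min_fold < 1:
        raise ParameterError(f"min_fold must be >= 1, got {min_fold}")
    if pseudocount < 0:
        raise ParameterError(f"pseudocount must be >= 0, got {pseudocount}")

    case = table["count_case"].to_numpy(dtype=float)
    ctrl = table["count_control"].to_numpy(dtype=float)
    if depth_normalize:
        lib_case = float(library_size_case) if library_size_case else case.sum()
        lib_ctrl = float(library_size_control) if library_size_control else ctrl.sum()
        if lib_case <= 0 or lib_ctrl <= 0:
            raise DataError("library sizes must be positive")
        target = 0.5 * (lib_case + lib_ctrl)
        case_adj = case * target / lib_case
        ctrl_adj = ctrl * target / lib_ctrl
    else:
        case_adj, ctrl_adj = case, ctrl
    fold = (case_adj + pseudocount) / (ctrl_adj + pseudocount)

    passes = (case >= min_copies) & ((fold >= min_fold) | (fold <= 1.0 / min_fold))
    out = pd.DataFrame(
        {
            "mirna_id": table["mirna_id"].to_numpy(),
            "count_case": case.astype(int),
            "count_control": ctrl.astype(int),
            "fold_change": fold,
            "passes": passes,
            "direction": np.where(fold >= 1.0, "up", "down"),
        }
    )
    out = out.sort_values("fold_change", ascending=False, kind="mergesort")
    return out.reset_index(drop=True)
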