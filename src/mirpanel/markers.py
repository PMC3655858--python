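"""Two-phase differential-expression marker selection.

Phase one (training): per-miRNA case/control fold change and Student's
t-test; a miRNA is selected when its mean fold change passes the cutoff
(default > 2, in either direction) and its p-value is below alpha
(default 0.05).  Phase two (validation): the selected miRNAs are re-tested
in an independent cohort and kept only if the direction of change agrees
with training and the validation p-value is again below alpha.

Fold changes are reported on the raw concentration scale (ratio of group
arithmetic means), while the t-test defaults to log10 concentrations —
serum miRNA levels are approximately log-normal, and testing on the log
scale protects the type-I error.  A ``test_scale="raw"`` option reproduces
a literal t-test on raw concentrations.
"""

from __future__ import annotations

from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .errors import DataError, ParameterError

__all__ = ["differential_stats", "select_markers", "validate_markers"]


def _group_matrix(
    conc: pd.DataFrame,
    metadata: pd.DataFrame,
    phase: str | None,
    group: str,
) -> pd.DataFrame:
    meta = metadata
    if phase is not None:
        meta = meta[meta["phase"] == phase]
    ids = meta.loc[meta["group"] == group, "sample_id"]
    ids = [i for i in ids if i in conc.index]
    return conc.loc[ids]


def differential_stats(
    conc: pd.DataFrame,
    metadata: pd.DataFrame,
    phase: str | None = "training",
    case_group: str = "AMI",
    control_group: str = "control",
    alpha: float = 0.05,
    min_fold: float = 2.0,
    test_scale: str = "log10",
    equal_var: bool = True,
    up_only: bool = False,
    fdr: bool = False,
) -> pd.DataFrame:
    """Per-miRNA fold change, t-test and selection flag for one phase.

    Returns a DataFrame indexed like ``conc.columns`` with columns
    mirna_id, fold_change, t_statistic, p_value, n_case, n_control,
    direction and selected.  ``equal_var=True`` gives the pooled-variance
    Student's t-test; False gives Welch.  ``fdr=True`` applies
    Benjamini-Hochberg to the p-values before the alpha comparison.
    """
    if not 0 < alpha < 1:
        raise ParameterError(f"alpha must be in (0, 1), got {alpha}")
    if min_fold < 1:
        raise ParameterError(f"min_fold must be >= 1, got {min_fold}")
    if test_scale not in ("log10", "raw"):
        raise ParameterError(f"test_scale must be 'log10' or 'raw', got {test_scale!r}")

    case = _group_matrix(conc, metadata, phase, case_group)
    ctrl = _group_matrix(conc, metadata, phase, control_group)
    if len(case) < 2 or len(ctrl) < 2:
        raise DataError(
            f"need >= 2 samples per group in phase {phase!r}: "
            f"{case_group}={len(case)}, {control_group}={len(ctrl)}"
        )

    case_m = case.to_numpy(dtype=float)
    ctrl_m = ctrl.to_numpy(dtype=float)
    ctrl_mean = ctrl_m.mean(axis=0)
    if np.any(ctrl_mean <= 0):
        bad = conc.columns[ctrl_mean <= 0][0]
        raise DataError(
            f"control mean is non-positive for {bad!r}; apply a pseudo-floor "
            "(e.g. the limit of detection) before differential testing"
        )
    fold = case_m.mean(axis=0) / ctrl_mean

    if test_scale == "log10":
        if np.any(case_m <= 0) or np.any(ctrl_m <= 0):
            raise DataError(
                "non-positive concentrations cannot be log-transformed; "
                "apply a pseudo-floor or use test_scale='raw'"
            )
        t, p = stats.ttest_ind(np.log10(case_m), np.log10(ctrl_m),
                               axis=0, equal_var=equal_var)
    else:
        t, p = stats.ttest_ind(case_m, ctrl_m, axis=0, equal_var=equal_var)
    # identical group values give 0/0 -> define t=0, p=1 (no evidence)
    t = np.where(np.isnan(t), 0.0, t)
    p = np.where(np.isnan(p), 1.0, p)

    p_sel = p
    if fdr:
        from statsmodels.stats.multitest import multipletests

        p_sel = multipletests(p, method="fdr_bh")[1]

    direction = np.where(fold >= 1.0, "up", "down")
    fold_pass = (fold > min_fold) | (fold < 1.0 / min_fold)
    if up_only:
        fold_pass &= fold > 1.0
    selected = fold_pass & (p_sel < alpha)

    out = pd.DataFrame(
        {
            "mirna_id": conc.columns,
            "fold_change": fold,
            "t_statistic": t,
            "p_value": p_sel if fdr else p,
            "n_case": len(case),
            "n_control": len(ctrl),
            "direction": direction,
            "selected": selected,
        }
    ).set_index("mirna_id", drop=False)
    out.index.name = None
    return out


def select_markers(results: pd.DataFrame) -> list[str]:
    """Ids of selected miRNAs, by ascending p-value; ties broken by id."""
    if len(results) == 0:
        raise DataError("empty differential-result table")
    hits = results[results["selected"]]
    hits = hits.sort_values(["p_value", "mirna_id"], kind="mergesort")
    return list(hits["mirna_id"])


def validate_markers(
    conc: pd.DataFrame,
    metadata: pd.DataFrame,
    selected: Sequence[str],
    training_direction: Mapping[str, str],
    phase: str | None = "validation",
    case_group: str = "AMI",
    control_group: str = "control",
    alpha: float = 0.05,
    test_scale: str = "log10",
    equal_var: bool = True,
) -> pd.DataFrame:
    """Re-test selected markers in the validation cohort.

    A marker is ``consistent`` iff its validation direction matches the
    training direction AND its validation p-value is below alpha.
    """
    missing = [m for m in selected if m not in conc.columns]
    if missing:
        raise DataError(f"markers absent from validation data: {missing}")
    res = differential_stats(
        conc[list(selected)],
        metadata,
        phase=phase,
        case_group=case_group,
        control_group=control_group,
        alpha=alpha,
        min_fold=1.0,
        test_scale=test_scale,
        equal_var=equal_var,
    )
    rows = []
    for m in selected:
        if m not in training_direction:
            raise DataError(f"no training direction recorded for {m!r}")
        r = res.loc[m]
        consistent = (r["direction"] == training_direction[m]) and (
            r["p_value"] < alpha
        )
        rows.append(
            {
                "mirna_id": m,
                "training_direction": training_direction[m],
                "fold_change": r["fold_change"],
                "p_value": r["p_value"],
                "direction": r["direction"],
                "consistent": bool(consistent),
            }
        )
    out = pd.DataFrame(rows).set_index("mirna_id", drop=False)
    out.index.name = None
    return out
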