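"""Dichotomized weighted risk-score function (RSF) for a marker panel.

Each marker j is reduced to a binary indicator s_ij: 1 if sample i's
serum level exceeds the upper bound of the control population's central
95% reference interval, else 0.  A univariate logistic regression of
disease status on each indicator gives the marker weight W_j (its
log odds ratio), and the per-sample score is the linear combination

    RSF_i = sum_j W_j * s_ij.

Samples ranked by RSF are then classified with an ROC-derived cutoff.
The model is strictly univariate-weight / binary-indicator: no joint or
penalized regression, no continuous-expression scores.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import DataError, ParameterError

__all__ = [
    "RiskModel",
    "RiskScores",
    "reference_upper_limit",
    "dichotomize",
    "fit_weights",
    "build_risk_model",
    "compute_rsf",
]

#: z multiplier for the upper bound of the central 95% reference interval,
#: as conventionally rounded in clinical chemistry.
_Z_UPPER_95 = 1.96


@dataclass
class RiskModel:
    """Thresholds and logistic weights defining the RSF for one contrast.

    ``contrast`` is (case label, reference label); thresholds come from the
    reference group only.  ``separation_flags`` marks markers whose 2x2
    table had an empty cell, where the weight is the Haldane-Anscombe
    corrected log odds ratio rather than a (divergent) MLE.
    """

    markers: list[str]
    thresholds: dict[str, float]
    weights: dict[str, float]
    contrast: tuple[str, str]
    separation_flags: dict[str, bool] = field(default_factory=dict)
    converged: dict[str, bool] = field(default_factory=dict)
    reference_method: str = "parametric"

    def __post_init__(self) -> None:
        for j in self.markers:
            if j not in self.thresholds or j not in self.weights:
                raise DataError(f"risk model incomplete for marker {j!r}")
            if not self.thresholds[j] > 0:
                raise DataError(f"threshold for {j!r} must be > 0")
            if not np.isfinite(self.weights[j]):
                raise DataError(f"weight for {j!r} must be finite")

    def to_json(self) -> str:
        payload = {
            "format_version": 1,
            "markers": self.markers,
            "thresholds": self.thresholds,
            "weights": self.weights,
            "contrast": list(self.contrast),
            "separation_flags": self.separation_flags,
            "converged": self.converged,
            "reference_method": self.reference_method,
        }
        return json.dumps(payload, sort_keys=True, indent=2)

    @classmethod
    def from_json(cls, text: str) -> "RiskModel":
        d = json.loads(text)
        return cls(
            markers=list(d["markers"]),
            thresholds={k: float(v) for k, v in d["thresholds"].items()},
            weights={k: float(v) for k, v in d["weights"].items()},
            contrast=tuple(d["contrast"]),
            separation_flags=d.get("separation_flags", {}),
            converged=d.get("converged", {}),
            reference_method=d.get("reference_method", "parametric"),
        )


@dataclass
class RiskScores:
    """Per-sample binary indicators, RSF values and descending ranks."""

    s: pd.DataFrame
    rsf: pd.Series
    rank: pd.Series


def reference_upper_limit(control_values, method: str = "parametric") -> float:
    """Upper bound of the central 95% reference interval of control levels.

    parametric (default): 10**(mean + 1.96*sd) of the log10 values — the
    clinical-chemistry convention for log-normally distributed analytes.
    empirical: the 97.5th percentile with linear interpolation, for when
    the distributional assumption is not trusted.  Requires at least 8
    positive control values.
    """
    x = np.asarray(control_values, dtype=float)
    if x.size < 8:
        raise DataError(f"reference interval needs >= 8 control values, got {x.size}")
    if np.any(x <= 0) or not np.all(np.isfinite(x)):
        raise DataError("control values must be positive and finite")
    if method == "parametric":
        lg = np.log10(x)
        sd = lg.std(ddof=1)
        return float(10.0 ** (lg.mean() + _Z_UPPER_95 * sd))
    if method == "empirical":
        return float(np.percentile(x, 97.5, method="linear"))
    raise ParameterError(f"unknown reference method {method!r}")


def dichotomize(conc: pd.DataFrame, thresholds: Mapping[str, float]) -> pd.DataFrame:
    """Binary exceedance indicators: s_ij = 1 iff conc_ij > threshold_j.

    The inequality is strict — a value exactly at the reference limit is
    scored 0.
    """
    out = {}
    for col in conc.columns:
        if col not in thresholds:
            raise DataError(f"no threshold for marker {col!r}")
        out[col] = (conc[col].to_numpy(dtype=float) > thresholds[col]).astype(int)
    return pd.DataFrame(out, index=conc.index)


def _haldane_log_or(a: float, b: float, c: float, d: float) -> float:
    """Log odds ratio with the Haldane-Anscombe +0.5 continuity correction."""
    return float(np.log(((a + 0.5) * (d + 0.5)) / ((b + 0.5) * (c + 0.5))))


def fit_weights(
    s: pd.DataFrame,
    labels: Sequence[int],
    tol: float = 1e-8,
    maxiter: int = 100,
) -> tuple[dict[str, float], dict[str, bool], dict[str, bool]]:
    """Univariate logistic weights: one regression of disease on each s_j.

    For each marker an intercept + slope logistic model is fit by IRLS
    (statsmodels GLM, binomial family); the slope is the weight.  With a
    binary predictor the MLE equals the 2x2 log odds ratio, so a table
    with an empty cell has no finite MLE (complete/quasi separation): the
    weight is then the Haldane-Anscombe corrected log odds ratio and the
    marker's separation flag is set.

    Returns (weights, separation_flags, converged).
    """
    import statsmodels.api as sm

    y = np.asarray(labels, dtype=float)
    if set(np.unique(y)) != {0.0, 1.0}:
        raise DataError("labels must contain both classes (0 and 1)")
    weights: dict[str, float] = {}
    sep: dict[str, bool] = {}
    conv: dict[str, bool] = {}
    for col in s.columns:
        sj = s[col].to_numpy(dtype=float)
        if not set(np.unique(sj)) <= {0.0, 1.0}:
            raise DataError(f"indicator column {col!r} is not binary")
        a = float(np.sum((y == 1) & (sj == 1)))  # cases exceeding
        b = float(np.sum((y == 1) & (sj == 0)))
        c = float(np.sum((y == 0) & (sj == 1)))  # controls exceeding
        d = float(np.sum((y == 0) & (sj == 0)))
        if min(a, b, c, d) == 0.0:
            weights[col] = _haldane_log_or(a, b, c, d)
            sep[col] = True
            conv[col] = True
            continue
        exog = sm.add_constant(sj)
        res = sm.GLM(y, exog, family=sm.families.Binomial()).fit(
            maxiter=maxiter, tol=tol
        )
        weights[col] = float(res.params[1])
        sep[col] = False
        conv[col] = bool(res.converged)
    return weights, sep, conv


def build_risk_model(
    conc: pd.DataFrame,
    labels: Sequence[int],
    markers: Sequence[str],
    contrast: tuple[str, str] = ("case", "control"),
    reference_method: str = "parametric",
) -> RiskModel:
    """Derive thresholds from the reference group and fit marker weights.

    ``labels`` are 1 for the case group and 0 for the contrast's reference
    group; thresholds use reference-group samples only, so case samples
    never influence them.
    """
    markers = list(markers)
    missing = [m for m in markers if m not in conc.columns]
    if missing:
        raise DataError(f"markers absent from concentration matrix: {missing}")
    y = np.asarray(labels, dtype=int)
    if y.shape[0] != conc.shape[0]:
        raise DataError("labels length must match number of samples")
    ref = conc.loc[y == 0, markers]
    thresholds = {
        j: reference_upper_limit(ref[j].to_numpy(), method=reference_method)
        for j in markers
    }
    s = dichotomize(conc[markers], thresholds)
    weights, sep, conv = fit_weights(s, y)
    return RiskModel(
        markers=markers,
        thresholds=thresholds,
        weights=weights,
        contrast=tuple(contrast),
        separation_flags=sep,
        converged=conv,
        reference_method=reference_method,
    )


def compute_rsf(s: pd.DataFrame, model: RiskModel) -> RiskScores:
    """RSF_i = sum_j W_j * s_ij, with samples ranked by descending score."""
    if list(s.columns) != list(model.markers):
        raise DataError(
            f"indicator columns {list(s.columns)} do not match model markers "
            f"{list(model.markers)}"
        )
    w = np.array([model.weights[j] for j in model.markers], dtype=float)
    vals = s.to_numpy(dtype=float)
    if not set(np.unique(vals)) <= {0.0, 1.0}:
        raise DataError("indicator matrix must be binary")
    rsf = pd.Series(vals @ w, index=s.index, name="rsf")
    rank = rsf.rank(ascending=False, method="min").astype(int)
    return RiskScores(s=s.copy(), rsf=rsf, rank=rank)
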