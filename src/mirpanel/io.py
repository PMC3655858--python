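"""Plain-text table formats exchanged between pipeline stages.

All artifacts are TSV (tables) or JSON (models, reports):

* metadata:       sample_id, group, phase [, ctnt, ckmb, ...]
* concentrations: samples as rows, miRNAs as columns (index sample_id)
* Cq long table:  sample_id, mirna_id, replicate, cq (empty cq = no amplification)
* counts:         mirna_id, count_case, count_control
* calibration:    mirna_id, conc_fm, cq
* standard curves / risk models: JSON

Every writer's output re-parses through the matching reader without loss;
the round trip is part of the test contract.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Mapping

import pandas as pd

from .errors import DataError
from .qpcr import StandardCurve, fit_standard_curve

__all__ = [
    "read_metadata", "write_metadata",
    "read_concentration", "write_concentration",
    "read_cq", "write_cq",
    "read_counts", "write_counts",
    "read_calibration", "fit_curves_from_calibration",
    "read_curves_json", "write_curves_json",
]


def _require(df: pd.DataFrame, cols: set[str], what: str) -> pd.DataFrame:
    missing = cols - set(df.columns)
    if missing:
        raise DataError(f"{what} missing columns: {sorted(missing)}")
    return df


def read_metadata(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    return _require(df, {"sample_id", "group", "phase"}, "metadata table")


def write_metadata(df: pd.DataFrame, path) -> None:
    _require(df, {"sample_id", "group", "phase"}, "metadata table")
    df.to_csv(path, sep="\t", index=False)


def read_concentration(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", index_col="sample_id")
    df.columns.name = None
    return df


def write_concentration(df: pd.DataFrame, path) -> None:
    out = df.copy()
    out.index.name = "sample_id"
    out.to_csv(path, sep="\t")


def read_cq(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    df = _require(df, {"sample_id", "mirna_id", "replicate", "cq"}, "Cq table")
    df["cq"] = pd.to_numeric(df["cq"], errors="coerce")
    return df


def write_cq(df: pd.DataFrame, path) -> None:
    _require(df, {"sample_id", "mirna_id", "replicate", "cq"}, "Cq table")
    df.to_csv(path, sep="\t", index=False)


def read_counts(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    return _require(df, {"mirna_id", "count_case", "count_control"}, "count table")


def write_counts(df: pd.DataFrame, path) -> None:
    _require(df, {"mirna_id", "count_case", "count_control"}, "count table")
    df.to_csv(path, sep="\t", index=False)


def read_calibration(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    return _require(df, {"mirna_id", "conc_fm", "cq"}, "calibration table")


def fit_curves_from_calibration(calibration: pd.DataFrame
                                ) -> dict[str, StandardCurve]:
    """One fitted standard curve per miRNA in a long calibration table."""
    _require(calibration, {"mirna_id", "conc_fm", "cq"}, "calibration table")
    curves = {}
    for mid, grp in calibration.groupby("mirna_id", sort=False):
        curves[mid] = fit_standard_curve(grp["conc_fm"], grp["cq"], mirna_id=mid)
    return curves


def write_curves_json(curves: Mapping[str, StandardCurve], path) -> None:
    payload = {
        "format_version": 1,
        "curves": {
            m: {
                "intercept": c.intercept,
                "slope": c.slope,
                "r_squared": c.r_squared,
                "conc_range": list(c.conc_range),
                "efficiency_warning": c.efficiency_warning,
            }
            for m, c in curves.items()
        },
    }
    Path(path).write_text(json.dumps(payload, sort_keys=True, indent=2))


def read_curves_json(path) -> dict[str, StandardCurve]:
    d = json.loads(Path(path).read_text())
    return {
        m: StandardCurve(
            mirna_id=m,
            intercept=float(v["intercept"]),
            slope=float(v["slope"]),
            r_squared=float(v.get("r_squared", 1.0)),
            conc_range=tuple(v.get("conc_range", (1.0, 1e5))),
            efficiency_warning=bool(v.get("efficiency_warning", False)),
        )
        for m, v in d["curves"].items()
    }
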