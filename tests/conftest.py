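import numpy as np
import pandas as pd
import pytest

from mirpanel.qpcr import StandardCurve
from mirpanel.synthetic import CohortConfig, PhaseSizes, PlantedMarker, TrueCohort

#: Perfect-doubling slope: one cycle per twofold dilution.
DOUBLING_SLOPE = -1.0 / np.log10(2.0)


@pytest.fixture
def doubling_curve() -> StandardCurve:
    return StandardCurve(mirna_id="miR-test", intercept=40.0,
                         slope=DOUBLING_SLOPE, conc_range=(1.0, 1e5))


def make_cohort(conc: dict[str, list[float]], groups: list[str],
                phase: str = "training") -> TrueCohort:
    """Hand-built cohort: one concentration list per miRNA, groups aligned."""
    n = len(groups)
    meta = pd.DataFrame(
        {
            "sample_id": [f"S{i:04d}" for i in range(n)],
            "group": groups,
            "phase": [phase] * n,
        }
    )
    mat = pd.DataFrame(conc, index=meta["sample_id"])
    mat.index.name = "sample_id"
    cfg = CohortConfig(
        n_mirna=len(conc),
        sizes={phase: PhaseSizes(control=groups.count("control"),
                                 ami=groups.count("AMI"),
                                 ap=groups.count("AP"))},
        planted_markers=[],
        seed=0,
    )
    cohort = TrueCohort(metadata=meta, true_conc=mat, config=cfg)
    return cohort


@pytest.fixture
def two_group_conc() -> tuple[pd.DataFrame, pd.DataFrame]:
    """conc matrix + metadata: 3 cases {2,4,6}, 3 controls {1,2,3}."""
    meta = pd.DataFrame(
        {
            "sample_id": [f"S{i}" for i in range(6)],
            "group": ["AMI"] * 3 + ["control"] * 3,
            "phase": ["training"] * 6,
        }
    )
    conc = pd.DataFrame({"miR-x": [2.0, 4.0, 6.0, 1.0, 2.0, 3.0]},
                        index=meta["sample_id"])
    conc.index.name = "sample_id"
    return conc, meta
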