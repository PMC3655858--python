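"""Seeded synthetic serum-miRNA cohorts with planted effect sizes.

No raw patient measurements are publicly deposited for the study design
this package implements, so every downstream stage is exercised on
synthetic cohorts whose ground truth is known.  The generative model:

* per-miRNA serum concentration is log-normal — log10(conc) for miRNA j
  in group g is Normal(baseline_mean_j + planted_log10_fold_{j,g},
  baseline_sd_j); concentrations are in fM and strictly positive;
* sequencing pools mix equal serum volumes per donor, so the pool
  concentration of a miRNA is the arithmetic mean over the pool's
  members, and reads are a single multinomial draw of ``library_size``
  reads with probabilities proportional to pooled concentration;
* RT-qPCR replicates are generated through the standard-curve relation,
  Cq = intercept + slope*log10(conc) + Normal(0, cq_noise_sd), in
  triplicate per sample x miRNA.

All randomness flows from one integer seed through named per-stage
sub-streams, so any stage can be re-run independently and a fixed config
reproduces byte-identical tables.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from pydantic import BaseModel, Field, model_validator

from .errors import ConfigurationError, DataError
from .qpcr import StandardCurve

__all__ = [
    "PlantedMarker",
    "PhaseSizes",
    "CohortConfig",
    "TrueCohort",
    "default_config",
    "generate_cohort",
    "simulate_pool_counts",
    "simulate_cq",
    "make_true_curves",
    "simulate_calibration",
    "GROUPS",
    "PHASES",
]

GROUPS = ("control", "AMI", "AP")
PHASES = ("screen", "training", "validation")

# RNG sub-stream tags (stable: changing them changes every seeded output)
_STREAM_CONC = 1
_STREAM_COVARIATES = 2
_STREAM_POOL = 3
_STREAM_CURVES = 4
_STREAM_CALIBRATION = 5
_STREAM_CQ = 6

#: Conventional-biomarker group parameters (mean, sd) used to simulate the
#: cTnT (ng/ml) and CK-MB (U/L) covariate columns.  These are synthetic
#: stand-ins moment-matched to typical clinical values for controls, acute
#: myocardial infarction and angina pectoris; they feed the comparator ROC
#: scorers only.
COVARIATE_PARAMS: dict[str, dict[str, tuple[float, float]]] = {
    "ctnt": {"control": (0.15, 0.27), "AMI": (0.77, 0.74), "AP": (0.14, 0.21)},
    "ckmb": {"control": (15.26, 20.91), "AMI": (80.84, 121.17), "AP": (13.06, 12.60)},
}


def _rng(seed: int, stream: int, extra: int = 0) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence((seed, stream, extra)))


def _group_tag(group: str) -> int:
    return zlib.crc32(group.encode()) & 0x7FFFFFFF


class PlantedMarker(BaseModel):
    """A miRNA with known log10 fold changes planted per disease group."""

    mirna_id: str
    log10_fold: dict[str, float] = Field(default_factory=dict)


class PhaseSizes(BaseModel):
    """Sample counts per group for one study phase."""

    control: int = 0
    ami: int = 0
    ap: int = 0

    @model_validator(mode="after")
    def _non_negative(self) -> "PhaseSizes":
        for name in ("control", "ami", "ap"):
            if getattr(self, name) < 0:
                raise ConfigurationError(f"phase size {name!r} must be >= 0")
        return self


class CohortConfig(BaseModel):
    """Full description of a synthetic cohort.

    ``baseline_log10_mean`` / ``baseline_log10_sd`` may be a scalar
    (shared by all miRNAs) or one value per miRNA; means default to an
    even spread over 1-4 log10 fM.  ``cq_noise_sd`` is the replicate Cq
    standard deviation in cycles; ``library_size`` the total reads per
    sequencing pool.
    """

    n_mirna: int = 50
    sizes: dict[str, PhaseSizes] = Field(
        default_factory=lambda: {
            "screen": PhaseSizes(control=20, ami=20),
            "training": PhaseSizes(control=20, ami=20),
            "validation": PhaseSizes(control=80, ami=97, ap=182),
        }
    )
    planted_markers: list[PlantedMarker] = Field(default_factory=list)
    baseline_log10_mean: float | list[float] | None = None
    baseline_log10_sd: float | list[float] = 0.12
    cq_noise_sd: float = 0.15
    library_size: int = 3_000_000
    include_covariates: bool = True
    seed: int = 0

    @model_validator(mode="after")
    def _validate(self) -> "CohortConfig":
        if self.n_mirna <= 0:
            raise ConfigurationError("n_mirna must be > 0")
        if self.library_size <= 0:
            raise ConfigurationError("library_size must be > 0")
        if self.cq_noise_sd < 0:
            raise ConfigurationError("cq_noise_sd must be >= 0")
        sds = np.atleast_1d(np.asarray(self.baseline_log10_sd, dtype=float))
        if np.any(sds <= 0):
            raise ConfigurationError("baseline_log10_sd must be > 0")
        for arr_name in ("baseline_log10_mean", "baseline_log10_sd"):
            v = getattr(self, arr_name)
            if isinstance(v, list) and len(v) != self.n_mirna:
                raise ConfigurationError(
                    f"{arr_name} must have length n_mirna={self.n_mirna}, "
                    f"got {len(v)}"
                )
        planted_ids = [pm.mirna_id for pm in self.planted_markers]
        if len(planted_ids) != len(set(planted_ids)):
            raise ConfigurationError("planted_markers: duplicate miRNA ids")
        if len(planted_ids) > self.n_mirna:
            raise ConfigurationError(
                f"planted_markers: {len(planted_ids)} markers exceed "
                f"n_mirna={self.n_mirna}"
            )
        for pm in self.planted_markers:
            for g in pm.log10_fold:
                if g not in GROUPS:
                    raise ConfigurationError(
                        f"planted_markers: unknown group {g!r} for {pm.mirna_id!r}"
                    )
        return self

    def mirna_ids(self) -> list[str]:
        planted = [pm.mirna_id for pm in self.planted_markers]
        fillers = [f"miR-sim-{i:03d}" for i in range(self.n_mirna - len(planted))]
        return planted + fillers

    def baseline_means(self) -> np.ndarray:
        if self.baseline_log10_mean is None:
            return np.linspace(1.0, 4.0, self.n_mirna)
        return np.broadcast_to(
            np.asarray(self.baseline_log10_mean, dtype=float), (self.n_mirna,)
        ).copy()

    def baseline_sds(self) -> np.ndarray:
        return np.broadcast_to(
            np.asarray(self.baseline_log10_sd, dtype=float), (self.n_mirna,)
        ).copy()

    def effect_matrix(self) -> pd.DataFrame:
        """Planted log10 fold changes, groups x miRNAs (controls all zero)."""
        ids = self.mirna_ids()
        eff = pd.DataFrame(0.0, index=list(GROUPS), columns=ids)
        for pm in self.planted_markers:
            for g, f in pm.log10_fold.items():
                eff.loc[g, pm.mirna_id] = f
        return eff


#: Planted AMI panel for the default study-shaped cohort: six markers with
#: fold changes spanning 2.5-5x over controls; the three markers also
#: altered in angina pectoris carry their own AP effects, two of them
#: larger than in AMI.
DEFAULT_PANEL: list[tuple[str, float, float]] = [
    # (mirna_id, AMI fold, AP fold) on the raw scale
    ("miR-1", 2.5, 1.0),
    ("miR-134", 3.0, 1.0),
    ("miR-186", 3.5, 2.0),
    ("miR-208", 4.0, 6.0),
    ("miR-223", 4.5, 1.0),
    ("miR-499", 5.0, 8.0),
]


def default_config(seed: int = 0, **overrides) -> CohortConfig:
    """The study-shaped default cohort: 6 planted markers, 50 miRNAs,
    screen pools 20/20, training 20/20, validation 97 AMI / 80 controls,
    182 angina patients."""
    planted = [
        PlantedMarker(
            mirna_id=mid,
            log10_fold={"AMI": float(np.log10(ami)), "AP": float(np.log10(ap))},
        )
        for mid, ami, ap in DEFAULT_PANEL
    ]
    kwargs = dict(planted_markers=planted, seed=seed)
    kwargs.update(overrides)
    return CohortConfig(**kwargs)


@dataclass
class TrueCohort:
    """Sample metadata plus the noiseless ground-truth concentrations (fM)."""

    metadata: pd.DataFrame
    true_conc: pd.DataFrame
    config: CohortConfig

    def samples(self, phase: str | None = None, group: str | None = None
                ) -> list[str]:
        m = self.metadata
        if phase is not None:
            m = m[m["phase"] == phase]
        if group is not None:
            m = m[m["group"] == group]
        return list(m["sample_id"])


def _lognormal_from_moments(rng, mean: float, sd: float, size: int) -> np.ndarray:
    """Lognormal draws moment-matched to an arithmetic mean and SD."""
    sigma2 = np.log1p((sd / mean) ** 2)
    mu = np.log(mean) - sigma2 / 2.0
    return rng.lognormal(mean=mu, sigma=np.sqrt(sigma2), size=size)


def generate_cohort(config: CohortConfig) -> TrueCohort:
    """Draw the full cohort: metadata and true per-sample concentrations."""
    ids = config.mirna_ids()
    means = config.baseline_means()
    sds = config.baseline_sds()
    eff = config.effect_matrix()

    rows = []
    for phase in PHASES:
        sizes = config.sizes.get(phase, PhaseSizes())
        for group, n in (("control", sizes.control), ("AMI", sizes.ami),
                         ("AP", sizes.ap)):
            rows.extend({"group": group, "phase": phase} for _ in range(n))
    if not rows:
        raise ConfigurationError("sizes: no samples configured in any phase")
    meta = pd.DataFrame(rows)
    meta.insert(0, "sample_id", [f"S{i:04d}" for i in range(len(meta))])

    rng = _rng(config.seed, _STREAM_CONC)
    shift = eff.loc[meta["group"], ids].to_numpy()          # samples x mirnas
    log10_conc = (
        means[None, :] + shift
        + rng.normal(0.0, 1.0, size=(len(meta), len(ids))) * sds[None, :]
    )
    conc = pd.DataFrame(10.0 ** log10_conc, index=meta["sample_id"], columns=ids)
    conc.index.name = "sample_id"

    if config.include_covariates:
        crng = _rng(config.seed, _STREAM_COVARIATES)
        for cov, params in COVARIATE_PARAMS.items():
            vals = np.empty(len(meta))
            for group, (m, s) in params.items():
                mask = (meta["group"] == group).to_numpy()
                vals[mask] = _lognormal_from_moments(crng, m, s, int(mask.sum()))
            meta[cov] = vals

    return TrueCohort(metadata=meta, true_conc=conc, config=config)


def simulate_pool_counts(
    cohort: TrueCohort,
    group: str,
    config: CohortConfig | None = None,
    phase: str = "screen",
) -> pd.Series:
    """Sequencing reads for one pooled library as a single multinomial draw.

    The pool mixes equal serum volumes, so its per-miRNA concentration is
    the arithmetic mean over the group's ``phase`` samples; read
    probabilities are those concentrations normalized to sum to 1 and the
    total equals ``library_size``.
    """
    config = config or cohort.config
    samples = cohort.samples(phase=phase, group=group)
    if not samples:
        raise DataError(f"no {phase!r}-phase samples in group {group!r}")
    pooled = cohort.true_conc.loc[samples].mean(axis=0)
    p = (pooled / pooled.sum()).to_numpy()
    rng = _rng(config.seed, _STREAM_POOL, _group_tag(group))
    counts = rng.multinomial(config.library_size, p)
    return pd.Series(counts, index=cohort.true_conc.columns, name=group)


def make_true_curves(config: CohortConfig) -> dict[str, StandardCurve]:
    """Deterministic per-assay 'true' standard curves for the cohort.

    Intercepts vary around 38 cycles and slopes around the perfect-doubling
    value -3.32, reflecting assay-to-assay efficiency differences.
    """
    rng = _rng(config.seed, _STREAM_CURVES)
    curves = {}
    for mid in config.mirna_ids():
        intercept = float(rng.normal(38.0, 0.8))
        slope = float(np.clip(rng.normal(-1.0 / np.log10(2.0), 0.08), -3.9, -3.0))
        curves[mid] = StandardCurve(
            mirna_id=mid, intercept=intercept, slope=slope, r_squared=1.0,
            conc_range=(1.0, 1e5),
        )
    return curves


def simulate_calibration(
    config: CohortConfig,
    curves: Mapping[str, StandardCurve],
    concs: Sequence[float] = (1.0, 10.0, 100.0, 1e3, 1e4, 1e5),
) -> pd.DataFrame:
    """Dilution-series Cq table (mirna_id, conc_fm, cq) with replicate noise."""
    rng = _rng(config.seed, _STREAM_CALIBRATION)
    rows = []
    for mid in config.mirna_ids():
        c = curves[mid]
        for conc in concs:
            cq = c.intercept + c.slope * np.log10(conc)
            rows.append((mid, conc, cq + rng.normal(0.0, config.cq_noise_sd)))
    return pd.DataFrame(rows, columns=["mirna_id", "conc_fm", "cq"])


def simulate_cq(
    cohort: TrueCohort,
    curves: Mapping[str, StandardCurve],
    config: CohortConfig | None = None,
    phases: Sequence[str] | None = ("training", "validation"),
    mirnas: Sequence[str] | None = None,
    n_replicates: int = 3,
) -> pd.DataFrame:
    """Triplicate Cq measurements through the standard-curve relation.

    Returns a long table (sample_id, mirna_id, replicate, cq) for the
    requested phases (default: the individually measured training and
    validation phases; the screen phase is pooled-sequencing only).
    """
    config = config or cohort.config
    mirnas = list(mirnas) if mirnas is not None else list(cohort.true_conc.columns)
    for m in mirnas:
        if m not in curves:
            raise DataError(f"no standard curve for miRNA {m!r}")
        if m not in cohort.true_conc.columns:
            raise DataError(f"miRNA {m!r} is not simulated in this cohort")
    meta = cohort.metadata
    if phases is not None:
        meta = meta[meta["phase"].isin(phases)]
    samples = list(meta["sample_id"])
    if not samples:
        raise DataError(f"no samples in phases {phases!r}")

    conc = cohort.true_conc.loc[samples, mirnas].to_numpy()
    intercept = np.array([curves[m].intercept for m in mirnas])
    slope = np.array([curves[m].slope for m in mirnas])
    cq_true = intercept[None, :] + slope[None, :] * np.log10(conc)

    rng = _rng(config.seed, _STREAM_CQ)
    noise = rng.normal(0.0, config.cq_noise_sd,
                       size=(len(samples), len(mirnas), n_replicates))
    cq = cq_true[:, :, None] + noise

    s_idx, m_idx, r_idx = np.meshgrid(
        np.arange(len(samples)), np.arange(len(mirnas)),
        np.arange(n_replicates), indexing="ij",
    )
    return pd.DataFrame(
        {
            "sample_id": np.asarray(samples, dtype=object)[s_idx.ravel()],
            "mirna_id": np.asarray(mirnas, dtype=object)[m_idx.ravel()],
            "replicate": r_idx.ravel() + 1,
            "cq": cq.ravel(),
        }
    )
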