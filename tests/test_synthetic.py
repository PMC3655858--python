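"""Generator contracts: determinism, bookkeeping, planted-effect recovery,
pool-count sampling and the Cq simulation through the standard curve."""

import numpy as np
import pandas as pd
import pytest

from mirpanel.errors import ConfigurationError, DataError
from mirpanel.qpcr import StandardCurve
from mirpanel.synthetic import (
    CohortConfig,
    PhaseSizes,
    PlantedMarker,
    default_config,
    generate_cohort,
    make_true_curves,
    simulate_cq,
    simulate_pool_counts,
)
from .conftest import DOUBLING_SLOPE, make_cohort


def small_config(seed=0, **kw):
    defaults = dict(
        n_mirna=5,
        sizes={"screen": PhaseSizes(control=4, ami=4),
               "training": PhaseSizes(control=20, ami=20)},
        planted_markers=[PlantedMarker(mirna_id="miR-1",
                                       log10_fold={"AMI": 0.5})],
        seed=seed,
    )
    defaults.update(kw)
    return CohortConfig(**defaults)


class TestGenerateCohort:
    def test_same_seed_is_byte_identical(self):
        a = generate_cohort(small_config(seed=7))
        b = generate_cohort(small_config(seed=7))
        pd.testing.assert_frame_equal(a.metadata, b.metadata)
        pd.testing.assert_frame_equal(a.true_conc, b.true_conc)

    def test_different_seed_differs(self):
        a = generate_cohort(small_config(seed=7))
        b = generate_cohort(small_config(seed=8))
        assert not np.allclose(a.true_conc, b.true_conc)

    def test_phase_group_bookkeeping(self):
        cohort = generate_cohort(small_config())
        training = cohort.metadata[cohort.metadata["phase"] == "training"]
        assert len(training) == 40
        assert (training["group"] == "control").sum() == 20
        assert (training["group"] == "AMI").sum() == 20
        assert len(cohort.metadata) == len(cohort.true_conc)
        assert (cohort.true_conc.to_numpy() > 0).all()

    @pytest.mark.parametrize(
        "overrides, field",
        [
            (dict(n_mirna=0), "n_mirna"),
            (dict(library_size=0), "library_size"),
            (dict(baseline_log10_sd=0.0), "baseline_log10_sd"),
            (dict(cq_noise_sd=-1.0), "cq_noise_sd"),
        ],
    )
    def test_invalid_config_names_field(self, overrides, field):
        with pytest.raises((ConfigurationError, ValueError), match=field):
            small_config(**overrides)

    def test_planted_markers_bounded_by_panel_size(self):
        too_many = [PlantedMarker(mirna_id=f"miR-{i}", log10_fold={"AMI": 0.3})
                    for i in range(6)]
        with pytest.raises((ConfigurationError, ValueError),
                           match="planted_markers"):
            small_config(planted_markers=too_many)

    def test_planted_markers_unknown_group_rejected(self):
        with pytest.raises((ConfigurationError, ValueError), match="group"):
            small_config(
                planted_markers=[PlantedMarker(mirna_id="miR-1",
                                               log10_fold={"ZOMBIE": 1.0})]
            )

    def test_planted_fold_recovered_in_geometric_means(self):
        # ratio of group geometric means estimates the planted raw fold
        cfg = CohortConfig(
            n_mirna=1,
            sizes={"training": PhaseSizes(control=10_000, ami=10_000)},
            planted_markers=[PlantedMarker(mirna_id="miR-1",
                                           log10_fold={"AMI": 0.48})],
            baseline_log10_mean=2.0,
            baseline_log10_sd=0.25,
            seed=11,
        )
        cohort = generate_cohort(cfg)
        case = cohort.true_conc.loc[cohort.samples(group="AMI"), "miR-1"]
        ctrl = cohort.true_conc.loc[cohort.samples(group="control"), "miR-1"]
        ratio = 10 ** (np.log10(case).mean() - np.log10(ctrl).mean())
        assert 2.8 <= ratio <= 3.2

    def test_effect_size_recovery_bound(self):
        # planted log10 fold recovered within 4*sd/sqrt(n) in >= 19/20 seeds
        f, sd, n = 0.3, 0.2, 1000
        hits = 0
        for seed in range(20):
            cfg = CohortConfig(
                n_mirna=1,
                sizes={"training": PhaseSizes(control=n, ami=n)},
                planted_markers=[PlantedMarker(mirna_id="miR-1",
                                               log10_fold={"AMI": f})],
                baseline_log10_mean=2.0,
                baseline_log10_sd=sd,
                seed=seed,
            )
            cohort = generate_cohort(cfg)
            lg = np.log10(cohort.true_conc["miR-1"])
            grp = cohort.metadata.set_index("sample_id")["group"]
            diff = lg[grp == "AMI"].mean() - lg[grp == "control"].mean()
            hits += abs(diff - f) <= 4 * sd / np.sqrt(n)
        assert hits >= 19


class TestPoolCounts:
    def test_counts_sum_to_library_size(self):
        cfg = small_config()
        cohort = generate_cohort(cfg)
        counts = simulate_pool_counts(cohort, "AMI")
        assert counts.sum() == cfg.library_size
        assert (counts >= 0).all()

    def test_degenerate_pool_gets_all_reads(self):
        cohort = make_cohort(
            {"miR-a": [100.0, 100.0], "miR-b": [0.0, 0.0]},
            ["AMI", "AMI"], phase="screen",
        )
        counts = simulate_pool_counts(cohort, "AMI")
        assert counts["miR-a"] == cohort.config.library_size
        assert counts["miR-b"] == 0

    def test_empty_group_errors(self):
        cohort = generate_cohort(small_config())
        with pytest.raises(DataError, match="AP"):
            simulate_pool_counts(cohort, "AP")

    def test_mean_count_ratio_tracks_concentration_ratio(self):
        # 5:1 pooled concentrations, library 6e5: binomial expectation 5.0
        ratios = []
        for seed in range(200):
            cohort = make_cohort(
                {"miR-a": [500.0, 500.0], "miR-b": [100.0, 100.0]},
                ["AMI", "AMI"], phase="screen",
            )
            cohort.config.seed = seed
            cohort.config.library_size = 600_000
            counts = simulate_pool_counts(cohort, "AMI")
            ratios.append(counts["miR-a"] / counts["miR-b"])
        assert 4.8 <= np.mean(ratios) <= 5.2


class TestSimulateCq:
    def test_noiseless_cq_at_curve_anchor(self, doubling_curve):
        cohort = make_cohort({"miR-test": [1.0, 1024.0]}, ["AMI", "AMI"])
        cohort.config.cq_noise_sd = 0.0
        cq = simulate_cq(cohort, {"miR-test": doubling_curve},
                         phases=["training"])
        s0, s1 = cohort.metadata["sample_id"]
        np.testing.assert_allclose(
            cq.loc[cq["sample_id"] == s0, "cq"], 40.0, atol=1e-12)
        # 10 doublings at perfect-doubling slope shift Cq by exactly -10
        np.testing.assert_allclose(
            cq.loc[cq["sample_id"] == s1, "cq"], 30.0, atol=1e-9)

    def test_triplicate_contract(self):
        cfg = small_config()
        cohort = generate_cohort(cfg)
        curves = make_true_curves(cfg)
        cq = simulate_cq(cohort, curves, phases=["training"])
        per_well = cq.groupby(["sample_id", "mirna_id"]).size()
        assert (per_well == 3).all()
        assert len(cq) == 40 * cfg.n_mirna * 3

    def test_missing_curve_names_mirna(self):
        cohort = generate_cohort(small_config())
        with pytest.raises(DataError, match="miR-1"):
            simulate_cq(cohort, {}, phases=["training"])

    def test_seeded_cq_determinism(self):
        cfg = small_config(seed=3)
        cohort = generate_cohort(cfg)
        curves = make_true_curves(cfg)
        a = simulate_cq(cohort, curves, phases=["training"])
        b = simulate_cq(cohort, curves, phases=["training"])
        pd.testing.assert_frame_equal(a, b)
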