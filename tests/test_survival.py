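"""Survival association: cohort filter, KM, log-rank, permutations, FDR,
between-arm comparisons and clustering."""

import itertools

import numpy as np
import pandas as pd
import pytest
from lifelines.statistics import logrank_test as ll_logrank

from cnsurv import survival
from cnsurv.survival import (
    associate_genomewide,
    between_arm_tests,
    cluster_enrichment,
    cluster_samples,
    filter_cohort,
    flag_significance,
    km_estimate,
    logrank_statistic,
    permutation_fdr,
    permutation_pvalue,
)


def clinical_frame(rows):
    return pd.DataFrame(
        rows,
        columns=[
            "sample_id", "arm", "pfs_days", "event", "cycles",
            "death_progression", "msi", "tumour_cell_pct",
        ],
    )


class TestFilterCohort:
    @pytest.mark.parametrize(
        "cycles,death,msi,kept",
        [
            (3, False, False, True),   # >= 3 cycles
            (2, True, False, True),    # 2 cycles but died of progression
            (2, False, False, False),  # 2 cycles, no progression death
            (5, False, True, False),   # MSI excluded regardless
            (1, True, False, False),   # a single cycle never qualifies
        ],
    )
    def test_rules(self, cycles, death, msi, kept):
        clin = clinical_frame([("s", "CAP", 100.0, 1, cycles, death, msi, 0.8)])
        assert (len(filter_cohort(clin)) == 1) is kept

    def test_missing_cycles_excluded(self):
        clin = clinical_frame([("s", "CAP", 100.0, 1, np.nan, False, False, 0.8)])
        assert len(filter_cohort(clin)) == 0


class TestKm:
    def test_product_limit_by_hand(self):
        est = km_estimate([10, 20, 30], [1, 1, 1])
        surv = est["curve"].set_index("time")["survival"]
        assert surv.loc[10] == pytest.approx(2 / 3)
        assert surv.loc[20] == pytest.approx(1 / 3)
        assert surv.loc[30] == pytest.approx(0.0)
        assert est["median"] == 20

    def test_single_event(self):
        assert km_estimate([5], [1])["median"] == 5

    def test_all_censored_median_na(self):
        est = km_estimate([5, 10, 15], [0, 0, 0])
        assert np.isnan(est["median"])


class TestLogrank:
    def test_hand_computed_example(self):
        # carriers fail at 1,2; non-carriers at 3,4: U=7/6, V=17/36
        stat = logrank_statistic([1, 2, 3, 4], [1, 1, 1, 1], [True, True, False, False])
        assert stat == pytest.approx((7 / 6) ** 2 / (17 / 36), abs=1e-9)

    def test_identical_groups_zero(self):
        stat = logrank_statistic([1, 1, 2, 2], [1, 1, 1, 1], [True, False, True, False])
        assert stat == pytest.approx(0.0, abs=1e-12)

    def test_matches_lifelines(self, rng):
        for _ in range(5):
            n = 40
            t = rng.exponential(100, n)
            e = (rng.random(n) < 0.8).astype(int)
            g = rng.random(n) < 0.4
            if g.all() or not g.any():
                continue
            ours = logrank_statistic(t, e, g)
            ref = ll_logrank(t[g], t[~g], e[g], e[~g]).test_statistic
            assert ours == pytest.approx(ref, rel=1e-9)

    def test_no_events_zero(self):
        assert logrank_statistic([1, 2, 3], [0, 0, 0], [True, False, True]) == 0.0


class TestPermutationP:
    def test_plus_one_convention_floor(self):
        # perfectly separated groups, n large enough that no permutation ties
        t = np.r_[np.arange(1, 16), np.arange(100, 115)].astype(float)
        e = np.ones(30, int)
        g = np.r_[np.ones(15, bool), np.zeros(15, bool)]
        p = permutation_pvalue(t, e, g, n_perm=999, seed=0)
        assert p == pytest.approx(1 / 1000)

    def test_degenerate_labels_p_one(self):
        assert permutation_pvalue([1, 2, 3], [1, 1, 1], [True, True, True], n_perm=10) == 1.0

    def test_matches_exhaustive_enumeration_small_n(self, rng):
        # n=8, 4 carriers: enumerate all 70 assignments
        t = rng.exponential(50, 8)
        e = np.array([1, 1, 0, 1, 1, 1, 0, 1])
        g = np.zeros(8, bool)
        g[:4] = True
        obs = logrank_statistic(t, e, g)
        stats = []
        for combo in itertools.combinations(range(8), 4):
            lab = np.zeros(8, bool)
            lab[list(combo)] = True
            stats.append(logrank_statistic(t, e, lab))
        p_enum = np.mean(np.asarray(stats) >= obs - 1e-12)
        p_samp = permutation_pvalue(t, e, g, n_perm=20_000, seed=1)
        assert p_samp == pytest.approx(p_enum, abs=0.02)

    def test_invariant_to_sample_order(self, rng):
        t = rng.exponential(100, 30)
        e = (rng.random(30) < 0.8).astype(int)
        g = rng.random(30) < 0.5
        p1 = permutation_pvalue(t, e, g, n_perm=4000, seed=9)
        perm = rng.permutation(30)
        p2 = permutation_pvalue(t[perm], e[perm], g[perm], n_perm=4000, seed=9)
        assert p1 == pytest.approx(p2, abs=0.03)


def null_cohort(rng, n=60, arm="CAP"):
    return clinical_frame(
        [
            (f"s{i}", arm, float(rng.exponential(200)), int(rng.random() < 0.85),
             6, False, False, 0.8)
            for i in range(n)
        ]
    )


class TestGenomewide:
    def test_small_group_skipped(self, rng):
        clin = null_cohort(rng, n=30)
        calls = pd.DataFrame(
            [[1] * 3 + [0] * 27], columns=clin["sample_id"], index=["r0"]
        )
        scan = associate_genomewide(calls, clin, "CAP", n_perm=50, min_group=5, seed=0)
        gain = scan.results.query("kind == 'gain'")
        assert (gain["skipped"] == "group below minimum size").all()

    def test_driver_detected_and_tiers(self, rng):
        n = 80
        carriers = np.zeros(n, bool)
        carriers[:24] = True
        t = np.where(carriers, rng.exponential(60, n), rng.exponential(250, n))
        clin = clinical_frame(
            [(f"s{i}", "CAP", float(t[i]), 1, 6, False, False, 0.8) for i in range(n)]
        )
        calls = pd.DataFrame(
            np.vstack([-carriers.astype(int), rng.integers(-1, 2, n)]),
            columns=clin["sample_id"], index=["driver", "null"],
        )
        scan = associate_genomewide(calls, clin, "CAP", n_perm=2000, min_group=5, seed=3)
        row = scan.results.query("region == 'driver' and kind == 'loss'").iloc[0]
        assert row["perm_p"] < 0.005
        assert row["median_carrier"] < row["median_noncarrier"]
        flagged = flag_significance([scan])
        assert flagged.query("region == 'driver' and kind == 'loss'")["tier1"].iloc[0]

    def test_permutation_archive_shape(self, rng):
        clin = null_cohort(rng, n=40)
        calls = pd.DataFrame(
            rng.integers(-1, 2, size=(3, 40)), columns=clin["sample_id"],
            index=["r0", "r1", "r2"],
        )
        scan = associate_genomewide(calls, clin, "CAP", n_perm=100, min_group=2, seed=1)
        tested = scan.results.query("skipped == ''")
        assert scan.permuted_p.shape == (100, len(tested))
        assert ((scan.permuted_p > 0) & (scan.permuted_p <= 1)).all().all()


class TestFdr:
    def test_no_discoveries_is_one(self, rng):
        assert permutation_fdr(np.full(10, 0.9), rng.random((50, 10)), 0.005) == 1.0

    def test_pure_null_near_one(self, rng):
        obs = rng.random(200)
        perm = rng.random((100, 200))
        fdr = permutation_fdr(obs, perm, 0.05)
        assert 0.5 < fdr <= 1.0

    def test_planted_signal_lowers_fdr(self, rng):
        obs = np.r_[np.full(20, 1e-4), rng.random(180)]
        perm = rng.random((100, 200))
        assert permutation_fdr(obs, perm, 0.005) < 0.2


class TestBetweenArm:
    def test_three_arms_three_pairs_per_stratum(self, rng):
        clin = pd.concat(
            [null_cohort(rng, 30, "CAP"), null_cohort(rng, 30, "CAPIRI"),
             null_cohort(rng, 30, "CAPOX-B")]
        )
        clin["sample_id"] = [f"s{i}" for i in range(len(clin))]
        calls = pd.Series(rng.choice([-1, 0, 1], len(clin)), index=clin["sample_id"])
        out = between_arm_tests(calls, clin, "gain")
        assert len(out) == 6  # 3 pairs x {carrier, noncarrier}
        assert set(out["stratum"]) == {"carrier", "noncarrier"}

    def test_empty_stratum_reported_na(self, rng):
        clin = pd.concat([null_cohort(rng, 20, "A"), null_cohort(rng, 20, "B")])
        clin["sample_id"] = [f"s{i}" for i in range(len(clin))]
        calls = pd.Series(0, index=clin["sample_id"])  # nobody carries anything
        out = between_arm_tests(calls, clin, "gain", arms=("A", "B"))
        carrier_rows = out.query("stratum == 'carrier'")
        assert carrier_rows["p"].isna().all()


class TestClustering:
    def test_recovers_silent_vs_aberrant_groups(self, rng):
        # aberrant genomes share a recurrent gain/loss signature; silent ones
        # are mostly flat — mirrors the silent-cluster structure of MSI tumours
        signature = rng.choice([-1, 1], size=40)
        silent = np.where(rng.random((40, 30)) < 0.05, 1, 0)
        aberrant = np.where(
            rng.random((40, 30)) < 0.15, 0, np.broadcast_to(signature[:, None], (40, 30))
        )
        calls = pd.DataFrame(
            np.hstack([silent, aberrant]),
            columns=[f"sil{i}" for i in range(30)] + [f"ab{i}" for i in range(30)],
        )
        labels = cluster_samples(calls, k=2)
        sil_label = labels[[c for c in labels.index if c.startswith("sil")]].mode()[0]
        agreement = (
            (labels[[c for c in labels.index if c.startswith("sil")]] == sil_label).mean()
            + (labels[[c for c in labels.index if c.startswith("ab")]] != sil_label).mean()
        ) / 2
        assert agreement >= 0.95

    def test_msi_enrichment_chi_square(self):
        # silent cluster of 97 holding 19 of 21 MSI tumours vs 252 others
        labels = pd.Series([1] * 97 + [2] * 252)
        flags = pd.Series([True] * 19 + [False] * 78 + [True] * 2 + [False] * 250)
        stat, p = cluster_enrichment(labels, flags)
        assert p < 0.001

    def test_k_larger_than_n_rejected(self, rng):
        calls = pd.DataFrame(rng.integers(-1, 2, size=(5, 3)))
        with pytest.raises(ValueError):
            cluster_samples(calls, k=10)
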