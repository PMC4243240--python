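"""Gene mapping, dosage correlation, amplicon cataloguing, Kruskal-Wallis and
cell-line validation."""

import numpy as np
import pandas as pd
import pytest
from scipy.stats import kruskal as scipy_kruskal
from scipy.stats import ranksums

from cnsurv.integration import (
    cellline_region_status,
    detect_amplicons,
    dosage_correlation,
    kruskal_wallis,
    map_genes_to_region,
    recurrent_amplicons,
    select_candidate_genes,
    validate_regions_in_celllines,
)
from cnsurv.synthetic import CellLinePanel, PairedExpressionDataset, simulate_cellline_panel

from conftest import make_annotation


def gene_frame(rows):
    return pd.DataFrame(rows, columns=["gene_id", "chromosome", "start", "end"])


class TestGeneMapping:
    genes = gene_frame([("g1", "chr1", 10, 20), ("g2", "chr1", 50, 60), ("g3", "chr2", 10, 20)])

    def test_one_bp_overlap_mapped(self):
        hit = map_genes_to_region(self.genes, {"chromosome": "chr1", "start": 19, "end": 30})
        assert list(hit["gene_id"]) == ["g1"]

    def test_half_open_boundary_not_mapped(self):
        hit = map_genes_to_region(self.genes, {"chromosome": "chr1", "start": 20, "end": 30})
        assert len(hit) == 0

    def test_all_contained_genes_returned(self):
        hit = map_genes_to_region(self.genes, {"chromosome": "chr1", "start": 0, "end": 100})
        assert list(hit["gene_id"]) == ["g1", "g2"]

    def test_shift_invariance(self):
        shifted = self.genes.assign(start=self.genes.start + 1000, end=self.genes.end + 1000)
        a = map_genes_to_region(self.genes, {"chromosome": "chr1", "start": 15, "end": 55})
        b = map_genes_to_region(shifted, {"chromosome": "chr1", "start": 1015, "end": 1055})
        assert list(a["gene_id"]) == list(b["gene_id"])


class TestDosageCorrelation:
    def test_perfect_monotone(self):
        cn = np.arange(10, dtype=float)
        rho, p = dosage_correlation(cn, cn)
        assert rho == pytest.approx(1.0)
        assert p < 0.01

    def test_negative_correlation_one_sided_p_near_one(self):
        cn = np.arange(10, dtype=float)
        rho, p = dosage_correlation(cn, -cn)
        assert rho == pytest.approx(-1.0)
        assert p > 0.95

    def test_constant_cn_undefined(self):
        rho, p = dosage_correlation(np.zeros(10), np.arange(10.0))
        assert np.isnan(rho) and np.isnan(p)

    def test_too_few_samples_rejected(self):
        with pytest.raises(ValueError):
            dosage_correlation(np.array([1.0, 2.0]), np.array([1.0, 2.0]))


class TestCandidateGenes:
    def make_inputs(self, rng):
        genes = gene_frame([("gA", "chr1", 0, 100), ("gB", "chr1", 200, 300),
                            ("gC", "chr1", 400, 500)])
        regions = pd.DataFrame(
            {"chromosome": ["chr1", "chr1"], "start": [0, 200], "end": [150, 350],
             "n_probes": [2, 2], "probe_start": [0, 2], "probe_end": [2, 4],
             "arm": ["p", "p"]},
            index=["r1", "r2"],
        )
        flagged = pd.DataFrame(
            {"region": ["r1", "r1", "r2"], "kind": ["gain", "gain", "loss"],
             "arm": ["CAP", "CAPIRI", "CAP"],
             "tier1": [True, False, False], "tier2": [False, False, True],
             "skipped": ["", "", ""]}
        )
        n = 30
        cn = pd.DataFrame(
            rng.choice([-1, 0, 1], size=(2, n)).astype(float),
            index=["gA", "gB"], columns=[f"s{i}" for i in range(n)],
        )
        expr = cn * 1.0 + rng.normal(0, 0.3, size=(2, n))
        expr.loc["gB"] = rng.normal(size=n)  # gB not dosage sensitive
        paired = PairedExpressionDataset(copy_number=cn, expression=expr)
        return flagged, regions, genes, paired

    def test_tier_assignment_and_retention(self, rng):
        flagged, regions, genes, paired = self.make_inputs(rng)
        out = select_candidate_genes(flagged, regions, genes, paired).set_index("gene_id")
        assert out.loc["gA", "tier"] == "A"
        assert out.loc["gA", "status"] == "retained"
        assert out.loc["gB", "tier"] == "B"
        assert out.loc["gB", "status"] == "rejected"
        assert "gC" not in out.index  # not on a flagged region

    def test_gene_missing_from_paired_data_untested(self, rng):
        flagged, regions, genes, paired = self.make_inputs(rng)
        paired.copy_number.drop(index="gA", inplace=True)
        out = select_candidate_genes(flagged, regions, genes, paired).set_index("gene_id")
        assert out.loc["gA", "status"] == "untested"


class TestAmplicons:
    def test_runs_detected_per_sample(self):
        ann = make_annotation({"chr1": 10, "chr2": 5})
        calls = pd.DataFrame({"s1": [0, 2, 2, 0, 0, 2, 0, 0, 0, 0, 2, 2, 0, 0, 0]})
        events = detect_amplicons(calls, ann)
        assert len(events) == 3
        assert list(events["n_probes"]) == [2, 1, 2]
        assert list(events["chromosome"]) == ["chr1", "chr1", "chr2"]

    def test_run_not_bridged_across_chromosomes(self):
        ann = make_annotation({"chr1": 3, "chr2": 3})
        calls = pd.DataFrame({"s1": [0, 2, 2, 2, 2, 0]})
        events = detect_amplicons(calls, ann)
        assert len(events) == 2

    def test_shared_locus_frequency(self):
        events = pd.DataFrame(
            [(f"s{i}", "chr8", 100 + 10 * i, 200 + 10 * i, 5) for i in range(5)],
            columns=["sample_id", "chromosome", "start", "end", "n_probes"],
        )
        loci = recurrent_amplicons(events, min_freq=4)
        assert len(loci) == 1
        assert loci.iloc[0]["frequency"] == 5
        # intersection span of the member events
        assert loci.iloc[0]["start"] == 140 and loci.iloc[0]["end"] == 200

    def test_disjoint_events_below_min_freq(self):
        events = pd.DataFrame(
            [("s1", "chr8", 100, 200, 5), ("s2", "chr8", 500, 600, 5)],
            columns=["sample_id", "chromosome", "start", "end", "n_probes"],
        )
        assert len(recurrent_amplicons(events, min_freq=4)) == 0
        assert len(recurrent_amplicons(events, min_freq=1)) == 2

    def test_frequency_invariant_to_sample_order(self, rng):
        events = pd.DataFrame(
            [(f"s{i}", "chr1", int(rng.integers(0, 500)), 0, 3) for i in range(20)],
            columns=["sample_id", "chromosome", "start", "end", "n_probes"],
        )
        events["end"] = events["start"] + 100
        a = recurrent_amplicons(events, min_freq=1)
        b = recurrent_amplicons(events.sample(frac=1, random_state=7), min_freq=1)
        pd.testing.assert_frame_equal(a, b)


class TestKruskalWallis:
    def test_hand_ranked_example(self):
        H, p = kruskal_wallis([1, 2, 3, 4, 5, 6], ["a", "a", "a", "b", "b", "b"])
        assert H == pytest.approx(3.857142857, abs=1e-6)
        assert p == pytest.approx(0.0495, abs=0.001)

    def test_matches_scipy_with_ties(self, rng):
        for _ in range(5):
            x = rng.integers(0, 6, 20).astype(float)  # heavy ties
            g = rng.integers(0, 3, 20)
            if len(set(g)) < 2 or np.ptp(x) == 0:
                continue
            ours_H, ours_p = kruskal_wallis(x, g)
            ref = scipy_kruskal(*[x[g == k] for k in set(g)])
            assert ours_H == pytest.approx(ref.statistic, rel=1e-9)
            assert ours_p == pytest.approx(ref.pvalue, rel=1e-9)

    def test_two_groups_equals_squared_ranksum_z(self, rng):
        x = rng.normal(size=24)
        g = np.r_[np.zeros(12), np.ones(12)]
        H, _ = kruskal_wallis(x, g)
        z = ranksums(x[g == 0], x[g == 1]).statistic
        assert H == pytest.approx(z**2, rel=1e-9)

    def test_identical_values_h_zero_p_one(self):
        assert kruskal_wallis([5, 5, 5, 5], [0, 0, 1, 1]) == (0.0, 1.0)

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError):
            kruskal_wallis([1, 2, 3], [0, 0, 0])


class TestCellLines:
    region = pd.Series(
        {"chromosome": "chr6", "start": 10_000_000, "end": 20_000_000,
         "type": "gain", "label": "6q"}
    )

    def seg(self, rows):
        return pd.DataFrame(rows, columns=["line_id", "chromosome", "start", "end", "copy"])

    def test_any_overlap_gain(self):
        segs = self.seg([("L1", "chr6", 19_500_000, 25_000_000, 3)])
        assert cellline_region_status(segs, self.region, "gain")

    def test_diploid_only_normal(self):
        segs = self.seg([("L1", "chr6", 0, 30_000_000, 2)])
        assert not cellline_region_status(segs, self.region, "gain")

    def test_state_must_match_kind(self):
        segs = self.seg([("L1", "chr6", 12_000_000, 18_000_000, 1)])
        assert not cellline_region_status(segs, self.region, "gain")
        assert cellline_region_status(segs, self.region, "loss")

    def test_validation_recovers_planted_shift(self):
        regions = pd.DataFrame(
            [("chr6", 10_000_000, 20_000_000, "gain", "6q")],
            columns=["chromosome", "start", "end", "type", "label"],
        )
        panel, truth = simulate_cellline_panel(
            200, regions, effect={"6q": -1.0}, seed=11, crc_lines=31
        )
        out = validate_regions_in_celllines(panel, regions, "SN-38")
        full = out.query("panel == 'all'").iloc[0]
        assert full["n_aberrant"] + full["n_normal"] == 200
        assert full["p"] < 0.05
        assert set(out["panel"]) == {"all", "CRC-panel", "other"}

    def test_small_stratum_na(self):
        regions = pd.DataFrame(
            [("chr6", 10, 20, "gain", "r")],
            columns=["chromosome", "start", "end", "type", "label"],
        )
        panel = CellLinePanel(
            segments=self.seg([("L1", "chr6", 0, 100, 3), ("L2", "chr6", 0, 100, 3)]),
            ic50=pd.DataFrame(
                {"line_id": ["L1", "L2"], "drug": "SN-38", "log_ic50": [0.1, 0.4]}
            ),
        )
        out = validate_regions_in_celllines(panel, regions, "SN-38")
        assert out["p"].isna().all()
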