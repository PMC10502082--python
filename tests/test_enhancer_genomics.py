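import numpy as np
import pandas as pd
import pytest

from zganet.enhancer_genomics import (
    assign_four_groups,
    call_regulation,
    define_ars,
    gc_content,
    h3k27ac_status,
    motif_enrichment,
    score_rescue,
    select_tdars,
)


class TestDefineArs:
    def test_region_arithmetic_half_open(self):
        out = define_ars(pd.DataFrame({"chrom": ["chr1"], "summit": [1000]}))
        r = out.iloc[0]
        assert (r.start, r.end) == (945, 1055)
        assert r.end - r.start == 110
        assert not r.clipped

    def test_nearby_summits_give_overlapping_unmerged_regions(self):
        out = define_ars(pd.DataFrame({"chrom": ["chr1", "chr1"], "summit": [1000, 1010]}))
        assert len(out) == 2
        assert out.iloc[0].end > out.iloc[1].start

    def test_clipping_at_contig_start_flagged(self):
        out = define_ars(pd.DataFrame({"chrom": ["ctg"], "summit": [30]}))
        r = out.iloc[0]
        assert (r.start, r.end) == (0, 85)
        assert r.clipped

    def test_off_chromosome_summit_rejected(self):
        with pytest.raises(ValueError, match="off chromosome"):
            define_ars(pd.DataFrame({"chrom": ["c"], "summit": [500]}), chrom_sizes={"c": 400})


class TestCallRegulation:
    def test_consensus_down(self):
        assert call_regulation([(-1.2, 0.01)] * 4) == "down"

    def test_consensus_up(self):
        assert call_regulation([(0.8, 0.02)] * 4) == "up"

    def test_one_insignificant_normalization_breaks_consensus(self):
        assert call_regulation([(-1.2, 0.01)] * 3 + [(-1.2, 0.06)]) == "same"

    def test_mixed_signs_break_consensus(self):
        assert call_regulation([(-1.0, 0.01), (1.0, 0.01), (-1.0, 0.01), (-1.0, 0.01)]) == "same"

    def test_wrong_pair_count_rejected(self):
        with pytest.raises(ValueError, match="four"):
            call_regulation([(-1, 0.01)] * 3)


class TestTdars:
    def regions(self):
        return pd.DataFrame({"region_id": ["r1"], "chrom": ["c"], "start": [945], "end": [1055], "summit": [1000]})

    def test_single_bp_overlap_is_eligible(self):
        peaks = {"tf": pd.DataFrame({"chrom": ["c"], "start": [1054], "end": [1200]})}
        calls = pd.Series({"r1": "down"})
        assert select_tdars(self.regions(), calls, peaks).loc["r1"]

    def test_touching_intervals_do_not_overlap(self):
        peaks = {"tf": pd.DataFrame({"chrom": ["c"], "start": [1055], "end": [1200]})}
        calls = pd.Series({"r1": "down"})
        assert not select_tdars(self.regions(), calls, peaks).loc["r1"]

    def test_down_without_tf_binding_is_not_tdar(self):
        peaks = {"tf": pd.DataFrame({"chrom": ["c"], "start": [5000], "end": [5100]})}
        assert not select_tdars(self.regions(), pd.Series({"r1": "down"}), peaks).loc["r1"]

    def test_bound_but_not_down_is_not_tdar(self):
        peaks = {"tf": pd.DataFrame({"chrom": ["c"], "start": [990], "end": [1010]})}
        assert not select_tdars(self.regions(), pd.Series({"r1": "same"}), peaks).loc["r1"]


class TestFourGroups:
    @pytest.mark.parametrize(
        "p_call,n_call,group",
        [("down", "down", "1.PN"), ("down", "same", "2.P"), ("same", "down", "3.N"), ("same", "up", "4.-")],
    )
    def test_group_assignment(self, p_call, n_call, group):
        tdar = pd.Series({"r": True})
        out = assign_four_groups(tdar, pd.Series({"r": p_call}), pd.Series({"r": n_call}))
        assert out.loc["r"] == group

    def test_partition_covers_every_tdar_exactly_once(self):
        rng = np.random.default_rng(0)
        ids = [f"r{i}" for i in range(200)]
        tdar = pd.Series(True, index=ids)
        p = pd.Series(rng.choice(["down", "same", "up"], 200), index=ids)
        n = pd.Series(rng.choice(["down", "same", "up"], 200), index=ids)
        groups = assign_four_groups(tdar, p, n)
        assert len(groups) == 200
        assert groups.value_counts().sum() == 200
        assert set(groups.unique()) <= {"1.PN", "2.P", "3.N", "4.-"}


class TestH3K27ac:
    def test_floored_wt_below_threshold_is_not_acetylated(self):
        res = h3k27ac_status({"WT": 0.05, "MZp": 0.05})
        assert res["floored"]["WT"] == 0.1
        assert not res["acetylated"]

    def test_activator_call_from_log2_drop(self):
        res = h3k27ac_status({"WT": 0.8, "MZp": 0.4})
        assert res["status"]["MZp"] == "+"  # log2(0.5) = -1 < -0.7

    def test_blocker_call_from_log2_rise(self):
        res = h3k27ac_status({"WT": 0.4, "MZn": 0.8})
        assert res["status"]["MZn"] == "-"  # log2(2) = 1 > 0.7

    def test_small_change_is_neutral(self):
        res = h3k27ac_status({"WT": 0.4, "MZs": 0.5})
        assert res["status"]["MZs"] == "0"

    def test_swap_antisymmetry(self):
        # swapping WT and mutant means maps "+" <-> "-" and fixes "0"
        rng = np.random.default_rng(1)
        for _ in range(50):
            wt, mut = rng.uniform(0.15, 2.0, 2)
            a = h3k27ac_status({"WT": wt, "M": mut})["status"]["M"]
            b = h3k27ac_status({"WT": mut, "M": wt})["status"]["M"]
            assert {a, b} in ({"+", "-"}, {"0"})

    def test_missing_wt_rejected(self):
        with pytest.raises(KeyError):
            h3k27ac_status({"MZp": 0.4})


class TestRescue:
    def test_clear_rescue(self):
        assert score_rescue(8.0, 2.0, 5.0)  # log2(2.5) > log2(1.6)

    def test_geometric_mean_boundary_is_not_rescued(self):
        assert not score_rescue(8.0, 2.0, 4.0)  # inj = sqrt(wt*ctrl) exactly

    def test_no_gain_is_not_rescued(self):
        assert not score_rescue(8.0, 2.0, 2.0)

    def test_equivalent_to_geometric_mean_criterion_on_random_triples(self):
        rng = np.random.default_rng(7)
        agree = 0
        for _ in range(1000):
            wt, ctrl, inj = 10 ** rng.uniform(-2, 2, 3)
            agree += score_rescue(wt, ctrl, inj) == (inj > np.sqrt(wt * ctrl))
        assert agree == 1000

    def test_non_positive_signal_rejected(self):
        with pytest.raises(ValueError):
            score_rescue(0.0, 1.0, 1.0)


class TestMotifEnrichment:
    def summits(self):
        return pd.DataFrame({"chrom": ["c", "c"], "summit": [1000, 5000]})

    def test_identical_densities_give_zero(self):
        hits = pd.DataFrame(
            {"chrom": ["c"] * 4, "start": [995, 4995, 1995, 5995], "end": [1005, 5005, 2005, 6005]}
        )
        res = motif_enrichment(hits, self.summits())
        assert res["enrichment"] == pytest.approx(0.0)

    def test_double_density_gives_one(self):
        hits = pd.DataFrame(
            {
                "chrom": ["c"] * 6,
                "start": [990, 1005, 4990, 5005, 1995, 5995],
                "end": [1000, 1015, 5000, 5015, 2005, 6005],
            }
        )
        res = motif_enrichment(hits, self.summits())
        assert res["enrichment"] == pytest.approx(1.0)

    def test_half_open_boundary_hit_not_counted(self):
        # window is [summit-30, summit+30); a hit ending exactly at summit-30
        # does not overlap
        hits = pd.DataFrame({"chrom": ["c", "c"], "start": [960, 1990], "end": [970, 2000]})
        res = motif_enrichment(hits, pd.DataFrame({"chrom": ["c"], "summit": [1000]}))
        assert res["ar_density"] == 0.0

    def test_zero_control_density_flagged(self):
        hits = pd.DataFrame({"chrom": ["c"], "start": [995], "end": [1005]})
        res = motif_enrichment(hits, pd.DataFrame({"chrom": ["c"], "summit": [1000]}))
        assert not res["defined"] and np.isnan(res["enrichment"])


class TestGcContent:
    def test_pure_gc(self):
        assert gc_content("GC" * 55) == 1.0

    def test_pure_at(self):
        assert gc_content("AT" * 55) == 0.0

    def test_balanced(self):
        assert gc_content("ACGT" * 27 + "AC") == pytest.approx(0.5)

    def test_n_bases_excluded_from_denominator(self):
        assert gc_content("N" * 10 + "GC" * 50) == 1.0

    def test_all_n_undefined(self):
        assert np.isnan(gc_content("N" * 110))

    def test_invalid_characters_rejected(self):
        with pytest.raises(ValueError, match="invalid characters"):
            gc_content("X" * 110)

    def test_wrong_length_rejected(self):
        with pytest.raises(ValueError, match="110"):
            gc_content("ACGT")
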