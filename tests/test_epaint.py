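"""Sliding-window profiles, percentile painting and genome assignment."""

from __future__ import annotations

import math

import numpy as np
import pandas as pd
import pytest

from gbspaint.epaint import (
    ConsensusMap,
    PaintTrack,
    WindowProfile,
    assign_genomes,
    export_circos,
    percentile_paint,
    read_circos_highlights,
    read_map,
    window_profiles,
    write_map,
)


def _map_one_chrom(positions, length=10.0, chrom="M1"):
    return ConsensusMap({chrom: length},
                        {f"L{i}": (chrom, p) for i, p in enumerate(positions)})


def _calls(strings):
    return pd.Series({f"L{i}": s for i, s in enumerate(strings)})


class TestMapIO:
    def test_round_trip(self, tmp_path):
        cmap = ConsensusMap({"M1": 50.0, "M2": 80.0},
                            {"L1": ("M1", 3.25), "L2": ("M2", 79.0)})
        write_map(cmap, tmp_path / "m.tsv")
        back = read_map(tmp_path / "m.tsv")
        assert back.chromosomes == cmap.chromosomes
        assert back.loci == cmap.loci

    def test_unknown_chromosome_rejected(self):
        with pytest.raises(ValueError):
            ConsensusMap({"M1": 50.0}, {"L1": ("M9", 3.0)})

    def test_position_outside_chromosome_rejected(self):
        with pytest.raises(ValueError):
            ConsensusMap({"M1": 50.0}, {"L1": ("M1", 60.0)})


class TestWindowProfiles:
    def test_presence_frequency(self):
        cmap = _map_one_chrom([4.0, 5.0, 6.0])
        prof = window_profiles(_calls(["a", "", "a"]), cmap, window=30)
        # every window spans all three loci on this short chromosome
        assert np.allclose(prof.table["f"], 2 / 3)

    def test_haplotype_diversity(self):
        cmap = _map_one_chrom([4.0, 5.0, 6.0])
        prof = window_profiles(_calls(["ab", "", "a"]), cmap, window=30)
        assert np.allclose(prof.table["v"], 1.5)  # 3 letters / 2 present

    def test_all_present_gives_unit_frequency(self):
        cmap = _map_one_chrom(list(np.linspace(0.5, 9.5, 10)))
        prof = window_profiles(_calls(["a"] * 10), cmap, window=4)
        assert np.allclose(prof.table["f"], 1.0)

    def test_diversity_missing_when_nothing_present(self):
        cmap = _map_one_chrom([5.0])
        prof = window_profiles(_calls([""]), cmap, window=2)
        row = prof.table.set_index("position").loc[5.0]
        assert row["f"] == 0.0 and math.isnan(row["v"])

    def test_empty_window_carries_missing_values(self):
        cmap = _map_one_chrom([9.5], length=100.0)
        prof = window_profiles(_calls(["a"]), cmap, window=4)
        far = prof.table.set_index("position").loc[60.0]
        assert far["n"] == 0 and math.isnan(far["f"])

    def test_wide_window_gives_constant_profile(self):
        rng = np.random.default_rng(0)
        pos = np.sort(rng.uniform(0, 10, size=12))
        calls = _calls([rng.choice(["", "a", "ab"]) for _ in range(12)])
        cmap = _map_one_chrom(list(pos))
        prof = window_profiles(calls, cmap, window=40)  # >= 2x length
        assert prof.table["f"].nunique() == 1

    def test_invariant_to_locus_order(self):
        rng = np.random.default_rng(1)
        pos = np.sort(rng.uniform(0, 10, size=9))
        cmap = _map_one_chrom(list(pos))
        calls = _calls([rng.choice(["", "a", "abc"]) for _ in range(9)])
        prof1 = window_profiles(calls, cmap, window=6)
        prof2 = window_profiles(calls.sample(frac=1, random_state=3), cmap, window=6)
        pd.testing.assert_frame_equal(prof1.table, prof2.table)

    def test_unscored_locus_rejected(self):
        cmap = _map_one_chrom([1.0, 2.0])
        with pytest.raises(ValueError):
            window_profiles(pd.Series({"L0": "a"}), cmap)


def _grid_profile(values, chrom="M1", group="g"):
    tab = pd.DataFrame({
        "chromosome": chrom,
        "position": np.arange(len(values), dtype=float),
        "n": 1,
        "f": np.asarray(values, dtype=float),
        "v": np.nan,
    })
    return WindowProfile(group=group, window=30, step=1.0, table=tab)


class TestPercentilePaint:
    def test_constant_profile_paints_nothing(self):
        track = percentile_paint(_grid_profile([0.5] * 50), q=66.7)
        assert track.intervals == []

    def test_matches_independent_percentile_arithmetic(self):
        values = list(range(100))
        track = percentile_paint(_grid_profile(values), q=66.0)
        thr = np.percentile(np.array(values, dtype=float), 66.0)
        expected = sum(1 for v in values if v > thr)
        painted = sum(e - s for _, s, e in track.intervals)
        assert painted == expected
        assert track.threshold == pytest.approx(thr)

    def test_raising_q_never_enlarges_painted_set(self):
        rng = np.random.default_rng(2)
        for _ in range(20):
            prof = _grid_profile(rng.random(60))
            prev = None
            for q in (20, 40, 60, 80):
                track = percentile_paint(prof, q=q)
                painted = {
                    (c, p) for c, s, e in track.intervals
                    for p in np.arange(s, e)
                }
                if prev is not None:
                    assert painted <= prev
                prev = painted

    def test_adjacent_points_merge_into_maximal_intervals(self):
        track = percentile_paint(_grid_profile([0, 0, 1, 1, 0, 1, 0]), q=50)
        assert track.intervals == [("M1", 2.0, 4.0), ("M1", 5.0, 6.0)]

    def test_all_missing_profile_gives_empty_track(self):
        track = percentile_paint(_grid_profile([np.nan] * 10), q=50)
        assert track.intervals == []

    def test_percentile_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            percentile_paint(_grid_profile([1, 2]), q=0)


def _track(group, intervals):
    return PaintTrack(group=group, metric="f", percentile=50, threshold=0.5,
                      intervals=intervals)


class TestAssignGenomes:
    def _setup(self, length=100.0):
        cmap = ConsensusMap({"M1": length}, {"L0": ("M1", 50.0)})
        grid = _grid_profile([1.0] * 101, chrom="M1", group="A_diploid")
        return cmap, {"A_diploid": grid}

    def test_a_only_chromosome(self):
        cmap, profiles = self._setup()
        assignment = assign_genomes(
            _track("A_diploid", [("M1", 0.0, 101.0)]),
            _track("C_diploid", []),
            _track("DC_tetraploid", []),
            profiles, cmap)
        assert assignment.primary == {"M1": "A"}
        assert assignment.segments["M1"] == [(0.0, 100.0, "A")]

    def test_dc_and_c_without_a_is_c(self):
        cmap, profiles = self._setup()
        assignment = assign_genomes(
            _track("A_diploid", []),
            _track("C_diploid", [("M1", 0.0, 101.0)]),
            _track("DC_tetraploid", [("M1", 0.0, 101.0)]),
            profiles, cmap)
        assert assignment.primary == {"M1": "C"}

    def test_dc_alone_is_d(self):
        cmap, profiles = self._setup()
        assignment = assign_genomes(
            _track("A_diploid", []),
            _track("C_diploid", []),
            _track("DC_tetraploid", [("M1", 0.0, 101.0)]),
            profiles, cmap)
        assert assignment.primary == {"M1": "D"}

    def test_terminal_translocation_segments(self):
        cmap, profiles = self._setup()
        # D chromosome with a C-painted terminal third
        assignment = assign_genomes(
            _track("A_diploid", []),
            _track("C_diploid", [("M1", 70.0, 101.0)]),
            _track("DC_tetraploid", [("M1", 0.0, 101.0)]),
            profiles, cmap)
        assert assignment.primary == {"M1": "D"}
        segs = assignment.segments["M1"]
        assert [g for _, _, g in segs] == ["D", "C"]
        assert segs[0][1] == pytest.approx(69.5, abs=1.0)

    def test_short_run_absorbed_in_report_but_kept_in_full(self):
        cmap, profiles = self._setup()
        # 10 cM C-painted blip inside a D chromosome (< 15 % of 100 cM)
        assignment = assign_genomes(
            _track("A_diploid", []),
            _track("C_diploid", [("M1", 40.0, 50.0)]),
            _track("DC_tetraploid", [("M1", 0.0, 101.0)]),
            profiles, cmap)
        assert [g for _, _, g in assignment.segments["M1"]] == ["D", "C", "D"]
        assert [g for _, _, g in assignment.report_segments["M1"]] == ["D"]

    def test_ambiguous_filled_from_nearest_neighbour(self):
        cmap, profiles = self._setup()
        # A and DC both painted on [40,60) -> ambiguous, flanked by A
        assignment = assign_genomes(
            _track("A_diploid", [("M1", 0.0, 101.0)]),
            _track("C_diploid", []),
            _track("DC_tetraploid", [("M1", 40.0, 60.0)]),
            profiles, cmap)
        assert assignment.segments["M1"] == [(0.0, 100.0, "A")]


class TestCircos:
    def test_karyotype_has_21_records(self, tmp_path, study_ref):
        paths = export_circos(study_ref.cmap, [], tmp_path)
        lines = paths["karyotype"].read_text().strip().splitlines()
        assert len(lines) == 21
        assert all(line.startswith("chr -") for line in lines)

    def test_empty_track_still_written(self, tmp_path):
        cmap = ConsensusMap({"M1": 10.0}, {})
        paths = export_circos(cmap, [_track("g", [])], tmp_path)
        hl = paths["highlight:g:f"]
        assert hl.exists() and hl.read_text() == ""

    def test_interval_round_trip_to_hundredth_cm(self, tmp_path):
        cmap = ConsensusMap({"M1": 100.0}, {})
        intervals = [("M1", 12.34, 56.78), ("M1", 60.0, 99.99)]
        paths = export_circos(cmap, [_track("g", intervals)], tmp_path)
        back = read_circos_highlights(paths["highlight:g:f"])
        for (c1, s1, e1), (c2, s2, e2) in zip(intervals, back):
            assert c1 == c2
            assert abs(s1 - s2) <= 0.005 + 1e-9
            assert abs(e1 - e2) <= 0.005 + 1e-9
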