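"""Per-SNP ROH incidence, thresholding and island merging."""

import math

import numpy as np
import pytest
from conftest import make_matrix, random_matrix

from rohscan.detect import ROHSegment
from rohscan.islands import (ROHIsland, SnpIncidenceTrack, incidence_threshold,
                             manhattan_export, merge_islands, read_manhattan,
                             snp_incidence, write_islands_bed)


def track_from(incidences: dict[str, list[float]], spacing=1000,
               n_samples=10) -> SnpIncidenceTrack:
    return SnpIncidenceTrack(
        n_samples=n_samples,
        positions={c: (np.arange(len(v)) + 1) * spacing
                   for c, v in incidences.items()},
        incidence={c: np.array(v, dtype=float) for c, v in incidences.items()},
    )


class TestSnpIncidence:
    def test_counts_fraction_of_covered_samples(self):
        rows = ["o" * 10] * 20
        m = make_matrix(rows)
        segs = [ROHSegment(f"S{i + 1:03d}", "1", 3000, 7000, 5, 0, 0)
                for i in range(10)]
        track = snp_incidence(segs, m)
        inc = track.incidence["1"]
        assert inc[3] == 0.5   # position 4000, inside the 10 covering samples
        assert inc[0] == 0.0

    def test_no_segments_gives_zero_incidence(self):
        m = make_matrix(["oooo", "hhhh"])
        track = snp_incidence([], m)
        assert np.all(track.incidence["1"] == 0)

    def test_unknown_chromosome_raises(self):
        m = make_matrix(["oooo"])
        with pytest.raises(ValueError, match="absent"):
            snp_incidence([ROHSegment("S001", "9", 1, 10, 2, 0, 0)], m)

    def test_matches_interval_stabbing_brute_force(self):
        rng = np.random.default_rng(5)
        m = random_matrix(rng, n_samples=6, n_snps=200)
        pos = m.chromosomes["1"].positions
        segs = []
        for si in range(6):
            for _ in range(rng.integers(0, 5)):
                a, b = np.sort(rng.integers(pos[0], pos[-1], size=2))
                segs.append(ROHSegment(f"S{si + 1:03d}", "1", int(a),
                                       int(max(b, a + 1)), 2, 0, 0))
        track = snp_incidence(segs, m)
        for i, p in enumerate(pos):
            covered = {
                s.sample for s in segs if s.start <= p <= s.end}
            assert track.incidence["1"][i] == pytest.approx(len(covered) / 6)


class TestIncidenceThreshold:
    def test_fixed_mode_returns_value_unchanged(self):
        track = track_from({"1": [0.1, 0.2]})
        assert incidence_threshold(track, "fixed", 0.30) == 0.30

    def test_quantile_of_constant_track_is_the_constant(self):
        track = track_from({"1": [0.4] * 50})
        assert incidence_threshold(track, "quantile", 0.01) == 0.4

    def test_quantile_matches_sort_and_index_brute_force(self):
        rng = np.random.default_rng(9)
        values = rng.random(1000)
        track = track_from({"1": list(values)})
        for q in (0.01, 0.05, 0.25):
            expected = np.sort(values)[math.ceil((1 - q) * 1000) - 1]
            assert incidence_threshold(track, "quantile", q) == expected

    def test_invalid_inputs_raise(self):
        track = track_from({"1": [0.1]})
        with pytest.raises(ValueError):
            incidence_threshold(track, "quantile", 0.0)
        with pytest.raises(ValueError):
            incidence_threshold(track, "fixed", 1.5)
        with pytest.raises(ValueError):
            incidence_threshold(track_from({}), "quantile", 0.01)
        with pytest.raises(ValueError):
            incidence_threshold(track, "median-ish", 0.5)


class TestMergeIslands:
    def test_all_below_threshold_gives_no_islands(self):
        track = track_from({"1": [0.1] * 20})
        assert merge_islands(track, 0.3) == []

    def test_single_block_of_high_incidence(self):
        inc = [0.0] * 5 + [1.0] * 5 + [0.0] * 5
        track = track_from({"1": inc})
        (island,) = merge_islands(track, 0.3)
        assert island.n_snps == 5
        assert island.start == 6000
        assert island.end == 10_000
        assert island.max_incidence == 1.0

    def test_min_snps_drops_short_runs(self):
        track = track_from({"1": [0.0, 1.0, 0.0, 1.0, 1.0, 0.0]})
        islands = merge_islands(track, 0.5, min_snps=2)
        assert len(islands) == 1
        assert islands[0].n_snps == 2

    def test_gap_allowance_bridges_single_dips(self):
        inc = [1.0, 1.0, 0.1, 1.0, 1.0]
        track = track_from({"1": inc})
        assert len(merge_islands(track, 0.5, max_gap_snps=0)) == 2
        bridged = merge_islands(track, 0.5, max_gap_snps=1)
        assert len(bridged) == 1
        assert bridged[0].n_snps == 4  # the dip SNP is not a member

    def test_matches_exhaustive_run_enumeration(self):
        rng = np.random.default_rng(3)
        for _ in range(20):
            inc = rng.random(100)
            track = track_from({"1": list(inc)})
            islands = merge_islands(track, 0.6, max_gap_snps=0, min_snps=1)
            # brute force: maximal runs of consecutive above-threshold SNPs
            runs, cur = [], []
            for i, v in enumerate(inc):
                if v >= 0.6:
                    cur.append(i)
                elif cur:
                    runs.append(cur)
                    cur = []
            if cur:
                runs.append(cur)
            assert len(islands) == len(runs)
            for isl, run in zip(islands, runs):
                assert isl.start == (run[0] + 1) * 1000
                assert isl.end == (run[-1] + 1) * 1000
                assert isl.n_snps == len(run)

    def test_total_island_snps_non_increasing_in_threshold(self):
        rng = np.random.default_rng(13)
        inc = rng.random(300)
        track = track_from({"1": list(inc)})
        totals = []
        for thr in (0.2, 0.4, 0.6, 0.8):
            totals.append(sum(i.n_snps
                              for i in merge_islands(track, thr, min_snps=1)))
        assert totals == sorted(totals, reverse=True)

    def test_islands_sorted_and_disjoint(self):
        rng = np.random.default_rng(21)
        track = track_from({"1": list(rng.random(200)),
                            "2": list(rng.random(200))})
        islands = merge_islands(track, 0.5, min_snps=1)
        for a, b in zip(islands, islands[1:]):
            if a.chrom == b.chrom:
                assert a.end < b.start


def test_island_recovery_on_implanted_common_region():
    """A region autozygous in 95% of samples over 5% background autozygosity
    is recovered as exactly one island at the fixed 30% threshold."""
    from rohscan.detect import ROHParameters, call_segments
    from rohscan.simulate import (ImplantRegion, SimulationConfig,
                                  simulate_genotypes)

    cfg = SimulationConfig(
        n_samples=20, chromosomes=[("1", 20_000_000)], snp_spacing_bp=500,
        target_autozygosity=0.05, tract_mean_bp=2_000_000,
        tract_min_bp=100_000, het_error_rate=0.001,
        implant_regions=[ImplantRegion("1", 9_000_000, 10_000_000, 0.95)],
        seed=11)
    matrix, _ = simulate_genotypes(cfg)
    segs = call_segments(matrix, ROHParameters(min_length_bp=100_000))
    track = snp_incidence(segs, matrix)
    islands = merge_islands(track, incidence_threshold(track, "fixed", 0.30))
    assert len(islands) == 1
    island = islands[0]
    # the island is the implanted region up to edge smear of a few SNPs
    assert abs(island.start - 9_000_000) < 10_000
    assert abs(island.end - 10_000_000) < 10_000
    assert island.max_incidence >= 0.9


class TestManhattanExport:
    def test_row_count_and_threshold_line(self, tmp_path):
        track = track_from({"1": [0.1, 0.5, 0.9]})
        p = tmp_path / "inc.tsv"
        manhattan_export(track, 0.30, p)
        lines = p.read_text().splitlines()
        assert lines[0] == "#threshold=0.3"
        assert len(lines) == 2 + 3  # threshold + header + data

    def test_round_trip_preserves_track_values(self, tmp_path):
        rng = np.random.default_rng(2)
        track = track_from({"1": list(np.round(rng.random(50), 6)),
                            "2": list(np.round(rng.random(30), 6))})
        p = tmp_path / "inc.tsv"
        manhattan_export(track, 0.42, p)
        back, thr = read_manhattan(p)
        assert thr == 0.42
        for chrom in track.positions:
            assert np.array_equal(back.positions[chrom], track.positions[chrom])
            assert np.allclose(back.incidence[chrom], track.incidence[chrom])

    def test_islands_bed_export(self, tmp_path):
        isl = ROHIsland("1", 101, 200, 5, 1.0, 0.8)
        p = tmp_path / "isl.bed"
        write_islands_bed([isl], p)
        assert p.read_text() == "1\t100\t200\tisland_1\t0.8000\n"
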