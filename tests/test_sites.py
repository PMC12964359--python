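"""The motif stage: track reading, best-hit filtering, sharded processing."""

import numpy as np
import pandas as pd
import pytest

from regprior import (
    BindingSite,
    Region,
    RegionSet,
    best_hit_per_region_tf,
    process_sharded,
    read_sites,
)
from regprior.sites import MATCH_COLUMNS, ReadStats, canonical_match_sort


def brute_force_best_hits(regions, sites, threshold):
    """Independent oracle: O(n*m) all-pairs overlap scan.

    A site matches a region iff the half-open intervals intersect by at
    least one base; per (region, TF) the best (score desc, start asc,
    end asc) site at or above the threshold is kept.
    """
    best = {}
    for region in regions:
        for s in sites:
            if s.score < threshold:
                continue
            if s.scaffold != region.scaffold:
                continue
            if not (s.start < region.end and region.start < s.end):
                continue
            key = (region.transcript_id, s.tf_name)
            cand = (-s.score, s.start, s.end)
            if key not in best or cand < best[key][0]:
                best[key] = (cand, region, s.score)
    rows = [
        (tf, tid, region.gene_id, region.gene_name, score)
        for (tid, tf), (_, region, score) in best.items()
    ]
    df = pd.DataFrame(rows, columns=MATCH_COLUMNS)
    df["best_score"] = df["best_score"].astype("int64")
    return canonical_match_sort(df)


def random_instance(rng, max_regions=100, max_sites=1000):
    scaffolds = ["chr1", "chr2", "chr3"]
    n_regions = int(rng.integers(1, max_regions + 1))
    n_sites = int(rng.integers(1, max_sites + 1))
    regions = []
    for i in range(n_regions):
        start = int(rng.integers(0, 5_000))
        regions.append(
            Region(
                scaffolds[int(rng.integers(3))],
                start,
                start + int(rng.integers(1, 400)),
                f"T{i}",
                f"G{i // 2}",
            )
        )
    tfs = [f"TF{j}" for j in range(5)]
    sites = []
    for _ in range(n_sites):
        start = int(rng.integers(0, 5_500))
        sites.append(
            BindingSite(
                scaffolds[int(rng.integers(3))],
                start,
                start + int(rng.integers(1, 30)),
                tfs[int(rng.integers(5))],
                int(rng.integers(0, 1000)),
            )
        )
    return RegionSet(regions), sites


class TestReadSites:
    def write_track(self, path, rows):
        path.write_text("".join("\t".join(map(str, r)) + "\n" for r in rows))

    def test_tf_filter_restricts_stream(self, tmp_path):
        track = tmp_path / "t.bed"
        self.write_track(
            track,
            [
                ("chr1", 10, 20, "A", 500),
                ("chr1", 30, 40, "B", 600),
                ("chr1", 50, 60, "A", 700),
                ("chr2", 10, 20, "C", 800),
                ("chr2", 30, 40, "B", 900),
            ],
        )
        out = list(read_sites(track, tf_filter={"A"}))
        assert len(out) == 2 and all(s.tf_name == "A" for s in out)

    def test_empty_file_yields_nothing(self, tmp_path):
        track = tmp_path / "empty.bed"
        track.write_text("")
        assert list(read_sites(track)) == []

    def test_malformed_rows_skipped_and_counted(self, tmp_path):
        track = tmp_path / "t.bed"
        self.write_track(
            track,
            [
                ("chr1", 10, 20, "A", 500),
                ("chr1", 40, 30, "A", 500),       # end <= start
                ("chr1", 50, 60, "A", "high"),    # unparseable score
                ("chr1", "x", 70, "A", 500),      # unparseable coordinate
            ],
        )
        stats = ReadStats()
        out = list(read_sites(track, stats=stats))
        assert len(out) == 1
        assert stats.skipped == 3


class TestBestHit:
    def region(self):
        return RegionSet([Region("chr1", 100, 200, "T1", "G1")])

    def test_best_score_retained(self):
        sites = [
            BindingSite("chr1", 120, 130, "A", 500),
            BindingSite("chr1", 150, 160, "A", 620),
        ]
        df = best_hit_per_region_tf(self.region(), sites, 400)
        assert len(df) == 1
        assert df.iloc[0]["best_score"] == 620

    def test_threshold_excludes_low_scores(self):
        df = best_hit_per_region_tf(
            self.region(), [BindingSite("chr1", 120, 130, "A", 399)], 400
        )
        assert df.empty

    def test_boundary_overlap_counts(self):
        sites = [
            BindingSite("chr1", 90, 105, "A", 700),   # clips the region start
            BindingSite("chr1", 150, 160, "A", 620),
        ]
        df = best_hit_per_region_tf(self.region(), sites, 400)
        assert len(df) == 1 and df.iloc[0]["best_score"] == 700

    def test_abutting_site_does_not_match(self):
        # half-open: [80, 100) shares no base with [100, 200)
        df = best_hit_per_region_tf(
            self.region(), [BindingSite("chr1", 80, 100, "A", 700)], 400
        )
        assert df.empty

    def test_matches_brute_force_oracle(self):
        """Indexed filtering equals the all-pairs scan on random instances."""
        rng = np.random.default_rng(2024)
        for _ in range(100):
            regions, sites = random_instance(rng)
            threshold = int(rng.integers(0, 800))
            fast = best_hit_per_region_tf(regions, sites, threshold)
            slow = brute_force_best_hits(regions, sites, threshold)
            pd.testing.assert_frame_equal(fast, slow)

    def test_threshold_monotonicity(self):
        rng = np.random.default_rng(5)
        regions, sites = random_instance(rng, max_regions=30, max_sites=300)
        rows = {
            t: set(
                map(
                    tuple,
                    best_hit_per_region_tf(regions, sites, t)[
                        ["tf_name", "transcript_id"]
                    ].itertuples(index=False),
                )
            )
            for t in (0, 200, 400, 600)
        }
        assert rows[600] <= rows[400] <= rows[200] <= rows[0]


class TestSharding:
    @pytest.fixture()
    def tracked_instance(self, tmp_path):
        rng = np.random.default_rng(11)
        regions, sites = random_instance(rng, max_regions=40, max_sites=400)
        whole = tmp_path / "all.bed"
        rows = sorted(
            (s.scaffold, s.start, s.end, s.tf_name, s.score) for s in sites
        )
        whole.write_text("".join("\t".join(map(str, r)) + "\n" for r in rows))
        per_tf = tmp_path / "by_tf"
        per_tf.mkdir()
        for tf in {s.tf_name for s in sites}:
            (per_tf / f"{tf}.bed").write_text(
                "".join("\t".join(map(str, r)) + "\n" for r in rows if r[3] == tf)
            )
        return regions, sites, whole, per_tf

    def test_layout_equivalence(self, tracked_instance):
        regions, sites, whole, per_tf = tracked_instance
        a = process_sharded(regions, str(whole), layout="whole-genome")
        b = process_sharded(regions, str(per_tf), layout="per-TF")
        pd.testing.assert_frame_equal(a, b)
        pd.testing.assert_frame_equal(a, best_hit_per_region_tf(regions, sites, 400))

    def test_worker_invariance(self, tracked_instance):
        regions, _, whole, _ = tracked_instance
        serial = process_sharded(regions, str(whole), workers=1)
        parallel = process_sharded(regions, str(whole), workers=4)
        pd.testing.assert_frame_equal(serial, parallel)

    def test_shard_partition_invariance(self, tracked_instance):
        regions, _, whole, _ = tracked_instance
        default = process_sharded(regions, str(whole))
        lumped = process_sharded(
            regions, str(whole), shards=[{"chr1", "chr3"}, {"chr2"}]
        )
        pd.testing.assert_frame_equal(default, lumped)

    def test_site_scaffold_without_regions_ignored(self, tmp_path):
        regions = RegionSet([Region("chr1", 100, 200, "T1", "G1")])
        track = tmp_path / "t.bed"
        track.write_text("chr9\t120\t130\tA\t900\nchr1\t120\t130\tA\t900\n")
        df = process_sharded(regions, str(track))
        assert len(df) == 1 and df.iloc[0]["transcript_id"] == "T1"

    def test_incomplete_shards_rejected(self, tmp_path):
        regions = RegionSet([Region("chr1", 100, 200, "T1", "G1")])
        track = tmp_path / "t.bed"
        track.write_text("chr1\t120\t130\tA\t900\n")
        with pytest.raises(ValueError, match="do not cover"):
            process_sharded(regions, str(track), shards=[{"chr2"}])
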