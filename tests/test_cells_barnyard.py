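import itertools

import numpy as np
import pandas as pd
import pytest

from txciatac import cells_barnyard as by
from txciatac import fixtures as fx
from txciatac.fragments import count_species


def _counts(values, prefix="BC"):
    return pd.Series(values, index=[f"{prefix}{i}" for i in range(len(values))])


class TestFixedThreshold:
    def test_boundary(self):
        res = by.call_cells_fixed(_counts([999, 1000, 1001]))
        assert res.calls["is_cell"].tolist() == [False, True, True]

    def test_empty(self):
        res = by.call_cells_fixed(_counts([]))
        assert res.calls.empty

    def test_monotone_in_threshold(self):
        counts = _counts([10, 500, 1500, 3000])
        lo = by.call_cells_fixed(counts, min_reads=500).calls["is_cell"]
        hi = by.call_cells_fixed(counts, min_reads=2000).calls["is_cell"]
        assert (hi <= lo).all()


def _best_two_partition(log_counts):
    """Exhaustive 1-D 2-means oracle: minimize within-cluster sum of squares
    over all threshold splits of the sorted values."""
    xs = np.sort(log_counts)
    best, best_split = np.inf, None
    for i in range(1, len(xs)):
        a, b = xs[:i], xs[i:]
        ss = ((a - a.mean()) ** 2).sum() + ((b - b.mean()) ** 2).sum()
        if ss < best:
            best, best_split = ss, i
    return set(np.round(xs[best_split:], 9))


class TestKmeansThreshold:
    def test_matches_exhaustive_partition(self):
        counts = _counts([126, 158, 7943, 10000])  # 10^{2.1, 2.2, 3.9, 4.0}
        res = by.call_cells_kmeans(counts, seed=0)
        assert res.calls["is_cell"].tolist() == [False, False, True, True]
        assert res.threshold == 7943
        oracle_top = _best_two_partition(np.log10(counts.to_numpy()))
        called_top = set(np.round(np.log10(counts[res.calls["is_cell"]].to_numpy()), 9))
        assert called_top == oracle_top

    def test_bimodal_fixture_recovery(self):
        spec = fx.FixtureSpec(seed=2, n_cells=100, true_collision_fraction=0.1)
        frags, truth = fx.make_hybrid_fragments(spec)
        counts = count_species(frags)["total_unique"]
        res = by.call_cells_kmeans(counts, seed=0)
        called = set(res.calls.index[res.calls["is_cell"]])
        planted = set(truth.loc[truth["kind"] != "debris", "barcode"])
        jaccard = len(called & planted) / len(called | planted)
        assert jaccard >= 0.99

    def test_floor_excludes_low_barcodes(self):
        counts = _counts([50, 99, 100, 5000, 6000])
        res = by.call_cells_kmeans(counts, min_reads_floor=100, seed=0)
        assert not res.calls.loc["BC0", "is_cell"]
        assert not res.calls.loc["BC1", "is_cell"]

    def test_degenerate_counts_rejected(self):
        with pytest.raises(ValueError, match="fixed threshold"):
            by.call_cells_kmeans(_counts([500, 500, 500, 500]), seed=0)

    def test_seed_stable_on_separated_data(self):
        counts = _counts([120, 130, 140, 9000, 9500, 10000])
        a = by.call_cells_kmeans(counts, seed=1)
        b = by.call_cells_kmeans(counts, seed=99)
        assert a.calls["is_cell"].equals(b.calls["is_cell"])

    def test_threshold_between_cluster_means(self):
        counts = _counts([120, 130, 140, 9000, 9500, 10000])
        res = by.call_cells_kmeans(counts, seed=0)
        lo_mean, hi_mean = res.cluster_means
        assert lo_mean < np.log10(res.threshold) <= hi_mean


def _species_df(rows):
    df = pd.DataFrame(rows, columns=["hg", "mm"])
    df.index = [f"BC{i}" for i in range(len(df))]
    df["total_unique"] = df["hg"] + df["mm"]
    return df


class TestClassifySpecies:
    def test_purity_rule(self):
        calls = by.classify_species(_species_df([(95, 5), (85, 15), (50, 50)]))
        assert calls["label"].tolist() == ["hg", "collision", "collision"]

    def test_boundary_inclusive(self):
        calls = by.classify_species(_species_df([(90, 10)]))
        assert calls["label"].iloc[0] == "hg"

    def test_major_fraction(self):
        calls = by.classify_species(_species_df([(75, 25)]))
        assert calls["major_fraction"].iloc[0] == pytest.approx(0.75)


class TestCollisionRate:
    def test_balanced_mix_doubles(self):
        calls = by.classify_species(_species_df([(50, 50)] * 5 + [(100, 0)] * 50 + [(0, 100)] * 45))
        res = by.estimate_collision_rate(calls, (0.5, 0.5))
        assert res["observed_rate"] == pytest.approx(0.05)
        assert res["corrected_rate"] == pytest.approx(0.10)

    def test_zero_observed(self):
        calls = by.classify_species(_species_df([(100, 0)] * 10))
        res = by.estimate_collision_rate(calls, (0.5, 0.5))
        assert res["corrected_rate"] == 0.0

    def test_unbalanced_mix(self):
        rows = [(50, 50)] * 3 + [(100, 0)] * 73 + [(0, 100)] * 24
        calls = by.classify_species(_species_df(rows))
        res = by.estimate_collision_rate(calls, (0.75, 0.25))
        assert res["corrected_rate"] == pytest.approx(0.03 / 0.375)

    def test_pure_mix_rejected(self):
        calls = by.classify_species(_species_df([(100, 0)] * 10))
        with pytest.raises(ValueError):
            by.estimate_collision_rate(calls, (1.0, 0.0))

    def test_capped_at_one(self):
        calls = by.classify_species(_species_df([(50, 50)] * 80 + [(100, 0)] * 20))
        res = by.estimate_collision_rate(calls, (0.5, 0.5))
        assert res["corrected_rate"] == 1.0

    def test_monte_carlo_oracle_agreement(self):
        """Independent pairing simulation: plant doublets at a known rate,
        classify with the purity rule, and check the corrected estimate."""
        rng = np.random.default_rng(0)
        true_rate = 0.12
        n_cells = 5000
        estimates = []
        for _ in range(20):
            is_doublet = rng.random(n_cells) < true_rate
            depth = rng.integers(500, 1500, size=(n_cells, 2))
            sp = rng.integers(0, 2, size=(n_cells, 2))
            hg = np.where(sp[:, 0] == 0, depth[:, 0], 0) + np.where(
                is_doublet & (sp[:, 1] == 0), depth[:, 1], 0
            )
            mm = np.where(sp[:, 0] == 1, depth[:, 0], 0) + np.where(
                is_doublet & (sp[:, 1] == 1), depth[:, 1], 0
            )
            df = pd.DataFrame({"hg": hg, "mm": mm})
            df.index = [f"BC{i}" for i in range(n_cells)]
            df["total_unique"] = df["hg"] + df["mm"]
            calls = by.classify_species(df)
            estimates.append(by.estimate_collision_rate(calls, (0.5, 0.5))["corrected_rate"])
        estimates = np.asarray(estimates)
        sem = estimates.std(ddof=1) / np.sqrt(len(estimates))
        assert abs(estimates.mean() - true_rate) < 3 * sem + 1e-3


class TestMergeBeadMultiplets:
    def _frags(self, rows):
        return pd.DataFrame(rows, columns=["chrom", "start", "end", "barcode", "dup_count"])

    def test_identity_map(self):
        frags = self._frags([("hg_toy", 0, 100, "BEADAAAA" + "T" * 8, 1)])
        out = by.merge_bead_multiplets(frags, {})
        pd.testing.assert_frame_equal(out, frags)

    def test_disjoint_fragments_sum(self):
        tn5 = "T" * 8
        frags = self._frags(
            [("hg_toy", 0, 100, "BEAD0001" + tn5, 1), ("hg_toy", 500, 600, "BEAD0002" + tn5, 1)]
        )
        out = by.merge_bead_multiplets(frags, {"BEAD0001": "G1", "BEAD0002": "G1"})
        assert out["barcode"].nunique() == 1
        assert len(out) == 2

    def test_shared_fragment_union(self):
        tn5 = "T" * 8
        frags = self._frags(
            [
                ("hg_toy", 0, 100, "BEAD0001" + tn5, 2),
                ("hg_toy", 0, 100, "BEAD0002" + tn5, 3),
                ("hg_toy", 500, 600, "BEAD0002" + tn5, 1),
            ]
        )
        out = by.merge_bead_multiplets(frags, {"BEAD0001": "G1", "BEAD0002": "G1"})
        # set-union oracle: 2 + 1 unique keys after merging, dup counts summed
        assert len(out) == 2
        assert out.loc[out["start"] == 0, "dup_count"].iloc[0] == 5

    def test_unique_counts_never_increase(self):
        tn5 = "T" * 8
        rng = np.random.default_rng(1)
        rows = [
            ("hg_toy", int(s) * 50, int(s) * 50 + 100, f"BEAD{rng.integers(4):04d}" + tn5, 1)
            for s in rng.integers(0, 10, size=40)
        ]
        frags = self._frags(rows).groupby(
            ["chrom", "start", "end", "barcode"], as_index=False
        )["dup_count"].sum()
        gmap = {f"BEAD{i:04d}": "G1" for i in range(4)}
        out = by.merge_bead_multiplets(frags, gmap)
        assert len(out) <= len(frags)
        assert out["dup_count"].sum() == frags["dup_count"].sum()

    def test_conflicting_group_map_rejected(self):
        with pytest.raises(ValueError, match="two groups"):
            by.group_map_from_lists({"G1": ["B1"], "G2": ["B1"]})
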