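from itertools import product

import numpy as np
import pandas as pd
import pytest

from txciatac import fixtures as fx
from txciatac import snv_motif as sm


def _write_vcf(tmp_path, body, n_samples=3):
    header = (
        "##fileformat=VCFv4.2\n"
        '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n'
        '##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Read depth">\n'
        "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
        + "\t".join(f"rep{i}" for i in range(1, n_samples + 1))
        + "\n"
    )
    path = tmp_path / "test.vcf"
    path.write_text(header + body)
    return path


class TestFilterSnvs:
    def test_qual_boundary(self, tmp_path):
        body = (
            "chr1\t100\t.\tA\tG\t19.9\tPASS\t.\tGT:DP\t1/1:5\t1/1:5\t1/1:5\n"
            "chr1\t200\t.\tA\tG\t20\tPASS\t.\tGT:DP\t1/1:5\t1/1:5\t1/1:5\n"
        )
        out = sm.filter_snvs(_write_vcf(tmp_path, body))
        assert out["pos"].tolist() == [200]

    def test_depth_sum_boundary(self, tmp_path):
        body = (
            "chr1\t100\t.\tA\tG\t60\tPASS\t.\tGT:DP\t1/1:3\t1/1:3\t1/1:3\n"
            "chr1\t200\t.\tA\tG\t60\tPASS\t.\tGT:DP\t1/1:4\t1/1:3\t1/1:3\n"
        )
        out = sm.filter_snvs(_write_vcf(tmp_path, body))
        assert out["pos"].tolist() == [200]

    def test_genotype_concordance(self, tmp_path):
        body = (
            "chr1\t100\t.\tA\tG\t60\tPASS\t.\tGT:DP\t0/1:10\t0/1:10\t1/1:10\n"
            "chr1\t200\t.\tA\tG\t60\tPASS\t.\tGT:DP\t0/1:10\t1/1:10\t0/0:10\n"
        )
        out = sm.filter_snvs(_write_vcf(tmp_path, body))
        assert out["pos"].tolist() == [100]

    def test_phased_genotypes_normalized(self, tmp_path):
        body = "chr1\t100\t.\tA\tG\t60\tPASS\t.\tGT:DP\t0|1:10\t1/0:10\t1/1:10\n"
        out = sm.filter_snvs(_write_vcf(tmp_path, body))
        assert len(out) == 1  # 0|1 and 1/0 are the same unphased genotype

    def test_non_snv_dropped_and_counted(self, tmp_path):
        body = (
            "chr1\t100\t.\tAT\tG\t60\tPASS\t.\tGT:DP\t1/1:10\t1/1:10\t1/1:10\n"
            "chr1\t200\t.\tA\tG,T\t60\tPASS\t.\tGT:DP\t1/1:10\t1/1:10\t1/1:10\n"
            "chr1\t300\t.\tA\tG\t60\tPASS\t.\tGT:DP\t1/1:10\t1/1:10\t1/1:10\n"
        )
        out = sm.filter_snvs(_write_vcf(tmp_path, body))
        assert out["pos"].tolist() == [300]
        assert out.attrs["n_dropped_non_snv"] == 2

    def test_non_three_replicates_majority(self, tmp_path):
        body = "chr1\t100\t.\tA\tG\t60\tPASS\t.\tGT:DP\t1/1:10\t1/1:10\t0/0:10\t0/0:10\n"
        with pytest.warns(UserWarning, match="majority"):
            out = sm.filter_snvs(_write_vcf(tmp_path, body, n_samples=4))
        assert out.empty  # 2 of 4 is not a strict majority


class TestHotspots:
    HOTSPOTS = {
        "chr8_hotspot": ("chr8", 68_000_000, 93_000_000),
        "chr19_hotspot": ("chr19", 16_500_000, 26_500_000),
    }

    def test_boundary_inclusive(self):
        snvs = pd.DataFrame(
            {"chrom": ["chr8", "chr8", "chr8"], "pos": [68_000_000, 93_000_000, 93_000_001],
             "ref": list("AAA"), "alt": list("GGG")}
        )
        out = sm.assign_hotspots(snvs, self.HOTSPOTS)
        assert out["hotspot"].tolist() == ["chr8_hotspot", "chr8_hotspot", "outside"]

    def test_other_chromosome_outside(self):
        snvs = pd.DataFrame({"chrom": ["chr1"], "pos": [68_000_000], "ref": ["A"], "alt": ["G"]})
        assert sm.assign_hotspots(snvs, self.HOTSPOTS)["hotspot"].tolist() == ["outside"]

    def test_counts_sum(self):
        rng = np.random.default_rng(0)
        snvs = pd.DataFrame(
            {
                "chrom": rng.choice(["chr8", "chr19", "chr1"], 100),
                "pos": rng.integers(1, 100_000_000, 100),
                "ref": ["A"] * 100,
                "alt": ["G"] * 100,
            }
        )
        out = sm.assign_hotspots(snvs, self.HOTSPOTS)
        assert out["hotspot"].value_counts().sum() == 100


class TestJaccard:
    def test_identical(self):
        a = {("chr1", 1, "A", "G"), ("chr1", 2, "C", "T")}
        assert sm.jaccard_snv_sets(a, set(a)) == 1.0

    def test_disjoint(self):
        assert sm.jaccard_snv_sets({("chr1", 1, "A", "G")}, {("chr1", 2, "A", "G")}) == 0.0

    def test_partial_overlap(self):
        a = {(c, i, "A", "G") for c, i in [("c", 1), ("c", 2), ("c", 3), ("c", 4)]}
        b = {(c, i, "A", "G") for c, i in [("c", 3), ("c", 4), ("c", 5), ("c", 6)]}
        assert sm.jaccard_snv_sets(a, b) == pytest.approx(1 / 3)

    def test_symmetric(self):
        rng = np.random.default_rng(1)
        a = {("c", int(i), "A", "G") for i in rng.integers(0, 50, 20)}
        b = {("c", int(i), "A", "G") for i in rng.integers(0, 50, 20)}
        assert sm.jaccard_snv_sets(a, b) == sm.jaccard_snv_sets(b, a)
        assert 0.0 <= sm.jaccard_snv_sets(a, b) <= 1.0

    def test_both_empty(self):
        with pytest.warns(UserWarning):
            assert sm.jaccard_snv_sets(set(), set()) == 0.0


class TestApplySnvs:
    def test_no_snvs_identity(self):
        seqs = {"p1": "ACGTACGT"}
        out = sm.apply_snvs_to_sequence(seqs, pd.DataFrame(columns=["chrom", "pos", "ref", "alt"]))
        assert out == seqs

    def test_single_substitution(self):
        seqs = {"p1": "ACGTACGT"}
        snvs = pd.DataFrame({"chrom": ["p1"], "pos": [3], "ref": ["G"], "alt": ["T"]})
        out = sm.apply_snvs_to_sequence(seqs, snvs)
        assert out["p1"] == "ACTTACGT"
        assert sum(a != b for a, b in zip(out["p1"], seqs["p1"])) == 1

    def test_ref_mismatch_raises(self):
        seqs = {"p1": "ACGTACGT"}
        snvs = pd.DataFrame({"chrom": ["p1"], "pos": [3], "ref": ["A"], "alt": ["T"]})
        with pytest.raises(ValueError, match="reference mismatch"):
            sm.apply_snvs_to_sequence(seqs, snvs)


def _enumerate_tail(int_weights, background):
    """All 4^w word scores with their background probabilities."""
    scores, probs = [], []
    w = int_weights.shape[1]
    for word in product(range(4), repeat=w):
        scores.append(sum(int_weights[b, j] for j, b in enumerate(word)))
        probs.append(np.prod([background[b] for b in word]))
    return np.array(scores), np.array(probs)


class TestPwmScanning:
    def test_threshold_dp_equals_enumeration(self):
        # uniform background: all probabilities are exact dyadic rationals, so
        # the DP and the exhaustive enumeration agree to the last bit
        rng = np.random.default_rng(7)
        background = np.full(4, 0.25)
        for width in (4, 5, 6, 7, 8):
            pfm = rng.integers(0, 30, size=(4, width)).astype(float) + 1
            lods = sm.pfm_to_pwm(pfm, background)
            int_w = np.round(lods / sm.SCORE_GRANULARITY).astype(np.int64)
            got = sm.threshold_from_pvalue(int_w, background, 1e-4)
            scores, probs = _enumerate_tail(int_w, background)
            # the DP threshold is valid and one lower would admit too much tail
            assert probs[scores >= got].sum() <= 1e-4
            assert probs[scores >= got - 1].sum() > 1e-4
            # word classification identical to enumerating every word's tail
            for s in np.unique(scores):
                enum_hit = probs[scores >= s].sum() <= 1e-4
                assert (s >= got) == enum_hit

    def test_consensus_sequence_hits(self):
        pfm = fx._consensus_pfm("TGACGTCA")
        hits = sm.scan_motifs({"s": "AAAA" + "TGACGTCA" + "AAAA"}, {"m": pfm},
                              background=np.full(4, 0.25))
        assert hits["n_hits"].iloc[0] >= 1

    def test_strand_symmetry(self):
        rng = np.random.default_rng(9)
        seq = "".join("ACGT"[i] for i in rng.integers(0, 4, 300))
        rc = seq.translate(str.maketrans("ACGT", "TGCA"))[::-1]
        pfm = rng.integers(0, 25, size=(4, 7)).astype(float) + 1
        bg = np.full(4, 0.25)
        fwd = sm.scan_motifs({"s": seq}, {"m": pfm}, background=bg)
        rev = sm.scan_motifs({"s": rc}, {"m": pfm}, background=bg)
        assert fwd["n_hits"].iloc[0] == rev["n_hits"].iloc[0]

    def test_short_sequence_zero_hits(self):
        pfm = fx._consensus_pfm("TGACGTCA")
        hits = sm.scan_motifs({"s": "ACGT"}, {"m": pfm}, background=np.full(4, 0.25))
        assert hits["n_hits"].iloc[0] == 0

    def test_jaspar_round_trip(self, tmp_path):
        pfms = {"MA0001.1": fx._consensus_pfm("ACGTAC"), "MA0002.1": fx._consensus_pfm("TTTTGG")}
        fx.write_jaspar(pfms, tmp_path / "m.jaspar")
        parsed = sm.read_jaspar(tmp_path / "m.jaspar")
        assert set(parsed) == set(pfms)
        for k in pfms:
            assert np.allclose(parsed[k], pfms[k])


class TestDeltas:
    def test_labels(self):
        ref = pd.DataFrame({"peak": ["p1", "p2", "p3"], "motif": ["m"] * 3, "n_hits": [0, 2, 1]})
        alt = pd.DataFrame({"peak": ["p1", "p2", "p3"], "motif": ["m"] * 3, "n_hits": [1, 1, 1]})
        out = sm.motif_deltas(ref, alt).set_index("peak")
        assert out.loc["p1", "delta"] == "gained"
        assert out.loc["p2", "delta"] == "lost"
        assert out.loc["p3", "delta"] == "unchanged"


class TestFunctionalMotifTest:
    def _deltas(self, gains, losses, motif="m1"):
        rows = [(p, motif, 0, 1, "gained") for p in gains]
        rows += [(p, motif, 1, 0, "lost") for p in losses]
        return pd.DataFrame(rows, columns=["peak", "motif", "n_ref_hits", "n_alt_hits", "delta"])

    def test_opening_motif_detected(self):
        rng = np.random.default_rng(0)
        gains = [f"g{i}" for i in range(20)]
        losses = [f"l{i}" for i in range(20)]
        diff = pd.DataFrame(
            {
                "peak": gains + losses,
                "log2fc": np.concatenate([rng.normal(1.5, 0.5, 20), rng.normal(-1.5, 0.5, 20)]),
            }
        )
        res = sm.functional_motif_test(self._deltas(gains, losses), diff)
        assert res["significant"].iloc[0]
        assert res["direction"].iloc[0] == "opening"

    def test_gains_only_motif_skipped(self):
        diff = pd.DataFrame({"peak": ["g0", "g1"], "log2fc": [1.0, 2.0]})
        res = sm.functional_motif_test(self._deltas(["g0", "g1"], []), diff)
        assert res.empty
        assert res.attrs["skipped_motifs"] == ["m1"]

    def test_zero_variance_permutation_fallback(self):
        diff = pd.DataFrame({"peak": ["g0", "g1", "l0", "l1"], "log2fc": [1.0, 1.0, -1.0, -1.0]})
        res = sm.functional_motif_test(self._deltas(["g0", "g1"], ["l0", "l1"]), diff)
        assert np.isinf(res["t_statistic"].iloc[0])
        assert 0 < res["p_raw"].iloc[0] <= 1

    def test_bh_adjustment_monotone(self):
        p = np.array([0.001, 0.01, 0.02, 0.8])
        adj = sm.benjamini_hochberg(p)
        assert (np.diff(adj[np.argsort(p)]) >= 0).all()
        assert (adj >= p).all()


class TestCountExplained:
    def _setup(self):
        functional = pd.DataFrame(
            {"motif": ["m1"], "t_statistic": [5.0], "p_raw": [1e-4], "n_gain_peaks": [5],
             "n_loss_peaks": [5], "mean_diff": [2.0], "p_adj": [1e-3], "significant": [True],
             "direction": ["opening"]}
        )
        deltas = pd.DataFrame(
            {
                "peak": ["p1", "p2", "p3"],
                "motif": ["m1", "m1", "m1"],
                "n_ref_hits": [0, 0, 1],
                "n_alt_hits": [1, 1, 1],
                "delta": ["gained", "gained", "unchanged"],
            }
        )
        diff = pd.DataFrame(
            {"peak": ["p1", "p2", "p3"], "cell_type": ["t"] * 3, "log2fc": [1.0, -1.0, 1.0]}
        )
        return functional, deltas, diff

    def test_coherence_rule(self):
        functional, deltas, diff = self._setup()
        out = sm.count_explained(functional, deltas, diff)
        # p1: gained + positive lfc => explained; p2 incoherent; p3 unchanged
        assert out["explained"].iloc[0] == 1
        assert out["unexplained"].iloc[0] == 2

    def test_conservation(self):
        functional, deltas, diff = self._setup()
        out = sm.count_explained(functional, deltas, diff)
        assert (out["explained"] + out["unexplained"]).equals(out["total"])
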