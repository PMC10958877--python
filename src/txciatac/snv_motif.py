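"""SNV filtering, hotspot assignment, and SNV-driven motif gain/loss analysis.

Alternative peak sequences are built by substituting filtered SNVs into the
reference peak sequences. Position frequency matrices are converted to
log-odds weight matrices with a MOODS-style pseudocount and scanned on both
strands at a score threshold derived from a p-value cutoff; the threshold is
computed exactly by dynamic programming over the discretized score
distribution under a 0-order background. Motifs whose gains/losses associate
with the direction of differential accessibility (Student's t-test, BH
corrected) are called functional, and differential peaks carrying a coherent
instance are counted as explained.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Dict, Iterable, List, Optional, Tuple

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "filter_snvs",
    "assign_hotspots",
    "jaccard_snv_sets",
    "apply_snvs_to_sequence",
    "PWM",
    "read_jaspar",
    "scan_motifs",
    "motif_deltas",
    "functional_motif_test",
    "count_explained",
    "benjamini_hochberg",
]

BASES = "ACGT"
BASE_INDEX = {b: i for i, b in enumerate(BASES)}
COMPLEMENT = str.maketrans("ACGT", "TGCA")

#: score discretization granularity, in bits, for the threshold DP
SCORE_GRANULARITY = 0.01
DEFAULT_PSEUDOCOUNT = 0.8
DEFAULT_PVALUE = 1e-4


# ---------------------------------------------------------------------------
# SNV handling


def filter_snvs(vcf_path, min_qual: float = 20.0, min_depth_sum: int = 10) -> pd.DataFrame:
    """Filter a multi-sample VCF to high-confidence, replicate-concordant SNVs.

    Keeps biallelic single-nucleotide records with QUAL >= ``min_qual``, a
    summed per-sample DP >= ``min_depth_sum``, and the same genotype in at
    least two of three replicates (for other replicate counts the rule
    generalizes to a strict majority, with a warning). Genotypes are compared
    unphased. Returns a DataFrame with columns chrom, pos (1-based), ref,
    alt, qual, depth_sum plus ``n_dropped_non_snv`` in ``.attrs``.
    """
    from cyvcf2 import VCF

    rows = []
    n_non_snv = 0
    vcf = VCF(str(vcf_path))
    n_samples = len(vcf.samples)
    if n_samples != 3:
        warnings.warn(
            f"{n_samples} replicates instead of 3; genotype concordance generalized to a majority"
        )
    needed = 2 if n_samples == 3 else n_samples // 2 + 1
    for var in vcf:
        if not var.is_snp or len(var.ALT) != 1:
            n_non_snv += 1
            continue
        qual = var.QUAL if var.QUAL is not None else 0.0
        if qual < min_qual:
            continue
        depths = var.format("DP")
        depth = int(depths.sum()) if depths is not None else 0
        if depth < min_depth_sum:
            continue
        gts = [
            tuple(sorted(g[:-1]))  # drop phasing flag; compare unphased
            for g in var.genotypes
            if -1 not in g[:-1]
        ]
        if not gts:
            continue
        modal = max(set(gts), key=gts.count)
        if gts.count(modal) < needed:
            continue
        rows.append((var.CHROM, var.POS, var.REF, var.ALT[0], float(qual), depth))
    vcf.close()
    out = pd.DataFrame(rows, columns=["chrom", "pos", "ref", "alt", "qual", "depth_sum"])
    out.attrs["n_dropped_non_snv"] = n_non_snv
    return out


def assign_hotspots(snvs: pd.DataFrame, hotspots: Dict[str, tuple]) -> pd.DataFrame:
    """Label each SNV with the name of the hotspot containing it or "outside".

    ``hotspots`` maps name -> (chrom, start, end) with 1-based *closed*
    coordinates as conventionally printed; both endpoints are inside.
    """
    labels = []
    for chrom, pos in zip(snvs["chrom"], snvs["pos"]):
        label = "outside"
        for name, (h_chrom, h_start, h_end) in hotspots.items():
            if chrom == h_chrom and h_start <= pos <= h_end:
                label = name
                break
        labels.append(label)
    return snvs.assign(hotspot=labels)


def jaccard_snv_sets(a: Iterable[tuple], b: Iterable[tuple]) -> float:
    """Jaccard similarity of SNV sets keyed by (chrom, pos, ref, alt)."""
    a, b = set(a), set(b)
    union = a | b
    if not union:
        warnings.warn("both SNV sets empty; Jaccard defined as 0")
        return 0.0
    return len(a & b) / len(union)


def apply_snvs_to_sequence(sequences: Dict[str, str], snvs: pd.DataFrame) -> Dict[str, str]:
    """Substitute SNV alt alleles into reference peak sequences.

    SNV chrom must name a sequence; pos is 1-based. A reference-allele
    mismatch raises (it indicates a coordinate bug), substitutions preserve
    length.
    """
    out = {name: list(seq) for name, seq in sequences.items()}
    for chrom, pos, ref, alt in zip(snvs["chrom"], snvs["pos"], snvs["ref"], snvs["alt"]):
        if chrom not in out:
            continue
        seq = out[chrom]
        idx = pos - 1
        if idx < 0 or idx >= len(seq):
            raise ValueError(f"SNV {chrom}:{pos} outside sequence bounds (len {len(seq)})")
        if seq[idx] != ref:
            raise ValueError(
                f"reference mismatch at {chrom}:{pos}: sequence has {seq[idx]!r}, VCF says {ref!r}"
            )
        seq[idx] = alt
    return {name: "".join(seq) for name, seq in out.items()}


# ---------------------------------------------------------------------------
# PWM scanning


@dataclass
class PWM:
    """Integer-discretized log-odds weight matrix with its score threshold.

    ``weights`` is a (4, width) integer array of log2-odds scores in units of
    ``granularity`` bits; ``threshold`` is the smallest integer score whose
    tail probability under the background does not exceed the p-value cutoff.
    """

    motif_id: str
    weights: np.ndarray
    threshold: int
    background: np.ndarray
    granularity: float = SCORE_GRANULARITY

    @property
    def width(self) -> int:
        return self.weights.shape[1]


def read_jaspar(path) -> Dict[str, np.ndarray]:
    """Parse JASPAR-format PFMs into ``{motif_id: (4, width) count matrix}``."""
    from Bio import motifs as bio_motifs

    pfms = {}
    with open(path) as fh:
        for m in bio_motifs.parse(fh, "jaspar"):
            mat = np.array([m.counts[b] for b in BASES], dtype=float)
            key = m.matrix_id if m.matrix_id else m.name
            pfms[key] = mat
    return pfms


def pfm_to_pwm(pfm: np.ndarray, background: np.ndarray, pseudocount: float = DEFAULT_PSEUDOCOUNT) -> np.ndarray:
    """MOODS-style log2-odds matrix: the pseudocount is distributed across
    bases in proportion to the background."""
    pfm = np.asarray(pfm, dtype=float)
    col_sums = pfm.sum(axis=0)
    if (col_sums <= 0).any():
        raise ValueError("PFM column with nonpositive sum")
    probs = (pfm + pseudocount * background[:, None]) / (col_sums + pseudocount)
    return np.log2(probs / background[:, None])


def score_distribution(int_weights: np.ndarray, background: np.ndarray):
    """Exact distribution of window scores under an i.i.d. background.

    Dynamic programming: convolve, column by column, the four (probability,
    integer score) outcomes. Returns ``(scores offset, probability array)``
    where probability[i] is P(score == offset + i).
    """
    w = int_weights
    offset = 0
    dist = np.array([1.0])
    for j in range(w.shape[1]):
        col = w[:, j]
        new_lo = offset + int(col.min())
        new_hi = offset + len(dist) - 1 + int(col.max())
        new = np.zeros(new_hi - new_lo + 1)
        for b in range(4):
            shift = int(col[b]) + offset - new_lo
            new[shift : shift + len(dist)] += background[b] * dist
        dist = new
        offset = new_lo
    return offset, dist


def threshold_from_pvalue(int_weights: np.ndarray, background: np.ndarray, p_value: float) -> int:
    """Smallest integer score whose background tail probability is <= p_value."""
    offset, dist = score_distribution(int_weights, background)
    tail = np.cumsum(dist[::-1])[::-1]
    idx = np.searchsorted(-tail, -p_value, side="left")
    # idx is the first position with tail <= p_value
    if idx >= len(tail):
        return offset + len(tail)  # unreachable score: no hit can pass
    return offset + int(idx)


def build_pwm(
    motif_id: str,
    pfm: np.ndarray,
    background: np.ndarray,
    p_value: float = DEFAULT_PVALUE,
    pseudocount: float = DEFAULT_PSEUDOCOUNT,
    granularity: float = SCORE_GRANULARITY,
) -> PWM:
    lods = pfm_to_pwm(pfm, background, pseudocount)
    int_weights = np.round(lods / granularity).astype(np.int64)
    threshold = threshold_from_pvalue(int_weights, background, p_value)
    return PWM(motif_id, int_weights, threshold, background, granularity)


def sequence_background(sequences: Iterable[str]) -> np.ndarray:
    """0-order base composition of the supplied sequences (ACGT order)."""
    counts = np.zeros(4)
    for seq in sequences:
        for b, i in BASE_INDEX.items():
            counts[i] += seq.count(b)
    if counts.sum() == 0:
        return np.full(4, 0.25)
    return counts / counts.sum()


def _count_hits_one_strand(seq_idx: np.ndarray, pwm: PWM) -> int:
    w = pwm.width
    n = len(seq_idx) - w + 1
    if n <= 0:
        return 0
    windows = np.lib.stride_tricks.sliding_window_view(seq_idx, w)
    scores = np.take_along_axis(pwm.weights.T, windows.T, axis=1).sum(axis=0)
    return int(np.count_nonzero(scores >= pwm.threshold))


def count_hits(sequence: str, pwm: PWM) -> int:
    """Number of PWM matches on both strands; overlaps counted individually."""
    seq = sequence.upper()
    fwd = np.array([BASE_INDEX.get(b, -1) for b in seq])
    if (fwd < 0).any():  # mask non-ACGT by a base that scores worst everywhere
        fwd = np.where(fwd < 0, int(np.argmin(pwm.weights.sum(axis=1))), fwd)
    rev = np.array([BASE_INDEX[b] for b in seq.translate(COMPLEMENT)[::-1]])
    return _count_hits_one_strand(fwd, pwm) + _count_hits_one_strand(rev, pwm)


def scan_motifs(
    sequences: Dict[str, str],
    pfms: Dict[str, np.ndarray],
    p_value: float = DEFAULT_PVALUE,
    pseudocount: float = DEFAULT_PSEUDOCOUNT,
    background: Optional[np.ndarray] = None,
) -> pd.DataFrame:
    """Hit counts per (sequence, motif) at the given p-value cutoff.

    The background defaults to the composition of the supplied sequences.
    Returns a long DataFrame with columns peak, motif, n_hits.
    """
    if background is None:
        background = sequence_background(sequences.values())
    background = np.asarray(background, dtype=float)
    pwms = {
        motif_id: build_pwm(motif_id, pfm, background, p_value, pseudocount)
        for motif_id, pfm in pfms.items()
    }
    rows = []
    for seq_id, seq in sequences.items():
        for motif_id, pwm in pwms.items():
            rows.append((seq_id, motif_id, count_hits(seq, pwm)))
    return pd.DataFrame(rows, columns=["peak", "motif", "n_hits"])


# ---------------------------------------------------------------------------
# Gain/loss analysis


def motif_deltas(ref_hits: pd.DataFrame, alt_hits: pd.DataFrame) -> pd.DataFrame:
    """Per (peak, motif) change in match counts between reference and
    SNV-substituted sequences."""
    merged = ref_hits.merge(
        alt_hits, on=["peak", "motif"], how="outer", suffixes=("_ref", "_alt")
    ).fillna(0)
    diff = merged["n_hits_alt"] - merged["n_hits_ref"]
    merged["delta"] = np.select([diff > 0, diff < 0], ["gained", "lost"], default="unchanged")
    return merged.rename(columns={"n_hits_ref": "n_ref_hits", "n_hits_alt": "n_alt_hits"})


def benjamini_hochberg(pvals: np.ndarray) -> np.ndarray:
    """BH-adjusted p-values (monotone step-up)."""
    pvals = np.asarray(pvals, dtype=float)
    n = len(pvals)
    order = np.argsort(pvals)
    ranked = pvals[order] * n / np.arange(1, n + 1)
    adj = np.minimum.accumulate(ranked[::-1])[::-1]
    out = np.empty(n)
    out[order] = np.minimum(adj, 1.0)
    return out


def _permutation_pvalue(x: np.ndarray, y: np.ndarray, n_perm: int = 10_000, seed: int = 0) -> float:
    rng = np.random.default_rng(seed)
    pooled = np.concatenate([x, y])
    observed = abs(x.mean() - y.mean())
    n_x = len(x)
    hits = 0
    for _ in range(n_perm):
        rng.shuffle(pooled)
        if abs(pooled[:n_x].mean() - pooled[n_x:].mean()) >= observed - 1e-15:
            hits += 1
    return (hits + 1) / (n_perm + 1)


def functional_motif_test(
    deltas: pd.DataFrame,
    diff_peaks: pd.DataFrame,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Test each motif for association between gain/loss and accessibility
    log2 fold-change.

    Per motif with at least one gained and one lost peak, a two-sample
    Student's t-test compares log2FC between the gained-peak and lost-peak
    groups; p-values are BH-adjusted across tested motifs. A significant
    motif with a higher gained-group mean is "opening", otherwise "closing".
    Motifs lacking either gains or losses are skipped and reported in
    ``.attrs["skipped_motifs"]``.
    """
    lfc = diff_peaks.set_index("peak")["log2fc"]
    rows = []
    skipped = []
    for motif, grp in deltas.groupby("motif"):
        gained = grp.loc[grp["delta"] == "gained", "peak"]
        lost = grp.loc[grp["delta"] == "lost", "peak"]
        x = lfc.reindex(gained).dropna().to_numpy()
        y = lfc.reindex(lost).dropna().to_numpy()
        if len(x) == 0 or len(y) == 0:
            skipped.append(motif)
            continue
        if np.var(x) == 0 and np.var(y) == 0:
            if x.mean() == y.mean():
                t, p = 0.0, 1.0
            else:
                t = math_inf_sign(x.mean() - y.mean())
                p = _permutation_pvalue(x, y)
        else:
            t, p = stats.ttest_ind(x, y, equal_var=True)
        rows.append((motif, float(t), float(p), len(x), len(y), x.mean() - y.mean()))
    out = pd.DataFrame(
        rows, columns=["motif", "t_statistic", "p_raw", "n_gain_peaks", "n_loss_peaks", "mean_diff"]
    )
    if len(out):
        out["p_adj"] = benjamini_hochberg(out["p_raw"].to_numpy())
    else:
        out["p_adj"] = pd.Series(dtype=float)
    out["significant"] = out["p_adj"] <= alpha
    out["direction"] = np.where(out["t_statistic"] > 0, "opening", "closing")
    out.attrs["skipped_motifs"] = skipped
    return out


def math_inf_sign(x: float) -> float:
    return float(np.inf) if x > 0 else float(-np.inf)


def count_explained(
    functional: pd.DataFrame,
    deltas: pd.DataFrame,
    diff_peaks: pd.DataFrame,
) -> pd.DataFrame:
    """Count differential peaks explained by functional-motif instances.

    A peak is explained if it carries at least one gain/loss instance coherent
    with a functional motif's direction: for an opening motif, a gained match
    on a peak with log2FC > 0 or a lost match with log2FC < 0; reversed for
    closing motifs. Each peak counts once per cell type; explained +
    unexplained equals the number of differential peaks.
    """
    sig = functional[functional["significant"]]
    direction = dict(zip(sig["motif"], sig["direction"]))
    delta_by_peak = deltas[deltas["delta"].isin(["gained", "lost"])]
    explained_peaks = set()
    for peak, motif, delta in zip(delta_by_peak["peak"], delta_by_peak["motif"], delta_by_peak["delta"]):
        d = direction.get(motif)
        if d is None:
            continue
        rows = diff_peaks[diff_peaks["peak"] == peak]
        for _, row in rows.iterrows():
            lfc = row["log2fc"]
            coherent = (
                (d == "opening" and ((delta == "gained" and lfc > 0) or (delta == "lost" and lfc < 0)))
                or (d == "closing" and ((delta == "gained" and lfc < 0) or (delta == "lost" and lfc > 0)))
            )
            if coherent:
                explained_peaks.add((row.get("cell_type", "all"), peak))
    rows = []
    group_col = "cell_type" if "cell_type" in diff_peaks.columns else None
    if group_col:
        for cell_type, grp in diff_peaks.groupby(group_col):
            total = grp["peak"].nunique()
            n_exp = len({p for ct, p in explained_peaks if ct == cell_type})
            rows.append((cell_type, n_exp, total - n_exp, total))
    else:
        total = diff_peaks["peak"].nunique()
        n_exp = len(explained_peaks)
        rows.append(("all", n_exp, total - n_exp, total))
    return pd.DataFrame(rows, columns=["cell_type", "explained", "unexplained", "total"])
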