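"""Synthetic, fully ground-truthed fixtures at toy scale.

Everything downstream — demultiplexing, barnyard analysis, QC, doublet
detection, and the SNV/motif workflow — can be exercised without any external
download: kilobase two-species toy genomes, whitelists with guaranteed
correction margins, FASTQ runs with planted barcode truth, fragment files
with planted collisions and a debris mode, binary matrices with planted
doublets, and motif datasets with planted functional motifs.

All generators draw from a single ``numpy.random.default_rng(spec.seed)``
stream per call, so a fixed spec yields byte-identical outputs.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from math import comb
from pathlib import Path
from typing import Dict, Optional, Tuple

import numpy as np
import pandas as pd
from scipy import sparse

from .barcodes import MOSAIC_END, TN5_LEN

__all__ = [
    "FixtureSpec",
    "make_barcode_whitelists",
    "make_synthetic_run",
    "make_hybrid_fragments",
    "make_count_matrix",
    "make_motif_dataset",
]

BASES = np.array(list("ACGT"))


@dataclass(frozen=True)
class FixtureSpec:
    """Parameters shared by all fixture generators."""

    seed: int = 0
    n_cells: int = 200
    genome_sizes: Dict[str, Tuple[str, int]] = field(
        default_factory=lambda: {"human": ("hg_toy", 50_000), "mouse": ("mm_toy", 50_000)}
    )
    error_rate: float = 0.0
    true_collision_fraction: float = 0.0
    doublet_fraction: float = 0.0
    n_peaks: int = 100
    n_motifs: int = 4

    def __post_init__(self) -> None:
        for name in ("error_rate", "true_collision_fraction", "doublet_fraction"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        for species, (contig, length) in self.genome_sizes.items():
            if length < 1_000:
                raise ValueError(f"genome for {species!r} shorter than 1 kb")
        if self.n_cells < 1:
            raise ValueError("n_cells must be >= 1")


# ---------------------------------------------------------------------------
# Whitelists


def _random_barcodes(
    rng: np.random.Generator,
    n: int,
    length: int,
    min_dist: int = 3,
    max_attempts_per_code: int = 2_000,
) -> list:
    """Greedy random code with pairwise Hamming distance >= ``min_dist``.

    The Hamming sphere-packing bound is checked up front so clearly impossible
    requests (e.g. 70,000 distinct 8-mers at distance 3) fail immediately;
    feasible-looking but unreachable requests fail after the attempt budget.
    """
    radius = (min_dist - 1) // 2
    sphere = sum(comb(length, i) * 3**i for i in range(radius + 1))
    bound = 4**length // sphere
    if n > bound:
        raise ValueError(
            f"{n} barcodes of length {length} at min distance {min_dist} exceed the "
            f"sphere-packing bound ({bound})"
        )
    codes: list = []
    arrays: list = []
    attempts = 0
    while len(codes) < n:
        candidate = rng.integers(0, 4, size=length)
        attempts += 1
        if arrays and min(int((candidate != a).sum()) for a in arrays) < min_dist:
            if attempts > max_attempts_per_code * (len(codes) + 1):
                raise ValueError(
                    f"could not place {n} barcodes of length {length} at distance {min_dist} "
                    f"(stuck after {len(codes)})"
                )
            continue
        arrays.append(candidate)
        codes.append("".join(BASES[candidate]))
    return codes


def make_barcode_whitelists(
    spec: FixtureSpec,
    n_tn5: int = 96,
    n_gem: Optional[int] = None,
    n_i7: int = 4,
    min_dist: int = 3,
) -> Dict[str, list]:
    """Generate the three whitelists (Tn5 8-mers, GEM 16-mers, i7 8-mers).

    All sets respect a minimum pairwise Hamming distance of ``min_dist`` so
    distance-2 correction is unambiguous for single substitutions. The GEM
    whitelist defaults to twice ``n_cells`` entries.
    """
    rng = np.random.default_rng(spec.seed)
    if n_gem is None:
        n_gem = max(2 * spec.n_cells, 16)
    return {
        "tn5": _random_barcodes(rng, n_tn5, TN5_LEN, min_dist),
        "gem": _random_barcodes(rng, n_gem, 16, min_dist),
        "i7": _random_barcodes(rng, n_i7, 8, min_dist),
    }


def write_whitelists(whitelists: Dict[str, list], out_dir) -> None:
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    for level, entries in whitelists.items():
        (out_dir / f"{level}_whitelist.txt").write_text("\n".join(entries) + "\n")


# ---------------------------------------------------------------------------
# Synthetic sequencing run


def _random_dna(rng: np.random.Generator, length: int) -> str:
    return "".join(BASES[rng.integers(0, 4, size=length)])


def _inject_errors(rng: np.random.Generator, seq: str, error_rate: float) -> str:
    if error_rate == 0:
        return seq
    chars = np.array(list(seq))
    hit = rng.random(len(chars)) < error_rate
    for i in np.nonzero(hit)[0]:
        alternatives = [b for b in "ACGT" if b != chars[i]]
        chars[i] = alternatives[rng.integers(0, 3)]
    return "".join(chars)


def make_synthetic_run(
    spec: FixtureSpec,
    whitelists: Dict[str, list],
    out_dir,
    reads_per_cell: int = 20,
    read_length: int = 50,
) -> pd.DataFrame:
    """Write R1/R2/I1/I2 FASTQs plus a truth table mapping read ids to their
    true barcodes, species, and cell.

    R2 is the true Tn5 barcode (8 bp) + mosaic end (19 bp) + genomic sequence;
    substitution errors at ``error_rate`` are injected into the barcode
    segments of R2, I1, and I2. Truth rows are in bijection with reads.
    """
    rng = np.random.default_rng(spec.seed)
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    species_names = list(spec.genome_sizes)
    cells = []
    for c in range(spec.n_cells):
        cells.append(
            {
                "cell": f"cell{c:05d}",
                "species": species_names[rng.integers(0, len(species_names))],
                "tn5": whitelists["tn5"][rng.integers(0, len(whitelists["tn5"]))],
                "gem": whitelists["gem"][rng.integers(0, len(whitelists["gem"]))],
                "i7": whitelists["i7"][rng.integers(0, len(whitelists["i7"]))],
            }
        )
    qual_r = "I" * read_length
    truth_rows = []
    with open(out_dir / "R1.fastq", "w") as r1, open(out_dir / "R2.fastq", "w") as r2, open(
        out_dir / "I1.fastq", "w"
    ) as i1, open(out_dir / "I2.fastq", "w") as i2:
        read_no = 0
        for cell in cells:
            for _ in range(reads_per_cell):
                rid = f"read{read_no:07d}"
                read_no += 1
                genomic1 = _random_dna(rng, read_length)
                genomic2 = _random_dna(rng, read_length)
                tn5_obs = _inject_errors(rng, cell["tn5"], spec.error_rate)
                gem_obs = _inject_errors(rng, cell["gem"], spec.error_rate)
                i7_obs = _inject_errors(rng, cell["i7"], spec.error_rate)
                r2_seq = tn5_obs + MOSAIC_END + genomic2
                r1.write(f"@{rid}\n{genomic1}\n+\n{qual_r}\n")
                r2.write(f"@{rid}\n{r2_seq}\n+\n{'I' * len(r2_seq)}\n")
                i1.write(f"@{rid}\n{i7_obs}\n+\n{'I' * len(i7_obs)}\n")
                i2.write(f"@{rid}\n{gem_obs}\n+\n{'I' * len(gem_obs)}\n")
                truth_rows.append(
                    (rid, cell["i7"], cell["gem"], cell["tn5"], cell["species"], cell["cell"])
                )
    truth = pd.DataFrame(truth_rows, columns=["read_id", "i7", "gem", "tn5", "species", "cell"])
    truth.to_csv(out_dir / "truth.tsv", sep="\t", index=False)
    return truth


# ---------------------------------------------------------------------------
# Hybrid-genome fragments


def make_hybrid_fragments(
    spec: FixtureSpec,
    out_path=None,
    mean_log10_depth: float = 3.3,
    sd_log10_depth: float = 0.2,
    debris_fraction: float = 0.5,
    debris_log10_depth: float = 2.0,
    contamination: float = 0.002,
    fragment_size: Tuple[int, int] = (50, 500),
    species_mix: Optional[Dict[str, float]] = None,
):
    """Fragments BED with planted species labels, collisions, and debris.

    Singlet barcodes draw all but a ``contamination`` share of their fragments
    from their own species' contig; planted collision barcodes merge two
    cells' fragment pools. Debris barcodes add a low-count mode so the log10
    read-depth distribution is bimodal (as assumed by the k-means threshold).

    Returns ``(fragments DataFrame, truth DataFrame)`` and optionally writes
    the BED to ``out_path``.
    """
    rng = np.random.default_rng(spec.seed)
    species_names = list(spec.genome_sizes)
    if species_mix is None:
        species_mix = {s: 1.0 / len(species_names) for s in species_names}
    probs = np.array([species_mix[s] for s in species_names])

    n_collisions = round(spec.true_collision_fraction * spec.n_cells)
    n_singlets = spec.n_cells - n_collisions
    truth_rows = []
    frag_rows = []

    def sample_fragments(barcode: str, species: str, depth: int):
        contig, length = spec.genome_sizes[species]
        other = [s for s in species_names if s != species]
        for _ in range(depth):
            sp = species
            if other and rng.random() < contamination:
                sp = other[rng.integers(0, len(other))]
            c, ln = spec.genome_sizes[sp]
            size = int(rng.integers(fragment_size[0], fragment_size[1]))
            start = int(rng.integers(0, max(1, ln - size)))
            frag_rows.append((c, start, start + size, barcode, int(rng.integers(1, 4))))

    for i in range(n_singlets):
        barcode = f"BC{i:05d}"
        species = species_names[rng.choice(len(species_names), p=probs)]
        depth = int(round(10 ** rng.normal(mean_log10_depth, sd_log10_depth)))
        sample_fragments(barcode, species, depth)
        truth_rows.append((barcode, species, depth, "singlet"))

    for i in range(n_collisions):
        barcode = f"BC{n_singlets + i:05d}"
        sp_a = species_names[rng.choice(len(species_names), p=probs)]
        sp_b = species_names[rng.choice(len(species_names), p=probs)]
        depth_a = int(round(10 ** rng.normal(mean_log10_depth, sd_log10_depth)))
        depth_b = int(round(10 ** rng.normal(mean_log10_depth, sd_log10_depth)))
        sample_fragments(barcode, sp_a, depth_a)
        sample_fragments(barcode, sp_b, depth_b)
        label = "collision" if sp_a != sp_b else "homotypic_collision"
        truth_rows.append((barcode, f"{sp_a}+{sp_b}", depth_a + depth_b, label))

    n_debris = round(debris_fraction * spec.n_cells)
    for i in range(n_debris):
        barcode = f"DEBRIS{i:05d}"
        species = species_names[rng.choice(len(species_names), p=probs)]
        depth = max(1, int(round(10 ** rng.normal(debris_log10_depth, 0.15))))
        sample_fragments(barcode, species, depth)
        truth_rows.append((barcode, species, depth, "debris"))

    fragments = pd.DataFrame(
        frag_rows, columns=["chrom", "start", "end", "barcode", "dup_count"]
    ).sort_values(["chrom", "start", "end", "barcode"], ignore_index=True)
    truth = pd.DataFrame(truth_rows, columns=["barcode", "species", "depth", "kind"])
    if out_path is not None:
        fragments.to_csv(out_path, sep="\t", header=False, index=False)
        truth.to_csv(Path(out_path).with_suffix(".truth.tsv"), sep="\t", index=False)
    return fragments, truth


# ---------------------------------------------------------------------------
# Binary matrix with planted doublets


def make_count_matrix(
    spec: FixtureSpec,
    n_clusters: int = 5,
    in_block_rate: float = 0.9,
    background_rate: float = 0.02,
):
    """Binarized cells x peaks matrix with planted clusters and doublets.

    Clusters occupy distinct peak blocks; doublets are element-wise ORs of two
    singlet profiles drawn from distinct clusters. Returns
    ``(csr matrix, barcodes, peak names, truth DataFrame)`` where truth flags
    exactly ``round(doublet_fraction * n_cells)`` barcodes as doublets.
    """
    if spec.n_peaks < 50:
        raise ValueError("need n_peaks >= 50")
    rng = np.random.default_rng(spec.seed)
    n_doublets = round(spec.doublet_fraction * spec.n_cells)
    n_singlets = spec.n_cells - n_doublets
    block = spec.n_peaks // n_clusters

    def singlet_profile(cluster: int) -> np.ndarray:
        p = np.full(spec.n_peaks, background_rate)
        p[cluster * block : (cluster + 1) * block] = in_block_rate
        return (rng.random(spec.n_peaks) < p).astype(np.int8)

    profiles = []
    truth_rows = []
    for i in range(n_singlets):
        cluster = int(rng.integers(0, n_clusters))
        profiles.append(singlet_profile(cluster))
        truth_rows.append((f"CELL{i:05d}", cluster, False))
    for i in range(n_doublets):
        c1 = int(rng.integers(0, n_clusters))
        c2 = int((c1 + 1 + rng.integers(0, n_clusters - 1)) % n_clusters)
        merged = np.maximum(singlet_profile(c1), singlet_profile(c2))
        profiles.append(merged)
        truth_rows.append((f"CELL{n_singlets + i:05d}", -1, True))
    order = rng.permutation(spec.n_cells)
    mat = sparse.csr_matrix(np.array(profiles)[order])
    truth = pd.DataFrame(truth_rows, columns=["barcode", "cluster", "is_doublet"]).iloc[order]
    truth = truth.reset_index(drop=True)
    barcodes = truth["barcode"].tolist()
    peak_names = [f"peak{j:05d}" for j in range(spec.n_peaks)]
    return mat, barcodes, peak_names, truth


# ---------------------------------------------------------------------------
# Motif dataset


_PLANTED_MOTIF_CORE = "TGACGTCA"  # palindromic 8-mer core for planted motifs


def _consensus_pfm(consensus: str, weight: int = 20, off: int = 1) -> np.ndarray:
    """A sharp PFM whose consensus is the given sequence."""
    base_index = {b: i for i, b in enumerate("ACGT")}
    pfm = np.full((4, len(consensus)), off, dtype=float)
    for j, b in enumerate(consensus):
        pfm[base_index[b], j] = weight
    return pfm


def write_jaspar(pfms: Dict[str, np.ndarray], path) -> None:
    with open(path, "w") as fh:
        for motif_id, pfm in pfms.items():
            fh.write(f">{motif_id} {motif_id}\n")
            for base, row in zip("ACGT", pfm):
                values = " ".join(f"{int(v):6d}" for v in row)
                fh.write(f"{base} [{values} ]\n")


def make_motif_dataset(
    spec: FixtureSpec,
    out_dir=None,
    peak_length: int = 200,
    n_gain: int = 25,
    n_loss: int = 25,
    effect_size: float = 1.5,
    noise_sd: float = 0.5,
    vcf_replicates: int = 3,
) -> dict:
    """Peak FASTA + SNV VCF + PFMs + differential-peak table with planted truth.

    One planted "opening" motif: on gain peaks an SNV turns a near-consensus
    site into a consensus match (log2FC drawn with a +``effect_size`` shift);
    on loss peaks an SNV destroys a planted consensus match (-``effect_size``
    shift). The remaining ``n_motifs - 1`` decoy motifs have no planted sites
    or association. Returns a dict with sequences, snvs, pfms, diff_table,
    and truth; files are written when ``out_dir`` is given.
    """
    if spec.n_motifs < 2:
        raise ValueError("need n_motifs >= 2")
    rng = np.random.default_rng(spec.seed)
    core = _PLANTED_MOTIF_CORE
    w = len(core)
    pfms = {"MFX0001": _consensus_pfm(core)}
    for k in range(1, spec.n_motifs):
        decoy = "".join(BASES[rng.integers(0, 4, size=w)])
        pfms[f"MFX{k + 1:04d}"] = _consensus_pfm(decoy)

    n_peaks = max(spec.n_peaks, n_gain + n_loss + 10)
    sequences: Dict[str, str] = {}
    snv_rows = []
    lfc_rows = []
    truth_gain, truth_loss = [], []

    def clean_random_seq() -> str:
        # resample until free of the planted core on either strand
        rc = core[::-1].translate(str.maketrans("ACGT", "TGCA"))
        while True:
            s = "".join(BASES[rng.integers(0, 4, size=peak_length)])
            if core not in s and rc not in s:
                return s

    for i in range(n_peaks):
        name = f"peak{i:05d}"
        seq = clean_random_seq()
        site = int(rng.integers(20, peak_length - 20 - w))
        if i < n_gain:
            # plant a 1-mismatch site; the SNV restores the consensus
            mism = int(rng.integers(0, w))
            ref_base = core[mism]
            wrong = rng.choice([b for b in "ACGT" if b != ref_base])
            planted = core[:mism] + wrong + core[mism + 1 :]
            seq = seq[:site] + planted + seq[site + w :]
            snv_rows.append((name, site + mism + 1, wrong, ref_base))
            lfc = rng.normal(effect_size, noise_sd)
            truth_gain.append(name)
        elif i < n_gain + n_loss:
            # plant a consensus site; the SNV destroys it
            seq = seq[:site] + core + seq[site + w :]
            mism = int(rng.integers(0, w))
            ref_base = core[mism]
            alt = rng.choice([b for b in "ACGT" if b != ref_base])
            snv_rows.append((name, site + mism + 1, ref_base, alt))
            lfc = rng.normal(-effect_size, noise_sd)
            truth_loss.append(name)
        else:
            lfc = rng.normal(0.0, noise_sd)
            if rng.random() < 0.3:  # neutral SNVs outside any planted site
                pos = int(rng.integers(1, 15))
                ref_base = seq[pos - 1]
                alt = rng.choice([b for b in "ACGT" if b != ref_base])
                snv_rows.append((name, pos, ref_base, alt))
        sequences[name] = seq
        lfc_rows.append((name, "typeA", lfc, 0.01))

    snvs = pd.DataFrame(snv_rows, columns=["chrom", "pos", "ref", "alt"])
    snvs["qual"] = 60.0
    snvs["depth_sum"] = 30
    diff_table = pd.DataFrame(lfc_rows, columns=["peak", "cell_type", "log2fc", "fdr"])
    truth = {
        "functional_motifs": ["MFX0001"],
        "gain_peaks": truth_gain,
        "loss_peaks": truth_loss,
    }
    result = {
        "sequences": sequences,
        "snvs": snvs,
        "pfms": pfms,
        "diff_table": diff_table,
        "truth": truth,
    }
    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        with open(out_dir / "peaks.fasta", "w") as fh:
            for name, seq in sequences.items():
                fh.write(f">{name}\n{seq}\n")
        write_vcf(snvs, out_dir / "snvs.vcf", n_replicates=vcf_replicates)
        write_jaspar(pfms, out_dir / "motifs.jaspar")
        diff_table.to_csv(out_dir / "diff_peaks.tsv", sep="\t", index=False)
        pd.Series(truth["functional_motifs"]).to_csv(
            out_dir / "truth_functional_motifs.txt", index=False, header=False
        )
    return result


def write_vcf(snvs: pd.DataFrame, path, n_replicates: int = 3) -> None:
    """Write SNVs as a VCF 4.2 with per-replicate GT:DP fields."""
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        for chrom in pd.unique(snvs["chrom"]):
            fh.write(f"##contig=<ID={chrom}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write('##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Read depth">\n')
        samples = "\t".join(f"rep{i + 1}" for i in range(n_replicates))
        fh.write(f"#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t{samples}\n")
        for _, row in snvs.iterrows():
            qual = row.get("qual", 60.0)
            depth = int(row.get("depth_sum", 30)) // n_replicates
            fields = "\t".join(f"1/1:{depth}" for _ in range(n_replicates))
            fh.write(
                f"{row['chrom']}\t{row['pos']}\t.\t{row['ref']}\t{row['alt']}\t{qual}\tPASS\t.\tGT:DP\t{fields}\n"
            )
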