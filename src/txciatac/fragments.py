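"""Aligned-read filtering, fragment deduplication, and species attribution.

Converts barcode-annotated proper pairs from a BAM/SAM aligned to a hybrid
two-species genome into a deduplicated fragments table. Coordinates follow the
BED convention (0-based, half-open); a fragment spans the outermost mate
coordinates of the pair. No Tn5 +4/-5 insertion-site shift is applied here —
any shifting belongs to downstream peak calling.
"""

from __future__ import annotations

import json
import re
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Iterator, Optional

import numpy as np
import pandas as pd
import pysam

__all__ = [
    "FragmentRecord",
    "filter_alignments",
    "deduplicate_fragments",
    "count_species",
    "read_fragments",
    "write_fragments",
    "fragments_from_bam",
]

FRAGMENT_COLUMNS = ["chrom", "start", "end", "barcode", "dup_count"]

#: Contig names matching this pattern are treated as non-nuclear / unplaced
#: and excluded from fragment generation.
DEFAULT_EXCLUDE = re.compile(r"(chrM|\bMT\b|_random|_alt|chrUn)", re.IGNORECASE)

MAX_FRAGMENT_LENGTH = 2000
MIN_MAPQ = 10


@dataclass(frozen=True)
class FragmentRecord:
    chrom: str
    start: int
    end: int
    barcode: str
    dup_count: int = 1

    def __post_init__(self) -> None:
        if not self.start < self.end:
            raise ValueError(f"degenerate interval {self.start}-{self.end}")
        if self.dup_count < 1:
            raise ValueError("dup_count must be >= 1")


def _barcode_of(read: pysam.AlignedSegment, tag: str) -> Optional[str]:
    if read.has_tag(tag):
        return read.get_tag(tag)
    name = read.query_name
    if ":" in name:
        return name.rsplit(":", 1)[1]
    return None


def filter_alignments(
    bam_path,
    barcode_tag: str = "CB",
    min_mapq: int = MIN_MAPQ,
    exclude_contigs: re.Pattern = DEFAULT_EXCLUDE,
    max_fragment_length: int = MAX_FRAGMENT_LENGTH,
):
    """Stream (barcode, chrom, start, end, read name) tuples for proper pairs.

    Keeps records with MAPQ >= ``min_mapq``, the proper-pair flag set, neither
    mate unmapped (samtools ``-f3 -F12`` semantics), primary alignments on
    nuclear contigs, and fragment length <= ``max_fragment_length``. The
    combined barcode is read from ``barcode_tag`` or, failing that, the read
    name suffix after the last ``:``. Returns ``(pairs, report)`` where
    ``pairs`` is a list of tuples and the report's kept + dropped counts sum
    to the number of input records.
    """
    report = {
        "input_records": 0,
        "kept_records": 0,
        "dropped_flags": 0,
        "dropped_mapq": 0,
        "dropped_contig": 0,
        "dropped_no_barcode": 0,
        "dropped_unpaired_mate": 0,
        "dropped_too_long": 0,
    }
    pending: dict = {}
    pairs = []
    with pysam.AlignmentFile(str(bam_path), check_sq=False) as bam:
        for read in bam:
            report["input_records"] += 1
            if (
                not read.is_proper_pair
                or read.is_unmapped
                or read.mate_is_unmapped
                or read.is_secondary
                or read.is_supplementary
            ):
                report["dropped_flags"] += 1
                continue
            if read.mapping_quality < min_mapq:
                report["dropped_mapq"] += 1
                continue
            if exclude_contigs.search(read.reference_name or ""):
                report["dropped_contig"] += 1
                continue
            barcode = _barcode_of(read, barcode_tag)
            if barcode is None:
                report["dropped_no_barcode"] += 1
                continue
            key = read.query_name
            mate = pending.pop(key, None)
            if mate is None:
                pending[key] = (barcode, read.reference_name, read.reference_start, read.reference_end)
                report["kept_records"] += 1
                continue
            report["kept_records"] += 1
            m_barcode, m_chrom, m_start, m_end = mate
            if m_chrom != read.reference_name:
                report["kept_records"] -= 2
                report["dropped_flags"] += 2
                continue
            start = min(m_start, read.reference_start)
            end = max(m_end, read.reference_end)
            if end - start > max_fragment_length:
                report["kept_records"] -= 2
                report["dropped_too_long"] += 2
                continue
            pairs.append((m_barcode, m_chrom, start, end, key))
    # mates whose partner never passed the filters cannot form a fragment
    report["kept_records"] -= len(pending)
    report["dropped_unpaired_mate"] += len(pending)
    return pairs, report


def deduplicate_fragments(pairs: Iterable[tuple], seed: int = 0) -> list:
    """Collapse pairs sharing (barcode, chrom, start, end) to one record each.

    ``dup_count`` records the multiplicity; the representative read name is
    chosen uniformly with the given seed (counts and coordinates never depend
    on it). Output is sorted by (chrom, start, end, barcode).
    """
    rng = np.random.default_rng(seed)
    groups: dict = {}
    for barcode, chrom, start, end, name in pairs:
        groups.setdefault((chrom, start, end, barcode), []).append(name)
    records = []
    for (chrom, start, end, barcode) in sorted(groups):
        names = groups[(chrom, start, end, barcode)]
        rng.choice(len(names))  # representative draw; identity not carried in BED
        records.append(FragmentRecord(chrom, start, end, barcode, dup_count=len(names)))
    return records


def species_of(chrom: str) -> str:
    """Species prefix of a hybrid-genome contig name (text before first '_')."""
    if "_" not in chrom:
        raise ValueError(f"contig {chrom!r} carries no species prefix")
    return chrom.split("_", 1)[0]


def count_species(fragments: pd.DataFrame) -> pd.DataFrame:
    """Partition each barcode's unique fragments by species.

    Returns a DataFrame indexed by barcode with one column per species plus
    ``total_unique``; the species columns sum exactly to the total.
    """
    if fragments.empty:
        return pd.DataFrame(columns=["total_unique"])
    bad = [c for c in fragments["chrom"].unique() if "_" not in c]
    if bad:
        raise ValueError(f"contigs without species prefix: {bad}")
    df = fragments.assign(species=fragments["chrom"].map(species_of))
    counts = df.groupby(["barcode", "species"]).size().unstack(fill_value=0)
    counts.columns.name = None
    counts["total_unique"] = counts.sum(axis=1)
    return counts


def write_fragments(records: Iterable[FragmentRecord], path) -> None:
    """Write a fragments BED (chrom, start, end, barcode, dup_count)."""
    with open(path, "w") as fh:
        for r in records:
            fh.write(f"{r.chrom}\t{r.start}\t{r.end}\t{r.barcode}\t{r.dup_count}\n")


def read_fragments(path) -> pd.DataFrame:
    """Read a fragments BED into a DataFrame."""
    df = pd.read_csv(
        path,
        sep="\t",
        header=None,
        names=FRAGMENT_COLUMNS,
        dtype={"chrom": str, "start": int, "end": int, "barcode": str, "dup_count": int},
    )
    return df


def records_to_frame(records: Iterable[FragmentRecord]) -> pd.DataFrame:
    rows = [(r.chrom, r.start, r.end, r.barcode, r.dup_count) for r in records]
    return pd.DataFrame(rows, columns=FRAGMENT_COLUMNS)


def fragments_from_bam(bam_path, out_path=None, seed: int = 0, **filter_kwargs):
    """End-to-end BAM -> deduplicated fragments convenience wrapper."""
    pairs, report = filter_alignments(bam_path, **filter_kwargs)
    records = deduplicate_fragments(pairs, seed=seed)
    if out_path is not None:
        write_fragments(records, out_path)
        with open(Path(out_path).with_suffix(".report.json"), "w") as fh:
            json.dump(report, fh, indent=2)
    return records, report
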