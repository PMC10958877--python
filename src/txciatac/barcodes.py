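"""Barcode extraction, error correction, and sample demultiplexing.

Reads carry three barcode levels: an i7 sample index (index read 1), a droplet
GEM bead barcode (index read 2), and an 8 bp Tn5 pre-index at the start of
read 2 followed by the 19 bp mosaic-end spacer. Each level is corrected
against its whitelist; reads whose observed barcode matches more than one
whitelist entry within the allowed distance are discarded as ambiguous.
"""

from __future__ import annotations

import gzip
import json
from dataclasses import dataclass
from pathlib import Path
from typing import Iterator, Optional, TextIO

__all__ = [
    "BarcodeWhitelist",
    "ReadAnnotation",
    "TN5_LEN",
    "MOSAIC_END",
    "extract_tn5",
    "correct_barcode",
    "build_combined_barcode",
    "split_combined_barcode",
    "demultiplex",
    "read_whitelist",
    "read_sample_sheet",
]

TN5_LEN = 8
#: Canonical Tn5 mosaic-end recognition sequence trimmed from read 2.
MOSAIC_END = "AGATGTGTATAAGAGACAG"
_TRIM = TN5_LEN + len(MOSAIC_END)  # 27 bp

OK = "ok"
UNCORRECTABLE = "uncorrectable"
AMBIGUOUS = "ambiguous"


@dataclass(frozen=True)
class BarcodeWhitelist:
    """A fixed-length barcode whitelist for one level."""

    level: str  # one of {"tn5", "gem", "i7"}
    entries: frozenset

    def __post_init__(self) -> None:
        if not self.entries:
            raise ValueError(f"empty whitelist for level {self.level!r}")
        lengths = {len(e) for e in self.entries}
        if len(lengths) != 1:
            raise ValueError(f"mixed barcode lengths in {self.level!r} whitelist: {lengths}")
        bad = {e for e in self.entries if set(e) - set("ACGT")}
        if bad:
            raise ValueError(f"non-ACGT barcodes in {self.level!r} whitelist: {sorted(bad)[:3]}")

    @property
    def length(self) -> int:
        return len(next(iter(self.entries)))


@dataclass
class ReadAnnotation:
    read_id: str
    i7: Optional[str]
    gem: Optional[str]
    tn5: Optional[str]
    status: str

    @property
    def ok(self) -> bool:
        return self.status == OK


def extract_tn5(read2_seq: str, read2_qual: Optional[str] = None):
    """Split read 2 into its raw Tn5 barcode and the genomic portion.

    The first 8 bp are the Tn5 barcode; bases 8-27 are the mosaic end and are
    discarded; the remainder is genomic. Returns
    ``(tn5_raw, genomic_seq, genomic_qual)``; a read not longer than 27 bp
    yields ``(None, None, None)`` so callers can mark it uncorrectable rather
    than silently truncate.
    """
    if len(read2_seq) <= _TRIM:
        return None, None, None
    tn5 = read2_seq[:TN5_LEN]
    genomic = read2_seq[_TRIM:]
    qual = read2_qual[_TRIM:] if read2_qual is not None else None
    return tn5, genomic, qual


def _hamming(a: str, b: str) -> int:
    return sum(x != y for x, y in zip(a, b))


def _levenshtein(a: str, b: str) -> int:
    prev = list(range(len(b) + 1))
    for i, ca in enumerate(a, 1):
        cur = [i]
        for j, cb in enumerate(b, 1):
            cur.append(min(prev[j] + 1, cur[-1] + 1, prev[j - 1] + (ca != cb)))
        prev = cur
    return prev[-1]


def correct_barcode(
    observed: str,
    whitelist: BarcodeWhitelist,
    max_dist: int = 2,
    metric: str = "hamming",
):
    """Correct an observed barcode against a whitelist.

    An exact whitelist match is accepted outright. Otherwise, if exactly one
    whitelist entry lies within ``max_dist`` it is returned; if several do the
    read is ambiguous (ties are never broken); if none do it is
    uncorrectable. With the default Hamming metric a length mismatch is
    uncorrectable. Returns ``(barcode_or_None, status)``.
    """
    if observed in whitelist.entries:
        return observed, OK
    if metric == "hamming":
        if len(observed) != whitelist.length:
            return None, UNCORRECTABLE
        dist = _hamming
    elif metric == "levenshtein":
        dist = _levenshtein
    else:
        raise ValueError(f"unknown metric {metric!r}")
    candidates = [e for e in whitelist.entries if dist(observed, e) <= max_dist]
    if not candidates:
        return None, UNCORRECTABLE
    if len(candidates) > 1:
        return None, AMBIGUOUS
    return candidates[0], OK


def build_combined_barcode(i7: str, gem: str, tn5: str) -> str:
    """Concatenate the three corrected barcodes as ``i7 | gem | tn5``."""
    for name, value in (("i7", i7), ("gem", gem), ("tn5", tn5)):
        if not value:
            raise ValueError(f"missing {name} barcode component")
    return i7 + gem + tn5


def split_combined_barcode(combined: str, i7_len: int, gem_len: int):
    """Invert :func:`build_combined_barcode` given the component lengths."""
    return (
        combined[:i7_len],
        combined[i7_len : i7_len + gem_len],
        combined[i7_len + gem_len :],
    )


# ---------------------------------------------------------------------------
# FASTQ plumbing


def _open_text(path, mode: str = "rt") -> TextIO:
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, mode)
    return open(path, mode)


def iter_fastq(path) -> Iterator[tuple]:
    """Yield ``(read_id, sequence, quality)`` from a 4-line FASTQ file."""
    with _open_text(path) as fh:
        while True:
            header = fh.readline()
            if not header:
                return
            seq = fh.readline().rstrip("\n")
            fh.readline()
            qual = fh.readline().rstrip("\n")
            yield header.rstrip("\n")[1:].split()[0], seq, qual


def write_fastq_record(fh: TextIO, read_id: str, seq: str, qual: str) -> None:
    fh.write(f"@{read_id}\n{seq}\n+\n{qual}\n")


def read_whitelist(path, level: str) -> BarcodeWhitelist:
    """Load a one-barcode-per-line whitelist file."""
    with _open_text(path) as fh:
        entries = frozenset(line.strip() for line in fh if line.strip())
    return BarcodeWhitelist(level=level, entries=entries)


def read_sample_sheet(path) -> dict:
    """Parse a TSV sample sheet of ``sample <tab> i7 <tab> tn5,tn5,...``.

    Returns a mapping ``(i7, tn5) -> sample``. Overlapping well assignments
    across samples raise before any read is processed.
    """
    assignments: dict = {}
    with _open_text(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            sample, i7, wells = line.split("\t")
            for tn5 in wells.split(","):
                key = (i7, tn5)
                if key in assignments and assignments[key] != sample:
                    raise ValueError(
                        f"well {key} assigned to both {assignments[key]!r} and {sample!r}"
                    )
                assignments[key] = sample
    if not assignments:
        raise ValueError(f"empty sample sheet: {path}")
    return assignments


class _CachedCorrector:
    """Memoized wrapper so each distinct observed barcode is corrected once."""

    def __init__(self, whitelist: BarcodeWhitelist, max_dist: int, metric: str):
        self.whitelist = whitelist
        self.max_dist = max_dist
        self.metric = metric
        self._cache: dict = {}

    def __call__(self, observed: str):
        hit = self._cache.get(observed)
        if hit is None:
            hit = correct_barcode(observed, self.whitelist, self.max_dist, self.metric)
            self._cache[observed] = hit
        return hit


def demultiplex(
    r1_path,
    r2_path,
    i1_path,
    i2_path,
    whitelists: dict,
    sample_sheet: dict,
    out_dir,
    max_dist: int = 2,
    metric: str = "hamming",
) -> dict:
    """Demultiplex a run into per-sample FASTQ pairs with combined barcodes.

    ``whitelists`` maps level name -> :class:`BarcodeWhitelist`;
    ``sample_sheet`` maps ``(i7, tn5) -> sample``. Every read with all three
    barcodes corrected (status ``ok``) and a sample-sheet entry is written to
    ``<out_dir>/<sample>_R{1,2}.fastq`` with the combined barcode appended to
    the read name after a ``:`` delimiter. Returns a JSON-serializable report
    whose per-category counts sum to the input read count.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    correctors = {
        level: _CachedCorrector(whitelists[level], max_dist, metric)
        for level in ("i7", "gem", "tn5")
    }
    report = {
        "total_reads": 0,
        "ok": 0,
        "ambiguous": 0,
        "uncorrectable": 0,
        "unassigned_ok": 0,
        "per_level": {lv: {OK: 0, AMBIGUOUS: 0, UNCORRECTABLE: 0} for lv in ("i7", "gem", "tn5")},
        "per_sample": {},
    }
    handles: dict = {}

    def sample_handles(sample: str):
        if sample not in handles:
            handles[sample] = (
                open(out_dir / f"{sample}_R1.fastq", "w"),
                open(out_dir / f"{sample}_R2.fastq", "w"),
            )
        return handles[sample]

    try:
        for (rid1, s1, q1), (rid2, s2, q2), (_, i1_seq, _), (_, i2_seq, _) in zip(
            iter_fastq(r1_path), iter_fastq(r2_path), iter_fastq(i1_path), iter_fastq(i2_path)
        ):
            report["total_reads"] += 1
            tn5_raw, genomic, gqual = extract_tn5(s2, q2)
            i7, st_i7 = correctors["i7"](i1_seq)
            gem, st_gem = correctors["gem"](i2_seq)
            if tn5_raw is None:  # too short to carry barcode + mosaic end
                tn5, st_tn5 = None, UNCORRECTABLE
            else:
                tn5, st_tn5 = correctors["tn5"](tn5_raw)
            statuses = {"i7": st_i7, "gem": st_gem, "tn5": st_tn5}
            for lv, st in statuses.items():
                report["per_level"][lv][st] += 1
            if all(st == OK for st in statuses.values()):
                sample = sample_sheet.get((i7, tn5))
                if sample is None:
                    report["unassigned_ok"] += 1
                    continue
                report["ok"] += 1
                report["per_sample"][sample] = report["per_sample"].get(sample, 0) + 1
                combined = build_combined_barcode(i7, gem, tn5)
                name = f"{rid1}:{combined}"
                fh1, fh2 = sample_handles(sample)
                write_fastq_record(fh1, name, s1, q1)
                write_fastq_record(fh2, name, genomic, gqual)
            elif AMBIGUOUS in statuses.values():
                report["ambiguous"] += 1
            else:
                report["uncorrectable"] += 1
    finally:
        for fh1, fh2 in handles.values():
            fh1.close()
            fh2.close()
    with open(out_dir / "demux_report.json", "w") as fh:
        json.dump(report, fh, indent=2)
    return report
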