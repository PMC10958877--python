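"""Shared fixtures: small synthetic datasets and a SAM builder."""

from __future__ import annotations

import pytest

from txciatac import fixtures as fx


@pytest.fixture(scope="session")
def small_spec() -> fx.FixtureSpec:
    return fx.FixtureSpec(seed=11, n_cells=40)


@pytest.fixture(scope="session")
def whitelists(small_spec):
    return fx.make_barcode_whitelists(small_spec)


SAM_HEADER = (
    "@HD\tVN:1.6\tSO:unsorted\n"
    "@SQ\tSN:hg_toy\tLN:50000\n"
    "@SQ\tSN:mm_toy\tLN:50000\n"
    "@SQ\tSN:hg_chrM\tLN:16000\n"
)


def make_sam_pair(
    name: str,
    chrom: str,
    start: int,
    end: int,
    barcode: str,
    mapq: int = 30,
    read_len: int = 50,
    proper: bool = True,
):
    """Two SAM lines for one paired fragment [start, end) in BED coordinates."""
    flag1 = 99 if proper else 97  # proper pair bit toggled
    flag2 = 147 if proper else 145
    pos1 = start + 1  # SAM is 1-based
    pos2 = end - read_len + 1
    tlen = end - start
    seq = "A" * read_len
    qual = "I" * read_len
    cb = f"CB:Z:{barcode}"
    line1 = f"{name}\t{flag1}\t{chrom}\t{pos1}\t{mapq}\t{read_len}M\t=\t{pos2}\t{tlen}\t{seq}\t{qual}\t{cb}"
    line2 = f"{name}\t{flag2}\t{chrom}\t{pos2}\t{mapq}\t{read_len}M\t=\t{pos1}\t{-tlen}\t{seq}\t{qual}\t{cb}"
    return line1 + "\n" + line2 + "\n"


@pytest.fixture
def sam_file(tmp_path):
    """Factory writing a SAM file from pair specs."""

    def build(pair_blocks, path_name="reads.sam"):
        path = tmp_path / path_name
        path.write_text(SAM_HEADER + "".join(pair_blocks))
        return path

    return build
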