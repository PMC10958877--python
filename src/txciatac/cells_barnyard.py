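"""Cell calling, species classification, and collision-rate estimation.

A barnyard design mixes cells of two species so that barcode collisions
(one barcode covering two or more cells) surface as mixed-species profiles.
Only heterotypic collisions are directly observable; under random pairing at
species proportions (p, q) they represent a fraction ``2 p q`` of all
collisions, so the observed rate is corrected by dividing by that factor.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.cluster import KMeans

__all__ = [
    "CellCall",
    "call_cells_fixed",
    "call_cells_kmeans",
    "classify_species",
    "estimate_collision_rate",
    "merge_bead_multiplets",
    "group_map_from_lists",
]

COLLISION = "collision"
PURITY_THRESHOLD = 0.9


@dataclass
class CellCallResult:
    calls: pd.DataFrame  # barcode-indexed: total_unique, is_cell
    threshold: float
    method: str


def call_cells_fixed(counts: pd.Series, min_reads: int = 1000) -> CellCallResult:
    """Fixed-threshold cell calling: a barcode is a cell iff its unique-read
    count is at least ``min_reads``."""
    counts = counts.astype(int)
    if (counts < 0).any():
        raise ValueError("negative counts")
    calls = pd.DataFrame({"total_unique": counts, "is_cell": counts >= min_reads})
    return CellCallResult(calls=calls, threshold=float(min_reads), method="fixed")


def call_cells_kmeans(
    counts: pd.Series,
    min_reads_floor: int = 100,
    k: int = 2,
    n_init: int = 50,
    seed: int = 0,
) -> CellCallResult:
    """Automatic cell threshold by 1-D k-means on log10 unique-read counts.

    Barcodes below ``min_reads_floor`` are excluded from clustering (and never
    called cells). Cells are the members of the higher-mean cluster; the
    reported threshold is that cluster's minimum count.
    """
    counts = counts.astype(int)
    eligible = counts[counts >= min_reads_floor]
    if len(eligible) < 2:
        raise ValueError("need at least two barcodes above the floor for k-means")
    x = np.log10(eligible.to_numpy(dtype=float)).reshape(-1, 1)
    if np.allclose(x, x[0]):
        raise ValueError("degenerate counts (all equal); use a fixed threshold instead")
    km = KMeans(n_clusters=k, n_init=n_init, random_state=seed).fit(x)
    top = int(np.argmax(km.cluster_centers_.ravel()))
    in_top = km.labels_ == top
    threshold = float(eligible.to_numpy()[in_top].min())
    is_cell = pd.Series(False, index=counts.index)
    is_cell.loc[eligible.index[in_top]] = True
    calls = pd.DataFrame({"total_unique": counts, "is_cell": is_cell})
    res = CellCallResult(calls=calls, threshold=threshold, method="kmeans")
    res.cluster_means = np.sort(km.cluster_centers_.ravel())  # log10 space
    return res


def classify_species(
    species_counts: pd.DataFrame,
    purity: float = PURITY_THRESHOLD,
) -> pd.DataFrame:
    """Label each cell barcode by its major species or as a collision.

    ``species_counts`` is the output of :func:`txciatac.fragments.count_species`
    restricted to called cells: one column per species plus ``total_unique``.
    A barcode is a bona fide single cell iff at least ``purity`` of its reads
    come from one species; otherwise it is a collision. No pseudo-counts enter
    the classification.
    """
    species_cols = [c for c in species_counts.columns if c != "total_unique"]
    mat = species_counts[species_cols].to_numpy(dtype=float)
    totals = mat.sum(axis=1)
    if (totals == 0).any():
        raise ValueError("barcodes with zero reads cannot be classified")
    major_idx = mat.argmax(axis=1)
    major_fraction = mat.max(axis=1) / totals
    labels = np.where(
        major_fraction >= purity,
        np.asarray(species_cols, dtype=object)[major_idx],
        COLLISION,
    )
    return pd.DataFrame(
        {"major_fraction": major_fraction, "label": labels},
        index=species_counts.index,
    )


def estimate_collision_rate(
    species_calls: pd.DataFrame,
    mix_proportions=None,
) -> dict:
    """Correct the observed heterotypic collision fraction for cryptic
    same-species collisions.

    Under random pairing at species proportions (p, q), heterotypic doublets
    are a ``2 p q`` share of all doublets, so
    ``corrected = observed / (2 p q)``, capped at 1. With a 50/50 mix this
    doubles the observed rate. ``mix_proportions`` defaults to the proportions
    observed among non-collision cells.
    """
    n_cells = len(species_calls)
    if n_cells == 0:
        raise ValueError("no cells to estimate from")
    n_het = int((species_calls["label"] == COLLISION).sum())
    observed = n_het / n_cells
    if mix_proportions is None:
        singles = species_calls.loc[species_calls["label"] != COLLISION, "label"]
        shares = singles.value_counts(normalize=True)
        if len(shares) < 2:
            raise ValueError("cannot infer mix proportions from a single species")
        p = float(shares.iloc[0])
        q = 1.0 - p
    else:
        p, q = float(mix_proportions[0]), float(mix_proportions[1])
        if not np.isclose(p + q, 1.0):
            raise ValueError("mix proportions must sum to 1")
    if p <= 0 or q <= 0:
        raise ValueError("heterotypic collisions unobservable at a pure mix")
    corrected = min(1.0, observed / (2.0 * p * q))
    return {
        "n_cells": n_cells,
        "n_heterotypic": n_het,
        "observed_rate": observed,
        "mix_proportions": (p, q),
        "corrected_rate": corrected,
    }


def group_map_from_lists(groups: dict) -> dict:
    """Invert ``group -> [bead barcodes]`` to ``bead -> group``, rejecting
    beads listed in more than one group."""
    bead_to_group: dict = {}
    for group, beads in groups.items():
        for bead in beads:
            if bead in bead_to_group and bead_to_group[bead] != group:
                raise ValueError(f"bead barcode {bead!r} assigned to two groups")
            bead_to_group[bead] = group
    return bead_to_group


def merge_bead_multiplets(
    fragments: pd.DataFrame,
    group_map: dict,
    tn5_len: int = 8,
) -> pd.DataFrame:
    """Merge bead barcodes inferred to share a droplet, then re-deduplicate.

    Fragment barcodes are ``bead + tn5`` strings; the bead component (all but
    the last ``tn5_len`` bases) is replaced by its droplet-group id while the
    Tn5 component is preserved. Fragments that become identical under the
    merged key are collapsed (dup_counts summed), so unique counts never
    increase.
    """
    bead = fragments["barcode"].str[:-tn5_len]
    tn5 = fragments["barcode"].str[-tn5_len:]
    merged_barcode = bead.map(lambda b: group_map.get(b, b)) + tn5
    out = fragments.assign(barcode=merged_barcode)
    out = (
        out.groupby(["chrom", "start", "end", "barcode"], as_index=False)["dup_count"]
        .sum()
        .sort_values(["chrom", "start", "end", "barcode"], ignore_index=True)
    )
    return out[["chrom", "start", "end", "barcode", "dup_count"]]
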