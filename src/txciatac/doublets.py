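"""Simulated-doublet detection on a binarized cells x peaks matrix.

The workflow: filter the binary matrix (peaks first, then cells), transform
with log(TF x IDF), fit a 30-component projection on observed cells only,
project simulated doublets (binarized sums of random cell pairs) into that
space, L2-normalize, count simulated-doublet neighbors among k_adj nearest
neighbors in components 2..30, convert the neighbor fraction to a doublet
score, and threshold using a two-component Gaussian mixture fit to the
simulated-cell scores.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd
from scipy import sparse
from sklearn.decomposition import PCA
from sklearn.mixture import GaussianMixture
from sklearn.neighbors import NearestNeighbors

__all__ = [
    "BinaryMatrix",
    "binarize_matrix",
    "filter_matrix",
    "tfidf_log",
    "simulate_doublets",
    "adjusted_k",
    "embed_and_score",
    "threshold_scores",
    "detect_doublets",
]

TFIDF_SCALE = 1e4
DEFAULT_EXPECTED_RATE = 0.1
SIM_RATIO = 0.5  # simulated doublets per observed cell


@dataclass
class BinaryMatrix:
    """Cells x peaks binary accessibility matrix with filtering provenance."""

    values: sparse.csr_matrix
    cells: list
    peaks: list
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.values = sparse.csr_matrix(self.values)
        if self.values.shape != (len(self.cells), len(self.peaks)):
            raise ValueError("matrix shape does not match cell/peak labels")


def filter_matrix(
    values: sparse.spmatrix,
    cells: list,
    peaks: list,
    min_cells: int = 50,
    min_features: int = 200,
) -> BinaryMatrix:
    """Binarize then drop low-support peaks and low-complexity cells.

    Peaks present in fewer than ``min_cells`` cells are removed first; cells
    with fewer than ``min_features`` remaining peaks are removed second (the
    order matters and is recorded in provenance).
    """
    x = sparse.csr_matrix(values)
    x.data = np.ones_like(x.data)
    peak_support = np.asarray((x > 0).sum(axis=0)).ravel()
    keep_peaks = peak_support >= min_cells
    x = x[:, keep_peaks]
    cell_features = np.asarray((x > 0).sum(axis=1)).ravel()
    keep_cells = cell_features >= min_features
    x = x[keep_cells, :]
    if x.shape[0] == 0 or x.shape[1] == 0:
        raise ValueError(
            f"empty matrix after filtering: {int(keep_cells.sum())} cells x "
            f"{int(keep_peaks.sum())} peaks (min_cells={min_cells}, min_features={min_features})"
        )
    return BinaryMatrix(
        values=x,
        cells=[c for c, k in zip(cells, keep_cells) if k],
        peaks=[p for p, k in zip(peaks, keep_peaks) if k],
        provenance={
            "min_cells": min_cells,
            "min_features": min_features,
            "order": "peaks_then_cells",
            "n_cells_in": len(cells),
            "n_peaks_in": len(peaks),
        },
    )


def binarize_matrix(
    fragments: pd.DataFrame,
    peaks: pd.DataFrame,
    min_cells: int = 50,
    min_features: int = 200,
) -> BinaryMatrix:
    """Build the binary cells x peaks matrix from fragments and peak intervals.

    An entry is 1 iff at least one fragment of the cell overlaps the peak by
    >= 1 bp. Peaks must already be merged and blacklist-free.
    """
    peaks = peaks.reset_index(drop=True)
    barcodes = sorted(fragments["barcode"].unique())
    bc_idx = {b: i for i, b in enumerate(barcodes)}
    rows, cols = [], []
    for chrom, peak_grp in peaks.groupby("chrom"):
        frags = fragments[fragments["chrom"] == chrom]
        if frags.empty:
            continue
        p_start = peak_grp["start"].to_numpy()
        p_end = peak_grp["end"].to_numpy()
        p_ids = peak_grp.index.to_numpy()
        f_start = frags["start"].to_numpy()
        f_end = frags["end"].to_numpy()
        f_bc = frags["barcode"].to_numpy()
        lo = np.searchsorted(p_end, f_start, side="right")
        hi = np.searchsorted(p_start, f_end, side="left")
        for s, e, bc in zip(lo, hi, f_bc):
            for j in range(s, e):
                rows.append(bc_idx[bc])
                cols.append(p_ids[j])
    peak_names = [f"{c}:{s}-{e}" for c, s, e in zip(peaks["chrom"], peaks["start"], peaks["end"])]
    mat = sparse.csr_matrix(
        (np.ones(len(rows)), (rows, cols)), shape=(len(barcodes), len(peaks))
    )
    mat.data = np.ones_like(mat.data)  # collapse duplicate entries to 1
    return filter_matrix(mat, barcodes, peak_names, min_cells=min_cells, min_features=min_features)


def tfidf_log(
    matrix: sparse.spmatrix,
    idf: Optional[np.ndarray] = None,
    scale: float = TFIDF_SCALE,
    raw: bool = False,
):
    """log(TF x IDF) transform.

    TF is each entry divided by its cell's total; IDF is
    ``n_cells / n_cells_with_peak`` (computed from ``matrix`` unless an
    external ``idf`` is supplied, e.g. the observed matrix's IDF when
    transforming simulated doublets). The default returns
    ``log1p(scale * TF * IDF)``; ``raw=True`` returns ``log(TF * IDF)`` on the
    nonzero entries.

    Returns ``(transformed csr matrix, idf vector)``.
    """
    x = sparse.csr_matrix(matrix, dtype=float)
    row_sums = np.asarray(x.sum(axis=1)).ravel()
    if (row_sums == 0).any():
        raise ValueError("zero rows present; filter cells first")
    if idf is None:
        doc_freq = np.asarray((x > 0).sum(axis=0)).ravel()
        if (doc_freq == 0).any():
            raise ValueError("zero columns present; filter peaks first")
        idf = x.shape[0] / doc_freq
    tf = sparse.diags(1.0 / row_sums) @ x
    tfidf = tf @ sparse.diags(idf)
    out = tfidf.tocsr()
    if raw:
        out.data = np.log(out.data)
    else:
        out.data = np.log1p(scale * out.data)
    return out, np.asarray(idf, dtype=float)


def simulate_doublets(matrix: sparse.spmatrix, seed: int = 0) -> sparse.csr_matrix:
    """Create ``floor(n_cells / 2)`` simulated doublets as binarized sums
    (element-wise OR) of two distinct randomly sampled cells."""
    x = sparse.csr_matrix(matrix)
    n = x.shape[0]
    if n < 4:
        raise ValueError("need at least 4 cells to simulate doublets")
    rng = np.random.default_rng(seed)
    n_sim = n // 2
    a = rng.integers(0, n, size=n_sim)
    b = rng.integers(0, n, size=n_sim)
    clash = a == b
    while clash.any():
        b[clash] = rng.integers(0, n, size=int(clash.sum()))
        clash = a == b
    summed = x[a] + x[b]
    summed.data = np.ones_like(summed.data)
    return sparse.csr_matrix(summed)


def adjusted_k(n_obs: int, sim_ratio: float = SIM_RATIO) -> int:
    """Neighbor count adjusted for the simulated-cell share of the embedding:
    ``k_adj = round(k * (1 + r))`` with ``k = round(0.5 * sqrt(n_obs))``."""
    k = round(0.5 * np.sqrt(n_obs))
    return max(1, round(k * (1.0 + sim_ratio)))


def _scrublet_score(q: np.ndarray, rho: float, r: float) -> np.ndarray:
    """Convert simulated-neighbor fractions to doublet probabilities given the
    expected doublet rate ``rho`` and simulation ratio ``r``."""
    num = q * rho / r
    return num / (1.0 - q + num)


@dataclass
class DoubletScores:
    obs: pd.DataFrame  # index barcode; columns q, score
    sim_scores: np.ndarray
    k_adj: int
    threshold: Optional[float] = None


def embed_and_score(
    obs_tfidf: sparse.spmatrix,
    sim_tfidf: sparse.spmatrix,
    barcodes: list,
    n_components: int = 30,
    expected_rate: float = DEFAULT_EXPECTED_RATE,
    sim_ratio: float = SIM_RATIO,
    seed: int = 0,
) -> DoubletScores:
    """Project observed + simulated cells and score simulated-neighbor excess.

    The ``n_components``-dimensional projection is fit on the observed matrix
    only; simulated doublets are projected into it. All rows are
    L2-normalized, neighbors are found in components 2..n using
    ``k_adj = round(k * (1 + r))`` with ``k = round(0.5 * sqrt(n_obs))``, and
    ``q = (n_sim_neighbors + 1) / (k_adj + 2)`` feeds the doublet-score
    formula.
    """
    obs = sparse.csr_matrix(obs_tfidf)
    sim = sparse.csr_matrix(sim_tfidf)
    n_obs, n_sim = obs.shape[0], sim.shape[0]
    rank_cap = min(obs.shape) - 1
    if n_components > rank_cap:
        warnings.warn(f"reducing n_components from {n_components} to {rank_cap}")
        n_components = rank_cap
    pca = PCA(n_components=n_components, random_state=seed)
    obs_proj = pca.fit_transform(obs.toarray())
    sim_proj = pca.transform(sim.toarray())
    combined = np.vstack([obs_proj, sim_proj])
    norms = np.linalg.norm(combined, axis=1, keepdims=True)
    norms[norms == 0] = 1.0
    combined = combined / norms
    space = combined[:, 1:]  # components 2..n
    k_adj = adjusted_k(n_obs, sim_ratio)
    nn = NearestNeighbors(n_neighbors=k_adj + 1).fit(space)
    _, idx = nn.kneighbors(space)
    idx = idx[:, 1:]  # drop self
    is_sim = idx >= n_obs
    q = (is_sim.sum(axis=1) + 1.0) / (k_adj + 2.0)
    scores = _scrublet_score(q, expected_rate, sim_ratio)
    obs_df = pd.DataFrame({"q": q[:n_obs], "score": scores[:n_obs]}, index=pd.Index(barcodes, name="barcode"))
    return DoubletScores(obs=obs_df, sim_scores=scores[n_obs:], k_adj=k_adj)


def threshold_scores(
    sim_scores: np.ndarray,
    posterior: float = 0.95,
    n_restarts: int = 10,
    seed: int = 0,
):
    """Doublet-score threshold from a 2-component Gaussian mixture fit to the
    simulated-cell scores.

    The threshold is the smallest score whose posterior membership in the
    higher-mean ("neotypic") component reaches ``posterior``. Degenerate fits
    (indistinguishable components) fall back to the 95th percentile with a
    warning. Returns ``(threshold, used_fallback)``.
    """
    sim_scores = np.asarray(sim_scores, dtype=float)
    if sim_scores.size < 50:
        raise ValueError("need >= 50 simulated scores to fit the mixture")
    x = sim_scores.reshape(-1, 1)
    if np.allclose(sim_scores, sim_scores[0]):
        warnings.warn("identical simulated scores; falling back to 95th percentile")
        return float(np.percentile(sim_scores, 95)), True
    best = None
    for i in range(n_restarts):
        gm = GaussianMixture(n_components=2, random_state=seed + i, n_init=1)
        try:
            gm.fit(x)
        except ValueError:
            continue
        if best is None or gm.lower_bound_ > best.lower_bound_:
            best = gm
    if best is None:
        warnings.warn("mixture fit failed; falling back to 95th percentile")
        return float(np.percentile(sim_scores, 95)), True
    means = best.means_.ravel()
    sds = np.sqrt(best.covariances_.ravel())
    if abs(means[0] - means[1]) < 1e-6 * max(sds.max(), 1e-12) or abs(means[0] - means[1]) < 1e-9:
        warnings.warn("mixture components indistinguishable; falling back to 95th percentile")
        return float(np.percentile(sim_scores, 95)), True
    hi = int(np.argmax(means))
    grid = np.linspace(sim_scores.min(), sim_scores.max(), 4001)
    post = best.predict_proba(grid.reshape(-1, 1))[:, hi]
    crossing = np.nonzero(post >= posterior)[0]
    # keep only the contiguous high-score block (posterior can also exceed the
    # cutoff in a low-score tail when variances differ wildly)
    valid = crossing[grid[crossing] > means.min()]
    if valid.size == 0:
        warnings.warn("no posterior crossing found; falling back to 95th percentile")
        return float(np.percentile(sim_scores, 95)), True
    return float(grid[valid[0]]), False


def detect_doublets(
    matrix: BinaryMatrix,
    seed: int = 0,
    expected_rate: float = DEFAULT_EXPECTED_RATE,
    n_components: int = 30,
) -> DoubletScores:
    """Full pipeline: TF-IDF, simulate, embed, score, and threshold."""
    obs_tfidf, idf = tfidf_log(matrix.values)
    sim = simulate_doublets(matrix.values, seed=seed)
    sim_tfidf, _ = tfidf_log(sim, idf=idf)
    result = embed_and_score(
        obs_tfidf,
        sim_tfidf,
        matrix.cells,
        n_components=n_components,
        expected_rate=expected_rate,
        seed=seed,
    )
    threshold, _ = threshold_scores(result.sim_scores, seed=seed)
    result.threshold = threshold
    result.obs["is_doublet"] = result.obs["score"] >= threshold
    return result
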