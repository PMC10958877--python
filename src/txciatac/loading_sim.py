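"""Poisson droplet-loading model for molecular vs. cellular hashing.

Molecular hashing pre-indexes nuclei with one of ``m`` Tn5 barcodes before
droplet encapsulation, so multi-cell droplets remain deconvolutable as long as
no barcode is duplicated within the droplet. Cellular hashing labels whole
cells, so any multi-cell droplet must be discarded. This module provides the
duplicate-barcode probability, the per-droplet occupancy cap implied by a
duplicate tolerance, closed-form and Monte Carlo expected usable-cell counts,
and a loading-input optimizer.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from scipy import optimize, stats

__all__ = [
    "DropletModel",
    "SimResult",
    "duplicate_prob",
    "occupancy_cap",
    "expected_usable",
    "simulate_loading_mc",
    "optimize_loading",
]

#: Occupancy ceiling used when truncating infinite Poisson sums; the tail mass
#: beyond this occupancy is negligible for any lambda reachable in practice.
_MAX_OCCUPANCY = 200


@dataclass(frozen=True)
class DropletModel:
    """Parameters of one droplet-generator lane.

    Parameters
    ----------
    n_loaded:
        Number of nuclei loaded into the lane (``N``).
    droplets:
        Number of bead-containing droplets generated (``D``).
    loss:
        Fraction of loaded nuclei lost to dead volume, bursting, and empty
        droplets; captured nuclei per droplet are Poisson with mean
        ``lambda = N / D * (1 - loss)``.
    m:
        Number of pre-index barcodes for molecular hashing, or ``None`` for
        cellular hashing (singlet droplets only).
    p_max:
        Within-droplet duplicate-barcode probability above which a droplet is
        considered undemultiplexable (molecular hashing only).
    count_duplicated:
        If True (default), every cell in a retained molecular-hashing droplet
        counts as usable; if False, only cells whose barcode is unique within
        the droplet count.
    """

    n_loaded: float
    droplets: int = 100_000
    loss: float = 0.35
    m: Optional[int] = 96
    p_max: float = 0.10
    count_duplicated: bool = True

    def __post_init__(self) -> None:
        if self.n_loaded < 0:
            raise ValueError("n_loaded must be nonnegative")
        if not 0 <= self.loss < 1:
            raise ValueError("loss must be in [0, 1)")
        if self.m is not None and self.m < 1:
            raise ValueError("m must be >= 1 for molecular hashing")

    @property
    def lam(self) -> float:
        """Mean captured nuclei per droplet."""
        return self.n_loaded / self.droplets * (1.0 - self.loss)

    @property
    def molecular(self) -> bool:
        return self.m is not None


@dataclass
class SimResult:
    n_loaded: float
    expected_usable: float
    expected_unusable: float
    mode: str
    seed: Optional[int] = None
    se_usable: float = 0.0

    @property
    def ratio(self) -> float:
        """Unusable-to-usable cell ratio."""
        if self.expected_usable == 0:
            return math.inf
        return self.expected_unusable / self.expected_usable


def duplicate_prob(m: int, n: int) -> float:
    """Probability that a droplet holding ``n`` cells pre-indexed from ``m``
    barcodes contains at least one duplicated barcode.

    ``P = 1 - prod_{i=0}^{n-1} (m - i)/m`` for ``n <= m``; ``P = 1`` otherwise.
    """
    if m < 1:
        raise ValueError("m must be >= 1")
    if n < 0:
        raise ValueError("n must be >= 0")
    if n <= 1:
        return 0.0
    if n > m:
        return 1.0
    prod = 1.0
    for i in range(n):
        prod *= (m - i) / m
    return 1.0 - prod


def occupancy_cap(m: int, p_max: float = 0.10) -> int:
    """Largest droplet occupancy whose duplicate probability stays within
    ``p_max``; droplets above the cap are undemultiplexable."""
    if m < 2:
        raise ValueError("m must be >= 2")
    n = 1
    while duplicate_prob(m, n + 1) <= p_max:
        n += 1
    return n


def expected_usable(model: DropletModel) -> SimResult:
    """Closed-form expected usable / unusable cells for one lane.

    Cellular hashing keeps only singlet droplets: ``usable = D * lam * e^-lam``.
    Molecular hashing keeps droplets up to the occupancy cap and counts all of
    their cells (or only unique-barcode cells when ``count_duplicated`` is
    False): ``usable = D * sum_{n=1}^{cap} w(n) * Pois(n; lam)``.
    """
    lam = model.lam
    d = model.droplets
    total = d * lam
    if lam == 0:
        return SimResult(model.n_loaded, 0.0, 0.0, mode="analytic")
    if not model.molecular:
        usable = d * lam * math.exp(-lam)
    else:
        cap = occupancy_cap(model.m, model.p_max) if model.p_max < 1 else _MAX_OCCUPANCY
        ns = np.arange(1, cap + 1)
        pmf = stats.poisson.pmf(ns, lam)
        if model.count_duplicated:
            weights = ns.astype(float)
        else:
            # expected cells with a within-droplet-unique barcode
            weights = ns * ((model.m - 1) / model.m) ** (ns - 1)
        usable = d * float(np.sum(weights * pmf))
    return SimResult(model.n_loaded, usable, total - usable, mode="analytic")


def simulate_loading_mc(model: DropletModel, seed: int, n_reps: int = 10) -> SimResult:
    """Monte Carlo counterpart of :func:`expected_usable`.

    Draws per-droplet occupancies from a Poisson distribution and applies the
    cap rule (molecular) or singlet rule (cellular), averaging over ``n_reps``
    independent lanes.
    """
    if n_reps < 1:
        raise ValueError("n_reps must be >= 1")
    rng = np.random.default_rng(seed)
    lam = model.lam
    cap = None
    if model.molecular:
        cap = occupancy_cap(model.m, model.p_max) if model.p_max < 1 else None
    usable = np.empty(n_reps)
    totals = np.empty(n_reps)
    for rep in range(n_reps):
        occ = rng.poisson(lam, size=model.droplets)
        totals[rep] = occ.sum()
        if not model.molecular:
            usable[rep] = np.count_nonzero(occ == 1)
        else:
            kept = occ if cap is None else occ[occ <= cap]
            if model.count_duplicated or model.m == 1:
                usable[rep] = kept.sum()
            else:
                counts = np.zeros(model.droplets if cap is None else kept.size)
                for j, n in enumerate(kept):
                    if n == 0:
                        continue
                    draws = rng.integers(0, model.m, size=n)
                    _, reps = np.unique(draws, return_counts=True)
                    counts[j] = np.count_nonzero(reps == 1)
                usable[rep] = counts.sum()
    mean_usable = float(usable.mean())
    se = float(usable.std(ddof=1) / math.sqrt(n_reps)) if n_reps > 1 else 0.0
    return SimResult(
        model.n_loaded,
        mean_usable,
        float(totals.mean()) - mean_usable,
        mode="monte_carlo",
        seed=seed,
        se_usable=se,
    )


@dataclass
class LoadingCurve:
    n_grid: np.ndarray
    usable: np.ndarray
    best_n: float
    best_usable: float
    results: list = field(default_factory=list)


def optimize_loading(
    template: DropletModel,
    n_grid: Optional[np.ndarray] = None,
    refine: bool = True,
) -> LoadingCurve:
    """Sweep loading inputs, returning the expected-usable curve and its
    maximizer (analytic mode; optionally refined by bounded scalar search)."""
    if n_grid is None:
        n_grid = np.arange(1_000, 1_500_001, 1_000)
    n_grid = np.asarray(n_grid, dtype=float)
    if n_grid.size == 0:
        raise ValueError("n_grid must be nonempty")

    def usable_at(n: float) -> float:
        model = DropletModel(
            n_loaded=n,
            droplets=template.droplets,
            loss=template.loss,
            m=template.m,
            p_max=template.p_max,
            count_duplicated=template.count_duplicated,
        )
        return expected_usable(model).expected_usable

    usable = np.array([usable_at(n) for n in n_grid])
    i = int(np.argmax(usable))
    best_n, best_usable = float(n_grid[i]), float(usable[i])
    if refine and 0 < i < n_grid.size - 1:
        res = optimize.minimize_scalar(
            lambda n: -usable_at(n),
            bounds=(n_grid[i - 1], n_grid[i + 1]),
            method="bounded",
        )
        if -res.fun > best_usable:
            best_n, best_usable = float(res.x), float(-res.fun)
    return LoadingCurve(n_grid=n_grid, usable=usable, best_n=best_n, best_usable=best_usable)
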