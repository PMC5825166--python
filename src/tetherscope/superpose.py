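"""Rigid superposition, RMSD/GDT deviation scores, and local-deviation flags.

Two conformations of the same domain are compared by least-squares
(Kabsch) superposition of mapped Cα atoms. Global deviation is summarized
by RMSD and by a single-threshold GDT score (percentage of residues that
fit under one rigid superposition within a 4 Å cutoff, found with a
seed-extend search). Local deviation regions are residues whose post-
superposition Cα-Cα distance exceeds the mean of the distance distribution
by more than twice its standard deviation; pairs are then categorized by
whether those regions fall on the domain-domain interface.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum

import numpy as np

__all__ = [
    "Superposition",
    "DeviationProfile",
    "DeviationCategory",
    "DegenerateGeometryError",
    "kabsch_superpose",
    "apply_superposition",
    "gdt_score",
    "significant_regions",
    "contiguous_regions",
    "classify_pair",
    "deviation_profile",
]


class DegenerateGeometryError(ValueError):
    """Point sets too small or collinear for a unique superposition."""


class DeviationCategory(str, Enum):
    INTERFACE_ONLY = "interface-only"
    NON_INTERFACE_ONLY = "non-interface-only"
    BOTH = "both"
    NONE = "none"


@dataclass(frozen=True)
class Superposition:
    """Rigid transform mapping point set b onto a: x -> rotation @ x + translation."""

    rotation: np.ndarray
    translation: np.ndarray
    rmsd: float


@dataclass
class DeviationProfile:
    """Per-residue Cα deviations of a superposed pair with summary scores."""

    distances: np.ndarray          # per mapped residue, Å
    mean: float
    sd: float                      # population sd
    flagged: list[int]             # indices into the mapped-residue list
    rmsd: float
    gdt: float

    @property
    def deviation_score(self) -> float:
        """100 - GDT: higher means more structural deviation."""
        return 100.0 - self.gdt


def kabsch_superpose(xa: np.ndarray, xb: np.ndarray) -> Superposition:
    """Optimal least-squares superposition of ``xb`` onto ``xa``.

    Standard Kabsch/SVD solution with the reflection branch excluded, so
    the returned rotation always has determinant +1. Requires at least 3
    non-collinear points in 1:1 correspondence.
    """
    xa = np.asarray(xa, float)
    xb = np.asarray(xb, float)
    if xa.shape != xb.shape or xa.ndim != 2 or xa.shape[1] != 3:
        raise ValueError("point sets must both be N x 3")
    n = xa.shape[0]
    if n < 3:
        raise DegenerateGeometryError("need at least 3 points")
    ca, cb = xa.mean(axis=0), xb.mean(axis=0)
    pa, pb = xa - ca, xb - cb
    if np.linalg.matrix_rank(pa, tol=1e-8) < 2 or np.linalg.matrix_rank(
        pb, tol=1e-8
    ) < 2:
        raise DegenerateGeometryError("points are collinear")
    h = pb.T @ pa
    u, _, vt = np.linalg.svd(h)
    d = np.sign(np.linalg.det(vt.T @ u.T))
    rot = vt.T @ np.diag([1.0, 1.0, d]) @ u.T
    trans = ca - rot @ cb
    moved = xb @ rot.T + trans
    rmsd = float(np.sqrt(np.mean(np.sum((xa - moved) ** 2, axis=1))))
    return Superposition(rotation=rot, translation=trans, rmsd=rmsd)


def apply_superposition(sup: Superposition, x: np.ndarray) -> np.ndarray:
    return np.asarray(x, float) @ sup.rotation.T + sup.translation


def _fit_subset(xa, xb, subset):
    sup = kabsch_superpose(xa[subset], xb[subset])
    return np.linalg.norm(xa - apply_superposition(sup, xb), axis=1)


def gdt_score(
    xa: np.ndarray,
    xb: np.ndarray,
    cutoff: float = 4.0,
    max_iter: int = 20,
) -> float:
    """Single-threshold GDT score in [0, 100].

    Seed-extend search in the MaxSub spirit: every contiguous window of
    lengths 4, N/4, N/2 and N seeds a superposition; each seed is then
    extended two ways — (a) iterative re-superposition on the residues
    currently within ``cutoff`` until the included set stabilizes (capped
    at ``max_iter`` rounds) and (b) greedy growth, adding the closest
    compatible residue at a time. Only self-consistent sets count toward
    the score: a set scores iff all its members lie within the cutoff
    under the superposition fitted on that same set. Ties prefer the
    larger set, then the lower RMSD over it.
    """
    xa = np.asarray(xa, float)
    xb = np.asarray(xb, float)
    n = xa.shape[0]
    if n < 4:
        raise DegenerateGeometryError("GDT needs at least 4 residues")
    lengths = sorted({4, max(4, n // 4), max(4, n // 2), n})
    best_count, best_rmsd = 0, np.inf

    def consider(members, dists):
        """Score a candidate set if it is self-consistent."""
        nonlocal best_count, best_rmsd
        members = np.asarray(members)
        if members.size < 3 or not np.all(dists[members] <= cutoff):
            return
        rmsd = float(np.sqrt(np.mean(dists[members] ** 2)))
        if members.size > best_count or (
            members.size == best_count and rmsd < best_rmsd
        ):
            best_count, best_rmsd = members.size, rmsd

    for length in lengths:
        for start in range(0, n - length + 1):
            subset = np.arange(start, start + length)
            try:
                dists = _fit_subset(xa, xb, subset)
            except DegenerateGeometryError:
                continue
            # extension A: re-superpose on everything within the cutoff
            # until the included set is stable
            included = np.flatnonzero(dists <= cutoff)
            for _ in range(max_iter):
                if included.size < 3:
                    break
                try:
                    dists = _fit_subset(xa, xb, included)
                except DegenerateGeometryError:
                    break
                consider(included, dists)
                new_included = np.flatnonzero(dists <= cutoff)
                if np.array_equal(new_included, included):
                    break
                included = new_included
            # extension B: grow the seed greedily, closest residue first,
            # keeping the grown set entirely within the cutoff
            members = list(subset)
            try:
                dists = _fit_subset(xa, xb, np.asarray(members))
            except DegenerateGeometryError:
                continue
            while True:
                member_set = set(members)
                outside = [i for i in np.argsort(dists) if i not in member_set]
                grown = False
                for cand in outside:
                    trial = np.asarray(sorted(members + [cand]))
                    try:
                        d_trial = _fit_subset(xa, xb, trial)
                    except DegenerateGeometryError:
                        continue
                    if np.all(d_trial[trial] <= cutoff):
                        members = list(trial)
                        dists = d_trial
                        grown = True
                        break
                if not grown:
                    break
            consider(np.asarray(members), dists)
    return 100.0 * best_count / n


def significant_regions(
    distances: np.ndarray, mean: float | None = None, sd: float | None = None
) -> list[int]:
    """Indices whose deviation exceeds mean + 2*sd (population sd, strict >)."""
    d = np.asarray(distances, float)
    if d.size < 2:
        raise ValueError("need at least 2 mapped residues")
    mu = float(d.mean()) if mean is None else mean
    sigma = float(d.std()) if sd is None else sd
    # absolute floor keeps pure floating-point noise (self-comparison)
    # from producing flags when the whole distribution is ~0 Å
    threshold = max(mu + 2.0 * sigma, 1e-6)
    return [int(i) for i in np.flatnonzero(d > threshold)]


def contiguous_regions(flagged: list[int]) -> list[tuple[int, int]]:
    """Group sorted flagged indices into inclusive (start, end) runs."""
    if not flagged:
        return []
    flagged = sorted(flagged)
    regions = []
    start = prev = flagged[0]
    for i in flagged[1:]:
        if i == prev + 1:
            prev = i
        else:
            regions.append((start, prev))
            start = prev = i
    regions.append((start, prev))
    return regions


def classify_pair(
    flagged: set[int] | list[int], interface: set[int] | frozenset[int]
) -> DeviationCategory:
    """Categorize a pair by where its significant deviations fall.

    The four observed categories: deviations confined to the interface,
    confined to non-interface regions, present in both, or absent.
    """
    flags = set(flagged)
    iface = set(interface)
    if not flags:
        return DeviationCategory.NONE
    on_iface = flags & iface
    off_iface = flags - iface
    if on_iface and off_iface:
        return DeviationCategory.BOTH
    if on_iface:
        return DeviationCategory.INTERFACE_ONLY
    return DeviationCategory.NON_INTERFACE_ONLY


def deviation_profile(
    xa: np.ndarray, xb: np.ndarray, gdt_cutoff: float = 4.0
) -> DeviationProfile:
    """Full deviation analysis of mapped Cα coordinate sets.

    Superposes ``xb`` onto ``xa`` over all mapped Cα (global Kabsch),
    records per-residue distances, flags the > mean + 2 sd residues and
    computes RMSD and the GDT score.
    """
    sup = kabsch_superpose(xa, xb)
    moved = apply_superposition(sup, xb)
    dists = np.linalg.norm(np.asarray(xa, float) - moved, axis=1)
    mean, sd = float(dists.mean()), float(dists.std())
    flagged = significant_regions(dists, mean, sd)
    gdt = gdt_score(xa, xb, cutoff=gdt_cutoff)
    return DeviationProfile(
        distances=dists,
        mean=mean,
        sd=sd,
        flagged=flagged,
        rmsd=sup.rmsd,
        gdt=gdt,
    )
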