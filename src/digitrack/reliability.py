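"""Reliability statistics for attention maps.

Inter-subject correlation (ISC), the permutation-based convergence-to-
stability analysis, and split-half stability.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from itertools import combinations
from typing import NamedTuple

import numpy as np

from .maps import AttentionMap, ConstantMapError, map_correlation

__all__ = [
    "ConvergenceCurve",
    "MinSubjectsResult",
    "inter_subject_correlation",
    "convergence_curve",
    "min_subjects_for_variance",
    "split_half_stability",
]

log = logging.getLogger(__name__)


@dataclass
class ConvergenceCurve:
    """Percent of variance explained by n-1 subjects of the n-subject map.

    ``pct_variance[i]`` corresponds to ``n_values[i]`` (n runs 2..N),
    averaged over ``n_permutations`` random subject orderings.
    """

    n_values: np.ndarray
    pct_variance: np.ndarray
    n_permutations: int
    image_id: str = ""
    method: str = ""

    def __post_init__(self) -> None:
        self.n_values = np.asarray(self.n_values, dtype=int)
        self.pct_variance = np.asarray(self.pct_variance, dtype=float)
        if len(self.n_values) != len(self.pct_variance):
            raise ValueError("n_values and pct_variance must match in length")
        if np.any((self.pct_variance < 0) | (self.pct_variance > 100)):
            raise ValueError("pct_variance must lie in [0, 100]")


class MinSubjectsResult(NamedTuple):
    n_subjects: int
    converged: bool


def inter_subject_correlation(maps_by_subject: list[AttentionMap]) -> float:
    """Mean Pearson correlation over all unordered subject pairs.

    Pairs involving a constant map are skipped with a warning; if every
    pair is skipped the ISC is undefined and an error is raised.
    """
    if len(maps_by_subject) < 2:
        raise ValueError("ISC needs at least 2 subjects")
    rs = []
    skipped = 0
    for i, j in combinations(range(len(maps_by_subject)), 2):
        try:
            rs.append(map_correlation(maps_by_subject[i], maps_by_subject[j]))
        except ConstantMapError:
            skipped += 1
            log.warning("ISC: skipping constant-map pair (%d, %d)", i, j)
    if not rs:
        raise ConstantMapError("all subject pairs had constant maps")
    if skipped:
        log.warning("ISC: %d of %d pairs skipped", skipped,
                    skipped + len(rs))
    return float(np.mean(rs))


def _pct_variance_curve(grids: list[np.ndarray]) -> np.ndarray:
    """For one subject ordering: 100*r^2 between cumulative means of the
    first n-1 and first n subject maps, for n = 2..N."""
    csum = np.cumsum(np.stack(grids, axis=0), axis=0)
    out = np.empty(len(grids) - 1)
    for n in range(2, len(grids) + 1):
        prev = csum[n - 2] / (n - 1)
        curr = csum[n - 1] / n
        try:
            r = map_correlation(prev, curr)
        except ConstantMapError:
            r = 0.0
        out[n - 2] = 100.0 * r * r
    return out


def convergence_curve(maps_by_subject: list[AttentionMap],
                      n_permutations: int = 40,
                      seed: int | np.random.Generator = 0,
                      image_id: str = "", method: str = "") -> ConvergenceCurve:
    """Average, over random subject orderings, of the percent of variance of
    the n-subject group map already explained by n-1 subjects.

    For each of ``n_permutations`` seeded permutations the cumulative group
    maps for 1..N subjects are formed and, for n in 2..N, 100*r^2 between
    the (n-1)- and n-subject maps is recorded; curves are averaged.
    """
    n_sub = len(maps_by_subject)
    if n_sub < 2:
        raise ValueError("convergence analysis needs at least 2 subjects")
    rng = np.random.default_rng(seed)
    grids = [m.grid for m in maps_by_subject]
    curves = np.empty((n_permutations, n_sub - 1))
    for p in range(n_permutations):
        order = rng.permutation(n_sub)
        curves[p] = _pct_variance_curve([grids[i] for i in order])
    return ConvergenceCurve(
        n_values=np.arange(2, n_sub + 1),
        pct_variance=np.clip(curves.mean(axis=0), 0.0, 100.0),
        n_permutations=n_permutations,
        image_id=image_id, method=method,
    )


def min_subjects_for_variance(curve: ConvergenceCurve,
                              level: float = 95.0) -> MinSubjectsResult:
    """Smallest n whose curve value exceeds ``level`` *and stays above it*
    for every larger n. If the curve never stabilizes above the level the
    cohort size N is returned with ``converged=False``."""
    above = curve.pct_variance > level
    # last index where the curve is NOT above the level
    not_above = np.nonzero(~above)[0]
    if len(not_above) == len(above):
        return MinSubjectsResult(int(curve.n_values[-1]), False)
    if len(not_above) == 0:
        return MinSubjectsResult(int(curve.n_values[0]), True)
    first_stable = not_above[-1] + 1
    if first_stable >= len(above):
        return MinSubjectsResult(int(curve.n_values[-1]), False)
    return MinSubjectsResult(int(curve.n_values[first_stable]), True)


def split_half_stability(maps_by_subject: list[AttentionMap], n: int,
                         n_resamples: int = 40,
                         seed: int | np.random.Generator = 0) -> float:
    """Mean correlation between group maps of two disjoint n-subject halves.

    Measures how well n subjects predict the exploration of n other
    subjects; requires 2n <= N.
    """
    n_sub = len(maps_by_subject)
    if 2 * n > n_sub:
        raise ValueError(f"2n = {2 * n} exceeds cohort size {n_sub}")
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(seed)
    grids = np.stack([m.grid for m in maps_by_subject], axis=0)
    rs = []
    for _ in range(n_resamples):
        order = rng.permutation(n_sub)
        g1 = grids[order[:n]].mean(axis=0)
        g2 = grids[order[n:2 * n]].mean(axis=0)
        rs.append(map_correlation(g1, g2))
    return float(np.mean(rs))
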