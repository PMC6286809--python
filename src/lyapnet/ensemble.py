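"""Elite selection and community combination of best-found structures.

A λ-scan yields one best-found candidate per GA run (~190 with default
settings). Rather than trusting a single winner, the final network is the
consensus of a *community*: the candidates lying in a bounded region around
the elite in the (zero-count, residual) plane. Their binarized structures
are averaged position-wise and thresholded, which empirically both improves
accuracy and stabilizes the output across repeated runs.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np

from .ga import CandidateSolution

__all__ = [
    "CommunityBounds",
    "select_elite",
    "select_community",
    "combine_structures",
]


@dataclass(frozen=True)
class CommunityBounds:
    """Bounds defining the community around the elite candidate.

    zero_tolerance: half-width of the zero-count band, as a fraction of the
        elite's zero count (default ±5%).
    residual_tolerance: the community keeps candidates whose residual is at
        least (1 − residual_tolerance) times the elite's (a lower bound only:
        the pool already consists of best-found candidates, so only
        candidates *below* the elite's residual band are suspect of
        overfitting denser structures).
    binarization_threshold: fractional support above which a position becomes
        an edge in the combined structure (default 0.5; 0.4 is looser and
        raises both TPR and FPR).
    """

    zero_tolerance: float = 0.05
    residual_tolerance: float = 0.05
    binarization_threshold: float = 0.5

    def __post_init__(self):
        if not (0.0 < self.zero_tolerance < 1.0):
            raise ValueError("zero_tolerance must be in (0, 1)")
        if not (0.0 < self.residual_tolerance < 1.0):
            raise ValueError("residual_tolerance must be in (0, 1)")
        if not (0.0 < self.binarization_threshold < 1.0):
            raise ValueError("binarization_threshold must be in (0, 1)")


def select_elite(candidates: list[CandidateSolution]) -> CandidateSolution:
    """Pick the elite candidate on joint sparsity/residual grounds.

    Among candidates whose log10-residual is at or below the median, take
    the one with the most zeros; ties broken by smaller residual, then by
    earliest run index. Deterministic.
    """
    if not candidates:
        raise ValueError("cannot select an elite from an empty candidate list")
    residuals = np.array([c.residual for c in candidates])
    med = float(np.median(residuals))
    eligible = [c for c in candidates if c.residual <= med]
    if not eligible:  # all residuals identical handled above; safety net
        eligible = list(candidates)
    return min(eligible, key=lambda c: (-c.zero_count, c.residual, c.run_index))


def select_community(
    candidates: list[CandidateSolution],
    elite: CandidateSolution,
    bounds: CommunityBounds = CommunityBounds(),
) -> list[CandidateSolution]:
    """Candidates in the bounded region around the elite.

    Kept: zero_count within ±zero_tolerance of the elite's (band rounded
    outward to integers) and residual ≥ (1 − residual_tolerance) · elite's.
    The elite itself is always a member.
    """
    z_lo = math.floor((1.0 - bounds.zero_tolerance) * elite.zero_count)
    z_hi = math.ceil((1.0 + bounds.zero_tolerance) * elite.zero_count)
    r_lo = (1.0 - bounds.residual_tolerance) * elite.residual
    community = [
        c
        for c in candidates
        if (z_lo <= c.zero_count <= z_hi and c.residual >= r_lo) or c is elite
    ]
    if elite not in community:
        community.insert(0, elite)
    return community


def combine_structures(
    community: list[CandidateSolution],
    bounds: CommunityBounds = CommunityBounds(),
    min_sparsity: float | None = 0.5,
) -> tuple[np.ndarray, np.ndarray]:
    """Average binarized community structures and threshold into a consensus.

    Per-position fractional support = mean of the 0/1 structures; positions
    with support below the threshold are set to zero, all others (including
    exact ties at the threshold) to one.

    Returns ``(final_structure, support)``. A warning is emitted when the
    consensus sparsity falls below ``min_sparsity`` — the advised caution
    when loosening the threshold.
    """
    if not community:
        raise ValueError("community is empty")
    stack = np.stack([np.asarray(c.structure, dtype=bool) for c in community])
    support = stack.mean(axis=0)
    final = support >= bounds.binarization_threshold
    if min_sparsity is not None:
        sparsity = 1.0 - final.sum() / final.size
        if sparsity < min_sparsity:
            warnings.warn(
                f"combined structure sparsity {sparsity:.3f} fell below "
                f"{min_sparsity:.2f}; consider a stricter binarization threshold",
                stacklevel=2,
            )
    return final, support
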