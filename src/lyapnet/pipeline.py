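"""End-to-end inference: replicates → covariance/fluctuation → GA → network.

The observable input is a replicate-by-metabolite matrix of steady-state
measurements. Its sample covariance C and the per-metabolite replicate
standard deviations (as the diagonal fluctuation matrix D) feed the
vectorized Lyapunov system; a λ-scan of the sparsity-constrained GA produces
candidate structures; the elite/community/consensus stage yields the final
directed network. Optional global max-normalization rescales the whole data
matrix into [0, 1] before estimating C and D, which can improve their mutual
consistency in the Lyapunov equation.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np

from .ensemble import (
    CommunityBounds,
    combine_structures,
    select_community,
    select_elite,
)
from .ga import CandidateSolution, GAConfig, PriorMask, lambda_scan
from .lyapunov import VectorizedSystem, check_symmetric, vectorize_lyapunov

logger = logging.getLogger(__name__)

__all__ = [
    "ReplicateDataset",
    "InferenceResult",
    "compute_covariance",
    "estimate_fluctuation",
    "normalize_dataset",
    "infer_network",
]


@dataclass
class ReplicateDataset:
    """Replicate-by-metabolite data matrix with labels and provenance.

    values: (m, n) array, m ≥ 2 replicates of n metabolite concentrations;
    column order defines the Jacobian index order throughout the package.
    provenance is one of "measured", "simulated", "normalized".
    """

    values: np.ndarray
    names: list[str]
    provenance: str = "measured"

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("replicate data must be a 2-D matrix")
        if self.values.shape[0] < 2:
            raise ValueError("need at least two replicates")
        if self.values.shape[1] != len(self.names):
            raise ValueError(
                f"{len(self.names)} metabolite names for "
                f"{self.values.shape[1]} data columns"
            )
        if len(set(self.names)) != len(self.names):
            raise ValueError("duplicate metabolite names")
        if not np.all(np.isfinite(self.values)):
            bad = np.argwhere(~np.isfinite(self.values))[0]
            raise ValueError(
                f"missing/non-finite value at replicate {bad[0]}, "
                f"metabolite '{self.names[bad[1]]}'"
            )

    @property
    def m(self) -> int:
        return self.values.shape[0]

    @property
    def n(self) -> int:
        return self.values.shape[1]


@dataclass
class InferenceResult:
    """Everything produced by one end-to-end inference run."""

    structure: np.ndarray  # (n, n) bool adjacency of the consensus network
    support: np.ndarray  # (n, n) fractional support in [0, 1]
    elite: CandidateSolution
    community: list[CandidateSolution]
    candidates: list[CandidateSolution]
    names: list[str]
    diagnostics: dict = field(default_factory=dict)

    def elite_jacobian(self) -> np.ndarray:
        return self.elite.jacobian(len(self.names))


def compute_covariance(data: ReplicateDataset) -> np.ndarray:
    """Sample covariance of the replicates (m − 1 denominator)."""
    C = np.cov(data.values, rowvar=False, ddof=1)
    C = np.atleast_2d(C)
    if np.all(C == 0):
        raise ValueError(
            "replicate data are constant: covariance is identically zero and "
            "carries no network information"
        )
    return 0.5 * (C + C.T)


def estimate_fluctuation(data: ReplicateDataset) -> np.ndarray:
    """Fluctuation intensities D_i = replicate standard deviation (m − 1).

    The replicate spread is the observable proxy for the intrinsic-noise
    magnitudes driving each metabolite; off-diagonal intensities are assumed
    zero.
    """
    sd = data.values.std(axis=0, ddof=1)
    zero = np.flatnonzero(sd == 0)
    if zero.size:
        raise ValueError(
            f"metabolite '{data.names[zero[0]]}' has zero replicate standard "
            "deviation; its fluctuation intensity is undefined"
        )
    return sd


def normalize_dataset(data: ReplicateDataset) -> ReplicateDataset:
    """Scale the whole matrix into [0, 1] by its single global maximum."""
    mx = data.values.max()
    if mx <= 0:
        raise ValueError("cannot normalize data with a nonpositive maximum")
    return ReplicateDataset(
        values=data.values / mx, names=list(data.names), provenance="normalized"
    )


def infer_network(
    data: ReplicateDataset | None = None,
    covariance: np.ndarray | None = None,
    fluctuation: np.ndarray | None = None,
    cfg: GAConfig | None = None,
    bounds: CommunityBounds | None = None,
    mask: PriorMask | None = None,
    normalize: bool = False,
    names: list[str] | None = None,
) -> InferenceResult:
    """Infer a directed network from replicates or from (C, D) directly.

    Orchestrates: vectorize the Lyapunov equation → λ-scan GA → elite
    selection → community selection → consensus combination. Fully
    reproducible from ``cfg.rng_seed``. When both raw data and a user
    covariance are supplied, the user covariance wins and a warning is
    logged.
    """
    cfg = cfg or GAConfig()
    bounds = bounds or CommunityBounds()

    if data is not None:
        if normalize:
            data = normalize_dataset(data)
        data_C = compute_covariance(data)
        data_D = estimate_fluctuation(data)
        if covariance is not None:
            warnings.warn(
                "both replicate data and a covariance matrix supplied; "
                "using the covariance and ignoring the data",
                stacklevel=2,
            )
        else:
            covariance = data_C
        if fluctuation is None:
            fluctuation = data_D
        if names is None:
            names = list(data.names)
    if covariance is None or fluctuation is None:
        raise ValueError(
            "supply either replicate data or both a covariance matrix and a "
            "fluctuation vector"
        )
    covariance = check_symmetric(np.asarray(covariance, dtype=float))
    n = covariance.shape[0]
    if names is None:
        names = [f"M{i + 1}" for i in range(n)]

    try:
        sys = vectorize_lyapunov(covariance, fluctuation)
    except ValueError as exc:
        raise ValueError(f"[vectorize] {exc}") from exc
    cond_A = float(np.linalg.cond(sys.A))
    logger.info("vectorized system: n=%d, cond(A)=%.3e", n, cond_A)

    candidates = lambda_scan(sys, cfg, mask)
    elite = select_elite(candidates)
    community = select_community(candidates, elite, bounds)
    final_vec, support_vec = combine_structures(
        community, bounds, min_sparsity=cfg.min_sparsity
    )

    per_lambda_best = {}
    for c in candidates:
        if c.lam not in per_lambda_best or c.fitness > per_lambda_best[c.lam]:
            per_lambda_best[c.lam] = c.fitness
    diagnostics = {
        "condition_number": cond_A,
        "n_candidates": len(candidates),
        "community_size": len(community),
        "per_lambda_best_fitness": per_lambda_best,
        "elite_zero_count": elite.zero_count,
        "elite_residual": elite.residual,
    }
    return InferenceResult(
        structure=final_vec.reshape((n, n), order="F"),
        support=support_vec.reshape((n, n), order="F"),
        elite=elite,
        community=community,
        candidates=candidates,
        names=list(names),
        diagnostics=diagnostics,
    )
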