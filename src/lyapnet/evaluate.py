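"""Evaluation metrics and the Gaussian-graphical-model baseline.

Reconstruction quality is summarized by the true-positive rate (TPR), the
false-positive rate (FPR), and the g-score √(TPR·(1−FPR)), which collapses
both into a single number in [0, 1]. The GGM baseline infers an undirected
network from full-order partial Pearson correlations: invert the correlation
matrix P = R⁻¹, take ρ_ij = −P_ij/√(P_ii P_jj), and test each coefficient
with the t-statistic on m − n degrees of freedom at a raw p-value cutoff.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass

import numpy as np
import scipy.stats

from .pipeline import ReplicateDataset

__all__ = [
    "EvaluationResult",
    "tpr_fpr",
    "g_score",
    "sparsity_of",
    "ggm_infer",
    "jacobian_value_agreement",
    "reproducibility",
]


@dataclass(frozen=True)
class EvaluationResult:
    """TPR/FPR/g-score over a set of evaluated Jacobian positions."""

    tpr: float
    fpr: float
    g_score: float
    positions_evaluated: int
    diagonal_included: bool


def g_score(tpr: float, fpr: float) -> float:
    """g-score = √(TPR · (1 − FPR)), a single-number reconstruction score."""
    if not (0.0 <= tpr <= 1.0) or not (0.0 <= fpr <= 1.0):
        raise ValueError(f"TPR and FPR must be in [0, 1], got ({tpr}, {fpr})")
    return float(np.sqrt(tpr * (1.0 - fpr)))


def tpr_fpr(
    predicted: np.ndarray,
    true: np.ndarray,
    include_diagonal: bool = True,
) -> EvaluationResult:
    """TPR and FPR of a predicted structure against the true structure.

    Positives are the nonzero entries of the true structure over the
    evaluated positions (all n² by default; the diagonal can be excluded).
    """
    pred = np.asarray(predicted).astype(bool)
    truth = np.asarray(true).astype(bool)
    if pred.shape != truth.shape:
        raise ValueError(f"shape mismatch: {pred.shape} vs {truth.shape}")
    if pred.ndim == 1:
        n = int(round(np.sqrt(pred.size)))
        pred = pred.reshape((n, n), order="F")
        truth = truth.reshape((n, n), order="F")
    keep = np.ones(pred.shape, dtype=bool)
    if not include_diagonal:
        np.fill_diagonal(keep, False)
    p, t = pred[keep], truth[keep]
    P = int(t.sum())
    N = int((~t).sum())
    if P == 0 or N == 0:
        raise ValueError(
            "true structure has no positives or no negatives over the "
            "evaluated positions; TPR/FPR are undefined"
        )
    tp = int((p & t).sum())
    fp = int((p & ~t).sum())
    tpr = tp / P
    fpr = fp / N
    return EvaluationResult(
        tpr=tpr,
        fpr=fpr,
        g_score=g_score(tpr, fpr),
        positions_evaluated=int(keep.sum()),
        diagonal_included=include_diagonal,
    )


def sparsity_of(structure: np.ndarray) -> float:
    """Fraction of zero entries: zeros / total (1 = empty, 0 = complete digraph)."""
    s = np.asarray(structure)
    if s.size == 0:
        raise ValueError("empty structure")
    return float((s == 0).sum() / s.size)


def ggm_infer(
    data: ReplicateDataset,
    p_cutoff: float = 0.01,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Gaussian graphical model: significant full-order partial correlations.

    Returns ``(adjacency, partial_correlations, p_values)``; the adjacency
    is symmetric with an empty diagonal, an edge wherever the two-sided
    p-value of the partial correlation falls below ``p_cutoff``.
    """
    m, n = data.m, data.n
    if m <= n + 2:
        raise ValueError(
            f"GGM needs more replicates than metabolites + 2 (m={m}, n={n})"
        )
    R = np.corrcoef(data.values, rowvar=False)
    try:
        P = np.linalg.inv(R)
    except np.linalg.LinAlgError as exc:
        raise ValueError(
            "correlation matrix is singular; more replicates (or fewer "
            "collinear metabolites) are required"
        ) from exc
    denom = np.sqrt(np.outer(np.diag(P), np.diag(P)))
    pcor = -P / denom
    np.fill_diagonal(pcor, 1.0)
    pcor = np.clip(0.5 * (pcor + pcor.T), -1.0, 1.0)

    dof = m - n  # m samples, n - 2 controlling variables per pair
    with np.errstate(divide="ignore", invalid="ignore"):
        tstat = pcor * np.sqrt(dof / (1.0 - pcor**2))
    pvals = 2.0 * scipy.stats.t.sf(np.abs(tstat), dof)
    np.fill_diagonal(pvals, 1.0)
    adjacency = pvals < p_cutoff
    np.fill_diagonal(adjacency, False)
    return adjacency, pcor, pvals


def jacobian_value_agreement(
    candidates,
    true_J: np.ndarray,
) -> tuple[list[tuple[float, float]], float]:
    """Spearman correlation of fitted vs true Jacobian values per candidate.

    For each community candidate, ranks are compared over the union of its
    support and the true nonzero positions (available in simulation studies
    only). Returns the per-candidate (rho, p) list and the median rho.
    """
    true_J = np.asarray(true_J, dtype=float)
    n = true_J.shape[0]
    true_vec = true_J.reshape(-1, order="F")
    results: list[tuple[float, float]] = []
    for cand in candidates:
        fitted = np.zeros(n * n)
        fitted[cand.support] = cand.j_values
        positions = np.flatnonzero((fitted != 0) | (true_vec != 0))
        if positions.size < 3:
            raise ValueError(
                "fewer than 3 comparable positions; Spearman rank correlation "
                "is not meaningful"
            )
        rho, p = scipy.stats.spearmanr(fitted[positions], true_vec[positions])
        results.append((float(rho), float(p)))
    median_rho = float(np.median([r for r, _ in results]))
    return results, median_rho


def reproducibility(run_outputs, truth: np.ndarray | None = None) -> float:
    """Fraction of runs whose final structure matches the reference.

    With ground truth given, the reference is the truth; otherwise the modal
    structure across runs.
    """
    structures = [np.asarray(s).astype(bool).ravel() for s in run_outputs]
    if len(structures) < 2:
        raise ValueError("need at least two runs to assess reproducibility")
    if truth is not None:
        ref = np.asarray(truth).astype(bool).ravel()
    else:
        counts = Counter(s.tobytes() for s in structures)
        ref_bytes = counts.most_common(1)[0][0]
        ref = np.frombuffer(ref_bytes, dtype=bool)
    matches = sum(1 for s in structures if np.array_equal(s, ref))
    return matches / len(structures)
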