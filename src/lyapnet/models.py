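"""Shipped kinetic models used as ground truth in benchmarks and examples.

``yeast_glycolysis_synthetic`` is a *synthetic* 13-metabolite stand-in with
glycolysis-like topology (see its docstring); ``mass_action_chain`` is a
small nonlinear chain used to exercise the steady-state and Jacobian
machinery on a model whose fixed point is known in closed form.
"""

from __future__ import annotations

import numpy as np

from .simulate import KineticModel

__all__ = ["yeast_glycolysis_synthetic", "mass_action_chain"]


GLYCOLYSIS_NAMES = [
    "GLC",
    "G6P",
    "F6P",
    "FBP",
    "DHAP",
    "GAP",
    "BPG",
    "P3G",
    "PEP",
    "PYR",
    "AcAld",
    "NADH",
    "ATP",
]

# directed influences (target row i, source column j, J_ij): the upper
# glycolytic chain GLC→G6P→F6P→FBP→{DHAP,GAP}, the TPI shuttle DHAP⇌GAP,
# the lower chain GAP→BPG→P3G→PEP→PYR→AcAld, NADH produced at the GAPDH
# step and consumed with acetaldehyde, ATP consumed by HK/PFK and produced
# by PGK/PK with feedback onto HK and PFK.
_GLYCOLYSIS_EDGES = [
    (1, 0, 2.5),
    (2, 1, 1.8),
    (3, 2, 3.0),
    (4, 3, 0.9),
    (5, 3, 0.9),
    (5, 4, 4.5),
    (4, 5, 0.6),
    (6, 5, 1.2),
    (7, 6, 6.0),
    (8, 7, 0.4),
    (9, 8, 2.2),
    (10, 9, 1.5),
    (11, 5, 0.8),
    (11, 10, -1.1),
    (10, 11, -0.7),
    (12, 6, 0.9),
    (12, 8, 1.6),
    (12, 0, -0.5),
    (12, 2, -0.8),
    (3, 12, -0.3),
    (1, 12, 0.2),
]

_GLYCOLYSIS_DIAG = [
    -1.2, -2.0, -3.2, -1.9, -4.8, -5.6, -6.5, -1.1, -2.5, -1.8, -2.1, -1.4, -2.6,
]

# per-metabolite turnover scales (1/time): fast triose/BPG intermediates,
# slow substrate and cofactor pools — kinetic models span orders of
# magnitude in row timescales, which is what makes their covariance
# informative about individual edges
_GLYCOLYSIS_RATES = [
    0.3, 1.0, 2.0, 1.5, 6.0, 8.0, 20.0, 3.0, 2.5, 0.5, 1.0, 0.8, 0.4,
]

_GLYCOLYSIS_STEADY_STATE = [
    1.0, 0.8, 0.3, 1.5, 0.5, 0.1, 0.05, 0.4, 0.2, 1.0, 0.15, 0.3, 2.0,
]


def yeast_glycolysis_synthetic() -> KineticModel:
    """Synthetic 13-metabolite glycolysis-like benchmark model.

    A hand-designed *synthetic stand-in*, not a published kinetic model: the
    dynamics are linear, dC/dt = J (C − C_s), with a fixed sparse Jacobian
    whose topology mirrors yeast glycolysis (hexose chain, triose shuttle,
    NADH and ATP coupling). Row timescales span roughly two orders of
    magnitude (fast triose-phosphate turnover, slow substrate/cofactor
    pools), so Jacobian entry magnitudes span about three — the regime of
    real kinetic models. It provides a deterministic 13-node ground truth
    (34 nonzero Jacobian entries, sparsity 135/169 ≈ 0.80) at the network
    size typical of small-scale metabolic inference benchmarks.
    """
    n = 13
    J = np.zeros((n, n))
    for i, j, v in _GLYCOLYSIS_EDGES:
        J[i, j] = v
    J[np.diag_indices(n)] = _GLYCOLYSIS_DIAG
    J = np.diag(_GLYCOLYSIS_RATES) @ J
    C_s = np.array(_GLYCOLYSIS_STEADY_STATE, dtype=float)
    sparsity = float((J == 0).sum() / (n * n))

    def rhs(C, J=J, b=C_s):
        return (np.asarray(C) - b) @ J.T

    return KineticModel(
        rhs=rhs,
        n=n,
        names=list(GLYCOLYSIS_NAMES),
        parameters={
            "J": J.copy(),
            "steady_state": C_s.copy(),
            "sparsity": sparsity,
            "vectorized": True,
        },
        jacobian=lambda C, J=J: J.copy(),
        name="yeast_glycolysis_synthetic",
    )


def mass_action_chain(n: int = 5, v_in: float = 1.0, k: float | None = None) -> KineticModel:
    """Nonlinear mass-action chain M1 → M2 → … → Mn with constant inflow.

    The second step is bimolecular (rate k₂·C₂²), all others first-order, so
    the model is genuinely nonlinear while its steady state remains available
    in closed form: C₁ = v_in/k₁, C₂ = √(v_in/k₂), C_i = v_in/k_i (i ≥ 3).
    """
    if n < 3:
        raise ValueError("chain needs at least 3 metabolites")
    rates = np.linspace(1.0, 2.0, n) if k is None else np.full(n, float(k))

    def rhs(C, rates=rates, v_in=v_in, n=n):
        C = np.asarray(C, dtype=float)
        v = rates * C
        v[1] = rates[1] * C[1] ** 2  # bimolecular step
        dC = np.empty(n)
        dC[0] = v_in - v[0]
        dC[1:] = v[:-1] - v[1:]
        return dC

    def jacobian(C, rates=rates, n=n):
        C = np.asarray(C, dtype=float)
        J = np.zeros((n, n))
        deriv = rates.copy()
        deriv[1] = 2.0 * rates[1] * C[1]
        for i in range(n):
            J[i, i] = -deriv[i]
            if i > 0:
                J[i, i - 1] = deriv[i - 1]
        return J

    ss = np.empty(n)
    ss[0] = v_in / rates[0]
    ss[1] = np.sqrt(v_in / rates[1])
    ss[2:] = v_in / rates[2:]
    return KineticModel(
        rhs=rhs,
        n=n,
        parameters={"rates": rates, "v_in": v_in, "steady_state": ss},
        jacobian=jacobian,
        name=f"mass_action_chain_n{n}",
    )
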