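"""Non-negative matrix factorization of scan matrices into components.

The scan matrix V (n points × m channels) is factored as V ≈ W·H with W, H
non-negative: each row of H is a component's spectrum ("feature"), each column
of W that component's weight at every scan position ("concentration").  The
rank r is the number of gas types plus two, one extra component each for the
sensor baseline and the inter-sensor gap noise.

The factorization uses the classical Frobenius-objective multiplicative
updates (Lee–Seung), which preserve non-negativity and never increase the
objective, with seeded random initialization for reproducibility.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .scan import WavenumberAxis
from .simulate import GasSignature, signature_spectrum

__all__ = [
    "UnmixingResult",
    "choose_rank",
    "clip_nonnegative",
    "nmf",
    "normalize_components",
    "match_components",
]

#: Denominator guard in the multiplicative updates.
EPS = 1e-12


@dataclass
class UnmixingResult:
    """Factor matrices and diagnostics from one NMF run.

    W is n × r (per-position component weights), H is r × m (component
    spectra); objective_trace holds the Frobenius reconstruction error after
    every iteration and is non-increasing.
    """

    W: np.ndarray
    H: np.ndarray
    r: int
    objective_trace: np.ndarray
    seed: int
    iterations: int
    converged: bool
    zero_components: tuple[int, ...] = ()

    def __post_init__(self) -> None:
        if self.W.shape[1] != self.r or self.H.shape[0] != self.r:
            raise ValueError("factor shapes inconsistent with rank")
        if (self.W < 0).any() or (self.H < 0).any():
            raise ValueError("factors must be non-negative")

    def reconstruction(self) -> np.ndarray:
        return self.W @ self.H


def choose_rank(n_gas_types: int) -> int:
    """Rank rule: number of gas types plus two (baseline and noise components)."""
    if n_gas_types < 0:
        raise ValueError("number of gas types must be non-negative")
    return n_gas_types + 2


def clip_nonnegative(V: np.ndarray) -> tuple[np.ndarray, float]:
    """Zero out negative entries; returns (clipped matrix, clipped fraction)."""
    V = np.asarray(V, dtype=float)
    if np.isnan(V).any():
        raise ValueError("matrix contains NaN entries")
    negative = V < 0
    fraction = float(negative.mean()) if V.size else 0.0
    if fraction:
        V = np.where(negative, 0.0, V)
    return V, fraction


def nmf(
    V: np.ndarray,
    r: int,
    seed: int = 42,
    max_iter: int = 2000,
    tol: float = 1e-6,
) -> UnmixingResult:
    """Factor a non-negative matrix by Frobenius multiplicative updates.

    H ← H ⊙ (WᵀV) / (WᵀW H + δ) and W ← W ⊙ (V Hᵀ) / (W H Hᵀ + δ) with
    δ = 1e-12, initialized from seeded uniform random in (0, 1] scaled by
    √(mean(V)/r).  Stops when the relative objective decrease falls below
    ``tol`` or after ``max_iter`` iterations.

    Deterministic under ``seed``.
    """
    V = np.asarray(V, dtype=float)
    if V.ndim != 2:
        raise ValueError("V must be a matrix")
    if (V < 0).any():
        raise ValueError("V must be non-negative; use clip_nonnegative first")
    n, m = V.shape
    if not 1 <= r <= min(n, m):
        raise ValueError(f"rank {r} must be in [1, min(n, m) = {min(n, m)}]")

    rng = np.random.default_rng(seed)
    scale = np.sqrt(max(V.mean(), EPS) / r)
    # uniform in (0, 1]: avoids exactly-zero entries that updates cannot revive
    W = scale * (1.0 - rng.random((n, r)))
    H = scale * (1.0 - rng.random((r, m)))

    trace = []
    prev = np.linalg.norm(V - W @ H)
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        H *= (W.T @ V) / (W.T @ W @ H + EPS)
        W *= (V @ H.T) / (W @ (H @ H.T) + EPS)
        obj = np.linalg.norm(V - W @ H)
        trace.append(obj)
        if prev > 0 and (prev - obj) / prev < tol:
            converged = True
            break
        prev = obj

    return UnmixingResult(
        W=W, H=H, r=r,
        objective_trace=np.asarray(trace),
        seed=seed, iterations=it, converged=converged,
    )


def normalize_components(result: UnmixingResult) -> UnmixingResult:
    """Rescale each H row to unit maximum and reorder by total concentration.

    The matching W column is scaled inversely so the product W·H is unchanged.
    Components are then reordered by descending total W-column sum, so the
    dominant gas appears first.  All-zero components are left unscaled and
    flagged in ``zero_components``.
    """
    W = result.W.copy()
    H = result.H.copy()
    zero: list[int] = []
    for i in range(result.r):
        peak = H[i].max()
        if peak <= 0:
            zero.append(i)
            continue
        H[i] /= peak
        W[:, i] *= peak
    order = np.argsort(-W.sum(axis=0), kind="stable")
    return UnmixingResult(
        W=W[:, order], H=H[order], r=result.r,
        objective_trace=result.objective_trace,
        seed=result.seed, iterations=result.iterations,
        converged=result.converged,
        zero_components=tuple(int(np.where(order == z)[0][0]) for z in zero),
    )


def match_components(
    H: np.ndarray,
    signatures: Mapping[str, GasSignature] | Sequence[GasSignature],
    axis: WavenumberAxis,
    threshold: float = 0.8,
) -> dict[int, str]:
    """Assign each component spectrum to a gas or to "interference".

    Each H row is compared with every signature spectrum by Pearson
    correlation; assignments are made greedily by descending correlation,
    injectively over gases, and only when the correlation reaches
    ``threshold``.  Unassigned components are labeled "interference".
    """
    H = np.asarray(H, dtype=float)
    if H.size == 0:
        raise ValueError("empty feature matrix")
    if H.shape[1] != len(axis):
        raise ValueError("H column count must match the axis length")

    sigs = dict(signatures) if isinstance(signatures, Mapping) else {
        s.name: s for s in signatures
    }
    ref = {name: signature_spectrum(s, axis) for name, s in sigs.items()}

    def corr(a: np.ndarray, b: np.ndarray) -> float:
        if a.std() == 0 or b.std() == 0:
            return 0.0
        return float(np.corrcoef(a, b)[0, 1])

    candidates = [
        (corr(H[i], spec), i, name)
        for i in range(H.shape[0])
        for name, spec in ref.items()
    ]
    # descending correlation; ties broken toward the lower component index
    candidates.sort(key=lambda t: (-t[0], t[1]))

    assignment = {i: "interference" for i in range(H.shape[0])}
    used_gases: set[str] = set()
    assigned: set[int] = set()
    for c, i, name in candidates:
        if c < threshold:
            break
        if i in assigned or name in used_gases:
            continue
        assignment[i] = name
        used_gases.add(name)
        assigned.add(i)
    return assignment
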