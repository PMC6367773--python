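"""Joint orthogonality NMF with network regularization and sparsity.

The model factorizes three sample-matched expression matrices
X1 (S x N1, lncRNA), X2 (S x N2, miRNA), X3 (S x N3, mRNA) as
Xi ~ W Hi^T with one shared non-negative basis W (S x K) and
layer-specific non-negative coefficient matrices Hi (Ni x K).
The objective minimized is

    sum_i ( ||Xi - W Hi^T||_F^2 + (alpha/2) ||Hi^T Hi - I||_F^2 )
    - lambda1 Tr(H2^T A H1) - lambda2 Tr(H2^T B H3) - lambda3 Tr(H3^T C H3)
    + gamma1 ||W||_F^2 + gamma2 sum_i ||Hi||_1

subject to W >= 0, Hi >= 0, where A (miRNA x lncRNA) and B (miRNA x mRNA)
are binary interaction networks and C (mRNA x mRNA) a symmetric weighted
gene network.  The orthogonality term pushes module loadings apart, the
trace terms pull interacting molecules into the same factorization
column, and the L1/L2 penalties keep the solution sparse.

The optimizer is the KKT-derived multiplicative scheme:

    W  <- W  * (X1 H1 + X2 H2 + X3 H3)
            / (W H1^T H1 + W H2^T H2 + W H3^T H3 + gamma1 W)
    H1 <- H1 * (X1^T W + alpha H1 + (lambda1/2) A^T H2)
            / (H1 W^T W + alpha H1 H1^T H1 + gamma2/2)
    H2 <- H2 * (X2^T W + alpha H2 + (lambda1/2) A H1 + (lambda2/2) B H3)
            / (H2 W^T W + alpha H2 H2^T H2 + gamma2/2)
    H3 <- H3 * (X3^T W + alpha H3 + (lambda2/2) B^T H2 + lambda3 C H3)
            / (H3 W^T W + alpha H3 H3^T H3 + gamma2/2)

(the gene-gene term enters the H3 numerator with coefficient lambda3,
not lambda3/2, because C appears quadratically in the objective).  All
ratios are element-wise; every denominator gets a small epsilon guard.
Updates are applied in the order W, H1, H2, H3, each using the most
recently updated factors.
"""

from __future__ import annotations

import warnings
from typing import Optional, Tuple

import numpy as np

from .datatypes import (
    FactorizationResult,
    Hyperparameters,
    InteractionData,
    NumericalError,
    TriOmicsDataset,
    ValidationError,
)

__all__ = ["EPSILON", "objective", "update_step", "initialize_factors", "fit"]

#: stabilizer added to every multiplicative-update denominator
EPSILON = 1e-10


def _check_dims(
    dataset: TriOmicsDataset, nets: InteractionData, state: FactorizationResult
) -> None:
    S = dataset.n_samples
    n1, n2, n3 = (
        dataset.lnc.n_molecules,
        dataset.mir.n_molecules,
        dataset.mrna.n_molecules,
    )
    K = state.K
    if state.W.shape != (S, K):
        raise ValidationError(f"W shape {state.W.shape} != ({S}, {K})")
    for name, H, n in (("H1", state.H1, n1), ("H2", state.H2, n2), ("H3", state.H3, n3)):
        if H.shape != (n, K):
            raise ValidationError(f"{name} shape {H.shape} != ({n}, {K})")
    if nets.A.shape != (n2, n1) or nets.B.shape != (n2, n3) or nets.C.shape != (n3, n3):
        raise ValidationError("interaction matrix dimensions inconsistent with dataset")


def objective(
    dataset: TriOmicsDataset,
    nets: InteractionData,
    hp: Hyperparameters,
    state: FactorizationResult,
) -> float:
    """Evaluate the full objective at the given factors."""
    _check_dims(dataset, nets, state)
    W = state.W
    K = state.K
    eye = np.eye(K)
    total = 0.0
    for X, H in (
        (dataset.lnc.values, state.H1),
        (dataset.mir.values, state.H2),
        (dataset.mrna.values, state.H3),
    ):
        R = X - W @ H.T
        total += float(np.sum(R * R))
        G = H.T @ H - eye
        total += 0.5 * hp.alpha * float(np.sum(G * G))
    total -= hp.lambda1 * float(np.trace(state.H2.T @ nets.A @ state.H1))
    total -= hp.lambda2 * float(np.trace(state.H2.T @ nets.B @ state.H3))
    total -= hp.lambda3 * float(np.trace(state.H3.T @ nets.C @ state.H3))
    total += hp.gamma1 * float(np.sum(W * W))
    total += hp.gamma2 * float(
        np.sum(np.abs(state.H1)) + np.sum(np.abs(state.H2)) + np.sum(np.abs(state.H3))
    )
    if not np.isfinite(total):
        raise NumericalError("objective is non-finite")
    return total


def _guarded_update(factor: np.ndarray, num: np.ndarray, den: np.ndarray, name: str,
                    iteration: Optional[int] = None) -> np.ndarray:
    if np.any(num < 0):
        raise NumericalError(
            f"negative numerator entry in {name} update"
            + (f" at iteration {iteration}" if iteration is not None else "")
        )
    out = factor * (num / (den + EPSILON))
    if not np.all(np.isfinite(out)):
        raise NumericalError(
            f"non-finite entry in {name} update"
            + (f" at iteration {iteration}" if iteration is not None else "")
        )
    return out


def update_step(
    dataset: TriOmicsDataset,
    nets: InteractionData,
    hp: Hyperparameters,
    state: FactorizationResult,
    iteration: Optional[int] = None,
) -> FactorizationResult:
    """One full multiplicative update sweep (W, then H1, H2, H3)."""
    _check_dims(dataset, nets, state)
    X1, X2, X3 = dataset.lnc.values, dataset.mir.values, dataset.mrna.values
    A, B, C = nets.A, nets.B, nets.C
    out = state.copy()
    W, H1, H2, H3 = out.W, out.H1, out.H2, out.H3

    num = X1 @ H1 + X2 @ H2 + X3 @ H3
    den = W @ (H1.T @ H1) + W @ (H2.T @ H2) + W @ (H3.T @ H3) + hp.gamma1 * W
    W = _guarded_update(W, num, den, "W", iteration)

    WtW = W.T @ W
    num = X1.T @ W + hp.alpha * H1 + 0.5 * hp.lambda1 * (A.T @ H2)
    den = H1 @ WtW + hp.alpha * H1 @ (H1.T @ H1) + 0.5 * hp.gamma2
    H1 = _guarded_update(H1, num, den, "H1", iteration)

    num = X2.T @ W + hp.alpha * H2 + 0.5 * hp.lambda1 * (A @ H1) + 0.5 * hp.lambda2 * (B @ H3)
    den = H2 @ WtW + hp.alpha * H2 @ (H2.T @ H2) + 0.5 * hp.gamma2
    H2 = _guarded_update(H2, num, den, "H2", iteration)

    num = X3.T @ W + hp.alpha * H3 + 0.5 * hp.lambda2 * (B.T @ H2) + hp.lambda3 * (C @ H3)
    den = H3 @ WtW + hp.alpha * H3 @ (H3.T @ H3) + 0.5 * hp.gamma2
    H3 = _guarded_update(H3, num, den, "H3", iteration)

    out.W, out.H1, out.H2, out.H3 = W, H1, H2, H3
    return out


def initialize_factors(
    dataset: TriOmicsDataset, hp: Hyperparameters
) -> FactorizationResult:
    """Strictly positive seeded initialization.

    Entries are drawn i.i.d. uniform on (0, 1]; W is then rescaled so the
    initial reconstruction W H^T of the first non-empty layer matches that
    layer's Frobenius norm.  Strict positivity matters: a zero entry can
    never revive under multiplicative updates.
    """
    hp.validate_for(dataset)
    rng = np.random.default_rng(hp.seed)
    S, K = dataset.n_samples, hp.K

    def draw(*shape):
        return 1.0 - rng.random(shape)  # uniform on (0, 1]

    W = draw(S, K)
    H1 = draw(dataset.lnc.n_molecules, K)
    H2 = draw(dataset.mir.n_molecules, K)
    H3 = draw(dataset.mrna.n_molecules, K)

    for X, H in (
        (dataset.lnc.values, H1),
        (dataset.mir.values, H2),
        (dataset.mrna.values, H3),
    ):
        if X.shape[1] == 0:
            continue
        norm_X = np.linalg.norm(X)
        norm_WH = np.linalg.norm(W @ H.T)
        if norm_X > 0 and norm_WH > 0:
            W *= norm_X / norm_WH
        break

    return FactorizationResult(
        W=W,
        H1=H1,
        H2=H2,
        H3=H3,
        seed_used=hp.seed,
        lnc_ids=list(dataset.lnc.molecule_ids),
        mir_ids=list(dataset.mir.molecule_ids),
        mrna_ids=list(dataset.mrna.molecule_ids),
    )


def fit(
    dataset: TriOmicsDataset,
    nets: InteractionData,
    hp: Hyperparameters,
    init: Optional[FactorizationResult] = None,
) -> FactorizationResult:
    """Run multiplicative updates from a seeded start until the relative
    objective change drops below ``hp.tol`` or ``hp.max_iter`` is reached.

    Identical seeds give bit-identical results.  A caller-supplied ``init``
    (e.g. for warm starts) overrides the seeded initialization.
    """
    state = init.copy() if init is not None else initialize_factors(dataset, hp)
    trace = [objective(dataset, nets, hp, state)]
    converged = False
    iterations = 0
    for it in range(1, hp.max_iter + 1):
        state = update_step(dataset, nets, hp, state, iteration=it)
        obj = objective(dataset, nets, hp, state)
        trace.append(obj)
        iterations = it
        rel_change = abs(trace[-1] - trace[-2]) / max(1.0, abs(trace[-2]))
        if rel_change < hp.tol:
            converged = True
            break
    if not converged:
        warnings.warn(
            f"factorization stopped at max_iter={hp.max_iter} without reaching "
            f"tol={hp.tol}",
            RuntimeWarning,
            stacklevel=2,
        )
    state.objective_trace = trace
    state.iterations_run = iterations
    state.converged = converged
    state.seed_used = hp.seed
    return state
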