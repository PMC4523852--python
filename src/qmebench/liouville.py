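"""Small superoperator helpers (row-major vectorization, vec(AXB) = (A⊗Bᵀ)vec X)."""

from __future__ import annotations

import numpy as np

__all__ = ["left_mul", "right_mul", "commutator_sop", "hamiltonian_liouvillian"]


def left_mul(A: np.ndarray) -> np.ndarray:
    """Superoperator for X ↦ A·X."""
    return np.kron(A, np.eye(A.shape[0]))


def right_mul(A: np.ndarray) -> np.ndarray:
    """Superoperator for X ↦ X·A."""
    return np.kron(np.eye(A.shape[0]), A.T)


def commutator_sop(A: np.ndarray) -> np.ndarray:
    """Superoperator for X ↦ [A, X]."""
    return left_mul(A) - right_mul(A)


def hamiltonian_liouvillian(H: np.ndarray) -> np.ndarray:
    """Superoperator for X ↦ −i[H, X]."""
    return -1j * commutator_sop(H)
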