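"""Time-series container for density-matrix dynamics.

Solvers report the reduced density matrix in the exciton basis
{|χ₊⟩, |χ₋⟩}; Choi-extended dynamics use 4×4 system⊗ancilla matrices.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = ["Trajectory"]

_CSV_COLUMNS = [
    "t_fs",
    "re_rho_pp", "im_rho_pp",
    "re_rho_pm", "im_rho_pm",
    "re_rho_mp", "im_rho_mp",
    "re_rho_mm", "im_rho_mm",
]


@dataclass
class Trajectory:
    """Time grid (fs) plus density matrices and derived observables."""

    times: np.ndarray
    states: np.ndarray  # (n_times, d, d) complex
    basis: str = "exciton"
    metadata: dict = field(default_factory=dict)

    def __post_init__(self):
        self.times = np.asarray(self.times, dtype=float)
        self.states = np.asarray(self.states, dtype=complex)
        if self.states.ndim != 3 or self.states.shape[0] != len(self.times):
            raise ValueError("states must have shape (n_times, d, d)")

    @property
    def dim(self) -> int:
        return self.states.shape[1]

    def population(self, i: int = 0) -> np.ndarray:
        """Re ρ_ii(t); i = 0 is the upper exciton |χ₊⟩."""
        return self.states[:, i, i].real

    def coherence_abs(self, i: int = 1, j: int = 0) -> np.ndarray:
        """|ρ_ij(t)|; default is the exciton coherence |ρ₋₊|."""
        return np.abs(self.states[:, i, j])

    def trace(self) -> np.ndarray:
        return np.einsum("tii->t", self.states)

    def hermiticity_defect(self) -> float:
        return float(np.max(np.abs(self.states - np.conj(self.states.transpose(0, 2, 1)))))

    def to_dataframe(self) -> pd.DataFrame:
        if self.dim != 2:
            raise ValueError("CSV schema is defined for 2×2 system trajectories")
        s = self.states
        return pd.DataFrame(
            {
                "t_fs": self.times,
                "re_rho_pp": s[:, 0, 0].real, "im_rho_pp": s[:, 0, 0].imag,
                "re_rho_pm": s[:, 0, 1].real, "im_rho_pm": s[:, 0, 1].imag,
                "re_rho_mp": s[:, 1, 0].real, "im_rho_mp": s[:, 1, 0].imag,
                "re_rho_mm": s[:, 1, 1].real, "im_rho_mm": s[:, 1, 1].imag,
            }
        )

    def to_csv(self, path) -> None:
        """Write the schema t_fs, re/im of all four elements, 17 sig digits."""
        self.to_dataframe().to_csv(Path(path), index=False, float_format="%.17g")

    @classmethod
    def from_csv(cls, path, basis: str = "exciton") -> "Trajectory":
        df = pd.read_csv(path)
        missing = [c for c in _CSV_COLUMNS if c not in df.columns]
        if missing:
            raise ValueError(f"trajectory CSV missing columns: {missing}")
        n = len(df)
        states = np.empty((n, 2, 2), dtype=complex)
        states[:, 0, 0] = df["re_rho_pp"] + 1j * df["im_rho_pp"]
        states[:, 0, 1] = df["re_rho_pm"] + 1j * df["im_rho_pm"]
        states[:, 1, 0] = df["re_rho_mp"] + 1j * df["im_rho_mp"]
        states[:, 1, 1] = df["re_rho_mm"] + 1j * df["im_rho_mm"]
        return cls(times=df["t_fs"].to_numpy(), states=states, basis=basis)
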