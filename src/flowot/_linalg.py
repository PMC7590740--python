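"""Symmetric-matrix helpers shared by the distance and barycenter code."""

from __future__ import annotations

import numpy as np

# Eigenvalues below this are treated as zero before taking matrix square
# roots, so near-singular covariances stay numerically SPD.
EIG_FLOOR = 1e-12


def sym(a: np.ndarray) -> np.ndarray:
    return (a + a.T) / 2.0


def spd_sqrt(a: np.ndarray) -> np.ndarray:
    """Principal square root of a symmetric PSD matrix via eigendecomposition."""
    w, v = np.linalg.eigh(sym(a))
    w = np.clip(w, EIG_FLOOR, None)
    return sym((v * np.sqrt(w)) @ v.T)


def spd_inv_sqrt(a: np.ndarray) -> np.ndarray:
    w, v = np.linalg.eigh(sym(a))
    w = np.clip(w, EIG_FLOOR, None)
    return sym((v / np.sqrt(w)) @ v.T)


def check_spd(a: np.ndarray, name: str = "covariance") -> None:
    w = np.linalg.eigvalsh(sym(a))
    if w[0] <= 0:
        raise np.linalg.LinAlgError(
            f"{name} is not positive definite (min eigenvalue {w[0]:.3e})"
        )


def logdet_spd(a: np.ndarray) -> float:
    sign, ld = np.linalg.slogdet(sym(a))
    if sign <= 0:
        raise np.linalg.LinAlgError("matrix is singular or not positive")
    return float(ld)
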