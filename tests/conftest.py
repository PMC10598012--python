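"""Shared fixtures and independent oracles."""

from __future__ import annotations

import numpy as np
import pytest


def torus_curve(p: int, q: int, R: float = 30.0, r: float = 10.0,
                n: int = 240, phase: float = 0.0) -> np.ndarray:
    """Parametric (p, q) torus-knot polygon (open chain covering the curve)."""
    u = np.linspace(0.0, 2.0 * np.pi, n, endpoint=False)
    w = q * u + phase
    return np.c_[(R + r * np.cos(w)) * np.cos(p * u),
                 (R + r * np.cos(w)) * np.sin(p * u),
                 r * np.sin(w)]


def quaternion_superpose_rmsd(mobile: np.ndarray, target: np.ndarray) -> float:
    """Independent superposition oracle (Horn quaternion eigenvalue method).

    Returns the minimal RMSD between the two point sets over all proper
    rigid motions, computed from the largest eigenvalue of the 4x4
    quaternion profile matrix — no SVD, no rotation matrix construction.
    """
    P = mobile - mobile.mean(axis=0)
    Q = target - target.mean(axis=0)
    M = P.T @ Q
    Sxx, Sxy, Sxz = M[0]
    Syx, Syy, Syz = M[1]
    Szx, Szy, Szz = M[2]
    K = np.array([
        [Sxx + Syy + Szz, Syz - Szy, Szx - Sxz, Sxy - Syx],
        [Syz - Szy, Sxx - Syy - Szz, Sxy + Syx, Szx + Sxz],
        [Szx - Sxz, Sxy + Syx, -Sxx + Syy - Szz, Syz + Szy],
        [Sxy - Syx, Szx + Sxz, Syz + Szy, -Sxx - Syy + Szz],
    ])
    lam_max = np.linalg.eigvalsh(K)[-1]
    n = P.shape[0]
    msd = ((P**2).sum() + (Q**2).sum() - 2.0 * lam_max) / n
    return float(np.sqrt(max(msd, 0.0)))


@pytest.fixture
def rng():
    return np.random.default_rng(20250925)


@pytest.fixture(scope="session")
def trefoil_model():
    """One search-accepted (2,3) design model, reused across tests."""
    from knottrp import RepeatArchitecture, SearchRanges, search_design

    return search_design(SearchRanges(p=2, q=3), RepeatArchitecture(20, 3, 25, 3),
                         seed=11, budget=800)


@pytest.fixture(scope="session")
def pentafoil_model():
    """One search-accepted (2,5) design model."""
    from knottrp import RepeatArchitecture, SearchRanges, search_design

    return search_design(SearchRanges(p=2, q=5), RepeatArchitecture(24, 3, 22, 3),
                         seed=11, budget=800)
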