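"""Shared helpers: seed handling and small numeric utilities."""

from __future__ import annotations

import numpy as np

# Stage names used to derive independent per-stage streams from one root seed.
_STAGE_NAMES = (
    "pedigree",
    "environments",
    "breeding",
    "optimum",
    "cuewindow",
    "mixedmodels",
    "selection",
    "predict",
    "residual_sim",
)


def rng_from_seed(seed, *keys) -> np.random.Generator:
    """Return a Generator derived from ``seed`` and an optional tuple of keys.

    All randomness in the package flows through this function so that one root
    seed determines every stage reproducibly.  Keys may be strings (hashed
    stably) or integers.
    """
    ints = []
    for k in keys:
        if isinstance(k, str):
            # stable 32-bit hash (Python's hash() is salted per process)
            h = 2166136261
            for ch in k.encode():
                h = ((h ^ ch) * 16777619) & 0xFFFFFFFF
            ints.append(h)
        else:
            ints.append(int(k) & 0xFFFFFFFF)
    ss = np.random.SeedSequence([int(seed) & 0x7FFFFFFF] + ints)
    return np.random.default_rng(ss)


def as_psd(mat: np.ndarray, tol: float = 1e-8) -> np.ndarray:
    """Project a symmetric matrix onto the PSD cone (eigenvalue clipping)."""
    m = 0.5 * (mat + mat.T)
    w, v = np.linalg.eigh(m)
    if w.min() >= -tol:
        return m
    w = np.clip(w, 0.0, None)
    return (v * w) @ v.T


def check_psd(mat: np.ndarray, tol: float = 1e-8) -> bool:
    m = np.asarray(mat, dtype=float)
    if m.shape[0] != m.shape[1] or not np.allclose(m, m.T, atol=tol):
        return False
    return bool(np.linalg.eigvalsh(0.5 * (m + m.T)).min() >= -tol)
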