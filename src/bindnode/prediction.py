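"""Turning class probabilities into binding calls.

A residue is called binding to class C when its probability for C reaches
the decision threshold (0.5 by default, inclusive); several classes may
fire on the same residue. The derived binary binding call is the logical
OR of the three class calls, and the reliability score of a residue is its
maximum class probability — higher reliability empirically means higher
precision.
"""

from __future__ import annotations

import numpy as np

DEFAULT_THRESHOLD = 0.5


def _check_probs(probs: np.ndarray) -> np.ndarray:
    probs = np.asarray(probs, dtype=np.float64)
    if probs.ndim != 2 or probs.shape[1] != 3:
        raise ValueError(f"expected L×3 probabilities, got {probs.shape}")
    if not np.all(np.isfinite(probs)):
        raise ValueError("non-finite probabilities")
    return probs


def call_binding(probs: np.ndarray, threshold: float = DEFAULT_THRESHOLD) -> np.ndarray:
    """Per-class calls: call[i, c] = 1 iff probs[i, c] >= threshold."""
    if not 0.0 < threshold < 1.0:
        raise ValueError("threshold must be in (0, 1)")
    return (_check_probs(probs) >= threshold).astype(np.int8)


def to_binary(
    probs: np.ndarray, threshold: float = DEFAULT_THRESHOLD
) -> tuple[np.ndarray, np.ndarray]:
    """(binary binding call, reliability) per residue.

    Binding iff any class fires at ``threshold``; reliability is the
    maximum of the three class probabilities.
    """
    probs = _check_probs(probs)
    calls = call_binding(probs, threshold)
    return calls.any(axis=1).astype(np.int8), probs.max(axis=1)


def binary_from_calls(calls: np.ndarray) -> np.ndarray:
    """Binary reduction of an existing L×3 call matrix (logical OR)."""
    calls = np.asarray(calls)
    if calls.ndim != 2 or calls.shape[1] != 3:
        raise ValueError(f"expected L×3 calls, got {calls.shape}")
    return calls.any(axis=1).astype(np.int8)
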