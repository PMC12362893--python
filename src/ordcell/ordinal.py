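"""Ordinal regression over sequential cell states.

An n-state ordered classification is decomposed into n-1 conditional binary
subtasks "is the cell beyond stage j?". Subtask j is trained only on the
nested subset S_j of cells whose true state index exceeds j-1 (S_1 is the
whole training set), so each binary problem is conditioned on having passed
the previous stage. At prediction time the cumulative probabilities
P(y > stage_j) = sigmoid(z_j) are thresholded and counted:

    q = 1 + sum_j I(P(y > stage_j) > threshold)

which is monotone in every cumulative probability and needs no monotonicity
of the sigma sequence itself.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.special import expit


@dataclass
class ConditionalSubsets:
    """The nested training subsets S_1 ⊇ S_2 ⊇ ... ⊇ S_{n-1} (cell indices)."""

    subsets: list[np.ndarray]

    @property
    def sizes(self) -> list[int]:
        return [len(s) for s in self.subsets]

    @property
    def total(self) -> int:
        return int(sum(self.sizes))


def build_subsets(labels: np.ndarray, n_states: int) -> ConditionalSubsets:
    """Construct the n-1 conditional subsets from 1-based state labels.

    S_j contains the cells whose state index is > j-1 (i.e. state j or later);
    S_1 is everything. Emits a warning when a subset beyond S_1 is empty,
    since its binary subtask is then degenerate.
    """
    y = np.asarray(labels, dtype=np.int64)
    if y.ndim != 1:
        raise ValueError("labels must be a 1-d vector of state indices")
    if np.any((y < 1) | (y > n_states)):
        raise ValueError(f"state indices must lie in 1..{n_states}")
    subsets = [np.flatnonzero(y > j - 1) for j in range(1, n_states)]
    for j, s in enumerate(subsets, start=1):
        if len(s) == 0:
            warnings.warn(
                f"conditional subset S_{j} is empty; its binary subtask is degenerate"
            )
    return ConditionalSubsets(subsets)


def ordinal_loss(
    logits: np.ndarray,
    labels: np.ndarray,
    subsets: ConditionalSubsets | None = None,
) -> float:
    """The ordinal regression loss (numpy reference; mirrored by the nn op).

    For each threshold j and each cell in S_j, a binary cross-entropy against
    the indicator y > stage_j, summed and normalized by sum_j |S_j|. The
    "log(sigma(z)) - z" branch is computed as log(1 - sigma(z)) through the
    stable -softplus(z) identity (the two are algebraically equal).
    """
    z = np.atleast_2d(np.asarray(logits, dtype=float))
    y = np.asarray(labels, dtype=np.int64)
    n_states = z.shape[1] + 1
    if subsets is None:
        subsets = build_subsets(y, n_states)
    total = subsets.total
    if total == 0:
        warnings.warn("no subsets to train on; ordinal loss defined as 0")
        return 0.0
    j = np.arange(1, n_states)
    member = (y[:, None] > (j - 1)[None, :]).astype(float)
    target = (y[:, None] > j[None, :]).astype(float)
    log_sig = -np.logaddexp(0.0, -z)
    log_one_minus = -np.logaddexp(0.0, z)
    val = -(member * (target * log_sig + (1 - target) * log_one_minus)).sum() / total
    return float(val)


def decode_state(logits: np.ndarray, threshold: float = 0.5) -> np.ndarray | int:
    """Decode state index q = 1 + sum_j I(sigmoid(z_j) > threshold).

    Accepts a single (n_states-1,) logit vector or a (batch, n_states-1)
    matrix; returns an int or an int vector of 1-based state indices.
    """
    return decode_state_from_probs(expit(np.asarray(logits, dtype=float)), threshold)


def decode_state_from_probs(probs: np.ndarray, threshold: float = 0.5):
    """Same decoding, starting from cumulative probabilities sigma(z_j)."""
    p = np.asarray(probs, dtype=float)
    q = 1 + (p > threshold).sum(axis=-1)
    return int(q) if np.isscalar(q) or q.ndim == 0 else q.astype(np.int64)


def cumulative_probabilities(logits: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Cumulative probabilities sigma(z_j) and derived per-state masses.

    The mass of state j is P(y > stage_{j-1}) - P(y > stage_j), with boundary
    terms 1 and 0. When the sigma sequence is not non-increasing, negative
    differences are clipped at 0 and the masses renormalized — for reporting
    only; decoding never relies on monotonicity.
    """
    z = np.asarray(logits, dtype=float)
    sigma = expit(z)
    padded = np.concatenate(
        [np.ones(sigma.shape[:-1] + (1,)), sigma, np.zeros(sigma.shape[:-1] + (1,))],
        axis=-1,
    )
    masses = padded[..., :-1] - padded[..., 1:]
    masses = np.clip(masses, 0.0, None)
    norm = masses.sum(axis=-1, keepdims=True)
    masses = np.where(norm > 0, masses / norm, masses)
    return sigma, masses


@dataclass
class OrdinalLogits:
    """Per-cell threshold logits plus the decoding threshold."""

    z: np.ndarray
    threshold: float = 0.5

    def __post_init__(self):
        self.z = np.asarray(self.z, dtype=float)
        if not 0 < self.threshold < 1:
            raise ValueError("threshold must lie in (0, 1)")

    @property
    def n_states(self) -> int:
        return self.z.shape[-1] + 1

    def probabilities(self) -> tuple[np.ndarray, np.ndarray]:
        return cumulative_probabilities(self.z)

    def decode(self):
        return decode_state(self.z, self.threshold)
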