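"""Attention-weight wavelength importance for the attention CNN.

The attention layer sits directly on the multi-channel spectral input, so
its softmax weights can be read as the relevance the network assigns to
each wavelength.  The raw importance of a wavelength is the attention it
receives as a *key*, weighted by the spectral values at that wavelength:
summing attention_weight x channel value over samples, heads, query
positions and input channels leaves one scalar per key wavelength.  Raw
profiles are computed per held-out fold at test time, then aggregated as
the across-fold mean of absolute values and normalized by the maximum, so
the reported profile lies in [0, 1] with max exactly 1.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .io import WavelengthGrid


@dataclass
class ImportanceProfile:
    """Normalized per-wavelength relevance (max = 1) on a grid."""

    grid: WavelengthGrid
    importance: np.ndarray
    n_folds: int = 1
    variety: str = ""

    def __post_init__(self) -> None:
        self.importance = np.asarray(self.importance, dtype=float)
        if self.importance.shape != (len(self.grid),):
            raise ValueError("importance length does not match grid")
        if np.any(self.importance < 0) or not np.isclose(
            self.importance.max(), 1.0
        ):
            raise ValueError("profile must be normalized to [0, 1] with max 1")


def weighted_importance(att: np.ndarray, X: np.ndarray) -> np.ndarray:
    """Raw per-wavelength importance from one model's attention.

    Parameters
    ----------
    att : (N, heads, L, L) attention tensor, softmax over the key axis.
    X : (N, L, D) the channel values the model attended over (the scaled
        network input).

    Returns the length-L vector  imp[m] = sum_{n,h,q,d} att[n,h,q,m] X[n,m,d],
    i.e. attention received by wavelength m times the total signal there.
    """
    att = np.asarray(att, dtype=float)
    X = np.asarray(X, dtype=float)
    if att.ndim != 4 or X.ndim != 3:
        raise ValueError("att must be (N, H, L, L) and X (N, L, D)")
    if att.shape[0] != X.shape[0] or att.shape[3] != X.shape[1]:
        raise ValueError(
            f"shape mismatch: attention {att.shape} vs input {X.shape}"
        )
    received = att.sum(axis=(1, 2))  # (N, L): over heads and query positions
    channel_sum = X.sum(axis=2)  # (N, L)
    return np.einsum("nl,nl->l", received, channel_sum)


def aggregate_folds(
    profiles: Sequence[np.ndarray],
    grid: WavelengthGrid | None = None,
    variety: str = "",
):
    """Mean of |raw profiles| across folds, normalized by the maximum."""
    if not profiles:
        raise ValueError("need at least one profile")
    mat = np.vstack([np.abs(np.asarray(p, dtype=float)) for p in profiles])
    if mat.ndim != 2:
        raise ValueError("profiles must be equal-length vectors")
    mean = mat.mean(axis=0)
    peak = mean.max()
    if peak == 0:
        raise ValueError("degenerate all-zero importance profile")
    norm = mean / peak
    if grid is None:
        return norm
    return ImportanceProfile(grid, norm, n_folds=len(profiles), variety=variety)


def top_k(profile: ImportanceProfile, k: int = 5) -> list[tuple[float, float]]:
    """The k most important wavelengths, descending by importance.

    Ties break toward the lower wavelength.  Returns (wavelength_nm,
    importance) pairs.
    """
    if k <= 0:
        raise ValueError("k must be positive")
    L = len(profile.grid)
    if k > L:
        raise ValueError(f"k={k} exceeds the {L} wavelengths")
    order = sorted(
        range(L), key=lambda i: (-profile.importance[i], profile.grid.values[i])
    )
    return [
        (float(profile.grid.values[i]), float(profile.importance[i]))
        for i in order[:k]
    ]
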