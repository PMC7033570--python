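"""Composition of k-spaced amino-acid pairs (CKSAAP).

For each gap k = 0..k_max, the encoder counts every ordered residue pair
``(window[j], window[j+k+1])`` over the 21-letter alphabet (X counts
like any residue) and divides by the number of available pair positions
``L - k - 1``, so each gap block is a proper frequency distribution.
The vector length is ``(k_max + 1) * 21 * 21``.
"""

from __future__ import annotations

from typing import Iterable, Sequence

import numpy as np
from sklearn.base import BaseEstimator, TransformerMixin

from .alphabet import ALPHABET, AA_INDEX
from .io import Fragment

_M = len(ALPHABET)


def encode_cksaap(fragment: Fragment | str, k_max: int = 1) -> np.ndarray:
    """Per-gap ordered-pair frequencies of one window.

    Requires window length ``L >= k_max + 2`` so every gap admits at
    least one pair.
    """
    window = fragment.window if isinstance(fragment, Fragment) else fragment
    if k_max < 0:
        raise ValueError(f"k_max must be >= 0, got {k_max}")
    L = len(window)
    if L < k_max + 2:
        raise ValueError(
            f"window length {L} too short for k_max={k_max} (need >= {k_max + 2})"
        )
    idx = np.fromiter((AA_INDEX[c] for c in window), dtype=np.intp, count=L)
    out = np.zeros((k_max + 1, _M, _M), dtype=float)
    for k in range(k_max + 1):
        first = idx[: L - k - 1]
        second = idx[k + 1 :]
        np.add.at(out[k], (first, second), 1.0)
        out[k] /= L - k - 1
    return out.ravel()


def feature_names_cksaap(k_max: int) -> list[str]:
    """Names like ``k0_AA`` ... ``k1_XX``, matching the value order."""
    if k_max < 0:
        raise ValueError(f"k_max must be >= 0, got {k_max}")
    return [
        f"k{k}_{a}{b}"
        for k in range(k_max + 1)
        for a in ALPHABET
        for b in ALPHABET
    ]


class CKSAAPEncoder(TransformerMixin, BaseEstimator):
    """Stateless k-spaced pair-composition transformer.

    Parameters
    ----------
    k_max : int, default 1
        Largest gap between pair members; pairs are counted for every
        gap 0..k_max.
    """

    def __init__(self, k_max: int = 1):
        self.k_max = k_max

    def fit(self, X: Sequence[str], y=None) -> "CKSAAPEncoder":
        windows = [x.window if isinstance(x, Fragment) else x for x in X]
        if windows:
            self.window_length_ = len(windows[0])
        self.feature_names_ = feature_names_cksaap(self.k_max)
        self.n_features_out_ = len(self.feature_names_)
        return self

    def transform(self, X: Iterable[Fragment | str]) -> np.ndarray:
        return np.array([encode_cksaap(x, self.k_max) for x in X])

    def get_feature_names_out(self, input_features=None) -> np.ndarray:
        return np.asarray(feature_names_cksaap(self.k_max), dtype=object)
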