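"""Information-entropy encoding (IEE) of lysine-centered fragments.

Each training class (butyrylated / non-butyrylated) defines a stochastic
"system": a per-position residue probability matrix ``P^i(alpha)``
estimated as occurrence frequencies over that class's training
fragments. Two families of Shannon entropies summarise a system:

* the entropy of one residue's occurrence profile across positions,
  ``IEA(alpha) = sum_i -P^i(alpha) log P^i(alpha)``; and
* the entropy of the residue distribution at one position,
  ``IEP(i) = sum_alpha -P^i(alpha) log P^i(alpha)``,

with the convention ``0 log 0 = 0`` and base-2 logarithms by default.

A candidate fragment is encoded by the entropy *variation* it induces
when added to each system: for every residue alpha the feature is
``[IEA(alpha) - IEA_s(alpha)]_pos - [IEA(alpha) - IEA_s(alpha)]_neg``
(the subscript s denoting the system after the fragment is added), and
likewise per position. The result is a ``21 + (2N+1)``-dimensional
vector; residues that become more "expected" under the butyrylation
system than under the background system produce a signed signal.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
from sklearn.base import BaseEstimator, TransformerMixin

from .alphabet import ALPHABET, AA_INDEX
from .io import Fragment


def _windows_of(fragments: Iterable[Fragment | str]) -> list[str]:
    return [f.window if isinstance(f, Fragment) else f for f in fragments]


def _window_to_indices(window: str) -> np.ndarray:
    try:
        return np.fromiter((AA_INDEX[c] for c in window), dtype=np.intp,
                           count=len(window))
    except KeyError as exc:
        raise ValueError(f"residue {exc.args[0]!r} outside the alphabet") from None


def _neg_p_log_p(p: np.ndarray, base: float) -> np.ndarray:
    """Elementwise -p*log(p) with 0 log 0 := 0."""
    out = np.zeros_like(p, dtype=float)
    mask = p > 0
    out[mask] = -p[mask] * np.log(p[mask]) / np.log(base)
    return out


@dataclass
class EntropySystem:
    """Per-position residue counts for one training class.

    ``counts`` is a 21 x (2N+1) non-negative integer matrix; column sums
    all equal ``n_samples``. Probabilities are counts / n_samples.
    """

    counts: np.ndarray
    n_samples: int
    polarity: str = "positive"

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=np.int64)
        if self.counts.ndim != 2 or self.counts.shape[0] != len(ALPHABET):
            raise ValueError(
                f"counts must be {len(ALPHABET)} x window-length, "
                f"got shape {self.counts.shape}"
            )
        if (self.counts < 0).any():
            raise ValueError("counts must be non-negative")
        colsums = self.counts.sum(axis=0)
        if not (colsums == self.n_samples).all():
            raise ValueError(
                f"every column of counts must sum to n_samples={self.n_samples}; "
                f"got column sums {colsums}"
            )
        if self.polarity not in ("positive", "negative"):
            raise ValueError(f"unknown polarity {self.polarity!r}")

    @property
    def window_length(self) -> int:
        return self.counts.shape[1]

    @property
    def probabilities(self) -> np.ndarray:
        return self.counts / self.n_samples

    @classmethod
    def from_fragments(
        cls, fragments: Iterable[Fragment | str], polarity: str = "positive"
    ) -> "EntropySystem":
        windows = _windows_of(fragments)
        if not windows:
            raise ValueError("cannot build a system from an empty collection")
        length = len(windows[0])
        if any(len(w) != length for w in windows):
            raise ValueError("fragments have inconsistent window lengths")
        counts = np.zeros((len(ALPHABET), length), dtype=np.int64)
        cols = np.arange(length)
        for w in windows:
            counts[_window_to_indices(w), cols] += 1
        return cls(counts, n_samples=len(windows), polarity=polarity)

    def augmented(self, fragment: Fragment | str) -> "EntropySystem":
        """A new system with the fragment's residues tallied in (input unchanged)."""
        window = fragment.window if isinstance(fragment, Fragment) else fragment
        if len(window) != self.window_length:
            raise ValueError(
                f"fragment window length {len(window)} does not match "
                f"system window length {self.window_length}"
            )
        counts = self.counts.copy()
        counts[_window_to_indices(window), np.arange(len(window))] += 1
        return EntropySystem(counts, self.n_samples + 1, self.polarity)

    def removed(self, fragment: Fragment | str) -> "EntropySystem":
        """Inverse of :meth:`augmented`, for leave-one-out encoding."""
        window = fragment.window if isinstance(fragment, Fragment) else fragment
        if len(window) != self.window_length:
            raise ValueError("window length mismatch")
        counts = self.counts.copy()
        idx = _window_to_indices(window)
        cols = np.arange(len(window))
        if (counts[idx, cols] < 1).any():
            raise ValueError("fragment is not contained in the system counts")
        counts[idx, cols] -= 1
        return EntropySystem(counts, self.n_samples - 1, self.polarity)

    def residue_entropies(self, base: float = 2.0) -> np.ndarray:
        """IEA(alpha) for every alphabet residue (length-21 vector)."""
        return _neg_p_log_p(self.probabilities, base).sum(axis=1)

    def position_entropies(self, base: float = 2.0) -> np.ndarray:
        """IEP(i) for every window position (length-(2N+1) vector)."""
        return _neg_p_log_p(self.probabilities, base).sum(axis=0)

    # --- serialization: TSV count matrix + JSON sidecar ---

    def save(self, prefix: str | Path) -> None:
        prefix = Path(prefix)
        with open(prefix.with_suffix(".tsv"), "w") as fh:
            fh.write("residue\t" + "\t".join(
                str(i + 1) for i in range(self.window_length)) + "\n")
            for aa, row in zip(ALPHABET, self.counts):
                fh.write(aa + "\t" + "\t".join(str(int(c)) for c in row) + "\n")
        meta = {
            "n_samples": int(self.n_samples),
            "polarity": self.polarity,
            "window_half_width": (self.window_length - 1) // 2,
        }
        with open(prefix.with_suffix(".json"), "w") as fh:
            json.dump(meta, fh, indent=1)

    @classmethod
    def load(cls, prefix: str | Path) -> "EntropySystem":
        prefix = Path(prefix)
        with open(prefix.with_suffix(".json")) as fh:
            meta = json.load(fh)
        rows = {}
        with open(prefix.with_suffix(".tsv")) as fh:
            fh.readline()
            for line in fh:
                fields = line.rstrip("\n").split("\t")
                rows[fields[0]] = [int(x) for x in fields[1:]]
        counts = np.array([rows[aa] for aa in ALPHABET], dtype=np.int64)
        return cls(counts, meta["n_samples"], meta["polarity"])


def build_system(
    fragments: Iterable[Fragment | str], polarity: str = "positive"
) -> EntropySystem:
    """Tally per-position residue counts over one class's fragments."""
    return EntropySystem.from_fragments(fragments, polarity)


def entropy_of_residue(
    system: EntropySystem, residue: str, base: float = 2.0
) -> float:
    """IEA(residue): entropy of one residue's profile across positions."""
    if residue not in AA_INDEX:
        raise ValueError(f"residue {residue!r} outside the alphabet")
    return float(system.residue_entropies(base)[AA_INDEX[residue]])


def entropy_of_position(
    system: EntropySystem, position: int, base: float = 2.0
) -> float:
    """IEP(position): entropy of the residue distribution at one position (1-based)."""
    if not 1 <= position <= system.window_length:
        raise ValueError(
            f"position {position} out of range 1..{system.window_length}"
        )
    return float(system.position_entropies(base)[position - 1])


def augmented_system(system: EntropySystem, fragment: Fragment | str) -> EntropySystem:
    """Re-estimate the system over n+1 samples including *fragment*."""
    return system.augmented(fragment)


def encode_fragment(
    pos_system: EntropySystem,
    neg_system: EntropySystem,
    fragment: Fragment | str,
    base: float = 2.0,
) -> np.ndarray:
    """Encode one fragment as its paired entropy variations.

    Returns the concatenation of the 21-value residue block
    (PVIEA - NVIEA) and the (2N+1)-value position block (PVIEP - NVIEP).
    Neither system is mutated.
    """
    if pos_system.window_length != neg_system.window_length:
        raise ValueError("positive and negative systems have different window lengths")
    window = fragment.window if isinstance(fragment, Fragment) else fragment
    if len(window) != pos_system.window_length:
        raise ValueError(
            f"fragment window length {len(window)} does not match systems "
            f"({pos_system.window_length})"
        )
    pos_aug = pos_system.augmented(window)
    neg_aug = neg_system.augmented(window)
    pviea = pos_system.residue_entropies(base) - pos_aug.residue_entropies(base)
    nviea = neg_system.residue_entropies(base) - neg_aug.residue_entropies(base)
    pviep = pos_system.position_entropies(base) - pos_aug.position_entropies(base)
    nviep = neg_system.position_entropies(base) - neg_aug.position_entropies(base)
    return np.concatenate([pviea - nviea, pviep - nviep])


def iee_feature_names(window_length: int) -> list[str]:
    """Feature names matching :func:`encode_fragment` output order."""
    return [f"iee_aa_{aa}" for aa in ALPHABET] + [
        f"iee_pos_{i + 1}" for i in range(window_length)
    ]


class IEEEncoder(TransformerMixin, BaseEstimator):
    """Entropy-variation encoder with the scikit-learn transformer API.

    ``fit(X, y)`` builds the positive and negative entropy systems from
    training windows (``X`` an array-like of window strings, ``y`` binary
    labels with 1 = butyrylated). ``transform`` encodes any windows of
    the same width against the frozen systems; training windows are
    encoded exactly like new ones (added to the system that already
    contains them) unless ``leave_one_out`` is requested via
    :meth:`transform_training`.

    Parameters
    ----------
    log_base : float, default 2.0
        Base of the entropy logarithm. Any base rescales all features
        uniformly ahead of min-max normalization.
    """

    def __init__(self, log_base: float = 2.0):
        self.log_base = log_base

    def fit(self, X: Sequence[str], y: Sequence[int]) -> "IEEEncoder":
        windows = _windows_of(X)
        y = np.asarray(y).ravel()
        if len(windows) != len(y):
            raise ValueError("X and y have different lengths")
        if not ((y == 0) | (y == 1)).all():
            raise ValueError("y must be binary with 1 = positive class")
        pos = [w for w, lab in zip(windows, y) if lab == 1]
        neg = [w for w, lab in zip(windows, y) if lab == 0]
        if not pos or not neg:
            raise ValueError("both classes must be present to build the systems")
        self.pos_system_ = build_system(pos, "positive")
        self.neg_system_ = build_system(neg, "negative")
        if self.pos_system_.window_length != self.neg_system_.window_length:
            raise ValueError("positive and negative windows differ in length")
        self.window_length_ = self.pos_system_.window_length
        self.feature_names_ = iee_feature_names(self.window_length_)
        self.n_features_out_ = len(self.feature_names_)
        return self

    def transform(self, X: Sequence[str]) -> np.ndarray:
        self._check_fitted()
        windows = _windows_of(X)
        return np.array(
            [
                encode_fragment(self.pos_system_, self.neg_system_, w, self.log_base)
                for w in windows
            ]
        )

    def transform_training(
        self, X: Sequence[str], y: Sequence[int]
    ) -> np.ndarray:
        """Leave-one-out encoding of training windows.

        Each window is first removed from its own class's system, then
        encoded as a genuinely new sample. A sensitivity-analysis
        alternative to the default shared transform.
        """
        self._check_fitted()
        windows = _windows_of(X)
        y = np.asarray(y).ravel()
        rows = []
        for w, lab in zip(windows, y):
            pos = self.pos_system_.removed(w) if lab == 1 else self.pos_system_
            neg = self.neg_system_.removed(w) if lab == 0 else self.neg_system_
            rows.append(encode_fragment(pos, neg, w, self.log_base))
        return np.array(rows)

    def get_feature_names_out(self, input_features=None) -> np.ndarray:
        self._check_fitted()
        return np.asarray(self.feature_names_, dtype=object)

    def _check_fitted(self) -> None:
        if not hasattr(self, "pos_system_"):
            raise RuntimeError("IEEEncoder must be fitted before transform")
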