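"""Descriptive statistics of butyrylated vs background fragments.

These are the tabular counterparts of the usual visual diagnostics for a
PTM-site dataset: per-position residue frequencies with information
content (sequence logo), per-(position, residue) enrichment between the
two classes with two-proportion tests (two-sample logo), per-class
entropy profiles, and mean k-spaced pair frequency matrices (heatmap).
All statistics are exported as tidy tables; rendering is left to the
caller.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable

import numpy as np
import pandas as pd
from scipy.stats import norm

from .alphabet import ALPHABET
from .cksaap import encode_cksaap
from .entropy import build_system
from .io import Fragment

_M = len(ALPHABET)


def _windows_of(fragments: Iterable[Fragment | str]) -> list[str]:
    windows = [f.window if isinstance(f, Fragment) else f for f in fragments]
    if not windows:
        raise ValueError("fragment collection is empty")
    if len({len(w) for w in windows}) != 1:
        raise ValueError("fragments have inconsistent window lengths")
    return windows


@dataclass
class PositionFrequencyTable:
    """Per-position residue frequencies for one fragment class."""

    frequencies: pd.DataFrame  # index residues, columns 1-based positions
    information_content: pd.Series  # log2(21) - entropy, per position
    n_samples: int


def position_frequencies(fragments: Iterable[Fragment | str]) -> PositionFrequencyTable:
    """Residue frequency matrix plus per-position information content.

    The information content is ``log2(21) - IEP(i)`` — the height of a
    sequence-logo stack over the 21-letter alphabet.
    """
    windows = _windows_of(fragments)
    system = build_system(windows)
    positions = list(range(1, system.window_length + 1))
    freqs = pd.DataFrame(
        system.probabilities, index=list(ALPHABET), columns=positions
    )
    ic = pd.Series(
        np.log2(_M) - system.position_entropies(base=2.0),
        index=positions,
        name="information_content",
    )
    return PositionFrequencyTable(freqs, ic, system.n_samples)


def residue_enrichment(
    positives: Iterable[Fragment | str],
    negatives: Iterable[Fragment | str],
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Per-(position, residue) difference in proportions between classes.

    Each cell gets a two-proportion z-test (pooled standard error); the
    tidy output has columns position, residue, prop_positive,
    prop_negative, difference, z, p_value and flag
    (enriched/depleted/none at the stated alpha). Swapping the classes
    negates difference and z and swaps the flags.
    """
    pos_windows = _windows_of(positives)
    neg_windows = _windows_of(negatives)
    if len(pos_windows[0]) != len(neg_windows[0]):
        raise ValueError("positive and negative windows differ in length")
    pos_sys = build_system(pos_windows, "positive")
    neg_sys = build_system(neg_windows, "negative")
    n1, n2 = pos_sys.n_samples, neg_sys.n_samples
    rows = []
    for j in range(pos_sys.window_length):
        for i, residue in enumerate(ALPHABET):
            x1 = int(pos_sys.counts[i, j])
            x2 = int(neg_sys.counts[i, j])
            p1, p2 = x1 / n1, x2 / n2
            pooled = (x1 + x2) / (n1 + n2)
            se = np.sqrt(pooled * (1 - pooled) * (1 / n1 + 1 / n2))
            if se == 0:
                z, p_value = 0.0, 1.0
            else:
                z = (p1 - p2) / se
                p_value = 2 * norm.sf(abs(z))
            flag = "none"
            if p_value < alpha:
                flag = "enriched" if p1 > p2 else "depleted"
            rows.append(
                {
                    "position": j + 1,
                    "residue": residue,
                    "prop_positive": p1,
                    "prop_negative": p2,
                    "difference": p1 - p2,
                    "z": z,
                    "p_value": p_value,
                    "flag": flag,
                }
            )
    return pd.DataFrame(rows)


def entropy_profiles(
    positives: Iterable[Fragment | str],
    negatives: Iterable[Fragment | str],
    base: float = 2.0,
) -> dict[str, pd.Series]:
    """Per-residue and per-position entropy series for both classes.

    Returns the four labeled series PIEA/NIEA (indexed by residue) and
    PIEP/NIEP (indexed by 1-based position), computed with the same
    entropy code path as the encoder.
    """
    pos_sys = build_system(_windows_of(positives), "positive")
    neg_sys = build_system(_windows_of(negatives), "negative")
    if pos_sys.window_length != neg_sys.window_length:
        raise ValueError("positive and negative windows differ in length")
    residues = list(ALPHABET)
    positions = list(range(1, pos_sys.window_length + 1))
    return {
        "PIEA": pd.Series(pos_sys.residue_entropies(base), index=residues, name="PIEA"),
        "NIEA": pd.Series(neg_sys.residue_entropies(base), index=residues, name="NIEA"),
        "PIEP": pd.Series(pos_sys.position_entropies(base), index=positions, name="PIEP"),
        "NIEP": pd.Series(neg_sys.position_entropies(base), index=positions, name="NIEP"),
    }


def pair_heatmap(
    fragments: Iterable[Fragment | str], k_max: int = 1
) -> np.ndarray:
    """Mean k-spaced pair frequencies, shape (k_max+1, 21, 21).

    The elementwise mean of each fragment's pair-composition vector;
    every gap slice sums to 1.
    """
    windows = _windows_of(fragments)
    vectors = np.array([encode_cksaap(w, k_max) for w in windows])
    return vectors.mean(axis=0).reshape(k_max + 1, _M, _M)


def heatmap_frame(matrix: np.ndarray, gap: int) -> pd.DataFrame:
    """One gap slice of :func:`pair_heatmap` as a labeled DataFrame."""
    return pd.DataFrame(matrix[gap], index=list(ALPHABET), columns=list(ALPHABET))
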