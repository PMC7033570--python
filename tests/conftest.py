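"""Shared fixtures and independent brute-force oracles.

The oracle implementations deliberately avoid the package's vectorised
code paths: they re-tally probability matrices with dictionaries and
evaluate the entropy and pair-count definitions literally, so agreement
is a genuine cross-check.
"""

from __future__ import annotations

import math
from collections import Counter

import numpy as np
import pytest

from butyrsite import ALPHABET, generate_paper_scale


# ------------------------------------------------------------------ oracles

def brute_probability(windows: list[str]) -> dict[tuple[str, int], float]:
    """P^i(alpha) by literal counting, keyed by (residue, 0-based position)."""
    n = len(windows)
    length = len(windows[0])
    probs: dict[tuple[str, int], float] = {}
    for i in range(length):
        column = Counter(w[i] for w in windows)
        for aa in ALPHABET:
            probs[(aa, i)] = column.get(aa, 0) / n
    return probs


def brute_residue_entropy(windows: list[str], residue: str, base: float = 2.0) -> float:
    """Sum over positions of -p log p for one residue's profile."""
    probs = brute_probability(windows)
    total = 0.0
    for i in range(len(windows[0])):
        p = probs[(residue, i)]
        if p > 0:
            total += -p * math.log(p, base)
    return total


def brute_position_entropy(windows: list[str], position: int, base: float = 2.0) -> float:
    """Sum over the alphabet of -p log p at one 0-based position."""
    probs = brute_probability(windows)
    total = 0.0
    for aa in ALPHABET:
        p = probs[(aa, position)]
        if p > 0:
            total += -p * math.log(p, base)
    return total


def brute_encode(
    pos_windows: list[str],
    neg_windows: list[str],
    fragment: str,
    base: float = 2.0,
) -> np.ndarray:
    """Literal entropy-variation encoding rebuilt from scratch."""
    length = len(fragment)
    aa_block = []
    for aa in ALPHABET:
        pviea = brute_residue_entropy(pos_windows, aa, base) - brute_residue_entropy(
            pos_windows + [fragment], aa, base
        )
        nviea = brute_residue_entropy(neg_windows, aa, base) - brute_residue_entropy(
            neg_windows + [fragment], aa, base
        )
        aa_block.append(pviea - nviea)
    pos_block = []
    for i in range(length):
        pviep = brute_position_entropy(pos_windows, i, base) - brute_position_entropy(
            pos_windows + [fragment], i, base
        )
        nviep = brute_position_entropy(neg_windows, i, base) - brute_position_entropy(
            neg_windows + [fragment], i, base
        )
        pos_block.append(pviep - nviep)
    return np.array(aa_block + pos_block)


def brute_pair_counts(window: str, k: int) -> dict[tuple[str, str], int]:
    """Ordered k-spaced pair counts by a double loop over index pairs."""
    counts: dict[tuple[str, str], int] = {}
    for j in range(len(window)):
        j2 = j + k + 1
        if j2 < len(window):
            pair = (window[j], window[j2])
            counts[pair] = counts.get(pair, 0) + 1
    return counts


def brute_auc(scores, labels) -> float:
    """Mann-Whitney AUC by exhaustive positive-negative pair comparison."""
    pos = [s for s, l in zip(scores, labels) if l == 1]
    neg = [s for s, l in zip(scores, labels) if l == 0]
    wins = sum(
        1.0 if p > n else 0.5 if p == n else 0.0 for p in pos for n in neg
    )
    return wins / (len(pos) * len(neg))


def random_windows(rng: np.random.Generator, n: int, length: int) -> list[str]:
    """Random K-centered windows over the 21-letter alphabet."""
    half = length // 2
    out = []
    for _ in range(n):
        chars = rng.choice(list(ALPHABET), size=length)
        chars[half] = "K"
        out.append("".join(chars))
    return out


# ------------------------------------------------------------------ fixtures

@pytest.fixture
def oracles():
    """Bundle of brute-force reference implementations."""
    return {
        "probability": brute_probability,
        "residue_entropy": brute_residue_entropy,
        "position_entropy": brute_position_entropy,
        "encode": brute_encode,
        "pair_counts": brute_pair_counts,
        "auc": brute_auc,
        "random_windows": random_windows,
    }


@pytest.fixture
def toy_pos_windows():
    return ["AKA", "CKA"]


@pytest.fixture
def toy_neg_windows():
    return ["GKG", "GKC"]


@pytest.fixture(scope="session")
def paper_scale_data():
    """One synthetic dataset at the study's sample sizes (seed fixed)."""
    return generate_paper_scale(seed=7)
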