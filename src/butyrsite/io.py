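"""Sequence and site-annotation I/O, window extraction, dataset assembly.

Candidate sites are lysines (K). A fragment is the (2N+1)-residue window
centered on a K, padded with ``X`` where the window overhangs a protein
terminus. Site tables are tab-separated with a header line
``protein_id<TAB>position<TAB>label`` (1-based positions, label one of
``positive``/``negative``/``unlabeled``); lines starting with ``#`` are
comments.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
from Bio import SeqIO

from .alphabet import AA20, ALPHABET, PAD

LABELS = ("positive", "negative", "unlabeled")


@dataclass(frozen=True)
class SequenceRecord:
    """One protein sequence."""

    id: str
    sequence: str
    description: str = ""

    def __post_init__(self) -> None:
        if not self.sequence:
            raise ValueError(f"sequence for {self.id!r} is empty")


@dataclass(frozen=True)
class SiteAnnotation:
    """One lysine position in one protein with a supervision label."""

    protein_id: str
    position: int  # 1-based
    label: str = "unlabeled"

    def __post_init__(self) -> None:
        if self.position < 1:
            raise ValueError(
                f"position must be 1-based and positive, got {self.position}"
            )
        if self.label not in LABELS:
            raise ValueError(
                f"unknown label {self.label!r}; expected one of {LABELS}"
            )


@dataclass(frozen=True)
class Fragment:
    """A (2N+1)-residue window centered on a lysine."""

    protein_id: str
    center_position: int  # 1-based position of the central K in the protein
    window: str
    label: str = "unlabeled"

    def __post_init__(self) -> None:
        n = len(self.window)
        if n % 2 == 0:
            raise ValueError(f"window length must be odd, got {n}")
        if self.window[n // 2] != "K":
            raise ValueError(
                f"central residue of window {self.window!r} is not K"
            )
        stripped = self.window.strip(PAD)
        if PAD in stripped:
            raise ValueError(
                f"X may appear only as a contiguous prefix/suffix: {self.window!r}"
            )
        bad = set(self.window) - set(ALPHABET)
        if bad:
            raise ValueError(
                f"window contains residues outside the alphabet: {sorted(bad)}"
            )
        if self.label not in LABELS:
            raise ValueError(f"unknown label {self.label!r}")

    @property
    def half_width(self) -> int:
        return len(self.window) // 2


@dataclass
class Dataset:
    """An ordered collection of equal-width fragments."""

    fragments: list[Fragment]
    window_half_width: int
    role: str = "train"

    def __post_init__(self) -> None:
        width = 2 * self.window_half_width + 1
        seen: set[tuple[str, int]] = set()
        for frag in self.fragments:
            if len(frag.window) != width:
                raise ValueError(
                    f"fragment {frag.protein_id}:{frag.center_position} has "
                    f"window length {len(frag.window)}, expected {width}"
                )
            key = (frag.protein_id, frag.center_position)
            if key in seen:
                raise ValueError(f"duplicate fragment for {key}")
            seen.add(key)

    def __len__(self) -> int:
        return len(self.fragments)

    @property
    def windows(self) -> list[str]:
        return [f.window for f in self.fragments]

    @property
    def labels(self) -> np.ndarray:
        """Binary labels (positive=1, negative=0) over labeled fragments."""
        out = []
        for f in self.fragments:
            if f.label == "positive":
                out.append(1)
            elif f.label == "negative":
                out.append(0)
            else:
                raise ValueError(
                    f"fragment {f.protein_id}:{f.center_position} is unlabeled"
                )
        return np.asarray(out, dtype=int)


def _clean_sequence(seq: str, record_id: str, policy: str) -> str:
    seq = seq.upper()
    bad = [c for c in seq if c not in AA20]
    if not bad:
        return seq
    if policy == "strict":
        raise ValueError(
            f"protein {record_id!r} contains non-standard residue(s) "
            f"{sorted(set(bad))}; use policy='mask' to remap them to X"
        )
    if policy == "mask":
        return "".join(c if c in AA20 else PAD for c in seq)
    raise ValueError(f"unknown residue policy {policy!r}; use 'strict' or 'mask'")


def read_fasta(path: str | Path, policy: str = "strict") -> list[SequenceRecord]:
    """Read a FASTA file into :class:`SequenceRecord` objects.

    Parameters
    ----------
    path
        FASTA file; multi-line sequences are allowed.
    policy
        How to treat residues outside the 20-letter alphabet: ``"strict"``
        rejects the file with an error naming the protein and residue,
        ``"mask"`` remaps them to ``X``.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"FASTA file not found: {path}")
    text = path.read_text()
    if not text.strip():
        raise ValueError(f"FASTA file is empty: {path}")
    for lineno, line in enumerate(text.splitlines(), start=1):
        if line.strip():
            if not line.startswith(">"):
                raise ValueError(
                    f"{path}:{lineno}: expected a FASTA header line "
                    f"starting with '>', got {line[:30]!r}"
                )
            break
    records = []
    for rec in SeqIO.parse(str(path), "fasta"):
        records.append(
            SequenceRecord(
                id=rec.id,
                sequence=_clean_sequence(str(rec.seq), rec.id, policy),
                description=rec.description,
            )
        )
    if not records:
        raise ValueError(f"no FASTA records parsed from {path}")
    return records


def write_fasta(records: Iterable[SequenceRecord], path: str | Path) -> None:
    with open(path, "w") as fh:
        for rec in records:
            header = rec.description if rec.description else rec.id
            fh.write(f">{header}\n")
            for i in range(0, len(rec.sequence), 60):
                fh.write(rec.sequence[i : i + 60] + "\n")


def _as_sequence_map(
    sequences: Mapping[str, str] | Iterable[SequenceRecord] | None,
) -> dict[str, str] | None:
    if sequences is None:
        return None
    if isinstance(sequences, Mapping):
        return dict(sequences)
    return {rec.id: rec.sequence for rec in sequences}


def read_sites(
    path: str | Path,
    sequences: Mapping[str, str] | Iterable[SequenceRecord] | None = None,
) -> list[SiteAnnotation]:
    """Read a sites TSV and validate annotations.

    When *sequences* are supplied, each position is checked to be in range
    and, for positive/negative labels, to fall on a lysine. Duplicate
    (protein, position) rows keep the first occurrence with a warning.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"sites file not found: {path}")
    seq_map = _as_sequence_map(sequences)
    sites: list[SiteAnnotation] = []
    seen: set[tuple[str, int]] = set()
    header_done = False
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip() or line.lstrip().startswith("#"):
                continue
            fields = line.split("\t")
            if not header_done:
                header_done = True
                expected = ["protein_id", "position", "label"]
                if [f.strip().lower() for f in fields[:3]] != expected:
                    raise ValueError(
                        f"{path}:{lineno}: expected header "
                        f"'protein_id\\tposition\\tlabel', got {line!r}"
                    )
                continue
            if len(fields) < 3:
                raise ValueError(
                    f"{path}:{lineno}: expected 3 tab-separated columns, "
                    f"got {len(fields)}"
                )
            protein_id, pos_text, label = (f.strip() for f in fields[:3])
            try:
                position = int(pos_text)
            except ValueError:
                raise ValueError(
                    f"{path}:{lineno}: position {pos_text!r} is not an integer"
                ) from None
            site = SiteAnnotation(protein_id, position, label)
            if seq_map is not None:
                if protein_id not in seq_map:
                    raise ValueError(
                        f"{path}:{lineno}: unknown protein {protein_id!r}"
                    )
                seq = seq_map[protein_id]
                if position > len(seq):
                    raise ValueError(
                        f"{path}:{lineno}: position {position} out of range "
                        f"for {protein_id!r} (length {len(seq)})"
                    )
                if label in ("positive", "negative") and seq[position - 1] != "K":
                    raise ValueError(
                        f"{path}:{lineno}: residue at {protein_id}:{position} "
                        f"is {seq[position - 1]!r}, not a lysine"
                    )
            key = (protein_id, position)
            if key in seen:
                warnings.warn(
                    f"duplicate annotation for {key}; keeping the first",
                    stacklevel=2,
                )
                continue
            seen.add(key)
            sites.append(site)
    return sites


def write_sites(sites: Iterable[SiteAnnotation], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("protein_id\tposition\tlabel\n")
        for s in sites:
            fh.write(f"{s.protein_id}\t{s.position}\t{s.label}\n")


def extract_fragment(
    seq: SequenceRecord, position: int, n: int, label: str = "unlabeled"
) -> Fragment:
    """Cut the (2n+1)-residue window centered on the K at *position*.

    Overhang beyond either terminus is filled with ``X``: an upstream
    deficit becomes a leading-X prefix, a downstream deficit a trailing-X
    suffix.
    """
    if not 1 <= position <= len(seq.sequence):
        raise ValueError(
            f"position {position} out of range for {seq.id!r} "
            f"(length {len(seq.sequence)})"
        )
    if seq.sequence[position - 1] != "K":
        raise ValueError(
            f"residue at {seq.id}:{position} is "
            f"{seq.sequence[position - 1]!r}, not a lysine"
        )
    start = position - 1 - n
    stop = position - 1 + n + 1
    left_pad = max(0, -start)
    right_pad = max(0, stop - len(seq.sequence))
    core = seq.sequence[max(0, start) : min(len(seq.sequence), stop)]
    window = PAD * left_pad + core + PAD * right_pad
    return Fragment(seq.id, position, window, label)


def enumerate_candidate_sites(seq: SequenceRecord) -> list[int]:
    """All 1-based lysine positions in the sequence, ascending."""
    return [i + 1 for i, c in enumerate(seq.sequence) if c == "K"]


def sample_negatives(
    sequences: Iterable[SequenceRecord],
    positives: Iterable[SiteAnnotation],
    count: int,
    seed: int,
) -> list[SiteAnnotation]:
    """Draw *count* distinct non-positive K sites without replacement.

    The draw is reproducible for a fixed *seed* and never overlaps a
    positive annotation.
    """
    positive_keys = {(p.protein_id, p.position) for p in positives}
    candidates = [
        (rec.id, pos)
        for rec in sequences
        for pos in enumerate_candidate_sites(rec)
        if (rec.id, pos) not in positive_keys
    ]
    if count > len(candidates):
        raise ValueError(
            f"requested {count} negatives but only {len(candidates)} "
            f"non-positive K sites are available"
        )
    rng = np.random.default_rng(seed)
    chosen = rng.choice(len(candidates), size=count, replace=False)
    return [
        SiteAnnotation(candidates[i][0], candidates[i][1], "negative")
        for i in sorted(chosen)
    ]


def build_dataset(
    sequences: Iterable[SequenceRecord],
    sites: Iterable[SiteAnnotation],
    n: int,
    role: str = "train",
) -> Dataset:
    """Extract one fragment per annotated site at half-width *n*."""
    seq_map = {rec.id: rec for rec in sequences}
    fragments = []
    for site in sites:
        if site.protein_id not in seq_map:
            raise ValueError(f"unknown protein {site.protein_id!r}")
        fragments.append(
            extract_fragment(seq_map[site.protein_id], site.position, n, site.label)
        )
    return Dataset(fragments, window_half_width=n, role=role)


def write_fragments(dataset: Dataset, path: str | Path) -> None:
    """Write a fragments TSV: protein_id, position, window, label."""
    with open(path, "w") as fh:
        fh.write("protein_id\tposition\twindow\tlabel\n")
        for f in dataset.fragments:
            fh.write(f"{f.protein_id}\t{f.center_position}\t{f.window}\t{f.label}\n")


def read_fragments(path: str | Path, role: str = "train") -> Dataset:
    """Read a fragments TSV back into a :class:`Dataset` (lossless)."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"fragments file not found: {path}")
    fragments = []
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if header[:4] != ["protein_id", "position", "window", "label"]:
            raise ValueError(f"{path}: unexpected fragments header {header}")
        for line in fh:
            if not line.strip():
                continue
            pid, pos, window, label = line.rstrip("\n").split("\t")[:4]
            fragments.append(Fragment(pid, int(pos), window, label))
    if not fragments:
        raise ValueError(f"{path}: no fragments")
    return Dataset(fragments, window_half_width=len(fragments[0].window) // 2, role=role)
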