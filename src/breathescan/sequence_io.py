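"""Promoter sequence input, validation, encoding and synthesis.

The simulated object is a one-dimensional chain of base pairs.  Sequence
identity enters the physics only through the strength of the intra-base-pair
potential, so a sequence is reduced to a two-class code (A-T vs C-G pair).
G-C "clamp" pairs are appended at both ends of every simulated chain to keep
the boundaries closed; they are bookkept here and excluded from all analysis.

Genomic positions are labelled relative to the translation start: +1 is the
'A' of the ATG codon, upstream positions are negative, and there is no
position 0.  When a sequence carries no ATG annotation the whole sequence is
treated as upstream of the gene (labels -N .. -1).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

__all__ = [
    "PromoterSequence",
    "EncodedChain",
    "SyntheticWindow",
    "read_fasta",
    "write_fasta",
    "encode",
    "at_content",
    "generate_synthetic_promoter",
]

_VALID = set("ACGT")

AT = 0
GC = 1


@dataclass(frozen=True)
class PromoterSequence:
    """A validated nucleotide sequence.

    Parameters
    ----------
    id : str
        Record identifier.
    bases : str
        Uppercase A/C/G/T string.
    atg_offset : int, optional
        0-based index of the 'A' of the translation-start ATG within
        ``bases``.  ``None`` means the sequence is entirely upstream.
    """

    id: str
    bases: str
    atg_offset: Optional[int] = None

    def __post_init__(self):
        bad = [(i, b) for i, b in enumerate(self.bases) if b not in _VALID]
        if bad:
            i, b = bad[0]
            raise ValueError(
                f"record {self.id!r}: invalid symbol {b!r} at position {i}"
            )
        if len(self.bases) == 0:
            raise ValueError(f"record {self.id!r}: empty sequence")
        if self.atg_offset is not None and not (
            0 <= self.atg_offset < len(self.bases)
        ):
            raise ValueError(
                f"record {self.id!r}: atg_offset {self.atg_offset} outside "
                f"sequence of length {len(self.bases)}"
            )

    def __len__(self) -> int:
        return len(self.bases)


@dataclass(frozen=True)
class SyntheticWindow:
    """Ground-truth coordinates of a planted A/T-rich window."""

    start: int
    width: int
    at_fraction: float

    @property
    def stop(self) -> int:
        return self.start + self.width


@dataclass
class EncodedChain:
    """Two-class (A-T / C-G) encoding of a sequence plus boundary clamps.

    Attributes
    ----------
    pair_class : ndarray of int8, length N
        ``AT`` (0) or ``GC`` (1) per simulated site, clamps included.
    analysis_mask : ndarray of bool, length N
        True on real-sequence sites, False on clamps.
    position_labels : ndarray of int, length N
        Signed genomic label per site (no 0; +1 at the 'A' of ATG).  Clamp
        sites carry the sentinel 0 and must never be read through the mask.
    """

    seq_id: str
    pair_class: np.ndarray
    analysis_mask: np.ndarray
    position_labels: np.ndarray
    clamp_len: int

    def __post_init__(self):
        self.pair_class = np.asarray(self.pair_class, dtype=np.int8)
        self.analysis_mask = np.asarray(self.analysis_mask, dtype=bool)
        self.position_labels = np.asarray(self.position_labels, dtype=np.int64)

    def __len__(self) -> int:
        return len(self.pair_class)

    @property
    def n_sites(self) -> int:
        return len(self.pair_class)

    def label_of_site(self, site: int) -> int:
        """Genomic label of a simulated site; clamps map to the nearest
        real site's label."""
        mask_idx = np.flatnonzero(self.analysis_mask)
        site = int(np.clip(site, mask_idx[0], mask_idx[-1]))
        return int(self.position_labels[site])

    def site_of_label(self, label: int) -> int:
        hits = np.flatnonzero(self.position_labels == label)
        if hits.size == 0:
            raise KeyError(f"label {label} not present")
        return int(hits[0])


def _normalize(raw: str, rec_id: str) -> str:
    s = raw.upper().replace("U", "T")
    for i, b in enumerate(s):
        if b not in _VALID:
            raise ValueError(
                f"record {rec_id!r}: invalid symbol {b!r} at position {i} "
                "(IUPAC ambiguity codes, including N, are rejected)"
            )
    return s


def read_fasta(path) -> list[PromoterSequence]:
    """Read a multi-record FASTA file into validated sequences.

    Lowercase letters and U are normalized; any symbol outside A/C/G/T/U is
    an error naming the record and offending position.
    """
    records = list(SeqIO.parse(str(path), "fasta"))
    if not records:
        raise ValueError(f"no FASTA records found in {path}")
    out = []
    for rec in records:
        out.append(PromoterSequence(id=rec.id, bases=_normalize(str(rec.seq), rec.id)))
    return out


def write_fasta(seqs: Sequence[PromoterSequence], path) -> None:
    recs = [SeqRecord(Seq(s.bases), id=s.id, description="") for s in seqs]
    SeqIO.write(recs, str(path), "fasta")


def encode(seq: PromoterSequence, clamp_len: int = 10) -> EncodedChain:
    """Encode a sequence as an A-T/G-C chain with ``clamp_len`` G-C clamps
    appended at each end."""
    if clamp_len < 0:
        raise ValueError("clamp_len must be >= 0")
    n = len(seq)
    classes = np.fromiter(
        (AT if b in "AT" else GC for b in seq.bases), dtype=np.int8, count=n
    )
    pair_class = np.concatenate(
        [np.full(clamp_len, GC, np.int8), classes, np.full(clamp_len, GC, np.int8)]
    )
    mask = np.zeros(n + 2 * clamp_len, dtype=bool)
    mask[clamp_len : clamp_len + n] = True

    atg = seq.atg_offset if seq.atg_offset is not None else n
    idx = np.arange(n)
    labels_seq = np.where(idx >= atg, idx - atg + 1, idx - atg)
    labels = np.zeros(n + 2 * clamp_len, dtype=np.int64)
    labels[clamp_len : clamp_len + n] = labels_seq
    return EncodedChain(
        seq_id=seq.id,
        pair_class=pair_class,
        analysis_mask=mask,
        position_labels=labels,
        clamp_len=clamp_len,
    )


def at_content(seq: PromoterSequence) -> float:
    """Fraction of A or T bases in the (unclamped) sequence."""
    n = len(seq)
    if n == 0:
        raise ValueError("empty sequence")
    return sum(1 for b in seq.bases if b in "AT") / n


def generate_synthetic_promoter(
    length: int,
    background_at: float,
    windows: Sequence[tuple[int, int, float]] = (),
    seed: int = 0,
    id: str = "synthetic",
) -> tuple[PromoterSequence, list[SyntheticWindow]]:
    """Draw a random promoter-like sequence with planted A/T-rich windows.

    Each site is A or T with probability ``background_at`` outside the
    windows and ``window_at`` inside; within the A/T (or C/G) choice the two
    letters are equiprobable.  Windows are (start, width, window_at) in
    0-based sequence coordinates and must not overlap.

    Returns the sequence together with the ground-truth window coordinates.
    """
    if length <= 0:
        raise ValueError("length must be positive")
    if not 0.0 <= background_at <= 1.0:
        raise ValueError("background_at must be in [0, 1]")
    wins = [SyntheticWindow(int(s), int(w), float(f)) for s, w, f in windows]
    for w in wins:
        if w.width <= 0 or w.start < 0 or w.stop > length:
            raise ValueError(f"window {w} outside sequence of length {length}")
        if not 0.0 <= w.at_fraction <= 1.0:
            raise ValueError("window at_fraction must be in [0, 1]")
    for a, b in zip(sorted(wins, key=lambda w: w.start), sorted(wins, key=lambda w: w.start)[1:]):
        if b.start < a.stop:
            raise ValueError(f"overlapping windows {a} and {b}")

    p_at = np.full(length, background_at)
    for w in wins:
        p_at[w.start : w.stop] = w.at_fraction
    rng = np.random.default_rng(seed)
    is_at = rng.random(length) < p_at
    which = rng.integers(0, 2, size=length)  # A/T or C/G letter choice
    letters = np.where(is_at, np.where(which == 0, "A", "T"), np.where(which == 0, "C", "G"))
    seq = PromoterSequence(id=id, bases="".join(letters))
    return seq, wins


def write_ground_truth(windows: Sequence[SyntheticWindow], path) -> None:
    """Sidecar JSON with the planted-window coordinates of a synthetic run."""
    payload = [
        {"start": w.start, "width": w.width, "at_fraction": w.at_fraction}
        for w in windows
    ]
    Path(path).write_text(json.dumps(payload, indent=1))
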