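"""Sequence composition features for contig binning.

Two signals are extracted per contig: GC content and canonical
tetranucleotide frequencies (TNF). Both are genome-specific signatures:
contigs drawn from the same genome share a composition profile, which the
refinement stage uses to purge contigs that coverage clustering mis-binned.

Tetranucleotides are collapsed by reverse complement because an assembled
contig has no defined strand: each 4-mer is mapped to the lexicographically
smaller of itself and its reverse complement, giving 136 canonical classes
(16 palindromes plus 120 complementary pairs).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

N_CANONICAL = 136

_BASE_CODE = np.full(256, -1, dtype=np.int64)
for _i, _b in enumerate("ACGT"):
    _BASE_CODE[ord(_b)] = _i
    _BASE_CODE[ord(_b.lower())] = _i


def _revcomp_code(code: int) -> int:
    """Reverse-complement of a 4-mer encoded base-4 (A=0, C=1, G=2, T=3)."""
    rc = 0
    for _ in range(4):
        rc = rc * 4 + (3 - code % 4)
        code //= 4
    return rc


def _canonical_table() -> tuple[np.ndarray, list[str]]:
    canon = [min(c, _revcomp_code(c)) for c in range(256)]
    keys = sorted(set(canon))
    slot = {k: i for i, k in enumerate(keys)}
    table = np.array([slot[c] for c in canon], dtype=np.int64)
    alphabet = "ACGT"
    names = []
    for k in keys:
        s, c = "", k
        for _ in range(4):
            s = alphabet[c % 4] + s
            c //= 4
        names.append(s)
    return table, names


#: maps each of the 256 raw 4-mer codes to its canonical slot in [0, 136)
CANONICAL_SLOT, CANONICAL_KMERS = _canonical_table()
assert len(CANONICAL_KMERS) == N_CANONICAL


@dataclass(frozen=True)
class ContigFeatures:
    """GC fraction and canonical TNF vector of one contig."""

    gc: float
    tnf: np.ndarray

    def __post_init__(self) -> None:
        if not 0.0 <= self.gc <= 1.0:
            raise ValueError(f"gc must lie in [0, 1], got {self.gc}")
        if self.tnf.shape != (N_CANONICAL,):
            raise ValueError("tnf must be a 136-vector")


def _encode(sequence: str) -> np.ndarray:
    return _BASE_CODE[np.frombuffer(sequence.encode("ascii"), dtype=np.uint8)]


def gc_content(sequence: str) -> float:
    """GC fraction over unambiguous bases; N and other symbols are excluded."""
    codes = _encode(sequence)
    acgt = codes >= 0
    n_valid = int(acgt.sum())
    if n_valid == 0:
        raise ValueError("sequence contains no A/C/G/T bases")
    gc = int(((codes == 1) | (codes == 2)).sum())
    return gc / n_valid


def tetranucleotide_freqs(sequence: str, *, name: str | None = None) -> np.ndarray:
    """Canonical tetranucleotide relative frequencies of a sequence.

    Sliding windows of width 4 and step 1; windows containing any non-ACGT
    symbol are skipped; counts are strand-collapsed to the 136 canonical
    classes and normalised to sum to 1.

    Raises ``ValueError`` (naming the contig when ``name`` is given) if no
    window is free of ambiguous bases.
    """
    codes = _encode(sequence)
    if codes.size < 4:
        raise ValueError(
            f"sequence {name or '<unnamed>'} shorter than 4 bp: no 4-mer window"
        )
    w0, w1, w2, w3 = codes[:-3], codes[1:-2], codes[2:-1], codes[3:]
    valid = (w0 >= 0) & (w1 >= 0) & (w2 >= 0) & (w3 >= 0)
    if not valid.any():
        raise ValueError(
            f"sequence {name or '<unnamed>'} has no 4-mer window free of "
            "ambiguous bases"
        )
    kmers = (w0[valid] * 64 + w1[valid] * 16 + w2[valid] * 4 + w3[valid])
    counts = np.bincount(CANONICAL_SLOT[kmers], minlength=N_CANONICAL)
    return counts / counts.sum()


def contig_features(sequence: str, *, name: str | None = None) -> ContigFeatures:
    """Convenience bundle of :func:`gc_content` and :func:`tetranucleotide_freqs`."""
    return ContigFeatures(gc=gc_content(sequence), tnf=tetranucleotide_freqs(sequence, name=name))
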