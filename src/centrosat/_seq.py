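"""Low-level DNA string utilities shared across the pipeline.

Sequences are plain upper-case ACGT strings throughout; numpy is used only
for bulk k-mer extraction where Python loops would dominate runtime.
"""

from __future__ import annotations

import numpy as np

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")

# base -> 2-bit code; anything outside ACGT maps to 0 (A)
_ENC = np.zeros(256, dtype=np.int64)
_ENC[ord("C")] = 1
_ENC[ord("G")] = 2
_ENC[ord("T")] = 3


def revcomp(seq: str) -> str:
    """Reverse complement of a DNA string."""
    return seq.translate(_COMPLEMENT)[::-1]


def rotations(seq: str) -> list[str]:
    """All circular rotations of ``seq`` (length = len(seq), may repeat)."""
    return [seq[i:] + seq[:i] for i in range(len(seq))]


def canonical_monomer(seq: str) -> str:
    """Canonical form of a tandem-repeat monomer.

    Lexicographically minimal string over all rotations of the monomer and
    of its reverse complement, making downstream comparisons invariant to
    read-out register and strand.
    """
    candidates = rotations(seq) + rotations(revcomp(seq))
    return min(candidates)


def kmer_codes(seq: str, k: int) -> np.ndarray:
    """2-bit-packed integer codes of every k-mer of ``seq`` (len(seq)-k+1).

    k must be <= 31 so codes fit in int64. Non-ACGT characters are encoded
    as A; callers on simulated data never see them.
    """
    if k > 31:
        raise ValueError("k must be <= 31 for int64 packing")
    enc = _ENC[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]
    n = len(seq) - k + 1
    if n <= 0:
        return np.empty(0, dtype=np.int64)
    codes = np.zeros(n, dtype=np.int64)
    for j in range(k):
        codes = codes * 4 + enc[j : j + n]
    return codes


def random_dna(rng: np.random.Generator, length: int) -> str:
    """Uniform i.i.d. DNA of the given length."""
    return "".join(np.array(list("ACGT"))[rng.integers(0, 4, size=length)])


def mutate(rng: np.random.Generator, seq: str, rate: float) -> str:
    """Substitute each base independently with probability ``rate``.

    Substitutions always change the base (chosen uniformly among the other
    three), so ``rate`` is the expected per-base divergence from ``seq``.
    """
    if rate <= 0:
        return seq
    arr = list(seq)
    hits = np.flatnonzero(rng.random(len(arr)) < rate)
    for i in hits:
        arr[i] = "ACGT".replace(arr[i], "")[rng.integers(0, 3)]
    return "".join(arr)
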