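"""Low-level DNA sequence utilities shared across the package.

Everything here operates on plain uppercase strings over {A,C,G,T,N}.
Coordinates are 0-based half-open throughout the package.
"""

from __future__ import annotations

import numpy as np

DNA = "ACGT"
_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")

#: conserved box C motif of box C/D snoRNAs
BOX_C = "TGATGA"
#: box D variants; the canonical form first
BOX_D = ("CTGA", "ATGA")
#: canonical fungal 5' splice-donor consensus
DONOR = "GTAAGT"
#: canonical fungal branch-point consensus
BRANCH = "TACTAAC"
#: 3' splice acceptor dinucleotide
ACCEPTOR = "AG"


def revcomp(seq: str) -> str:
    """Reverse complement of *seq* (N maps to N)."""
    return seq.translate(_COMPLEMENT)[::-1]


def hamming(a: str, b: str) -> int:
    """Mismatch count between equal-length words; N counts as a mismatch."""
    if len(a) != len(b):
        raise ValueError("hamming requires equal-length words")
    return sum(1 for x, y in zip(a, b) if x != y or x == "N" or y == "N")


def motif_mismatches(word: str, motif: str) -> int:
    """Mismatches of *word* against *motif*; 'N' in the word never matches."""
    return sum(1 for x, y in zip(word, motif) if x != y or x == "N")


def random_dna(rng: np.random.Generator, n: int) -> str:
    """i.i.d. uniform DNA of length *n*."""
    return "".join(DNA[i] for i in rng.integers(0, 4, size=n))


def _has_confounding_motif(seq: str) -> int:
    """Return the index of the first exact donor word or near-branch word
    (within 2 mismatches of the branch consensus) in *seq*, or -1."""
    for i in range(len(seq) - len(DONOR) + 1):
        if seq[i : i + len(DONOR)] == DONOR:
            return i
    for i in range(len(seq) - len(BRANCH) + 1):
        if motif_mismatches(seq[i : i + len(BRANCH)], BRANCH) <= 2:
            return i
    return -1


def random_dna_clean(rng: np.random.Generator, n: int, max_tries: int = 200) -> str:
    """Random DNA free of exact donor words and near-branch-consensus words.

    Used for cluster-internal filler so that planted splice signals are the
    unique exact-consensus signals in a simulated cluster (unambiguous ground
    truth).  Offending windows are locally resampled.
    """
    seq = list(random_dna(rng, n))
    for _ in range(max_tries):
        i = _has_confounding_motif("".join(seq))
        if i < 0:
            return "".join(seq)
        w = len(BRANCH)
        for j in range(i, min(i + w, n)):
            seq[j] = DNA[rng.integers(0, 4)]
    raise RuntimeError("could not generate motif-free sequence")


def is_clean(seq: str) -> bool:
    """True when *seq* carries no exact donor / near-branch confounder."""
    return _has_confounding_motif(seq) < 0


def mutate(
    seq: str,
    rate: float,
    rng: np.random.Generator,
    protected: set[int] | frozenset[int] = frozenset(),
) -> str:
    """Apply i.i.d. point substitutions at *rate* per site, skipping
    *protected* offsets.  Substitutions always change the base."""
    if rate <= 0.0 or not seq:
        return seq
    arr = np.frombuffer(seq.encode(), dtype=np.uint8).copy()
    hit = rng.random(len(seq)) < rate
    if protected:
        idx = np.fromiter(protected, dtype=np.int64)
        hit[idx[idx < len(seq)]] = False
    (pos,) = np.nonzero(hit)
    if pos.size == 0:
        return seq
    lut = {ord(b): [ord(c) for c in DNA if c != b] for b in DNA}
    for p in pos:
        base = int(arr[p])
        if base not in lut:  # leave N untouched
            continue
        arr[p] = lut[base][rng.integers(0, 3)]
    return arr.tobytes().decode()
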