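"""Tetranucleotide composition profiles and compositional distance.

A DNA sequence is summarized as the relative frequencies of all 256
overlapping 4-mers over {A, C, G, T}. Compositional similarity between two
sequences is the Manhattan (L1) distance between their frequency vectors,
which lies in [0, 2] for vectors on the probability simplex. Windows
containing any non-ACGT symbol (N and other IUPAC codes) are skipped, and
the denominator is the number of windows actually counted, so vectors stay
on the simplex in the presence of ambiguous bases.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

K = 4
N_KMERS = 4**K  # 256

#: strand-handling modes for window counting
STRAND_MODES = ("forward", "symmetric")

_CODE = np.full(256, -1, dtype=np.int8)
for _i, _b in enumerate("ACGT"):
    _CODE[ord(_b)] = _i
    _CODE[ord(_b.lower())] = _i

# permutation sending each 4-mer index to the index of its reverse complement
_RC = np.array(
    [
        ((3 - (i & 3)) << 6)
        | ((3 - ((i >> 2) & 3)) << 4)
        | ((3 - ((i >> 4) & 3)) << 2)
        | (3 - ((i >> 6) & 3))
        for i in range(N_KMERS)
    ],
    dtype=np.intp,
)


def kmer_index(kmer: str) -> int:
    """Lexicographic index of a 4-mer (AAAA=0 ... TTTT=255)."""
    if len(kmer) != K:
        raise ValueError(f"expected a {K}-mer, got {kmer!r}")
    idx = 0
    for ch in kmer:
        code = _CODE[ord(ch)]
        if code < 0:
            raise ValueError(f"non-ACGT symbol in {kmer!r}")
        idx = (idx << 2) | int(code)
    return idx


@dataclass
class KmerVector:
    """256-dimensional tetranucleotide relative-frequency vector.

    ``values`` sums to 1 when ``n_counted > 0`` and is all-zero otherwise.
    ``n_counted`` is the number of valid (all-ACGT) 4-mer windows observed
    on the forward strand.
    """

    values: np.ndarray = field(repr=False)
    n_counted: int = 0

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.shape != (N_KMERS,):
            raise ValueError(f"values must have shape ({N_KMERS},)")

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, KmerVector):
            return NotImplemented
        return self.n_counted == other.n_counted and np.array_equal(
            self.values, other.values
        )


def _zero_vector() -> KmerVector:
    return KmerVector(values=np.zeros(N_KMERS), n_counted=0)


def tetra_vector(seq: str, strand: str = "forward") -> KmerVector:
    """Compute the tetranucleotide frequency vector of ``seq``.

    Case-insensitive; windows containing any symbol other than A/C/G/T are
    skipped entirely. Sequences with no valid window yield an all-zero
    vector with ``n_counted = 0`` (callers decide how to treat those; the
    classifier marks such reads ``too_short``).

    With ``strand="symmetric"`` every window contributes both itself and
    its reverse complement, making the vector identical for a sequence and
    its reverse complement.
    """
    if strand not in STRAND_MODES:
        raise ValueError(f"strand must be one of {STRAND_MODES}, got {strand!r}")
    try:
        raw = np.frombuffer(seq.encode("ascii"), dtype=np.uint8)
    except UnicodeEncodeError as exc:
        raise ValueError("sequence contains non-ASCII characters") from exc
    if raw.size < K:
        return _zero_vector()
    codes = _CODE[raw]
    valid = codes >= 0
    safe = np.where(valid, codes, 0).astype(np.intp)
    idx = (safe[:-3] << 6) | (safe[1:-2] << 4) | (safe[2:-1] << 2) | safe[3:]
    ok = valid[:-3] & valid[1:-2] & valid[2:-1] & valid[3:]
    n = int(ok.sum())
    if n == 0:
        return _zero_vector()
    counts = np.bincount(idx[ok], minlength=N_KMERS).astype(np.float64)
    if strand == "symmetric":
        counts = counts + counts[_RC]
    return KmerVector(values=counts / counts.sum(), n_counted=n)


def manhattan(a: KmerVector, b: KmerVector) -> float:
    """Manhattan (L1) distance between two normalized 4-mer vectors.

    Bounded by 2 on the simplex; 0 iff the vectors are identical. Raises
    on degenerate (all-zero) vectors — there is no meaningful composition
    to compare.
    """
    if a.n_counted == 0 or b.n_counted == 0:
        raise ValueError("cannot compute distance for a vector with no counted windows")
    return float(np.abs(a.values - b.values).sum())


def reverse_complement(seq: str) -> str:
    return seq.translate(_RC_TABLE)[::-1]


_RC_TABLE = str.maketrans("ACGTacgtNn", "TGCAtgcaNn")
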