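"""MinHash sketching of genomes and Mash distance matrices.

A genome is reduced to the *s* smallest 64-bit hash values of its canonical
k-mers (a "bottom sketch").  For two sketches the Jaccard index of the
underlying k-mer sets is estimated from the bottom-s values of the merged
sketch, and converted to an evolutionary distance with the Mash formula

    D = -(1/k) * ln( 2j / (1 + j) )

which approximates 1 - ANI for moderately diverged genomes.  ``j = 0``
(no shared hashes) is capped at D = 1.0 so the distance stays a bounded
quantity suitable for clustering.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

DEFAULT_KMER_SIZE = 21
DEFAULT_SKETCH_SIZE = 1000

#: Constant seed mixed into the k-mer hash.  Fixed so that sketches are
#: reproducible across runs and platforms; not user-tunable by design.
HASH_SEED = np.uint64(0x9E2A83C1)

_BASE_CODES = np.full(256, 255, dtype=np.uint8)
for _i, _b in enumerate(b"ACGT"):
    _BASE_CODES[_b] = _i
    _BASE_CODES[_b + 32] = _i  # lower case


def _splitmix64(x: np.ndarray) -> np.ndarray:
    """Vectorised splitmix64 finalizer (64-bit avalanche)."""
    with np.errstate(over="ignore"):
        z = (x + np.uint64(0x9E3779B97F4A7C15)).astype(np.uint64)
        z ^= z >> np.uint64(30)
        z *= np.uint64(0xBF58476D1CE4E5B9)
        z ^= z >> np.uint64(27)
        z *= np.uint64(0x94D049BB133111EB)
        z ^= z >> np.uint64(31)
    return z


def canonical_kmer_codes(sequence: str, k: int) -> tuple[np.ndarray, int]:
    """Return 2-bit-packed canonical k-mer codes and the count of skipped windows.

    A k-mer and its reverse complement are collapsed onto the lexicographically
    smaller of their integer encodings.  Windows containing a non-ACGT base are
    skipped (their count is returned and logged by callers).
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    if k > 31:
        raise ValueError("k-mer length above 31 does not fit a 64-bit code")
    seq = np.frombuffer(sequence.encode("ascii"), dtype=np.uint8)
    n = seq.size
    if n < k:
        raise ValueError(f"sequence length {n} is shorter than k={k}")
    codes = _BASE_CODES[seq]
    valid = codes != 255
    m = n - k + 1
    fwd = np.zeros(m, dtype=np.uint64)
    rev = np.zeros(m, dtype=np.uint64)
    codes64 = np.where(valid, codes, 0).astype(np.uint64)
    comp64 = np.uint64(3) - codes64
    for j in range(k):
        fwd |= codes64[j : j + m] << np.uint64(2 * (k - 1 - j))
        rev |= comp64[j : j + m] << np.uint64(2 * j)
    # windows touching an invalid base are dropped
    bad = np.cumsum(np.concatenate(([0], (~valid).astype(np.int64))))
    window_ok = (bad[k:] - bad[:-k]) == 0
    canon = np.minimum(fwd[window_ok], rev[window_ok])
    return canon, int(m - window_ok.sum())


@dataclass
class Sketch:
    """Bottom-s MinHash sketch of one genome.

    ``hashes`` is a strictly increasing array of at most ``s`` 64-bit values.
    """

    genome_id: str
    k: int
    s: int
    hashes: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        self.hashes = np.asarray(self.hashes, dtype=np.uint64)
        if self.hashes.size > self.s:
            raise ValueError("sketch holds more hashes than its size bound")
        if self.hashes.size > 1 and not np.all(self.hashes[1:] > self.hashes[:-1]):
            raise ValueError("sketch hashes must be strictly increasing")


def sketch(
    sequences: str | list[str],
    genome_id: str = "",
    k: int = DEFAULT_KMER_SIZE,
    s: int = DEFAULT_SKETCH_SIZE,
) -> Sketch:
    """Sketch a genome given as one sequence or a list of contig sequences.

    K-mers are pooled across contigs; no k-mer spans a contig boundary.
    """
    if isinstance(sequences, str):
        sequences = [sequences]
    if not sequences:
        raise ValueError("no sequences given")
    all_codes = []
    skipped = 0
    for seq in sequences:
        codes, n_skipped = canonical_kmer_codes(seq, k)
        skipped += n_skipped
        all_codes.append(codes)
    if skipped:
        logger.info("genome %s: skipped %d k-mer windows with non-ACGT bases", genome_id, skipped)
    distinct = np.unique(np.concatenate(all_codes))
    hashed = np.sort(_splitmix64(distinct ^ HASH_SEED))
    return Sketch(genome_id=genome_id, k=k, s=s, hashes=hashed[:s])


def jaccard_estimate(a: Sketch, b: Sketch) -> float:
    """Estimate the k-mer Jaccard index from the bottom-s of the merged sketch."""
    if a.k != b.k:
        raise ValueError(f"k-mer sizes differ: {a.k} vs {b.k}")
    if a.hashes.size == 0 or b.hashes.size == 0:
        raise ValueError("cannot compare an empty sketch")
    s = min(a.s, b.s)
    merged = np.union1d(a.hashes, b.hashes)[:s]
    shared = np.intersect1d(a.hashes, b.hashes, assume_unique=True)
    n_shared = np.searchsorted(shared, merged[-1], side="right") if shared.size else 0
    return float(n_shared) / float(merged.size)


def mash_from_jaccard(j: float, k: int) -> float:
    if j <= 0.0:
        return 1.0
    if j >= 1.0:
        return 0.0
    return float(min(1.0, -np.log(2.0 * j / (1.0 + j)) / k))


def mash_distance(a: Sketch, b: Sketch) -> float:
    """Mash distance between two sketches (0 for identical, capped at 1)."""
    return mash_from_jaccard(jaccard_estimate(a, b), a.k)


def exact_jaccard(seq_a: str, seq_b: str, k: int = DEFAULT_KMER_SIZE) -> float:
    """Exact Jaccard index of the full canonical k-mer sets (brute force)."""
    ka = np.unique(canonical_kmer_codes(seq_a, k)[0])
    kb = np.unique(canonical_kmer_codes(seq_b, k)[0])
    inter = np.intersect1d(ka, kb, assume_unique=True).size
    union = ka.size + kb.size - inter
    return inter / union if union else 1.0


def exact_mash_distance(seq_a: str, seq_b: str, k: int = DEFAULT_KMER_SIZE) -> float:
    """Mash-formula distance from the exact Jaccard index (oracle-quality)."""
    return mash_from_jaccard(exact_jaccard(seq_a, seq_b, k), k)


@dataclass
class DistanceMatrix:
    """Symmetric genome-by-genome Mash distance matrix."""

    ids: list[str]
    D: np.ndarray

    def __post_init__(self) -> None:
        self.D = np.asarray(self.D, dtype=float)
        n = len(self.ids)
        if self.D.shape != (n, n):
            raise ValueError("matrix shape does not match id count")
        if len(set(self.ids)) != n:
            raise ValueError("duplicate genome ids")
        if not np.allclose(self.D, self.D.T, atol=1e-12):
            raise ValueError("distance matrix is not symmetric")
        if np.any(np.diag(self.D) != 0):
            raise ValueError("distance matrix diagonal must be zero")
        if self.D.min() < 0 or self.D.max() > 1:
            raise ValueError("distances must lie in [0, 1]")

    def submatrix(self, ids: list[str]) -> "DistanceMatrix":
        idx = [self.ids.index(g) for g in ids]
        return DistanceMatrix(list(ids), self.D[np.ix_(idx, idx)])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.D, index=self.ids, columns=self.ids)


def distance_matrix(sketches: list[Sketch]) -> DistanceMatrix:
    """All-pairs Mash distances for a list of sketches sharing one k."""
    if len(sketches) < 2:
        raise ValueError("need at least two sketches")
    ids = [sk.genome_id for sk in sketches]
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate genome ids among sketches")
    ks = {sk.k for sk in sketches}
    if len(ks) > 1:
        raise ValueError(f"sketches mix k-mer sizes: {sorted(ks)}")
    n = len(sketches)
    D = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            D[i, j] = D[j, i] = mash_distance(sketches[i], sketches[j])
    return DistanceMatrix(ids, D)
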