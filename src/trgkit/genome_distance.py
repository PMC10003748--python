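"""MinHash genome sketching and Mash-style whole-genome distances.

Canonical k-mers (lexicographic minimum of a k-mer and its reverse
complement) are hashed with a 64-bit splitmix finisher over the 2-bit
packed k-mer, seeded for determinism; a sketch keeps the s smallest hash
values. The Jaccard index of two genomes is estimated from the bottom-s
of the merged sketch and converted to the Mash distance
``d = -(1/k) * ln(2j / (1 + j))``.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import math

import numpy as np

DEFAULT_K = 21
DEFAULT_SKETCH = 100_000
_HASH_SEED = 42

_NT_CODE = {"A": 0, "C": 1, "G": 2, "T": 3}
_COMP = {"A": "T", "C": "G", "G": "C", "T": "A"}

_MASK64 = (1 << 64) - 1


def _splitmix64(x: int) -> int:
    x = (x + 0x9E3779B97F4A7C15) & _MASK64
    z = x
    z = ((z ^ (z >> 30)) * 0xBF58476D1CE4E5B9) & _MASK64
    z = ((z ^ (z >> 27)) * 0x94D049BB133111EB) & _MASK64
    return (z ^ (z >> 31)) & _MASK64


def _canonical(kmer: str) -> str:
    rc = "".join(_COMP[c] for c in reversed(kmer))
    return kmer if kmer <= rc else rc


def _pack(kmer: str) -> int:
    v = 0
    for c in kmer:
        v = (v << 2) | _NT_CODE[c]
    return v


def hash_kmer(kmer: str, seed: int = _HASH_SEED) -> int:
    """64-bit hash of the canonical form of a k-mer."""
    return _splitmix64(_pack(_canonical(kmer)) ^ seed)


@dataclass
class MinHashSketch:
    genome_id: str
    k: int
    s: int
    hashes: list[int]

    def __post_init__(self) -> None:
        if any(b <= a for a, b in zip(self.hashes, self.hashes[1:])):
            raise ValueError("sketch hashes must be strictly increasing")
        if len(self.hashes) > self.s:
            raise ValueError("sketch larger than its nominal size")


def sketch(genome, k: int = DEFAULT_K, s: int = DEFAULT_SKETCH) -> MinHashSketch:
    """MinHash sketch of a genome (k-mers containing N are skipped)."""
    if k < 1 or s < 1:
        raise ValueError("k and s must be positive")
    if hasattr(genome, "contigs"):
        genome_id = genome.genome_id
        sequences = [seq for _cid, seq in genome.contigs]
    else:
        genome_id = "genome"
        sequences = [str(genome)]
    hashes: set[int] = set()
    for seq in sequences:
        for i in range(len(seq) - k + 1):
            kmer = seq[i : i + k]
            if "N" in kmer:
                continue
            hashes.add(hash_kmer(kmer))
    bottom = sorted(hashes)[:s]
    return MinHashSketch(genome_id=genome_id, k=k, s=s, hashes=bottom)


def jaccard_estimate(a: MinHashSketch, b: MinHashSketch) -> float:
    """Merged-sketch (bottom-s of the union) Jaccard estimator."""
    if a.k != b.k:
        raise ValueError(f"k-mer sizes differ: {a.k} vs {b.k}")
    s = min(a.s, b.s)
    set_a, set_b = set(a.hashes), set(b.hashes)
    union_bottom = sorted(set_a | set_b)[:s]
    if not union_bottom:
        return 0.0
    shared = sum(1 for h in union_bottom if h in set_a and h in set_b)
    return shared / len(union_bottom)


def mash_distance(j: float, k: int = DEFAULT_K) -> float:
    """Mash distance from a Jaccard estimate; 0 at j=1, capped at 1 for j=0."""
    if not (0.0 <= j <= 1.0):
        raise ValueError("Jaccard estimate must be in [0, 1]")
    if j == 0.0:
        return 1.0
    if j == 1.0:
        return 0.0
    return -math.log(2.0 * j / (1.0 + j)) / k


def distance(genome_a, genome_b, k: int = DEFAULT_K, s: int = DEFAULT_SKETCH) -> float:
    return mash_distance(jaccard_estimate(sketch(genome_a, k, s), sketch(genome_b, k, s)), k)


def distance_matrix(genomes, k: int = DEFAULT_K, s: int = DEFAULT_SKETCH):
    """Symmetric Mash distance matrix as (ids, ndarray)."""
    sketches = [sketch(g, k, s) for g in genomes]
    n = len(sketches)
    mat = np.zeros((n, n))
    for i in range(n):
        for j_ in range(i + 1, n):
            d = mash_distance(jaccard_estimate(sketches[i], sketches[j_]), k)
            mat[i, j_] = mat[j_, i] = d
    return [s_.genome_id for s_ in sketches], mat


def sketch_to_json(s: MinHashSketch, path) -> None:
    with open(path, "w") as out:
        json.dump(
            {"genome_id": s.genome_id, "k": s.k, "s": s.s, "hashes": s.hashes},
            out,
        )


def sketch_from_json(path) -> MinHashSketch:
    with open(path) as handle:
        d = json.load(handle)
    return MinHashSketch(**d)


def matrix_to_tsv(ids, mat, path) -> None:
    with open(path, "w") as out:
        out.write("\t" + "\t".join(ids) + "\n")
        for i, gid in enumerate(ids):
            out.write(gid + "\t" + "\t".join(f"{v:.6f}" for v in mat[i]) + "\n")
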