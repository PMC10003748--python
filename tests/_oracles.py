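"""Independent reference implementations used as test oracles.

Everything here is deliberately written in the most transparent style
possible (plain recursion / exhaustive enumeration / textbook DP) and
shares no code with the package's optimized implementations.
"""

from functools import lru_cache

from Bio.Seq import Seq

STOPS = {"TAA", "TAG", "TGA"}


def translate_codon(codon: str) -> str:
    if "N" in codon:
        return "X"
    aa = str(Seq(codon).translate(table=11))
    return aa


def sw_protein_oracle(a: str, b: str, score_fn, gap_open: int, gap_ext: int) -> int:
    """Affine-gap local alignment score by straightforward 3-matrix DP.

    Gap of length g costs gap_open + (g - 1) * gap_ext.
    """
    NEG = -(10**9)
    n, m = len(a), len(b)
    M = [[NEG] * (m + 1) for _ in range(n + 1)]
    X = [[NEG] * (m + 1) for _ in range(n + 1)]  # gap in b
    Y = [[NEG] * (m + 1) for _ in range(n + 1)]  # gap in a
    best = 0
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            prev = max(M[i - 1][j - 1], X[i - 1][j - 1], Y[i - 1][j - 1], 0)
            M[i][j] = prev + score_fn(a[i - 1], b[j - 1])
            X[i][j] = max(M[i - 1][j] - gap_open, X[i - 1][j] - gap_ext)
            Y[i][j] = max(M[i][j - 1] - gap_open, Y[i][j - 1] - gap_ext)
            best = max(best, M[i][j])
    return best


def fs_align_oracle(
    query: str,
    dna: str,
    score_fn,
    gap_open: int,
    gap_ext: int,
    fs_pen: int,
    stop_score: int,
    count_events: bool = False,
):
    """Best local frameshift-aware score on the given strand, by memoized
    recursion over the move grammar (residue consumes 2/3/4 nt; DNA gap
    consumes a codon; query gap consumes a residue).

    With ``count_events`` the minimum (frameshifts + stops) among optimal
    paths is returned alongside the score.
    """
    m, L = len(query), len(dna)

    def step_value(i, j, k):
        """Score of aligning query[i-1] to the k-nt window ending at j."""
        if k == 2:
            base = 0
        else:
            codon = dna[j - 3 : j]
            if codon in STOPS:
                base = stop_score
            else:
                base = score_fn(query[i - 1], translate_codon(codon))
        if k != 3:
            base -= fs_pen
        return base

    @lru_cache(maxsize=None)
    def best_end_M(i, j):
        """Best score of a path ending with a residue step at (i, j)."""
        if i < 1:
            return None
        out = None
        for k in (2, 3, 4):
            if j - k < 0:
                continue
            sub = step_value(i, j, k)
            preds = [0]
            for layer in ("M", "D", "I"):
                v = best_end(layer, i - 1, j - k)
                if v is not None:
                    preds.append(v)
            cand = max(preds) + sub
            out = cand if out is None else max(out, cand)
        return out

    @lru_cache(maxsize=None)
    def best_end(layer, i, j):
        if layer == "M":
            return best_end_M(i, j)
        if layer == "D":  # gap in query: consumed codon, no residue
            if j < 3:
                return None
            outs = []
            vm = best_end("M", i, j - 3)
            if vm is not None:
                outs.append(vm - gap_open)
            vd = best_end("D", i, j - 3)
            if vd is not None:
                outs.append(vd - gap_ext)
            vi = best_end("I", i, j - 3)
            if vi is not None:
                outs.append(vi - gap_open)
            return max(outs) if outs else None
        # layer I: gap in DNA: consumed residue, no nt
        if i < 1:
            return None
        outs = []
        vm = best_end("M", i - 1, j)
        if vm is not None:
            outs.append(vm - gap_open)
        vd = best_end("D", i - 1, j)
        if vd is not None:
            outs.append(vd - gap_open)
        vi = best_end("I", i - 1, j)
        if vi is not None:
            outs.append(vi - gap_ext)
        return max(outs) if outs else None

    best = 0
    for i in range(1, m + 1):
        for j in range(0, L + 1):
            v = best_end("M", i, j)
            if v is not None and v > best:
                best = v
    return best


def fs_align_enumerate(query, dna, score_fn, gap_open, gap_ext, fs_pen, stop_score):
    """Exhaustive depth-first enumeration of *all* legal local paths.

    Exponential; only usable for very small inputs. Returns the best score.
    """
    m, L = len(query), len(dna)
    STOP_SET = STOPS
    best = [0]

    def step_value(i, j, k):
        if k == 2:
            base = 0
        else:
            codon = dna[j : j + 3] if k == 3 else dna[j + 1 : j + 4]
            if codon in STOP_SET:
                base = stop_score
            else:
                base = score_fn(query[i], translate_codon(codon))
        if k != 3:
            base -= fs_pen
        return base

    def extend(i, j, score, last):
        # a path may end after any residue step
        if last == "M":
            best[0] = max(best[0], score)
        for k in (2, 3, 4):
            if i < m and j + k <= L:
                extend(i + 1, j + k, score + step_value(i, j, k), "M")
        if j + 3 <= L and last != "start":
            cost = gap_ext if last == "D" else gap_open
            extend(i, j + 3, score - cost, "D")
        if i < m and last != "start":
            cost = gap_ext if last == "I" else gap_open
            extend(i + 1, j, score - cost, "I")

    for i0 in range(m):
        for j0 in range(L + 1):
            extend(i0, j0, 0, "start")
    return best[0]


class UnionFind:
    """Textbook union-find for the clustering oracle."""

    def __init__(self, items):
        self.parent = {x: x for x in items}

    def find(self, x):
        while self.parent[x] != x:
            self.parent[x] = self.parent[self.parent[x]]
            x = self.parent[x]
        return x

    def union(self, a, b):
        ra, rb = self.find(a), self.find(b)
        if ra != rb:
            self.parent[ra] = rb

    def components(self):
        groups = {}
        for x in self.parent:
            groups.setdefault(self.find(x), set()).add(x)
        return sorted(groups.values(), key=lambda s: sorted(s)[0])


def six_frame_orfs(seq: str, min_len_codons: int, starts=("ATG", "GTG", "TTG")):
    """Brute-force unannotated-ORF scan used as the extract_orfs oracle.

    Returns (start, end, strand) forward-strand intervals including the
    stop codon, for maximal first-start -> stop ORFs in all six frames.
    """
    results = []
    rc = str(Seq(seq).reverse_complement())
    for strand, s in (("+", seq), ("-", rc)):
        for frame in range(3):
            codons = [
                (i, s[i : i + 3])
                for i in range(frame, len(s) - 2, 3)
            ]
            start = None
            for i, codon in codons:
                if codon in STOPS:
                    if start is not None:
                        a, b = start, i + 3
                        if (b - a) // 3 - 1 >= min_len_codons:
                            if strand == "+":
                                results.append((a, b, "+"))
                            else:
                                results.append((len(s) - b, len(s) - a, "-"))
                        start = None
                elif start is None and codon in starts:
                    start = i
    return sorted(results)
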