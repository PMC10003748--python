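"""Numba kernel for frameshift/stop-aware local protein-vs-DNA alignment.

The grammar of a local alignment path:

* residue step: one query residue consumes 2, 3 or 4 nt. 3 nt is in-frame
  and scores ``matrix[q, aa(codon)]``; 4 nt treats the first nt as inserted
  (frameshift, +1) and scores the last three; 2 nt treats one nt of the
  codon as deleted (frameshift, -1) and scores as 'X' (0). Either shifted
  step pays ``frameshift_penalty``. A consumed codon that is a stop scores
  ``stop_match_score`` against any residue instead of the matrix value.
* DNA gap step: 3 nt consumed, no residue (affine: open for the first
  codon, extend per further codon).
* query gap step: one residue consumed, no DNA (affine likewise).

Scores are standard affine-gap local (Smith-Waterman-like): a path may
start and end anywhere; layer M holds paths ending in a residue step.
"""

import numpy as np
from numba import njit

NEG = -(10**8)

# pointer encoding for layer M: 0 = fresh start before this step;
# otherwise src * 16 + k with src 1=M, 2=D, 3=I and k the nt consumed.


@njit(cache=True)
def fs_align_kernel(
    q, dna, mat, codon_aa, codon_stop,
    gap_open, gap_ext, fs_pen, stop_score, x_index,
):
    m = q.shape[0]
    L = dna.shape[0]
    M = np.full((m + 1, L + 1), NEG, dtype=np.int32)
    D = np.full((m + 1, L + 1), NEG, dtype=np.int32)
    I = np.full((m + 1, L + 1), NEG, dtype=np.int32)
    ptrM = np.zeros((m + 1, L + 1), dtype=np.int8)
    ptrD = np.zeros((m + 1, L + 1), dtype=np.int8)
    ptrI = np.zeros((m + 1, L + 1), dtype=np.int8)

    best = 0
    best_i = -1
    best_j = -1

    for i in range(1, m + 1):
        qi = q[i - 1]
        for j in range(L + 1):
            # layer M: residue-consuming step ending exactly at (i, j)
            bestM = NEG
            bestP = 0
            # preference order: k=3 (no event) first, then k=2, then k=4;
            # within k: fresh start, then M, D, I predecessors.
            for kk in range(3):
                if kk == 0:
                    k = 3
                elif kk == 1:
                    k = 2
                else:
                    k = 4
                if j - k < 0:
                    continue
                # substitution value for this step
                if k == 2:
                    sub = 0 - fs_pen
                else:
                    c0 = dna[j - 3]
                    c1 = dna[j - 2]
                    c2 = dna[j - 1]
                    if c0 < 4 and c1 < 4 and c2 < 4:
                        ci = c0 * 16 + c1 * 4 + c2
                        if codon_stop[ci]:
                            sub = stop_score
                        else:
                            sub = mat[qi, codon_aa[ci]]
                    else:
                        sub = mat[qi, x_index]
                    if k == 4:
                        sub -= fs_pen
                # candidate predecessors in preference order
                pj = j - k
                v = sub  # fresh start
                if v > bestM:
                    bestM = v
                    bestP = k  # src 0 -> code = k (fresh)
                v = M[i - 1, pj] + sub
                if v > bestM:
                    bestM = v
                    bestP = 16 + k
                v = D[i - 1, pj] + sub
                if v > bestM:
                    bestM = v
                    bestP = 32 + k
                v = I[i - 1, pj] + sub
                if v > bestM:
                    bestM = v
                    bestP = 48 + k
            M[i, j] = bestM
            ptrM[i, j] = bestP

            # layer D: gap in query (codon consumed, no residue)
            if j >= 3:
                vD = NEG
                pD = 0
                v = M[i, j - 3] - gap_open
                if v > vD:
                    vD = v
                    pD = 1
                v = D[i, j - 3] - gap_ext
                if v > vD:
                    vD = v
                    pD = 2
                v = I[i, j - 3] - gap_open
                if v > vD:
                    vD = v
                    pD = 3
                D[i, j] = vD
                ptrD[i, j] = pD

            # layer I: gap in DNA (residue consumed, no nt)
            vI = NEG
            pI = 0
            v = M[i - 1, j] - gap_open
            if v > vI:
                vI = v
                pI = 1
            v = D[i - 1, j] - gap_open
            if v > vI:
                vI = v
                pI = 2
            v = I[i - 1, j] - gap_ext
            if v > vI:
                vI = v
                pI = 3
            I[i, j] = vI
            ptrI[i, j] = pI

            if M[i, j] > best:
                best = M[i, j]
                best_i = i
                best_j = j

    return best, best_i, best_j, ptrM, ptrD, ptrI
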