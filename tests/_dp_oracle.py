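"""Independent brute-force Gotoh DP used as the alignment oracle in tests.

Pure-Python, list-based, written separately from the package's numba kernel.
Same contract: semi-global (free terminal gaps in the exon row only), affine
gaps costing gap_open + L*gap_extend, N never matches, tie order
diagonal > up > left, smallest footprint end wins final ties.
"""

from __future__ import annotations

NEG = float("-inf")


def oracle_align(exon: str, region: str, match: int, mismatch: int, gap_open: int, gap_extend: int):
    """Return (score, identity_pct, target_start, target_end, aligned_exon, aligned_target)."""
    m, n = len(exon), len(region)
    M = [[NEG] * (n + 1) for _ in range(m + 1)]
    X = [[NEG] * (n + 1) for _ in range(m + 1)]
    Y = [[NEG] * (n + 1) for _ in range(m + 1)]
    pM = [[0] * (n + 1) for _ in range(m + 1)]
    pX = [[0] * (n + 1) for _ in range(m + 1)]
    pY = [[0] * (n + 1) for _ in range(m + 1)]
    M[0][0] = 0
    for j in range(1, n + 1):
        X[0][j] = 0
        pX[0][j] = 2
    go_ge = gap_open + gap_extend
    for i in range(1, m + 1):
        a = M[i - 1][0] + go_ge
        b = Y[i - 1][0] + gap_extend
        if a >= b:
            Y[i][0], pY[i][0] = a, 0
        else:
            Y[i][0], pY[i][0] = b, 1
        qc = exon[i - 1]
        Mi, Xi, Yi = M[i], X[i], Y[i]
        Mp, Xp, Yp = M[i - 1], X[i - 1], Y[i - 1]
        for j in range(1, n + 1):
            tc = region[j - 1]
            s = match if (qc == tc and qc != "N" and tc != "N") else mismatch
            best, p = Mp[j - 1], 0
            if Yp[j - 1] > best:
                best, p = Yp[j - 1], 1
            if Xp[j - 1] > best:
                best, p = Xp[j - 1], 2
            Mi[j] = best + s
            pM[i][j] = p
            best, p = Mi[j - 1] + go_ge, 0
            if Yi[j - 1] + go_ge > best:
                best, p = Yi[j - 1] + go_ge, 1
            if Xi[j - 1] + gap_extend > best:
                best, p = Xi[j - 1] + gap_extend, 2
            Xi[j], pX[i][j] = best, p
            best, p = Mp[j] + go_ge, 0
            if Yp[j] + gap_extend > best:
                best, p = Yp[j] + gap_extend, 1
            if Xp[j] + go_ge > best:
                best, p = Xp[j] + go_ge, 2
            Yi[j], pY[i][j] = best, p

    best, bj, bstate = NEG, -1, 0
    for j in range(1, n + 1):
        if M[m][j] > best:
            best, bj, bstate = M[m][j], j, 0
        if Y[m][j] > best:
            best, bj, bstate = Y[m][j], j, 1

    i, j, st = m, bj, bstate
    qcols, tcols = [], []
    while i > 0:
        if st == 0:
            qcols.append(exon[i - 1])
            tcols.append(region[j - 1])
            st = pM[i][j]
            i -= 1
            j -= 1
        elif st == 1:
            qcols.append(exon[i - 1])
            tcols.append("-")
            st = pY[i][j]
            i -= 1
        else:
            qcols.append("-")
            tcols.append(region[j - 1])
            st = pX[i][j]
            j -= 1
    aligned_exon = "".join(reversed(qcols))
    aligned_target = "".join(reversed(tcols))
    matches = sum(
        1 for a, b in zip(aligned_exon, aligned_target) if a == b and a != "-" and a != "N"
    )
    identity = 100.0 * matches / len(aligned_exon)
    return int(best), identity, j, bj, aligned_exon, aligned_target
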