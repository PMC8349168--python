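"""Independent brute-force oracles used to check the moment machinery.

Everything here is deliberately written as plain double loops (and exact
rational arithmetic for the Hahn polynomials) so it shares no code with the
vectorised implementations it checks.
"""

from fractions import Fraction
from math import factorial, sqrt

MOMENT_ORDERS = [(0, 0), (0, 1), (0, 2), (0, 3), (1, 0), (1, 1), (1, 2), (2, 0), (2, 1), (3, 0)]


def raw_moment(matrix, q, r):
    total = 0.0
    for i, row in enumerate(matrix):
        for j, v in enumerate(row):
            total += (i ** q) * (j ** r) * v
    return total


def central_moment(matrix, q, r):
    m00 = raw_moment(matrix, 0, 0)
    if m00 == 0:
        return 0.0
    xbar = raw_moment(matrix, 1, 0) / m00
    ybar = raw_moment(matrix, 0, 1) / m00
    total = 0.0
    for i, row in enumerate(matrix):
        for j, v in enumerate(row):
            total += ((i - xbar) ** q) * ((j - ybar) ** r) * v
    return total


def _pochhammer(a, k):
    out = Fraction(1)
    for m in range(k):
        out *= a + m
    return out


def hahn_polynomial_exact(n, x, size):
    """Degree-n Hahn polynomial (both shape parameters 0) at integer x.

    Term-by-term exact-rational evaluation of the terminating hypergeometric
    series 3F2(-n, n+1, -x; 1, -(size-1); 1).
    """
    N = size - 1
    total = Fraction(0)
    for j in range(n + 1):
        num = _pochhammer(-n, j) * _pochhammer(n + 1, j) * _pochhammer(-x, j)
        den = _pochhammer(1, j) * _pochhammer(-N, j) * factorial(j)
        total += num / den
    return total


def hahn_orthonormal(n, size):
    """Values of the orthonormalised degree-n Hahn polynomial on the support."""
    values = [hahn_polynomial_exact(n, x, size) for x in range(size)]
    norm_sq = sum(v * v for v in values)
    scale = sqrt(float(norm_sq))
    return [float(v) / scale for v in values]


def hahn_moment(matrix, q, r):
    size = len(matrix)
    hq = hahn_orthonormal(q, size)
    hr = hahn_orthonormal(r, size)
    total = 0.0
    for i, row in enumerate(matrix):
        for j, v in enumerate(row):
            total += hq[i] * hr[j] * v
    return total


def auc_mann_whitney(scores, truth):
    """AUC as the normalised Mann-Whitney U statistic (ties count half)."""
    pos = [s for s, t in zip(scores, truth) if t == 1]
    neg = [s for s, t in zip(scores, truth) if t == 0]
    wins = 0.0
    for p in pos:
        for n in neg:
            if p > n:
                wins += 1.0
            elif p == n:
                wins += 0.5
    return wins / (len(pos) * len(neg))
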