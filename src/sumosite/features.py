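"""Positional descriptors and statistical moments for peptide windows.

A 41-code window is summarised by:

* ``FV`` — frequency vector, 21 residue-code counts;
* ``SVV`` — site vicinity vector, the 41 codes in sequence order;
* ``AAPIV`` / ``R-AAPIV`` — accumulative absolute position incidence vectors:
  for each residue code, the sum of the 1-based positions at which it occurs,
  on the forward / reversed window;
* ``PRIM`` / ``R-PRIM`` — 21x21 position-relative incidence matrices:
  entry (i, j) sums, over the positions p of residue i, the offset of p from
  the first occurrence of residue j;
* raw, central and discrete orthogonal Hahn moments of order q+r <= 3 (ten
  (q, r) pairs) of three matrices: the 7x7 row-major matrixisation of the
  window codes, PRIM and R-PRIM.

The assembled descriptor concatenates 3 matrices x 30 moments + FV(21) +
AAPIV(21) + R-AAPIV(21) + SVV(41) = 194 values, in that fixed order.
"""

from __future__ import annotations

import logging
import math
from functools import lru_cache
from typing import Sequence

import numpy as np

from sumosite.seqio import N_CODES, PeptideWindow, encode_window

logger = logging.getLogger(__name__)

#: (q, r) exponent pairs of the ten order-<=3 moments, in the fixed order.
MOMENT_ORDERS: tuple[tuple[int, int], ...] = (
    (0, 0), (0, 1), (0, 2), (0, 3),
    (1, 0), (1, 1), (1, 2),
    (2, 0), (2, 1),
    (3, 0),
)

FEATURE_LENGTH = 194

MOMENT_FAMILIES = ("raw", "central", "hahn")


def _as_codes(codes) -> np.ndarray:
    arr = np.asarray(codes, dtype=np.int64)
    if arr.ndim != 1 or arr.size == 0:
        raise ValueError("codes must be a non-empty 1-D integer sequence")
    if arr.min() < 1 or arr.max() > N_CODES:
        raise ValueError("codes must lie in [1, 21]")
    return arr


def frequency_vector(codes) -> np.ndarray:
    """Count occurrences of each residue code; index 0 is code 1 (A)."""
    arr = _as_codes(codes)
    return np.bincount(arr - 1, minlength=N_CODES).astype(np.int64)


def site_vicinity_vector(codes) -> np.ndarray:
    """The window's own codes in order, as floats (order-sensitive slot)."""
    return _as_codes(codes).astype(float)


def aapiv(codes) -> np.ndarray:
    """Sum of 1-based positions at which each residue code occurs."""
    arr = _as_codes(codes)
    positions = np.arange(1, arr.size + 1)
    out = np.zeros(N_CODES, dtype=np.int64)
    np.add.at(out, arr - 1, positions)
    return out


def raapiv(codes) -> np.ndarray:
    """AAPIV of the reversed window."""
    return aapiv(_as_codes(codes)[::-1])


def prim(codes) -> np.ndarray:
    """Position-relative incidence matrix (21x21).

    ``Z[i, j]`` sums, over every 1-based position p carrying residue code
    i+1, the offset ``p - firstpos(j+1)``; rows/columns of absent residues
    are zero.
    """
    arr = _as_codes(codes)
    pos = np.arange(1, arr.size + 1)
    present = np.zeros(N_CODES, dtype=bool)
    first = np.zeros(N_CODES, dtype=np.int64)
    pos_sum = np.zeros(N_CODES, dtype=np.int64)
    count = np.zeros(N_CODES, dtype=np.int64)
    for p, c in zip(pos, arr - 1):
        if not present[c]:
            present[c] = True
            first[c] = p
        pos_sum[c] += p
        count[c] += 1
    # Z[i, j] = sum_p(p | code i) - count_i * firstpos(j), for present i and j
    Z = pos_sum[:, None] - count[:, None] * first[None, :]
    Z[~present, :] = 0
    Z[:, ~present] = 0
    return Z.astype(np.int64)


def rprim(codes) -> np.ndarray:
    """PRIM of the reversed window."""
    return prim(_as_codes(codes)[::-1])


def to_square_matrix(values, pad: float = 0.0) -> np.ndarray:
    """Reshape a flat sequence into the minimal square matrix, row-major.

    ``n = ceil(sqrt(len(values)))``; trailing cells take ``pad``.
    """
    flat = np.asarray(values, dtype=float).ravel()
    if flat.size == 0:
        raise ValueError("values must be non-empty")
    n = math.isqrt(flat.size)
    if n * n < flat.size:
        n += 1
    out = np.full(n * n, pad, dtype=float)
    out[: flat.size] = flat
    return out.reshape(n, n)


@lru_cache(maxsize=8)
def hahn_basis(size: int, max_degree: int | None = None) -> np.ndarray:
    """Orthonormal discrete Hahn polynomial values on support {0, ..., size-1}.

    Row n holds the degree-n Hahn polynomial with both shape parameters 0
    (the member whose orthogonality weight is uniform), evaluated by summing
    its hypergeometric series term by term and divided by the square root of
    its summed squared norm over the support. Rows are pairwise orthonormal
    to machine precision.
    """
    if size < 2:
        raise ValueError("support size must be >= 2")
    if max_degree is None:
        max_degree = size - 1
    if max_degree >= size:
        raise ValueError("degree must be < support size")
    N = size - 1
    basis = np.zeros((max_degree + 1, size), dtype=float)
    for n in range(max_degree + 1):
        for x in range(size):
            term = 1.0
            total = 1.0
            for j in range(n):
                # ratio of consecutive series terms of
                # 3F2(-n, n+1, -x; 1, -N; 1)
                term *= (j - n) * (n + 1 + j) * (j - x)
                term /= (1 + j) * (j - N) * (1 + j)
                total += term
            basis[n, x] = total
    norms = np.sqrt((basis ** 2).sum(axis=1))
    return basis / norms[:, None]


def raw_moments(matrix) -> np.ndarray:
    """Raw moments M_qr = sum_ij i^q j^r m[i, j] (0-based indices), q+r<=3."""
    m = np.asarray(matrix, dtype=float)
    idx = np.arange(m.shape[0], dtype=float)
    jdx = np.arange(m.shape[1], dtype=float)
    return np.array(
        [(idx[:, None] ** q * jdx[None, :] ** r * m).sum() for q, r in MOMENT_ORDERS]
    )


def central_moments(matrix) -> np.ndarray:
    """Centroid-centred moments mu_qr; all zero (with a warning) if sum is 0."""
    m = np.asarray(matrix, dtype=float)
    m00 = m.sum()
    if m00 == 0.0:
        logger.warning("all-zero matrix: central moments defined as 0")
        return np.zeros(len(MOMENT_ORDERS))
    idx = np.arange(m.shape[0], dtype=float)
    jdx = np.arange(m.shape[1], dtype=float)
    xbar = (idx[:, None] * m).sum() / m00
    ybar = (jdx[None, :] * m).sum() / m00
    di = idx - xbar
    dj = jdx - ybar
    return np.array(
        [((di[:, None] ** q) * (dj[None, :] ** r) * m).sum() for q, r in MOMENT_ORDERS]
    )


def hahn_moments(matrix) -> np.ndarray:
    """Hahn moments H_qr = sum_ij h_q(i) h_r(j) m[i, j], q+r<=3.

    ``h_n`` is the orthonormal Hahn polynomial of :func:`hahn_basis` on the
    matrix's own support; the matrix must be square with n >= 4 (orders up to
    3 need four support points).
    """
    m = np.asarray(matrix, dtype=float)
    if m.ndim != 2 or m.shape[0] != m.shape[1]:
        raise ValueError("matrix must be square")
    if m.shape[0] < 4:
        raise ValueError("Hahn moments up to order 3 need support size >= 4")
    basis = hahn_basis(m.shape[0], 3)
    proj = basis @ m @ basis.T  # proj[q, r] = sum_ij h_q(i) h_r(j) m[i, j]
    return np.array([proj[q, r] for q, r in MOMENT_ORDERS])


def matrix_moments(matrix) -> np.ndarray:
    """The 30 moments of one matrix: raw(10) | central(10) | Hahn(10)."""
    return np.concatenate([raw_moments(matrix), central_moments(matrix), hahn_moments(matrix)])


def assemble_features(window: PeptideWindow | Sequence[int] | np.ndarray) -> np.ndarray:
    """Assemble the 194-dimensional descriptor of one window.

    Layout: moments of the 7x7 sequence matrix (30), of PRIM (30), of R-PRIM
    (30), FV (21), AAPIV (21), R-AAPIV (21), SVV (41).
    """
    if isinstance(window, PeptideWindow):
        codes = encode_window(window)
    else:
        codes = _as_codes(window)
    vec = np.concatenate(
        [
            matrix_moments(to_square_matrix(codes)),
            matrix_moments(prim(codes).astype(float)),
            matrix_moments(rprim(codes).astype(float)),
            frequency_vector(codes).astype(float),
            aapiv(codes).astype(float),
            raapiv(codes).astype(float),
            site_vicinity_vector(codes),
        ]
    )
    if vec.size != FEATURE_LENGTH:
        raise AssertionError(f"descriptor length {vec.size} != {FEATURE_LENGTH}")
    if not np.all(np.isfinite(vec)):
        raise ValueError("non-finite value in assembled descriptor")
    return vec


def feature_names() -> list[str]:
    """Stable names of the 194 slots, in assembly order."""
    names: list[str] = []
    for block in ("seq", "prim", "rprim"):
        for family in MOMENT_FAMILIES:
            names += [f"{block}_{family}_m{q}{r}" for q, r in MOMENT_ORDERS]
    names += [f"fv_{c}" for c in range(1, 22)]
    names += [f"aapiv_{c}" for c in range(1, 22)]
    names += [f"raapiv_{c}" for c in range(1, 22)]
    names += [f"svv_{p}" for p in range(1, 42)]
    assert len(names) == FEATURE_LENGTH
    return names


def featurize_windows(windows: Sequence[PeptideWindow], with_labels: bool = True):
    """Featurize windows into a DataFrame (one row per window).

    Columns are :func:`feature_names`; a ``label`` column is appended when
    ``with_labels`` is true and every window carries one.
    """
    import pandas as pd

    rows = np.array([assemble_features(w) for w in windows]) if windows else np.empty((0, FEATURE_LENGTH))
    df = pd.DataFrame(rows, columns=feature_names())
    if with_labels and windows and all(w.label is not None for w in windows):
        df["label"] = [w.label for w in windows]
    return df


def feature_schema() -> dict:
    """JSON-serialisable description of the descriptor layout."""
    blocks = []
    start = 0
    for block in ("seq", "prim", "rprim"):
        for family in MOMENT_FAMILIES:
            blocks.append({"name": f"{block}_{family}_moments", "start": start, "length": 10})
            start += 10
    for name, length in (("fv", 21), ("aapiv", 21), ("raapiv", 21), ("svv", 41)):
        blocks.append({"name": name, "start": start, "length": length})
        start += length
    return {
        "length": FEATURE_LENGTH,
        "moment_orders": [list(o) for o in MOMENT_ORDERS],
        "blocks": blocks,
        "columns": feature_names(),
    }
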