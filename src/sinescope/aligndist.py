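"""Needleman–Wunsch global alignment, distance matrices, and PCA.

The distance reported for a pair is identity-based, 1 − matches/columns,
so it is bounded in [0,1] and comparable across sequence lengths; the
raw alignment score is retained alongside.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

_VALID = frozenset("ACGTN")


@dataclass(frozen=True)
class AlignmentResult:
    aligned_a: str
    aligned_b: str
    score: float
    n_columns: int
    n_matches: int

    @property
    def distance(self) -> float:
        return 1.0 - self.n_matches / self.n_columns


@dataclass(frozen=True)
class DistanceMatrix:
    ids: tuple[str, ...]
    matrix: np.ndarray

    def __post_init__(self) -> None:
        m = self.matrix
        if m.shape != (len(self.ids), len(self.ids)):
            raise ValueError("matrix shape does not match ids")
        if not np.allclose(m, m.T):
            raise ValueError("distance matrix is not symmetric")


@dataclass(frozen=True)
class PcaEmbedding:
    coordinates: np.ndarray  # n × k
    explained_variance: np.ndarray  # first k eigenvalues
    eigenvalues: np.ndarray  # all eigenvalues, non-increasing


def _score_matrix(a: str, b: str, match: float, mismatch: float, gap: float) -> np.ndarray:
    """Full NW score matrix H of shape (len(a)+1, len(b)+1).

    Rows are filled with vectorized numpy; the left-dependency within a
    row is resolved exactly for linear gap penalties via the running-max
    identity H[j] = gap*j + max_{k<=j}(C[k] - gap*k).
    """
    n, m = len(a), len(b)
    av = np.frombuffer(a.encode(), dtype=np.uint8)
    bv = np.frombuffer(b.encode(), dtype=np.uint8)
    n_code = ord("N")
    # substitution scores per (i,j): match only for equal non-N bases
    H = np.empty((n + 1, m + 1), dtype=np.float64)
    H[0, :] = gap * np.arange(m + 1)
    jidx = np.arange(m + 1, dtype=np.float64)
    for i in range(1, n + 1):
        s = np.where((bv == av[i - 1]) & (bv != n_code) & (av[i - 1] != n_code), match, mismatch)
        C = np.empty(m + 1)
        C[0] = gap * i
        C[1:] = np.maximum(H[i - 1, :-1] + s, H[i - 1, 1:] + gap)
        H[i, :] = gap * jidx + np.maximum.accumulate(C - gap * jidx)
    return H


def global_align(
    a: str,
    b: str,
    match: float = 1.0,
    mismatch: float = -1.0,
    gap: float = -2.0,
) -> AlignmentResult:
    """Optimal global alignment under linear gap penalties.

    Traceback ties are broken in the fixed order diagonal > up > left so
    results are deterministic. N never counts as a match.
    """
    if not a or not b:
        raise ValueError("cannot align an empty sequence")
    for name, seq in (("a", a), ("b", b)):
        bad = set(seq) - _VALID
        if bad:
            raise ValueError(f"sequence {name} contains invalid characters {sorted(bad)}")
    H = _score_matrix(a, b, match, mismatch, gap)
    i, j = len(a), len(b)
    out_a: list[str] = []
    out_b: list[str] = []
    eps = 1e-9
    while i > 0 or j > 0:
        if i > 0 and j > 0:
            ca, cb = a[i - 1], b[j - 1]
            s = match if (ca == cb and ca != "N") else mismatch
            if abs(H[i, j] - (H[i - 1, j - 1] + s)) < eps:
                out_a.append(ca)
                out_b.append(cb)
                i -= 1
                j -= 1
                continue
        if i > 0 and abs(H[i, j] - (H[i - 1, j] + gap)) < eps:
            out_a.append(a[i - 1])
            out_b.append("-")
            i -= 1
            continue
        out_a.append("-")
        out_b.append(b[j - 1])
        j -= 1
    aligned_a = "".join(reversed(out_a))
    aligned_b = "".join(reversed(out_b))
    n_matches = sum(
        1 for x, y in zip(aligned_a, aligned_b) if x == y and x != "-" and x != "N"
    )
    return AlignmentResult(
        aligned_a=aligned_a,
        aligned_b=aligned_b,
        score=float(H[len(a), len(b)]),
        n_columns=len(aligned_a),
        n_matches=n_matches,
    )


def distance_matrix(
    seqs: "list[str] | dict[str, str]",
    match: float = 1.0,
    mismatch: float = -1.0,
    gap: float = -2.0,
) -> DistanceMatrix:
    """Identity distances for all unordered pairs (each aligned once)."""
    if isinstance(seqs, dict):
        ids = tuple(seqs)
        values = [seqs[i] for i in ids]
    else:
        ids = tuple(f"s{i}" for i in range(len(seqs)))
        values = list(seqs)
    n = len(values)
    if n < 2:
        raise ValueError("need at least two sequences")
    mat = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            d = global_align(values[i], values[j], match, mismatch, gap).distance
            mat[i, j] = mat[j, i] = d
    return DistanceMatrix(ids=ids, matrix=mat)


def pca_embed(dm: DistanceMatrix, k: int = 2, standardize: bool = True) -> PcaEmbedding:
    """Embed distance-matrix rows by PCA.

    Rows are observations, columns features. Columns are centered and,
    when ``standardize``, scaled to unit variance (zero-variance columns
    are centered only). Component signs are fixed by making each
    component's largest-magnitude loading positive.
    """
    X = np.asarray(dm.matrix, dtype=float)
    n = X.shape[0]
    if n < 3:
        raise ValueError("need at least 3 observations")
    if not (0 < k < n):
        raise ValueError("k must satisfy 0 < k < n")
    Xc = X - X.mean(axis=0)
    if standardize:
        sd = Xc.std(axis=0, ddof=1)
        nonzero = sd > 0
        Xc[:, nonzero] = Xc[:, nonzero] / sd[nonzero]
    cov = Xc.T @ Xc / (n - 1)
    eigvals, eigvecs = np.linalg.eigh(cov)
    order = np.argsort(eigvals)[::-1]
    eigvals = np.clip(eigvals[order], 0.0, None)
    eigvecs = eigvecs[:, order]
    for c in range(eigvecs.shape[1]):
        lead = np.argmax(np.abs(eigvecs[:, c]))
        if eigvecs[lead, c] < 0:
            eigvecs[:, c] = -eigvecs[:, c]
    coords = Xc @ eigvecs[:, :k]
    return PcaEmbedding(
        coordinates=coords,
        explained_variance=eigvals[:k].copy(),
        eigenvalues=eigvals,
    )
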