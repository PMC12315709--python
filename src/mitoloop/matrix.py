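"""Binned contact matrices: binning, iterative (ICE) balancing, expected-by-
distance profiles and observed/expected views.

Matrices are stored as scipy.sparse upper-triangle counts; balancing follows
the iterative-correction scheme (equalize marginals), computed while ignoring
the first ``ignore_diags`` diagonals and bins masked by a MAD filter on log
coverage.  Balanced values are ``w_i * w_j * count(i, j)`` with weights
scaled so the mean unmasked marginal equals 1.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from scipy import sparse

from .core import ContactList, ValidationError

logger = logging.getLogger(__name__)


class BalancingError(RuntimeError):
    pass


@dataclass
class BinnedMatrix:
    """Symmetric intra-chromosomal contact matrix, upper triangle stored.

    Bin ``k`` covers ``[k * bin_size, (k + 1) * bin_size)``.  ``weights`` is
    None until :func:`ice_balance` has run; ``mask`` flags bins excluded from
    balancing and downstream statistics.
    """

    chrom: str
    bin_size: int
    n_bins: int
    counts: sparse.csr_matrix
    weights: Optional[np.ndarray] = None
    mask: np.ndarray = field(default=None)  # type: ignore[assignment]
    ignore_diags: int = 0

    def __post_init__(self) -> None:
        if self.mask is None:
            self.mask = np.zeros(self.n_bins, dtype=bool)

    @property
    def is_balanced(self) -> bool:
        return self.weights is not None

    def symmetric(self) -> sparse.csr_matrix:
        """Full symmetric count matrix (diagonal counted once)."""
        upper = sparse.triu(self.counts)
        return (upper + upper.T - sparse.diags(upper.diagonal())).tocsr()

    def balanced_symmetric(self) -> sparse.csr_matrix:
        if self.weights is None:
            raise ValidationError("matrix is not balanced")
        w = np.where(np.isnan(self.weights), 0.0, self.weights)
        d = sparse.diags(w)
        return (d @ self.symmetric() @ d).tocsr()

    def total_count(self) -> float:
        return float(sparse.triu(self.counts).sum())


@dataclass
class ExpectedProfile:
    """Mean balanced signal per diagonal, indexed by bin separation."""

    chrom: str
    bin_size: int
    ignore_diags: int
    values: np.ndarray      # expected(d) for d in [ignore_diags, n_bins)
    n_valid: np.ndarray     # unmasked pair count per diagonal

    def at(self, d: int) -> float:
        if d < self.ignore_diags or d >= self.ignore_diags + len(self.values):
            return np.nan
        return float(self.values[d - self.ignore_diags])

    def as_array(self, n_bins: int) -> np.ndarray:
        """expected indexed directly by separation d in [0, n_bins); NaN where undefined."""
        out = np.full(n_bins, np.nan)
        hi = min(n_bins, self.ignore_diags + len(self.values))
        out[self.ignore_diags:hi] = self.values[: hi - self.ignore_diags]
        return out


def bin_contacts(contacts: ContactList, chrom: str, chrom_length: int, bin_size: int) -> BinnedMatrix:
    """Bin intra-chromosomal contacts of *chrom* into an upper-triangle matrix.

    Inter-chromosomal records and records on other chromosomes are ignored
    (their number is logged).  Total matrix mass equals the number of
    retained contacts (counts summed).
    """
    if bin_size <= 0:
        raise ValidationError("bin_size must be positive")
    pos1, pos2, count = contacts.intra(chrom)
    dropped = len(contacts) - len(pos1)
    if dropped:
        logger.info("bin_contacts: ignoring %d records not intra-%s", dropped, chrom)
    n_bins = int(np.ceil(chrom_length / bin_size))
    i = pos1 // bin_size
    j = pos2 // bin_size
    if len(i) and (i.max() >= n_bins or j.max() >= n_bins):
        raise ValidationError("contact positions beyond chrom_length")
    counts = sparse.coo_matrix(
        (count.astype(np.float64), (i, j)), shape=(n_bins, n_bins)
    ).tocsr()
    counts.sum_duplicates()
    return BinnedMatrix(chrom=chrom, bin_size=bin_size, n_bins=n_bins, counts=counts)


def _offdiag(sym: sparse.csr_matrix, ignore_diags: int) -> sparse.csr_matrix:
    """Zero the central ``|i - j| < ignore_diags`` band."""
    if ignore_diags <= 0:
        return sym
    coo = sym.tocoo()
    keep = np.abs(coo.row - coo.col) >= ignore_diags
    return sparse.coo_matrix(
        (coo.data[keep], (coo.row[keep], coo.col[keep])), shape=sym.shape
    ).tocsr()


def ice_balance(
    matrix: BinnedMatrix,
    ignore_diags: int = 2,
    mad_max: float = 5.0,
    tol: float = 1e-5,
    max_iter: int = 200,
) -> BinnedMatrix:
    """Iteratively balance the matrix so unmasked marginals are equal.

    Marginals exclude the first *ignore_diags* diagonals.  Bins whose log
    coverage falls more than *mad_max* median absolute deviations below the
    median (or with zero coverage) are masked.  Convergence: variance of the
    mean-normalized unmasked marginals below *tol*.  Weights are stored in
    place (and returned) with NaN on masked bins.
    """
    if matrix.counts.nnz == 0:
        raise BalancingError("cannot balance an empty matrix")
    sym = _offdiag(matrix.symmetric(), ignore_diags)
    coverage = np.asarray(sym.sum(axis=1)).ravel()

    mask = coverage <= 0
    nz = coverage > 0
    if nz.any():
        logcov = np.log(coverage[nz])
        med = np.median(logcov)
        mad = np.median(np.abs(logcov - med))
        if mad > 0:
            low = np.zeros_like(mask)
            low[nz] = logcov < med - mad_max * mad
            mask |= low
    if mask.all():
        raise BalancingError("all bins masked; nothing to balance")

    unmasked = ~mask
    w = np.ones(matrix.n_bins)
    w[mask] = 0.0
    converged = False
    for _ in range(max_iter):
        marg = w * (sym @ w)
        m = marg[unmasked]
        mean = m.mean()
        if mean == 0:
            raise BalancingError("zero mean marginal on unmasked bins")
        rel = m / mean
        if np.var(rel) < tol:
            converged = True
            break
        update = np.ones(matrix.n_bins)
        update[unmasked] = np.sqrt(rel)
        w = w / update
    if not converged:
        logger.warning(
            "ice_balance: not converged after %d iterations (var=%.3g)",
            max_iter, float(np.var(rel)),
        )
    # scale so the mean unmasked marginal is exactly 1
    marg = w * (sym @ w)
    scale = marg[unmasked].mean()
    if scale > 0:
        w = w / np.sqrt(scale)
    weights = w.astype(float)
    weights[mask] = np.nan
    matrix.weights = weights
    matrix.mask = mask
    matrix.ignore_diags = ignore_diags
    return matrix


def marginal_variance(matrix: BinnedMatrix) -> float:
    """Variance of mean-normalized unmasked balanced marginals (QC metric)."""
    sym = _offdiag(matrix.balanced_symmetric(), matrix.ignore_diags)
    marg = np.asarray(sym.sum(axis=1)).ravel()[~matrix.mask]
    return float(np.var(marg / marg.mean()))


def expected_by_distance(matrix: BinnedMatrix) -> ExpectedProfile:
    """Mean balanced value per diagonal over unmasked bin pairs.

    Zeros count: the mean at separation d is the summed balanced signal on
    diagonal d divided by the number of unmasked (i, i + d) pairs.
    """
    if not matrix.is_balanced:
        raise ValidationError("expected_by_distance requires a balanced matrix")
    n = matrix.n_bins
    d0 = matrix.ignore_diags
    coo = sparse.triu(matrix.balanced_symmetric()).tocoo()
    sep = coo.col - coo.row
    keep = sep >= d0
    sums = np.bincount(sep[keep], weights=coo.data[keep], minlength=n)[d0:]

    unmasked = (~matrix.mask).astype(np.int64)
    n_valid = np.empty(n - d0, dtype=np.int64)
    for k, d in enumerate(range(d0, n)):
        n_valid[k] = int(np.sum(unmasked[: n - d] * unmasked[d:]))
    with np.errstate(invalid="ignore", divide="ignore"):
        values = np.where(n_valid > 0, sums / np.maximum(n_valid, 1), np.nan)
    return ExpectedProfile(
        chrom=matrix.chrom, bin_size=matrix.bin_size, ignore_diags=d0,
        values=values, n_valid=n_valid,
    )


class OEMatrix:
    """Observed/expected view over a balanced matrix.

    Entries are ``balanced(i, j) / expected(|i - j|)``; masked bins and
    ignored diagonals are NaN.  Dense windows are materialized on demand so
    large chromosomes stay sparse.
    """

    def __init__(self, matrix: BinnedMatrix, profile: ExpectedProfile) -> None:
        if not matrix.is_balanced:
            raise ValidationError("observed_over_expected requires a balanced matrix")
        if profile.bin_size != matrix.bin_size:
            raise ValidationError("profile bin size does not match matrix")
        self.matrix = matrix
        self.profile = profile
        self._balanced = matrix.balanced_symmetric()
        self._expected = profile.as_array(matrix.n_bins)
        bad = np.isfinite(self._expected) & (self._expected == 0)
        if bad.any():
            logger.warning("observed_over_expected: %d diagonals have zero expected", int(bad.sum()))
            self._expected[bad] = np.nan

    @property
    def n_bins(self) -> int:
        return self.matrix.n_bins

    @property
    def bin_size(self) -> int:
        return self.matrix.bin_size

    def window(self, r0: int, r1: int, c0: int, c1: int) -> np.ndarray:
        """Dense O/E window for rows [r0, r1) and columns [c0, c1)."""
        n = self.matrix.n_bins
        if not (0 <= r0 < r1 <= n and 0 <= c0 < c1 <= n):
            raise ValidationError("window out of matrix bounds")
        obs = np.asarray(self._balanced[r0:r1, c0:c1].todense(), dtype=float)
        rows = np.arange(r0, r1)[:, None]
        cols = np.arange(c0, c1)[None, :]
        exp = self._expected[np.abs(rows - cols)]
        with np.errstate(invalid="ignore", divide="ignore"):
            oe = obs / exp
        oe[self.matrix.mask[r0:r1], :] = np.nan
        oe[:, self.matrix.mask[c0:c1]] = np.nan
        return oe

    def toarray(self) -> np.ndarray:
        return self.window(0, self.n_bins, 0, self.n_bins)


def observed_over_expected(matrix: BinnedMatrix, profile: ExpectedProfile) -> OEMatrix:
    """O/E view of a balanced matrix against its expected-by-distance profile."""
    return OEMatrix(matrix, profile)
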