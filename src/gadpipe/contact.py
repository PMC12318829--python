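"""Binned intra-chromosomal Hi-C contact matrices: reading, validation and
ICE (iterative correction) balancing.

A :class:`ContactMatrix` is a dense symmetric ``n_bins x n_bins`` array of
non-negative contact intensities at a fixed resolution on one chromosome.
Balancing follows the iterative-correction scheme: bin marginals are
repeatedly equalised by dividing each entry by the product of its row and
column marginal ratios until the per-iteration bias change falls below a
tolerance.  Low-coverage bins are masked (rows/columns zeroed) before
balancing.  The balanced matrix is rescaled so that the mean unmasked
off-diagonal intensity matches the input — a no-op for downstream GAD
scores, which are ratios.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "ContactMatrix",
    "BalanceResult",
    "read_contact_matrix",
    "read_bin_table",
    "write_contact_matrix",
    "ice_balance",
]

_SYM_RTOL = 1e-9


@dataclass
class ContactMatrix:
    """Symmetric binned contact intensities on one chromosome.

    ``masked_bins`` are bin indices excluded from balancing and scoring;
    their rows and columns are zero after balancing.
    """

    chrom: str
    bin_size: int
    values: np.ndarray
    masked_bins: frozenset[int] = field(default_factory=frozenset)

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 2 or v.shape[0] != v.shape[1]:
            raise ValueError(f"contact matrix must be square, got shape {v.shape}")
        if not np.isfinite(v).all():
            raise ValueError("contact matrix contains non-finite values")
        if (v < 0).any():
            raise ValueError("contact matrix contains negative values")
        if not np.allclose(v, v.T, rtol=_SYM_RTOL, atol=1e-12):
            raise ValueError("contact matrix is not symmetric")
        if self.bin_size <= 0:
            raise ValueError(f"bin_size must be positive, got {self.bin_size}")
        self.values = v
        self.masked_bins = frozenset(int(i) for i in self.masked_bins)
        for i in self.masked_bins:
            if not 0 <= i < self.n_bins:
                raise ValueError(f"masked bin {i} outside matrix extent")

    @property
    def n_bins(self) -> int:
        return self.values.shape[0]

    @property
    def extent(self) -> int:
        """Chromosome extent covered by the matrix, in bases."""
        return self.n_bins * self.bin_size


@dataclass(frozen=True)
class BalanceResult:
    """Outcome of ICE balancing.

    ``biases`` holds one positive multiplier per bin (NaN on masked bins);
    the balanced matrix is ``input[i, j] / (biases[i] * biases[j])`` up to
    the mean-preserving rescale.
    """

    biases: np.ndarray
    n_iterations: int
    converged: bool
    final_variation: float
    masked_bins: frozenset[int]


def read_bin_table(path) -> pd.DataFrame:
    """Read a bin table TSV (chrom, start, end, bin_id; 0-based half-open).

    Validates that all bins share one chromosome, tile it contiguously and
    have a constant width.
    """
    bins = pd.read_csv(
        path, sep="\t", names=["chrom", "start", "end", "bin_id"], header=None,
        comment="#",
    )
    if bins.empty:
        raise ValueError(f"{path}: empty bin table")
    if bins["chrom"].nunique() != 1:
        raise ValueError(f"{path}: bin table spans multiple chromosomes")
    bins = bins.sort_values("bin_id").reset_index(drop=True)
    widths = bins["end"] - bins["start"]
    if widths.nunique() != 1:
        bad = bins.loc[widths != widths.iloc[0]].index[0]
        raise ValueError(
            f"{path}: inconsistent bin width at line {bad + 1} "
            f"({widths.iloc[bad]} bp vs {widths.iloc[0]} bp)"
        )
    if not (bins["start"].values == bins["bin_id"].values * widths.iloc[0]).all():
        raise ValueError(f"{path}: bins do not tile the chromosome contiguously")
    return bins


def read_contact_matrix(path, format: str, bin_table_path) -> ContactMatrix:
    """Read a contact matrix from dense TSV or COO triplet TSV.

    Dense input may be upper-triangular; it is mirrored to full symmetric
    form.  COO triplets ``(bin_i, bin_j, value)`` are placed symmetrically.
    Bin size and chromosome come from the bin table.
    """
    bins = read_bin_table(bin_table_path)
    n = len(bins)
    chrom = str(bins["chrom"].iloc[0])
    bin_size = int((bins["end"] - bins["start"]).iloc[0])

    if format == "dense":
        m = pd.read_csv(path, sep="\t", header=None, comment="#").to_numpy(float)
        if m.shape[0] != m.shape[1]:
            raise ValueError(
                f"{path}: dense matrix is not square ({m.shape[0]}x{m.shape[1]})"
            )
        if m.shape[0] != n:
            raise ValueError(
                f"{path}: matrix size {m.shape[0]} does not match bin table ({n})"
            )
        neg = np.argwhere(m < 0)
        if neg.size:
            raise ValueError(f"{path}: negative value at line {neg[0][0] + 1}")
        lower = np.tril(m, k=-1)
        if not lower.any():
            m = m + m.T - np.diag(np.diag(m))  # mirror upper triangle
        values = m
    elif format == "coo":
        coo = pd.read_csv(
            path, sep="\t", names=["bin_i", "bin_j", "value"], header=None,
            comment="#",
        )
        values = np.zeros((n, n))
        for line, (i, j, v) in enumerate(
            coo.itertuples(index=False, name=None), start=1
        ):
            i, j = int(i), int(j)
            if not (0 <= i < n and 0 <= j < n):
                raise ValueError(f"{path}: bin index out of range at line {line}")
            if v < 0:
                raise ValueError(f"{path}: negative value at line {line}")
            values[i, j] = v
            values[j, i] = v
    else:
        raise ValueError(f"unknown format {format!r}; expected 'dense' or 'coo'")

    return ContactMatrix(chrom=chrom, bin_size=bin_size, values=values)


def write_contact_matrix(m: ContactMatrix, matrix_path, bin_table_path) -> None:
    """Write the upper triangle (incl. diagonal) as COO TSV plus a bin table."""
    iu = np.triu_indices(m.n_bins)
    vals = m.values[iu]
    nz = vals != 0
    pd.DataFrame(
        {"bin_i": iu[0][nz], "bin_j": iu[1][nz], "value": vals[nz]}
    ).to_csv(matrix_path, sep="\t", header=False, index=False)
    ids = np.arange(m.n_bins)
    pd.DataFrame(
        {
            "chrom": m.chrom,
            "start": ids * m.bin_size,
            "end": (ids + 1) * m.bin_size,
            "bin_id": ids,
        }
    ).to_csv(bin_table_path, sep="\t", header=False, index=False)


def ice_balance(
    m: ContactMatrix,
    tol: float = 1e-5,
    max_iter: int = 200,
    mask_quantile: float = 0.02,
) -> tuple[ContactMatrix, BalanceResult]:
    """Iterative-correction balancing of a contact matrix.

    Bins with a raw marginal below the ``mask_quantile`` quantile of
    nonzero marginals *and* below half the median nonzero marginal are
    masked; the second guard keeps masking restricted to genuinely
    low-coverage bins, which also makes balancing idempotent.  Marginals
    of the remaining bins are equalised by repeated division with the
    per-bin marginal ratio until the largest relative bias change drops
    below ``tol``.  Non-convergence within ``max_iter`` sets
    ``converged=False`` (with a warning) rather than raising.
    """
    if not m.values.any():
        raise ValueError("cannot balance an all-zero contact matrix")

    W = m.values.copy()
    marg = W.sum(axis=1)
    nz = marg[marg > 0]
    thresh = float(np.quantile(nz, mask_quantile, method="lower"))
    low = (marg <= thresh) & (marg < 0.5 * float(np.median(nz)))
    mask = low | (marg == 0)
    for i in m.masked_bins:
        mask[i] = True
    if (~mask).sum() < 2:
        raise ValueError("fewer than 2 unmasked bins; cannot balance")
    W[mask, :] = 0.0
    W[:, mask] = 0.0

    unmasked = ~mask
    biases = np.ones(m.n_bins)
    variation = np.inf
    it = 0
    for it in range(1, max_iter + 1):
        s = W.sum(axis=1)
        db = np.ones(m.n_bins)
        db[unmasked] = s[unmasked] / s[unmasked].mean()
        db[db == 0] = 1.0
        W /= np.outer(db, db)
        biases *= db
        variation = float(np.abs(db[unmasked] - 1.0).max())
        if variation < tol:
            break
    converged = variation < tol
    if not converged:
        warnings.warn(
            f"ICE did not converge in {max_iter} iterations "
            f"(final variation {variation:.3g})",
            RuntimeWarning,
            stacklevel=2,
        )

    # rescale so mean unmasked off-diagonal intensity matches the input
    off = ~np.eye(m.n_bins, dtype=bool) & np.outer(unmasked, unmasked)
    target = float(m.values[off].mean())
    current = float(W[off].mean())
    if current > 0:
        factor = target / current
        W *= factor
        biases /= np.sqrt(factor)

    W = (W + W.T) / 2.0  # remove fp drift; exact symmetry preserved
    biases_out = biases.copy()
    biases_out[mask] = np.nan
    masked = frozenset(int(i) for i in np.flatnonzero(mask))
    balanced = ContactMatrix(
        chrom=m.chrom, bin_size=m.bin_size, values=W, masked_bins=masked
    )
    return balanced, BalanceResult(
        biases=biases_out,
        n_iterations=it,
        converged=converged,
        final_variation=variation,
        masked_bins=masked,
    )
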