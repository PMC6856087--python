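"""Marker quality control, imputation, and the genomic relationship matrix.

The genomic relationship matrix (GRM) realized from SNP dosages is the
kinship object every downstream model consumes: GBLUP uses it as the
covariance of line effects, and the feedforward networks consume its
Cholesky factor as a feature encoding.  The GRM here is ``G = W W^T / p``
where ``W`` is the lines x markers dosage matrix (column-centered by
default, VanRaden-style) and ``p`` the number of markers.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.linalg import cholesky as _cholesky, LinAlgError

__all__ = [
    "MarkerMatrix",
    "GRM",
    "CholeskyFactor",
    "qc_markers",
    "impute_missing",
    "compute_grm",
    "cholesky_factor",
]


@dataclass
class MarkerMatrix:
    """Biallelic SNP calls for a set of lines.

    ``dosages`` holds allele counts in {0, 1, 2} as floats with ``nan``
    marking missing calls; after imputation fractional dosages are allowed.
    """

    dosages: np.ndarray  # (n_lines, n_markers), float, nan = missing
    line_ids: list[str]
    marker_ids: list[str]

    def __post_init__(self) -> None:
        self.dosages = np.asarray(self.dosages, dtype=float)
        if self.dosages.ndim != 2:
            raise ValueError("dosages must be a 2-D lines x markers array")
        if self.dosages.shape != (len(self.line_ids), len(self.marker_ids)):
            raise ValueError("dosage shape does not match id lists")
        if len(set(self.line_ids)) != len(self.line_ids):
            raise ValueError("duplicate line ids")
        if len(set(self.marker_ids)) != len(self.marker_ids):
            raise ValueError("duplicate marker ids")

    @property
    def n_lines(self) -> int:
        return self.dosages.shape[0]

    @property
    def n_markers(self) -> int:
        return self.dosages.shape[1]

    @property
    def missing_mask(self) -> np.ndarray:
        return np.isnan(self.dosages)

    def to_csv(self, path) -> None:
        df = pd.DataFrame(self.dosages, index=self.line_ids, columns=self.marker_ids)
        df.to_csv(path, index_label="line", na_rep="NA")

    @classmethod
    def from_csv(cls, path) -> "MarkerMatrix":
        df = pd.read_csv(path, index_col=0, na_values=["NA"])
        return cls(df.to_numpy(dtype=float), [str(i) for i in df.index], [str(c) for c in df.columns])


@dataclass
class GRM:
    """Symmetric PSD line-relationship matrix with its line labels."""

    matrix: np.ndarray  # (J, J)
    line_ids: list[str]

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        J = len(self.line_ids)
        if self.matrix.shape != (J, J):
            raise ValueError("GRM shape does not match line ids")
        if not np.allclose(self.matrix, self.matrix.T, atol=1e-8):
            raise ValueError("GRM must be symmetric")

    @property
    def n_lines(self) -> int:
        return len(self.line_ids)

    def to_csv(self, path) -> None:
        pd.DataFrame(self.matrix, index=self.line_ids, columns=self.line_ids).to_csv(
            path, index_label="line"
        )

    @classmethod
    def from_csv(cls, path) -> "GRM":
        df = pd.read_csv(path, index_col=0)
        return cls(df.to_numpy(dtype=float), [str(i) for i in df.index])


@dataclass
class CholeskyFactor:
    """Upper-triangular U with U^T U = G + jitter * I.

    The feature encoding for the networks uses the transpose ``U^T``
    (lower triangular), so that rows of ``Z_G U^T`` reproduce the GRM
    covariance: ``(Z_G U^T)(Z_G U^T)^T = Z_G G Z_G^T``.
    """

    upper: np.ndarray  # (J, J) upper triangular
    line_ids: list[str]
    jitter: float = 0.0

    @property
    def lower_t(self) -> np.ndarray:
        """U^T, the encoding factor."""
        return self.upper.T

    def to_csv(self, path) -> None:
        pd.DataFrame(self.upper, index=self.line_ids, columns=self.line_ids).to_csv(
            path, index_label="line"
        )


def qc_markers(m: MarkerMatrix, max_missing: float = 0.10, min_maf: float = 0.05) -> MarkerMatrix:
    """Drop markers with too many missing calls or too rare a minor allele.

    A marker survives when its missing fraction is <= ``max_missing`` AND its
    minor allele frequency is >= ``min_maf``.  MAF is computed on non-missing
    calls as ``min(f, 1 - f)`` with ``f`` = mean dosage / 2.  Marker order is
    preserved.
    """
    if m.n_markers == 0:
        raise ValueError("empty marker matrix")
    miss_frac = np.mean(m.missing_mask, axis=0)
    with np.errstate(invalid="ignore"):
        f = np.nanmean(m.dosages, axis=0) / 2.0
    f = np.where(np.isnan(f), 0.0, f)  # all-missing marker: MAF 0, drops
    maf = np.minimum(f, 1.0 - f)
    keep = (miss_frac <= max_missing) & (maf >= min_maf)
    if not keep.any():
        raise ValueError(
            f"quality control removed all {m.n_markers} markers "
            f"(max_missing={max_missing}, min_maf={min_maf})"
        )
    kept_ids = [mid for mid, k in zip(m.marker_ids, keep) if k]
    return MarkerMatrix(m.dosages[:, keep], list(m.line_ids), kept_ids)


def impute_missing(m: MarkerMatrix) -> MarkerMatrix:
    """Replace missing calls with the marker's mean dosage over observed calls."""
    dos = m.dosages.copy()
    mask = np.isnan(dos)
    if not mask.any():
        return MarkerMatrix(dos, list(m.line_ids), list(m.marker_ids))
    n_obs = (~mask).sum(axis=0)
    if (n_obs == 0).any():
        bad = [mid for mid, n in zip(m.marker_ids, n_obs) if n == 0]
        raise ValueError(f"markers with no observed calls (run QC first): {bad[:5]}")
    col_means = np.nanmean(dos, axis=0)
    rows, cols = np.where(mask)
    dos[rows, cols] = col_means[cols]
    return MarkerMatrix(dos, list(m.line_ids), list(m.marker_ids))


def compute_grm(m: MarkerMatrix, center: bool = True) -> GRM:
    """Genomic relationship matrix G = W W^T / p.

    With ``center=True`` (default) the dosage columns are mean-centered
    before the cross-product, the VanRaden-style realized kinship.  With
    ``center=False`` raw dosages are used.
    """
    if m.n_markers == 0:
        raise ValueError("cannot compute a GRM from zero markers")
    if np.isnan(m.dosages).any():
        raise ValueError("marker matrix has missing values; impute first")
    W = m.dosages
    if center:
        W = W - W.mean(axis=0, keepdims=True)
    G = W @ W.T / m.n_markers
    G = (G + G.T) / 2.0  # enforce exact symmetry
    return GRM(G, list(m.line_ids))


def cholesky_factor(g: GRM, jitter_start: float = 1e-8) -> CholeskyFactor:
    """Upper Cholesky factor of the GRM, adding the smallest jitter that works.

    Tries ``G + eps * I`` for eps in the geometric ladder
    {0, jitter_start, 10*jitter_start, ...} capped at 1e-2 * trace(G)/J, and
    returns the first factorization that succeeds together with the eps used.
    """
    G = g.matrix
    J = g.n_lines
    cap = 1e-2 * np.trace(G) / J if np.trace(G) > 0 else 1e-2
    ladder = [0.0]
    eps = jitter_start
    while eps <= cap:
        ladder.append(eps)
        eps *= 10.0
    if ladder[-1] < cap:
        ladder.append(cap)
    for eps in ladder:
        try:
            U = _cholesky(G + eps * np.eye(J), lower=False)
            return CholeskyFactor(U, list(g.line_ids), jitter=eps)
        except LinAlgError:
            continue
    raise ValueError(
        f"GRM could not be factorized even with jitter {ladder[-1]:.3g}; "
        "matrix is not a valid relationship matrix"
    )
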