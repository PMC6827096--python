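"""Genomic relationship matrices and GBLUP prediction.

The GRM follows the Yang et al. (2010) estimator: off-diagonals are
averages of products of standardized dosages,

    G_jk = (1/N) sum_i (x_ij - 2 p_i)(x_ik - 2 p_i) / (2 p_i (1 - p_i)),

and diagonals use the less biased form

    G_jj = 1 + (1/N) sum_i (x_ij^2 - (1 + 2 p_i) x_ij + 2 p_i^2)
                           / (2 p_i (1 - p_i)).

GBLUP fits y = Xb + g + e with g ~ N(0, G sigma_g^2), e ~ N(0, I sigma_e^2)
on the reference subset and predicts validation breeding values by genomic
regression g_v = G_vr (G_rr + lambda I)^(-1) (y - X b); b is the GLS
fixed-effect estimate.  lambda = sigma_e^2 / sigma_g^2 defaults to
(1 - h2)/h2 when the simulation's heritability is known; an EM-REML
estimator of the variance components is provided as an optional path.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.linalg import cho_factor, cho_solve, eigh

from .panel import GenotypePanel

__all__ = [
    "GRM",
    "compute_grm",
    "GBLUPSolver",
    "fit_gblup",
    "estimate_variances_reml",
]


@dataclass
class GRM:
    matrix: np.ndarray
    ids: np.ndarray
    n_markers: int
    freqs: np.ndarray
    diagonal: str = "yang"
    metadata: dict = field(default_factory=dict)

    @property
    def n(self) -> int:
        return self.matrix.shape[0]

    def index_of(self, ids) -> np.ndarray:
        lookup = {v: i for i, v in enumerate(self.ids)}
        return np.array([lookup[v] for v in ids], dtype=np.int64)

    def save(self, prefix: str) -> None:
        """Persist as ``<prefix>.grm.npy`` plus a ``<prefix>.grm.ids`` text
        sidecar (one line per individual: id, allele-frequency count in
        header)."""
        np.save(prefix + ".grm.npy", self.matrix)
        np.save(prefix + ".freqs.npy", self.freqs)
        with open(prefix + ".grm.ids", "w") as fh:
            fh.write(f"#n_markers={self.n_markers}\tdiagonal={self.diagonal}\n")
            for i in self.ids:
                fh.write(f"{i}\n")

    @classmethod
    def load(cls, prefix: str) -> "GRM":
        matrix = np.load(prefix + ".grm.npy")
        freqs = np.load(prefix + ".freqs.npy")
        with open(prefix + ".grm.ids") as fh:
            header = fh.readline().lstrip("#").split()
            meta = dict(kv.split("=") for kv in header)
            ids = np.array([line.strip() for line in fh if line.strip()],
                           dtype=object)
        return cls(matrix, ids, int(meta["n_markers"]), freqs,
                   meta.get("diagonal", "yang"))


def _gram(z: np.ndarray) -> np.ndarray:
    """z z' / m via BLAS syrk on one triangle, symmetrized blockwise.

    ``z`` must be C-contiguous (n, m); ``z.T`` is then a no-copy Fortran
    view, so peak extra memory is just the (n, n) result.
    """
    n, m = z.shape
    from scipy.linalg.blas import dsyrk, ssyrk

    syrk = ssyrk if z.dtype == np.float32 else dsyrk
    c = syrk(1.0 / m, z.T, trans=1, lower=0)  # upper triangle of z z' / m
    step = 1024
    for i in range(0, n, step):  # mirror upper into lower without big temps
        hi = min(i + step, n)
        c[hi:, i:hi] = c[i:hi, hi:].T
        block = c[i:hi, i:hi]
        block += np.triu(block, 1).T
    return c


def compute_grm(
    panel: GenotypePanel | np.ndarray,
    freqs: np.ndarray | None = None,
    ids: np.ndarray | None = None,
    diagonal: str = "yang",
    dtype=np.float32,
) -> GRM:
    """Yang-estimator GRM from a phased panel or a dosage matrix.

    ``freqs`` defaults to allele frequencies of the pooled sample itself.
    Any marker with frequency 0 or 1 under the chosen reference is an
    error (its standardization is undefined) and is reported by index.
    ``diagonal='vanraden'`` keeps the plain standardized-dosage diagonal,
    for which the all-entry sum of the sample-frequency GRM is exactly 0.
    """
    if isinstance(panel, GenotypePanel):
        if panel.missing is not None and panel.missing.any():
            raise ValueError("GRM requires complete dosages; impute or filter first")
        dosage = panel.dosage(dtype)
        if ids is None:
            ids = panel.ids
    else:
        dosage = np.array(panel, dtype=dtype)  # copy: standardized in place below
        if ids is None:
            ids = np.arange(dosage.shape[0])
    if diagonal not in ("yang", "vanraden"):
        raise ValueError("diagonal must be 'yang' or 'vanraden'")
    n, m = dosage.shape
    if freqs is None:
        freqs = dosage.mean(axis=0, dtype=np.float64) / 2.0
    freqs = np.asarray(freqs, dtype=np.float64)
    bad = np.flatnonzero((freqs <= 0.0) | (freqs >= 1.0))
    if bad.size:
        raise ValueError(
            f"{bad.size} marker(s) with allele frequency 0 or 1 under the "
            f"chosen reference (first: index {bad[0]}); drop them first"
        )
    het = 2.0 * freqs * (1.0 - freqs)
    diag = None
    if diagonal == "yang":
        diag = np.empty(n)
        step = 1024  # chunked to avoid a second full-size float matrix
        for i in range(0, n, step):
            x = dosage[i : i + step].astype(np.float64)
            diag[i : i + step] = 1.0 + (
                (x * x - (1.0 + 2.0 * freqs) * x + 2.0 * freqs**2) / het
            ).mean(axis=1)
    # standardize in place: dosage buffer becomes z
    z = dosage
    z -= (2.0 * freqs).astype(dtype)
    z /= np.sqrt(het).astype(dtype)
    g = _gram(np.ascontiguousarray(z))
    if diag is not None:
        np.fill_diagonal(g, diag.astype(g.dtype))
    return GRM(
        matrix=g,
        ids=np.asarray(ids),
        n_markers=m,
        freqs=freqs,
        diagonal=diagonal,
    )


class GBLUPSolver:
    """Factorized GBLUP system for one reference set, reusable across traits.

    Factorizes V = G_rr + ridge + lambda I once; each call to
    :meth:`predict` solves for a new phenotype vector.  ``ridge`` (relative
    to the mean diagonal) stabilizes near-duplicate resampled individuals.
    """

    def __init__(
        self,
        g_rr: np.ndarray,
        x_ref: np.ndarray | None,
        lam: float,
        ridge: float = 1e-6,
    ):
        if lam <= 0:
            raise ValueError("lambda must be positive")
        g_rr = np.asarray(g_rr, dtype=np.float64)
        n = g_rr.shape[0]
        self.g_rr = g_rr
        self.x = (
            np.ones((n, 1)) if x_ref is None else np.asarray(x_ref, dtype=np.float64)
        )
        if self.x.shape[0] != n:
            raise ValueError("fixed-effect design rows != reference size")
        v = g_rr + (lam + ridge * float(np.mean(np.diag(g_rr)))) * np.eye(n)
        self._cho = cho_factor(v, lower=True)
        self._vinv_x = cho_solve(self._cho, self.x)
        xtvx = self.x.T @ self._vinv_x
        if np.linalg.matrix_rank(xtvx) < xtvx.shape[0]:
            raise np.linalg.LinAlgError("singular fixed-effect design")
        self._xtvx = xtvx

    def predict(
        self, y_ref: np.ndarray, g_cross: np.ndarray | None = None
    ) -> tuple[np.ndarray, np.ndarray]:
        """GLS fixed effects and GEBVs.

        ``g_cross`` holds GRM rows (targets x reference); defaults to the
        reference block itself, giving reference-set GEBVs.
        """
        y_ref = np.asarray(y_ref, dtype=np.float64)
        b_hat = np.linalg.solve(self._xtvx, self._vinv_x.T @ y_ref)
        alpha = cho_solve(self._cho, y_ref - self.x @ b_hat)
        target = self.g_rr if g_cross is None else np.asarray(g_cross, np.float64)
        return b_hat, target @ alpha


def fit_gblup(
    y_ref: np.ndarray,
    x_ref: np.ndarray | None,
    grm: GRM | np.ndarray,
    reference_idx: np.ndarray,
    lam: float,
    validation_idx: np.ndarray | None = None,
    ridge: float = 1e-6,
) -> tuple[np.ndarray, np.ndarray]:
    """One-shot GBLUP: returns (b_hat, gebv) with GEBVs for *all* GRM ids.

    ``y_ref``/``x_ref`` are aligned to ``reference_idx`` (rows of the GRM).
    Validation GEBVs are ``gebv[validation_idx]``.
    """
    g = grm.matrix if isinstance(grm, GRM) else np.asarray(grm)
    reference_idx = np.asarray(reference_idx)
    if validation_idx is not None and np.intersect1d(
        reference_idx, validation_idx
    ).size:
        raise ValueError("reference and validation overlap")
    solver = GBLUPSolver(
        g[np.ix_(reference_idx, reference_idx)], x_ref, lam, ridge=ridge
    )
    b_hat, gebv_all = solver.predict(y_ref, g[:, reference_idx])
    return b_hat, gebv_all


def estimate_variances_reml(
    y: np.ndarray,
    x: np.ndarray | None,
    grm: GRM | np.ndarray,
    tol: float = 1e-6,
    max_iter: int = 200,
) -> tuple[float, float]:
    """EM-REML variance components (sigma_g^2, sigma_e^2) for y = Xb + g + e.

    Works in the eigenbasis of G so every iteration is O(n^2).  Issues a
    warning and returns the last iterate if not converged within
    ``max_iter`` iterations at relative tolerance ``tol``.
    """
    y = np.asarray(y, dtype=np.float64)
    n = len(y)
    if n < 30:
        raise ValueError("need n >= 30 for variance-component estimation")
    g = grm.matrix if isinstance(grm, GRM) else np.asarray(grm)
    g = np.asarray(g, dtype=np.float64)
    x = np.ones((n, 1)) if x is None else np.asarray(x, dtype=np.float64)

    d, u = eigh(g)
    d = np.clip(d, 1e-9, None)
    ty, tx = u.T @ y, u.T @ x

    vy = float(np.var(y))
    sg2, se2 = 0.5 * vy + 1e-8, 0.5 * vy + 1e-8
    for _ in range(max_iter):
        v = sg2 * d + se2
        w = 1.0 / v
        wx = tx * w[:, None]
        xtvx = tx.T @ wx
        beta = np.linalg.solve(xtvx, wx.T @ ty)
        r = ty - tx @ beta
        pr = w * r  # P y in the eigenbasis
        # tr(P M) for diagonal M: sum(w m) - tr((X'V-1X)^-1 X'V-1 M V-1 X)
        xtvx_inv = np.linalg.inv(xtvx)
        def tr_p(mdiag):
            a = wx * mdiag[:, None]
            return float(mdiag @ w - np.einsum("ij,jk,ik->", a, xtvx_inv, wx))
        sg2_new = sg2 + (sg2**2 / n) * (float(pr @ (d * pr)) - tr_p(d))
        se2_new = se2 + (se2**2 / n) * (float(pr @ pr) - tr_p(np.ones(n)))
        sg2_new = max(sg2_new, 1e-12)
        se2_new = max(se2_new, 1e-12)
        if (
            abs(sg2_new - sg2) <= tol * max(sg2, 1e-12)
            and abs(se2_new - se2) <= tol * max(se2, 1e-12)
        ):
            return sg2_new, se2_new
        sg2, se2 = sg2_new, se2_new
    warnings.warn("EM-REML did not converge; returning last iterate", stacklevel=2)
    return sg2, se2
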