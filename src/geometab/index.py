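"""Metabolic index (MI): collapse a site × metabolite matrix to one scalar
per site.

The MI is a linear combination MI_i = Σ_j w_j z_ij of the standardized
metabolite concentrations z_ij = (x_ij − μ_j)/σ_j, with three weighting
schemes:

``mean``
    w_j = 1/N — every metabolite equally relevant.
``cov``
    w_j = CoV_j / Σ_j CoV_j with CoV_j = σ_j/μ_j computed on the *raw*
    concentration scale (on standardized data μ = 0 would make σ/μ
    undefined); emphasizes metabolites with high relative variability.
``pca``
    w = first principal component of the standardized matrix; emphasizes
    the variance among sampling positions. Loadings have unit norm and
    the sign convention fixes the largest-|loading| coordinate positive.

Population standard deviations (÷ n) are used throughout, matching the
standard-scaler convention, so the PCA index variance equals the top
eigenvalue of the standardized-data covariance exactly.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "ScaledMatrix",
    "standard_scale",
    "MIResult",
    "MetabolicIndex",
    "mi_mean",
    "mi_cov",
    "mi_pca",
]

SCHEMES = ("mean", "cov", "pca")


@dataclass
class ScaledMatrix:
    """Standardized matrix with the scaling parameters that produced it."""

    values: pd.DataFrame           # standardized, zero-variance cols dropped
    mu: pd.Series                  # per-metabolite mean (raw scale)
    sigma: pd.Series               # per-metabolite population sd (raw scale)
    dropped: list[str] = field(default_factory=list)


def _as_frame(matrix) -> pd.DataFrame:
    if isinstance(matrix, pd.DataFrame):
        return matrix.astype(float)
    arr = np.asarray(matrix, dtype=float)
    if arr.ndim != 2:
        raise ValueError("matrix must be 2-D (sites × metabolites)")
    return pd.DataFrame(arr, columns=[f"m{j}" for j in range(arr.shape[1])])


def standard_scale(matrix) -> ScaledMatrix:
    """z_ij = (x_ij − μ_j)/σ_j with population σ; drops constant columns."""
    frame = _as_frame(matrix)
    if len(frame) < 2:
        raise ValueError("need at least 2 sites to standardize")
    mu = frame.mean(axis=0)
    sigma = frame.std(axis=0, ddof=0)
    dropped = list(sigma.index[sigma == 0.0])
    if dropped:
        warnings.warn(f"zero-variance metabolites excluded: {dropped}",
                      stacklevel=2)
    keep = [c for c in frame.columns if c not in dropped]
    z = (frame[keep] - mu[keep]) / sigma[keep]
    return ScaledMatrix(z, mu, sigma, dropped)


@dataclass
class MIResult:
    """Per-site metabolic index with the weights that produced it."""

    scheme: str
    weights: pd.Series                  # per metabolite
    index: pd.Series                    # per site
    loadings: pd.Series | None = None   # pca only (unit norm)
    explained_var_fraction: float | None = None
    dropped: list[str] = field(default_factory=list)

    def summary(self) -> str:
        lines = [f"Metabolic index — scheme: {self.scheme}",
                 f"  sites: {len(self.index)}, metabolites: {len(self.weights)}"]
        if self.explained_var_fraction is not None:
            lines.append(f"  PC1 explained variance fraction: "
                         f"{self.explained_var_fraction:.4f}")
        if self.dropped:
            lines.append(f"  excluded metabolites: {', '.join(self.dropped)}")
        lines.append("  weights:")
        for name, w in self.weights.items():
            lines.append(f"    {name:<14s} {w:+.6f}")
        return "\n".join(lines)


class MetabolicIndex:
    """Model object: raw concentration matrix + scheme; ``fit`` → MIResult.

    Standardization is part of the fit, so every scheme is invariant to
    affine rescaling of any raw metabolite column.
    """

    def __init__(self, matrix, scheme: str = "pca"):
        if scheme not in SCHEMES:
            raise ValueError(f"scheme must be one of {SCHEMES}, got {scheme!r}")
        self.raw = _as_frame(matrix)
        self.scheme = scheme

    @classmethod
    def from_dataframe(cls, frame: pd.DataFrame, scheme: str = "pca",
                       metabolites: list[str] | None = None) -> "MetabolicIndex":
        cols = metabolites if metabolites is not None else list(frame.columns)
        return cls(frame[cols], scheme)

    def fit(self) -> MIResult:
        scaled = standard_scale(self.raw)
        if self.scheme == "mean":
            return self._fit_mean(scaled)
        if self.scheme == "cov":
            return self._fit_cov(scaled)
        return self._fit_pca(scaled)

    # -- schemes ------------------------------------------------------------
    @staticmethod
    def _fit_mean(scaled: ScaledMatrix) -> MIResult:
        z = scaled.values
        n = z.shape[1]
        w = pd.Series(np.full(n, 1.0 / n), index=z.columns)
        return MIResult("mean", w, z.mean(axis=1), dropped=scaled.dropped)

    def _fit_cov(self, scaled: ScaledMatrix) -> MIResult:
        z = scaled.values
        mu = scaled.mu[z.columns]
        sigma = scaled.sigma[z.columns]
        zero_mu = list(mu.index[mu == 0.0])
        if zero_mu:
            warnings.warn(f"metabolites with zero mean excluded from CoV "
                          f"weighting: {zero_mu}", stacklevel=2)
        keep = [c for c in z.columns if c not in zero_mu]
        cov = (sigma[keep] / mu[keep])
        total = cov.sum()
        if total == 0.0:
            raise ValueError("all CoV weights are zero; CoV index undefined")
        w = cov / total
        idx = z[keep] @ w
        return MIResult("cov", w, idx, dropped=scaled.dropped + zero_mu)

    @staticmethod
    def _fit_pca(scaled: ScaledMatrix) -> MIResult:
        z = scaled.values.to_numpy()
        n = z.shape[0]
        cov = z.T @ z / n            # population covariance of standardized data
        eigval, eigvec = np.linalg.eigh(cov)
        if cov.shape[0] > 1 and eigval[-1] - eigval[-2] < 1e-9:
            warnings.warn("top two eigenvalues are tied within 1e-9; "
                          "PC1 direction resolved by deterministic eigensolver "
                          "order", stacklevel=2)
        load = eigvec[:, -1]
        pivot = int(np.argmax(np.abs(load)))
        if load[pivot] < 0:
            load = -load
        idx = z @ load
        explained = float(eigval[-1] / eigval.sum()) if eigval.sum() > 0 else 0.0
        loadings = pd.Series(load, index=scaled.values.columns)
        return MIResult("pca", loadings.copy(),
                        pd.Series(idx, index=scaled.values.index),
                        loadings=loadings,
                        explained_var_fraction=explained,
                        dropped=scaled.dropped)


def mi_mean(matrix) -> MIResult:
    """Equal-weight MI of the standardized matrix."""
    return MetabolicIndex(matrix, "mean").fit()


def mi_cov(matrix) -> MIResult:
    """CoV-weighted MI: raw-scale σ/μ weights applied to standardized data."""
    return MetabolicIndex(matrix, "cov").fit()


def mi_pca(matrix) -> MIResult:
    """PC1 MI: projection of standardized rows on the leading eigenvector."""
    return MetabolicIndex(matrix, "pca").fit()
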