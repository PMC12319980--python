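"""Generalized polynomial chaos (gPC) surrogates over tissue-conductivity
priors.

The quantity of interest q(sigma) — e.g. the |E| values on a cortical shell
or the B_z values in a slice — is expanded in a tensor-product basis of
Legendre polynomials, orthonormal with respect to independent uniform priors
on the per-tissue conductivity ranges:

    q(sigma) ~= sum_{alpha in A} u_alpha Psi_alpha(sigma)

with total-degree truncation of the multi-index set A. Coefficients are fit
by (lightly regularized) least squares on Latin-hypercube samples; the total
degree is grown until a k-fold cross-validated normalized RMSE drops below a
tolerance. Because the basis is orthonormal, the surrogate's mean is the
constant-term coefficient, the variance is the sum of squared non-constant
coefficients, and Sobol sensitivity indices are ratios of coefficient groups.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from itertools import product

import numpy as np
from scipy.stats import qmc

from .metrics import relative_difference, relative_std  # noqa: F401 (module API)

__all__ = [
    "ConductivityPrior",
    "GPCModel",
    "train_gpc",
    "gpc_predict",
    "gpc_mean",
    "gpc_variance",
    "sobol_indices",
    "relative_std",
    "relative_difference",
]


@dataclass
class ConductivityPrior:
    """Ordered tissue list with independent uniform ranges [low, high) in S/m."""

    tissues: list
    ranges: dict  # tissue -> (low, high)

    def __post_init__(self):
        self.tissues = list(self.tissues)
        for t in self.tissues:
            lo, hi = self.ranges[t]
            if not lo < hi:
                raise ValueError(f"tissue {t!r}: need low < high, got ({lo}, {hi})")

    @property
    def dim(self) -> int:
        return len(self.tissues)

    def bounds(self) -> np.ndarray:
        return np.array([self.ranges[t] for t in self.tissues], float)

    def to_unit(self, sigma: np.ndarray) -> np.ndarray:
        """Map conductivities to the reference cube [-1, 1]^d."""
        b = self.bounds()
        return 2.0 * (np.asarray(sigma, float) - b[:, 0]) / (b[:, 1] - b[:, 0]) - 1.0

    def from_unit(self, x: np.ndarray) -> np.ndarray:
        b = self.bounds()
        return b[:, 0] + (np.asarray(x, float) + 1.0) / 2.0 * (b[:, 1] - b[:, 0])


def _total_degree_indices(dim: int, degree: int) -> np.ndarray:
    idx = [a for a in product(range(degree + 1), repeat=dim) if sum(a) <= degree]
    idx.sort(key=lambda a: (sum(a), a))
    return np.array(idx, int)


def _legendre_table(x: np.ndarray, max_deg: int) -> np.ndarray:
    """Orthonormal Legendre values psi_n(x) = sqrt(2n+1) P_n(x), (n_pts, deg+1).

    Orthonormality is with respect to the uniform density 1/2 on [-1, 1].
    """
    x = np.asarray(x, float)
    P = np.empty(x.shape + (max_deg + 1,))
    P[..., 0] = 1.0
    if max_deg >= 1:
        P[..., 1] = x
    for n in range(1, max_deg):
        P[..., n + 1] = ((2 * n + 1) * x * P[..., n] - n * P[..., n - 1]) / (n + 1)
    return P * np.sqrt(2 * np.arange(max_deg + 1) + 1.0)


def _design_matrix(x_unit: np.ndarray, multi_indices: np.ndarray) -> np.ndarray:
    max_deg = int(multi_indices.max(initial=0))
    tables = [_legendre_table(x_unit[:, d], max_deg) for d in range(x_unit.shape[1])]
    Psi = np.ones((x_unit.shape[0], len(multi_indices)))
    for m, alpha in enumerate(multi_indices):
        for d, a in enumerate(alpha):
            if a:
                Psi[:, m] *= tables[d][:, a]
    return Psi


def _ridge_lstsq(Psi: np.ndarray, y: np.ndarray, lam: float) -> np.ndarray:
    n, m = Psi.shape
    aug = np.vstack([Psi, np.sqrt(lam) * np.eye(m)])
    rhs = np.vstack([y, np.zeros((m, y.shape[1]))])
    coef, *_ = np.linalg.lstsq(aug, rhs, rcond=None)
    return coef


@dataclass
class GPCModel:
    """Trained surrogate: multi-index set, coefficients, prior and CV error."""

    prior: ConductivityPrior
    multi_indices: np.ndarray       # (n_basis, d)
    coefficients: np.ndarray        # (n_basis, n_outputs)
    cv_error: float
    degree: int
    samples: np.ndarray = field(default=None, repr=False)  # training sigmas

    def __post_init__(self):
        if not (self.multi_indices.sum(axis=1) == 0).any():
            raise ValueError("the zero multi-index must be in the basis")
        if len(self.multi_indices) != len(self.coefficients):
            raise ValueError("one coefficient row per multi-index required")

    def predict(self, sigma: np.ndarray) -> np.ndarray:
        """Evaluate the expansion at one conductivity vector (no extrapolation)."""
        sigma = np.asarray(sigma, float)
        b = self.prior.bounds()
        if np.any(sigma < b[:, 0] - 1e-12) or np.any(sigma > b[:, 1] + 1e-12):
            raise ValueError(
                f"conductivities {sigma} outside the prior ranges; "
                "the surrogate does not extrapolate"
            )
        Psi = _design_matrix(self.prior.to_unit(sigma)[None, :], self.multi_indices)
        return (Psi @ self.coefficients)[0]

    def mean(self) -> np.ndarray:
        i0 = int(np.flatnonzero(self.multi_indices.sum(axis=1) == 0)[0])
        return self.coefficients[i0].copy()

    def variance(self) -> np.ndarray:
        nz = self.multi_indices.sum(axis=1) > 0
        return (self.coefficients[nz] ** 2).sum(axis=0)

    def std(self) -> np.ndarray:
        return np.sqrt(self.variance())

    def _effective_variance(self) -> np.ndarray:
        """Variance with numerically-zero entries (constant outputs, where
        Sobol indices are defined as 0) masked out."""
        var = self.variance()
        total = (self.coefficients**2).sum(axis=0)
        return np.where(var > 1e-20 * total, var, 0.0)

    def sobol_first(self) -> dict:
        """First-order Sobol index field per tissue (0 where variance is 0)."""
        var = self._effective_variance()
        out = {}
        for d, t in enumerate(self.prior.tissues):
            only = (self.multi_indices[:, d] > 0) & (
                self.multi_indices.sum(axis=1) == self.multi_indices[:, d]
            )
            num = (self.coefficients[only] ** 2).sum(axis=0)
            with np.errstate(invalid="ignore", divide="ignore"):
                s = np.where(var > 0, num / np.where(var > 0, var, 1.0), 0.0)
            out[t] = s
        return out

    def sobol_total(self) -> dict:
        var = self._effective_variance()
        out = {}
        for d, t in enumerate(self.prior.tissues):
            active = self.multi_indices[:, d] > 0
            num = (self.coefficients[active] ** 2).sum(axis=0)
            out[t] = np.where(var > 0, num / np.where(var > 0, var, 1.0), 0.0)
        return out

    def save(self, path):
        np.savez_compressed(
            path,
            multi_indices=self.multi_indices,
            coefficients=self.coefficients,
            cv_error=self.cv_error,
            degree=self.degree,
            prior=json.dumps(
                {"tissues": self.prior.tissues,
                 "ranges": {t: list(self.prior.ranges[t]) for t in self.prior.tissues}}
            ),
        )

    @classmethod
    def load(cls, path) -> "GPCModel":
        with np.load(path, allow_pickle=False) as z:
            meta = json.loads(str(z["prior"]))
            return cls(
                ConductivityPrior(meta["tissues"],
                                  {t: tuple(r) for t, r in meta["ranges"].items()}),
                z["multi_indices"],
                z["coefficients"],
                float(z["cv_error"]),
                int(z["degree"]),
            )


def train_gpc(forward_fn, prior: ConductivityPrior, tol: float = 0.01,
              kfold: int = 10, seed: int = 0, max_degree: int = 4,
              oversampling: float = 2.0, ridge: float = 1e-12) -> GPCModel:
    """Fit an adaptive-degree gPC surrogate of ``forward_fn``.

    ``forward_fn`` maps a conductivity vector (ordered as ``prior.tissues``)
    to a 1D output array and must be deterministic. Latin-hypercube samples
    (``oversampling`` times the basis size) are drawn on the prior box;
    forward evaluations are cached and reused as the degree grows. Training
    stops when the k-fold cross-validated normalized RMSE reaches ``tol``,
    or warns at the degree cap.
    """
    rng_seq = np.random.SeedSequence(seed)
    sampler = qmc.LatinHypercube(d=prior.dim, seed=int(rng_seq.generate_state(1)[0] % 2**31))
    X = np.empty((0, prior.dim))
    Y = None

    best = None
    for degree in range(1, max_degree + 1):
        A = _total_degree_indices(prior.dim, degree)
        n_needed = int(np.ceil(oversampling * len(A)))
        n_needed = max(n_needed, len(A) + 2, kfold)
        if n_needed > len(X):
            x_new = qmc.scale(sampler.random(n_needed - len(X)), -1.0, 1.0)
            y_new = np.array(
                [np.asarray(forward_fn(prior.from_unit(x)), float).ravel()
                 for x in x_new]
            )
            X = np.vstack([X, x_new])
            Y = y_new if Y is None else np.vstack([Y, y_new])

        Psi = _design_matrix(X, A)
        coef = _ridge_lstsq(Psi, Y, ridge)
        cv = _kfold_error(Psi, Y, kfold, ridge, seed)
        best = GPCModel(prior, A, coef, cv, degree,
                        samples=prior.from_unit(X))
        if cv <= tol:
            return best
    warnings.warn(
        f"gPC cross-validation error {best.cv_error:.3g} did not reach "
        f"tolerance {tol} at the degree cap {max_degree}"
    )
    return best


def _kfold_error(Psi, Y, kfold, ridge, seed) -> float:
    n = len(Psi)
    k = min(kfold, n)
    perm = np.random.default_rng(seed).permutation(n)
    num = 0.0
    for f in range(k):
        test = perm[f::k]
        train = np.setdiff1d(perm, test)
        coef = _ridge_lstsq(Psi[train], Y[train], ridge)
        num += ((Psi[test] @ coef - Y[test]) ** 2).sum()
    spread = ((Y - Y.mean(axis=0)) ** 2).sum()
    denom = max(spread, 1e-18 * (Y**2).sum(), 1e-300)
    return float(np.sqrt(num / denom))


def gpc_predict(model: GPCModel, sigma) -> np.ndarray:
    return model.predict(sigma)


def gpc_mean(model: GPCModel) -> np.ndarray:
    return model.mean()


def gpc_variance(model: GPCModel) -> np.ndarray:
    return model.variance()


def sobol_indices(model: GPCModel) -> tuple[dict, dict]:
    """(first-order, total-order) Sobol index fields per tissue."""
    return model.sobol_first(), model.sobol_total()
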