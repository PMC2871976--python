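"""Relevance vector regression: sparse Bayesian linear-basis regression.

The model treats the kernel columns (plus an offset column of ones) as basis
functions. With design matrix ``Phi = [1, K]`` (N rows, N+1 columns), targets
t and weights w:

* likelihood      ``p(t | w, s2) = N(t | Phi w, s2 I)``
* weight prior    ``p(w | alpha) = prod_i N(w_i | 0, 1/alpha_i)``
* posterior       ``p(w | t, alpha, s2) = N(w | mu, Sigma)`` with
  ``Sigma = (Phi' Phi / s2 + A)^-1``, ``A = diag(alpha)``, and
  ``mu = Sigma Phi' t / s2``
* evidence        ``p(t | alpha, s2) = N(t | 0, C)``,
  ``C = s2 I + Phi A^-1 Phi'``.

Fitting maximises the evidence (type-II maximum likelihood) over the
hyperparameters alpha and the noise variance s2 with the classic fixed-point
re-estimation rules. During optimisation many alpha_i diverge — automatic
relevance determination — and their bases are pruned; the training samples
whose kernel columns survive are the relevance vectors.

The public surface follows the statsmodels convention: :class:`RVR` is the
model (data + design), :meth:`RVR.fit` returns :class:`RVRResults` carrying
the posterior, diagnostics, ``summary()``, ``predict()`` and
``weight_map()``.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy import linalg

from .features import (
    BrainVolume,
    DesignMatrix,
    FeatureMatrix,
    KernelMatrix,
    build_design,
    devectorize,
    linear_kernel,
)

__all__ = [
    "FitConfig",
    "RVR",
    "RVRResults",
    "compute_posterior",
    "log_marginal_likelihood",
]

_LOG2PI = np.log(2.0 * np.pi)


@dataclass
class FitConfig:
    """Optimiser settings for the evidence maximisation.

    The model definition fixes only the objective; these are the numerical
    choices. ``max_iter = 0`` disables hyperparameter updates entirely (the
    fixed-prior / ridge limit). ``alpha_init`` of None means the default
    ``(1/N)^2``. ``seed`` is unused by the deterministic fit but recorded so
    run manifests can carry one provenance field for every stage.
    """

    max_iter: int = 500
    tol: float = 1e-4  # convergence threshold on max |delta log alpha|
    alpha_prune_threshold: float = 1e12
    alpha_init: float | None = None
    sigma2_init_fraction: float = 0.1
    jitter: float = 1e-10
    seed: int | None = None

    def __post_init__(self):
        if self.max_iter < 0:
            raise ValueError("max_iter must be >= 0")
        if not (0 < self.tol < 1):
            raise ValueError("tol must be in (0, 1)")
        for name in ("alpha_prune_threshold", "sigma2_init_fraction", "jitter"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.alpha_init is not None and self.alpha_init <= 0:
            raise ValueError("alpha_init must be positive")


def _chol_with_jitter(H: np.ndarray, jitter: float):
    """Cholesky with escalating diagonal jitter (x10, three retries)."""
    base = jitter * max(np.trace(H), 1.0)
    bump = 0.0
    for attempt in range(4):
        try:
            return linalg.cho_factor(H + bump * np.eye(H.shape[0]), lower=True)
        except linalg.LinAlgError:
            bump = base * 10.0**attempt
    raise linalg.LinAlgError(
        "matrix not positive definite after jitter escalation "
        f"(final jitter {bump:.3e}, trace {np.trace(H):.3e})"
    )


def compute_posterior(
    Phi: np.ndarray,
    t: np.ndarray,
    alpha: np.ndarray,
    sigma2: float,
    jitter: float = 1e-10,
) -> tuple[np.ndarray, np.ndarray]:
    """Posterior mean and covariance of the weights for fixed hyperparameters.

    ``Sigma = (Phi' Phi / sigma2 + diag(alpha))^-1`` and
    ``mu = Sigma Phi' t / sigma2``, computed through a stabilised symmetric
    (Cholesky) solve.
    """
    Phi = np.asarray(Phi, dtype=float)
    t = np.asarray(t, dtype=float).ravel()
    alpha = np.asarray(alpha, dtype=float).ravel()
    if Phi.ndim != 2 or Phi.shape[0] != t.size or Phi.shape[1] != alpha.size:
        raise ValueError("inconsistent dimensions between Phi, t and alpha")
    if sigma2 <= 0 or np.any(alpha <= 0):
        raise ValueError("alpha and sigma2 must be positive")
    H = Phi.T @ Phi / sigma2 + np.diag(alpha)
    c = _chol_with_jitter(H, jitter)
    Sigma = linalg.cho_solve(c, np.eye(H.shape[0]))
    Sigma = 0.5 * (Sigma + Sigma.T)
    mu = linalg.cho_solve(c, Phi.T @ t) / sigma2
    return mu, Sigma


def log_marginal_likelihood(
    Phi: np.ndarray,
    t: np.ndarray,
    alpha: np.ndarray,
    sigma2: float,
    jitter: float = 1e-10,
) -> float:
    """Log evidence ``log N(t | 0, C)`` with ``C = sigma2 I + Phi A^-1 Phi'``.

    Evaluated by a Cholesky factorisation of the dense N x N covariance —
    exact and stable at the cohort sizes this package targets.
    """
    Phi = np.asarray(Phi, dtype=float)
    t = np.asarray(t, dtype=float).ravel()
    alpha = np.asarray(alpha, dtype=float).ravel()
    if Phi.shape[0] != t.size or Phi.shape[1] != alpha.size:
        raise ValueError("inconsistent dimensions between Phi, t and alpha")
    if sigma2 <= 0 or np.any(alpha <= 0):
        raise ValueError("alpha and sigma2 must be positive")
    n = t.size
    C = sigma2 * np.eye(n) + (Phi / alpha) @ Phi.T
    c = _chol_with_jitter(C, jitter)
    logdet = 2.0 * np.sum(np.log(np.diag(c[0])))
    quad = float(t @ linalg.cho_solve(c, t))
    return -0.5 * (n * _LOG2PI + logdet + quad)


class RVR:
    """Relevance vector regression model.

    Parameters
    ----------
    endog : array-like, shape (N,)
        Training targets (clinical scores).
    design : DesignMatrix
        Basis matrix ``[1, K]`` built on the training kernel.
    features : FeatureMatrix, optional
        Training voxel features; required only for weight-map
        back-projection with a linear kernel.
    """

    def __init__(
        self,
        endog,
        design: DesignMatrix,
        features: FeatureMatrix | None = None,
    ):
        self.endog = np.asarray(endog, dtype=float).ravel()
        if not np.all(np.isfinite(self.endog)):
            raise ValueError("NaN or infinite value in targets")
        if not isinstance(design, DesignMatrix):
            raise TypeError("design must be a DesignMatrix")
        if design.Phi.shape[0] != self.endog.size:
            raise ValueError("design rows != number of targets")
        if design.Phi.shape[0] != design.n_train:
            raise ValueError("training design must be square in its kernel block")
        if not np.all(np.isfinite(design.Phi)):
            raise ValueError("NaN or infinite value in design matrix")
        self.design = design
        self.features = features
        self.nobs = self.endog.size
        # Internal basis normalization: divide the kernel block by the RMS of
        # its entries so the optimiser always starts from a comparably scaled
        # problem. Undone transparently at prediction / back-projection time,
        # it makes fitted predictions exactly invariant to an overall kernel
        # rescaling instead of relying on ARD to absorb it numerically.
        B = design.Phi[:, 1:]
        s = float(np.sqrt(np.mean(B**2))) if B.size else 1.0
        self.internal_scale = s if s > 0 else 1.0
        self.exog = np.column_stack([design.Phi[:, 0], B / self.internal_scale])

    @classmethod
    def from_features(cls, scores, features: FeatureMatrix, condition: bool = True):
        """Build the linear-kernel design from training voxel features."""
        K = linear_kernel(features, features, condition=condition)
        return cls(scores, build_design(K), features=features)

    @classmethod
    def from_cohort(cls, cohort, fwhm_mm: float = 0.0, condition: bool = True):
        """Convenience constructor from a synthetic (or loaded) cohort."""
        X = cohort.to_features(fwhm_mm=fwhm_mm)
        return cls.from_features(cohort.scores, X, condition=condition)

    def fit(self, config: FitConfig | None = None) -> "RVRResults":
        """Maximise the evidence over (alpha, sigma2) and return results.

        Uses the fixed-point re-estimation rules: with
        ``gamma_i = 1 - alpha_i Sigma_ii`` (the well-determinedness of
        basis i), ``alpha_i <- gamma_i / mu_i^2`` and
        ``sigma2 <- ||t - Phi mu||^2 / (N - sum gamma)``. Bases whose alpha
        exceeds the prune threshold are removed (ARD). Iterates until the
        largest change in log alpha falls below ``tol`` or ``max_iter`` is
        reached; the returned state is the iterate with the highest evidence
        seen, so the final evidence never falls below the initial one.
        """
        cfg = config or FitConfig()
        Phi_full = self.exog
        t = self.endog
        n, m = Phi_full.shape

        var_t = float(np.var(t))
        sigma2_floor = max(1e-6 * var_t, 1e-12)
        sigma2 = max(cfg.sigma2_init_fraction * var_t, sigma2_floor)
        alpha0 = cfg.alpha_init if cfg.alpha_init is not None else (1.0 / n) ** 2
        active = np.arange(m)
        alpha = np.full(m, alpha0, dtype=float)

        def subdesign(act):
            return Phi_full if act.size == m else Phi_full[:, act]

        def evidence(act, al, s2):
            return log_marginal_likelihood(
                subdesign(act), t, al[act], s2, jitter=cfg.jitter
            )

        llf_init = evidence(active, alpha, sigma2)
        trace = [llf_init]
        best = (llf_init, active.copy(), alpha.copy(), sigma2)
        converged = cfg.max_iter == 0
        n_iter = 0

        for n_iter in range(1, cfg.max_iter + 1):
            Phi = subdesign(active)
            mu, Sigma = compute_posterior(Phi, t, alpha[active], sigma2, cfg.jitter)
            gamma = 1.0 - alpha[active] * np.diag(Sigma)
            gamma = np.clip(gamma, 0.0, 1.0)
            with np.errstate(divide="ignore", invalid="ignore"):
                alpha_new = np.where(mu**2 > 0, gamma / mu**2, np.inf)
            alpha_new = np.maximum(alpha_new, 1e-12)
            resid = t - Phi @ mu
            denom = max(n - float(gamma.sum()), 1e-9)
            sigma2 = max(float(resid @ resid) / denom, sigma2_floor)

            keep = alpha_new < cfg.alpha_prune_threshold
            delta = np.max(
                np.abs(np.log(alpha_new[keep]) - np.log(alpha[active][keep]))
            ) if keep.any() else 0.0
            alpha[active] = alpha_new
            active = active[keep]
            if active.size == 0:
                # everything pruned: degenerate flat model, stop here
                break
            llf = evidence(active, alpha, sigma2)
            trace.append(llf)
            if llf > best[0]:
                best = (llf, active.copy(), alpha.copy(), sigma2)
            if delta < cfg.tol:
                converged = True
                break

        llf, active, alpha, sigma2 = best
        if active.size:
            mu, Sigma = compute_posterior(
                subdesign(active), t, alpha[active], sigma2, cfg.jitter
            )
        else:
            mu = np.zeros(0)
            Sigma = np.zeros((0, 0))
        flags = []
        if n == 1:
            flags.append("degenerate_n1")
        if active.size == 0:
            flags.append("all_bases_pruned")
        return RVRResults(
            model=self,
            mu=mu,
            Sigma=Sigma,
            alpha=alpha,
            sigma2=sigma2,
            active_idx=active,
            llf=llf,
            llf_init=llf_init,
            evidence_trace=np.array(trace),
            n_iter=n_iter,
            converged=converged,
            config=cfg,
            flags=flags,
        )


@dataclass
class RVRResults:
    """A fitted RVR: posterior, hyperparameters and diagnostics.

    ``active_idx`` indexes columns of ``Phi = [1, K]``; index 0 is the
    offset basis, indices ``i >= 1`` correspond to training subject
    ``i - 1``. ``mu`` and ``Sigma`` are over the active set only.
    """

    model: RVR
    mu: np.ndarray
    Sigma: np.ndarray
    alpha: np.ndarray
    sigma2: float
    active_idx: np.ndarray
    llf: float
    llf_init: float
    evidence_trace: np.ndarray
    n_iter: int
    converged: bool
    config: FitConfig
    flags: list[str] = field(default_factory=list)

    # -- basic properties ---------------------------------------------------

    @property
    def nobs(self) -> int:
        return self.model.nobs

    @property
    def relevance_idx(self) -> np.ndarray:
        """Training-sample indices of the relevance vectors (offset excluded)."""
        return self.active_idx[self.active_idx > 0] - 1

    @property
    def relevance_ratio(self) -> float:
        """Fraction of training samples surviving ARD pruning, in [0, 1]."""
        return float(self.relevance_idx.size) / float(self.nobs)

    @property
    def offset(self) -> float:
        """Posterior mean of the offset weight (0 if the offset was pruned)."""
        pos = np.nonzero(self.active_idx == 0)[0]
        return float(self.mu[pos[0]]) if pos.size else 0.0

    # -- prediction ---------------------------------------------------------

    def _design_rows(self, test) -> np.ndarray:
        if isinstance(test, KernelMatrix):
            test = build_design(test)
        if isinstance(test, DesignMatrix):
            if test.train_hash != self.model.design.train_hash:
                raise ValueError(
                    "basis misalignment: test kernel was built against a "
                    "different training set or conditioning scale"
                )
            arr = test.Phi
        else:
            arr = np.asarray(test, dtype=float)
            if arr.ndim != 2 or arr.shape[1] != self.model.design.Phi.shape[1]:
                raise ValueError("test design must have n_train + 1 columns")
        # apply the model's internal basis normalization to the kernel block
        out = arr.copy()
        out[:, 1:] /= self.model.internal_scale
        return out

    def predict(self, test, return_var: bool = False):
        """Predictive mean (and optionally variance) for test rows.

        ``mean = Phi_test[:, active] mu``; the predictive variance is
        ``sigma2 + phi' Sigma phi`` per row — noise plus weight uncertainty —
        so it is never below the noise floor.
        """
        Phi_test = self._design_rows(test)[:, self.active_idx]
        mean = Phi_test @ self.mu if self.mu.size else np.zeros(Phi_test.shape[0])
        if not return_var:
            return mean
        if self.mu.size:
            var = self.sigma2 + np.einsum(
                "ij,jk,ik->i", Phi_test, self.Sigma, Phi_test
            )
        else:
            var = np.full(Phi_test.shape[0], self.sigma2)
        return mean, var

    def predict_features(self, features: FeatureMatrix):
        """Predict from raw voxel features of new subjects (linear kernel)."""
        if self.model.features is None:
            raise ValueError("model was not built from features")
        K = linear_kernel(features, self.model.features, condition=False)
        K = KernelMatrix(
            K=K.K / self.model.design.scale,
            train_subject_ids=K.train_subject_ids,
            row_subject_ids=K.row_subject_ids,
            scale=self.model.design.scale,
        )
        return self.predict(K, return_var=True)

    # -- weight map ---------------------------------------------------------

    def weight_map(
        self, features: FeatureMatrix | None = None
    ) -> tuple[BrainVolume, float]:
        """Back-project the fitted weights into voxel space.

        With the linear kernel, the predicted score of a new image equals the
        dot product of this weighting image with the image's features plus
        the returned offset constant. Voxel weights are
        ``sum_i mu_i x_i / scale`` over the active non-offset bases, where
        ``scale`` is the kernel conditioning divisor.
        """
        X = features if features is not None else self.model.features
        if X is None:
            raise ValueError(
                "weight_map requires the training FeatureMatrix (linear kernel)"
            )
        if X.n_subjects != self.nobs:
            raise ValueError("feature rows != training samples")
        w = np.zeros(X.n_voxels)
        rel = self.relevance_idx
        if rel.size:
            mu_rel = self.mu[self.active_idx > 0]
            w = (mu_rel @ X.X[rel]) / (
                self.model.design.scale * self.model.internal_scale
            )
        vol = devectorize(w, X.mask, voxel_size_mm=X.voxel_size_mm, signed=True)
        return vol, self.offset

    # -- reporting ----------------------------------------------------------

    def summary(self) -> str:
        lines = [
            "Relevance Vector Regression Results",
            "=" * 46,
            f"{'No. observations:':<30}{self.nobs}",
            f"{'Basis functions:':<30}{self.nobs + 1} (offset + kernel)",
            f"{'Relevance vectors:':<30}{self.relevance_idx.size}",
            f"{'Relevance ratio:':<30}{self.relevance_ratio:.3f}",
            f"{'Offset weight:':<30}{self.offset:.4f}",
            f"{'Noise variance sigma^2:':<30}{self.sigma2:.6g}",
            f"{'Log evidence (init):':<30}{self.llf_init:.4f}",
            f"{'Log evidence (final):':<30}{self.llf:.4f}",
            f"{'Iterations:':<30}{self.n_iter}",
            f"{'Converged:':<30}{self.converged}",
        ]
        if self.flags:
            lines.append(f"{'Flags:':<30}{', '.join(self.flags)}")
        lines.append("=" * 46)
        return "\n".join(lines)

    # -- serialization ------------------------------------------------------

    def save(self, path) -> None:
        """Serialize the fitted state to a single JSON file."""
        payload = {
            "mu": self.mu.tolist(),
            "Sigma": self.Sigma.tolist(),
            "alpha": np.where(np.isfinite(self.alpha), self.alpha, -1.0).tolist(),
            "sigma2": self.sigma2,
            "active_idx": self.active_idx.tolist(),
            "llf": self.llf,
            "llf_init": self.llf_init,
            "n_iter": self.n_iter,
            "converged": self.converged,
            "flags": self.flags,
            "train_hash": self.model.design.train_hash,
            "train_subject_ids": self.model.design.train_subject_ids,
            "kernel_scale": self.model.design.scale,
            "config": {
                "max_iter": self.config.max_iter,
                "tol": self.config.tol,
                "alpha_prune_threshold": self.config.alpha_prune_threshold,
                "alpha_init": self.config.alpha_init,
                "sigma2_init_fraction": self.config.sigma2_init_fraction,
                "jitter": self.config.jitter,
                "seed": self.config.seed,
            },
        }
        Path(path).write_text(json.dumps(payload, indent=2))
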