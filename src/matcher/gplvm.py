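"""One-dimensional Bayesian GPLVM pseudotime inference.

The model: each observed cell-by-feature matrix Y (n cells x d features,
standardized per feature) is generated from a scalar latent position t per
cell through a nonlinear map f with a Gaussian-process prior and additive
Gaussian noise::

    Y = f(t) + eps,   f ~ GP(0, k),   eps ~ N(0, sigma^2 I)

with the squared-exponential (RBF) kernel
``k(t_i, t_j) = sigma_rbf^2 * exp(-(t_i - t_j)^2 / (2 l^2))`` and a standard
normal prior on t. Inference maximizes the collapsed variational lower
bound of Titsias & Lawrence with a small set of inducing inputs, yielding a
Gaussian posterior N(mu_n, s_n) per cell. The shared variant ties one latent
per cell across two simultaneously measured modalities, each with its own
kernel hyperparameters and inducing inputs.

The latent sign is arbitrary; orientation is resolved downstream in
:mod:`matcher.alignment`, never here.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Sequence, Union

import numpy as np
import scipy.linalg
import scipy.optimize

from .datamodel import (CellFeatureMatrix, CorrespondenceError,
                        DegenerateDataError, MatcherError)

logger = logging.getLogger("matcher")

_LOG2PI = float(np.log(2.0 * np.pi))
_NUGGET = 1e-6  # relative diagonal nugget on the inducing-point Gram matrix


@dataclass(frozen=True)
class KernelParams:
    """RBF kernel hyperparameters plus the observation noise variance."""

    rbf_variance: float   # sigma_rbf^2
    lengthscale: float    # l
    noise_variance: float  # sigma^2

    def __post_init__(self) -> None:
        for name in ("rbf_variance", "lengthscale", "noise_variance"):
            v = getattr(self, name)
            if not (np.isfinite(v) and v > 0):
                raise MatcherError(f"{name} must be strictly positive and finite, got {v}")


def rbf_kernel(t_i, t_j, params: KernelParams):
    """Squared-exponential covariance sigma_rbf^2 * exp(-(t_i-t_j)^2 / (2 l^2)).

    Accepts scalars or arrays (broadcast); symmetric in its arguments and
    positive semi-definite on any finite point set.
    """
    t_i = np.asarray(t_i, dtype=float)
    t_j = np.asarray(t_j, dtype=float)
    if not (np.all(np.isfinite(t_i)) and np.all(np.isfinite(t_j))):
        raise MatcherError("rbf_kernel: non-finite inputs")
    d = t_i - t_j
    out = params.rbf_variance * np.exp(-(d * d) / (2.0 * params.lengthscale**2))
    return float(out) if out.ndim == 0 else out


def rbf_gram(x: np.ndarray, z: np.ndarray, sf2: float, l2: float) -> np.ndarray:
    d = x[:, None] - z[None, :]
    return sf2 * np.exp(-(d * d) / (2.0 * l2))


def _chol_with_jitter(M: np.ndarray) -> np.ndarray:
    """Cholesky with adaptive diagonal jitter: 1e-8 up to 1e-2 (x10 steps)."""
    scale = max(float(np.mean(np.diag(M))), 1.0)
    jitter = 0.0
    for _ in range(8):
        try:
            return scipy.linalg.cholesky(M + jitter * np.eye(M.shape[0]), lower=True)
        except scipy.linalg.LinAlgError:
            jitter = 1e-8 * scale if jitter == 0.0 else jitter * 10.0
            if jitter > 1e-2 * scale:
                break
    raise MatcherError("Cholesky failed even with maximum jitter 1e-2; "
                       "kernel matrix numerically singular")


def _view_bound_and_grads(Y, mu, s, z, sf2, l2, noise):
    """Data term of the collapsed bound for one modality, plus gradients.

    Returns ``(F, dmu, ds, dz, dsf2, dl2, dnoise)`` where F excludes the KL
    term (which is shared across views in the shared model).
    """
    n, d = Y.shape
    m = z.size
    Im = np.eye(m)

    dz = z[:, None] - z[None, :]
    # baseline nugget proportional to sf2 keeps Kmm invertible while leaving
    # the objective smooth in all parameters (an adaptive, discontinuous
    # jitter breaks the quasi-Newton line search)
    E = np.exp(-(dz * dz) / (2.0 * l2)) + _NUGGET * Im
    Kmm = sf2 * E

    d1 = l2 + s                       # (n,)
    r = mu[:, None] - z[None, :]      # (n, m)
    Psi1 = sf2 * np.sqrt(l2 / d1)[:, None] * np.exp(-(r * r) / (2.0 * d1[:, None]))

    d2 = l2 + 2.0 * s                 # (n,)
    zbar = 0.5 * (z[:, None] + z[None, :])       # (m, m)
    u = mu[:, None, None] - zbar[None, :, :]     # (n, m, m)
    T2 = (sf2 * sf2) * np.sqrt(l2 / d2)[:, None, None] * np.exp(
        -(dz * dz)[None, :, :] / (4.0 * l2) - (u * u) / d2[:, None, None])
    Psi2 = T2.sum(axis=0)
    psi0 = n * sf2

    Lm = _chol_with_jitter(Kmm)
    A = Kmm + Psi2 / noise
    La = _chol_with_jitter(A)
    Kmm_inv = scipy.linalg.cho_solve((Lm, True), Im)
    A_inv = scipy.linalg.cho_solve((La, True), Im)
    logdetK = 2.0 * float(np.sum(np.log(np.diag(Lm))))
    logdetA = 2.0 * float(np.sum(np.log(np.diag(La))))

    B = Psi1.T @ Y                    # (m, d)
    AinvB = A_inv @ B
    trYY = float(np.sum(Y * Y))
    trBAB = float(np.sum(B * AinvB))
    trKinvPsi2 = float(np.sum(Kmm_inv * Psi2))

    F = (-(n * d / 2.0) * (_LOG2PI + np.log(noise))
         + (d / 2.0) * (logdetK - logdetA)
         - trYY / (2.0 * noise) + trBAB / (2.0 * noise**2)
         - d * psi0 / (2.0 * noise) + d * trKinvPsi2 / (2.0 * noise))

    # -- adjoints of the matrix-valued intermediates -------------------
    G_A = -(d / 2.0) * A_inv - (AinvB @ AinvB.T) / (2.0 * noise**2)
    P1 = (Y @ AinvB.T) / noise**2                       # dF/dPsi1, (n, m)
    P2 = G_A / noise + (d / (2.0 * noise)) * Kmm_inv    # dF/dPsi2, (m, m)
    KiP2Ki = Kmm_inv @ Psi2 @ Kmm_inv
    C = (d / 2.0) * Kmm_inv + G_A - (d / (2.0 * noise)) * KiP2Ki  # dF/dKmm

    dnoise = (-(n * d) / (2.0 * noise)
              - float(np.sum(G_A * Psi2)) / noise**2
              + trYY / (2.0 * noise**2)
              - trBAB / noise**3
              + d * psi0 / (2.0 * noise**2)
              - d * trKinvPsi2 / (2.0 * noise**2))

    # -- chain rule into the scalar parameters -------------------------
    dsf2 = float(np.sum(C * E)) - (d / (2.0 * noise)) * n  # Kmm path + psi0 path
    dl2 = float(np.sum(C * Kmm * (dz * dz))) / (2.0 * l2**2)
    dz_grad = 2.0 * np.sum(C * Kmm * (-dz / l2), axis=1)

    W1 = P1 * Psi1
    d1c = d1[:, None]
    dmu = np.sum(W1 * (-r / d1c), axis=1)
    dz_grad += np.sum(W1 * (r / d1c), axis=0)
    ds = np.sum(W1 * (-0.5 / d1c + (r * r) / (2.0 * d1c * d1c)), axis=1)
    dl2 += float(np.sum(W1 * (0.5 / l2 - 0.5 / d1c + (r * r) / (2.0 * d1c * d1c))))
    dsf2 += float(np.sum(W1)) / sf2

    W2 = P2[None, :, :] * T2
    d2c = d2[:, None, None]
    dmu += np.sum(W2 * (-2.0 * u / d2c), axis=(1, 2))
    # d2 = l2 + 2 s_n, so the chain factor 2 is already folded into these terms
    ds += np.sum(W2 * (-1.0 / d2c + 2.0 * (u * u) / (d2c * d2c)), axis=(1, 2))
    dz_grad += 2.0 * np.sum(W2 * (-dz[None, :, :] / (2.0 * l2) + u / d2c), axis=(0, 2))
    dl2 += float(np.sum(W2 * (0.5 / l2 - 0.5 / d2c
                              + (dz * dz)[None, :, :] / (4.0 * l2**2)
                              + (u * u) / (d2c * d2c))))
    dsf2 += 2.0 * float(np.sum(W2)) / sf2

    return F, dmu, ds, dz_grad, dsf2, dl2, dnoise


def _standardize(values: np.ndarray, feature_ids: Sequence[str]):
    mean = values.mean(axis=0)
    std = values.std(axis=0)
    keep = std > 0
    if not np.all(keep):
        dropped = [f for f, k in zip(feature_ids, keep) if not k]
        logger.warning("dropping %d zero-variance feature(s): %s%s",
                       len(dropped), dropped[:5], "..." if len(dropped) > 5 else "")
    if not np.any(keep):
        raise DegenerateDataError("all features have zero variance; no usable signal")
    Z = (values[:, keep] - mean[keep]) / std[keep]
    kept_ids = [f for f, k in zip(feature_ids, keep) if k]
    return Z, mean[keep], std[keep], kept_ids


def _pca_scores(Z: np.ndarray) -> np.ndarray:
    """First principal-component scores of a standardized matrix, unit variance."""
    Zc = Z - Z.mean(axis=0)
    U, S, _ = np.linalg.svd(Zc, full_matrices=False)
    scores = U[:, 0] * S[0]
    sd = scores.std()
    if sd == 0:
        raise DegenerateDataError("degenerate data: zero variance along first "
                                  "principal component (all cells identical?)")
    return scores / sd


class _ViewData:
    def __init__(self, matrix: Union[CellFeatureMatrix, np.ndarray],
                 modality_name: Optional[str] = None):
        if isinstance(matrix, CellFeatureMatrix):
            self.cell_ids = list(matrix.cell_ids)
            values = matrix.values
            feature_ids = list(matrix.feature_ids)
            self.modality_name = modality_name or matrix.modality_name
        else:
            values = np.asarray(matrix, dtype=float)
            self.cell_ids = [f"cell{i}" for i in range(values.shape[0])]
            feature_ids = [f"f{j}" for j in range(values.shape[1])]
            self.modality_name = modality_name or "modality"
        if values.shape[0] < 3:
            raise MatcherError(f"need at least 3 cells, got {values.shape[0]}")
        self.Z, self.feature_mean, self.feature_std, self.feature_ids = \
            _standardize(values, feature_ids)


def _pack(mu, log_s, views):
    parts = [mu, log_s]
    for v in views:
        parts.extend([v["z"], v["log_hyp"]])
    return np.concatenate(parts)


def _fit_latent(view_data: list[_ViewData], n_inducing: int, n_restarts: int,
                max_iter: int, seed: int):
    """Optimize the collapsed bound for one or more views sharing one latent."""
    n = len(view_data[0].cell_ids)
    if n < n_inducing:
        raise MatcherError(f"n_cells ({n}) must be >= n_inducing ({n_inducing})")
    Zcat = np.hstack([v.Z for v in view_data])
    mu_pca = _pca_scores(Zcat)
    m = n_inducing
    n_views = len(view_data)

    def unpack(x):
        mu = x[:n]
        s = np.exp(x[n:2 * n])
        views = []
        off = 2 * n
        for _ in range(n_views):
            z = x[off:off + m]
            sf2, l2, noise = np.exp(x[off + m:off + m + 3])
            views.append((z, sf2, l2, noise))
            off += m + 3
        return mu, s, views

    def objective(x):
        mu, s, views = unpack(x)
        F = 0.0
        gmu = np.zeros(n)
        gs = np.zeros(n)
        gviews = []
        for (z, sf2, l2, noise), vd in zip(views, view_data):
            f, dmu, ds, dzv, dsf2, dl2, dnoise = _view_bound_and_grads(
                vd.Z, mu, s, z, sf2, l2, noise)
            F += f
            gmu += dmu
            gs += ds
            gviews.append((dzv, dsf2 * sf2, dl2 * l2, dnoise * noise))
        # KL[q(t) || N(0,1)], counted once
        F -= 0.5 * float(np.sum(mu * mu + s - np.log(s) - 1.0))
        gmu -= mu
        gs -= 0.5 * (1.0 - 1.0 / s)
        glog_s = gs * s
        parts = [-gmu, -glog_s]
        for dzv, dlsf2, dll2, dlnoise in gviews:
            parts.extend([-dzv, -np.array([dlsf2, dll2, dlnoise])])
        return -F, np.concatenate(parts)

    rng = np.random.default_rng(seed)
    bounds = ([(None, None)] * n + [(-12.0, 8.0)] * n
              + ([(None, None)] * m + [(-12.0, 12.0)] * 3) * n_views)
    noise_idx = [2 * n + v * (m + 3) + m + 2 for v in range(n_views)]
    opts = {"maxiter": max_iter, "maxfun": 3 * max_iter,
            "ftol": 1e-12, "gtol": 1e-7, "maxcor": 40}

    def optimize(x0):
        """Two-stage schedule: the noise variances are pinned during a first
        pass (collapsing noise too early stalls the line search on stiff
        low-noise problems), then everything is freed and polished until the
        bound stops improving."""
        pinned = list(bounds)
        for i in noise_idx:
            pinned[i] = (x0[i], x0[i])
        res = scipy.optimize.minimize(
            objective, x0, jac=True, method="L-BFGS-B", bounds=pinned,
            options={**opts, "maxiter": min(500, max_iter)})
        x, fun = res.x, np.inf
        for _ in range(4):
            res = scipy.optimize.minimize(objective, x, jac=True,
                                          method="L-BFGS-B", bounds=bounds,
                                          options=opts)
            x = res.x
            if not np.isfinite(res.fun) or fun - res.fun < 1e-7 * abs(res.fun):
                break
            fun = res.fun
        return res

    best = None
    diagnostics = []
    for restart in range(n_restarts):
        mu0 = mu_pca.copy()
        log_hyp0 = np.log([1.0, 1.0, 0.1])  # sigma_rbf^2, l^2, sigma^2
        if restart > 0:  # seeded perturbations of the PCA start
            mu0 = mu0 + 0.2 * rng.standard_normal(n)
            log_hyp0 = log_hyp0 + 0.3 * rng.standard_normal(3)
        log_s0 = np.full(n, np.log(0.5))
        views0 = [{"z": np.quantile(mu0, np.linspace(0.0, 1.0, m)),
                   "log_hyp": log_hyp0.copy()} for _ in range(n_views)]
        x0 = _pack(mu0, log_s0, views0)
        try:
            f0, _ = objective(x0)
            res = optimize(x0)
        except MatcherError as exc:
            diagnostics.append(f"restart {restart}: {exc}")
            continue
        if not np.isfinite(res.fun):
            diagnostics.append(f"restart {restart}: non-finite objective")
            continue
        diagnostics.append(f"restart {restart}: elbo {-res.fun:.4f} "
                           f"(init {-f0:.4f}, {res.nit} iter)")
        if best is None or res.fun < best[0].fun:
            best = (res, -f0)
    if best is None:
        raise MatcherError("GPLVM optimization failed in all restarts: "
                           + "; ".join(diagnostics))
    res, elbo_init = best
    mu, s, views = unpack(res.x)
    return mu, s, views, float(-res.fun), float(elbo_init), diagnostics


class GPLVMView:
    """Fitted per-modality quantities: kernel, inducing inputs, predictive map."""

    def __init__(self, *, kernel: KernelParams, inducing_inputs, weights,
                 Kmm_inv, A_inv, feature_mean, feature_std, feature_ids,
                 modality_name):
        self.kernel = kernel
        self.inducing_inputs = np.asarray(inducing_inputs, dtype=float)
        self._weights = np.asarray(weights, dtype=float)      # (m, d)
        self._Kmm_inv = np.asarray(Kmm_inv, dtype=float)
        self._A_inv = np.asarray(A_inv, dtype=float)
        self.feature_mean = np.asarray(feature_mean, dtype=float)
        self.feature_std = np.asarray(feature_std, dtype=float)
        self.feature_ids = list(feature_ids)
        self.modality_name = modality_name

    @classmethod
    def build(cls, vd: _ViewData, mu, s, z, sf2, l2, noise) -> "GPLVMView":
        d1 = l2 + s
        r = mu[:, None] - z[None, :]
        Psi1 = sf2 * np.sqrt(l2 / d1)[:, None] * np.exp(-(r * r) / (2.0 * d1[:, None]))
        d2 = l2 + 2.0 * s
        dz = z[:, None] - z[None, :]
        zbar = 0.5 * (z[:, None] + z[None, :])
        u = mu[:, None, None] - zbar[None, :, :]
        Psi2 = ((sf2 * sf2) * np.sqrt(l2 / d2)[:, None, None] * np.exp(
            -(dz * dz)[None, :, :] / (4.0 * l2) - (u * u) / d2[:, None, None])
        ).sum(axis=0)
        Im = np.eye(z.size)
        Kmm = rbf_gram(z, z, sf2, l2) + _NUGGET * sf2 * Im  # as in training
        Lm = _chol_with_jitter(Kmm)
        La = _chol_with_jitter(Kmm + Psi2 / noise)
        Kmm_inv = scipy.linalg.cho_solve((Lm, True), Im)
        A_inv = scipy.linalg.cho_solve((La, True), Im)
        weights = A_inv @ (Psi1.T @ vd.Z) / noise
        kernel = KernelParams(rbf_variance=float(sf2), lengthscale=float(np.sqrt(l2)),
                              noise_variance=float(noise))
        return cls(kernel=kernel, inducing_inputs=z, weights=weights,
                   Kmm_inv=Kmm_inv, A_inv=A_inv, feature_mean=vd.feature_mean,
                   feature_std=vd.feature_std, feature_ids=vd.feature_ids,
                   modality_name=vd.modality_name)

    def predict(self, t_star, destandardize: bool = False):
        """Posterior predictive mean (and per-feature variance) at latent t_star.

        On the standardized scale predictions revert to the zero prior mean
        far outside the trained latent range. With ``destandardize`` the
        output is mapped back to the modality's original units.
        """
        t_star = np.atleast_1d(np.asarray(t_star, dtype=float))
        if not np.all(np.isfinite(t_star)):
            raise MatcherError("predict: non-finite latent values")
        sf2 = self.kernel.rbf_variance
        l2 = self.kernel.lengthscale**2
        Ksm = rbf_gram(t_star, self.inducing_inputs, sf2, l2)
        mean = Ksm @ self._weights
        M = self._Kmm_inv - self._A_inv
        var_lat = sf2 - np.sum((Ksm @ M) * Ksm, axis=1) + self.kernel.noise_variance
        var_lat = np.maximum(var_lat, 1e-12)
        var = np.tile(var_lat[:, None], (1, mean.shape[1]))
        if destandardize:
            mean = mean * self.feature_std[None, :] + self.feature_mean[None, :]
            var = var * (self.feature_std[None, :] ** 2)
        return mean, var

    def to_dict(self) -> dict:
        return {
            "kernel": {"rbf_variance": self.kernel.rbf_variance,
                       "lengthscale": self.kernel.lengthscale,
                       "noise_variance": self.kernel.noise_variance},
            "inducing_inputs": self.inducing_inputs.tolist(),
            "weights": self._weights.tolist(),
            "Kmm_inv": self._Kmm_inv.tolist(),
            "A_inv": self._A_inv.tolist(),
            "feature_mean": self.feature_mean.tolist(),
            "feature_std": self.feature_std.tolist(),
            "feature_ids": self.feature_ids,
            "modality_name": self.modality_name,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "GPLVMView":
        return cls(kernel=KernelParams(**d["kernel"]),
                   inducing_inputs=d["inducing_inputs"], weights=d["weights"],
                   Kmm_inv=d["Kmm_inv"], A_inv=d["A_inv"],
                   feature_mean=d["feature_mean"], feature_std=d["feature_std"],
                   feature_ids=d["feature_ids"], modality_name=d["modality_name"])


class GPLVMResults:
    """Results of a single-modality 1-D Bayesian GPLVM fit.

    Attributes
    ----------
    latent_mean, latent_variance : per-cell posterior moments of pseudotime
    kernel : KernelParams
    inducing_inputs : array of shape (n_inducing,)
    elbo, elbo_init : final and initial variational lower bound
    """

    def __init__(self, *, view: GPLVMView, latent_mean, latent_variance,
                 elbo, elbo_init, cell_ids, seed, diagnostics=None):
        self._view = view
        self.latent_mean = np.asarray(latent_mean, dtype=float)
        self.latent_variance = np.asarray(latent_variance, dtype=float)
        self.elbo = float(elbo)
        self.elbo_init = float(elbo_init)
        self.cell_ids = list(cell_ids)
        self.seed = int(seed)
        self.diagnostics = diagnostics or []

    kernel = property(lambda self: self._view.kernel)
    inducing_inputs = property(lambda self: self._view.inducing_inputs)
    feature_ids = property(lambda self: self._view.feature_ids)
    feature_mean = property(lambda self: self._view.feature_mean)
    feature_std = property(lambda self: self._view.feature_std)
    modality_name = property(lambda self: self._view.modality_name)

    def predict(self, t_star, destandardize: bool = False):
        return self._view.predict(t_star, destandardize=destandardize)

    def summary(self) -> str:
        k = self.kernel
        lines = [
            f"Bayesian GPLVM fit: modality {self.modality_name!r}",
            f"  cells: {len(self.cell_ids)}  features kept: {len(self.feature_ids)}",
            f"  inducing inputs: {self.inducing_inputs.size}  seed: {self.seed}",
            f"  ELBO: {self.elbo:.4f} (init {self.elbo_init:.4f})",
            f"  kernel: rbf_variance={k.rbf_variance:.4g} lengthscale={k.lengthscale:.4g} "
            f"noise_variance={k.noise_variance:.4g}",
            f"  latent mean range: [{self.latent_mean.min():.3f}, {self.latent_mean.max():.3f}]",
        ]
        return "\n".join(lines)

    def to_json(self, path) -> None:
        d = {"type": "gplvm", "view": self._view.to_dict(),
             "latent_mean": self.latent_mean.tolist(),
             "latent_variance": self.latent_variance.tolist(),
             "elbo": self.elbo, "elbo_init": self.elbo_init,
             "cell_ids": self.cell_ids, "seed": self.seed}
        from .io import atomic_write_text
        atomic_write_text(path, json.dumps(d))

    @classmethod
    def from_json(cls, path) -> "GPLVMResults":
        d = json.loads(Path(path).read_text())
        if d.get("type") != "gplvm":
            raise MatcherError(f"{path}: not a serialized GPLVM fit")
        return cls(view=GPLVMView.from_dict(d["view"]),
                   latent_mean=d["latent_mean"], latent_variance=d["latent_variance"],
                   elbo=d["elbo"], elbo_init=d["elbo_init"],
                   cell_ids=d["cell_ids"], seed=d["seed"])


class BayesianGPLVM:
    """Model object for 1-D pseudotime inference from one modality.

    Parameters
    ----------
    Y : CellFeatureMatrix or ndarray (cells x features)
        Features are standardized to zero mean / unit variance internally;
        zero-variance features are dropped with a warning.
    n_inducing : number of inducing inputs (default 10)
    n_restarts : optimization restarts (PCA init + seeded perturbations)
    max_iter : L-BFGS iteration cap per restart
    """

    def __init__(self, Y, n_inducing: int = 10, n_restarts: int = 3,
                 max_iter: int = 3000):
        if n_inducing < 1:
            raise MatcherError("n_inducing must be >= 1")
        self._vd = _ViewData(Y)
        self.n_inducing = int(n_inducing)
        self.n_restarts = int(n_restarts)
        self.max_iter = int(max_iter)

    def fit(self, seed: int = 0) -> GPLVMResults:
        mu, s, views, elbo, elbo_init, diag = _fit_latent(
            [self._vd], self.n_inducing, self.n_restarts, self.max_iter, seed)
        z, sf2, l2, noise = views[0]
        view = GPLVMView.build(self._vd, mu, s, z, sf2, l2, noise)
        return GPLVMResults(view=view, latent_mean=mu, latent_variance=s,
                            elbo=elbo, elbo_init=elbo_init,
                            cell_ids=self._vd.cell_ids, seed=seed,
                            diagnostics=diag)


class SharedGPLVMResults:
    """Results of a shared-latent GPLVM fit over two (or more) modalities
    measured on the same cells: one latent posterior per cell, separate
    kernel hyperparameters and predictive maps per modality."""

    def __init__(self, *, views: list[GPLVMView], latent_mean, latent_variance,
                 elbo, elbo_init, cell_ids, seed, diagnostics=None):
        self._views = views
        self.latent_mean = np.asarray(latent_mean, dtype=float)
        self.latent_variance = np.asarray(latent_variance, dtype=float)
        self.elbo = float(elbo)
        self.elbo_init = float(elbo_init)
        self.cell_ids = list(cell_ids)
        self.seed = int(seed)
        self.diagnostics = diagnostics or []

    @property
    def modality_names(self) -> list[str]:
        return [v.modality_name for v in self._views]

    def view(self, modality: str) -> GPLVMView:
        for v in self._views:
            if v.modality_name == modality:
                return v
        raise MatcherError(f"no modality {modality!r} in shared fit "
                           f"(have {self.modality_names})")

    def kernel(self, modality: str) -> KernelParams:
        return self.view(modality).kernel

    def predict(self, modality: str, t_star, destandardize: bool = False):
        return self.view(modality).predict(t_star, destandardize=destandardize)

    def summary(self) -> str:
        lines = [f"Shared Bayesian GPLVM fit over {self.modality_names}",
                 f"  cells: {len(self.cell_ids)}  seed: {self.seed}",
                 f"  ELBO: {self.elbo:.4f} (init {self.elbo_init:.4f})"]
        for v in self._views:
            k = v.kernel
            lines.append(f"  [{v.modality_name}] rbf_variance={k.rbf_variance:.4g} "
                         f"lengthscale={k.lengthscale:.4g} noise_variance={k.noise_variance:.4g}")
        return "\n".join(lines)


class SharedBayesianGPLVM:
    """Shared-latent GPLVM for simultaneously measured modalities.

    All matrices must carry identical cell IDs in identical order (true
    correspondence); each modality keeps its own kernel hyperparameters.
    Initialization is PCA on the concatenated standardized matrices.
    """

    def __init__(self, matrices: Sequence[CellFeatureMatrix], n_inducing: int = 10,
                 n_restarts: int = 3, max_iter: int = 3000):
        if len(matrices) < 2:
            raise MatcherError("shared GPLVM needs at least two modalities")
        ref = matrices[0]
        for other in matrices[1:]:
            if list(other.cell_ids) != list(ref.cell_ids):
                diff = sorted(set(ref.cell_ids) ^ set(other.cell_ids))
                if diff:
                    raise CorrespondenceError(
                        f"cell ID mismatch between {ref.modality_name!r} and "
                        f"{other.modality_name!r}; symmetric difference: {diff}")
                raise CorrespondenceError(
                    f"cell order differs between {ref.modality_name!r} and "
                    f"{other.modality_name!r}; reorder to true correspondence")
        self._vds = [_ViewData(mat) for mat in matrices]
        self.n_inducing = int(n_inducing)
        self.n_restarts = int(n_restarts)
        self.max_iter = int(max_iter)

    def fit(self, seed: int = 0) -> SharedGPLVMResults:
        mu, s, views, elbo, elbo_init, diag = _fit_latent(
            self._vds, self.n_inducing, self.n_restarts, self.max_iter, seed)
        built = [GPLVMView.build(vd, mu, s, *vp) for vd, vp in zip(self._vds, views)]
        return SharedGPLVMResults(views=built, latent_mean=mu, latent_variance=s,
                                  elbo=elbo, elbo_init=elbo_init,
                                  cell_ids=self._vds[0].cell_ids, seed=seed,
                                  diagnostics=diag)


def fit_gplvm(Y, config) -> GPLVMResults:
    """Functional wrapper: fit a 1-D Bayesian GPLVM under a RunConfig."""
    model = BayesianGPLVM(Y, n_inducing=config.n_inducing,
                          n_restarts=config.n_restarts, max_iter=config.max_iter)
    return model.fit(seed=config.subseed(f"gplvm:{model._vd.modality_name}"))


def fit_shared_gplvm(Y1, Y2, config) -> SharedGPLVMResults:
    """Functional wrapper: fit the shared-latent GPLVM for two matched modalities."""
    model = SharedBayesianGPLVM([Y1, Y2], n_inducing=config.n_inducing,
                                n_restarts=config.n_restarts, max_iter=config.max_iter)
    return model.fit(seed=config.subseed("shared_gplvm"))


def predict_from_latent(fit, t_star, destandardize: bool = False):
    """Posterior predictive feature values (and variances) at latent positions."""
    return fit.predict(t_star, destandardize=destandardize)
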