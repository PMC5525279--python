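"""Monotone warping from pseudotime to uniform master time.

A warping function is learned by aligning sample quantiles of pseudotime
with the theoretical quantiles of a uniform(0, 1) variable: the sample
quantiles are the independent coordinates, the uniform quantiles the
dependent coordinates, and the map is approximated either by GP regression
(RBF kernel, marginal-likelihood hyperparameters) or by exact piecewise
linear interpolation through the anchors. A GP mean that fails a dense-grid
monotonicity check falls back to interpolation, which is monotone by
construction because the anchors are.

Quantile levels include 0 and 1, so the smallest and largest pseudotime
anchors map exactly to master time 0 and 1; evaluation outside the anchor
range clamps to [0, 1] (master time is bounded by construction).
"""

from __future__ import annotations

import json
import warnings
from pathlib import Path
from typing import Optional

import numpy as np
from sklearn.gaussian_process import GaussianProcessRegressor
from sklearn.gaussian_process.kernels import RBF, ConstantKernel, WhiteKernel

from .datamodel import MatcherError
from .io import atomic_write_text

_GRID_SIZE = 1000
_MONOTONE_TOL = -1e-9


def normalize_pseudotime(t) -> np.ndarray:
    """Affinely rescale pseudotime so min -> 0 and max -> 1 (order-preserving)."""
    t = np.asarray(t, dtype=float)
    if not np.all(np.isfinite(t)):
        raise MatcherError("normalize_pseudotime: non-finite values")
    lo, hi = float(t.min()), float(t.max())
    if hi == lo:
        raise MatcherError("cannot normalize: all pseudotime values are equal "
                           "(no ordering information)")
    return (t - lo) / (hi - lo)


class WarpingFunction:
    """Monotone map pseudotime -> master time in [0, 1], with an inverse.

    Attributes
    ----------
    anchor_pseudotime : nondecreasing sample quantiles of pseudotime
    anchor_master : the matching uniform quantiles in [0, 1]
    method_used : ``"gp"`` or ``"interp"``
    """

    def __init__(self, anchor_pseudotime, anchor_master, method_used: str,
                 grid: Optional[np.ndarray] = None,
                 grid_values: Optional[np.ndarray] = None):
        self.anchor_pseudotime = np.asarray(anchor_pseudotime, dtype=float)
        self.anchor_master = np.asarray(anchor_master, dtype=float)
        if np.any(np.diff(self.anchor_pseudotime) < 0) or np.any(np.diff(self.anchor_master) < 0):
            raise MatcherError("warping anchors must be nondecreasing")
        if method_used not in ("gp", "interp"):
            raise MatcherError(f"unknown warping method {method_used!r}")
        self.method_used = method_used
        if method_used == "gp":
            if grid is None or grid_values is None:
                raise MatcherError("gp warping requires a tabulated smoother grid")
            self._grid = np.asarray(grid, dtype=float)
            self._grid_values = np.asarray(grid_values, dtype=float)
        else:
            # piecewise-linear through deduplicated anchors
            self._grid, self._grid_values = _dedupe_anchors(
                self.anchor_pseudotime, self.anchor_master)

    # -- evaluation ----------------------------------------------------
    def apply(self, t) -> np.ndarray:
        """Map pseudotime to master time; clamped to [0, 1] outside the anchors."""
        t = np.asarray(t, dtype=float)
        if not np.all(np.isfinite(t)):
            raise MatcherError("apply_warping: non-finite input")
        out = np.interp(t, self._grid, self._grid_values)
        return np.clip(out, 0.0, 1.0)

    def invert(self, m) -> np.ndarray:
        """Map master time in [0, 1] back to pseudotime (monotone inverse)."""
        m = np.asarray(m, dtype=float)
        if not np.all(np.isfinite(m)) or np.any(m < 0) or np.any(m > 1):
            raise MatcherError("invert_warping: master time must lie in [0, 1]")
        return np.interp(m, self._grid_values, self._grid)

    __call__ = apply

    # -- serialization -------------------------------------------------
    def to_dict(self) -> dict:
        return {"anchor_pseudotime": self.anchor_pseudotime.tolist(),
                "anchor_master": self.anchor_master.tolist(),
                "method_used": self.method_used,
                "grid": self._grid.tolist(),
                "grid_values": self._grid_values.tolist()}

    @classmethod
    def from_dict(cls, d: dict) -> "WarpingFunction":
        return cls(d["anchor_pseudotime"], d["anchor_master"], d["method_used"],
                   grid=d["grid"], grid_values=d["grid_values"])

    def to_json(self, path) -> None:
        atomic_write_text(path, json.dumps({"type": "warp", **self.to_dict()}))

    @classmethod
    def from_json(cls, path) -> "WarpingFunction":
        d = json.loads(Path(path).read_text())
        if d.get("type") != "warp":
            raise MatcherError(f"{path}: not a serialized warping function")
        return cls.from_dict(d)


def _dedupe_anchors(x: np.ndarray, y: np.ndarray):
    """Collapse tied pseudotime anchors (mean master per tie group) so the
    tabulated map is a function; endpoints stay pinned at 0 and 1."""
    ux, inverse = np.unique(x, return_inverse=True)
    uy = np.zeros_like(ux)
    counts = np.zeros_like(ux)
    np.add.at(uy, inverse, y)
    np.add.at(counts, inverse, 1.0)
    uy = uy / counts
    uy[0], uy[-1] = y[0], y[-1]
    uy = np.maximum.accumulate(uy)
    return ux, uy


def _is_monotone(values: np.ndarray) -> bool:
    return bool(np.all(np.diff(values) >= _MONOTONE_TOL))


def learn_warping(t, n_quantiles: int = 50, method: str = "auto",
                  random_state: int = 0) -> WarpingFunction:
    """Learn the pseudotime -> master-time warping by quantile alignment.

    Parameters
    ----------
    t : pseudotime values (typically normalized to [0, 1])
    n_quantiles : number of quantile anchors, evenly spaced levels in [0, 1]
        including both endpoints (default 50)
    method : ``"gp"``, ``"interp"`` or ``"auto"``; ``auto`` fits GP regression
        and falls back to interpolation when the GP mean is not monotone
    """
    t = np.asarray(t, dtype=float)
    if not np.all(np.isfinite(t)):
        raise MatcherError("learn_warping: non-finite pseudotime")
    if n_quantiles < 2:
        raise MatcherError("n_quantiles must be >= 2")
    if method not in ("gp", "interp", "auto"):
        raise MatcherError(f"unknown warping method {method!r}")
    if np.unique(t).size < n_quantiles:
        warnings.warn(
            f"only {np.unique(t).size} distinct pseudotime values for "
            f"{n_quantiles} quantile anchors; anchors will contain ties",
            stacklevel=2)
    levels = np.linspace(0.0, 1.0, n_quantiles)
    anchors_t = np.quantile(t, levels)  # linear-interpolation sample quantiles
    anchors_m = levels

    if method in ("gp", "auto"):
        grid, values, monotone = _fit_gp_warp(anchors_t, anchors_m, random_state)
        if monotone:
            return WarpingFunction(anchors_t, anchors_m, "gp",
                                   grid=grid, grid_values=values)
        if method == "gp":
            warnings.warn("GP warping mean is not monotone; falling back to "
                          "linear interpolation", stacklevel=2)
    return WarpingFunction(anchors_t, anchors_m, "interp")


def _fit_gp_warp(anchors_t: np.ndarray, anchors_m: np.ndarray, random_state: int):
    """GP regression of master on pseudotime quantiles; returns a dense
    tabulation of the mean, affinely rescaled to pin the endpoint anchors
    at exactly 0 and 1, plus a monotonicity verdict on a 1000-point grid."""
    x, y = _dedupe_anchors(anchors_t, anchors_m)
    span = x[-1] - x[0]
    if span <= 0:
        return None, None, False
    # anchors are (near-)noiseless sample quantiles, so the white-noise term
    # is capped low: the GP should closely interpolate, not oversmooth
    kernel = (ConstantKernel(1.0, (1e-3, 1e3))
              * RBF(length_scale=span / 4.0, length_scale_bounds=(span / 50.0, span * 10.0))
              + WhiteKernel(noise_level=1e-8, noise_level_bounds=(1e-12, 1e-4)))
    gpr = GaussianProcessRegressor(kernel=kernel, normalize_y=True,
                                   random_state=random_state)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        gpr.fit(x[:, None], y)
    grid = np.linspace(x[0], x[-1], _GRID_SIZE)
    mean = gpr.predict(grid[:, None])
    lo, hi = mean[0], mean[-1]
    if hi <= lo or not _is_monotone(mean):
        return None, None, False
    values = (mean - lo) / (hi - lo)  # positive affine map: monotonicity preserved
    return grid, values, True


def apply_warping(w: WarpingFunction, t) -> np.ndarray:
    return w.apply(t)


def invert_warping(w: WarpingFunction, m) -> np.ndarray:
    return w.invert(m)
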