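"""Seeded synthetic-data generator with known ground truth.

The generator emulates the synthetic study used to validate the pipeline:
master time drawn uniformly on [0, 1] for each cell, mapped to pseudotime
through a monotone warping function, then hundreds of features generated as
smooth (logistic-sigmoid) functions of pseudotime with additive Gaussian
noise. Defaults: 100 cells, 600 features, noiseless feature range 16 so
that noise sigma = 9 exceeds 50% of the range.

Warping families: ``identity``, ``power:a`` (t = u**a) and
``beta_cdf:alpha,beta`` (t = Beta CDF of u) — all monotone on [0, 1].
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Optional, Sequence

import numpy as np
import pandas as pd
import scipy.stats

from .datamodel import CellFeatureMatrix, MatcherError


def parse_warp(spec: str) -> Callable[[np.ndarray], np.ndarray]:
    """Parse a warp-family string into a monotone map [0,1] -> [0,1]."""
    if spec == "identity":
        return lambda u: np.asarray(u, dtype=float)
    if spec.startswith("power:"):
        a = float(spec.split(":", 1)[1])
        if a <= 0:
            raise MatcherError(f"power warp exponent must be positive, got {a}")
        return lambda u: np.asarray(u, dtype=float) ** a
    if spec.startswith("beta_cdf:"):
        try:
            alpha, beta = (float(x) for x in spec.split(":", 1)[1].split(","))
        except ValueError:
            raise MatcherError(f"malformed beta_cdf warp {spec!r}; "
                               "expected beta_cdf:alpha,beta") from None
        if alpha <= 0 or beta <= 0:
            raise MatcherError("beta_cdf warp parameters must be positive")
        return lambda u: scipy.stats.beta.cdf(u, alpha, beta)
    raise MatcherError(f"unknown warp family {spec!r}; expected identity, "
                       "power:a or beta_cdf:alpha,beta")


@dataclass
class SimSpec:
    """Specification of one simulated modality."""

    n_cells: int = 100
    n_features: int = 600
    warp_family: str = "power:2"
    noise_sigma: float = 9.0
    feature_range: float = 16.0
    seed: int = 0
    modality_name: str = "sim"

    def __post_init__(self) -> None:
        if self.n_cells < 3:
            raise MatcherError("n_cells must be >= 3")
        if self.n_features < 1:
            raise MatcherError("n_features must be >= 1")
        if self.noise_sigma < 0:
            raise MatcherError("noise_sigma must be nonnegative")
        if self.feature_range <= 0:
            raise MatcherError("feature_range must be positive")
        parse_warp(self.warp_family)  # validates


@dataclass
class SimResult:
    """A simulated modality plus its generating ground truth."""

    spec: SimSpec
    true_master: np.ndarray
    true_pseudotime: np.ndarray
    Y: CellFeatureMatrix
    feature_params: pd.DataFrame  # center, slope, sign, amplitude per feature

    def noiseless(self, pseudotime: Optional[np.ndarray] = None) -> np.ndarray:
        """Evaluate the noiseless generating functions at given pseudotimes."""
        t = self.true_pseudotime if pseudotime is None else np.asarray(pseudotime, float)
        p = self.feature_params
        return _sigmoid_features(t, p["center"].to_numpy(), p["slope"].to_numpy(),
                                 p["sign"].to_numpy(), p["amplitude"].to_numpy())

    def truth_table(self) -> pd.DataFrame:
        return pd.DataFrame({"cell_id": self.Y.cell_ids,
                             "true_master": self.true_master,
                             "true_pseudotime": self.true_pseudotime})


def _sigmoid_features(t, centers, slopes, signs, amplitudes) -> np.ndarray:
    g = 1.0 / (1.0 + np.exp(-slopes[None, :] * (t[:, None] - centers[None, :])))
    return signs[None, :] * amplitudes[None, :] * g


def _draw_feature_params(rng: np.random.Generator, n_features: int,
                         feature_range: float) -> pd.DataFrame:
    centers = rng.uniform(0.1, 0.9, n_features)
    slopes = rng.uniform(4.0, 12.0, n_features)
    signs = rng.choice([-1.0, 1.0], n_features)
    # scale so the noiseless range over pseudotime in [0,1] equals feature_range
    g1 = 1.0 / (1.0 + np.exp(-slopes * (1.0 - centers)))
    g0 = 1.0 / (1.0 + np.exp(-slopes * (0.0 - centers)))
    amplitudes = feature_range / (g1 - g0)
    return pd.DataFrame({"center": centers, "slope": slopes, "sign": signs,
                         "amplitude": amplitudes})


def simulate_modality(spec: SimSpec,
                      master: Optional[np.ndarray] = None,
                      cell_ids: Optional[Sequence[str]] = None) -> SimResult:
    """Simulate one modality; fully reproducible from ``spec.seed``.

    ``master`` may be supplied to share one master-time draw between
    modalities (paired simulations); otherwise it is drawn uniform(0, 1).
    """
    rng = np.random.default_rng(spec.seed)
    if master is None:
        master = rng.uniform(0.0, 1.0, spec.n_cells)
    else:
        master = np.asarray(master, dtype=float)
        if master.shape != (spec.n_cells,):
            raise MatcherError(f"supplied master time has shape {master.shape}, "
                               f"expected ({spec.n_cells},)")
    warp = parse_warp(spec.warp_family)
    pseudotime = warp(master)
    params = _draw_feature_params(rng, spec.n_features, spec.feature_range)
    clean = _sigmoid_features(pseudotime, params["center"].to_numpy(),
                              params["slope"].to_numpy(), params["sign"].to_numpy(),
                              params["amplitude"].to_numpy())
    Yv = clean + spec.noise_sigma * rng.standard_normal(clean.shape)
    if cell_ids is None:
        cell_ids = [f"cell{i:04d}" for i in range(spec.n_cells)]
    feature_ids = [f"{spec.modality_name}_g{j:04d}" for j in range(spec.n_features)]
    Y = CellFeatureMatrix(Yv, cell_ids, feature_ids, modality_name=spec.modality_name)
    return SimResult(spec=spec, true_master=master, true_pseudotime=pseudotime,
                     Y=Y, feature_params=params)


def simulate_paired_modalities(specA: SimSpec, specB: SimSpec,
                               subsample: Optional[tuple[float, float]] = None,
                               seed: Optional[int] = None):
    """Two modalities generated from one shared master-time draw.

    Each modality applies its own warp, feature set and noise. With
    ``subsample=(fA, fB)`` the two modalities keep disjoint random cell
    subsets of those fractions, emulating different cells measured by
    different assays. Returns ``(resultA, resultB, correspondence)`` where
    ``correspondence`` is the per-cell ground truth over the full draw with
    membership flags for each modality.
    """
    if specA.n_cells != specB.n_cells:
        raise MatcherError("paired simulation requires equal n_cells before subsampling")
    if seed is None:
        seed = specA.seed
    rng = np.random.default_rng(seed)
    n = specA.n_cells
    master = rng.uniform(0.0, 1.0, n)
    cell_ids = [f"cell{i:04d}" for i in range(n)]
    resA = simulate_modality(specA, master=master, cell_ids=cell_ids)
    resB = simulate_modality(specB, master=master, cell_ids=cell_ids)

    in_A = np.ones(n, dtype=bool)
    in_B = np.ones(n, dtype=bool)
    if subsample is not None:
        fA, fB = subsample
        if not (0 < fA <= 1 and 0 < fB <= 1 and fA + fB <= 1.0 + 1e-12):
            raise MatcherError("subsample fractions must be in (0, 1] and sum to <= 1 "
                               "(disjoint subsets)")
        nA, nB = int(np.floor(fA * n)), int(np.floor(fB * n))
        if nA < 10 or nB < 10:
            raise MatcherError(f"subsampling leaves fewer than 10 cells "
                               f"({nA} and {nB}); increase n_cells or fractions")
        perm = rng.permutation(n)
        in_A = np.zeros(n, dtype=bool)
        in_B = np.zeros(n, dtype=bool)
        in_A[perm[:nA]] = True
        in_B[perm[nA:nA + nB]] = True
        resA = _subset_result(resA, in_A)
        resB = _subset_result(resB, in_B)

    correspondence = pd.DataFrame({"cell_id": cell_ids, "true_master": master,
                                   "in_A": in_A, "in_B": in_B})
    return resA, resB, correspondence


def _subset_result(res: SimResult, keep: np.ndarray) -> SimResult:
    cells = [c for c, k in zip(res.Y.cell_ids, keep) if k]
    return SimResult(spec=res.spec, true_master=res.true_master[keep],
                     true_pseudotime=res.true_pseudotime[keep],
                     Y=res.Y.subset_cells(cells), feature_params=res.feature_params)


def true_correspondence_correlations(resA: SimResult, resB: SimResult,
                                     correspondence: pd.DataFrame,
                                     pairs: Sequence[tuple[str, str]],
                                     method: str = "spearman") -> pd.DataFrame:
    """Oracle cross-modality correlations using the generating cell matching.

    Correlates feature values across the *full* shared master-time draw —
    every cell, regardless of which modality retained it after subsampling —
    by re-evaluating each modality's generating functions (plus the
    modality's noise level) at the shared cells. Because both modalities are
    evaluated on the same cells this is the true-correspondence correlation
    the alignment-based estimate is trying to recover.
    """
    master = correspondence["true_master"].to_numpy()
    rngA = np.random.default_rng(resA.spec.seed + 1_000_003)
    rngB = np.random.default_rng(resB.spec.seed + 2_000_003)
    tA = parse_warp(resA.spec.warp_family)(master)
    tB = parse_warp(resB.spec.warp_family)(master)
    YA = resA.noiseless(tA) + resA.spec.noise_sigma * rngA.standard_normal((master.size, resA.spec.n_features))
    YB = resB.noiseless(tB) + resB.spec.noise_sigma * rngB.standard_normal((master.size, resB.spec.n_features))
    idxA = {f: j for j, f in enumerate(resA.Y.feature_ids)}
    idxB = {f: j for j, f in enumerate(resB.Y.feature_ids)}
    rows = []
    for fa, fb in pairs:
        a = YA[:, idxA[fa]]
        b = YB[:, idxB[fb]]
        if method == "spearman":
            r = scipy.stats.spearmanr(a, b).statistic
        else:
            r = scipy.stats.pearsonr(a, b).statistic
        rows.append({"feature_a": fa, "feature_b": fb, "true_r": float(r)})
    return pd.DataFrame(rows)


def noise_sweep(base_spec: SimSpec, sigmas: Sequence[float], n_reps: int,
                seed: int = 0, config=None) -> pd.DataFrame:
    """Accuracy (|Pearson| between true and inferred master time) per noise level.

    Runs the full pipeline (GPLVM fit, normalization, quantile warping) on a
    fresh simulation for every (sigma, rep) and reports per-run accuracy;
    orientation is resolved by taking the absolute correlation.
    """
    from .alignment import build_modality_model
    from .datamodel import RunConfig

    if any(s < 0 for s in sigmas):
        raise MatcherError("noise sigmas must be nonnegative")
    if config is None:
        config = RunConfig(seed=seed)
    rows = []
    rng = np.random.default_rng(seed)
    for sigma in sigmas:
        for rep in range(n_reps):
            rep_seed = int(rng.integers(0, 2**31 - 1))
            spec = SimSpec(n_cells=base_spec.n_cells, n_features=base_spec.n_features,
                           warp_family=base_spec.warp_family, noise_sigma=float(sigma),
                           feature_range=base_spec.feature_range, seed=rep_seed,
                           modality_name=base_spec.modality_name)
            sim = simulate_modality(spec)
            model = build_modality_model(sim.Y, config.replace(seed=rep_seed))
            r = scipy.stats.pearsonr(model.master_time, sim.true_master).statistic
            rows.append({"sigma": float(sigma), "rep": rep, "seed": rep_seed,
                         "accuracy": abs(float(r))})
    return pd.DataFrame(rows)
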