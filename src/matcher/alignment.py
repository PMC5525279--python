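"""Alignment of per-modality pseudotime models into a common master-time frame.

This module composes the pipeline per modality (GPLVM fit -> orientation ->
[0,1] normalization -> quantile warping -> master time), generates
corresponding measurements across modalities through the generative model,
and provides the downstream statistics: cross-modality feature correlations,
the before/after decoupling test (Fisher r-to-z plus a permutation test),
shared master time from a shared GPLVM, and lagging-cell identification.

The statsmodels-style entry point is :class:`MatcherModel` /
:class:`MatcherResults`; the module-level functions are the underlying
operations.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import scipy.stats

from .datamodel import (CellFeatureMatrix, MatcherError, RunConfig,
                        parse_orientation_rule)
from .gplvm import GPLVMResults, GPLVMView, SharedGPLVMResults, fit_gplvm
from .io import atomic_write_text
from .warping import WarpingFunction, learn_warping, normalize_pseudotime

logger = logging.getLogger("matcher")

_MIN_MARKER_CORR = 0.1


def orient(fit: GPLVMResults, rule: str = "keep",
           marker_values: Optional[np.ndarray] = None) -> tuple[str, np.ndarray]:
    """Resolve latent orientation; returns ``("keep"|"reverse", oriented latent)``.

    Orientation cannot be inferred from data alone, so it is driven by an
    explicit rule or by prior knowledge of a marker feature's direction:
    ``marker:<feature>:<increasing|decreasing>`` reverses the latent iff the
    sign of Spearman(latent, marker) contradicts the declared direction.
    A marker with |Spearman| < 0.1 is refused as uninformative.
    """
    kind, marker, direction = parse_orientation_rule(rule)
    latent = np.asarray(fit.latent_mean, dtype=float)
    if kind == "keep":
        return "keep", latent
    if kind == "reverse":
        return "reverse", -latent
    if marker_values is None:
        if marker not in fit.feature_ids:
            raise MatcherError(f"orientation marker {marker!r} not present in "
                               f"modality {fit.modality_name!r}")
        raise MatcherError("marker orientation requires the observed marker "
                           "values; pass marker_values")
    marker_values = np.asarray(marker_values, dtype=float)
    rho = scipy.stats.spearmanr(latent, marker_values).statistic
    if not np.isfinite(rho) or abs(rho) < _MIN_MARKER_CORR:
        raise MatcherError(
            f"uninformative marker {marker!r}: |Spearman| = "
            f"{abs(rho) if np.isfinite(rho) else float('nan'):.3f} < {_MIN_MARKER_CORR}; "
            "refusing to guess orientation")
    wants_increasing = direction == "increasing"
    is_increasing = rho > 0
    if wants_increasing == is_increasing:
        logger.info("orientation of %s: keep (marker %s %s, Spearman %.3f)",
                    fit.modality_name, marker, direction, rho)
        return "keep", latent
    logger.info("orientation of %s: reverse (marker %s %s, Spearman %.3f)",
                fit.modality_name, marker, direction, rho)
    return "reverse", -latent


@dataclass
class ModalityModel:
    """Oriented, scale-normalized pseudotime model for one modality."""

    modality_name: str
    fit: GPLVMResults
    orientation_applied: str            # "keep" or "reverse"
    warp: WarpingFunction
    pseudotime: np.ndarray              # oriented, normalized to [0, 1]
    master_time: np.ndarray             # in [0, 1]
    observed: Optional[CellFeatureMatrix] = None

    @property
    def cell_ids(self) -> list[str]:
        return self.fit.cell_ids

    def master_time_records(self) -> list[dict]:
        return [{"cell_id": c, "modality": self.modality_name,
                 "pseudotime": float(p), "master_time": float(m)}
                for c, p, m in zip(self.cell_ids, self.pseudotime, self.master_time)]

    def to_json(self, path) -> None:
        d = {"type": "modality_model", "modality_name": self.modality_name,
             "orientation_applied": self.orientation_applied,
             "warp": self.warp.to_dict(),
             "pseudotime": self.pseudotime.tolist(),
             "master_time": self.master_time.tolist(),
             "fit": {"view": self.fit._view.to_dict(),
                     "latent_mean": self.fit.latent_mean.tolist(),
                     "latent_variance": self.fit.latent_variance.tolist(),
                     "elbo": self.fit.elbo, "elbo_init": self.fit.elbo_init,
                     "cell_ids": self.fit.cell_ids, "seed": self.fit.seed}}
        atomic_write_text(path, json.dumps(d))

    @classmethod
    def from_json(cls, path) -> "ModalityModel":
        d = json.loads(Path(path).read_text())
        if d.get("type") != "modality_model":
            raise MatcherError(f"{path}: not a serialized modality model")
        f = d["fit"]
        fit = GPLVMResults(view=GPLVMView.from_dict(f["view"]),
                           latent_mean=f["latent_mean"],
                           latent_variance=f["latent_variance"], elbo=f["elbo"],
                           elbo_init=f["elbo_init"], cell_ids=f["cell_ids"],
                           seed=f["seed"])
        return cls(modality_name=d["modality_name"], fit=fit,
                   orientation_applied=d["orientation_applied"],
                   warp=WarpingFunction.from_dict(d["warp"]),
                   pseudotime=np.asarray(d["pseudotime"], dtype=float),
                   master_time=np.asarray(d["master_time"], dtype=float))


def build_modality_model(Y: CellFeatureMatrix, config: RunConfig,
                         fit: Optional[GPLVMResults] = None) -> ModalityModel:
    """Compose fit -> orient -> normalize -> warp into a ModalityModel."""
    if fit is None:
        fit = fit_gplvm(Y, config)
    rule = config.orientation.get(Y.modality_name, "keep")
    kind, marker, _ = parse_orientation_rule(rule)
    marker_values = Y.feature_vector(marker) if kind == "marker" else None
    applied, oriented = orient(fit, rule, marker_values=marker_values)
    pseudotime = normalize_pseudotime(oriented)
    warp = learn_warping(pseudotime, n_quantiles=config.n_quantiles,
                         method=config.warp_method,
                         random_state=config.subseed(f"warp:{Y.modality_name}"))
    master = warp.apply(pseudotime)
    return ModalityModel(modality_name=Y.modality_name, fit=fit,
                         orientation_applied=applied, warp=warp,
                         pseudotime=pseudotime, master_time=master, observed=Y)


@dataclass
class CorrespondenceSet:
    """Generated counterpart measurements in a target modality for query cells."""

    query_cell_ids: list[str]
    pivot_master_time: np.ndarray
    target_modality: str
    generated: pd.DataFrame            # query cells x target features
    predictive_variance: pd.DataFrame  # same shape

    def __post_init__(self) -> None:
        if not np.all(np.isfinite(self.generated.to_numpy())):
            raise MatcherError("generated measurements contain non-finite values")


def infer_correspondence(source: ModalityModel, target: ModalityModel,
                         cells: Optional[Sequence[str]] = None,
                         destandardize: bool = True) -> CorrespondenceSet:
    """Infer what the query cells would look like in the target modality.

    Each source cell's master time is mapped through the target's inverse
    warping to a target pseudotime, and the target GPLVM's posterior
    predictive mean at that pseudotime is returned (de-standardized to the
    target's original feature scale by default).
    """
    if cells is None:
        cells = list(source.cell_ids)
    else:
        cells = list(cells)
    if len(cells) == 0:
        raise MatcherError("empty query cell subset")
    pos = {c: i for i, c in enumerate(source.cell_ids)}
    missing = [c for c in cells if c not in pos]
    if missing:
        raise MatcherError(f"query cells not in source modality: {missing}")
    idx = [pos[c] for c in cells]
    m = source.master_time[idx]
    # target pseudotime is normalized [0,1]; invert the target warp, then map
    # back to the target's latent scale for prediction
    t_norm = target.warp.invert(m)
    lat = np.asarray(target.fit.latent_mean, dtype=float)
    if target.orientation_applied == "reverse":
        lat = -lat
    lo, hi = float(lat.min()), float(lat.max())
    t_latent = lo + t_norm * (hi - lo)
    if target.orientation_applied == "reverse":
        t_latent = -t_latent
    mean, var = target.fit.predict(t_latent, destandardize=destandardize)
    gen = pd.DataFrame(mean, index=pd.Index(cells, name="cell_id"),
                       columns=target.fit.feature_ids)
    pv = pd.DataFrame(var, index=gen.index, columns=gen.columns)
    return CorrespondenceSet(query_cell_ids=cells, pivot_master_time=m,
                             target_modality=target.modality_name,
                             generated=gen, predictive_variance=pv)


def cross_modality_correlation(source: ModalityModel, target: ModalityModel,
                               feat_A: Sequence[str], feat_B: Sequence[str],
                               method: str = "spearman") -> pd.DataFrame:
    """Correlate observed source features against generated target features.

    Spearman by default (captures nonlinear monotone relationships); entries
    for zero-variance features are NaN rather than silently 0.
    """
    if method not in ("spearman", "pearson"):
        raise MatcherError(f"unknown correlation method {method!r}")
    if source.observed is None:
        raise MatcherError("source model carries no observed matrix")
    obs = source.observed.subset_features(list(feat_A))
    corr = infer_correspondence(source, target)
    missing = [f for f in feat_B if f not in corr.generated.columns]
    if missing:
        raise MatcherError(f"features not in target modality: {missing}")
    gen = corr.generated[list(feat_B)].to_numpy()
    A = obs.values
    out = np.full((len(feat_A), len(feat_B)), np.nan)
    for i in range(len(feat_A)):
        a = A[:, i]
        if np.std(a) == 0:
            continue  # undefined; stays NaN
        for j in range(len(feat_B)):
            b = gen[:, j]
            if np.std(b) == 0:
                continue
            if method == "spearman":
                out[i, j] = scipy.stats.spearmanr(a, b).statistic
            else:
                out[i, j] = scipy.stats.pearsonr(a, b).statistic
    return pd.DataFrame(out, index=pd.Index(list(feat_A), name="feature_a"),
                        columns=list(feat_B))


@dataclass
class DecouplingResult:
    """Before/after-split comparison of the coupling between two master times."""

    split_point: float
    r_before: float
    r_after: float
    fisher_z: float
    p_fisher: float
    p_perm: float
    n_perm: int
    n_before: int
    n_after: int
    observed_perm_stat: float

    def summary(self) -> str:
        return (f"Decoupling test at split {self.split_point}\n"
                f"  Pearson before: {self.r_before:.4f} (n={self.n_before})  "
                f"after: {self.r_after:.4f} (n={self.n_after})\n"
                f"  Fisher z: {self.fisher_z:.4f}  one-tailed p: {self.p_fisher:.4g}\n"
                f"  permutation p ({self.n_perm} draws, Spearman statistic): "
                f"{self.p_perm:.4g}")


def fisher_r_to_z(r1: float, n1: int, r2: float, n2: int) -> tuple[float, float]:
    """Fisher r-to-z comparison of two independent correlations.

    z = (atanh r1 - atanh r2) / sqrt(1/(n1-3) + 1/(n2-3)); the one-tailed p
    tests H0: r1 <= r2 (small p means r1 is credibly larger).
    """
    if n1 <= 3 or n2 <= 3:
        raise MatcherError("Fisher r-to-z needs more than 3 observations per group")
    # clamp so perfectly correlated groups (r = 1) compare as equal (z = 0)
    r1 = float(np.clip(r1, -1.0 + 1e-15, 1.0 - 1e-15))
    r2 = float(np.clip(r2, -1.0 + 1e-15, 1.0 - 1e-15))
    z = (np.arctanh(r1) - np.arctanh(r2)) / np.sqrt(1.0 / (n1 - 3) + 1.0 / (n2 - 3))
    p = float(scipy.stats.norm.sf(z))
    return float(z), p


def _rowwise_pearson(X: np.ndarray, Y: np.ndarray) -> np.ndarray:
    Xc = X - X.mean(axis=1, keepdims=True)
    Yc = Y - Y.mean(axis=1, keepdims=True)
    num = (Xc * Yc).sum(axis=1)
    den = np.sqrt((Xc * Xc).sum(axis=1) * (Yc * Yc).sum(axis=1))
    with np.errstate(invalid="ignore", divide="ignore"):
        return num / den


def _rowwise_spearman(X: np.ndarray, Y: np.ndarray) -> np.ndarray:
    rx = scipy.stats.rankdata(X, axis=1)
    ry = scipy.stats.rankdata(Y, axis=1)
    return _rowwise_pearson(rx, ry)


def decoupling_test(m1, m2, split: float = 0.3, n_perm: int = 100_000,
                    seed: int = 0) -> DecouplingResult:
    """Test whether two modalities' master times decouple early in the process.

    Cells are split by thresholding ``m1`` at ``split``; Pearson correlations
    between m1 and m2 are compared across the two groups via Fisher r-to-z
    (one-tailed, H0: r_before <= r_after). A permutation test redraws random
    divisions into groups of floor(0.3 n) and the remainder, computes the
    Spearman correlation difference in each, and reports the add-one
    empirical p value for the observed Spearman difference.
    """
    m1 = np.asarray(m1, dtype=float)
    m2 = np.asarray(m2, dtype=float)
    if m1.shape != m2.shape or m1.ndim != 1:
        raise MatcherError("m1 and m2 must be equal-length 1-D master-time vectors "
                           "over the same cells")
    if not (0.0 < split < 1.0):
        raise MatcherError(f"split point {split} outside (0, 1)")
    if n_perm < 1:
        raise MatcherError("n_perm must be >= 1")
    n = m1.size
    before = m1 < split
    after = ~before
    n1, n2 = int(before.sum()), int(after.sum())
    if n1 < 4 or n2 < 4:
        raise MatcherError(f"threshold split leaves too-small groups "
                           f"({n1} before, {n2} after); need >= 4 each")
    r1 = float(scipy.stats.pearsonr(m1[before], m2[before]).statistic)
    r2 = float(scipy.stats.pearsonr(m1[after], m2[after]).statistic)
    z, p_fisher = fisher_r_to_z(r1, n1, r2, n2)

    s1 = float(scipy.stats.spearmanr(m1[before], m2[before]).statistic)
    s2 = float(scipy.stats.spearmanr(m1[after], m2[after]).statistic)
    observed = s1 - s2

    k = int(np.floor(0.3 * n))  # "approximately 30%" of cells
    if k < 2:
        raise MatcherError(f"permutation group of floor(0.3*{n}) = {k} cells is "
                           "too small for a correlation")
    rng = np.random.default_rng(seed)
    exceed = 0
    chunk = max(1, min(n_perm, int(5e6 // max(n, 1))))
    done = 0
    while done < n_perm:
        b = min(chunk, n_perm - done)
        order = np.argsort(rng.random((b, n)), axis=1)
        g1 = order[:, :k]
        g2 = order[:, k:]
        d1 = _rowwise_spearman(np.take(m1, g1), np.take(m2, g1))
        d2 = _rowwise_spearman(np.take(m1, g2), np.take(m2, g2))
        stat = d1 - d2
        exceed += int(np.sum(stat >= observed))
        done += b
    p_perm = (1.0 + exceed) / (1.0 + n_perm)  # add-one estimator, never zero
    return DecouplingResult(split_point=float(split), r_before=r1, r_after=r2,
                            fisher_z=z, p_fisher=p_fisher, p_perm=float(p_perm),
                            n_perm=int(n_perm), n_before=n1, n_after=n2,
                            observed_perm_stat=float(observed))


def decoupling_split_scan(m1, m2, splits: Sequence[float], n_perm: int = 100_000,
                          seed: int = 0) -> pd.DataFrame:
    """Robustness utility: rerun the decoupling test at alternate split points."""
    rows = []
    for i, sp in enumerate(splits):
        res = decoupling_test(m1, m2, split=float(sp), n_perm=n_perm, seed=seed + i)
        rows.append({"split": float(sp), "r_before": res.r_before,
                     "r_after": res.r_after, "fisher_z": res.fisher_z,
                     "p_fisher": res.p_fisher, "p_perm": res.p_perm})
    return pd.DataFrame(rows)


def shared_master_time(shared_fit: SharedGPLVMResults, config: RunConfig,
                       orientation_rule: str = "keep",
                       marker_values: Optional[np.ndarray] = None):
    """Master time from a shared-latent fit: one value per cell.

    The shared latent is oriented (explicit rule or marker), normalized to
    [0, 1], and warped by quantile alignment exactly as in the per-modality
    pipeline. Returns ``(master_time, warp, orientation_applied)``.
    """
    kind, marker, direction = parse_orientation_rule(orientation_rule)
    latent = np.asarray(shared_fit.latent_mean, dtype=float)
    if kind == "keep":
        applied = "keep"
    elif kind == "reverse":
        applied, latent = "reverse", -latent
    else:
        if marker_values is None:
            raise MatcherError("marker orientation requires marker_values")
        rho = scipy.stats.spearmanr(latent, marker_values).statistic
        if not np.isfinite(rho) or abs(rho) < _MIN_MARKER_CORR:
            raise MatcherError(f"uninformative marker {marker!r} for shared latent")
        flip = (direction == "increasing") != (rho > 0)
        applied = "reverse" if flip else "keep"
        if flip:
            latent = -latent
    pseudotime = normalize_pseudotime(latent)
    warp = learn_warping(pseudotime, n_quantiles=config.n_quantiles,
                         method=config.warp_method,
                         random_state=config.subseed("warp:shared"))
    return warp.apply(pseudotime), warp, applied


def identify_lagging_cells(master, time_point: Sequence[str],
                           time_point_order: Sequence[str]) -> np.ndarray:
    """Flag cells whose master time overlaps the previous time point's range.

    A cell lags iff its master time is <= the maximum master time among
    cells of the immediately preceding experimental time point; cells of the
    first time point never lag.
    """
    master = np.asarray(master, dtype=float)
    time_point = list(time_point)
    if len(time_point) != master.size:
        raise MatcherError("time_point labels must match master-time length")
    order = list(time_point_order)
    if len(set(order)) != len(order):
        raise MatcherError("time_point_order contains duplicates")
    unknown = sorted(set(time_point) - set(order))
    if unknown:
        raise MatcherError(f"unordered time-point labels: {unknown}")
    present = [tp for tp in order if tp in set(time_point)]
    if len(present) < 2:
        return np.zeros(master.size, dtype=bool)
    flags = np.zeros(master.size, dtype=bool)
    for prev, curr in zip(present[:-1], present[1:]):
        prev_max = master[[t == prev for t in time_point]].max()
        sel = np.array([t == curr for t in time_point])
        flags[sel] = master[sel] <= prev_max
    return flags


# ---------------------------------------------------------------------------
# statsmodels-style facade
# ---------------------------------------------------------------------------

class MatcherModel:
    """Manifold alignment of one or more single-cell modalities.

    Parameters
    ----------
    modalities : sequence of CellFeatureMatrix (distinct modality names)
    config : RunConfig, optional

    ``fit()`` runs the full per-modality pipeline and returns a
    :class:`MatcherResults`.
    """

    def __init__(self, modalities: Sequence[CellFeatureMatrix],
                 config: Optional[RunConfig] = None):
        modalities = list(modalities)
        if not modalities:
            raise MatcherError("at least one modality is required")
        names = [m.modality_name for m in modalities]
        if len(set(names)) != len(names):
            raise MatcherError(f"duplicate modality names: {names}")
        self.modalities = modalities
        self.config = config or RunConfig()

    def fit(self) -> "MatcherResults":
        models = {Y.modality_name: build_modality_model(Y, self.config)
                  for Y in self.modalities}
        return MatcherResults(models, self.config)


class MatcherResults:
    """Fitted alignment: per-modality models in a common master-time frame."""

    def __init__(self, models: dict[str, ModalityModel], config: RunConfig):
        self.models = models
        self.config = config

    def __getitem__(self, modality: str) -> ModalityModel:
        try:
            return self.models[modality]
        except KeyError:
            raise MatcherError(f"no modality {modality!r}; have "
                               f"{sorted(self.models)}") from None

    def master_time(self, modality: str) -> np.ndarray:
        return self[modality].master_time

    def master_time_table(self) -> pd.DataFrame:
        records = []
        for model in self.models.values():
            records.extend(model.master_time_records())
        return pd.DataFrame(records)

    def infer_correspondence(self, source: str, target: str,
                             cells: Optional[Sequence[str]] = None) -> CorrespondenceSet:
        return infer_correspondence(self[source], self[target], cells=cells)

    def cross_modality_correlation(self, source: str, target: str,
                                   feat_A: Sequence[str], feat_B: Sequence[str],
                                   method: Optional[str] = None) -> pd.DataFrame:
        return cross_modality_correlation(self[source], self[target], feat_A,
                                          feat_B,
                                          method=method or self.config.corr_method)

    def decoupling_test(self, modality1: str, modality2: str, split: float = 0.3,
                        n_perm: int = 100_000) -> DecouplingResult:
        m1model, m2model = self[modality1], self[modality2]
        if list(m1model.cell_ids) != list(m2model.cell_ids):
            raise MatcherError("decoupling test requires the two modalities to be "
                               "measured on the same cells in the same order")
        return decoupling_test(m1model.master_time, m2model.master_time,
                               split=split, n_perm=n_perm,
                               seed=self.config.subseed("decoupling"))

    def summary(self) -> str:
        lines = ["Manifold alignment results",
                 f"  seed: {self.config.seed}  inducing inputs: {self.config.n_inducing}"
                 f"  quantiles: {self.config.n_quantiles}"]
        for name, model in self.models.items():
            ks = scipy.stats.kstest(model.master_time, "uniform").statistic
            k = model.fit.kernel
            lines.append(
                f"  [{name}] cells={len(model.cell_ids)} "
                f"features={len(model.fit.feature_ids)} elbo={model.fit.elbo:.2f} "
                f"orientation={model.orientation_applied} warp={model.warp.method_used} "
                f"KS(master vs U[0,1])={ks:.3f} lengthscale={k.lengthscale:.3g}")
        return "\n".join(lines)
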