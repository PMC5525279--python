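"""Feature engineering for single-cell epigenomic and transcriptomic matrices.

Covers the standard preparation steps upstream of pseudotime inference:
peak binarization, aggregation of peaks/sites into per-group signatures
(e.g. per transcription-factor motif), minimum-event cell filtering, the
per-cell scale-factor normalizations used for chromatin-accessibility and
histone-mark signature matrices, marker-correlated methylation-site
selection, and gene-expression signature construction from gene lists.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import scipy.stats

from .datamodel import CellFeatureMatrix, MatcherError

logger = logging.getLogger("matcher")


@dataclass
class RegionMembershipMap:
    """feature_id -> set of group labels (a peak may hit several TF motifs)."""

    membership: dict[str, set[str]]

    def __post_init__(self) -> None:
        groups: set[str] = set()
        for f, gs in self.membership.items():
            if not gs:
                raise MatcherError(f"feature {f!r} maps to no groups")
            groups |= set(gs)
        if not groups:
            raise MatcherError("membership map is empty")
        self.groups = sorted(groups)

    @classmethod
    def from_tsv(cls, path) -> "RegionMembershipMap":
        df = pd.read_csv(path, sep="\t", header=None, names=["feature_id", "group"],
                         dtype=str)
        membership: dict[str, set[str]] = {}
        for f, g in zip(df["feature_id"], df["group"]):
            membership.setdefault(f, set()).add(g)
        return cls(membership)


@dataclass
class ScaleFactorSpec:
    """Which per-cell scale-factor formula to apply.

    ``atac``: s_j = (sum_j t_j / n) / (1000 * t_j) — equalizes per-cell
    accessible-peak totals, with the 1000 keeping values near 1.
    ``chip``: s_j = 10 * (sum_j t_j / n) / t_j — equalizes per-cell signature
    totals, with the 10 keeping values near 1.
    """

    kind: str

    def __post_init__(self) -> None:
        if self.kind not in ("atac", "chip"):
            raise MatcherError(f"unknown scale-factor kind {self.kind!r}")

    def factors(self, totals: np.ndarray) -> np.ndarray:
        mean_total = totals.mean()
        if self.kind == "atac":
            return mean_total / (1000.0 * totals)
        return 10.0 * mean_total / totals


def binarize_counts(counts) -> np.ndarray:
    """Integer read counts -> binary detected/undetected (value > 0 -> 1)."""
    counts = np.asarray(counts)
    if not np.all(np.isfinite(counts.astype(float))):
        raise MatcherError("binarize_counts: non-finite values")
    if np.any(counts < 0) or np.any(np.asarray(counts, float) % 1 != 0):
        raise MatcherError("binarize_counts expects nonnegative integer counts")
    return (counts > 0).astype(float)


def aggregate_signatures(X: CellFeatureMatrix,
                         membership: RegionMembershipMap) -> CellFeatureMatrix:
    """Sum member features per group -> cells x groups signature matrix."""
    unknown = sorted(set(membership.membership) - set(X.feature_ids))
    if unknown:
        raise MatcherError(f"membership map references unknown features: {unknown}")
    col = {f: j for j, f in enumerate(X.feature_ids)}
    out = np.zeros((X.n_cells, len(membership.groups)))
    gidx = {g: k for k, g in enumerate(membership.groups)}
    for f, groups in membership.membership.items():
        for g in groups:
            out[:, gidx[g]] += X.values[:, col[f]]
    return CellFeatureMatrix(out, X.cell_ids, membership.groups,
                             modality_name=X.modality_name)


def filter_cells_min_events(X: CellFeatureMatrix, threshold: int = 1000):
    """Drop cells with fewer than ``threshold`` total detected events.

    The cutoff is strict: a cell with exactly ``threshold`` events is kept.
    Returns ``(filtered matrix, removal report DataFrame)``.
    """
    totals = X.values.sum(axis=1)
    keep = totals >= threshold
    removed = pd.DataFrame({"cell_id": [c for c, k in zip(X.cell_ids, keep) if not k],
                            "total_events": totals[~keep]})
    if not np.any(keep):
        logger.warning("all %d cells fall below the %d-event threshold; "
                       "returning an empty matrix", X.n_cells, threshold)
        empty = CellFeatureMatrix(np.empty((0, X.n_features)), [], X.feature_ids,
                                  X.modality_name)
        return empty, removed
    kept = [c for c, k in zip(X.cell_ids, keep) if k]
    return X.subset_cells(kept), removed


def scale_normalize(F: CellFeatureMatrix, spec: ScaleFactorSpec,
                    totals: Sequence[float]) -> CellFeatureMatrix:
    """Multiply each cell's row by its scale factor (see ScaleFactorSpec)."""
    totals = np.asarray(totals, dtype=float)
    if totals.shape != (F.n_cells,):
        raise MatcherError(f"totals length {totals.size} != {F.n_cells} cells")
    zero = np.where(totals <= 0)[0]
    if zero.size:
        raise MatcherError("zero or negative event total for cell(s): "
                           f"{[F.cell_ids[i] for i in zero]}")
    s = spec.factors(totals)
    return CellFeatureMatrix(F.values * s[:, None], F.cell_ids, F.feature_ids,
                             F.modality_name)


def select_methylation_sites(M: CellFeatureMatrix, marker_feature: str,
                             min_corr: float = 0.2) -> list[str]:
    """Retain sites whose Pearson correlation with a marker site is >= min_corr.

    Only a subset of methylation sites varies systematically with the
    process of interest; anchoring on a validated marker keeps that subset.
    The marker itself is always retained (r = 1).
    """
    marker = M.feature_vector(marker_feature)
    if np.std(marker) == 0:
        raise MatcherError(f"marker feature {marker_feature!r} has zero variance")
    mk = marker - marker.mean()
    denom_m = np.sqrt((mk * mk).sum())
    V = M.values - M.values.mean(axis=0, keepdims=True)
    denom = np.sqrt((V * V).sum(axis=0))
    with np.errstate(invalid="ignore", divide="ignore"):
        r = (V.T @ mk) / (denom * denom_m)
    keep = r >= min_corr
    keep[M.feature_ids.index(marker_feature)] = True
    return [f for f, k in zip(M.feature_ids, keep) if k]


def expression_signatures(E: CellFeatureMatrix,
                          gene_lists: Mapping[str, Sequence[str]]) -> CellFeatureMatrix:
    """Aggregate gene expression into per-list signatures.

    Steps: (1) drop genes appearing on more than one list; (2) z-score each
    remaining gene across cells (zero-variance genes dropped); (3) per cell,
    sum z-scored member genes per list and the total sum over all expressed
    (z-scored) genes; (4) the signature is the z-score across cells of
    (list sum - total sum).
    """
    if not gene_lists:
        raise MatcherError("no gene lists supplied")
    counts: dict[str, int] = {}
    for genes in gene_lists.values():
        for g in set(genes):
            counts[g] = counts.get(g, 0) + 1
    shared = {g for g, c in counts.items() if c > 1}
    if shared:
        logger.info("dropping %d gene(s) shared between lists", len(shared))
    dedup = {name: [g for g in dict.fromkeys(genes) if g not in shared]
             for name, genes in gene_lists.items()}
    for name, genes in dedup.items():
        if not genes:
            raise MatcherError(f"gene list {name!r} is empty after deduplication")
        missing = sorted(set(genes) - set(E.feature_ids))
        if missing:
            raise MatcherError(f"gene list {name!r} references unknown genes: {missing}")

    sd = E.values.std(axis=0)
    usable = sd > 0
    dropped = [g for g, u in zip(E.feature_ids, usable) if not u]
    if dropped:
        logger.warning("dropping %d zero-variance gene(s) from signatures", len(dropped))
    Z = (E.values[:, usable] - E.values[:, usable].mean(axis=0)) / sd[usable]
    zcol = {g: j for j, g in enumerate(f for f, u in zip(E.feature_ids, usable) if u)}
    total = Z.sum(axis=1)

    names = list(dedup)
    sig = np.empty((E.n_cells, len(names)))
    for k, name in enumerate(names):
        cols = [zcol[g] for g in dedup[name] if g in zcol]
        if not cols:
            raise MatcherError(f"gene list {name!r} has no usable (nonconstant) genes")
        diff = Z[:, cols].sum(axis=1) - total
        s = diff.std()
        if s == 0:
            raise MatcherError(f"signature {name!r} is constant across cells")
        sig[:, k] = (diff - diff.mean()) / s
    return CellFeatureMatrix(sig, E.cell_ids, names, modality_name=E.modality_name)


def drop_latent_outliers(Y: CellFeatureMatrix, k_mad: float = 5.0, seed: int = 0,
                         n_inducing: int = 10):
    """Generic outlier-cell removal: drop cells beyond k MADs from the median
    of a pilot 1-D GPLVM latent. Returns (filtered matrix, removed cell IDs)."""
    from .gplvm import BayesianGPLVM

    fit = BayesianGPLVM(Y, n_inducing=min(n_inducing, Y.n_cells),
                        n_restarts=1).fit(seed=seed)
    lat = fit.latent_mean
    med = np.median(lat)
    mad = np.median(np.abs(lat - med))
    if mad == 0:
        return Y, []
    keep = np.abs(lat - med) <= k_mad * mad
    removed = [c for c, kk in zip(Y.cell_ids, keep) if not kk]
    if removed:
        logger.info("dropping %d latent-outlier cell(s): %s", len(removed), removed)
    kept = [c for c, kk in zip(Y.cell_ids, keep) if kk]
    return Y.subset_cells(kept), removed


def variance_top_k(E: CellFeatureMatrix, k: int) -> CellFeatureMatrix:
    """Plain per-gene variance top-k filter (stand-in for trajectory-aware
    gene selection performed by external tools)."""
    if k < 1:
        raise MatcherError("k must be >= 1")
    var = E.values.var(axis=0)
    order = np.argsort(-var, kind="stable")[:k]
    order = np.sort(order)  # preserve original feature order
    feats = [E.feature_ids[j] for j in order]
    return E.subset_features(feats)
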