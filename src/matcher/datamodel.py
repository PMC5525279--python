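"""Core data containers: cell-by-feature matrices, metadata, and run configuration.

The internal convention everywhere in this package is cells in rows,
features in columns. Inputs stored the other way round must be transposed
at load time (``read_matrix(..., transpose=True)``).
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd


class MatcherError(Exception):
    """Base class for all errors raised by this package."""


class DegenerateDataError(MatcherError):
    """Raised when a matrix carries no usable variation (e.g. all cells identical)."""


class CorrespondenceError(MatcherError):
    """Raised when two modalities that require matched cells disagree on cell IDs."""


def _find_duplicates(ids: Sequence[str]) -> list[str]:
    seen: set[str] = set()
    dups: list[str] = []
    for x in ids:
        if x in seen and x not in dups:
            dups.append(x)
        seen.add(x)
    return dups


class CellFeatureMatrix:
    """A single-modality observation matrix: cells in rows, named features in columns.

    Parameters
    ----------
    values : array-like, shape (n_cells, n_features)
        Finite numeric measurements (log-normalized expression, aggregated
        methylation, accessibility or histone-mark signatures, ...).
    cell_ids, feature_ids : sequences of unique strings
    modality_name : str
        Free-text tag, e.g. ``"rna"`` or ``"atac"``.
    """

    def __init__(self, values, cell_ids, feature_ids, modality_name: str = "modality"):
        values = np.asarray(values, dtype=float)
        if values.ndim != 2:
            raise MatcherError(f"values must be 2-D, got shape {values.shape}")
        cell_ids = [str(c) for c in cell_ids]
        feature_ids = [str(f) for f in feature_ids]
        if values.shape != (len(cell_ids), len(feature_ids)):
            raise MatcherError(
                f"shape mismatch: values {values.shape} vs "
                f"{len(cell_ids)} cells x {len(feature_ids)} features"
            )
        dup_c = _find_duplicates(cell_ids)
        if dup_c:
            raise MatcherError(f"duplicate cell IDs: {dup_c}")
        dup_f = _find_duplicates(feature_ids)
        if dup_f:
            raise MatcherError(f"duplicate feature IDs: {dup_f}")
        if not np.all(np.isfinite(values)):
            bad = np.argwhere(~np.isfinite(values))[0]
            raise MatcherError(
                f"non-finite value at cell {cell_ids[bad[0]]!r}, "
                f"feature {feature_ids[bad[1]]!r}; apply a missing-value policy first"
            )
        self.values = values
        self.cell_ids = cell_ids
        self.feature_ids = feature_ids
        self.modality_name = modality_name

    @property
    def n_cells(self) -> int:
        return self.values.shape[0]

    @property
    def n_features(self) -> int:
        return self.values.shape[1]

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, modality_name: str = "modality") -> "CellFeatureMatrix":
        return cls(df.to_numpy(dtype=float), list(df.index), list(df.columns), modality_name)

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=pd.Index(self.cell_ids, name="cell_id"),
                            columns=self.feature_ids)

    def subset_cells(self, cells: Sequence[str]) -> "CellFeatureMatrix":
        idx = {c: i for i, c in enumerate(self.cell_ids)}
        missing = [c for c in cells if c not in idx]
        if missing:
            raise MatcherError(f"unknown cell IDs: {missing}")
        rows = [idx[c] for c in cells]
        return CellFeatureMatrix(self.values[rows], list(cells), self.feature_ids,
                                 self.modality_name)

    def subset_features(self, features: Sequence[str]) -> "CellFeatureMatrix":
        idx = {f: i for i, f in enumerate(self.feature_ids)}
        missing = [f for f in features if f not in idx]
        if missing:
            raise MatcherError(f"unknown feature IDs: {missing}")
        cols = [idx[f] for f in features]
        return CellFeatureMatrix(self.values[:, cols], self.cell_ids, list(features),
                                 self.modality_name)

    def feature_vector(self, feature_id: str) -> np.ndarray:
        try:
            j = self.feature_ids.index(feature_id)
        except ValueError:
            raise MatcherError(f"feature {feature_id!r} not present in modality "
                               f"{self.modality_name!r}") from None
        return self.values[:, j]

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return (f"CellFeatureMatrix({self.modality_name!r}, "
                f"{self.n_cells} cells x {self.n_features} features)")


@dataclass
class CellMetadata:
    """Optional per-cell annotations: experimental time points and, when two
    modalities were measured on the same physical cells, a correspondence key."""

    cell_ids: list[str]
    time_point: Optional[list[str]] = None
    time_point_order: Optional[list[str]] = None
    correspondence_key: Optional[list[str]] = None

    def __post_init__(self) -> None:
        dup = _find_duplicates(self.cell_ids)
        if dup:
            raise MatcherError(f"duplicate cell IDs in metadata: {dup}")
        for name in ("time_point", "correspondence_key"):
            v = getattr(self, name)
            if v is not None and len(v) != len(self.cell_ids):
                raise MatcherError(f"{name} length {len(v)} != {len(self.cell_ids)} cells")
        if self.time_point is not None and self.time_point_order is not None:
            unknown = sorted(set(self.time_point) - set(self.time_point_order))
            if unknown:
                raise MatcherError(f"time points missing from declared order: {unknown}")

    def aligned_to(self, matrix: CellFeatureMatrix) -> "CellMetadata":
        """Reorder to match a matrix's cell order; errors if the sets differ."""
        if set(self.cell_ids) != set(matrix.cell_ids):
            diff = sorted(set(self.cell_ids) ^ set(matrix.cell_ids))
            raise MatcherError(f"metadata/matrix cell ID mismatch: {diff}")
        pos = {c: i for i, c in enumerate(self.cell_ids)}
        order = [pos[c] for c in matrix.cell_ids]

        def take(v):
            return None if v is None else [v[i] for i in order]

        return CellMetadata(list(matrix.cell_ids), take(self.time_point),
                            self.time_point_order, take(self.correspondence_key))


_WARP_METHODS = ("gp", "interp", "auto")
_CORR_METHODS = ("spearman", "pearson")


@dataclass
class RunConfig:
    """Run-wide configuration; one global seed drives every stochastic step.

    ``orientation`` maps modality names to one of ``keep``, ``reverse`` or
    ``marker:<feature_id>:<increasing|decreasing>``.
    """

    seed: int = 0
    n_inducing: int = 10
    n_quantiles: int = 50
    warp_method: str = "auto"
    orientation: dict[str, str] = field(default_factory=dict)
    corr_method: str = "spearman"
    n_restarts: int = 3
    max_iter: int = 3000
    impute_missing: bool = False

    def __post_init__(self) -> None:
        if self.n_inducing < 1:
            raise MatcherError("n_inducing must be >= 1")
        if self.n_quantiles < 2:
            raise MatcherError("n_quantiles must be >= 2")
        if self.warp_method not in _WARP_METHODS:
            raise MatcherError(f"warp_method must be one of {_WARP_METHODS}")
        if self.corr_method not in _CORR_METHODS:
            raise MatcherError(f"corr_method must be one of {_CORR_METHODS}")
        for mod, rule in self.orientation.items():
            parse_orientation_rule(rule)  # raises if unresolvable

    def subseed(self, step: str) -> int:
        """Deterministic per-step sub-seed (< 2**31) derived from the global seed."""
        h = np.uint32(2166136261)
        for b in f"{self.seed}:{step}".encode():
            h = np.uint32((int(h) ^ b) * 16777619 & 0xFFFFFFFF)
        return int(h) % (2**31 - 1)

    def replace(self, **kw) -> "RunConfig":
        return dataclasses.replace(self, **kw)

    # -- flat key=value config file ------------------------------------
    @classmethod
    def from_file(cls, path) -> "RunConfig":
        kw: dict = {}
        orientation: dict[str, str] = {}
        for lineno, raw in enumerate(Path(path).read_text().splitlines(), 1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            if "=" not in line:
                raise MatcherError(f"{path}:{lineno}: expected key=value, got {raw!r}")
            key, _, value = line.partition("=")
            key, value = key.strip(), value.strip()
            if key.startswith("orientation."):
                orientation[key.split(".", 1)[1]] = value
            elif key in ("seed", "n_inducing", "n_quantiles", "n_restarts", "max_iter"):
                kw[key] = int(value)
            elif key == "impute_missing":
                kw[key] = value.lower() in ("1", "true", "yes")
            elif key in ("warp_method", "corr_method"):
                kw[key] = value
            else:
                raise MatcherError(f"{path}:{lineno}: unknown config key {key!r}")
        if orientation:
            kw["orientation"] = orientation
        return cls(**kw)

    def to_file(self, path) -> None:
        lines = [
            f"seed = {self.seed}",
            f"n_inducing = {self.n_inducing}",
            f"n_quantiles = {self.n_quantiles}",
            f"warp_method = {self.warp_method}",
            f"corr_method = {self.corr_method}",
            f"n_restarts = {self.n_restarts}",
            f"max_iter = {self.max_iter}",
            f"impute_missing = {str(self.impute_missing).lower()}",
        ]
        for mod in sorted(self.orientation):
            lines.append(f"orientation.{mod} = {self.orientation[mod]}")
        Path(path).write_text("\n".join(lines) + "\n")


def parse_orientation_rule(rule: str) -> tuple[str, Optional[str], Optional[str]]:
    """Parse an orientation rule into ``(kind, marker_feature, direction)``.

    ``kind`` is ``keep``, ``reverse`` or ``marker``.
    """
    if rule in ("keep", "reverse"):
        return rule, None, None
    parts = rule.split(":")
    if len(parts) == 3 and parts[0] == "marker" and parts[2] in ("increasing", "decreasing"):
        if not parts[1]:
            raise MatcherError(f"orientation rule {rule!r}: empty marker feature")
        return "marker", parts[1], parts[2]
    raise MatcherError(
        f"unresolvable orientation rule {rule!r}; expected 'keep', 'reverse' or "
        "'marker:<feature_id>:<increasing|decreasing>'"
    )
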