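"""Multivariate variant comparison: occupancy feature vectors, PCA, ranking.

Each trajectory (replica) is summarised as a feature vector of per-residue
occupancies of three broad secondary-structure classes — right-handed
helix, combined beta/PPII, and unstructured — and the collection is
decomposed by PCA. Variants are ranked by the Euclidean distance of their
mean projection from the wild-type mean in the leading components.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.decomposition import PCA as _SKPCA

from .rama import CLASSES, OccupancyProfile

__all__ = [
    "DEFAULT_GROUPING",
    "FeatureMatrix",
    "PCAModel",
    "VariantRanking",
    "build_features",
    "fit_pca",
    "project",
    "rank_variants",
]

#: Default collapse of the five Ramachandran classes into three broad ones.
#: alphaL is merged into "unstructured" (minority class for non-glycine
#: residues); the grouping is a configurable partition.
DEFAULT_GROUPING: dict[str, tuple[str, ...]] = {
    "helix": ("alphaR",),
    "extended": ("beta", "PPII"),
    "unstructured": ("alphaL", "unassigned"),
}


@dataclass
class FeatureMatrix:
    """Per-trajectory broad-class occupancy vectors.

    ``values`` is (n_rows, 3 * n_interior_residues), residue-major and
    class-minor; ``row_labels`` holds (variant, replica) pairs.
    """

    values: np.ndarray
    row_labels: list[tuple[str, int | str]]
    column_labels: list[str]

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.row_labels), len(self.column_labels)):
            raise ValueError("feature matrix shape/label mismatch")

    @property
    def variants(self) -> list[str]:
        return sorted({v for v, _ in self.row_labels})

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.values, columns=self.column_labels)
        df.insert(0, "variant", [v for v, _ in self.row_labels])
        df.insert(1, "replica", [r for _, r in self.row_labels])
        return df


def build_features(
    profiles: list[OccupancyProfile],
    grouping: dict[str, tuple[str, ...]] | None = None,
) -> FeatureMatrix:
    """Collapse five-class occupancy profiles into broad-class feature rows.

    One row per profile (trajectory); deterministic column order
    (residue-major, group-minor in the grouping's insertion order).
    """
    grouping = grouping or DEFAULT_GROUPING
    flat = [c for members in grouping.values() for c in members]
    if sorted(flat) != sorted(CLASSES):
        raise ValueError("grouping must partition the five classes")
    ref = profiles[0]
    for p in profiles[1:]:
        if not np.array_equal(p.residue_indices, ref.residue_indices):
            raise ValueError("profiles cover different residue ranges")
    group_idx = [
        [CLASSES.index(c) for c in members] for members in grouping.values()
    ]
    rows = []
    labels = []
    for p in profiles:
        collapsed = np.stack(
            [p.fractions[:, idx].sum(axis=1) for idx in group_idx], axis=1
        )  # (R, n_groups)
        rows.append(collapsed.ravel())
        labels.append((p.variant_label, p.replica_id))
    columns = [
        f"res{res}_{gname}"
        for res in ref.residue_indices
        for gname in grouping
    ]
    return FeatureMatrix(np.array(rows), labels, columns)


@dataclass
class PCAModel:
    """Centered PCA decomposition with a deterministic sign convention."""

    mean: np.ndarray
    components: np.ndarray  # (k, n_features), orthonormal rows
    explained_variance: np.ndarray
    explained_variance_ratio: np.ndarray

    @property
    def n_components(self) -> int:
        return self.components.shape[0]

    def to_dict(self) -> dict:
        return {
            "mean": self.mean.tolist(),
            "components": self.components.tolist(),
            "explained_variance": self.explained_variance.tolist(),
            "explained_variance_ratio": self.explained_variance_ratio.tolist(),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "PCAModel":
        return cls(
            np.array(d["mean"]),
            np.array(d["components"]),
            np.array(d["explained_variance"]),
            np.array(d["explained_variance_ratio"]),
        )


def fit_pca(matrix: FeatureMatrix | np.ndarray) -> PCAModel:
    """Fit centered (unscaled) PCA by full SVD.

    Signs are fixed so the largest-magnitude loading of each component is
    positive. An all-identical-rows matrix yields zero explained variance
    and all-zero projections rather than an error.
    """
    X = matrix.values if isinstance(matrix, FeatureMatrix) else np.asarray(matrix, float)
    if X.ndim != 2 or X.shape[0] < 2:
        raise ValueError("need a 2-D matrix with >= 2 rows")
    if not np.isfinite(X).all():
        raise ValueError("feature matrix contains non-finite entries")
    k = min(X.shape)
    pca = _SKPCA(n_components=k, svd_solver="full")
    with np.errstate(invalid="ignore", divide="ignore"):  # rank-0 edge case
        pca.fit(X)
    comps = pca.components_.copy()
    for i in range(comps.shape[0]):
        j = np.argmax(np.abs(comps[i]))
        if comps[i, j] < 0:
            comps[i] = -comps[i]
    ratio = pca.explained_variance_ratio_.copy()
    total = pca.explained_variance_.sum()
    if total == 0.0:  # degenerate: all rows identical
        ratio = np.zeros_like(ratio)
    return PCAModel(
        mean=pca.mean_.copy(),
        components=comps,
        explained_variance=pca.explained_variance_.copy(),
        explained_variance_ratio=ratio,
    )


def project(model: PCAModel, rows: np.ndarray, k: int | None = None) -> np.ndarray:
    """Project feature rows onto the first k components."""
    rows = np.atleast_2d(np.asarray(rows, dtype=float))
    if rows.shape[1] != model.mean.shape[0]:
        raise ValueError("feature dimension mismatch with the fitted model")
    k = model.n_components if k is None else k
    if k > model.n_components:
        raise ValueError(f"k={k} exceeds {model.n_components} fitted components")
    return (rows - model.mean) @ model.components[:k].T


@dataclass
class VariantRanking:
    """Per-variant mean projection, distance to wild type, and rank."""

    table: pd.DataFrame  # columns: label, distance, rank, pc1..pck
    wild_type_label: str
    k: int

    @property
    def order(self) -> list[str]:
        return list(self.table["label"])


def rank_variants(
    scores: np.ndarray,
    row_labels: list[tuple[str, int | str]],
    wild_type_label: str,
    k: int = 2,
) -> VariantRanking:
    """Rank variants by distance from wild type in reduced PC space.

    ``scores`` are per-trajectory projections (n_rows, >= k). Each
    variant's replicas are averaged in projected space; distances are
    Euclidean in the first k dimensions; sort ascending, ties broken
    alphabetically by label.
    """
    scores = np.asarray(scores, dtype=float)
    if scores.shape[0] != len(row_labels):
        raise ValueError("scores/labels length mismatch")
    if scores.shape[1] < k:
        raise ValueError(f"scores carry {scores.shape[1]} dims, need k={k}")
    variants = {}
    for (variant, _), row in zip(row_labels, scores):
        variants.setdefault(variant, []).append(row[:k])
    if wild_type_label not in variants:
        raise ValueError(f"wild-type label {wild_type_label!r} absent from scores")
    means = {v: np.mean(rows, axis=0) for v, rows in variants.items()}
    wt = means[wild_type_label]
    records = [
        {"label": v, "distance": float(np.linalg.norm(m - wt)),
         **{f"pc{i+1}": float(m[i]) for i in range(k)}}
        for v, m in means.items()
    ]
    df = pd.DataFrame(records).sort_values(
        ["distance", "label"], kind="mergesort", ignore_index=True
    )
    df.insert(1, "rank", np.arange(1, len(df) + 1))
    return VariantRanking(table=df, wild_type_label=wild_type_label, k=k)
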