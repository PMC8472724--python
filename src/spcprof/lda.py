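"""Per-protein F-ratio selection, Mahalanobis cohort assignment and
hierarchical clustering of run profiles.

The selection step screens each protein with a one-way ANOVA across the
cohorts: F is the model mean square over the error mean square, the
p-value comes from the F distribution with (g-1, n-g) degrees of freedom.
Proteins with F above and p below their thresholds are the "selected"
discriminant features. Group assignment then uses the Mahalanobis
distance to each cohort centroid under a single pooled covariance
(diagonal by default — with far more proteins than runs a full pooled
covariance is singular).
"""

from __future__ import annotations

import logging
import math
from collections.abc import Sequence
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster import hierarchy

from .core import AnnotationTable, SpectralCountMatrix, map_accessions
from .errors import ValidationError
from .profiling import normalize_runs

logger = logging.getLogger(__name__)

DEFAULT_F_THRESHOLD = 3.4
DEFAULT_P_THRESHOLD = 0.05


def protein_f_ratio(values_by_group: Sequence[Sequence[float]]) -> tuple[float, float]:
    """One-way ANOVA F ratio and p-value for one protein.

    Degenerate cases: zero error mean square with unequal group means
    returns ``(inf, 0.0)``; all observations identical returns ``(0.0, 1.0)``.
    """
    groups = [np.asarray(g, dtype=float) for g in values_by_group]
    if len(groups) < 2:
        raise ValidationError("protein_f_ratio needs >= 2 groups")
    if any(g.size == 0 for g in groups):
        raise ValidationError("every group needs >= 1 observation")
    n = sum(g.size for g in groups)
    g = len(groups)
    if n <= g:
        raise ValidationError("total observations must exceed the number of groups")
    grand = np.concatenate(groups).mean()
    ss_between = sum(grp.size * (grp.mean() - grand) ** 2 for grp in groups)
    ss_within = sum(((grp - grp.mean()) ** 2).sum() for grp in groups)
    ms_between = ss_between / (g - 1)
    ms_within = ss_within / (n - g)
    if ms_within == 0.0:
        if ms_between == 0.0:
            return 0.0, 1.0
        return math.inf, 0.0
    f_ratio = ms_between / ms_within
    p_value = float(stats.f.sf(f_ratio, g - 1, n - g))
    return float(f_ratio), p_value


@dataclass(frozen=True)
class LdaRecord:
    """Per-protein screening outcome."""

    protein: str
    f_ratio: float
    p_value: float
    selected: bool


def select_lda_sps(
    matrix: SpectralCountMatrix,
    f_thr: float = DEFAULT_F_THRESHOLD,
    p_thr: float = DEFAULT_P_THRESHOLD,
    collapse_by_gene: bool = True,
    ann: AnnotationTable | None = None,
    normalize: bool = True,
) -> list[LdaRecord]:
    """Screen every protein with the F/p dual threshold across cohorts.

    With ``collapse_by_gene`` and an annotation table, rows sharing a gene
    are summed before screening. Counts are depth-normalized by default.
    """
    if collapse_by_gene and ann is not None:
        matrix = map_accessions(matrix, ann, collapse_by_gene=True)
    cohorts = sorted(set(matrix.cohort_labels))
    if len(cohorts) < 2:
        raise ValidationError("select_lda_sps needs >= 2 cohorts")
    for cohort in cohorts:
        if len(matrix.cohort_run_ids(cohort)) < 2:
            raise ValidationError(f"cohort {cohort!r} needs >= 2 runs")
    values = normalize_runs(matrix) if normalize else matrix.counts.astype(float)
    group_cols = [matrix.cohort_run_ids(c) for c in cohorts]
    records = []
    for protein in values.index:
        row = values.loc[protein]
        groups = [row[cols].to_numpy() for cols in group_cols]
        f_ratio, p_value = protein_f_ratio(groups)
        selected = f_ratio > f_thr and p_value < p_thr
        records.append(LdaRecord(str(protein), f_ratio, p_value, selected))
    return records


def selected_proteins(records: Sequence[LdaRecord]) -> list[str]:
    return [r.protein for r in records if r.selected]


def lda_records_frame(records: Sequence[LdaRecord]) -> pd.DataFrame:
    return pd.DataFrame(
        [(r.protein, r.f_ratio, r.p_value, r.selected) for r in records],
        columns=["protein", "f_ratio", "p_value", "selected"],
    )


# ---------------------------------------------------------------------------
# Mahalanobis assignment
# ---------------------------------------------------------------------------

_VAR_FLOOR = 1e-8
_SHRINKAGE = 0.25


@dataclass
class AssignmentResult:
    """Per-run predicted cohort and distances to every cohort centroid."""

    run_ids: list[str]
    true_cohorts: list[str]
    predicted: list[str]
    distances: pd.DataFrame  # runs x cohorts

    @property
    def accuracy(self) -> float:
        hits = sum(t == p for t, p in zip(self.true_cohorts, self.predicted))
        return hits / len(self.predicted)


def _pooled_within(values: np.ndarray, labels: np.ndarray,
                   cohorts: Sequence[str]) -> tuple[np.ndarray, dict[str, np.ndarray]]:
    """Pooled within-group scatter matrix and group means (runs x features)."""
    n, p = values.shape
    means = {}
    scatter = np.zeros((p, p))
    for cohort in cohorts:
        block = values[labels == cohort]
        mu = block.mean(axis=0)
        means[cohort] = mu
        centered = block - mu
        scatter += centered.T @ centered
    dof = n - len(cohorts)
    return scatter / dof, means


def mahalanobis_assign(
    matrix: SpectralCountMatrix,
    covariance_mode: str = "diagonal_pooled",
    normalize: bool = True,
) -> AssignmentResult:
    """Assign each run to the cohort with minimal Mahalanobis distance.

    ``diagonal_pooled`` uses only the pooled per-protein variances;
    ``shrunk_pooled`` shrinks the full pooled covariance toward its
    diagonal and falls back to the diagonal mode if still singular.
    """
    if covariance_mode not in ("diagonal_pooled", "shrunk_pooled"):
        raise ValidationError(f"unknown covariance_mode {covariance_mode!r}")
    cohorts = sorted(set(matrix.cohort_labels))
    for cohort in cohorts:
        if len(matrix.cohort_run_ids(cohort)) < 2:
            raise ValidationError(f"cohort {cohort!r} needs >= 2 runs")
    frame = normalize_runs(matrix) if normalize else matrix.counts.astype(float)
    values = frame.to_numpy().T  # runs x proteins
    labels = np.array(matrix.cohort_labels)
    cov, means = _pooled_within(values, labels, cohorts)

    inv = None
    if covariance_mode == "shrunk_pooled":
        shrunk = (1 - _SHRINKAGE) * cov + _SHRINKAGE * np.diag(np.diag(cov))
        try:
            inv = np.linalg.inv(shrunk)
        except np.linalg.LinAlgError:
            logger.warning("shrunk pooled covariance singular; "
                           "falling back to diagonal_pooled")
            inv = None
    if inv is None:
        variances = np.maximum(np.diag(cov), _VAR_FLOOR)
        inv = np.diag(1.0 / variances)

    dist = np.zeros((values.shape[0], len(cohorts)))
    for j, cohort in enumerate(cohorts):
        delta = values - means[cohort]
        dist[:, j] = np.sqrt(np.einsum("ij,jk,ik->i", delta, inv, delta))
    predicted = [cohorts[j] for j in dist.argmin(axis=1)]
    distances = pd.DataFrame(dist, index=matrix.run_ids, columns=cohorts)
    return AssignmentResult(
        run_ids=matrix.run_ids,
        true_cohorts=list(labels),
        predicted=predicted,
        distances=distances,
    )


def mahalanobis_distance(
    point: np.ndarray, mean: np.ndarray, covariance: np.ndarray
) -> float:
    """Mahalanobis distance of one point to a group mean."""
    delta = np.asarray(point, dtype=float) - np.asarray(mean, dtype=float)
    inv = np.linalg.inv(np.asarray(covariance, dtype=float))
    return float(np.sqrt(delta @ inv @ delta))


# ---------------------------------------------------------------------------
# Hierarchical clustering
# ---------------------------------------------------------------------------


@dataclass
class ClusteringResult:
    """Dendrogram over runs plus the agglomerative coefficient."""

    run_ids: list[str]
    linkage_matrix: np.ndarray
    agglomerative_coefficient: float

    def cut(self, k: int) -> dict[str, int]:
        """Flat cluster labels (1..k) per run at a k-cluster cut."""
        labels = hierarchy.fcluster(self.linkage_matrix, t=k, criterion="maxclust")
        return dict(zip(self.run_ids, (int(v) for v in labels)))

    def merge_table(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.linkage_matrix,
            columns=["child_a", "child_b", "height", "n_leaves"],
        )

    def to_newick(self) -> str:
        tree = hierarchy.to_tree(self.linkage_matrix)

        def fmt(node, parent_height: float) -> str:
            length = max(parent_height - node.dist, 0.0)
            if node.is_leaf():
                return f"{self.run_ids[node.id]}:{length:.6g}"
            children = ",".join(fmt(c, node.dist) for c in (node.left, node.right))
            return f"({children}):{length:.6g}"

        return fmt(tree, tree.dist) + ";"


def agglomerative_coefficient(linkage_matrix: np.ndarray) -> float:
    """AC = mean over leaves of (1 - d_first / d_final).

    ``d_first`` is the height at which a leaf is first merged, ``d_final``
    the final merge height. A zero-height tree has AC 0 by convention.
    """
    n_leaves = linkage_matrix.shape[0] + 1
    d_final = float(linkage_matrix[-1, 2])
    if d_final == 0.0:
        return 0.0
    first = np.full(n_leaves, np.nan)
    for a, b, height, _ in linkage_matrix:
        for child in (int(a), int(b)):
            if child < n_leaves and np.isnan(first[child]):
                first[child] = height
    # leaves merged only inside non-leaf clusters inherit that merge height
    # (cannot happen with scipy linkage output, every leaf appears once)
    return float(np.mean(1.0 - first / d_final))


def hierarchical_cluster(
    matrix: SpectralCountMatrix,
    linkage: str = "ward",
    metric: str = "euclidean",
    normalize: bool = True,
) -> ClusteringResult:
    """Cluster runs on their (normalized) count vectors.

    Runs are sorted lexicographically by run_id before clustering so the
    dendrogram is stable regardless of input column order.
    """
    if linkage not in ("ward", "average"):
        raise ValidationError(f"unsupported linkage {linkage!r}")
    if matrix.shape[1] < 2:
        raise ValidationError("hierarchical_cluster needs >= 2 runs")
    frame = normalize_runs(matrix) if normalize else matrix.counts.astype(float)
    run_ids = sorted(matrix.run_ids)
    data = frame[run_ids].to_numpy().T  # runs x proteins
    if np.ptp(data) == 0:
        # all runs identical: zero-height star tree
        z = np.zeros((len(run_ids) - 1, 4))
        z[:, 0] = np.arange(len(run_ids) - 1)
        z[0, 0] = 0
        z[0, 1] = 1
        for i in range(1, len(run_ids) - 1):
            z[i, 0] = len(run_ids) + i - 1
            z[i, 1] = i + 1
        z[:, 3] = np.arange(2, len(run_ids) + 1)
        return ClusteringResult(run_ids, z, 0.0)
    z = hierarchy.linkage(data, method=linkage, metric=metric)
    return ClusteringResult(run_ids, z, agglomerative_coefficient(z))


__all__ = [
    "AssignmentResult",
    "ClusteringResult",
    "DEFAULT_F_THRESHOLD",
    "DEFAULT_P_THRESHOLD",
    "LdaRecord",
    "agglomerative_coefficient",
    "hierarchical_cluster",
    "lda_records_frame",
    "mahalanobis_assign",
    "mahalanobis_distance",
    "protein_f_ratio",
    "select_lda_sps",
    "selected_proteins",
]
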