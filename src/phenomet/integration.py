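"""Multivariate integration of phenotypes and metabolites.

Phenotypic features (height, projected areas, color counts) and TIC-
normalized metabolite intensities live on incommensurable scales, so every
variable is autoscaled — mean-centered and divided by its sample standard
deviation — before joint analysis.  On the autoscaled matrix:

* PCA (covariance of the z-scored columns) summarizes sample structure;
  each tolerance class gets a 95% confidence circle in the PC1–PC2 plane,
  radius sqrt(chi2_{2,0.95}) times the RMS within-class distance of scores
  to the class centroid;
* hierarchical clustering uses one minus the Pearson correlation between
  row profiles as the distance, with configurable linkage (default
  average); cutting the tree at k = 3 yields candidate tolerance classes;
* the combined phenotype/metabolite correlation matrix reports, for every
  variable, its Pearson r and sign relative to an anchor variable (default
  side-projected area, the biomass proxy), exposing clusters of metabolites
  that rise with biomass and fall with senescence indicators;
* a separation report turns per-class confidence circles into an explicit
  separated / not-separated verdict via pairwise circle-overlap fractions.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform
from sklearn.decomposition import PCA

from .errors import DegenerateDataError, InsufficientDataError, ScalingError

__all__ = [
    "autoscale",
    "OrdinationResult",
    "pca",
    "HCAResult",
    "hca",
    "CorrelationCluster",
    "correlate_blocks",
    "SeparationReport",
    "classify_separation",
    "circle_overlap_fraction",
]

logger = logging.getLogger(__name__)

CHI2_2_95 = float(stats.chi2.ppf(0.95, df=2))


# ---------------------------------------------------------------------------
# autoscaling
# ---------------------------------------------------------------------------

def autoscale(df: pd.DataFrame, *, constant_policy: str = "error") -> pd.DataFrame:
    """Column-wise z-scores: mean-center, divide by the column SD.

    Uses the population SD (divisor n), the convention of standard scalers,
    so each output column has exactly unit variance.  Constant columns make
    the z-score undefined: with ``constant_policy="error"`` they raise,
    naming the offenders; with ``"drop"`` they are removed and logged.
    """
    if len(df) < 2:
        raise InsufficientDataError("autoscaling needs at least 2 rows")
    values = df.to_numpy(dtype=float)
    if np.isnan(values).any():
        raise ScalingError("missing values present; impute or drop before autoscaling")
    sd = values.std(axis=0)
    constant = np.flatnonzero(sd == 0)
    if constant.size:
        names = [df.columns[i] for i in constant]
        if constant_policy == "drop":
            logger.warning("dropping constant column(s): %s", names)
            df = df.drop(columns=names)
            values = df.to_numpy(dtype=float)
            sd = values.std(axis=0)
        else:
            raise ScalingError(f"constant column(s) cannot be autoscaled: {names}")
    z = (values - values.mean(axis=0)) / sd
    return pd.DataFrame(z, index=df.index, columns=df.columns)


# ---------------------------------------------------------------------------
# PCA with per-class confidence circles
# ---------------------------------------------------------------------------

@dataclass
class OrdinationResult:
    scores: pd.DataFrame                # samples x components
    loadings: pd.DataFrame              # variables x components
    explained_variance_ratio: np.ndarray
    class_circles: dict[str, tuple[np.ndarray, float]] = field(default_factory=dict)
    labels: pd.Series | None = None


def _confidence_circles(scores: pd.DataFrame, labels: pd.Series):
    """95% circle per class in the PC1–PC2 plane: center = class centroid,
    radius = sqrt(chi2_{2,0.95}) x RMS distance of class scores to it."""
    circles: dict[str, tuple[np.ndarray, float]] = {}
    pts = scores.iloc[:, :2].to_numpy()
    lab = labels.reindex(scores.index)
    for cls_name in pd.unique(lab.dropna()):
        sub = pts[(lab == cls_name).to_numpy()]
        center = sub.mean(axis=0)
        rms = float(np.sqrt(np.mean(np.sum((sub - center) ** 2, axis=1))))
        circles[cls_name] = (center, np.sqrt(CHI2_2_95) * rms)
    return circles


def pca(
    matrix: pd.DataFrame,
    n_components: int = 2,
    *,
    labels: pd.Series | None = None,
) -> OrdinationResult:
    """PCA of an autoscaled matrix with a deterministic sign convention.

    Components come from the covariance of the (already autoscaled) input;
    each component is flipped so its largest-magnitude loading is positive,
    making scores reproducible across runs and platforms.  ``n_components``
    beyond the matrix rank is truncated with a log warning.
    """
    if len(matrix) < 3:
        raise InsufficientDataError("PCA needs at least 3 rows")
    values = matrix.to_numpy(dtype=float)
    rank = int(np.linalg.matrix_rank(values - values.mean(axis=0)))
    max_comp = min(rank, min(values.shape))
    if n_components > max_comp:
        logger.warning("n_components=%d exceeds rank %d; truncating", n_components, max_comp)
        n_components = max_comp
    fit = PCA(n_components=max_comp, svd_solver="full").fit(values)
    comps = fit.components_  # components x variables
    flip = np.sign(comps[np.arange(comps.shape[0]), np.argmax(np.abs(comps), axis=1)])
    comps = comps * flip[:, None]
    scores_full = (values - fit.mean_) @ comps.T
    names = [f"PC{i + 1}" for i in range(max_comp)]
    scores = pd.DataFrame(scores_full[:, :n_components], index=matrix.index,
                          columns=names[:n_components])
    loadings = pd.DataFrame(comps[:n_components].T, index=matrix.columns,
                            columns=names[:n_components])
    evr = fit.explained_variance_ratio_[:n_components]
    result = OrdinationResult(
        scores=scores, loadings=loadings, explained_variance_ratio=evr, labels=labels
    )
    if labels is not None:
        if scores_full.shape[1] >= 2:
            plane = pd.DataFrame(scores_full[:, :2], index=matrix.index)
        else:  # rank-1 data: circles live on the PC1 axis
            plane = pd.DataFrame(
                np.column_stack([scores_full[:, 0], np.zeros(len(matrix))]),
                index=matrix.index,
            )
        result.class_circles = _confidence_circles(plane, labels)
    return result


# ---------------------------------------------------------------------------
# hierarchical clustering with correlation distance
# ---------------------------------------------------------------------------

@dataclass
class HCAResult:
    linkage: np.ndarray
    labels: pd.Series            # k-cut cluster ids, aligned to input rows
    distance: pd.DataFrame       # 1 − r between row profiles
    newick: str


def _linkage_to_newick(Z: np.ndarray, leaf_names: list[str]) -> str:
    tree = hierarchy.to_tree(Z)

    def rec(node, parent_dist):
        length = max(parent_dist - node.dist, 0.0)
        if node.is_leaf():
            return f"{leaf_names[node.id]}:{length:.6g}"
        left = rec(node.left, node.dist)
        right = rec(node.right, node.dist)
        return f"({left},{right}):{length:.6g}"

    return rec(tree, tree.dist) + ";"


def hca(
    matrix: pd.DataFrame,
    *,
    linkage: str = "average",
    k: int = 3,
) -> HCAResult:
    """Cluster rows with Pearson-correlation distance d = 1 − r.

    Invariant to positive-scale affine transforms of each row.  Constant
    rows make the correlation undefined and raise, naming the rows.
    """
    if len(matrix) < 2:
        raise InsufficientDataError("HCA needs at least 2 rows")
    values = matrix.to_numpy(dtype=float)
    sd = values.std(axis=1)
    bad = [str(matrix.index[i]) for i in np.flatnonzero(sd == 0)]
    if bad:
        raise DegenerateDataError(f"constant row(s) under correlation distance: {bad}")
    r = np.corrcoef(values)
    d = np.clip(1.0 - r, 0.0, 2.0)
    np.fill_diagonal(d, 0.0)
    Z = hierarchy.linkage(squareform(d, checks=False), method=linkage)
    cut = hierarchy.fcluster(Z, t=k, criterion="maxclust")
    names = [str(i) for i in matrix.index]
    return HCAResult(
        linkage=Z,
        labels=pd.Series(cut, index=matrix.index, name="cluster"),
        distance=pd.DataFrame(d, index=matrix.index, columns=matrix.index),
        newick=_linkage_to_newick(Z, names),
    )


# ---------------------------------------------------------------------------
# combined correlation analysis
# ---------------------------------------------------------------------------

@dataclass
class CorrelationCluster:
    correlation: pd.DataFrame          # variables x variables Pearson r
    linkage: np.ndarray                # variable dendrogram (1 − r distance)
    cluster_labels: pd.Series          # k-cut over variables
    anchor: str
    anchor_sign: pd.Series             # sign of r(variable, anchor)
    anchor_r: pd.Series


def correlate_blocks(
    phenotypes: pd.DataFrame,
    metabolites: pd.DataFrame,
    *,
    anchor: str = "area_side",
    k: int = 3,
    linkage: str = "average",
) -> CorrelationCluster:
    """Joint Pearson correlation of phenotype and metabolite variables.

    Blocks are inner-joined on their row keys (samples/ecotypes), each
    variable autoscaled, and the full within- and cross-block correlation
    matrix computed.  Variables are clustered on 1 − r, and every variable
    is reported with its correlation (and sign) against the anchor variable
    — by default side-projected area, the biomass proxy — which is how
    metabolites that track biomass positively and senescence negatively
    show up as a signed cluster.
    """
    common = phenotypes.index.intersection(metabolites.index)
    if len(common) < 3:
        raise InsufficientDataError("need at least 3 shared rows between blocks")
    combined = pd.concat(
        [phenotypes.loc[common], metabolites.loc[common]], axis=1
    )
    if anchor not in combined.columns:
        raise DegenerateDataError(f"anchor variable {anchor!r} not present")
    scaled = autoscale(combined)
    r = pd.DataFrame(
        np.corrcoef(scaled.to_numpy(dtype=float), rowvar=False),
        index=scaled.columns, columns=scaled.columns,
    )
    d = np.clip(1.0 - r.to_numpy(), 0.0, 2.0)
    np.fill_diagonal(d, 0.0)
    Z = hierarchy.linkage(squareform(d, checks=False), method=linkage)
    cut = hierarchy.fcluster(Z, t=k, criterion="maxclust")
    anchor_r = r[anchor].drop(index=anchor)
    return CorrelationCluster(
        correlation=r,
        linkage=Z,
        cluster_labels=pd.Series(cut, index=r.index, name="cluster"),
        anchor=anchor,
        anchor_sign=np.sign(anchor_r).rename("sign"),
        anchor_r=anchor_r.rename("r"),
    )


# ---------------------------------------------------------------------------
# class-separation report
# ---------------------------------------------------------------------------

def circle_overlap_fraction(c1, r1: float, c2, r2: float) -> float:
    """Intersection area of two discs as a fraction of the smaller disc."""
    c1 = np.asarray(c1, dtype=float)
    c2 = np.asarray(c2, dtype=float)
    d = float(np.linalg.norm(c1 - c2))
    rmin, rmax = sorted((r1, r2))
    if rmin <= 0:
        return 0.0
    if d >= r1 + r2:
        return 0.0
    if d <= rmax - rmin:
        return 1.0
    # standard lens area
    a1 = r1**2 * np.arccos((d**2 + r1**2 - r2**2) / (2 * d * r1))
    a2 = r2**2 * np.arccos((d**2 + r2**2 - r1**2) / (2 * d * r2))
    a3 = 0.5 * np.sqrt(
        max((-d + r1 + r2) * (d + r1 - r2) * (d - r1 + r2) * (d + r1 + r2), 0.0)
    )
    lens = a1 + a2 - a3
    return float(lens / (np.pi * rmin**2))


@dataclass
class SeparationReport:
    centroid_distances: pd.DataFrame
    overlap_fractions: pd.DataFrame
    separated: bool | None           # None when < 2 classes


def classify_separation(ordination: OrdinationResult) -> SeparationReport:
    """Do the per-class 95% confidence circles separate in the PC1–PC2 plane?

    Reports pairwise centroid distances and circle-overlap fractions;
    ``separated`` is True iff no pair of circles overlaps.  Degenerate with
    a single class (verdict None).
    """
    circles = ordination.class_circles
    names = list(circles)
    n = len(names)
    dist = pd.DataFrame(0.0, index=names, columns=names)
    over = pd.DataFrame(0.0, index=names, columns=names)
    for i, a in enumerate(names):
        for j, b in enumerate(names):
            if i == j:
                over.iloc[i, j] = 1.0
                continue
            ca, ra = circles[a]
            cb, rb = circles[b]
            dist.iloc[i, j] = float(np.linalg.norm(ca - cb))
            over.iloc[i, j] = circle_overlap_fraction(ca, ra, cb, rb)
    if n < 2:
        return SeparationReport(dist, over, separated=None)
    off = ~np.eye(n, dtype=bool)
    separated = bool((over.to_numpy()[off] == 0.0).all())
    return SeparationReport(dist, over, separated=separated)
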