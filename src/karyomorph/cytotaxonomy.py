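"""Distance-based comparison of accessions: Euclidean UPGMA clustering with
cophenetic diagnostics, Gower-similarity principal coordinate analysis, and
the asymmetry scatter specification.

The UPGMA and PCoA routines are implemented directly (they are small and
need deterministic tie-breaking / switchable eigenvalue conventions); the
test-suite cross-checks them against scipy.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from typing import Literal, Sequence

import numpy as np
from scipy.spatial.distance import pdist, squareform
from scipy.stats import pearsonr

from .errors import DegenerateInputError, KaryomorphError
from .measurements_io import KaryotypeSummary, ParameterMatrix

GowerTransform = Literal["sqrt", "linear"]
VarianceDenominator = Literal["positive", "absolute"]


# ---------------------------------------------------------------------------
# matrices
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class DistanceMatrix:
    labels: tuple[str, ...]
    values: np.ndarray

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "labels", tuple(self.labels))
        object.__setattr__(self, "values", values)
        n = len(self.labels)
        if values.shape != (n, n):
            raise KaryomorphError(f"distance matrix must be {n}x{n}, got {values.shape}")
        if not np.allclose(values, values.T, atol=1e-9):
            raise KaryomorphError("distance matrix is not symmetric")
        if not np.allclose(np.diag(values), 0.0, atol=1e-9):
            raise KaryomorphError("distance matrix has a nonzero diagonal")
        if (values < -1e-12).any():
            raise KaryomorphError("distance matrix has negative entries")

    @property
    def n(self) -> int:
        return len(self.labels)

    def condensed(self) -> np.ndarray:
        return squareform(self.values, checks=False)


@dataclass(frozen=True)
class SimilarityMatrix:
    labels: tuple[str, ...]
    values: np.ndarray

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "labels", tuple(self.labels))
        object.__setattr__(self, "values", values)
        n = len(self.labels)
        if values.shape != (n, n):
            raise KaryomorphError(f"similarity matrix must be {n}x{n}, got {values.shape}")
        if not np.allclose(values, values.T, atol=1e-9):
            raise KaryomorphError("similarity matrix is not symmetric")
        if (values < -1e-9).any() or (values > 1 + 1e-9).any():
            raise KaryomorphError("similarities must lie in [0, 1]")

    @property
    def n(self) -> int:
        return len(self.labels)


def euclidean_distances(matrix: ParameterMatrix, *, standardize: bool = False) -> DistanceMatrix:
    """Pairwise Euclidean distances between accessions.

    With ``standardize=True`` columns are z-scored (sample SD) first; the
    default operates on raw parameter values.
    """
    if matrix.n < 2:
        raise KaryomorphError("need at least 2 accessions")
    values = matrix.values
    if standardize:
        sd = values.std(axis=0, ddof=1)
        if (sd == 0).any():
            raise KaryomorphError("cannot standardize a constant column")
        values = (values - values.mean(axis=0)) / sd
    return DistanceMatrix(matrix.labels, squareform(pdist(values)))


def gower_similarity(matrix: ParameterMatrix) -> SimilarityMatrix:
    """Range-normalized Gower similarity over quantitative columns.

    S(i,j) = mean_k (1 − |x_ik − x_jk| / range_k); constant columns
    contribute similarity 1 everywhere.
    """
    if matrix.n < 2:
        raise KaryomorphError("need at least 2 accessions")
    X = matrix.values
    rng = X.max(axis=0) - X.min(axis=0)
    diffs = np.abs(X[:, None, :] - X[None, :, :])
    with np.errstate(invalid="ignore", divide="ignore"):
        per_col = 1.0 - np.where(rng > 0, diffs / np.where(rng > 0, rng, 1.0), 0.0)
    return SimilarityMatrix(matrix.labels, per_col.mean(axis=2))


# ---------------------------------------------------------------------------
# UPGMA
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class DendrogramNode:
    """Subtree of a dendrogram; leaves have height 0 and a label."""

    height: float
    children: tuple["DendrogramNode", ...] = ()
    label: str | None = None

    @property
    def is_leaf(self) -> bool:
        return not self.children

    def leaves(self) -> tuple[str, ...]:
        if self.is_leaf:
            return (self.label,)
        return tuple(l for child in self.children for l in child.leaves())


@dataclass(frozen=True)
class Dendrogram:
    root: DendrogramNode
    labels: tuple[str, ...]

    def __post_init__(self) -> None:
        leaves = self.root.leaves()
        if sorted(leaves) != sorted(self.labels) or len(set(leaves)) != len(leaves):
            raise KaryomorphError("dendrogram leaves do not match labels exactly once")

    def cophenetic_matrix(self) -> DistanceMatrix:
        """Pairwise merge heights (the ultrametric the tree represents)."""
        index = {l: i for i, l in enumerate(self.labels)}
        n = len(self.labels)
        out = np.zeros((n, n))

        def visit(node: DendrogramNode) -> list[str]:
            if node.is_leaf:
                return [node.label]
            groups = [visit(c) for c in node.children]
            for ga, gb in itertools.combinations(groups, 2):
                for a in ga:
                    for b in gb:
                        out[index[a], index[b]] = out[index[b], index[a]] = node.height
            return [l for g in groups for l in g]

        visit(self.root)
        return DistanceMatrix(self.labels, out)

    def to_newick(self) -> str:
        """Newick string with ultrametric branch lengths (leaf depth = root height / 2)."""

        def render(node: DendrogramNode, parent_height: float) -> str:
            branch = (parent_height - node.height) / 2.0
            if node.is_leaf:
                return f"{node.label}:{branch:.6g}"
            inner = ",".join(render(c, node.height) for c in node.children)
            return f"({inner}):{branch:.6g}"

        if self.root.is_leaf:
            return f"{self.root.label}:0;"
        inner = ",".join(render(c, self.root.height) for c in self.root.children)
        return f"({inner});"


def upgma(dist: DistanceMatrix) -> Dendrogram:
    """Average-linkage agglomeration; merge height = mean inter-cluster distance.

    Ties are broken by the lexicographically smallest pair of cluster
    labels (a cluster is labelled by its smallest leaf), making the tree
    deterministic across platforms.
    """
    if dist.n < 2:
        raise KaryomorphError("need at least 2 labels")

    nodes: dict[int, DendrogramNode] = {
        i: DendrogramNode(0.0, label=l) for i, l in enumerate(dist.labels)
    }
    sizes = {i: 1 for i in nodes}
    keys = {i: dist.labels[i] for i in nodes}  # smallest leaf label per cluster
    d = {
        (i, j): float(dist.values[i, j])
        for i, j in itertools.combinations(range(dist.n), 2)
    }
    next_id = dist.n

    def dd(i: int, j: int) -> float:
        return d[(i, j) if i < j else (j, i)]

    while len(nodes) > 1:
        best = min(
            (
                (dd(i, j), tuple(sorted((keys[i], keys[j]))), i, j)
                for i, j in itertools.combinations(sorted(nodes), 2)
            ),
            key=lambda t: (t[0], t[1]),
        )
        height, _, a, b = best
        merged = DendrogramNode(height, children=(nodes[a], nodes[b]))
        for k in list(nodes):
            if k in (a, b):
                continue
            d[(k, next_id) if k < next_id else (next_id, k)] = (
                sizes[a] * dd(k, a) + sizes[b] * dd(k, b)
            ) / (sizes[a] + sizes[b])
        nodes[next_id] = merged
        sizes[next_id] = sizes[a] + sizes[b]
        keys[next_id] = min(keys[a], keys[b])
        for k in (a, b):
            del nodes[k], sizes[k], keys[k]
        next_id += 1

    (root,) = nodes.values()
    return Dendrogram(root=root, labels=dist.labels)


def cophenetic_correlation(tree: Dendrogram, dist: DistanceMatrix) -> float:
    """Pearson correlation between original and cophenetic pairwise distances."""
    if sorted(tree.labels) != sorted(dist.labels):
        raise KaryomorphError("tree leaves do not match distance labels")
    order = [dist.labels.index(l) for l in tree.labels]
    original = DistanceMatrix(
        tree.labels, dist.values[np.ix_(order, order)]
    ).condensed()
    coph = tree.cophenetic_matrix().condensed()
    if np.allclose(original, original[0]) or np.allclose(coph, coph[0]):
        raise DegenerateInputError("cophenetic correlation undefined: constant distances")
    return float(pearsonr(original, coph)[0])


def cut_clusters(tree: Dendrogram, height: float) -> list[tuple[str, ...]]:
    """Partition of the leaves obtained by cutting all merges above *height*.

    Clusters are maximal subtrees whose merge height is <= the cut height;
    they are returned sorted by their smallest leaf label.
    """
    if height < 0:
        raise KaryomorphError("cut height must be >= 0")

    clusters: list[tuple[str, ...]] = []

    def visit(node: DendrogramNode) -> None:
        if node.height <= height:
            clusters.append(tuple(sorted(node.leaves())))
        else:
            for child in node.children:
                visit(child)

    visit(tree.root)
    return sorted(clusters, key=lambda c: c[0])


# ---------------------------------------------------------------------------
# PCoA
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class Ordination:
    """Principal coordinates: sample scores, eigenvalues, and variance shares.

    ``coordinates`` has one column per retained (positive-eigenvalue) axis,
    scaled by the square root of the eigenvalue.  ``eigenvalues`` contains
    the full spectrum in descending order; ``percent_variance`` covers the
    retained axes only.
    """

    labels: tuple[str, ...]
    coordinates: np.ndarray
    eigenvalues: np.ndarray
    percent_variance: np.ndarray

    @property
    def n_axes(self) -> int:
        return self.coordinates.shape[1]


def similarity_to_distance(
    sim: SimilarityMatrix, *, transform: GowerTransform = "sqrt"
) -> DistanceMatrix:
    """Convert similarities to distances: ``sqrt`` uses √(1−S) (metric-
    preserving for quantitative Gower), ``linear`` uses 1−S."""
    comp = np.clip(1.0 - sim.values, 0.0, None)
    np.fill_diagonal(comp, 0.0)
    if transform == "sqrt":
        comp = np.sqrt(comp)
    elif transform != "linear":
        raise KaryomorphError(f"unknown transform {transform!r}")
    return DistanceMatrix(sim.labels, comp)


def pcoa_from_distances(
    dist: DistanceMatrix,
    *,
    variance_denominator: VarianceDenominator = "positive",
    eig_tol: float = 1e-10,
) -> Ordination:
    """Classical metric scaling of a distance matrix.

    The squared distances are double-centered (−d²/2), eigendecomposed, and
    axes with positive eigenvalues are retained.  Variance shares divide by
    the sum of positive eigenvalues (default) or by the sum of absolute
    eigenvalues (``"absolute"``, the convention of some legacy software).
    """
    n = dist.n
    centering = np.eye(n) - np.ones((n, n)) / n
    b = centering @ (-0.5 * dist.values**2) @ centering
    eigval, eigvec = np.linalg.eigh((b + b.T) / 2.0)
    order = np.argsort(eigval)[::-1]
    eigval, eigvec = eigval[order], eigvec[:, order]

    scale = max(abs(eigval[0]), 1.0)
    positive = eigval > eig_tol * scale
    if not positive.any():
        raise DegenerateInputError("no positive eigenvalues: degenerate configuration")

    coords = eigvec[:, positive] * np.sqrt(eigval[positive])
    if variance_denominator == "positive":
        denom = eigval[positive].sum()
    elif variance_denominator == "absolute":
        denom = np.abs(eigval).sum()
    else:
        raise KaryomorphError(f"unknown variance denominator {variance_denominator!r}")
    percent = 100.0 * eigval[positive] / denom
    return Ordination(dist.labels, coords, eigval, percent)


def pcoa(
    sim: SimilarityMatrix,
    *,
    transform: GowerTransform = "sqrt",
    variance_denominator: VarianceDenominator = "positive",
) -> Ordination:
    """Principal coordinate analysis of a similarity matrix (see
    :func:`similarity_to_distance` and :func:`pcoa_from_distances`)."""
    dist = similarity_to_distance(sim, transform=transform)
    return pcoa_from_distances(dist, variance_denominator=variance_denominator)


# ---------------------------------------------------------------------------
# asymmetry scatter
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ScatterPoint:
    label: str
    cv_cl: float
    m_ca: float


@dataclass(frozen=True)
class ScatterSpec:
    """Point-per-accession specification of the CV_CL vs M_CA scatter plot."""

    points: tuple[ScatterPoint, ...]
    x_label: str = "CV_CL"
    y_label: str = "M_CA"


def asymmetry_scatter(summaries: Sequence[KaryotypeSummary]) -> ScatterSpec:
    """Build the interchromosomal (CV_CL) vs intrachromosomal (M_CA)
    asymmetry scatter specification, one labelled point per accession."""
    points = tuple(ScatterPoint(s.accession_id, s.cv_cl, s.m_ca) for s in summaries)
    return ScatterSpec(points=points)


def render_dendrogram(tree: Dendrogram, *, width: float = 520.0, row_height: float = 22.0) -> str:
    """Deterministic horizontal SVG dendrogram (root left, leaves right)."""
    from ._svg import SvgCanvas

    leaves = tree.root.leaves()
    margin = 60.0
    height = 2 * margin + row_height * max(len(leaves) - 1, 1)
    root_h = tree.root.height or 1.0
    y_of = {l: margin + i * row_height for i, l in enumerate(leaves)}
    x_right = width - 110.0

    def x_of(h: float) -> float:
        return x_right - h / root_h * (x_right - margin)

    canvas = SvgCanvas(width, height)

    def visit(node: DendrogramNode) -> float:
        if node.is_leaf:
            y = y_of[node.label]
            canvas.text(x_right + 6.0, y + 3.0, node.label, size=9.0, anchor="start")
            return y
        child_pos = [(visit(c), c.height) for c in node.children]
        x = x_of(node.height)
        ys = [y for y, _ in child_pos]
        canvas.line(x, min(ys), x, max(ys))
        for y, child_h in child_pos:
            canvas.line(x, y, x_of(child_h), y)
        return float(np.mean(ys))

    y_root = visit(tree.root)
    canvas.line(x_of(tree.root.height), y_root, x_of(tree.root.height) - 10.0, y_root)
    # distance axis
    canvas.line(margin, height - margin / 2, x_right, height - margin / 2)
    canvas.text(margin, height - margin / 2 + 14.0, f"{root_h:.3g}", size=8.0)
    canvas.text(x_right, height - margin / 2 + 14.0, "0", size=8.0)
    return canvas.to_string()


def render_scatter(spec: ScatterSpec, *, width: float = 480.0, height: float = 360.0) -> str:
    """Deterministic SVG rendering of a scatter specification."""
    from ._svg import SvgCanvas

    canvas = SvgCanvas(width, height)
    margin = 50.0
    if spec.points:
        xs = [p.cv_cl for p in spec.points]
        ys = [p.m_ca for p in spec.points]
        x_lo, x_hi = min(xs), max(xs)
        y_lo, y_hi = min(ys), max(ys)
        x_span = (x_hi - x_lo) or 1.0
        y_span = (y_hi - y_lo) or 1.0

        def sx(v: float) -> float:
            return margin + (v - x_lo) / x_span * (width - 2 * margin)

        def sy(v: float) -> float:
            return height - margin - (v - y_lo) / y_span * (height - 2 * margin)

        canvas.line(margin, height - margin, width - margin, height - margin)
        canvas.line(margin, margin, margin, height - margin)
        for point in spec.points:
            canvas.circle(sx(point.cv_cl), sy(point.m_ca), 3.0)
            canvas.text(sx(point.cv_cl), sy(point.m_ca) - 6.0, point.label, size=8.0)
        canvas.text(width / 2, height - margin / 3, spec.x_label)
        canvas.text(margin / 3, height / 2, spec.y_label)
    return canvas.to_string()
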