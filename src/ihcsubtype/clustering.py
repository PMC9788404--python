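"""Hierarchical clustering of patients with multiscale-bootstrap support.

Patients are clustered on their seven-marker percent-positivity vectors with
correlation distance and average linkage (UPGMA).  Cluster robustness is
assessed by multiscale bootstrap: the marker axis is resampled at several
relative sizes r (default 0.5-1.4), the cohort is reclustered ``nboot`` times
per scale, and each original cluster's bootstrap probability BP_r is the
fraction of resampled trees containing an identical member set.  The
approximately unbiased (AU) support extrapolates across scales: with
psi(r) = Phi^-1(1 - BP_r), the signed-distance/curvature model

    psi(r) ~= v*sqrt(r) + c/sqrt(r)

is fitted by weighted least squares, and AU = 1 - Phi(v - c) corrects the
naive bootstrap probability (BP = 1 - Phi(v + c)) for the curvature of the
cluster-region boundary.  Clusters with AU >= 0.95 are deemed significant.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import norm

from .datamodel import CohortMatrix

#: Default relative resampling sizes, matching the conventional 0.5..1.4 grid.
DEFAULT_R_GRID: tuple[float, ...] = (0.5, 0.6, 0.7, 0.8, 0.9, 1.0, 1.1, 1.2, 1.3, 1.4)


# ---------------------------------------------------------------------------
# distances


def correlation_distance(matrix: CohortMatrix | np.ndarray) -> np.ndarray:
    """Pearson-correlation distance d(i,j) = 1 - cor(x_i, x_j) between patients.

    Raises
    ------
    ValueError
        If any patient's marker vector has zero variance (correlation is
        undefined); the error names the offending patients.
    """
    if isinstance(matrix, CohortMatrix):
        X = matrix.values
        ids = matrix.patient_ids
    else:
        X = np.asarray(matrix, dtype=float)
        ids = [str(i) for i in range(X.shape[0])]
    if X.shape[0] < 2:
        raise ValueError("need at least 2 patients")
    flat = np.std(X, axis=1) == 0
    if flat.any():
        bad = [ids[i] for i in np.where(flat)[0]]
        raise ValueError(f"zero-variance marker vectors for patients: {bad}")
    corr = np.corrcoef(X)
    corr = (corr + corr.T) / 2.0  # corrcoef is not bitwise symmetric
    d = 1.0 - corr
    np.fill_diagonal(d, 0.0)
    return np.clip(d, 0.0, 2.0)


def _bootstrap_correlation_distance(X: np.ndarray) -> np.ndarray:
    """Correlation distance tolerant of zero-variance rows.

    Marker resampling can leave a patient with a constant vector; such a
    patient is treated as uncorrelated with everyone (distance 1), which
    keeps the resampled tree defined without aborting the bootstrap.
    """
    X = np.asarray(X, dtype=float)
    mu = X.mean(axis=1, keepdims=True)
    sd = X.std(axis=1, keepdims=True)
    ok = sd[:, 0] > 0
    Z = np.zeros_like(X)
    np.divide(X - mu, sd, out=Z, where=sd > 0)
    corr = (Z @ Z.T) / X.shape[1]
    corr = (corr + corr.T) / 2.0
    corr[~ok, :] = 0.0
    corr[:, ~ok] = 0.0
    d = 1.0 - corr
    np.fill_diagonal(d, 0.0)
    return np.clip(d, 0.0, 2.0)


# ---------------------------------------------------------------------------
# UPGMA


@dataclass(frozen=True)
class ClusterNode:
    """One internal node of the dendrogram (ids n..2n-2, leaves 0..n-1)."""

    id: int
    left: int
    right: int
    height: float
    members: frozenset[int]


@dataclass
class ClusterTree:
    """UPGMA dendrogram over patients, optionally carrying bootstrap support.

    ``nodes`` are the n-1 internal nodes in merge order; ``support`` (set by
    :func:`attach_support`) holds per-node BP/AU values and fit diagnostics.
    """

    labels: list[str]
    nodes: list[ClusterNode]
    support: pd.DataFrame | None = None
    bp_counts: pd.DataFrame | None = None
    r_grid: tuple[float, ...] | None = None
    nboot: int | None = None
    seed: int | None = None

    @property
    def n_leaves(self) -> int:
        return len(self.labels)

    @property
    def root(self) -> ClusterNode:
        return self.nodes[-1]

    def member_labels(self, node: ClusterNode) -> list[str]:
        return sorted(self.labels[i] for i in node.members)

    def to_linkage(self) -> np.ndarray:
        """Convert to a scipy ``linkage`` matrix (for dendrogram drawing)."""
        n = self.n_leaves
        sizes = {i: 1 for i in range(n)}
        Z = np.zeros((n - 1, 4))
        for k, node in enumerate(self.nodes):
            sizes[node.id] = sizes[node.left] + sizes[node.right]
            Z[k] = [node.left, node.right, node.height, sizes[node.id]]
        return Z

    def to_newick(self, digits: int = 6) -> str:
        """Newick string with AU/BP support as bracketed node comments."""
        support = {}
        if self.support is not None:
            support = {
                int(row.Index): (row.au, row.bp)
                for row in self.support.itertuples()
            }
        by_id = {node.id: node for node in self.nodes}

        def render(node_id: int, parent_height: float) -> str:
            if node_id < self.n_leaves:
                blen = parent_height
                return f"{self.labels[node_id]}:{blen:.{digits}g}"
            node = by_id[node_id]
            inner = ",".join(
                render(child, parent_height=node.height)
                for child in (node.left, node.right)
            )
            comment = ""
            if node_id in support:
                au, bp = support[node_id]
                comment = f"[&AU={au:.4f},BP={bp:.4f}]"
            blen = parent_height - node.height
            return f"({inner}){comment}:{blen:.{digits}g}"

        root = self.root
        inner = ",".join(render(c, root.height) for c in (root.left, root.right))
        return f"({inner});"


def average_linkage_tree(
    distances: np.ndarray, labels: list[str] | None = None
) -> ClusterTree:
    """UPGMA tree from a symmetric distance matrix.

    The merge height of each internal node is the unweighted mean distance
    between the two merged clusters' members.  Ties are broken
    deterministically: among equally close pairs, merge the one whose
    clusters have the lexicographically smallest representative leaf labels.
    """
    D = np.asarray(distances, dtype=float).copy()
    n = D.shape[0]
    if D.ndim != 2 or D.shape[0] != D.shape[1]:
        raise ValueError("distance matrix must be square")
    if not np.allclose(D, D.T, atol=1e-10):
        raise ValueError("distance matrix must be symmetric")
    if labels is None:
        labels = [str(i) for i in range(n)]
    if len(labels) != n:
        raise ValueError("labels length must match matrix size")

    np.fill_diagonal(D, np.inf)
    active = np.ones(n, dtype=bool)
    sizes = np.ones(n)
    members: list[frozenset[int]] = [frozenset([i]) for i in range(n)]
    node_of = list(range(n))  # dendrogram node id currently held by each slot
    rep = list(labels)  # lexicographic representative per slot (tie-break)
    nodes: list[ClusterNode] = []

    upper = np.triu(np.ones((n, n), dtype=bool), k=1)
    for step in range(n - 1):
        masked = np.where(active[:, None] & active[None, :] & upper, D, np.inf)
        height = masked.min()
        ii, jj = np.where(masked == height)
        pairs = list(zip(ii.tolist(), jj.tolist()))
        if len(pairs) > 1:
            pairs.sort(key=lambda p: tuple(sorted((rep[p[0]], rep[p[1]]))))
        i, j = pairs[0]

        new_id = n + step
        nodes.append(
            ClusterNode(
                id=new_id,
                left=node_of[i],
                right=node_of[j],
                height=float(height),
                members=members[i] | members[j],
            )
        )
        # UPGMA update into slot i
        others = active.copy()
        others[[i, j]] = False
        D[i, others] = (sizes[i] * D[i, others] + sizes[j] * D[j, others]) / (
            sizes[i] + sizes[j]
        )
        D[others, i] = D[i, others]
        active[j] = False
        D[j, :] = np.inf
        D[:, j] = np.inf
        sizes[i] += sizes[j]
        members[i] = members[i] | members[j]
        node_of[i] = new_id
        rep[i] = min(rep[i], rep[j])

    return ClusterTree(labels=list(labels), nodes=nodes)


# ---------------------------------------------------------------------------
# multiscale bootstrap


def multiscale_bootstrap(
    matrix: CohortMatrix,
    tree: ClusterTree,
    r_grid: tuple[float, ...] = DEFAULT_R_GRID,
    nboot: int = 1000,
    seed: int = 0,
) -> pd.DataFrame:
    """Bootstrap probabilities BP_r of every internal node at each scale.

    At scale r the marker axis (size m) is resampled with replacement to
    round(r*m) markers, patients are reclustered, and a node scores a hit
    when some node of the resampled tree has exactly the same member set.
    Returns a DataFrame indexed by node id with one column per scale,
    holding hit fractions in [0, 1].
    """
    X = matrix.values
    m = X.shape[1]
    sizes = [int(np.floor(r * m + 0.5)) for r in r_grid]
    too_small = [r for r, s in zip(r_grid, sizes) if s < 2]
    if too_small:
        raise ValueError(f"scales {too_small} resample fewer than 2 markers")

    rng = np.random.default_rng(seed)
    counts = np.zeros((len(tree.nodes), len(r_grid)), dtype=int)
    node_sets = [node.members for node in tree.nodes]
    for si, m_r in enumerate(sizes):
        for _ in range(nboot):
            cols = rng.integers(0, m, size=m_r)
            d = _bootstrap_correlation_distance(X[:, cols])
            boot_tree = average_linkage_tree(d, tree.labels)
            present = {node.members for node in boot_tree.nodes}
            for k, s in enumerate(node_sets):
                if s in present:
                    counts[k, si] += 1
    return pd.DataFrame(
        counts / nboot,
        index=pd.Index([n.id for n in tree.nodes], name="node"),
        columns=pd.Index(list(r_grid), name="r"),
    )


@dataclass
class AUFit:
    """AU/BP fit for one node: support values plus diagnostics."""

    au: float
    bp_smoothed: float
    v: float
    c: float
    rss: float
    flag: str  # "ok" | "pinned" | "degenerate"


def fit_au(
    bp_by_scale: np.ndarray | pd.Series,
    r_grid: tuple[float, ...] = DEFAULT_R_GRID,
    nboot: int = 1000,
) -> AUFit:
    """Fit the multiscale model to one node's per-scale BP values.

    psi(r) = Phi^-1(1 - BP_r) is regressed on (sqrt(r), 1/sqrt(r)) by least
    squares weighted with the binomial information nboot*phi(psi)^2/(BP(1-BP)),
    BP clipped to [1/(nboot+1), nboot/(nboot+1)].  AU = 1 - Phi(v - c) and the
    smoothed BP = 1 - Phi(v + c).

    Nodes whose BP is 0 or 1 at every scale are pinned to AU 0/1 (flag
    "pinned"); a fit with fewer than two informative scales falls back to the
    scale-nearest-1 BP (flag "degenerate") with a warning.
    """
    bp = np.asarray(bp_by_scale, dtype=float)
    r = np.asarray(r_grid, dtype=float)
    if bp.shape != r.shape:
        raise ValueError("bp_by_scale and r_grid lengths differ")
    near1 = int(np.argmin(np.abs(r - 1.0)))
    usable = (bp > 0) & (bp < 1)

    if not usable.any():
        pinned = 1.0 if bp[near1] >= 0.5 else 0.0
        return AUFit(au=pinned, bp_smoothed=pinned, v=np.nan, c=np.nan, rss=0.0, flag="pinned")
    if usable.sum() < 2:
        warnings.warn(
            "degenerate multiscale fit (fewer than 2 informative scales); "
            "reporting the scale-1 bootstrap probability as AU",
            stacklevel=2,
        )
        return AUFit(
            au=float(bp[near1]),
            bp_smoothed=float(bp[near1]),
            v=np.nan,
            c=np.nan,
            rss=np.nan,
            flag="degenerate",
        )

    lo, hi = 1.0 / (nboot + 1), nboot / (nboot + 1.0)
    bp_u = np.clip(bp[usable], lo, hi)
    r_u = r[usable]
    psi = norm.ppf(1.0 - bp_u)
    X = np.column_stack([np.sqrt(r_u), 1.0 / np.sqrt(r_u)])
    w = nboot * norm.pdf(psi) ** 2 / (bp_u * (1.0 - bp_u))
    XtW = X.T * w
    try:
        beta = np.linalg.solve(XtW @ X, XtW @ psi)
    except np.linalg.LinAlgError:
        warnings.warn("singular multiscale design; falling back to scale-1 BP", stacklevel=2)
        return AUFit(
            au=float(bp[near1]),
            bp_smoothed=float(bp[near1]),
            v=np.nan,
            c=np.nan,
            rss=np.nan,
            flag="degenerate",
        )
    v, c = float(beta[0]), float(beta[1])
    resid = psi - X @ beta
    return AUFit(
        au=float(1.0 - norm.cdf(v - c)),
        bp_smoothed=float(1.0 - norm.cdf(v + c)),
        v=v,
        c=c,
        rss=float(np.sum(w * resid**2)),
        flag="ok",
    )


def attach_support(
    tree: ClusterTree,
    matrix: CohortMatrix,
    r_grid: tuple[float, ...] = DEFAULT_R_GRID,
    nboot: int = 1000,
    seed: int = 0,
) -> ClusterTree:
    """Run the multiscale bootstrap and store AU/BP per node on the tree."""
    bp = multiscale_bootstrap(matrix, tree, r_grid=r_grid, nboot=nboot, seed=seed)
    near1 = int(np.argmin(np.abs(np.asarray(r_grid) - 1.0)))
    rows = []
    for node in tree.nodes:
        fit = fit_au(bp.loc[node.id].to_numpy(), r_grid=r_grid, nboot=nboot)
        rows.append(
            {
                "node": node.id,
                "n_members": len(node.members),
                "bp": float(bp.loc[node.id].iloc[near1]),
                "au": fit.au,
                "bp_smoothed": fit.bp_smoothed,
                "v": fit.v,
                "c": fit.c,
                "rss": fit.rss,
                "flag": fit.flag,
            }
        )
    tree.support = pd.DataFrame(rows).set_index("node")
    tree.bp_counts = bp
    tree.r_grid = tuple(r_grid)
    tree.nboot = nboot
    tree.seed = seed
    return tree


def significant_clusters(
    tree: ClusterTree, alpha: float = 0.95
) -> tuple[list[ClusterNode], list[str]]:
    """Maximal non-root clusters with AU >= alpha, plus unassigned patients.

    The root is excluded (it trivially contains every patient and its BP is 1
    at every scale).  A significant cluster nested inside another selected
    cluster is dropped; patients outside every selected cluster are returned
    as unassigned labels.
    """
    if tree.support is None:
        raise ValueError("attach_support must be run before selecting clusters")
    candidates = [
        node
        for node in tree.nodes
        if node is not tree.root and tree.support.loc[node.id, "au"] >= alpha
    ]
    candidates.sort(key=lambda n: len(n.members), reverse=True)
    selected: list[ClusterNode] = []
    for node in candidates:
        if not any(node.members <= s.members for s in selected):
            selected.append(node)
    covered: set[int] = set().union(*(s.members for s in selected)) if selected else set()
    unassigned = [tree.labels[i] for i in range(tree.n_leaves) if i not in covered]
    return selected, unassigned


# ---------------------------------------------------------------------------
# cluster labeling


@dataclass
class ClusterLabel:
    """Rule-based immunophenotype label for one cluster."""

    major: str  # luminal / mixed / basal / unclassified
    ck5: str  # "+" / "-"
    gata3: str  # "+" / "-"
    marker_summary: dict[str, float] = field(default_factory=dict)

    @property
    def sub(self) -> str:
        return f"CK5{self.ck5}/GATA3{self.gata3}"


def label_cluster(
    member_ids: list[str],
    matrix: CohortMatrix,
    cutoff: float = 20.0,
    statistic: str = "median",
) -> ClusterLabel:
    """Label a cluster from its member-level CK20/CK18 summary expression.

    Cluster-level expression is the per-marker median (or mean) percent over
    members; luminal = CK20 and CK18 both >= cutoff, mixed = only CK18,
    basal = neither.  The CK20+/CK18- pattern has no label in the scheme and
    is reported as "unclassified" with a warning.  CK5/GATA3 medians against
    the same cutoff give the sub-label.
    """
    if not member_ids:
        raise ValueError("empty cluster")
    frame = matrix.to_frame().loc[list(member_ids)]
    if statistic == "median":
        summary = frame.median()
    elif statistic == "mean":
        summary = frame.mean()
    else:
        raise ValueError(f"unknown statistic {statistic!r}")
    ck20, ck18 = float(summary["CK20"]), float(summary["CK18"])
    if ck18 >= cutoff:
        major = "luminal" if ck20 >= cutoff else "mixed"
    elif ck20 >= cutoff:
        major = "unclassified"
        warnings.warn(
            "cluster-level CK20+/CK18- pattern has no luminal/basal/mixed label",
            stacklevel=2,
        )
    else:
        major = "basal"
    return ClusterLabel(
        major=major,
        ck5="+" if float(summary["CK5"]) >= cutoff else "-",
        gata3="+" if float(summary["GATA3"]) >= cutoff else "-",
        marker_summary={m: float(summary[m]) for m in matrix.markers},
    )
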