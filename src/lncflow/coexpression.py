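"""Weighted gene coexpression network analysis, implemented from scratch.

Pipeline: Pearson similarity -> soft-threshold adjacency A = |r|^beta ->
topological overlap matrix (TOM, Zhang & Horvath 2005) -> average-linkage
hierarchical clustering on 1 - TOM with a static cut -> module eigengenes ->
module--trait correlation, gene significance, and TOM-thresholded edge
export for Cytoscape.

The unsigned network is the default; a signed variant (adjacency
((1 + r)/2)^beta) is available via ``signed=True``.  Expression is
log2(FPKM + 1)-transformed before correlation unless ``log_transform=False``.

The core is the sklearn-style :class:`CoexpressionNetwork` estimator
(``fit`` on a samples x genes matrix, fitted attributes with trailing
underscores); the module-level functions are the individual numerical
steps and remain usable on their own.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster.hierarchy import average, fcluster
from scipy.spatial.distance import squareform
from sklearn.base import BaseEstimator

# WGCNA's conventional size-ranked module palette
MODULE_COLORS = [
    "turquoise", "blue", "brown", "yellow", "green", "red", "black", "pink",
    "magenta", "purple", "greenyellow", "tan", "salmon", "cyan",
    "midnightblue", "lightcyan", "grey60", "lightgreen", "lightyellow",
    "royalblue", "darkred", "darkgreen", "darkturquoise", "darkgrey",
    "orange", "darkorange", "white", "skyblue", "saddlebrown", "steelblue",
]
UNASSIGNED = "grey"


# ---------------------------------------------------------------------------
# numerical steps
# ---------------------------------------------------------------------------


def similarity(expr: np.ndarray | pd.DataFrame) -> np.ndarray:
    """Pearson correlation between genes.

    ``expr`` is genes x samples; at least 3 samples are required and
    zero-variance genes are rejected (their correlation is undefined).
    """
    X = np.asarray(expr, dtype=float)
    if X.ndim != 2 or X.shape[1] < 3:
        raise ValueError("need a genes x samples matrix with >= 3 samples")
    sd = X.std(axis=1)
    if np.any(sd == 0):
        idx = np.nonzero(sd == 0)[0]
        ids = (
            [expr.index[i] for i in idx]
            if isinstance(expr, pd.DataFrame)
            else idx.tolist()
        )
        raise ValueError(f"zero-variance genes: {ids}")
    S = np.corrcoef(X)
    S = np.clip(S, -1.0, 1.0)
    np.fill_diagonal(S, 1.0)
    return (S + S.T) / 2


def adjacency(S: np.ndarray, beta: int, signed: bool = False) -> np.ndarray:
    """Soft-threshold connection strengths; zero diagonal."""
    if beta < 1:
        raise ValueError("beta must be a positive integer")
    base = (1 + S) / 2 if signed else np.abs(S)
    A = base**beta
    np.fill_diagonal(A, 0.0)
    return A


def scale_free_fit(k: np.ndarray, n_bins: int = 10) -> float:
    """R^2 of the linear fit of log10 p(k) against log10 k over connectivity
    bins (the scale-free topology fit index)."""
    k = np.asarray(k, dtype=float)
    k = k[k > 0]
    if k.size < 3:
        return 0.0
    edges = np.linspace(k.min(), k.max() + 1e-12, n_bins + 1)
    counts, _ = np.histogram(k, bins=edges)
    centers = np.array(
        [k[(k >= edges[i]) & (k < edges[i + 1])].mean() if counts[i] else np.nan
         for i in range(n_bins)]
    )
    mask = counts > 0
    if mask.sum() < 3:
        return 0.0
    x = np.log10(centers[mask])
    y = np.log10(counts[mask] / counts.sum())
    if np.allclose(x, x[0]):
        return 0.0
    r = np.corrcoef(x, y)[0, 1]
    return float(r * r) if np.isfinite(r) else 0.0


def pick_beta(
    S: np.ndarray,
    candidates=range(1, 21),
    r2_target: float = 0.8,
    signed: bool = False,
) -> int:
    """Smallest soft power whose scale-free fit R^2 reaches *r2_target*;
    falls back to the candidate with maximal R^2 when none does."""
    if S.shape[0] < 30:
        raise ValueError("need >= 30 genes to assess scale-free fit")
    best_beta, best_r2 = None, -np.inf
    for beta in candidates:
        A = adjacency(S, beta, signed=signed)
        r2 = scale_free_fit(A.sum(axis=0))
        if r2 >= r2_target:
            return int(beta)
        if r2 > best_r2:
            best_beta, best_r2 = int(beta), r2
    return best_beta


def tom(A: np.ndarray) -> np.ndarray:
    """Topological overlap matrix of a weighted adjacency.

    TOM[i,j] = (sum_u A[i,u] A[u,j] + A[i,j]) / (min(k_i, k_j) + 1 - A[i,j])
    with k_i the weighted connectivity; diagonal set to 1.
    """
    A = np.asarray(A, dtype=float)
    if A.ndim != 2 or A.shape[0] != A.shape[1]:
        raise ValueError("adjacency must be square")
    if not np.allclose(A, A.T, atol=1e-10):
        raise ValueError("adjacency must be symmetric")
    if not np.allclose(np.diag(A), 0.0):
        raise ValueError("adjacency diagonal must be zero")
    k = A.sum(axis=0)
    L = A @ A
    denom = np.minimum.outer(k, k) + 1.0 - A
    T = (L + A) / denom
    np.fill_diagonal(T, 1.0)
    return (T + T.T) / 2


def detect_modules(
    T: np.ndarray,
    min_module_size: int = 30,
    cut_height: float = 0.995,
) -> np.ndarray:
    """Average-linkage clustering on 1 - TOM with a static tree cut.

    Clusters below *min_module_size* are labelled ``grey``; the rest are
    named by the conventional palette in decreasing size order.
    """
    n = T.shape[0]
    if n == 1:
        return np.array([UNASSIGNED if min_module_size > 1 else MODULE_COLORS[0]])
    d = 1.0 - T
    np.fill_diagonal(d, 0.0)
    d = np.clip((d + d.T) / 2, 0.0, None)
    Z = average(squareform(d, checks=False))
    raw = fcluster(Z, t=cut_height, criterion="distance")
    labels = np.full(n, UNASSIGNED, dtype=object)
    sizes = pd.Series(raw).value_counts()
    ranked = [
        c for c in sizes.index
        if sizes[c] >= min_module_size
    ]
    # deterministic order: size desc, then first-occurrence
    first_pos = {c: int(np.argmax(raw == c)) for c in ranked}
    ranked.sort(key=lambda c: (-sizes[c], first_pos[c]))
    for color, cluster in zip(MODULE_COLORS, ranked):
        labels[raw == cluster] = color
    if len(ranked) > len(MODULE_COLORS):
        for i, cluster in enumerate(ranked[len(MODULE_COLORS):]):
            labels[raw == cluster] = f"module{len(MODULE_COLORS) + i + 1}"
    return labels


def eigengene(expr_module: np.ndarray | pd.DataFrame) -> np.ndarray:
    """First principal component over samples of a gene-standardized module
    submatrix (genes x samples), sign-oriented to correlate positively with
    the module's mean expression profile."""
    X = np.asarray(expr_module, dtype=float)
    if X.ndim != 2 or X.shape[0] < 2:
        raise ValueError("module needs >= 2 genes")
    sd = X.std(axis=1, keepdims=True)
    if np.any(sd == 0):
        sd = np.where(sd == 0, 1.0, sd)
    Z = (X - X.mean(axis=1, keepdims=True)) / sd
    _, _, vt = np.linalg.svd(Z, full_matrices=False)
    e = vt[0]
    ref = Z.mean(axis=0)
    if ref.std() > 0 and np.corrcoef(e, ref)[0, 1] < 0:
        e = -e
    elif ref.std() == 0 and e.sum() < 0:
        e = -e
    return e


def _pearson_with_p(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """Pearson r and its two-sided p from the t transform on n-2 df."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    n = x.size
    if n < 3:
        raise ValueError("need >= 3 samples")
    if x.std() == 0 or y.std() == 0:
        raise ValueError("constant vector in correlation")
    r = float(np.corrcoef(x, y)[0, 1])
    r = max(-1.0, min(1.0, r))
    if abs(r) == 1.0:
        return r, 0.0
    t = r * np.sqrt((n - 2) / (1 - r * r))
    p = 2.0 * stats.t.sf(abs(t), df=n - 2)
    return r, float(p)


def module_trait(
    eigengenes: pd.DataFrame, traits: pd.DataFrame
) -> pd.DataFrame:
    """Pearson correlation (with t-based two-sided p) between every module
    eigengene (rows: modules, cols: samples) and every trait column."""
    if not eigengenes.columns.equals(traits.index):
        traits = traits.loc[eigengenes.columns]
    rows = []
    for mod in eigengenes.index:
        for trait in traits.columns:
            r, p = _pearson_with_p(
                eigengenes.loc[mod].to_numpy(), traits[trait].to_numpy()
            )
            rows.append({"module": mod, "trait": trait, "r": r, "p": p})
    return pd.DataFrame(rows)


def gene_significance(
    expr: pd.DataFrame, trait: pd.Series
) -> pd.Series:
    """GS = |Pearson r(gene, trait)| per gene (expr: genes x samples)."""
    trait = trait.loc[expr.columns]
    X = expr.to_numpy(float)
    y = trait.to_numpy(float)
    Xc = X - X.mean(axis=1, keepdims=True)
    yc = y - y.mean()
    denom = np.sqrt((Xc**2).sum(axis=1) * (yc**2).sum())
    with np.errstate(invalid="ignore", divide="ignore"):
        r = (Xc @ yc) / denom
    r = np.where(np.isfinite(r), r, 0.0)
    return pd.Series(np.abs(r), index=expr.index, name="GS")


def module_membership(
    expr: pd.DataFrame, eigengenes: pd.DataFrame, modules: pd.Series
) -> pd.Series:
    """|r(gene, own-module eigengene)| for the GS-vs-membership scatter."""
    out = {}
    for g in expr.index:
        mod = modules[g]
        if mod == UNASSIGNED or mod not in eigengenes.index:
            out[g] = np.nan
            continue
        out[g] = abs(
            float(
                np.corrcoef(
                    expr.loc[g].to_numpy(float),
                    eigengenes.loc[mod].to_numpy(float),
                )[0, 1]
            )
        )
    return pd.Series(out, name="MM")


def export_edges(
    T: np.ndarray,
    ids,
    threshold: float = 0.08,
    node_types: dict[str, str] | None = None,
) -> pd.DataFrame:
    """Undirected edge list with TOM >= threshold, each pair once, annotated
    with node types (e.g. lncRNA / lipid-gene / other) for Cytoscape."""
    ids = list(ids)
    node_types = node_types or {}
    iu, ju = np.triu_indices(len(ids), k=1)
    mask = T[iu, ju] >= threshold
    return pd.DataFrame(
        {
            "source": [ids[i] for i in iu[mask]],
            "target": [ids[j] for j in ju[mask]],
            "tom": T[iu[mask], ju[mask]],
            "source_type": [node_types.get(ids[i], "other") for i in iu[mask]],
            "target_type": [node_types.get(ids[j], "other") for j in ju[mask]],
        }
    )


def lnc_lipid_partners(
    edges: pd.DataFrame, lnc_ids, lipid_ids, comparison: str = ""
) -> pd.DataFrame:
    """All (lncRNA, lipid-gene) pairs present in the thresholded edge list."""
    lnc = set(lnc_ids)
    lipid = set(lipid_ids)
    if lnc & lipid:
        raise ValueError("lncRNA and lipid-gene id sets must be disjoint")
    rows = []
    for _, e in edges.iterrows():
        s, t = e["source"], e["target"]
        pair = None
        if s in lnc and t in lipid:
            pair = (s, t)
        elif t in lnc and s in lipid:
            pair = (t, s)
        if pair:
            rows.append(
                {
                    "lncRNA": pair[0],
                    "lipid_gene": pair[1],
                    "tom": e["tom"],
                    "comparison": comparison,
                }
            )
    return pd.DataFrame(rows, columns=["lncRNA", "lipid_gene", "tom", "comparison"])


def deg_screen(
    expr: pd.DataFrame,
    groups: "pd.Series | dict",
    min_abs_log2fc: float = 1.0,
) -> list[str]:
    """Convenience screen: genes with |log2 fold change| >= threshold between
    the means of two sample groups (on FPKM + 1).

    This is a pre-filter for network construction, not a differential-
    expression test; proper DEG calling is expected upstream.
    """
    groups = pd.Series(groups)
    levels = sorted(groups.unique())
    if len(levels) != 2:
        raise ValueError(f"need exactly 2 groups, got {levels}")
    a = expr[groups[groups == levels[0]].index].mean(axis=1)
    b = expr[groups[groups == levels[1]].index].mean(axis=1)
    lfc = np.log2(b + 1.0) - np.log2(a + 1.0)
    return list(expr.index[np.abs(lfc) >= min_abs_log2fc])


# ---------------------------------------------------------------------------
# estimator
# ---------------------------------------------------------------------------


class CoexpressionNetwork(BaseEstimator):
    """Weighted coexpression network as an sklearn-style estimator.

    Parameters
    ----------
    beta : int or None
        Soft-thresholding power; when None it is chosen by scale-free fit.
    r2_target : float
        Scale-free fit target used when beta is None.
    min_module_size, cut_height : module detection parameters.
    signed : bool
        Signed adjacency ((1+r)/2)^beta instead of |r|^beta.
    log_transform : bool
        Apply log2(x + 1) to the expression values before correlating.
    tom_threshold : float
        TOM cutoff used by :meth:`edges`.

    Attributes (after ``fit``)
    --------------------------
    similarity_, adjacency_, tom_ : (n_genes, n_genes) arrays
    beta_ : the power actually used
    labels_ : module label per gene ("grey" = unassigned)
    modules_ : pd.Series mapping gene id -> label
    eigengenes_ : pd.DataFrame modules x samples
    """

    def __init__(
        self,
        beta: int | None = None,
        r2_target: float = 0.8,
        min_module_size: int = 30,
        cut_height: float = 0.995,
        signed: bool = False,
        log_transform: bool = True,
        tom_threshold: float = 0.08,
    ) -> None:
        self.beta = beta
        self.r2_target = r2_target
        self.min_module_size = min_module_size
        self.cut_height = cut_height
        self.signed = signed
        self.log_transform = log_transform
        self.tom_threshold = tom_threshold

    def fit(self, X, y=None):
        """Fit on a samples x genes matrix (DataFrame columns = gene ids)."""
        if isinstance(X, pd.DataFrame):
            self.gene_ids_ = list(X.columns)
            self.sample_ids_ = list(X.index)
            M = X.to_numpy(float)
        else:
            M = np.asarray(X, float)
            self.gene_ids_ = [f"g{i}" for i in range(M.shape[1])]
            self.sample_ids_ = [f"s{i}" for i in range(M.shape[0])]
        if M.ndim != 2 or M.shape[0] < 3:
            raise ValueError("need a samples x genes matrix with >= 3 samples")
        if self.log_transform:
            if (M < 0).any():
                raise ValueError("negative expression under log transform")
            M = np.log2(M + 1.0)
        expr = M.T  # genes x samples
        self.similarity_ = similarity(expr)
        self.beta_ = (
            int(self.beta)
            if self.beta is not None
            else pick_beta(
                self.similarity_, r2_target=self.r2_target, signed=self.signed
            )
        )
        self.adjacency_ = adjacency(self.similarity_, self.beta_, self.signed)
        self.tom_ = tom(self.adjacency_)
        self.labels_ = detect_modules(
            self.tom_, self.min_module_size, self.cut_height
        )
        self.modules_ = pd.Series(self.labels_, index=self.gene_ids_, name="module")
        egs = {}
        for mod in sorted(set(self.labels_) - {UNASSIGNED}):
            idx = np.nonzero(self.labels_ == mod)[0]
            if idx.size >= 2:
                egs[mod] = eigengene(expr[idx])
        self.eigengenes_ = pd.DataFrame(egs, index=self.sample_ids_).T
        self._expr_ = pd.DataFrame(
            expr, index=self.gene_ids_, columns=self.sample_ids_
        )
        return self

    def fit_transform(self, X, y=None) -> pd.DataFrame:
        """Fit and return the module eigengene matrix (samples x modules)."""
        return self.fit(X).eigengenes_.T

    def module_trait(self, traits: pd.DataFrame) -> pd.DataFrame:
        self._check_fitted()
        return module_trait(self.eigengenes_, traits)

    def gene_significance(self, trait: pd.Series) -> pd.DataFrame:
        self._check_fitted()
        gs = gene_significance(self._expr_, trait)
        mm = module_membership(self._expr_, self.eigengenes_, self.modules_)
        return pd.DataFrame(
            {"module": self.modules_, "GS": gs, "MM": mm}
        )

    def edges(self, node_types: dict[str, str] | None = None) -> pd.DataFrame:
        self._check_fitted()
        return export_edges(
            self.tom_, self.gene_ids_, self.tom_threshold, node_types
        )

    def _check_fitted(self) -> None:
        if not hasattr(self, "tom_"):
            raise RuntimeError("estimator is not fitted")
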