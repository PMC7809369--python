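"""Signed weighted co-expression network construction and module detection.

The network is built from Pearson correlations between gene profiles:
the signed similarity s_ij = (1 + cor_ij)/2 is raised to a
soft-thresholding power beta chosen so that the resulting weighted
network approximates scale-free topology. Gene pairs are then compared
through the topological overlap measure (TOM), which rewards shared
neighbourhoods as well as direct adjacency, and modules are the
branches of an average-linkage dendrogram of the TOM dissimilarity.
Each module is summarised by its eigengene — the first singular vector
over samples of the standardised module submatrix — and every gene
receives a module-membership centrality kME, its correlation with each
eigengene. Modules whose eigengenes are nearly collinear are merged.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform
from sklearn.base import BaseEstimator, ClusterMixin

from .containers import ExpressionMatrix, ModuleSet

__all__ = [
    "MODULE_COLORS",
    "SoftThresholdReport",
    "signed_adjacency",
    "scale_free_fit",
    "pick_soft_threshold",
    "tom_matrix",
    "ModuleDetector",
    "detect_modules",
]

#: size-ordered module colour palette (conventional labels)
MODULE_COLORS = (
    "turquoise", "blue", "brown", "yellow", "green", "red", "black",
    "pink", "magenta", "purple", "greenyellow", "tan", "salmon", "cyan",
    "midnightblue", "lightcyan", "grey60", "lightgreen", "lightyellow",
    "royalblue", "darkred", "darkgreen", "darkturquoise", "darkgrey",
    "orange", "darkorange", "white", "skyblue", "saddlebrown", "steelblue",
    "paleturquoise", "violet", "darkolivegreen", "darkmagenta",
)


@dataclass
class SoftThresholdReport:
    """Scale-free fit and mean connectivity per candidate power."""

    powers: list[int]
    fit_r2: dict[int, float]
    mean_connectivity: dict[int, float]
    chosen_power: int


def signed_adjacency(X: np.ndarray, power: int | float) -> np.ndarray:
    """Signed adjacency ((1 + cor)/2)^power for genes × samples ``X``.

    Constant gene rows have undefined correlation and raise.
    """
    X = np.asarray(X, dtype=float)
    sd = X.std(axis=1)
    if np.any(sd == 0):
        bad = list(np.where(sd == 0)[0][:5])
        raise ValueError(f"constant gene rows (undefined correlation) at indices {bad}")
    cor = np.corrcoef(X)
    adj = ((1.0 + cor) / 2.0) ** power
    np.fill_diagonal(adj, 1.0)
    return adj


def scale_free_fit(connectivity: np.ndarray, n_bins: int = 10) -> tuple[float, float]:
    """Signed R² of the log–log degree-distribution regression.

    Connectivities are split into ``n_bins`` equal-occupancy bins;
    log10 mean frequency is regressed on log10 mean connectivity. The
    returned fit index is R² multiplied by the negative of the slope's
    sign, so a decaying (scale-free-like) degree distribution scores
    positively. Also returns the slope.
    """
    k = np.asarray(connectivity, dtype=float)
    k = k[np.isfinite(k)]
    edges = np.quantile(k, np.linspace(0, 1, n_bins + 1))
    edges = np.unique(edges)
    if len(edges) < 3:
        return 0.0, 0.0
    idx = np.clip(np.searchsorted(edges, k, side="right") - 1, 0, len(edges) - 2)
    mean_k, freq = [], []
    for b in range(len(edges) - 1):
        mask = idx == b
        width = edges[b + 1] - edges[b]
        if mask.sum() == 0 or width <= 0:
            continue
        mk = k[mask].mean()
        if mk <= 0:
            continue
        mean_k.append(mk)
        # equal-occupancy bins: the density estimate is count/(n·width)
        freq.append(mask.sum() / (len(k) * width))
    if len(mean_k) < 3:
        return 0.0, 0.0
    x = np.log10(mean_k)
    y = np.log10(freq)
    slope, intercept = np.polyfit(x, y, 1)
    yhat = slope * x + intercept
    ss_res = np.sum((y - yhat) ** 2)
    ss_tot = np.sum((y - y.mean()) ** 2)
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 0.0
    return float(-np.sign(slope) * r2), float(slope)


def pick_soft_threshold(
    em: ExpressionMatrix | np.ndarray,
    powers=range(1, 31),
    r2_cut: float = 0.8,
) -> SoftThresholdReport:
    """Evaluate candidate soft-thresholding powers on the signed network.

    The chosen power is the smallest one whose scale-free fit index
    reaches ``r2_cut``; if none does, the power with the best fit is
    used instead.
    """
    X = em.values.values if isinstance(em, ExpressionMatrix) else np.asarray(em, float)
    if X.shape[0] < 2:
        raise ValueError("need at least 2 genes")
    if X.shape[1] < 20:
        warnings.warn("fewer than 20 samples: soft-threshold fit is unreliable", stacklevel=2)
    sd = X.std(axis=1)
    if np.any(sd == 0):
        bad = list(np.where(sd == 0)[0][:5])
        raise ValueError(f"constant gene rows (undefined correlation) at indices {bad}")
    cor = np.corrcoef(X)
    sim = (1.0 + cor) / 2.0
    np.fill_diagonal(sim, 0.0)
    powers = list(powers)
    fits: dict[int, float] = {}
    meank: dict[int, float] = {}
    for beta in powers:
        k = (sim**beta).sum(axis=1)
        fits[beta] = scale_free_fit(k)[0]
        meank[beta] = float(k.mean())
    chosen = next((b for b in powers if fits[b] >= r2_cut), None)
    if chosen is None:
        chosen = max(powers, key=lambda b: fits[b])
    if max(fits.values()) < 0.1:
        warnings.warn(
            "degenerate connectivity distribution: no power achieves a "
            "meaningful scale-free fit", stacklevel=2,
        )
    return SoftThresholdReport(powers, fits, meank, chosen)


def tom_matrix(adjacency: np.ndarray) -> np.ndarray:
    """Topological overlap ω_ij = (ℓ_ij + a_ij) / (min(k_i,k_j) + 1 − a_ij).

    ℓ_ij sums adjacency products over shared neighbours u ∉ {i, j};
    connectivity k excludes the diagonal. ω is symmetric with unit
    diagonal and values in [0, 1].
    """
    A = np.asarray(adjacency, dtype=float)
    if A.ndim != 2 or A.shape[0] != A.shape[1]:
        raise ValueError("adjacency must be square")
    if not np.allclose(A, A.T, atol=1e-10):
        raise ValueError("adjacency must be symmetric")
    if A.min() < -1e-12 or A.max() > 1 + 1e-12:
        raise ValueError("adjacency values must lie in [0, 1]")
    A = A.copy()
    np.fill_diagonal(A, 0.0)
    L = A @ A  # (i,j) entry sums over u≠i,j because diag(A)=0
    k = A.sum(axis=1)
    denom = np.minimum.outer(k, k) + 1.0 - A
    with np.errstate(invalid="ignore", divide="ignore"):
        omega = (L + A) / denom
    omega[~np.isfinite(omega)] = 0.0
    omega = np.clip((omega + omega.T) / 2.0, 0.0, 1.0)
    np.fill_diagonal(omega, 1.0)
    return omega


def _eigengene(Z: np.ndarray) -> np.ndarray:
    """First right singular vector over samples of a z-scored block,
    oriented to correlate non-negatively with the mean profile."""
    _, _, vt = np.linalg.svd(Z, full_matrices=False)
    v = vt[0]
    mean_profile = Z.mean(axis=0)
    if np.dot(v, mean_profile) < 0:
        v = -v
    return v


def _zscore_rows(X: np.ndarray) -> np.ndarray:
    mu = X.mean(axis=1, keepdims=True)
    sd = X.std(axis=1, keepdims=True)
    sd[sd == 0] = 1.0
    return (X - mu) / sd


class ModuleDetector(ClusterMixin, BaseEstimator):
    """Cluster genes into co-expression modules (sklearn-style).

    Unlike most sklearn clusterers this groups the *columns* of ``X``
    (shape n_samples × n_genes), in the spirit of
    :class:`sklearn.cluster.FeatureAgglomeration`: genes are the
    objects being clustered, samples provide the observations.

    Parameters
    ----------
    power : soft-thresholding power for the signed adjacency.
    min_module_size : smallest branch size kept as a module; smaller
        branches are pooled into "grey".
    merge_cut : modules whose eigengene dissimilarity 1 − cor falls
        below this value are merged iteratively.
    cut_height : static cut on the average-linkage dendrogram of the
        TOM dissimilarity, expressed as a fraction of the dendrogram's
        maximum merge height. A relative cut keeps the branch/noise
        separation stable across noise levels and soft-threshold
        powers, where any fixed absolute height is brittle (the
        all-noise merges concentrate just below a data-dependent top).

    Attributes
    ----------
    labels_ : colour label per gene ("grey" = unassigned).
    eigengenes_ : module × sample array, unit-norm rows.
    kme_ : gene × module correlation with the eigengenes.
    module_names_ : ordered module labels (largest first).
    """

    def __init__(
        self,
        power: int = 6,
        min_module_size: int = 30,
        merge_cut: float = 0.3,
        cut_height: float = 0.9,
    ):
        self.power = power
        self.min_module_size = min_module_size
        self.merge_cut = merge_cut
        self.cut_height = cut_height

    def fit(self, X, y=None):
        X = np.asarray(X, dtype=float)
        if X.ndim != 2:
            raise ValueError("X must be 2-D (samples × genes)")
        n_samples, n_genes = X.shape
        if n_samples < 3:
            raise ValueError("eigengenes require at least 3 samples")
        if n_genes < self.min_module_size:
            raise ValueError("fewer genes than min_module_size")
        G = X.T  # genes × samples
        adj = signed_adjacency(G, self.power)
        tom = tom_matrix(adj)
        diss = 1.0 - tom
        np.fill_diagonal(diss, 0.0)
        Zlink = linkage(squareform(diss, checks=False), method="average")
        flat = fcluster(Zlink, t=self.cut_height * Zlink[:, 2].max(), criterion="distance")

        labels = self._assign_colors(flat)
        Z = _zscore_rows(G)
        labels, eig, names = self._merge_modules(Z, labels)
        kme = self._kme(Z, eig)

        self.labels_ = np.asarray(labels, dtype=object)
        self.eigengenes_ = eig
        self.module_names_ = names
        self.kme_ = kme
        self.linkage_ = Zlink
        self.tom_ = tom
        return self

    def _assign_colors(self, flat: np.ndarray) -> np.ndarray:
        ids, counts = np.unique(flat, return_counts=True)
        keep = ids[counts >= self.min_module_size]
        # size-ordered colours; ties resolved by first gene position
        first_pos = {i: int(np.argmax(flat == i)) for i in keep}
        order = sorted(keep, key=lambda i: (-counts[ids == i][0], first_pos[i]))
        colour_of = {i: MODULE_COLORS[r % len(MODULE_COLORS)] for r, i in enumerate(order)}
        return np.array([colour_of.get(c, "grey") for c in flat], dtype=object)

    def _module_eigengenes(self, Z: np.ndarray, labels: np.ndarray):
        names = [c for c in pd.unique(labels) if c != "grey"]
        sizes = {c: int((labels == c).sum()) for c in names}
        names.sort(key=lambda c: (-sizes[c], MODULE_COLORS.index(c) if c in MODULE_COLORS else 999))
        eig = np.stack([_eigengene(Z[labels == c]) for c in names]) if names else np.empty((0, Z.shape[1]))
        return names, eig

    def _merge_modules(self, Z: np.ndarray, labels: np.ndarray):
        labels = labels.copy()
        while True:
            names, eig = self._module_eigengenes(Z, labels)
            if len(names) < 2:
                return labels, eig, names
            cor = np.corrcoef(eig)
            diss = 1.0 - cor
            np.fill_diagonal(diss, np.inf)
            i, j = np.unravel_index(np.argmin(diss), diss.shape)
            if diss[i, j] >= self.merge_cut:
                return labels, eig, names
            a, b = sorted((i, j))  # absorb into the larger (earlier-ordered) module
            labels[labels == names[b]] = names[a]

    @staticmethod
    def _kme(Z: np.ndarray, eig: np.ndarray) -> np.ndarray:
        if eig.shape[0] == 0:
            return np.empty((Z.shape[0], 0))
        n = Z.shape[1]
        Zn = Z / np.sqrt((Z**2).sum(axis=1, keepdims=True))
        En = eig - eig.mean(axis=1, keepdims=True)
        En = En / np.sqrt((En**2).sum(axis=1, keepdims=True))
        return np.clip(Zn @ En.T, -1.0, 1.0)

    def fit_predict(self, X, y=None):
        return self.fit(X).labels_


def detect_modules(
    em: ExpressionMatrix,
    power: int,
    min_module_size: int = 30,
    merge_cut: float = 0.3,
    cut_height: float = 0.9,
) -> ModuleSet:
    """Detect, label and merge co-expression modules; see :class:`ModuleDetector`."""
    det = ModuleDetector(
        power=power,
        min_module_size=min_module_size,
        merge_cut=merge_cut,
        cut_height=cut_height,
    ).fit(em.values.values.T)
    assignment = pd.Series(det.labels_, index=em.values.index, name="module")
    eigengenes = pd.DataFrame(det.eigengenes_, index=det.module_names_, columns=em.sample_ids)
    kme = pd.DataFrame(det.kme_, index=em.values.index, columns=det.module_names_)
    return ModuleSet(assignment=assignment, eigengenes=eigengenes, kme=kme)
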