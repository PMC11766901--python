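"""Distance-based and rank-based comparison of fungal communities.

Composition differences between sample groups (host species, parish,
lesion type) are tested with one-factor PERMANOVA on Bray-Curtis
dissimilarities of square-root-transformed counts, preceded by a
homogeneity-of-dispersion check (PERMDISP: ANOVA on distances to group
centroids in principal-coordinate space, permutation p-value).  Univariate
per-sample quantities (richness, diversity indices) are compared with the
Kruskal-Wallis test and Dunn's pairwise post-hoc z with Bonferroni
correction.  Host-level assemblage profiles are clustered with UPGMA on
Euclidean distances; the cophenetic correlation measures how faithfully
the dendrogram represents the distances.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from scipy.spatial.distance import pdist, squareform

from .core_data import CommunityMatrix
from .fingerprint import Dendrogram, SimilarityMatrix, upgma

DEFAULT_MIN_RECORDS = 5   # samples with fewer records are too sparse to compare


@dataclass
class DistanceMatrix:
    labels: list[str]
    D: np.ndarray
    metric: str

    def __post_init__(self) -> None:
        self.D = np.asarray(self.D, dtype=float)
        if self.D.shape != (len(self.labels),) * 2:
            raise ValueError("distance matrix shape does not match labels")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.D, index=self.labels, columns=self.labels)


@dataclass
class PermanovaResult:
    factor: str
    df_among: int
    df_within: int
    pseudo_F: float
    R2: float
    p: float
    n_perm: int
    seed: int


def filter_min_records(matrix: CommunityMatrix,
                       min_records: int = DEFAULT_MIN_RECORDS) -> CommunityMatrix:
    """Drop samples with fewer than min_records records before testing."""
    keep = matrix.counts.sum(axis=1) >= min_records
    if not keep.any():
        raise ValueError(f"no samples with >= {min_records} records")
    return CommunityMatrix(counts=matrix.counts.loc[keep], rank=matrix.rank)


def bray_curtis(matrix: CommunityMatrix, transform: str = "sqrt") -> DistanceMatrix:
    """Bray-Curtis dissimilarity between samples.

    transform: 'sqrt' (default; damps dominant taxa) or 'none'."""
    X = matrix.counts.to_numpy(dtype=float)
    zero = X.sum(axis=1) == 0
    if zero.any():
        bad = [matrix.sample_ids[i] for i in np.nonzero(zero)[0]]
        raise ValueError(f"all-zero samples have undefined distance: {bad}")
    if transform == "sqrt":
        X = np.sqrt(X)
    elif transform != "none":
        raise ValueError("transform must be 'sqrt' or 'none'")
    D = squareform(pdist(X, metric="braycurtis"))
    return DistanceMatrix(labels=matrix.sample_ids, D=D, metric="bray_curtis")


# ---------------------------------------------------------------------------
# PERMANOVA (Anderson's distance-based decomposition)
# ---------------------------------------------------------------------------

def _ss_total(D2: np.ndarray) -> float:
    n = D2.shape[0]
    return float(D2[np.triu_indices(n, 1)].sum() / n)


def _ss_within(D2: np.ndarray, codes: np.ndarray, n_groups: int) -> float:
    ss = 0.0
    for g in range(n_groups):
        idx = np.nonzero(codes == g)[0]
        sub = D2[np.ix_(idx, idx)]
        ss += sub[np.triu_indices(len(idx), 1)].sum() / len(idx)
    return float(ss)


def permanova(D: DistanceMatrix, groups: Mapping[str, str] | pd.Series,
              n_perm: int = 999, seed: int = 0,
              factor: str = "group", exhaustive: bool = False) -> PermanovaResult:
    """One-factor PERMANOVA: pseudo-F from among/within sums of squared
    distances, p-value by free permutation of sample labels (equivalent to
    residual permutation for a single factor).

    groups maps sample label -> group level; every group needs >= 2 samples.
    With exhaustive=True all distinct label arrangements are enumerated
    (exact p; only sensible for small n).
    """
    labels = D.labels
    g = pd.Series(groups).loc[labels]
    levels, codes = np.unique(g.to_numpy(), return_inverse=True)
    a = len(levels)
    if a < 2:
        raise ValueError("need at least 2 groups")
    sizes = np.bincount(codes)
    if (sizes < 2).any():
        small = [levels[i] for i in np.nonzero(sizes < 2)[0]]
        raise ValueError(f"singleton groups not allowed: {small}")
    n = len(labels)
    D2 = D.D ** 2
    ss_t = _ss_total(D2)
    ss_w = _ss_within(D2, codes, a)
    ss_a = ss_t - ss_w
    df_a, df_w = a - 1, n - a
    F_obs = (ss_a / df_a) / (ss_w / df_w)

    def perm_F(perm_codes: np.ndarray) -> float:
        ss_w_p = _ss_within(D2, perm_codes, a)
        return ((ss_t - ss_w_p) / df_a) / (ss_w_p / df_w)

    if exhaustive:
        from itertools import permutations as _perms
        seen = set()
        exceed = total = 0
        for perm in _perms(codes):
            if perm in seen:
                continue
            seen.add(perm)
            total += 1
            if perm_F(np.array(perm)) >= F_obs - 1e-12:
                exceed += 1
        p = exceed / total
        n_perm = total
    else:
        rng = np.random.default_rng(seed)
        exceed = 0
        for _ in range(n_perm):
            if perm_F(rng.permutation(codes)) >= F_obs:
                exceed += 1
        p = (exceed + 1) / (n_perm + 1)
    return PermanovaResult(factor=factor, df_among=df_a, df_within=df_w,
                           pseudo_F=float(F_obs), R2=float(ss_a / ss_t),
                           p=float(p), n_perm=n_perm, seed=seed)


def permanova_pairwise(D: DistanceMatrix, groups: Mapping[str, str] | pd.Series,
                       n_perm: int = 999, seed: int = 0) -> pd.DataFrame:
    """All pairwise PERMANOVAs with Bonferroni-adjusted p-values."""
    g = pd.Series(groups).loc[D.labels]
    levels = sorted(g.unique())
    pairs = list(combinations(levels, 2))
    rows = []
    for k, (la, lb) in enumerate(pairs):
        keep = g.isin([la, lb]).to_numpy()
        idx = np.nonzero(keep)[0]
        sub = DistanceMatrix(labels=[D.labels[i] for i in idx],
                             D=D.D[np.ix_(idx, idx)], metric=D.metric)
        res = permanova(sub, g[keep], n_perm=n_perm, seed=seed + k,
                        factor=f"{la} vs {lb}")
        rows.append({"group_a": la, "group_b": lb, "pseudo_F": res.pseudo_F,
                     "R2": res.R2, "p": res.p,
                     "p_bonferroni": min(res.p * len(pairs), 1.0)})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Homogeneity of multivariate dispersion (PERMDISP)
# ---------------------------------------------------------------------------

def _pcoa_coords(D: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Principal-coordinate embedding; returns (real-axis coords, imaginary-
    axis coords) from positive and negative eigenvalues respectively."""
    n = D.shape[0]
    J = np.eye(n) - np.ones((n, n)) / n
    B = -0.5 * J @ (D ** 2) @ J
    vals, vecs = np.linalg.eigh((B + B.T) / 2)
    order = np.argsort(vals)[::-1]
    vals, vecs = vals[order], vecs[:, order]
    tol = 1e-10 * max(abs(vals).max(), 1.0)
    pos = vals > tol
    neg = vals < -tol
    real = vecs[:, pos] * np.sqrt(vals[pos])
    imag = vecs[:, neg] * np.sqrt(-vals[neg])
    return real, imag


def dispersion_homogeneity(D: DistanceMatrix, groups: Mapping[str, str] | pd.Series,
                           n_perm: int = 999, seed: int = 0) -> tuple[float, float]:
    """PERMDISP: ANOVA F on sample distances to their group centroid in
    PCoA space, with a permutation p-value.

    Negative eigenvalues are handled by the imaginary-axis correction: the
    squared centroid distance is the real-part contribution minus the
    imaginary-part contribution (floored at 0 before the square root)."""
    g = pd.Series(groups).loc[D.labels]
    levels, codes = np.unique(g.to_numpy(), return_inverse=True)
    if len(levels) < 2:
        raise ValueError("need at least 2 groups")
    real, imag = _pcoa_coords(D.D)
    if real.size == 0 or np.allclose(D.D, 0):
        raise ValueError("degenerate distance matrix: all samples identical")

    def centroid_dists(codes_: np.ndarray) -> np.ndarray:
        z = np.empty(len(codes_))
        for gidx in range(len(levels)):
            idx = np.nonzero(codes_ == gidx)[0]
            cr = real[idx].mean(axis=0)
            d2 = ((real[idx] - cr) ** 2).sum(axis=1)
            if imag.size:
                ci = imag[idx].mean(axis=0)
                d2 = d2 - ((imag[idx] - ci) ** 2).sum(axis=1)
            z[idx] = np.sqrt(np.maximum(d2, 0.0))
        return z

    def anova_F(z: np.ndarray, codes_: np.ndarray) -> float:
        grand = z.mean()
        ss_a = sum(len(z[codes_ == i]) * (z[codes_ == i].mean() - grand) ** 2
                   for i in range(len(levels)))
        ss_w = sum(((z[codes_ == i] - z[codes_ == i].mean()) ** 2).sum()
                   for i in range(len(levels)))
        df_a, df_w = len(levels) - 1, len(z) - len(levels)
        if ss_w == 0:
            return np.inf
        return (ss_a / df_a) / (ss_w / df_w)

    z_obs = centroid_dists(codes)
    F_obs = anova_F(z_obs, codes)
    rng = np.random.default_rng(seed)
    exceed = 0
    for _ in range(n_perm):
        # permute the centroid-distance residuals across groups
        perm = rng.permutation(len(codes))
        if anova_F(z_obs[perm], codes) >= F_obs:
            exceed += 1
    p = (exceed + 1) / (n_perm + 1)
    return float(F_obs), float(p)


# ---------------------------------------------------------------------------
# Kruskal-Wallis + Dunn
# ---------------------------------------------------------------------------

def kruskal_dunn(values: Mapping[str, float] | pd.Series,
                 groups: Mapping[str, str] | pd.Series) -> tuple[float, float, pd.DataFrame]:
    """Tie-corrected Kruskal-Wallis H with Dunn pairwise post-hoc tests.

    Returns (H, p, table); the Dunn table has pairwise z, raw two-sided p,
    and Bonferroni-adjusted p (multiplier = number of pairs)."""
    v = pd.Series(values)
    g = pd.Series(groups).loc[v.index]
    levels = sorted(g.unique())
    if len(levels) < 2:
        raise ValueError("need at least 2 groups")
    samples = [v[g == lev].to_numpy() for lev in levels]
    flat = v.to_numpy()
    if np.ptp(flat) == 0:
        raise ValueError("all values tied: H undefined")
    H, p = stats.kruskal(*samples)

    # Dunn: mean ranks on the pooled ranking with tie-corrected variance
    ranks = stats.rankdata(flat)
    n = len(flat)
    _, tie_counts = np.unique(flat, return_counts=True)
    tie_term = (tie_counts ** 3 - tie_counts).sum() / (12.0 * (n - 1))
    mean_rank = {lev: ranks[(g == lev).to_numpy()].mean() for lev in levels}
    sizes = {lev: int((g == lev).sum()) for lev in levels}
    pairs = list(combinations(levels, 2))
    rows = []
    for la, lb in pairs:
        se = np.sqrt((n * (n + 1) / 12.0 - tie_term)
                     * (1.0 / sizes[la] + 1.0 / sizes[lb]))
        z = (mean_rank[la] - mean_rank[lb]) / se
        praw = 2 * stats.norm.sf(abs(z))
        rows.append({"group_a": la, "group_b": lb, "z": float(z),
                     "p": float(praw),
                     "p_bonferroni": float(min(praw * len(pairs), 1.0))})
    return float(H), float(p), pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Host-level hierarchical clustering
# ---------------------------------------------------------------------------

def host_hca(profiles: pd.DataFrame) -> tuple[Dendrogram, float]:
    """UPGMA of host assemblage profiles on Euclidean distance.

    profiles: hosts x taxa table (e.g. AO percentages).  Returns the
    dendrogram (heights on the 100 - distance pseudo-similarity scale used
    by the shared UPGMA machinery) and the cophenetic correlation c between
    original and dendrogram-implied distances."""
    if profiles.shape[0] < 3:
        raise ValueError("need at least 3 hosts to cluster")
    D = squareform(pdist(profiles.to_numpy(dtype=float), metric="euclidean"))
    sim = SimilarityMatrix(labels=list(profiles.index), S_pct=100.0 - D)
    dend = upgma(sim)
    coph = 100.0 - dend.cophenetic_similarity().S_pct
    iu = np.triu_indices(len(D), 1)
    if np.ptp(D[iu]) == 0 or np.ptp(coph[iu]) == 0:
        c = 1.0 if np.allclose(D[iu], coph[iu]) else 0.0
    else:
        c = float(np.corrcoef(D[iu], coph[iu])[0, 1])
    return dend, c
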