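"""Fingerprint similarity, UPGMA dendrograms, cut-off taxonomy, and the IRC.

MSP-PCR genomic fingerprints are densitometric band-intensity vectors over
uniform base-pair bins (200-3500 bp).  Percent similarity between two
profiles is 100 x the Pearson correlation of their intensity vectors.
Profiles from two primers (csM13 and (GTG)5) are combined into a consensus
similarity matrix, clustered with UPGMA, and the dendrogram is cut at fixed
percent-similarity levels to delineate taxa:

* 65% -> clusters of fungal genera
* 75% -> MOTUs (molecular operational taxonomic units; species proxy)
* 85% -> genomic types (GTs; strain proxy)
* 95% -> reproducibility limit: pairs above it are indistinguishable, and
  same-genus pairs from the same lesion above it count as redundant
  isolations of one organism (isolation redundancy coefficient, IRC).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter1d

PRIMERS = ("csM13", "GTG5")
GENUS_CUTOFF = 65.0
MOTU_CUTOFF = 75.0
GT_CUTOFF = 85.0
REPRODUCIBILITY_CUTOFF = 95.0


# ---------------------------------------------------------------------------
# Profiles and similarity
# ---------------------------------------------------------------------------

@dataclass
class FingerprintProfile:
    """One record's band-intensity vector for one primer."""

    record_id: str
    primer: str
    intensities: np.ndarray
    is_duplicate_of: str | None = None   # set on re-run profiles of a record

    def __post_init__(self) -> None:
        self.intensities = np.asarray(self.intensities, dtype=float)
        if (self.intensities < 0).any():
            raise ValueError(f"negative band intensity in profile {self.record_id}")


@dataclass
class SimilarityMatrix:
    """Symmetric percent-similarity matrix (Pearson r x 100, diagonal 100)."""

    labels: list[str]
    S_pct: np.ndarray

    def __post_init__(self) -> None:
        self.S_pct = np.asarray(self.S_pct, dtype=float)
        n = len(self.labels)
        if self.S_pct.shape != (n, n):
            raise ValueError("similarity matrix shape does not match labels")

    def value(self, a: str, b: str) -> float:
        i, j = self.labels.index(a), self.labels.index(b)
        return float(self.S_pct[i, j])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.S_pct, index=self.labels, columns=self.labels)


def smooth_profiles(profiles: Sequence[FingerprintProfile],
                    bandwidth: float = 1.0) -> list[FingerprintProfile]:
    """Optional Gaussian curve smoothing of densitometric traces (bins)."""
    return [
        FingerprintProfile(p.record_id, p.primer,
                           gaussian_filter1d(p.intensities, sigma=bandwidth),
                           p.is_duplicate_of)
        for p in profiles
    ]


def pearson_similarity(profiles: Sequence[FingerprintProfile]) -> SimilarityMatrix:
    """Percent similarity matrix: S[i, j] = 100 x corr(x_i, x_j).

    All profiles must be from one primer and share the bin grid.  A profile
    with zero variance has no defined correlation and raises an error.
    """
    if len(profiles) < 2:
        raise ValueError("need at least 2 profiles")
    primers = {p.primer for p in profiles}
    if len(primers) > 1:
        raise ValueError(f"profiles mix primers: {sorted(primers)}")
    lengths = {len(p.intensities) for p in profiles}
    if len(lengths) > 1:
        raise ValueError("profiles do not share a common bin grid")
    X = np.vstack([p.intensities for p in profiles])
    sd = X.std(axis=1)
    flat = [p.record_id for p, s in zip(profiles, sd) if s == 0]
    if flat:
        raise ValueError(f"zero-variance profiles (no bands): {flat}")
    S = 100.0 * np.corrcoef(X)
    np.fill_diagonal(S, 100.0)
    return SimilarityMatrix(labels=[p.record_id for p in profiles], S_pct=S)


def consensus_similarity(sim_a: SimilarityMatrix,
                         sim_b: SimilarityMatrix) -> SimilarityMatrix:
    """Element-wise mean of two primers' similarity matrices.

    This is the composite-experiment analogue: averaging preserves the order
    of similarities from each primer and lets bands resolved by either
    primer contribute to discrimination.
    """
    if sim_a.labels != sim_b.labels:
        if set(sim_a.labels) != set(sim_b.labels):
            raise ValueError("similarity matrices cover different records")
        order = [sim_b.labels.index(l) for l in sim_a.labels]
        sim_b = SimilarityMatrix(labels=sim_a.labels,
                                 S_pct=sim_b.S_pct[np.ix_(order, order)])
    return SimilarityMatrix(labels=list(sim_a.labels),
                            S_pct=(sim_a.S_pct + sim_b.S_pct) / 2.0)


# ---------------------------------------------------------------------------
# UPGMA on percent similarity
# ---------------------------------------------------------------------------

@dataclass
class Dendrogram:
    """UPGMA tree with merge heights on the percent-similarity scale.

    merges[k] = (left, right, similarity, size) in scipy linkage convention:
    ids < n are leaves; id n + k is the cluster created by merge k.  Heights
    are non-increasing from 100 at the leaves (ultrametric).
    """

    labels: list[str]
    merges: np.ndarray   # (n-1, 4): left id, right id, merge similarity, size

    @property
    def n_leaves(self) -> int:
        return len(self.labels)

    def linkage(self) -> np.ndarray:
        """scipy-style linkage matrix on the dissimilarity scale d = 100 - S."""
        Z = self.merges.copy()
        Z[:, 2] = 100.0 - Z[:, 2]
        return Z

    def cophenetic_similarity(self) -> SimilarityMatrix:
        """Pairwise similarity implied by the tree (the merge height joining
        each leaf pair)."""
        n = self.n_leaves
        members: dict[int, list[int]] = {i: [i] for i in range(n)}
        C = np.full((n, n), 100.0)
        for k, (a, b, s, _size) in enumerate(self.merges):
            la, lb = members.pop(int(a)), members.pop(int(b))
            for i in la:
                for j in lb:
                    C[i, j] = C[j, i] = s
            members[n + k] = la + lb
        return SimilarityMatrix(labels=list(self.labels), S_pct=C)

    def to_newick(self) -> str:
        """Newick with branch lengths on the dissimilarity scale (100 - S)."""
        n = self.n_leaves
        height: dict[int, float] = {i: 0.0 for i in range(n)}
        node: dict[int, str] = {i: self.labels[i] for i in range(n)}
        for k, (a, b, s, _size) in enumerate(self.merges):
            a, b = int(a), int(b)
            h = 100.0 - s
            la = h - height[a]
            lb = h - height[b]
            node[n + k] = f"({node[a]}:{la:.6g},{node[b]}:{lb:.6g})"
            height[n + k] = h
        return node[n + len(self.merges) - 1] + ";"


def upgma(sim: SimilarityMatrix) -> Dendrogram:
    """Average-linkage agglomerative clustering of a percent-similarity matrix.

    Works on the dissimilarity d = 100 - S (range 0-200 since negative
    Pearson similarities are kept).  When several pairs tie at the minimum
    dissimilarity the pair whose smallest member labels sort first is merged,
    which makes the topology deterministic.
    """
    n = len(sim.labels)
    if n < 2:
        raise ValueError("need at least 2 leaves to cluster")
    work = 100.0 - sim.S_pct.astype(float)
    work = (work + work.T) / 2.0     # enforce exact symmetry
    np.fill_diagonal(work, np.inf)
    # row r of `work` represents cluster row_id[r]; merged-away rows are inf
    row_id = np.arange(n)
    sizes = np.ones(n)
    minlabel = [sim.labels[i] for i in range(n)]      # per row, for tie-breaks
    merges = np.zeros((n - 1, 4))
    for step in range(n - 1):
        d_min = work.min()
        ti, tj = np.nonzero(work == d_min)
        # lexicographically smallest member-label pair among ties
        best = None
        for i, j in zip(ti, tj):
            if i >= j:
                continue
            key = tuple(sorted((minlabel[i], minlabel[j])))
            if best is None or key < best[0]:
                best = (key, int(i), int(j))
        _, ra, rb = best
        na, nb = sizes[ra], sizes[rb]
        merges[step] = (row_id[ra], row_id[rb], 100.0 - d_min, na + nb)
        # average-linkage update: d(new, k) = (na d(a,k) + nb d(b,k)) / (na+nb)
        alive = np.isfinite(work).any(axis=1)
        alive[[ra, rb]] = False
        new_row = (na * work[ra] + nb * work[rb]) / (na + nb)
        work[ra, alive] = new_row[alive]
        work[alive, ra] = new_row[alive]
        work[rb, :] = np.inf
        work[:, rb] = np.inf
        work[ra, ra] = np.inf
        row_id[ra] = n + step
        sizes[ra] = na + nb
        minlabel[ra] = min(minlabel[ra], minlabel[rb])
    return Dendrogram(labels=list(sim.labels), merges=merges)


def cut_clusters(dend: Dendrogram, threshold_pct: float) -> dict[str, int]:
    """Partition leaves: two leaves share a cluster iff their cophenetic
    similarity >= threshold.  Returns label -> cluster index (0-based,
    ordered by first appearance)."""
    if not (0 < threshold_pct <= 100):
        raise ValueError("threshold must be in (0, 100]")
    n = dend.n_leaves
    members: dict[int, list[int]] = {i: [i] for i in range(n)}
    comp = {i: i for i in range(n)}
    for k, (a, b, s, _size) in enumerate(dend.merges):
        la, lb = members.pop(int(a)), members.pop(int(b))
        if s >= threshold_pct:
            target = comp[la[0]]
            for leaf in la + lb:
                comp[leaf] = target
        members[n + k] = la + lb
    # relabel components in order of first leaf
    out: dict[str, int] = {}
    relabel: dict[int, int] = {}
    for i in range(n):
        c = comp[i]
        if c not in relabel:
            relabel[c] = len(relabel)
        out[dend.labels[i]] = relabel[c]
    return out


@dataclass
class TaxonomyAssignment:
    """Nested genus-cluster / MOTU / GT partition from one dendrogram."""

    genus_cluster: dict[str, int]
    motu: dict[str, int]
    gt: dict[str, int]

    def to_frame(self) -> pd.DataFrame:
        labels = list(self.genus_cluster)
        return pd.DataFrame({
            "record_id": labels,
            "genus_cluster": [f"G{self.genus_cluster[l]:03d}" for l in labels],
            "motu_id": [f"MOTU{self.motu[l]:04d}" for l in labels],
            "gt_id": [f"GT{self.gt[l]:04d}" for l in labels],
        })


def assign_taxonomy(dend: Dendrogram,
                    genus_cutoff: float = GENUS_CUTOFF,
                    motu_cutoff: float = MOTU_CUTOFF,
                    gt_cutoff: float = GT_CUTOFF) -> TaxonomyAssignment:
    """Cut one consensus dendrogram at the three taxonomy cut-off levels.

    Because all three partitions cut the same ultrametric tree they are
    nested: same GT => same MOTU => same genus cluster.
    """
    if not (genus_cutoff < motu_cutoff < gt_cutoff):
        raise ValueError("cutoffs must increase: genus < motu < gt")
    return TaxonomyAssignment(
        genus_cluster=cut_clusters(dend, genus_cutoff),
        motu=cut_clusters(dend, motu_cutoff),
        gt=cut_clusters(dend, gt_cutoff),
    )


# ---------------------------------------------------------------------------
# Reproducibility and redundancy
# ---------------------------------------------------------------------------

def reproducibility_cutoff(
    duplicate_pairs: Mapping[str, Sequence[tuple[FingerprintProfile, FingerprintProfile]]],
    conservative_level: float = REPRODUCIBILITY_CUTOFF,
) -> dict[str, float]:
    """Per-primer mean duplicate similarity and the overall/conservative cutoff.

    duplicate_pairs maps primer -> list of (original run, repeated run).
    The overall cutoff is the mean of the per-primer means; the conservative
    cutoff floors it to the declared conservative level (95 by default) and
    is the threshold above which two profiles cannot be told apart.
    """
    per_primer: dict[str, float] = {}
    for primer, pairs in duplicate_pairs.items():
        if not pairs:
            raise ValueError(f"no duplicate pairs for primer {primer}")
        sims = []
        for orig, rerun in pairs:
            x, y = orig.intensities, rerun.intensities
            if x.std() == 0 or y.std() == 0:
                raise ValueError(f"zero-variance duplicate profile for {orig.record_id}")
            sims.append(100.0 * float(np.corrcoef(x, y)[0, 1]))
        per_primer[primer] = float(np.mean(sims))
    overall = float(np.mean(list(per_primer.values())))
    return {**per_primer, "overall": overall, "conservative": conservative_level}


def irc(records: pd.DataFrame, similarity: SimilarityMatrix,
        threshold_pct: float = REPRODUCIBILITY_CUTOFF) -> tuple[float, list[str]]:
    """Isolation redundancy coefficient.

    Records of the same genus isolated from the same lesion whose pairwise
    (consensus) similarity is >= the reproducibility threshold are taken to
    be re-isolations of one organism.  Within each (genus, sample) group the
    >= threshold pairs form a graph; each connected component of size k
    contributes k - 1 redundant records (transitive redundancy is counted
    once).  Returns (IRC percent, redundant record ids).
    """
    idx = {label: i for i, label in enumerate(similarity.labels)}
    missing = [r for r in records["record_id"] if r not in idx]
    if missing:
        raise ValueError(f"records without fingerprint similarity: {missing[:5]}")
    redundant: list[str] = []
    for (_genus, _sample), group in records.groupby(["genus", "sample_id"], sort=True):
        ids = list(group["record_id"])
        if len(ids) < 2:
            continue
        # union-find over >= threshold pairs
        parent = {r: r for r in ids}

        def find(r: str) -> str:
            while parent[r] != r:
                parent[r] = parent[parent[r]]
                r = parent[r]
            return r

        for i in range(len(ids)):
            for j in range(i + 1, len(ids)):
                if similarity.S_pct[idx[ids[i]], idx[ids[j]]] >= threshold_pct:
                    parent[find(ids[i])] = find(ids[j])
        comps: dict[str, list[str]] = {}
        for r in ids:
            comps.setdefault(find(r), []).append(r)
        for comp in comps.values():
            if len(comp) > 1:
                redundant.extend(sorted(comp)[1:])
    total = len(records)
    pct = 100.0 * len(redundant) / total if total else 0.0
    return pct, sorted(redundant)


def irc_percent(n_redundant: int, n_records: int) -> float:
    """IRC from pre-counted totals: 100 x redundant / total records."""
    if n_records <= 0:
        raise ValueError("total records must be positive")
    return 100.0 * n_redundant / n_records


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

def read_fingerprints(path) -> dict[str, list[FingerprintProfile]]:
    """Wide TSV (record_id, primer, is_duplicate_of, bin_0001...) -> profiles
    grouped by primer."""
    df = pd.read_csv(path, sep="\t")
    bins = [c for c in df.columns if c.startswith("bin_")]
    out: dict[str, list[FingerprintProfile]] = {}
    for _, row in df.iterrows():
        dup = row.get("is_duplicate_of")
        dup = None if pd.isna(dup) else str(dup)
        out.setdefault(row["primer"], []).append(
            FingerprintProfile(str(row["record_id"]), row["primer"],
                               row[bins].to_numpy(dtype=float), dup))
    return out


def write_fingerprints(profiles: Iterable[FingerprintProfile], path) -> None:
    rows = []
    for p in profiles:
        row = {"record_id": p.record_id, "primer": p.primer,
               "is_duplicate_of": p.is_duplicate_of if p.is_duplicate_of else ""}
        row.update({f"bin_{i + 1:04d}": v for i, v in enumerate(p.intensities)})
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)
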