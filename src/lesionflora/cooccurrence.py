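"""Probabilistic pairwise taxon co-occurrence (exact hypergeometric model).

For two taxa occupying n1 and n2 of M samples, the number of jointly
occupied samples j under random, independent placement follows the
hypergeometric distribution

    P(j) = C(n1, j) C(M - n1, n2 - j) / C(M, n2).

The observed overlap j_obs is compared with its exact tails:
p_gt = P(j >= j_obs) and p_lt = P(j <= j_obs), both inclusive of the
observed value.  A pair is *positive* when p_gt < alpha, *negative* when
p_lt < alpha, *random* otherwise; pairs whose expected overlap
n1 n2 / M falls below a threshold (1 sample by default) are *filtered*
out as having too little occurrence data to test.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats

from .core_data import CommunityMatrix

CLASSES = ("positive", "negative", "random", "filtered")


@dataclass
class CoocPair:
    taxon_a: str
    taxon_b: str
    n1: int
    n2: int
    M: int
    j_obs: int
    expected: float
    p_lt: float
    p_gt: float
    cls: str


def incidence_from_matrix(matrix: CommunityMatrix) -> pd.DataFrame:
    """Binary presence matrix (count > 0) with the same labels."""
    return (matrix.counts > 0).astype(int)


def pair_distribution(M: int, n1: int, n2: int) -> tuple[np.ndarray, np.ndarray]:
    """Exact distribution of the shared-sample count j.

    Returns (support, probabilities) with support
    j = max(0, n1 + n2 - M) .. min(n1, n2)."""
    if not (0 <= n1 <= M and 0 <= n2 <= M):
        raise ValueError("need 0 <= n1, n2 <= M")
    lo = max(0, n1 + n2 - M)
    hi = min(n1, n2)
    j = np.arange(lo, hi + 1)
    # hypergeometric: draw n2 samples, count how many hit the n1 occupied ones
    probs = stats.hypergeom.pmf(j, M, n1, n2)
    return j, probs


def pair_tails(M: int, n1: int, n2: int, j_obs: int) -> tuple[float, float]:
    """(p_lt, p_gt): inclusive lower and upper exact tail probabilities."""
    dist = stats.hypergeom(M, n1, n2)
    p_lt = float(dist.cdf(j_obs))
    p_gt = float(dist.sf(j_obs - 1))
    return p_lt, p_gt


def analyze_pairs(incidence: pd.DataFrame, expected_threshold: float = 1.0,
                  alpha: float = 0.05, bh_correct: bool = False
                  ) -> tuple[list[CoocPair], pd.DataFrame]:
    """Test all C(T, 2) taxon pairs; returns (pairs, class-count summary).

    bh_correct applies a Benjamini-Hochberg adjustment to the smaller tail
    p-values before classification (off by default, matching the model's
    standard usage without multiplicity correction)."""
    taxa = list(incidence.columns)
    if len(taxa) < 2:
        raise ValueError("need at least 2 taxa")
    inc = incidence.to_numpy() > 0
    M = inc.shape[0]
    occ = inc.sum(axis=0)
    joint = inc.T.astype(int) @ inc.astype(int)
    pairs: list[CoocPair] = []
    for i, j in combinations(range(len(taxa)), 2):
        n1, n2 = int(occ[i]), int(occ[j])
        j_obs = int(joint[i, j])
        expected = n1 * n2 / M
        p_lt, p_gt = pair_tails(M, n1, n2, j_obs)
        if expected < expected_threshold:
            cls = "filtered"
        else:
            cls = "pending"
        pairs.append(CoocPair(taxa[i], taxa[j], n1, n2, M, j_obs,
                              expected, p_lt, p_gt, cls))
    testable = [p for p in pairs if p.cls == "pending"]
    if bh_correct and testable:
        pvals = np.array([min(p.p_lt, p.p_gt) for p in testable])
        order = np.argsort(pvals)
        adj = np.empty_like(pvals)
        m = len(pvals)
        running = 1.0
        for rank_pos in range(m - 1, -1, -1):
            idx = order[rank_pos]
            running = min(running, pvals[idx] * m / (rank_pos + 1))
            adj[idx] = running
        for p, a in zip(testable, adj):
            direction = "pos" if p.p_gt <= p.p_lt else "neg"
            if a < alpha:
                p.cls = "positive" if direction == "pos" else "negative"
            else:
                p.cls = "random"
    else:
        for p in testable:
            if p.p_gt < alpha:
                p.cls = "positive"
            elif p.p_lt < alpha:
                p.cls = "negative"
            else:
                p.cls = "random"
    summary = summarize_pairs(pairs)
    return pairs, summary


def summarize_pairs(pairs: list[CoocPair]) -> pd.DataFrame:
    """Counts and percentages per classification."""
    total = len(pairs)
    unfiltered = sum(1 for p in pairs if p.cls != "filtered")
    rows = []
    for cls in CLASSES:
        n = sum(1 for p in pairs if p.cls == cls)
        base = total if cls == "filtered" else unfiltered
        rows.append({"class": cls, "n_pairs": n,
                     "pct": 100.0 * n / base if base else 0.0})
    rows.append({"class": "total", "n_pairs": total, "pct": 100.0})
    rows.append({"class": "unfiltered", "n_pairs": unfiltered,
                 "pct": 100.0 * unfiltered / total if total else 0.0})
    return pd.DataFrame(rows)


def per_taxon_summary(pairs: list[CoocPair]) -> pd.DataFrame:
    """Per-taxon percentage of its unfiltered pairs in each class.

    Taxa whose pairs were all filtered are flagged (undefined proportions)."""
    taxa: dict[str, dict[str, int]] = {}
    for p in pairs:
        for t in (p.taxon_a, p.taxon_b):
            d = taxa.setdefault(t, {c: 0 for c in CLASSES})
            d[p.cls] += 1
    rows = []
    for t, d in sorted(taxa.items()):
        unfiltered = d["positive"] + d["negative"] + d["random"]
        row = {"taxon": t, "n_pairs": sum(d.values()), "n_unfiltered": unfiltered,
               "all_filtered": unfiltered == 0}
        for cls in ("positive", "negative", "random"):
            row[f"pct_{cls}"] = 100.0 * d[cls] / unfiltered if unfiltered else float("nan")
        rows.append(row)
    return pd.DataFrame(rows)


def pairs_to_frame(pairs: list[CoocPair]) -> pd.DataFrame:
    return pd.DataFrame([{
        "taxon_a": p.taxon_a, "taxon_b": p.taxon_b, "n1": p.n1, "n2": p.n2,
        "M": p.M, "j_obs": p.j_obs, "expected": p.expected,
        "p_lt": p.p_lt, "p_gt": p.p_gt, "class": p.cls,
    } for p in pairs])
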