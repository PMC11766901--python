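"""Abundance/frequency measures and classical diversity indices.

All statistics operate on per-taxon record counts n_i (i = 1..S taxa,
N = total records) and, for incidence-based quantities, the number of
samples m in which each taxon occurred:

* AO, abundance of occurrence  = 100 n_i / N (percent of all records)
* FO, frequency of occurrence  = 100 k_i / m (percent of samples occupied)
* Simpson complement           1 - sum n_i (n_i - 1) / (N (N - 1))
* Shannon H' (common log)      -sum p_i log10 p_i, evenness J' = H'/log10 S
* Fisher's logseries alpha     alpha = N (1 - x)/x with x solving
                               S/N = [(1 - x)/x] [-ln(1 - x)]
* Margalef (S - 1)/ln N and Menhinick S/sqrt(N) richness indices
* IR, isolation rate           records per sample

Shannon is computed with the common logarithm (base 10), so H'max = log10 S
and J' is in [0, 1].
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import optimize, stats

FREQUENCY_GROUPS = ("very frequent", "frequent", "infrequent", "rare")


def abundance_of_occurrence(n_i: int, N: int) -> float:
    """AO percent: share of all fungal records belonging to one taxon."""
    if N <= 0:
        raise ValueError("total records N must be positive")
    if not (0 <= n_i <= N):
        raise ValueError("need 0 <= n_i <= N")
    return 100.0 * n_i / N


def frequency_of_occurrence(k_samples: int, m_samples: int) -> float:
    """FO percent: share of samples in which a taxon occurred."""
    if m_samples <= 0:
        raise ValueError("number of samples m must be positive")
    if not (0 <= k_samples <= m_samples):
        raise ValueError("need 0 <= k <= m")
    return 100.0 * k_samples / m_samples


def classify_frequency(ao_pct: float) -> str:
    """Abundance class from AO: rare (0, 1], infrequent (1, 2],
    frequent (2, 5], very frequent (5, 100].  Boundaries belong to the
    lower class, matching the ">2-5%" style of the class definitions."""
    if not (0 <= ao_pct <= 100):
        raise ValueError("AO percent must be in [0, 100]")
    if ao_pct > 5:
        return "very frequent"
    if ao_pct > 2:
        return "frequent"
    if ao_pct > 1:
        return "infrequent"
    return "rare"


def simpson(counts: Sequence[int]) -> float:
    """Simpson diversity in complement form: 1 - sum n_i(n_i-1) / (N(N-1)).

    Probability that two records drawn without replacement belong to
    different taxa; increases with diversity."""
    n = np.asarray(counts, dtype=float)
    n = n[n > 0]
    N = n.sum()
    if N < 2:
        raise ValueError("Simpson index needs N >= 2 records")
    return float(1.0 - (n * (n - 1)).sum() / (N * (N - 1)))


def shannon(counts: Sequence[int]) -> float:
    """Shannon diversity H' in common-log (base 10) units."""
    n = np.asarray(counts, dtype=float)
    n = n[n > 0]
    if n.sum() <= 0:
        raise ValueError("need at least one record")
    p = n / n.sum()
    return float(-(p * np.log10(p)).sum())


def evenness(h_prime: float, S: int) -> float:
    """Shannon evenness J' = H'/log10 S (H'max for S taxa)."""
    if S < 2:
        raise ValueError("evenness undefined for S < 2")
    return h_prime / np.log10(S)


def fisher_alpha(S: int, N: int, tol: float = 1e-10) -> tuple[float, float]:
    """Fisher's logseries alpha and its nuisance parameter x.

    Solves S/N = [(1 - x)/x] [-ln(1 - x)] for x in (0, 1) by bracketed
    root-finding, then alpha = N (1 - x)/x.  Requires 1 <= S < N (with
    S = N every record is a singleton and the series degenerates)."""
    if not (1 <= S < N):
        raise ValueError("fisher_alpha requires 1 <= S < N")
    target = S / N

    def g(x: float) -> float:
        return (1.0 - x) / x * (-np.log1p(-x)) - target

    # g is decreasing in x: g -> 1 - S/N > 0 as x -> 0+, -> -S/N < 0 as x -> 1-
    x = optimize.brentq(g, 1e-12, 1.0 - 1e-12, xtol=tol)
    alpha = N * (1.0 - x) / x
    return float(alpha), float(x)


def margalef(S: int, N: int) -> float:
    """Margalef richness D_Mg = (S - 1)/ln N."""
    if N < 2:
        raise ValueError("Margalef index needs N >= 2")
    return float((S - 1) / np.log(N))


def menhinick(S: int, N: int) -> float:
    """Menhinick richness D_Mn = S/sqrt(N)."""
    if N < 1:
        raise ValueError("Menhinick index needs N >= 1")
    return float(S / np.sqrt(N))


def isolation_rate(n_records: int, n_samples: int) -> float:
    """IR: fungal records per sample examined."""
    if n_samples <= 0:
        raise ValueError("number of samples must be positive")
    return n_records / n_samples


@dataclass
class DiversityProfile:
    """The battery of indices for one community."""

    S: int
    N: int
    D: float
    H: float
    J: float
    alpha: float
    x: float
    D_Mg: float
    D_Mn: float
    IR: float

    def to_series(self) -> pd.Series:
        return pd.Series({
            "S": self.S, "N": self.N, "D": self.D, "H_prime": self.H,
            "J_prime": self.J, "alpha": self.alpha, "x": self.x,
            "D_Mg": self.D_Mg, "D_Mn": self.D_Mn, "IR": self.IR,
        })


def diversity_profile(counts: Sequence[int], n_samples: int) -> DiversityProfile:
    """All indices for one community's taxon count vector."""
    n = np.asarray(counts, dtype=float)
    n = n[n > 0]
    S, N = int(len(n)), int(n.sum())
    h = shannon(n)
    alpha, x = fisher_alpha(S, N) if S < N else (float("inf"), 1.0)
    return DiversityProfile(
        S=S, N=N, D=simpson(n), H=h, J=evenness(h, S) if S >= 2 else float("nan"),
        alpha=alpha, x=x, D_Mg=margalef(S, N), D_Mn=menhinick(S, N),
        IR=isolation_rate(N, n_samples),
    )


def frequency_table(counts: pd.Series, incidence: pd.Series, m_samples: int,
                    motus_per_taxon: Mapping[str, int] | None = None) -> pd.DataFrame:
    """Per-taxon AO, FO and frequency group, ordered by descending AO."""
    N = int(counts.sum())
    rows = []
    for taxon in counts.index:
        ao = abundance_of_occurrence(int(counts[taxon]), N)
        fo = frequency_of_occurrence(int(incidence[taxon]), m_samples)
        row = {"taxon": taxon, "n_records": int(counts[taxon]), "AO": ao,
               "FO": fo, "frequency_group": classify_frequency(ao)}
        if motus_per_taxon is not None:
            row["n_MOTUs"] = motus_per_taxon.get(taxon, 0)
        rows.append(row)
    table = pd.DataFrame(rows).sort_values(
        ["AO", "taxon"], ascending=[False, True]).reset_index(drop=True)
    return table


def ao_fo_correlation(freq_table: pd.DataFrame) -> tuple[float, float, int]:
    """Tie-corrected Spearman correlation between AO and FO.

    Returns (rho, p-value, degrees of freedom n - 2)."""
    if len(freq_table) < 3:
        raise ValueError("need at least 3 taxa")
    ao = freq_table["AO"].to_numpy()
    fo = freq_table["FO"].to_numpy()
    if np.ptp(ao) == 0 or np.ptp(fo) == 0:
        raise ValueError("constant AO or FO column: correlation undefined")
    rho, p = stats.spearmanr(ao, fo)
    return float(rho), float(p), len(freq_table) - 2


def taxa_overlap(taxa_by_host: Mapping[str, Sequence[str]]) -> pd.DataFrame:
    """Venn-style overlap: taxa present in exactly each subset of hosts.

    Returns one row per non-empty host combination with the count of taxa
    whose host set is exactly that combination and its percentage of the
    union of all taxa."""
    if len(taxa_by_host) < 2:
        raise ValueError("need at least 2 host sets")
    hosts = sorted(taxa_by_host)
    sets = {h: set(taxa_by_host[h]) for h in hosts}
    union = set().union(*sets.values())
    total = len(union)
    rows = []
    for r in range(1, len(hosts) + 1):
        for combo in combinations(hosts, r):
            inside = set.intersection(*(sets[h] for h in combo))
            outside = set().union(*(sets[h] for h in hosts if h not in combo)) \
                if len(combo) < len(hosts) else set()
            exact = inside - outside
            rows.append({
                "hosts": "+".join(combo), "n_hosts": r, "n_taxa": len(exact),
                "pct_of_union": 100.0 * len(exact) / total if total else 0.0,
            })
    return pd.DataFrame(rows)


def shared_fraction(taxa_by_host: Mapping[str, Sequence[str]]) -> tuple[int, int, float]:
    """Taxa shared by *all* hosts: (shared count, union size, percent)."""
    sets = [set(v) for v in taxa_by_host.values()]
    union = set().union(*sets)
    shared = set.intersection(*sets)
    pct = 100.0 * len(shared) / len(union) if union else 0.0
    return len(shared), len(union), pct
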