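"""Accumulation curves, nonparametric richness estimators, asymptote fits.

Extrapolated taxon richness is estimated three ways, as is usual for
incompletely sampled communities:

* abundance-based estimators from the rare tail of the frequency counts
  f_k (taxa with exactly k records): Chao1 and ACE;
* incidence-based estimators from the counts Q_k of taxa present in
  exactly k samples: first/second-order jackknife and the bootstrap;
* the asymptote of nonlinear models fitted to the sample-based
  accumulation curve (asymptotic regression, logistic, Lomolino,
  Michaelis-Menten, Weibull), selected by AICc/BIC with the > 2 rule.

Chao1 uses the (N-1)/N small-sample multiplier:
Shat = S_obs + ((N-1)/N) f1^2 / (2 f2), with the f1(f1-1)/2 fallback when
f2 = 0.  Estimator uncertainty is obtained by bootstrap over samples.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .core_data import AbundanceVector, CommunityMatrix
from .sad_models import ic_weights


@dataclass
class RichnessEstimate:
    estimator: str
    S_hat: float
    SE: float = float("nan")
    CI95: tuple[float, float] = (float("nan"), float("nan"))

    def to_series(self) -> pd.Series:
        return pd.Series({"estimator": self.estimator, "S_hat": self.S_hat,
                          "SE": self.SE, "CI_lo": self.CI95[0], "CI_hi": self.CI95[1]})


@dataclass
class AccumulationCurve:
    """Mean taxon count (with percentile CI) after m of M samples."""

    m: np.ndarray
    mean_richness: np.ndarray
    ci_low: np.ndarray
    ci_high: np.ndarray
    n_permutations: int
    seed: int


# ---------------------------------------------------------------------------
# Accumulation curve
# ---------------------------------------------------------------------------

def accumulation_curve(matrix: CommunityMatrix, n_perm: int = 1000,
                       seed: int = 0) -> AccumulationCurve:
    """Randomised sample-based accumulation: mean cumulative richness over
    permuted sample orders, with 2.5/97.5 percentile bounds."""
    presence = (matrix.counts.to_numpy() > 0)
    M, T = presence.shape
    if M < 2:
        raise ValueError("need at least 2 samples")
    rng = np.random.default_rng(seed)
    rich = np.empty((n_perm, M))
    for p in range(n_perm):
        order = rng.permutation(M)
        seen = np.cumsum(presence[order], axis=0) > 0
        rich[p] = seen.sum(axis=1)
    return AccumulationCurve(
        m=np.arange(1, M + 1),
        mean_richness=rich.mean(axis=0),
        ci_low=np.percentile(rich, 2.5, axis=0),
        ci_high=np.percentile(rich, 97.5, axis=0),
        n_permutations=n_perm, seed=seed,
    )


# ---------------------------------------------------------------------------
# Nonparametric estimators (point formulas)
# ---------------------------------------------------------------------------

def chao1(S_obs: int, f1: int, f2: int, N: int, variant: str = "small_sample") -> float:
    """Chao1 lower-bound richness estimator.

    small_sample (default): S + ((N-1)/N) f1^2/(2 f2);
    classic: S + f1^2/(2 f2).  When f2 = 0 the f1(f1-1)/2 fallback is used
    (bias-corrected form)."""
    if f1 < 0 or f2 < 0 or S_obs < 0:
        raise ValueError("counts must be non-negative")
    corr = (N - 1) / N if variant == "small_sample" else 1.0
    if f2 > 0:
        return S_obs + corr * f1 ** 2 / (2 * f2)
    return S_obs + corr * f1 * (f1 - 1) / 2.0


def ace(f: Mapping[int, int], rare_cutoff: int = 10) -> float:
    """Abundance-based coverage estimator.

    f maps abundance k -> number of taxa with k records.  Taxa with
    k <= rare_cutoff are 'rare'; sample coverage C = 1 - f1/N_rare;
    Shat = S_abund + S_rare/C + (f1/C) gamma^2 with the usual squared
    coefficient of variation gamma^2 (floored at 0)."""
    f1 = f.get(1, 0)
    S_rare = sum(v for k, v in f.items() if 1 <= k <= rare_cutoff)
    S_abund = sum(v for k, v in f.items() if k > rare_cutoff)
    N_rare = sum(k * v for k, v in f.items() if 1 <= k <= rare_cutoff)
    if S_rare == 0:
        return float(S_abund)
    if N_rare == f1:
        # all rare taxa are singletons: coverage 0, fall back to Chao1
        N = sum(k * v for k, v in f.items())
        return chao1(S_abund + S_rare, f1, f.get(2, 0), N)
    C = 1.0 - f1 / N_rare
    ssum = sum(k * (k - 1) * v for k, v in f.items() if 1 <= k <= rare_cutoff)
    gamma2 = max((S_rare / C) * ssum / (N_rare * (N_rare - 1)) - 1.0, 0.0)
    return S_abund + S_rare / C + (f1 / C) * gamma2


def jackknife(S_obs: int, Q1: int, Q2: int, m: int) -> tuple[float, float]:
    """First- and second-order jackknife from incidence uniques/duplicates."""
    if m < 2:
        raise ValueError("need m >= 2 samples")
    jack1 = S_obs + Q1 * (m - 1) / m
    jack2 = S_obs + Q1 * (2 * m - 3) / m - Q2 * (m - 2) ** 2 / (m * (m - 1))
    return jack1, jack2


def bootstrap_richness(incidence_props: Sequence[float], m: int) -> float:
    """Smith & van Belle bootstrap: S + sum_i (1 - p_i)^m over observed taxa,
    p_i = fraction of samples occupied by taxon i."""
    p = np.asarray(incidence_props, dtype=float)
    if ((p <= 0) | (p > 1)).any():
        raise ValueError("incidence proportions must be in (0, 1]")
    return float(len(p) + ((1 - p) ** m).sum())


# ---------------------------------------------------------------------------
# Estimates with bootstrap uncertainty
# ---------------------------------------------------------------------------

def _estimates_from_matrix(matrix: CommunityMatrix) -> dict[str, float]:
    av = AbundanceVector.from_matrix(matrix)
    counts = av.counts.to_numpy()
    f = {int(k): int(v) for k, v in zip(*np.unique(counts, return_counts=True))}
    Q1, Q2 = av.Q(1), av.Q(2)
    m = av.m
    j1, j2 = jackknife(av.S, Q1, Q2, m)
    props = av.incidence.to_numpy() / m
    return {
        "chao1": chao1(av.S, av.f(1), av.f(2), av.N),
        "ace": ace(f),
        "jack1": j1,
        "jack2": j2,
        "bootstrap": bootstrap_richness(props, m),
    }


def richness_estimates(matrix: CommunityMatrix, n_boot: int = 200,
                       seed: int = 0) -> list[RichnessEstimate]:
    """All nonparametric estimators with SE/CI from a bootstrap over samples."""
    point = _estimates_from_matrix(matrix)
    rng = np.random.default_rng(seed)
    M = matrix.n_samples
    boot: dict[str, list[float]] = {k: [] for k in point}
    for _ in range(n_boot):
        rows = rng.integers(0, M, size=M)
        resampled = CommunityMatrix(
            counts=matrix.counts.iloc[rows].reset_index(drop=True)
            .rename(index=lambda i: f"b{i}"),
            rank=matrix.rank)
        try:
            est = _estimates_from_matrix(resampled)
        except ValueError:
            continue
        for k, v in est.items():
            boot[k].append(v)
    out = []
    for name, s_hat in point.items():
        draws = np.asarray(boot[name])
        se = float(draws.std(ddof=1)) if len(draws) > 1 else float("nan")
        ci = (float(np.percentile(draws, 2.5)), float(np.percentile(draws, 97.5))) \
            if len(draws) > 1 else (float("nan"), float("nan"))
        out.append(RichnessEstimate(name, float(s_hat), se, ci))
    return out


# ---------------------------------------------------------------------------
# Asymptotic curve fitting
# ---------------------------------------------------------------------------

def _asymptotic_regression(m, a, b, c):
    return a - (a - b) * np.exp(-c * m)


def _logistic(m, a, b, c):
    return a / (1.0 + np.exp((b - m) / c))


def _lomolino(m, a, b, c):
    return a / (1.0 + b ** np.log(c / m))


def _michaelis_menten(m, a, b):
    return a * m / (b + m)


def _weibull(m, a, b, c):
    return a * (1.0 - np.exp(-b * m ** c))


_CURVES: dict[str, tuple[Callable, Callable]] = {
    # model -> (function, self-start from (m, S) data); asymptote = param a
    "asymptotic_regression": (_asymptotic_regression,
                              lambda m, s: (1.1 * s[-1], max(s[0], 1e-3), 0.1)),
    "logistic": (_logistic, lambda m, s: (1.1 * s[-1], np.median(m), m[-1] / 4)),
    "lomolino": (_lomolino, lambda m, s: (1.1 * s[-1], 2.0, np.median(m))),
    "michaelis_menten": (_michaelis_menten, lambda m, s: (1.1 * s[-1], np.median(m))),
    "weibull": (_weibull, lambda m, s: (1.1 * s[-1], s[0] / max(s[-1], 1.0), 1.0)),
}


def fit_asymptotic_models(curve: AccumulationCurve,
                          models: Sequence[str] = tuple(_CURVES)) -> pd.DataFrame:
    """Nonlinear least-squares fit of accumulation-curve models.

    Returns one row per converged model with its parameters, asymptote
    (the limiting-richness parameter a), residual-based gaussian logLik,
    AICc/BIC (n = number of curve points), chi-squared GOF p, and
    Delta/weight columns with the > 2 best-model rule."""
    m = curve.m.astype(float)
    s = curve.mean_richness
    if len(m) < 5:
        raise ValueError("need an accumulation curve with >= 5 points")
    rows = []
    for name in models:
        func, start = _CURVES[name]
        p0 = start(m, s)
        try:
            popt, _ = optimize.curve_fit(func, m, s, p0=p0, maxfev=20000)
        except (RuntimeError, ValueError):
            continue
        pred = func(m, *popt)
        resid = s - pred
        n, k = len(m), len(popt)
        sigma2 = float((resid ** 2).mean())
        if sigma2 <= 0:
            sigma2 = 1e-12
        ll = -0.5 * n * (np.log(2 * np.pi * sigma2) + 1.0)
        kk = k + 1     # + residual variance
        aicc = -2 * ll + 2 * kk + (2 * kk * (kk + 1) / (n - kk - 1) if n - kk - 1 > 0 else np.inf)
        bic = -2 * ll + kk * np.log(n)
        with np.errstate(divide="ignore", invalid="ignore"):
            chi2 = float(np.nansum(resid ** 2 / np.where(pred > 0, pred, np.nan)))
        dof = max(n - k, 1)
        rows.append({"model": name, "params": tuple(float(v) for v in popt),
                     "asymptote": float(popt[0]), "logLik": ll, "AICc": aicc,
                     "BIC": bic, "chi2_stat": chi2,
                     "chi2_p": float(stats.chi2.sf(chi2, dof))})
    if not rows:
        raise RuntimeError("no asymptotic model converged")
    table = pd.DataFrame(rows)
    table["dAICc"] = table["AICc"] - table["AICc"].min()
    table["dBIC"] = table["BIC"] - table["BIC"].min()
    table["w_AICc"] = ic_weights(table["dAICc"].to_numpy())
    table["w_BIC"] = ic_weights(table["dBIC"].to_numpy())
    order = table["AICc"].sort_values().index
    best = np.zeros(len(table), dtype=bool)
    if len(order) == 1 or table.loc[order[1], "AICc"] - table.loc[order[0], "AICc"] > 2:
        best[table.index.get_loc(order[0])] = True
    table["best_AICc"] = best
    return table.sort_values("AICc").reset_index(drop=True)


def abundance_cv(counts: Sequence[int], sample_sd: bool = False) -> float:
    """Coefficient of variation of taxon abundances: sd/mean.

    Zero only when all taxa are equally abundant (homogeneous assemblage)."""
    n = np.asarray(counts, dtype=float)
    n = n[n > 0]
    if len(n) < 2:
        raise ValueError("CV needs at least 2 taxa")
    mean = n.mean()
    if mean == 0:
        raise ValueError("zero mean abundance")
    sd = n.std(ddof=1 if sample_sd else 0)
    return float(sd / mean)
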