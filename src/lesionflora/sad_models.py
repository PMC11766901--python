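"""Species-abundance-distribution models, goodness of fit, model selection.

Five classical SAD models are fitted by maximum likelihood to the vector of
per-taxon record counts (the MOTU or genus abundance distribution):

* logseries      — P(n) = -x^n / (n ln(1-x)), one parameter x in (0, 1);
                   Fisher's alpha = N (1 - x)/x
* lognormal      — continuous lognormal density on untransformed abundances
                   (mu, sigma on the log scale)
* geometric      — Motomura's geometric series: rank i receives a share
                   proportional to k (1 - k)^(i-1); multinomial likelihood
                   over ranks, one parameter k
* broken stick   — MacArthur's model, no free parameters: expected share of
                   rank i is (1/S) sum_{j=i..S} 1/j
* neutral (mZSM) — metacommunity zero-sum multinomial: expected number of
                   species of abundance n proportional to
                   (theta/n)(1 - n/J)^(theta-1); the biodiversity number
                   theta is fitted and the zero-sum size J is pinned to N
                   (charged as two data-determined quantities in the ICs)

Goodness of fit uses Pearson chi-squared over Preston doubling octaves
(1, 2-3, 4-7, ...; classes pooled right-to-left until each expected count
is >= 1) and a Kolmogorov-Smirnov comparison of the empirical and model
abundance CDFs.  Strength of fit uses AICc (small-sample n = S, the number
of taxa) and BIC, with Akaike/Schwarz weights; a model is flagged best only
when the gap to the runner-up exceeds 2.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .diversity import fisher_alpha

MODELS = ("logseries", "lognormal", "geometric", "broken_stick", "neutral_mzsm")


@dataclass
class RankAbundance:
    """Per-taxon counts sorted from most to least abundant."""

    counts: np.ndarray

    def __post_init__(self) -> None:
        c = np.asarray(self.counts, dtype=int)
        c = c[c > 0]
        if len(c) == 0:
            raise ValueError("empty abundance vector")
        self.counts = np.sort(c)[::-1]

    @property
    def S(self) -> int:
        return int(len(self.counts))

    @property
    def N(self) -> int:
        return int(self.counts.sum())


@dataclass
class SADFit:
    """Result of one model's maximum-likelihood fit."""

    model: str
    params: dict
    logLik: float
    k: int                      # number of free parameters
    S: int
    N: int
    chi2_stat: float = float("nan")
    chi2_p: float = float("nan")
    ks_stat: float = float("nan")
    ks_p: float = float("nan")

    @property
    def AICc(self) -> float:
        n = self.S
        penalty = 2 * self.k * (self.k + 1) / (n - self.k - 1) if n - self.k - 1 > 0 else np.inf
        return -2 * self.logLik + 2 * self.k + penalty

    @property
    def BIC(self) -> float:
        return -2 * self.logLik + self.k * np.log(self.S)


# ---------------------------------------------------------------------------
# Model likelihoods
# ---------------------------------------------------------------------------

def _logseries_loglik(counts: np.ndarray, x: float) -> float:
    return float(np.sum(np.log(stats.logser.pmf(counts, x))))


def fit_logseries(ra: RankAbundance, tie_to_sn: bool = False) -> SADFit:
    """ML logseries fit; by default x is free, optionally tied to (S, N)
    through the Fisher relation (the two coincide: the ML estimate of x
    solves the same equation)."""
    if ra.S < 2:
        raise ValueError("logseries fit needs S >= 2")
    if ra.S == ra.N:
        raise ValueError("all-singleton community: logseries boundary (x -> 0)")
    if tie_to_sn:
        alpha, x = fisher_alpha(ra.S, ra.N)
    else:
        res = optimize.minimize_scalar(
            lambda x: -_logseries_loglik(ra.counts, x),
            bounds=(1e-9, 1 - 1e-9), method="bounded",
            options={"xatol": 1e-12})
        x = float(res.x)
        alpha = ra.N * (1 - x) / x
    return SADFit(model="logseries", params={"x": x, "alpha": alpha},
                  logLik=_logseries_loglik(ra.counts, x), k=1, S=ra.S, N=ra.N)


def fit_lognormal(ra: RankAbundance) -> SADFit:
    """ML continuous lognormal on untransformed abundances."""
    if ra.S < 3:
        raise ValueError("lognormal fit needs S >= 3")
    logs = np.log(ra.counts.astype(float))
    mu = float(logs.mean())
    sigma = float(logs.std())          # population sd = ML estimate
    if sigma < 1e-9:
        raise ValueError("degenerate lognormal fit: all abundances equal (sigma -> 0)")
    ll = float(stats.lognorm.logpdf(ra.counts, s=sigma, scale=np.exp(mu)).sum())
    return SADFit(model="lognormal", params={"mu": mu, "sigma": sigma},
                  logLik=ll, k=2, S=ra.S, N=ra.N)


def geometric_shares(k: float, S: int) -> np.ndarray:
    """Normalised expected share of each rank under the geometric series."""
    i = np.arange(S)
    w = k * (1 - k) ** i
    return w / w.sum()


def _rank_loglik(counts: np.ndarray, shares: np.ndarray) -> float:
    """Multinomial log-likelihood of ranked counts given rank shares
    (without the count-invariant multinomial coefficient)."""
    return float(np.sum(counts * np.log(shares)))


def fit_geometric(ra: RankAbundance) -> SADFit:
    """ML geometric series: one dominance parameter k in (0, 1)."""
    if ra.S < 2:
        raise ValueError("geometric fit needs S >= 2")
    res = optimize.minimize_scalar(
        lambda k: -_rank_loglik(ra.counts, geometric_shares(k, ra.S)),
        bounds=(1e-9, 1 - 1e-9), method="bounded", options={"xatol": 1e-12})
    k = float(res.x)
    return SADFit(model="geometric", params={"k": k},
                  logLik=_rank_loglik(ra.counts, geometric_shares(k, ra.S)),
                  k=1, S=ra.S, N=ra.N)


def broken_stick_expected(S: int, N: int) -> np.ndarray:
    """Expected abundance of each rank: E[n_i] = (N/S) sum_{j=i..S} 1/j."""
    if S < 1:
        raise ValueError("S must be >= 1")
    inv = 1.0 / np.arange(1, S + 1)
    tail = np.cumsum(inv[::-1])[::-1]      # sum_{j=i..S} 1/j
    return N / S * tail


def fit_broken_stick(ra: RankAbundance) -> SADFit:
    """Broken stick has no free parameters; likelihood is the multinomial
    over ranks with the model's fixed shares."""
    if ra.S < 2:
        raise ValueError("broken stick fit needs S >= 2")
    shares = broken_stick_expected(ra.S, 1)    # N = 1 -> shares sum to 1
    return SADFit(model="broken_stick", params={},
                  logLik=_rank_loglik(ra.counts, shares), k=0, S=ra.S, N=ra.N)


def mzsm_pmf(theta: float, J: int) -> np.ndarray:
    """Normalised mZSM species-abundance pmf over n = 1..J-1."""
    n = np.arange(1, J)
    with np.errstate(divide="ignore"):
        logw = np.log(theta) - np.log(n) + (theta - 1) * np.log1p(-n / J)
    w = np.exp(logw - logw.max())
    return w / w.sum()


def fit_neutral_mzsm(ra: RankAbundance) -> SADFit:
    """ML metacommunity zero-sum multinomial.

    Theta (the fundamental biodiversity number) is fitted by 1-D ML; the
    zero-sum community size J is pinned to the observed total N.  The
    information criteria charge the model k = 2 data-determined quantities
    (theta and J), the accounting used for neutral-model fits in community
    SAD comparisons; this matters because the mZSM approaches the
    logseries as J grows and the two otherwise tie."""
    if ra.S < 2:
        raise ValueError("mZSM fit needs S >= 2")
    J = ra.N
    counts = ra.counts

    def nll(log_theta: float) -> float:
        pmf = mzsm_pmf(np.exp(log_theta), J)
        with np.errstate(divide="ignore"):
            ll = np.log(pmf[counts - 1])
        ll[~np.isfinite(ll)] = -745.0      # observed count of probability ~0
        return -float(ll.sum())

    res = optimize.minimize_scalar(nll, bounds=(np.log(1e-3), np.log(1e6)),
                                   method="bounded", options={"xatol": 1e-10})
    if not res.success:
        raise RuntimeError(f"mZSM optimiser failed: {res.message}")
    theta = float(np.exp(res.x))
    return SADFit(model="neutral_mzsm", params={"theta": theta, "J": J},
                  logLik=-float(res.fun), k=2, S=ra.S, N=ra.N)


_FITTERS = {
    "logseries": fit_logseries,
    "lognormal": fit_lognormal,
    "geometric": fit_geometric,
    "broken_stick": fit_broken_stick,
    "neutral_mzsm": fit_neutral_mzsm,
}


def fit_all(ra: RankAbundance, models=MODELS, gof: bool = True) -> list[SADFit]:
    fits = []
    for m in models:
        fit = _FITTERS[m](ra)
        if gof:
            goodness_of_fit(ra, fit)
        fits.append(fit)
    return fits


# ---------------------------------------------------------------------------
# Goodness of fit
# ---------------------------------------------------------------------------

def octave_edges(max_count: int) -> np.ndarray:
    """Preston doubling class lower edges 1, 2, 4, 8, ... covering max_count."""
    n_oct = int(np.ceil(np.log2(max_count + 1))) if max_count >= 1 else 1
    return 2 ** np.arange(max(n_oct, 2) + 1)    # upper edge beyond max


def _model_abundance_cdf(fit: SADFit):
    """Model CDF over abundance n, as (support, cdf) arrays."""
    S, N = fit.S, fit.N
    if fit.model == "logseries":
        n = np.arange(1, N + 1)
        pmf = stats.logser.pmf(n, fit.params["x"])
        pmf = pmf / pmf.sum()
        return n, np.cumsum(pmf)
    if fit.model == "neutral_mzsm":
        pmf = mzsm_pmf(fit.params["theta"], N)
        n = np.arange(1, N)
        return n, np.cumsum(pmf)
    if fit.model == "lognormal":
        n = np.arange(1, N + 1)
        dist = stats.lognorm(s=fit.params["sigma"], scale=np.exp(fit.params["mu"]))
        cdf = dist.cdf(n)
        return n, cdf / cdf[-1]
    # rank models: CDF = fraction of ranks with predicted abundance <= n
    if fit.model == "geometric":
        pred = fit.N * geometric_shares(fit.params["k"], S)
    else:
        pred = broken_stick_expected(S, N)
    n = np.arange(1, int(np.ceil(pred.max())) + 1)
    cdf = np.array([(pred <= v).mean() for v in n])
    return n, cdf


def goodness_of_fit(ra: RankAbundance, fit: SADFit) -> tuple[float, float]:
    """Chi-squared over pooled octave classes and KS on the abundance CDF.

    The chi-squared compares observed numbers of taxa per doubling octave
    with the model's expected numbers (S x class probability, or the count
    of predicted rank abundances per octave for the rank-based models);
    octaves are pooled right-to-left until every expected count is >= 1.
    A fit is conventionally accepted when p > 0.05.  Updates `fit` in place
    and returns (chi2_p, ks_p)."""
    counts = ra.counts
    edges = octave_edges(int(counts.max()))
    if len(edges) < 3:
        raise ValueError("need at least 2 octave classes for the chi-squared test")
    observed = np.histogram(counts, bins=edges)[0].astype(float)

    support, cdf = _model_abundance_cdf(fit)
    full_cdf = np.concatenate([[0.0], cdf])

    def cdf_at(v: float) -> float:
        """Model CDF at integer abundance v (0 below support, 1 above)."""
        i = np.searchsorted(support, v, side="right")
        return float(full_cdf[min(i, len(cdf))])

    class_p = np.array([cdf_at(hi - 1) - cdf_at(lo - 1)
                        for lo, hi in zip(edges[:-1], edges[1:])])
    total_p = class_p.sum()
    expected = ra.S * (class_p / total_p if total_p > 0 else class_p)

    # pool right-to-left until each expected >= 1
    obs, exp = list(observed), list(expected)
    i = len(exp) - 1
    while i > 0:
        if exp[i] < 1.0:
            exp[i - 1] += exp[i]
            obs[i - 1] += obs[i]
            del exp[i], obs[i]
        i -= 1
    if exp and exp[0] < 1.0 and len(exp) > 1:
        exp[1] += exp[0]
        obs[1] += obs[0]
        del exp[0], obs[0]
    obs_a, exp_a = np.asarray(obs), np.asarray(exp)
    if len(exp_a) < 2:
        raise ValueError("fewer than 2 pooled octave classes")
    exp_a = exp_a * obs_a.sum() / exp_a.sum()
    chi2 = float(((obs_a - exp_a) ** 2 / exp_a).sum())
    dof = max(len(exp_a) - 1 - fit.k, 1)
    chi2_p = float(stats.chi2.sf(chi2, dof))

    # KS: empirical vs model CDF evaluated on the model support
    ecdf = np.searchsorted(np.sort(counts), support, side="right") / ra.S
    D = float(np.abs(ecdf - cdf).max())
    ks_p = float(stats.kstwo.sf(D, ra.S))

    fit.chi2_stat, fit.chi2_p = chi2, chi2_p
    fit.ks_stat, fit.ks_p = D, ks_p
    return chi2_p, ks_p


# ---------------------------------------------------------------------------
# Model selection
# ---------------------------------------------------------------------------

def ic_weights(deltas: np.ndarray) -> np.ndarray:
    """Akaike/Schwarz weights from Delta-IC values: exp(-D/2)/sum."""
    d = np.asarray(deltas, dtype=float)
    w = np.exp(-(d - d.min()) / 2.0)
    return w / w.sum()


def model_selection(fits: list[SADFit]) -> pd.DataFrame:
    """Delta-AICc / Delta-BIC table with weights and the > 2 best-model rule."""
    if not fits:
        raise ValueError("no fits supplied")
    rows = pd.DataFrame({
        "model": [f.model for f in fits],
        "logLik": [f.logLik for f in fits],
        "k": [f.k for f in fits],
        "AICc": [f.AICc for f in fits],
        "BIC": [f.BIC for f in fits],
        "chi2_p": [f.chi2_p for f in fits],
        "ks_p": [f.ks_p for f in fits],
    })
    rows["dAICc"] = rows["AICc"] - rows["AICc"].min()
    rows["dBIC"] = rows["BIC"] - rows["BIC"].min()
    rows["w_AICc"] = ic_weights(rows["dAICc"].to_numpy())
    rows["w_BIC"] = ic_weights(rows["dBIC"].to_numpy())
    for ic in ("AICc", "BIC"):
        flag = np.zeros(len(rows), dtype=bool)
        order = rows[ic].sort_values().index
        if len(order) == 1 or \
                rows.loc[order[1], ic] - rows.loc[order[0], ic] > 2:
            flag[rows.index.get_loc(order[0])] = True
        rows[f"best_{ic}"] = flag
    return rows.sort_values("AICc").reset_index(drop=True)
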