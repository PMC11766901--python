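# lesionflora

Community ecology of culturable fungi isolated from foliar lesions of
ornamental palms, built around PCR-fingerprint taxonomy rather than
sequence data. The package is aimed at mycologists and plant pathologists
who survey lesion mycota by isolating fungi, fingerprinting every isolate
with two MSP-PCR primers (csM13 and (GTG)₅), and then asking ecological
questions: how diverse is the community, which abundance model describes
it, how many taxa were missed, which taxa co-occur, and whether
composition differs between palm host species.

## What it computes

**Fingerprint taxonomy.** Band-intensity profiles are compared with the
Pearson correlation (percent similarity), the two primers are combined
into a consensus similarity matrix, and UPGMA clustering is cut at fixed
levels: 65 % → genus clusters, 75 % → MOTUs (molecular operational
taxonomic units, a species proxy), 85 % → genomic types (strains). Repeat
runs of 10 % of isolates set the reproducibility ceiling (~95 %); records
of the same genus from the same lesion paired above it are counted as
redundant re-isolations of one organism — the isolation redundancy
coefficient, IRC = 100 × redundant/total records.

**Diversity.** With nᵢ records of taxon *i*, N = Σnᵢ, S taxa, m samples:
abundance of occurrence AO = 100 nᵢ/N, frequency of occurrence
FO = 100 kᵢ/m, Simpson complement D = 1 − Σnᵢ(nᵢ−1)/(N(N−1)), Shannon
H′ = −Σpᵢ log₁₀ pᵢ with evenness J′ = H′/log₁₀ S, Fisher's logseries α
solving S/N = [(1−x)/x][−ln(1−x)] with α = N(1−x)/x, Margalef
(S−1)/ln N, Menhinick S/√N, and the isolation rate (records per lesion).

**Abundance structure.** Maximum-likelihood fits of five species
abundance distributions (logseries, lognormal, geometric series, broken
stick, neutral mZSM) with χ² goodness of fit over Preston octaves,
Kolmogorov–Smirnov checks, and AICc/BIC model selection with Akaike
weights and the Δ>2 rule.

**Richness extrapolation.** Sample-based accumulation curves (1000
randomised orderings), Chao1 (with the (N−1)/N small-sample factor), ACE,
first/second-order jackknife, bootstrap, and the asymptotes of five
nonlinear accumulation models (asymptotic regression, logistic, Lomolino,
Michaelis–Menten, Weibull).

**Co-occurrence.** The exact hypergeometric (Veech) model for every taxon
pair: P(j shared samples) = C(n₁,j)C(M−n₁,n₂−j)/C(M,n₂), with pairs of
expected overlap < 1 filtered and the rest classed positive / negative /
random at α = 0.05.

**Host comparison.** PERMANOVA (pseudo-F, R², permutation p) on
Bray–Curtis dissimilarities of square-root counts, multivariate
dispersion homogeneity, Kruskal–Wallis with Dunn/Bonferroni post-hocs,
and UPGMA clustering of host profiles with the cophenetic correlation.

**Synthetic surveys.** `lesionflora.synthetic` generates a full survey —
logseries taxon pool, 9 palm hosts with 134 lesions, host-tilted
composition, injected isolation redundancy, and nested two-primer
fingerprints — so every stage is testable end to end with known truth.

## Worked example

```python
import lesionflora as lf
from lesionflora.core_data import AbundanceVector
from lesionflora.sad_models import RankAbundance, fit_all, model_selection

data = lf.simulate_dataset(lf.SimulationConfig(seed=1))
m = lf.build_matrix(data["records"], data["metadata"], rank="motu")
av = AbundanceVector.from_matrix(m)

prof = lf.diversity_profile(av.counts.to_numpy(), av.m)
print(f"S = {prof.S} MOTUs, N = {prof.N} records over {av.m} lesions")
print(f"Fisher's alpha = {prof.alpha:.2f}, H' = {prof.H:.2f}, J' = {prof.J:.2f}")

sel = model_selection(fit_all(RankAbundance(av.counts.to_numpy())))
print(sel[["model", "logLik", "AICc", "dAICc", "w_AICc"]]
      .round(2).to_string(index=False))
```

prints

```
S = 320 MOTUs, N = 2064 records over 134 lesions
Fisher's alpha = 105.99, H' = 2.24, J' = 0.89
       model    logLik     AICc    dAICc  w_AICc
   logseries   -855.10  1712.22     0.00    0.72
neutral_mzsm   -855.05  1714.13     1.92    0.28
   lognormal   -872.08  1748.20    35.98    0.00
   geometric -10722.76 21447.53 19735.31    0.00
broken_stick -10750.87 21501.74 19789.52    0.00
```

The simulated survey reproduces the study conditions exactly (320 MOTUs
in 2064 records; α ≈ 106). The logseries carries most of the AICc weight,
with the neutral mZSM — which converges to the logseries at large
community size — a close second and the even-abundance models rejected
outright: the hallmark of a community with a few dominant taxa and a long
rare tail.

A command-line interface mirrors the stages
(`lesionflora simulate | cluster | diversity | sad | richness | cooccur |
compare | run`); see `lesionflora --help`.

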