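"""Synthetic communities and fingerprints with the structure of the study system.

The generator emulates a survey of culturable fungi from palm foliar
lesions so that every pipeline stage can be exercised without real data:

* a taxon pool with Fisher-logseries relative abundances (default alpha
  chosen so ~320 MOTUs arise from 2064 records), MOTUs nested in genera
  with a skewed genus-size distribution (capped at 17 MOTUs per genus),
  and assemblage-type labels allocating ~56% of records to coelomycetes;
* a sampling design of 9 palm host species with 32/31/19/14/13/12/8/3/2
  lesions each (134 samples), four lesion morphotypes, per-host
  Dirichlet-tilted composition (weaker tilt per lesion type), per-sample
  MOTU counts with median ~5 and maximum ~38, and re-isolations of the
  same organism injected at a configurable redundancy rate;
* two-primer MSP-PCR fingerprints built from a nested variance hierarchy
  (genus > MOTU > genomic type > organism > measurement noise) whose
  shared-variance fractions put expected Pearson similarities between the
  taxonomy cut-offs (same genus ~70%, same MOTU ~82%, same GT ~90%, same
  organism ~96%), plus 10% duplicate re-runs for the reproducibility
  cut-off.

All randomness flows from one seeded generator; `truth` records the true
partition and parameters for recovery tests.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from .core_data import ASSEMBLAGE_TYPES, LESION_TYPES
from .diversity import fisher_alpha
from .fingerprint import FingerprintProfile, PRIMERS

DEFAULT_HOSTS = (
    "Chamaerops humilis", "Phoenix canariensis", "Chrysalidocarpus lutescens",
    "Trachycarpus fortunei", "Phoenix reclinata", "Phoenix dactylifera",
    "Washingtonia filifera", "Phoenix roebelenii", "Chamaedorea elegans",
)
DEFAULT_SAMPLES_PER_HOST = (32, 31, 19, 14, 13, 12, 8, 3, 2)
LESION_PROBS = (0.49, 0.16, 0.18, 0.17)         # TDB, LLS, SLS, PP shares
ASSEMBLAGE_SHARES = (0.56, 0.39, 0.04, 0.008, 0.002)


@dataclass
class FingerprintConfig:
    """Variance budget of the nested fingerprint hierarchy.

    The similarity targets are expected Pearson correlations (x100 percent)
    between profiles whose deepest shared level is the named one; they must
    interleave the 65/75/85/95 taxonomy cut-offs."""

    n_bins: int = 400                 # ~8-bp bins over 200-3500 bp
    band_sparsity: float = 0.25       # fraction of bins banded per component
    genus_similarity: float = 0.70    # MOTUs of one genus (between 65 and 75)
    motu_similarity: float = 0.82     # GTs of one MOTU (between 75 and 85)
    gt_similarity: float = 0.90       # organisms of one GT (between 85 and 95)
    duplicate_similarity: float = 0.96  # re-measurements of one organism
    duplicate_fraction: float = 0.10  # records re-run per primer
    baseline: float = 4.0             # offset keeping intensities non-negative


@dataclass
class SimulationConfig:
    seed: int = 0
    n_hosts: int = 9
    samples_per_host: tuple = DEFAULT_SAMPLES_PER_HOST
    total_records: int = 2064
    alpha: float = 106.0              # community logseries alpha (~320 MOTUs)
    host_effect: float = 8.0          # per-taxon Dirichlet concentration over
                                      # hosts; smaller = stronger host fidelity
    lesion_type_effect: float = 40.0  # ditto over lesion types (weaker tilt)
    genus_concentration: float = 500.0  # new-genus tendency of the genus CRP
    max_motus_per_genus: int = 17
    gts_per_motu_mean: float = 1.6
    sample_capacity_shape: float = 0.25  # Gamma shape of per-lesion capacity
    sample_capacity_max: float = 2.0     # truncation of the capacity draw
    clump: float = 0.10               # within-host clumping of a taxon's records
    clump_abundance_scale: float = 0.6  # commoner taxa spread over more lesions
    redundancy_rate: float = 0.0654   # expected fraction of re-isolations
    fingerprint: FingerprintConfig = field(default_factory=FingerprintConfig)

    def __post_init__(self) -> None:
        if len(self.samples_per_host) != self.n_hosts:
            raise ValueError("samples_per_host length must equal n_hosts")
        if not (0 <= self.redundancy_rate < 1):
            raise ValueError("redundancy_rate must be in [0, 1)")


@dataclass
class TaxonPool:
    """True community: per-MOTU abundance, genus nesting, GT inventory."""

    taxa: pd.DataFrame       # motu_id, genus, assemblage_type, count, n_gts
    alpha: float
    x: float

    @property
    def p(self) -> np.ndarray:
        return self.taxa["count"].to_numpy() / self.taxa["count"].sum()


# ---------------------------------------------------------------------------
# Community pool
# ---------------------------------------------------------------------------

def simulate_community(cfg: SimulationConfig,
                       rng: np.random.Generator | None = None) -> TaxonPool:
    """Logseries taxon pool with nested genera and assemblage labels.

    The logseries nuisance parameter x follows from (alpha, N) via
    x = N/(N + alpha).  S = round(alpha ln(1 + N/alpha)) species receive iid
    logseries abundances which are then nudged (weighted single-record
    moves) until they sum to exactly N without losing any species, so the
    realised (S, N) pair recovers alpha."""
    rng = np.random.default_rng(cfg.seed) if rng is None else rng
    N = cfg.total_records
    alpha = cfg.alpha
    if alpha <= 0 or N < 2:
        raise ValueError("need alpha > 0 and total_records >= 2")
    x = N / (N + alpha)
    S = int(round(alpha * np.log1p(N / alpha)))
    if S < 2 or S >= N:
        raise ValueError(f"infeasible alpha for N: implied S = {S}")
    counts = stats.logser.rvs(x, size=S, random_state=rng).astype(int)
    while counts.sum() > N:
        w = (counts - 1).astype(float)
        if w.sum() == 0:
            break
        counts[rng.choice(S, p=w / w.sum())] -= 1
    while counts.sum() < N:
        counts[rng.choice(S, p=counts / counts.sum())] += 1

    # genus nesting: abundance-weighted restaurant process.  MOTUs are
    # inserted from most to least abundant; a MOTU joins an existing genus
    # with odds proportional to that genus's record total and to the MOTU's
    # own abundance (common MOTUs accrete into a few speciose, dominant
    # genera; rare MOTUs mostly found their own), with genus size capped.
    theta = cfg.genus_concentration
    insert_order = np.argsort(counts)[::-1]
    genus_of = np.zeros(len(counts), dtype=int)
    sizes: list[int] = []
    records_in: list[float] = []
    for i in insert_order:
        open_g = [g for g, s in enumerate(sizes) if s < cfg.max_motus_per_genus]
        w = np.array([records_in[g] for g in open_g], dtype=float)
        new_genus_weight = theta / counts[i]
        if open_g and w.sum() > 0 and \
                rng.random() < w.sum() / (w.sum() + new_genus_weight):
            g = open_g[rng.choice(len(open_g), p=w / w.sum())]
        else:
            g = len(sizes)
            sizes.append(0)
            records_in.append(0.0)
        sizes[g] += 1
        records_in[g] += counts[i]
        genus_of[i] = g

    order = rng.permutation(len(counts))    # random order for the share walk
    taxa = pd.DataFrame({
        "motu_id": [f"MOTU{i + 1:04d}" for i in range(len(counts))],
        "genus": [f"Genus{genus_of[i] + 1:03d}" for i in range(len(counts))],
        "count": counts,
    }).iloc[order].reset_index(drop=True)

    # assemblage labels per genus: greedy fill toward the target record
    # shares (dominant genera claimed first by whichever assemblage type is
    # furthest below its target), randomised among comparable deficits
    genus_counts = taxa.groupby("genus")["count"].sum().sort_values(ascending=False)
    targets = np.array(ASSEMBLAGE_SHARES) * genus_counts.sum()
    assigned = np.zeros(len(ASSEMBLAGE_TYPES))
    assemblage_of = {}
    for genus, c in genus_counts.items():
        deficit = np.maximum(targets - assigned, 0.0)
        if deficit.sum() == 0:
            k = int(np.argmax(targets - assigned))
        else:
            k = int(rng.choice(len(deficit), p=deficit / deficit.sum()))
        assigned[k] += c
        assemblage_of[genus] = ASSEMBLAGE_TYPES[k]
    taxa["assemblage_type"] = taxa["genus"].map(assemblage_of)

    # genomic types per MOTU: 1 + Poisson, at least 1
    taxa["n_gts"] = 1 + rng.poisson(max(cfg.gts_per_motu_mean - 1, 0), size=len(taxa))
    realised_alpha, realised_x = fisher_alpha(len(taxa), int(taxa["count"].sum()))
    return TaxonPool(taxa=taxa.sort_values("motu_id").reset_index(drop=True),
                     alpha=realised_alpha, x=realised_x)


# ---------------------------------------------------------------------------
# Sampling design
# ---------------------------------------------------------------------------

def simulate_sampling(pool: TaxonPool, cfg: SimulationConfig,
                      rng: np.random.Generator | None = None
                      ) -> tuple[pd.DataFrame, pd.DataFrame, dict]:
    """Allocate the pool's records to hosts and lesions.

    Every pool record is placed, so the realised totals (N, S, logseries
    shape) equal the pool's.  Each taxon draws a host-preference vector
    from a Dirichlet over hosts (concentration = host_effect; smaller =
    stronger fidelity) and, within a host, spreads its records over
    lesions with weights combining a truncated-Gamma per-lesion capacity
    (richness overdispersion: median ~5 MOTUs per lesion with a long
    upper tail), a per-taxon lesion-type preference (weak Dirichlet tilt),
    and a Gamma clumping factor whose shape grows with log abundance
    (commoner taxa occupy more lesions).  Finally a configurable fraction
    of records becomes re-isolations of an organism already recorded in
    the same lesion (ground truth for the IRC).

    Returns (records, metadata, truth)."""
    rng = np.random.default_rng(cfg.seed + 1) if rng is None else rng
    taxa = pool.taxa
    counts = taxa["count"].to_numpy()
    S = len(taxa)
    hosts = list(DEFAULT_HOSTS[:cfg.n_hosts]) if cfg.n_hosts <= len(DEFAULT_HOSTS) \
        else [f"Host{i + 1:02d}" for i in range(cfg.n_hosts)]
    n_h = np.asarray(cfg.samples_per_host)
    M = int(n_h.sum())
    q = n_h / M

    # metadata: samples nested in trees (most trees contribute one lesion)
    meta_rows = []
    sid = 0
    tree = 0
    for h, n_samp in zip(hosts, n_h):
        parish = f"Parish{1 + sum(map(ord, h)) % 4}"
        k = 0
        while k < n_samp:
            tree += 1
            per_tree = int(min(1 + (rng.random() < 0.3), n_samp - k))
            for _ in range(per_tree):
                sid += 1
                k += 1
                meta_rows.append({
                    "sample_id": f"S{sid:03d}", "tree_id": f"T{tree:03d}",
                    "host_species": h, "parish": parish,
                    "lesion_type": LESION_TYPES[rng.choice(4, p=LESION_PROBS)],
                })
    metadata = pd.DataFrame(meta_rows)
    sample_host = np.repeat(np.arange(len(hosts)), n_h)
    lesion_idx = metadata["lesion_type"].map(
        {lt: i for i, lt in enumerate(LESION_TYPES)}).to_numpy()

    capacity = np.minimum(rng.gamma(cfg.sample_capacity_shape, size=M),
                          cfg.sample_capacity_max) + 1e-9

    alloc = np.zeros((M, S), dtype=int)     # records of taxon j in sample i
    lesion_probs = np.asarray(LESION_PROBS)
    for j, n_j in enumerate(counts):
        host_pref = rng.dirichlet(np.maximum(cfg.host_effect * q, 1e-6))
        lesion_pref = rng.dirichlet(np.maximum(
            cfg.lesion_type_effect * lesion_probs, 1e-6))
        per_host = rng.multinomial(n_j, host_pref)
        shape = cfg.clump * (1.0 + cfg.clump_abundance_scale * np.log(n_j))
        for h, k in enumerate(per_host):
            if k == 0:
                continue
            idx = np.nonzero(sample_host == h)[0]
            g = rng.gamma(shape, size=len(idx)) + 1e-12
            w = capacity[idx] * g * lesion_pref[lesion_idx[idx]]
            alloc[idx, j] += rng.multinomial(k, w / w.sum())
    # every lesion yielded at least one record in the survey design:
    # top up empty samples from the richest same-host sample
    for s in np.nonzero(alloc.sum(axis=1) == 0)[0]:
        idx = np.nonzero(sample_host == sample_host[s])[0]
        donor = idx[np.argmax(alloc[idx].sum(axis=1))]
        t = int(np.argmax(alloc[donor]))
        alloc[donor, t] -= 1
        alloc[s, t] += 1

    rec_rows = []
    rid = 0
    gt_names = {m: [f"{m}-GT{j + 1}" for j in range(int(g))]
                for m, g in zip(taxa["motu_id"], taxa["n_gts"])}
    genus_of = dict(zip(taxa["motu_id"], taxa["genus"]))
    assemb_of = dict(zip(taxa["motu_id"], taxa["assemblage_type"]))
    org = 0
    sample_ids = metadata["sample_id"].to_numpy()
    for s in range(M):
        for j in np.nonzero(alloc[s])[0]:
            motu = taxa["motu_id"].iloc[j]
            gts = gt_names[motu]
            for _ in range(int(alloc[s, j])):
                rid += 1
                org += 1
                rec_rows.append({
                    "record_id": f"R{rid:04d}", "sample_id": sample_ids[s],
                    "genus": genus_of[motu], "motu_id": motu,
                    "gt_id": gts[rng.choice(len(gts))],
                    "assemblage_type": assemb_of[motu],
                    "organism_id": f"O{org:04d}",
                })
    records = pd.DataFrame(rec_rows)

    # inject redundancy: some records become re-isolations of an earlier
    # record of the same MOTU from the same lesion
    dup_candidates = records.index[records.duplicated(["sample_id", "motu_id"])]
    n_red = int(round(cfg.redundancy_rate * len(records)))
    n_red = min(n_red, len(dup_candidates))
    redundant_idx = rng.choice(dup_candidates, size=n_red, replace=False)
    first_org = records.drop_duplicates(["sample_id", "motu_id"]).set_index(
        ["sample_id", "motu_id"])["organism_id"]
    first_gt = records.drop_duplicates(["sample_id", "motu_id"]).set_index(
        ["sample_id", "motu_id"])["gt_id"]
    for i in redundant_idx:
        key = (records.at[i, "sample_id"], records.at[i, "motu_id"])
        records.at[i, "organism_id"] = first_org[key]
        records.at[i, "gt_id"] = first_gt[key]

    truth = {
        "seed": cfg.seed,
        "alpha_pool": pool.alpha,
        "n_records": len(records),
        "n_motus": int(records["motu_id"].nunique()),
        "n_genera": int(records["genus"].nunique()),
        "redundant_records": sorted(records.loc[redundant_idx, "record_id"]),
        "redundancy_rate": n_red / len(records),
    }
    return records, metadata, truth


# ---------------------------------------------------------------------------
# Fingerprints
# ---------------------------------------------------------------------------

def _sparse_component(rng: np.random.Generator, n_bins: int, var: float,
                      sparsity: float) -> np.ndarray:
    """Zero-mean banded component with the requested per-bin variance."""
    mask = rng.random(n_bins) < sparsity
    comp = np.zeros(n_bins)
    comp[mask] = rng.normal(0.0, np.sqrt(var / sparsity), size=mask.sum())
    return comp


def simulate_fingerprints(records: pd.DataFrame, cfg: SimulationConfig,
                          rng: np.random.Generator | None = None
                          ) -> dict[str, list[FingerprintProfile]]:
    """Two-primer fingerprint profiles for each record, plus duplicate
    re-runs of a random fraction of records per primer.

    Profiles are sums of nested components (genus, MOTU, GT, organism)
    plus per-measurement noise; component variances realise the configured
    expected similarities.  `is_duplicate_of` marks the re-runs."""
    fp = cfg.fingerprint
    rng = np.random.default_rng(cfg.seed + 2) if rng is None else rng
    v_genus = fp.genus_similarity
    v_motu = fp.motu_similarity - fp.genus_similarity
    v_gt = fp.gt_similarity - fp.motu_similarity
    v_org = fp.duplicate_similarity - fp.gt_similarity
    v_meas = 1.0 - fp.duplicate_similarity
    if min(v_motu, v_gt, v_org, v_meas) <= 0:
        raise ValueError("similarity targets must increase: genus < motu < gt < duplicate < 1")

    out: dict[str, list[FingerprintProfile]] = {}
    for primer in PRIMERS:
        cache: dict[tuple, np.ndarray] = {}

        def component(key: tuple, var: float, sparsity: float) -> np.ndarray:
            if key not in cache:
                cache[key] = _sparse_component(rng, fp.n_bins, var, sparsity)
            return cache[key]

        profiles = []
        for rec in records.itertuples():
            base = (
                component(("genus", rec.genus), v_genus, fp.band_sparsity)
                + component(("motu", rec.motu_id), v_motu, fp.band_sparsity)
                + component(("gt", rec.motu_id, rec.gt_id), v_gt, 1.0)
                + component(("org", rec.organism_id), v_org, 1.0)
            )
            meas = base + rng.normal(0.0, np.sqrt(v_meas), fp.n_bins)
            profiles.append(FingerprintProfile(
                rec.record_id, primer,
                np.maximum(fp.baseline + meas, 0.0)))
            cache[("base", rec.record_id)] = base
        # duplicate re-runs of a random subset
        n_dup = max(1, int(round(fp.duplicate_fraction * len(records))))
        dup_rows = rng.choice(len(records), size=n_dup, replace=False)
        for i in dup_rows:
            rec = records.iloc[i]
            base = cache[("base", rec["record_id"])]
            meas = base + rng.normal(0.0, np.sqrt(v_meas), fp.n_bins)
            profiles.append(FingerprintProfile(
                f"{rec['record_id']}-dup", primer,
                np.maximum(fp.baseline + meas, 0.0),
                is_duplicate_of=rec["record_id"]))
        out[primer] = profiles
    return out


# ---------------------------------------------------------------------------
# One-call dataset
# ---------------------------------------------------------------------------

def simulate_dataset(cfg: SimulationConfig | None = None,
                     with_fingerprints: bool = False) -> dict:
    """Full synthetic survey: pool, records, metadata, truth and optionally
    fingerprints.  Everything derives from cfg.seed."""
    cfg = cfg or SimulationConfig()
    rng = np.random.default_rng(cfg.seed)
    pool = simulate_community(cfg, rng)
    records, metadata, truth = simulate_sampling(pool, cfg, rng)
    out = {"config": cfg, "pool": pool, "records": records,
           "metadata": metadata, "truth": truth}
    if with_fingerprints:
        out["fingerprints"] = simulate_fingerprints(records, cfg, rng)
    return out


def write_dataset(data: dict, out_dir: str | Path) -> None:
    """Emit records.tsv, samples.tsv, truth.json (and fingerprints.tsv)."""
    import json
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    data["records"].to_csv(out / "records.tsv", sep="\t", index=False)
    data["metadata"].to_csv(out / "samples.tsv", sep="\t", index=False)
    truth = dict(data["truth"])
    truth["config"] = asdict(data["config"])
    with open(out / "truth.json", "w") as fh:
        json.dump(truth, fh, indent=2, default=str)
    if "fingerprints" in data:
        from .fingerprint import write_fingerprints
        all_profiles = [p for plist in data["fingerprints"].values() for p in plist]
        write_fingerprints(all_profiles, out / "fingerprints.tsv")
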