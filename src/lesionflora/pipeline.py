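"""End-to-end orchestration: simulate/load -> cluster -> analyse -> report.

`run_all` executes every stage on one dataset and writes a TSV/JSON report
bundle: taxonomy partitions, frequency tables, diversity profiles per host,
SAD model selection, richness extrapolation, co-occurrence classes, and
host-level community comparison.  Every table is stamped with the seed and
a hash of the configuration so a rerun with identical inputs is
reproducible byte for byte.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import community_stats, cooccurrence, core_data, diversity, fingerprint, richness, sad_models
from .core_data import AbundanceVector, CommunityMatrix

log = logging.getLogger("lesionflora")


@dataclass
class RunConfig:
    records_path: str | None = None
    metadata_path: str | None = None
    fingerprints_path: str | None = None
    rank: str = "motu"
    cutoffs: tuple = (65.0, 75.0, 85.0, 95.0)
    cooccur_threshold: float = 1.0
    alpha: float = 0.05
    n_perm: int = 999
    sac_perm: int = 1000
    min_records: int = 5
    seed: int = 0
    out_dir: str = "lesionflora_out"

    def __post_init__(self) -> None:
        if list(self.cutoffs) != sorted(set(self.cutoffs)):
            raise ValueError("cutoffs must be strictly increasing")

    def digest(self) -> str:
        """Hash of the analysis-relevant configuration (output location
        excluded so reruns into different directories compare equal)."""
        payload = {k: v for k, v in asdict(self).items() if k != "out_dir"}
        return hashlib.sha256(
            json.dumps(payload, sort_keys=True, default=str).encode()
        ).hexdigest()[:12]


def _stamp(df: pd.DataFrame, config: RunConfig) -> pd.DataFrame:
    df = df.copy()
    df["config_hash"] = config.digest()
    df["seed"] = config.seed
    return df


def run_all(config: RunConfig, records: pd.DataFrame | None = None,
            metadata: pd.DataFrame | None = None) -> dict:
    """Execute the full analysis; returns the in-memory bundle and writes
    TSVs under config.out_dir.  Stage failures are recorded in the error
    manifest and later stages that do not depend on them still run."""
    t0 = time.time()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    bundle: dict = {"config": asdict(config), "errors": {}}

    if records is None:
        if config.records_path is None:
            raise ValueError("either in-memory records or records_path required")
        records, metadata = core_data.read_records(
            config.records_path, config.metadata_path)
    log.info("loaded %d records / %d samples", len(records), len(metadata))

    # --- fingerprint stage (optional): assign motu/gt from profiles -------
    if config.fingerprints_path:
        profiles = fingerprint.read_fingerprints(config.fingerprints_path)
        mains = {pr: [p for p in ps if p.is_duplicate_of is None]
                 for pr, ps in profiles.items()}
        sims = {pr: fingerprint.pearson_similarity(ps) for pr, ps in mains.items()}
        sim = (fingerprint.consensus_similarity(*sims.values())
               if len(sims) == 2 else next(iter(sims.values())))
        dend = fingerprint.upgma(sim)
        tax = fingerprint.assign_taxonomy(dend, *config.cutoffs[:3])
        tf = tax.to_frame()
        records = records.drop(columns=["motu_id", "gt_id"], errors="ignore") \
            .merge(tf[["record_id", "motu_id", "gt_id"]], on="record_id", how="left")
        dups = {pr: [(next(q for q in ps if q.record_id == p.is_duplicate_of), p)
                     for p in ps if p.is_duplicate_of is not None]
                for pr, ps in profiles.items()}
        if all(dups.values()):
            bundle["reproducibility"] = fingerprint.reproducibility_cutoff(dups)
        irc_pct, redundant = fingerprint.irc(records, sim, config.cutoffs[-1])
        bundle["irc"] = {"pct": irc_pct, "n_redundant": len(redundant)}
        (out / "irc.json").write_text(json.dumps(bundle["irc"]))

    # --- community matrices ----------------------------------------------
    try:
        matrix = core_data.build_matrix(records, metadata, rank=config.rank)
    except Exception as exc:        # e.g. missing motu_id without fingerprints
        raise core_data.IntegrityError(
            f"cannot build {config.rank} matrix: {exc}") from exc
    av = AbundanceVector.from_matrix(matrix)
    bundle["totals"] = {"records": matrix.n_records, "samples": matrix.n_samples,
                        "taxa": av.S}

    # --- diversity & frequency tables ------------------------------------
    freq = diversity.frequency_table(av.counts, av.incidence, av.m)
    bundle["frequency_table"] = freq
    _stamp(freq, config).to_csv(out / "frequency_table.tsv", sep="\t", index=False)
    profiles_rows = []
    overall = diversity.diversity_profile(av.counts.to_numpy(), av.m).to_series()
    overall["group"] = "all"
    profiles_rows.append(overall)
    host_taxa = {}
    for host, sub in core_data.matrices_by(matrix, metadata, "host").items():
        sav = AbundanceVector.from_matrix(sub)
        try:
            row = diversity.diversity_profile(sav.counts.to_numpy(), sav.m).to_series()
        except ValueError as exc:
            bundle["errors"][f"diversity:{host}"] = str(exc)
            continue
        row["group"] = host
        profiles_rows.append(row)
        host_taxa[host] = list(sav.counts.index)
    div = pd.DataFrame(profiles_rows)
    bundle["diversity"] = div
    _stamp(div, config).to_csv(out / "diversity.tsv", sep="\t", index=False)
    if len(host_taxa) >= 2:
        bundle["overlap"] = diversity.taxa_overlap(host_taxa)
        _stamp(bundle["overlap"], config).to_csv(out / "overlap.tsv", sep="\t", index=False)

    # --- SAD model selection ----------------------------------------------
    try:
        ra = sad_models.RankAbundance(av.counts.to_numpy())
        fits = sad_models.fit_all(ra)
        sel = sad_models.model_selection(fits)
        bundle["sad"] = sel
        _stamp(sel, config).to_csv(out / "sad_selection.tsv", sep="\t", index=False)
    except Exception as exc:
        bundle["errors"]["sad"] = str(exc)

    # --- richness ----------------------------------------------------------
    try:
        curve = richness.accumulation_curve(matrix, n_perm=config.sac_perm,
                                            seed=config.seed)
        est = pd.DataFrame([e.to_series() for e in
                            richness.richness_estimates(matrix, seed=config.seed)])
        asym = richness.fit_asymptotic_models(curve)
        est = pd.concat([est, pd.DataFrame([{
            "estimator": "asymptotic",
            "S_hat": asym.loc[asym["best_AICc"].idxmax() if asym["best_AICc"].any()
                              else asym["AICc"].idxmin(), "asymptote"],
        }])], ignore_index=True)
        bundle["richness"] = est
        bundle["accumulation"] = curve
        bundle["asymptotic_fits"] = asym
        _stamp(est, config).to_csv(out / "richness.tsv", sep="\t", index=False)
    except Exception as exc:
        bundle["errors"]["richness"] = str(exc)

    # --- co-occurrence ------------------------------------------------------
    try:
        inc = cooccurrence.incidence_from_matrix(matrix)
        pairs, summary = cooccurrence.analyze_pairs(
            inc, expected_threshold=config.cooccur_threshold, alpha=config.alpha)
        bundle["cooccurrence"] = summary
        _stamp(summary, config).to_csv(out / "cooccurrence_summary.tsv",
                                       sep="\t", index=False)
        _stamp(cooccurrence.pairs_to_frame(pairs), config).to_csv(
            out / "cooccurrence_pairs.tsv", sep="\t", index=False)
    except Exception as exc:
        bundle["errors"]["cooccurrence"] = str(exc)

    # --- host comparison ----------------------------------------------------
    try:
        filt = community_stats.filter_min_records(matrix, config.min_records)
        groups = metadata.set_index("sample_id")["host_species"]
        counts = groups.loc[filt.sample_ids].value_counts()
        keep_levels = counts[counts >= 2].index
        keep = groups.loc[filt.sample_ids].isin(keep_levels)
        filt = CommunityMatrix(counts=filt.counts.loc[keep.to_numpy()],
                               rank=filt.rank)
        D = community_stats.bray_curtis(filt)
        res = community_stats.permanova(D, groups, n_perm=config.n_perm,
                                        seed=config.seed, factor="host")
        disp_F, disp_p = community_stats.dispersion_homogeneity(
            D, groups, n_perm=config.n_perm, seed=config.seed)
        perm_df = pd.DataFrame([{
            "factor": res.factor, "df_among": res.df_among,
            "df_within": res.df_within, "pseudo_F": res.pseudo_F, "R2": res.R2,
            "p": res.p, "dispersion_F": disp_F, "dispersion_p": disp_p,
        }])
        bundle["permanova"] = perm_df
        _stamp(perm_df, config).to_csv(out / "permanova.tsv", sep="\t", index=False)
        richness_per_sample = (filt.counts > 0).sum(axis=1)
        H, p_kw, dunn = community_stats.kruskal_dunn(
            richness_per_sample, groups.loc[filt.sample_ids])
        bundle["kruskal"] = {"H": H, "p": p_kw}
        _stamp(dunn, config).to_csv(out / "dunn.tsv", sep="\t", index=False)
        # host-level HCA on AO profiles
        ao = filt.counts.groupby(groups.loc[filt.sample_ids]).sum()
        ao = 100 * ao.div(ao.sum(axis=1), axis=0)
        if len(ao) >= 3:
            dend, coph = community_stats.host_hca(ao)
            bundle["hca"] = {"cophenetic_c": coph, "newick": dend.to_newick()}
            (out / "host_dendrogram.nwk").write_text(dend.to_newick())
    except Exception as exc:
        bundle["errors"]["comparison"] = str(exc)

    bundle["runtime_s"] = time.time() - t0
    report = {"config": bundle["config"], "config_hash": config.digest(),
              "totals": bundle.get("totals"), "errors": bundle["errors"],
              "runtime_s": bundle["runtime_s"]}
    (out / "run_report.json").write_text(json.dumps(report, indent=2, default=str))
    log.info("pipeline finished in %.1fs (%d stage errors)",
             bundle["runtime_s"], len(bundle["errors"]))
    return bundle
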