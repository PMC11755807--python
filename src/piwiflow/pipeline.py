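"""End-to-end orchestration of the TE/piRNA analysis stages.

``run_all`` executes: simulate -> quantify (read-level validation on a
sample subset) -> dea (TE and piRNA; MDS-vs-CTR and LR-vs-HR contrasts)
-> aggstats (totals, ratio, control cutoffs, correlations) -> survive
(KM / log-rank per stratification, multivariate Cox with stepwise
selection) -> network (per seed) -> enrich, writing plain-text outputs and
a YAML run manifest with the configuration hash, seeds and per-stage
record counts.  Any stage failure aborts with the stage name while
preserving partial outputs.
"""

from __future__ import annotations

import hashlib
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd
import yaml

from piwiflow import aggstats, enrich, netmod, normdea, pirnaquant, survival as surv
from piwiflow.containers import ConfigError, PiwiflowError
from piwiflow.synthcohort import (
    DEFAULT_ADAPTER,
    DEFAULT_UMI_LEN,
    CohortConfig,
    generate_cohort,
    generate_reads,
    molecule_table,
    write_cohort,
)

log = logging.getLogger("piwiflow")

ALL_STAGES = ("simulate", "quantify", "dea", "aggstats", "survive", "network", "enrich")


class StageError(PiwiflowError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage


@dataclass
class RunConfig:
    outdir: str = "piwiflow_run"
    seed: int = 0
    stages: list[str] = field(default_factory=lambda: list(ALL_STAGES))
    cohort: dict[str, Any] = field(default_factory=dict)
    adapter: str = DEFAULT_ADAPTER
    umi_len: int = DEFAULT_UMI_LEN
    #: samples validated at read level and the molecule budget per sample
    quantify_samples: int = 1
    quantify_max_molecules: int = 4000
    dup_rate: float = 1.0
    error_rate: float = 0.002
    fdr_cutoff: float = 0.05
    fdr_cutoff_strict: float = 0.001
    endpoint: str = "OS"
    network_k: int = 10
    network_seeds: list[str] = field(default_factory=lambda: ["PIWIL2", "piR_018780", "FAM", "HERV-Fc1"])
    #: panel size cap for the complete correlation graph (top variance + seeds)
    network_panel_size: int = 300
    n_perm: int = 500
    gmt: str | None = None
    n_gene_sets: int = 50
    gene_set_size: int = 25

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f for f in cls.__dataclass_fields__}
        bad = set(raw) - known
        if bad:
            raise ConfigError(f"unknown run-config fields: {sorted(bad)}")
        return cls(**raw)


def _hash_config(cfg: RunConfig) -> str:
    blob = yaml.safe_dump(asdict(cfg), sort_keys=True).encode()
    return hashlib.sha256(blob).hexdigest()[:16]


def run_all(config: RunConfig) -> dict[str, Any]:
    """Run the enabled stages in order and return the manifest dict."""
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest: dict[str, Any] = {
        "config_hash": _hash_config(config),
        "seed": config.seed,
        "stages": {},
    }
    state: dict[str, Any] = {}
    for stage in config.stages:
        if stage not in ALL_STAGES:
            raise ConfigError(f"unknown stage {stage!r}")
        fn = globals()[f"_stage_{stage}"]
        try:
            record = fn(config, outdir, state)
        except Exception as exc:  # persist partial outputs, then abort
            manifest["stages"][stage] = {"status": "failed", "error": str(exc)}
            _write_manifest(manifest, outdir)
            raise StageError(stage, exc) from exc
        record["status"] = "ok"
        manifest["stages"][stage] = record
        log.info("stage %s: %s", stage, record)
    _write_manifest(manifest, outdir)
    return manifest


def _write_manifest(manifest: dict[str, Any], outdir: Path) -> None:
    with open(outdir / "manifest.yaml", "w") as fh:
        yaml.safe_dump(manifest, fh, sort_keys=True)


def _require(state: dict, key: str, stage: str):
    if key not in state:
        raise ConfigError(f"stage {stage!r} needs outputs of an earlier stage ({key}); "
                          "enable it or provide the files")
    return state[key]


# ---------------------------------------------------------------- stages


def _stage_simulate(config: RunConfig, outdir: Path, state: dict) -> dict:
    cc = CohortConfig(**{**config.cohort, "seed": config.seed})
    cohort = generate_cohort(cc)
    paths = write_cohort(cohort, outdir / "sim")
    state["cohort"] = cohort
    return {
        "n_samples": int(cohort.clinical.shape[0]),
        "n_te": int(cohort.te_counts.counts.shape[0]),
        "n_pirna": int(cohort.pirna_counts.counts.shape[0]),
        "n_pcg": int(cohort.pcg_counts.counts.shape[0]),
        "files": {k: str(v) for k, v in paths.items()},
    }


def _stage_quantify(config: RunConfig, outdir: Path, state: dict) -> dict:
    cohort = _require(state, "cohort", "quantify")
    qdir = outdir / "quantify"
    qdir.mkdir(parents=True, exist_ok=True)
    ref = pirnaquant.PiRNAReference(cohort.truth.pirna_sequences)
    rng = np.random.default_rng(config.seed + 101)
    records = {}
    for sample in cohort.pirna_counts.samples[: config.quantify_samples]:
        col = cohort.pirna_counts.counts[sample]
        total = int(col.sum())
        if total > config.quantify_max_molecules:
            # down-sample molecules to the read-level validation budget
            probs = col.to_numpy() / total
            col = pd.Series(
                rng.multinomial(config.quantify_max_molecules, probs), index=col.index
            )
        fastq = qdir / f"{sample}.fastq"
        stats = generate_reads(
            molecule_table(col), cohort.truth.pirna_sequences, fastq,
            adapter=config.adapter, umi_len=config.umi_len,
            dup_rate=config.dup_rate, error_rate=config.error_rate,
            seed=config.seed + 7,
        )
        counts = pirnaquant.quantify(fastq, ref, adapter=config.adapter, umi_len=config.umi_len)
        counts.to_frame().to_csv(qdir / f"{sample}_counts.tsv", sep="\t", index=False)
        pd.Series(counts.attrition).to_csv(qdir / f"{sample}_attrition.tsv", sep="\t", header=False)
        # truth concordance at the unique-sequence level
        truth_by_seq = col.groupby(col.index.map(ref.id_to_seq)).sum()
        dedup = pd.Series({s: e["dedup_count"] for s, e in counts.entries.items()})
        both = truth_by_seq.index.intersection(dedup.index)
        exact = int((truth_by_seq.reindex(both) == dedup.reindex(both)).sum())
        records[str(sample)] = {**stats, "sequences_quantified": int(len(dedup)),
                                "sequences_matching_truth": exact,
                                "dedup_total": int(dedup.sum())}
    return {"samples": records}


def _stage_dea(config: RunConfig, outdir: Path, state: dict) -> dict:
    cohort = _require(state, "cohort", "dea")
    ddir = outdir / "dea"
    ddir.mkdir(parents=True, exist_ok=True)
    clin = cohort.clinical
    record: dict[str, Any] = {}
    deas: dict[str, pd.DataFrame] = {}
    # size factors are estimated per sequencing library: the RNA-seq library
    # (PCGs + TEs, anchored by the PCG majority) and the small-RNA library
    # (piRNAs + miRNA-like background); a shift affecting all TEs or all
    # piRNAs would otherwise be absorbed by the median of ratios
    sf_rna = normdea.size_factors(cohort.rna_library())
    sf_small = normdea.size_factors(cohort.small_library())
    state["sf_rna"], state["sf_small"] = sf_rna, sf_small
    for kind, cm in (("te", cohort.te_counts), ("pirna", cohort.pirna_counts), ("pcg", cohort.pcg_counts)):
        sf = sf_rna if kind in ("te", "pcg") else sf_small
        state[f"sf_{kind}"] = sf
        state[f"norm_{kind}"] = normdea.normalize(cm, sf)
        for contrast, (mask, levels) in {
            "mds_vs_ctr": (clin["group"].notna(), clin["group"].map(lambda g: "CTR" if g == "CTR" else "MDS")),
            "lr_vs_hr": (clin["group"] != "CTR", clin["group"]),
        }.items():
            labels = levels[mask]
            sub = cm.counts.loc[:, mask[mask].index]
            order = ["CTR", "MDS"] if contrast == "mds_vs_ctr" else ["LR-MDS", "HR-MDS"]
            labels = pd.Series(pd.Categorical(labels, categories=order, ordered=True), index=labels.index)
            dea = normdea.nb_wald_test(sub, sf, labels)
            dea.to_csv(ddir / f"{kind}_{contrast}.tsv", sep="\t", index_label="feature")
            deas[f"{kind}_{contrast}"] = dea
            calls = normdea.call_significant(dea, config.fdr_cutoff)
            strict = normdea.call_significant(dea, config.fdr_cutoff_strict)
            record[f"{kind}_{contrast}"] = {
                "n_tested": int(len(dea)),
                f"sig_fdr{config.fdr_cutoff}": len(calls["up"]) + len(calls["down"]),
                f"sig_fdr{config.fdr_cutoff_strict}": len(strict["up"]) + len(strict["down"]),
            }
    state["deas"] = deas
    return record


def _stage_aggstats(config: RunConfig, outdir: Path, state: dict) -> dict:
    cohort = _require(state, "cohort", "aggstats")
    adir = outdir / "aggstats"
    adir.mkdir(parents=True, exist_ok=True)
    norm_te = _require(state, "norm_te", "aggstats")
    norm_pi = _require(state, "norm_pirna", "aggstats")
    clin = cohort.clinical
    tot = aggstats.totals(norm_te, norm_pi, groups=clin["group"])
    frac, cohort_mean = aggstats.composition(norm_te, cohort.te_counts.annotations["class"])
    frac.to_csv(adir / "composition.tsv", sep="\t", index_label="sample")

    is_ctr = clin["group"] == "CTR"
    rules = {
        "total_te": aggstats.control_cutoff(tot["total_te"], is_ctr, "control-minimum", "total_te"),
        "total_pirna": aggstats.control_cutoff(tot["total_pirna"], is_ctr, "control-maximum", "total_pirna"),
        "ratio": aggstats.control_cutoff(tot["ratio"], is_ctr, "control-minimum", "ratio"),
    }
    # PIWIL2 stratification by the control maximum, on normalized expression
    piwil2 = _require(state, "norm_pcg", "aggstats").loc["PIWIL2"]
    rules["PIWIL2"] = aggstats.control_cutoff(piwil2, is_ctr, "control-maximum", "PIWIL2")
    for stat, rule in rules.items():
        values = piwil2 if stat == "PIWIL2" else tot[stat]
        tot[f"{stat}_stratum"] = rule.assign(values)
    tot["PIWIL2"] = piwil2
    tot.to_csv(adir / "sample_totals.tsv", sep="\t", index_label="sample")
    state["totals"] = tot
    state["cutoffs"] = rules

    r_all, p_all = aggstats.pearson(tot["total_te"], tot["total_pirna"])
    lr = tot[clin["group"] == "LR-MDS"]
    hr = tot[clin["group"] == "HR-MDS"]
    t_te, p_te = aggstats.welch_t(lr["total_te"], hr["total_te"])
    t_pi, p_pi = aggstats.welch_t(lr["total_pirna"], hr["total_pirna"])
    f_te, pa_te = aggstats.welch_anova(
        tot[is_ctr]["total_te"], lr["total_te"], hr["total_te"]
    )
    r_piwil2, p_piwil2 = aggstats.pearson(piwil2, tot["total_pirna"])
    record = {
        "pearson_te_vs_pirna": {"r": round(r_all, 4), "p": float(p_all)},
        "pearson_piwil2_vs_pirna": {"r": round(r_piwil2, 4), "p": float(p_piwil2)},
        "welch_t_total_te_lr_vs_hr": {"t": round(t_te, 3), "p": float(p_te)},
        "welch_t_total_pirna_lr_vs_hr": {"t": round(t_pi, 3), "p": float(p_pi)},
        "welch_anova_total_te": {"F": round(f_te, 3), "p": float(pa_te)},
        "class_composition_mean": {k: round(float(v), 4) for k, v in cohort_mean.items()},
        "cutoffs": {k: {"mode": r.mode, "cutoff": float(r.cutoff)} for k, r in rules.items()},
    }
    with open(adir / "summary.yaml", "w") as fh:
        yaml.safe_dump(record, fh, sort_keys=True)
    return record


def _stage_survive(config: RunConfig, outdir: Path, state: dict) -> dict:
    cohort = _require(state, "cohort", "survive")
    sdir = outdir / "survive"
    sdir.mkdir(parents=True, exist_ok=True)
    tot = _require(state, "totals", "survive")
    clin = cohort.clinical
    mds = clin.index[clin["group"] != "CTR"]
    record: dict[str, Any] = {}
    for endpoint in ("OS", "PFS"):
        srec = cohort.survival[cohort.survival["endpoint"] == endpoint].set_index("sample")
        srec = srec.loc[srec.index.intersection(mds)]
        ep_rec: dict[str, Any] = {}
        for stat in ("total_te", "total_pirna", "ratio", "PIWIL2"):
            strata = tot.loc[srec.index, f"{stat}_stratum"]
            if strata.nunique() < 2:
                ep_rec[stat] = {"note": "single stratum; no test"}
                continue
            chi2, p = surv.logrank(srec["time"], srec["event"], strata)
            medians = {}
            for level in ("low", "high"):
                sub = srec[strata == level]
                km = surv.km_curve(sub["time"], sub["event"])
                km.table.to_csv(sdir / f"km_{endpoint}_{stat}_{level}.tsv", sep="\t", index=False)
                medians[level] = None if np.isnan(km.median) else float(km.median)
            # univariate Cox on the binary stratum for the figure-style HR
            risk_level = "low" if stat in ("total_te", "ratio") else "high"
            x = pd.DataFrame({stat: (strata == risk_level).astype(float)})
            try:
                uni = surv.cox_fit(srec["time"].to_numpy(), srec["event"].to_numpy(), x)
                hr_ci = {"HR": float(uni.hr[0]), "CI95": [float(v[0]) for v in uni.ci]}
            except surv.FitError as exc:
                hr_ci = {"HR": None, "note": str(exc)}
            ep_rec[stat] = {"logrank_chi2": round(float(chi2), 3), "logrank_p": float(p),
                            "median_months": medians, **hr_ci}
        # multivariate Cox with stepwise selection
        ords = surv.ipssr_ordinalize(clin.loc[srec.index])
        cand = ords.astype(float)
        cand["age"] = clin.loc[srec.index, "age"].astype(float)
        cand["female_sex"] = (clin.loc[srec.index, "sex"] == "F").astype(float)
        for stat in ("PIWIL2", "ratio"):
            risk_level = "low" if stat == "ratio" else "high"
            cand[f"{stat}_{risk_level}"] = (tot.loc[srec.index, f"{stat}_stratum"] == risk_level).astype(float)
        model = surv.stepwise_cox(srec["time"].to_numpy(), srec["event"].to_numpy(), cand)
        if model.names:
            model.summary().to_csv(sdir / f"mva_{endpoint}.tsv", sep="\t")
        ep_rec["stepwise_mva"] = {
            "selected": model.names,
            "HR": {n: round(float(h), 3) for n, h in zip(model.names, model.hr)},
            "p": {n: float(p) for n, p in zip(model.names, model.p)},
        }
        record[endpoint] = ep_rec
    state["survive"] = record
    return record


def _stage_network(config: RunConfig, outdir: Path, state: dict) -> dict:
    cohort = _require(state, "cohort", "network")
    ndir = outdir / "network"
    ndir.mkdir(parents=True, exist_ok=True)
    panel = pd.concat([_require(state, "norm_pcg", "network"),
                       _require(state, "norm_te", "network"),
                       _require(state, "norm_pirna", "network")])
    kinds = pd.concat(
        [cm.annotations["kind"] for cm in (cohort.pcg_counts, cohort.te_counts, cohort.pirna_counts)]
    )
    # complete-graph construction is quadratic; keep the panel to the most
    # variable molecules plus the requested seeds
    logx = np.log2(panel + 1.0)
    var = logx.var(axis=1)
    keep = var.sort_values(ascending=False).index[: config.network_panel_size]
    keep = keep.union(pd.Index([s for s in config.network_seeds if s in panel.index]))
    graph = netmod.build_graph(panel.loc[keep], kinds=kinds)
    record: dict[str, Any] = {"panel_size": int(len(keep))}
    state["modules"] = {}
    for seed_mol in config.network_seeds:
        if seed_mol not in graph:
            record[seed_mol] = {"note": "seed not in panel"}
            continue
        module = netmod.extract_module(graph, seed_mol, k=config.network_k)
        module = netmod.filter_edges(module, graph)
        files = netmod.export_graph(module, graph, ndir, prefix=seed_mol.replace("/", "_"))
        state["modules"][seed_mol] = module
        record[seed_mol] = {
            "members": len(module.members),
            "retained_edges": int(len(module.edges)),
            "q3_threshold": round(float(module.q3_threshold), 4),
            "files": files,
        }
    state["graph"] = graph
    return record


def _stage_enrich(config: RunConfig, outdir: Path, state: dict) -> dict:
    cohort = _require(state, "cohort", "enrich")
    edir = outdir / "enrich"
    edir.mkdir(parents=True, exist_ok=True)
    deas = _require(state, "deas", "enrich")
    dea = deas["pcg_lr_vs_hr"]
    scores = dea["stat"].astype(float)
    universe = dea.index.tolist()
    if config.gmt:
        sets = enrich.read_gmt(config.gmt)
    else:
        # hallmark-style synthetic collection drawn from the cohort's PCG universe
        rng = np.random.default_rng(config.seed + 303)
        sets = {
            f"SYNSET_{i + 1:03d}": list(rng.choice(universe, size=config.gene_set_size, replace=False))
            for i in range(config.n_gene_sets)
        }
        enrich.write_gmt(sets, edir / "synthetic_sets.gmt")
    gsea = enrich.gsea_significance(scores, sets, n_perm=config.n_perm, seed=config.seed + 404)
    gsea.to_csv(edir / "gsea.tsv", sep="\t", index=False)
    record: dict[str, Any] = {
        "gsea_sets": int(len(gsea)),
        "gsea_flagged_fdr0.2": int(gsea["flagged"].sum()),
    }
    for seed_mol, module in state.get("modules", {}).items():
        pcgs = [m for m in module.members if m in set(universe)]
        if not pcgs:
            continue
        ora = enrich.ora_hypergeom(pcgs, universe, sets)
        ora.to_csv(edir / f"ora_{seed_mol.replace('/', '_')}.tsv", sep="\t", index=False)
        record[f"ora_{seed_mol}"] = {"module_pcgs": len(pcgs),
                                     "sig_fdr0.05": int((ora["FDR"] < 0.05).sum())}
    return record
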