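"""Synthetic MDS-like cohort generator with recorded ground truth.

Emulates the statistical structure of a three-group cohort (healthy
controls, lower-risk and higher-risk MDS patients) profiled by parallel
RNA-seq (transposable elements + protein-coding genes) and small RNA-seq
(piRNAs):

* negative-binomial count matrices with a group-level log2 shift of TE
  expression (suppression in HR-MDS) and piRNA expression (elevation in
  HR-MDS);
* a latent bivariate-normal per-sample factor pair driving total TE and
  total piRNA levels with a configurable (negative) correlation;
* ``PIWIL2`` latent log-expression coupled to the piRNA factor;
* clinical covariates with blast counts enriched above 5% in the HR group;
* exponential overall/progression-free survival with group, age and
  latent-factor effects plus independent uniform censoring;
* raw small-RNA reads (insert + 3' adapter + UMI) with configurable PCR
  duplication and substitution errors.

Every stochastic choice is recorded in a :class:`SyntheticTruth` object so
downstream stages can be tested by parameter recovery.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
import yaml

from piwiflow.containers import ConfigError, CountMatrix, IntegrityError

GROUPS = ("CTR", "LR-MDS", "HR-MDS")
BASES = np.array(list("ACGT"))

#: 3' adapter of the QIAseq-style small-RNA read layout (configurable).
DEFAULT_ADAPTER = "AACTGTAGGCACCATCAAT"
DEFAULT_UMI_LEN = 12


@dataclass
class CohortConfig:
    """Parameters of the synthetic cohort.

    The defaults mirror the cohort shape and effect directions of the MDS
    study design this package targets: 17 controls / 45 LR-MDS / 35 HR-MDS,
    TE suppression and piRNA elevation in HR-MDS, a negative latent
    correlation between per-sample total TE and total piRNA levels, and a
    positive log hazard ratio for HR-MDS.
    """

    n_ctr: int = 17
    n_lr: int = 45
    n_hr: int = 35
    n_te: int = 687
    n_pirna: int = 257
    n_pcg: int = 1500
    #: mean log2 shift of every TE feature in HR-MDS (negative = suppression)
    te_hr_logfc: float = -1.0
    #: mean log2 shift of every piRNA feature in HR-MDS (positive = elevation)
    pirna_hr_logfc: float = 1.0
    #: correlation of the per-sample latent (TE, piRNA) factor pair
    latent_rho: float = -0.4
    #: NB dispersion alpha with variance = mu + alpha * mu^2
    dispersion: float = 0.2
    #: regression coefficient of PIWIL2 latent log2-expression on the piRNA factor
    piwil2_coupling: float = 1.0
    #: baseline OS hazard, events per month
    baseline_hazard: float = 0.02
    #: log hazard-ratio of HR-MDS vs LR-MDS
    hr_group_loghr: float = 1.1
    #: maximum administrative censoring time, months
    censor_time_max: float = 72.0
    seed: int = 0
    # --- secondary knobs (kept stable across analyses) ---
    #: SD of the latent per-sample factors on the log2 scale
    latent_sd: float = 0.5
    #: SD of per-sample library depth on the log2 scale (both libraries)
    depth_sd: float = 0.25
    #: expected fraction of total TE signal per class
    te_class_weights: Mapping[str, float] = field(
        default_factory=lambda: {"SINE": 0.79, "LINE": 0.15, "ERV": 0.06}
    )
    #: log hazard-ratio per year of age
    age_loghr: float = 0.03
    #: log hazard-ratio per unit of (piRNA factor - TE factor)
    latent_hazard_coef: float = 0.6
    #: PFS hazard as a multiple of the OS hazard
    pfs_hazard_mult: float = 1.4
    #: fraction of piRNA identifiers sharing a sequence with an earlier one
    pirna_duplicate_frac: float = 0.02
    #: miRNA-like background features of the small-RNA library; they carry no
    #: group shift or latent coupling and anchor median-of-ratios size factors
    #: (as the stable miRNA majority does in real small RNA-seq data)
    n_mirna: int = 300

    def validate(self) -> None:
        for name in ("n_ctr", "n_lr", "n_hr", "n_te", "n_pirna", "n_pcg", "n_mirna"):
            v = getattr(self, name)
            if not isinstance(v, (int, np.integer)) or v <= 0:
                raise ConfigError(f"{name} must be a strictly positive integer, got {v!r}")
        if self.dispersion < 0:
            raise ConfigError(f"dispersion must be >= 0, got {self.dispersion!r}")
        if not -1.0 <= self.latent_rho <= 1.0:
            raise ConfigError(f"latent_rho must lie in [-1, 1], got {self.latent_rho!r}")
        if self.baseline_hazard <= 0:
            raise ConfigError(f"baseline_hazard must be > 0, got {self.baseline_hazard!r}")
        if self.censor_time_max <= 0:
            raise ConfigError(f"censor_time_max must be > 0, got {self.censor_time_max!r}")
        if self.latent_sd < 0:
            raise ConfigError(f"latent_sd must be >= 0, got {self.latent_sd!r}")
        if self.depth_sd < 0:
            raise ConfigError(f"depth_sd must be >= 0, got {self.depth_sd!r}")
        if not 0.0 <= self.pirna_duplicate_frac < 1.0:
            raise ConfigError(
                f"pirna_duplicate_frac must lie in [0, 1), got {self.pirna_duplicate_frac!r}"
            )
        if self.n_pcg < 2:
            raise ConfigError("n_pcg must be >= 2 to accommodate PIWIL2 and PIWIL4")


@dataclass
class SyntheticTruth:
    """Ground truth behind one generated cohort.

    Attributes
    ----------
    sample_factors
        Per-sample table: group, latent TE/piRNA factors, true OS/PFS
        hazards (MDS samples only for the hazards).
    feature_means
        Per-feature table: kind, baseline mean and true mean per group
        (before the per-sample latent factor and library depth).
    pirna_sequences
        Mapping from piRNA identifier to its reference nucleotide sequence.
    """

    sample_factors: pd.DataFrame
    feature_means: pd.DataFrame
    pirna_sequences: dict[str, str]


@dataclass
class Cohort:
    te_counts: CountMatrix
    pirna_counts: CountMatrix
    pcg_counts: CountMatrix
    mirna_counts: CountMatrix
    clinical: pd.DataFrame
    survival: pd.DataFrame
    truth: SyntheticTruth
    config: CohortConfig

    def rna_library(self) -> CountMatrix:
        """RNA-seq library: protein-coding genes + TEs share one library,
        so size factors are estimated on their combined matrix (the PCG
        majority anchors the median of ratios)."""
        return CountMatrix(
            pd.concat([self.pcg_counts.counts, self.te_counts.counts]),
            pd.concat([self.pcg_counts.annotations, self.te_counts.annotations]),
        )

    def small_library(self) -> CountMatrix:
        """Small RNA-seq library: piRNAs + miRNA-like background features."""
        return CountMatrix(
            pd.concat([self.mirna_counts.counts, self.pirna_counts.counts]),
            pd.concat([self.mirna_counts.annotations, self.pirna_counts.annotations]),
        )


def _nb_sample(rng: np.random.Generator, mu: np.ndarray, dispersion: float) -> np.ndarray:
    """NB draw with variance mu + dispersion * mu^2 (Poisson when dispersion=0)."""
    if dispersion == 0:
        return rng.poisson(mu)
    n = 1.0 / dispersion
    p = n / (n + mu)
    return rng.negative_binomial(n, p)


def _random_sequences(rng: np.random.Generator, n: int, lmin: int = 26, lmax: int = 31) -> list[str]:
    lengths = rng.integers(lmin, lmax + 1, size=n)
    return ["".join(rng.choice(BASES, size=l)) for l in lengths]


def _te_annotations(rng: np.random.Generator, n_te: int, weights: Mapping[str, float]) -> pd.DataFrame:
    classes = list(weights)
    probs = np.asarray([weights[c] for c in classes], dtype=float)
    probs = probs / probs.sum()
    clades = {"SINE": ["Alu", "MIR"], "LINE": ["L1", "L2"], "ERV": ["ERV1", "ERV2", "ERV3"]}
    ids, klass, clade = [], [], []
    # two named features exercised by the downstream per-molecule analyses
    ids += ["FAM", "HERV-Fc1"]
    klass += ["SINE", "ERV"]
    clade += ["Alu", "ERV1"]
    for i in range(n_te - 2):
        c = classes[rng.choice(len(classes), p=probs)]
        ids.append(f"TE{i + 1:04d}")
        klass.append(c)
        clade.append(clades.get(c, [c])[rng.integers(0, len(clades.get(c, [c])))])
    return pd.DataFrame({"kind": "TE", "class": klass, "clade": clade}, index=pd.Index(ids, name="id"))


def generate_cohort(config: CohortConfig) -> Cohort:
    """Generate count matrices, clinical/survival tables and ground truth.

    Counts are drawn NB(mean = baseline * 2**(group shift + latent factor)
    * library depth, dispersion); the two per-sample latent factors come
    from a bivariate normal with correlation ``latent_rho``; PIWIL2's mean
    is tied to the piRNA factor through ``piwil2_coupling``; OS/PFS times
    are exponential with log-hazard = log(baseline_hazard) + group, age and
    latent-factor terms, censored uniformly on (0, censor_time_max].
    """
    config.validate()
    rng = np.random.default_rng(config.seed)

    groups = np.repeat(GROUPS, [config.n_ctr, config.n_lr, config.n_hr])
    n = len(groups)
    samples = pd.Index([f"S{i + 1:03d}" for i in range(n)], name="sample")
    is_hr = (groups == "HR-MDS").astype(float)
    is_mds = groups != "CTR"

    # latent per-sample factor pair (log2 scale)
    cov = (config.latent_sd ** 2) * np.array(
        [[1.0, config.latent_rho], [config.latent_rho, 1.0]]
    )
    factors = rng.multivariate_normal([0.0, 0.0], cov, size=n)
    u_te, u_pi = factors[:, 0], factors[:, 1]

    # per-library sequencing depth (RNA-seq and small RNA-seq are separate libraries)
    depth_rna = 2.0 ** rng.normal(0.0, config.depth_sd, size=n)
    depth_small = 2.0 ** rng.normal(0.0, config.depth_sd, size=n)

    # --- TE matrix ---
    te_ann = _te_annotations(rng, config.n_te, config.te_class_weights)
    te_base = 2.0 ** rng.normal(6.0, 1.5, size=config.n_te)
    te_shift = config.te_hr_logfc * is_hr  # applied to every TE feature in HR
    te_mu = te_base[:, None] * 2.0 ** (te_shift + u_te)[None, :] * depth_rna[None, :]
    te_counts = _nb_sample(rng, te_mu, config.dispersion)

    # --- piRNA matrix ---
    pirna_ids = ["piR_018780"] + [f"piR_{i + 1:06d}" for i in range(config.n_pirna - 1)]
    pirna_ann = pd.DataFrame(
        {"kind": "piRNA", "class": "", "clade": ""}, index=pd.Index(pirna_ids, name="id")
    )
    pi_base = 2.0 ** rng.normal(7.0, 1.5, size=config.n_pirna)
    pi_shift = config.pirna_hr_logfc * is_hr
    pi_mu = pi_base[:, None] * 2.0 ** (pi_shift + u_pi)[None, :] * depth_small[None, :]
    pirna_counts = _nb_sample(rng, pi_mu, config.dispersion)

    # piRNA reference sequences, with a small piRNABank-style redundancy:
    # a fraction of identifiers reuse the sequence of an earlier identifier
    seqs = _random_sequences(rng, config.n_pirna)
    n_dup = int(round(config.pirna_duplicate_frac * config.n_pirna))
    if n_dup and config.n_pirna > n_dup:
        dup_targets = rng.integers(0, config.n_pirna - n_dup, size=n_dup)
        for k, tgt in enumerate(dup_targets):
            seqs[config.n_pirna - n_dup + k] = seqs[tgt]
    pirna_sequences = dict(zip(pirna_ids, seqs))

    # --- miRNA-like background of the small-RNA library ---
    mirna_ids = [f"MIR{i + 1:04d}" for i in range(config.n_mirna)]
    mirna_ann = pd.DataFrame(
        {"kind": "miRNA", "class": "", "clade": ""}, index=pd.Index(mirna_ids, name="id")
    )
    mirna_base = 2.0 ** rng.normal(8.0, 1.5, size=config.n_mirna)
    mirna_mu = mirna_base[:, None] * depth_small[None, :]
    mirna_counts = _nb_sample(rng, mirna_mu, config.dispersion)

    # --- PCG matrix (PIWIL2 coupled to the piRNA latent factor) ---
    pcg_ids = ["PIWIL2", "PIWIL4"] + [f"GENE{i + 1:04d}" for i in range(config.n_pcg - 2)]
    pcg_ann = pd.DataFrame(
        {"kind": "PCG", "class": "", "clade": ""}, index=pd.Index(pcg_ids, name="id")
    )
    pcg_base = 2.0 ** rng.normal(7.0, 1.5, size=config.n_pcg)
    pcg_log_shift = np.zeros((config.n_pcg, n))
    pcg_log_shift[0] = config.piwil2_coupling * u_pi  # PIWIL2
    pcg_mu = pcg_base[:, None] * 2.0 ** pcg_log_shift * depth_rna[None, :]
    pcg_counts = _nb_sample(rng, pcg_mu, config.dispersion)

    # --- clinical covariates ---
    age = np.clip(rng.normal(70.0, 10.0, size=n), 30.0, 95.0)
    sex_female = rng.random(n) < 0.45
    blasts = np.where(
        groups == "CTR",
        rng.uniform(0.0, 2.0, size=n),
        np.where(
            groups == "LR-MDS",
            np.clip(rng.gamma(1.5, 1.5, size=n), 0.0, 18.0),
            np.clip(3.0 + rng.gamma(2.0, 3.0, size=n), 0.0, 19.5),
        ),
    )
    hemoglobin = np.clip(rng.normal(10.0, 2.0, size=n) - 0.8 * is_hr, 4.0, 16.0)
    platelets = np.clip(rng.lognormal(np.log(150.0) - 0.4 * is_hr, 0.6, size=n), 5.0, 800.0)
    neutrophils = np.clip(rng.lognormal(np.log(1.6) - 0.3 * is_hr, 0.7, size=n), 0.05, 15.0)
    cyto_probs = {
        "CTR": [0.25, 0.6, 0.15, 0.0, 0.0],
        "LR-MDS": [0.15, 0.55, 0.2, 0.07, 0.03],
        "HR-MDS": [0.05, 0.3, 0.3, 0.2, 0.15],
    }
    cytogenetics = np.array(
        [rng.choice(5, p=cyto_probs[g]) for g in groups], dtype=int
    )
    ipssr = np.where(
        groups == "CTR", 0.0,
        np.where(groups == "LR-MDS", rng.uniform(1.0, 3.5, size=n), rng.uniform(4.0, 8.5, size=n)),
    )
    clinical = pd.DataFrame(
        {
            "group": groups,
            "age": np.round(age, 1),
            "sex": np.where(sex_female, "F", "M"),
            "blasts": np.round(blasts, 1),
            "hemoglobin": np.round(hemoglobin, 1),
            "platelets": np.round(platelets, 1),
            "neutrophils": np.round(neutrophils, 2),
            "cytogenetics": cytogenetics,
            "ipssr_score": np.round(ipssr, 1),
        },
        index=samples,
    )

    # --- survival (MDS patients only; controls are healthy donors) ---
    log_h = (
        math.log(config.baseline_hazard)
        + config.hr_group_loghr * is_hr
        + config.age_loghr * (age - 70.0)
        + config.latent_hazard_coef * (u_pi - u_te)
    )
    hazard_os = np.exp(log_h)
    hazard_pfs = hazard_os * config.pfs_hazard_mult
    records = []
    for endpoint, hazard in (("OS", hazard_os), ("PFS", hazard_pfs)):
        event_t = rng.exponential(1.0 / hazard)
        censor_t = rng.uniform(0.0, config.censor_time_max, size=n)
        censor_t = np.maximum(censor_t, 1e-3)  # censoring on (0, censor_time_max]
        time = np.minimum(event_t, censor_t)
        event = (event_t <= censor_t).astype(int)
        rec = pd.DataFrame(
            {"sample": samples, "endpoint": endpoint, "time": np.maximum(time, 1e-3), "event": event}
        )
        records.append(rec[np.asarray(is_mds)])
    survival = pd.concat(records, ignore_index=True)

    # --- ground truth ---
    sample_factors = pd.DataFrame(
        {
            "group": groups,
            "latent_te": u_te,
            "latent_pirna": u_pi,
            "depth_rna": depth_rna,
            "depth_small": depth_small,
            "hazard_os": np.where(is_mds, hazard_os, np.nan),
            "hazard_pfs": np.where(is_mds, hazard_pfs, np.nan),
        },
        index=samples,
    )
    fm_rows = []
    for ids, base, shift_hr, kind in (
        (te_ann.index, te_base, config.te_hr_logfc, "TE"),
        (pirna_ids, pi_base, config.pirna_hr_logfc, "piRNA"),
        (pcg_ids, pcg_base, 0.0, "PCG"),
        (mirna_ids, mirna_base, 0.0, "miRNA"),
    ):
        fm = pd.DataFrame(
            {
                "kind": kind,
                "baseline_mean": base,
                "mean_CTR": base,
                "mean_LR": base,
                "mean_HR": base * 2.0 ** shift_hr,
            },
            index=pd.Index(ids, name="id"),
        )
        fm_rows.append(fm)
    feature_means = pd.concat(fm_rows)

    truth = SyntheticTruth(
        sample_factors=sample_factors,
        feature_means=feature_means,
        pirna_sequences=pirna_sequences,
    )
    return Cohort(
        te_counts=CountMatrix(pd.DataFrame(te_counts, index=te_ann.index, columns=samples), te_ann),
        pirna_counts=CountMatrix(
            pd.DataFrame(pirna_counts, index=pirna_ann.index, columns=samples), pirna_ann
        ),
        pcg_counts=CountMatrix(pd.DataFrame(pcg_counts, index=pcg_ann.index, columns=samples), pcg_ann),
        mirna_counts=CountMatrix(
            pd.DataFrame(mirna_counts, index=mirna_ann.index, columns=samples), mirna_ann
        ),
        clinical=clinical,
        survival=survival,
        truth=truth,
        config=config,
    )


def molecule_table(pirna_molecule_counts: Mapping[str, int] | pd.Series) -> pd.DataFrame:
    """Expand per-piRNA molecule counts into one row per true molecule."""
    if isinstance(pirna_molecule_counts, pd.Series):
        items = pirna_molecule_counts.items()
    else:
        items = pirna_molecule_counts.items()
    rows = []
    k = 0
    for pid, cnt in items:
        for _ in range(int(cnt)):
            rows.append((f"mol{k:07d}", pid))
            k += 1
    return pd.DataFrame(rows, columns=["molecule_id", "pirna_id"])


def generate_reads(
    molecules: pd.DataFrame,
    reference: Mapping[str, str],
    out_fastq: str | Path,
    adapter: str = DEFAULT_ADAPTER,
    umi_len: int = DEFAULT_UMI_LEN,
    dup_rate: float = 0.0,
    error_rate: float = 0.0,
    seed: int = 0,
    read_length: int = 75,
) -> dict[str, int]:
    """Write a synthetic small-RNA FASTQ for a table of true molecules.

    Each read is ``insert + adapter + UMI`` padded with ``A`` to
    ``read_length``; every true molecule receives one random UMI and
    ``1 + Poisson(dup_rate)`` PCR copies that reuse it; substitution errors
    hit insert bases independently at ``error_rate`` (never reproducing the
    original base).  Returns counters: molecules, reads written.
    """
    if umi_len < 1:
        raise ConfigError(f"umi_len must be >= 1, got {umi_len!r}")
    unknown = set(molecules["pirna_id"]) - set(reference)
    if unknown:
        raise IntegrityError(f"molecules reference unknown piRNA identifiers: {sorted(unknown)[:5]}")
    rng = np.random.default_rng(seed)
    n_reads = 0
    with open(out_fastq, "w") as fh:
        for _, row in molecules.iterrows():
            insert = reference[row["pirna_id"]].upper().replace("U", "T")
            umi = "".join(rng.choice(BASES, size=umi_len))
            copies = 1 + rng.poisson(dup_rate)
            for c in range(copies):
                bases = np.array(list(insert))
                if error_rate > 0 and len(bases):
                    hit = rng.random(len(bases)) < error_rate
                    for i in np.flatnonzero(hit):
                        choices = [b for b in "ACGT" if b != bases[i]]
                        bases[i] = choices[rng.integers(0, 3)]
                seq = "".join(bases) + adapter + umi
                if len(seq) < read_length:
                    seq = seq + "A" * (read_length - len(seq))
                fh.write(f"@{row['molecule_id']}:{c}\n{seq}\n+\n{'I' * len(seq)}\n")
                n_reads += 1
    return {"molecules": int(len(molecules)), "reads": n_reads}


def write_reference_fasta(reference: Mapping[str, str], path: str | Path) -> None:
    with open(path, "w") as fh:
        for pid, seq in reference.items():
            fh.write(f">{pid}\n{seq}\n")


def write_cohort(cohort: Cohort, outdir: str | Path) -> dict[str, str]:
    """Write the cohort as plain TSV/FASTA files plus a YAML run manifest."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {}
    for name, cm in (
        ("te_counts", cohort.te_counts),
        ("pirna_counts", cohort.pirna_counts),
        ("pcg_counts", cohort.pcg_counts),
        ("mirna_counts", cohort.mirna_counts),
    ):
        cpath = outdir / f"{name}.tsv"
        apath = outdir / f"{name}_annotations.tsv"
        cm.to_tsv(cpath, apath)
        paths[name] = str(cpath)
        paths[f"{name}_annotations"] = str(apath)
    cohort.clinical.to_csv(outdir / "clinical.tsv", sep="\t", index_label="sample")
    cohort.survival.to_csv(outdir / "survival.tsv", sep="\t", index=False)
    cohort.truth.sample_factors.to_csv(outdir / "truth_samples.tsv", sep="\t", index_label="sample")
    cohort.truth.feature_means.to_csv(outdir / "truth_features.tsv", sep="\t", index_label="id")
    write_reference_fasta(cohort.truth.pirna_sequences, outdir / "pirna_reference.fasta")
    paths.update(
        clinical=str(outdir / "clinical.tsv"),
        survival=str(outdir / "survival.tsv"),
        pirna_reference=str(outdir / "pirna_reference.fasta"),
    )
    cfg = asdict(cohort.config)
    cfg["te_class_weights"] = dict(cfg["te_class_weights"])
    manifest = {"config": cfg, "files": paths, "n_samples": int(cohort.clinical.shape[0])}
    with open(outdir / "manifest.yaml", "w") as fh:
        yaml.safe_dump(manifest, fh, sort_keys=True)
    paths["manifest"] = str(outdir / "manifest.yaml")
    return paths
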