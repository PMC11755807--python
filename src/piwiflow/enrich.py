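"""Gene-set enrichment: preranked GSEA running-sum statistic with
gene-label permutation significance, and hypergeometric over-representation
analysis (ORA) for network-module gene lists.

The enrichment score (ES) is the signed extremum of the classical
weighted Kolmogorov-Smirnov running sum over a ranked gene list: genes in
the set increment the sum by |score|^p normalized by the total hit weight,
genes outside decrement it by 1/(N - N_hit).  Significance uses gene-label
permutations (set membership reassigned to random rank positions), NES
normalization by the mean |null ES| of matching sign, add-one permutation
p-values and the sign-stratified NES-comparison FDR convention.
"""

from __future__ import annotations

from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests


def read_gmt(path: str | Path) -> dict[str, list[str]]:
    """Parse a GMT file: one set per line, ``name <tab> description <tab>
    gene1 <tab> gene2 ...``; duplicate genes within a set are dropped."""
    sets: dict[str, list[str]] = {}
    with open(path) as fh:
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 3 or not parts[0]:
                continue
            name = parts[0]
            if name in sets:
                raise ValueError(f"duplicate gene-set name {name!r} in {path}")
            seen: list[str] = []
            for g in parts[2:]:
                if g and g not in seen:
                    seen.append(g)
            sets[name] = seen
    return sets


def write_gmt(sets: Mapping[str, Sequence[str]], path: str | Path) -> None:
    with open(path, "w") as fh:
        for name, genes in sets.items():
            fh.write(name + "\tna\t" + "\t".join(genes) + "\n")


def _rank(scores: pd.Series) -> pd.Series:
    """Descending score order with deterministic tie-break by gene id."""
    s = pd.Series(scores, dtype=float)
    if s.index.duplicated().any():
        raise ValueError("ranked gene list must have unique genes")
    order = sorted(s.index, key=lambda g: (-s[g], str(g)))
    return s.loc[order]


def _es_from_positions(w: np.ndarray, positions: np.ndarray) -> float:
    """ES for hit positions (0-based, sorted ascending) in a ranked list
    whose per-rank hit weights are ``w`` (already |score|^p)."""
    n = w.size
    m = positions.size
    wh = w[positions]
    nr = wh.sum()
    inc = wh / nr if nr > 0 else np.full(m, 1.0 / m)
    dm = 1.0 / (n - m) if n > m else 0.0
    cum_hit = np.cumsum(inc)
    miss_before = positions - np.arange(m)
    after = cum_hit - miss_before * dm
    before = np.concatenate(([0.0], cum_hit[:-1])) - miss_before * dm
    pos_max = float(after.max())
    neg_min = float(min(before.min(), 0.0))
    return pos_max if pos_max >= -neg_min else neg_min


def gsea_es(scores: pd.Series, gene_set: Iterable[str], weight: float = 1.0) -> float:
    """Enrichment score of one gene set against a scored gene list.

    ``scores`` maps gene to ranking score (e.g. a signed test statistic);
    the list is ranked by descending score internally.  Only set genes
    present in the list count as hits.
    """
    ranked = _rank(scores)
    genes = list(ranked.index)
    hit = np.array([g in set(gene_set) for g in genes])
    if not hit.any():
        raise ValueError("gene set has no overlap with the ranked list")
    w = np.abs(ranked.to_numpy()) ** weight
    return _es_from_positions(w, np.flatnonzero(hit))


def gsea_significance(
    scores: pd.Series,
    sets: Mapping[str, Sequence[str]],
    n_perm: int = 1000,
    seed: int = 0,
    weight: float = 1.0,
    fdr_flag: float = 0.2,
) -> pd.DataFrame:
    """Permutation significance for a collection of gene sets.

    Returns a DataFrame (set, size, ES, NES, p, FDR, flagged, leading_edge)
    sorted by FDR then set name.  ``flagged`` marks sets below the
    ``fdr_flag`` FDR threshold (0.2 by default).
    """
    if n_perm < 100:
        raise ValueError("n_perm must be >= 100")
    ranked = _rank(scores)
    genes = list(ranked.index)
    gene_pos = {g: i for i, g in enumerate(genes)}
    n = len(genes)
    w = np.abs(ranked.to_numpy()) ** weight
    rng = np.random.default_rng(seed)

    names, sizes, es_obs, leading = [], [], [], []
    null_es: list[np.ndarray] = []
    for name, members in sets.items():
        positions = np.array(sorted(gene_pos[g] for g in members if g in gene_pos), dtype=int)
        if positions.size == 0:
            continue
        m = positions.size
        es = _es_from_positions(w, positions)
        null = np.empty(n_perm)
        for b in range(n_perm):
            perm = np.sort(rng.choice(n, size=m, replace=False))
            null[b] = _es_from_positions(w, perm)
        # leading edge: hits at or before the extremum of the running sum
        le = _leading_edge(w, positions, es, genes)
        names.append(name)
        sizes.append(m)
        es_obs.append(es)
        null_es.append(null)
        leading.append(",".join(le))

    es_obs_arr = np.array(es_obs)
    nes_obs = np.full(len(names), np.nan)
    pvals = np.ones(len(names))
    nes_null_all: list[np.ndarray] = []
    for i, null in enumerate(null_es):
        same = null * np.sign(es_obs_arr[i]) > 0 if es_obs_arr[i] != 0 else np.zeros_like(null, bool)
        pos_mean = np.abs(null[null > 0]).mean() if (null > 0).any() else np.nan
        neg_mean = np.abs(null[null < 0]).mean() if (null < 0).any() else np.nan
        denom = pos_mean if es_obs_arr[i] >= 0 else neg_mean
        if np.isfinite(denom) and denom > 0:
            nes_obs[i] = es_obs_arr[i] / denom
        if same.any():
            pvals[i] = (1.0 + (np.abs(null[same]) >= abs(es_obs_arr[i])).sum()) / (1.0 + same.sum())
        # null NES for the FDR step, normalized per set and per sign
        nn = np.full_like(null, np.nan)
        if np.isfinite(pos_mean) and pos_mean > 0:
            nn[null > 0] = null[null > 0] / pos_mean
        if np.isfinite(neg_mean) and neg_mean > 0:
            nn[null < 0] = null[null < 0] / neg_mean
        nes_null_all.append(nn[np.isfinite(nn)])

    pool = np.concatenate(nes_null_all) if nes_null_all else np.empty(0)
    fdr = np.ones(len(names))
    for i, nes in enumerate(nes_obs):
        if not np.isfinite(nes) or nes == 0:
            continue
        same_null = pool[np.sign(pool) == np.sign(nes)]
        same_obs = nes_obs[np.isfinite(nes_obs) & (np.sign(nes_obs) == np.sign(nes))]
        num = (np.abs(same_null) >= abs(nes)).mean() if same_null.size else 1.0
        den = (np.abs(same_obs) >= abs(nes)).mean() if same_obs.size else 1.0
        fdr[i] = min(1.0, num / den) if den > 0 else 1.0

    out = pd.DataFrame(
        {
            "set": names,
            "size": sizes,
            "ES": es_obs_arr,
            "NES": nes_obs,
            "p": pvals,
            "FDR": fdr,
            "flagged": fdr < fdr_flag,
            "leading_edge": leading,
        }
    ).sort_values(["FDR", "set"], kind="stable").reset_index(drop=True)
    return out


def _leading_edge(w: np.ndarray, positions: np.ndarray, es: float, genes: list[str]) -> list[str]:
    n, m = w.size, positions.size
    wh = w[positions]
    nr = wh.sum()
    inc = wh / nr if nr > 0 else np.full(m, 1.0 / m)
    dm = 1.0 / (n - m) if n > m else 0.0
    cum_hit = np.cumsum(inc)
    miss_before = positions - np.arange(m)
    after = cum_hit - miss_before * dm
    before = np.concatenate(([0.0], cum_hit[:-1])) - miss_before * dm
    if es >= 0:
        peak = int(np.argmax(after))
        return [genes[p] for p in positions[: peak + 1]]
    trough = int(np.argmin(before))
    return [genes[p] for p in positions[trough:]]


def ora_hypergeom(
    module_genes: Iterable[str],
    universe: Iterable[str],
    sets: Mapping[str, Sequence[str]],
) -> pd.DataFrame:
    """Upper-tail hypergeometric over-representation of each set in a module.

    P(X >= k) for overlap k given |universe| = M, |set n universe| = K and
    |module| = n, with BH FDR across sets.  The module must be a subset of
    the universe.
    """
    module = set(module_genes)
    uni = set(universe)
    if not module <= uni:
        raise ValueError("module genes must be a subset of the universe")
    m_size = len(module)
    m_total = len(uni)
    rows = []
    for name, members in sets.items():
        in_uni = set(members) & uni
        k = len(module & in_uni)
        p = float(stats.hypergeom.sf(k - 1, m_total, len(in_uni), m_size))
        rows.append((name, len(in_uni), k, min(p, 1.0)))
    out = pd.DataFrame(rows, columns=["set", "set_size", "overlap", "p"])
    if len(out):
        _, fdr, _, _ = multipletests(out["p"], method="fdr_bh")
        out["FDR"] = fdr
    else:
        out["FDR"] = []
    return out.sort_values(["p", "set"], kind="stable").reset_index(drop=True)
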