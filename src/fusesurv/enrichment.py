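"""Embedding-to-pathway interpretation.

Genes are ranked by their Spearman correlation with one embedding
dimension across samples; the ranked list feeds a preranked gene-set
enrichment analysis (weighted Kolmogorov-Smirnov running sum with a
gene-label permutation null, NES normalized by the signed-null mean,
BH-adjusted permutation p-values), and individual features can be
median-split for Kaplan-Meier / log-rank survival stratification.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .metrics import km_estimate, log_rank_test

logger = logging.getLogger(__name__)

__all__ = [
    "RankedGeneList",
    "EnrichmentResult",
    "read_gmt",
    "spearman_rank_genes",
    "enrichment_score",
    "gsea_preranked",
    "median_stratify_survival",
]


@dataclass
class RankedGeneList:
    """Genes with Spearman scores, sorted descending (ties by gene id)."""

    genes: np.ndarray
    scores: np.ndarray
    constant_flags: np.ndarray | None = None

    def __post_init__(self):
        if len(self.genes) != len(self.scores):
            raise ValueError("genes and scores must align")


@dataclass
class EnrichmentResult:
    table: pd.DataFrame  # per set: es, nes, p, q, n_hits
    leading_edge: dict  # set name -> list of genes


def read_gmt(path) -> dict:
    """Standard GMT: one set per line (name, description, member genes)."""
    sets = {}
    with open(path) as fh:
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 3:
                continue
            sets[parts[0]] = [g for g in parts[2:] if g]
    return sets


def spearman_rank_genes(embedding_dim, expr, genes=None) -> RankedGeneList:
    """Per-gene Spearman rho (average-rank ties) against an embedding
    dimension, sorted descending with ties broken by gene identifier.
    Constant genes get rho = 0 and are flagged."""
    e = np.asarray(embedding_dim, float)
    if len(e) < 3:
        raise ValueError("need at least 3 samples for a rank correlation")
    if isinstance(expr, pd.DataFrame):
        genes = np.asarray(expr.columns)
        X = expr.to_numpy(float)
    else:
        X = np.asarray(expr, float)
        genes = np.asarray(genes if genes is not None else np.arange(X.shape[1]))
    re = stats.rankdata(e)
    rx = stats.rankdata(X, axis=0)
    re_c = re - re.mean()
    rx_c = rx - rx.mean(axis=0)
    denom = np.sqrt((re_c**2).sum() * (rx_c**2).sum(axis=0))
    constant = denom == 0
    with np.errstate(invalid="ignore", divide="ignore"):
        rho = (re_c @ rx_c) / denom
    rho = np.where(constant, 0.0, rho)
    order = np.lexsort((genes, -rho))
    return RankedGeneList(
        genes=genes[order], scores=rho[order], constant_flags=constant[order]
    )


def enrichment_score(ranked_scores, hit_mask, p: float = 1.0):
    """Weighted KS running sum; returns (ES, running_sum, peak_index).

    Hit steps are proportional to ``|score|**p`` (normalized over hits),
    miss steps uniform, so the sum returns to 0 at the end of the list;
    ES is the extremum of largest magnitude (signed).
    """
    s = np.abs(np.asarray(ranked_scores, float)) ** p
    hit = np.asarray(hit_mask, bool)
    nr = s[hit].sum()
    n_miss = (~hit).sum()
    if nr == 0 or n_miss == 0:
        raise ValueError("gene set hits (with nonzero weight) and misses both required")
    steps = np.where(hit, s / nr, -1.0 / n_miss)
    running = np.cumsum(steps)
    peak = int(np.argmax(np.abs(running)))
    return float(running[peak]), running, peak


def gsea_preranked(ranked: RankedGeneList, sets: dict, weight: float = 1.0,
                   n_perm: int = 1000, seed: int = 0, min_size: int = 2) -> EnrichmentResult:
    """Preranked GSEA with a gene-label permutation null.

    Per set: ES from the weighted running sum; permutation p from nulls
    of matching ES sign; NES = ES / mean |null ES| of that sign; FDR via
    Benjamini-Hochberg over the permutation p-values. Sets overlapping
    the ranking in fewer than ``min_size`` genes are skipped (logged).
    """
    genes = ranked.genes
    scores = ranked.scores
    rng = np.random.default_rng(seed)
    gene_pos = {g: i for i, g in enumerate(genes)}
    rows = []
    leading = {}
    null_cache = {}
    for name, members in sets.items():
        pos = np.array(sorted(gene_pos[g] for g in members if g in gene_pos), dtype=int)
        if len(pos) < min_size:
            logger.info("gsea: skipping %s (overlap %d < %d)", name, len(pos), min_size)
            continue
        hit = np.zeros(len(genes), dtype=bool)
        hit[pos] = True
        es, running, peak = enrichment_score(scores, hit, weight)
        k = len(pos)
        if k not in null_cache:
            null = np.empty(n_perm)
            for b in range(n_perm):
                perm_hit = np.zeros(len(genes), dtype=bool)
                perm_hit[rng.choice(len(genes), size=k, replace=False)] = True
                null[b], _, _ = enrichment_score(scores, perm_hit, weight)
            null_cache[k] = null
        null = null_cache[k]
        same_sign = null[np.sign(null) == np.sign(es)] if es != 0 else null
        if len(same_sign) == 0:
            pval = 1.0 / (n_perm + 1)
            nes = np.nan
        else:
            pval = (1 + np.sum(np.abs(same_sign) >= abs(es))) / (1 + len(same_sign))
            nes = es / np.mean(np.abs(same_sign))
        if es >= 0:
            le = [genes[i] for i in range(peak + 1) if hit[i]]
        else:
            le = [genes[i] for i in range(peak, len(genes)) if hit[i]]
        leading[name] = le
        rows.append({"set": name, "es": es, "nes": nes, "p": pval, "n_hits": k})
    table = pd.DataFrame(rows)
    if len(table):
        table["q"] = multipletests(table["p"], method="fdr_bh")[1]
        table = table.set_index("set")
    return EnrichmentResult(table=table, leading_edge=leading)


def median_stratify_survival(feature, time, event):
    """Median-split a feature into high (strictly above the median) and
    low groups; returns (groups, (chi2, p), {group: KM step function})."""
    x = np.asarray(feature, float)
    if np.all(x == x[0]):
        raise ValueError("feature is constant; cannot stratify")
    med = np.median(x)
    groups = np.where(x > med, "high", "low")
    n_tied = int(np.sum(x == med))
    if n_tied > 0.5 * len(x):
        sizes = {g: int(np.sum(groups == g)) for g in ("high", "low")}
        warnings.warn(f"more than half the values tie at the median; group sizes {sizes}")
    time = np.asarray(time, float)
    event = np.asarray(event, int)
    lr = log_rank_test(groups, time, event)
    km = {
        g: km_estimate(time[groups == g], event[groups == g]) for g in ("high", "low")
    }
    return groups, lr, km
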