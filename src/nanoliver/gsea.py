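"""Ranked gene-set enrichment from scratch.

Genes are ranked by the signed significance metric
``-log10(p) * sign(log2fc)``; a gene set's enrichment score (ES) is the
signed extremum of the weighted Kolmogorov-Smirnov running sum (hit
increments proportional to ``|metric|^w``, miss decrements ``1/(N - Nh)``).
The null is built by gene-label permutation — with triplicate designs
phenotype permutation is degenerate — and the normalized enrichment score
(NES), nominal p and FDR follow the sign-matched convention: positive and
negative scores are each compared against null scores of their own sign.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd


@dataclass
class RankedGeneList:
    """Genes with metrics in strictly decreasing rank order."""

    genes: list[str]
    metrics: np.ndarray

    def __len__(self) -> int:
        return len(self.genes)


@dataclass
class EnrichmentResult:
    name: str
    size: int
    es: float
    nes: float
    p_nominal: float
    fdr: float
    leading_edge: list[str] = field(default_factory=list)
    n_perm: int = 0
    seed: int | None = None
    flagged: bool = False  # degenerate same-sign null


def rank_genes(stats_table: pd.DataFrame, p_column: str = "p") -> RankedGeneList:
    """Rank a DE table by ``-log10(p) * sign(log2fc)``, descending.

    Zero p values are clipped to the smallest positive float before the
    log; genes with missing p are excluded.  Ties are broken by gene id so
    the order is deterministic.
    """
    tab = stats_table[stats_table[p_column].notna()]
    p = np.clip(tab[p_column].to_numpy(dtype=float), np.finfo(float).tiny, None)
    metric = -np.log10(p) * np.sign(tab["log2fc"].to_numpy(dtype=float))
    order = sorted(range(len(tab)), key=lambda i: (-metric[i], tab.index[i]))
    return RankedGeneList(
        genes=[tab.index[i] for i in order], metrics=metric[np.array(order, dtype=int)]
    )


def _es_core(metrics: np.ndarray, hit_mask: np.ndarray, weight: float) -> tuple[float, np.ndarray]:
    n = metrics.size
    n_hits = int(hit_mask.sum())
    if n_hits == 0:
        raise ValueError("gene set has no genes in the ranked list")
    if n_hits == n:
        raise ValueError("gene set covers every ranked gene; miss increment undefined")
    w = np.where(hit_mask, np.abs(metrics) ** weight, 0.0)
    total = w.sum()
    if total == 0:  # all hit metrics are exactly 0: fall back to equal weights
        w = hit_mask.astype(float)
        total = w.sum()
    steps = w / total - (~hit_mask).astype(float) / (n - n_hits)
    running = np.cumsum(steps)
    i_ext = int(np.argmax(np.abs(running)))
    return float(running[i_ext]), running


def enrichment_score(
    ranked: RankedGeneList, gene_set, weight: float = 1.0
) -> tuple[float, np.ndarray]:
    """Weighted KS enrichment score and the full running sum."""
    gene_set = set(gene_set)
    hit_mask = np.fromiter((g in gene_set for g in ranked.genes), dtype=bool, count=len(ranked))
    return _es_core(ranked.metrics, hit_mask, weight)


def leading_edge(ranked: RankedGeneList, gene_set, weight: float = 1.0) -> list[str]:
    """Hit genes at or before (after, for negative ES) the running-sum extremum."""
    gene_set = set(gene_set)
    hit_mask = np.fromiter((g in gene_set for g in ranked.genes), dtype=bool, count=len(ranked))
    es, running = _es_core(ranked.metrics, hit_mask, weight)
    i_ext = int(np.argmax(np.abs(running)))
    if es >= 0:
        idx = np.nonzero(hit_mask[: i_ext + 1])[0]
    else:
        idx = np.nonzero(hit_mask[i_ext:])[0] + i_ext
    return [ranked.genes[i] for i in idx]


def _null_es(
    metrics: np.ndarray, set_size: int, n_perm: int, rng: np.random.Generator, weight: float
) -> np.ndarray:
    """Null ES from random same-size gene-label sets, vectorized."""
    n = metrics.size
    absw = np.abs(metrics) ** weight
    out = np.empty(n_perm)
    for i in range(n_perm):
        idx = rng.choice(n, size=set_size, replace=False)
        hit = np.zeros(n, dtype=bool)
        hit[idx] = True
        w = np.where(hit, absw, 0.0)
        total = w.sum()
        if total == 0:
            w = hit.astype(float)
            total = float(set_size)
        running = np.cumsum(w / total - (~hit) / (n - set_size))
        out[i] = running[int(np.argmax(np.abs(running)))]
    return out


def permutation_test(
    ranked: RankedGeneList,
    gene_sets: dict[str, set],
    n_perm: int = 1000,
    seed: int = 0,
    weight: float = 1.0,
) -> list[EnrichmentResult]:
    """Gene-label permutation test for a collection of gene sets.

    Per set: null ES from ``n_perm`` random same-size sets;
    ``nes = es / mean(|null es| of matching sign)``;
    ``p = (1 + #{same-sign nulls with |null| >= |es|}) / (1 + n_same_sign)``.
    FDR compares each set's |NES| against the pooled sign-matched null NES
    distribution, divided by the fraction of observed |NES| at least as
    extreme (clipped to [p-floor, 1]).  Fully reproducible for fixed seed.
    """
    if n_perm < 100:
        raise ValueError("n_perm must be >= 100")
    rng = np.random.default_rng(seed)
    prelim = []
    null_nes_pool: list[np.ndarray] = []
    for name in sorted(gene_sets):
        gene_set = set(gene_sets[name]) & set(ranked.genes)
        es, _ = enrichment_score(ranked, gene_sets[name], weight)
        null = _null_es(ranked.metrics, len(gene_set), n_perm, rng, weight)
        same = null[np.sign(null) == np.sign(es)] if es != 0 else null
        flagged = same.size == 0
        denom = np.abs(same).mean() if same.size else np.abs(null).mean()
        denom = denom if denom > 0 else 1.0
        nes = es / denom
        p = (1.0 + int((np.abs(same) >= abs(es)).sum())) / (1.0 + same.size)
        p = max(p, 1.0 / (n_perm + 1.0))
        pos = null[null > 0]
        neg = null[null < 0]
        null_nes = np.concatenate(
            [
                pos / (pos.mean() if pos.size else 1.0),
                neg / (np.abs(neg).mean() if neg.size else 1.0),
            ]
        )
        null_nes_pool.append(null_nes)
        prelim.append((name, gene_set, es, nes, p, flagged))

    all_null_nes = np.concatenate(null_nes_pool) if null_nes_pool else np.array([])
    obs_nes = np.array([r[3] for r in prelim])
    results = []
    for name, gene_set, es, nes, p, flagged in prelim:
        if all_null_nes.size and nes != 0:
            same_null = all_null_nes[np.sign(all_null_nes) == np.sign(nes)]
            same_obs = obs_nes[np.sign(obs_nes) == np.sign(nes)]
            num = (np.abs(same_null) >= abs(nes)).mean() if same_null.size else 1.0
            den = (np.abs(same_obs) >= abs(nes)).mean() if same_obs.size else 1.0
            fdr = min(1.0, num / max(den, 1.0 / max(len(prelim), 1)))
        else:
            fdr = 1.0
        results.append(
            EnrichmentResult(
                name=name,
                size=len(gene_set),
                es=es,
                nes=nes,
                p_nominal=p,
                fdr=fdr,
                leading_edge=leading_edge(ranked, gene_set, weight),
                n_perm=n_perm,
                seed=seed,
                flagged=flagged,
            )
        )
    return results


def results_table(results: list[EnrichmentResult]) -> pd.DataFrame:
    """Tabulate enrichment results for TSV export."""
    return pd.DataFrame(
        {
            "name": [r.name for r in results],
            "size": [r.size for r in results],
            "es": [r.es for r in results],
            "nes": [r.nes for r in results],
            "p_nominal": [r.p_nominal for r in results],
            "fdr": [r.fdr for r in results],
            "leading_edge": [",".join(r.leading_edge) for r in results],
        }
    )
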