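"""Negative-binomial differential expression and gene-signature rules.

The test is a deliberately transparent approximation of the standard
NB-GLM Wald workflow: median-of-ratios size factors, method-of-moments
dispersion with a fitted mean-dispersion trend, delta-method standard
errors on the log2 fold change of normalized group means (pseudocount
0.5), a two-sided normal Wald p value and Benjamini-Hochberg adjustment.
No empirical-Bayes dispersion or fold-change shrinkage is applied.

Signature construction implements the study-style rules: strict
``baseMean > 50, FDR < 0.01, |log2FC| > 2`` filtering; per-direction
top-N with a deterministic ranking key; two-sample intersection for the
hepatocyte signature; an asymmetric up-capped/down-uncapped HCC
signature; and an at-least-k-of-n multi-study consensus.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

LOG2 = np.log(2.0)


@dataclass
class GeneSignature:
    """Direction-labelled gene sets with provenance of how they were built."""

    name: str
    up_genes: set[str]
    down_genes: set[str]
    provenance: dict = field(default_factory=dict)

    def __post_init__(self):
        overlap = self.up_genes & self.down_genes
        if overlap:
            raise ValueError(f"genes in both directions: {sorted(overlap)[:5]}")

    @property
    def size(self) -> int:
        return len(self.up_genes) + len(self.down_genes)


def size_factors(counts: pd.DataFrame) -> pd.Series:
    """Median-of-ratios normalization factors (unscaled).

    For each gene expressed in every sample, the ratio of each sample's
    count to the gene's geometric mean is computed; a sample's factor is
    the median ratio.  Requires at least one gene with nonzero counts in
    all samples.
    """
    all_pos = (counts > 0).all(axis=1)
    if not all_pos.any():
        raise ValueError(
            "no gene has nonzero counts in every sample; "
            "consider a pseudo-reference fallback on filtered genes"
        )
    sub = counts.loc[all_pos].astype(float)
    log_geo = np.log(sub).mean(axis=1)
    ratios = np.log(sub).sub(log_geo, axis=0)
    return np.exp(ratios.median(axis=0)).rename("size_factor")


def _fit_dispersion_trend(base_mean: np.ndarray, disp_raw: np.ndarray) -> np.ndarray:
    """Fit alpha(mu) = a0 + a1/mu across genes and evaluate it per gene.

    Uses only genes with a positive raw moment estimate; the fit is an
    iterated least squares with outlier trimming so a few wild
    method-of-moments estimates do not tilt the trend.
    """
    ok = (disp_raw > 0) & (base_mean > 0)
    if ok.sum() < 10:
        return np.maximum(disp_raw, 1e-8)
    x = 1.0 / base_mean[ok]
    y = disp_raw[ok]
    keep = np.ones(y.size, dtype=bool)
    a0, a1 = float(np.median(y)), 0.0
    for _ in range(5):
        X = np.column_stack([np.ones(keep.sum()), x[keep]])
        coef, *_ = np.linalg.lstsq(X, y[keep], rcond=None)
        a0, a1 = float(coef[0]), float(coef[1])
        pred = a0 + a1 * x
        resid = y - pred
        mad = np.median(np.abs(resid)) + 1e-12
        keep = np.abs(resid) < 5 * mad
    trend = a0 + a1 / np.maximum(base_mean, 1e-8)
    return np.maximum(trend, 1e-8)


def nb_wald_test(
    counts: pd.DataFrame,
    groups,
    size_factors_: pd.Series | None = None,
    reference: str | None = None,
    dispersion: str = "trend",
) -> pd.DataFrame:
    """Two-group NB Wald test on a genes × samples count matrix.

    ``groups`` labels each column; the fold change is
    treatment / ``reference`` (default: first label in sorted order).
    Dispersions are method-of-moments on normalized counts, either used
    gene-wise (``dispersion='genewise'``) or, by default, moderated by a
    fitted mean-dispersion trend (``'trend'``) which keeps the normal Wald
    statistic calibrated at triplicate sample sizes.  All-zero genes are
    excluded from testing (and from the BH adjustment).

    Returns a DataFrame indexed by gene with columns
    ``baseMean, log2fc, se, wald, p, padj``.
    """
    groups = pd.Series(list(groups), index=counts.columns)
    labels = sorted(groups.unique())
    if len(labels) != 2:
        raise ValueError(f"need exactly two groups, got {labels}")
    if reference is None:
        reference = labels[0]
    treatment = [g for g in labels if g != reference][0]
    if dispersion not in ("trend", "genewise"):
        raise ValueError("dispersion must be 'trend' or 'genewise'")

    nonzero = counts.sum(axis=1) > 0
    n_dropped = int((~nonzero).sum())
    if n_dropped:
        warnings.warn(f"{n_dropped} all-zero genes excluded from testing")
    counts = counts.loc[nonzero]

    if size_factors_ is None:
        size_factors_ = size_factors(counts)
    sf = size_factors_.reindex(counts.columns).to_numpy(dtype=float)
    q = counts.to_numpy(dtype=float) / sf[None, :]
    base_mean = q.mean(axis=1)

    cols_ref = (groups == reference).to_numpy()
    cols_trt = (groups == treatment).to_numpy()
    n_ref, n_trt = int(cols_ref.sum()), int(cols_trt.sum())
    if min(n_ref, n_trt) < 2:
        raise ValueError("need at least 2 samples per group")
    m_ref = q[:, cols_ref].mean(axis=1)
    m_trt = q[:, cols_trt].mean(axis=1)

    # pooled within-group variance of normalized counts -> moment dispersion
    var_ref = q[:, cols_ref].var(axis=1, ddof=1)
    var_trt = q[:, cols_trt].var(axis=1, ddof=1)
    pooled_var = ((n_ref - 1) * var_ref + (n_trt - 1) * var_trt) / (n_ref + n_trt - 2)
    # E[var of normalized count] ~ mu * mean(1/s) + alpha * mu^2
    inv_sf_ref = float(np.mean(1.0 / sf[cols_ref]))
    inv_sf_trt = float(np.mean(1.0 / sf[cols_trt]))
    inv_sf = (n_ref * inv_sf_ref + n_trt * inv_sf_trt) / (n_ref + n_trt)
    with np.errstate(divide="ignore", invalid="ignore"):
        disp_raw = (pooled_var - base_mean * inv_sf) / base_mean**2
    disp_raw = np.where(np.isfinite(disp_raw), disp_raw, 0.0)
    if dispersion == "trend":
        alpha = _fit_dispersion_trend(base_mean, disp_raw)
    else:
        alpha = np.maximum(disp_raw, 1e-8)

    pseudo = 0.5
    log2fc = np.log2(m_trt + pseudo) - np.log2(m_ref + pseudo)
    var_mean_ref = (m_ref * inv_sf_ref + alpha * m_ref**2) / n_ref
    var_mean_trt = (m_trt * inv_sf_trt + alpha * m_trt**2) / n_trt
    se = np.sqrt(
        var_mean_trt / ((m_trt + pseudo) ** 2) + var_mean_ref / ((m_ref + pseudo) ** 2)
    ) / LOG2
    se = np.maximum(se, 1e-12)
    wald = log2fc / se
    p = 2.0 * stats.norm.sf(np.abs(wald))
    padj = multipletests(p, method="fdr_bh")[1]
    return pd.DataFrame(
        {
            "baseMean": base_mean,
            "log2fc": log2fc,
            "se": se,
            "wald": wald,
            "p": p,
            "padj": np.maximum(padj, p),
        },
        index=counts.index,
    )


def filter_de(
    stats_table: pd.DataFrame,
    min_base_mean: float = 50.0,
    max_fdr: float = 0.01,
    min_abs_l2fc: float = 2.0,
) -> tuple[set[str], set[str]]:
    """Strict-inequality DE filter: baseMean > 50, FDR < 0.01, |l2fc| > 2.

    Returns ``(up_genes, down_genes)`` split by fold-change sign.
    """
    passing = stats_table[
        (stats_table["baseMean"] > min_base_mean)
        & (stats_table["padj"] < max_fdr)
        & (stats_table["log2fc"].abs() > min_abs_l2fc)
    ]
    up = set(passing.index[passing["log2fc"] > 0])
    down = set(passing.index[passing["log2fc"] < 0])
    return up, down


def top_n(
    stats_table: pd.DataFrame,
    direction: str,
    n: int = 500,
    genes: set[str] | None = None,
    rank_by: str = "padj",
) -> list[str]:
    """Top-``n`` genes of one direction among filter survivors.

    Default ranking: padj ascending, ties by |log2fc| descending, ties by
    gene id; ``rank_by='lfc'`` ranks by |log2fc| first instead.  Pass the
    relevant ``filter_de`` output as ``genes`` to restrict to survivors.
    """
    if direction not in ("up", "down"):
        raise ValueError("direction must be 'up' or 'down'")
    sub = stats_table
    if genes is not None:
        sub = sub.loc[sub.index.intersection(genes)]
    sub = sub[sub["log2fc"] > 0] if direction == "up" else sub[sub["log2fc"] < 0]
    df = sub.assign(_abs=sub["log2fc"].abs(), _gene=sub.index)
    if rank_by == "padj":
        df = df.sort_values(["padj", "_abs", "_gene"], ascending=[True, False, True])
    elif rank_by == "lfc":
        df = df.sort_values(["_abs", "padj", "_gene"], ascending=[False, True, True])
    else:
        raise ValueError("rank_by must be 'padj' or 'lfc'")
    return list(df.index[:n])


def build_hepatocyte_signature(
    stats_sample1: pd.DataFrame,
    stats_sample2: pd.DataFrame,
    n: int = 500,
    name: str = "hepatocyte",
    **filter_kwargs,
) -> GeneSignature:
    """Common hepatocyte signature from two primary-cell DE tables.

    Each sample's DE table (vs the same reference) is filtered and its
    top-``n`` up and down genes taken; the signature is the per-direction
    intersection.  A gene going up in one sample and down in the other is
    excluded and reported in provenance.
    """
    tops = {}
    for key, tab in (("s1", stats_sample1), ("s2", stats_sample2)):
        up, down = filter_de(tab, **filter_kwargs)
        tops[key] = {
            "up": set(top_n(tab, "up", n, genes=up)),
            "down": set(top_n(tab, "down", n, genes=down)),
        }
    up = tops["s1"]["up"] & tops["s2"]["up"]
    down = tops["s1"]["down"] & tops["s2"]["down"]
    conflicts = (tops["s1"]["up"] & tops["s2"]["down"]) | (tops["s1"]["down"] & tops["s2"]["up"])
    up -= conflicts
    down -= conflicts
    return GeneSignature(
        name=name,
        up_genes=up,
        down_genes=down,
        provenance={"top_n": n, "conflicts": sorted(conflicts), **filter_kwargs},
    )


def build_hcc_signature(
    stats_table: pd.DataFrame, n_up: int = 500, name: str = "HCC", **filter_kwargs
) -> GeneSignature:
    """HCC-style signature: top-``n_up`` upregulated genes, *all* passing
    downregulated genes (no cap on the down direction)."""
    up, down = filter_de(stats_table, **filter_kwargs)
    up_list = top_n(stats_table, "up", n_up, genes=up)
    if not up and not down:
        warnings.warn("no genes pass the DE filter; signature is empty")
    return GeneSignature(
        name=name,
        up_genes=set(up_list),
        down_genes=set(down),
        provenance={"n_up": n_up, "n_down_uncapped": len(down), **filter_kwargs},
    )


def consensus_signature(
    study_sets: list[tuple[set[str], set[str]]], k: int = 3, name: str = "consensus"
) -> GeneSignature:
    """Genes up (down) in at least ``k`` of the studies' up (down) sets.

    A gene reaching the threshold in both directions is excluded from both
    and reported in provenance.
    """
    if k > len(study_sets):
        raise ValueError(f"k={k} exceeds the number of studies ({len(study_sets)})")
    up_counts: dict[str, int] = {}
    down_counts: dict[str, int] = {}
    for up, down in study_sets:
        for g in up:
            up_counts[g] = up_counts.get(g, 0) + 1
        for g in down:
            down_counts[g] = down_counts.get(g, 0) + 1
    up = {g for g, c in up_counts.items() if c >= k}
    down = {g for g, c in down_counts.items() if c >= k}
    both = up & down
    return GeneSignature(
        name=name,
        up_genes=up - both,
        down_genes=down - both,
        provenance={"k": k, "n_studies": len(study_sets), "both_directions": sorted(both)},
    )
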