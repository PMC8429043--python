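"""Dual-context single-molecule methylation analysis for GpC-footprinting data.

NOMe-seq style experiments treat nuclei with the GpC methyltransferase
M.CviPI, so that cytosines in GC dinucleotides report chromatin
accessibility while cytosines in CG dinucleotides retain endogenous
methylation.  Read on a nanopore instrument without bisulfite conversion,
every cytosine carries one of two orthogonal signals, disambiguated purely
by sequence context:

* ``GCH`` — preceded by G, not followed by G: enzymatic, accessibility.
* ``HCG`` — followed by G, not preceded by G: endogenous CpG methylation.
* ``GCG`` — both patterns overlap: ambiguous, excluded from either track.
* ``HCH`` — neither: uninformative.

This module classifies contexts, scores per-site log-likelihood ratios with
a per-k-mer Gaussian naive-Bayes emission model, calls methylation states,
filters contaminant reads (cell-free DNA fully methylated by the enzyme),
aggregates calls into per-site proportions, smooths tracks with a
triangular kernel, and profiles promoter windows around TSSs.

Call tables are pandas DataFrames with columns
``chrom, strand, pos, context, read_id, llr, call`` (0-based positions of
the C on its own strand; LLR is the natural-log likelihood ratio of
methylated over unmethylated).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

CONTEXT_GCH = "GCH"
CONTEXT_HCG = "HCG"
CONTEXT_GCG = "GCG"
CONTEXT_HCH = "HCH"
CONTEXTS = (CONTEXT_GCH, CONTEXT_HCG, CONTEXT_GCG, CONTEXT_HCH)

#: Contexts produced by the GpC methyltransferase readout (accessibility).
GC_CONTEXTS = (CONTEXT_GCH, CONTEXT_GCG)

CALL_METH = "methylated"
CALL_UNMETH = "unmethylated"
CALL_AMBIG = "ambiguous"

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def revcomp(seq: str) -> str:
    """Reverse complement of a DNA string (ACGTN alphabet)."""
    return seq.translate(_COMPLEMENT)[::-1]


def classify_context(sequence: str, pos: int, strand: str) -> str | None:
    """Classify the cytosine at ``pos`` into GCH / HCG / GCG / HCH.

    ``pos`` is a 0-based coordinate on the forward (reference) strand.  For
    ``strand == '-'`` the reference base must be ``G`` (a C on the minus
    strand) and the flanks are read 5'->3' on the minus strand.

    Returns ``None`` when a flanking base falls outside the sequence
    (no-context sites, excluded downstream).  Raises ``ValueError`` when the
    base at ``pos`` is not a cytosine on the requested strand.
    """
    if strand not in ("+", "-"):
        raise ValueError(f"strand must be '+' or '-', got {strand!r}")
    base = sequence[pos]
    if strand == "+":
        if base != "C":
            raise ValueError(f"base at {pos} on + strand is {base!r}, not C")
        if pos == 0 or pos == len(sequence) - 1:
            return None
        prev, nxt = sequence[pos - 1], sequence[pos + 1]
    else:
        if base != "G":
            raise ValueError(f"base at {pos} on - strand is {base!r}, not C")
        if pos == 0 or pos == len(sequence) - 1:
            return None
        # 5' neighbour on the minus strand is the complement of pos+1
        prev = sequence[pos + 1].translate(_COMPLEMENT)
        nxt = sequence[pos - 1].translate(_COMPLEMENT)
    is_g_before = prev == "G"
    is_g_after = nxt == "G"
    if is_g_before and is_g_after:
        return CONTEXT_GCG
    if is_g_before:
        return CONTEXT_GCH
    if is_g_after:
        return CONTEXT_HCG
    return CONTEXT_HCH


def catalog_sites(sequence: str, chrom: str = "chr1") -> pd.DataFrame:
    """Catalog every cytosine on both strands with its context.

    Edge cytosines without both flanks are omitted.  Returns a DataFrame
    with columns ``chrom, pos, strand, context`` sorted by position.
    """
    rows: list[tuple[str, int, str, str]] = []
    for pos in range(1, len(sequence) - 1):
        base = sequence[pos]
        if base == "C":
            ctx = classify_context(sequence, pos, "+")
            if ctx is not None:
                rows.append((chrom, pos, "+", ctx))
        elif base == "G":
            ctx = classify_context(sequence, pos, "-")
            if ctx is not None:
                rows.append((chrom, pos, "-", ctx))
    return pd.DataFrame(rows, columns=["chrom", "pos", "strand", "context"])


# ---------------------------------------------------------------------------
# Emission model
# ---------------------------------------------------------------------------


@dataclass
class EmissionModel:
    """Per-k-mer Gaussian signal model for methylated vs unmethylated C.

    ``table`` is indexed by k-mer with columns
    ``mean_unmeth, sd_unmeth, mean_meth, sd_meth, n_unmeth, n_meth``.
    ``omitted`` lists k-mers dropped for having too few training events.
    """

    table: pd.DataFrame
    k: int = 6
    offset: int = 2
    omitted: list[str] = field(default_factory=list)

    def __contains__(self, kmer: str) -> bool:
        return kmer in self.table.index


def train_emission_model(
    events: pd.DataFrame,
    min_events: int = 20,
    sd_floor: float = 1e-6,
    k: int = 6,
    offset: int = 2,
) -> EmissionModel:
    """Fit per-(k-mer, label) Gaussian parameters from labeled signal events.

    ``events`` needs columns ``kmer, signal, label`` with labels ``meth`` /
    ``unmeth`` (training runs with known ground truth: PCR-amplified DNA is
    fully unmethylated; enzyme-treated PCR product fully methylated).
    K-mers with fewer than ``min_events`` events for either label are
    omitted and reported.  Zero-variance fits are floored at ``sd_floor``
    with a warning.
    """
    required = {"kmer", "signal", "label"}
    if not required.issubset(events.columns):
        raise ValueError(f"events must have columns {sorted(required)}")
    grouped = events.groupby(["kmer", "label"])["signal"].agg(["mean", "std", "count"])
    rows = {}
    omitted = []
    for kmer, sub in grouped.groupby(level=0):
        sub = sub.droplevel(0)
        if (
            "meth" not in sub.index
            or "unmeth" not in sub.index
            or sub.loc["meth", "count"] < min_events
            or sub.loc["unmeth", "count"] < min_events
        ):
            omitted.append(kmer)
            continue
        sd_u = sub.loc["unmeth", "std"]
        sd_m = sub.loc["meth", "std"]
        if not np.isfinite(sd_u) or sd_u < sd_floor or not np.isfinite(sd_m) or sd_m < sd_floor:
            warnings.warn(f"zero/near-zero variance for k-mer {kmer}; flooring sd at {sd_floor}")
            sd_u = max(sd_u if np.isfinite(sd_u) else 0.0, sd_floor)
            sd_m = max(sd_m if np.isfinite(sd_m) else 0.0, sd_floor)
        rows[kmer] = (
            sub.loc["unmeth", "mean"],
            sd_u,
            sub.loc["meth", "mean"],
            sd_m,
            int(sub.loc["unmeth", "count"]),
            int(sub.loc["meth", "count"]),
        )
    table = pd.DataFrame.from_dict(
        rows,
        orient="index",
        columns=["mean_unmeth", "sd_unmeth", "mean_meth", "sd_meth", "n_unmeth", "n_meth"],
    )
    table.index.name = "kmer"
    return EmissionModel(table=table, k=k, offset=offset, omitted=sorted(omitted))


def _log_normal_pdf(x: float, mean: float, sd: float) -> float:
    return -0.5 * math.log(2.0 * math.pi) - math.log(sd) - 0.5 * ((x - mean) / sd) ** 2


def score_site(
    events: list[tuple[str, float]],
    model: EmissionModel,
    skip_missing: bool = True,
) -> float:
    """Naive-Bayes LLR over the signal events covering one cytosine site.

    Each event is a ``(kmer, signal)`` pair; events are treated as
    independent, so the site LLR is the sum of per-event Gaussian
    log-density differences (methylated minus unmethylated).  Events whose
    k-mer is absent from the model are skipped when ``skip_missing`` (a
    count is available via :func:`score_site_detailed`), otherwise raise.
    """
    llr, _, n_skipped = score_site_detailed(events, model)
    if n_skipped and not skip_missing:
        raise KeyError(f"{n_skipped} event k-mer(s) missing from emission model")
    return llr


def score_site_detailed(
    events: list[tuple[str, float]], model: EmissionModel
) -> tuple[float, int, int]:
    """Like :func:`score_site` but returns ``(llr, n_used, n_skipped)``."""
    llr = 0.0
    n_used = 0
    n_skipped = 0
    tab = model.table
    for kmer, signal in events:
        if kmer not in tab.index:
            n_skipped += 1
            continue
        row = tab.loc[kmer]
        llr += _log_normal_pdf(signal, row["mean_meth"], row["sd_meth"]) - _log_normal_pdf(
            signal, row["mean_unmeth"], row["sd_unmeth"]
        )
        n_used += 1
    return llr, n_used, n_skipped


# ---------------------------------------------------------------------------
# Calling and filtering
# ---------------------------------------------------------------------------


def call_methylation(llr: float, threshold: float = 2.0) -> str:
    """Three-way call from an LLR: the boundary ``|llr| == threshold`` is
    a definite call, the open interval in between is ambiguous."""
    if threshold <= 0:
        raise ValueError("threshold must be positive")
    if llr >= threshold:
        return CALL_METH
    if llr <= -threshold:
        return CALL_UNMETH
    return CALL_AMBIG


def call_table(calls: pd.DataFrame, threshold: float = 2.0) -> pd.DataFrame:
    """Vectorized :func:`call_methylation` adding/overwriting a ``call``
    column on a call-table DataFrame."""
    if threshold <= 0:
        raise ValueError("threshold must be positive")
    llr = calls["llr"].to_numpy()
    out = np.where(llr >= threshold, CALL_METH, np.where(llr <= -threshold, CALL_UNMETH, CALL_AMBIG))
    calls = calls.copy()
    calls["call"] = out
    return calls


def filter_contaminant_reads(
    calls: pd.DataFrame,
    window_sites: int = 80,
    min_frac: float = 0.75,
) -> tuple[pd.DataFrame, list[str]]:
    """Drop reads that look like fully GpC-methylated contaminant DNA.

    A read is dropped iff some window of exactly ``window_sites``
    consecutive GC-context calls (GCH or GCG, in genomic order, ambiguous
    calls excluded from both the count and window membership) contains at
    least ``ceil(min_frac * window_sites)`` methylated calls.  Reads with
    fewer than ``window_sites`` informative GC calls are always kept, so
    "at least 80 sites" is honoured: any longer qualifying stretch contains
    a qualifying 80-site window.

    Returns ``(kept_calls, dropped_read_ids)``.
    """
    need = int(math.ceil(min_frac * window_sites))
    dropped: list[str] = []
    gc = calls[calls["context"].isin(GC_CONTEXTS) & (calls["call"] != CALL_AMBIG)]
    for read_id, sub in gc.groupby("read_id", sort=False):
        m = (sub.sort_values("pos")["call"] == CALL_METH).to_numpy(dtype=int)
        if m.size < window_sites:
            continue
        csum = np.concatenate([[0], np.cumsum(m)])
        window_counts = csum[window_sites:] - csum[:-window_sites]
        if window_counts.max() >= need:
            dropped.append(read_id)
    kept = calls[~calls["read_id"].isin(dropped)]
    return kept, dropped


def aggregate_sites(calls: pd.DataFrame, min_coverage: int = 4) -> pd.DataFrame:
    """Per-site methylation proportions over definite calls.

    proportion = methylated / (methylated + unmethylated); ambiguous calls
    count in neither term.  Sites with fewer than ``min_coverage`` definite
    calls are excluded.  Contaminant reads should already be removed.
    """
    definite = calls[calls["call"] != CALL_AMBIG]
    grouped = definite.groupby(["chrom", "pos", "strand", "context"], sort=True)["call"]
    n_meth = grouped.apply(lambda s: int((s == CALL_METH).sum()))
    n_tot = grouped.size()
    out = pd.DataFrame({"n_meth": n_meth, "n_unmeth": n_tot - n_meth}).reset_index()
    cov = out["n_meth"] + out["n_unmeth"]
    out = out[cov >= min_coverage].reset_index(drop=True)
    out["proportion"] = out["n_meth"] / (out["n_meth"] + out["n_unmeth"])
    return out


# ---------------------------------------------------------------------------
# Smoothing and promoter profiles
# ---------------------------------------------------------------------------


def smooth_levels(values, width: int = 5) -> np.ndarray:
    """Triangular-kernel mean smoothing over an ordered site track.

    Weights for width 5 are (1, 2, 3, 2, 1); at the track edges the kernel
    is renormalized over the in-range sites, so a constant input maps to
    itself and the output stays within [min(x), max(x)].
    """
    if width < 1 or width % 2 == 0:
        raise ValueError("width must be a positive odd integer")
    x = np.asarray(values, dtype=float)
    n = x.size
    h = (width - 1) // 2
    w = np.array([h + 1 - abs(k) for k in range(-h, h + 1)], dtype=float)
    out = np.empty(n)
    for i in range(n):
        lo = max(0, i - h)
        hi = min(n, i + h + 1)
        ww = w[lo - i + h : hi - i + h]
        out[i] = np.dot(ww, x[lo:hi]) / ww.sum()
    return out


def smooth_track(summaries: pd.DataFrame, width: int = 5) -> pd.DataFrame:
    """Apply :func:`smooth_levels` per (chrom, strand, context) track,
    adding a ``smoothed_level`` column. Sites are ordered by position."""
    summaries = summaries.sort_values(["chrom", "strand", "context", "pos"]).copy()
    summaries["smoothed_level"] = np.nan
    for _, idx in summaries.groupby(["chrom", "strand", "context"], sort=False).groups.items():
        summaries.loc[idx, "smoothed_level"] = smooth_levels(
            summaries.loc[idx, "proportion"].to_numpy(), width
        )
    return summaries.reset_index(drop=True)


def promoter_profile(
    summaries: pd.DataFrame,
    tss: pd.DataFrame,
    flank: int = 1500,
    level_column: str = "proportion",
) -> pd.DataFrame:
    """Mean accessibility (GCH) and CpG methylation (HCG) around each TSS.

    ``tss`` needs columns ``gene, chrom, tss`` (0-based TSS positions).
    The window is the stated inclusive ``|pos - tss| <= flank``; GCG sites
    are excluded from both tracks.  Windows with zero sites of a context
    report NaN, never 0.
    """
    rows = []
    for _, t in tss.iterrows():
        near = summaries[
            (summaries["chrom"] == t["chrom"])
            & (summaries["pos"] >= t["tss"] - flank)
            & (summaries["pos"] <= t["tss"] + flank)
        ]
        gch = near[near["context"] == CONTEXT_GCH][level_column]
        hcg = near[near["context"] == CONTEXT_HCG][level_column]
        rows.append(
            {
                "gene": t["gene"],
                "chrom": t["chrom"],
                "tss": t["tss"],
                "mean_gch_level": gch.mean() if len(gch) else np.nan,
                "n_gch_sites": len(gch),
                "mean_hcg_level": hcg.mean() if len(hcg) else np.nan,
                "n_hcg_sites": len(hcg),
            }
        )
    return pd.DataFrame(rows)
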