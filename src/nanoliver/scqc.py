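"""Single-cell RNA-seq quality control and five-phase cell-cycle scoring.

Matrices are pandas DataFrames with cells as rows and genes as columns.
QC thresholds are class-specific (induced hepatocytes vs fetal-liver
oncogene samples carry different cutoffs) and the wording of the rules is
strict: a cell with *exactly* the minimum gene count or *exactly* the
mitochondrial ceiling passes.  Cell-cycle scores are per-phase means of
z-scored log-normalized marker expression, with a fixed phase order as the
tie-break for the argmax assignment.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

PHASES = ["G1/S", "S", "G2/M", "M", "M/G1"]


@dataclass
class ClassThresholds:
    min_mapped_reads: int | None
    min_genes: int
    max_mito_fraction: float


@dataclass
class QcThresholds:
    """Per-sample-class QC cutoffs; defaults follow the study conditions."""

    classes: dict[str, ClassThresholds] = field(
        default_factory=lambda: {
            "iHep": ClassThresholds(50_000, 4000, 0.06),
            "HFL_CMT": ClassThresholds(None, 2500, 0.10),
        }
    )


def cell_metrics(
    counts: pd.DataFrame, mito_prefixes: tuple[str, ...] = ("MT-", "mt-")
) -> pd.DataFrame:
    """Per-cell genes_detected and mito_fraction from a counts matrix."""
    totals = counts.sum(axis=1)
    mito_cols = [g for g in counts.columns if str(g).startswith(mito_prefixes)]
    mito = counts[mito_cols].sum(axis=1) if mito_cols else pd.Series(0.0, index=counts.index)
    return pd.DataFrame(
        {
            "genes_detected": (counts > 0).sum(axis=1),
            "mito_fraction": (mito / totals.replace(0, np.nan)).fillna(0.0),
        }
    )


def qc_filter(
    cells: pd.DataFrame,
    thresholds: QcThresholds | None = None,
    default_class: str | None = None,
) -> tuple[list[str], pd.DataFrame]:
    """Filter cells on mapped reads, genes detected, and mito fraction.

    ``cells`` needs columns ``mapped_reads, genes_detected, mito_fraction``
    and ``sample_class`` (or pass ``default_class``).  Exclusion is strict
    ("fewer than" / "greater than"): boundary values are kept.

    Returns ``(kept_cell_ids, excluded)`` where ``excluded`` lists each
    removed cell with a semicolon-joined reason string.
    """
    if thresholds is None:
        thresholds = QcThresholds()
    rows = []
    kept = []
    for cell_id, row in cells.iterrows():
        cls = row.get("sample_class", default_class) or default_class
        if cls is None or cls not in thresholds.classes:
            raise ValueError(
                f"unknown sample class {cls!r} for cell {cell_id}; pass default_class"
            )
        t = thresholds.classes[cls]
        reasons = []
        if t.min_mapped_reads is not None and row["mapped_reads"] < t.min_mapped_reads:
            reasons.append(f"mapped_reads<{t.min_mapped_reads}")
        if row["genes_detected"] < t.min_genes:
            reasons.append(f"genes_detected<{t.min_genes}")
        if row["mito_fraction"] > t.max_mito_fraction:
            reasons.append(f"mito_fraction>{t.max_mito_fraction}")
        if reasons:
            rows.append({"cell": cell_id, "reason": ";".join(reasons)})
        else:
            kept.append(cell_id)
    return kept, pd.DataFrame(rows, columns=["cell", "reason"])


def gene_filter(counts: pd.DataFrame, min_cells: int = 5) -> pd.DataFrame:
    """Keep genes detected (count > 0) in at least ``min_cells`` cells."""
    detected = (counts > 0).sum(axis=0)
    return counts.loc[:, detected >= min_cells]


def downsample_cells(
    counts: pd.DataFrame,
    n: int = 500,
    seed: int = 0,
    sample_labels: pd.Series | None = None,
) -> pd.DataFrame:
    """Uniformly subsample up to ``n`` cells per sample, without replacement.

    Samples with at most ``n`` cells pass through whole.  With no
    ``sample_labels`` the whole matrix is one sample.  Original row order
    is preserved; reproducible for fixed seed.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(seed)
    if sample_labels is None:
        sample_labels = pd.Series("all", index=counts.index)
    keep: list = []
    for label in pd.unique(sample_labels):
        ids = list(counts.index[sample_labels == label])
        if len(ids) <= n:
            keep.extend(ids)
        else:
            chosen = rng.choice(len(ids), size=n, replace=False)
            keep.extend(ids[i] for i in sorted(chosen))
    return counts.loc[[c for c in counts.index if c in set(keep)]]


def lognormalize(counts: pd.DataFrame, scale: float = 10_000.0) -> pd.DataFrame:
    """Library-size normalize and log-transform: ln(1 + scale·x/total)."""
    totals = counts.sum(axis=1)
    if (totals == 0).any():
        bad = list(counts.index[totals == 0])[:5]
        raise ValueError(f"zero-total cells (should not survive QC): {bad}")
    return np.log1p(counts.div(totals, axis=0) * scale)


def cell_cycle_scores(
    normalized: pd.DataFrame,
    phase_markers: dict[str, list[str]],
    standardize: bool = True,
) -> pd.DataFrame:
    """Five-phase cell-cycle scores and argmax phase assignment.

    Each phase score is the mean over that phase's marker genes of the
    gene's expression z-scored across cells (``standardize=False`` uses the
    raw normalized mean instead).  Markers absent from the matrix are
    dropped (reported via the returned frame's ``attrs['missing_markers']``);
    a phase with zero present markers is an error.  Ties in the argmax are
    broken by the fixed phase order G1/S < S < G2/M < M < M/G1.
    """
    missing: dict[str, list[str]] = {}
    scores = pd.DataFrame(index=normalized.index)
    for phase in PHASES:
        if phase not in phase_markers:
            raise ValueError(f"missing marker list for phase {phase}")
        present = [g for g in phase_markers[phase] if g in normalized.columns]
        absent = [g for g in phase_markers[phase] if g not in normalized.columns]
        if absent:
            missing[phase] = absent
        if not present:
            raise ValueError(f"no markers for phase {phase} present in the matrix")
        sub = normalized[present]
        if standardize:
            sd = sub.std(axis=0, ddof=0)
            sub = (sub - sub.mean(axis=0)).div(sd.replace(0, np.nan), axis=1).fillna(0.0)
        scores[phase] = sub.mean(axis=1)
    assigned = scores[PHASES].to_numpy().argmax(axis=1)  # argmax takes first max: phase order
    scores["assigned_phase"] = [PHASES[i] for i in assigned]
    scores.attrs["missing_markers"] = missing
    return scores


def relative_expression(normalized: pd.DataFrame) -> pd.DataFrame:
    """Expression of each gene in each cell relative to the gene's mean
    across all cells; genes with zero mean are excluded (reported via
    ``attrs['excluded_genes']``)."""
    means = normalized.mean(axis=0)
    excluded = list(means.index[means == 0])
    kept = normalized.loc[:, means > 0]
    out = kept.div(means[means > 0], axis=1)
    out.attrs["excluded_genes"] = excluded
    return out
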