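"""Synthetic data with ground truth for every pipeline stage.

Each generator is a pure function of its arguments and an explicit seed
(one ``numpy.random.Generator`` per call, no global state), and emits truth
tables sufficient to score the downstream analysis:

* a random genome with planted promoters and TSSs,
* a true methylome (per-site binary states: open promoters carry enzymatic
  GCH methylation, background is mostly closed; HCG methylation is a
  genome-wide Bernoulli),
* per-read methylation call tables with Gaussian LLR noise and a tunable
  fraction of contaminant (near-fully GC-methylated) reads,
* negative-binomial bulk count matrices with planted fold changes,
* single-cell count matrices with planted cell-cycle phases and planted
  low-quality cells,
* chimeric long reads spanning vector backbone, insert and host flanks.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .methylation import CALL_AMBIG, CALL_METH, CALL_UNMETH, GC_CONTEXTS, catalog_sites

PHASES = ["G1/S", "S", "G2/M", "M", "M/G1"]


@dataclass
class SyntheticGenome:
    """A random ACGT genome with annotated promoters and TSSs."""

    name: str
    sequence: str
    tss_list: list[tuple[int, str]]
    promoters: list[tuple[int, int]] = field(default_factory=list)  # 0-based half-open

    def __post_init__(self):
        if not self.sequence:
            raise ValueError("sequence must be non-empty")
        if set(self.sequence) - set("ACGT"):
            raise ValueError("sequence alphabet restricted to ACGT")
        for pos, _ in self.tss_list:
            if not 0 <= pos < len(self.sequence):
                raise ValueError(f"TSS position {pos} outside genome")

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass
class TrueMethylome:
    """Per-site latent methylation states plus the open-chromatin intervals."""

    genome: SyntheticGenome
    sites: pd.DataFrame  # chrom, pos, strand, context, true_state
    promoters: list[tuple[int, int]]
    seed: int


@dataclass
class SimulationConfig:
    """Knobs for all generators; defaults are the study conditions."""

    seed: int = 0
    # NaNoMe call-table simulation
    coverage: float = 20.0
    llr_mean_effect: float = 4.0
    llr_sd: float = 1.0
    contamination_fraction: float = 0.05
    read_length: int = 5000
    # bulk RNA-seq
    n_genes: int = 5000
    n_samples_per_group: int = 3
    de_fraction: float = 0.1
    lfc_scale: float = 3.0
    dispersion_scale: float = 0.05
    # single-cell RNA-seq
    n_cells: int = 500
    phase_proportions: tuple[float, ...] = (0.2, 0.2, 0.2, 0.2, 0.2)
    lowq_fraction: float = 0.1

    def __post_init__(self):
        for name in ("contamination_fraction", "de_fraction", "lowq_fraction"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if abs(sum(self.phase_proportions) - 1.0) > 1e-9:
            raise ValueError("phase_proportions must sum to 1")
        if self.llr_sd < 0 or self.llr_mean_effect < 0:
            raise ValueError("llr noise parameters must be non-negative")


def make_genome(
    length: int,
    gc_fraction: float = 0.45,
    n_promoters: int = 8,
    seed: int = 0,
    promoter_width: int = 200,
    name: str = "chrS",
) -> SyntheticGenome:
    """Random genome with ``n_promoters`` non-overlapping promoters.

    Bases are i.i.d. with P(G) = P(C) = gc_fraction/2.  Each promoter is a
    ``promoter_width`` interval whose midpoint is the TSS (all forward
    strand); promoters are placed on a jittered grid so they never overlap.
    The default width mimics a nucleosome-depleted region: short enough
    that no 80-GC-site window fits inside one open promoter, as in real
    chromatin where accessible stretches are far smaller than the
    contaminant filter's window.
    """
    if length < 1000:
        raise ValueError("length must be >= 1000")
    if not 0.0 < gc_fraction < 1.0:
        raise ValueError("gc_fraction must be strictly between 0 and 1")
    if n_promoters * 2 * promoter_width > length:
        raise ValueError(
            f"length {length} too small to place {n_promoters} non-overlapping promoters"
        )
    rng = np.random.default_rng(seed)
    p = np.array([(1 - gc_fraction) / 2, gc_fraction / 2, gc_fraction / 2, (1 - gc_fraction) / 2])
    seq = "".join(rng.choice(list("ACGT"), size=length, p=p))
    promoters: list[tuple[int, int]] = []
    tss_list: list[tuple[int, str]] = []
    if n_promoters > 0:
        slot = length // n_promoters
        for i in range(n_promoters):
            lo = i * slot
            start = int(rng.integers(lo, lo + max(1, slot - promoter_width)))
            end = start + promoter_width
            promoters.append((start, end))
            tss_list.append(((start + end) // 2, "+"))
    return SyntheticGenome(name=name, sequence=seq, tss_list=tss_list, promoters=promoters)


def simulate_methylome(
    genome: SyntheticGenome,
    promoter_open_prob: float = 0.8,
    background_open_prob: float = 0.15,
    cpg_meth_prob: float = 0.7,
    seed: int = 0,
) -> TrueMethylome:
    """Assign true binary methylation states to every cytosine site.

    GCH sites inside promoter intervals are methylated (accessible) with
    ``promoter_open_prob``, elsewhere with ``background_open_prob``; HCG
    sites are methylated with ``cpg_meth_prob``.  GCG sites are generated
    (state drawn like GCH) but remain flagged ambiguous by their context.
    """
    for v in (promoter_open_prob, background_open_prob, cpg_meth_prob):
        if not 0.0 <= v <= 1.0:
            raise ValueError("probabilities must be in [0, 1]")
    sites = catalog_sites(genome.sequence, chrom=genome.name)
    if not (sites["context"].isin(GC_CONTEXTS)).any():
        raise ValueError("genome contains no GC-context sites")
    rng = np.random.default_rng(seed)
    pos = sites["pos"].to_numpy()
    in_promoter = np.zeros(len(sites), dtype=bool)
    for start, end in genome.promoters:
        in_promoter |= (pos >= start) & (pos < end)
    p_open = np.where(in_promoter, promoter_open_prob, background_open_prob)
    is_gc = sites["context"].isin(GC_CONTEXTS).to_numpy()
    p_meth = np.where(is_gc, p_open, np.where(sites["context"] == "HCG", cpg_meth_prob, 0.0))
    sites = sites.copy()
    sites["true_state"] = rng.random(len(sites)) < p_meth
    return TrueMethylome(genome=genome, sites=sites, promoters=list(genome.promoters), seed=seed)


def simulate_call_table(
    methylome: TrueMethylome, cfg: SimulationConfig
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-read, per-site LLR call table with truth labels.

    Reads cover contiguous intervals of ``cfg.read_length`` bp at mean
    depth ``cfg.coverage``.  At each covered informative site the LLR is
    drawn from Normal(+effect, sd) if the true state is methylated, else
    Normal(-effect, sd).  A ``contamination_fraction`` of reads have their
    GC-site states replaced by Bernoulli(0.9) methylated — emulating
    cell-free DNA fully exposed to the GpC enzyme — before LLRs are drawn.

    Returns ``(calls, read_truth)``; ``calls`` additionally carries the
    per-site ``true_state``, and ``read_truth`` has one row per read with
    its interval and contaminant flag.
    """
    if cfg.coverage < 1:
        raise ValueError("coverage must be >= 1")
    rng = np.random.default_rng(cfg.seed)
    genome_len = len(methylome.genome)
    read_length = min(cfg.read_length, genome_len)
    n_reads = max(1, int(round(cfg.coverage * genome_len / read_length)))
    sites = methylome.sites.sort_values("pos").reset_index(drop=True)
    site_pos = sites["pos"].to_numpy()
    is_contaminant = rng.random(n_reads) < cfg.contamination_fraction

    frames = []
    truth_rows = []
    for i in range(n_reads):
        start = int(rng.integers(0, max(1, genome_len - read_length + 1)))
        end = start + read_length
        lo, hi = np.searchsorted(site_pos, [start, end])
        covered = sites.iloc[lo:hi]
        state = covered["true_state"].to_numpy().copy()
        if is_contaminant[i]:
            gc_mask = covered["context"].isin(GC_CONTEXTS).to_numpy()
            state[gc_mask] = rng.random(gc_mask.sum()) < 0.9
        mean = np.where(state, cfg.llr_mean_effect, -cfg.llr_mean_effect)
        llr = rng.normal(mean, cfg.llr_sd) if cfg.llr_sd > 0 else mean.astype(float)
        frames.append(
            pd.DataFrame(
                {
                    "chrom": covered["chrom"].to_numpy(),
                    "strand": covered["strand"].to_numpy(),
                    "pos": covered["pos"].to_numpy(),
                    "context": covered["context"].to_numpy(),
                    "read_id": f"read_{i:05d}",
                    "llr": llr,
                    "true_state": state,
                }
            )
        )
        truth_rows.append(
            {
                "read_id": f"read_{i:05d}",
                "start": start,
                "end": end,
                "contaminant": bool(is_contaminant[i]),
            }
        )
    calls = pd.concat(frames, ignore_index=True)
    read_truth = pd.DataFrame(truth_rows)
    return calls, read_truth


def simulate_emission_events(
    kmers: list[str],
    n_per_label: int = 1000,
    mean_unmeth: float = 100.0,
    shift: float = 4.0,
    sd: float = 2.0,
    seed: int = 0,
) -> pd.DataFrame:
    """Labeled (kmer, signal, label) training events for the emission model.

    Each k-mer gets its own baseline current level (spread around
    ``mean_unmeth``); methylation shifts the level by ``shift`` pA-like
    units.  Returns the events along with columns ``true_mean`` for
    oracle checks.
    """
    rng = np.random.default_rng(seed)
    frames = []
    for kmer in kmers:
        base = mean_unmeth + rng.normal(0, 5)
        for label, mu in (("unmeth", base), ("meth", base + shift)):
            frames.append(
                pd.DataFrame(
                    {
                        "kmer": kmer,
                        "signal": rng.normal(mu, sd, size=n_per_label),
                        "label": label,
                        "true_mean": mu,
                        "true_sd": sd,
                    }
                )
            )
    return pd.concat(frames, ignore_index=True)


# ---------------------------------------------------------------------------
# Count matrices
# ---------------------------------------------------------------------------


def simulate_counts_bulk(cfg: SimulationConfig) -> tuple[pd.DataFrame, pd.DataFrame, np.ndarray]:
    """Two-group negative-binomial count matrix with planted DE genes.

    Gene means are log-normal (median ~200); dispersions are gene-wise,
    ``dispersion_scale`` on average; a ``de_fraction`` of genes carry a
    log2 fold change of ±``lfc_scale`` in group B.  Library-size factors
    are log-uniform in [2^-0.5, 2^0.5].

    Returns ``(counts, truth, size_factors)`` where ``counts`` is a
    genes × samples DataFrame (samples ``A_1.. B_n``) and ``truth`` has
    per-gene ``base_mean, true_log2fc, is_de, dispersion``.
    """
    if cfg.n_samples_per_group < 2:
        raise ValueError("need at least 2 samples per group")
    rng = np.random.default_rng(cfg.seed)
    n_genes, n = cfg.n_genes, cfg.n_samples_per_group
    genes = [f"gene_{i:05d}" for i in range(n_genes)]
    samples = [f"A_{j + 1}" for j in range(n)] + [f"B_{j + 1}" for j in range(n)]
    base_mean = np.exp(rng.normal(math.log(200.0), 1.0, size=n_genes))
    dispersion = cfg.dispersion_scale * np.exp(rng.normal(0, 0.3, size=n_genes))
    is_de = rng.random(n_genes) < cfg.de_fraction
    sign = rng.choice([-1.0, 1.0], size=n_genes)
    true_l2fc = np.where(is_de, sign * cfg.lfc_scale, 0.0)
    sf = np.exp2(rng.uniform(-0.5, 0.5, size=2 * n))

    mean_a = base_mean[:, None] * np.ones(n)[None, :]
    mean_b = base_mean[:, None] * np.exp2(true_l2fc)[:, None] * np.ones(n)[None, :]
    mu = np.concatenate([mean_a, mean_b], axis=1) * sf[None, :]
    # NB with mean mu and dispersion alpha: gamma-Poisson mixture
    shape = 1.0 / dispersion[:, None]
    lam = rng.gamma(shape, mu / shape)
    counts = rng.poisson(lam)
    counts_df = pd.DataFrame(counts, index=genes, columns=samples)
    truth = pd.DataFrame(
        {
            "gene": genes,
            "base_mean": base_mean,
            "true_log2fc": true_l2fc,
            "is_de": is_de,
            "dispersion": dispersion,
        }
    ).set_index("gene")
    return counts_df, truth, sf


def default_phase_markers(n_per_phase: int = 20) -> dict[str, list[str]]:
    """Disjoint synthetic marker gene lists, one per cell-cycle phase."""
    markers = {}
    for p, phase in enumerate(PHASES):
        tag = phase.replace("/", "")
        markers[phase] = [f"MK_{tag}_{i:02d}" for i in range(n_per_phase)]
    return markers


def simulate_counts_sc(
    cfg: SimulationConfig,
    phase_markers: dict[str, list[str]] | None = None,
    n_background_genes: int = 6000,
    marker_fold: float = 4.0,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Cell × gene count matrix with planted phases and low-quality cells.

    Cells are assigned one of the five cell-cycle phases by a multinomial
    draw of ``cfg.phase_proportions``; a cell overexpresses its own phase's
    marker genes ``marker_fold``-fold.  A ``lowq_fraction`` of cells are
    planted below QC thresholds: half get their counts thinned to detect
    few genes and few mapped reads, half get a high mitochondrial
    fraction.  Mitochondrial genes are named ``MT-xx``.  The gene-space is
    sized so that healthy cells detect well over the study's 4000-gene
    cutoff while thinned cells fall far below it.

    Returns ``(counts, truth)``; truth has per-cell ``phase, lowq,
    lowq_mode, mapped_reads, mito_fraction``.
    """
    if phase_markers is None:
        phase_markers = default_phase_markers()
    if len(phase_markers) != 5:
        raise ValueError("need exactly five phase marker lists")
    all_markers: list[str] = []
    for phase, lst in phase_markers.items():
        if set(lst) & set(all_markers):
            raise ValueError("phase marker lists must be disjoint")
        all_markers.extend(lst)
    rng = np.random.default_rng(cfg.seed)
    mito_genes = [f"MT-{i:02d}" for i in range(10)]
    background = [f"BG_{i:04d}" for i in range(n_background_genes)]
    genes = all_markers + mito_genes + background
    n_cells = cfg.n_cells
    cells = [f"cell_{i:04d}" for i in range(n_cells)]

    phase_idx = rng.choice(len(PHASES), size=n_cells, p=np.asarray(cfg.phase_proportions))
    lowq = rng.random(n_cells) < cfg.lowq_fraction
    lowq_mode = np.where(rng.random(n_cells) < 0.5, "few_genes", "high_mito")
    lowq_mode = np.where(lowq, lowq_mode, "none")

    base = 5.0
    mu = np.full((n_cells, len(genes)), base)
    gene_index = {g: j for j, g in enumerate(genes)}
    for p, phase in enumerate(PHASES):
        rows = phase_idx == p
        cols = [gene_index[g] for g in phase_markers[phase]]
        mu[np.ix_(rows, cols)] *= marker_fold
    mito_cols = [gene_index[g] for g in mito_genes]
    mu[:, mito_cols] = 2.0  # <0.1% mito at baseline
    # planted high-mito cells: ~12% of UMI from the 10 MT- genes
    mu[lowq_mode == "high_mito", :] = np.where(
        np.isin(np.arange(len(genes)), mito_cols)[None, :],
        400.0,
        mu[lowq_mode == "high_mito", :],
    )
    counts = rng.poisson(mu)
    thin = lowq_mode == "few_genes"
    counts[thin] = rng.binomial(counts[thin], 0.02)

    counts_df = pd.DataFrame(counts, index=cells, columns=genes)
    totals = counts_df.sum(axis=1)
    mito_frac = counts_df[mito_genes].sum(axis=1) / totals.replace(0, np.nan)
    mapped = (totals * 40).astype(int)  # reads-per-UMI proxy
    mapped[thin] = (mapped[thin] * 0.5).astype(int)
    truth = pd.DataFrame(
        {
            "cell": cells,
            "phase": [PHASES[p] for p in phase_idx],
            "lowq": lowq,
            "lowq_mode": lowq_mode,
            "mapped_reads": mapped.to_numpy(),
            "mito_fraction": mito_frac.fillna(0.0).to_numpy(),
        }
    ).set_index("cell")
    return counts_df, truth


# ---------------------------------------------------------------------------
# Insertion reads
# ---------------------------------------------------------------------------


def random_dna(rng: np.random.Generator, length: int) -> str:
    return "".join(rng.choice(list("ACGT"), size=length))


def make_constructs(
    host: SyntheticGenome,
    names: tuple[str, ...] = ("HNF4A", "MYC"),
    insert_len: int = 400,
    backbone_len: int = 500,
    seed: int = 0,
    include_cas9: bool = False,
) -> list:
    """Lentiviral constructs whose inserts are copies of host loci.

    All constructs share one random vector backbone.  Each named construct
    takes its insert verbatim from a distinct host interval (its native
    locus), mimicking host-gene cDNAs; an optional Cas9-like construct has
    a random insert and no native locus.
    """
    from .insertions import Construct

    rng = np.random.default_rng(seed)
    backbone = random_dna(rng, backbone_len)
    glen = len(host.sequence)
    constructs = []
    slot = glen // (len(names) + 1)
    for i, name in enumerate(names):
        start = slot * i + slot // 2
        end = start + insert_len
        constructs.append(
            Construct(
                name=name,
                backbone=backbone,
                insert=host.sequence[start:end],
                native_locus=(start, end),
            )
        )
    if include_cas9:
        constructs.append(
            Construct(name="Cas9", backbone=backbone, insert=random_dna(rng, insert_len))
        )
    return constructs


def simulate_insertion_reads(
    host: SyntheticGenome,
    constructs: list,
    n_loci: int,
    support_per_locus: int,
    n_native_reads: int = 0,
    n_background_reads: int = 10,
    seed: int = 0,
    flank_len: int = 300,
) -> tuple[dict[str, str], pd.DataFrame]:
    """Long reads around planted lentiviral integration loci.

    * chimeric reads: host left flank + backbone + insert + host right
      flank at each of ``n_loci`` integration sites, ``support_per_locus``
      reads each (flank lengths jittered ±20%);
    * native reads: the insert-gene sequence embedded at its native host
      locus with *no* backbone (transcribed-from-genome lookalikes);
    * background reads: pure host sequence.

    Returns ``(reads, truth)``: reads as an id -> sequence dict, truth with
    one row per read (``kind, construct, locus_pos``).
    """
    if support_per_locus < 1 and n_loci > 0:
        raise ValueError("support_per_locus must be >= 1")
    rng = np.random.default_rng(seed)
    genome = host.sequence
    glen = len(genome)
    native_intervals = [c.native_locus for c in constructs if c.native_locus is not None]

    def in_native(p: int) -> bool:
        return any(s - flank_len <= p < e + flank_len for s, e in native_intervals)

    loci: list[int] = []
    attempts = 0
    while len(loci) < n_loci:
        attempts += 1
        if attempts > 1000 * max(1, n_loci):
            raise ValueError("host too short to place the requested integration loci")
        p = int(rng.integers(flank_len * 2, glen - flank_len * 2))
        if in_native(p):
            continue
        if all(abs(p - q) > 4 * flank_len for q in loci):
            loci.append(p)

    reads: dict[str, str] = {}
    rows = []
    for li, locus in enumerate(loci):
        construct = constructs[int(rng.integers(0, len(constructs)))]
        for r in range(support_per_locus):
            lf = int(flank_len * rng.uniform(0.8, 1.2))
            rf = int(flank_len * rng.uniform(0.8, 1.2))
            seq = (
                genome[locus - lf : locus]
                + construct.backbone
                + construct.insert
                + genome[locus : locus + rf]
            )
            rid = f"chimeric_{li}_{r}"
            reads[rid] = seq
            rows.append(
                {"read_id": rid, "kind": "chimeric", "construct": construct.name, "locus_pos": locus}
            )
    native_constructs = [c for c in constructs if c.native_locus is not None]
    for i in range(n_native_reads):
        c = native_constructs[i % len(native_constructs)]
        s, e = c.native_locus
        lo = max(0, s - flank_len)
        hi = min(glen, e + flank_len)
        rid = f"native_{i}"
        reads[rid] = genome[lo:s] + c.insert + genome[e:hi]
        rows.append({"read_id": rid, "kind": "native", "construct": c.name, "locus_pos": s})
    for i in range(n_background_reads):
        start = int(rng.integers(0, glen - 2 * flank_len))
        rid = f"background_{i}"
        reads[rid] = genome[start : start + 2 * flank_len]
        rows.append({"read_id": rid, "kind": "background", "construct": None, "locus_pos": None})
    truth = pd.DataFrame(rows)
    return reads, truth
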