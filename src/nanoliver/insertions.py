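"""Lentiviral integration-site detection from long reads.

A genuine vector-derived read carries both the lentiviral backbone and the
cloned insert; its host-genome flanks anchor the integration locus.  Reads
carrying only the insert sequence are indistinguishable from the host
gene's native locus (the inserts are cDNAs of host genes), so detection
requires: (1) a dual alignment of at least ``min_dual_len`` bp to both the
backbone and the insert, (2) host-flank anchoring, (3) exclusion of
anchors falling in the insert gene's native locus, and (4) at least two
supporting reads per clustered locus.

Pairwise alignment is delegated to Biopython's ``PairwiseAligner`` (local
mode, affine gaps); multiple non-overlapping hits per read are recovered by
iteratively masking the best-scoring read interval.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from Bio import Align

from .methylation import revcomp

STATUS_ACCEPTED = "accepted"
STATUS_NATIVE = "rejected_native"
STATUS_SINGLETON = "rejected_singleton"


@dataclass
class Construct:
    """A lentiviral expression construct: shared vector backbone plus the
    cloned transgene insert, with the insert gene's native host locus when
    the insert is a host gene (absent e.g. for Cas9)."""

    name: str
    backbone: str
    insert: str
    native_locus: tuple[int, int] | None = None  # 0-based half-open on host


@dataclass
class LocalAlignment:
    """One local alignment of a target sequence within a read."""

    read_id: str
    target: str  # e.g. "backbone", "MYC:insert", "host"
    read_start: int
    read_end: int
    target_start: int
    target_end: int
    strand: str  # orientation of the target relative to the read
    score: float
    identity: float

    @property
    def aligned_length(self) -> int:
        return self.read_end - self.read_start


@dataclass
class InsertionEvent:
    """A clustered candidate integration locus."""

    chrom: str
    position: int
    construct: str
    supporting_read_ids: list[str]
    status: str
    orientations: list[str] = field(default_factory=list)

    @property
    def support(self) -> int:
        return len(self.supporting_read_ids)


def _make_aligner(scoring: tuple[float, float, float, float]) -> Align.PairwiseAligner:
    match, mismatch, gap_open, gap_extend = scoring
    aligner = Align.PairwiseAligner()
    aligner.mode = "local"
    aligner.match_score = match
    aligner.mismatch_score = mismatch
    aligner.open_gap_score = gap_open + gap_extend
    aligner.extend_gap_score = gap_extend
    return aligner


def _identity(alignment) -> float:
    counts = alignment.counts()
    aligned = counts.identities + counts.mismatches
    return counts.identities / aligned if aligned else 0.0


def local_align(
    query: str,
    target: str,
    scoring: tuple[float, float, float, float] = (2.0, -4.0, -4.0, -2.0),
    min_score: float = 40.0,
    read_id: str = "query",
    target_label: str = "target",
    max_hits: int = 20,
) -> list[LocalAlignment]:
    """All non-overlapping local alignments of ``target`` within ``query``.

    Both orientations of the target are searched; hits are recovered
    best-first by masking the matched query interval with ``N`` and
    realigning, until the best score drops below ``min_score``.  Results
    are sorted by query position and deterministic for fixed inputs.
    """
    if not query or not target:
        raise ValueError("query and target must be non-empty")
    aligner = _make_aligner(scoring)
    target_rc = revcomp(target)
    masked = list(query)
    hits: list[LocalAlignment] = []
    for _ in range(max_hits):
        q = "".join(masked)
        best = None
        best_strand = "+"
        for strand, t in (("+", target), ("-", target_rc)):
            res = aligner.align(q, t)
            if res.score >= min_score and (best is None or res.score > best.score):
                best = res[0]
                best_strand = strand
        if best is None:
            break
        q_start = int(best.aligned[0][0][0])
        q_end = int(best.aligned[0][-1][1])
        t_start = int(best.aligned[1][0][0])
        t_end = int(best.aligned[1][-1][1])
        if best_strand == "-":
            t_start, t_end = len(target) - t_end, len(target) - t_start
        hits.append(
            LocalAlignment(
                read_id=read_id,
                target=target_label,
                read_start=q_start,
                read_end=q_end,
                target_start=t_start,
                target_end=t_end,
                strand=best_strand,
                score=float(best.score),
                identity=_identity(best),
            )
        )
        for i in range(q_start, q_end):
            masked[i] = "N"
    hits.sort(key=lambda h: (h.read_start, h.read_end, h.target))
    return hits


def find_construct_reads(
    reads: dict[str, str],
    constructs: list[Construct],
    scoring: tuple[float, float, float, float] = (2.0, -4.0, -4.0, -2.0),
    min_score: float = 40.0,
) -> dict[str, list[LocalAlignment]]:
    """Map every construct's backbone and insert onto each read.

    Returns only reads with at least one construct alignment; the shared
    backbone is aligned once (labelled ``backbone``), inserts are labelled
    ``<name>:insert``.
    """
    if not constructs:
        raise ValueError("constructs must be non-empty")
    backbones: dict[str, str] = {}
    for c in constructs:
        backbones.setdefault(c.backbone, "backbone")
    tagged: dict[str, list[LocalAlignment]] = {}
    for read_id, seq in reads.items():
        found: list[LocalAlignment] = []
        for backbone in backbones:
            found.extend(
                local_align(seq, backbone, scoring, min_score, read_id, "backbone")
            )
        for c in constructs:
            found.extend(
                local_align(seq, c.insert, scoring, min_score, read_id, f"{c.name}:insert")
            )
        if found:
            tagged[read_id] = sorted(found, key=lambda h: (h.read_start, h.read_end, h.target))
    return tagged


def classify_dual(alignments: list[LocalAlignment], min_len: int = 30) -> bool:
    """True iff the read has >= ``min_len`` bp aligned to both the backbone
    and an insert (boundary inclusive)."""
    max_backbone = max(
        (a.aligned_length for a in alignments if a.target == "backbone"), default=0
    )
    max_insert = max(
        (a.aligned_length for a in alignments if a.target.endswith(":insert")), default=0
    )
    return max_backbone >= min_len and max_insert >= min_len


def _flank_segments(
    read_len: int, alignments: list[LocalAlignment], min_flank: int
) -> list[tuple[int, int]]:
    """Maximal read intervals not covered by any construct alignment."""
    covered = np.zeros(read_len, dtype=bool)
    for a in alignments:
        covered[a.read_start : a.read_end] = True
    segments = []
    start = None
    for i in range(read_len + 1):
        free = i < read_len and not covered[i]
        if free and start is None:
            start = i
        elif not free and start is not None:
            if i - start >= min_flank:
                segments.append((start, i))
            start = None
    return segments


def locate_insertions(
    reads: dict[str, str],
    tagged: dict[str, list[LocalAlignment]],
    host_sequence: str,
    constructs: list[Construct],
    chrom: str = "host",
    min_dual_len: int = 30,
    min_flank: int = 50,
    cluster_radius: int = 50,
    min_support: int = 2,
    min_host_score: float = 60.0,
    scoring: tuple[float, float, float, float] = (2.0, -4.0, -4.0, -2.0),
) -> tuple[list[InsertionEvent], list[str]]:
    """Cluster host-flank anchors of dual-aligned reads into insertion events.

    Only reads passing :func:`classify_dual` are considered.  Each
    uncovered read segment of >= ``min_flank`` bp is aligned to the host;
    the anchor is the host coordinate of the flank boundary abutting the
    construct.  Anchors within ``cluster_radius`` are merged
    (single-linkage on sorted positions).  A cluster is ``rejected_native``
    when it overlaps the construct's native locus or when any supporting
    read's host-flank alignment does (the inserts are host-gene cDNAs, so
    such reads are not integration evidence); clusters with fewer than
    ``min_support`` reads are ``rejected_singleton``.

    Returns ``(events, unanchored_read_ids)``.
    """
    native = {c.name: c.native_locus for c in constructs}
    # (host pos, read_id, construct, orientation, flank-overlaps-native)
    anchors: list[tuple[int, str, str, str, bool]] = []
    unanchored: list[str] = []
    for read_id, alns in tagged.items():
        if not classify_dual(alns, min_dual_len):
            continue
        insert_names = [a.target.split(":")[0] for a in alns if a.target.endswith(":insert")]
        construct_name = insert_names[0] if insert_names else "?"
        locus = native.get(construct_name)
        read_seq = reads[read_id]
        segments = _flank_segments(len(read_seq), alns, min_flank)
        read_anchors = []
        native_hit = False
        for seg_start, seg_end in segments:
            flank = read_seq[seg_start:seg_end]
            hits = local_align(
                flank, host_sequence, scoring, min_host_score, read_id, "host", max_hits=1
            )
            if not hits:
                continue
            h = hits[0]
            if locus is not None and h.target_start < locus[1] and h.target_end > locus[0]:
                native_hit = True
            # junction side: flank before the construct anchors at its host end,
            # flank after the construct anchors at its host start
            construct_starts = [a.read_start for a in alns]
            before = seg_end <= min(construct_starts)
            if h.strand == "+":
                pos = h.target_end if before else h.target_start
            else:
                pos = h.target_start if before else h.target_end
            read_anchors.append((int(pos), h.strand))
        if not read_anchors:
            unanchored.append(read_id)
            continue
        # one anchor per read: the leftmost flank fixes the locus
        pos, strand = read_anchors[0]
        anchors.append((pos, read_id, construct_name, strand, native_hit))

    events: list[InsertionEvent] = []
    anchors.sort(key=lambda a: a[0])
    cluster: list[tuple[int, str, str, str]] = []

    def flush(cluster):
        if not cluster:
            return
        positions = [a[0] for a in cluster]
        center = int(round(float(np.median(positions))))
        read_ids = sorted({a[1] for a in cluster})
        names = [a[2] for a in cluster]
        name = max(set(names), key=names.count)
        locus = native.get(name)
        any_native = any(a[4] for a in cluster)
        if any_native or (
            locus is not None
            and locus[0] - cluster_radius <= center < locus[1] + cluster_radius
        ):
            status = STATUS_NATIVE
        elif len(read_ids) < min_support:
            status = STATUS_SINGLETON
        else:
            status = STATUS_ACCEPTED
        events.append(
            InsertionEvent(
                chrom=chrom,
                position=center,
                construct=name,
                supporting_read_ids=read_ids,
                status=status,
                orientations=[a[3] for a in cluster],
            )
        )

    for a in anchors:
        if cluster and a[0] - cluster[-1][0] > cluster_radius:
            flush(cluster)
            cluster = []
        cluster.append(a)
    flush(cluster)
    events.sort(key=lambda e: e.position)
    return events, unanchored
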