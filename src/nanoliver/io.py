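"""File formats: call-table TSV, wiggle, GMT, BED6, FASTA, counts.

Internal coordinates are 0-based half-open everywhere; conversion happens
only at format boundaries (wiggle is 1-based).  Every writer can prepend
``#``-prefixed provenance comment lines (config hash, seed) which the
readers skip.

Call-table TSV dialect (nanopolish-like), tab-separated with header:

    chromosome  strand  start  end  read_name  log_lik_ratio  sequence_context

``start`` is the 0-based position of the cytosine on its own strand and
``end = start + 1``; ``sequence_context`` is one of GCH/HCG/GCG/HCH.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

CALL_TABLE_COLUMNS = [
    "chromosome",
    "strand",
    "start",
    "end",
    "read_name",
    "log_lik_ratio",
    "sequence_context",
]


class CallTableError(ValueError):
    pass


def provenance_header(**fields) -> str:
    """``#``-prefixed comment block recording run provenance."""
    return "".join(f"# {k}: {v}\n" for k, v in fields.items())


def write_call_table(calls: pd.DataFrame, path, header_fields: dict | None = None) -> None:
    """Write an internal call table (chrom/strand/pos/context/read_id/llr)."""
    out = pd.DataFrame(
        {
            "chromosome": calls["chrom"],
            "strand": calls["strand"],
            "start": calls["pos"].astype(int),
            "end": calls["pos"].astype(int) + 1,
            "read_name": calls["read_id"],
            "log_lik_ratio": calls["llr"],
            "sequence_context": calls["context"],
        }
    )
    with open(path, "w") as fh:
        if header_fields:
            fh.write(provenance_header(**header_fields))
        out.to_csv(fh, sep="\t", index=False)


def read_call_table(path) -> pd.DataFrame:
    """Read a call-table TSV; malformed rows raise with their line number."""
    with open(path) as fh:
        lines = fh.readlines()
    data_lines = [(i + 1, ln.rstrip("\n")) for i, ln in enumerate(lines) if not ln.startswith("#")]
    if not data_lines:
        raise CallTableError(f"{path}: empty file without header")
    header = data_lines[0][1].split("\t")
    missing = [c for c in CALL_TABLE_COLUMNS if c not in header]
    if missing:
        raise CallTableError(f"{path}: missing required column(s) {missing}")
    idx = {c: header.index(c) for c in CALL_TABLE_COLUMNS}
    rows = []
    for lineno, ln in data_lines[1:]:
        if not ln.strip():
            continue
        fields = ln.split("\t")
        try:
            rows.append(
                (
                    fields[idx["chromosome"]],
                    fields[idx["strand"]],
                    int(fields[idx["start"]]),
                    fields[idx["read_name"]],
                    float(fields[idx["log_lik_ratio"]]),
                    fields[idx["sequence_context"]],
                )
            )
        except (ValueError, IndexError) as exc:
            raise CallTableError(f"{path}: malformed row at line {lineno}: {exc}") from exc
    return pd.DataFrame(
        rows, columns=["chrom", "strand", "pos", "read_id", "llr", "context"]
    )[["chrom", "strand", "pos", "context", "read_id", "llr"]]


def write_wiggle(
    summaries: pd.DataFrame,
    path,
    value_column: str = "proportion",
    track_name: str = "methylation",
    header_fields: dict | None = None,
) -> None:
    """variableStep wiggle (1-based positions), one declaration per chrom.

    Input must be position-sorted within each chromosome.
    """
    with open(path, "w") as fh:
        if header_fields:
            fh.write(provenance_header(**header_fields))
        fh.write(f'track type=wiggle_0 name="{track_name}"\n')
        for chrom, sub in summaries.groupby("chrom", sort=True):
            pos = sub["pos"].to_numpy()
            if not np.all(np.diff(pos) >= 0):
                raise ValueError(f"summaries for {chrom} are not position-sorted")
            fh.write(f"variableStep chrom={chrom}\n")
            for p, v in zip(pos, sub[value_column].to_numpy()):
                fh.write(f"{int(p) + 1}\t{v:.6g}\n")


def read_wiggle(path) -> pd.DataFrame:
    """Parse a variableStep wiggle back to 0-based (chrom, pos, value)."""
    rows = []
    chrom = None
    with open(path) as fh:
        for ln in fh:
            ln = ln.strip()
            if not ln or ln.startswith(("#", "track")):
                continue
            if ln.startswith("variableStep"):
                chrom = dict(kv.split("=") for kv in ln.split()[1:])["chrom"]
                continue
            p, v = ln.split("\t")
            rows.append((chrom, int(p) - 1, float(v)))
    return pd.DataFrame(rows, columns=["chrom", "pos", "value"])


def write_gmt(signatures: dict[str, list[str]], path, description: str = "nanoliver") -> None:
    """GMT: one line per gene set (name, description, genes...)."""
    with open(path, "w") as fh:
        for name, genes in signatures.items():
            fh.write("\t".join([name, description, *sorted(genes)]) + "\n")


def read_gmt(path) -> dict[str, list[str]]:
    sets: dict[str, list[str]] = {}
    with open(path) as fh:
        for ln in fh:
            fields = ln.rstrip("\n").split("\t")
            if len(fields) < 3:
                continue
            sets[fields[0]] = fields[2:]
    return sets


def write_bed6(intervals: pd.DataFrame, path, header_fields: dict | None = None) -> None:
    """BED6 from columns chrom, start, end, name, score, strand (0-based
    half-open, as BED expects)."""
    with open(path, "w") as fh:
        if header_fields:
            fh.write(provenance_header(**header_fields))
        for _, r in intervals.iterrows():
            fh.write(
                f"{r['chrom']}\t{int(r['start'])}\t{int(r['end'])}\t"
                f"{r.get('name', '.')}\t{r.get('score', 0)}\t{r.get('strand', '+')}\n"
            )


def write_fasta(sequences: dict[str, str], path) -> None:
    records = [SeqRecord(Seq(seq), id=name, description="") for name, seq in sequences.items()]
    SeqIO.write(records, str(path), "fasta")


def read_fasta(path) -> dict[str, str]:
    return {rec.id: str(rec.seq) for rec in SeqIO.parse(str(path), "fasta")}


def write_counts_tsv(counts: pd.DataFrame, path, header_fields: dict | None = None) -> None:
    with open(path, "w") as fh:
        if header_fields:
            fh.write(provenance_header(**header_fields))
        counts.to_csv(fh, sep="\t")


def read_counts_tsv(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col=0, comment="#")


def file_checksum(path) -> str:
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()


def write_manifest(manifest: dict, path) -> None:
    Path(path).write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
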