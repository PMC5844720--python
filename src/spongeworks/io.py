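"""Readers and writers for the pipeline's on-disk formats.

FASTA/FASTQ go through Biopython, GTF through gffutils (in-memory db),
GraphML through networkx.  All coordinates on disk are 1-based inclusive
GTF convention.  Parsers reject malformed records rather than coercing.

Also hosts the raw small-RNA read-cleaning cascade: reads are removed if a
3' adapter is present, if more than 5% of bases are unknown (N), or if more
than 50% of bases have Phred quality of at most 10; each removed read is
counted once under the first failing rule, and Q20/Q30/GC are reported for
the clean reads.
"""

from __future__ import annotations

import os
from typing import Iterable, Mapping, Sequence

import gffutils
import networkx as nx
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .types import (
    CleanReadReport,
    CountMatrix,
    DEResult,
    ReadRecord,
    TranscriptRecord,
    de_results_to_frame,
)

__all__ = [
    "read_fastq",
    "write_fastq",
    "clean_reads",
    "read_fasta",
    "write_fasta",
    "read_gtf",
    "write_gtf",
    "read_counts",
    "write_counts",
    "write_de_table",
    "read_de_table",
    "write_network",
    "read_network",
]


# ---------------------------------------------------------------- FASTQ

def read_fastq(path: str | os.PathLike) -> list[ReadRecord]:
    records: list[ReadRecord] = []
    try:
        for i, rec in enumerate(SeqIO.parse(str(path), "fastq"), start=1):
            records.append(
                ReadRecord(
                    id=rec.id,
                    sequence=str(rec.seq).upper(),
                    qualities=list(rec.letter_annotations["phred_quality"]),
                )
            )
    except ValueError as exc:
        raise ValueError(f"malformed FASTQ record ~#{len(records) + 1}: {exc}") from exc
    return records


def write_fastq(reads: Iterable[ReadRecord], path: str | os.PathLike) -> None:
    recs = []
    for r in reads:
        rec = SeqRecord(Seq(r.sequence), id=r.id, description="")
        rec.letter_annotations["phred_quality"] = list(r.qualities)
        recs.append(rec)
    SeqIO.write(recs, str(path), "fastq")


def _adapter_match_pos(seq: str, adapter: str, min_match: int = 8) -> int:
    """Leftmost position where the read runs into the adapter at its 3' end.

    The read suffix from that position must equal a prefix of the adapter
    and be at least ``min_match`` nt long.  Returns -1 when absent.
    """
    n = len(seq)
    for i in range(0, n - min_match + 1):
        tail = n - i
        if tail > len(adapter):
            continue
        if seq[i:] == adapter[:tail]:
            return i
    return -1


def clean_reads(
    reads: Iterable[ReadRecord],
    adapter: str = "",
    maxN_frac: float = 0.05,
    lowq_threshold: int = 10,
    lowq_frac: float = 0.5,
    adapter_policy: str = "remove",
    adapter_min_match: int = 8,
) -> tuple[list[ReadRecord], CleanReadReport]:
    """Apply the three-rule cleaning cascade to small-RNA reads.

    Rules in order: (a) 3' adapter present (removed, or trimmed and kept
    under ``adapter_policy='trim'``); (b) N fraction strictly above
    ``maxN_frac``; (c) fraction of bases at Phred <= ``lowq_threshold``
    strictly above ``lowq_frac``.
    """
    if not 0 < maxN_frac <= 1 or not 0 < lowq_frac <= 1:
        raise ValueError("fraction thresholds must lie in (0, 1]")
    if adapter_policy not in ("remove", "trim"):
        raise ValueError(f"unknown adapter policy {adapter_policy!r}")
    report = CleanReadReport()
    clean: list[ReadRecord] = []
    n_bases = q20 = q30 = gc = 0
    for read in reads:
        report.n_input += 1
        seq, quals = read.sequence, read.qualities
        if adapter:
            pos = _adapter_match_pos(seq, adapter, adapter_min_match)
            if pos != -1:
                if adapter_policy == "remove" or pos == 0:
                    report.n_adapter_removed += 1
                    continue
                seq, quals = seq[:pos], quals[:pos]
        if seq.count("N") / len(seq) > maxN_frac:
            report.n_highN_removed += 1
            continue
        if sum(1 for q in quals if q <= lowq_threshold) / len(quals) > lowq_frac:
            report.n_lowqual_removed += 1
            continue
        report.n_clean += 1
        clean.append(ReadRecord(id=read.id, sequence=seq, qualities=quals))
        n_bases += len(seq)
        q20 += sum(1 for q in quals if q >= 20)
        q30 += sum(1 for q in quals if q >= 30)
        gc += seq.count("G") + seq.count("C")
    if n_bases:
        report.q20 = q20 / n_bases
        report.q30 = q30 / n_bases
        report.gc_content = gc / n_bases
    report.check()
    return clean, report


# ---------------------------------------------------------------- FASTA

def read_fasta(path: str | os.PathLike) -> dict[str, str]:
    seqs: dict[str, str] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seqs:
            raise ValueError(f"duplicate sequence id {rec.id!r}")
        seqs[rec.id] = str(rec.seq).upper()
    return seqs


def write_fasta(seqs: Mapping[str, str], path: str | os.PathLike) -> None:
    recs = [SeqRecord(Seq(s), id=sid, description="") for sid, s in seqs.items()]
    SeqIO.write(recs, str(path), "fasta")


# ---------------------------------------------------------------- GTF

def read_gtf(path: str | os.PathLike) -> list[TranscriptRecord]:
    """Parse transcript+exon features into TranscriptRecords.

    Requires ``gene_id`` and ``transcript_id`` attributes; reads
    ``class_code`` and ``biotype`` when present.  Exons outside their
    transcript span, duplicate transcript ids and unknown strands are
    errors.
    """
    db = gffutils.create_db(
        str(path),
        ":memory:",
        force=True,
        keep_order=True,
        disable_infer_genes=True,
        disable_infer_transcripts=True,
    )
    transcripts: dict[str, dict] = {}
    order: list[str] = []
    for feat in db.features_of_type("transcript"):
        tid = feat.attributes["transcript_id"][0]
        if tid in transcripts:
            raise ValueError(f"duplicate transcript id {tid!r}")
        if feat.strand not in ("+", "-"):
            raise ValueError(f"{tid}: unknown strand {feat.strand!r}")
        transcripts[tid] = {
            "id": tid,
            "gene_id": feat.attributes["gene_id"][0],
            "chrom": feat.seqid,
            "start": feat.start,
            "end": feat.end,
            "strand": feat.strand,
            "class_code": feat.attributes.get("class_code", [None])[0],
            "biotype": feat.attributes.get("biotype", [None])[0],
            "exons": [],
        }
        order.append(tid)
    for feat in db.features_of_type("exon"):
        tid = feat.attributes["transcript_id"][0]
        if tid not in transcripts:
            raise ValueError(f"exon references unknown transcript {tid!r}")
        transcripts[tid]["exons"].append((feat.start, feat.end))
    out = []
    for tid in order:
        d = transcripts[tid]
        d["exons"].sort()
        out.append(TranscriptRecord(**d))  # validates exon-in-span invariant
    return out


def write_gtf(records: Sequence[TranscriptRecord], path: str | os.PathLike) -> None:
    with open(path, "w") as fh:
        for t in records:
            attrs = f'gene_id "{t.gene_id}"; transcript_id "{t.id}";'
            if t.class_code:
                attrs += f' class_code "{t.class_code}";'
            if t.biotype:
                attrs += f' biotype "{t.biotype}";'
            fh.write(
                f"{t.chrom}\tspongeworks\ttranscript\t{t.start}\t{t.end}\t.\t"
                f"{t.strand}\t.\t{attrs}\n"
            )
            for s, e in t.exons:
                fh.write(
                    f"{t.chrom}\tspongeworks\texon\t{s}\t{e}\t.\t"
                    f"{t.strand}\t.\t{attrs}\n"
                )


# ---------------------------------------------------------------- counts

def read_counts(
    path: str | os.PathLike, samples_path: str | os.PathLike | None = None
) -> CountMatrix:
    df = pd.read_csv(path, sep="\t", index_col=0)
    if (df.to_numpy() < 0).any():
        raise ValueError("negative entry in counts table")
    conditions = library_sizes = None
    if samples_path is not None:
        meta = pd.read_csv(samples_path, sep="\t", index_col=0)
        conditions = meta["condition"]
        if "library_size" in meta.columns:
            library_sizes = meta["library_size"]
    return CountMatrix(df, conditions=conditions, library_sizes=library_sizes)


def write_counts(
    counts: CountMatrix,
    path: str | os.PathLike,
    samples_path: str | os.PathLike | None = None,
) -> None:
    df = counts.counts.copy()
    df.index.name = "feature_id"
    df.to_csv(path, sep="\t")
    if samples_path is not None:
        meta = pd.DataFrame(
            {
                "condition": counts.conditions
                if counts.conditions is not None
                else "unknown",
                "library_size": counts.library_sizes,
            },
            index=counts.sample_ids,
        )
        meta.index.name = "sample"
        meta.to_csv(samples_path, sep="\t")


# ---------------------------------------------------------------- DE table

def write_de_table(results: Sequence[DEResult], path: str | os.PathLike) -> None:
    """DE table with (id, log2fc, direction, p, p_adj) plus condition means."""
    frame = de_results_to_frame(results)
    frame.to_csv(path, sep="\t", float_format="%.6g")


def read_de_table(path: str | os.PathLike) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col=0)


# ---------------------------------------------------------------- networks

def write_network(
    graph: nx.Graph, path: str | os.PathLike, format: str = "graphml"
) -> None:
    """Write a role-attributed network as GraphML or an edge TSV."""
    for node, data in graph.nodes(data=True):
        if data.get("role") not in ("miRNA", "lncRNA", "mRNA"):
            raise ValueError(f"node {node!r} lacks a valid role attribute")
    if format == "graphml":
        nx.write_graphml(graph, str(path))
    elif format == "edge-tsv":
        rows = []
        for u, v, data in sorted(graph.edges(data=True)):
            rows.append(
                {
                    "source": u,
                    "target": v,
                    "source_role": graph.nodes[u]["role"],
                    "target_role": graph.nodes[v]["role"],
                    "n_sites": data.get("n_sites", 0),
                }
            )
        pd.DataFrame(
            rows, columns=["source", "target", "source_role", "target_role", "n_sites"]
        ).to_csv(path, sep="\t", index=False)
    else:
        raise ValueError(f"unknown network format {format!r}")


def read_network(path: str | os.PathLike, format: str = "graphml") -> nx.Graph:
    if format == "graphml":
        return nx.read_graphml(str(path))
    if format == "edge-tsv":
        df = pd.read_csv(path, sep="\t")
        g = nx.Graph()
        for row in df.itertuples(index=False):
            g.add_node(row.source, role=row.source_role)
            g.add_node(row.target, role=row.target_role)
            g.add_edge(row.source, row.target, n_sites=int(row.n_sites))
        return g
    raise ValueError(f"unknown network format {format!r}")
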