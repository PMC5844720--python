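"""Expression quantification for small-RNA tags and long transcripts.

Small-RNA expression is normalised as TPM = 1e6 * C / L where C is a tag's
read count and L the sample's total clean reads — deliberately without a
length term, since miRNA tags are near-uniform in length.  Long transcripts
use FPKM (count / exonic kilobases / million mapped fragments), with
gene-level values obtained by summing the FPKMs of the gene's transcripts.

Known-miRNA identification follows the two-criterion rule for sequenced
tags: a perfect (no-mismatch) substring match to a miRNA precursor, whose
placement overlaps the annotated mature sequence by at least 16 nt.
"""

from __future__ import annotations

from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .seq import to_dna
from .types import CountMatrix, ExpressionMatrix, TranscriptRecord

__all__ = [
    "compute_tpm",
    "compute_fpkm",
    "gene_fpkm",
    "identify_known_mirnas",
]


def compute_tpm(counts: CountMatrix) -> ExpressionMatrix:
    """Tag TPM: 1e6 * count / library size, per sample. No length term."""
    lib = counts.library_sizes.astype(float)
    if (lib <= 0).any():
        bad = list(lib.index[lib <= 0])
        raise ValueError(f"zero library size for samples {bad}")
    values = counts.counts.astype(float).div(lib, axis=1) * 1e6
    return ExpressionMatrix(values=values, unit="TPM")


def compute_fpkm(
    counts: CountMatrix, annotation: Sequence[TranscriptRecord]
) -> ExpressionMatrix:
    """FPKM per transcript: count / (exonic kb * mapped millions)."""
    lengths = {t.id: t.exonic_length for t in annotation}
    missing = [f for f in counts.feature_ids if f not in lengths]
    if missing:
        raise ValueError(f"no annotation for features {missing[:5]}")
    kb = pd.Series({f: lengths[f] / 1e3 for f in counts.feature_ids})
    if (kb <= 0).any():
        raise ValueError("transcript with zero exonic length")
    millions = counts.library_sizes.astype(float) / 1e6
    if (millions <= 0).any():
        raise ValueError("zero library size")
    values = counts.counts.astype(float).div(millions, axis=1).div(kb, axis=0)
    return ExpressionMatrix(values=values, unit="FPKM")


def gene_fpkm(
    transcript_fpkm: ExpressionMatrix, transcript_to_gene: Mapping[str, str]
) -> ExpressionMatrix:
    """Gene FPKM = sum of the FPKMs of the transcripts in the gene group."""
    if transcript_fpkm.unit != "FPKM":
        raise ValueError("gene_fpkm expects FPKM input")
    missing = [t for t in transcript_fpkm.values.index if t not in transcript_to_gene]
    if missing:
        raise ValueError(f"no gene mapping for transcripts {missing[:5]}")
    genes = transcript_fpkm.values.index.map(transcript_to_gene)
    summed = transcript_fpkm.values.groupby(genes).sum()
    summed.index.name = "gene_id"
    return ExpressionMatrix(values=summed, unit="FPKM")


def _best_mature_overlap(tag_start: int, tag_len: int, mat_start: int, mat_len: int) -> int:
    lo = max(tag_start, mat_start)
    hi = min(tag_start + tag_len, mat_start + mat_len)
    return max(0, hi - lo)


def identify_known_mirnas(
    tags: Mapping[str, str],
    precursors: Mapping[str, str],
    matures: Mapping[str, str],
    min_overlap: int = 16,
) -> dict[str, str]:
    """Assign sequenced small-RNA tags to known miRNAs.

    A tag maps to miRNA ``m`` iff it occurs as an exact substring of ``m``'s
    precursor (sense strand) at a placement overlapping ``m``'s mature
    interval by at least ``min_overlap`` nt (offsets allowed).  Unassignable
    tags are labelled ``"novel"``.  Ambiguous tags go to the miRNA with the
    largest mature overlap, ties broken lexicographically by miRNA id; each
    tag is assigned once.

    Parameters
    ----------
    tags : mapping of tag id to sequence (RNA or DNA alphabet).
    precursors, matures : reference sequences keyed by miRNA id.
    """
    if not precursors or not matures:
        raise ValueError("empty miRNA reference")
    mat_pos: dict[str, tuple[int, int]] = {}
    prec_dna = {}
    for mid, prec in precursors.items():
        p = to_dna(prec)
        prec_dna[mid] = p
        mat = to_dna(matures.get(mid, ""))
        idx = p.find(mat) if mat else -1
        if idx < 0:
            continue  # mature not locatable in precursor: cannot satisfy rule 2
        mat_pos[mid] = (idx, len(mat))

    assignment: dict[str, str] = {}
    for tag_id in sorted(tags):
        tag = to_dna(tags[tag_id])
        best: tuple[int, str] | None = None
        for mid in sorted(mat_pos):
            prec = prec_dna[mid]
            mstart, mlen = mat_pos[mid]
            # every exact placement of the tag within the precursor
            start = prec.find(tag)
            overlap = 0
            while start != -1:
                overlap = max(
                    overlap, _best_mature_overlap(start, len(tag), mstart, mlen)
                )
                start = prec.find(tag, start + 1)
            if overlap >= min_overlap:
                if best is None or overlap > best[0]:
                    best = (overlap, mid)
        assignment[tag_id] = best[1] if best else "novel"
    return assignment
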