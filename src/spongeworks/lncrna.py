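"""The four-step lncRNA prediction cascade over assembled transcripts.

Steps, applied in order with short-circuiting:

1. keep only transcripts whose Cuffcompare class code is one of j,i,o,u,x
   (novel isoform / intronic / exonic overlap / intergenic / antisense);
2. keep only transcripts of at least 200 nt;
3. transcripts matching a known-lncRNA reference (blastn stand-in: shared
   k-mer seeded gapless alignment, identity >= 0.95 over >= 0.90 of the
   shorter sequence by default) are labelled known lncRNAs;
4. remaining transcripts without protein-coding potential (no ORF of 100+
   codons and no ORF covering half the transcript) are novel lncRNAs;
   the rest are removed as coding.

Known plus novel lncRNAs form the set carried downstream.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

from .seq import STOP_CODONS, to_dna
from .types import LNCRNA_CLASS_CODES, TranscriptRecord

__all__ = [
    "CodingPotentialScore",
    "filter_class_codes",
    "filter_length",
    "match_known_lncrnas",
    "classify_coding",
    "predict_lncrnas",
]


@dataclass
class CodingPotentialScore:
    longest_orf_codons: int
    orf_coverage: float
    verdict: str  # coding | noncoding


def filter_class_codes(
    transcripts: Sequence[TranscriptRecord],
    retained_codes: frozenset[str] = LNCRNA_CLASS_CODES,
) -> list[TranscriptRecord]:
    """Step 1: retain transcripts with a lncRNA-compatible class code."""
    for t in transcripts:
        if t.class_code is None:
            raise ValueError(f"{t.id}: class_code not set")
    return [t for t in transcripts if t.class_code in retained_codes]


def filter_length(
    transcripts: Sequence[TranscriptRecord], min_len: int = 200
) -> list[TranscriptRecord]:
    """Step 2: drop transcripts shorter than ``min_len`` (strict)."""
    return [t for t in transcripts if _tx_length(t) >= min_len]


def _tx_length(t: TranscriptRecord) -> int:
    return len(t.sequence) if t.sequence is not None else t.exonic_length


def _identity_on_diagonal(q: str, r: str, q_pos: int, r_pos: int) -> tuple[int, int]:
    """Matches and aligned length for the full gapless overlap on a diagonal."""
    off = r_pos - q_pos
    q_start = max(0, -off)
    q_end = min(len(q), len(r) - off)
    if q_end <= q_start:
        return 0, 0
    matches = sum(
        1 for i in range(q_start, q_end) if q[i] == r[i + off]
    )
    return matches, q_end - q_start


def _best_gapless_hit(query: str, ref: str, k: int = 11) -> tuple[float, float]:
    """Best (identity, coverage-of-shorter) over shared-k-mer diagonals."""
    if len(query) < k or len(ref) < k:
        return 0.0, 0.0
    ref_kmers: dict[str, list[int]] = {}
    for i in range(len(ref) - k + 1):
        ref_kmers.setdefault(ref[i : i + k], []).append(i)
    diagonals: set[int] = set()
    for i in range(len(query) - k + 1):
        for j in ref_kmers.get(query[i : i + k], ()):
            diagonals.add(j - i)
    shorter = min(len(query), len(ref))
    best = (0.0, 0.0)
    for off in diagonals:
        matches, aligned = _identity_on_diagonal(query, ref, 0, off) if off >= 0 else _identity_on_diagonal(query, ref, -off, 0)
        if aligned == 0:
            continue
        ident = matches / aligned
        cov = aligned / shorter
        if ident > best[0] or (ident == best[0] and cov > best[1]):
            best = (ident, cov)
    return best


def match_known_lncrnas(
    transcripts: Sequence[TranscriptRecord],
    reference: Mapping[str, str],
    identity_min: float = 0.95,
    coverage_min: float = 0.90,
    k: int = 11,
) -> tuple[list[TranscriptRecord], list[TranscriptRecord]]:
    """Step 3: split candidates into (known, remaining) by reference match.

    A transcript is known iff its best gapless hit against any reference
    sequence reaches ``identity_min`` over at least ``coverage_min`` of the
    shorter of the two sequences.
    """
    if not reference:
        raise ValueError("empty known-lncRNA reference")
    ref_dna = {rid: to_dna(rs) for rid, rs in reference.items()}
    known: list[TranscriptRecord] = []
    remaining: list[TranscriptRecord] = []
    for t in transcripts:
        if t.sequence is None:
            raise ValueError(f"{t.id}: sequence required for reference matching")
        q = to_dna(t.sequence)
        hit = False
        for rs in ref_dna.values():
            ident, cov = _best_gapless_hit(q, rs, k=k)
            if ident >= identity_min and cov >= coverage_min:
                hit = True
                break
        (known if hit else remaining).append(t)
    return known, remaining


def classify_coding(
    transcript: TranscriptRecord | str,
    min_orf_codons: int = 100,
    min_orf_coverage: float = 0.5,
) -> CodingPotentialScore:
    """Step 4 scorer: ORF-based coding-potential call (CPC/TransDecoder stand-in).

    Scans the three forward frames for ORFs starting at ATG and running to
    the first in-frame stop (or the end of the transcript).  Codons are
    counted from the ATG through the stop inclusive.  The verdict is coding
    iff the longest ORF reaches ``min_orf_codons`` codons or covers at least
    ``min_orf_coverage`` of the transcript.
    """
    seq = transcript if isinstance(transcript, str) else transcript.sequence
    if seq is None:
        raise ValueError("sequence required")
    s = to_dna(seq)
    n = len(s)
    best_nt = 0
    for frame in range(3):
        i = frame
        while i + 3 <= n:
            if s[i : i + 3] == "ATG":
                j = i
                stop_found = False
                while j + 3 <= n:
                    if s[j : j + 3] in STOP_CODONS:
                        stop_found = True
                        break
                    j += 3
                orf_nt = (j + 3 - i) if stop_found else (j - i)
                best_nt = max(best_nt, orf_nt)
                # next ATG search continues past this start codon
            i += 3
    codons = best_nt // 3
    coverage = best_nt / n if n else 0.0
    verdict = (
        "coding"
        if codons >= min_orf_codons or coverage >= min_orf_coverage
        else "noncoding"
    )
    return CodingPotentialScore(
        longest_orf_codons=codons, orf_coverage=coverage, verdict=verdict
    )


def predict_lncrnas(
    transcripts: Sequence[TranscriptRecord],
    reference: Mapping[str, str],
    min_len: int = 200,
    identity_min: float = 0.95,
    coverage_min: float = 0.90,
    min_orf_codons: int = 100,
    min_orf_coverage: float = 0.5,
) -> list[TranscriptRecord]:
    """Run the full cascade; every input receives exactly one label.

    Labels: ``rejected:class_code``, ``rejected:length``, ``known_lncRNA``,
    ``novel_lncRNA``, ``coding``.
    """
    retained = set(t.id for t in filter_class_codes(transcripts))
    for t in transcripts:
        if t.id not in retained:
            t.label = "rejected:class_code"
    stage2 = [t for t in transcripts if t.id in retained]
    long_enough = set(t.id for t in filter_length(stage2, min_len=min_len))
    for t in stage2:
        if t.id not in long_enough:
            t.label = "rejected:length"
    stage3 = [t for t in stage2 if t.id in long_enough]
    known, remaining = match_known_lncrnas(
        stage3, reference, identity_min=identity_min, coverage_min=coverage_min
    )
    for t in known:
        t.label = "known_lncRNA"
    for t in remaining:
        score = classify_coding(
            t, min_orf_codons=min_orf_codons, min_orf_coverage=min_orf_coverage
        )
        t.label = "coding" if score.verdict == "coding" else "novel_lncRNA"
    return list(transcripts)
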