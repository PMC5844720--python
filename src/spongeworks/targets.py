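"""MicroRNA response element (MRE) prediction and lncRNA target assignment.

Seed matching implements the canonical site hierarchy.  With the miRNA
written 5'->3', the seed is nucleotides 2-8.  On the target (5'->3', DNA
space) the site patterns are:

    6mer     reverse complement of miRNA nt 2-7
    7mer-m8  reverse complement of miRNA nt 2-8 (adds a match to nt 8,
             one base 5' of the 6mer on the target)
    7mer-A1  6mer followed by an A opposite miRNA nt 1 (3' on the target)
    8mer     7mer-m8 followed by the A1 adenosine

Every occurrence of the 6mer core is reported once, labelled with the most
specific class supported by its flanking bases, with the span covering the
matched bases (6, 7 or 8 nt, 1-based inclusive).

Two site-class regimes act as independent "predictors" for the intersection
rule: strict = {7mer-m8, 8mer}, lenient = all four classes; per-miRNA target
gene sets are combined at the gene level (intersection by default).

lncRNA targets in cis are genes within a +/-10 kb window of the lncRNA
locus; antisense targets are transcripts overlapping the lncRNA on the
opposite strand, annotated with the longest contiguous perfectly
complementary run between the two sequences as a hybridisation proxy.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

from .seq import revcomp, to_dna
from .types import MRESite, TranscriptRecord

__all__ = [
    "SITE_CLASSES",
    "STRICT_CLASSES",
    "LENIENT_CLASSES",
    "CisPair",
    "AntisensePair",
    "find_seed_sites",
    "sites_to_gene_sets",
    "combine_predictions",
    "assign_cis_targets",
    "find_antisense_targets",
]

SITE_CLASSES = ("6mer", "7mer-A1", "7mer-m8", "8mer")
STRICT_CLASSES = frozenset({"7mer-m8", "8mer"})
LENIENT_CLASSES = frozenset(SITE_CLASSES)


@dataclass(frozen=True)
class CisPair:
    lncrna_id: str
    gene_id: str
    distance: int  # signed gap in bases; 0 when spans overlap
    relation: str  # upstream | downstream | overlap


@dataclass(frozen=True)
class AntisensePair:
    lncrna_id: str
    transcript_id: str
    overlap: int  # overlapping bases (>= 1)
    complementarity: int  # longest contiguous complementary run


def seed_patterns(mirna_seq: str) -> dict[str, str]:
    """Target-strand DNA patterns for the four canonical site classes."""
    m = to_dna(mirna_seq)
    if len(m) < 8:
        raise ValueError(f"miRNA shorter than 8 nt: {mirna_seq!r}")
    core6 = revcomp(m[1:7])  # nt 2-7
    m8 = revcomp(m[7])  # complement of nt 8, 5' flank on the target
    return {
        "6mer": core6,
        "7mer-A1": core6 + "A",
        "7mer-m8": m8 + core6,
        "8mer": m8 + core6 + "A",
    }


def find_seed_sites(
    mirnas: Mapping[str, str],
    targets: Mapping[str, str],
    site_classes: Iterable[str] = SITE_CLASSES,
    predictor: str = "seed-scan",
) -> list[MRESite]:
    """Scan target sequences for canonical seed-match sites.

    Each occurrence of a miRNA's 6mer core yields one site labelled with the
    most specific class among the requested ``site_classes`` that its
    flanking bases support; sites are reported in deterministic order
    (miRNA id, target id, position).
    """
    wanted = set(site_classes)
    unknown = wanted - set(SITE_CLASSES)
    if unknown:
        raise ValueError(f"unknown site classes {sorted(unknown)}")
    sites: list[MRESite] = []
    target_dna = {tid: to_dna(ts) for tid, ts in targets.items()}
    for mid in sorted(mirnas):
        pats = seed_patterns(mirnas[mid])
        core = pats["6mer"]
        m8_flank = pats["7mer-m8"][0]
        for tid in sorted(target_dna):
            t = target_dna[tid]
            pos = t.find(core)
            while pos != -1:
                has_m8 = pos > 0 and t[pos - 1] == m8_flank
                has_a1 = pos + 6 < len(t) and t[pos + 6] == "A"
                if has_m8 and has_a1:
                    cls, s, e = "8mer", pos - 1, pos + 6
                elif has_m8:
                    cls, s, e = "7mer-m8", pos - 1, pos + 5
                elif has_a1:
                    cls, s, e = "7mer-A1", pos, pos + 6
                else:
                    cls, s, e = "6mer", pos, pos + 5
                if cls in wanted:
                    sites.append(
                        MRESite(
                            mirna_id=mid,
                            target_id=tid,
                            start=s + 1,
                            end=e + 1,
                            site_class=cls,
                            predictor=predictor,
                        )
                    )
                pos = t.find(core, pos + 1)
    return sites


def sites_to_gene_sets(
    sites: Sequence[MRESite],
    target_to_gene: Mapping[str, str] | None = None,
) -> dict[str, set[str]]:
    """Per-miRNA target gene sets; targets map through ``target_to_gene``."""
    out: dict[str, set[str]] = {}
    for s in sites:
        gene = target_to_gene.get(s.target_id, s.target_id) if target_to_gene else s.target_id
        out.setdefault(s.mirna_id, set()).add(gene)
    return out


def combine_predictions(
    predictions: Sequence[Mapping[str, set[str]]],
    mode: str = "intersection",
) -> dict[str, set[str]]:
    """Combine per-miRNA target gene sets from several predictors.

    ``intersection`` keeps, per miRNA, the genes called by every predictor
    (the same target genes of the same miRNAs); ``union`` keeps genes called
    by any predictor.
    """
    if not predictions:
        raise ValueError("need at least one predictor")
    if mode not in ("intersection", "union"):
        raise ValueError(f"unknown mode {mode!r}")
    mirnas: set[str] = set()
    for p in predictions:
        mirnas.update(p)
    combined: dict[str, set[str]] = {}
    for m in mirnas:
        sets = [set(p.get(m, set())) for p in predictions]
        if mode == "intersection":
            genes = set.intersection(*sets)
        else:
            genes = set.union(*sets)
        combined[m] = genes
    return combined


def _gap(a_start: int, a_end: int, b_start: int, b_end: int) -> int:
    """Gap in bases between two 1-based inclusive spans; 0 if they overlap."""
    if b_start > a_end:
        return b_start - a_end - 1
    if a_start > b_end:
        return a_start - b_end - 1
    return 0


def assign_cis_targets(
    lncrnas: Sequence[TranscriptRecord],
    genes: Sequence[TranscriptRecord],
    window: int = 10_000,
) -> list[CisPair]:
    """Pair each lncRNA with genes within ``window`` bases (inclusive).

    Distance is the gap between the nearest span ends on the same
    chromosome, any strand; overlapping spans pair at distance 0.  The
    relation is reported from the lncRNA's perspective on the genomic
    forward axis (gene entirely left of the lncRNA -> upstream).
    """
    pairs: list[CisPair] = []
    by_chrom: dict[str, list[TranscriptRecord]] = {}
    for g in genes:
        by_chrom.setdefault(g.chrom, []).append(g)
    for lnc in lncrnas:
        for g in by_chrom.get(lnc.chrom, []):
            if g.id == lnc.id:
                continue
            gap = _gap(lnc.start, lnc.end, g.start, g.end)
            if gap > window:
                continue
            if gap == 0:
                relation, dist = "overlap", 0
            elif g.end < lnc.start:
                relation, dist = "upstream", -gap
            else:
                relation, dist = "downstream", gap
            pairs.append(
                CisPair(
                    lncrna_id=lnc.id,
                    gene_id=g.gene_id or g.id,
                    distance=dist,
                    relation=relation,
                )
            )
    return pairs


def _longest_complementary_run(a: str, b: str) -> int:
    """Longest contiguous run where ``a`` pairs with ``b`` reversed.

    A cheap stand-in for a hybridisation energy: both sequences 5'->3', so
    ``a`` is compared against the reverse complement of ``b`` and the
    longest common substring length returned.
    """
    rb = revcomp(to_dna(b))
    a = to_dna(a)
    if not a or not rb:
        return 0
    # classic O(len(a)*len(rb)) longest-common-substring rolling row
    best = 0
    prev = [0] * (len(rb) + 1)
    for ca in a:
        cur = [0] * (len(rb) + 1)
        for j, cb in enumerate(rb, start=1):
            if ca == cb:
                cur[j] = prev[j - 1] + 1
                if cur[j] > best:
                    best = cur[j]
        prev = cur
    return best


def find_antisense_targets(
    lncrnas: Sequence[TranscriptRecord],
    transcripts: Sequence[TranscriptRecord],
) -> list[AntisensePair]:
    """Transcripts overlapping a lncRNA on the opposite genomic strand."""
    pairs: list[AntisensePair] = []
    by_chrom: dict[str, list[TranscriptRecord]] = {}
    for t in transcripts:
        by_chrom.setdefault(t.chrom, []).append(t)
    for lnc in lncrnas:
        for t in by_chrom.get(lnc.chrom, []):
            if t.id == lnc.id or t.strand == lnc.strand:
                continue
            lo = max(lnc.start, t.start)
            hi = min(lnc.end, t.end)
            overlap = hi - lo + 1
            if overlap < 1:
                continue
            comp = 0
            if lnc.sequence and t.sequence:
                comp = _longest_complementary_run(lnc.sequence, t.sequence)
            pairs.append(
                AntisensePair(
                    lncrna_id=lnc.id,
                    transcript_id=t.id,
                    overlap=overlap,
                    complementarity=comp,
                )
            )
    return pairs
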