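"""Synthetic transcriptome, counts and ground-truth sponge network.

The generator emulates a two-condition bulk study — tumour vs matched
normal tissue, three samples per group — over three feature classes
(mRNAs, lncRNA candidates, miRNAs):

* counts are negative binomial (variance = mean + dispersion * mean^2;
  Poisson at dispersion 0) with a designated fraction of features per class
  carrying an implanted signed log2 fold change;
* mRNAs carry an open reading frame of 100+ codons; lncRNA candidates are
  200+ nt, ORF-free by the coding-potential rule, and labelled with
  Cuffcompare class codes from the retained set {j,i,o,u,x};
* a ground-truth sponge network is implanted: selected DE miRNAs receive
  perfect 8mer seed sites on DE lncRNAs and DE mRNAs whose fold-change
  directions oppose the miRNA's, so every implanted triplet satisfies the
  ceRNA co-regulation rule.

Decoy purity is a hard guarantee: transcript sequences are sampled so that
no canonical seed match of ANY simulated miRNA occurs anywhere except the
implanted sites.  Because a kilobase of unconstrained random sequence
contains many chance seed matches when hundreds of miRNAs are simulated,
sequences are built base-by-base, rejecting bases that would complete a
forbidden seed 6mer (with bounded restarts), rather than by resampling
whole transcripts.

Everything is driven by one root seed; per-stage generators are spawned
deterministically, so a fixed SimConfig reproduces byte-identical fixtures.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from . import io as io_formats
from .lncrna import classify_coding
from .seq import STOP_CODONS, revcomp, to_rna
from .targets import find_seed_sites, seed_patterns
from .types import CountMatrix, MRESite, ReadRecord, SpongeTriplet, TranscriptRecord

__all__ = [
    "SimConfig",
    "GroundTruth",
    "SimOutput",
    "generate_transcriptome",
    "simulate_counts",
    "simulate_small_rna_reads",
    "generate_term_annotation",
    "generate_all",
    "write_fixture",
    "read_fixture",
    "SMALL_RNA_ADAPTER",
]

BASES = "ACGT"

#: Illumina TruSeq small-RNA 3' adapter, used for the simulated raw reads.
SMALL_RNA_ADAPTER = "TGGAATTCTCGGGTGCCAAGG"

_NONSTOP_CODONS = tuple(
    a + b + c
    for a in BASES
    for b in BASES
    for c in BASES
    if a + b + c not in STOP_CODONS
)


@dataclass
class SimConfig:
    """Study-design parameters for the synthetic fixture.

    Defaults describe the emulated study: 3 tumour vs 3 matched control
    samples, 500 mRNAs / 150 lncRNA candidates / 200 miRNAs, 10% of each
    class differentially expressed at |log2FC| = 2 around a baseline mean
    of 200 counts, negative-binomial dispersion 0.05.
    """

    n_mrna: int = 500
    n_lncrna: int = 150
    n_mirna: int = 200
    n_samples_per_group: int = 3
    baseline_mean: float = 200.0
    nb_dispersion: float = 0.05
    frac_de: float = 0.1
    implanted_log2fc: float = 2.0
    sites_per_true_pair: int = 2
    genome_length: int = 2_000_000
    seed: int = 42
    max_attempts: int = 1000  # bounded-retry cap for constrained sampling

    def __post_init__(self) -> None:
        if self.n_mrna < 1 or self.n_lncrna < 1:
            raise ValueError("need at least one mRNA and one lncRNA")
        if self.n_mirna < 0:
            raise ValueError("n_mirna must be >= 0")
        if self.n_samples_per_group < 1:
            raise ValueError("need at least one sample per group")
        if self.baseline_mean <= 0 or not np.isfinite(self.baseline_mean):
            raise ValueError("baseline_mean must be positive and finite")
        if self.nb_dispersion < 0:
            raise ValueError("nb_dispersion must be non-negative")
        if not 0 <= self.frac_de <= 1:
            raise ValueError("frac_de must lie in [0, 1]")
        if self.implanted_log2fc <= 0:
            raise ValueError("implanted_log2fc must be positive")
        if self.sites_per_true_pair < 1:
            raise ValueError("sites_per_true_pair must be >= 1")
        if self.frac_de > 0:
            for name, n in (
                ("n_mrna", self.n_mrna),
                ("n_lncrna", self.n_lncrna),
                ("n_mirna", self.n_mirna),
            ):
                if n > 0 and self.frac_de * n < 1:
                    raise ValueError(
                        f"frac_de * {name} < 1: no DE feature in that class"
                    )
        if self.genome_length < 20_000:
            raise ValueError("genome_length too small to place transcripts")


@dataclass
class GroundTruth:
    """What was implanted, for downstream recovery scoring."""

    de_features: dict[str, float] = field(default_factory=dict)
    true_sites: list[MRESite] = field(default_factory=list)
    true_triplets: list[SpongeTriplet] = field(default_factory=list)
    mirna_ids: list[str] = field(default_factory=list)
    mrna_ids: list[str] = field(default_factory=list)
    lncrna_ids: list[str] = field(default_factory=list)
    known_lncrna_ids: list[str] = field(default_factory=list)


@dataclass
class SimOutput:
    """Everything one simulation run produces."""

    config: SimConfig
    annotation: list[TranscriptRecord]
    sequences: dict[str, str]
    mirnas: dict[str, tuple[str, str]]  # id -> (precursor DNA, mature RNA)
    truth: GroundTruth
    long_counts: CountMatrix
    small_counts: CountMatrix
    reads: list[ReadRecord]
    terms: pd.DataFrame  # columns: term_id, name, namespace, gene_id


def _stage_rng(seed: int, stage: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence(entropy=seed, spawn_key=(stage,)))


def _random_seq(rng: np.random.Generator, length: int) -> str:
    return "".join(BASES[i] for i in rng.integers(0, 4, size=length))


def _constrained_seq(
    rng: np.random.Generator,
    length: int,
    forbidden: frozenset[str],
    max_attempts: int,
    prefix: str = "",
) -> str:
    """Random sequence in which no forbidden 6mer occurs (incl. across
    the junction with ``prefix``)."""
    for _ in range(max_attempts):
        draws = rng.integers(0, 4, size=length)
        out: list[str] = []
        context = prefix[-5:]
        dead = False
        for d in draws:
            placed = False
            for k in range(4):
                b = BASES[(d + k) % 4]
                window = (context + "".join(out[-5:]))[-5:] if len(out) < 5 else "".join(out[-5:])
                if len(window) == 5 and window + b in forbidden:
                    continue
                out.append(b)
                placed = True
                break
            if not placed:
                dead = True
                break
        if not dead:
            return "".join(out)
    raise RuntimeError(
        "could not sample a seed-free sequence within the attempt cap; "
        "sequence space too constrained (too many miRNAs for the alphabet)"
    )


def _gen_lncrna_seq(
    rng: np.random.Generator, length: int, forbidden: frozenset[str], max_attempts: int
) -> str:
    """Seed-free lncRNA sequence that the coding-potential rule calls noncoding."""
    for _ in range(max_attempts):
        seq = _constrained_seq(rng, length, forbidden, max_attempts)
        if classify_coding(seq).verdict == "noncoding":
            return seq
    raise RuntimeError("could not sample a noncoding lncRNA sequence")


def _gen_mrna_seq(
    rng: np.random.Generator,
    len_utr5: int,
    n_codons: int,
    len_utr3: int,
    forbidden: frozenset[str],
    max_attempts: int,
) -> tuple[str, int, int]:
    """Seed-free mRNA: UTR5 + (ATG, n_codons-2 sense codons, stop) + UTR3.

    Returns (sequence, cds_start, cds_end) with 0-based half-open CDS.
    """
    for _ in range(max_attempts):
        try:
            utr5 = _constrained_seq(rng, len_utr5, forbidden, 5)
            parts = [utr5]

            def _ok(chunk: str) -> bool:
                ctx = "".join(parts)[-5:]
                s = ctx + chunk
                return not any(
                    s[i : i + 6] in forbidden for i in range(len(s) - 5)
                )

            if not _ok("ATG"):
                continue
            parts.append("ATG")
            dead = False
            for _ in range(n_codons - 2):
                placed = False
                for ci in rng.permutation(len(_NONSTOP_CODONS))[:24]:
                    codon = _NONSTOP_CODONS[ci]
                    if _ok(codon):
                        parts.append(codon)
                        placed = True
                        break
                if not placed:
                    dead = True
                    break
            if dead:
                continue
            stops = list(STOP_CODONS)
            stop = next((s for i in rng.permutation(3) if _ok(s := stops[i])), None)
            if stop is None:
                continue
            parts.append(stop)
            cds = "".join(parts[1:])
            utr3 = _constrained_seq(rng, len_utr3, forbidden, 5, prefix="".join(parts))
            seq = utr5 + cds + utr3
            if any(seq[i : i + 6] in forbidden for i in range(len(seq) - 5)):
                continue
            return seq, len_utr5, len_utr5 + len(cds)
        except RuntimeError:
            continue
    raise RuntimeError("could not sample a seed-free mRNA sequence")


def _gen_mirnas(
    rng: np.random.Generator, n: int, max_attempts: int
) -> tuple[dict[str, tuple[str, str]], frozenset[str]]:
    """Mature (22 nt RNA) + precursor (~75 nt DNA) pairs with distinct,
    non-cross-matching seeds.

    No miRNA's 6mer seed-match core may occur inside any other miRNA's 8mer
    site pattern, so an implanted site can never be attributed to a second
    miRNA.
    """
    mirnas: dict[str, tuple[str, str]] = {}
    cores: set[str] = set()
    window6: set[str] = set()  # all 6mers inside any accepted 8mer pattern
    for i in range(n):
        for _ in range(max_attempts):
            mature_dna = _random_seq(rng, 22)
            pats = seed_patterns(mature_dna)
            pat8 = pats["8mer"]
            my_windows = {pat8[j : j + 6] for j in range(3)}
            core = pats["6mer"]
            if core in window6 or cores & my_windows:
                continue
            prec_len = int(rng.integers(70, 91))
            offset = int(rng.integers(0, prec_len - 22 + 1))
            prec = (
                _random_seq(rng, offset)
                + mature_dna
                + _random_seq(rng, prec_len - offset - 22)
            )
            if prec.count(mature_dna) != 1:
                continue
            mid = f"miR-{i + 1:04d}"
            mirnas[mid] = (prec, to_rna(mature_dna))
            cores.add(core)
            window6 |= my_windows
            break
        else:
            raise RuntimeError("could not sample distinct miRNA seeds")
    return mirnas, frozenset(cores)


def _pick_de(
    rng: np.random.Generator, ids: list[str], frac: float, lfc: float
) -> dict[str, float]:
    n_de = int(round(frac * len(ids)))
    if n_de == 0:
        return {}
    chosen = [str(x) for x in rng.choice(ids, size=n_de, replace=False)]
    half = n_de // 2
    signs = np.array([1.0] * (n_de - half) + [-1.0] * half)
    return {fid: float(s * lfc) for fid, s in zip(chosen, signs)}


def _implant_sites(
    rng: np.random.Generator,
    seq: str,
    mirna_mature_dna: str,
    n_sites: int,
    lo: int,
    hi: int,
    all_matures: Mapping[str, str],
    mirna_id: str,
    target_id: str,
    max_attempts: int,
) -> tuple[str, list[MRESite]] | None:
    """Overwrite ``n_sites`` perfect 8mer sites into ``seq[lo:hi]``.

    Verifies afterwards that the scanner finds exactly the implanted sites
    for the implanted miRNA and nothing for any other; returns None when no
    placement passes within the cap.
    """
    pat8 = seed_patterns(mirna_mature_dna)["8mer"]
    if hi - lo < n_sites * 20:
        return None
    for _ in range(max_attempts):
        positions = sorted(rng.choice(np.arange(lo, hi - 8), size=n_sites, replace=False))
        if any(b - a < 14 for a, b in zip(positions, positions[1:])):
            continue
        s = seq
        for p in positions:
            s = s[:p] + pat8 + s[p + 8 :]
        found = find_seed_sites(dict(all_matures), {target_id: s})
        # pattern at 0-based p spans [p, p+7] -> 1-based [p+1, p+8]
        expected = {
            (mirna_id, target_id, p + 1, p + 8, "8mer") for p in positions
        }
        got = {
            (x.mirna_id, x.target_id, x.start, x.end, x.site_class) for x in found
        }
        if got == expected:
            sites = [
                MRESite(
                    mirna_id=mirna_id,
                    target_id=target_id,
                    start=p + 1,
                    end=p + 8,
                    site_class="8mer",
                    predictor="implanted",
                )
                for p in positions
            ]
            return s, sites
    return None


def generate_transcriptome(
    config: SimConfig,
) -> tuple[list[TranscriptRecord], dict[str, str], dict[str, tuple[str, str]], GroundTruth]:
    """Build annotation, sequences, miRNAs and the implanted ground truth."""
    rng = _stage_rng(config.seed, 0)
    truth = GroundTruth()

    mirnas, forbidden = _gen_mirnas(rng, config.n_mirna, config.max_attempts)
    truth.mirna_ids = list(mirnas)
    matures_dna = {mid: mat.replace("U", "T") for mid, (_, mat) in mirnas.items()}

    mrna_ids = [f"TX-M{i + 1:04d}" for i in range(config.n_mrna)]
    lnc_ids = [f"TX-L{i + 1:04d}" for i in range(config.n_lncrna)]
    truth.mrna_ids = mrna_ids
    truth.lncrna_ids = lnc_ids

    # implanted fold changes per class
    truth.de_features.update(
        _pick_de(rng, mrna_ids, config.frac_de, config.implanted_log2fc)
    )
    truth.de_features.update(
        _pick_de(rng, lnc_ids, config.frac_de, config.implanted_log2fc)
    )
    truth.de_features.update(
        _pick_de(rng, truth.mirna_ids, config.frac_de, config.implanted_log2fc)
    )

    # sponge modules: each DE lncRNA gets a DE miRNA of opposite direction
    # and 1-3 DE mRNAs co-directional with the lncRNA
    sign = lambda fid: np.sign(truth.de_features[fid])
    de_lnc = [f for f in lnc_ids if f in truth.de_features]
    de_mir = [f for f in truth.mirna_ids if f in truth.de_features]
    de_mrna_pool = {
        s: [f for f in mrna_ids if f in truth.de_features and sign(f) == s]
        for s in (1.0, -1.0)
    }
    modules: list[tuple[str, str, list[str]]] = []  # (mirna, lncrna, mrnas)
    mir_by_sign = {
        s: [m for m in de_mir if sign(m) == s] for s in (1.0, -1.0)
    }
    rr = {1.0: 0, -1.0: 0}
    for lid in de_lnc:
        s = sign(lid)
        partners = mir_by_sign.get(-s, [])
        pool = de_mrna_pool[s]
        if not partners or not pool:
            continue
        mid = partners[rr[-s] % len(partners)]
        rr[-s] += 1
        n_m = min(int(rng.integers(1, 4)), len(pool))
        chosen = [pool.pop(0) for _ in range(n_m)]
        modules.append((mid, lid, chosen))

    # sequences
    sequences: dict[str, str] = {}
    cds_bounds: dict[str, tuple[int, int]] = {}
    for tid in mrna_ids:
        len5 = int(rng.integers(50, 151))
        n_codons = int(rng.integers(110, 201))
        len3 = int(rng.integers(260, 451))
        seq, a, b = _gen_mrna_seq(
            rng, len5, n_codons, len3, forbidden, config.max_attempts
        )
        sequences[tid] = seq
        cds_bounds[tid] = (a, b)
    for tid in lnc_ids:
        length = int(rng.integers(400, 1001))
        sequences[tid] = _gen_lncrna_seq(rng, length, forbidden, config.max_attempts)

    # implant sites and record truth
    for mid, lid, gids in modules:
        mat = matures_dna[mid]
        res = _implant_sites(
            rng,
            sequences[lid],
            mat,
            config.sites_per_true_pair,
            10,
            len(sequences[lid]) - 10,
            matures_dna,
            mid,
            lid,
            config.max_attempts,
        )
        if res is None:
            raise RuntimeError(f"could not implant sites on {lid}")
        sequences[lid], lsites = res
        if classify_coding(sequences[lid]).verdict != "noncoding":
            raise RuntimeError(f"implant made {lid} coding")
        truth.true_sites.extend(lsites)
        g_ok: list[str] = []
        for gid in gids:
            cds_end = cds_bounds[gid][1]
            res = _implant_sites(
                rng,
                sequences[gid],
                mat,
                config.sites_per_true_pair,
                cds_end + 5,
                len(sequences[gid]) - 10,
                matures_dna,
                mid,
                gid,
                config.max_attempts,
            )
            if res is None:
                raise RuntimeError(f"could not implant sites on {gid}")
            sequences[gid], gsites = res
            truth.true_sites.extend(gsites)
            g_ok.append(gid)
        for gid in g_ok:
            truth.true_triplets.append(
                SpongeTriplet(
                    mirna_id=mid,
                    lncrna_id=lid,
                    mrna_id=gid,
                    mirna_direction="up" if sign(mid) > 0 else "down",
                    lncrna_direction="up" if sign(lid) > 0 else "down",
                    mrna_direction="up" if sign(gid) > 0 else "down",
                    n_sites_lncrna=config.sites_per_true_pair,
                    n_sites_mrna=config.sites_per_true_pair,
                )
            )

    # genomic placement: uniform, single chromosome, random strand
    annotation: list[TranscriptRecord] = []
    lnc_codes = sorted("jioux")
    for tid in mrna_ids + lnc_ids:
        length = len(sequences[tid])
        start = int(rng.integers(1, config.genome_length - length))
        strand = "+" if rng.integers(0, 2) == 0 else "-"
        is_mrna = tid in cds_bounds
        annotation.append(
            TranscriptRecord(
                id=tid,
                gene_id=f"G-{tid[3:]}",
                chrom="chr1",
                start=start,
                end=start + length - 1,
                strand=strand,
                class_code="=" if is_mrna else lnc_codes[int(rng.integers(0, 5))],
                sequence=sequences[tid],
                biotype="mRNA" if is_mrna else "lncRNA_candidate",
            )
        )

    # half of the lncRNAs are present in the known-lncRNA reference
    n_known = len(lnc_ids) // 2
    truth.known_lncrna_ids = sorted(
        str(x) for x in rng.choice(lnc_ids, size=n_known, replace=False)
    )
    return annotation, sequences, mirnas, truth


def _nb_draw(
    rng: np.random.Generator, mean: np.ndarray, dispersion: float, size: tuple[int, int]
) -> np.ndarray:
    mean = np.broadcast_to(np.asarray(mean, dtype=float)[:, None], size)
    if np.any(mean < 0) or not np.all(np.isfinite(mean)):
        raise ValueError("negative or non-finite mean")
    if dispersion == 0:
        return rng.poisson(mean)
    n = 1.0 / dispersion
    p = n / (n + mean)
    return rng.negative_binomial(n, p)


def simulate_counts(
    annotation: list[TranscriptRecord],
    truth: GroundTruth,
    config: SimConfig,
) -> tuple[CountMatrix, CountMatrix]:
    """Draw NB counts for long RNAs and miRNA tags under the implanted design."""
    ann_ids = {t.id for t in annotation}
    missing = [
        f
        for f in truth.de_features
        if f not in ann_ids and f not in truth.mirna_ids
    ]
    if missing:
        raise ValueError(f"DE features absent from annotation: {missing[:5]}")
    rng = _stage_rng(config.seed, 1)
    n = config.n_samples_per_group
    samples = [f"Ctr{i + 1}" for i in range(n)] + [f"Tum{i + 1}" for i in range(n)]
    conditions = {s: ("control" if s.startswith("Ctr") else "tumour") for s in samples}

    def _matrix(feature_ids: list[str]) -> CountMatrix:
        base = np.full(len(feature_ids), config.baseline_mean)
        tum = base.copy()
        for i, fid in enumerate(feature_ids):
            if fid in truth.de_features:
                tum[i] = base[i] * 2.0 ** truth.de_features[fid]
        ctr_counts = _nb_draw(rng, base, config.nb_dispersion, (len(feature_ids), n))
        tum_counts = _nb_draw(rng, tum, config.nb_dispersion, (len(feature_ids), n))
        df = pd.DataFrame(
            np.hstack([ctr_counts, tum_counts]), index=feature_ids, columns=samples
        )
        return CountMatrix(df, conditions=conditions)

    long_ids = [t.id for t in annotation]
    long_counts = _matrix(long_ids)
    small_counts = _matrix(list(truth.mirna_ids))
    return long_counts, small_counts


def simulate_small_rna_reads(
    mirnas: Mapping[str, tuple[str, str]],
    config: SimConfig,
    n_clean: int = 1200,
    n_adapter: int = 100,
    n_highN: int = 60,
    n_lowqual: int = 80,
) -> list[ReadRecord]:
    """A small raw small-RNA FASTQ: mature-tag reads plus known contaminants.

    Contaminants exercise each cleaning rule: reads running into the 3'
    adapter, reads with >5% N, and reads with >50% of bases at Phred <= 10.
    """
    rng = _stage_rng(config.seed, 2)
    reads: list[ReadRecord] = []
    if not mirnas:
        return reads
    mids = list(mirnas)
    idx = rng.integers(0, len(mids), size=n_clean + n_adapter + n_highN + n_lowqual)
    k = 0
    for kind, count in (
        ("clean", n_clean),
        ("adapter", n_adapter),
        ("highN", n_highN),
        ("lowqual", n_lowqual),
    ):
        for _ in range(count):
            mat = mirnas[mids[idx[k]]][1].replace("U", "T")
            quals = list(rng.integers(33, 41, size=len(mat)))
            seq = mat
            if kind == "adapter":
                seq = mat + SMALL_RNA_ADAPTER[:12]
                quals = quals + list(rng.integers(33, 41, size=12))
            elif kind == "highN":
                pos = rng.choice(len(seq), size=3, replace=False)
                seq = "".join(
                    "N" if i in pos else b for i, b in enumerate(seq)
                )
            elif kind == "lowqual":
                n_low = int(np.ceil(0.6 * len(quals)))
                low_pos = rng.choice(len(quals), size=n_low, replace=False)
                for p in low_pos:
                    quals[p] = int(rng.integers(2, 11))
            reads.append(
                ReadRecord(id=f"read-{k + 1:06d}-{kind}", sequence=seq, qualities=[int(q) for q in quals])
            )
            k += 1
    return reads


def generate_term_annotation(
    annotation: list[TranscriptRecord],
    truth: GroundTruth,
    config: SimConfig,
    n_terms: int = 30,
    n_enriched: int = 3,
) -> pd.DataFrame:
    """Synthetic GO/pathway-style term map over mRNA gene ids.

    Most terms draw members uniformly; ``n_enriched`` terms are biased
    toward DE mRNA genes so the over-representation stage has signal.
    """
    rng = _stage_rng(config.seed, 3)
    gene_of = {t.id: t.gene_id for t in annotation}
    genes = sorted({gene_of[t] for t in truth.mrna_ids})
    de_genes = sorted({gene_of[t] for t in truth.mrna_ids if t in truth.de_features})
    rows = []
    for i in range(n_terms):
        term = f"TERM:{i + 1:04d}"
        size = int(rng.integers(5, 41))
        if i < n_enriched and de_genes:
            n_bias = min(len(de_genes), max(4, size // 2))
            members = set(rng.choice(de_genes, size=n_bias, replace=False))
            others = [g for g in genes if g not in members]
            extra = min(size - n_bias, len(others))
            if extra > 0:
                members |= set(rng.choice(others, size=extra, replace=False))
        else:
            members = set(rng.choice(genes, size=min(size, len(genes)), replace=False))
        for g in sorted(members):
            rows.append(
                {
                    "term_id": term,
                    "name": f"synthetic term {i + 1}",
                    "namespace": "SYN",
                    "gene_id": g,
                }
            )
    return pd.DataFrame(rows, columns=["term_id", "name", "namespace", "gene_id"])


def generate_all(config: SimConfig) -> SimOutput:
    """Run every generator stage under one root seed."""
    annotation, sequences, mirnas, truth = generate_transcriptome(config)
    long_counts, small_counts = simulate_counts(annotation, truth, config)
    reads = simulate_small_rna_reads(mirnas, config)
    terms = generate_term_annotation(annotation, truth, config)
    return SimOutput(
        config=config,
        annotation=annotation,
        sequences=sequences,
        mirnas=mirnas,
        truth=truth,
        long_counts=long_counts,
        small_counts=small_counts,
        reads=reads,
        terms=terms,
    )


# ------------------------------------------------------------- fixture I/O

def write_fixture(sim: SimOutput, directory: str | os.PathLike) -> dict[str, str]:
    """Write the full fixture file set; returns logical-name -> path."""
    d = Path(directory)
    d.mkdir(parents=True, exist_ok=True)
    paths = {
        "annotation": d / "annotation.gtf",
        "transcripts": d / "transcripts.fa",
        "mirna_mature": d / "mirna_mature.fa",
        "mirna_precursor": d / "mirna_precursor.fa",
        "known_lncrnas": d / "known_lncrnas.fa",
        "long_counts": d / "long_counts.tsv",
        "small_counts": d / "small_counts.tsv",
        "samples": d / "samples.tsv",
        "truth": d / "truth.tsv",
        "truth_sites": d / "truth_sites.tsv",
        "truth_de": d / "truth_de.tsv",
        "terms": d / "terms.tsv",
        "reads": d / "reads.fastq",
    }
    io_formats.write_gtf(sim.annotation, paths["annotation"])
    io_formats.write_fasta(sim.sequences, paths["transcripts"])
    io_formats.write_fasta(
        {mid: mat for mid, (_, mat) in sim.mirnas.items()}, paths["mirna_mature"]
    )
    io_formats.write_fasta(
        {mid: prec for mid, (prec, _) in sim.mirnas.items()},
        paths["mirna_precursor"],
    )
    io_formats.write_fasta(
        {f"ref-{lid}": sim.sequences[lid] for lid in sim.truth.known_lncrna_ids},
        paths["known_lncrnas"],
    )
    io_formats.write_counts(sim.long_counts, paths["long_counts"], paths["samples"])
    io_formats.write_counts(sim.small_counts, paths["small_counts"])
    pd.DataFrame(
        [
            {
                "mirna_id": t.mirna_id,
                "lncrna_id": t.lncrna_id,
                "mrna_id": t.mrna_id,
                "mirna_direction": t.mirna_direction,
                "lncrna_direction": t.lncrna_direction,
                "mrna_direction": t.mrna_direction,
                "n_sites_lncrna": t.n_sites_lncrna,
                "n_sites_mrna": t.n_sites_mrna,
            }
            for t in sim.truth.true_triplets
        ],
        columns=[
            "mirna_id",
            "lncrna_id",
            "mrna_id",
            "mirna_direction",
            "lncrna_direction",
            "mrna_direction",
            "n_sites_lncrna",
            "n_sites_mrna",
        ],
    ).to_csv(paths["truth"], sep="\t", index=False)
    pd.DataFrame(
        [
            {
                "mirna_id": s.mirna_id,
                "target_id": s.target_id,
                "start": s.start,
                "end": s.end,
                "site_class": s.site_class,
            }
            for s in sim.truth.true_sites
        ],
        columns=["mirna_id", "target_id", "start", "end", "site_class"],
    ).to_csv(paths["truth_sites"], sep="\t", index=False)
    pd.DataFrame(
        sorted(sim.truth.de_features.items()),
        columns=["feature_id", "log2fc"],
    ).to_csv(paths["truth_de"], sep="\t", index=False)
    sim.terms.to_csv(paths["terms"], sep="\t", index=False)
    io_formats.write_fastq(sim.reads, paths["reads"])
    return {k: str(v) for k, v in paths.items()}


def read_fixture(directory: str | os.PathLike) -> dict:
    """Reload the on-disk fixture into in-memory objects."""
    d = Path(directory)
    annotation = io_formats.read_gtf(d / "annotation.gtf")
    sequences = io_formats.read_fasta(d / "transcripts.fa")
    for t in annotation:
        t.sequence = sequences.get(t.id)
    return {
        "annotation": annotation,
        "sequences": sequences,
        "mirna_mature": io_formats.read_fasta(d / "mirna_mature.fa"),
        "mirna_precursor": io_formats.read_fasta(d / "mirna_precursor.fa"),
        "known_lncrnas": io_formats.read_fasta(d / "known_lncrnas.fa"),
        "long_counts": io_formats.read_counts(d / "long_counts.tsv", d / "samples.tsv"),
        "small_counts": io_formats.read_counts(d / "small_counts.tsv", d / "samples.tsv"),
        "truth_triplets": pd.read_csv(d / "truth.tsv", sep="\t"),
        "truth_sites": pd.read_csv(d / "truth_sites.tsv", sep="\t"),
        "truth_de": pd.read_csv(d / "truth_de.tsv", sep="\t"),
        "terms": pd.read_csv(d / "terms.tsv", sep="\t"),
        "reads": io_formats.read_fastq(d / "reads.fastq"),
    }
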