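"""Core data containers shared across the pipeline.

Coordinates are 1-based inclusive throughout (GTF convention); conversion to
0-based half-open happens only at BED export boundaries.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

VALID_STRANDS = ("+", "-")

#: Cuffcompare class codes retained as lncRNA candidates (novel isoform,
#: intronic, generic exonic overlap, intergenic, antisense overlap).
LNCRNA_CLASS_CODES = frozenset("jioux")


@dataclass
class TranscriptRecord:
    """One assembled transcript: location, structure, and classification state.

    ``label`` tracks the lncRNA-prediction cascade outcome: ``candidate``
    (untested), ``known_lncRNA``, ``novel_lncRNA``, ``coding``, or
    ``rejected:<reason>``.
    """

    id: str
    gene_id: str
    chrom: str
    start: int  # 1-based inclusive
    end: int
    strand: str
    exons: list[tuple[int, int]] = field(default_factory=list)
    class_code: str | None = None
    sequence: str | None = None
    biotype: str | None = None
    label: str = "candidate"

    def __post_init__(self) -> None:
        if self.end < self.start:
            raise ValueError(f"{self.id}: end {self.end} < start {self.start}")
        if self.strand not in VALID_STRANDS:
            raise ValueError(f"{self.id}: unknown strand {self.strand!r}")
        if not self.exons:
            self.exons = [(self.start, self.end)]
        for s, e in self.exons:
            if s < self.start or e > self.end or e < s:
                raise ValueError(
                    f"{self.id}: exon ({s},{e}) outside transcript span "
                    f"({self.start},{self.end})"
                )
        if self.sequence is not None and len(self.sequence) != self.exonic_length:
            raise ValueError(
                f"{self.id}: sequence length {len(self.sequence)} != exonic "
                f"length {self.exonic_length}"
            )

    @property
    def exonic_length(self) -> int:
        return sum(e - s + 1 for s, e in self.exons)

    @property
    def span_length(self) -> int:
        return self.end - self.start + 1


class CountMatrix:
    """Features x samples digital expression counts.

    Wraps a non-negative integer DataFrame together with per-sample library
    sizes (total clean reads; defaults to column sums) and condition labels
    (``tumour`` / ``control``).
    """

    def __init__(
        self,
        counts: pd.DataFrame,
        conditions: Mapping[str, str] | pd.Series | None = None,
        library_sizes: Mapping[str, int] | pd.Series | None = None,
    ) -> None:
        if counts.index.has_duplicates:
            dups = counts.index[counts.index.duplicated()].tolist()
            raise ValueError(f"duplicate feature ids: {dups[:5]}")
        if counts.columns.has_duplicates:
            raise ValueError("duplicate sample ids")
        arr = counts.to_numpy()
        if not np.issubdtype(arr.dtype, np.integer):
            if not np.allclose(arr, np.round(arr)):
                raise ValueError("counts must be integers")
            counts = counts.round().astype(np.int64)
        if (counts.to_numpy() < 0).any():
            raise ValueError("counts must be non-negative")
        self.counts = counts.astype(np.int64)
        colsums = self.counts.sum(axis=0)
        if library_sizes is None:
            self.library_sizes = colsums.astype(np.int64)
        else:
            ls = pd.Series(library_sizes, dtype=np.int64).reindex(counts.columns)
            if ls.isna().any():
                raise ValueError("library_sizes missing for some samples")
            if (ls < colsums).any():
                raise ValueError("library_sizes smaller than column sums")
            self.library_sizes = ls
        if conditions is None:
            self.conditions = None
        else:
            cond = pd.Series(conditions, dtype=object).reindex(counts.columns)
            if cond.isna().any():
                raise ValueError("condition label missing for some samples")
            self.conditions = cond

    @property
    def feature_ids(self) -> list[str]:
        return list(self.counts.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.counts.columns)

    def samples_for(self, condition: str) -> list[str]:
        if self.conditions is None:
            raise ValueError("no condition labels set")
        return list(self.conditions.index[self.conditions == condition])

    def subset(self, feature_ids: Iterable[str]) -> "CountMatrix":
        ids = [f for f in feature_ids if f in self.counts.index]
        return CountMatrix(
            self.counts.loc[ids],
            conditions=self.conditions,
            library_sizes=self.library_sizes,
        )

    def __repr__(self) -> str:  # pragma: no cover
        return (
            f"CountMatrix({self.counts.shape[0]} features x "
            f"{self.counts.shape[1]} samples)"
        )


@dataclass
class ExpressionMatrix:
    """Normalised expression values with their unit (TPM or FPKM)."""

    values: pd.DataFrame
    unit: str

    def __post_init__(self) -> None:
        if self.unit not in ("TPM", "FPKM"):
            raise ValueError(f"unknown unit {self.unit!r}")
        if (self.values.to_numpy() < 0).any():
            raise ValueError("expression values must be non-negative")


@dataclass(frozen=True)
class MRESite:
    """One predicted microRNA response element on a target transcript."""

    mirna_id: str
    target_id: str
    start: int  # 1-based inclusive on the target
    end: int
    site_class: str  # 6mer | 7mer-A1 | 7mer-m8 | 8mer
    predictor: str = "seed-scan"

    _CLASS_LEN = {"6mer": 6, "7mer-A1": 7, "7mer-m8": 7, "8mer": 8}

    def __post_init__(self) -> None:
        expected = self._CLASS_LEN.get(self.site_class)
        if expected is None:
            raise ValueError(f"unknown site class {self.site_class!r}")
        if self.end - self.start + 1 != expected:
            raise ValueError(
                f"{self.site_class} span must be {expected} nt, got "
                f"{self.end - self.start + 1}"
            )


@dataclass(frozen=True)
class SpongeTriplet:
    """The atomic ceRNA unit: one miRNA with MREs on a lncRNA and an mRNA."""

    mirna_id: str
    lncrna_id: str
    mrna_id: str
    mirna_direction: str = "ns"
    lncrna_direction: str = "ns"
    mrna_direction: str = "ns"
    n_sites_lncrna: int = 0
    n_sites_mrna: int = 0

    @property
    def key(self) -> tuple[str, str, str]:
        return (self.mirna_id, self.lncrna_id, self.mrna_id)


@dataclass
class DEResult:
    """Per-feature differential-expression call between tumour and control."""

    feature_id: str
    mean_ctr: float
    mean_tum: float
    log2fc: float
    p_raw: float
    p_adj: float
    direction: str = "ns"  # up | down | ns


def de_results_to_frame(results: Sequence[DEResult]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "id": [r.feature_id for r in results],
            "mean_ctr": [r.mean_ctr for r in results],
            "mean_tum": [r.mean_tum for r in results],
            "log2fc": [r.log2fc for r in results],
            "p": [r.p_raw for r in results],
            "p_adj": [r.p_adj for r in results],
            "direction": [r.direction for r in results],
        }
    ).set_index("id")


@dataclass
class ReadRecord:
    """A single small-RNA sequencing read with per-base Phred qualities."""

    id: str
    sequence: str
    qualities: list[int]

    def __post_init__(self) -> None:
        if len(self.sequence) != len(self.qualities):
            raise ValueError(
                f"{self.id}: sequence/quality length mismatch "
                f"({len(self.sequence)} vs {len(self.qualities)})"
            )


@dataclass
class CleanReadReport:
    """Tally of the read-cleaning cascade; categories are disjoint."""

    n_input: int = 0
    n_adapter_removed: int = 0
    n_highN_removed: int = 0
    n_lowqual_removed: int = 0
    n_clean: int = 0
    q20: float = float("nan")
    q30: float = float("nan")
    gc_content: float = float("nan")

    def check(self) -> None:
        total = (
            self.n_clean
            + self.n_adapter_removed
            + self.n_highN_removed
            + self.n_lowqual_removed
        )
        if total != self.n_input:
            raise AssertionError(
                f"report categories sum to {total}, expected {self.n_input}"
            )
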