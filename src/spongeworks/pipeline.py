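"""End-to-end orchestration: simulate -> clean -> quantify -> DE ->
classify -> MRE -> network -> enrich.

Each stage writes its outputs under the run directory and contributes
record counts to a JSON manifest that also carries the package version, a
hash of the resolved configuration and a checksum of every output file —
two runs with the same configuration produce byte-identical trees.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import os
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from . import io as io_formats
from .diffexpr import DEThresholds, call_differential
from .enrich import TermAnnotation, hypergeom_enrich, top_terms
from .lncrna import predict_lncrnas
from .network import build_global_network, export_network, filter_coregulated, network_stats
from .quantify import compute_fpkm, compute_tpm, gene_fpkm, identify_known_mirnas
from .simulate import (
    SMALL_RNA_ADAPTER,
    SimConfig,
    generate_all,
    read_fixture,
    write_fixture,
)
from .targets import (
    LENIENT_CLASSES,
    STRICT_CLASSES,
    assign_cis_targets,
    combine_predictions,
    find_seed_sites,
    sites_to_gene_sets,
    find_antisense_targets,
)
from .types import de_results_to_frame

__all__ = ["PipelineConfig", "run_pipeline"]

STAGES = (
    "simulate",
    "clean",
    "quantify",
    "diffexpr",
    "classify",
    "mre",
    "network",
    "enrich",
)


@dataclass
class PipelineConfig:
    """Every stage parameter, with the study's thresholds as defaults."""

    out_dir: str = "spongeworks-run"
    input_dir: str | None = None  # pre-existing fixture; None -> simulate
    seed: int = 42
    # simulation (ignored when input_dir is given)
    sim: SimConfig = field(default_factory=SimConfig)
    # cleaning
    adapter: str = SMALL_RNA_ADAPTER
    maxN_frac: float = 0.05
    lowq_threshold: int = 10
    lowq_frac: float = 0.5
    # differential expression
    min_abs_log2fc: float = 1.0
    max_p: float = 0.05
    use_adjusted: bool = True
    # lncRNA cascade
    min_lncrna_len: int = 200
    identity_min: float = 0.95
    coverage_min: float = 0.90
    # targets
    cis_window: int = 10_000
    mature_min_overlap: int = 16
    mre_mode: str = "intersection"  # intersection | union
    # network
    network_mode: str = "coregulated"  # coregulated | global

    def __post_init__(self) -> None:
        if isinstance(self.sim, dict):
            self.sim = SimConfig(**self.sim)
        self.sim = dataclasses.replace(self.sim, seed=self.seed)
        self.validate()

    def validate(self) -> None:
        DEThresholds(self.min_abs_log2fc, self.max_p, self.use_adjusted)
        if self.mre_mode not in ("intersection", "union"):
            raise ValueError(f"unknown mre_mode {self.mre_mode!r}")
        if self.network_mode not in ("coregulated", "global"):
            raise ValueError(f"unknown network_mode {self.network_mode!r}")
        if self.cis_window < 0 or self.mature_min_overlap < 1:
            raise ValueError("invalid window/overlap")
        if not 0 < self.maxN_frac <= 1 or not 0 < self.lowq_frac <= 1:
            raise ValueError("cleaning fractions must lie in (0, 1]")
        if self.input_dir is not None and not Path(self.input_dir).is_dir():
            raise ValueError(f"input_dir {self.input_dir!r} does not exist")

    @classmethod
    def from_yaml(cls, path: str | os.PathLike) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls(**data)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        return d


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def _stage_error(stage: str, exc: Exception) -> RuntimeError:
    return RuntimeError(f"pipeline stage {stage!r} failed: {exc}")


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute all stages in dependency order; returns the manifest dict."""
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "version": __version__,
        "config": config.to_dict(),
        "config_hash": hashlib.sha256(
            json.dumps(config.to_dict(), sort_keys=True).encode()
        ).hexdigest(),
        "stages": {},
        "outputs": {},
    }

    def record(stage: str, **counts) -> None:
        manifest["stages"][stage] = counts

    # ---- simulate / load -------------------------------------------------
    try:
        if config.input_dir is None:
            sim = generate_all(config.sim)
            fixture_dir = out / "fixture"
            write_fixture(sim, fixture_dir)
        else:
            fixture_dir = Path(config.input_dir)
        fx = read_fixture(fixture_dir)
        record(
            "simulate",
            status="generated" if config.input_dir is None else "loaded",
            n_transcripts=len(fx["annotation"]),
            n_mirnas=len(fx["mirna_mature"]),
            n_reads=len(fx["reads"]),
        )
    except Exception as exc:  # noqa: BLE001 - stage boundary
        raise _stage_error("simulate", exc)

    annotation = fx["annotation"]
    mrna_tx = [t for t in annotation if t.biotype == "mRNA"]
    gene_of = {t.id: t.gene_id for t in annotation}

    # ---- clean -----------------------------------------------------------
    try:
        clean_dir = out / "clean"
        clean_dir.mkdir(exist_ok=True)
        clean, report = io_formats.clean_reads(
            fx["reads"],
            adapter=config.adapter,
            maxN_frac=config.maxN_frac,
            lowq_threshold=config.lowq_threshold,
            lowq_frac=config.lowq_frac,
        )
        io_formats.write_fastq(clean, clean_dir / "clean_reads.fastq")
        with open(clean_dir / "clean_report.json", "w") as fh:
            json.dump(dataclasses.asdict(report), fh, indent=2, sort_keys=True)
            fh.write("\n")
        record(
            "clean",
            n_input=report.n_input,
            n_clean=report.n_clean,
            n_adapter_removed=report.n_adapter_removed,
            n_highN_removed=report.n_highN_removed,
            n_lowqual_removed=report.n_lowqual_removed,
        )
    except Exception as exc:
        raise _stage_error("clean", exc)

    # ---- quantify --------------------------------------------------------
    try:
        qdir = out / "quantify"
        qdir.mkdir(exist_ok=True)
        tpm = compute_tpm(fx["small_counts"])
        tpm.values.to_csv(qdir / "mirna_tpm.tsv", sep="\t", float_format="%.6g")
        fpkm = compute_fpkm(fx["long_counts"], annotation)
        fpkm.values.to_csv(qdir / "fpkm_transcript.tsv", sep="\t", float_format="%.6g")
        gfpkm = gene_fpkm(fpkm, gene_of)
        gfpkm.values.to_csv(qdir / "fpkm_gene.tsv", sep="\t", float_format="%.6g")
        assignment = identify_known_mirnas(
            dict(fx["mirna_mature"]),
            fx["mirna_precursor"],
            fx["mirna_mature"],
            min_overlap=config.mature_min_overlap,
        )
        pd.Series(assignment, name="mirna_id").rename_axis("tag_id").to_csv(
            qdir / "mirna_assignment.tsv", sep="\t"
        )
        n_assigned = sum(1 for v in assignment.values() if v != "novel")
        record(
            "quantify",
            n_tpm_features=tpm.values.shape[0],
            n_fpkm_transcripts=fpkm.values.shape[0],
            n_fpkm_genes=gfpkm.values.shape[0],
            n_tags_assigned=n_assigned,
        )
    except Exception as exc:
        raise _stage_error("quantify", exc)

    # ---- differential expression ----------------------------------------
    try:
        dedir = out / "de"
        dedir.mkdir(exist_ok=True)
        thresholds = DEThresholds(
            config.min_abs_log2fc, config.max_p, config.use_adjusted
        )
        de_long = call_differential(fx["long_counts"], thresholds)
        de_small = call_differential(fx["small_counts"], thresholds)
        io_formats.write_de_table(de_long, dedir / "de_long.tsv")
        io_formats.write_de_table(de_small, dedir / "de_small.tsv")
        directions = {r.feature_id: r.direction for r in de_long + de_small}
        record(
            "diffexpr",
            n_tested=len(de_long) + len(de_small),
            n_de_long=sum(1 for r in de_long if r.direction != "ns"),
            n_de_small=sum(1 for r in de_small if r.direction != "ns"),
        )
    except Exception as exc:
        raise _stage_error("diffexpr", exc)

    # ---- lncRNA classification + positional targets ----------------------
    try:
        cdir = out / "classify"
        cdir.mkdir(exist_ok=True)
        predict_lncrnas(
            annotation,
            fx["known_lncrnas"],
            min_len=config.min_lncrna_len,
            identity_min=config.identity_min,
            coverage_min=config.coverage_min,
        )
        labels = pd.DataFrame(
            {"id": [t.id for t in annotation], "label": [t.label for t in annotation]}
        ).set_index("id")
        labels.to_csv(cdir / "lncrna_labels.tsv", sep="\t")
        lnc_set = [
            t for t in annotation if t.label in ("known_lncRNA", "novel_lncRNA")
        ]
        cis = assign_cis_targets(lnc_set, mrna_tx, window=config.cis_window)
        pd.DataFrame(
            [dataclasses.asdict(p) for p in cis],
            columns=["lncrna_id", "gene_id", "distance", "relation"],
        ).to_csv(cdir / "cis_pairs.tsv", sep="\t", index=False)
        anti = find_antisense_targets(lnc_set, mrna_tx)
        pd.DataFrame(
            [dataclasses.asdict(p) for p in anti],
            columns=["lncrna_id", "transcript_id", "overlap", "complementarity"],
        ).to_csv(cdir / "antisense_pairs.tsv", sep="\t", index=False)
        record(
            "classify",
            n_lncrna=len(lnc_set),
            n_known=sum(1 for t in lnc_set if t.label == "known_lncRNA"),
            n_novel=sum(1 for t in lnc_set if t.label == "novel_lncRNA"),
            n_cis_pairs=len(cis),
            n_antisense_pairs=len(anti),
        )
    except Exception as exc:
        raise _stage_error("classify", exc)

    # ---- MRE scan --------------------------------------------------------
    try:
        mdir = out / "mre"
        mdir.mkdir(exist_ok=True)
        de_ids = {f for f, d in directions.items() if d != "ns"}
        de_mirnas = {
            mid: seq
            for mid, seq in fx["mirna_mature"].items()
            if mid in de_ids
        }
        target_seqs = {
            t.id: t.sequence
            for t in annotation
            if t.id in de_ids
            and (t.biotype == "mRNA" or t.label in ("known_lncRNA", "novel_lncRNA"))
        }
        strict = find_seed_sites(
            de_mirnas, target_seqs, site_classes=STRICT_CLASSES, predictor="strict"
        )
        lenient = find_seed_sites(
            de_mirnas, target_seqs, site_classes=LENIENT_CLASSES, predictor="lenient"
        )
        combined = combine_predictions(
            [sites_to_gene_sets(strict), sites_to_gene_sets(lenient)],
            mode=config.mre_mode,
        )
        sites = [
            s for s in lenient if s.target_id in combined.get(s.mirna_id, set())
        ]
        pd.DataFrame(
            [
                {
                    "mirna_id": s.mirna_id,
                    "target_id": s.target_id,
                    "start": s.start,
                    "end": s.end,
                    "site_class": s.site_class,
                }
                for s in sites
            ],
            columns=["mirna_id", "target_id", "start", "end", "site_class"],
        ).to_csv(mdir / "sites.tsv", sep="\t", index=False)
        record(
            "mre",
            n_mirnas_scanned=len(de_mirnas),
            n_targets_scanned=len(target_seqs),
            n_sites=len(sites),
        )
    except Exception as exc:
        raise _stage_error("mre", exc)

    # ---- network ---------------------------------------------------------
    try:
        ndir = out / "network"
        ndir.mkdir(exist_ok=True)
        lnc_ids = {
            t.id
            for t in annotation
            if t.label in ("known_lncRNA", "novel_lncRNA")
        }
        mrna_ids = {t.id for t in mrna_tx}
        net = build_global_network(sites, directions, lnc_ids, mrna_ids)
        if config.network_mode == "coregulated":
            net = filter_coregulated(net)
        export_network(net, ndir / "cerna")
        pd.DataFrame(
            [
                {
                    "mirna_id": t.mirna_id,
                    "lncrna_id": t.lncrna_id,
                    "mrna_id": t.mrna_id,
                    "mirna_direction": t.mirna_direction,
                    "lncrna_direction": t.lncrna_direction,
                    "mrna_direction": t.mrna_direction,
                }
                for t in net.triplets
            ],
            columns=[
                "mirna_id",
                "lncrna_id",
                "mrna_id",
                "mirna_direction",
                "lncrna_direction",
                "mrna_direction",
            ],
        ).to_csv(ndir / "triplets.tsv", sep="\t", index=False)
        stats = network_stats(net)
        record(
            "network",
            n_mirna=stats["n_mirna"],
            n_lncrna=stats["n_lncrna"],
            n_mrna=stats["n_mrna"],
            n_interactions=stats["n_interactions"],
        )
    except Exception as exc:
        raise _stage_error("network", exc)

    # ---- enrichment ------------------------------------------------------
    try:
        edir = out / "enrich"
        edir.mkdir(exist_ok=True)
        terms_df = fx["terms"]
        ann = [
            TermAnnotation(
                term_id=tid,
                name=grp["name"].iloc[0],
                namespace=grp["namespace"].iloc[0],
                members=frozenset(grp["gene_id"]),
            )
            for tid, grp in terms_df.groupby("term_id", sort=True)
        ]
        universe = sorted({g for a in ann for g in a.members})
        de_genes = sorted(
            {
                gene_of[t.id]
                for t in mrna_tx
                if directions.get(t.id, "ns") != "ns"
            }
        )
        results = hypergeom_enrich(de_genes, ann, universe)
        frame = pd.DataFrame(
            [
                {
                    "term_id": r.term_id,
                    "name": r.name,
                    "k": r.k,
                    "n": r.n,
                    "K": r.K,
                    "N": r.N,
                    "enrichment_factor": r.enrichment_factor,
                    "p": r.p,
                    "q": r.q,
                }
                for r in results
            ]
        )
        frame.to_csv(edir / "enrichment.tsv", sep="\t", index=False, float_format="%.6g")
        top = top_terms(results)
        frame[frame["term_id"].isin([r.term_id for r in top])].to_csv(
            edir / "top_terms.tsv", sep="\t", index=False, float_format="%.6g"
        )
        record(
            "enrich",
            n_terms=len(results),
            n_selected_genes=len(de_genes),
            n_significant=sum(1 for r in results if r.significant),
            n_top=len(top),
        )
    except Exception as exc:
        raise _stage_error("enrich", exc)

    # ---- manifest --------------------------------------------------------
    for path in sorted(out.rglob("*")):
        if path.is_file() and path.name != "manifest.json":
            manifest["outputs"][str(path.relative_to(out))] = _sha256(path)
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return manifest
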