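"""The synthetic-data generator: determinism, implant soundness, count model."""

import numpy as np
import pytest

from spongeworks.lncrna import classify_coding
from spongeworks.simulate import (
    SimConfig,
    generate_all,
    generate_transcriptome,
    read_fixture,
    simulate_counts,
    write_fixture,
)
from spongeworks.targets import find_seed_sites, seed_patterns


class TestConfigValidation:
    @pytest.mark.parametrize(
        "kwargs",
        [
            {"n_mrna": 0},
            {"n_samples_per_group": 0},
            {"baseline_mean": 0},
            {"nb_dispersion": -1},
            {"frac_de": 1.5},
            {"implanted_log2fc": 0},
            {"sites_per_true_pair": 0},
            {"frac_de": 0.001},  # frac_de * n < 1 for every class
        ],
    )
    def test_invalid_configs_rejected(self, kwargs):
        with pytest.raises(ValueError):
            SimConfig(**kwargs)


class TestDeterminism:
    def test_same_seed_reproduces_everything(self):
        cfg = SimConfig(n_mrna=30, n_lncrna=15, n_mirna=10, seed=5)
        a = generate_all(cfg)
        b = generate_all(cfg)
        assert a.sequences == b.sequences
        assert a.mirnas == b.mirnas
        assert a.truth.de_features == b.truth.de_features
        assert a.truth.true_sites == b.truth.true_sites
        assert a.truth.true_triplets == b.truth.true_triplets
        assert a.long_counts.counts.equals(b.long_counts.counts)
        assert a.small_counts.counts.equals(b.small_counts.counts)

    def test_fixture_files_byte_identical(self, tmp_path):
        cfg = SimConfig(n_mrna=30, n_lncrna=15, n_mirna=10, seed=5)
        d1, d2 = tmp_path / "a", tmp_path / "b"
        p1 = write_fixture(generate_all(cfg), d1)
        p2 = write_fixture(generate_all(cfg), d2)
        for key in p1:
            assert open(p1[key], "rb").read() == open(p2[key], "rb").read()


class TestImplantSoundness:
    def test_single_pair_single_site_recovered(self):
        # frac_de 0.4 puts one up- and one down-regulated feature in each
        # class, so at least one opposite-direction sponge module can form
        cfg = SimConfig(
            n_mrna=10,
            n_lncrna=5,
            n_mirna=5,
            frac_de=0.4,
            sites_per_true_pair=1,
            seed=3,
        )
        annotation, sequences, mirnas, truth = generate_transcriptome(cfg)
        assert truth.true_sites, "expected at least one implanted pair"
        matures = {mid: mat for mid, (_, mat) in mirnas.items()}
        for site in truth.true_sites:
            pat = seed_patterns(matures[site.mirna_id])["8mer"]
            assert sequences[site.target_id][site.start - 1 : site.end] == pat
        found = find_seed_sites(matures, sequences)
        got = {(s.mirna_id, s.target_id, s.start, s.end) for s in found}
        want = {(s.mirna_id, s.target_id, s.start, s.end) for s in truth.true_sites}
        assert got == want

    def test_decoys_carry_no_canonical_site(self, small_sim):
        matures = {mid: mat for mid, (_, mat) in small_sim.mirnas.items()}
        targeted = {s.target_id for s in small_sim.truth.true_sites}
        decoys = {
            tid: seq
            for tid, seq in small_sim.sequences.items()
            if tid not in targeted
        }
        assert find_seed_sites(matures, decoys) == []

    def test_no_mirnas_means_empty_truth(self):
        cfg = SimConfig(n_mrna=10, n_lncrna=5, n_mirna=0, frac_de=0.2, seed=2)
        _, _, mirnas, truth = generate_transcriptome(cfg)
        assert mirnas == {}
        assert truth.true_sites == [] and truth.true_triplets == []

    def test_transcript_class_contracts(self, small_sim):
        for t in small_sim.annotation:
            if t.biotype == "mRNA":
                assert classify_coding(t.sequence).longest_orf_codons >= 100
                assert t.class_code == "="
            else:
                assert len(t.sequence) >= 200
                assert t.class_code in set("jioux")
                assert classify_coding(t.sequence).verdict == "noncoding"

    def test_triplets_satisfy_sponge_direction_rule(self, small_sim):
        for t in small_sim.truth.true_triplets:
            assert t.lncrna_direction == t.mrna_direction
            assert t.mirna_direction != t.lncrna_direction
            assert {t.mirna_direction, t.lncrna_direction} <= {"up", "down"}


class TestCountModel:
    def test_poisson_mean_within_one_percent(self):
        cfg = SimConfig(
            n_mrna=3,
            n_lncrna=1,
            n_mirna=0,
            frac_de=0.0,
            baseline_mean=100.0,
            nb_dispersion=0.0,
            n_samples_per_group=5000,
            seed=8,
        )
        annotation, _, _, truth = generate_transcriptome(cfg)
        long_counts, _ = simulate_counts(annotation, truth, cfg)
        means = long_counts.counts.mean(axis=1)
        assert np.allclose(means, 100.0, rtol=0.01)

    def test_poisson_variance_mean_ratio(self):
        cfg = SimConfig(
            n_mrna=3,
            n_lncrna=1,
            n_mirna=0,
            frac_de=0.0,
            baseline_mean=100.0,
            nb_dispersion=0.0,
            n_samples_per_group=5000,
            seed=9,
        )
        annotation, _, _, truth = generate_transcriptome(cfg)
        long_counts, _ = simulate_counts(annotation, truth, cfg)
        ratio = long_counts.counts.var(axis=1) / long_counts.counts.mean(axis=1)
        assert ((ratio > 0.9) & (ratio < 1.1)).all()

    def test_implanted_fold_change_ratio(self):
        # 5,000 replicate draws per condition; |log2FC| = 2 -> ratio near 4
        cfg = SimConfig(
            n_mrna=2,
            n_lncrna=2,
            n_mirna=0,
            frac_de=0.5,
            implanted_log2fc=2.0,
            baseline_mean=100.0,
            n_samples_per_group=5000,
            seed=10,
        )
        annotation, _, _, truth = generate_transcriptome(cfg)
        long_counts, _ = simulate_counts(annotation, truth, cfg)
        ctr = long_counts.samples_for("control")
        tum = long_counts.samples_for("tumour")
        for fid, lfc in truth.de_features.items():
            ratio = (
                long_counts.counts.loc[fid, tum].mean()
                / long_counts.counts.loc[fid, ctr].mean()
            )
            expected = 2.0**lfc
            assert ratio == pytest.approx(expected, rel=0.05)
            if lfc > 0:
                assert 3.8 <= ratio <= 4.2

    def test_same_seed_identical_matrices(self):
        cfg = SimConfig(n_mrna=10, n_lncrna=5, n_mirna=5, frac_de=0.2, seed=4)
        ann, _, _, truth = generate_transcriptome(cfg)
        a = simulate_counts(ann, truth, cfg)
        b = simulate_counts(ann, truth, cfg)
        assert a[0].counts.equals(b[0].counts)
        assert a[1].counts.equals(b[1].counts)


class TestFixtureIO:
    def test_manifest_and_round_trip(self, tmp_path, small_sim):
        d = tmp_path / "fx"
        paths = write_fixture(small_sim, d)
        files = {p.name for p in d.iterdir()}
        assert sum(f.endswith(".gtf") for f in files) == 1
        assert sum(f.endswith(".fa") for f in files) >= 2
        assert {"long_counts.tsv", "small_counts.tsv"} <= files
        assert "truth.tsv" in files

        fx = read_fixture(d)
        # annotation round-trip
        back = {t.id: t for t in fx["annotation"]}
        for t in small_sim.annotation:
            r = back[t.id]
            assert (r.start, r.end, r.strand, r.class_code, r.exons) == (
                t.start,
                t.end,
                t.strand,
                t.class_code,
                t.exons,
            )
        assert fx["sequences"] == small_sim.sequences
        assert fx["long_counts"].counts.equals(small_sim.long_counts.counts)
        assert len(fx["truth_triplets"]) == len(small_sim.truth.true_triplets)
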