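"""The synthetic genome generator: structural contracts, determinism,
mutation-engine calibration, and on-disk round trips."""

import numpy as np
import pandas as pd
import pytest

from wzgenefate import io
from wzgenefate.codons import STOP_CODONS, translate
from wzgenefate.simulate import (
    ConfigError,
    SimulationConfig,
    diverge_cds,
    extract_sequences,
    inject_lesion,
    simulate_coverage,
    simulate_expression,
    simulate_genome,
)


def _mini(**overrides):
    base = dict(
        seed=11,
        n_autosomes=3,
        chrom_length_bp=40_000,
        genes_per_chromosome=5,
        cds_codons_range=(60, 120),
        exons_per_gene_range=(1, 4),
        n_w_duplicates=8,
        samples_per_sex=2,
        mean_depth_x=20.0,
    )
    base.update(overrides)
    return SimulationConfig(**base)


class TestGenome:
    def test_chromosome_count_and_classes(self):
        genome, _, _ = simulate_genome(_mini(n_autosomes=3))
        assert len(genome) == 5
        assert [c.true_class for c in genome].count("autosome") == 3
        by_name = {c.name: c for c in genome}
        assert by_name["Z"].copy_number == {"male": 2, "female": 1}
        assert by_name["W"].copy_number == {"male": 0, "female": 1}

    def test_genes_do_not_overlap(self, small_sim):
        genes = small_sim["genes"]
        by_chrom = {}
        for g in genes:
            by_chrom.setdefault(g.chrom, []).append((g.start, g.end))
        for spans in by_chrom.values():
            spans.sort()
            for (s1, e1), (s2, e2) in zip(spans, spans[1:]):
                assert e1 <= s2

    def test_retro_fraction_one_gives_intronless_w_genes(self):
        _, genes, truth = simulate_genome(_mini(retro_fraction=1.0))
        w_genes = [g for g in genes if g.chrom == "W"]
        assert len(w_genes) == 8
        assert all(g.intron_count == 0 for g in w_genes)
        assert set(truth["mechanism"]) == {"retrotransposition"}

    def test_retro_mechanism_truth_matches_introns(self, small_sim):
        truth = small_sim["truth"].set_index("w_gene")
        models = {g.gene_id: g for g in small_sim["genes"]}
        for w, row in truth.iterrows():
            if row["mechanism"] == "retrotransposition":
                assert models[w].intron_count == 0

    def test_no_lesions_when_pseudogene_fraction_zero(self):
        genome, genes, truth = simulate_genome(_mini(pseudogene_fraction=0.0))
        assert not truth["pseudogene"].any()
        cds_map, _ = extract_sequences(genome, genes)
        for w in truth["w_gene"]:
            cds = cds_map[w]
            assert len(cds) % 3 == 0
            internal = [cds[i : i + 3] for i in range(0, len(cds) - 3, 3)]
            assert not any(c in STOP_CODONS for c in internal)

    def test_truth_covers_every_w_gene_once(self, small_sim):
        w_ids = sorted(g.gene_id for g in small_sim["genes"] if g.chrom == "W")
        assert sorted(small_sim["truth"]["w_gene"]) == w_ids
        assert small_sim["truth"]["w_gene"].is_unique

    def test_infeasible_config_names_constraint(self):
        with pytest.raises(ConfigError, match="do not fit chromosome length"):
            simulate_genome(_mini(chrom_length_bp=2_000, genes_per_chromosome=10))

    def test_bad_proportion_rejected(self):
        with pytest.raises(ConfigError, match="retro_fraction"):
            _mini(retro_fraction=1.5)

    def test_determinism(self):
        a = simulate_genome(_mini())
        b = simulate_genome(_mini())
        assert [c.sequence for c in a[0]] == [c.sequence for c in b[0]]
        assert [g.exons for g in a[1]] == [g.exons for g in b[1]]
        pd.testing.assert_frame_equal(a[2], b[2])


class TestMutationEngine:
    def test_realized_ds_tracks_target_over_many_duplicates(self, rng):
        # mechanistic check of the event engine itself, >= 200 duplicates
        target = 0.3
        realized = []
        body = None
        from wzgenefate.simulate import _random_cds

        for _ in range(200):
            body = _random_cds(100, rng)[:-3]
            _, r = diverge_cds(body, target, kappa=2.0, omega=0.2, rng=rng)
            realized.append(r)
        assert abs(np.mean(realized) - target) < 0.02

    def test_diverged_sequence_stays_in_frame_and_stop_free(self, rng):
        from wzgenefate.simulate import _random_cds

        body = _random_cds(150, rng)[:-3]
        mut, _ = diverge_cds(body, 0.8, rng=rng)
        assert len(mut) == len(body)
        assert "*" not in translate(mut)

    def test_zero_divergence_is_identity(self, rng):
        from wzgenefate.simulate import _random_cds

        body = _random_cds(80, rng)[:-3]
        mut, r = diverge_cds(body, 0.0, rng=rng)
        assert mut == body and r == 0.0

    def test_lesion_types(self, rng):
        from wzgenefate.simulate import _random_cds

        stops = shifts = 0
        for _ in range(40):
            cds = _random_cds(100, rng)
            mutated, kind, pos, delta = inject_lesion(cds, rng)
            if kind == "premature_stop":
                stops += 1
                assert delta == 0 and len(mutated) == len(cds)
                prot = translate(mutated)
                assert "*" in prot[:-1]
                # interior placement
                assert 0.1 * 100 <= pos / 3 <= 0.9 * 100
            else:
                shifts += 1
                assert abs(delta) in (1, 2)
                assert len(mutated) == len(cds) + delta
        assert stops and shifts


class TestCoverage:
    def test_male_w_depth_is_zero(self, small_sim, small_config):
        tracks = simulate_coverage(small_sim["genome"], "male", small_config)
        w = next(t for t in tracks if t.chrom == "W")
        assert not w.depths.any()

    def test_female_autosome_mean_near_target(self, small_sim, small_config):
        tracks = simulate_coverage(small_sim["genome"], "female", small_config)
        a = next(t for t in tracks if t.chrom == "chr1")
        se = np.sqrt(small_config.mean_depth_x / len(a.depths))
        assert abs(a.depths.mean() - small_config.mean_depth_x) < 3 * se

    def test_same_seed_same_tracks(self, small_sim, small_config):
        t1 = simulate_coverage(small_sim["genome"], "female", small_config, sample_index=2)
        t2 = simulate_coverage(small_sim["genome"], "female", small_config, sample_index=2)
        for a, b in zip(t1, t2):
            assert np.array_equal(a.depths, b.depths)

    def test_unknown_sex_rejected(self, small_sim, small_config):
        with pytest.raises(ValueError, match="unknown sex"):
            simulate_coverage(small_sim["genome"], "hermaphrodite", small_config)


class TestExpression:
    def test_silenced_fraction_one_keeps_all_w_below_threshold(self):
        cfg = _mini(fpkm_silenced_fraction=1.0)
        genome, genes, truth = simulate_genome(cfg)
        fpkm = simulate_expression(genes, truth, cfg)
        w_ids = [g.gene_id for g in genes if g.chrom == "W"]
        assert (fpkm.loc[w_ids] < 0.5).all().all()

    def test_expressed_flag_implies_mixed_above_threshold(self, small_sim, small_fpkm):
        truth = small_sim["truth"]
        for w in truth.loc[truth["expressed"], "w_gene"]:
            assert small_fpkm.loc[w, "mixed"] > 0.5

    def test_gonad_replicate_count(self, small_config, small_fpkm):
        gonad_cols = [c for c in small_fpkm.columns if c.startswith("gonad_")]
        assert len(gonad_cols) == small_config.samples_per_sex


class TestRoundTrips:
    def test_fasta_round_trip(self, small_sim, tmp_path):
        seqs = {c.name: c.sequence for c in small_sim["genome"]}
        io.write_fasta(seqs, tmp_path / "g.fa")
        assert io.read_fasta(tmp_path / "g.fa") == seqs

    def test_gff3_round_trip(self, small_sim, tmp_path):
        io.write_gff3(small_sim["genes"], tmp_path / "g.gff3")
        back = {g.gene_id: g for g in io.read_gff3(tmp_path / "g.gff3")}
        for g in small_sim["genes"]:
            assert back[g.gene_id].chrom == g.chrom
            assert back[g.gene_id].strand == g.strand
            assert back[g.gene_id].exons == g.exons

    def test_bedgraph_round_trip(self, small_coverage, tmp_path):
        tracks, _ = small_coverage
        t = tracks[0]
        io.write_bedgraph(t, tmp_path / "t.bedgraph")
        (back,) = io.read_bedgraph(tmp_path / "t.bedgraph", sample_id=t.sample_id, sex=t.sex)
        assert back.chrom == t.chrom
        assert np.array_equal(back.depths, t.depths)
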