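import numpy as np
import pandas as pd
import pytest

import txoverlap as tx
from txoverlap.datatypes import ConfigError
from txoverlap.synthetic import gene_symbol


def default_study(**kw):
    base = dict(n_genes=300, n_case=6, n_control=6, n_de=30, seed=0)
    base.update(kw)
    return tx.StudyConfig(**base)


class TestStudyConfig:
    @pytest.mark.parametrize(
        "kw,match",
        [
            (dict(n_case=1), "n_case"),
            (dict(noise_sd=0.0), "noise_sd"),
            (dict(frac_up=1.5), "frac_up"),
            (dict(n_de=400), "n_de"),
        ],
    )
    def test_invalid_config_names_field(self, kw, match):
        with pytest.raises(ConfigError, match=match):
            default_study(**kw)


class TestSimulateDataset:
    def test_shapes_and_planted_shift(self):
        cfg = default_study(n_probes_per_gene=2, effect_size=3.0, noise_sd=0.05)
        ds = tx.simulate_dataset(cfg)
        assert ds.matrix.n_probes == 600
        assert ds.matrix.n_samples == 12
        assert len(ds.de_directions) == 30
        # all probes of a DE gene carry the same shift
        case = ds.design.case_samples
        ctrl = ds.design.control_samples
        for gene, direction in ds.de_directions.items():
            probes = ds.annotation.mapping[ds.annotation.mapping == gene].index
            assert len(probes) == 2
            for probe in probes:
                diff = (
                    ds.matrix.values.loc[probe, case].mean()
                    - ds.matrix.values.loc[probe, ctrl].mean()
                )
                assert diff == pytest.approx(3.0 * direction, abs=0.25)

    def test_frac_up_count_exact(self):
        ds = tx.simulate_dataset(default_study(frac_up=0.7))
        ups = sum(1 for d in ds.de_directions.values() if d == 1)
        assert ups == round(0.7 * 30)

    def test_seed_determinism_bit_identical(self):
        a = tx.simulate_dataset(default_study(seed=7))
        b = tx.simulate_dataset(default_study(seed=7))
        assert a.matrix.values.equals(b.matrix.values)
        assert a.de_directions == b.de_directions

    def test_null_effect_size_yields_alpha_level_calls(self):
        cfg = default_study(n_genes=2000, n_de=0, effect_size=0.0, seed=3)
        ds = tx.simulate_dataset(cfg)
        records = tx.differential_expression(ds.matrix, ds.design)
        frac = (records["p_value"] < 0.05).mean()
        assert abs(frac - 0.05) <= 3 * np.sqrt(0.05 * 0.95 / 2000)

    def test_high_power_recovers_all_planted_at_fdr(self):
        cfg = default_study(
            n_case=10, n_control=10, effect_size=4.0, noise_sd=0.1, seed=5
        )
        ds = tx.simulate_dataset(cfg)
        records = tx.differential_expression(ds.matrix, ds.design, ds.annotation)
        sig = tx.select_signature(records, ds.annotation, tx.SelectionConfig(), "d")
        assert sig.directions == ds.de_directions


class TestHomologTable:
    def test_full_coverage_maps_everything(self):
        t = tx.simulate_homolog_table(["A", "B"], ["a", "b"], 1.0, seed=0)
        assert len(t) == 2

    def test_zero_coverage_empty(self):
        t = tx.simulate_homolog_table(["A", "B"], ["a", "b"], 0.0, seed=0)
        assert len(t) == 0

    def test_exact_group_count(self):
        ua = [f"A{i}" for i in range(1000)]
        ub = [f"B{i}" for i in range(1000)]
        t = tx.simulate_homolog_table(ua, ub, 0.8, seed=4)
        assert len(t) == 800

    def test_one_gene_per_species_per_group(self):
        t = tx.simulate_homolog_table(
            [f"A{i}" for i in range(50)], [f"B{i}" for i in range(50)], 0.5, seed=2
        )
        per_group = t.table.groupby(["group_id", "taxon_id"]).size()
        assert (per_group == 1).all()

    def test_empty_universe_rejected(self):
        with pytest.raises(ConfigError):
            tx.simulate_homolog_table([], ["a"], 0.5, seed=0)


def multi_config(**kw):
    study = dict(
        n_genes=800, n_case=8, n_control=8, n_de=120,
        effect_size=4.0, noise_sd=0.1, seed=0,
    )
    base = dict(
        studies={lab: tx.StudyConfig(**study) for lab in ("eoe", "ad", "aa")},
        species={"eoe": "9606", "ad": "9606", "aa": "9606"},
        pairwise_shared={("eoe", "ad"): 40, ("eoe", "aa"): 25, ("ad", "aa"): 15},
        triple_shared=10,
        concordance_frac=1.0,
        seed=21,
    )
    base.update(kw)
    return tx.MultiDiseaseConfig(**base)


class TestSimulateMultiDisease:
    def test_planted_shared_counts_exact(self):
        res = tx.simulate_multi_disease(multi_config())
        truth = res.truth
        assert len(truth.shared_pairs[("eoe", "ad")]) == 40
        assert len(truth.shared_pairs[("eoe", "aa")]) == 25
        assert len(truth.shared_pairs[("ad", "aa")]) == 15
        for lab in ("eoe", "ad", "aa"):
            assert len(truth.de_genes[lab]) == 120
            assert len(truth.triple_genes[lab]) == 10
        # triple core is inside every pairwise core
        for pair in truth.shared_pairs:
            assert truth.triple_genes[pair[0]] <= set(truth.shared_pairs[pair])

    def test_shared_budget_violation_rejected(self):
        with pytest.raises(ConfigError, match="n_de"):
            multi = multi_config(
                pairwise_shared={("eoe", "ad"): 100, ("eoe", "aa"): 100, ("ad", "aa"): 15}
            )
            tx.simulate_multi_disease(multi)

    def test_triple_exceeding_pairwise_rejected(self):
        with pytest.raises(ConfigError, match="triple_shared"):
            multi_config(triple_shared=20)

    def test_no_planted_sharing_gives_chance_overlap(self):
        cfg = multi_config(
            pairwise_shared={}, triple_shared=0,
        )
        res = tx.simulate_multi_disease(cfg)
        sigs = {}
        for lab, ds in res.datasets.items():
            rec = tx.differential_expression(ds.matrix, ds.design, ds.annotation)
            sigs[lab] = tx.select_signature(rec, ds.annotation, tx.SelectionConfig(), lab)
        ov = tx.pairwise_overlap(sigs["eoe"], sigs["ad"])
        # planted sets are disjoint by construction, so zero overlap
        # (at most chance-level false positives survive the fold-change filter)
        assert ov.n_overlap == 0

    def test_planted_concordance_and_direction_split_exact(self):
        cfg = multi_config(
            studies={
                lab: tx.StudyConfig(
                    n_genes=800, n_case=8, n_control=8, n_de=200,
                    effect_size=4.0, noise_sd=0.1, frac_up=106 / 148, seed=0,
                )
                for lab in ("eoe", "ad", "aa")
            },
            pairwise_shared={("eoe", "ad"): 148, ("eoe", "aa"): 0, ("ad", "aa"): 0},
            triple_shared=0,
        )
        res = tx.simulate_multi_disease(cfg)
        pair = res.truth.shared_pairs[("eoe", "ad")]
        assert len(pair) == 148 and all(pair.values())
        ups = sum(
            1 for g in pair if res.truth.de_genes["eoe"][g] == 1
        )
        assert ups == 106
        for g in pair:
            assert res.truth.de_genes["eoe"][g] == res.truth.de_genes["ad"][g]

    def test_discordant_planting(self):
        cfg = multi_config(concordance_frac=0.5)
        res = tx.simulate_multi_disease(cfg)
        pair = ("eoe", "ad")
        flags = res.truth.shared_pairs[pair]
        exclusive = {g: c for g, c in flags.items()
                     if g not in res.truth.triple_genes["eoe"]}
        n_conc = sum(exclusive.values())
        assert n_conc == round(0.5 * len(exclusive))
        for g, conc in exclusive.items():
            same = res.truth.de_genes["eoe"][g] == res.truth.de_genes["ad"][g]
            assert same == conc

    def test_cross_species_symbols_and_homologs(self):
        cfg = multi_config(
            species={"eoe": "9606", "ad": "9606", "aa": "10090"},
            ortholog_fraction=0.6,
        )
        res = tx.simulate_multi_disease(cfg)
        assert res.homologs is not None
        assert len(res.homologs) == round(0.6 * 800)
        assert all(g.startswith("MGENE") for g in res.truth.de_genes["aa"])
        assert all(g.startswith("GENE") for g in res.truth.de_genes["eoe"])

    def test_seed_determinism(self):
        a = tx.simulate_multi_disease(multi_config())
        b = tx.simulate_multi_disease(multi_config())
        for lab in a.datasets:
            assert a.datasets[lab].matrix.values.equals(b.datasets[lab].matrix.values)
        assert a.truth.shared_pairs == b.truth.shared_pairs


class TestSimulateGeneSets:
    def test_seed_determinism(self):
        universe = [f"G{i}" for i in range(100)]
        a = tx.simulate_gene_sets(universe, 10, (5, 20), seed=6)
        b = tx.simulate_gene_sets(universe, 10, (5, 20), seed=6)
        assert a.sets == b.sets

    def test_size_range_validation(self):
        with pytest.raises(ConfigError, match="size_range"):
            tx.simulate_gene_sets(["A", "B"], 3, (1, 5), seed=0)

    def test_sizes_within_range(self):
        universe = [f"G{i}" for i in range(100)]
        c = tx.simulate_gene_sets(universe, 20, (5, 20), seed=1)
        assert all(5 <= len(s) <= 20 for s in c.sets.values())

    def test_gene_symbol_naming(self):
        assert gene_symbol("9606", 3) == "GENE00003"
        assert gene_symbol("10090", 3) == "MGENE00003"
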