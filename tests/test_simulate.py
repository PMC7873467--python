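"""Synthetic-data generator: determinism, planted structure, round-trips."""

import numpy as np
import pandas as pd
import pytest

import ceranet as cn
from ceranet.simulate import SizingError


class TestConfigValidation:
    def test_defaults_are_valid(self):
        cn.SyntheticConfig()

    @pytest.mark.parametrize(
        "kwargs",
        [
            {"n_patients": 0},
            {"frac_de": 1.5},
            {"frac_de": -0.1},
            {"noise_sd": -1},
            {"shared_mirna_count": 1000},
        ],
    )
    def test_bad_values_rejected(self, kwargs):
        with pytest.raises(ValueError):
            cn.SyntheticConfig(**kwargs)

    def test_oversized_planting_rejected(self):
        """Pairs needing more dedicated DE miRNAs than exist raise a
        sizing error rather than silently wiring fewer."""
        with pytest.raises(SizingError, match="miRNA"):
            cn.SyntheticConfig(n_mirna=20, n_planted_cerna_pairs=10, shared_mirna_count=5)


class TestDeterminism:
    def test_same_seed_same_dataset(self):
        a = cn.generate_dataset(cn.SyntheticConfig(rng_seed=5))
        b = cn.generate_dataset(cn.SyntheticConfig(rng_seed=5))
        for cls in a.expression.matrices:
            pd.testing.assert_frame_equal(a.expression.matrices[cls], b.expression.matrices[cls])
        pd.testing.assert_frame_equal(a.interactions.edges, b.interactions.edges)
        assert a.truth == b.truth

    def test_different_seed_different_dataset(self):
        a = cn.generate_dataset(cn.SyntheticConfig(rng_seed=1))
        b = cn.generate_dataset(cn.SyntheticConfig(rng_seed=2))
        assert not a.expression.matrices["mrna"].equals(b.expression.matrices["mrna"])

    def test_fixture_bytes_identical(self, tmp_path):
        for sub in ("x", "y"):
            cn.write_fixture(
                cn.generate_dataset(cn.SyntheticConfig(rng_seed=3)), tmp_path / sub
            )
        for name in ("mrna.tsv", "interactions.tsv", "truth.json", "samples.tsv"):
            assert (tmp_path / "x" / name).read_bytes() == (tmp_path / "y" / name).read_bytes()


class TestPlantedStructure:
    def test_truth_entities_exist_in_matrices(self, default_dataset):
        t, expr = default_dataset.truth, default_dataset.expression
        for cls, planted in t.planted_de.items():
            assert set(planted) <= set(expr.matrices[cls].index)
        lnc_index = set(expr.matrices["lncrna"].index)
        assert set(t.hub_lncrnas) | set(t.disease_lncrnas) <= lnc_index
        assert set(t.seed_genes) <= set(expr.matrices["mrna"].index)
        for lnc, mrna in t.planted_pairs:
            assert lnc in lnc_index and mrna in set(expr.matrices["mrna"].index)

    def test_pair_mirnas_are_planted_de_and_wired_to_both(self, default_dataset):
        t = default_dataset.truth
        iset = default_dataset.interactions
        for (lnc, mrna) in t.planted_pairs:
            shared = t.pair_mirnas[f"{lnc}|{mrna}"]
            for mir in shared:
                assert mir in t.planted_de["mirna"]
            assert set(shared) <= iset.mirna_partners(lnc)
            assert set(shared) <= iset.mirna_partners(mrna)

    def test_shared_counts_exceed_background_expectation(self, default_dataset):
        """Planted pairs share shared_mirna_count dedicated miRNAs; under
        the background density (2 edges per miRNA over ~360 targets) the
        expected chance overlap is far below 1."""
        cfg = default_dataset.config
        n_targets = cfg.n_mrna + cfg.n_lncrna
        p_edge = cfg.background_edges_per_mirna / n_targets
        expected_background = cfg.n_mirna * p_edge**2
        assert cfg.shared_mirna_count > 10 * expected_background

    def test_planted_de_fraction_matches_config(self, default_dataset):
        cfg = default_dataset.config
        for cls, n in (("mrna", cfg.n_mrna), ("lncrna", cfg.n_lncrna), ("mirna", cfg.n_mirna)):
            assert len(default_dataset.truth.planted_de[cls]) == round(cfg.frac_de * n)

    def test_hub_attains_max_lncrna_degree(self, cerna_network, default_dataset):
        """With a single planted hub over sparse background edges, the hub
        has the highest lncRNA degree in the assembled network."""
        hub = default_dataset.truth.hub_lncrnas[0]
        lnc_degrees = {
            n: d
            for n, d in cerna_network.degree()
            if cerna_network.nodes[n]["node_class"] == "lncRNA"
        }
        assert lnc_degrees[hub] == max(lnc_degrees.values())

    def test_null_config_plants_nothing(self):
        ds = cn.generate_dataset(cn.SyntheticConfig(frac_de=0.0, rng_seed=11))
        t = ds.truth
        assert all(not v for v in t.planted_de.values())
        assert not t.planted_pairs and not t.hub_lncrnas and not t.disease_lncrnas

    def test_null_false_positive_rate_calibrated(self):
        """frac_de=0 datasets yield a DE raw-p false-positive rate of
        about alpha (checked over 10 replicates at alpha=0.05)."""
        rates = []
        for seed in range(10):
            ds = cn.generate_dataset(
                cn.SyntheticConfig(frac_de=0.0, n_mrna=400, n_lncrna=5, n_mirna=5, rng_seed=seed)
            )
            res = cn.paired_moderated_test(ds.expression, "mrna")
            rates.append((res["p_raw"] < 0.05).mean())
        assert abs(np.mean(rates) - 0.05) < 0.012

    def test_planted_recovery_rate(self, default_dataset, de_results):
        """At log2fc 2 and noise 0.3 over 8 pairs the DE stage recovers at
        least 90% of planted features in every class."""
        for cls, res in de_results.items():
            truth = set(default_dataset.truth.planted_de[cls])
            called = set(res.index[res["significant"]])
            assert len(called & truth) / len(truth) >= 0.9


class TestFixtureRoundTrip:
    def test_write_then_read_identity(self, tmp_path, default_dataset):
        cn.write_fixture(default_dataset, tmp_path)
        back = cn.read_fixture(tmp_path)
        for cls in default_dataset.expression.matrices:
            pd.testing.assert_frame_equal(
                back.expression.matrices[cls],
                default_dataset.expression.matrices[cls],
                check_exact=False,
                rtol=1e-9,
            )
        a = back.interactions.edges.sort_values(list(back.interactions.edges.columns)).reset_index(drop=True)
        b = default_dataset.interactions.edges.sort_values(list(back.interactions.edges.columns)).reset_index(drop=True)
        pd.testing.assert_frame_equal(a, b)
        assert back.truth.planted_pairs == default_dataset.truth.planted_pairs
        assert back.truth.seed_genes == default_dataset.truth.seed_genes
        assert back.config == default_dataset.config

    def test_empty_interactions_write_header_only(self, tmp_path):
        ds = cn.generate_dataset(
            cn.SyntheticConfig(frac_de=0.0, background_edges_per_mirna=0, rng_seed=0)
        )
        files = cn.write_fixture(ds, tmp_path)
        lines = files["interactions"].read_text().splitlines()
        assert lines == ["mirna_id\ttarget_id\ttarget_class"]
        assert len(cn.read_fixture(tmp_path).interactions) == 0

    def test_sample_sheet_shape(self, tmp_path, default_dataset):
        files = cn.write_fixture(default_dataset, tmp_path)
        sheet = pd.read_csv(files["samples"], sep="\t")
        assert len(sheet) == 16
        assert sheet["patient_id"].nunique() == 8
        assert (sheet["patient_id"].value_counts() == 2).all()
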