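"""Synthetic community generator: structure dials and reproducibility."""

import numpy as np
import pytest

from aroidnet.diversity import bray_curtis_partition
from aroidnet.metrics import h2prime
from aroidnet.modularity import dirt_lpawb_plus
from aroidnet.pipeline import stratify
from aroidnet.simulate import (
    SyntheticConfig,
    generate_community,
    planted_web,
    reference_survey_config,
)
from aroidnet.webs import ValidationError


def small_config(**overrides) -> SyntheticConfig:
    base = dict(
        n_hosts=6,
        n_insects=12,
        n_elevations=3,
        units_per_elevation=(20, 15, 10),
        total_individuals=1200,
        n_blocks=3,
        kappa=0.8,
        tau=0.4,
        seed=0,
    )
    base.update(overrides)
    return SyntheticConfig(**base)


class TestConfigValidation:
    @pytest.mark.parametrize(
        "overrides",
        [
            dict(kappa=1.5),
            dict(tau=-0.1),
            dict(units_per_elevation=(20, 15)),
            dict(units_per_elevation=(20, 0, 10)),
            dict(n_blocks=9),
            dict(total_individuals=0),
        ],
    )
    def test_invalid_configs_rejected(self, overrides):
        with pytest.raises(ValidationError):
            small_config(**overrides)

    def test_reference_config_mirrors_survey_design(self):
        cfg = reference_survey_config()
        assert cfg.n_hosts == 8
        assert cfg.n_insects == 34
        assert sum(cfg.units_per_elevation) == 250
        assert cfg.units_per_elevation == (123, 94, 33)


class TestGeneration:
    def test_same_seed_identical_output(self):
        cfg = small_config(seed=5)
        rec1, _ = generate_community(cfg)
        rec2, _ = generate_community(cfg)
        assert rec1.frame.equals(rec2.frame)

    def test_different_seeds_differ(self):
        rec1, _ = generate_community(small_config(seed=1))
        rec2, _ = generate_community(small_config(seed=2))
        assert not rec1.frame.equals(rec2.frame)

    def test_records_aggregate_to_internal_web(self):
        rec, truth = generate_community(small_config(seed=3))
        agg = rec.to_web().to_frame().sort_index().sort_index(axis=1)
        internal = truth["web"]
        internal = internal.loc[internal.sum(axis=1) > 0, internal.sum(axis=0) > 0]
        internal = internal.sort_index().sort_index(axis=1)
        assert agg.equals(internal)

    def test_total_individuals_conserved(self):
        cfg = small_config(seed=4)
        rec, _ = generate_community(cfg)
        assert rec.frame["count"].sum() == cfg.total_individuals

    def test_reference_dominance_structure(self):
        rec, _ = generate_community(reference_survey_config(seed=0))
        web = rec.to_web()
        top4 = np.sort(web.row_totals)[::-1][:4].sum()
        assert top4 / web.m >= 0.6

    def test_unit_count_matches_design(self):
        cfg = small_config(seed=6)
        rec, _ = generate_community(cfg)
        # every sampled unit is at most counted once per stratum design
        n_units_max = sum(cfg.units_per_elevation)
        assert len(rec.units()) <= n_units_max


class TestStructureDials:
    def test_perfectly_modular_community_recovers_planted_blocks(self):
        """With kappa = 1 and a flat abundance distribution the web is
        block-diagonal with three near-equal blocks; the optimizer must
        recover the planted partition, whose Q is 1 - sum f_b^2 with
        f_b the realized block mass fractions (= 2/3 for equal blocks)."""
        cfg = small_config(kappa=1.0, tau=0.0, seed=7, abundance_sigma=0.0)
        rec, truth = generate_community(cfg)
        web = rec.to_web()
        part = dirt_lpawb_plus(web, n_restarts=10, seed=0)
        blocks = truth["insect_blocks"]
        masses = np.zeros(cfg.n_blocks)
        for label, total in zip(web.row_labels, web.row_totals):
            masses[blocks[label]] += total
        f = masses / masses.sum()
        assert part.q == pytest.approx(1 - np.sum(f**2), abs=1e-12)
        assert part.q == pytest.approx(2 / 3, abs=0.02)
        assert part.n_modules == 3

    def test_zero_turnover_shares_pools(self):
        rec, truth = generate_community(small_config(tau=0.0, seed=8))
        pools = truth["pools"]
        assert pools["low"] == pools["mid"] == pools["high"]

    def test_full_turnover_disjoint_adjacent_pools(self):
        rec, truth = generate_community(small_config(tau=1.0, seed=9))
        pools = {k: set(v) for k, v in truth["pools"].items()}
        assert not (pools["low"] & pools["mid"])
        assert not (pools["mid"] & pools["high"])

    def test_full_turnover_gives_pure_balanced_dissimilarity(self):
        rec, _ = generate_community(small_config(tau=1.0, seed=10))
        strata = stratify(rec, "elevation")
        x = strata["low"].to_frame().sum(axis=1)
        y = strata["mid"].to_frame().sum(axis=1)
        species = sorted(set(x.index) | set(y.index))
        d = bray_curtis_partition(
            x.reindex(species, fill_value=0), y.reindex(species, fill_value=0)
        )
        assert d.balanced == pytest.approx(1.0, abs=1e-12)
        assert d.total == pytest.approx(1.0, abs=1e-12)

    def test_kappa_monotonically_sharpens_structure(self):
        """Mean recovered modularity and specialization both increase
        with the within-block concentration dial."""
        seeds = range(6)
        means_q, means_h2 = [], []
        for kappa in (0.3, 0.6, 0.9):
            qs, h2s = [], []
            for seed in seeds:
                web = planted_web(small_config(kappa=kappa, tau=0.0, seed=seed,
                                               total_individuals=800))
                qs.append(dirt_lpawb_plus(web, n_restarts=5, seed=seed).q)
                h2s.append(h2prime(web))
            means_q.append(np.mean(qs))
            means_h2.append(np.mean(h2s))
        assert means_q[0] < means_q[1] < means_q[2]
        assert means_h2[0] < means_h2[1] < means_h2[2]
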