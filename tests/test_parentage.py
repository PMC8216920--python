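"""Parentage likelihoods, confidence simulation, assignment, relationship LRs."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from gorillakin import parentage as pg
from gorillakin.genodata import AlleleFrequencyTable, allele_frequencies, encode_size_arrays
from gorillakin.simdata import (
    SimulationConfig,
    _draw_founders,
    _freq_arrays,
    _mendelian,
    dyad_arrays,
    inject_genotyping_error,
    simulate_population,
)


def freqs_1locus(d, n=1000):
    return AlleleFrequencyTable({"L1": d}, {"L1": n})


class TestLodClosedForms:
    def test_trio_lod_ln2(self):
        # offspring AB, known mother AA, candidate father BB, p_B = 0.5
        f = freqs_1locus({100: 0.5, 101: 0.5})
        cfg = pg.ParentageConfig(error_rate=0.0)
        r = pg.parentage_lod({"L1": (100, 101)}, {"L1": (101, 101)}, f,
                             known_other_parent={"L1": (100, 100)}, config=cfg)
        assert r.lod == pytest.approx(math.log(2))
        assert r.n_mismatches == 0

    def test_single_parent_lod_ln4(self):
        # offspring AA, candidate AA, p_A = 0.25: transmission p_A vs HWE p_A^2
        f = freqs_1locus({100: 0.25, 101: 0.75})
        cfg = pg.ParentageConfig(error_rate=0.0)
        r = pg.parentage_lod({"L1": (100, 100)}, {"L1": (100, 100)}, f, config=cfg)
        assert r.lod == pytest.approx(math.log(4))

    def test_incompatible_locus(self):
        f = freqs_1locus({1: 0.25, 2: 0.25, 3: 0.25, 4: 0.25})
        cfg = pg.ParentageConfig(error_rate=0.0)
        r = pg.parentage_lod({"L1": (1, 2)}, {"L1": (3, 4)}, f, config=cfg)
        assert r.n_mismatches == 1
        assert r.lod == -np.inf

    def test_no_shared_locus_errors(self):
        f = AlleleFrequencyTable({"L1": {1: 1.0}}, {"L1": 10})
        with pytest.raises(ValueError, match="share"):
            pg.parentage_lod({"L1": None}, {"L1": (1, 1)}, f)


class TestTransmissionModel:
    @given(st.integers(0, 2**31 - 1), st.sampled_from([0.0, 0.01]))
    @settings(max_examples=25, deadline=None)
    def test_distribution_sums_to_one(self, seed, e):
        rng = np.random.default_rng(seed)
        k = int(rng.integers(2, 6))
        f = rng.dirichlet(np.ones(k))
        parents = (tuple(rng.integers(k, size=2)), tuple(rng.integers(k, size=2)))
        d = pg.transmission_distribution(f, parents=parents, error_rate=e)
        assert sum(d.values()) == pytest.approx(1.0)
        d1 = pg.transmission_distribution(f, parent=parents[0], error_rate=e)
        assert sum(d1.values()) == pytest.approx(1.0)

    def test_error_model_mismatch_frequency(self, sim_config, founder_freqs):
        """Injected genotype-replacement error produces Mendelian mismatches at
        a rate consistent with the error model."""
        rng = np.random.default_rng(5)
        sizes, probs = _freq_arrays(founder_freqs)
        n = 2000
        gm = _draw_founders(rng, n, sizes, probs)
        gf = _draw_founders(rng, n, sizes, probs)
        go = _mendelian(rng, gm, gf)
        e = 0.05
        hit = rng.random((n, 10)) < e
        go_err = np.where(hit[..., None], _draw_founders(rng, n, sizes, probs), go)
        fv = [founder_freqs.vectors()[l][1] for l in founder_freqs.loci]
        eo, _, _ = encode_size_arrays(np.sort(go_err, -1), founder_freqs)
        em, _, _ = encode_size_arrays(np.sort(gm, -1), founder_freqs)
        ef, _, _ = encode_size_arrays(np.sort(gf, -1), founder_freqs)
        _, mism = pg._lod_terms(eo, ef, fv, 0.0, gm=em)
        # a replaced genotype is trio-incompatible with probability < 1;
        # mismatch rate must be positive but below the raw error rate
        rate = mism.sum() / (n * 10)
        assert 0 < rate < e
        # and exactly zero without error
        eo0, _, _ = encode_size_arrays(np.sort(go, -1), founder_freqs)
        _, mism0 = pg._lod_terms(eo0, ef, fv, 0.0, gm=em)
        assert mism0.sum() == 0


class TestConfidenceSimulation:
    def test_deterministic_under_seed(self, founder_freqs):
        cfg = pg.ParentageConfig(n_sim_offspring=1500, seed=42)
        a = pg.simulate_confidence_thresholds(founder_freqs, 8, cfg)
        b = pg.simulate_confidence_thresholds(
            founder_freqs, 8, pg.ParentageConfig(n_sim_offspring=1500, seed=42))
        assert a == b

    def test_high_exclusion_panel_recovers_parent(self, founder_freqs):
        cfg = pg.ParentageConfig(error_rate=0.0, prop_candidates_sampled=1.0,
                                 n_sim_offspring=2000, seed=7)
        out = pg.simulate_confidence_thresholds(founder_freqs, 8, cfg)
        assert out["success_rate"] >= 0.95

    def test_monomorphic_panel_uninformative(self):
        f = AlleleFrequencyTable({"L1": {100: 1.0}}, {"L1": 100})
        cfg = pg.ParentageConfig(error_rate=0.0, prop_candidates_sampled=1.0,
                                 n_sim_offspring=500, seed=3)
        with pytest.warns(UserWarning, match="unreachable"):
            out = pg.simulate_confidence_thresholds(f, 10, cfg)
        assert out["strict"] == np.inf
        assert out["success_rate"] == pytest.approx(1 / 10, abs=0.05)

    def test_achieved_confidence_matches_nominal(self, founder_freqs):
        """Delta thresholds hold up on a fresh simulated test set (within 3%)."""
        cfg = pg.ParentageConfig(error_rate=0.01, prop_candidates_sampled=0.5,
                                 n_sim_offspring=4000, seed=3)
        thr = pg.simulate_confidence_thresholds(founder_freqs, 8, cfg)
        rng = np.random.default_rng(777)
        sizes, probs = _freq_arrays(founder_freqs)
        n, e = 4000, 0.01
        gm = _draw_founders(rng, n, sizes, probs)
        gf = _draw_founders(rng, n, sizes, probs)
        go = _mendelian(rng, gm, gf)
        hit = rng.random((n, 10)) < e
        go = np.where(hit[..., None], _draw_founders(rng, n, sizes, probs), go)
        pool = np.stack([gf] + [_draw_founders(rng, n, sizes, probs)
                                for _ in range(7)], axis=1)
        out = rng.random(n) < 0.5  # is the true father in the pool?
        absent = ~out
        pool[absent, 0] = _draw_founders(rng, int(absent.sum()), sizes, probs)
        fv = [founder_freqs.vectors()[l][1] for l in founder_freqs.loci]
        eo, _, _ = encode_size_arrays(np.sort(go, -1), founder_freqs)
        ep, _, _ = encode_size_arrays(np.sort(pool, -1), founder_freqs)
        lods, _ = pg._lod_terms(eo[:, None], ep, fv, e)
        top = np.argmax(lods, axis=1)
        part = np.partition(lods, -2, axis=1)
        delta = part[:, -1] - part[:, -2]
        correct = (top == 0) & out
        for name, level in (("relaxed", 0.80), ("strict", 0.95)):
            acc = delta >= thr[name]
            assert correct[acc].mean() >= level - 0.03


@pytest.fixture(scope="module")
def population():
    # a shallow pedigree over homogeneous founders keeps candidate males
    # unrelated to the true sire; deep histories or founder structure make
    # candidates kin of the silverbacks, which legitimately erodes
    # single-parent likelihood rankings
    cfg = SimulationConfig(generations=4, region_fst=None)
    table, truth, _ = simulate_population(cfg, seed=21)
    table = inject_genotyping_error(table, error_rate=0.01, seed=22)
    return table, truth


class TestAssignment:
    def test_assignment_reports_every_offspring(self, population):
        table, truth = population
        freqs = allele_frequencies(table)
        offspring = [i.id for i in table.individuals if i.role == "immature"][:6]
        mothers = [i.id for i in table.individuals if i.role == "adult_female"]
        fathers = [i.id for i in table.individuals
                   if i.sex == "male" and i.age_class == "adult"]
        cfg = pg.ParentageConfig(n_sim_offspring=1500, seed=9)
        res = pg.assign_parentage(table, offspring, mothers, fathers, freqs, cfg)
        seen = {r.offspring for r in res}
        assert seen == set(offspring)
        # every result has a usable confidence label
        assert {r.confidence for r in res} <= {"strict", "relaxed", "none"}

    def test_top_father_matches_truth(self, population):
        """The top paternity candidate is the true father for most offspring."""
        table, truth = population
        freqs = allele_frequencies(table)
        from gorillakin.genodata import encode

        enc = encode(table, freqs)
        fathers = [i.id for i in table.individuals
                   if i.sex == "male" and i.age_class == "adult"]
        offspring = [i.id for i in table.individuals if i.role == "immature"]
        gf = enc.geno[[enc.index_of(i) for i in fathers]]
        hits = tot = 0
        for oid in offspring:
            true_f = truth.pedigree[oid][1]
            if true_f not in fathers:
                continue
            lods, _ = pg._lod_terms(enc.geno[enc.index_of(oid)], gf,
                                    enc.freq_vectors, 0.01)
            hits += fathers[int(np.argmax(lods))] == true_f
            tot += 1
        assert tot > 10
        assert hits / tot >= 0.9


class TestRelationshipLRs:
    def test_u_is_identity(self, founder_freqs):
        loci = founder_freqs.loci
        g = {loc: (founder_freqs.alleles(loc)[0],) * 2 for loc in loci}
        out = pg.relationship_likelihood_ratios(g, dict(g), founder_freqs,
                                                min_shared_loci=1)
        u = [r for r in out if r.relationship == "U"][0]
        assert u.likelihood_ratio == pytest.approx(1.0)
        assert not u.significant

    def test_po_impossible_when_no_shared_allele(self):
        f = AlleleFrequencyTable({"L1": {1: 0.25, 2: 0.25, 3: 0.25, 4: 0.25}},
                                 {"L1": 100})
        cfg = pg.ParentageConfig(error_rate=0.0)
        out = pg.relationship_likelihood_ratios({"L1": (1, 2)}, {"L1": (3, 4)}, f,
                                                config=cfg, min_shared_loci=1)
        po = [r for r in out if r.relationship == "PO"][0]
        assert po.likelihood_ratio == 0.0

    def test_fs_vs_u_classification(self, sim_config, founder_freqs):
        fv = [founder_freqs.vectors()[l][1] for l in founder_freqs.loci]
        gx, gy, _ = dyad_arrays(sim_config, "FS", 500, seed=5, freqs=founder_freqs)
        ex, _, _ = encode_size_arrays(gx, founder_freqs)
        ey, _, _ = encode_size_arrays(gy, founder_freqs)
        fs_ratio = pg.relationship_lr_batch(ex, ey, fv, 0.01)["FS"]
        assert float(np.median(fs_ratio)) > 10
        ux, uy, _ = dyad_arrays(sim_config, "U", 500, seed=6, freqs=founder_freqs)
        exu, _, _ = encode_size_arrays(ux, founder_freqs)
        eyu, _, _ = encode_size_arrays(uy, founder_freqs)
        u_ratio = pg.relationship_lr_batch(exu, eyu, fv, 0.01)["FS"]
        assert float(np.mean(u_ratio > 10)) < 0.05
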