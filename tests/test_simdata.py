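"""Synthetic-data generators: Mendelian consistency, reproducibility, rates."""

import numpy as np
import pytest

from gorillakin.genodata import allele_frequencies, diversity_summary
from gorillakin.simdata import (
    SimulationConfig,
    dyad_arrays,
    founder_frequency_table,
    inject_genotyping_error,
    simulate_population,
    simulate_proximity_scans,
    simulate_relationship_dyads,
)


class TestDyads:
    def test_po_share_allele_at_every_locus(self, sim_config, founder_freqs):
        gx, gy, _ = dyad_arrays(sim_config, "PO", 500, seed=3, freqs=founder_freqs)
        share = ((gx[..., 0:1] == gy) | (gx[..., 1:2] == gy)).any(axis=-1)
        assert share.all()

    def test_same_seed_identical(self, sim_config):
        t1, _ = simulate_relationship_dyads(sim_config, "FS", 20, seed=9)
        t2, _ = simulate_relationship_dyads(sim_config, "FS", 20, seed=9)
        assert t1.genotypes == t2.genotypes

    def test_truth_labels_dyads(self, sim_config):
        table, truth = simulate_relationship_dyads(sim_config, "HS", 5, seed=1)
        assert truth.relationship("d00000_a", "d00000_b") == "HS"
        assert len(table.individuals) == 10

    def test_founder_he_near_target(self, sim_config):
        """Dirichlet(1) over 7 alleles targets expected He = 0.75."""
        rng = np.random.default_rng(0)
        hes = []
        for k in range(40):
            f = founder_frequency_table(sim_config, seed=int(rng.integers(2**31)))
            hes.append(diversity_summary(f, unbiased=False).mean_he)
        assert float(np.mean(hes)) == pytest.approx(0.75, abs=0.05)


class TestPopulation:
    def test_census_roles(self, sim_config):
        table, truth, locs = simulate_population(sim_config, seed=5)
        roles = {}
        for i in table.individuals:
            roles[i.role] = roles.get(i.role, 0) + 1
        assert roles["silverback"] == 4
        assert roles["adult_female"] == 16
        assert roles["solitary_male"] == 4
        assert roles["immature"] == 32
        assert len(locs) == 4

    def test_deterministic_under_seed(self, sim_config):
        t1, _, _ = simulate_population(sim_config, seed=8)
        t2, _, _ = simulate_population(sim_config, seed=8)
        assert t1.genotypes == t2.genotypes
        assert [i.id for i in t1.individuals] == [i.id for i in t2.individuals]

    def test_no_extragroup_paternity_when_rate_zero(self):
        cfg = SimulationConfig(extragroup_paternity_rate=0.0)
        table, truth, _ = simulate_population(cfg, seed=4)
        sires = {i.group_id: i.id for i in table.individuals
                 if i.role == "silverback"}
        for i in table.individuals:
            if i.role == "immature":
                assert truth.pedigree[i.id][1] == sires[i.group_id]

    def test_realized_extragroup_rate(self):
        """Fraction of immatures sired outside the group tracks the config rate."""
        rng = np.random.default_rng(2)
        egp = n = 0
        for rep in range(12):
            cfg = SimulationConfig(females_per_group=6, offspring_per_female=2)
            table, truth, _ = simulate_population(cfg, seed=int(rng.integers(2**31)))
            sires = {i.group_id: i.id for i in table.individuals
                     if i.role == "silverback"}
            for i in table.individuals:
                if i.role == "immature":
                    n += 1
                    egp += truth.pedigree[i.id][1] != sires[i.group_id]
        rate = egp / n
        expected = 2 / 27
        se = np.sqrt(expected * (1 - expected) / n)
        assert abs(rate - expected) < 4 * se

    def test_mendelian_consistency_before_error(self, sim_config):
        """Immatures never mismatch their true parents without genotyping error."""
        cfg = SimulationConfig(mutation_rate=0.0)
        table, truth, _ = simulate_population(cfg, seed=6)
        by_id = {i.id: i for i in table.individuals}
        for i in table.individuals:
            if i.role != "immature":
                continue
            mom, dad = truth.pedigree[i.id]
            if mom not in by_id or dad not in by_id:
                continue
            for loc in table.loci:
                o = table.genotype(i.id, loc)
                m = table.genotype(mom, loc)
                f = table.genotype(dad, loc)
                ok = any(a in m and b in f or a in f and b in m
                         for a, b in (o, o[::-1]))
                assert ok, (i.id, loc)

    def test_low_migration_increases_rst(self, founder_freqs):
        """Drift oracle: less migration means more differentiation."""
        from gorillakin.spatial import rst

        common = dict(generations=25, mutation_rate=1e-3, females_per_group=6,
                      extragroup_paternity_rate=0.0, n_solitary_males=0,
                      male_dispersal="adjacent")
        vals = {}
        # stay-prob 0.5 mixes the two demes maximally (0.0 would merely swap
        # the gene pools each generation, which does not homogenize)
        for label, stay in (("high_mig", 0.5), ("low_mig", 0.95)):
            r = []
            for seed in (11, 12, 13):
                cfg = SimulationConfig.linear(2, 10.0, female_stay_prob=stay,
                                              male_local_prob=stay, **common)
                table, _, _ = simulate_population(cfg, seed=seed)
                part = {i.id: i.group_id for i in table.individuals}
                res, _ = rst(table, part, n_perm=0, seed=0)
                r.append(res.rst)
            vals[label] = float(np.mean(r))
        assert vals["low_mig"] > vals["high_mig"]


class TestErrorInjection:
    def test_all_rates_zero_is_identity(self, sim_config):
        table, _, _ = simulate_population(sim_config, seed=3)
        out = inject_genotyping_error(table, 0.0, 0.0, 0.0, seed=1)
        assert out.genotypes == table.genotypes

    def test_error_rate_one_is_hwe_redraw(self, sim_config):
        """Full replacement redraws every genotype from Hardy-Weinberg: the
        fraction left unchanged equals the mean HWE probability of the
        original genotypes."""
        table, truth, _ = simulate_population(sim_config, seed=3)
        freqs = allele_frequencies(table)
        out = inject_genotyping_error(table, 1.0, 0.0, 0.0, seed=1, freqs=freqs)
        expected = []
        for (iid, loc), g in table.genotypes.items():
            f = freqs.frequencies[loc]
            p = f[g[0]] * f[g[1]] * (2 if g[0] != g[1] else 1)
            expected.append(p)
        unchanged = sum(out.genotypes[k] == table.genotypes[k]
                        for k in table.genotypes)
        mu = float(np.sum(expected))
        sd = float(np.sqrt(np.sum([p * (1 - p) for p in expected])))
        assert abs(unchanged - mu) < 4 * sd

    def test_dropout_heterozygosity_deficit(self, sim_config, founder_freqs):
        gx, _, _ = dyad_arrays(sim_config, "U", 1500, seed=5, freqs=founder_freqs)
        from gorillakin.simdata import _arrays_to_table

        ids = [f"i{k}" for k in range(1500)]
        table = _arrays_to_table(ids, sim_config, gx)
        rate = 0.2
        out = inject_genotyping_error(table, 0.0, rate, 0.0, seed=2)
        het_in = sum(g[0] != g[1] for g in table.genotypes.values())
        het_out = sum(g[0] != g[1] for g in out.genotypes.values())
        expected = het_in * (1 - rate)
        assert abs(het_out - expected) < 4 * np.sqrt(het_in * rate * (1 - rate))

    def test_missing_rate(self, sim_config):
        table, _, _ = simulate_population(sim_config, seed=3)
        out = inject_genotyping_error(table, 0.0, 0.0, 0.5, seed=2)
        miss = sum(g is None for g in out.genotypes.values())
        assert 0.4 < miss / len(out.genotypes) < 0.6


class TestProximityScans:
    def test_empty(self):
        scans, hours = simulate_proximity_scans([], 10, 1.0, lambda d: 0.5, seed=0)
        assert scans == [] and hours == {}

    def test_near_probability_respected(self):
        dyads = [("a", "b")]
        scans, hours = simulate_proximity_scans(dyads, 4000, 10.0,
                                                lambda d: 0.3, seed=1)
        near = sum(s.category in ("0-5", "6-10") for s in scans)
        assert near / 4000 == pytest.approx(0.3, abs=0.03)
        assert hours[frozenset(("a", "b"))] == 10.0

    def test_effect_detected_with_power(self, founder_freqs, sim_config):
        """Monotone near_prob(relatedness) yields positive Spearman rho."""
        from gorillakin.proximity import build_dyad_proximity
        from gorillakin.relatedness import matrix_from_size_arrays
        from scipy import stats

        rng = np.random.default_rng(3)
        detected = 0
        n_rep = 30
        for _ in range(n_rep):
            r_vals = rng.uniform(0, 0.5, size=21)
            dyads = [(f"a{k}", f"b{k}") for k in range(21)]
            near = {frozenset(d): 0.2 + r_vals[k] for k, d in enumerate(dyads)}
            scans, hours = simulate_proximity_scans(
                dyads, 60, 5.0, near, seed=int(rng.integers(2**31)))
            prox = build_dyad_proximity(scans, hours)
            idx = {tuple(sorted(p.dyad)): p.index for p in prox}
            x = [idx[tuple(sorted(d))] for d in dyads]
            detected += stats.spearmanr(x, r_vals).statistic > 0
        assert detected / n_rep >= 0.8
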