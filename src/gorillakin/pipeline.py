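"""End-to-end pipeline: load -> filter -> diversity -> relatedness ->
parentage -> kin tests -> spatial -> proximity, with per-stage outputs and a
run manifest.  The pipeline is a pure function of (inputs, config, seed):
rerunning with the same config reproduces every numeric output.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from . import genodata, kin_structure, parentage, proximity, relatedness, spatial

logger = logging.getLogger(__name__)

ALL_STAGES = ("diversity", "relatedness", "parentage", "kin_tests", "spatial",
              "proximity")


class StageError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage


@dataclass
class RunConfig:
    genotypes: str
    output_dir: str
    dialect: str = "csv"
    locations: str | None = None
    distances: str | None = None   # optional override matrix CSV (km)
    scans: str | None = None
    hours: str | None = None
    estimator: str = "QG"
    min_valid_loci: int = 7
    min_shared_loci: int = 5
    n_perm: int = 10_000
    pair_test_n_perm: int = 1000
    seed: int = 0
    error_rate: float = 0.01
    prop_candidates_sampled: float = 0.5
    n_sim_offspring: int = 10_000
    stages: tuple = ALL_STAGES

    @classmethod
    def from_file(cls, path) -> "RunConfig":
        import yaml

        with open(path) as fh:
            raw = yaml.safe_load(fh)
        raw["stages"] = tuple(raw.get("stages", ALL_STAGES))
        return cls(**raw)


def _config_hash(config: RunConfig) -> str:
    blob = json.dumps(asdict(config), sort_keys=True, default=str)
    return hashlib.sha256(blob.encode()).hexdigest()[:16]


def run_pipeline(config: RunConfig) -> dict:
    """Execute the configured stages; returns the manifest dict."""
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(config.seed)
    stage_seed = {s: int(rng.integers(2**31)) for s in ALL_STAGES}
    manifest = {"config": asdict(config), "config_hash": _config_hash(config),
                "seed": config.seed, "stage_seeds": stage_seed, "outputs": {}}

    table = genodata.read_genotypes(config.genotypes, dialect=config.dialect)
    table = genodata.filter_individuals(table, config.min_valid_loci)
    freqs = genodata.allele_frequencies(table, description="all typed individuals")

    adults = [ind for ind in table.individuals if ind.age_class == "adult"]
    adult_ids = {ind.id for ind in adults}
    matrices = {}

    def record(stage, name, path):
        manifest["outputs"].setdefault(stage, []).append(str(path))

    if "diversity" in config.stages:
        try:
            div = genodata.diversity_summary(freqs)
            div.per_locus.to_csv(out / "diversity_per_locus.tsv", sep="\t", index=False)
            (out / "diversity.json").write_text(div.to_json())
            record("diversity", "per_locus", out / "diversity_per_locus.tsv")
            record("diversity", "summary", out / "diversity.json")
        except Exception as exc:
            raise StageError("diversity", exc) from exc

    if "relatedness" in config.stages:
        try:
            for est in relatedness.ESTIMATORS:
                m = relatedness.relatedness_matrix(
                    table, freqs, estimator=est,
                    subset=lambda ind: ind.age_class == "adult",
                    min_shared_loci=config.min_shared_loci)
                matrices[est] = m
            main = matrices[config.estimator.upper()]
            main_p = relatedness.matrix_significance(
                table, main, freqs, n_perm=config.pair_test_n_perm,
                seed=stage_seed["relatedness"])
            matrices[config.estimator.upper()] = main_p
            main_p.to_long().to_csv(out / "relatedness_long.tsv", sep="\t", index=False)
            conc = relatedness.estimator_concordance(list(matrices.values()))
            conc.to_csv(out / "estimator_concordance.tsv", sep="\t", index=False)
            record("relatedness", "long", out / "relatedness_long.tsv")
            record("relatedness", "concordance", out / "estimator_concordance.tsv")
        except Exception as exc:
            raise StageError("relatedness", exc) from exc

    if "parentage" in config.stages:
        try:
            offspring = [i.id for i in table.individuals if i.age_class == "immature"]
            mothers = [i.id for i in adults if i.sex == "female"]
            fathers = [i.id for i in adults if i.sex == "male"]
            if offspring and mothers and fathers:
                pcfg = parentage.ParentageConfig(
                    error_rate=config.error_rate,
                    prop_candidates_sampled=config.prop_candidates_sampled,
                    n_sim_offspring=config.n_sim_offspring,
                    seed=stage_seed["parentage"])
                results = parentage.assign_parentage(
                    table, offspring, mothers, fathers, freqs, pcfg)
                pd.DataFrame([asdict(r) for r in results]).to_csv(
                    out / "parentage.tsv", sep="\t", index=False)
                record("parentage", "assignments", out / "parentage.tsv")
        except Exception as exc:
            raise StageError("parentage", exc) from exc

    if "kin_tests" in config.stages:
        try:
            est = config.estimator.upper()
            m = matrices.get(est) or relatedness.relatedness_matrix(
                table, freqs, estimator=est,
                subset=lambda ind: ind.age_class == "adult",
                min_shared_loci=config.min_shared_loci)
            reports = {}
            females = [i.id for i in adults if i.sex == "female" and i.group_id]
            flabels = {i: table.individual(i).group_id for i in females}
            if len(set(flabels.values())) >= 2:
                res = kin_structure.group_mean_relatedness_test(
                    m, flabels, n_perm=config.n_perm, seed=stage_seed["kin_tests"])
                reports["female_within_group"] = {
                    g: {"observed": r.observed_mean, "p": r.p_value,
                        "n_perm": r.n_perm} for g, r in res.items()}
            silverback = {ind.group_id: ind.id for ind in adults
                          if ind.role == "silverback"}
            own = {f: silverback.get(table.individual(f).group_id) for f in females}
            own = {f: m_ for f, m_ in own.items() if m_ is not None}
            males = [i.id for i in adults if i.sex == "male"]
            if own and males:
                r = kin_structure.focal_male_relatedness_test(
                    m, list(own), own, males, n_perm=config.n_perm,
                    seed=stage_seed["kin_tests"])
                reports["female_vs_own_silverback"] = {
                    "observed": r.observed_mean, "p": r.p_value,
                    "p_two_tailed": r.p_two_tailed, "n_perm": r.n_perm}
            countries = {i.id: table.individual(i.id).country
                         for i in adults if table.individual(i.id).country}
            for sex in ("female", "male"):
                try:
                    res = kin_structure.partition_relatedness_test(
                        m, countries, table=table, sex_filter=sex,
                        n_perm=config.n_perm, seed=stage_seed["kin_tests"])
                    reports[f"{sex}_within_country"] = {
                        c: {"observed": r.observed_mean, "p": r.p_value}
                        for c, r in res.items()}
                except ValueError:
                    pass
            if m.p is not None:
                summary = kin_structure.significant_pair_summary(
                    m, {i.id: i.group_id for i in adults if i.group_id})
                reports["significant_pairs"] = summary.to_dict(orient="records")
            (out / "kin_tests.json").write_text(json.dumps(reports, indent=2))
            record("kin_tests", "report", out / "kin_tests.json")
        except Exception as exc:
            raise StageError("kin_tests", exc) from exc

    if "spatial" in config.stages and config.locations:
        try:
            locs = spatial.read_locations_csv(config.locations)
            override = None
            if config.distances:
                override = pd.read_csv(config.distances, index_col=0)
            D = spatial.geographic_distance_matrix(locs, override=override)
            country_of = {lc.group_id: lc.country for lc in locs}
            part_country = {i.id: country_of.get(i.group_id) for i in adults
                            if country_of.get(i.group_id)}
            glob, _ = spatial.rst(table, part_country, n_perm=config.n_perm,
                                  seed=stage_seed["spatial"])
            part_group = {i.id: i.group_id for i in adults if i.group_id}
            _, pairwise = spatial.rst(table, part_group, n_perm=0,
                                      seed=stage_seed["spatial"])
            ibd = spatial.ibd_regression(pairwise, D, n_perm=config.n_perm,
                                         seed=stage_seed["spatial"])
            report = {"rst_between_countries": {"rst": glob.rst, "p": glob.p_value},
                      "ibd": {"slope": ibd.slope, "intercept": ibd.intercept,
                              "p": ibd.p_value, "log_base": "e"}}
            ibd.pairs.to_csv(out / "ibd_pairs.tsv", sep="\t", index=False)
            (out / "spatial.json").write_text(json.dumps(report, indent=2))
            record("spatial", "report", out / "spatial.json")
            record("spatial", "pairs", out / "ibd_pairs.tsv")
        except Exception as exc:
            raise StageError("spatial", exc) from exc

    if "proximity" in config.stages and config.scans:
        try:
            scans = proximity.read_scans_csv(config.scans)
            hours = proximity.read_hours_csv(config.hours)
            dyads = proximity.build_dyad_proximity(scans, hours)
            est = config.estimator.upper()
            m = matrices.get(est) or relatedness.relatedness_matrix(
                table, freqs, estimator=est,
                subset=lambda ind: ind.age_class == "adult",
                min_shared_loci=config.min_shared_loci)
            rho, p, n = proximity.proximity_relatedness_correlation(dyads, m)
            report = {"spearman_rho": rho, "p": p, "n_dyads": n}
            pd.DataFrame([{"id1": d.ids[0], "id2": d.ids[1],
                           "n_near": d.n_scans_near, "n_total": d.n_scans_total,
                           "hours": d.focal_hours, "index": d.index}
                          for d in dyads]).to_csv(out / "proximity.tsv", sep="\t",
                                                  index=False)
            (out / "proximity.json").write_text(json.dumps(report, indent=2))
            record("proximity", "report", out / "proximity.json")
        except Exception as exc:
            raise StageError("proximity", exc) from exc

    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, default=str))
    return manifest
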