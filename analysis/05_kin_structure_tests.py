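#!/usr/bin/env python
"""Permutation tests for kin association among adults: are females more
related within groups than across, more related to their own silverback than
to other males, and more related within regions (by sex)?"""

import argparse
import json
from pathlib import Path

from gorillakin import genodata, kin_structure, relatedness

BASE = Path(__file__).resolve().parent.parent / "results"


def main(seed: int, n_perm: int):
    table = genodata.read_genotypes(BASE / "data" / "genotypes.csv")
    table = genodata.filter_individuals(table, 7)
    freqs = genodata.allele_frequencies(table)
    adults = [i for i in table.individuals if i.age_class == "adult"]
    m = relatedness.relatedness_matrix(table, freqs, estimator="QG",
                                       subset=lambda i: i.age_class == "adult")
    report = {}

    females = [i.id for i in adults if i.sex == "female"]
    flabels = {i.id: i.group_id for i in adults if i.sex == "female"}
    res = kin_structure.group_mean_relatedness_test(m, flabels, n_perm=n_perm,
                                                    seed=seed)
    report["female_within_group"] = {
        g: {"observed_mean": r.observed_mean, "p": r.p_value}
        for g, r in res.items()}

    silverback = {i.group_id: i.id for i in adults if i.role == "silverback"}
    own = {f: silverback[g] for f, g in flabels.items() if g in silverback}
    males = [i.id for i in adults if i.sex == "male"]
    r = kin_structure.focal_male_relatedness_test(m, list(own), own, males,
                                                  n_perm=n_perm, seed=seed)
    report["female_vs_own_silverback"] = {
        "observed_mean": r.observed_mean, "p_one_tailed": r.p_value,
        "p_two_tailed": r.p_two_tailed}

    countries = {i.id: i.country for i in adults}
    for sex in ("female", "male"):
        res = kin_structure.partition_relatedness_test(
            m, countries, table=table, sex_filter=sex, n_perm=n_perm, seed=seed)
        report[f"{sex}_within_region"] = {
            c: {"observed_mean": r.observed_mean, "p": r.p_value}
            for c, r in res.items()}

    mp = relatedness.matrix_significance(table, m, freqs, n_perm=500, seed=seed)
    fem_pairs = kin_structure.significant_pair_summary(
        mp, {i.id: i.group_id for i in adults if i.sex == "female"})
    report["significant_female_pairs"] = fem_pairs.to_dict(orient="records")

    (BASE / "kin_structure.json").write_text(json.dumps(report, indent=2))
    print(json.dumps(report, indent=2))


if __name__ == "__main__":
    ap = argparse.ArgumentParser()
    ap.add_argument("--seed", type=int, default=0)
    ap.add_argument("--n-perm", type=int, default=10_000)
    args = ap.parse_args()
    main(args.seed, args.n_perm)
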