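#!/usr/bin/env python
"""Do within-group female dyads that spend more time within 10 m of each other
tend to be genetic kin?  Spearman correlation between the scans-per-hour
proximity index and QG relatedness."""

import json
from pathlib import Path

import pandas as pd

from gorillakin import genodata, proximity, relatedness

BASE = Path(__file__).resolve().parent.parent / "results"


def main():
    table = genodata.read_genotypes(BASE / "data" / "genotypes.csv")
    table = genodata.filter_individuals(table, 7)
    freqs = genodata.allele_frequencies(table)
    m = relatedness.relatedness_matrix(table, freqs, estimator="QG",
                                       subset=lambda i: i.age_class == "adult")
    scans = proximity.read_scans_csv(BASE / "data" / "scans.csv")
    hours = proximity.read_hours_csv(BASE / "data" / "hours.csv")
    dyads = proximity.build_dyad_proximity(scans, hours)
    rho, p, n = proximity.proximity_relatedness_correlation(dyads, m)

    pd.DataFrame([{"id1": d.ids[0], "id2": d.ids[1], "n_near": d.n_scans_near,
                   "n_total": d.n_scans_total, "hours": d.focal_hours,
                   "index": d.index, "qg": m.value(*d.ids)}
                  for d in dyads]).to_csv(BASE / "proximity_dyads.tsv",
                                          sep="\t", index=False)
    report = {"spearman_rho": rho, "p_two_sided": p, "n_dyads": n}
    (BASE / "proximity.json").write_text(json.dumps(report, indent=2))
    print(f"Spearman rho = {rho:.3f}, p = {p:.3f}, N = {n} within-group "
          "female dyads")


if __name__ == "__main__":
    main()
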