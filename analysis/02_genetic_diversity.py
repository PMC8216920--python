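#!/usr/bin/env python
"""Locus diversity of the synthetic genotypes: allele counts, expected
heterozygosity, probability of identity.  Applies the more-than-six-valid-loci
filter before anything else, exactly as the downstream analyses do."""

from pathlib import Path

from gorillakin import genodata

BASE = Path(__file__).resolve().parent.parent / "results"


def main():
    table = genodata.read_genotypes(BASE / "data" / "genotypes.csv")
    table = genodata.filter_individuals(table, min_valid_loci=7)
    freqs = genodata.allele_frequencies(table, description="all typed individuals")
    div = genodata.diversity_summary(freqs)
    div.per_locus.to_csv(BASE / "diversity_per_locus.tsv", sep="\t", index=False)
    (BASE / "diversity.json").write_text(div.to_json())
    print(div.per_locus.to_string(index=False))
    print(f"\n{len(table.individuals)} individuals pass the >6-valid-loci filter")
    print(f"mean alleles/locus {div.mean_allele_count:.2f}, "
          f"mean He {div.mean_he:.3f}, multilocus PID {div.multilocus_pid:.3e}")


if __name__ == "__main__":
    main()
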