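"""Genotype data model, file I/O, filtering, and locus-level diversity summaries.

The central container is :class:`GenotypeTable`: individuals (with sex, age
class, social role, group and country metadata) typed at a panel of
codominant microsatellite loci, each genotype an unordered pair of integer
allele sizes or missing.  Allele frequencies computed from a reference
subset of the table parameterize every downstream estimator and likelihood.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

SEXES = ("male", "female", "unknown")
AGE_CLASSES = ("adult", "immature")
ROLES = ("silverback", "adult_female", "immature", "solitary_male")

#: sentinel for an untyped locus
MISSING = None


class GenodataError(ValueError):
    """Invalid genotype data (validation failure)."""


class ParseError(GenodataError):
    """Malformed input file."""


@dataclass(frozen=True)
class Individual:
    """One sampled animal with its social metadata."""

    id: str
    sex: str = "unknown"
    age_class: str = "adult"
    role: str = "adult_female"
    group_id: str | None = None
    country: str | None = None

    def __post_init__(self):
        if self.sex not in SEXES:
            raise GenodataError(f"individual {self.id!r}: unknown sex {self.sex!r}")
        if self.age_class not in AGE_CLASSES:
            raise GenodataError(
                f"individual {self.id!r}: unknown age class {self.age_class!r}"
            )
        if self.role not in ROLES:
            raise GenodataError(f"individual {self.id!r}: unknown role {self.role!r}")
        if self.role == "silverback" and (self.sex != "male" or self.age_class != "adult"):
            raise GenodataError(
                f"individual {self.id!r}: silverback implies adult male"
            )


@dataclass
class GenotypeTable:
    """Individuals x loci table of unordered allele-size pairs.

    ``genotypes[(ind_id, locus)]`` is a sorted ``(a1, a2)`` tuple of positive
    integer allele sizes, or absent/None when the locus failed to type.
    Homozygotes repeat the allele size.
    """

    individuals: list[Individual]
    loci: list[str]
    genotypes: dict[tuple[str, str], tuple[int, int] | None]

    def __post_init__(self):
        ids = [ind.id for ind in self.individuals]
        if len(set(ids)) != len(ids):
            dup = sorted({i for i in ids if ids.count(i) > 1})
            raise GenodataError(f"duplicate individual id(s): {dup}")
        if len(set(self.loci)) != len(self.loci):
            raise GenodataError("duplicate locus names in panel")
        for (iid, loc), g in self.genotypes.items():
            if g is None:
                continue
            if len(g) != 2 or any(not isinstance(a, (int, np.integer)) or a <= 0 for a in g):
                raise GenodataError(
                    f"genotype for ({iid}, {loc}) must be two positive integers, got {g!r}"
                )

    # -- convenience accessors -------------------------------------------
    @property
    def ids(self) -> list[str]:
        return [ind.id for ind in self.individuals]

    def individual(self, iid: str) -> Individual:
        for ind in self.individuals:
            if ind.id == iid:
                return ind
        raise KeyError(iid)

    def genotype(self, iid: str, locus: str):
        return self.genotypes.get((iid, locus))

    def genotypes_of(self, iid: str) -> dict[str, tuple[int, int] | None]:
        return {loc: self.genotypes.get((iid, loc)) for loc in self.loci}

    def n_valid_loci(self, iid: str) -> int:
        return sum(self.genotypes.get((iid, loc)) is not None for loc in self.loci)

    def subset(self, ids) -> "GenotypeTable":
        keep = set(ids)
        inds = [ind for ind in self.individuals if ind.id in keep]
        gts = {
            (iid, loc): g
            for (iid, loc), g in self.genotypes.items()
            if iid in keep
        }
        return GenotypeTable(inds, list(self.loci), gts)

    def to_frame(self) -> pd.DataFrame:
        """Wide DataFrame: metadata columns then <locus>.a1/<locus>.a2."""
        rows = []
        for ind in self.individuals:
            row = {
                "id": ind.id,
                "sex": ind.sex,
                "age_class": ind.age_class,
                "role": ind.role,
                "group": ind.group_id or "",
                "country": ind.country or "",
            }
            for loc in self.loci:
                g = self.genotypes.get((ind.id, loc))
                row[f"{loc}.a1"] = "" if g is None else g[0]
                row[f"{loc}.a2"] = "" if g is None else g[1]
            rows.append(row)
        return pd.DataFrame(rows)


@dataclass
class AlleleFrequencyTable:
    """Per-locus allele-size -> frequency maps with provenance.

    ``sample_size[locus]`` counts typed *genes* (2 x typed individuals).
    """

    frequencies: dict[str, dict[int, float]]
    sample_size: dict[str, int]
    reference_set: str = ""

    def __post_init__(self):
        for loc, freqs in self.frequencies.items():
            tot = sum(freqs.values())
            if abs(tot - 1.0) > 1e-9:
                raise GenodataError(f"frequencies at {loc} sum to {tot}, not 1")
            if any(f <= 0 for f in freqs.values()):
                raise GenodataError(f"non-positive frequency at {loc}")

    @property
    def loci(self) -> list[str]:
        return list(self.frequencies)

    def alleles(self, locus: str) -> list[int]:
        return sorted(self.frequencies[locus])

    def vectors(self, loci=None):
        """Per-locus (allele_sizes array, frequency array) in sorted-size order."""
        out = {}
        for loc in loci if loci is not None else self.loci:
            sizes = np.array(self.alleles(loc), dtype=np.int64)
            f = np.array([self.frequencies[loc][int(s)] for s in sizes])
            out[loc] = (sizes, f)
        return out


@dataclass
class DiversitySummary:
    """Per-locus allele counts and expected heterozygosity, plus multilocus PID."""

    per_locus: pd.DataFrame  # columns: locus, n_alleles, he, pid
    mean_allele_count: float
    mean_he: float
    multilocus_pid: float

    def to_json(self) -> str:
        return json.dumps(
            {
                "per_locus": self.per_locus.to_dict(orient="records"),
                "mean_allele_count": self.mean_allele_count,
                "mean_he": self.mean_he,
                "multilocus_pid": self.multilocus_pid,
            }
        )


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

_META_COLS = ["id", "sex", "age_class", "role", "group", "country"]


def _parse_allele(token, row, col) -> int | None:
    s = str(token).strip()
    if s in ("", "0", "nan", "NA"):
        return None
    try:
        v = int(float(s))
    except ValueError:
        raise ParseError(f"malformed allele token {token!r} at row {row}, column {col}")
    if v <= 0:
        return None
    return v


def read_genotypes(path, dialect: str = "csv") -> GenotypeTable:
    """Read a genotype table from ``path`` in the given dialect.

    ``csv``: header ``id,sex,age_class,role,group,country,<locus>.a1,<locus>.a2,...``
    with empty field or ``0`` meaning missing.  ``genepop``: 4- or 6-digit
    allele codes, ``0000``/``000000`` missing; POP blocks become group ids.
    """
    if dialect == "csv":
        return _read_csv(path)
    if dialect == "genepop":
        return _read_genepop(path)
    raise ValueError(f"unsupported dialect {dialect!r}")


def _read_csv(path) -> GenotypeTable:
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    missing_meta = [c for c in _META_COLS if c not in df.columns]
    if missing_meta:
        raise ParseError(f"missing metadata column(s): {missing_meta}")
    locus_cols = [c for c in df.columns if c not in _META_COLS]
    loci: list[str] = []
    for c in locus_cols:
        if not (c.endswith(".a1") or c.endswith(".a2")):
            raise ParseError(f"unrecognized column {c!r} (expected <locus>.a1/.a2)")
        base = c[:-3]
        if base not in loci:
            loci.append(base)
    for loc in loci:
        if f"{loc}.a1" not in df.columns or f"{loc}.a2" not in df.columns:
            raise ParseError(f"locus {loc!r} lacks paired .a1/.a2 columns")

    individuals, genotypes = [], {}
    for ridx, row in df.iterrows():
        ind = Individual(
            id=row["id"],
            sex=row["sex"] or "unknown",
            age_class=row["age_class"] or "adult",
            role=row["role"] or "adult_female",
            group_id=row["group"] or None,
            country=row["country"] or None,
        )
        individuals.append(ind)
        for loc in loci:
            a1 = _parse_allele(row[f"{loc}.a1"], ridx + 2, f"{loc}.a1")
            a2 = _parse_allele(row[f"{loc}.a2"], ridx + 2, f"{loc}.a2")
            if (a1 is None) != (a2 is None):
                raise ParseError(
                    f"half-typed genotype for {ind.id} at {loc} (row {ridx + 2})"
                )
            genotypes[(ind.id, loc)] = None if a1 is None else tuple(sorted((a1, a2)))
    return GenotypeTable(individuals, loci, genotypes)


def _read_genepop(path) -> GenotypeTable:
    with open(path) as fh:
        lines = [ln.rstrip("\n") for ln in fh]
    if not lines:
        raise ParseError("empty GenePop file")
    # line 1 is a free title; then locus names until first POP
    loci: list[str] = []
    i = 1
    while i < len(lines) and lines[i].strip().upper() != "POP":
        for name in lines[i].replace(",", " ").split():
            loci.append(name)
        i += 1
    if i == len(lines):
        raise ParseError("no POP block found")

    individuals, genotypes = [], {}
    pop_idx = 0
    while i < len(lines):
        if lines[i].strip().upper() == "POP":
            pop_idx += 1
            i += 1
            continue
        line = lines[i].strip()
        i += 1
        if not line:
            continue
        if "," not in line:
            raise ParseError(f"GenePop sample line lacks comma: {line!r}")
        name, geno_part = line.split(",", 1)
        tokens = geno_part.split()
        if len(tokens) != len(loci):
            raise ParseError(
                f"individual {name.strip()!r}: {len(tokens)} genotypes for {len(loci)} loci"
            )
        iid = name.strip()
        ind = Individual(id=iid, group_id=f"pop{pop_idx}")
        individuals.append(ind)
        for loc, tok in zip(loci, tokens):
            if len(tok) not in (4, 6) or not tok.isdigit():
                raise ParseError(
                    f"malformed allele token {tok!r} for {iid} at locus {loc}"
                )
            half = len(tok) // 2
            a1, a2 = int(tok[:half]), int(tok[half:])
            if a1 == 0 or a2 == 0:
                genotypes[(iid, loc)] = None
            else:
                genotypes[(iid, loc)] = tuple(sorted((a1, a2)))
    return GenotypeTable(individuals, loci, genotypes)


def write_genotypes(table: GenotypeTable, path, dialect: str = "csv") -> None:
    """Write ``table`` to ``path``; inverse of :func:`read_genotypes`."""
    if dialect == "csv":
        table.to_frame().to_csv(path, index=False)
        return
    if dialect == "genepop":
        width = 3 if any(
            g is not None and max(g) > 99 for g in table.genotypes.values()
        ) else 2
        groups: dict[str, list[Individual]] = {}
        for ind in table.individuals:
            groups.setdefault(ind.group_id or "pop1", []).append(ind)
        with open(path, "w") as fh:
            fh.write("gorillakin export\n")
            for loc in table.loci:
                fh.write(loc + "\n")
            for members in groups.values():
                fh.write("POP\n")
                for ind in members:
                    codes = []
                    for loc in table.loci:
                        g = table.genotypes.get((ind.id, loc))
                        if g is None:
                            codes.append("0" * (2 * width))
                        else:
                            codes.append(f"{g[0]:0{width}d}{g[1]:0{width}d}")
                    fh.write(f"{ind.id} , " + " ".join(codes) + "\n")
        return
    raise ValueError(f"unsupported dialect {dialect!r}")


# ---------------------------------------------------------------------------
# Filtering and summaries
# ---------------------------------------------------------------------------


def filter_individuals(table: GenotypeTable, min_valid_loci: int = 7) -> GenotypeTable:
    """Keep individuals typed at >= ``min_valid_loci`` loci (default: more than six)."""
    if min_valid_loci < 0:
        raise ValueError("min_valid_loci must be >= 0")
    keep, removed = [], []
    for ind in table.individuals:
        (keep if table.n_valid_loci(ind.id) >= min_valid_loci else removed).append(ind.id)
    if removed:
        logger.info("filter_individuals removed %d individual(s): %s", len(removed), removed)
    if not keep:
        warnings.warn("all individuals removed by valid-locus filter", stacklevel=2)
    return table.subset(keep)


def allele_frequencies(table: GenotypeTable, reference_filter=None,
                       description: str | None = None) -> AlleleFrequencyTable:
    """Observed allele frequencies over a reference subset of individuals.

    ``reference_filter`` is a predicate over :class:`Individual`; default is
    all successfully typed individuals.
    """
    if reference_filter is None:
        ref = list(table.individuals)
        desc = description or "all individuals"
    else:
        ref = [ind for ind in table.individuals if reference_filter(ind)]
        desc = description or "filtered subset"
    if not ref:
        raise GenodataError("reference subset is empty")
    freqs: dict[str, dict[int, float]] = {}
    nsizes: dict[str, int] = {}
    for loc in table.loci:
        counts: dict[int, int] = {}
        n = 0
        for ind in ref:
            g = table.genotypes.get((ind.id, loc))
            if g is None:
                continue
            for a in g:
                counts[a] = counts.get(a, 0) + 1
                n += 1
        if n == 0:
            raise GenodataError(f"locus {loc!r} typed in no reference individual")
        freqs[loc] = {a: c / n for a, c in sorted(counts.items())}
        nsizes[loc] = n
    return AlleleFrequencyTable(freqs, nsizes, reference_set=desc)


def _locus_pid(f: np.ndarray) -> float:
    # probability two random HWE individuals share the genotype at this locus
    hom = float(np.sum(f**4))
    outer = np.outer(f, f)
    het = float(np.sum(np.triu(4.0 * outer**2, k=1)))
    return hom + het


def diversity_summary(freqs: AlleleFrequencyTable, unbiased: bool = True) -> DiversitySummary:
    """Allele counts, expected heterozygosity, and multilocus probability of identity.

    He defaults to Nei's unbiased estimator ``n/(n-1) * (1 - sum p^2)`` with
    n = typed genes; set ``unbiased=False`` for the raw Gini-Simpson form.
    PID per locus is ``sum p_i^4 + sum_{i<j} (2 p_i p_j)^2``; multilocus PID
    is the product over loci.
    """
    rows = []
    pid = 1.0
    for loc in freqs.loci:
        _, f = freqs.vectors([loc])[loc]
        he = 1.0 - float(np.sum(f**2))
        n = freqs.sample_size[loc]
        if unbiased and n > 1:
            he *= n / (n - 1)
        he = min(he, 1.0 - 1e-15)
        lp = _locus_pid(f)
        pid *= lp
        rows.append({"locus": loc, "n_alleles": len(f), "he": he, "pid": lp})
    per_locus = pd.DataFrame(rows)
    return DiversitySummary(
        per_locus=per_locus,
        mean_allele_count=float(per_locus["n_alleles"].mean()),
        mean_he=float(per_locus["he"].mean()),
        multilocus_pid=pid,
    )


# ---------------------------------------------------------------------------
# Numeric encoding shared by estimators and likelihoods
# ---------------------------------------------------------------------------


@dataclass
class EncodedGenotypes:
    """Genotype table recoded to per-locus allele indices for vectorized math.

    ``geno[i, l, :]`` are indices into the locus-l allele vector, or -1 when
    missing.  ``freq_vectors[l]`` are the matching frequency arrays; ``sizes[l]``
    the integer allele sizes.
    """

    ids: list[str]
    loci: list[str]
    geno: np.ndarray          # (n, L, 2) int, -1 = missing
    freq_vectors: list[np.ndarray]
    allele_sizes: list[np.ndarray]
    sample_size: np.ndarray   # (L,) typed genes behind each frequency vector

    @property
    def valid(self) -> np.ndarray:
        return self.geno[:, :, 0] >= 0

    def index_of(self, iid: str) -> int:
        return self.ids.index(iid)


def encode_size_arrays(geno_sizes: np.ndarray, freqs: AlleleFrequencyTable):
    """Recode an (..., L, 2) allele-size array to indices into ``freqs`` vectors.

    Missing entries (negative sizes) stay -1.  Returns
    ``(indices, freq_vectors, sample_size)`` over the table's locus order.
    """
    loci = freqs.loci
    vecs = freqs.vectors(loci)
    out = np.full_like(geno_sizes, -1)
    for l, loc in enumerate(loci):
        sizes = vecs[loc][0]
        g = geno_sizes[..., l, :]
        idx = np.searchsorted(sizes, g)
        idx_c = np.clip(idx, 0, len(sizes) - 1)
        ok = (g >= 0)
        if np.any(ok & (sizes[idx_c] != g)):
            raise GenodataError(f"allele size absent from frequency table at {loc}")
        out[..., l, :] = np.where(ok, idx_c, -1)
    fv = [vecs[loc][1] for loc in loci]
    ss = np.array([freqs.sample_size[loc] for loc in loci])
    return out, fv, ss


def encode(table: GenotypeTable, freqs: AlleleFrequencyTable,
           ids=None) -> EncodedGenotypes:
    """Recode allele sizes as indices into each locus's frequency vector.

    Raises if any observed allele is absent from ``freqs`` (estimators and
    likelihoods require every allele to carry a frequency).
    """
    ids = list(ids) if ids is not None else table.ids
    loci = [loc for loc in table.loci if loc in freqs.frequencies]
    vecs = freqs.vectors(loci)
    lookup = [
        {int(s): k for k, s in enumerate(vecs[loc][0])} for loc in loci
    ]
    geno = np.full((len(ids), len(loci), 2), -1, dtype=np.int64)
    for i, iid in enumerate(ids):
        for l, loc in enumerate(loci):
            g = table.genotypes.get((iid, loc))
            if g is None:
                continue
            try:
                geno[i, l, 0] = lookup[l][g[0]]
                geno[i, l, 1] = lookup[l][g[1]]
            except KeyError as exc:
                raise GenodataError(
                    f"allele {exc.args[0]} of {iid} at {loc} absent from frequency table"
                ) from None
    return EncodedGenotypes(
        ids=ids,
        loci=loci,
        geno=geno,
        freq_vectors=[vecs[loc][1] for loc in loci],
        allele_sizes=[vecs[loc][0] for loc in loci],
        sample_size=np.array([freqs.sample_size[loc] for loc in loci]),
    )
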