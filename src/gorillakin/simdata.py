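"""Forward simulation of polygynous multi-group populations with known truth.

The generator emulates the structure of a habituated western-gorilla study
system: ~10 microsatellite loci with ~7 alleles each and expected
heterozygosity around 0.75 (Dirichlet(1) founder frequencies over 7 equally
spaced allele sizes give E[He] = 0.75 exactly), four breeding groups split
over two regions 9-61 km apart, one silverback siring each group's offspring
except for a small extragroup-paternity rate (2/27 by default), obligatory
female natal dispersal biased toward the nearest group, stepwise (+/-1)
allele-size mutation with reflecting bounds, and a genotyping layer injecting
replacement error, allelic dropout and missingness.

Demography is deliberately minimal: non-overlapping generations with a fixed
census per group (one silverback, a fixed number of breeding females); when a
generation under-produces recruits of one sex, surviving adults carry over to
keep the census constant.  Everything is reproducible bit-for-bit under a
fixed seed.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .genodata import AlleleFrequencyTable, GenotypeTable, Individual
from .spatial import GroupLocation, geographic_distance_matrix

# study-like default layout: two regions, within-region spacing 9.1 / 2.0 km,
# between-region spacing ~57-66 km (on the equator, 1 deg lon = 111.195 km)
DEFAULT_COORDINATES = (
    (0.0, 0.0),       # region A, group 1
    (0.0, -0.08184),  # region A, group 2 (9.1 km from group 1)
    (0.0, 0.51261),   # region B, group 3 (57.0 km from group 1)
    (0.0, 0.53060),   # region B, group 4
)
DEFAULT_COUNTRIES = ("A", "A", "B", "B")


@dataclass
class SimulationConfig:
    """Study conditions for the synthetic population.

    Founder frequencies are Dirichlet(``dirichlet_alpha``) draws over
    ``n_alleles`` consecutive integer allele sizes per locus unless
    ``founder_frequencies`` is given explicitly.
    """

    n_loci: int = 10
    n_alleles: int = 7
    dirichlet_alpha: float = 1.0
    founder_frequencies: dict | None = None  # locus -> {size: freq}
    n_groups: int = 4
    coordinates: tuple = DEFAULT_COORDINATES
    countries: tuple = DEFAULT_COUNTRIES
    females_per_group: int = 4
    n_solitary_males: int = 4
    offspring_per_female: int = 2
    extragroup_paternity_rate: float = 2.0 / 27.0
    female_stay_prob: float = 0.0        # natal dispersal is obligatory by default
    female_nearest_prob: float = 0.8     # dispersal mass on the nearest group
    male_dispersal: str = "adjacent"     # "panmictic" removes male spatial limits
    male_local_prob: float = 0.5         # with "adjacent": stay-local probability
    generations: int = 4
    # Balding-Nichols founder differentiation between regions (countries):
    # region frequencies ~ Dirichlet(p * (1-F)/F), so F is the expected
    # frequency-scale differentiation already present at founding.  The modeled
    # groups sit in a much larger unmodeled population; founding them from
    # differentiated regional pools stands in for that deep history without
    # draining heterozygosity through drift in a tiny closed system.
    # None = identical founder pools everywhere (pure stepping-stone runs).
    region_fst: float | None = 0.08
    mutation_rate: float = 5e-4          # SMM +/-1 per allele copy per generation
    genotyping_error_rate: float = 0.01
    dropout_rate: float = 0.0
    missing_rate: float = 0.0

    # allele-size scaffold: locus l spans sizes base..base+n_alleles-1 with
    # +/- smm_margin slack for mutation before reflecting
    size_base: int = 100
    size_spacing: int = 20
    smm_margin: int = 6

    def __post_init__(self):
        for name in ("extragroup_paternity_rate", "female_stay_prob",
                     "female_nearest_prob", "male_local_prob", "mutation_rate",
                     "genotyping_error_rate", "dropout_rate", "missing_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if len(self.coordinates) != self.n_groups:
            raise ValueError("coordinates must match n_groups")

    def locus_names(self) -> list[str]:
        return [f"L{l + 1:02d}" for l in range(self.n_loci)]

    def size_bounds(self, l: int) -> tuple[int, int]:
        lo = self.size_base + l * self.size_spacing
        return lo - self.smm_margin, lo + self.n_alleles - 1 + self.smm_margin

    @classmethod
    def linear(cls, n_demes: int, spacing_km: float = 10.0, **kwargs):
        """Demes on a line (stepping-stone layout), ``spacing_km`` apart."""
        deg = spacing_km / 111.19492664455873  # km per degree longitude at lat 0
        coords = tuple((0.0, k * deg) for k in range(n_demes))
        countries = tuple("A" for _ in range(n_demes))
        return cls(n_groups=n_demes, coordinates=coords, countries=countries,
                   **kwargs)


@dataclass
class TruthRecord:
    """Ground truth retained by the generators."""

    pedigree: dict = field(default_factory=dict)      # id -> (mother, father)
    natal_group: dict = field(default_factory=dict)   # id -> group of birth
    deme: dict = field(default_factory=dict)          # id -> final group
    dispersal: dict = field(default_factory=dict)     # id -> [(from, to), ...]
    dyad_category: dict = field(default_factory=dict)  # frozenset -> PO/FS/HS/U

    def relationship(self, a: str, b: str) -> str:
        """Immediate pedigree category of a dyad: PO, FS, HS, or U."""
        key = frozenset((a, b))
        if key in self.dyad_category:
            return self.dyad_category[key]
        pa = self.pedigree.get(a, (None, None))
        pb = self.pedigree.get(b, (None, None))
        if a in pb or b in pa:
            return "PO"
        shared = sum(1 for x in pa if x is not None and x in pb)
        if shared == 2:
            return "FS"
        if shared == 1:
            return "HS"
        return "U"


# ---------------------------------------------------------------------------
# Founder frequencies and low-level draws (allele sizes throughout)
# ---------------------------------------------------------------------------


def founder_frequency_table(config: SimulationConfig, seed=None,
                            nominal_genes: int = 1000) -> AlleleFrequencyTable:
    """The generator's founder frequencies as an AlleleFrequencyTable."""
    if config.founder_frequencies is not None:
        freqs = config.founder_frequencies
    else:
        rng = np.random.default_rng(seed)
        freqs = {}
        for l, loc in enumerate(config.locus_names()):
            lo = config.size_base + l * config.size_spacing
            p = rng.dirichlet(np.full(config.n_alleles, config.dirichlet_alpha))
            p = np.maximum(p, 1e-6)
            p /= p.sum()
            freqs[loc] = {lo + k: float(p[k]) for k in range(config.n_alleles)}
    return AlleleFrequencyTable(
        frequencies=freqs,
        sample_size={loc: nominal_genes for loc in freqs},
        reference_set="simulation founder frequencies",
    )


def _freq_arrays(freqs: AlleleFrequencyTable):
    vecs = freqs.vectors()
    sizes = [vecs[loc][0] for loc in freqs.loci]
    probs = [vecs[loc][1] for loc in freqs.loci]
    return sizes, probs


def _draw_founders(rng, n, sizes, probs):
    L = len(sizes)
    g = np.empty((n, L, 2), dtype=np.int64)
    for l in range(L):
        g[:, l, :] = rng.choice(sizes[l], size=(n, 2), p=probs[l])
    return g


def _mendelian(rng, gm, gf):
    """One offspring genotype (allele sizes) per mother/father row."""
    n, L, _ = gm.shape
    a = np.take_along_axis(gm, rng.integers(2, size=(n, L))[..., None], 2)[..., 0]
    b = np.take_along_axis(gf, rng.integers(2, size=(n, L))[..., None], 2)[..., 0]
    return np.stack([a, b], axis=-1)


def _mutate_smm(rng, g, config: SimulationConfig):
    """Stepwise +/-1 mutation with reflecting bounds at the locus size range."""
    if config.mutation_rate <= 0:
        return g
    hit = rng.random(g.shape) < config.mutation_rate
    if not hit.any():
        return g
    step = rng.choice([-1, 1], size=g.shape)
    out = g + np.where(hit, step, 0)
    for l in range(g.shape[1]):
        lo, hi = config.size_bounds(l)
        col = out[:, l, :]
        col[col < lo] = lo + 1  # reflect
        col[col > hi] = hi - 1
    return out


def _sort_alleles(g):
    return np.sort(g, axis=-1)


def _arrays_to_table(ids, config_or_loci, geno_sizes, individuals=None) -> GenotypeTable:
    loci = (config_or_loci.locus_names()
            if isinstance(config_or_loci, SimulationConfig) else list(config_or_loci))
    if individuals is None:
        individuals = [Individual(id=i) for i in ids]
    g = _sort_alleles(geno_sizes)
    genotypes = {}
    for i, iid in enumerate(ids):
        for l, loc in enumerate(loci):
            if g[i, l, 0] < 0:
                genotypes[(iid, loc)] = None
            else:
                genotypes[(iid, loc)] = (int(g[i, l, 0]), int(g[i, l, 1]))
    return GenotypeTable(individuals, loci, genotypes)


# ---------------------------------------------------------------------------
# Relationship dyads
# ---------------------------------------------------------------------------


def dyad_arrays(config: SimulationConfig, relationship: str, n_dyads: int,
                seed=None, freqs: AlleleFrequencyTable | None = None):
    """Fast path: (gx, gy) allele-size arrays of shape (n_dyads, L, 2).

    Founders are Hardy-Weinberg draws from the founder frequencies; offspring
    follow Mendelian transmission.  No mutation or genotyping error: these
    dyads validate estimators under clean conditions.
    """
    rng = np.random.default_rng(seed)
    if freqs is None:
        freqs = founder_frequency_table(config, seed=rng.integers(2**31))
    sizes, probs = _freq_arrays(freqs)
    n = n_dyads
    if relationship == "U":
        gx = _draw_founders(rng, n, sizes, probs)
        gy = _draw_founders(rng, n, sizes, probs)
    elif relationship == "PO":
        gx = _draw_founders(rng, n, sizes, probs)
        mate = _draw_founders(rng, n, sizes, probs)
        gy = _mendelian(rng, gx, mate)
    elif relationship == "FS":
        gm = _draw_founders(rng, n, sizes, probs)
        gf = _draw_founders(rng, n, sizes, probs)
        gx = _mendelian(rng, gm, gf)
        gy = _mendelian(rng, gm, gf)
    elif relationship == "HS":
        gf = _draw_founders(rng, n, sizes, probs)  # shared sire
        gm1 = _draw_founders(rng, n, sizes, probs)
        gm2 = _draw_founders(rng, n, sizes, probs)
        gx = _mendelian(rng, gm1, gf)
        gy = _mendelian(rng, gm2, gf)
    else:
        raise ValueError(f"unknown relationship {relationship!r}")
    return _sort_alleles(gx), _sort_alleles(gy), freqs


def simulate_relationship_dyads(config: SimulationConfig, relationship: str,
                                n_dyads: int, seed=None):
    """GenotypeTable of ``n_dyads`` dyads of the requested category, plus truth."""
    gx, gy, freqs = dyad_arrays(config, relationship, n_dyads, seed=seed)
    ids, rows = [], []
    truth = TruthRecord()
    geno = np.empty((2 * n_dyads,) + gx.shape[1:], dtype=np.int64)
    for k in range(n_dyads):
        ia, ib = f"d{k:05d}_a", f"d{k:05d}_b"
        ids.extend([ia, ib])
        geno[2 * k], geno[2 * k + 1] = gx[k], gy[k]
        truth.dyad_category[frozenset((ia, ib))] = relationship
    table = _arrays_to_table(ids, config, geno)
    return table, truth


# ---------------------------------------------------------------------------
# Forward population simulation
# ---------------------------------------------------------------------------


class _Registry:
    """Allocates string ids and tracks genotypes/pedigree during the forward run."""

    def __init__(self):
        self.counter = 0
        self.truth = TruthRecord()

    def new_id(self, prefix: str) -> str:
        self.counter += 1
        return f"{prefix}{self.counter:05d}"


def _dispersal_weights(D: np.ndarray, natal: int, nearest_prob: float):
    """Destination weights over demes for a female leaving ``natal``."""
    n = D.shape[0]
    others = [d for d in range(n) if d != natal]
    order = sorted(others, key=lambda d: D[natal, d])
    w = np.zeros(n)
    if len(others) == 1:
        w[others[0]] = 1.0
        return w
    w[order[0]] = nearest_prob
    rest = np.array([1.0 / D[natal, d] for d in order[1:]])
    w[order[1:]] = (1.0 - nearest_prob) * rest / rest.sum()
    return w


def simulate_population(config: SimulationConfig | None = None, seed=None,
                        max_retries: int = 10):
    """Forward-simulate the multi-group population.

    Returns ``(table, truth, locations)``: the final census as a
    GenotypeTable (silverbacks, adult females, immatures of the last
    generation, and solitary males), the TruthRecord, and group locations.
    Genotyping error/dropout/missingness are *not* applied here; pass the
    table through :func:`inject_genotyping_error`.
    """
    config = config or SimulationConfig()
    rng = np.random.default_rng(seed)
    for attempt in range(max_retries):
        try:
            return _simulate_population_once(config, rng)
        except _ExtinctGroup as exc:
            warnings.warn(f"{exc}; regenerating (attempt {attempt + 1})", stacklevel=2)
    raise RuntimeError("population simulation failed after retries")


class _ExtinctGroup(RuntimeError):
    pass


def _region_founder_probs(config: SimulationConfig, rng, probs):
    """Per-region founder frequency vectors (Balding-Nichols around global)."""
    regions = sorted(set(config.countries))
    if config.region_fst is None or len(regions) < 2:
        return {r: probs for r in regions}
    c = (1.0 - config.region_fst) / config.region_fst
    out = {}
    for r in regions:
        vecs = []
        for p in probs:
            q = rng.dirichlet(np.maximum(c * p, 1e-3))
            q = np.maximum(q, 1e-9)
            vecs.append(q / q.sum())
        out[r] = vecs
    return out


def _simulate_population_once(config: SimulationConfig, rng):
    freqs = founder_frequency_table(config, seed=rng.integers(2**31))
    sizes, probs = _freq_arrays(freqs)
    region_probs = _region_founder_probs(config, rng, probs)
    G, F = config.n_groups, config.females_per_group
    locations = [
        GroupLocation(group_id=f"G{d + 1}", latitude=config.coordinates[d][0],
                      longitude=config.coordinates[d][1],
                      country=config.countries[d])
        for d in range(G)
    ]
    D = geographic_distance_matrix(locations).values

    reg = _Registry()
    truth = reg.truth

    def register(iid, deme, mother=None, father=None):
        truth.pedigree[iid] = (mother, father)
        truth.natal_group[iid] = locations[deme].group_id
        truth.deme[iid] = locations[deme].group_id

    # founders, drawn from their region's founder pool
    def deme_probs(d):
        return region_probs[config.countries[d]]

    sb_ids = [reg.new_id("SB") for _ in range(G)]
    sb_geno = np.concatenate(
        [_draw_founders(rng, 1, sizes, deme_probs(d)) for d in range(G)])
    fem_ids = [[reg.new_id("F") for _ in range(F)] for _ in range(G)]
    fem_geno = [_draw_founders(rng, F, sizes, deme_probs(d)) for d in range(G)]
    sol_ids = [reg.new_id("SM") for _ in range(config.n_solitary_males)]
    sol_host = [int(rng.integers(G)) for _ in sol_ids]
    sol_geno = (np.concatenate(
        [_draw_founders(rng, 1, sizes, deme_probs(h)) for h in sol_host])
        if sol_ids else np.empty((0, config.n_loci, 2), dtype=np.int64))
    for d in range(G):
        register(sb_ids[d], d)
        for i in range(F):
            register(fem_ids[d][i], d)
    for s, host in zip(sol_ids, sol_host):
        register(s, host)

    disp_w = [_dispersal_weights(D, d, config.female_nearest_prob) for d in range(G)]

    offspring = None
    for gen in range(config.generations):
        # --- reproduction ---------------------------------------------------
        kids = []  # (id, deme, is_female, genotype row index)
        moms, dads, demes = [], [], []
        for d in range(G):
            outside = [(sb_ids[dd], sb_geno[dd]) for dd in range(G) if dd != d]
            outside += list(zip(sol_ids, sol_geno))
            for i in range(F):
                for _ in range(config.offspring_per_female):
                    if outside and rng.random() < config.extragroup_paternity_rate:
                        fid, fg = outside[int(rng.integers(len(outside)))]
                    else:
                        fid, fg = sb_ids[d], sb_geno[d]
                    moms.append((fem_ids[d][i], fem_geno[d][i]))
                    dads.append((fid, fg))
                    demes.append(d)
        gm = np.stack([m[1] for m in moms])
        gf = np.stack([f[1] for f in dads])
        geno = _mutate_smm(rng, _mendelian(rng, gm, gf), config)
        sexes = rng.random(len(moms)) < 0.5  # True = female
        for k in range(len(moms)):
            iid = reg.new_id("IM" if gen == config.generations - 1 else "X")
            register(iid, demes[k], mother=moms[k][0], father=dads[k][0])
            kids.append((iid, demes[k], bool(sexes[k]), k))
        offspring = (kids, geno)

        if gen == config.generations - 1:
            break

        # --- recruitment ----------------------------------------------------
        fem_kids = [(iid, d, k) for iid, d, is_f, k in kids if is_f]
        male_kids = [(iid, d, k) for iid, d, is_f, k in kids if not is_f]

        # female dispersal: each daughter picks a destination deme
        arrivals: list[list] = [[] for _ in range(G)]
        for iid, natal, k in fem_kids:
            if rng.random() < config.female_stay_prob:
                dest = natal
            else:
                dest = int(rng.choice(G, p=disp_w[natal]))
            if dest != natal:
                truth.dispersal.setdefault(iid, []).append(
                    (locations[natal].group_id, locations[dest].group_id))
            truth.deme[iid] = locations[dest].group_id
            arrivals[dest].append((iid, k))

        new_fem_ids, new_fem_geno = [], []
        for d in range(G):
            picks = list(arrivals[d])
            rng.shuffle(picks)
            picks = picks[:F]
            ids_d = [iid for iid, _ in picks]
            geno_d = [geno[k] for _, k in picks]
            # carry over current females if this generation under-produced
            carry = list(range(F))
            rng.shuffle(carry)
            while len(ids_d) < F and carry:
                j = carry.pop()
                ids_d.append(fem_ids[d][j])
                geno_d.append(fem_geno[d][j])
            if len(ids_d) < F:
                raise _ExtinctGroup(f"group {locations[d].group_id} ran out of females")
            new_fem_ids.append(ids_d)
            new_fem_geno.append(np.stack(geno_d))

        # silverback recruitment
        new_sb_ids, new_sb_geno = [], []
        used = set()
        for d in range(G):
            if config.male_dispersal == "adjacent":
                if rng.random() < config.male_local_prob:
                    pool = [mk for mk in male_kids if mk[1] == d and mk[0] not in used]
                else:
                    order = sorted((dd for dd in range(G) if dd != d),
                                   key=lambda dd: D[d, dd])
                    pool = [mk for mk in male_kids if mk[1] == order[0] and mk[0] not in used]
                if not pool:
                    pool = [mk for mk in male_kids if mk[0] not in used]
            else:
                pool = [mk for mk in male_kids if mk[0] not in used]
            if pool:
                iid, natal, k = pool[int(rng.integers(len(pool)))]
                used.add(iid)
                if natal != d:
                    truth.dispersal.setdefault(iid, []).append(
                        (locations[natal].group_id, locations[d].group_id))
                truth.deme[iid] = locations[d].group_id
                new_sb_ids.append(iid)
                new_sb_geno.append(geno[k])
            else:  # no males this generation: the old silverback survives
                new_sb_ids.append(sb_ids[d])
                new_sb_geno.append(sb_geno[d])
        remaining = [mk for mk in male_kids if mk[0] not in used]
        rng.shuffle(remaining)
        ns = config.n_solitary_males
        new_sol = remaining[:ns]
        new_sol_ids = [mk[0] for mk in new_sol]
        new_sol_geno = [geno[mk[2]] for mk in new_sol]
        new_sol_host = [int(rng.integers(G)) for _ in new_sol]
        while len(new_sol_ids) < ns:  # carry over old solitary males
            j = len(new_sol_ids)
            new_sol_ids.append(sol_ids[j])
            new_sol_geno.append(sol_geno[j])
            new_sol_host.append(sol_host[j])

        sb_ids, sb_geno = new_sb_ids, np.stack(new_sb_geno)
        fem_ids, fem_geno = new_fem_ids, new_fem_geno
        if new_sol_ids:
            sol_ids, sol_geno = new_sol_ids, np.stack(new_sol_geno)
            sol_host = new_sol_host
        else:
            sol_ids, sol_geno, sol_host = [], sol_geno[:0], []

    # --- final census --------------------------------------------------------
    ids, inds, genos = [], [], []
    for d in range(G):
        gname, country = locations[d].group_id, locations[d].country
        ids.append(sb_ids[d])
        inds.append(Individual(id=sb_ids[d], sex="male", age_class="adult",
                               role="silverback", group_id=gname, country=country))
        genos.append(sb_geno[d])
        truth.deme[sb_ids[d]] = gname
        for i in range(F):
            ids.append(fem_ids[d][i])
            inds.append(Individual(id=fem_ids[d][i], sex="female", age_class="adult",
                                   role="adult_female", group_id=gname, country=country))
            genos.append(fem_geno[d][i])
            truth.deme[fem_ids[d][i]] = gname
    kids, kid_geno = offspring
    for iid, d, is_f, k in kids:
        ids.append(iid)
        inds.append(Individual(id=iid, sex="female" if is_f else "male",
                               age_class="immature", role="immature",
                               group_id=locations[d].group_id,
                               country=locations[d].country))
        genos.append(kid_geno[k])
    for k, (s, host) in enumerate(zip(sol_ids, sol_host)):
        ids.append(s)
        inds.append(Individual(id=s, sex="male", age_class="adult",
                               role="solitary_male",
                               group_id=locations[host].group_id,
                               country=locations[host].country))
        genos.append(sol_geno[k])
        truth.deme[s] = locations[host].group_id

    table = _arrays_to_table(ids, config, np.stack(genos), individuals=inds)
    return table, truth, locations


# ---------------------------------------------------------------------------
# Genotyping-error injection
# ---------------------------------------------------------------------------


def inject_genotyping_error(table: GenotypeTable, error_rate: float = 0.01,
                            dropout_rate: float = 0.0, missing_rate: float = 0.0,
                            seed=None,
                            freqs: AlleleFrequencyTable | None = None) -> GenotypeTable:
    """Apply missingness, allelic dropout, and replacement error per genotype.

    Events are checked independently in the order missing -> dropout ->
    error; a missing genotype short-circuits.  Replacement genotypes are
    Hardy-Weinberg draws from ``freqs`` (computed from the input table when
    not given).
    """
    for name, r in (("error_rate", error_rate), ("dropout_rate", dropout_rate),
                    ("missing_rate", missing_rate)):
        if not 0.0 <= r <= 1.0:
            raise ValueError(f"{name} must be in [0, 1]")
    if freqs is None and error_rate > 0:
        from .genodata import allele_frequencies
        freqs = allele_frequencies(table, description="error-injection reference")
    rng = np.random.default_rng(seed)
    vecs = freqs.vectors() if freqs is not None else {}
    new = {}
    for ind in table.individuals:
        for loc in table.loci:
            g = table.genotypes.get((ind.id, loc))
            if g is None:
                new[(ind.id, loc)] = None
                continue
            if missing_rate > 0 and rng.random() < missing_rate:
                new[(ind.id, loc)] = None
                continue
            if dropout_rate > 0 and g[0] != g[1] and rng.random() < dropout_rate:
                a = g[int(rng.integers(2))]
                g = (a, a)
            if error_rate > 0 and rng.random() < error_rate:
                s, p = vecs[loc]
                draw = rng.choice(s, size=2, p=p)
                g = (int(draw.min()), int(draw.max()))
            new[(ind.id, loc)] = g
    return GenotypeTable(list(table.individuals), list(table.loci), new)


# ---------------------------------------------------------------------------
# Proximity scans
# ---------------------------------------------------------------------------


def simulate_proximity_scans(dyads, scans_per_dyad: int, hours_per_dyad,
                             near_prob, seed=None):
    """Synthetic scan records for a list of dyads.

    ``near_prob`` maps a dyad (any 2-element iterable of ids) to the
    probability that a scan falls below 10 m (split evenly between the 0-5 m
    and 6-10 m categories); it may be a dict keyed by frozenset or a callable.
    Returns ``(scans, hours)`` with hours keyed by frozenset.
    """
    from .proximity import ScanRecord

    rng = np.random.default_rng(seed)
    get_p = near_prob if callable(near_prob) else (
        lambda d: near_prob[frozenset(d)])
    get_h = hours_per_dyad if callable(hours_per_dyad) else (
        lambda d: hours_per_dyad[frozenset(d)]
        if isinstance(hours_per_dyad, dict) else hours_per_dyad)
    scans, hours = [], {}
    for dyad in dyads:
        a, b = tuple(sorted(dyad))
        p = float(get_p((a, b)))
        hours[frozenset((a, b))] = float(get_h((a, b)))
        for s in range(scans_per_dyad):
            focal, partner = (a, b) if s % 2 == 0 else (b, a)
            if rng.random() < p:
                cat = "0-5" if rng.random() < 0.5 else "6-10"
            else:
                cat = ">=10"
            scans.append(ScanRecord(focal=focal, partner=partner,
                                    timestamp=f"t{s:05d}", category=cat))
    return scans, hours
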