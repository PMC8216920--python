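"""Geographic distances, R_ST differentiation, and isolation by distance.

R_ST is the microsatellite analog of F_ST: genetic differentiation measured
on allele *sizes*, appropriate under stepwise mutation.  Here it is computed
by a one-way analysis of variance of allele sizes with populations as groups
(gene copies as observations), with the among-population variance component
over the total; multilocus values sum the components across loci.
Significance comes from permuting individuals among populations.

Isolation by distance is assessed by regressing pairwise R_ST/(1 - R_ST) on
the natural log of geographic distance (km); the slope's one-tailed p-value
comes from permuting the location assignment of populations — a Mantel-type
test.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .genodata import GenotypeTable

EARTH_RADIUS_KM = 6371.0088  # WGS84 mean radius


class SpatialError(ValueError):
    pass


@dataclass(frozen=True)
class GroupLocation:
    group_id: str
    latitude: float | None
    longitude: float | None
    country: str | None = None

    def __post_init__(self):
        if self.latitude is not None and abs(self.latitude) > 90:
            raise SpatialError(f"latitude out of range for {self.group_id}")
        if self.longitude is not None and abs(self.longitude) > 180:
            raise SpatialError(f"longitude out of range for {self.group_id}")


@dataclass
class RstResult:
    partition: str
    rst: float
    p_value: float | None
    n_perm: int
    seed: int | None


@dataclass
class IbdResult:
    slope: float
    intercept: float
    p_value: float
    n_perm: int
    seed: int | None
    pairs: pd.DataFrame  # pop_a, pop_b, distance_km, rst, rst_ratio


def haversine_km(lat1, lon1, lat2, lon2) -> float:
    """Great-circle distance in km on the mean-radius sphere."""
    phi1, phi2 = np.radians(lat1), np.radians(lat2)
    dphi = phi2 - phi1
    dlmb = np.radians(lon2) - np.radians(lon1)
    a = np.sin(dphi / 2) ** 2 + np.cos(phi1) * np.cos(phi2) * np.sin(dlmb / 2) ** 2
    return float(2 * EARTH_RADIUS_KM * np.arcsin(np.sqrt(a)))


def geographic_distance_matrix(locations: list[GroupLocation],
                               override: pd.DataFrame | None = None) -> pd.DataFrame:
    """Pairwise group distances in km (geodesic), or the supplied override.

    An override matrix (square DataFrame indexed by group id) is the
    canonical path when printed distances are to be reproduced exactly.
    """
    names = [loc.group_id for loc in locations]
    if override is not None:
        missing = [g for g in names if g not in override.index or g not in override.columns]
        if missing:
            raise SpatialError(f"override distance matrix lacks group(s): {missing}")
        D = override.loc[names, names].astype(float)
        if not np.allclose(D.values, D.values.T):
            raise SpatialError("override distance matrix is not symmetric")
        return D
    for loc in locations:
        if loc.latitude is None or loc.longitude is None:
            raise SpatialError(f"no coordinates for group {loc.group_id!r} and no override")
    n = len(locations)
    D = np.zeros((n, n))
    for i, j in itertools.combinations(range(n), 2):
        d = haversine_km(locations[i].latitude, locations[i].longitude,
                         locations[j].latitude, locations[j].longitude)
        D[i, j] = D[j, i] = d
    return pd.DataFrame(D, index=names, columns=names)


# ---------------------------------------------------------------------------
# R_ST
# ---------------------------------------------------------------------------


def _size_arrays(table: GenotypeTable, partition: dict):
    """Per-locus allele-size observations with per-gene population codes."""
    pops = sorted(set(partition.values()))
    pop_code = {p: k for k, p in enumerate(pops)}
    per_locus = []
    ind_codes = []
    for loc in table.loci:
        sizes, codes, owners = [], [], []
        for idx, ind in enumerate(table.individuals):
            if ind.id not in partition:
                continue
            g = table.genotypes.get((ind.id, loc))
            if g is None:
                continue
            sizes.extend(g)
            codes.extend([pop_code[partition[ind.id]]] * 2)
            owners.extend([idx] * 2)
        per_locus.append((np.array(sizes, dtype=float),
                          np.array(codes, dtype=int),
                          np.array(owners, dtype=int)))
    return pops, per_locus


def _variance_components(y: np.ndarray, codes: np.ndarray, n_pops: int):
    """One-way ANOVA components: (sigma2_among, sigma2_within)."""
    N = len(y)
    counts = np.bincount(codes, minlength=n_pops).astype(float)
    present = counts > 0
    d = int(present.sum())
    if d < 2 or N <= d:
        return 0.0, 0.0
    sums = np.bincount(codes, weights=y, minlength=n_pops)
    means = np.where(present, sums / np.maximum(counts, 1), 0.0)
    grand = y.mean()
    ssb = float(np.sum(counts[present] * (means[present] - grand) ** 2))
    ssw = float(np.sum((y - means[codes]) ** 2))
    msb = ssb / (d - 1)
    msw = ssw / (N - d)
    n0 = (N - np.sum(counts**2) / N) / (d - 1)
    s2a = (msb - msw) / n0
    return s2a, msw


def _rst_value(per_locus, n_pops: int, codes_by_gene=None) -> float:
    s2a_sum, tot_sum = 0.0, 0.0
    informative = False
    for li, (y, codes, _) in enumerate(per_locus):
        if len(y) == 0:
            continue
        c = codes if codes_by_gene is None else codes_by_gene[li]
        if np.ptp(y) > 0:
            informative = True
        s2a, s2w = _variance_components(y, c, n_pops)
        s2a_sum += s2a
        tot_sum += s2a + s2w
    if not informative:
        raise SpatialError("allele sizes are monomorphic: R_ST undefined")
    if tot_sum == 0.0:
        return 0.0
    return s2a_sum / tot_sum


def rst(table: GenotypeTable, partition: dict, n_perm: int = 10_000,
        seed: int | None = None) -> tuple[RstResult, pd.DataFrame]:
    """Global R_ST with permutation p, plus pairwise values for all pop pairs.

    ``partition`` maps individual id -> population label.  The p-value is the
    fraction of individual-level permutations whose R_ST >= observed.
    """
    pops = sorted(set(partition.values()))
    if len(pops) < 2:
        raise SpatialError("need at least two populations")
    _, per_locus = _size_arrays(table, partition)
    observed = _rst_value(per_locus, len(pops))

    # permute individuals among populations (an individual keeps both alleles
    # at every locus together)
    rng = np.random.default_rng(seed)
    part_ids = [i for i in table.ids if i in partition]
    orig_code = {p: k for k, p in enumerate(pops)}
    ind_code = np.array([orig_code[partition[i]] for i in part_ids])
    id_pos = {iid: k for k, iid in enumerate(part_ids)}
    # precompute each gene copy's owner position once; a permutation then only
    # relabels owners
    owner_pos = []
    for y, codes, owners in per_locus:
        owner_pos.append(np.array([id_pos[table.ids[o]] for o in owners], dtype=int)
                         if len(owners) else np.array([], dtype=int))
    count = 0
    for _ in range(n_perm):
        shuffled = ind_code[rng.permutation(len(ind_code))]
        codes_by_gene = [shuffled[pos] if len(pos) else pos for pos in owner_pos]
        try:
            r = _rst_value(per_locus, len(pops), codes_by_gene)
        except SpatialError:
            continue
        if r >= observed:
            count += 1
    p = count / n_perm if n_perm > 0 else None

    rows = []
    for pa, pb in itertools.combinations(pops, 2):
        sub = {i: g for i, g in partition.items() if g in (pa, pb)}
        _, pl = _size_arrays(table, sub)
        try:
            r_pair = _rst_value(pl, 2)
        except SpatialError:
            r_pair = np.nan
        rows.append({"pop_a": pa, "pop_b": pb, "rst": r_pair})
    return (
        RstResult(partition=",".join(pops), rst=observed, p_value=p,
                  n_perm=n_perm, seed=seed),
        pd.DataFrame(rows),
    )


# ---------------------------------------------------------------------------
# Isolation by distance
# ---------------------------------------------------------------------------


def ibd_regression(pairwise_rst: pd.DataFrame, distances: pd.DataFrame,
                   n_perm: int = 10_000, seed: int | None = None) -> IbdResult:
    """OLS of R_ST/(1-R_ST) on ln(distance km), Mantel-type location permutation.

    ``pairwise_rst`` needs columns pop_a, pop_b, rst.  Pairs with R_ST = 1
    (infinite transform) are excluded with a warning.  One-tailed p = fraction
    of location-permuted slopes >= the observed slope.
    """
    pops = sorted(set(pairwise_rst["pop_a"]) | set(pairwise_rst["pop_b"]))
    if len(pops) < 3:
        raise SpatialError("need at least three populations for an IBD regression")
    pos = {p: k for k, p in enumerate(pops)}
    D = distances.loc[pops, pops].values.astype(float)

    ia = pairwise_rst["pop_a"].map(pos).to_numpy()
    ib = pairwise_rst["pop_b"].map(pos).to_numpy()
    r = pairwise_rst["rst"].to_numpy(dtype=float)
    usable = np.isfinite(r) & (r < 1.0)
    if np.any(~usable & np.isfinite(r)):
        warnings.warn("pair(s) with R_ST = 1 excluded from IBD regression", stacklevel=2)
    ia, ib, r = ia[usable], ib[usable], r[usable]
    if len(r) < 3:
        raise SpatialError("fewer than 3 usable population pairs")
    d = D[ia, ib]
    if np.any(d <= 0):
        raise SpatialError("all pairwise distances must be positive")
    y = r / (1.0 - r)
    x = np.log(d)
    slope, intercept = np.polyfit(x, y, 1)

    rng = np.random.default_rng(seed)
    count = 0
    for _ in range(n_perm):
        perm = rng.permutation(len(pops))
        xp = np.log(D[perm[ia], perm[ib]])
        sp = np.polyfit(xp, y, 1)[0]
        if sp >= slope:
            count += 1
    pairs = pd.DataFrame({
        "pop_a": [pops[i] for i in ia], "pop_b": [pops[i] for i in ib],
        "distance_km": d, "rst": r, "rst_ratio": y,
    })
    return IbdResult(slope=float(slope), intercept=float(intercept),
                     p_value=count / n_perm, n_perm=n_perm, seed=seed, pairs=pairs)


def read_locations_csv(path) -> list[GroupLocation]:
    """Locations CSV: columns group,lat,lon,country (lat/lon may be blank)."""
    df = pd.read_csv(path)
    out = []
    for _, row in df.iterrows():
        out.append(GroupLocation(
            group_id=str(row["group"]),
            latitude=None if pd.isna(row.get("lat")) else float(row["lat"]),
            longitude=None if pd.isna(row.get("lon")) else float(row["lon"]),
            country=None if pd.isna(row.get("country")) else str(row["country"]),
        ))
    return out
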