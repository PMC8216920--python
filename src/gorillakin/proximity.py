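"""Dyadic spatial-proximity indices from instantaneous scan samples, and
their correlation with genetic relatedness.

Scans record the distance category between a focal female and each visible
partner at 10-minute intervals: 0-5 m, 6-10 m, or >=10 m; an unrecorded
distance is treated as >=10 m.  A dyad's proximity index is the number of
scans at <10 m (i.e. the 0-5 m and 6-10 m categories pooled) per hour of
focal sampling on that dyad, pooled over both focal directions.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .relatedness import RelatednessMatrix

CATEGORIES = ("0-5", "6-10", ">=10", "unrecorded")
NEAR_CATEGORIES = frozenset({"0-5", "6-10"})  # "<10 m"


class ProximityError(ValueError):
    pass


@dataclass(frozen=True)
class ScanRecord:
    focal: str
    partner: str
    timestamp: str
    category: str

    def __post_init__(self):
        if self.focal == self.partner:
            raise ProximityError(f"focal equals partner: {self.focal}")
        if self.category not in CATEGORIES:
            raise ProximityError(f"unknown distance category {self.category!r}")


@dataclass(frozen=True)
class DyadProximity:
    dyad: frozenset
    n_scans_near: int
    n_scans_total: int
    focal_hours: float
    index: float  # near scans per focal hour

    @property
    def ids(self) -> tuple[str, str]:
        return tuple(sorted(self.dyad))


def build_dyad_proximity(scans: list[ScanRecord], hours: dict) -> list[DyadProximity]:
    """Pool scans over both focal directions and normalize by dyad focal hours.

    ``hours`` maps a dyad (frozenset of two ids, or sorted tuple) to focal
    hours; every observed dyad must have positive hours.
    """
    hours_norm = {frozenset(k): v for k, v in hours.items()}
    near: dict[frozenset, int] = {}
    total: dict[frozenset, int] = {}
    for scan in scans:
        d = frozenset((scan.focal, scan.partner))
        total[d] = total.get(d, 0) + 1
        if scan.category in NEAR_CATEGORIES:
            near[d] = near.get(d, 0) + 1
    out = []
    for d, n_tot in sorted(total.items(), key=lambda kv: tuple(sorted(kv[0]))):
        h = hours_norm.get(d)
        if h is None or h <= 0:
            raise ProximityError(
                f"zero or missing focal hours for observed dyad {tuple(sorted(d))}"
            )
        n_near = near.get(d, 0)
        out.append(DyadProximity(dyad=d, n_scans_near=n_near, n_scans_total=n_tot,
                                 focal_hours=float(h), index=n_near / h))
    return out


def _spearman_exact_p(x: np.ndarray, y: np.ndarray, rho: float) -> float:
    """Two-sided exact p by full enumeration of rank permutations."""
    n = len(x)
    rx = stats.rankdata(x)
    ry = stats.rankdata(y)
    count, total = 0, 0
    target = abs(rho) - 1e-12
    for perm in itertools.permutations(range(n)):
        r = stats.pearsonr(rx, ry[list(perm)]).statistic
        total += 1
        if abs(r) >= target:
            count += 1
    return count / total


def proximity_relatedness_correlation(proximity: list[DyadProximity],
                                      matrix: RelatednessMatrix,
                                      exact_max_n: int = 8):
    """Spearman rank correlation between dyad proximity index and relatedness.

    Uses tie-corrected (average) ranks; the p-value is exact (full
    permutation enumeration) for n <= ``exact_max_n``, otherwise the
    large-sample approximation.  Returns ``(rho, p, n)``.
    """
    xs, ys = [], []
    known = set(matrix.ids)
    for dp in proximity:
        a, b = dp.ids
        if a not in known or b not in known:
            continue
        v = matrix.value(a, b)
        if not np.isfinite(v):
            continue
        xs.append(dp.index)
        ys.append(v)
    n = len(xs)
    if n < 3:
        raise ProximityError(f"only {n} dyads with both measures; need >= 3")
    x, y = np.asarray(xs), np.asarray(ys)
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ProximityError("constant vector: correlation undefined")
    res = stats.spearmanr(x, y)
    rho = float(res.statistic)
    if n <= exact_max_n and not math.isnan(rho):
        p = _spearman_exact_p(x, y, rho)
    else:
        p = float(res.pvalue)
    return rho, p, n


def read_scans_csv(path) -> list[ScanRecord]:
    """Scans CSV: columns focal,partner,datetime,category."""
    df = pd.read_csv(path, dtype=str)
    return [
        ScanRecord(focal=r["focal"], partner=r["partner"],
                   timestamp=r["datetime"], category=r["category"])
        for _, r in df.iterrows()
    ]


def read_hours_csv(path) -> dict:
    """Hours CSV: columns id1,id2,hours."""
    df = pd.read_csv(path)
    return {
        frozenset((str(r["id1"]), str(r["id2"]))): float(r["hours"])
        for _, r in df.iterrows()
    }
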