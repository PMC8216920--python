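"""Permutation tests for kin association within social units.

All tests share the same contract: an observed mean relatedness, a null
sample of the same statistic built by permutation or redrawing, and a
one-tailed p-value computed as (# null >= observed) / n_perm — the excess-
relatedness convention.  Undefined pairs (too few shared loci) are excluded
from both the observed and the null means so the two remain comparable.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .relatedness import RelatednessMatrix


@dataclass
class PermutationResult:
    unit: str
    observed_mean: float
    null_means: np.ndarray
    p_value: float
    n_perm: int
    seed: int | None
    p_two_tailed: float | None = None

    def p_corrected(self) -> float:
        """(b+1)/(n+1) variant that never returns exactly zero."""
        b = int(np.sum(self.null_means >= self.observed_mean))
        return (b + 1) / (self.n_perm + 1)

    def null_histogram(self, bins: int = 30) -> pd.DataFrame:
        counts, edges = np.histogram(self.null_means, bins=bins)
        return pd.DataFrame(
            {"bin_left": edges[:-1], "bin_right": edges[1:], "count": counts}
        )


def _mean_within(V: np.ndarray, members: np.ndarray) -> float:
    iu, ju = np.triu_indices(members.shape[-1], 1)
    vals = V[members[..., iu], members[..., ju]]
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        return np.nanmean(vals, axis=-1)


def group_mean_relatedness_test(matrix: RelatednessMatrix, labels: dict,
                                n_perm: int = 10_000, seed: int | None = None,
                                ) -> dict[str, PermutationResult]:
    """Within-group mean relatedness vs a null of reshuffled group membership.

    ``labels`` maps individual id -> group.  The null permutes individuals
    among groups, preserving group sizes; per group, one-tailed p = fraction
    of permuted within-group means >= the observed mean.
    """
    ids = [i for i in matrix.ids if i in labels]
    groups: dict[str, list[int]] = {}
    for i in ids:
        groups.setdefault(labels[i], []).append(matrix.index(i))
    if len(groups) < 2:
        raise ValueError("need at least two groups for a membership permutation test")
    for g, members in groups.items():
        if len(members) < 2:
            warnings.warn(f"group {g!r} has a single member; not tested", stacklevel=2)

    # pooled individual list ordered by group; each group owns a slot range
    ordered = list(groups)
    pooled = np.concatenate([groups[g] for g in ordered]).astype(int)
    slots, start = {}, 0
    for g in ordered:
        slots[g] = np.arange(start, start + len(groups[g]))
        start += len(groups[g])

    rng = np.random.default_rng(seed)
    V = matrix.values
    perms = np.argsort(rng.random((n_perm, len(pooled))), axis=1)
    permuted = pooled[perms]  # (n_perm, n)

    out = {}
    for g in ordered:
        if len(groups[g]) < 2:
            continue
        obs = float(_mean_within(V, np.array(groups[g])))
        null = _mean_within(V, permuted[:, slots[g]])
        null = np.asarray(null, dtype=float)
        p = float(np.sum(null >= obs)) / n_perm
        out[g] = PermutationResult(unit=g, observed_mean=obs, null_means=null,
                                   p_value=p, n_perm=n_perm, seed=seed)
    return out


def focal_male_relatedness_test(matrix: RelatednessMatrix, females, own_male: dict,
                                male_pool, n_perm: int = 10_000,
                                seed: int | None = None) -> PermutationResult:
    """Are females more related to their own silverback than to males at random?

    Observed = mean over females of relatedness(female, own male).  Null =
    for each female independently, a male drawn uniformly from ``male_pool``;
    the female-wise means form the null sample.  Reports the one-tailed
    (excess relatedness) p and a two-tailed companion.
    """
    male_pool = list(male_pool)
    if not male_pool:
        raise ValueError("male pool is empty")
    females = list(females)
    fi = np.array([matrix.index(f) for f in females])
    mi = np.array([matrix.index(m) for m in male_pool])
    own = np.array([matrix.index(own_male[f]) for f in females])
    V = matrix.values
    obs_vals = V[fi, own]
    obs = float(np.nanmean(obs_vals))

    rng = np.random.default_rng(seed)
    draws = rng.integers(len(male_pool), size=(n_perm, len(females)))
    null_vals = V[fi[None, :], mi[draws]]
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        null = np.nanmean(null_vals, axis=1)
    p_hi = float(np.sum(null >= obs)) / n_perm
    p_lo = float(np.sum(null <= obs)) / n_perm
    return PermutationResult(unit="females-vs-own-male", observed_mean=obs,
                             null_means=null, p_value=p_hi, n_perm=n_perm,
                             seed=seed, p_two_tailed=min(1.0, 2.0 * min(p_hi, p_lo)))


def partition_relatedness_test(matrix: RelatednessMatrix, labels: dict,
                               table=None, sex_filter: str | None = None,
                               n_perm: int = 10_000, seed: int | None = None,
                               ) -> dict[str, PermutationResult]:
    """Within-partition (e.g. country) mean relatedness test, optionally sex-specific.

    ``labels`` maps id -> partition.  With ``sex_filter`` the test is run on
    the individuals of that sex only (requires ``table`` for sex metadata).
    """
    if sex_filter is not None:
        if table is None:
            raise ValueError("sex_filter requires the genotype table for metadata")
        keep = {ind.id for ind in table.individuals if ind.sex == sex_filter}
        labels = {i: g for i, g in labels.items() if i in keep}
    if len(set(labels.values())) < 2:
        raise ValueError("need at least two partitions")
    return group_mean_relatedness_test(matrix, labels, n_perm=n_perm, seed=seed)


def significant_pair_summary(matrix: RelatednessMatrix, labels: dict,
                             alpha: float = 0.05) -> pd.DataFrame:
    """Counts and proportions of significantly related pairs, within vs among labels."""
    if matrix.p is None:
        raise ValueError("matrix carries no per-pair p-values")
    counts = {"within": [0, 0], "among": [0, 0]}  # [significant, total]
    for a, b in matrix.pairs():
        if a not in labels or b not in labels:
            continue
        i, j = matrix.index(a), matrix.index(b)
        if not np.isfinite(matrix.values[i, j]) or not np.isfinite(matrix.p[i, j]):
            continue
        key = "within" if labels[a] == labels[b] else "among"
        counts[key][1] += 1
        if matrix.p[i, j] < alpha:
            counts[key][0] += 1
    rows = []
    for key, (sig, tot) in counts.items():
        rows.append({"scope": key, "n_significant": sig, "n_pairs": tot,
                     "proportion": sig / tot if tot else np.nan})
    return pd.DataFrame(rows)
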