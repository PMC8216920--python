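"""Likelihood-based parentage assignment with simulated confidence, plus
pairwise relationship likelihood ratios.

The genotyping-error model is a single-parameter genotype replacement: with
probability ``e`` the recorded genotype is an independent Hardy-Weinberg
draw, otherwise it is the true genotype.  Applied to the offspring
observation conditional on the recorded candidate genotypes, this keeps every
likelihood closed-form:

    P_e(g_o | parents) = (1 - e) * T(g_o | parents) + e * P_HWE(g_o)

LOD scores are natural-log likelihood ratios of the candidate hypothesis over
the corresponding unrelated hypothesis, summed over loci typed in every
involved individual.  Confidence in an assignment is attached through the
standard simulation procedure: simulate offspring with candidate pools,
compute Delta = LOD(top) - LOD(second best), and find the smallest Delta
threshold at which the desired fraction of accepted assignments is correct.

Relationship likelihood ratios score a pair's genotypes under parent-
offspring, full-sib, half-sib and unrelated hypotheses via the IBD-coefficient
mixture P(g_x, g_y | R) = sum_m k_m(R) P_m(g_x, g_y), with significance
declared above a fixed ratio threshold (default 10).
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field

import numpy as np

from .genodata import AlleleFrequencyTable, GenotypeTable, encode

RELATIONSHIP_K = {
    "PO": (0.0, 1.0, 0.0),
    "FS": (0.25, 0.5, 0.25),
    "HS": (0.5, 0.5, 0.0),
    "U": (1.0, 0.0, 0.0),
}
LR_SIGNIFICANCE_THRESHOLD = 10.0

_NEG_INF = -np.inf


@dataclass
class ParentageConfig:
    """Settings for parentage likelihoods and confidence simulation."""

    error_rate: float = 0.01
    prop_candidates_sampled: float = 0.5
    confidence_levels: dict = field(
        default_factory=lambda: {"relaxed": 0.80, "strict": 0.95}
    )
    n_sim_offspring: int = 10_000
    seed: int | None = None

    def __post_init__(self):
        if not 0.0 <= self.error_rate < 0.5:
            raise ValueError("error_rate must be in [0, 0.5)")
        if not 0.0 < self.prop_candidates_sampled <= 1.0:
            raise ValueError("prop_candidates_sampled must be in (0, 1]")


@dataclass
class CandidateResult:
    offspring: str
    candidate_mother: str | None
    candidate_father: str | None
    lod: float
    delta: float
    n_mismatches: int
    confidence: str  # strict | relaxed | none
    analysis: str = "pair"  # pair | maternity | paternity


@dataclass(frozen=True)
class RelationshipLR:
    pair: tuple[str, str]
    relationship: str
    likelihood_ratio: float
    significant: bool


# ---------------------------------------------------------------------------
# Per-locus probability kernels (vectorized over leading batch shape)
# ---------------------------------------------------------------------------


def _hwe(o1, o2, f):
    return f[o1] * f[o2] * (1.0 + (o1 != o2))


def _transmit_prob(x, p1, p2):
    """Probability a parent (p1, p2) transmits allele index x."""
    return 0.5 * ((p1 == x).astype(float) + (p2 == x))


def _trans_single(o1, o2, p1, p2, f):
    """P(offspring {o1,o2} | one parent (p1,p2), other allele from HWE)."""
    m1 = _transmit_prob(o1, p1, p2)
    m2 = _transmit_prob(o2, p1, p2)
    return m1 * f[o2] + (o1 != o2) * m2 * f[o1]


def _trans_pair(o1, o2, m1a, m1b, f1a, f1b):
    """P(offspring {o1,o2} | mother (m1a,m1b), father (f1a,f1b))."""
    mm1 = _transmit_prob(o1, m1a, m1b)
    mm2 = _transmit_prob(o2, m1a, m1b)
    ff1 = _transmit_prob(o1, f1a, f1b)
    ff2 = _transmit_prob(o2, f1a, f1b)
    return mm1 * ff2 + (o1 != o2) * mm2 * ff1


def transmission_distribution(freq: np.ndarray, parent=None, parents=None,
                              error_rate: float = 0.0) -> dict:
    """Full offspring-genotype distribution at one locus (for validation).

    Keys are sorted allele-index pairs; values sum to 1 for any parents and
    any error rate.
    """
    k = len(freq)
    out = {}
    for i, j in itertools.combinations_with_replacement(range(k), 2):
        o1, o2 = np.int64(i), np.int64(j)
        hwe = float(_hwe(o1, o2, freq))
        if parents is not None:
            (ma, mb), (fa, fb) = parents
            t = float(_trans_pair(o1, o2, np.int64(ma), np.int64(mb),
                                  np.int64(fa), np.int64(fb)))
        elif parent is not None:
            pa, pb = parent
            t = float(_trans_single(o1, o2, np.int64(pa), np.int64(pb), freq))
        else:
            t = hwe
        out[(i, j)] = (1.0 - error_rate) * t + error_rate * hwe
    return out


def _lod_terms(go, gc, freq_vectors, e, gm=None):
    """Multilocus LOD and mismatch count for offspring vs candidate batches.

    ``go``/``gc`` (and optionally known other parent ``gm``) are (..., L, 2)
    allele-index arrays.  Loci missing in any involved genotype are skipped.
    With a known other parent the null hypothesis keeps that parent and
    replaces the candidate by a random individual.
    """
    L = go.shape[-2]
    lod = np.zeros(np.broadcast_shapes(go.shape[:-2], gc.shape[:-2]))
    mism = np.zeros_like(lod, dtype=int)
    any_locus = np.zeros_like(lod, dtype=bool)
    for l in range(L):
        f = freq_vectors[l]
        o1, o2 = go[..., l, 0], go[..., l, 1]
        c1, c2 = gc[..., l, 0], gc[..., l, 1]
        valid = (o1 >= 0) & (c1 >= 0)
        o1c, o2c = np.clip(o1, 0, None), np.clip(o2, 0, None)
        c1c, c2c = np.clip(c1, 0, None), np.clip(c2, 0, None)
        hwe = _hwe(o1c, o2c, f)
        if gm is None:
            t = _trans_single(o1c, o2c, c1c, c2c, f)
            num = (1.0 - e) * t + e * hwe
            den = hwe
        else:
            m1, m2 = gm[..., l, 0], gm[..., l, 1]
            valid = valid & (m1 >= 0)
            m1c, m2c = np.clip(m1, 0, None), np.clip(m2, 0, None)
            t = _trans_pair(o1c, o2c, m1c, m2c, c1c, c2c)
            t_null = _trans_single(o1c, o2c, m1c, m2c, f)
            num = (1.0 - e) * t + e * hwe
            den = (1.0 - e) * t_null + e * hwe
        with np.errstate(divide="ignore", invalid="ignore"):
            term = np.log(num) - np.log(den)
        lod = lod + np.where(valid, term, 0.0)
        mism = mism + (valid & (t <= 0.0))
        any_locus |= valid
    lod = np.where(any_locus, lod, np.nan)
    return lod, mism


def _encode_genotype_dict(gts: dict, freqs: AlleleFrequencyTable):
    loci = freqs.loci
    vecs = freqs.vectors(loci)
    g = np.full((len(loci), 2), -1, dtype=np.int64)
    for l, loc in enumerate(loci):
        pair = gts.get(loc)
        if pair is None:
            continue
        lut = {int(s): k for k, s in enumerate(vecs[loc][0])}
        g[l, 0], g[l, 1] = lut[pair[0]], lut[pair[1]]
    fv = [vecs[loc][1] for loc in loci]
    return g, fv


def parentage_lod(offspring: dict, candidate: dict, freqs: AlleleFrequencyTable,
                  known_other_parent: dict | None = None,
                  config: ParentageConfig | None = None,
                  offspring_id: str = "offspring",
                  candidate_id: str = "candidate") -> CandidateResult:
    """LOD and mismatch count of one candidate parent for one offspring.

    Genotypes are dicts locus -> (a1, a2).  With ``known_other_parent`` the
    candidate is evaluated as the second parent of a parent pair.
    """
    config = config or ParentageConfig()
    go, fv = _encode_genotype_dict(offspring, freqs)
    gc, _ = _encode_genotype_dict(candidate, freqs)
    gm = None
    if known_other_parent is not None:
        gm, _ = _encode_genotype_dict(known_other_parent, freqs)
    lod, mism = _lod_terms(go, gc, fv, config.error_rate, gm=gm)
    if np.isnan(lod):
        raise ValueError(f"{offspring_id} and {candidate_id} share no typed locus")
    return CandidateResult(
        offspring=offspring_id,
        candidate_mother=None if known_other_parent is None else candidate_id,
        candidate_father=candidate_id,
        lod=float(lod),
        delta=np.nan,
        n_mismatches=int(mism),
        confidence="none",
        analysis="single" if known_other_parent is None else "pair",
    )


# ---------------------------------------------------------------------------
# Confidence simulation
# ---------------------------------------------------------------------------


def _draw_hwe(rng, n, freq_vectors):
    L = len(freq_vectors)
    g = np.empty((n, L, 2), dtype=np.int64)
    for l, f in enumerate(freq_vectors):
        g[:, l, :] = rng.choice(len(f), size=(n, 2), p=f)
    return g


def _mendelian_offspring(rng, gm, gf):
    n, L, _ = gm.shape
    pick_m = rng.integers(2, size=(n, L))
    pick_f = rng.integers(2, size=(n, L))
    a = np.take_along_axis(gm, pick_m[..., None], axis=2)[..., 0]
    b = np.take_along_axis(gf, pick_f[..., None], axis=2)[..., 0]
    return np.stack([np.minimum(a, b), np.maximum(a, b)], axis=-1)


def _apply_error(rng, g, freq_vectors, e):
    if e <= 0:
        return g
    n = g.shape[0]
    hit = rng.random((n, g.shape[1])) < e
    repl = _draw_hwe(rng, n, freq_vectors)
    out = np.where(hit[..., None], repl, g)
    return out


def _delta_threshold(deltas: np.ndarray, correct: np.ndarray, level: float) -> float:
    """Smallest Delta such that assignments with Delta >= it are correct at >= level."""
    order = np.argsort(-deltas)
    frac = np.cumsum(correct[order]) / np.arange(1, len(deltas) + 1)
    ok = np.flatnonzero(frac >= level)
    if len(ok) == 0:
        return np.inf
    return float(deltas[order[ok[-1]]])


def simulate_confidence_thresholds(freqs: AlleleFrequencyTable, n_candidates: int,
                                   config: ParentageConfig | None = None,
                                   mode: str = "single",
                                   known_mother: bool = False) -> dict:
    """Simulated Delta thresholds for the configured confidence levels.

    ``mode='single'``: one-parent analysis over a pool of ``n_candidates``
    (the true parent sampled with ``prop_candidates_sampled``).
    ``mode='pair'``: joint parent-pair analysis; ``n_candidates`` is either a
    scalar (both pools) or a ``(n_mothers, n_fathers)`` tuple.
    ``known_mother`` scores single-parent candidates against a known mother.
    Returns ``{'strict': ..., 'relaxed': ..., 'success_rate': ...}``.
    """
    config = config or ParentageConfig()
    rng = np.random.default_rng(config.seed)
    vecs = freqs.vectors()
    fv = [vecs[loc][1] for loc in freqs.loci]
    n = config.n_sim_offspring
    e = config.error_rate

    gm_true = _draw_hwe(rng, n, fv)
    gf_true = _draw_hwe(rng, n, fv)
    go = _apply_error(rng, _mendelian_offspring(rng, gm_true, gf_true), fv, e)

    if mode == "pair":
        nm, nf = (n_candidates if isinstance(n_candidates, tuple)
                  else (n_candidates, n_candidates))
        moms = np.stack([gm_true] + [_draw_hwe(rng, n, fv) for _ in range(nm - 1)], axis=1)
        dads = np.stack([gf_true] + [_draw_hwe(rng, n, fv) for _ in range(nf - 1)], axis=1)
        m_in = rng.random(n) < config.prop_candidates_sampled
        f_in = rng.random(n) < config.prop_candidates_sampled
        # replace unsampled true parents by unrelated individuals
        moms[:, 0][~m_in] = _draw_hwe(rng, int((~m_in).sum()), fv)
        dads[:, 0][~f_in] = _draw_hwe(rng, int((~f_in).sum()), fv)
        lods = np.empty((n, nm, nf))
        for mi in range(nm):
            lod, _ = _lod_terms(go[:, None], dads, fv, e, gm=moms[:, mi][:, None])
            lods[:, mi, :] = lod
        flat = lods.reshape(n, nm * nf)
        # random tie-break so an uninformative panel assigns at chance level
        jitter = rng.random(flat.shape) * 1e-9
        top = np.argmax(flat + jitter, axis=1)
        part = np.partition(flat, -2, axis=1)
        delta = part[:, -1] - part[:, -2]
        correct = (top == 0) & m_in & f_in
    else:
        pool = np.stack([gf_true] + [_draw_hwe(rng, n, fv) for _ in range(n_candidates - 1)],
                        axis=1)
        f_in = rng.random(n) < config.prop_candidates_sampled
        pool[:, 0][~f_in] = _draw_hwe(rng, int((~f_in).sum()), fv)
        gm = gm_true[:, None] if known_mother else None
        lods, _ = _lod_terms(go[:, None], pool, fv, e, gm=gm)
        top = np.argmax(lods + rng.random(lods.shape) * 1e-9, axis=1)
        if lods.shape[1] >= 2:
            part = np.partition(lods, -2, axis=1)
            delta = part[:, -1] - part[:, -2]
        else:
            delta = lods[:, 0]
        correct = (top == 0) & f_in

    out = {"success_rate": float(np.mean(correct))}
    for name, level in config.confidence_levels.items():
        thr = _delta_threshold(delta, correct, level)
        if not np.isfinite(thr):
            warnings.warn(
                f"{name} confidence level {level} unreachable in simulation",
                stacklevel=2,
            )
        out[name] = thr
    return out


# ---------------------------------------------------------------------------
# Assignment over a genotype table
# ---------------------------------------------------------------------------


def _classify(delta: float, thresholds: dict, tie: bool) -> str:
    if tie or not np.isfinite(delta):
        return "none"
    if delta >= thresholds.get("strict", np.inf):
        return "strict"
    if delta >= thresholds.get("relaxed", np.inf):
        return "relaxed"
    return "none"


def assign_parentage(table: GenotypeTable, offspring_ids, mother_ids, father_ids,
                     freqs: AlleleFrequencyTable,
                     config: ParentageConfig | None = None) -> list[CandidateResult]:
    """Joint parent-pair assignment with single-parent fallback.

    For each offspring the mother x father grid is scored first; if the best
    pair does not reach relaxed confidence, separate maternity and paternity
    analyses are run.  Confidence classes come from Delta thresholds simulated
    under the same candidate-pool sizes.  Exact LOD ties leave the offspring
    unassigned.
    """
    config = config or ParentageConfig()
    mother_ids, father_ids = list(mother_ids), list(father_ids)
    if not mother_ids or not father_ids:
        raise ValueError("candidate mother and father sets must be non-empty")
    enc = encode(table, freqs)
    fv, e = enc.freq_vectors, config.error_rate

    pair_thr = simulate_confidence_thresholds(
        freqs, (len(mother_ids), len(father_ids)), config, mode="pair")
    mat_thr = simulate_confidence_thresholds(freqs, len(mother_ids), config)
    pat_thr = simulate_confidence_thresholds(freqs, len(father_ids), config)

    gm_all = enc.geno[[enc.index_of(i) for i in mother_ids]]
    gf_all = enc.geno[[enc.index_of(i) for i in father_ids]]

    results = []
    for oid in offspring_ids:
        go = enc.geno[enc.index_of(oid)]
        m_keep = [k for k, i in enumerate(mother_ids) if i != oid]
        f_keep = [k for k, i in enumerate(father_ids) if i != oid]
        gm, gf = gm_all[m_keep], gf_all[f_keep]
        lods = np.empty((len(m_keep), len(f_keep)))
        mism = np.empty_like(lods, dtype=int)
        for mi in range(len(m_keep)):
            lod, ms = _lod_terms(go, gf, fv, e, gm=gm[mi])
            lods[mi], mism[mi] = lod, ms
        flat = lods.ravel()
        order = np.argsort(-flat)
        best, second = flat[order[0]], flat[order[1]] if len(flat) > 1 else -np.inf
        delta = best - second
        tie = len(flat) > 1 and np.isclose(best, second, rtol=0, atol=1e-12)
        mi, fi = np.unravel_index(order[0], lods.shape)
        conf = _classify(delta, pair_thr, tie)
        if conf != "none":
            results.append(CandidateResult(
                offspring=oid, candidate_mother=mother_ids[m_keep[mi]],
                candidate_father=father_ids[f_keep[fi]], lod=float(best),
                delta=float(delta), n_mismatches=int(mism[mi, fi]),
                confidence=conf, analysis="pair"))
            continue
        # fall back to separate maternity and paternity analyses
        for pool_ids, keep, gpool, thr, label in (
            (mother_ids, m_keep, gm, mat_thr, "maternity"),
            (father_ids, f_keep, gf, pat_thr, "paternity"),
        ):
            lod1, ms1 = _lod_terms(go, gpool, fv, e)
            order1 = np.argsort(-lod1)
            best1 = lod1[order1[0]]
            second1 = lod1[order1[1]] if len(lod1) > 1 else -np.inf
            d1 = best1 - second1
            tie1 = len(lod1) > 1 and np.isclose(best1, second1, rtol=0, atol=1e-12)
            cid = pool_ids[keep[order1[0]]]
            results.append(CandidateResult(
                offspring=oid,
                candidate_mother=cid if label == "maternity" else None,
                candidate_father=cid if label == "paternity" else None,
                lod=float(best1), delta=float(d1),
                n_mismatches=int(ms1[order1[0]]),
                confidence=_classify(d1, thr, tie1), analysis=label))
    return results


# ---------------------------------------------------------------------------
# Pairwise relationship likelihood ratios
# ---------------------------------------------------------------------------


def relationship_lr_batch(gx: np.ndarray, gy: np.ndarray, freq_vectors,
                          error_rate: float = 0.01) -> dict:
    """log10-free likelihood ratios L(R)/L(U) for batches of genotype pairs.

    Returns ``{relationship: ratio array}``; ``U`` is identically 1.
    """
    L = gx.shape[-2]
    shape = np.broadcast_shapes(gx.shape[:-2], gy.shape[:-2])
    loglik = {rel: np.zeros(shape) for rel in RELATIONSHIP_K}
    for l in range(L):
        f = freq_vectors[l]
        x1, x2 = gx[..., l, 0], gx[..., l, 1]
        y1, y2 = gy[..., l, 0], gy[..., l, 1]
        valid = (x1 >= 0) & (y1 >= 0)
        x1c, x2c = np.clip(x1, 0, None), np.clip(x2, 0, None)
        y1c, y2c = np.clip(y1, 0, None), np.clip(y2, 0, None)
        hx, hy = _hwe(x1c, x2c, f), _hwe(y1c, y2c, f)
        p0 = hx * hy
        p1 = hx * _trans_single(y1c, y2c, x1c, x2c, f)
        p2 = hx * ((x1c == y1c) & (x2c == y2c))
        e = error_rate
        for rel, (k0, k1, k2) in RELATIONSHIP_K.items():
            pm = k0 * p0 + k1 * p1 + k2 * p2
            mixed = (1.0 - e) * pm + e * p0
            with np.errstate(divide="ignore"):
                term = np.log(mixed) - np.log(p0)
            loglik[rel] = loglik[rel] + np.where(valid, term, 0.0)
    return {rel: np.exp(ll) for rel, ll in loglik.items()}


def relationship_likelihood_ratios(x_genotypes: dict, y_genotypes: dict,
                                   freqs: AlleleFrequencyTable,
                                   config: ParentageConfig | None = None,
                                   min_shared_loci: int = 5,
                                   pair: tuple[str, str] = ("x", "y"),
                                   threshold: float = LR_SIGNIFICANCE_THRESHOLD,
                                   ) -> list[RelationshipLR]:
    """PO/FS/HS/U likelihood ratios against unrelated for one pair."""
    config = config or ParentageConfig()
    gx, fv = _encode_genotype_dict(x_genotypes, freqs)
    gy, _ = _encode_genotype_dict(y_genotypes, freqs)
    n_shared = int(np.sum((gx[:, 0] >= 0) & (gy[:, 0] >= 0)))
    if n_shared == 0:
        raise ValueError(f"pair {pair} shares no typed locus")
    if n_shared < min_shared_loci:
        raise ValueError(
            f"pair {pair} shares {n_shared} loci < minimum {min_shared_loci}")
    ratios = relationship_lr_batch(gx, gy, fv, config.error_rate)
    return [
        RelationshipLR(pair=pair, relationship=rel,
                       likelihood_ratio=float(ratios[rel]),
                       significant=bool(ratios[rel] > threshold) and rel != "U")
        for rel in ("PO", "FS", "HS", "U")
    ]
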