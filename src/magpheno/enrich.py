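"""Pre-ranked gene set enrichment analysis (GSEA) with leading edges.

Works on any strictly ordered ranking: MAGs ranked by association
t-statistics with sets of positively / negatively growth-associated MAGs,
or transcripts ranked by sign(fold change) x -log10(p) with metabolic
pathway sets (used at a >= 10-member floor and a q < 0.1 significance
rule). The enrichment score is the classic weighted Kolmogorov-Smirnov
running-sum statistic; the null is built from random same-size member
sets, p-values are sign-stratified permutation estimates, NES divides by
the mean same-sign null magnitude, and q-values are Benjamini-Hochberg
across sets.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from ._rand import substream
from .assoc import bh_adjust
from .errors import InvalidInputError, InvalidParameterError

MIN_SET_SIZE = 10


@dataclass
class EnrichmentResult:
    set_name: str
    size: int
    es: float
    nes: float
    p: float
    q: float
    leading_edge: list[str] = field(default_factory=list)
    skipped: str | None = None


def _validate_ranking(ranked: pd.Series) -> pd.Series:
    if ranked.index.has_duplicates:
        raise InvalidInputError("ranked list contains duplicate features")
    values = ranked.to_numpy(dtype=float)
    if np.any(np.diff(values) > 0):
        raise InvalidInputError("ranking metric must be sorted in descending order")
    return ranked


def enrichment_score(
    ranked: pd.Series,
    members: Iterable[str],
    weight: float = 1.0,
) -> tuple[float, int, np.ndarray]:
    """Weighted KS enrichment score of a member set in a ranked list.

    Hit steps are proportional to |metric|^weight (equal steps when every
    member metric is zero); miss steps are uniform. Returns
    (ES, peak index, running sum); the ES is the running-sum value of
    largest magnitude. A set equal to the whole universe (no misses) is
    degenerate and must be skipped by the caller.
    """
    ranked = _validate_ranking(ranked)
    hit = ranked.index.isin(set(members))
    n = len(ranked)
    n_hit = int(hit.sum())
    if n_hit == 0:
        raise InvalidInputError("set has no members in the ranked universe")
    if n_hit == n:
        raise InvalidInputError("set spans the entire universe (no misses defined)")
    metric = np.abs(ranked.to_numpy(dtype=float)) ** weight
    es, peak, running = _es_from_mask(metric, hit)
    return es, peak, running


def _es_from_mask(metric_pow: np.ndarray, hit: np.ndarray) -> tuple[float, int, np.ndarray]:
    n = len(metric_pow)
    n_hit = int(hit.sum())
    hit_weight = np.where(hit, metric_pow, 0.0)
    total = hit_weight.sum()
    if total <= 0:
        hit_weight = hit.astype(float)
        total = float(n_hit)
    steps = np.where(hit, hit_weight / total, -1.0 / (n - n_hit))
    running = np.cumsum(steps)
    peak = int(np.argmax(np.abs(running)))
    return float(running[peak]), peak, running


def leading_edge(
    ranked: pd.Series,
    members: Iterable[str],
    es: float,
    peak_index: int,
) -> list[str]:
    """Set members responsible for the enrichment signal.

    Positively enriched sets: members ranked at or before the running-sum
    maximum; negatively enriched: members at or after the minimum. Always a
    subset of the member set, in rank order.
    """
    members = set(members)
    ids = list(ranked.index)
    if es >= 0:
        sel = [f for f in ids[: peak_index + 1] if f in members]
    else:
        sel = [f for f in ids[peak_index:] if f in members]
    return sel


def gsea_preranked(
    ranked: pd.Series,
    sets: Mapping[str, Iterable[str]],
    n_perm: int = 10_000,
    seed: int = 0,
    min_size: int = MIN_SET_SIZE,
    weight: float = 1.0,
) -> pd.DataFrame:
    """Pre-ranked GSEA over a family of feature sets.

    The permutation null draws random same-size member sets from the ranked
    universe (shared across sets of equal size). p-values are
    sign-stratified:

        p = (1 + #{null ES >= ES}) / (1 + #{null ES >= 0})   for ES >= 0

    and symmetrically for negative scores; NES = ES / mean |same-sign null
    ES|. q-values are BH-adjusted across scored sets. Sets whose
    intersection with the universe is below ``min_size`` (or equal to the
    whole universe) are reported as skipped. Fixed seed gives identical
    results.
    """
    if n_perm < 100:
        raise InvalidParameterError("n_perm must be at least 100")
    ranked = _validate_ranking(ranked)
    rng = substream(seed, "gsea.permutations")
    universe = np.array(ranked.index)
    results: list[EnrichmentResult] = []
    null_cache: dict[int, np.ndarray] = {}
    scored: list[EnrichmentResult] = []
    for name in sorted(sets):
        members = set(sets[name]) & set(universe)
        size = len(members)
        if size < min_size:
            results.append(EnrichmentResult(name, size, np.nan, np.nan, np.nan, np.nan,
                                            skipped=f"fewer than {min_size} members in universe"))
            continue
        if size == len(universe):
            results.append(EnrichmentResult(name, size, np.nan, np.nan, np.nan, np.nan,
                                            skipped="set spans entire universe"))
            continue
        es, peak, _ = enrichment_score(ranked, members, weight=weight)
        if size not in null_cache:
            metric_pow = np.abs(ranked.to_numpy(dtype=float)) ** weight
            null_es = np.empty(n_perm)
            for b in range(n_perm):
                mask = np.zeros(len(universe), dtype=bool)
                mask[rng.choice(len(universe), size=size, replace=False)] = True
                null_es[b], _, _ = _es_from_mask(metric_pow, mask)
            null_cache[size] = null_es
        null_es = null_cache[size]
        if es >= 0:
            same = null_es[null_es >= 0]
            p = (1.0 + np.sum(null_es >= es)) / (1.0 + len(same))
            denom = np.mean(same) if len(same) else np.nan
        else:
            same = null_es[null_es < 0]
            p = (1.0 + np.sum(null_es <= es)) / (1.0 + len(same))
            denom = -np.mean(same) if len(same) else np.nan
        nes = es / denom if denom and np.isfinite(denom) and denom > 0 else np.nan
        le = leading_edge(ranked, members, es, peak)
        res = EnrichmentResult(name, size, es, nes, min(p, 1.0), np.nan, leading_edge=le)
        results.append(res)
        scored.append(res)
    if scored:
        qs = bh_adjust([r.p for r in scored])
        for r, q in zip(scored, qs):
            r.q = float(q)
    frame = pd.DataFrame(
        [
            {
                "set": r.set_name, "size": r.size, "ES": r.es, "NES": r.nes,
                "p": r.p, "q": r.q,
                "leading_edge": ",".join(r.leading_edge),
                "skipped": r.skipped,
            }
            for r in results
        ]
    ).set_index("set")
    return frame


def mag_association_sets(assoc_table: pd.DataFrame, q_cutoff: float = 0.05) -> dict[str, list[str]]:
    """Significantly positively / negatively WLZ-associated MAG sets.

    Built from a per-MAG association table with 'beta1' and 'q' columns, at
    the stated q < 0.05 rule.
    """
    sig = assoc_table[assoc_table["q"] < q_cutoff]
    return {
        "wlz_positive": sorted(sig.index[sig["beta1"] > 0]),
        "wlz_negative": sorted(sig.index[sig["beta1"] < 0]),
    }


def pathway_gene_sets(
    gene_roles: Mapping[str, str | None],
    pathway_definitions: Mapping[str, list[set[str]]],
    universe: Sequence[str] | None = None,
) -> dict[str, list[str]]:
    """Transcript sets per metabolic pathway from gene role annotations."""
    role_to_pathways: dict[str, set[str]] = {}
    for pathway, variants in pathway_definitions.items():
        for v in variants:
            for role in v:
                role_to_pathways.setdefault(role, set()).add(pathway)
    sets: dict[str, set[str]] = {p: set() for p in pathway_definitions}
    allowed = set(universe) if universe is not None else None
    for gene, role in gene_roles.items():
        if role is None or (allowed is not None and gene not in allowed):
            continue
        for pathway in role_to_pathways.get(role, ()):
            sets[pathway].add(gene)
    return {p: sorted(m) for p, m in sets.items() if m}
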