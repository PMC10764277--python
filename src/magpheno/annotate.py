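"""Domain-aware functional annotation of MAG proteins from alignment hits.

The workflow, applied per query protein (whole genes and gene fragments
alike):

1. keep the top ``k`` hits by bitscore;
2. cluster alignment start and end coordinates (density-based 1-D
   clustering) and use cluster centres as candidate domain boundaries,
   splitting multi-domain queries and attributing hits to the domain they
   overlap most; domains shorter than 35 residues are discarded;
3. per domain, fit a Gaussian kernel density to the hit identity
   distribution and remove hits below the highest-identity local minimum
   (keep everything when the distribution is unimodal);
4. annotate by plurality vote among surviving hits; high-identity hits to
   the reference outgroup vote against annotation (role withheld when the
   outgroup wins), and vote ties are broken by summed bitscore.

Coordinates are 1-based inclusive protein-residue positions throughout.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import signal, stats
from sklearn.cluster import DBSCAN

from .errors import InvalidInputError

OUTGROUP_LABEL = "__outgroup__"

MIN_DOMAIN_LEN = 35


@dataclass
class DomainCall:
    """A domain interval of one query with the hits attributed to it."""

    query_id: str
    start: int
    end: int
    member_hits: pd.DataFrame = field(repr=False)

    @property
    def length(self) -> int:
        return self.end - self.start + 1


@dataclass
class FunctionalAnnotation:
    query_id: str
    start: int
    end: int
    role: str | None
    votes: int = 0
    n_hits: int = 0
    summed_bitscore: float = 0.0
    threshold: float = 0.0


# ---------------------------------------------------------------------------

def select_top_hits(hits: pd.DataFrame, k: int = 50) -> pd.DataFrame:
    """Top ``k`` hits of one query by descending bitscore.

    Ties at the boundary are broken deterministically by subject id.
    """
    if hits.empty:
        return hits
    ordered = hits.sort_values(
        ["bitscore", "sseqid"], ascending=[False, True], kind="mergesort"
    )
    return ordered.head(k)


def _cluster_centres_1d(values: np.ndarray, eps: float, min_cluster: int) -> list[int]:
    """Rounded means of DBSCAN clusters of 1-D coordinates.

    Falls back to a single centre (the rounded mean of everything) when no
    cluster reaches ``min_cluster`` members, so degenerate input still
    yields one domain.
    """
    values = np.asarray(values, dtype=float)
    labels = DBSCAN(eps=eps, min_samples=min_cluster).fit_predict(values.reshape(-1, 1))
    centres = [
        int(round(values[labels == lab].mean())) for lab in sorted(set(labels)) if lab != -1
    ]
    if not centres:
        centres = [int(round(values.mean()))]
    return sorted(set(centres))


def split_query_into_domains(
    hits: pd.DataFrame,
    cluster_eps: float = 10.0,
    min_cluster: int = 2,
    min_domain_len: int = MIN_DOMAIN_LEN,
) -> list[DomainCall]:
    """Split a query into domains from the clustered hit coordinates.

    Start coordinates and end coordinates are clustered separately; cluster
    centres are paired (each start centre with the nearest unused end centre
    to its right) to form candidate intervals. Hits are attributed to the
    interval they overlap most; intervals shorter than ``min_domain_len``
    are discarded.
    """
    if hits.empty:
        return []
    query_ids = hits["qseqid"].unique()
    if len(query_ids) != 1:
        raise InvalidInputError("split_query_into_domains expects hits of a single query")
    qid = query_ids[0]
    starts = _cluster_centres_1d(hits["qstart"].to_numpy(), cluster_eps, min_cluster)
    ends = _cluster_centres_1d(hits["qend"].to_numpy(), cluster_eps, min_cluster)

    intervals: list[tuple[int, int]] = []
    used: set[int] = set()
    for s in starts:
        candidates = [e for e in ends if e not in used and e >= s]
        if not candidates:
            continue
        e = candidates[0]
        used.add(e)
        intervals.append((s, e))
    if not intervals:
        intervals = [(min(starts), max(ends))] if max(ends) >= min(starts) else []
    intervals = [(s, e) for s, e in intervals if e - s + 1 >= min_domain_len]
    if not intervals:
        return []

    # attribute each hit to the interval it overlaps most (ties: leftmost)
    assignment = []
    for _, hit in hits.iterrows():
        overlaps = [
            max(0, min(hit["qend"], e) - max(hit["qstart"], s) + 1) for s, e in intervals
        ]
        assignment.append(int(np.argmax(overlaps)))
    assignment = np.array(assignment)
    domains = []
    for i, (s, e) in enumerate(intervals):
        members = hits.iloc[np.flatnonzero(assignment == i)]
        domains.append(DomainCall(query_id=qid, start=s, end=e, member_hits=members))
    return domains


def identity_threshold(
    identities: Sequence[float],
    grid_points: int = 512,
) -> float:
    """Identity cutoff separating confident from spurious hits.

    A Gaussian KDE (Silverman bandwidth) is fitted to the identity sample
    on an even grid over [0, 100]; the local density minimum at the highest
    identity is returned. Unimodal distributions have no interior minimum
    and yield 0 (keep all hits).
    """
    arr = np.asarray(list(identities), dtype=float)
    if arr.size == 0:
        raise InvalidInputError("identity_threshold requires at least one identity value")
    if arr.size < 3 or np.ptp(arr) < 1e-9:
        return 0.0
    try:
        kde = stats.gaussian_kde(arr, bw_method="silverman")
    except np.linalg.LinAlgError:
        return 0.0
    grid = np.linspace(0.0, 100.0, grid_points)
    density = kde(grid)
    minima = signal.argrelextrema(density, np.less)[0]
    # only minima interior to the sample range separate modes
    minima = [i for i in minima if arr.min() < grid[i] < arr.max()]
    if not minima:
        return 0.0
    return float(grid[max(minima)])


def annotate_domain(domain: DomainCall, threshold: float) -> FunctionalAnnotation:
    """Plurality-vote annotation of one domain after identity filtering.

    Hits with identity below ``threshold`` are removed. The plurality role
    among survivors is applied; if the plurality is the outgroup the
    annotation is withheld. Ties are broken by larger summed bitscore, and
    a residual tie abstains.
    """
    hits = domain.member_hits
    surviving = hits[hits["pident"] >= threshold]
    base = FunctionalAnnotation(
        query_id=domain.query_id,
        start=domain.start,
        end=domain.end,
        role=None,
        threshold=threshold,
    )
    if surviving.empty:
        return base
    labels = surviving["role"].fillna(OUTGROUP_LABEL)
    votes = labels.value_counts()
    top = votes.max()
    leaders = sorted(votes.index[votes == top])
    if len(leaders) > 1:
        scores = {
            lab: surviving.loc[labels == lab, "bitscore"].sum() for lab in leaders
        }
        best = max(scores.values())
        best_labels = sorted(lab for lab, s in scores.items() if s == best)
        if len(best_labels) > 1:
            return base  # irresolvable tie: abstain
        winner = best_labels[0]
    else:
        winner = leaders[0]
    if winner == OUTGROUP_LABEL:
        # high-identity outgroup hits vote against applying any annotation
        return FunctionalAnnotation(
            query_id=domain.query_id, start=domain.start, end=domain.end, role=None,
            votes=int(votes[winner]), n_hits=len(surviving),
            summed_bitscore=float(surviving["bitscore"].sum()), threshold=threshold,
        )
    return FunctionalAnnotation(
        query_id=domain.query_id,
        start=domain.start,
        end=domain.end,
        role=str(winner),
        votes=int(votes[winner]),
        n_hits=len(surviving),
        summed_bitscore=float(surviving.loc[labels == winner, "bitscore"].sum()),
        threshold=threshold,
    )


def attach_roles(hits: pd.DataFrame, refmap: pd.DataFrame | Mapping[str, str | None]) -> pd.DataFrame:
    """Join the subject -> role sidecar onto a hits table.

    Outgroup subjects get role ``NaN``; the ``outgroup`` flag column (0/1)
    is honoured when present.
    """
    hits = hits.copy()
    if isinstance(refmap, pd.DataFrame):
        mapping = refmap.set_index("subject_id")["role"]
        if "outgroup" in refmap.columns:
            og = refmap.set_index("subject_id")["outgroup"].astype(bool)
            mapping = mapping.where(~og, other=None)
    else:
        mapping = pd.Series(dict(refmap))
    hits["role"] = hits["sseqid"].map(mapping)
    return hits


def annotate_genome(
    proteins: Iterable[str] | Mapping[str, str],
    hits_table: pd.DataFrame,
    refmap: pd.DataFrame | Mapping[str, str | None],
    top_k: int = 50,
    cluster_eps: float = 10.0,
    min_cluster: int = 2,
    min_domain_len: int = MIN_DOMAIN_LEN,
) -> list[FunctionalAnnotation]:
    """Annotate every query protein (or fragment) of a genome.

    ``proteins`` lists the query ids (a mapping id -> sequence also works);
    queries with no hits are emitted with role ``None``. One annotation is
    produced per (query, domain). Output order is deterministic (sorted by
    query id, then domain start) regardless of hit order.
    """
    ids = sorted(proteins.keys() if isinstance(proteins, Mapping) else proteins)
    if hits_table.empty:
        return [FunctionalAnnotation(q, 0, 0, None) for q in ids]
    hits_table = attach_roles(hits_table, refmap)
    grouped = dict(tuple(hits_table.groupby("qseqid", sort=True)))
    out: list[FunctionalAnnotation] = []
    for qid in ids:
        hits = grouped.get(qid)
        if hits is None or hits.empty:
            out.append(FunctionalAnnotation(qid, 0, 0, None))
            continue
        top = select_top_hits(hits, k=top_k)
        domains = split_query_into_domains(
            top, cluster_eps=cluster_eps, min_cluster=min_cluster,
            min_domain_len=min_domain_len,
        )
        if not domains:
            out.append(FunctionalAnnotation(qid, 0, 0, None))
            continue
        for dom in sorted(domains, key=lambda d: d.start):
            if dom.member_hits.empty:
                out.append(FunctionalAnnotation(qid, dom.start, dom.end, None))
                continue
            thr = identity_threshold(dom.member_hits["pident"].to_numpy())
            out.append(annotate_domain(dom, thr))
    return out


def annotations_to_frame(annotations: Iterable[FunctionalAnnotation]) -> pd.DataFrame:
    """Tidy table of annotations (one row per query domain)."""
    return pd.DataFrame(
        [
            {
                "query_id": a.query_id,
                "domain_start": a.start,
                "domain_end": a.end,
                "role": a.role,
                "votes": a.votes,
                "n_hits": a.n_hits,
            }
            for a in annotations
        ]
    )


def role_presence_from_annotations(
    annotations_by_genome: Mapping[str, Iterable[FunctionalAnnotation]],
    roles: Sequence[str] | None = None,
) -> pd.DataFrame:
    """Genomes x roles presence/absence matrix from annotation calls."""
    rows = {}
    seen: set[str] = set()
    for genome in sorted(annotations_by_genome):
        present = {a.role for a in annotations_by_genome[genome] if a.role is not None}
        rows[genome] = present
        seen |= present
    columns = sorted(roles) if roles is not None else sorted(seen)
    data = pd.DataFrame(
        [[int(r in rows[g]) for r in columns] for g in sorted(rows)],
        index=sorted(rows),
        columns=columns,
    )
    return data
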