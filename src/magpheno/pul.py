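"""Polysaccharide utilization locus (PUL) detection and conservation analysis.

PULs are syntenic Bacteroidota gene clusters built around an adjacent
SusC/SusD transporter pair plus carbohydrate-active enzymes (CAZymes) and
regulators. This module detects PULs from role-annotated ORFs, classifies the
conservation of a reference PUL in query genomes (conserved / structurally
distinct / absent), encodes per-genome conservation profiles on the
{1, 0.5, 0} scale, and relates profile distance to per-genome growth
(WLZ) association coefficients.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from Bio import Align
from scipy import stats

from .errors import InsufficientDataError, InvalidInputError, InvalidParameterError

ROLE_SUSC = "SusC"
ROLE_SUSD = "SusD"
ROLE_REGULATOR = "regulator"
CAZYME_PREFIX = "CAZyme"

CONSERVED = "conserved"
STRUCTURALLY_DISTINCT = "structurally_distinct"
ABSENT = "absent"

#: encoding of conservation categories used for profile vectors
CATEGORY_CODES = {CONSERVED: 1.0, STRUCTURALLY_DISTINCT: 0.5, ABSENT: 0.0}


def is_cazyme(role_class: str) -> bool:
    return role_class.startswith(CAZYME_PREFIX)


def is_functional(role_class: str) -> bool:
    """SusC/SusD, CAZymes and regulators extend a PUL; 'other' ORFs do not."""
    return role_class in (ROLE_SUSC, ROLE_SUSD, ROLE_REGULATOR) or is_cazyme(role_class)


@dataclass
class ORFRecord:
    """A single open reading frame with its protein product and role class."""

    genome: str
    contig: str
    position: int  # ordinal position on the contig (1-based, unique per contig)
    strand: str
    protein: str
    role_class: str  # SusC | SusD | CAZyme:<family> | regulator | other


@dataclass
class PUL:
    pul_id: str
    genome: str
    orfs: list[ORFRecord]
    substrate: str | None = None
    provenance: dict = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.orfs)


@dataclass
class ConservationCall:
    ref_pul_id: str
    query_genome: str
    category: str
    evidence: dict = field(default_factory=dict)


@dataclass
class ConservationProfile:
    """Per-genome vector of conservation codes over a reference PUL repertoire."""

    genome: str
    codes: pd.Series  # index = reference PUL ids, values in {1, 0.5, 0}

    def distance_to(self, other: "ConservationProfile") -> float:
        a = self.codes
        b = other.codes.reindex(a.index)
        if b.isna().any():
            raise InvalidInputError("profiles cover different reference PULs")
        return float(np.linalg.norm(a.to_numpy() - b.to_numpy()))


# ---------------------------------------------------------------------------
# detection
# ---------------------------------------------------------------------------

def detect_puls(orfs: Iterable[ORFRecord], max_gap: int = 2) -> list[PUL]:
    """Detect PULs by seeding at adjacent SusC/SusD pairs and extending.

    Extension proceeds in both directions across CAZymes, regulators and
    further Sus proteins, tolerating at most ``max_gap`` intervening
    non-functional ('other' or missing) ORFs. Overlapping seed extensions on
    the same contig are merged into a single locus.
    """
    puls: list[PUL] = []
    by_contig: dict[tuple[str, str], list[ORFRecord]] = {}
    for orf in orfs:
        by_contig.setdefault((orf.genome, orf.contig), []).append(orf)
    for (genome, contig), lst in sorted(by_contig.items()):
        lst = sorted(lst, key=lambda o: o.position)
        positions = [o.position for o in lst]
        if len(set(positions)) != len(positions):
            raise InvalidInputError(f"duplicate ordinal positions on contig {contig}")
        seeds = [
            i
            for i in range(len(lst) - 1)
            if {lst[i].role_class, lst[i + 1].role_class} == {ROLE_SUSC, ROLE_SUSD}
            and lst[i + 1].position - lst[i].position == 1
        ]
        intervals = [_extend_seed(lst, i, i + 1, max_gap) for i in seeds]
        for lo, hi in _merge_intervals(intervals):
            members = lst[lo : hi + 1]
            pul_id = f"{genome}:{contig}:{members[0].position}-{members[-1].position}"
            puls.append(PUL(pul_id=pul_id, genome=genome, orfs=members))
    return puls


def _extend_seed(lst: list[ORFRecord], a: int, b: int, max_gap: int) -> tuple[int, int]:
    # rightwards
    hi, gap, k = b, 0, b
    while k + 1 < len(lst):
        hole = lst[k + 1].position - lst[k].position - 1  # dropped genes count as gaps
        if is_functional(lst[k + 1].role_class):
            if gap + hole <= max_gap:
                hi, gap = k + 1, 0
            else:
                break
        else:
            gap += hole + 1
            if gap > max_gap:
                break
        k += 1
    # leftwards
    lo, gap, k = a, 0, a
    while k - 1 >= 0:
        hole = lst[k].position - lst[k - 1].position - 1
        if is_functional(lst[k - 1].role_class):
            if gap + hole <= max_gap:
                lo, gap = k - 1, 0
            else:
                break
        else:
            gap += hole + 1
            if gap > max_gap:
                break
        k -= 1
    return lo, hi


def _merge_intervals(intervals: list[tuple[int, int]]) -> list[tuple[int, int]]:
    merged: list[tuple[int, int]] = []
    for lo, hi in sorted(intervals):
        if merged and lo <= merged[-1][1] + 1:
            merged[-1] = (merged[-1][0], max(merged[-1][1], hi))
        else:
            merged.append((lo, hi))
    return merged


# ---------------------------------------------------------------------------
# pairwise protein identity
# ---------------------------------------------------------------------------

def _make_aligner(infix: bool) -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score = 1.0
    aligner.mismatch_score = 0.0
    aligner.open_gap_score = -0.5
    aligner.extend_gap_score = -0.1
    if infix:
        # free end gaps on the target so a fragment may sit anywhere inside it
        if hasattr(aligner, "open_end_insertion_score"):
            aligner.open_end_insertion_score = 0.0
            aligner.extend_end_insertion_score = 0.0
        else:  # older Biopython naming
            aligner.target_end_open_gap_score = 0.0
            aligner.target_end_extend_gap_score = 0.0
    return aligner


_GLOBAL_ALIGNER = _make_aligner(infix=False)
_INFIX_ALIGNER = _make_aligner(infix=True)


def percent_identity(a: str, b: str) -> float:
    """Global-alignment identity: matches / alignment length, in [0, 1]."""
    if not a or not b:
        return 0.0
    if len(a) == len(b):
        # fast path: ungapped columns; the aligner can only do better, but for
        # same-family sequences (substitutions only) this is the intended value
        direct = sum(x == y for x, y in zip(a, b)) / len(a)
        if direct >= 0.8:
            return direct
    aln = _GLOBAL_ALIGNER.align(a, b)[0]
    return aln.counts().identities / aln.length


def fragment_identity(reference: str, fragment: str) -> float:
    """Identity of a candidate fragment over its own length, aligned inside
    the reference (free end gaps on the reference)."""
    if not reference or not fragment:
        return 0.0
    aln = _INFIX_ALIGNER.align(reference, fragment)[0]
    return aln.counts().identities / max(len(fragment), 1)


def _kmer_set(seq: str, k: int = 8) -> set[str]:
    return {seq[i : i + k] for i in range(len(seq) - k + 1)}


# ---------------------------------------------------------------------------
# conservation classification
# ---------------------------------------------------------------------------

def classify_conservation(
    ref_pul: PUL,
    query_orfs: Sequence[ORFRecord],
    min_identity: float = 0.9,
    frag_coverage: float = 0.8,
) -> ConservationCall:
    """Classify how well ``ref_pul`` is conserved in a query genome.

    conserved: every reference ORF has a >``min_identity`` full-length match,
    the matches form one contiguous block in identical (or strand-flipped,
    i.e. fully reversed) order, with no extra ORFs inserted.

    structurally_distinct: a homologous block exists but at least one ORF is
    missing or fragmented, extra ORFs are inserted, or the order differs.

    absent: no credible homologous block.
    """
    query_orfs = list(query_orfs)
    if not (0 < min_identity < 1):
        raise InvalidParameterError("min_identity must lie in (0, 1)")
    n_ref = len(ref_pul.orfs)
    if not query_orfs:
        return ConservationCall(ref_pul.pul_id, "<empty>", ABSENT, {"reason": "empty genome"})
    genome = query_orfs[0].genome

    q_kmers = [_kmer_set(q.protein) for q in query_orfs]
    status: list[str] = []
    best_match: list[int | None] = []
    identities: list[float] = []
    frag_hits: dict[int, list[int]] = {}
    for i, r in enumerate(ref_pul.orfs):
        r_kmers = _kmer_set(r.protein)
        best_ident, best_j = 0.0, None
        frag_cov = 0.0
        for j, q in enumerate(query_orfs):
            if not (r_kmers & q_kmers[j]):
                continue  # cheap screen: unrelated proteins share no 8-mers
            lr, lq = len(r.protein), len(q.protein)
            if lq >= 0.8 * lr:
                ident = percent_identity(r.protein, q.protein)
                if ident > best_ident:
                    best_ident, best_j = ident, j
            elif lq >= 0.15 * lr:
                if fragment_identity(r.protein, q.protein) > min_identity:
                    frag_hits.setdefault(i, []).append(j)
                    frag_cov += lq / lr
        if best_ident > min_identity:
            status.append("full")
            best_match.append(best_j)
        elif len(frag_hits.get(i, [])) >= 2 and frag_cov >= frag_coverage:
            status.append("fragmented")
            best_match.append(None)
        else:
            status.append("missing")
            best_match.append(None)
        identities.append(round(best_ident, 4))

    evidence: dict = {
        "orf_status": status,
        "orf_identities": identities,
        "defects": [],
    }
    matched = [j for j in best_match if j is not None]
    n_full = status.count("full")

    if n_full == n_ref:
        order_ok = _identical_organization(matched)
        extras = _count_insertions(query_orfs, matched)
        if order_ok and extras == 0:
            return ConservationCall(ref_pul.pul_id, genome, CONSERVED, evidence)
        if not order_ok:
            evidence["defects"].append("order differs")
        if extras:
            evidence["defects"].append(f"{extras} extra ORF(s) inserted")
        return ConservationCall(ref_pul.pul_id, genome, STRUCTURALLY_DISTINCT, evidence)

    for i, st in enumerate(status):
        if st != "full":
            evidence["defects"].append(f"{ref_pul.orfs[i].role_class} {st}")
    sus_found = any(
        st == "full" and ref_pul.orfs[i].role_class in (ROLE_SUSC, ROLE_SUSD)
        for i, st in enumerate(status)
    )
    caz_found = any(
        st in ("full", "fragmented") and is_cazyme(ref_pul.orfs[i].role_class)
        for i, st in enumerate(status)
    )
    block_exists = (2 * n_full >= n_ref) or (sus_found and caz_found)
    if block_exists:
        return ConservationCall(ref_pul.pul_id, genome, STRUCTURALLY_DISTINCT, evidence)
    return ConservationCall(ref_pul.pul_id, genome, ABSENT, evidence)


def _identical_organization(matched: list[int]) -> bool:
    """Query indices must be strictly monotone (either direction; a strand
    flip reverses the whole block and still counts as identical order)."""
    if len(matched) <= 1:
        return True
    diffs = np.diff(matched)
    return bool(np.all(diffs > 0) or np.all(diffs < 0))


def _count_insertions(query_orfs: Sequence[ORFRecord], matched: list[int]) -> int:
    """Number of unmatched query ORFs lying inside the matched block span."""
    if not matched:
        return 0
    contigs = {query_orfs[j].contig for j in matched}
    if len(contigs) > 1:
        return 0  # split across contigs: handled as an order defect instead
    lo, hi = min(matched), max(matched)
    return sum(1 for j in range(lo, hi + 1) if j not in matched)


# ---------------------------------------------------------------------------
# profile encoding and correlation
# ---------------------------------------------------------------------------

def encode_profile(
    calls: Iterable[ConservationCall],
    reference_pul_ids: Sequence[str] | None = None,
) -> ConservationProfile:
    """Encode one genome's conservation calls as a {1, 0.5, 0} vector.

    ``reference_pul_ids`` fixes the vector order; by default the call order
    is used. A missing or duplicated call for a reference PUL is an error.
    """
    calls = list(calls)
    if not calls:
        raise InvalidInputError("no conservation calls supplied")
    genomes = {c.query_genome for c in calls}
    if len(genomes) != 1:
        raise InvalidInputError("encode_profile expects calls for a single genome")
    by_pul = {}
    for c in calls:
        if c.ref_pul_id in by_pul:
            raise InvalidInputError(f"duplicate call for reference PUL {c.ref_pul_id}")
        by_pul[c.ref_pul_id] = c
    order = list(reference_pul_ids) if reference_pul_ids is not None else list(by_pul)
    missing = [p for p in order if p not in by_pul]
    if missing:
        raise InvalidInputError(f"missing calls for reference PULs: {missing}")
    codes = pd.Series(
        [CATEGORY_CODES[by_pul[p].category] for p in order], index=order, dtype=float
    )
    return ConservationProfile(genome=genomes.pop(), codes=codes)


def correlate_profiles_with_association(
    profiles: Mapping[str, ConservationProfile],
    beta1_per_genome: Mapping[str, float],
    reference_genome: str | None = None,
) -> tuple[float, float]:
    """Pearson correlation between PUL-profile distance and WLZ association.

    Distances are Euclidean, taken from each genome's profile to the
    reference genome's profile (all-conserved if ``reference_genome`` is not
    among the profiles). Pairing is by genome id; genomes lacking either a
    profile or a coefficient are dropped.
    """
    genomes = sorted(set(profiles) & set(beta1_per_genome))
    if reference_genome is not None and reference_genome in profiles:
        ref_profile = profiles[reference_genome]
    else:
        any_profile = next(iter(profiles.values()))
        ref_profile = ConservationProfile(
            genome=reference_genome or "<reference>",
            codes=pd.Series(1.0, index=any_profile.codes.index),
        )
    dist = np.array([profiles[g].distance_to(ref_profile) for g in genomes])
    beta = np.array([float(beta1_per_genome[g]) for g in genomes])
    if len(genomes) < 3:
        raise InsufficientDataError(
            f"need >=3 genomes with both a profile and a coefficient, got {len(genomes)}"
        )
    if np.ptp(dist) == 0 or np.ptp(beta) == 0:
        raise InvalidInputError("zero variance in distances or coefficients")
    r, p = stats.pearsonr(dist, beta)
    return float(r), float(p)


def conservation_matrix(profiles: Mapping[str, ConservationProfile]) -> pd.DataFrame:
    """Genomes x reference-PULs matrix of conservation codes."""
    return pd.DataFrame({g: p.codes for g, p in sorted(profiles.items())}).T
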