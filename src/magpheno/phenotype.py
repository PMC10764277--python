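"""Three-strategy binary metabolic phenotype prediction with consensus calls.

A phenotype is a binary statement ("this genome encodes a complete variant
of pathway P"). Three predictors vote per (genome, phenotype):

* pathway rules — one decision tree per phenotype trained on reference
  role presence/absence, mirroring curator pathway logic;
* machine learning — a per-phenotype random forest with grid-searched
  hyperparameters and optional leave-one-out evaluation;
* neighbour groups — MinHash genome distances group MAGs with close
  reference genomes (distance <= 0.1, ANI >= 90%); within a group the
  phenotype of the reference with the closest gene pattern (Hamming
  distance over the pathway's required roles) is adopted.

Votes are reconciled into a consensus value with a high/medium/low
confidence grade. Because genome incompleteness destroys genes but never
invents them, a neighbour-group vote of 1 overrides concordant 0 votes from
the other two methods (false-negative rescue); in an irreconcilable
disagreement the machine-learning vote wins.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier
from sklearn.tree import DecisionTreeClassifier

from .errors import (
    InvalidInputError,
    InvalidParameterError,
    UndefinedCallError,
)

ABSTAIN = "abstain"

DEFAULT_RF_GRID = ({"max_features": "sqrt", "min_samples_leaf": 1},
                   {"max_features": "sqrt", "min_samples_leaf": 3},
                   {"max_features": 0.333, "min_samples_leaf": 1},
                   {"max_features": 0.333, "min_samples_leaf": 3})


@dataclass
class PhenotypeCall:
    genome: str
    phenotype: str
    rule_vote: object
    ml_vote: object
    ng_vote: object
    consensus: int
    confidence: str


# ---------------------------------------------------------------------------
# pathway rules
# ---------------------------------------------------------------------------

@dataclass
class PathwayRule:
    phenotype: str
    features: list[str]
    tree: DecisionTreeClassifier | None
    constant: int | None = None  # set when the phenotype is constant in training
    training_accuracy: float = 1.0

    def predict(self, roles: pd.DataFrame) -> np.ndarray:
        if self.constant is not None:
            return np.full(len(roles), self.constant, dtype=int)
        X = roles.reindex(columns=self.features, fill_value=0).to_numpy()
        return self.tree.predict(X).astype(int)


def train_pathway_rules(
    ref_roles: pd.DataFrame,
    ref_bpm: pd.DataFrame,
    pathway_definitions: Mapping[str, list[set[str]]] | None = None,
) -> dict[str, PathwayRule]:
    """One decision tree per phenotype over role-presence predictors.

    When pathway definitions are available, predictors are restricted to
    that pathway's required roles (the roles curators deem load-bearing);
    otherwise all roles are used. Constant phenotypes yield a flagged
    always-0/always-1 rule.
    """
    ref_roles = ref_roles.loc[ref_bpm.index]
    rules: dict[str, PathwayRule] = {}
    for phenotype in ref_bpm.columns:
        y = ref_bpm[phenotype].to_numpy().astype(int)
        if pathway_definitions and phenotype in pathway_definitions:
            feats = sorted(set().union(*pathway_definitions[phenotype]))
        else:
            feats = list(ref_roles.columns)
        if len(np.unique(y)) == 1:
            rules[phenotype] = PathwayRule(phenotype, feats, None, constant=int(y[0]))
            continue
        X = ref_roles.reindex(columns=feats, fill_value=0).to_numpy()
        tree = DecisionTreeClassifier(
            criterion="gini", max_depth=max(1, len(feats)), random_state=0
        )
        tree.fit(X, y)
        acc = float((tree.predict(X) == y).mean())
        rules[phenotype] = PathwayRule(phenotype, feats, tree, training_accuracy=acc)
    return rules


def predict_rules(mag_roles: pd.DataFrame, rules: Mapping[str, PathwayRule]) -> pd.DataFrame:
    """Deterministic tree evaluation; roles absent from the matrix count as 0."""
    out = pd.DataFrame(index=mag_roles.index, dtype=int)
    for phenotype in sorted(rules):
        out[phenotype] = rules[phenotype].predict(mag_roles)
    return out


# ---------------------------------------------------------------------------
# machine learning
# ---------------------------------------------------------------------------

def predict_ml(
    ref_roles: pd.DataFrame,
    ref_bpm: pd.DataFrame,
    mag_roles: pd.DataFrame,
    n_trees: int = 200,
    grid: Sequence[Mapping] | None = DEFAULT_RF_GRID,
    seed: int = 0,
    loo: bool = False,
) -> tuple[pd.DataFrame, dict]:
    """Per-phenotype random forests trained on the reference collection.

    Hyperparameters are chosen per phenotype from ``grid`` by out-of-bag
    score; ``loo=True`` additionally reports leave-one-out accuracy for the
    chosen parameters. Constant phenotypes fall back to a flagged
    majority-class predictor. Fixed seed gives reproducible predictions.
    """
    if len(ref_bpm) < 4:
        raise InvalidInputError("need at least 4 reference genomes to train")
    ref_roles = ref_roles.loc[ref_bpm.index]
    features = list(ref_roles.columns)
    Xr = ref_roles.to_numpy()
    Xq = mag_roles.reindex(columns=features, fill_value=0).to_numpy()
    preds = pd.DataFrame(index=mag_roles.index, dtype=int)
    report: dict = {}
    for phenotype in sorted(ref_bpm.columns):
        y = ref_bpm[phenotype].to_numpy().astype(int)
        if len(np.unique(y)) == 1:
            preds[phenotype] = int(y[0])
            report[phenotype] = {"constant": True, "majority_class": int(y[0])}
            continue
        sub_seed = (seed + zlib.crc32(phenotype.encode())) & 0x7FFFFFFF
        best_params, best_score, best_rf = None, -np.inf, None
        for params in grid or ({"max_features": "sqrt", "min_samples_leaf": 1},):
            rf = RandomForestClassifier(
                n_estimators=n_trees, oob_score=True, bootstrap=True,
                random_state=sub_seed, **params,
            )
            rf.fit(Xr, y)
            if rf.oob_score_ > best_score:
                best_score, best_params, best_rf = rf.oob_score_, dict(params), rf
        preds[phenotype] = best_rf.predict(Xq).astype(int)
        entry = {"constant": False, "params": best_params, "oob_score": float(best_score)}
        if loo:
            hits = 0
            for i in range(len(y)):
                mask = np.ones(len(y), dtype=bool)
                mask[i] = False
                yi = y[mask]
                if len(np.unique(yi)) == 1:
                    hits += int(yi[0] == y[i])
                    continue
                rf_i = RandomForestClassifier(
                    n_estimators=n_trees, random_state=sub_seed, **best_params
                )
                rf_i.fit(Xr[mask], yi)
                hits += int(rf_i.predict(Xr[i : i + 1])[0] == y[i])
            entry["loo_accuracy"] = hits / len(y)
        report[phenotype] = entry
    return preds[sorted(ref_bpm.columns)], report


# ---------------------------------------------------------------------------
# MinHash sketches and neighbour groups
# ---------------------------------------------------------------------------

@dataclass
class MinHashSketch:
    genome_id: str
    k: int
    sketch_size: int
    hashes: np.ndarray  # sorted ascending, at most sketch_size values


@dataclass
class NeighborGroup:
    members: list[str]  # genome ids (MAGs and references)
    reference_members: list[str]
    distances: pd.DataFrame  # pairwise member distances


def sketch_sequences(
    genome_id: str,
    sequences: Iterable[str],
    k: int = 21,
    sketch_size: int = 1000,
) -> MinHashSketch:
    """Bottom-``sketch_size`` MinHash sketch of a genome's k-mers.

    k-mers are hashed with crc32 (stable across runs); the sketch keeps the
    smallest distinct hash values.
    """
    hashes: set[int] = set()
    crc32 = zlib.crc32
    for seq in sequences:
        raw = seq.encode("ascii")
        hashes.update(crc32(raw[i : i + k]) for i in range(len(raw) - k + 1))
    arr = np.fromiter(hashes, dtype=np.uint64, count=len(hashes))
    arr.sort()
    return MinHashSketch(genome_id, k, sketch_size, arr[:sketch_size])


def mash_distance(s1: MinHashSketch, s2: MinHashSketch) -> float:
    """Mash distance d = -(1/k) ln(2j / (1 + j)) from the merged bottom sketch.

    Disjoint sketches (j = 0) are capped at distance 1.
    """
    if s1.k != s2.k or s1.sketch_size != s2.sketch_size:
        raise InvalidParameterError("sketches must share k and sketch_size")
    merged = np.union1d(s1.hashes, s2.hashes)[: s1.sketch_size]
    common = np.intersect1d(s1.hashes, s2.hashes, assume_unique=True)
    shared = np.isin(merged, common, assume_unique=True).sum()
    if len(merged) == 0 or shared == 0:
        return 1.0
    j = shared / len(merged)
    return float(-np.log(2.0 * j / (1.0 + j)) / s1.k)


def assign_neighbor_groups(
    mag_sketches: Sequence[MinHashSketch],
    reference_sketches: Sequence[MinHashSketch],
    max_distance: float = 0.1,
    min_size: int = 4,
) -> list[NeighborGroup]:
    """Single-linkage grouping of MAGs with close reference genomes.

    Pairs at Mash distance <= ``max_distance`` are linked; connected
    components smaller than ``min_size`` are dissolved (their members stay
    ungrouped, and those MAGs abstain from neighbour-group prediction).
    """
    sketches = list(mag_sketches) + list(reference_sketches)
    ids = [s.genome_id for s in sketches]
    ref_ids = {s.genome_id for s in reference_sketches}
    n = len(sketches)
    dist = np.ones((n, n))
    np.fill_diagonal(dist, 0.0)
    for i in range(n):
        for j in range(i + 1, n):
            d = mash_distance(sketches[i], sketches[j])
            dist[i, j] = dist[j, i] = d
    parent = list(range(n))

    def find(x: int) -> int:
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for i in range(n):
        for j in range(i + 1, n):
            if dist[i, j] <= max_distance:
                parent[find(i)] = find(j)
    comps: dict[int, list[int]] = {}
    for i in range(n):
        comps.setdefault(find(i), []).append(i)
    groups = []
    for comp in sorted(comps.values(), key=lambda c: ids[c[0]]):
        if len(comp) < min_size:
            continue
        members = [ids[i] for i in comp]
        sub = pd.DataFrame(dist[np.ix_(comp, comp)], index=members, columns=members)
        groups.append(
            NeighborGroup(
                members=members,
                reference_members=[m for m in members if m in ref_ids],
                distances=sub,
            )
        )
    return groups


def predict_neighbor(
    mag_roles: pd.Series,
    group: NeighborGroup | None,
    ref_bpm: pd.DataFrame,
    pathway_definitions: Mapping[str, list[set[str]]],
    ref_roles: pd.DataFrame | None = None,
) -> pd.Series:
    """Adopt, per phenotype, the value of the closest-pattern group reference.

    The Hamming comparison is limited to the pathway's required roles, and a
    reference may be adopted even if some of its genes are absent from the
    query MAG. Equidistant references with conflicting phenotypes, or a
    group with no reference genome (or no group at all), abstain.
    """
    phenotypes = sorted(ref_bpm.columns)
    if group is None or not group.reference_members:
        return pd.Series([ABSTAIN] * len(phenotypes), index=phenotypes, dtype=object)
    refs = [g for g in group.reference_members if g in ref_bpm.index]
    if not refs:
        return pd.Series([ABSTAIN] * len(phenotypes), index=phenotypes, dtype=object)
    if ref_roles is None:
        raise InvalidInputError("predict_neighbor needs the reference role matrix")
    out = {}
    for phenotype in phenotypes:
        required = sorted(set().union(*pathway_definitions[phenotype]))
        q = mag_roles.reindex(required, fill_value=0).to_numpy()
        R = ref_roles.loc[refs].reindex(columns=required, fill_value=0).to_numpy()
        hamming = (R != q).sum(axis=1)
        best = hamming.min()
        values = {int(ref_bpm.loc[refs[i], phenotype]) for i in np.flatnonzero(hamming == best)}
        out[phenotype] = values.pop() if len(values) == 1 else ABSTAIN
    return pd.Series(out, dtype=object)[phenotypes]


# ---------------------------------------------------------------------------
# consensus
# ---------------------------------------------------------------------------

def consensus(rule_vote, ml_vote, ng_vote, ng_rescue: bool = True) -> tuple[int, str]:
    """Reconcile the three votes into (consensus value, confidence grade).

    unanimity -> that value, high. A participating neighbour vote in the
    majority -> majority value, medium. ng vote of 1 against rule = ml = 0
    -> 1 (false-negative rescue, low confidence) when ``ng_rescue`` is on,
    the majority 0 otherwise. ng abstaining: rules/ML agreeing -> that
    value, medium; disagreeing (irreconcilable) -> the ML value, low.
    """
    votes = [rule_vote, ml_vote, ng_vote]
    cast = [v for v in votes if v != ABSTAIN]
    if not cast:
        raise UndefinedCallError("all three methods abstained")
    if any(v not in (0, 1) for v in cast):
        raise InvalidParameterError(f"votes must be 0, 1 or abstain, got {votes}")
    if ng_vote == ABSTAIN:
        if rule_vote == ABSTAIN or ml_vote == ABSTAIN:
            only = cast[0]
            return int(only), "low"
        if rule_vote == ml_vote:
            return int(rule_vote), "medium"
        return int(ml_vote), "low"
    if rule_vote == ml_vote == ng_vote:
        return int(ng_vote), "high"
    if ng_rescue and ng_vote == 1 and rule_vote == 0 and ml_vote == 0:
        return 1, "low"
    # 2-vs-1 majority with the neighbour vote participating
    ones = sum(1 for v in cast if v == 1)
    majority = int(ones * 2 > len(cast))
    if rule_vote == ABSTAIN or ml_vote == ABSTAIN:
        # two participants only: ng + one other
        other = rule_vote if ml_vote == ABSTAIN else ml_vote
        if other == ng_vote:
            return int(ng_vote), "medium"
        if ng_rescue and ng_vote == 1 and other == 0:
            return 1, "low"
        return int(ml_vote) if ml_vote != ABSTAIN else int(ng_vote), "low"
    return majority, "medium"


def consensus_calls(
    rule_preds: pd.DataFrame,
    ml_preds: pd.DataFrame,
    ng_preds: pd.DataFrame,
    ng_rescue: bool = True,
) -> tuple[pd.DataFrame, list[PhenotypeCall]]:
    """Consensus BPM plus per-call records for every (genome, phenotype)."""
    genomes = list(rule_preds.index)
    phenotypes = sorted(rule_preds.columns)
    bpm = pd.DataFrame(0, index=genomes, columns=phenotypes, dtype=int)
    calls = []
    for g in genomes:
        for p in phenotypes:
            value, conf = consensus(
                rule_preds.loc[g, p], ml_preds.loc[g, p], ng_preds.loc[g, p],
                ng_rescue=ng_rescue,
            )
            bpm.loc[g, p] = value
            calls.append(
                PhenotypeCall(g, p, rule_preds.loc[g, p], ml_preds.loc[g, p],
                              ng_preds.loc[g, p], value, conf)
            )
    return bpm, calls


def predict_phenotypes(
    ref_roles: pd.DataFrame,
    ref_bpm: pd.DataFrame,
    mag_roles: pd.DataFrame,
    pathway_definitions: Mapping[str, list[set[str]]],
    mag_sequences: Mapping[str, Sequence[str]] | None = None,
    ref_sequences: Mapping[str, Sequence[str]] | None = None,
    seed: int = 0,
    n_trees: int = 200,
    grid: Sequence[Mapping] | None = DEFAULT_RF_GRID,
    sketch_k: int = 21,
    sketch_size: int = 1000,
    max_distance: float = 0.1,
    min_group_size: int = 4,
    ng_rescue: bool = True,
) -> tuple[pd.DataFrame, list[PhenotypeCall], dict]:
    """Full three-strategy prediction for a set of MAGs.

    When sequences are not supplied the neighbour-group strategy abstains
    for every MAG. Returns (consensus BPM, calls, report).
    """
    rules = train_pathway_rules(ref_roles, ref_bpm, pathway_definitions)
    rule_preds = predict_rules(mag_roles, rules)
    ml_preds, ml_report = predict_ml(
        ref_roles, ref_bpm, mag_roles, n_trees=n_trees, grid=grid, seed=seed
    )
    phenotypes = sorted(ref_bpm.columns)
    ng_preds = pd.DataFrame(ABSTAIN, index=mag_roles.index, columns=phenotypes, dtype=object)
    groups: list[NeighborGroup] = []
    if mag_sequences is not None and ref_sequences is not None:
        mag_sk = [
            sketch_sequences(g, mag_sequences[g], k=sketch_k, sketch_size=sketch_size)
            for g in sorted(mag_sequences)
        ]
        ref_sk = [
            sketch_sequences(g, ref_sequences[g], k=sketch_k, sketch_size=sketch_size)
            for g in sorted(ref_sequences)
        ]
        groups = assign_neighbor_groups(
            mag_sk, ref_sk, max_distance=max_distance, min_size=min_group_size
        )
        group_of = {m: grp for grp in groups for m in grp.members}
        for g in mag_roles.index:
            ng_preds.loc[g] = predict_neighbor(
                mag_roles.loc[g], group_of.get(g), ref_bpm, pathway_definitions,
                ref_roles=ref_roles,
            )
    bpm, calls = consensus_calls(rule_preds, ml_preds, ng_preds, ng_rescue=ng_rescue)
    report = {
        "ml": ml_report,
        "rule_training_accuracy": {p: rules[p].training_accuracy for p in rules},
        "n_neighbor_groups": len(groups),
        "rule_preds": rule_preds,
        "ml_preds": ml_preds,
        "ng_preds": ng_preds,
    }
    return bpm, calls, report


def filter_genes_to_intact_pathways(
    annotations: pd.DataFrame,
    consensus_bpm: pd.DataFrame,
    pathway_definitions: Mapping[str, list[set[str]]],
    genome_col: str = "genome",
    role_col: str = "role",
) -> pd.DataFrame:
    """Keep genes whose role belongs to a pathway called 1 in that genome.

    ``annotations`` is a tidy table with a genome column and a role column;
    unannotated genes (role null) are dropped.
    """
    role_to_pathways: dict[str, set[str]] = {}
    for pathway, variants in pathway_definitions.items():
        for v in variants:
            for role in v:
                role_to_pathways.setdefault(role, set()).add(pathway)

    def keep(row) -> bool:
        role = row[role_col]
        if role is None or (isinstance(role, float) and np.isnan(role)):
            return False
        genome = row[genome_col]
        if genome not in consensus_bpm.index:
            return False
        for pathway in role_to_pathways.get(role, ()):
            if consensus_bpm.loc[genome, pathway] == 1:
                return True
        return False

    if annotations.empty:
        return annotations
    mask = annotations.apply(keep, axis=1)
    return annotations[mask]
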