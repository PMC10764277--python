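"""Synthetic study generator with known ground truth.

Emulates every input the analysis pipeline consumes: a reference pangenome
of role-labelled proteins with a curated binary phenotype matrix (BPM),
metagenome-assembled genomes (MAGs) degraded from those references at a
stated completeness/contamination, tabular protein-alignment hits against
the reference database, a longitudinal two-arm cohort with planted
abundance->WLZ and treatment x week effects, negative-binomial
metatranscriptome counts, and PUL variants planted as conserved /
structurally distinct / absent.

Everything is deterministic for a fixed top-level seed: each stage draws
from a named substream of that seed.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from ._rand import substream
from .errors import InvalidConfigError, InvalidParameterError
from .pul import PUL, ORFRecord, ROLE_SUSC, ROLE_SUSD

AMINO_ACIDS = np.array(list("ACDEFGHIKLMNPQRSTVWY"))

ARM_TREATMENT = "MDCF-2"
ARM_CONTROL = "RUSF"


# ---------------------------------------------------------------------------
# configuration
# ---------------------------------------------------------------------------

@dataclass
class SimulationConfig:
    """Study conditions for the synthetic cohort and reference collection.

    Defaults mirror the study design the pipeline targets: MAGs at >=90%
    completeness and <=5% contamination, a two-arm trial (MDCF-2 vs RUSF)
    sampled over five study weeks, and negative-binomial transcript counts.
    """

    n_ref_genomes: int = 60
    n_phenotypes: int = 20
    roles_per_pathway: tuple[int, int] = (2, 4)
    n_participants: int = 40
    timepoints: tuple[float, ...] = (0.0, 4.0, 8.0, 12.0, 16.0)
    arms: tuple[str, str] = (ARM_TREATMENT, ARM_CONTROL)
    nb_dispersion: float = 0.3
    effect_sizes: dict = field(default_factory=dict)
    mag_completeness: float = 0.9
    mag_contamination: float = 0.05
    fragmentation_rate: float = 0.05
    prevalence_band: tuple[float, float] = (0.25, 0.75)
    mutation_rate: float = 0.025
    clade_size: int = 10
    clade_divergence: float = 0.12
    protein_length: tuple[int, int] = (120, 260)
    n_filler_families: int = 30
    n_outgroup_families: int = 8
    db_copies_per_family: int = 6
    seed: int = 0

    def validate(self) -> None:
        if self.n_ref_genomes <= 0 or self.n_phenotypes <= 0:
            raise InvalidConfigError("n_ref_genomes and n_phenotypes must be positive")
        if self.n_ref_genomes < 4:
            raise InvalidConfigError("n_ref_genomes must be >= 4 (minimum neighbour-group size)")
        for name in ("mag_completeness", "mag_contamination", "fragmentation_rate", "mutation_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise InvalidConfigError(f"{name} must lie in [0, 1], got {v}")
        lo, hi = self.prevalence_band
        if not 0.0 <= lo <= hi <= 1.0:
            raise InvalidConfigError("prevalence_band must be an ordered pair in [0, 1]")
        if list(self.timepoints) != sorted(set(self.timepoints)):
            raise InvalidConfigError("timepoints must be strictly increasing")
        if self.n_participants <= 0:
            raise InvalidConfigError("n_participants must be positive")
        if not 1 <= self.roles_per_pathway[0] <= self.roles_per_pathway[1]:
            raise InvalidConfigError("roles_per_pathway must be an ordered positive range")
        if self.nb_dispersion <= 0:
            raise InvalidConfigError("nb_dispersion must be positive")


# ---------------------------------------------------------------------------
# reference pangenome
# ---------------------------------------------------------------------------

@dataclass
class ProteinRecord:
    protein_id: str
    genome: str
    family: str
    role: str | None  # None for outgroup-derived / unannotated proteins
    sequence: str
    contig: str = "c1"
    position: int = 0
    offset: int = 0  # residue offset into the family ancestor (fragments)
    fragment_of: str | None = None
    provenance: str = "native"  # native | contaminant


@dataclass
class GenomeRecord:
    genome_id: str
    proteins: list[ProteinRecord]

    def role_set(self) -> set[str]:
        return {p.role for p in self.proteins if p.role is not None}

    def concatenated_sequence(self) -> str:
        return "".join(p.sequence for p in sorted(self.proteins, key=lambda p: p.protein_id))


@dataclass
class ReferencePangenome:
    genomes: dict[str, GenomeRecord]
    subsystems: dict[str, set[str]]
    pathway_definitions: dict[str, list[set[str]]]  # phenotype -> variant role sets
    truth_bpm: pd.DataFrame  # genomes x phenotypes, {0, 1}
    outgroup_proteins: set[str]
    reference_db: pd.DataFrame  # protein_id, family, role, outgroup, sequence
    family_sequences: dict[str, str]
    family_roles: dict[str, str | None]
    clade_of: dict[str, int] = field(default_factory=dict)

    def all_roles(self) -> list[str]:
        roles = set()
        for variants in self.pathway_definitions.values():
            for v in variants:
                roles |= v
        return sorted(roles)


def _random_protein(rng: np.random.Generator, length: int) -> str:
    return "".join(rng.choice(AMINO_ACIDS, size=length))


def _mutate(rng: np.random.Generator, seq: str, rate: float) -> str:
    arr = np.array(list(seq))
    mask = rng.random(arr.size) < rate
    if mask.any():
        subs = rng.choice(AMINO_ACIDS, size=int(mask.sum()))
        # force a true substitution at each mutated site
        same = subs == arr[mask]
        while same.any():
            subs[same] = rng.choice(AMINO_ACIDS, size=int(same.sum()))
            same = subs == arr[mask]
        arr[mask] = subs
    return "".join(arr)


def compute_truth_bpm(
    genome_roles: Mapping[str, set[str]],
    pathway_definitions: Mapping[str, list[set[str]]],
) -> pd.DataFrame:
    """Recompute the BPM from gene content: 1 iff some variant is complete."""
    genomes = sorted(genome_roles)
    phenotypes = sorted(pathway_definitions)
    data = np.zeros((len(genomes), len(phenotypes)), dtype=int)
    for i, g in enumerate(genomes):
        roles = genome_roles[g]
        for j, p in enumerate(phenotypes):
            data[i, j] = int(any(v <= roles for v in pathway_definitions[p]))
    return pd.DataFrame(data, index=genomes, columns=phenotypes)


def generate_reference_collection(config: SimulationConfig) -> ReferencePangenome:
    """Generate a clade-structured reference pangenome with an exact BPM.

    Each phenotype corresponds to a metabolic pathway with one or two role
    variants; a genome scores 1 iff it carries every role of some variant.
    Genomes fall into clades (``clade_size`` members each) that diverge from
    one another at ``clade_divergence`` per site and within themselves at
    ``mutation_rate``, so MinHash distances recover the clades. Pathway
    content tracks the clades: close neighbours tend to share whole pathway
    variants while distant clades carry divergent variants or only sparse
    remnants — the structure the neighbour-group predictor relies on.
    Phenotype prevalences are planted inside ``config.prevalence_band`` by
    exact positive counts, and genomes assigned 0 are post-edited so no
    variant is accidentally complete.
    """
    config.validate()
    rng_roles = substream(config.seed, "ref.roles")
    rng_seq = substream(config.seed, "ref.sequences")
    rng_assign = substream(config.seed, "ref.assign")

    n_g = config.n_ref_genomes
    genome_ids = [f"G{i:04d}" for i in range(n_g)]
    clade_of = {g: i // config.clade_size for i, g in enumerate(genome_ids)}
    n_clades = max(clade_of.values()) + 1
    clades = [[g for g in genome_ids if clade_of[g] == c] for c in range(n_clades)]

    pathway_definitions: dict[str, list[set[str]]] = {}
    subsystems: dict[str, set[str]] = {}
    lo, hi = config.roles_per_pathway
    for p in range(config.n_phenotypes):
        name = f"P{p:03d}"
        k = int(rng_roles.integers(lo, hi + 1))
        roles = [f"{name}:R{i}" for i in range(k)]
        variants = [set(roles)]
        if k >= 2 and rng_roles.random() < 0.4:
            variants.append(set(roles[:-1]) | {f"{name}:R{k - 1}alt"})
        pathway_definitions[name] = variants
        subsystems[name] = set().union(*variants)

    role_families = sorted(set().union(*subsystems.values()))
    filler_families = [f"HK{i:03d}" for i in range(config.n_filler_families)]
    outgroup_families = [f"OG{i:03d}" for i in range(config.n_outgroup_families)]
    all_families = role_families + filler_families + outgroup_families

    family_sequences: dict[str, str] = {}
    family_roles: dict[str, str | None] = {}
    clade_variant_seq: dict[tuple[str, int], str] = {}
    for fam in all_families:
        length = int(rng_seq.integers(config.protein_length[0], config.protein_length[1] + 1))
        family_sequences[fam] = _random_protein(rng_seq, length)
        if fam in outgroup_families:
            family_roles[fam] = None
        elif fam.startswith("HK"):
            family_roles[fam] = f"housekeeping:{fam}"
        else:
            family_roles[fam] = fam  # pathway roles are their own labels
        for c in range(n_clades):
            clade_variant_seq[(fam, c)] = _mutate(
                rng_seq, family_sequences[fam], config.clade_divergence
            )

    # plant phenotype content: positives fill whole clades first, so close
    # neighbours mostly agree on whole pathway variants
    carried: dict[str, set[str]] = {g: set() for g in genome_ids}
    planted = pd.DataFrame(0, index=genome_ids, columns=sorted(pathway_definitions), dtype=int)
    for name in sorted(pathway_definitions):
        variants = pathway_definitions[name]
        prev = rng_assign.uniform(*config.prevalence_band)
        n_pos = int(np.clip(round(prev * n_g), np.ceil(config.prevalence_band[0] * n_g),
                            np.floor(config.prevalence_band[1] * n_g)))
        clade_order = list(rng_assign.permutation(n_clades))
        pos: set[str] = set()
        for c in clade_order:
            if len(pos) >= n_pos:
                break
            take = clades[c][: n_pos - len(pos)]
            pos |= set(take)
        clade_variant_idx = {c: int(rng_assign.integers(len(variants))) for c in range(n_clades)}
        for g in genome_ids:
            if g in pos:
                variant = variants[clade_variant_idx[clade_of[g]]]
                carried[g] |= variant
                planted.loc[g, name] = 1
            else:
                # realistic absence: sparse remnants, occasionally a near-miss
                variant = variants[int(rng_assign.integers(len(variants)))]
                roles = sorted(variant)
                if rng_assign.random() < 0.1 and len(roles) > 1:
                    drop = int(rng_assign.integers(len(roles)))
                    keep = [r for i, r in enumerate(roles) if i != drop]
                else:
                    keep = [r for r in roles if rng_assign.random() < 0.15]
                carried[g] |= set(keep)
        # genomes assigned 0 must not accidentally complete any variant
        for g in genome_ids:
            if g in pos:
                continue
            for variant in variants:
                if variant <= carried[g]:
                    carried[g].discard(sorted(variant)[int(rng_assign.integers(len(variant)))])

    genomes: dict[str, GenomeRecord] = {}
    for g in genome_ids:
        clade = clade_of[g]
        fams = sorted(carried[g])
        fams += [f for f in filler_families if rng_assign.random() < 0.9]
        fams += list(rng_assign.choice(outgroup_families, size=2, replace=False))
        proteins = []
        half = max(1, len(fams) // 2)
        for idx, fam in enumerate(fams):
            seq = _mutate(rng_seq, clade_variant_seq[(fam, clade)], config.mutation_rate)
            contig = "c1" if idx < half else "c2"
            position = idx + 1 if idx < half else idx - half + 1
            proteins.append(
                ProteinRecord(
                    protein_id=f"{g}|{fam}",
                    genome=g,
                    family=fam,
                    role=family_roles[fam],
                    sequence=seq,
                    contig=contig,
                    position=position,
                )
            )
        genomes[g] = GenomeRecord(genome_id=g, proteins=proteins)

    genome_roles = {g: genomes[g].role_set() for g in genome_ids}
    truth = compute_truth_bpm(genome_roles, pathway_definitions)
    if not truth.equals(planted.loc[truth.index, truth.columns]):
        raise AssertionError("planted BPM inconsistent with generated gene content")

    # reference protein database: diverged members per family spread over the
    # clades, outgroup families flagged
    db_rows = []
    for fam in sorted(family_sequences):
        for c in range(config.db_copies_per_family):
            clade = c % n_clades
            seq = _mutate(rng_seq, clade_variant_seq[(fam, clade)], config.mutation_rate)
            db_rows.append(
                {
                    "protein_id": f"DB|{fam}|{c}",
                    "family": fam,
                    "role": family_roles[fam] if fam not in outgroup_families else None,
                    "outgroup": fam in outgroup_families,
                    "sequence": seq,
                }
            )
    reference_db = pd.DataFrame(db_rows)
    outgroup_proteins = set(reference_db.loc[reference_db["outgroup"], "protein_id"])

    return ReferencePangenome(
        genomes=genomes,
        subsystems=subsystems,
        pathway_definitions=pathway_definitions,
        truth_bpm=truth,
        outgroup_proteins=outgroup_proteins,
        reference_db=reference_db,
        family_sequences=family_sequences,
        family_roles=family_roles,
        clade_of=clade_of,
    )


# ---------------------------------------------------------------------------
# MAG degradation
# ---------------------------------------------------------------------------

def degrade_genome_to_mag(
    genome: GenomeRecord,
    completeness: float,
    contamination: float,
    fragmentation_rate: float,
    seed: int,
    contaminant_pool: Sequence[ProteinRecord] | None = None,
    mag_id: str | None = None,
) -> GenomeRecord:
    """Degrade a reference genome into a MAG.

    Each gene is retained independently with probability ``completeness``;
    retained genes are split into two fragments with probability
    ``fragmentation_rate``; contaminant genes are drawn from
    ``contaminant_pool`` at rate ``contamination`` per retained gene and
    tagged in provenance.
    """
    for name, v in (("completeness", completeness), ("contamination", contamination),
                    ("fragmentation_rate", fragmentation_rate)):
        if not 0.0 <= v <= 1.0:
            raise InvalidParameterError(f"{name} must lie in [0, 1], got {v}")
    if not genome.proteins:
        raise InvalidParameterError("cannot degrade an empty genome")
    rng = substream(seed, f"mag.{genome.genome_id}")
    mag_id = mag_id or f"{genome.genome_id}.mag"
    proteins: list[ProteinRecord] = []
    for p in genome.proteins:
        if rng.random() >= completeness:
            continue
        if rng.random() < fragmentation_rate and len(p.sequence) >= 60:
            cut = int(rng.integers(int(0.3 * len(p.sequence)), int(0.7 * len(p.sequence))))
            for tag, seq, off in ((1, p.sequence[:cut], 0), (2, p.sequence[cut:], cut)):
                proteins.append(
                    replace(
                        p,
                        protein_id=f"{mag_id}|{p.family}_f{tag}",
                        genome=mag_id,
                        sequence=seq,
                        offset=p.offset + off,
                        fragment_of=p.protein_id,
                    )
                )
        else:
            proteins.append(replace(p, protein_id=f"{mag_id}|{p.family}", genome=mag_id))
    if contamination > 0 and contaminant_pool:
        n_cont = rng.binomial(len(proteins), contamination)
        if n_cont:
            picks = rng.choice(len(contaminant_pool), size=min(n_cont, len(contaminant_pool)),
                               replace=False)
            for i in sorted(picks):
                src = contaminant_pool[int(i)]
                proteins.append(
                    replace(
                        src,
                        protein_id=f"{mag_id}|cont|{src.family}|{src.genome}",
                        genome=mag_id,
                        provenance="contaminant",
                    )
                )
    return GenomeRecord(genome_id=mag_id, proteins=proteins)


def contaminant_pool(pangenome: ReferencePangenome, exclude: str) -> list[ProteinRecord]:
    """All proteins of all reference genomes except ``exclude``."""
    pool: list[ProteinRecord] = []
    for g in sorted(pangenome.genomes):
        if g != exclude:
            pool.extend(pangenome.genomes[g].proteins)
    return pool


# ---------------------------------------------------------------------------
# simulated alignment hits (stands in for running an aligner)
# ---------------------------------------------------------------------------

OUTFMT6_COLUMNS = [
    "qseqid", "sseqid", "pident", "length", "mismatch", "gapopen",
    "qstart", "qend", "sstart", "send", "evalue", "bitscore",
]


def _positional_identity(a: str, b: str) -> float:
    n = min(len(a), len(b))
    if n == 0:
        return 0.0
    return sum(x == y for x, y in zip(a[:n], b[:n])) / n


def simulate_alignment_hits(
    pangenome: ReferencePangenome,
    query_genome: GenomeRecord,
    seed: int,
    n_true: int = 6,
    n_decoy: int = 4,
    decoy_identity: tuple[float, float] = (30.0, 50.0),
) -> pd.DataFrame:
    """Tabular (outfmt-6 dialect) hits of a genome's proteins vs the reference DB.

    True hits go to database members of the query protein's own family with
    the actual percent identity; decoy hits to random other families carry a
    low identity and proportionally low bitscore, emulating the spurious tail
    of a real alignment run.
    """
    rng = substream(seed, f"hits.{query_genome.genome_id}")
    db = pangenome.reference_db
    by_family = {fam: grp for fam, grp in db.groupby("family")}
    families = sorted(by_family)
    rows = []
    for p in sorted(query_genome.proteins, key=lambda x: x.protein_id):
        qlen = len(p.sequence)
        fam_db = by_family.get(p.family)
        if fam_db is not None:
            idx = np.arange(len(fam_db))
            if len(idx) > n_true:
                idx = rng.choice(idx, size=n_true, replace=False)
            for i in sorted(idx):
                subj = fam_db.iloc[int(i)]
                sseq = subj["sequence"]
                pid = 100.0 * _positional_identity(p.sequence, sseq[p.offset : p.offset + qlen])
                matches = int(round(pid / 100.0 * qlen))
                rows.append(
                    (
                        p.protein_id, subj["protein_id"], round(pid, 1), qlen,
                        qlen - matches, 0, 1, qlen, p.offset + 1, p.offset + qlen,
                        1e-30, round(2.0 * matches, 1),
                    )
                )
        others = [f for f in families if f != p.family]
        if others and n_decoy > 0:
            for f in rng.choice(others, size=min(n_decoy, len(others)), replace=False):
                subj = by_family[f].iloc[int(rng.integers(len(by_family[f])))]
                pid = rng.uniform(*decoy_identity)
                alen = max(30, int(0.6 * qlen))
                matches = int(round(pid / 100.0 * alen))
                rows.append(
                    (
                        p.protein_id, subj["protein_id"], round(pid, 1), alen,
                        alen - matches, 1, 1, alen, 1, alen,
                        1e-5, round(1.2 * matches, 1),
                    )
                )
    return pd.DataFrame(rows, columns=OUTFMT6_COLUMNS)


def reference_role_map(pangenome: ReferencePangenome) -> pd.DataFrame:
    """Sidecar table mapping reference protein ids to roles / outgroup flags."""
    db = pangenome.reference_db
    return pd.DataFrame(
        {
            "subject_id": db["protein_id"],
            "role": db["role"].where(~db["outgroup"], None),
            "outgroup": db["outgroup"].astype(int),
        }
    )


def simulate_multidomain_fixture(
    n_proteins: int,
    seed: int,
    n_hits_per_domain: int = 10,
    n_decoys_per_domain: int = 8,
    high_identity: float = 95.0,
    low_identity: float = 55.0,
    boundary_jitter: int = 3,
    outgroup_fraction: float = 0.0,
) -> tuple[dict[str, str], pd.DataFrame, pd.DataFrame, dict[str, list[tuple[int, int, str | None]]]]:
    """Fixture for the domain-splitting annotation workflow.

    Each protein is a fusion of two sequence families; hits against each
    half span that half's residue interval (with small coordinate jitter)
    at ``high_identity``, while decoy hits to wrong roles sit at
    ``low_identity``. A fraction of proteins have only outgroup hits.
    Returns (sequences, hits table, role map, per-protein truth of
    (start, end, role) domains; role None marks outgroup-only proteins).
    """
    rng = substream(seed, "fixture.multidomain")
    rows, role_rows, truth = [], [], {}
    sequences: dict[str, str] = {}
    seen_subjects = set()

    def add_subject(sid: str, role: str | None, outgroup: bool) -> None:
        if sid not in seen_subjects:
            seen_subjects.add(sid)
            role_rows.append({"subject_id": sid, "role": role, "outgroup": int(outgroup)})

    for i in range(n_proteins):
        qid = f"Q{i:04d}"
        len_a = int(rng.integers(90, 160))
        len_b = int(rng.integers(90, 160))
        total = len_a + len_b
        sequences[qid] = _random_protein(rng, total)
        is_outgroup = rng.random() < outgroup_fraction
        if is_outgroup:
            truth[qid] = [(1, total, None)]
            for h in range(n_hits_per_domain):
                sid = f"OGDB{i:04d}_{h}"
                add_subject(sid, None, True)
                pid = rng.normal(high_identity, 1.5)
                matches = int(round(pid / 100 * total))
                rows.append((qid, sid, round(pid, 1), total, total - matches, 0,
                             1, total, 1, total, 1e-30, round(2.0 * matches, 1)))
            continue
        role_a, role_b = f"roleA{i:04d}", f"roleB{i:04d}"
        truth[qid] = [(1, len_a, role_a), (len_a + 1, total, role_b)]
        for (d_start, d_end, role) in truth[qid]:
            dlen = d_end - d_start + 1
            for h in range(n_hits_per_domain):
                sid = f"DB{role}_{h}"
                add_subject(sid, role, False)
                pid = float(np.clip(rng.normal(high_identity, 1.5), 85.0, 100.0))
                qs = d_start + int(rng.integers(0, boundary_jitter + 1))
                qe = d_end - int(rng.integers(0, boundary_jitter + 1))
                alen = qe - qs + 1
                matches = int(round(pid / 100 * alen))
                rows.append((qid, sid, round(pid, 1), alen, alen - matches, 0,
                             qs, qe, 1, alen, 1e-30, round(2.0 * matches, 1)))
            for h in range(n_decoys_per_domain):
                sid = f"DBdecoy{i:04d}_{d_start}_{h}"
                add_subject(sid, f"decoy{i:04d}_{h}", False)
                pid = float(np.clip(rng.normal(low_identity, 3.0), 30.0, high_identity - 30.0))
                qs = d_start + int(rng.integers(0, boundary_jitter + 1))
                qe = d_end - int(rng.integers(0, boundary_jitter + 1))
                alen = qe - qs + 1
                matches = int(round(pid / 100 * alen))
                rows.append((qid, sid, round(pid, 1), alen, alen - matches, 1,
                             qs, qe, 1, alen, 1e-8, round(1.0 * matches, 1)))
    hits = pd.DataFrame(rows, columns=OUTFMT6_COLUMNS)
    refmap = pd.DataFrame(role_rows)
    return sequences, hits, refmap, truth


# ---------------------------------------------------------------------------
# longitudinal cohort
# ---------------------------------------------------------------------------

@dataclass
class SyntheticCohort:
    """Longitudinal two-arm cohort with planted effects.

    Count tables are stored features-in-rows / samples-in-columns; columns
    align with ``meta``'s index (sample ids).
    """

    dna_tpm: pd.DataFrame  # MAGs x samples
    transcript_counts: pd.DataFrame  # genes x samples (integers)
    gene_to_mag: pd.Series  # gene id -> MAG id
    meta: pd.DataFrame  # index sample_id; PID, study_week, arm, WLZ, quartile
    truth_effects: dict


def default_effect_sizes(mag_ids: Sequence[str], rng: np.random.Generator) -> dict:
    """Planted effects: 10% of MAGs positively WLZ-associated (beta1=+0.5),
    10% negatively (-0.5); positively associated MAGs also respond to
    treatment (beta3 = +0.15 log2-TPM per week in the MDCF-2 arm)."""
    n = len(mag_ids)
    k = max(1, n // 10)
    order = list(rng.permutation(list(mag_ids)))
    pos, neg = order[:k], order[k : 2 * k]
    wlz = {m: 0.5 for m in pos}
    wlz.update({m: -0.5 for m in neg})
    group_week = {m: 0.15 for m in pos}
    return {"wlz_beta1": wlz, "group_week_beta3": group_week}


def simulate_cohort(
    pangenome: ReferencePangenome,
    config: SimulationConfig,
    n_transcripts_per_genome: int | None = None,
) -> SyntheticCohort:
    """Simulate DNA abundances, WLZ trajectories and transcript counts.

    WLZ for participant i at week t is
    ``u_i + beta2 * t + sum_m beta1_m * z_m(i, t) + noise`` where ``z_m`` is
    the standardized log2 abundance of MAG m (the variance-stabilized scale
    on which the association models operate) and ``u_i`` is a participant
    random intercept. Transcript counts are negative binomial with planted
    treatment and treatment x week differential genes.
    """
    config.validate()
    mag_ids = sorted(pangenome.genomes)
    rng_meta = substream(config.seed, "cohort.meta")
    rng_ab = substream(config.seed, "cohort.abundance")
    rng_wlz = substream(config.seed, "cohort.wlz")
    rng_rna = substream(config.seed, "cohort.rna")

    effects = dict(config.effect_sizes) if config.effect_sizes else default_effect_sizes(
        mag_ids, substream(config.seed, "cohort.effects")
    )
    beta1 = {m: float(effects.get("wlz_beta1", {}).get(m, 0.0)) for m in mag_ids}
    beta3 = {m: float(effects.get("group_week_beta3", {}).get(m, 0.0)) for m in mag_ids}

    pids = [f"P{i:03d}" for i in range(config.n_participants)]
    arms = {pid: config.arms[i % 2] for i, pid in enumerate(pids)}
    weeks = list(config.timepoints)
    samples = [f"{pid}_wk{int(w):02d}" for pid in pids for w in weeks]
    meta = pd.DataFrame(
        {
            "PID": [s.split("_wk")[0] for s in samples],
            "study_week": [float(w) for _ in pids for w in weeks],
            "arm": [arms[s.split("_wk")[0]] for s in samples],
        },
        index=pd.Index(samples, name="sample_id"),
    )
    treated = (meta["arm"] == ARM_TREATMENT).to_numpy(float)
    week_arr = meta["study_week"].to_numpy()

    n_s = len(samples)
    n_m = len(mag_ids)
    mu = rng_ab.normal(3.5, 1.5, size=n_m)
    # planted-effect MAGs are kept comfortably above the abundance filter
    for i, m in enumerate(mag_ids):
        if beta1[m] != 0 or beta3[m] != 0:
            mu[i] = rng_ab.normal(5.0, 0.5)
    part_effect = rng_ab.normal(0.0, 0.8, size=(n_m, config.n_participants))
    pid_idx = meta["PID"].map({p: i for i, p in enumerate(pids)}).to_numpy()
    drift = rng_ab.normal(0.0, 0.02, size=n_m)
    log2tpm = (
        mu[:, None]
        + part_effect[:, pid_idx]
        + drift[:, None] * week_arr[None, :]
        + np.array([beta3[m] for m in mag_ids])[:, None] * (treated * week_arr)[None, :]
        + rng_ab.normal(0.0, 0.7, size=(n_m, n_s))
    )
    tpm = np.power(2.0, log2tpm)
    tpm[log2tpm < -1.0] = 0.0  # detection floor: very rare organisms drop out
    dna_tpm = pd.DataFrame(tpm, index=mag_ids, columns=samples)

    logged = np.log2(tpm + 1.0)
    sd = logged.std(axis=1)
    sd[sd == 0] = 1.0
    z = (logged - logged.mean(axis=1, keepdims=True)) / sd[:, None]
    u = rng_wlz.normal(0.0, 0.5, size=config.n_participants)
    beta1_vec = np.array([beta1[m] for m in mag_ids])
    wlz = (
        u[pid_idx]
        + 0.01 * week_arr
        + beta1_vec @ z
        + rng_wlz.normal(0.0, 0.3, size=n_s)
    )
    meta["WLZ"] = wlz

    # WLZ-response quartiles among treated participants (rate of change)
    slopes = {}
    wk = np.array(weeks)
    wk_c = wk - wk.mean()
    for i, pid in enumerate(pids):
        rows = meta.index[meta["PID"] == pid]
        y = meta.loc[rows, "WLZ"].to_numpy()
        slopes[pid] = float(wk_c @ y / (wk_c @ wk_c))
    treated_pids = [p for p in pids if arms[p] == ARM_TREATMENT]
    ranked = sorted(treated_pids, key=lambda p: slopes[p])
    q = max(1, len(treated_pids) // 4)
    lower, upper = set(ranked[:q]), set(ranked[-q:])
    meta["quartile"] = [
        "upper" if p in upper else "lower" if p in lower else "other" for p in meta["PID"]
    ]

    # transcripts: one per role-carrying gene of each genome
    genes, gene_mag, gene_role = [], [], []
    for m in mag_ids:
        picked = [p for p in pangenome.genomes[m].proteins if p.role is not None]
        if n_transcripts_per_genome is not None:
            picked = picked[:n_transcripts_per_genome]
        for p in picked:
            genes.append(p.protein_id)
            gene_mag.append(m)
            gene_role.append(p.role)
    gene_to_mag = pd.Series(gene_mag, index=genes, name="mag")

    # planted differentially expressed pathways: genes of two "responder"
    # pathways are induced by MDCF-2 (group effect) or increasingly over
    # time on treatment (interaction effect)
    phenos = sorted(pangenome.pathway_definitions)
    rng_pick = substream(config.seed, "cohort.de")
    up_group = phenos[int(rng_pick.integers(len(phenos)))]
    up_inter = phenos[int(rng_pick.integers(len(phenos)))]
    roles_group = set().union(*pangenome.pathway_definitions[up_group])
    roles_inter = set().union(*pangenome.pathway_definitions[up_inter])
    lfc_group = np.array([1.5 if r in roles_group else 0.0 for r in gene_role])
    lfc_inter = np.array([0.12 if r in roles_inter else 0.0 for r in gene_role])

    base = rng_rna.lognormal(mean=2.0, sigma=1.0, size=len(genes))
    mag_tpm = dna_tpm.reindex(gene_to_mag.to_numpy()).to_numpy()
    rel_dna = mag_tpm / (mag_tpm.mean(axis=1, keepdims=True) + 1e-9)
    lam = (
        base[:, None]
        * rel_dna
        * np.power(2.0, lfc_group[:, None] * treated[None, :]
                   + lfc_inter[:, None] * (treated * week_arr)[None, :])
    )
    lam[mag_tpm <= 0] = 0.0
    depth = rng_rna.uniform(0.8, 1.2, size=n_s)
    lam = lam * depth[None, :]
    shape = 1.0 / config.nb_dispersion
    with np.errstate(divide="ignore", invalid="ignore"):
        mix = rng_rna.gamma(shape, 1.0, size=lam.shape) * (lam / shape)
    counts = rng_rna.poisson(np.nan_to_num(mix))
    transcript_counts = pd.DataFrame(counts.astype(int), index=genes, columns=samples)

    truth = {
        "wlz_beta1": beta1,
        "group_week_beta3": beta3,
        "de_group_pathway": up_group,
        "de_interaction_pathway": up_inter,
        "de_group_lfc": 1.5,
        "de_interaction_lfc_per_week": 0.12,
    }
    return SyntheticCohort(
        dna_tpm=dna_tpm,
        transcript_counts=transcript_counts,
        gene_to_mag=gene_to_mag,
        meta=meta,
        truth_effects=truth,
    )


# ---------------------------------------------------------------------------
# PUL variants
# ---------------------------------------------------------------------------

PUL_MODES = ("conserved", "structurally_distinct", "absent")


def make_reference_pul(
    seed: int,
    n_cazymes: int = 3,
    genome: str = "REF",
    contig: str = "c1",
    start_position: int = 10,
    families: Sequence[str] = ("GH26", "GH43", "GH51", "GH130", "GH5"),
) -> PUL:
    """A reference PUL: regulator, SusC/SusD pair, then CAZymes."""
    rng = substream(seed, "pul.reference")
    roles = [ROLE_SUSC, ROLE_SUSD] + [
        f"CAZyme:{families[i % len(families)]}" for i in range(n_cazymes)
    ] + ["regulator"]
    orfs = []
    for i, role in enumerate(roles):
        length = int(rng.integers(180, 320)) if role in (ROLE_SUSC, ROLE_SUSD) else int(
            rng.integers(150, 260)
        )
        orfs.append(
            ORFRecord(
                genome=genome,
                contig=contig,
                position=start_position + i,
                strand="+",
                protein=_random_protein(rng, length),
                role_class=role,
            )
        )
    return PUL(pul_id=f"{genome}:PUL{seed}", genome=genome, orfs=orfs)


def plant_pul_variants(
    reference_pul: PUL,
    mode: str,
    seed: int,
    genome: str = "QRY",
    contig: str = "c1",
    start_position: int = 10,
    mutation_rate: float = 0.04,
) -> PUL | None:
    """Plant a conserved / structurally distinct / absent variant of a PUL.

    conserved: every ORF mutated to >90% identity, order preserved.
    structurally_distinct: exactly one structural defect (a CAZyme or a
    SusC/SusD deleted or fragmented, or an extra ORF inserted), recorded
    in the returned PUL's provenance.
    absent: returns None.
    """
    if mode not in PUL_MODES:
        raise InvalidParameterError(f"unknown PUL variant mode: {mode!r}")
    has_pair = any(
        {a.role_class, b.role_class} == {ROLE_SUSC, ROLE_SUSD}
        for a, b in zip(reference_pul.orfs, reference_pul.orfs[1:])
    )
    has_caz = any(o.role_class.startswith("CAZyme") for o in reference_pul.orfs)
    if not (has_pair and has_caz):
        raise InvalidParameterError("reference PUL needs an adjacent SusC/SusD pair and a CAZyme")
    if mode == "absent":
        return None
    rng = substream(seed, f"pul.variant.{reference_pul.pul_id}.{mode}")

    def mutated(o: ORFRecord, pos: int, seq: str | None = None) -> ORFRecord:
        return ORFRecord(
            genome=genome,
            contig=contig,
            position=pos,
            strand=o.strand,
            protein=seq if seq is not None else _mutate(rng, o.protein, mutation_rate),
            role_class=o.role_class,
        )

    if mode == "conserved":
        orfs = [mutated(o, start_position + i) for i, o in enumerate(reference_pul.orfs)]
        return PUL(
            pul_id=f"{genome}:{reference_pul.pul_id}:conserved",
            genome=genome,
            orfs=orfs,
            provenance={"mode": "conserved", "source": reference_pul.pul_id},
        )

    # structurally distinct: one defect among {delete CAZyme, delete SusC/SusD,
    # fragment a CAZyme, insert extra ORF}
    targets = [
        i for i, o in enumerate(reference_pul.orfs)
        if o.role_class.startswith("CAZyme") or o.role_class in (ROLE_SUSC, ROLE_SUSD)
    ]
    defect = ("delete", "fragment", "insert")[int(rng.integers(3))]
    orfs: list[ORFRecord] = []
    pos = start_position
    if defect == "insert":
        insert_at = int(rng.integers(1, len(reference_pul.orfs)))
        prov = {"mode": mode, "defect": "extra ORF inserted", "index": insert_at}
        for i, o in enumerate(reference_pul.orfs):
            if i == insert_at:
                orfs.append(
                    ORFRecord(genome, contig, pos, "+", _random_protein(rng, 200), "other")
                )
                pos += 1
            orfs.append(mutated(o, pos))
            pos += 1
    else:
        target = int(targets[int(rng.integers(len(targets)))])
        role = reference_pul.orfs[target].role_class
        prov = {"mode": mode, "defect": f"{defect} {role}", "index": target}
        for i, o in enumerate(reference_pul.orfs):
            if i != target:
                orfs.append(mutated(o, pos))
                pos += 1
            elif defect == "fragment":
                seq = _mutate(rng, o.protein, mutation_rate)
                cut = int(rng.integers(int(0.35 * len(seq)), int(0.65 * len(seq))))
                orfs.append(mutated(o, pos, seq[:cut]))
                orfs.append(mutated(o, pos + 1, seq[cut:]))
                pos += 2
            # defect == "delete": skip the target entirely
    return PUL(
        pul_id=f"{genome}:{reference_pul.pul_id}:distinct",
        genome=genome,
        orfs=orfs,
        provenance=prov,
    )


def embed_pul_in_genome(
    pul_orfs: Sequence[ORFRecord],
    seed: int,
    n_flanking: int = 6,
) -> list[ORFRecord]:
    """Surround planted PUL ORFs with unrelated 'other' ORFs on both sides."""
    if not pul_orfs:
        return []
    rng = substream(seed, "pul.embed")
    genome = pul_orfs[0].genome
    contig = pul_orfs[0].contig
    first = min(o.position for o in pul_orfs)
    last = max(o.position for o in pul_orfs)
    flank = []
    for i in range(n_flanking):
        flank.append(
            ORFRecord(genome, contig, first - n_flanking + i, "+",
                      _random_protein(rng, int(rng.integers(120, 240))), "other")
        )
        flank.append(
            ORFRecord(genome, contig, last + 1 + i, "+",
                      _random_protein(rng, int(rng.integers(120, 240))), "other")
        )
    return sorted(list(pul_orfs) + flank, key=lambda o: o.position)
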