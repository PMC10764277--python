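"""End-to-end orchestration: simulate -> annotate -> phenotype -> associate
-> enrich -> pul, with a machine-readable run report.

The run is driven by a validated configuration (unknown keys rejected), is
bit-reproducible for a fixed seed, writes every stage product as plain-text
tables with SHA-256 checksums, and — because the inputs are synthetic with
known truth — reports recovery metrics: consensus-phenotype accuracy,
planted-effect recovery, enrichment detection of planted sets, PUL category
accuracy and the conservation-association correlation.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import annotate, assoc, enrich, io, phenotype, pul, synthdata
from ._rand import substream
from .errors import InvalidConfigError

INCOMPLETE_MARKER = "INCOMPLETE"


@dataclass
class RunConfig:
    """Pipeline parameters; thresholds default to the study's printed values."""

    # scaled-down default study size (kept modest so a full run is quick)
    simulation: dict = field(default_factory=dict)
    n_mags: int = 10
    min_tpm: float = 5.0
    tpm_prevalence: float = 0.40
    min_cpm: float = 5.0
    cpm_prevalence: float = 0.35
    dna_floor_tpm: float = 0.5
    set_floor: int = 10
    mag_set_floor: int = 3
    q_association: float = 0.05
    q_enrichment: float = 0.1
    min_identity: float = 0.90
    max_mash_distance: float = 0.1
    n_perm: int = 2000
    n_trees: int = 100
    n_reference_puls: int = 6
    n_pul_genomes: int = 8
    stages: tuple[str, ...] = ("simulate", "annotate", "phenotype", "associate", "enrich", "pul")

    _KNOWN_STAGES = ("simulate", "annotate", "phenotype", "associate", "enrich", "pul")

    @classmethod
    def from_dict(cls, payload: dict) -> "RunConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(payload) - known
        if unknown:
            raise InvalidConfigError(f"unknown configuration key(s): {sorted(unknown)}")
        cfg = cls(**payload)
        sim_known = {f.name for f in dataclasses.fields(synthdata.SimulationConfig)}
        sim_unknown = set(cfg.simulation) - sim_known
        if sim_unknown:
            raise InvalidConfigError(f"unknown simulation key(s): {sorted(sim_unknown)}")
        bad = [s for s in cfg.stages if s not in cls._KNOWN_STAGES]
        if bad:
            raise InvalidConfigError(f"unknown stage(s): {bad}")
        return cfg

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        payload = yaml.safe_load(Path(path).read_text()) or {}
        if not isinstance(payload, dict):
            raise InvalidConfigError("run configuration must be a mapping")
        return cls.from_dict(payload)

    def resolved(self) -> dict:
        out = dataclasses.asdict(self)
        out["stages"] = list(self.stages)
        return out


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _simulation_config(config: RunConfig, seed: int) -> synthdata.SimulationConfig:
    defaults = dict(
        n_ref_genomes=30, n_phenotypes=12, n_participants=30,
        timepoints=(0.0, 4.0, 8.0, 12.0),
    )
    defaults.update(config.simulation)
    defaults["seed"] = seed
    return synthdata.SimulationConfig(**defaults)


def run_end_to_end(
    config: RunConfig,
    outdir: str | Path,
    seed: int = 0,
    force: bool = False,
) -> dict:
    """Run every enabled stage, write products + report.json, return the report.

    Re-running with unchanged config and seed is a no-op (the existing
    report is returned) unless ``force`` is set. A partial run leaves an
    INCOMPLETE marker in the output directory.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    resolved = config.resolved()
    run_key = hashlib.sha256(
        json.dumps({"config": resolved, "seed": seed}, sort_keys=True).encode()
    ).hexdigest()
    report_path = outdir / "report.json"
    if report_path.exists() and not force and not (outdir / INCOMPLETE_MARKER).exists():
        previous = json.loads(report_path.read_text())
        if previous.get("run_key") == run_key:
            previous["skipped"] = True
            return previous

    marker = outdir / INCOMPLETE_MARKER
    marker.write_text("run in progress\n")
    files: dict[str, str] = {}
    report: dict = {"run_key": run_key, "seed": seed, "config": resolved, "stages": {}}

    def emit(name: str, writer) -> None:
        path = outdir / name
        writer(path)
        files[name] = _sha256(path)

    stage_order = [s for s in config._KNOWN_STAGES if s in config.stages]
    # fail fast: every enabled stage must have its producer stages enabled
    for stage in stage_order:
        missing = [dep for dep in _STAGE_DEPENDS[stage] if dep not in stage_order]
        if missing:
            marker.unlink(missing_ok=True)
            raise InvalidConfigError(
                f"stage '{stage}' is enabled but depends on disabled stage(s): {missing}"
            )

    sim_cfg = _simulation_config(config, seed)
    pangenome = synthdata.generate_reference_collection(sim_cfg)
    cohort = synthdata.simulate_cohort(pangenome, sim_cfg)
    state: dict = {"pangenome": pangenome, "cohort": cohort, "sim_cfg": sim_cfg}

    runners = {
        "simulate": _stage_simulate,
        "annotate": _stage_annotate,
        "phenotype": _stage_phenotype,
        "associate": _stage_associate,
        "enrich": _stage_enrich,
        "pul": _stage_pul,
    }
    for stage in stage_order:
        report["stages"][stage] = runners[stage](config, state, seed, emit)

    report["files"] = dict(sorted(files.items()))
    report_path.write_text(json.dumps(report, indent=1, sort_keys=True))
    marker.unlink(missing_ok=True)
    return report


_STAGE_DEPENDS = {
    "simulate": (),
    "annotate": (),
    "phenotype": ("annotate",),
    "associate": (),
    "enrich": ("associate",),
    "pul": (),
}


def _stage_simulate(config: RunConfig, state: dict, seed: int, emit) -> dict:
    pangenome: synthdata.ReferencePangenome = state["pangenome"]
    cohort: synthdata.SyntheticCohort = state["cohort"]
    emit("dna_tpm.tsv", lambda p: io.write_counts_tsv(cohort.dna_tpm.round(4), p))
    emit("rna_counts.tsv", lambda p: io.write_counts_tsv(cohort.transcript_counts, p))
    emit("meta.tsv", lambda p: io.write_meta_tsv(cohort.meta.round(6), p))
    emit("pathways.json", lambda p: io.write_pathway_json(pangenome.pathway_definitions, p))
    emit("ref_bpm.tsv", lambda p: io.write_bpm_tsv(pangenome.truth_bpm, p))
    emit("truth.json", lambda p: io.write_truth_json(cohort.truth_effects, p))
    return {
        "n_reference_genomes": len(pangenome.genomes),
        "n_phenotypes": pangenome.truth_bpm.shape[1],
        "n_samples": cohort.meta.shape[0],
        "n_transcripts": cohort.transcript_counts.shape[0],
    }


def _stage_annotate(config: RunConfig, state: dict, seed: int, emit) -> dict:
    pangenome: synthdata.ReferencePangenome = state["pangenome"]
    sim_cfg: synthdata.SimulationConfig = state["sim_cfg"]
    genome_ids = sorted(pangenome.genomes)
    step = max(1, len(genome_ids) // config.n_mags)
    picks = genome_ids[::step][: config.n_mags]
    refmap = synthdata.reference_role_map(pangenome)
    annotations_by_mag: dict[str, list] = {}
    mags: dict[str, synthdata.GenomeRecord] = {}
    correct = total = 0
    frames = []
    for i, g in enumerate(picks):
        mag = synthdata.degrade_genome_to_mag(
            pangenome.genomes[g],
            sim_cfg.mag_completeness,
            sim_cfg.mag_contamination,
            sim_cfg.fragmentation_rate,
            seed=seed * 1000 + i,
            contaminant_pool=synthdata.contaminant_pool(pangenome, g),
        )
        mags[mag.genome_id] = mag
        hits = synthdata.simulate_alignment_hits(pangenome, mag, seed=seed * 1000 + i)
        anns = annotate.annotate_genome(
            [p.protein_id for p in mag.proteins], hits, refmap
        )
        annotations_by_mag[mag.genome_id] = anns
        truth_role = {p.protein_id: p.role for p in mag.proteins}
        called = {a.query_id: a.role for a in anns if a.role is not None}
        for pid, role in truth_role.items():
            if role is None:
                continue
            total += 1
            correct += int(called.get(pid) == role)
        frame = annotate.annotations_to_frame(anns)
        frame.insert(0, "genome", mag.genome_id)
        frames.append(frame)
    combined = pd.concat(frames, ignore_index=True)
    emit("annotations.tsv", lambda p: combined.to_csv(p, sep="\t", index=False))
    state["mags"] = mags
    state["annotations_by_mag"] = annotations_by_mag
    state["mag_sources"] = dict(zip([m for m in mags], picks))
    roles = pangenome.all_roles() + sorted(
        {r for r in pangenome.family_roles.values() if r and r.startswith("housekeeping")}
    )
    mag_roles = annotate.role_presence_from_annotations(annotations_by_mag, roles=roles)
    state["mag_roles"] = mag_roles
    emit("mag_roles.tsv", lambda p: io.write_bpm_tsv(mag_roles, p))
    return {
        "n_mags": len(mags),
        "role_recovery": round(correct / total, 4) if total else np.nan,
    }


def _stage_phenotype(config: RunConfig, state: dict, seed: int, emit) -> dict:
    pangenome: synthdata.ReferencePangenome = state["pangenome"]
    mag_roles: pd.DataFrame = state["mag_roles"]
    roles = list(mag_roles.columns)
    ref_roles = pd.DataFrame(
        [[int(r in pangenome.genomes[g].role_set()) for r in roles] for g in sorted(pangenome.genomes)],
        index=sorted(pangenome.genomes), columns=roles,
    )
    mag_seqs = {m: [p.sequence for p in rec.proteins] for m, rec in state["mags"].items()}
    ref_seqs = {g: [p.sequence for p in pangenome.genomes[g].proteins] for g in sorted(pangenome.genomes)}
    bpm, calls, rep = phenotype.predict_phenotypes(
        ref_roles, pangenome.truth_bpm, mag_roles, pangenome.pathway_definitions,
        mag_sequences=mag_seqs, ref_sequences=ref_seqs, seed=seed,
        n_trees=config.n_trees, max_distance=config.max_mash_distance,
    )
    emit("consensus_bpm.tsv", lambda p: io.write_bpm_tsv(bpm, p))
    sources = state["mag_sources"]
    truth = pangenome.truth_bpm.loc[[sources[m] for m in bpm.index]].set_axis(bpm.index)
    acc = float((bpm.to_numpy() == truth.to_numpy()).mean())
    rule_acc = float((rep["rule_preds"].to_numpy() == truth.to_numpy()).mean())
    confidence = pd.Series([c.confidence for c in calls]).value_counts().to_dict()
    state["consensus_bpm"] = bpm
    return {
        "consensus_accuracy": round(acc, 4),
        "rule_accuracy": round(rule_acc, 4),
        "n_neighbor_groups": rep["n_neighbor_groups"],
        "confidence_counts": confidence,
    }


def _stage_associate(config: RunConfig, state: dict, seed: int, emit) -> dict:
    cohort: synthdata.SyntheticCohort = state["cohort"]
    kept = assoc.filter_mags_tpm(cohort.dna_tpm, config.min_tpm, config.tpm_prevalence)
    pseudo_counts = cohort.dna_tpm.loc[kept].mul(100).round().astype(int)
    vst = assoc.variance_stabilize(pseudo_counts)
    wlz_table = assoc.associate_features(vst, cohort.meta, mode="wlz")
    emit("assoc_wlz.tsv", lambda p: io.write_table_tsv(wlz_table.round(6), p))
    arms = state["sim_cfg"].arms
    gt_table = assoc.associate_features(
        vst, cohort.meta, mode="group_time", group_levels=[arms[1], arms[0]],
    )  # control coded 0, treatment 1: positive beta3 = faster change on treatment
    emit("assoc_group_time.tsv", lambda p: io.write_table_tsv(gt_table.round(6), p))
    truth = cohort.truth_effects["wlz_beta1"]
    planted = [m for m, b in truth.items() if b != 0 and m in wlz_table.index]
    sign_ok = sum(
        int(np.sign(wlz_table.loc[m, "beta1"]) == np.sign(truth[m])) for m in planted
    )
    sig = wlz_table[wlz_table["q"] < config.q_association]
    state["assoc_wlz"] = wlz_table
    state["group_time"] = gt_table
    state["vst"] = vst
    return {
        "n_mags_after_filter": len(kept),
        "n_significant": int(len(sig)),
        "planted_effect_sign_recovery": round(sign_ok / len(planted), 4) if planted else np.nan,
    }


def _stage_enrich(config: RunConfig, state: dict, seed: int, emit) -> dict:
    cohort: synthdata.SyntheticCohort = state["cohort"]
    pangenome: synthdata.ReferencePangenome = state["pangenome"]
    wlz_table: pd.DataFrame = state["assoc_wlz"]
    gt_table: pd.DataFrame = state["group_time"]

    # (a) MAG-set GSEA: MAGs ranked by the treatment x week t-statistic,
    # sets = significantly positively / negatively WLZ-associated MAGs
    mag_sets = enrich.mag_association_sets(wlz_table, q_cutoff=config.q_association)
    ranked_mags = assoc.build_ranked_list(gt_table, metric_col="t3")
    mag_gsea = enrich.gsea_preranked(
        ranked_mags, mag_sets, n_perm=config.n_perm, seed=seed,
        min_size=config.mag_set_floor,
    )
    emit("gsea_mag_sets.tsv", lambda p: io.write_table_tsv(mag_gsea, p, index_label="set"))
    pos = mag_gsea.loc["wlz_positive"] if "wlz_positive" in mag_gsea.index else None
    positive_detected = bool(
        pos is not None and pd.isna(pos["skipped"]) and pos["NES"] > 0
        and pos["q"] < config.q_enrichment
    )

    # (b) transcript pathway GSEA after NB differential expression
    zeroed = assoc.zero_low_dna_transcripts(
        cohort.transcript_counts, cohort.dna_tpm, cohort.gene_to_mag,
        floor=config.dna_floor_tpm,
    )
    kept = assoc.cpm_filter(zeroed, config.min_cpm, config.cpm_prevalence)
    counts = zeroed.loc[kept]
    factors = assoc.tmm_factors(counts)
    arms = state["sim_cfg"].arms
    de = assoc.nb_differential_expression(
        counts, cohort.meta, norm_factors=factors, test="group",
        group_levels=[arms[1], arms[0]],
    )
    ranked = assoc.build_ranked_list(de)
    emit("ranked_transcripts.tsv", lambda p: io.write_ranked_tsv(ranked.round(6), p))
    gene_roles = {}
    for m, rec in pangenome.genomes.items():
        for prot in rec.proteins:
            if prot.role is not None:
                gene_roles[prot.protein_id] = prot.role
    sets = enrich.pathway_gene_sets(
        gene_roles, pangenome.pathway_definitions, universe=list(ranked.index)
    )
    pw_gsea = enrich.gsea_preranked(
        ranked, sets, n_perm=config.n_perm, seed=seed, min_size=config.set_floor,
    )
    emit("gsea_pathways.tsv", lambda p: io.write_table_tsv(pw_gsea, p, index_label="set"))
    planted_pw = cohort.truth_effects["de_group_pathway"]
    planted_detected = bool(
        planted_pw in pw_gsea.index
        and pd.isna(pw_gsea.loc[planted_pw, "skipped"])
        and pw_gsea.loc[planted_pw, "q"] < config.q_enrichment
    )
    le = []
    if planted_pw in pw_gsea.index and isinstance(pw_gsea.loc[planted_pw, "leading_edge"], str):
        le = [x for x in pw_gsea.loc[planted_pw, "leading_edge"].split(",") if x]
    return {
        "mag_positive_set_detected": positive_detected,
        "n_transcripts_tested": int(len(kept)),
        "planted_pathway": planted_pw,
        "planted_pathway_detected": planted_detected,
        "n_leading_edge_planted": len(le),
        "n_pathway_sets_scored": int(pw_gsea["skipped"].isna().sum()),
    }


def _stage_pul(config: RunConfig, state: dict, seed: int, emit) -> dict:
    """Plant PUL variants with conservation decaying alongside the planted
    WLZ association, classify them, and correlate profile distance vs beta1."""
    rng = substream(seed, "pipeline.pul")
    ref_puls = [
        synthdata.make_reference_pul(seed=seed * 37 + i, genome="REF")
        for i in range(config.n_reference_puls)
    ]
    n_genomes = config.n_pul_genomes
    beta1 = {}
    profiles = {}
    correct = total = 0
    call_rows = []
    for gi in range(n_genomes):
        genome = f"PULG{gi:02d}"
        # conservation tier: early genomes keep most PULs conserved,
        # later genomes progressively lose them
        n_cons = max(0, config.n_reference_puls - gi)
        planted_beta = 0.55 - 0.12 * gi + float(rng.normal(0, 0.02))
        beta1[genome] = planted_beta
        calls = []
        orfs_all = []
        for pi, rp in enumerate(ref_puls):
            if pi < n_cons:
                mode = "conserved"
            elif pi < n_cons + 2:
                mode = "structurally_distinct"
            else:
                mode = "absent"
            variant = synthdata.plant_pul_variants(
                rp, mode, seed=seed * 101 + gi * 17 + pi, genome=genome,
                contig=f"c{pi}", start_position=20,
            )
            orfs = (
                synthdata.embed_pul_in_genome(variant.orfs, seed=seed + gi * 7 + pi)
                if variant is not None else []
            )
            orfs_all.extend(orfs)
            call = pul.classify_conservation(rp, orfs, min_identity=config.min_identity)
            call = pul.ConservationCall(rp.pul_id, genome, call.category, call.evidence)
            calls.append(call)
            total += 1
            correct += int(call.category == mode)
            call_rows.append({"genome": genome, "ref_pul": rp.pul_id,
                              "planted": mode, "called": call.category})
        profiles[genome] = pul.encode_profile(calls, [rp.pul_id for rp in ref_puls])
    matrix = pul.conservation_matrix(profiles)
    emit("pul_conservation.tsv", lambda p: io.write_table_tsv(matrix, p, index_label="genome"))
    emit("pul_calls.tsv", lambda p: pd.DataFrame(call_rows).to_csv(p, sep="\t", index=False))
    r, pval = pul.correlate_profiles_with_association(profiles, beta1)
    emit(
        "pul_correlation.json",
        lambda p: Path(p).write_text(json.dumps(
            {"pearson_r": round(r, 6), "p": round(pval, 8), "n": n_genomes},
            indent=1, sort_keys=True,
        )),
    )
    return {
        "category_accuracy": round(correct / total, 4),
        "pearson_r": round(r, 4),
        "pearson_p": round(pval, 6),
    }
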