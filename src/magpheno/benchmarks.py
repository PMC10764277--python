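"""Recovery benchmarks on generator truth.

Each function regenerates synthetic inputs from a seed, runs one pipeline
capability end to end and measures recovery against the planted ground
truth. They back both the validation test suite and the reproduction
script, so the numbers those report are always recomputed from scratch.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from . import annotate, assoc, phenotype, pul, synthdata
from ._rand import substream

#: two-point hyperparameter grid used for the scaled consensus benchmark
FAST_RF_GRID = (
    {"max_features": "sqrt", "min_samples_leaf": 1},
    {"max_features": 0.333, "min_samples_leaf": 1},
)


def annotation_recovery(
    seed: int,
    n_proteins: int = 100,
    outgroup_fraction: float = 0.1,
    boundary_tolerance: int = 5,
) -> dict:
    """Domain-splitting annotation on two-domain fixtures with a >=30-point
    identity separation between true and decoy hits.

    Returns per-protein role recovery, boundary recovery (within
    ``boundary_tolerance`` residues) and the outgroup abstention rate.
    """
    seqs, hits, refmap, truth = synthdata.simulate_multidomain_fixture(
        n_proteins, seed=seed, outgroup_fraction=outgroup_fraction
    )
    anns = annotate.annotate_genome(seqs, hits, refmap)
    by_query: dict[str, list] = {}
    for a in anns:
        by_query.setdefault(a.query_id, []).append(a)
    role_ok = boundary_ok = annotatable = 0
    outgroup_ok = outgroup_n = 0
    for qid, doms in truth.items():
        got = by_query[qid]
        if doms[0][2] is None:
            outgroup_n += 1
            outgroup_ok += int(all(a.role is None for a in got))
            continue
        annotatable += 1
        planted_roles = {r for _, _, r in doms}
        role_ok += int(planted_roles <= {a.role for a in got})
        got_iv = sorted((a.start, a.end) for a in got)
        exp_iv = sorted((s, e) for s, e, _ in doms)
        boundary_ok += int(
            len(got_iv) == len(exp_iv)
            and all(
                abs(g[0] - e[0]) <= boundary_tolerance
                and abs(g[1] - e[1]) <= boundary_tolerance
                for g, e in zip(got_iv, exp_iv)
            )
        )
    return {
        "role_recovery": role_ok / annotatable,
        "boundary_recovery": boundary_ok / annotatable,
        "outgroup_abstention": outgroup_ok / outgroup_n if outgroup_n else np.nan,
        "n_proteins": n_proteins,
    }


def kde_threshold_separation(
    seed: int,
    n_per_mode: int = 50,
    high_mode: float = 95.0,
    low_mode: float = 55.0,
) -> dict:
    """Planted bimodal identity mixture: the threshold must sit between the
    modes and remove the low mode; unimodal input must keep everything."""
    rng = substream(seed, "benchmark.kde")
    ids = np.concatenate([
        np.clip(rng.normal(high_mode, 1.5, n_per_mode), 0, 100),
        rng.normal(low_mode, 3.0, n_per_mode),
    ])
    threshold = annotate.identity_threshold(ids)
    low = ids[ids < (high_mode + low_mode) / 2]
    unimodal = annotate.identity_threshold(rng.normal(88.0, 2.0, 100))
    return {
        "threshold": threshold,
        "between_modes": bool(low_mode + 5 < threshold < high_mode - 5),
        "low_mode_removed": float(np.mean(low < threshold)),
        "unimodal_threshold": unimodal,
    }


def consensus_recovery(
    seed: int,
    n_ref_genomes: int = 60,
    n_phenotypes: int = 20,
    completeness: float = 0.9,
    n_mags: int = 12,
    n_trees: int = 100,
    grid=FAST_RF_GRID,
) -> dict:
    """Three-strategy consensus phenotyping of MAGs degraded from the
    reference collection; accuracy measured against the planted BPM."""
    cfg = synthdata.SimulationConfig(
        n_ref_genomes=n_ref_genomes, n_phenotypes=n_phenotypes, seed=seed
    )
    pangenome = synthdata.generate_reference_collection(cfg)
    roles = pangenome.all_roles()
    ref_roles = pd.DataFrame(
        [[int(r in pangenome.genomes[g].role_set()) for r in roles]
         for g in sorted(pangenome.genomes)],
        index=sorted(pangenome.genomes), columns=roles,
    )
    genome_ids = sorted(pangenome.genomes)
    step = max(1, len(genome_ids) // n_mags)
    picks = genome_ids[::step][:n_mags]
    mags = {}
    for i, g in enumerate(picks):
        mags[g] = synthdata.degrade_genome_to_mag(
            pangenome.genomes[g], completeness, cfg.mag_contamination,
            cfg.fragmentation_rate, seed=seed * 1000 + i,
            contaminant_pool=synthdata.contaminant_pool(pangenome, g),
        )
    mag_roles = pd.DataFrame(
        [[int(r in m.role_set()) for r in roles] for m in mags.values()],
        index=[m.genome_id for m in mags.values()], columns=roles,
    )
    mag_seqs = {m.genome_id: [p.sequence for p in m.proteins] for m in mags.values()}
    ref_seqs = {g: [p.sequence for p in pangenome.genomes[g].proteins]
                for g in genome_ids}
    bpm, _, rep = phenotype.predict_phenotypes(
        ref_roles, pangenome.truth_bpm, mag_roles, pangenome.pathway_definitions,
        mag_sequences=mag_seqs, ref_sequences=ref_seqs, seed=seed,
        n_trees=n_trees, grid=grid,
    )
    truth = pangenome.truth_bpm.loc[picks].set_axis(bpm.index)
    return {
        "consensus_accuracy": float((bpm.to_numpy() == truth.to_numpy()).mean()),
        "rule_accuracy": float((rep["rule_preds"].to_numpy() == truth.to_numpy()).mean()),
        "ml_accuracy": float((rep["ml_preds"].to_numpy() == truth.to_numpy()).mean()),
        "n_calls": int(bpm.size),
    }


def lmm_beta_recovery(seed: int, n_reps: int = 100, beta1: float = 0.5) -> dict:
    """Planted-slope recovery: WLZ ~ beta1 x + week + (1|PID), 40
    participants x 5 timepoints per replicate."""
    estimates = []
    for rep in range(n_reps):
        rng = substream(seed, f"benchmark.lmm.{rep}")
        n_part, weeks = 40, np.array([0.0, 4, 8, 12, 16])
        pid = np.repeat(np.arange(n_part), len(weeks))
        week = np.tile(weeks, n_part)
        x = rng.normal(size=len(pid))
        u = rng.normal(0, 0.5, n_part)
        y = u[pid] + beta1 * x + 0.01 * week + rng.normal(0, 0.3, len(pid))
        fit = assoc.fit_lmm(
            pd.Series(y), pd.DataFrame({"x": x, "week": week}),
            pd.Series(pid.astype(str)),
        )
        estimates.append(fit["x"]["estimate"])
    return {"mean_estimate": float(np.mean(estimates)), "n_reps": n_reps,
            "planted": beta1}


def lmm_type_i_error(seed: int, n_reps: int = 500, alpha: float = 0.05) -> dict:
    """Null rejection rate of the beta1 test at nominal alpha."""
    rejections = 0
    for rep in range(n_reps):
        rng = substream(seed, f"benchmark.null.{rep}")
        n_part, nt = 20, 5
        pid = np.repeat(np.arange(n_part), nt)
        x = rng.normal(size=n_part * nt)
        u = rng.normal(0, 0.5, n_part)
        y = u[pid] + rng.normal(0, 0.5, n_part * nt)
        fit = assoc.fit_lmm(pd.Series(y), pd.DataFrame({"x": x}),
                            pd.Series(pid.astype(str)))
        rejections += int(fit["x"]["p"] < alpha)
    return {"type_i_error": rejections / n_reps, "n_reps": n_reps}


def lmm_ols_agreement(seed: int) -> dict:
    """Max |LMM - OLS| coefficient gap on a zero-group-variance fixture."""
    import statsmodels.api as sm

    rng = substream(seed, "benchmark.ols")
    n = 80
    x = rng.normal(size=n)
    y = 0.3 + 0.5 * x + rng.normal(0, 0.4, n)
    fixed = pd.DataFrame({"x": x})
    fit = assoc.fit_lmm(pd.Series(y), fixed, pd.Series([f"P{i % 20}" for i in range(n)]))
    ols = sm.OLS(y, sm.add_constant(fixed)).fit()
    gap = max(abs(fit["x"]["estimate"] - ols.params["x"]),
              abs(fit["const"]["estimate"] - ols.params["const"]))
    return {"max_abs_gap": float(gap)}


def pul_decay_correlation(
    seed: int,
    n_puls: int = 4,
    n_genomes: int = 6,
) -> dict:
    """Plant conservation decaying monotonically with the planted growth
    association, classify the variants and correlate distance vs beta1."""
    rng = substream(seed, "benchmark.puldecay")
    refs = [synthdata.make_reference_pul(seed=seed * 31 + i, n_cazymes=2)
            for i in range(n_puls)]
    beta1, profiles = {}, {}
    correct = total = 0
    for gi in range(n_genomes):
        genome = f"Q{gi}"
        n_cons = max(0, n_puls - gi)
        beta1[genome] = 0.55 - 0.1 * gi + float(rng.normal(0, 0.02))
        calls = []
        for pi, rp in enumerate(refs):
            mode = ("conserved" if pi < n_cons
                    else "structurally_distinct" if pi < n_cons + 1 else "absent")
            variant = synthdata.plant_pul_variants(
                rp, mode, seed=seed * 97 + gi * 13 + pi, genome=genome, contig=f"c{pi}"
            )
            orfs = (
                synthdata.embed_pul_in_genome(variant.orfs, seed=seed + gi + pi,
                                              n_flanking=3)
                if variant is not None else []
            )
            call = pul.classify_conservation(rp, orfs)
            total += 1
            correct += int(call.category == mode)
            calls.append(pul.ConservationCall(rp.pul_id, genome, call.category,
                                              call.evidence))
        profiles[genome] = pul.encode_profile(calls, [rp.pul_id for rp in refs])
    r, p = pul.correlate_profiles_with_association(profiles, beta1)
    return {"pearson_r": r, "pearson_p": p, "category_accuracy": correct / total}
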