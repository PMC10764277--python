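import numpy as np
import pandas as pd
import pytest

from magpheno import synthdata as sd


@pytest.fixture(scope="session")
def small_config():
    return sd.SimulationConfig(
        n_ref_genomes=20, n_phenotypes=8, clade_size=5, n_participants=12,
        timepoints=(0.0, 4.0, 8.0, 12.0), seed=11,
    )


@pytest.fixture(scope="session")
def pangenome(small_config):
    return sd.generate_reference_collection(small_config)


@pytest.fixture(scope="session")
def cohort(small_config, pangenome):
    return sd.simulate_cohort(pangenome, small_config)


@pytest.fixture(scope="session")
def role_matrix(pangenome):
    roles = pangenome.all_roles()
    return pd.DataFrame(
        [[int(r in pangenome.genomes[g].role_set()) for r in roles]
         for g in sorted(pangenome.genomes)],
        index=sorted(pangenome.genomes), columns=roles,
    )


def genome_role_matrix(pangenome, genomes, roles):
    """Role presence matrix for arbitrary genome records."""
    return pd.DataFrame(
        [[int(r in g.role_set()) for r in roles] for g in genomes],
        index=[g.genome_id for g in genomes], columns=roles,
    )


@pytest.fixture(scope="session")
def longitudinal_meta():
    """Balanced two-arm longitudinal design, 20 participants x 4 weeks."""
    n_part, weeks = 20, [0.0, 4.0, 8.0, 12.0]
    pids = [f"P{i:02d}" for i in range(n_part)]
    rows = []
    for i, pid in enumerate(pids):
        for w in weeks:
            rows.append({"sample_id": f"{pid}_w{int(w)}", "PID": pid,
                         "study_week": w, "arm": "MDCF-2" if i % 2 == 0 else "RUSF"})
    return pd.DataFrame(rows).set_index("sample_id")
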