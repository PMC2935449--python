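import pytest

from dubcensus.core import PSM
from dubcensus.inference import build_target_decoy_db
from dubcensus.synthetic import (
    SimConfig,
    generate_interactome,
    generate_proteome,
    simulate_runset,
)


@pytest.fixture(scope="session")
def small_config():
    return SimConfig(
        n_target_proteins=120,
        n_contaminants=5,
        n_baits=3,
        background_pool_size=15,
        seed=7,
    )


@pytest.fixture(scope="session")
def small_world(small_config):
    """Proteome + ground truth + searched (target-decoy) database + runs."""
    db = generate_proteome(small_config)
    truth = generate_interactome(db, small_config)
    searched = build_target_decoy_db(db.targets, db.contaminants)
    runs = simulate_runset(truth, searched, small_config)
    return db, truth, searched, runs


def make_psm(peptide="PEPTIDE", accessions=("P1",), score=3.0, interpretations=1,
             run_id="r1", spectrum_id="s1", charge=2):
    return PSM(
        run_id=run_id,
        spectrum_id=spectrum_id,
        peptide=peptide,
        charge=charge,
        score=score,
        interpretations=interpretations,
        accessions=frozenset(accessions),
    )
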