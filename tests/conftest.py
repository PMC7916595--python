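import numpy as np
import pandas as pd
import pytest

from complexome.quant import condition_profiles, map_channels_to_conditions, protein_ratio
from complexome.scenario import (
    AssemblyForm,
    GelModel,
    NoiseModel,
    ScenarioConfig,
    build_default_scenario,
    simulate_evidence,
)


@pytest.fixture(scope="session")
def default_scenario():
    return build_default_scenario()


@pytest.fixture(scope="session")
def default_run(default_scenario):
    """One simulated default-scenario dataset with profiles and ratios."""
    sc = default_scenario
    evidence = simulate_evidence(sc, seed=1)
    mapped = map_channels_to_conditions(evidence, sc.swap_map(), sc.conditions)
    profiles = condition_profiles(mapped, sc.conditions, sc.gel.n_slices)
    ratios = {
        pid: protein_ratio(pid, mapped, sc.conditions)
        for pid in sorted(mapped["protein_id"].unique())
    }
    return {
        "scenario": sc,
        "evidence": evidence,
        "mapped": mapped,
        "profiles": profiles,
        "ratios": ratios,
    }


def make_noise_free_scenario(**overrides):
    """Tiny deterministic scenario: no noise, no censoring, 1 peptide/protein."""
    defaults = dict(
        conditions=("wt", "ko"),
        forms=(
            AssemblyForm("dimer", 500.0, {"P1": 2, "P2": 1}, {"wt": 10.0, "ko": 10.0}),
            AssemblyForm("monomer", 100.0, {"P1": 1}, {"wt": 4.0, "ko": 1.0}),
            AssemblyForm("pool", 50.0, {"P3": 1}, {"wt": 6.0, "ko": 6.0}),
        ),
        gel=GelModel(n_slices=32),
        replicates=("wt", "ko"),
        peptides_per_protein=(1, 1),
        noise=NoiseModel(response_sd=0.0, measurement_sd=0.0, detection_floor=0.0),
        seed=7,
    )
    defaults.update(overrides)
    return ScenarioConfig(**defaults)


@pytest.fixture()
def noise_free_scenario():
    return make_noise_free_scenario()


def evidence_frame(rows):
    """Build a small evidence table from (exp, rep, slice, prot, pep, chan, inten) tuples."""
    return pd.DataFrame(
        rows,
        columns=[
            "experiment_id", "replicate", "slice_index", "protein_id",
            "peptide_sequence", "channel", "intensity",
        ],
    )


@pytest.fixture(scope="session")
def twenty_seed_ratios(default_scenario):
    """Protein ratios for 20 independent simulations of the default scenario."""
    sc = default_scenario
    out = []
    for seed in range(101, 121):
        ev = simulate_evidence(sc, seed=seed)
        mapped = map_channels_to_conditions(ev, sc.swap_map(), sc.conditions)
        ratios = {
            pid: protein_ratio(pid, mapped, sc.conditions)
            for pid in sorted(mapped["protein_id"].unique())
        }
        out.append(ratios)
    return out
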