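import numpy as np
import pandas as pd
import pytest

import allospot as a


@pytest.fixture(scope="session")
def toy_structure(tmp_path_factory):
    """A 60-residue-per-chain synthetic dimer and its parsed form."""
    synth = a.generate_structure(60, seed=2)
    path = tmp_path_factory.mktemp("pdb") / "toy.pdb"
    synth.to_pdb(path)
    return synth, a.load_dimer(path)


@pytest.fixture(scope="session")
def planted_scenario():
    hotspots = frozenset(range(10, 56, 5))
    return a.DmsScenario(n_positions=60, planted_hotspots=hotspots, seed=11)


@pytest.fixture(scope="session")
def planted_counts(planted_scenario):
    return a.generate_dms_counts(planted_scenario)


def make_count_table(variants):
    """Build a tidy count table from {(pos, wt, mut): {cond: [r1, r2, r3]}}."""
    rows = []
    for (pos, wt, mut), conds in variants.items():
        for cond, reps in conds.items():
            for rep, reads in enumerate(reps, start=1):
                rows.append((pos, wt, mut, 1, rep, cond, float(reads)))
    return pd.DataFrame(rows, columns=[
        "position", "wt_aa", "mut_aa", "sublibrary", "replicate", "condition",
        "reads",
    ])


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
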