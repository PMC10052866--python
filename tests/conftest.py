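import numpy as np
import pandas as pd
import pytest

from microdyn.tables import AbundanceTable


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(12345)


def make_table(values: dict, treatment="T") -> AbundanceTable:
    """Build an AbundanceTable from {replicate: days x taxa 2-D array-like}."""
    rows = []
    for rep, arr in values.items():
        arr = np.asarray(arr, dtype=float)
        for d in range(arr.shape[0]):
            for j in range(arr.shape[1]):
                rows.append((treatment, rep, d + 1, f"T{j:03d}", arr[d, j]))
    return AbundanceTable(
        pd.DataFrame(rows, columns=["treatment", "replicate", "day", "taxon_id", "abundance"])
    )


@pytest.fixture(scope="session")
def bistable_small():
    """Reduced bistable microcosm used across integration tests."""
    from microdyn.simulate import fixture_params, simulate_glv

    params = fixture_params("bistable", n_replicates=4, n_days=90)
    return simulate_glv(params, treatment="bistable")


def flip_day(table, treatment="bistable", replicate=1):
    """Day the invader guild (taxa 3-5) overtakes the resident guild (0-2)."""
    wide = table.wide(treatment, replicate)
    resident = wide[["T000", "T001", "T002"]].sum(axis=1)
    invader = wide[["T003", "T004", "T005"]].sum(axis=1)
    flipped = invader > resident
    return int(flipped.idxmax()) if flipped.any() else None


@pytest.fixture(scope="session")
def bistable_calibrated(bistable_small):
    """Detection-limited view of the bistable microcosm: multinomial reads
    with spike-ins, calibrated back to copy concentrations."""
    from microdyn.calibration import calibrate_reads
    from microdyn.simulate import SpikeInSet, simulate_reads

    reads = simulate_reads(bistable_small, SpikeInSet(), reads_per_sample=20_000, seed=21)
    table, _ = calibrate_reads(reads, min_presence=1)
    return table


@pytest.fixture(scope="session")
def chaotic_small():
    from microdyn.simulate import fixture_params, simulate_glv

    params = fixture_params("chaotic4", n_replicates=4, n_days=80)
    return simulate_glv(params, treatment="chaotic4")


@pytest.fixture(scope="session")
def stable_small():
    from microdyn.simulate import fixture_params, simulate_glv

    params = fixture_params("stable", n_replicates=4, n_days=70)
    return simulate_glv(params, treatment="stable")
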