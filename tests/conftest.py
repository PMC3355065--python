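import numpy as np
import pytest

from replitimer.signal_io import ProbeTable, ReplicateSet
from replitimer.synthetic import GenomeModel, OriginSpec, SimulationConfig


@pytest.fixture
def two_origin_genome():
    """One 200 kb chromosome, origins at 0 and 100 kb, fork 1 kb/min."""
    return GenomeModel(
        chromosomes=[("chrI", 200_000)],
        centromere_pos={"chrI": 50_000},
        origins=[
            OriginSpec("chrI", 0, 0.0),
            OriginSpec("chrI", 100_000, 10.0),
        ],
        fork_speed_v=1_000.0,
        s_duration_T=200.0,
    )


@pytest.fixture
def noise_free_cfg():
    return SimulationConfig(probe_spacing=500, n_cells=1, n_timepoints=200,
                            noise_sd=0.0, rng_seed=0)


def make_table(values_by_chrom, spacing=100, start=50):
    """ProbeTable on a uniform grid from per-chromosome value arrays."""
    data = {}
    for chrom, vals in values_by_chrom.items():
        vals = np.asarray(vals, float)
        pos = start + spacing * np.arange(vals.size, dtype=np.int64)
        data[chrom] = (pos, vals)
    return ProbeTable(data)


def make_replicates(values_by_chrom_list, condition="cond", spacing=100):
    return ReplicateSet(condition, [make_table(v, spacing=spacing)
                                    for v in values_by_chrom_list])
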