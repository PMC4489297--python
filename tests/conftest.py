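from pathlib import Path

import pytest

from grnkit.pipeline import BuildConfig
from grnkit.simulator import SimulationParams, SimulatedDataset, simulate_dataset


def make_build_config(dataset: SimulatedDataset, **overrides) -> BuildConfig:
    """Standard pipeline configuration over a simulated dataset with the
    permissive thresholds the planted effect sizes comfortably clear."""
    base = dict(
        center=dataset.truth.center,
        genes_path=dataset.genes,
        peaks_path=dataset.peaks,
        expression_path=dataset.expression,
        loops_path=dataset.loops,
        tracks=[
            (str(dataset.track_dhs), "DHS", "accessibility"),
            (str(dataset.track_h3k4me3), "H3K4me3", "active_mark"),
            (str(dataset.track_h3k27me3), "H3K27me3", "repressive_mark"),
        ],
        pwms_path=dataset.pwms,
        promoters_fasta=dataset.promoters,
        tf_list_path=dataset.tf_list,
        method="direct",
        min_abs_log2fc=0.5,
        max_stat=0.05,
        depth=1,
    )
    base.update(overrides)
    return BuildConfig(**base)


@pytest.fixture(scope="session")
def small_dataset(tmp_path_factory) -> SimulatedDataset:
    """A compact noiseless planted study for fast pipeline-level tests."""
    params = SimulationParams(
        n_genes=60, n_direct=12, fraction_loop_only=0.25,
        n_tf_among_direct=2, n_indirect_per_tf=4, fraction_accessible=0.5,
        seed=7,
    )
    return simulate_dataset(params, tmp_path_factory.mktemp("small_sim"))
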