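import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "repro", derandomize=True, deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("repro")

from gametophase.gametematrix import GameteMatrix, qc_sperm, select_reference_sperm
from gametophase.phasing import phase_pipeline
from gametophase.simdata import (
    SimConfig,
    simulate_donor,
    simulate_meiosis,
    simulate_sperm_calls,
)

#: suspicious-pair spacing scaled to the 10-Mb toy chromosomes (the 2-Mb
#: production default is sized for ~150-Mb chromosomes)
TOY_EVENT_SPACING_BP = 200_000


def make_matrix(states, positions=None, chrom="chr1", sperm_ids=None):
    """Hand-build a GameteMatrix from a (n_sites, n_sperm) code array."""
    calls = np.asarray(states, dtype=np.int8)
    n_sites, n_sperm = calls.shape
    if positions is None:
        positions = np.arange(1, n_sites + 1) * 10_000
    sites = pd.DataFrame(
        {
            "chrom": chrom,
            "pos": np.asarray(positions, dtype=int),
            "allele_a": "A",
            "allele_b": "C",
        }
    )
    if sperm_ids is None:
        sperm_ids = [f"s{i + 1:03d}" for i in range(n_sperm)]
    return GameteMatrix(sites, list(sperm_ids), calls)


@pytest.fixture(scope="session")
def small_sim():
    """3 x 5 Mb chromosomes, 60 sperm, study-like dropout and error."""
    cfg = SimConfig(
        n_chromosomes=3, chrom_length_bp=5_000_000, n_sperm=60,
        mean_crossovers_per_chrom=1.0, seed=2,
    )
    sites, truth = simulate_donor(cfg)
    simulate_meiosis(truth, cfg)
    matrix = simulate_sperm_calls(truth, cfg)
    return cfg, truth, matrix


@pytest.fixture(scope="session")
def phased_small(small_sim):
    cfg, truth, matrix = small_sim
    qc, _ = qc_sperm(matrix)
    ref = select_reference_sperm(qc)
    bin_map, markers, correction, report = phase_pipeline(
        matrix, ref, min_event_spacing_bp=TOY_EVENT_SPACING_BP
    )
    return dict(
        cfg=cfg, truth=truth, matrix=matrix, ref=ref,
        bin_map=bin_map, markers=markers, correction=correction, report=report,
    )
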