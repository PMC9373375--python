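import numpy as np
import pytest

from clonarch.io import (
    ClinicalRecord,
    CohortBundle,
    CopyNumberSegment,
    MutationRecord,
    SamplePurity,
)
from clonarch.simulate import SimulationConfig, simulate_cohort


@pytest.fixture(scope="session")
def small_cohort():
    """A 150-patient simulated cohort with its ground truth (fixed seed)."""
    cfg = SimulationConfig(n_patients=150, seed=42)
    bundle, truth = simulate_cohort(cfg)
    return cfg, bundle, truth


@pytest.fixture
def toy_bundle():
    """Hand-built 3-patient bundle covering the annotation edge cases."""
    muts = [
        MutationRecord("S1", "TP53", "17", 50, "missense", 30, 100),
        MutationRecord("S1", "GX", "X", 10, "missense", 10, 100),  # non-autosome
        MutationRecord("S2", "APC", "5", 200, "nonsense", 40, 80),
        MutationRecord("S2", "DEL0", "5", 900, "missense", 5, 100),  # cn=0 segment
        MutationRecord("S3", "NOSEG", "1", 123, "missense", 12, 60),  # no segment
        MutationRecord("S1", "SIL", "17", 70, "silent", 20, 100),
    ]
    segs = [
        CopyNumberSegment("S1", "17", 1, 100, 2),
        CopyNumberSegment("S1", "X", 1, 100, 1),
        CopyNumberSegment("S2", "5", 100, 500, 3),
        CopyNumberSegment("S2", "5", 800, 1000, 0),
    ]
    purs = [SamplePurity("S1", 0.6), SamplePurity("S2", 0.8), SamplePurity("S3", 0.5)]
    clin = [
        ClinicalRecord("S1", os_time=100.0, os_event=1),
        ClinicalRecord("S2", os_time=200.0, os_event=0),
        ClinicalRecord("S3", os_time=300.0, os_event=1),
    ]
    return CohortBundle(muts, segs, purs, clin)


def naive_ccf_posterior(t_alt, t_depth, purity, local_cn, grid=None):
    """Direct-probability (non-log) grid posterior: the independent oracle."""
    from math import comb

    from clonarch.ccf import ccf_grid, expected_vaf

    g = ccf_grid() if grid is None else grid
    probs = []
    for f in g:
        v = expected_vaf(purity, f, local_cn)
        probs.append(comb(t_depth, t_alt) * v**t_alt * (1 - v) ** (t_depth - t_alt))
    probs = np.array(probs)
    total = probs.sum()
    if total == 0 or probs.max() < 1e-250:  # underflow: oracle inapplicable
        return None
    return probs / total
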