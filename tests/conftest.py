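"""Shared fixtures: small seeded translatomes and pipeline runs.

Everything is generated programmatically; sizes are kept small enough for
the full suite to run on one CPU while leaving the anomaly-detection task
non-trivial (hundreds of ORFs, codon counts in the hundreds of thousands
only where a criterion demands full scale).
"""

from __future__ import annotations

import numpy as np
import pytest

from ribopause import (
    SimConfig,
    call_pauses,
    compute_tpm,
    generate_translatome,
    inject_pauses,
    normalize_profiles,
    partition_by_tpm,
)


@pytest.fixture(scope="session")
def small_translatome():
    """300 short ORFs with heterogeneous expression, ramps and dwell noise."""
    cfg = SimConfig(n_orfs=300, length_median=120, seed=11)
    profiles, sequences, truth = generate_translatome(cfg)
    return cfg, profiles, sequences, truth


@pytest.fixture(scope="session")
def small_pipeline(small_translatome):
    """Injected + called pipeline products on the small translatome."""
    _, profiles, sequences, _ = small_translatome
    tpm = compute_tpm(profiles)
    partition = partition_by_tpm(tpm)
    normalized = normalize_profiles(profiles)
    injected, truth = inject_pauses(normalized, seed=7)
    calls = call_pauses(injected, partition, n_trees=100, seed=13)
    return {
        "profiles": profiles,
        "sequences": sequences,
        "partition": partition,
        "normalized": normalized,
        "injected": injected,
        "truth": truth,
        "calls": calls,
    }


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20240101)
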