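"""Shared fixtures: miniature configurations and cached reference runs.

Simulation fixtures are session-scoped so that independent tests can
interrogate the same trajectory (event log audits, conservation checks,
profiles) without paying for extra runs.
"""

from __future__ import annotations

import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))

from heterosim import build_system, miniature_config, run_replica  # noqa: E402
from heterosim.config import PROTEINS, SystemConfig  # noqa: E402


@pytest.fixture(scope="session")
def mini_config():
    """Small boosted-rate system: 8 nucleosomes, 10 copies per protein.

    Rates and length are chosen so every seed produces a healthy number
    of methylation events for event-log audits."""
    return miniature_config(n_nucleosomes=8, copies=10, binding_boost=20.0,
                            pt_scale=2000.0, n_steps=120_000, report_interval=500)


@pytest.fixture(scope="session")
def mini_replica(mini_config):
    """One full miniature replica, reused by event-log and invariant tests."""
    return run_replica(mini_config, seed=1234)


@pytest.fixture(scope="session")
def mini_system(mini_config):
    """A freshly built (unrun) miniature system."""
    return build_system(mini_config, rng=np.random.default_rng(99))


@pytest.fixture(scope="session")
def proxy_config():
    """The desk-scale knockdown proxy: 24 nucleosomes, pt × 100."""
    return SystemConfig(
        n_nucleosomes=24,
        fiber_span_bp=24 * 196.0,
        protein_copies={p: 24 for p in PROTEINS},
        pt_scale=100.0,
        n_steps=1_000_000,
        report_interval=5_000,
    )
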