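"""Shared fixtures: small seeded synthetic studies used across the suite."""

from __future__ import annotations

import pytest

from tpd_qspr.synthetic import (GeneratorConfig, generate_library,
                                generate_study, standard_task_registry)


@pytest.fixture(scope="session")
def registry6():
    return standard_task_registry()


@pytest.fixture(scope="session")
def tiny_library():
    cfg = GeneratorConfig(
        n_per_modality={"heterobifunctional": 15, "glue": 15, "other": 15},
        seed=7,
    )
    return generate_library(cfg)


@pytest.fixture(scope="session")
def small_study(registry6):
    """Noisy sparse study, large enough to train a toy model."""
    cfg = GeneratorConfig(
        n_per_modality={"heterobifunctional": 40, "glue": 45, "other": 45},
        noise_sd=0.3,
        sparsity=0.85,
        replicate_rate=0.1,
        qualifier_rate=0.05,
        seed=11,
    )
    return generate_study(cfg, registry6)


@pytest.fixture(scope="session")
def clean_study(registry6):
    """Noiseless, dense, replicate-free study: labels equal the truth."""
    cfg = GeneratorConfig(
        n_per_modality={"heterobifunctional": 20, "glue": 20, "other": 20},
        noise_sd=0.0,
        sparsity=1.0,
        replicate_rate=0.0,
        qualifier_rate=0.0,
        seed=23,
    )
    return generate_study(cfg, registry6)
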