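"""Shared fixtures: a default reference set, packaged profiles, and cached
pipeline runs reused across test modules (simulation + alignment of ~2000
molecules is the expensive step, so runs are session-scoped)."""

from __future__ import annotations

import dataclasses

import pytest

from telomap.pipeline import AnalysisResult, analyze_molecules
from telomap.simulate import make_reference, profile_from_table1, simulate_cell_line

PROFILE_NAMES = ("U2OS", "Saos-2", "SK-MEL-2", "UMUC3", "LNCaP", "IMR90-S")

#: per-arm coverage used for paper-scale runs (~2000 arm-anchored molecules
#: over the 41-arm default reference)
PAPER_SCALE_PER_ARM = 50


@pytest.fixture(scope="session")
def reference():
    return make_reference(seed=1)


@pytest.fixture(scope="session")
def profiles():
    return {name: profile_from_table1(name) for name in PROFILE_NAMES}


@pytest.fixture(scope="session")
def run_cache(reference, profiles):
    """Lazily computed (profile, seed, noise, per_arm) -> (molecules, result)."""
    cache: dict[tuple, tuple] = {}

    def get(name: str, seed: int, noise: bool = True,
            per_arm: float = PAPER_SCALE_PER_ARM) -> tuple[list, AnalysisResult]:
        key = (name, seed, noise, per_arm)
        if key not in cache:
            prof = dataclasses.replace(profiles[name], mean_molecules_per_arm=per_arm)
            molecules = simulate_cell_line(prof, reference, seed=seed, apply_noise=noise)
            cache[key] = (molecules, analyze_molecules(molecules, reference))
        return cache[key]

    return get
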