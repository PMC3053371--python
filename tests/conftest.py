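"""Shared fixtures: one synthetic study bundle per session, plus the full
pipeline run over it and a strict/relaxed benchmark pair.  Everything is
generated from fixed seeds so the suite is deterministic."""

import numpy as np
import pytest

from remotethread.fixtures import (
    FixtureSpec,
    build_profile,
    diverge,
    gen_profile_family,
    gen_strict_relaxed_pair,
    generate_bundle,
    random_sequence,
)
from remotethread.pipeline import PipelineConfig, PipelineResources, run_proteome
from remotethread.search import calibrate_profile

SESSION_SEED = 0


@pytest.fixture(scope="session")
def bundle():
    return generate_bundle(FixtureSpec(seed=SESSION_SEED))


@pytest.fixture(scope="session")
def resources(bundle):
    return PipelineResources(
        profiles=bundle.profiles,
        library=bundle.library,
        structure_map=bundle.structure_map,
        cdf=bundle.cdf,
        orthologs=bundle.ortholog_table,
        ortholog_sequences=bundle.ortholog_sequences,
        essentials=bundle.essentials,
    )


@pytest.fixture(scope="session")
def proteome_run(bundle, resources):
    """Full pipeline over the default synthetic proteome."""
    calls, summary = run_proteome(bundle.proteome, resources, PipelineConfig())
    return calls, summary


@pytest.fixture(scope="session")
def srpair():
    """A strict (old) / relaxed (new) profile release pair with engineered
    far members, for the hide-and-seek benchmark."""
    spec = FixtureSpec(seed=SESSION_SEED)
    fam_rng = np.random.default_rng(np.random.SeedSequence([SESSION_SEED, 11]))
    fam = gen_profile_family(fam_rng, spec, 0, clan="CL000")
    pair_rng = np.random.default_rng(np.random.SeedSequence([SESSION_SEED, 97]))
    return fam, gen_strict_relaxed_pair(pair_rng, spec, fam)


@pytest.fixture(scope="session")
def small_profile():
    """One cheap calibrated profile plus its consensus, for unit tests."""
    rng = np.random.default_rng(123)
    consensus = random_sequence(rng, 50)
    members = [diverge(rng, consensus, 0.03) for _ in range(15)]
    profile = build_profile(members, "PF_UNIT", pseudocount=0.1)
    return calibrate_profile(profile, 300, seed=7), consensus
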