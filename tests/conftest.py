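"""Shared fixtures: the full-scale default fixture is generated once per
session; scaled-down mitogenome parameters serve the per-seed property
tests."""

from __future__ import annotations

import dataclasses
from types import SimpleNamespace

import pytest

from cmsforge import mitocompare, simulate


def scaled_mito_params(seed: int = 0) -> simulate.MitoSimParams:
    """A 40 kb stand-in for the full mitogenome, same planted chimera."""
    return simulate.MitoSimParams(
        genome_length=40_000,
        insert_position=11_000,
        n_references=2,
        donor_length=10_000,
        seed=seed,
    )


@pytest.fixture(scope="session")
def default_fixture():
    """Full-scale default fixture: 457,380 bp CMS genome, 3 references,
    donor panel, planted 549 bp chimeric ORF."""
    params = simulate.MitoSimParams()
    cms, refs, donors, truth = simulate.generate_mitogenomes(params)
    return SimpleNamespace(params=params, cms=cms, refs=refs, donors=donors, truth=truth)


@pytest.fixture(scope="session")
def default_regions(default_fixture):
    return mitocompare.specific_regions(default_fixture.cms, default_fixture.refs)


@pytest.fixture(scope="session")
def default_clones(default_fixture):
    params = simulate.TranscriptSimParams()
    clones, truth = simulate.generate_cdna_clones(params, default_fixture.truth.orf_seq)
    return SimpleNamespace(params=params, clones=clones, truth=truth)


@pytest.fixture(scope="session")
def default_race(default_fixture):
    params = dataclasses.replace(simulate.TranscriptSimParams(), n_clones=200)
    clones, truth = simulate.generate_race_ends(params, default_fixture.truth.orf_seq)
    return SimpleNamespace(params=params, clones=clones, truth=truth)
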