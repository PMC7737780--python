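"""Shared fixtures: synthetic families are generated once per session."""

import numpy as np
import pytest

from bbassembly.segmentation import align_to_template, extract_fragment
from bbassembly.fragment_db import build_database
from bbassembly.synthetic import ToyFamilySpec, make_toy_family


def angdiff(a, b):
    """Smallest absolute angular difference in degrees."""
    return abs((a - b + 180.0) % 360.0 - 180.0)


@pytest.fixture(scope="session")
def toy_family():
    """Six homologs, three segments, three planted conformational groups."""
    spec = ToyFamilySpec(
        n_structures=6,
        n_segments=3,
        n_conformational_groups=3,
        torsion_noise=2.0,
        seed=7,
    )
    family, gt = make_toy_family(spec)
    return family, gt


@pytest.fixture(scope="session")
def gate_family():
    """Single-group family whose fragments are ≤5° perturbations of the
    template's own loops — the database-gate scenario."""
    spec = ToyFamilySpec(
        n_structures=8,
        n_segments=3,
        n_conformational_groups=1,
        torsion_noise=5.0,
        seed=11,
    )
    family, gt = make_toy_family(spec)
    return family, gt


@pytest.fixture(scope="session")
def toy_fragments(toy_family):
    """All segment fragments of the toy family, extracted via alignment."""
    family, _ = toy_family
    out = []
    for hom in family.homologs:
        aln = align_to_template(hom, family.template, family.scheme)
        for name in family.scheme.segment_names:
            out.append(extract_fragment(hom, aln, name, family.scheme))
    return out


@pytest.fixture(scope="session")
def toy_db(toy_family, toy_fragments):
    family, _ = toy_family
    return build_database(family.template, family.scheme, toy_fragments)


@pytest.fixture(scope="session")
def gate_db(gate_family):
    family, _ = gate_family
    frags = []
    for hom in family.homologs:
        aln = align_to_template(hom, family.template, family.scheme)
        for name in family.scheme.segment_names:
            frags.append(extract_fragment(hom, aln, name, family.scheme))
    return build_database(family.template, family.scheme, frags)
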