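"""Shared fixtures: the default synthetic study and small building blocks."""

from __future__ import annotations

import numpy as np
import pytest

from ensdyn import synthetic
from ensdyn.elements import element_params
from ensdyn.ensemble_io import AtomRecord, Ensemble

#: canonical seed of the default study used across the suite
STUDY_SEED = 1


@pytest.fixture(scope="session")
def default_study():
    """The full-size default synthetic study (4 states x 808 models)."""
    return synthetic.generate_study(seed=STUDY_SEED)


@pytest.fixture(scope="session")
def small_study():
    """A reduced study for fast plumbing tests (not for tolerance checks)."""
    spec = synthetic.SyntheticSpec(n_residues=16, n_models=40, n_replicas=4)
    return synthetic.generate_study(spec, seed=STUDY_SEED)


def make_ensemble(coords: np.ndarray, names=None, elements=None,
                  resnums=None, state_label="", replica_ids=None) -> Ensemble:
    """Build an Ensemble from raw coordinates with minimal boilerplate.

    ``coords`` has shape (n_models, n_atoms, 3); atoms default to one CA
    carbon per residue, residues numbered from 1.
    """
    coords = np.asarray(coords, float)
    n_atoms = coords.shape[1]
    names = names or ["CA"] * n_atoms
    elements = elements or ["C"] * n_atoms
    resnums = resnums if resnums is not None else list(range(1, n_atoms + 1))
    atoms = []
    for i in range(n_atoms):
        mass, rvdw = element_params(elements[i])
        atoms.append(AtomRecord(serial=i + 1, name=names[i], element=elements[i],
                                residue_number=int(resnums[i]), residue_name="UNK",
                                chain="A", mass=mass, vdw_radius=rvdw))
    return Ensemble(atoms=atoms, coords=coords, state_label=state_label,
                    replica_ids=replica_ids)


@pytest.fixture
def rng():
    return np.random.default_rng(STUDY_SEED)
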