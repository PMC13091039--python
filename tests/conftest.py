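"""Shared fixtures: synthetic ensembles generated once per session."""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd
import pytest

from ensemblefp import (
    ConfidenceBundle,
    generate_ensemble,
    load_ensemble,
    par1_preset,
)

ROOT_SEED = 11


@pytest.fixture(scope="session")
def preset_spec():
    """Full-size two-state preset: 20 seed batches x 5 models."""
    return par1_preset(rng_seed=ROOT_SEED)


@pytest.fixture(scope="session")
def toy_dir(tmp_path_factory, preset_spec):
    out = tmp_path_factory.mktemp("toy100")
    truth = generate_ensemble(preset_spec, out)
    return out, truth


@pytest.fixture(scope="session")
def toy_ensemble(toy_dir):
    out, truth = toy_dir
    return load_ensemble(out, label="toy"), truth


@pytest.fixture(scope="session")
def small_spec():
    return par1_preset(n_seeds=4, models_per_seed=3, rng_seed=ROOT_SEED)


@pytest.fixture(scope="session")
def small_dir(tmp_path_factory, small_spec):
    out = tmp_path_factory.mktemp("toy12")
    truth = generate_ensemble(small_spec, out)
    return out, truth


@pytest.fixture(scope="session")
def small_ensemble(small_dir):
    out, truth = small_dir
    return load_ensemble(out, label="small"), truth


def make_bundle(
    pae: np.ndarray,
    tokens: list[tuple[str, int]] | None = None,
    iptm: float = 0.5,
    chain_pair_iptm: dict | None = None,
) -> ConfidenceBundle:
    """Hand-construct a confidence bundle for unit tests."""
    pae = np.asarray(pae, dtype=float)
    n = pae.shape[0]
    if tokens is None:
        tokens = [("A", i + 1) for i in range(n)]
    return ConfidenceBundle(
        plddt=np.full(n, 80.0),
        pae=pae,
        iptm=iptm,
        tokens=tokens,
        chain_pair_iptm=chain_pair_iptm,
    )


def minimal_cif(path: Path, lines_extra: str = "") -> Path:
    """Write a one-atom mmCIF (ALA 1, chain A, CA at origin)."""
    text = """data_minimal
loop_
_atom_site.group_PDB
_atom_site.id
_atom_site.type_symbol
_atom_site.label_atom_id
_atom_site.label_alt_id
_atom_site.label_comp_id
_atom_site.auth_asym_id
_atom_site.label_asym_id
_atom_site.label_entity_id
_atom_site.auth_seq_id
_atom_site.Cartn_x
_atom_site.Cartn_y
_atom_site.Cartn_z
_atom_site.occupancy
_atom_site.B_iso_or_equiv
ATOM 1 C CA . ALA A A 1 1 0.000 0.000 0.000 1.00 90.00
""" + lines_extra
    path.write_text(text)
    return path
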