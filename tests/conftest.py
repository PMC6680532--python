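"""Shared fixtures: synthetic scenarios generated once per session."""

from __future__ import annotations

import numpy as np
import pytest

from promisite import (PipelineConfig, SyntheticScenario, generate_scenario,
                       run_all)
from promisite.chains import Atom, ProteinChain


@pytest.fixture(scope="session")
def small_scenario(tmp_path_factory):
    """Two chain families x two sites, enough for every pipeline stage."""
    out = tmp_path_factory.mktemp("scenario_small")
    scenario = SyntheticScenario(seed=11, n_chain_families=2,
                                 chains_per_family=4, sites_per_family=2,
                                 pockets_per_site=5, ligand_families=4,
                                 ligands_per_family=3)
    truth = generate_scenario(scenario, out)
    return scenario, truth, out


@pytest.fixture(scope="session")
def small_pipeline(small_scenario, tmp_path_factory):
    scenario, truth, in_dir = small_scenario
    out = tmp_path_factory.mktemp("pipeline_small")
    result = run_all(in_dir, out, PipelineConfig(seed=scenario.seed))
    return scenario, truth, result


def make_chain(coords: np.ndarray, chain_uid: str = "cx:A",
               res_names: list[str] | None = None,
               atom_names: list[str] | None = None) -> ProteinChain:
    """Build a minimal chain with one atom per residue at given coordinates."""
    coords = np.asarray(coords, dtype=float)
    n = len(coords)
    res_names = res_names or ["ALA"] * n
    atom_names = atom_names or ["CA"] * n
    atoms = [Atom(name=atom_names[i], element=atom_names[i][0],
                  res_name=res_names[i], res_num=i + 1, coord=coords[i],
                  is_sidechain=atom_names[i] not in {"N", "CA", "C", "O", "OXT"})
             for i in range(n)]
    seq = "".join({"ALA": "A", "CYS": "C", "TYR": "Y", "TRP": "W",
                   "GLY": "G", "MET": "M"}.get(r, "A") for r in res_names)
    return ProteinChain(chain_uid=chain_uid, sequence=seq, atoms=atoms)
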