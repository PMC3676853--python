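"""Shared fixtures: analytic oracle structures and hand-written PDB text."""

from __future__ import annotations

import numpy as np
import pytest

import enmpair as ep


def pdb_atom_line(
    serial: int,
    resname: str,
    chain: str,
    resseq: int,
    x: float,
    y: float,
    z: float,
    *,
    name: str = " CA ",
    altloc: str = " ",
    icode: str = " ",
    occ: float = 1.0,
    b: float = 10.0,
    element: str = " C",
    record: str = "ATOM",
) -> str:
    return (
        f"{record:<6}{serial:>5} {name:<4}{altloc}{resname:>3} {chain}"
        f"{resseq:>4}{icode}   {x:8.3f}{y:8.3f}{z:8.3f}{occ:6.2f}{b:6.2f}"
        f"          {element:>2}"
    )


@pytest.fixture
def write_pdb(tmp_path):
    def _write(lines: list[str], name: str = "fixture.pdb"):
        path = tmp_path / name
        path.write_text("\n".join(lines + ["END"]) + "\n")
        return path

    return _write


@pytest.fixture(scope="session")
def path3():
    """Collinear 3-residue chain at 3.8 Å spacing: the analytic GNM oracle."""
    return ep.make_chain(3, 3.8, "line")


@pytest.fixture(scope="session")
def two_beads():
    """Two residues 1 Å apart along x: the analytic ANM oracle."""
    return ep.make_chain(2, 1.0, "line")


@pytest.fixture(scope="session")
def dumbbell_pair():
    """Open/closed synthetic conformer pair with ground-truth labels."""
    return ep.make_conformer_pair(ep.DumbbellSpec(seed=1), angle_deg=41.3)


def random_rigid_motion(rng: np.random.Generator):
    """A uniformly random proper rotation and a random translation."""
    from scipy.spatial.transform import Rotation

    r = Rotation.random(rng=rng).as_matrix()
    t = rng.normal(scale=20.0, size=3)
    return r, t
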