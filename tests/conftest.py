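"""Shared fixtures: a hand-written toy multi-model PDB and common objects."""

import numpy as np
import pytest

import pbflex as pf


def _atom_line(serial, name, resname, chain, resseq, xyz, element):
    pdb_name = name if len(name) >= 4 else f" {name:<3s}"
    x, y, z = xyz
    return (
        f"ATOM  {serial:5d} {pdb_name} {resname:>3s} {chain}{resseq:4d}    "
        f"{x:8.3f}{y:8.3f}{z:8.3f}  1.00  0.00          {element:>2s}"
    )


def make_toy_pdb_text(n_models=2, n_residues=6, drop=()):
    """Fixed-width PDB text written independently of the package's writer.

    ``drop`` is a set of (model_number, resseq, atom_name) to omit.
    Coordinates are a deterministic non-degenerate pattern, shifted by 0.1 A
    per model so frames differ.
    """
    lines = []
    for m in range(1, n_models + 1):
        lines.append(f"MODEL     {m:4d}")
        serial = 0
        for r in range(1, n_residues + 1):
            base = np.array([3.8 * r, (r % 2) * 1.5, 0.1 * m])
            for k, (name, el) in enumerate(
                [("N", "N"), ("CA", "C"), ("C", "C"), ("O", "O"), ("CB", "C")]
            ):
                if (m, r, name) in drop:
                    continue
                serial += 1
                xyz = base + [0.4 * k, 0.3 * (k % 2), 0.2 * k]
                lines.append(_atom_line(serial, name, "ALA", "A", r, xyz, el))
        lines.append("TER")
        lines.append("ENDMDL")
    lines.append("END")
    return "\n".join(lines) + "\n"


@pytest.fixture
def toy_pdb(tmp_path):
    path = tmp_path / "toy.pdb"
    path.write_text(make_toy_pdb_text())
    return path


@pytest.fixture(scope="session")
def pb_table():
    return pf.load_reference_table()


@pytest.fixture(scope="session")
def vhh_regions():
    return pf.RegionMap.default_vhh()


@pytest.fixture(scope="session")
def ideal_helix():
    return pf.build_ideal_conformation("helix", 12)


@pytest.fixture(scope="session")
def ideal_strand():
    return pf.build_ideal_conformation("strand", 12)


@pytest.fixture(scope="session")
def cys_ensemble():
    """Small harmonic ensemble with two cysteines, for mutation tests."""
    seq = "AAAAAAAAAC" + "AAAAAAAAAA" + "AAAACAAAAA"  # CYS at positions 10, 25
    ref = pf.build_ideal_conformation("helix", 30, sequence=seq)
    return pf.perturb_coordinates(
        ref, np.full(30, 0.15), n_frames=20, seed=11
    )
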