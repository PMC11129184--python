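import numpy as np
import pytest

from memallo import synthetic


@pytest.fixture(scope="session")
def site_walk():
    """Lipid walk around a toy protein with one planted four-residue site.

    25 lipids in a 60 Å box, 1 ns frames, 4000 frames, mean dwell 50 ns —
    enough bound segments for site clustering while staying fast.
    """
    center = np.array([30.0, 30.0, 30.0])
    protein = synthetic.toy_protein(center, near_radius=2.0)
    spec = synthetic.LipidKineticsSpec(
        box=np.array([60.0, 60.0, 60.0]),
        n_lipids=25,
        diffusion_step=2.0,
        site_centers=center[None, :],
        r_bind=4.0,
        mean_dwell=50.0,
        frame_dt=1.0,
        n_frames=4000,
        seed=7,
    )
    return synthetic.generate_lipid_walk(spec, protein)


@pytest.fixture()
def toy_pdb(tmp_path):
    """A 25-atom PDB: chains A-E, five Cα residues each."""
    path = tmp_path / "toy.pdb"
    lines = []
    serial = 0
    for ci, chain in enumerate("ABCDE"):
        for r in range(1, 6):
            serial += 1
            x, y, z = 3.8 * r, 2.0 * ci, 0.5 * r * ci
            lines.append(
                f"ATOM  {serial:5d}  CA  ALA {chain}{r:4d}    "
                f"{x:8.3f}{y:8.3f}{z:8.3f}  1.00  0.00           C"
            )
    path.write_text("\n".join(lines) + "\nEND\n")
    return path
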