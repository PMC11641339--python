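import pytest

from ignar.synthetic import gcignar1_fixture, gcignar2_fixture


@pytest.fixture(scope="session")
def ignar1():
    """Packaged ten-exon locus with its eleven isoform models."""
    return gcignar1_fixture()


@pytest.fixture(scope="session")
def ignar2():
    """Packaged nine-exon locus with its four isoform models."""
    return gcignar2_fixture()


def write_sg_pdb(path, atoms):
    """Write a minimal PDB of cysteine SG atoms.

    *atoms* is a sequence of (chain, resnum, x, y, z).
    """
    lines = []
    for serial, (chain, resnum, x, y, z) in enumerate(atoms, start=1):
        lines.append(
            f"ATOM  {serial:5d}  SG  CYS {chain}{resnum:4d}    "
            f"{x:8.3f}{y:8.3f}{z:8.3f}  1.00  0.00           S")
    path.write_text("\n".join(lines) + "\nEND\n")
    return path


@pytest.fixture
def sg_pdb_writer(tmp_path):
    def _write(atoms, name="model.pdb"):
        return write_sg_pdb(tmp_path / name, atoms)

    return _write
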