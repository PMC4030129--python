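import numpy as np
import pytest

from enmdyn import assign_domains, build_network
from enmdyn.synthetic import SyntheticSpec, make_helix, \
    make_two_domain_structure


@pytest.fixture(scope="session")
def two_domain():
    """Seeded two-domain hinge model with domain tags and bead indices."""
    model, defs = make_two_domain_structure(SyntheticSpec(seed=1))
    model = assign_domains(model, defs)
    return model, model.domain_indices()


@pytest.fixture(scope="session")
def globule100():
    """Compact 100-bead single-domain control structure."""
    model, _ = make_two_domain_structure(
        SyntheticSpec(n_core=100, n_insert=0, seed=0))
    return model


@pytest.fixture(scope="session")
def helix20():
    return make_helix(20)


@pytest.fixture()
def random_compact_net():
    """Factory for small connected random networks (compact globules)."""
    def factory(n=10, seed=0, r_c=8.0, **kw):
        model, _ = make_two_domain_structure(
            SyntheticSpec(n_core=n, n_insert=0, seed=seed))
        return model, build_network(model, r_c=r_c, **kw)
    return factory


def make_pdb_text(records):
    """Assemble minimal PDB ATOM records from (serial, name, resname,
    chain, resid, xyz, bfac, altloc, element) tuples."""
    lines = []
    for (serial, name, resname, chain, resid, xyz, bfac, altloc,
         element) in records:
        lines.append(
            f"ATOM  {serial:>5} {name:<4}{altloc:1}{resname:<3} {chain:1}"
            f"{resid:>4}    {xyz[0]:8.3f}{xyz[1]:8.3f}{xyz[2]:8.3f}"
            f"  1.00{bfac:6.2f}          {element:>2}")
    lines.append("END")
    return "\n".join(lines) + "\n"


@pytest.fixture()
def toy_pdb(tmp_path):
    """3-residue Cα-only PDB file with distinct B-factors."""
    recs = [
        (1, " CA ", "ALA", "A", 1, (0.0, 0.0, 0.0), 10.0, " ", "C"),
        (2, " CA ", "GLY", "A", 2, (3.8, 0.0, 0.0), 20.0, " ", "C"),
        (3, " CA ", "LEU", "A", 3, (7.6, 0.0, 0.0), 30.0, " ", "C"),
    ]
    p = tmp_path / "toy.pdb"
    p.write_text(make_pdb_text(recs))
    return p
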