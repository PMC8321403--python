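import numpy as np
import pytest

import memlip as ml


def particle(name="X", kind="lipid", mol=0, res=1, resname="POPC", chain="",
             region="NA", species="NA", leaflet="NA", role="other", mass=72.0):
    return {"name": name, "molecule_kind": kind, "molecule_id": mol,
            "residue_index": res, "residue_name": resname, "chain_id": chain,
            "region": region, "lipid_species": species, "leaflet": leaflet,
            "role": role, "mass": mass}


def make_topology(records):
    return ml.ParticleTopology.from_records(records)


def single_bead_system(positions, species_list, box=(10.0, 10.0, 10.0),
                       protein_positions=()):
    """One phosphate bead per lipid + optional single-bead protein residues."""
    records, coords = [], []
    mol = 0
    for pos in protein_positions:
        records.append(particle(name="BB", kind="protein", mol=mol, res=mol + 1,
                                resname="GLY", chain="P", region="TMR",
                                role="backbone"))
        coords.append(pos)
        mol += 1
    for pos, sp in zip(positions, species_list):
        records.append(particle(name="PO4", mol=mol, res=mol + 1, resname=sp,
                                species=sp, leaflet="inner", role="phosphate"))
        coords.append(pos)
        mol += 1
    topo = make_topology(records)
    frame = ml.Frame(np.asarray(coords, dtype=float), np.asarray(box, dtype=float))
    return topo, frame


@pytest.fixture(scope="session")
def kinetics_protein():
    """Widely spaced 8-chain protein so binding sites do not interfere."""
    spec = ml.ProteinSpec(n_helices=8, spacing=6.0, chain_ids=list("ABCDEFGH"),
                          tail_lengths=[8] * 8, ecd_sizes=[4] * 8, tilt_deg=[0.0] * 8)
    return ml.build_protein(spec)


@pytest.fixture(scope="session")
def demo_system(kinetics_protein):
    """Membrane + protein + binding sites shared by contact/kinetics tests."""
    # the exclusion hole covers the widely spaced chains (ring radius ~7.8 nm)
    # so no lipid starts in ambient contact with the protein
    membrane = ml.build_membrane(
        ml.MembraneSpec(lx=25.0, ly=25.0, protein_exclusion_radius=9.5), 150, seed=11)
    topo, frame0 = ml.combine_systems(membrane, kinetics_protein)
    sites = ml.pick_binding_sites(topo, frame0, 3.0, 8)
    return topo, frame0, sites


@pytest.fixture(scope="session")
def bound_run(demo_system):
    """Short binding run of PIP2/PIP3 with ground-truth log."""
    topo, frame0, sites = demo_system
    kin = ml.BindingKineticsSpec(kon={"PIP2": 1.0, "PIP3": 1.0},
                                 koff={"PIP2": 0.2, "PIP3": 0.3},
                                 site_indices=sites)
    traj, log = ml.simulate_trajectory(topo, frame0, kin, 300, 0.2, seed=5)
    return traj, log, sites
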