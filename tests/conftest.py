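import numpy as np
import pytest

from titrakit import (
    ResidueSpec,
    TitrationDesign,
    csp_profiles,
    design_ligand_series,
    galectin_demo_residues,
    simulate_titration,
)

#: medium-affinity reference scenario: Pt = 270 μM, Kd = 123 μM
PT_UM = 270.0
KD_MEDIUM_UM = 123.0
KD_WEAK_UM = 11_000.0


@pytest.fixture(scope="session")
def site_residues():
    """The nine planted binding-site residues of the demo panel."""
    return [r for r in galectin_demo_residues() if r.offset_H > 0][:9]


@pytest.fixture(scope="session")
def medium_series():
    """12-point ligand series designed for the 123 μM scenario."""
    return design_ligand_series(PT_UM, KD_MEDIUM_UM, 12, 10.0)


@pytest.fixture
def make_dataset(site_residues, medium_series):
    """Factory for synthetic titration datasets of the 9-residue panel."""

    def _make(kd=KD_MEDIUM_UM, seed=0, noise_H=0.002, noise_N=0.02, series=None):
        design = TitrationDesign(
            protein_total=PT_UM,
            ligand_points=list(series if series is not None else medium_series),
            residues=site_residues,
            true_Kd=kd,
            noise_H=noise_H,
            noise_N=noise_N,
            seed=seed,
        )
        return simulate_titration(design)

    return _make


@pytest.fixture
def noiseless_fit_inputs(make_dataset):
    ds = make_dataset(noise_H=0.0, noise_N=0.0, seed=1)
    return csp_profiles(ds), ds


def make_pdb(residues, b=10.0):
    """Toy PDB text: two atoms (N, CA) per residue, fixed geometry."""
    lines = []
    serial = 1
    for resseq, resname in residues:
        for name, elem, x in (("N", "N", 0.0), ("CA", "C", 1.5)):
            lines.append(
                f"ATOM  {serial:5d}  {name:<3s}{resname:>4s} A{resseq:4d}    "
                f"{x:8.3f}{0.0:8.3f}{float(resseq):8.3f}{1.00:6.2f}{b:6.2f}"
                f"          {elem:>2s}"
            )
            serial += 1
    lines.append("END")
    return "\n".join(lines) + "\n"


@pytest.fixture
def toy_pdb():
    return make_pdb([(158, "HIS"), (174, "ASN"), (222, "ASN")])
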