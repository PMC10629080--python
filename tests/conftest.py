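from __future__ import annotations

import numpy as np
import pytest

from fodm.model import HydroProfile, UnitReport, fit_gaussian_frame, summarize_unit
from fodm.scales import default_scale
from fodm.structure import ResiduePoint, StructuralUnit
from fodm.synthetic import GeneratorConfig, generate

# Hand-written three-residue PDB fixture with full heavy-atom records.
TINY_PDB = """\
ATOM      1  N   ALA A  10      11.104   6.134  -6.504  1.00  0.00           N
ATOM      2  CA  ALA A  10      11.639   6.071  -5.147  1.00  0.00           C
ATOM      3  C   ALA A  10      12.697   7.143  -4.934  1.00  0.00           C
ATOM      4  O   ALA A  10      13.560   7.330  -5.792  1.00  0.00           O
ATOM      5  CB  ALA A  10      12.217   4.682  -4.898  1.00  0.00           C
ATOM      6  N   GLY A  11      12.634   7.845  -3.805  1.00  0.00           N
ATOM      7  CA  GLY A  11      13.592   8.901  -3.503  1.00  0.00           C
ATOM      8  C   GLY A  11      13.791   9.840  -4.679  1.00  0.00           C
ATOM      9  O   GLY A  11      14.923  10.230  -4.962  1.00  0.00           O
ATOM     10  N   ILE A  12      12.707  10.212  -5.351  1.00  0.00           N
ATOM     11  CA  ILE A  12      12.783  11.118  -6.495  1.00  0.00           C
ATOM     12  C   ILE A  12      13.513  10.468  -7.667  1.00  0.00           C
ATOM     13  O   ILE A  12      14.269  11.135  -8.372  1.00  0.00           O
ATOM     14  CB  ILE A  12      11.384  11.603  -6.931  1.00  0.00           C
ATOM     15  CG1 ILE A  12      10.651  12.314  -5.789  1.00  0.00           C
ATOM     16  CG2 ILE A  12      11.503  12.529  -8.140  1.00  0.00           C
ATOM     17  CD1 ILE A  12       9.197  12.646  -6.103  1.00  0.00           C
END
"""


def unit_from_arrays(
    positions, hydrophobicities, chain_id: str = "A", label: str = "test-unit"
) -> StructuralUnit:
    """Build a unit directly from coordinate and hydrophobicity arrays."""
    positions = np.asarray(positions, float)
    h = np.asarray(hydrophobicities, float)
    residues = tuple(
        ResiduePoint(chain_id, i + 1, "", "ALA", tuple(positions[i]), float(h[i]))
        for i in range(len(h))
    )
    return StructuralUnit(label, residues)


def fake_report(t_values, o_values) -> UnitReport:
    """A UnitReport with prescribed T and O profiles, for divergence-level tests."""
    t = np.asarray(t_values, float)
    o = np.asarray(o_values, float)
    n = t.size
    rng = np.random.default_rng(0)
    unit = unit_from_arrays(rng.normal(size=(n, 3)) * 5.0, np.linspace(0.2, 0.8, n))
    frame = fit_gaussian_frame(unit)
    T = HydroProfile("T", t / t.sum())
    O = HydroProfile("O", o / o.sum())
    R = HydroProfile("R", np.full(n, 1.0 / n))
    from fodm.model import FodSummary, kl_divergence, m_profile, optimize_k

    d_ot = kl_divergence(O, T)
    d_or = kl_divergence(O, R)
    k, d_om = optimize_k(O, T)
    return UnitReport(
        unit=unit, frame=frame, T=T, O=O, R=R, M=m_profile(T, k),
        summary=FodSummary(d_ot, d_or, d_ot / (d_ot + d_or), k, d_om),
    )


@pytest.fixture
def tiny_pdb_path(tmp_path):
    p = tmp_path / "tiny.pdb"
    p.write_text(TINY_PDB)
    return p


@pytest.fixture(scope="session")
def scale():
    return default_scale()


@pytest.fixture(scope="session")
def micelle_unit():
    return generate(GeneratorConfig(ordering="micelle", seed=1))


@pytest.fixture(scope="session")
def inverted_unit():
    return generate(GeneratorConfig(ordering="inverted", seed=1))


@pytest.fixture(scope="session")
def micelle_report(micelle_unit):
    return summarize_unit(micelle_unit)
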