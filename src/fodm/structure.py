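"""Structure input: PDB/mmCIF reading, effective atoms, unit assembly.

Every residue is reduced to a single *effective atom* — the unweighted mean
position of its heavy atoms (backbone and side chain; glycine averages its
four backbone atoms) — plus one intrinsic hydrophobicity from the active
scale.  An ordered collection of such points over which a single Gaussian
frame is spanned (a complex, a chain, or a pseudo-domain) is a
:class:`StructuralUnit`.

Residue identity follows author numbering throughout, including insertion
codes; nothing is ever re-indexed sequentially.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import gemmi
import numpy as np

from .scales import STANDARD_AMINO_ACIDS, default_scale

__all__ = [
    "ResiduePoint",
    "StructuralUnit",
    "FragmentSelection",
    "ParsedResidue",
    "load_structure",
    "effective_atom",
    "build_unit",
    "parse_selection",
]

#: HETATM residue names treated as the corresponding standard amino acid.
DEFAULT_MODIFIED_RESIDUES: Mapping[str, str] = {"MSE": "MET"}


@dataclass(frozen=True)
class ResiduePoint:
    """One amino acid reduced to its effective atom.

    ``seq_id``/``icode`` are author numbering; ``position`` is the mean heavy
    atom position in Å; ``hydrophobicity`` is the intrinsic value H^r from
    the active scale, in [0, 1].
    """

    chain_id: str
    seq_id: int
    icode: str
    name: str
    position: tuple[float, float, float]
    hydrophobicity: float

    def __post_init__(self) -> None:
        if not all(np.isfinite(self.position)):
            raise ValueError(f"non-finite position for {self.key}")

    @property
    def key(self) -> tuple[str, int, str]:
        return (self.chain_id, self.seq_id, self.icode)

    @property
    def label(self) -> str:
        return f"{self.chain_id}{self.seq_id}{self.icode}".strip()


@dataclass(frozen=True)
class StructuralUnit:
    """Ordered residue collection spanned by one Gaussian frame."""

    label: str
    residues: tuple[ResiduePoint, ...]
    provenance: str = ""

    def __post_init__(self) -> None:
        if len(self.residues) < 2:
            raise ValueError(
                f"unit {self.label!r} has {len(self.residues)} residue(s); "
                "at least 2 required"
            )

    def __len__(self) -> int:
        return len(self.residues)

    @property
    def size(self) -> int:
        return len(self.residues)

    @property
    def positions(self) -> np.ndarray:
        """(N, 3) effective-atom coordinates in Å."""
        return np.asarray([r.position for r in self.residues], dtype=float)

    @property
    def hydrophobicities(self) -> np.ndarray:
        return np.asarray([r.hydrophobicity for r in self.residues], dtype=float)

    @property
    def chain_ids(self) -> list[str]:
        return [r.chain_id for r in self.residues]

    def index_of(self, chain_id: str, seq_id: int, icode: str = "") -> int:
        for i, r in enumerate(self.residues):
            if r.key == (chain_id, seq_id, icode):
                return i
        raise KeyError(f"residue {chain_id}:{seq_id}{icode} not in unit {self.label!r}")

    def subunit(self, indices: Sequence[int], label: str | None = None) -> "StructuralUnit":
        """A new unit from a subset of residue indices (order preserved)."""
        idx = sorted(set(int(i) for i in indices))
        if any(i < 0 or i >= len(self.residues) for i in idx):
            raise IndexError("subunit index out of range")
        return StructuralUnit(
            label=label or f"{self.label}[{len(idx)}]",
            residues=tuple(self.residues[i] for i in idx),
            provenance=f"{self.provenance} :: subset",
        )

    def chain(self, chain_id: str, label: str | None = None) -> "StructuralUnit":
        idx = [i for i, r in enumerate(self.residues) if r.chain_id == chain_id]
        if not idx:
            raise KeyError(f"chain {chain_id!r} not in unit {self.label!r}")
        return self.subunit(idx, label or f"{self.label}:{chain_id}")

    def translated(self, shift: Sequence[float]) -> "StructuralUnit":
        return self.transformed(np.eye(3), shift)

    def transformed(self, rotation: np.ndarray, shift: Sequence[float]) -> "StructuralUnit":
        """Rigid-body copy: x -> R x + t."""
        R = np.asarray(rotation, float)
        t = np.asarray(shift, float)
        new = tuple(
            ResiduePoint(
                r.chain_id, r.seq_id, r.icode, r.name,
                tuple(R @ np.asarray(r.position) + t), r.hydrophobicity,
            )
            for r in self.residues
        )
        return StructuralUnit(self.label, new, f"{self.provenance} :: rigid motion")


@dataclass(frozen=True)
class FragmentSelection:
    """A subset of a unit's residues, from author-numbered inclusive ranges."""

    unit: StructuralUnit
    member_indices: tuple[int, ...]
    label: str = ""

    def __post_init__(self) -> None:
        idx = self.member_indices
        if len(idx) == 0:
            raise ValueError("empty fragment selection")
        if len(set(idx)) != len(idx):
            raise ValueError("duplicate indices in fragment selection")
        if any(i < 0 or i >= self.unit.size for i in idx):
            raise IndexError("fragment index outside parent unit")

    @property
    def size(self) -> int:
        return len(self.member_indices)

    @classmethod
    def from_ranges(
        cls,
        unit: StructuralUnit,
        chain_id: str,
        ranges: Iterable[tuple[int, int]],
        label: str = "",
    ) -> "FragmentSelection":
        """Select author-numbered inclusive ranges on one chain of the unit.

        Missing residues inside a range (crystallographic gaps) are simply
        absent; a warning is emitted when a range selects fewer residues than
        its nominal span.
        """
        indices: list[int] = []
        for start, end in ranges:
            if end < start:
                raise ValueError(f"range endpoints reversed: {start}-{end}")
            hit = [
                i for i, r in enumerate(unit.residues)
                if r.chain_id == chain_id and start <= r.seq_id <= end
            ]
            if not hit:
                raise ValueError(
                    f"range {chain_id}:{start}-{end} selects no residues in "
                    f"unit {unit.label!r}"
                )
            if len(hit) < end - start + 1:
                warnings.warn(
                    f"range {chain_id}:{start}-{end} has gaps: "
                    f"{len(hit)}/{end - start + 1} residues present",
                    stacklevel=2,
                )
            indices.extend(hit)
        return cls(unit, tuple(sorted(set(indices))), label=label)


# ---------------------------------------------------------------------------
# Parsing

@dataclass(frozen=True)
class ParsedResidue:
    """A polymer residue with all its heavy-atom coordinates retained."""

    chain_id: str
    seq_id: int
    icode: str
    name: str
    atom_coords: np.ndarray  # (n_heavy, 3)

    @property
    def key(self) -> tuple[str, int, str]:
        return (self.chain_id, self.seq_id, self.icode)


def effective_atom(atom_coords: np.ndarray) -> np.ndarray:
    """Unweighted arithmetic mean of a residue's heavy-atom coordinates."""
    coords = np.asarray(atom_coords, dtype=float)
    if coords.ndim != 2 or coords.shape[0] == 0 or coords.shape[1] != 3:
        raise ValueError("expected a non-empty (n, 3) coordinate array")
    return coords.mean(axis=0)


def _pick_altlocs(residue: gemmi.Residue) -> list[gemmi.Atom]:
    """One atom per name: highest occupancy, ties to the lowest altloc id."""
    best: dict[str, gemmi.Atom] = {}
    for atom in residue:
        if atom.is_hydrogen():
            continue
        prev = best.get(atom.name)
        if prev is None:
            best[atom.name] = atom
        elif (atom.occ, prev.altloc or "~") > (prev.occ, atom.altloc or "~"):
            # higher occupancy wins; on equal occupancy the comparison above
            # favours the smaller altloc character of the kept atom
            best[atom.name] = atom
    return list(best.values())


def load_structure(
    path: str | Path,
    fmt: str | None = None,
    modified_residues: Mapping[str, str] = DEFAULT_MODIFIED_RESIDUES,
) -> dict[str, list[ParsedResidue]]:
    """Read a PDB or mmCIF file into chains of polymer residues.

    Only the first model is used.  Waters, ligands and hydrogens are
    excluded; HETATM amino acids listed in ``modified_residues`` are kept
    under their standard name (MSE -> MET by default).  ``fmt`` forces
    ``"pdb"`` or ``"mmcif"``; by default the format is detected from the
    file contents.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    try:
        if fmt is None:
            st = gemmi.read_structure(str(path))
        else:
            fmt_enum = {"pdb": gemmi.CoorFormat.Pdb, "mmcif": gemmi.CoorFormat.Mmcif}[fmt]
            st = gemmi.read_structure(str(path), format=fmt_enum)
    except (RuntimeError, ValueError, KeyError) as exc:
        raise ValueError(f"cannot parse structure file {path}: {exc}") from exc

    if len(st) == 0:
        raise ValueError(f"no models in {path}")
    model = st[0]

    chains: dict[str, list[ParsedResidue]] = {}
    for chain in model:
        residues: list[ParsedResidue] = []
        for res in chain:
            name = res.name.upper()
            if name in modified_residues:
                name = modified_residues[name].upper()
            elif name not in STANDARD_AMINO_ACIDS:
                continue
            atoms = _pick_altlocs(res)
            if not atoms:
                continue
            coords = np.array([[a.pos.x, a.pos.y, a.pos.z] for a in atoms])
            residues.append(
                ParsedResidue(
                    chain_id=chain.name,
                    seq_id=res.seqid.num,
                    icode=(res.seqid.icode or "").strip(),
                    name=name,
                    atom_coords=coords,
                )
            )
        if residues:
            # author order, insertion codes after their base number
            residues.sort(key=lambda r: (r.seq_id, r.icode))
            chains[chain.name] = residues
    if not chains:
        raise ValueError(f"no polymer residues in {path}")
    return chains


def parse_selection(text: str) -> tuple[str, list[tuple[int, int]] | None]:
    """Parse ``"chain[:start-end[,start-end...]]"`` (author numbering).

    Returns ``(chain_id, ranges)`` with ``ranges=None`` for a whole chain.
    """
    text = text.strip()
    if not text:
        raise ValueError("empty selection")
    if ":" not in text:
        return text, None
    chain_id, _, spec = text.partition(":")
    chain_id = chain_id.strip()
    if not chain_id:
        raise ValueError(f"selection {text!r} has no chain id")
    ranges: list[tuple[int, int]] = []
    for token in spec.split(","):
        token = token.strip()
        if not token:
            raise ValueError(f"empty range in selection {text!r}")
        if "-" in token[1:]:  # allow negative start numbers
            head, tail = token[1:].split("-", 1)
            start, end = int(token[0] + head), int(tail)
        else:
            start = end = int(token)
        if end < start:
            raise ValueError(f"range endpoints reversed in {token!r}")
        ranges.append((start, end))
    return chain_id, ranges


def build_unit(
    chains: Mapping[str, Sequence[ParsedResidue]],
    selections: str | Sequence[str],
    scale: Mapping[str, float] | None = None,
    label: str | None = None,
    provenance: str = "",
) -> StructuralUnit:
    """Assemble a :class:`StructuralUnit` from chain/range selections.

    ``selections`` is one selection string or a sequence of them (see
    :func:`parse_selection`); residues appear in selection order, each chain
    internally in author-sequence order.  Intrinsic hydrophobicities come
    from ``scale`` (default: the shipped normalized hydropathy scale);
    residue names absent from the scale are an error.
    """
    if isinstance(selections, str):
        selections = [selections]
    if scale is None:
        scale = default_scale()

    points: list[ResiduePoint] = []
    for sel in selections:
        chain_id, ranges = parse_selection(sel)
        if chain_id not in chains:
            raise KeyError(
                f"chain {chain_id!r} not found; available: {sorted(chains)}"
            )
        residues = list(chains[chain_id])
        if ranges is not None:
            kept: list[ParsedResidue] = []
            for start, end in ranges:
                hit = [r for r in residues if start <= r.seq_id <= end]
                if not hit:
                    raise ValueError(f"range {chain_id}:{start}-{end} selects no residues")
                if len(hit) < end - start + 1:
                    warnings.warn(
                        f"range {chain_id}:{start}-{end} has gaps "
                        f"({len(hit)}/{end - start + 1} present)",
                        stacklevel=2,
                    )
                kept.extend(hit)
            residues = sorted({r.key: r for r in kept}.values(),
                              key=lambda r: (r.seq_id, r.icode))
        for r in residues:
            if r.name not in scale:
                raise KeyError(
                    f"residue {r.name} at {r.chain_id}:{r.seq_id} has no "
                    "intrinsic hydrophobicity in the active scale"
                )
            points.append(
                ResiduePoint(
                    chain_id=r.chain_id,
                    seq_id=r.seq_id,
                    icode=r.icode,
                    name=r.name,
                    position=tuple(effective_atom(r.atom_coords)),
                    hydrophobicity=float(scale[r.name]),
                )
            )
    return StructuralUnit(
        label=label or "+".join(selections),
        residues=tuple(points),
        provenance=provenance or f"selection={'+'.join(selections)}",
    )
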