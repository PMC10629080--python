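"""Synthetic residue point clouds with controlled hydrophobicity ordering.

The generator realises the regimes the hydrophobicity-field analysis is
meant to distinguish, as bare point clouds:

* ``micelle`` — hydrophobic-in / polar-out: the highest intrinsic
  hydrophobicities are assigned to the positions of highest Gaussian
  density (the centre), so the observed field approximates the theoretical
  one and RD comes out low;
* ``inverted`` — the membrane-like opposite: hydrophobicity exposed at the
  surface, polar centre, high RD and high K;
* ``shuffled`` — no relation between position and hydrophobicity;
* ``interpolated`` — a tunable mix: a fraction ``alpha`` of
  centre/surface rank pairs of the micelle assignment are swapped, sweeping
  continuously from micelle (alpha=0) to inverted (alpha=1).

Positions are drawn from the encapsulating Gaussian truncated at three
sigma, one pseudo-atom per residue.  Units serialise to minimal CA-only PDB
files (a deliberately non-physical test format: no backbone geometry, no
sequence design) so the structure-reading path is testable offline.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Literal, Mapping

import numpy as np

from .scales import default_scale
from .structure import ResiduePoint, StructuralUnit

__all__ = [
    "GeneratorConfig",
    "ComplexFixture",
    "generate",
    "generate_complex_fixture",
    "write_pdb",
]

Ordering = Literal["micelle", "inverted", "shuffled", "interpolated"]

#: Chain identifiers used for multi-chain fixtures, in placement order.
_CHAIN_IDS = "ABCDEFGH"


@dataclass(frozen=True)
class GeneratorConfig:
    """Study conditions for one synthetic unit.

    Defaults model a ~100-residue globule: sigmas (6, 5, 4) Å give a
    three-sigma ellipsoid of roughly the volume of a 100-residue protein
    (~135 Å^3 per residue).  ``seed`` fully determines the output.
    """

    n_residues: int = 100
    ellipsoid_sigmas: tuple[float, float, float] = (6.0, 5.0, 4.0)
    ordering: Ordering = "micelle"
    alpha: float = 0.0            # only for ordering="interpolated"
    seed: int = 0
    n_chains: int = 1
    chain_offset: float | None = None   # Å between chain centres; default 6*sx+12
    patch_size: int = 10          # planted contact residues per chain pair
    scale: Mapping[str, float] | None = None

    def __post_init__(self) -> None:
        if self.n_residues < 10:
            raise ValueError("n_residues must be >= 10 for field tests")
        if self.ordering == "interpolated" and not 0.0 <= self.alpha <= 1.0:
            raise ValueError("alpha must lie in [0, 1]")
        if self.n_chains < 1 or self.n_chains > len(_CHAIN_IDS):
            raise ValueError(f"n_chains must be in 1..{len(_CHAIN_IDS)}")


def _sample_truncated_gaussian(
    rng: np.random.Generator, n: int, sigmas: np.ndarray
) -> np.ndarray:
    """n points from N(0, diag(sigmas^2)) truncated at 3 sigma per axis."""
    out = np.empty((0, 3))
    while out.shape[0] < n:
        draw = rng.normal(0.0, 1.0, size=(2 * n, 3))
        keep = np.all(np.abs(draw) <= 3.0, axis=1)
        out = np.vstack([out, draw[keep] * sigmas])
    return out[:n]


def _assign_hydrophobicities(
    rng: np.random.Generator,
    positions: np.ndarray,
    sigmas: np.ndarray,
    ordering: Ordering,
    alpha: float,
    scale: Mapping[str, float],
) -> tuple[np.ndarray, list[str]]:
    """Assign intrinsic hydrophobicities and residue names by ordering regime."""
    n = positions.shape[0]
    names20 = sorted(scale)
    drawn = [names20[i] for i in rng.integers(0, len(names20), size=n)]
    h_pool = np.array([scale[name] for name in drawn])

    # density rank: 0 = closest to the centre of the Gaussian
    density = -0.5 * np.sum((positions / sigmas) ** 2, axis=1)
    density_rank = np.argsort(np.argsort(-density, kind="stable"), kind="stable")

    h_desc = np.sort(h_pool)[::-1]
    if ordering == "micelle":
        assigned_rank = h_desc
    elif ordering == "inverted":
        assigned_rank = h_desc[::-1]
    elif ordering == "shuffled":
        assigned_rank = rng.permutation(h_pool)
    elif ordering == "interpolated":
        assigned_rank = h_desc.copy()
        n_pairs = n // 2
        n_swap = int(round(alpha * n_pairs))
        which = rng.choice(n_pairs, size=n_swap, replace=False)
        for k in which:
            j = n - 1 - k
            assigned_rank[[k, j]] = assigned_rank[[j, k]]
    else:  # pragma: no cover
        raise ValueError(f"unknown ordering {ordering!r}")

    h = assigned_rank[density_rank]
    # nearest-value mapping back to residue identities
    by_value = {}
    for name in names20:
        by_value.setdefault(scale[name], name)
    values = np.array(sorted(by_value))
    names = []
    for hv in h:
        nearest = values[np.argmin(np.abs(values - hv))]
        names.append(by_value[float(nearest)])
    return h, names


def _make_chain(
    rng: np.random.Generator,
    config: GeneratorConfig,
    chain_id: str,
    center: np.ndarray,
    scale: Mapping[str, float],
) -> list[ResiduePoint]:
    sigmas = np.asarray(config.ellipsoid_sigmas, float)
    pos = _sample_truncated_gaussian(rng, config.n_residues, sigmas)
    h, names = _assign_hydrophobicities(
        rng, pos, sigmas, config.ordering, config.alpha, scale
    )
    return [
        ResiduePoint(
            chain_id=chain_id,
            seq_id=i + 1,
            icode="",
            name=names[i],
            position=tuple(pos[i] + center),
            hydrophobicity=float(h[i]),
        )
        for i in range(config.n_residues)
    ]


def generate(config: GeneratorConfig) -> StructuralUnit:
    """Generate one synthetic unit (``n_chains`` chains side by side)."""
    rng = np.random.default_rng(config.seed)
    scale = dict(config.scale) if config.scale is not None else default_scale()
    sx = config.ellipsoid_sigmas[0]
    offset = config.chain_offset if config.chain_offset is not None else 6.0 * sx + 12.0
    residues: list[ResiduePoint] = []
    for c in range(config.n_chains):
        center = np.array([c * offset, 0.0, 0.0])
        residues.extend(_make_chain(rng, config, _CHAIN_IDS[c], center, scale))
    return StructuralUnit(
        label=f"synthetic-{config.ordering}-n{config.n_residues}-s{config.seed}",
        residues=tuple(residues),
        provenance=f"generated: {config}",
    )


@dataclass(frozen=True)
class ComplexFixture:
    """A multi-chain unit with a planted, known contact patch."""

    complex_unit: StructuralUnit
    chains: dict[str, StructuralUnit]
    planted_interface: dict[str, tuple[int, ...]]   # chain id -> seq ids
    config: GeneratorConfig

    def ground_truth(self) -> dict:
        return {
            "ordering": self.config.ordering,
            "seed": self.config.seed,
            "planted_interface": {c: list(s) for c, s in self.planted_interface.items()},
        }


def generate_complex_fixture(config: GeneratorConfig, max_attempts: int = 20) -> ComplexFixture:
    """A multi-chain fixture whose interface residues are known by design.

    Chains are placed along x with centres ``chain_offset`` apart (default
    leaves a 12 Å body gap, beyond the 9 Å contact radius, so chain bodies
    do not touch).  For every adjacent chain pair, ``patch_size`` residues
    of each chain are repositioned into the gap as matched pairs 5 Å apart
    across the interface — these planted residues are the ground-truth
    interface.  Arrangements with any inter-chain distance below 2 Å are
    rejected and resampled with a fresh derived seed.
    """
    if config.n_chains < 2:
        raise ValueError("complex fixture needs n_chains >= 2")
    scale = dict(config.scale) if config.scale is not None else default_scale()
    sigmas = np.asarray(config.ellipsoid_sigmas, float)
    sx = sigmas[0]
    offset = config.chain_offset if config.chain_offset is not None else 6.0 * sx + 12.0
    gap = offset - 6.0 * sx

    for attempt in range(max_attempts):
        rng = np.random.default_rng(config.seed + 100_003 * attempt)
        per_chain: dict[str, list[ResiduePoint]] = {}
        planted: dict[str, set[int]] = {c: set() for c in _CHAIN_IDS[: config.n_chains]}
        for c in range(config.n_chains):
            cid = _CHAIN_IDS[c]
            center = np.array([c * offset, 0.0, 0.0])
            per_chain[cid] = _make_chain(rng, config, cid, center, scale)

        for c in range(config.n_chains - 1):
            left, right = _CHAIN_IDS[c], _CHAIN_IDS[c + 1]
            mid_x = c * offset + 3.0 * sx + gap / 2.0
            k = min(config.patch_size, config.n_residues)
            idx_left = rng.choice(config.n_residues, size=k, replace=False)
            idx_right = rng.choice(config.n_residues, size=k, replace=False)
            yz = rng.uniform(-min(sigmas[1:]), min(sigmas[1:]), size=(k, 2))
            for p, (il, ir) in enumerate(zip(idx_left, idx_right)):
                for side, idx, x in (
                    (left, il, mid_x - 2.5),
                    (right, ir, mid_x + 2.5),
                ):
                    old = per_chain[side][idx]
                    per_chain[side][idx] = replace(
                        old, position=(x, float(yz[p, 0]), float(yz[p, 1]))
                    )
                    planted[side].add(old.seq_id)

        chains = {
            cid: StructuralUnit(cid, tuple(res), provenance="synthetic complex chain")
            for cid, res in per_chain.items()
        }
        all_res = tuple(r for cid in sorted(per_chain) for r in per_chain[cid])
        complex_unit = StructuralUnit(
            label=f"synthetic-complex-{config.n_chains}x{config.n_residues}-s{config.seed}",
            residues=all_res,
            provenance=f"generated: {config}",
        )
        if _min_interchain_distance(chains) >= 2.0:
            return ComplexFixture(
                complex_unit=complex_unit,
                chains=chains,
                planted_interface={c: tuple(sorted(s)) for c, s in planted.items()},
                config=config,
            )
    raise RuntimeError("could not place non-overlapping chains")


def _min_interchain_distance(chains: Mapping[str, StructuralUnit]) -> float:
    from scipy.spatial.distance import cdist

    ids = sorted(chains)
    best = np.inf
    for i, a in enumerate(ids):
        for b in ids[i + 1:]:
            best = min(best, cdist(chains[a].positions, chains[b].positions).min())
    return float(best)


def write_pdb(unit: StructuralUnit, path: str | Path, ground_truth: dict | None = None) -> None:
    """Serialise a unit as a minimal CA-only PDB file, one atom per residue.

    The single pseudo-atom is placed at the effective-atom position, so a
    round-trip through the structure reader reproduces the unit to PDB
    column precision (1e-3 Å).  If ``ground_truth`` is given it is written
    alongside as ``<path>.json``.
    """
    path = Path(path)
    lines = []
    for serial, r in enumerate(unit.residues, 1):
        x, y, z = r.position
        lines.append(
            f"ATOM  {serial:>5}  CA  {r.name:<3} {r.chain_id[:1]}{r.seq_id:>4}"
            f"{(r.icode or ' '):1}   {x:8.3f}{y:8.3f}{z:8.3f}  1.00  0.00"
            f"           C"
        )
    lines.append("END")
    path.write_text("\n".join(lines) + "\n")
    if ground_truth is not None:
        Path(str(path) + ".json").write_text(json.dumps(ground_truth, indent=2) + "\n")
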