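"""Fragment-level statistics, interfaces, residue elimination, T-status shifts.

RD is defined for any structural unit, but also for any fragment of one: the
parent unit's T and O profiles are restricted to the fragment's members and
renormalised, and the divergences are taken against the fragment-uniform
reference.  RD < 0.5 then reads "this fragment participates in the central
hydrophobic core".

Interfaces between chains are defined on effective atoms: a residue belongs
to the interface iff its effective atom lies within a cutoff (default the
9 Å interaction radius) of any effective atom of the partner chain.  The
resulting partition (interface vs rest, or per contacting partner) feeds the
same fragment-RD machinery.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy.spatial.distance import cdist

from .model import (
    DEFAULT_K_GRID,
    INTERACTION_CUTOFF,
    HydroProfile,
    UnitReport,
    kl_divergence,
    m_profile,
    optimize_k,
)
from .structure import FragmentSelection, StructuralUnit

__all__ = [
    "FragmentSummary",
    "ContactPartition",
    "EliminationResult",
    "TStatusChange",
    "fragment_rd",
    "detect_interface",
    "contact_classes",
    "partition_rd",
    "greedy_eliminate_to_core",
    "t_status_compare",
]


@dataclass(frozen=True)
class FragmentSummary:
    """(RD, K) of one fragment, computed on fragment-renormalised profiles."""

    label: str
    indices: tuple[int, ...]
    rd: float
    k_opt: float
    dkl_OT: float
    dkl_OR: float
    dkl_OM_at_kopt: float
    n_eliminated: int | None = None

    @property
    def size(self) -> int:
        return len(self.indices)

    @property
    def has_core(self) -> bool:
        return self.rd < 0.5


def _restrict(profile: HydroProfile, indices: Sequence[int], kind: str) -> HydroProfile:
    v = np.asarray(profile.values, float)[list(indices)]
    s = v.sum()
    if s <= 0:
        raise ValueError("fragment profile sums to zero; cannot renormalise")
    return HydroProfile(kind, v / s, normalization_constant=float(s))


def fragment_rd(
    report: UnitReport,
    fragment: FragmentSelection | Sequence[int],
    k_grid: Sequence[float] | None = None,
    label: str = "",
) -> FragmentSummary:
    """RD and K of a fragment inside its parent unit's frame.

    The parent's T and O (already evaluated in the parent frame) are
    restricted to the fragment members and renormalised; the uniform
    reference becomes 1/N_frag.  Fragments of fewer than 2 residues are
    degenerate and rejected.
    """
    if isinstance(fragment, FragmentSelection):
        indices = fragment.member_indices
        label = label or fragment.label
    else:
        indices = tuple(sorted(set(int(i) for i in fragment)))
    if len(indices) < 2:
        raise ValueError("fragment must have at least 2 residues for RD")
    t = _restrict(report.T, indices, "T")
    o = _restrict(report.O, indices, "O")
    r = HydroProfile("R", np.full(len(indices), 1.0 / len(indices)))
    d_ot = kl_divergence(o, t)
    d_or = kl_divergence(o, r)
    rd = d_ot / (d_ot + d_or)
    k_opt, d_om = optimize_k(o, t, k_grid)
    return FragmentSummary(
        label=label or f"{report.unit.label}[{len(indices)}]",
        indices=indices,
        rd=rd,
        k_opt=k_opt,
        dkl_OT=d_ot,
        dkl_OR=d_or,
        dkl_OM_at_kopt=d_om,
    )


@dataclass(frozen=True)
class ContactPartition:
    """Interface membership between two units (symmetric by construction)."""

    label_a: str
    label_b: str
    interface_a: tuple[int, ...]   # indices into unit A
    interface_b: tuple[int, ...]   # indices into unit B
    cutoff: float

    def split(self, unit: StructuralUnit, side: str) -> tuple[tuple[int, ...], tuple[int, ...]]:
        """(P-P, NoP-P) index partition of one side's unit."""
        iface = set(self.interface_a if side == "a" else self.interface_b)
        pp = tuple(i for i in range(unit.size) if i in iface)
        nopp = tuple(i for i in range(unit.size) if i not in iface)
        return pp, nopp


def detect_interface(
    unit_a: StructuralUnit,
    unit_b: StructuralUnit,
    cutoff: float = INTERACTION_CUTOFF,
) -> ContactPartition:
    """Residues of each unit within ``cutoff`` Å of the other unit.

    Distance is between effective atoms; membership is symmetric (a pair
    within the cutoff flags both partners).
    """
    d = cdist(unit_a.positions, unit_b.positions)
    close = d <= cutoff
    ia = tuple(int(i) for i in np.flatnonzero(close.any(axis=1)))
    ib = tuple(int(j) for j in np.flatnonzero(close.any(axis=0)))
    return ContactPartition(unit_a.label, unit_b.label, ia, ib, cutoff)


def contact_classes(
    unit: StructuralUnit,
    partners: Mapping[str, StructuralUnit],
    cutoff: float = INTERACTION_CUTOFF,
    free_label: str = "free",
) -> dict[str, tuple[int, ...]]:
    """Partition a unit's residues by which partner unit(s) they contact.

    Returns ``{partner_label: indices, ..., free_label: indices}``.  A
    residue contacting several partners appears under each of them; the
    ``free_label`` class collects residues contacting none.
    """
    classes: dict[str, tuple[int, ...]] = {}
    engaged = np.zeros(unit.size, dtype=bool)
    for name, partner in partners.items():
        part = detect_interface(unit, partner, cutoff)
        classes[name] = part.interface_a
        engaged[list(part.interface_a)] = True
    classes[free_label] = tuple(int(i) for i in np.flatnonzero(~engaged))
    return classes


def partition_rd(
    report: UnitReport,
    classes: Mapping[str, Sequence[int]],
    k_grid: Sequence[float] | None = None,
) -> dict[str, FragmentSummary]:
    """Fragment RD/K for every class of a residue partition.

    Classes with fewer than 2 members are reported as absent (omitted from
    the result), not as errors.
    """
    out: dict[str, FragmentSummary] = {}
    for name, indices in classes.items():
        if len(indices) < 2:
            continue
        out[name] = fragment_rd(report, indices, k_grid=k_grid, label=name)
    return out


@dataclass(frozen=True)
class EliminationResult:
    """Greedy residue-elimination trace toward RD < threshold."""

    eliminated: tuple[int, ...]        # original unit indices, removal order
    eliminated_keys: tuple[tuple[str, int, str], ...]
    rd_history: tuple[float, ...]      # RD before any removal, then after each
    threshold: float
    reached: bool

    @property
    def n_eliminated(self) -> int:
        return len(self.eliminated)

    @property
    def final_rd(self) -> float:
        return self.rd_history[-1]


def _rd_after_single_removal(o: np.ndarray, t: np.ndarray) -> np.ndarray:
    """RD of the renormalised (o, t) after removing each index in turn.

    Closed form: with a_i = 1 - o_i and b_i = 1 - t_i,
      D(o'|t') = [S_OT - o_i log2(o_i/t_i)] / a_i + log2(b_i / a_i)
      D(o'|r') = [S_O  - o_i log2(o_i)]     / a_i - log2(a_i) + log2(n - 1)
    where S_OT = sum o log2(o/t), S_O = sum o log2 o over the current set.
    """
    n = o.size
    with np.errstate(divide="ignore", invalid="ignore"):
        term_ot = np.where(o > 0, o * np.log2(o / t), 0.0)
        term_o = np.where(o > 0, o * np.log2(o), 0.0)
    s_ot = term_ot.sum()
    s_o = term_o.sum()
    a = 1.0 - o
    b = 1.0 - t
    d_ot = (s_ot - term_ot) / a + np.log2(b / a)
    d_or = (s_o - term_o) / a - np.log2(a) + np.log2(n - 1)
    return d_ot / (d_ot + d_or)


def greedy_eliminate_to_core(
    report: UnitReport,
    threshold: float = 0.5,
    min_size: int = 3,
) -> EliminationResult:
    """Greedy steepest-descent elimination of residues until RD < threshold.

    At each step the residue whose removal (with renormalisation of the
    retained T and O entries) yields the lowest RD is removed; ties break
    toward the lowest index, i.e. the lowest author number in unit order.
    Stops when RD drops below the threshold, when the unit would shrink
    below ``min_size``, or when no single removal strictly decreases RD
    (reported with ``reached=False``).
    """
    o = np.asarray(report.O.values, float).copy()
    t = np.asarray(report.T.values, float).copy()
    alive = list(range(o.size))
    d_ot = kl_divergence(o, t)
    d_or = kl_divergence(o, np.full(o.size, 1.0 / o.size))
    rd = d_ot / (d_ot + d_or)
    history = [rd]
    removed: list[int] = []
    while rd >= threshold and len(alive) > min_size:
        cand = _rd_after_single_removal(o, t)
        best = int(np.argmin(cand))
        if not cand[best] < rd:
            break
        removed.append(alive.pop(best))
        o = np.delete(o, best)
        t = np.delete(t, best)
        o /= o.sum()
        t /= t.sum()
        rd = float(cand[best])
        history.append(rd)
    unit = report.unit
    return EliminationResult(
        eliminated=tuple(removed),
        eliminated_keys=tuple(unit.residues[i].key for i in removed),
        rd_history=tuple(history),
        threshold=threshold,
        reached=rd < threshold,
    )


_NO_CHANGE = "no_change"
_EXCESS = "excess_in_before"
_DEFICIENCY = "deficiency_in_before"


@dataclass(frozen=True)
class TStatusChange:
    """Per-residue theoretical-status comparison between two conformations.

    ``delta = T_before - T_after`` on matched residues; above the threshold
    the residue shows an *excess* of theoretical hydrophobicity in the
    "before" form (it sat closer to the centre there), below the negative
    threshold a *deficiency* (it moved toward the centre in "after").
    """

    matched_keys: tuple[tuple[str, int, str], ...]
    before_indices: tuple[int, ...]
    after_indices: tuple[int, ...]
    t_before: np.ndarray
    t_after: np.ndarray
    threshold: float

    @property
    def delta(self) -> np.ndarray:
        return self.t_before - self.t_after

    @property
    def classes(self) -> np.ndarray:
        d = self.delta
        out = np.full(d.size, _NO_CHANGE, dtype=object)
        out[d > self.threshold] = _EXCESS
        out[d < -self.threshold] = _DEFICIENCY
        return out

    def crosstab(self, contact_map: Mapping[str, Iterable[int]]) -> "pd.DataFrame":
        """Contact-class (rows) x change-class (columns) residue counts.

        ``contact_map`` maps class labels to *before-unit* residue indices;
        each matched residue is counted once per contact class containing
        it, so row sums equal the matched sizes of the contact classes.
        """
        import pandas as pd

        cls = self.classes
        by_before = {b: k for k, b in enumerate(self.before_indices)}
        cols = [_NO_CHANGE, _EXCESS, _DEFICIENCY]
        rows = {}
        for name, indices in contact_map.items():
            counts = dict.fromkeys(cols, 0)
            for i in indices:
                k = by_before.get(int(i))
                if k is not None:
                    counts[cls[k]] += 1
            rows[name] = counts
        return pd.DataFrame.from_dict(rows, orient="index", columns=cols)


def t_status_compare(
    report_before: UnitReport,
    report_after: UnitReport,
    mapping: Mapping[int, int] | None = None,
    threshold: float | None = None,
) -> TStatusChange:
    """Compare per-residue T status between two conformations of a chain.

    ``mapping`` sends before-unit indices to after-unit indices; when omitted
    residues are matched by author (seq_id, insertion-code) pairs, so
    regions present in only one form (e.g. a cleaved N-terminal fragment)
    are excluded automatically.  The default threshold is half a uniform
    share of the before unit, 1/(2 N_before).
    """
    before, after = report_before.unit, report_after.unit
    if mapping is None:
        after_by_num = {(r.seq_id, r.icode): j for j, r in enumerate(after.residues)}
        mapping = {
            i: after_by_num[(r.seq_id, r.icode)]
            for i, r in enumerate(before.residues)
            if (r.seq_id, r.icode) in after_by_num
        }
    if not mapping:
        raise ValueError("empty residue correspondence between the two units")
    if threshold is None:
        threshold = 1.0 / (2.0 * before.size)
    bi = tuple(sorted(mapping))
    ai = tuple(mapping[i] for i in bi)
    return TStatusChange(
        matched_keys=tuple(before.residues[i].key for i in bi),
        before_indices=bi,
        after_indices=ai,
        t_before=np.asarray(report_before.T.values, float)[list(bi)],
        t_after=np.asarray(report_after.T.values, float)[list(ai)],
        threshold=float(threshold),
    )
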