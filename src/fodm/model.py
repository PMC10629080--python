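"""The fuzzy-oil-drop hydrophobicity fields and their divergence statistics.

A water-soluble globular protein is idealised as a spherical micelle:
hydrophobic residues buried, polar residues exposed.  The idealised
hydrophobicity density is a 3D Gaussian spanned over the molecule
(*theoretical* profile T).  The hydrophobicity actually encoded in the
structure (*observed* profile O) is obtained from pairwise inter-residue
interactions weighted by Levitt's polynomial within a 9 Å cutoff.  Both are
normalised to unit sum and compared with Kullback–Leibler divergence in bits:

    RD = D_KL(O|T) / (D_KL(O|T) + D_KL(O|R)),

where R is the uniform profile 1/N.  RD < 0.5 indicates that the structure
carries a central hydrophobic core; RD > 0.5 that it does not.

A non-aqueous folding environment (membrane, chaperone) is represented by
mixing T with its normalised complement:

    M = [T + K * (Tmax - T)_n]_n   (subscript n = normalise to unit sum),

and K is chosen to minimise D_KL(O|M) on a grid.  K = 0 recovers the pure
water field; large K approaches the inverted (membrane-like) field.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
from scipy.spatial.distance import cdist

from .structure import StructuralUnit

__all__ = [
    "GaussianFrame",
    "HydroProfile",
    "FodSummary",
    "UnitReport",
    "DEFAULT_K_GRID",
    "INTERACTION_CUTOFF",
    "fit_gaussian_frame",
    "theoretical_profile",
    "observed_profile",
    "uniform_profile",
    "kl_divergence",
    "relative_distance",
    "m_profile",
    "optimize_k",
    "summarize_unit",
    "levitt_weight",
]

#: Levitt interaction cutoff c, Å.
INTERACTION_CUTOFF = 9.0

#: Default K search grid: 0.0 .. 5.0, step 0.1 (one-decimal precision).
DEFAULT_K_GRID: np.ndarray = np.round(np.arange(0.0, 5.0 + 1e-9, 0.1), 10)

_NORM_TOL = 1e-9


@dataclass(frozen=True)
class GaussianFrame:
    """Centre, principal axes and sigmas of the encapsulating 3D Gaussian."""

    center: np.ndarray      # (3,) Å
    rotation: np.ndarray    # (3, 3) rows = axes; maps world -> frame coords
    sigmas: np.ndarray      # (3,) Å, strictly positive

    def __post_init__(self) -> None:
        R = np.asarray(self.rotation, float)
        if not np.allclose(R @ R.T, np.eye(3), atol=1e-8):
            raise ValueError("rotation is not orthonormal")
        if not np.isclose(np.linalg.det(R), 1.0, atol=1e-8):
            raise ValueError("rotation determinant is not +1")
        if np.any(np.asarray(self.sigmas) <= 0):
            raise ValueError("sigmas must be strictly positive")

    def to_frame(self, positions: np.ndarray) -> np.ndarray:
        """World coordinates -> frame coordinates (centre at origin)."""
        return (np.asarray(positions, float) - self.center) @ np.asarray(self.rotation).T


@dataclass(frozen=True)
class HydroProfile:
    """A normalised per-residue hydrophobicity distribution."""

    kind: str               # "T", "O", "R" or "M"
    values: np.ndarray      # (N,) nonnegative, sums to 1
    normalization_constant: float = 1.0

    def __post_init__(self) -> None:
        v = np.asarray(self.values, float)
        if v.ndim != 1 or v.size < 2:
            raise ValueError("profile needs at least 2 entries")
        if np.any(v < 0):
            raise ValueError("profile entries must be nonnegative")
        if abs(v.sum() - 1.0) > _NORM_TOL:
            raise ValueError(f"profile {self.kind} sums to {v.sum()!r}, not 1")

    def __len__(self) -> int:
        return len(self.values)


@dataclass(frozen=True)
class FodSummary:
    """The (RD, K, D_KL) bundle describing one unit or fragment."""

    dkl_OT: float           # bits
    dkl_OR: float           # bits
    rd: float               # D_KL(O|T) / (D_KL(O|T) + D_KL(O|R))
    k_opt: float
    dkl_OM_at_kopt: float   # bits

    @property
    def has_core(self) -> bool:
        """RD < 0.5: the observed distribution carries a hydrophobic core."""
        return self.rd < 0.5


@dataclass(frozen=True)
class UnitReport:
    """Full single-call result: frame, all four profiles and the summary."""

    unit: StructuralUnit
    frame: GaussianFrame
    T: HydroProfile
    O: HydroProfile
    R: HydroProfile
    M: HydroProfile
    summary: FodSummary


def fit_gaussian_frame(
    unit: StructuralUnit,
    sigma_rule: str = "max_extent",
    sigma_floor: float = 1.0,
) -> GaussianFrame:
    """Fit the encapsulating Gaussian to a unit's effective atoms.

    The centre is the mean effective-atom position and the axes are the
    principal axes of the effective-atom covariance.  Sigma along each axis
    encapsulates the molecule at three sigma: ``max_extent`` sets
    sigma_j = max_i |coordinate_ij - centre_j| / 3, ``range6`` sets
    sigma_j = (max_j - min_j) / 6.  Sigmas are floored at ``sigma_floor``
    (default 1 Å); a zero-extent (collinear/degenerate) cloud is an error.
    """
    pts = unit.positions
    if pts.shape[0] < 3:
        raise ValueError("need at least 3 residues to fit a Gaussian frame")
    center = pts.mean(axis=0)
    centered = pts - center
    cov = centered.T @ centered / pts.shape[0]
    eigvals, eigvecs = np.linalg.eigh(cov)
    # descending eigenvalue order; rows of R are the axes
    order = np.argsort(eigvals)[::-1]
    R = eigvecs[:, order].T
    if np.linalg.det(R) < 0:
        R[2] *= -1.0
    local = centered @ R.T
    if sigma_rule == "max_extent":
        extent = np.abs(local).max(axis=0)
        sigmas = extent / 3.0
    elif sigma_rule == "range6":
        extent = local.max(axis=0) - local.min(axis=0)
        sigmas = extent / 6.0
    else:
        raise ValueError(f"unknown sigma_rule {sigma_rule!r}")
    if np.any(extent <= 0):
        raise ValueError("degenerate point cloud: zero extent along a principal axis")
    if np.any(sigmas < sigma_floor):
        import warnings

        warnings.warn(
            f"sigma below {sigma_floor} Å floored (near-degenerate extent)",
            stacklevel=2,
        )
    sigmas = np.maximum(sigmas, sigma_floor)
    return GaussianFrame(center=center, rotation=R, sigmas=sigmas)


def theoretical_profile(unit: StructuralUnit, frame: GaussianFrame) -> HydroProfile:
    """T profile: the 3D Gaussian evaluated at each effective atom."""
    local = frame.to_frame(unit.positions)
    log_t = -0.5 * np.sum((local / frame.sigmas) ** 2, axis=1)
    raw = np.exp(log_t)
    total = raw.sum()
    return HydroProfile("T", raw / total, normalization_constant=float(total))


def levitt_weight(r: np.ndarray, cutoff: float = INTERACTION_CUTOFF) -> np.ndarray:
    """Levitt's interaction polynomial; 1 at r=0, 0 at r>=cutoff."""
    t2 = np.clip(np.asarray(r, float) / cutoff, 0.0, None) ** 2
    w = 1.0 - 0.5 * (7.0 * t2 - 9.0 * t2**2 + 5.0 * t2**3 - t2**4)
    return np.where(r <= cutoff, w, 0.0)


def observed_profile(
    unit: StructuralUnit,
    cutoff: float = INTERACTION_CUTOFF,
    include_self: bool = False,
) -> HydroProfile:
    """O profile: distance-weighted pairwise hydrophobic interactions.

    Each residue collects, over partners within ``cutoff``, the pair sum of
    intrinsic hydrophobicities weighted by Levitt's polynomial.  The self
    term (r=0, which would add a constant 2 H_i) is excluded by default.
    """
    pos = unit.positions
    h = unit.hydrophobicities
    dist = cdist(pos, pos)
    w = levitt_weight(dist, cutoff)
    if not include_self:
        np.fill_diagonal(w, 0.0)
    pair_h = h[:, None] + h[None, :]
    raw = (pair_h * w).sum(axis=1)
    total = raw.sum()
    if total <= 0:
        raise ValueError(
            "no observed interactions: no residue pair interacts within "
            f"{cutoff} Å with nonzero pair hydrophobicity"
        )
    return HydroProfile("O", raw / total, normalization_constant=float(total))


def uniform_profile(unit_or_n: StructuralUnit | int) -> HydroProfile:
    """R profile: 1/N per residue — no hydrophobic differentiation."""
    n = unit_or_n if isinstance(unit_or_n, int) else unit_or_n.size
    if n < 2:
        raise ValueError("uniform profile needs N >= 2")
    return HydroProfile("R", np.full(n, 1.0 / n), normalization_constant=float(n))


def kl_divergence(p: HydroProfile | np.ndarray, q: HydroProfile | np.ndarray) -> float:
    """D_KL(P|Q) in bits; terms with P_i = 0 contribute zero."""
    pv = np.asarray(p.values if isinstance(p, HydroProfile) else p, float)
    qv = np.asarray(q.values if isinstance(q, HydroProfile) else q, float)
    if pv.shape != qv.shape:
        raise ValueError("profiles have different lengths")
    mask = pv > 0
    if np.any(qv[mask] <= 0):
        raise ValueError("divergence undefined: P_i > 0 where Q_i = 0")
    return float(np.sum(pv[mask] * np.log2(pv[mask] / qv[mask])))


def relative_distance(
    O: HydroProfile | np.ndarray,
    T: HydroProfile | np.ndarray,
    R: HydroProfile | np.ndarray | None = None,
) -> float:
    """RD = D_KL(O|T) / (D_KL(O|T) + D_KL(O|R)) in [0, 1]."""
    ov = np.asarray(O.values if isinstance(O, HydroProfile) else O, float)
    if R is None:
        R = np.full(ov.size, 1.0 / ov.size)
    d_ot = kl_divergence(O, T)
    d_or = kl_divergence(O, R)
    denom = d_ot + d_or
    if denom == 0.0:
        raise ValueError("RD undefined: O matches both T and R exactly")
    return d_ot / denom


def m_profile(T: HydroProfile, K: float) -> HydroProfile:
    """M profile: T mixed with its normalised complement, weight K.

    The complement C_i = Tmax - T_i is normalised to unit sum, then
    T + K * C_n is renormalised.  K = 0 returns T exactly.  A constant T
    (complement identically zero) yields M = T for any K, with a warning.
    """
    if K < 0:
        raise ValueError("K must be nonnegative")
    t = np.asarray(T.values, float)
    comp = t.max() - t
    csum = comp.sum()
    if csum <= 0:
        import warnings

        warnings.warn("T is constant; M equals T for any K", stacklevel=2)
        return HydroProfile("M", t.copy())
    if K == 0:
        return HydroProfile("M", t.copy())
    mixed = t + K * (comp / csum)
    return HydroProfile("M", mixed / mixed.sum(), normalization_constant=float(mixed.sum()))


def optimize_k(
    O: HydroProfile,
    T: HydroProfile,
    grid: Iterable[float] | None = None,
) -> tuple[float, float]:
    """Grid search for the K minimising D_KL(O | M(K)).

    Returns ``(k_opt, dkl_OM)``; ties break toward the smallest K.  The grid
    must contain 0 so that D_KL(O|M(k_opt)) <= D_KL(O|T) always holds.
    """
    ks = DEFAULT_K_GRID if grid is None else np.asarray(sorted(grid), float)
    if ks.size == 0:
        raise ValueError("empty K grid")
    if not np.any(np.isclose(ks, 0.0)):
        raise ValueError("K grid must include 0")
    import warnings

    best_k, best_d = None, np.inf
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # constant-T warning once is enough
        for k in ks:
            d = kl_divergence(O, m_profile(T, float(k)))
            if d < best_d - 1e-15:
                best_k, best_d = float(k), d
    return best_k, float(best_d)


def summarize_unit(
    unit: StructuralUnit,
    cutoff: float = INTERACTION_CUTOFF,
    k_grid: Sequence[float] | None = None,
    frame: GaussianFrame | None = None,
    sigma_rule: str = "max_extent",
) -> UnitReport:
    """One call: frame, T, O, R, M(k_opt), D_KLs, RD and K for a unit.

    ``frame`` may be supplied to evaluate the unit inside an enclosing
    complex frame; by default the frame is fitted to the unit itself.
    """
    if frame is None:
        frame = fit_gaussian_frame(unit, sigma_rule=sigma_rule)
    T = theoretical_profile(unit, frame)
    O = observed_profile(unit, cutoff=cutoff)
    R = uniform_profile(unit)
    d_ot = kl_divergence(O, T)
    d_or = kl_divergence(O, R)
    rd = d_ot / (d_ot + d_or)
    k_opt, d_om = optimize_k(O, T, k_grid)
    M = m_profile(T, k_opt)
    summary = FodSummary(dkl_OT=d_ot, dkl_OR=d_or, rd=rd, k_opt=k_opt,
                         dkl_OM_at_kopt=d_om)
    return UnitReport(unit=unit, frame=frame, T=T, O=O, R=R, M=M, summary=summary)
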