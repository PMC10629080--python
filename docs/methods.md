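# Methods

## Fields and statistics

A structural unit is an ordered list of residues, each reduced to one
effective atom — the unweighted mean of its heavy-atom coordinates
(backbone and side chain; glycine averages its four backbone atoms;
hydrogens never contribute) — plus an intrinsic hydrophobicity in [0, 1].

**Theoretical field T.** A single 3D Gaussian is spanned over the unit. The
fitting rule is a design choice of this package: the centre is the mean
effective-atom position; the axes are the principal axes of the
effective-atom covariance (so the result is invariant under rigid motion of
the coordinates); and σ along each axis is the maximal absolute extent
along that axis divided by 3, i.e. the 3σ ellipsoid just encapsulates the
molecule. An alternative rule σ = range/6 is available
(`sigma_rule="range6"`). σ values are floored at 1 Å with a warning;
point clouds with zero extent along a principal axis (collinear or planar)
are rejected. T is the Gaussian density at the effective atoms, normalised
to unit sum.

**Observed field O.** For each residue, the sum over all other residues
within the 9 Å cutoff of `(H_i^r + H_j^r) · w(r_ij/c)` with Levitt's
polynomial weight `w(t) = 1 − ½(7t² − 9t⁴ + 5t⁶ − t⁸)`; `w(0) = 1`,
`w(1) = 0`. The self term (r = 0, a constant 2H_i^r) is excluded by
default and can be included via `include_self=True`. A unit in which no
pair interacts is rejected explicitly ("no observed interactions") rather
than returning an undefined profile.

**Divergences.** D_KL uses base-2 logarithms with the convention
`0·log(0/q) = 0`; `P_i > 0` where `Q_i = 0` is an error. RD is
`D_KL(O|T) / (D_KL(O|T) + D_KL(O|R))`; RD < 0.5 is read as "hydrophobic
core present". The environment-modified field is
`M = [T + K·(T_max − T)_n]_n`, with the complement normalised first and the
mixture renormalised afterwards; `T_max` is taken over the normalised T of
the same unit, and K = 0 returns T bit-for-bit. K is selected by exhaustive
search over a grid (default 0.0–5.0, step 0.1, matching the one-decimal
resolution at which K values are conventionally reported); ties break
toward the smallest K, and because 0 is always in the grid,
`D_KL(O|M(K_opt)) ≤ D_KL(O|T)` holds unconditionally.

## Intrinsic hydrophobicity scale

The analysis is parameterised by a 20-value scale. The shipped default is
the Kyte–Doolittle hydropathy index min–max normalised to [0, 1]
(ILE = 1, ARG = 0); any other scale can be supplied as a two-column text
file. Published analyses of this kind use a calibration that is not
publicly tabulated, so absolute RD/K values computed here can differ from
published figures by a scale-dependent offset; the comparisons in the test
suite therefore carry tolerances of ±0.05 on RD and ±0.2 on K rather than
printed-precision equality.

## Fragments, interfaces, elimination, T-status

*Fragments* restrict the parent unit's T and O to the selected members
(author-numbered inclusive ranges; insertion codes sort after their base
number), renormalise both, and compare against the fragment-uniform
1/N_frag. A fragment equal to the whole unit reproduces the global RD
exactly. This is also how chains are scored as components of a complex.

*Interfaces* are defined on effective atoms: residue i of chain A is in the
interface with chain B iff its effective atom is within the contact cutoff
of any effective atom of B. The cutoff defaults to the 9 Å interaction
radius, making "in contact" and "interacting" coincide; it is configurable.
Contact classes (per-partner and "free") and P-P/NoP-P partitions feed the
fragment machinery.

*Greedy elimination* removes, at each step, the residue whose removal —
with renormalisation of the retained T and O entries, not a recomputation
of O — lowers RD the most, until RD drops below the threshold (default
0.5), the unit reaches 3 residues, or no single removal strictly decreases
RD. Ties break toward the lowest position in unit order (lowest author
number). The per-candidate RD after removal is evaluated in closed form
from the current profile sums, which makes each step O(N); the closed form
is verified against a brute-force rescan in the tests. Published
elimination counts were produced by an unspecified rule, so they are
treated as factor-of-two checks, not exact targets; a one-shot ranking by
|T_i − O_i| was considered and rejected as a default because it cannot
guarantee monotone RD descent.

*T-status comparison* matches residues of two conformations by author
numbering (or an explicit index mapping), takes ΔT = T_before − T_after on
each unit's own normalised T, and classifies residues as unchanged, excess
(ΔT above threshold) or deficiency (below −threshold) in the "before" form.
The default threshold is half a uniform share, 1/(2N_before): a residue
must gain or lose at least half an average residue's worth of theoretical
hydrophobicity to count as moved. No numeric rule is standard here; this
one is scale-free and configurable.

## Synthetic study conditions

The generator emulates the hydrophobicity-ordering regimes the statistics
are meant to distinguish. Positions are drawn from the encapsulating
Gaussian truncated at 3σ, one pseudo-atom per residue; defaults are 100
residues and σ = (6, 5, 4) Å, giving a 3σ ellipsoid of roughly the volume
of a 100-residue globular protein (~135 Å³ per residue). Intrinsic
hydrophobicities are drawn uniformly from the active 20-value scale and
assigned to positions by rank: highest hydrophobicity to highest Gaussian
density ("micelle"), the reverse ("inverted"), at random ("shuffled"), or
with a fraction α of centre/surface rank pairs swapped ("interpolated",
sweeping continuously from micelle at α = 0 to inverted at α = 1). Residue
identities are the nearest-scale-value amino acids, so serialised fixtures
carry consistent names.

Complex fixtures place chains along x with a 12 Å body gap (beyond the 9 Å
contact radius) and then reposition a chosen number of residues per chain
pair into the gap as matched pairs 5 Å apart — the planted, ground-truth
interface. Arrangements with any inter-chain distance under 2 Å are
resampled from a derived seed.

What the generator does **not** emulate: chain connectivity and backbone
geometry, side-chain packing, sequence correlations, secondary structure,
crystallographic noise, missing residues. Passing tests on generated units
therefore demonstrate the correctness and discriminative behaviour of the
statistics under controlled ordering, not quantitative agreement with any
particular crystal structure; the crystal-structure comparisons in the test
suite cover that separately when the structure files are available.

## Numerical choices and limitations

- All profile arithmetic is double precision; normalisation constants are
  retained on each profile for diagnostics, and profile sums are enforced
  to 1 within 1e−9.
- Principal-axis frames inherit the eigenvector sign/order conventions of
  the symmetric eigensolver; since T depends only on squared coordinates
  over σ², results are insensitive to axis sign, and rigid-motion
  invariance of RD and K holds to 1e−9 (tested).
- Altloc atoms: the highest-occupancy conformer is kept per atom name, ties
  broken by altloc identifier order. Only the first model of a multi-model
  file is read. Waters, ligands and nucleic acids are excluded; MSE is
  mapped to MET by default via a configurable modified-residue table.
- Author numbering is preserved everywhere; ranges select what exists and
  warn on gaps. Sequential re-indexing is never performed.
- Problem sizes in the test suite and acceptance script (units of 100
  residues, 5–20 seeds per statistic) were chosen as the smallest sizes at
  which the ordering regimes separate cleanly and seed-to-seed variance is
  small relative to the separations being asserted.
- RD is a global summary: two very different local mismatch patterns can
  give the same RD. The per-residue profile TSV and the elimination trace
  are provided for exactly that reason.
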