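# Full analysis of the chaperone-client system: Hsp40/DnaJ dimer holding the
# unfolded alkaline-phosphatase client (PDB 6PSI, chains A, C, B) versus the
# folded phosphatase dimer (PDB 1EW8, chains A, B).
#
# Place the two structure files under data/structures/ (relative to the
# repository root) and run, from the repository root:
#
#   fodm table examples/crystal_structures.yaml
#
# Units score a selection inside its own fitted Gaussian; fragments restrict
# a parent unit's profiles (the component-of-complex view); partitions give
# the P-P / NoP-P and per-partner contact statistics; eliminations count the
# residues removed to reach RD < 0.5; the comparison classifies per-residue
# T-status changes between the unfolded and folded client.

structures:
  phoa_wt: ../data/structures/1EW8.pdb
  hsp40: ../data/structures/6PSI.cif

output_dir: crystal-out
cutoff: 9.0
k_grid: {max: 5.0, step: 0.1}

units:
  # folded client (1EW8)
  - {label: PhoA-AB, structure: phoa_wt, select: [A, B]}
  - {label: PhoA-A, structure: phoa_wt, select: [A]}
  - {label: PhoA-B, structure: phoa_wt, select: [B]}
  # chaperone complex and its chains (6PSI)
  - {label: Hsp40-Complex, structure: hsp40, select: [A, C, B]}
  - {label: Hsp40-AC, structure: hsp40, select: [A, C]}
  - {label: Hsp40-A, structure: hsp40, select: [A]}
  - {label: Hsp40-C, structure: hsp40, select: [C]}
  - {label: PhoA-U, structure: hsp40, select: [B]}
  # pseudo-domains of a single chaperone chain
  - {label: pd1, structure: hsp40, select: ["A:1-107"]}
  - {label: pd2, structure: hsp40, select: ["A:1-115"]}
  - {label: pd3, structure: hsp40, select: ["A:1-115,163-170"]}
  - {label: pd4, structure: hsp40, select: ["A:116-162,171-182"]}
  - {label: pd5, structure: hsp40, select: ["A:183-257"]}
  - {label: pd6, structure: hsp40, select: ["A:262-280"]}
  - {label: pd7, structure: hsp40, select: ["A:183-280"]}

fragments:
  # chains scored as components of their complex (complex-frame columns)
  - {label: PhoA-A@AB, unit: PhoA-AB, select: A}
  - {label: PhoA-B@AB, unit: PhoA-AB, select: B}
  - {label: Hsp40-A@Complex, unit: Hsp40-Complex, select: A}
  - {label: Hsp40-C@Complex, unit: Hsp40-Complex, select: C}
  - {label: PhoA-U@Complex, unit: Hsp40-Complex, select: B}
  # catalytic neighbourhoods (author position +/- 5) and disulfide segments
  - {label: CAT102, unit: PhoA-AB, select: "A:97-107"}
  - {label: CAT166, unit: PhoA-AB, select: "A:161-171"}
  - {label: SS168-178, unit: PhoA-AB, select: "A:168-178"}
  - {label: SS286-336, unit: PhoA-AB, select: "A:286-336"}

partitions:
  - {label: PhoA-A-interface, unit: PhoA-A, partners: {B: PhoA-B}}
  - {label: PhoA-U-contacts, unit: PhoA-U,
     partners: {Hsp40-A: Hsp40-A, Hsp40-C: Hsp40-C}}

eliminations:
  - {label: elim-PhoA-A, unit: PhoA-A, threshold: 0.5}
  - {label: elim-pd1, unit: pd1, threshold: 0.5}
  - {label: elim-pd5, unit: pd5, threshold: 0.5}

comparisons:
  # unfolded client vs its chain in the folded dimer, matched by author number
  - {label: PhoA-U-vs-WT, before: PhoA-U, after: PhoA-A,
     contacts: {Hsp40-A: Hsp40-A, Hsp40-C: Hsp40-C}}
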