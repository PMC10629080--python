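"""Deterministic TSV/JSON writers for profiles, summaries and comparisons."""

from __future__ import annotations

import json
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .analysis import EliminationResult, FragmentSummary, TStatusChange
from .model import UnitReport

__all__ = [
    "profile_frame",
    "write_profile_tsv",
    "unit_summary_dict",
    "fragment_summary_dict",
    "write_json",
    "comparison_frame",
]

_FLOAT_FMT = "%.10g"


def profile_frame(report: UnitReport) -> pd.DataFrame:
    """Per-residue profile table: chain, author id, name, T, O, R, M, |T-O|."""
    unit = report.unit
    return pd.DataFrame(
        {
            "chain": [r.chain_id for r in unit.residues],
            "author_seq_id": [r.seq_id for r in unit.residues],
            "icode": [r.icode for r in unit.residues],
            "residue_name": [r.name for r in unit.residues],
            "T": report.T.values,
            "O": report.O.values,
            "R": report.R.values,
            "M": report.M.values,
            "abs_T_minus_O": np.abs(report.T.values - report.O.values),
        }
    )


def write_profile_tsv(report: UnitReport, path: str | Path) -> None:
    profile_frame(report).to_csv(path, sep="\t", index=False, float_format=_FLOAT_FMT)


def unit_summary_dict(report: UnitReport) -> dict:
    s = report.summary
    return {
        "unit_label": report.unit.label,
        "n_residues": report.unit.size,
        "dkl_OT": s.dkl_OT,
        "dkl_OR": s.dkl_OR,
        "rd": s.rd,
        "k_opt": s.k_opt,
        "dkl_OM": s.dkl_OM_at_kopt,
        "has_core": s.has_core,
        "frame": {
            "center": [float(x) for x in report.frame.center],
            "sigmas": [float(x) for x in report.frame.sigmas],
        },
        "normalization": {
            "T": report.T.normalization_constant,
            "O": report.O.normalization_constant,
        },
    }


def fragment_summary_dict(summary: FragmentSummary) -> dict:
    out = {
        "unit_label": summary.label,
        "n_residues": summary.size,
        "dkl_OT": summary.dkl_OT,
        "dkl_OR": summary.dkl_OR,
        "rd": summary.rd,
        "k_opt": summary.k_opt,
        "dkl_OM": summary.dkl_OM_at_kopt,
        "has_core": summary.has_core,
    }
    if summary.n_eliminated is not None:
        out["n_eliminated"] = summary.n_eliminated
    return out


def elimination_dict(result: EliminationResult) -> dict:
    return {
        "threshold": result.threshold,
        "reached": result.reached,
        "n_eliminated": result.n_eliminated,
        "final_rd": result.final_rd,
        "rd_history": list(result.rd_history),
        "eliminated": [
            {"chain": c, "author_seq_id": s, "icode": i}
            for c, s, i in result.eliminated_keys
        ],
    }


def comparison_frame(change: TStatusChange, contact_of: Mapping[int, str] | None = None) -> pd.DataFrame:
    """Per-residue comparison table: author id, T before/after, delta, class."""
    rows = {
        "chain": [k[0] for k in change.matched_keys],
        "author_seq_id": [k[1] for k in change.matched_keys],
        "icode": [k[2] for k in change.matched_keys],
        "T_before": change.t_before,
        "T_after": change.t_after,
        "delta_T": change.delta,
        "class": change.classes,
    }
    if contact_of is not None:
        rows["contact_class"] = [
            contact_of.get(i, "free") for i in change.before_indices
        ]
    return pd.DataFrame(rows)


def write_json(data: dict, path: str | Path) -> None:
    Path(path).write_text(json.dumps(data, indent=2, sort_keys=True) + "\n")
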