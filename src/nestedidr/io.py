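"""Reading and writing the TSV artifacts.

Interchange format: tab-separated text with a header row; the first column
is ``candidate_id``, the remaining columns are replicate scores (higher =
stronger evidence).  A lab grouping maps each replicate column to a lab.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .estimation import ScoreMatrix
from .model import StudyDesign
from .scoring import PosteriorScores, prefix_mean_alpha
from .simulate import SimTruth

__all__ = [
    "read_score_matrix",
    "write_score_matrix",
    "write_truth",
    "read_truth",
    "write_posterior_scores",
]

log = logging.getLogger(__name__)


def _design_from_grouping(columns, grouping: dict[str, int] | list[int]) -> tuple[StudyDesign, list]:
    """Build a StudyDesign from a column -> lab mapping; returns the design
    and the column order (grouped by lab, original order within a lab)."""
    if isinstance(grouping, dict):
        missing = [c for c in columns if c not in grouping]
        if missing:
            raise ValueError(f"columns not assigned to any lab: {missing}")
        labs = [int(grouping[c]) for c in columns]
    else:
        if len(grouping) != len(columns):
            raise ValueError("grouping list must cover every score column")
        labs = [int(g) for g in grouping]
    uniq = sorted(set(labs))
    order = [i for lab in uniq for i, g in enumerate(labs) if g == lab]
    M = tuple(labs.count(lab) for lab in uniq)
    names = tuple(columns[i] for i in order)
    return StudyDesign(M=M, column_names=names), order


def read_score_matrix(path, grouping: dict[str, int] | list[int]) -> ScoreMatrix:
    """Read a TSV score table and group its columns by lab.

    Rows containing any missing value are dropped (with a logged count);
    duplicate candidate ids and non-numeric cells are fatal.
    """
    df = pd.read_csv(path, sep="\t")
    if df.shape[1] < 2:
        raise ValueError("expected a candidate_id column plus score columns")
    id_col = df.columns[0]
    ids = df[id_col].astype(str)
    dup = ids[ids.duplicated()].unique()
    if dup.size:
        raise ValueError(f"duplicate candidate ids: {list(dup[:5])}")
    score_cols = list(df.columns[1:])
    body = df[score_cols].apply(pd.to_numeric, errors="coerce")
    bad_cols = [
        c for c in score_cols if body[c].isna().sum() > df[c].isna().sum()
    ]
    if bad_cols:
        raise ValueError(f"non-numeric values in columns: {bad_cols}")
    keep = body.notna().all(axis=1)
    n_drop = int((~keep).sum())
    if n_drop:
        log.warning("dropped %d rows with missing values", n_drop)
    body, ids = body[keep], ids[keep]
    design, order = _design_from_grouping(score_cols, grouping)
    x = body.to_numpy(dtype=float)[:, order]
    return ScoreMatrix(x, design, ids.to_numpy())


def write_score_matrix(path, x: ScoreMatrix) -> None:
    df = pd.DataFrame(x.x, columns=list(x.design.column_names))
    df.insert(0, "candidate_id", x.candidate_ids)
    df.to_csv(path, sep="\t", index=False)


def write_truth(path, truth: SimTruth, candidate_ids) -> None:
    cols = {"candidate_id": candidate_ids, "G": truth.G}
    for l in range(truth.K.shape[1]):
        cols[f"K_{l + 1}"] = truth.K[:, l]
    pd.DataFrame(cols).to_csv(path, sep="\t", index=False)


def read_truth(path) -> SimTruth:
    df = pd.read_csv(path, sep="\t")
    k_cols = [c for c in df.columns if c.startswith("K_")]
    return SimTruth(df["G"].to_numpy(), df[k_cols].to_numpy())


def write_posterior_scores(path, scores: PosteriorScores) -> None:
    """TSV with idr_between, per-lab idr_within, and the smallest control
    level at which each candidate would be selected."""
    cols = {
        "candidate_id": scores.candidate_ids,
        "idr_between": scores.idr_between,
    }
    for l in range(scores.idr_within.shape[1]):
        cols[f"idr_within_lab{l + 1}"] = scores.idr_within[:, l]
    cols["prefix_mean_alpha"] = prefix_mean_alpha(scores.idr_between)
    pd.DataFrame(cols).to_csv(path, sep="\t", index=False, float_format="%.10g")
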