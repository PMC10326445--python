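"""Scaffold-independent analysis (SIA) scoring and motif calling.

SIA probes the nucleobase preference of a weak RNA-binding domain one
sequence position at a time: four quasi-degenerate 5-mer pools, each
fixing one position to A, C, G or U, are added to the protein and the
resulting chemical-shift perturbations compared.  The tighter the pool
binds, the further the fast-exchange peaks travel, so per-residue CSPs —
normalized and averaged — rank the four bases at that position.

Scored positions 1-4 correspond to oligo positions 2-5 of the 5-mer; the
unscored 5′ position is reported as a lowercase "n" in the called motif.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .binding import FitResult
from .csp import CSPWeights, weighted_csp
from .peaklist import PeakList
from .simulate import BASES, SCORED_POSITIONS, PoolSpec  # noqa: F401  (re-export)

logger = logging.getLogger(__name__)

__all__ = [
    "PoolSpec",
    "SIAScoreTable",
    "pool_csps",
    "sia_scores",
    "score_table",
    "call_motif",
]


@dataclass
class SIAScoreTable:
    """Normalized base-preference scores, 4 scored positions × 4 bases."""

    scores: pd.DataFrame  # index positions 1-4, columns A,C,G,U; values (0,1]
    peaks_used: list[str] = field(default_factory=list)
    normalization: str = "per_peak"

    def __post_init__(self) -> None:
        missing = [p for p in SCORED_POSITIONS if p not in self.scores.index]
        if missing:
            raise ValueError(f"score table missing scored positions {missing}")
        if list(self.scores.columns) != list(BASES):
            self.scores = self.scores[list(BASES)]

    def top_base(self, position: int) -> str:
        return str(self.scores.loc[position].idxmax())


def pool_csps(
    free: PeakList,
    bound: dict[str, PeakList],
    w: CSPWeights = CSPWeights(),
    residues: list[str] | None = None,
) -> pd.DataFrame:
    """CSP of each selected peak against the free spectrum, per pool.

    ``bound`` maps each base (A,C,G,U) to the peak list recorded with the
    pool fixing that base.  Returns a peaks × 4 DataFrame (ppm).  Residues
    missing from any pool are dropped with a warning naming them.
    """
    missing_bases = [b for b in BASES if b not in bound]
    if missing_bases:
        raise ValueError(f"missing pools for bases {missing_bases}")
    subset = residues if residues is not None else free.residue_ids
    rows, kept = [], []
    for rid in subset:
        ref = free.get(rid)
        if ref is None:
            logger.warning("residue %s absent from free spectrum; dropped", rid)
            continue
        vals = []
        for b in BASES:
            pk = bound[b].get(rid)
            if pk is None:
                logger.warning("residue %s absent from pool %s; dropped", rid, b)
                break
            vals.append(
                weighted_csp(pk.shift_h - ref.shift_h, pk.shift_n - ref.shift_n, w)
            )
        else:
            rows.append(vals)
            kept.append(rid)
    return pd.DataFrame(rows, index=kept, columns=list(BASES))


def sia_scores(
    csp_matrix: pd.DataFrame, normalization: str = "per_peak"
) -> pd.Series:
    """One score-table row: normalized, averaged CSPs for one position.

    ``per_peak`` (default): each peak's four CSPs are divided by that
    peak's maximum — every peak contributes equally — then averaged over
    peaks per base.  ``per_pool``: each pool's column is divided by its
    own maximum over peaks before averaging.  Peaks with all-zero CSPs
    carry no information and are dropped with a warning.
    """
    if csp_matrix.empty:
        raise ValueError("no peaks to score")
    if (csp_matrix.to_numpy() < 0).any():
        raise ValueError("CSP matrix must be non-negative")
    row_max = csp_matrix.max(axis=1)
    dead = row_max[row_max == 0].index
    if len(dead):
        logger.warning(
            "dropping peaks with all-zero CSPs (normalization undefined): %s",
            ", ".join(map(str, dead)),
        )
        csp_matrix = csp_matrix.drop(index=dead)
        if csp_matrix.empty:
            raise ValueError("all peaks had zero CSPs")
    if normalization == "per_peak":
        normed = csp_matrix.div(csp_matrix.max(axis=1), axis=0)
    elif normalization == "per_pool":
        normed = csp_matrix.div(csp_matrix.max(axis=0), axis=1)
    else:
        raise ValueError(f"unknown normalization {normalization!r}")
    return normed.mean(axis=0)


def score_table(
    rows: dict[int, pd.Series],
    peaks_used: list[str] | None = None,
    normalization: str = "per_peak",
) -> SIAScoreTable:
    """Assemble per-position score rows into a full table."""
    df = pd.DataFrame(dict(rows)).T.reindex(columns=list(BASES))
    df.index.name = "position"
    return SIAScoreTable(df, peaks_used or [], normalization)


def _position_call(
    scores: pd.Series, margin: float
) -> list[str]:
    """Bases within ``margin`` of the top score, best first."""
    ordered = scores.sort_values(ascending=False, kind="stable")
    top = float(ordered.iloc[0])
    return [b for b, v in ordered.items() if v >= top - margin]


def call_motif(
    table: SIAScoreTable,
    ambiguity_margin: float = 0.10,
    kd_refinements: dict[int, dict[str, FitResult]] | None = None,
) -> str:
    """Call the sequence-preference motif from a full SIA score table.

    Per position the top-scoring base is called; any base within
    ``ambiguity_margin`` (absolute score units) of the top is reported as
    an alternative ("X/Y").  A position where all four bases tie is fully
    ambiguous ("N").  If ``kd_refinements`` supplies follow-up binding
    fits for a position (base → FitResult), the tightest-K_D base among
    them resolves the ambiguity.  Output starts with the lowercase "n"
    of the unscored 5′ position; positions are dash-separated whenever
    any ambiguity remains, compacted to e.g. ``"nGGAC"`` otherwise.
    """
    kd_refinements = kd_refinements or {}
    parts = []
    for pos in SCORED_POSITIONS:
        alts = _position_call(table.scores.loc[pos], ambiguity_margin)
        if len(alts) > 1 and pos in kd_refinements:
            fits = kd_refinements[pos]
            usable = {
                b: f.aggregate_kd
                for b, f in fits.items()
                if np.isfinite(f.aggregate_kd)
            }
            if usable:
                alts = [min(usable, key=usable.get)]
        if len(alts) == 1:
            parts.append(alts[0])
        elif len(alts) >= len(BASES):
            parts.append("N")
        else:
            parts.append("/".join(alts))
    if all(len(p) == 1 and p != "N" for p in parts):
        return "n" + "".join(parts)
    return "n" + "-".join(parts)
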