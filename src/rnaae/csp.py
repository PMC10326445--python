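"""Weighted chemical-shift perturbations and titration trajectories.

The combined perturbation of an amide peak between two conditions is

    CSP = sqrt( (Δδ_H² + w_N·Δδ_N²) / 2 ),   w_N = 0.15 by default,

which down-weights the intrinsically larger ¹⁵N shift range so both
dimensions contribute comparably, and keeps ppm units.  A second variant,
in which the ¹⁵N difference is scaled before squaring (``(w_N·Δδ_N)²``),
is selectable; all downstream preference scores are ratios of CSPs of the
same peak and are therefore invariant to the choice.

Peaks are tracked across titration points either by their assignment
labels (when every spectrum is assigned) or by greedy nearest-neighbour
matching in weighted shift space — legitimate because fast-exchange peaks
move smoothly along the titration.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .peaklist import Peak, PeakList, TitrationSeries

logger = logging.getLogger(__name__)

__all__ = [
    "CSPWeights",
    "CSPProfile",
    "MatchedSeries",
    "weighted_csp",
    "match_peaks",
    "csp_profile",
    "select_responsive_residues",
]

MATCHED = "matched"
LOST = "lost"
AMBIGUOUS = "ambiguous"


@dataclass(frozen=True)
class CSPWeights:
    """Weights and formula variant for the combined shift perturbation.

    ``variant="half_sum_sqrt"`` (default): sqrt((h·Δδ_H² + n·Δδ_N²)/2).
    ``variant="scaled_n"``: sqrt(((h·Δδ_H)² + (n·Δδ_N)²)/2).
    """

    h_weight: float = 1.0
    n_weight: float = 0.15
    variant: str = "half_sum_sqrt"

    def __post_init__(self) -> None:
        if self.h_weight <= 0 or self.n_weight <= 0:
            raise ValueError("CSP weights must be positive")
        if self.variant not in ("half_sum_sqrt", "scaled_n"):
            raise ValueError(f"unknown CSP variant {self.variant!r}")


def weighted_csp(d_h, d_n, w: CSPWeights = CSPWeights()):
    """Combined ¹H/¹⁵N shift perturbation in ppm (vectorized).

    Symmetric in the sign of both inputs; zero iff both are zero.
    """
    d_h = np.asarray(d_h, dtype=float)
    d_n = np.asarray(d_n, dtype=float)
    if not (np.all(np.isfinite(d_h)) and np.all(np.isfinite(d_n))):
        raise ValueError("non-finite shift difference")
    if w.variant == "half_sum_sqrt":
        out = np.sqrt((w.h_weight * d_h**2 + w.n_weight * d_n**2) / 2.0)
    else:
        out = np.sqrt(((w.h_weight * d_h) ** 2 + (w.n_weight * d_n) ** 2) / 2.0)
    return float(out) if out.ndim == 0 else out


def _peak_distance(a: Peak, b: Peak, w: CSPWeights) -> float:
    return weighted_csp(a.shift_h - b.shift_h, a.shift_n - b.shift_n, w)


@dataclass
class MatchedSeries:
    """A titration series with peaks chained to the reference assignments.

    ``flags[residue][i]`` records whether the residue's peak at titration
    point *i* was matched, lost, or matched ambiguously.
    """

    series: TitrationSeries
    flags: dict[str, list[str]]


@dataclass
class CSPProfile:
    """Per-residue weighted-CSP trajectories against the free reference.

    ``values`` is residues × ratios (ppm; NaN where the peak was lost),
    ``flags`` the matching status per point.
    """

    values: pd.DataFrame
    flags: pd.DataFrame

    @property
    def residues(self) -> list[str]:
        return list(self.values.index)

    @property
    def ratios(self) -> np.ndarray:
        return self.values.columns.to_numpy(dtype=float)

    def to_csv(self, path) -> None:
        self.values.to_csv(path, index_label="residue")


def match_peaks(
    series: TitrationSeries,
    w: CSPWeights = CSPWeights(),
    max_step: float = 0.1,
    ambiguity_factor: float = 0.10,
) -> MatchedSeries:
    """Chain each reference peak across consecutive titration points.

    When every spectrum carries the same assignment labels the chain is
    the identity by label.  Otherwise peaks are assigned greedily by
    minimum weighted-CSP distance from the previous point, one-to-one,
    rejecting steps larger than ``max_step`` ppm.  A peak whose two best
    candidates lie within ``ambiguity_factor`` (relative) of each other is
    matched but flagged ambiguous.  Unmatched points are flagged lost and
    never interpolated; the track resumes from its last known position.
    """
    ref = series.reference
    track_ids = ref.residue_ids
    flags: dict[str, list[str]] = {rid: [MATCHED] for rid in track_ids}
    matched_lists: list[PeakList] = [ref]
    last_pos: dict[str, Peak] = {rid: ref.get(rid) for rid in track_ids}

    for pl in series.peaklists[1:]:
        if set(pl.residue_ids) == set(track_ids):
            # fully assigned spectrum: labels short-circuit tracking
            ordered = [pl.get(rid) for rid in track_ids]
            matched_lists.append(
                PeakList(ordered, pl.spectrum_label, pl.condition)
            )
            for rid, pk in zip(track_ids, ordered):
                flags[rid].append(MATCHED)
                last_pos[rid] = pk
            continue

        candidates = list(pl.peaks)
        dist = {
            (rid, j): _peak_distance(last_pos[rid], pk, w)
            for rid in track_ids
            for j, pk in enumerate(candidates)
        }
        assigned: dict[str, tuple[int, bool]] = {}
        free_tracks = set(track_ids)
        free_peaks = set(range(len(candidates)))
        while free_tracks and free_peaks:
            pairs = [
                (dist[rid, j], rid, j)
                for rid in free_tracks
                for j in free_peaks
                if dist[rid, j] <= max_step
            ]
            if not pairs:
                break
            d, rid, j = min(pairs)
            # ambiguity is a property of the distance structure, judged
            # against every candidate peak, not only unassigned ones
            rivals = sorted(
                dist[rid, k]
                for k in range(len(candidates))
                if k != j and dist[rid, k] <= max_step
            )
            ambiguous = bool(rivals) and rivals[0] <= d * (1 + ambiguity_factor)
            assigned[rid] = (j, ambiguous)
            free_tracks.remove(rid)
            free_peaks.remove(j)

        ordered = []
        for rid in track_ids:
            if rid in assigned:
                j, ambiguous = assigned[rid]
                pk = Peak(
                    rid,
                    candidates[j].shift_h,
                    candidates[j].shift_n,
                    candidates[j].intensity,
                )
                ordered.append(pk)
                flags[rid].append(AMBIGUOUS if ambiguous else MATCHED)
                last_pos[rid] = pk
            else:
                flags[rid].append(LOST)
        if not ordered:
            # keep the list non-empty: carry the reference forward as lost
            ordered = [last_pos[track_ids[0]]]
        matched_lists.append(PeakList(ordered, pl.spectrum_label, pl.condition))

    matched = TitrationSeries(
        protein_conc=series.protein_conc,
        ratios=series.ratios,
        peaklists=matched_lists,
        oligo=series.oligo,
    )
    return MatchedSeries(matched, flags)


def csp_profile(
    matched: MatchedSeries | TitrationSeries, w: CSPWeights = CSPWeights()
) -> CSPProfile:
    """CSP of every tracked residue at every ratio, against ratio 0."""
    if isinstance(matched, TitrationSeries):
        matched = match_peaks(matched, w)
    series, flags = matched.series, matched.flags
    ref = series.reference
    ratios = list(series.ratios)
    rows, frows, kept = [], [], []
    for rid in ref.residue_ids:
        ref_pk = ref.get(rid)
        if ref_pk is None:
            logger.warning("residue %s absent from reference; excluded", rid)
            continue
        vals, fl = [0.0], [MATCHED]
        for i, pl in enumerate(series.peaklists[1:], start=1):
            status = flags[rid][i]
            if status == LOST:
                vals.append(np.nan)
            else:
                pk = pl.get(rid)
                vals.append(_peak_distance(ref_pk, pk, w))
            fl.append(status)
        rows.append(vals)
        frows.append(fl)
        kept.append(rid)
    values = pd.DataFrame(rows, index=kept, columns=ratios)
    flag_df = pd.DataFrame(frows, index=kept, columns=ratios)
    return CSPProfile(values, flag_df)


def select_responsive_residues(
    profile: CSPProfile, min_fold: float = 3.0, quantile: float = 0.2
) -> list[str]:
    """Residues whose final-point CSP clears a data-driven noise floor.

    The floor is the median final-point CSP of the ``quantile`` least
    shifted residues; residues above ``min_fold`` times the floor are
    selected.  With noiseless data the floor can be 0, in which case any
    residue that moved at all is kept.
    """
    final = profile.values.iloc[:, -1].dropna()
    if final.empty:
        return []
    n_floor = max(1, int(round(quantile * len(final))))
    floor = float(final.nsmallest(n_floor).median())
    threshold = min_fold * floor
    return [rid for rid, v in final.items() if v > threshold]


def estimate_noise_floor(profile: CSPProfile, quantile: float = 0.2) -> float:
    """Noise-floor estimate: median final CSP of the least-shifted residues."""
    final = profile.values.iloc[:, -1].dropna()
    if final.empty:
        return float("nan")
    n_floor = max(1, int(round(quantile * len(final))))
    return float(final.nsmallest(n_floor).median())
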