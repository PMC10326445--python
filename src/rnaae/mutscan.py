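"""Affinity-enhancing (AE) mutant-candidate scanning.

Two rule sets, one per domain family:

* **KH** — the GxxG loop contacts the RNA backbone and tolerates
  mutation.  Loops whose two enclosed residues carry no positive charge
  (no K or R) are candidates for the GKKG affinity enhancement, which
  adds two backbone-contacting lysines without touching base readout.
* **RRM** — canonical single-stranded RNA binding uses three hallmark
  hydrophobic residues on the β-sheet plus a charged anchor residue
  contacting the backbone.  Sequences in an alignment that keep the
  hydrophobic hallmarks but lack K/R at the anchor column are candidates
  for a K (or R) anchor mutation.

All reported coordinates are 1-based inclusive on the ungapped sequence.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

from Bio import SeqIO

__all__ = [
    "DomainCandidate",
    "GxxGLocus",
    "find_gxxg_loops",
    "flag_ae_candidates_kh",
    "flag_ae_candidates_rrm",
    "read_fasta",
]

AA20 = set("ACDEFGHIKLMNPQRSTVWY")
POSITIVE = {"K", "R"}
HYDROPHOBIC = set("AVLIMFWY")
# glycine would spawn ambiguous overlapping motifs; proline cannot adopt
# the loop geometry
DEFAULT_EXCLUDED_INNER = frozenset("GP")


@dataclass(frozen=True)
class GxxGLocus:
    """One GxxG loop match: 1-based inclusive span and inner residues."""

    start: int
    end: int
    inner: str


@dataclass(frozen=True)
class DomainCandidate:
    """A proposed affinity-enhancing mutation site."""

    protein_id: str
    domain_kind: str  # "KH" or "RRM"
    site_start: int  # 1-based, ungapped
    site_end: int
    wild_type_site: str
    proposed_mutation: str
    rationale_flags: tuple[str, ...] = ()


def read_fasta(path: str | Path) -> list[tuple[str, str]]:
    """(id, sequence) pairs from a FASTA file (gaps preserved)."""
    return [(rec.id, str(rec.seq).upper()) for rec in SeqIO.parse(str(path), "fasta")]


def find_gxxg_loops(
    sequence: str,
    region: tuple[int, int] | None = None,
    excluded_inner: frozenset[str] = DEFAULT_EXCLUDED_INNER,
) -> list[GxxGLocus]:
    """All G-X-X-G matches with X outside ``excluded_inner`` ({G, P}).

    ``region`` restricts the search to a 1-based inclusive window (e.g.
    annotated KH-domain bounds).  Overlapping matches are all reported.
    """
    sequence = sequence.upper()
    bad = set(sequence) - AA20
    if bad:
        raise ValueError(f"invalid amino-acid characters: {sorted(bad)}")
    lo, hi = (1, len(sequence)) if region is None else region
    loci = []
    for i in range(lo - 1, min(hi, len(sequence)) - 3):
        window = sequence[i : i + 4]
        if (
            window[0] == "G"
            and window[3] == "G"
            and not set(window[1:3]) & excluded_inner
        ):
            loci.append(GxxGLocus(start=i + 1, end=i + 4, inner=window[1:3]))
    return loci


def flag_ae_candidates_kh(
    loci: list[GxxGLocus], sequence: str, protein_id: str = ""
) -> list[DomainCandidate]:
    """GxxG loops with no positive charge inside become GKKG proposals.

    A single K or R among the two enclosed residues disqualifies the
    loop — it already makes the backbone contact the mutation would add.
    """
    out = []
    for locus in loci:
        if set(locus.inner) & POSITIVE:
            continue
        out.append(
            DomainCandidate(
                protein_id=protein_id,
                domain_kind="KH",
                site_start=locus.start,
                site_end=locus.end,
                wild_type_site=f"G{locus.inner}G",
                proposed_mutation="GKKG",
                rationale_flags=("no-positive-charge-in-gxxg-loop",),
            )
        )
    return out


def _ungapped_index(gapped: str, column: int) -> int | None:
    """Map a 1-based alignment column to a 1-based ungapped index."""
    if gapped[column - 1] in "-.":
        return None
    return column - gapped[:column].count("-") - gapped[:column].count(".")


def flag_ae_candidates_rrm(
    alignment: list[tuple[str, str]],
    anchor_column: int,
    hallmark_columns: tuple[int, int, int],
) -> tuple[list[DomainCandidate], list[tuple[str, str]]]:
    """Anchor-position K/R proposals for canonically RNA-binding RRMs.

    ``alignment`` is (id, gapped sequence) pairs of equal aligned length;
    ``anchor_column`` and the three ``hallmark_columns`` are 1-based
    alignment columns taken from a reference annotation.  A sequence is a
    candidate when the anchor holds a non-gap, non-K/R residue and all
    three hallmark columns hold hydrophobic residues (canonical β-sheet
    binding mode).  Returns (candidates, excluded) where each exclusion
    names the failed criterion.
    """
    if len(hallmark_columns) != 3:
        raise ValueError("exactly three hallmark columns are required")
    lengths = {len(seq) for _, seq in alignment}
    if len(lengths) > 1:
        raise ValueError("aligned sequences must share one length")
    aln_len = lengths.pop() if lengths else 0
    for col in (anchor_column, *hallmark_columns):
        if not 1 <= col <= aln_len:
            raise ValueError(f"column {col} out of range 1..{aln_len}")
    candidates, excluded = [], []
    for pid, gapped in alignment:
        gapped = gapped.upper()
        anchor = gapped[anchor_column - 1]
        if anchor in "-.":
            excluded.append((pid, "gap-at-anchor"))
            continue
        if anchor in POSITIVE:
            excluded.append((pid, "already-charged-anchor"))
            continue
        hallmarks = [gapped[c - 1] for c in hallmark_columns]
        if any(h not in HYDROPHOBIC for h in hallmarks):
            excluded.append((pid, "non-canonical-binding-mode"))
            continue
        site = _ungapped_index(gapped, anchor_column)
        candidates.append(
            DomainCandidate(
                protein_id=pid,
                domain_kind="RRM",
                site_start=site,
                site_end=site,
                wild_type_site=anchor,
                proposed_mutation="K",
                rationale_flags=(
                    "uncharged-anchor",
                    "hallmark-hydrophobics-present",
                ),
            )
        )
    return candidates, excluded
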