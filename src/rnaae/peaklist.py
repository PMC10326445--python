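"""Assigned peak-list I/O and titration bookkeeping.

A peak list is the exported form of an assigned 2D ¹H-¹⁵N correlation
spectrum (HSQC/HMQC): one row per backbone amide, carrying the assignment
label and the two chemical shifts in ppm.  Two dialects are supported:

* ``csv`` — minimal comma-separated table ``assignment,1H_ppm,15N_ppm[,intensity]``
  (header optional on read, always written);
* ``sparky_list`` — the conventional assigned-list text format with an
  ``Assignment  w1  w2`` header, where w1 is the ¹⁵N and w2 the ¹H
  dimension, as in amide-detected Sparky exports.

Compound assignment labels such as ``G238N-H`` are reduced to the residue
label ``G238``.  All shifts are ppm and all concentrations μM throughout
the package; there is no unit-conversion layer.
"""

from __future__ import annotations

import csv as _csv
import logging
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import yaml

logger = logging.getLogger(__name__)

__all__ = [
    "Peak",
    "PeakList",
    "TitrationSeries",
    "PeakListError",
    "read_peak_list",
    "write_peak_list",
    "load_titration",
]

_LABEL_RE = re.compile(r"^([A-Za-z])(\d+)")


class PeakListError(ValueError):
    """Raised for malformed peak lists or titration configs."""


def normalize_label(raw: str) -> str:
    """Reduce an assignment label to ``<one-letter-aa><number>``.

    ``"G238N-H" -> "G238"``; already-minimal labels pass through.
    """
    m = _LABEL_RE.match(raw.strip())
    if not m:
        raise PeakListError(f"cannot parse assignment label {raw!r}")
    return f"{m.group(1).upper()}{m.group(2)}"


@dataclass(frozen=True)
class Peak:
    """One assigned backbone-amide cross peak."""

    residue_id: str
    shift_h: float  # ¹H chemical shift, ppm
    shift_n: float  # ¹⁵N chemical shift, ppm
    intensity: float | None = None

    def __post_init__(self) -> None:
        import math

        if not self.residue_id:
            raise PeakListError("residue_id must be non-empty")
        if not (math.isfinite(self.shift_h) and math.isfinite(self.shift_n)):
            raise PeakListError(
                f"non-finite chemical shift for {self.residue_id!r}"
            )


@dataclass
class PeakList:
    """An ordered collection of assigned peaks from one spectrum."""

    peaks: list[Peak]
    spectrum_label: str = ""
    condition: str = "free"  # "free" or "bound(<ratio>)"

    def __post_init__(self) -> None:
        if not self.peaks:
            raise PeakListError("PeakList must contain at least one peak")
        seen: set[str] = set()
        for p in self.peaks:
            if p.residue_id in seen:
                raise PeakListError(
                    f"duplicate assignment {p.residue_id!r} in "
                    f"{self.spectrum_label or 'peak list'}"
                )
            seen.add(p.residue_id)

    def __len__(self) -> int:
        return len(self.peaks)

    def __iter__(self):
        return iter(self.peaks)

    @property
    def residue_ids(self) -> list[str]:
        return [p.residue_id for p in self.peaks]

    def get(self, residue_id: str) -> Peak | None:
        for p in self.peaks:
            if p.residue_id == residue_id:
                return p
        return None


@dataclass
class TitrationSeries:
    """Peak lists for one protein titrated with one RNA ligand.

    ``ratios`` are protein:RNA molar ratios (RNA equivalents per protein),
    strictly increasing and starting at 0 (the free-protein reference).
    """

    protein_conc: float  # μM
    ratios: tuple[float, ...]
    peaklists: list[PeakList]
    oligo: str = ""

    def __post_init__(self) -> None:
        self.ratios = tuple(float(r) for r in self.ratios)
        if len(self.ratios) != len(self.peaklists):
            raise PeakListError("one peak list per ratio is required")
        if not self.ratios or self.ratios[0] != 0.0:
            raise PeakListError(
                "no free-protein reference: the series must start at ratio 0"
            )
        if any(b <= a for a, b in zip(self.ratios, self.ratios[1:])):
            raise PeakListError("ratios must be strictly increasing")
        if self.protein_conc <= 0:
            raise PeakListError("protein_conc must be positive (μM)")
        if self.oligo and not set(self.oligo) <= set("ACGUN"):
            raise PeakListError(f"oligo {self.oligo!r} not over A/C/G/U/N")

    @property
    def reference(self) -> PeakList:
        return self.peaklists[0]

    def __len__(self) -> int:
        return len(self.ratios)


def _detect_dialect(path: Path, dialect: str) -> str:
    if dialect != "auto":
        return dialect
    return "csv" if path.suffix.lower() == ".csv" else "sparky_list"


def read_peak_list(
    path: str | Path, dialect: str = "auto", spectrum_label: str | None = None
) -> PeakList:
    """Read an assigned peak list.

    ``dialect`` is one of ``csv``, ``sparky_list`` or ``auto``
    (``.csv`` extension → csv, anything else → sparky).
    """
    path = Path(path)
    dialect = _detect_dialect(path, dialect)
    if dialect not in ("csv", "sparky_list"):
        raise PeakListError(f"unknown dialect {dialect!r}")
    label = spectrum_label if spectrum_label is not None else path.stem
    peaks: list[Peak] = []
    with open(path, newline="") as fh:
        if dialect == "csv":
            for lineno, row in enumerate(_csv.reader(fh), start=1):
                if not row or not any(cell.strip() for cell in row):
                    continue
                # a header row is any row whose shift columns do not parse
                try:
                    sh, sn = float(row[1]), float(row[2])
                except (IndexError, ValueError):
                    if lineno == 1:
                        continue
                    raise PeakListError(
                        f"{path}: unparseable row at line {lineno}: {row!r}"
                    )
                inten = float(row[3]) if len(row) > 3 and row[3].strip() else None
                peaks.append(Peak(normalize_label(row[0]), sh, sn, inten))
        else:
            for lineno, line in enumerate(fh, start=1):
                stripped = line.strip()
                if not stripped or stripped.startswith(("Assignment", "#")):
                    continue
                tokens = stripped.split()
                try:
                    # w1 = ¹⁵N, w2 = ¹H in amide-detected lists
                    sn, sh = float(tokens[1]), float(tokens[2])
                except (IndexError, ValueError):
                    raise PeakListError(
                        f"{path}: unparseable row at line {lineno}: {stripped!r}"
                    )
                inten = float(tokens[3]) if len(tokens) > 3 else None
                peaks.append(Peak(normalize_label(tokens[0]), sh, sn, inten))
    if not peaks:
        raise PeakListError(f"{path}: no peaks found")
    return PeakList(peaks, spectrum_label=label)


def write_peak_list(pl: PeakList, path: str | Path, dialect: str = "auto") -> None:
    """Write a peak list losslessly (4 decimal places in ppm)."""
    path = Path(path)
    dialect = _detect_dialect(path, dialect)
    if dialect not in ("csv", "sparky_list"):
        raise PeakListError(f"unknown dialect {dialect!r}")
    with open(path, "w", newline="") as fh:
        if dialect == "csv":
            writer = _csv.writer(fh)
            writer.writerow(["assignment", "1H_ppm", "15N_ppm", "intensity"])
            for p in pl:
                writer.writerow(
                    [
                        p.residue_id,
                        f"{p.shift_h:.4f}",
                        f"{p.shift_n:.4f}",
                        "" if p.intensity is None else f"{p.intensity:.6g}",
                    ]
                )
        else:
            fh.write(f"{'Assignment':>16s} {'w1':>10s} {'w2':>10s}\n\n")
            for p in pl:
                fh.write(
                    f"{p.residue_id + 'N-H':>16s} {p.shift_n:10.4f} "
                    f"{p.shift_h:10.4f}\n"
                )


def load_titration(config_path: str | Path) -> TitrationSeries:
    """Load a titration series from a YAML config.

    Expected keys: ``protein_conc_uM``, ``oligo``, and ``spectra`` mapping
    each molar ratio to a peak-list path (relative paths are resolved
    against the config file's directory).  Entry order in the config is
    irrelevant; the series is sorted by ratio.  Peak lists whose residue
    sets differ from the reference are allowed — peaks broaden and vanish
    at higher ligand loads — but are logged.
    """
    config_path = Path(config_path)
    with open(config_path) as fh:
        cfg = yaml.safe_load(fh)
    for key in ("protein_conc_uM", "spectra"):
        if key not in cfg:
            raise PeakListError(f"{config_path}: missing config key {key!r}")
    entries = sorted(
        ((float(r), Path(p)) for r, p in cfg["spectra"].items()),
        key=lambda rp: rp[0],
    )
    if not entries or entries[0][0] != 0.0:
        raise PeakListError(
            f"{config_path}: no free-protein reference (ratio 0) in spectra"
        )
    base = config_path.parent
    peaklists = []
    for ratio, p in entries:
        pl = read_peak_list(p if p.is_absolute() else base / p)
        pl.condition = "free" if ratio == 0 else f"bound({ratio:g})"
        peaklists.append(pl)
    ref_ids = set(peaklists[0].residue_ids)
    for (ratio, _), pl in zip(entries, peaklists):
        diff = ref_ids.symmetric_difference(pl.residue_ids)
        if diff:
            logger.warning(
                "ratio %g: residue set differs from reference (%s)",
                ratio,
                ", ".join(sorted(diff)),
            )
    return TitrationSeries(
        protein_conc=float(cfg["protein_conc_uM"]),
        ratios=tuple(r for r, _ in entries),
        peaklists=peaklists,
        oligo=str(cfg.get("oligo", "")),
    )
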