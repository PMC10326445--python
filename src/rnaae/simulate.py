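"""Forward simulation of fast-exchange NMR titrations.

The ground truth is an additive (log-linear) sequence-affinity model: a
5-mer's dissociation constant is a reference K_D times independent fold
penalties for each non-preferred base at the four scored positions (oligo
positions 2-5; position 1 is unrecognized and free).  Quasi-degenerate
pools — all positions randomized except one — are simulated exactly by
solving the competitive multi-ligand equilibrium for the free protein
concentration, so pool spectra inherit the correct population-weighted
peak positions.

In fast exchange each synthetic amide peak moves from its free position
along a fixed direction by f_B·Δδ_max, where f_B is the fraction of
protein bound; directions have unit length in weighted-CSP space so the
trajectory's weighted CSP equals f_B·Δδ_max exactly.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from importlib import resources

import numpy as np
import yaml
from scipy.optimize import brentq

from .binding import fraction_bound
from .csp import CSPWeights
from .peaklist import Peak, PeakList, TitrationSeries

__all__ = [
    "ResidueParams",
    "SequenceAffinityModel",
    "MixtureEquilibrium",
    "PoolSpec",
    "sequence_kd",
    "enumerate_pool",
    "solve_competitive_equilibrium",
    "pool_effective_kd",
    "simulate_titration",
    "fmrp_fixture",
    "DEFAULT_RATIOS",
]

BASES = "ACGU"
SCORED_POSITIONS = (1, 2, 3, 4)  # map to oligo string indices 1..4
DEFAULT_RATIOS = (0.0, 0.5, 1.0, 2.0, 4.0, 6.0, 8.0, 10.0, 12.0)

_AA20 = "ACDEFGHIKLMNPQRSTVWY"


@dataclass(frozen=True)
class ResidueParams:
    """Free-state position, amplitude and direction of one synthetic amide."""

    residue_id: str
    free_h: float  # ppm
    free_n: float  # ppm
    dmax: float  # ppm, bound-state weighted-CSP amplitude
    dir_h: float  # unit direction in weighted-CSP space, ¹H component
    dir_n: float  # ¹⁵N component


@dataclass(frozen=True)
class PoolSpec:
    """A quasi-degenerate 5-mer pool with one fixed scored position."""

    position: int  # scored position 1-4
    base: str
    ratio: float = 4.0  # protein:RNA molar ratio used in the assay

    def __post_init__(self) -> None:
        if self.position not in SCORED_POSITIONS:
            raise ValueError("scored position must be 1-4")
        if self.base not in BASES:
            raise ValueError(f"base must be one of {BASES}")
        if self.ratio <= 0:
            raise ValueError("pool ratio must be positive")

    @property
    def oligo_pattern(self) -> str:
        """5-mer pattern with N's and the single fixed base."""
        pat = ["N"] * 5
        pat[self.position] = self.base  # scored pos p = oligo index p (pos p+1)
        return "".join(pat)


@dataclass
class SequenceAffinityModel:
    """Additive per-position affinity model mapping any 5-mer to a K_D."""

    kd_ref: float  # μM for the reference 5-mer
    reference: str
    penalties: dict[int, dict[str, float]]  # scored position -> base -> fold ≥ 1
    context_factor: float  # protein-variant fold multiplier (WT vs AE)
    residues: tuple[ResidueParams, ...]
    label: str = ""

    def __post_init__(self) -> None:
        if self.kd_ref <= 0 or self.context_factor <= 0:
            raise ValueError("kd_ref and context_factor must be positive")
        if len(self.reference) != 5 or not set(self.reference) <= set(BASES):
            raise ValueError("reference must be a 5-mer over A/C/G/U")
        for pos in SCORED_POSITIONS:
            table = self.penalties[pos]
            ref_base = self.reference[pos]
            if not np.isclose(table[ref_base], 1.0):
                raise ValueError(
                    f"reference base {ref_base} at scored position {pos} "
                    "must carry penalty 1"
                )
            if any(v < 1.0 for v in table.values()):
                raise ValueError("penalties are fold-multipliers ≥ 1")

    def kd(self, oligo: str) -> float:
        return sequence_kd(self, oligo)


def sequence_kd(model: SequenceAffinityModel, oligo: str) -> float:
    """K_D (μM) of a definite 5-mer under the additive model.

    Oligo position 1 (index 0) carries no penalty; scored positions 1-4
    read oligo indices 1-4.
    """
    if len(oligo) != 5 or not set(oligo) <= set(BASES):
        raise ValueError(f"oligo {oligo!r} must be a 5-mer over A/C/G/U")
    kd = model.kd_ref * model.context_factor
    for pos in SCORED_POSITIONS:
        kd *= model.penalties[pos][oligo[pos]]
    return kd


def enumerate_pool(pattern: str) -> list[str]:
    """All definite 5-mers matching a pattern with N wildcards."""
    if len(pattern) != 5 or not set(pattern) <= set(BASES + "N"):
        raise ValueError(f"pattern {pattern!r} must be a 5-mer over A/C/G/U/N")
    choices = [BASES if c == "N" else c for c in pattern]
    return ["".join(s) for s in itertools.product(*choices)]


@dataclass
class MixtureEquilibrium:
    """Solved competitive equilibrium of one protein and many ligands."""

    p_total: float  # μM
    species: list[tuple[float, float]]  # (total conc μM, kd μM)
    p_free: float
    bound: list[float]  # μM protein bound to each species

    @property
    def total_bound(self) -> float:
        return float(sum(self.bound))

    @property
    def fraction_bound(self) -> float:
        return self.total_bound / self.p_total


def solve_competitive_equilibrium(
    p_total: float, species: list[tuple[float, float]]
) -> MixtureEquilibrium:
    """Exact free-protein concentration for competing 1:1 ligands.

    Solves  p_free + Σ_i p_free·L_i / (kd_i + p_free) = p_total  by
    bracketed root finding on [0, p_total]; the left side is strictly
    increasing in p_free so the bracket always contains exactly one root.
    Residual is verified to < 1e-10 · p_total.
    """
    if p_total <= 0:
        raise ValueError("p_total must be positive")
    for conc, kd in species:
        if conc <= 0 or kd <= 0:
            raise ValueError("species concentrations and K_Ds must be positive")
    concs = np.array([c for c, _ in species])
    kds = np.array([k for _, k in species])

    def mass_balance(p_free: float) -> float:
        return p_free + float(np.sum(p_free * concs / (kds + p_free))) - p_total

    if not species:
        p_free = p_total
    else:
        p_free = brentq(mass_balance, 0.0, p_total, xtol=1e-15, rtol=8.9e-16)
    residual = abs(mass_balance(p_free))
    if residual > 1e-10 * p_total:  # pragma: no cover - brentq failure
        raise RuntimeError(f"equilibrium solver residual {residual:g} too large")
    bound = list(p_free * concs / (kds + p_free))
    return MixtureEquilibrium(p_total, list(species), float(p_free), bound)


def _pool_bound_fraction(
    model: SequenceAffinityModel, pattern: str, p: float, x: float
) -> float:
    """Fraction of protein bound to any member of a pool at ratio x."""
    if x == 0:
        return 0.0
    members = enumerate_pool(pattern)
    conc = x * p / len(members)
    species = [(conc, sequence_kd(model, seq)) for seq in members]
    return solve_competitive_equilibrium(p, species).fraction_bound


def pool_effective_kd(
    model: SequenceAffinityModel,
    pool: PoolSpec | str,
    method: str = "exact",
    protein_conc: float = 50.0,
    ratio: float | None = None,
) -> float:
    """Reduce a quasi-degenerate pool to one effective K_D (μM).

    ``harmonic``: K_eff = n / Σ(1/kd_i) over pool members — the
    equal-concentration competitive weak-binding limit.  ``exact``: the
    single-ligand K_D that reproduces the competitive solver's total
    bound fraction at the working concentrations, via the closed-form
    inversion K_D = p·(1−f)·(x−f)/f of the two-state quadratic.
    """
    if isinstance(pool, PoolSpec):
        pattern = pool.oligo_pattern
        if ratio is None:
            ratio = pool.ratio
    else:
        pattern = pool
        if ratio is None:
            ratio = 4.0
    kds = np.array([sequence_kd(model, s) for s in enumerate_pool(pattern)])
    if method == "harmonic":
        return float(len(kds) / np.sum(1.0 / kds))
    if method != "exact":
        raise ValueError(f"unknown method {method!r}")
    f = _pool_bound_fraction(model, pattern, protein_conc, ratio)
    return float(protein_conc * (1.0 - f) * (ratio - f) / f)


def simulate_titration(
    model: SequenceAffinityModel,
    oligo_or_pool: str | PoolSpec,
    protein_conc: float = 50.0,
    ratios: tuple[float, ...] = DEFAULT_RATIOS,
    noise_sd: float = 0.0,
    seed: int | np.random.Generator | None = None,
    weights: CSPWeights = CSPWeights(),
) -> TitrationSeries:
    """Simulate assigned peak lists along a titration schedule.

    At each ratio every residue's peak sits at
    ``free_position + f_B · Δδ_max · direction`` with i.i.d. Gaussian
    noise of standard deviation ``noise_sd`` ppm added in weighted-CSP
    units on each axis (¹H directly; ¹⁵N scaled by 1/sqrt(w_N) so noise
    is isotropic in the weighted space).  Seeded and reproducible.
    """
    if noise_sd < 0:
        raise ValueError("noise_sd must be non-negative")
    if isinstance(oligo_or_pool, PoolSpec):
        pattern = oligo_or_pool.oligo_pattern
    else:
        pattern = oligo_or_pool
    ratios = tuple(float(r) for r in ratios)
    rng = (
        seed
        if isinstance(seed, np.random.Generator)
        else np.random.default_rng(seed)
    )
    n_scale = 1.0 / np.sqrt(weights.n_weight)
    pooled = "N" in pattern
    if not pooled:
        kd = sequence_kd(model, pattern)
    peaklists = []
    for ratio in ratios:
        if pooled:
            f = _pool_bound_fraction(model, pattern, protein_conc, ratio)
        else:
            f = fraction_bound(ratio, kd, protein_conc)
        peaks = []
        for res in model.residues:
            h = res.free_h + f * res.dmax * res.dir_h
            n = res.free_n + f * res.dmax * res.dir_n
            if noise_sd > 0:
                h += rng.normal(0.0, noise_sd)
                n += rng.normal(0.0, noise_sd * n_scale)
            peaks.append(Peak(res.residue_id, h, n))
        label = f"{model.label or 'sim'}_{pattern}_r{ratio:g}"
        condition = "free" if ratio == 0 else f"bound({ratio:g})"
        peaklists.append(PeakList(peaks, spectrum_label=label, condition=condition))
    return TitrationSeries(
        protein_conc=protein_conc,
        ratios=ratios,
        peaklists=peaklists,
        oligo=pattern,
    )


def _make_residues(spec: dict, weights: CSPWeights = CSPWeights()) -> tuple[ResidueParams, ...]:
    rng = np.random.default_rng(int(spec["seed"]))
    count = int(spec["count"])
    first = int(spec["first_index"])
    dmax_lo, dmax_hi = spec["dmax_range_ppm"]
    h_lo, h_hi = spec["h_window_ppm"]
    n_lo, n_hi = spec["n_window_ppm"]
    out = []
    for i in range(count):
        aa = _AA20[rng.integers(len(_AA20))]
        free_h = rng.uniform(h_lo, h_hi)
        free_n = rng.uniform(n_lo, n_hi)
        dmax = rng.uniform(dmax_lo, dmax_hi)
        theta = rng.uniform(0.0, 2.0 * np.pi)
        # unit length in weighted-CSP space: sqrt((dh² + w_N·dn²)/2) = 1
        dir_h = np.sqrt(2.0) * np.cos(theta)
        dir_n = np.sqrt(2.0 / weights.n_weight) * np.sin(theta)
        out.append(
            ResidueParams(f"{aa}{first + i}", free_h, free_n, dmax, dir_h, dir_n)
        )
    return tuple(out)


def fmrp_fixture(variant: str = "AE") -> SequenceAffinityModel:
    """Packaged FMRP-KH1 affinity model (variant ``"WT"`` or ``"AE"``).

    Parameters are read from the versioned fixture file; the AE and WT
    models share penalties and residues and differ only by the 40-fold
    context factor of the affinity-enhancing GxxG→GKKG mutation.
    """
    variant = variant.upper()
    raw = resources.files("rnaae.data").joinpath("fmrp_fixture.yaml").read_text()
    cfg = yaml.safe_load(raw)
    if variant not in cfg["context_factor"]:
        raise ValueError(f"unknown variant {variant!r}; expected WT or AE")
    penalties = {
        int(pos): {b: float(v) for b, v in table.items()}
        for pos, table in cfg["penalties"].items()
    }
    return SequenceAffinityModel(
        kd_ref=float(cfg["kd_ref_uM"]),
        reference=str(cfg["reference"]),
        penalties=penalties,
        context_factor=float(cfg["context_factor"][variant]),
        residues=_make_residues(cfg["residues"]),
        label=f"FMRP_KH1_{variant}",
    )
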