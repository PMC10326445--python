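"""Single-site fast-exchange binding: isotherm, per-residue K_D fits.

Under fast exchange each amide peak sits at the population-weighted
average of its free and bound positions, so the observed CSP at molar
ratio x (RNA equivalents per protein, protein fixed at p μM) is

    CSP(x) = Δδ_max · f_B(x),
    f_B(x) = ( (1 + x + K_D/p) − sqrt((1 + x + K_D/p)² − 4x) ) / 2,

the physical root of the two-state mass-balance quadratic.  The same
curve in its conventional fitting form is A·(B + x − sqrt((B+x)² − 4x))
with A = Δδ_max/2 and B = 1 + K_D/p.  K_D is fitted per residue by
nonlinear least squares over (K_D, Δδ_max); the reported K_D is the
arithmetic mean over the fitted residues.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import lmfit
import numpy as np
import pandas as pd

from .csp import CSPProfile

logger = logging.getLogger(__name__)

__all__ = [
    "BindingModelParams",
    "FitResult",
    "SelectivityResult",
    "fraction_bound",
    "predicted_csp",
    "fit_kd",
    "bootstrap_aggregate_kd",
    "selectivity_ratio",
]

KD_MIN, KD_MAX = 1e-3, 1e6  # μM
DMAX_MIN, DMAX_MAX = 1e-6, 10.0  # ppm


@dataclass(frozen=True)
class BindingModelParams:
    """Parameters of the two-state fast-exchange model for one residue."""

    kd: float  # μM
    dmax: float  # ppm, bound-state CSP amplitude
    protein_conc: float  # μM

    def __post_init__(self) -> None:
        if self.kd <= 0:
            raise ValueError("kd must be positive (μM)")
        if self.dmax <= 0:
            raise ValueError("dmax must be positive (ppm)")
        if self.protein_conc <= 0:
            raise ValueError("protein_conc must be positive (μM)")

    @property
    def A(self) -> float:
        """Amplitude of the conventional fitting form, Δδ_max/2."""
        return self.dmax / 2.0

    @property
    def B(self) -> float:
        """Offset of the conventional fitting form, 1 + K_D/p."""
        return 1.0 + self.kd / self.protein_conc


def fraction_bound(x, kd, p):
    """Molar fraction of protein bound at protein:RNA molar ratio ``x``.

    Evaluated in the cancellation-safe form 2x / (s + sqrt(s² − 4x)) with
    s = 1 + x + K_D/p; lies in [0, 1], increases with x, decreases with
    K_D, and reduces to min(x, 1) in the stoichiometric (K_D → 0) limit.
    """
    x = np.asarray(x, dtype=float)
    if np.any(x < 0):
        raise ValueError("molar ratio must be non-negative")
    if np.any(np.asarray(kd) < 0):
        raise ValueError("kd must be non-negative")
    if np.any(np.asarray(p) <= 0):
        raise ValueError("protein concentration must be positive")
    s = 1.0 + x + np.asarray(kd, dtype=float) / p
    disc = np.sqrt(np.maximum(s * s - 4.0 * x, 0.0))
    with np.errstate(invalid="ignore", divide="ignore"):
        f = np.where(x > 0, 2.0 * x / (s + disc), 0.0)
    out = np.clip(f, 0.0, 1.0)
    return float(out) if out.ndim == 0 else out


def predicted_csp(x, params: BindingModelParams):
    """Observed CSP at molar ratio ``x`` in the A·(B + x − sqrt(...)) form.

    Algebraically identical to dmax · fraction_bound(x, kd, p).
    """
    x = np.asarray(x, dtype=float)
    b = params.B
    s = b + x
    out = params.A * (s - np.sqrt(s * s - 4.0 * x))
    return float(out) if out.ndim == 0 else out


def _csp_model(x, kd, dmax, p):
    return dmax * fraction_bound(x, kd, p)


@dataclass
class FitResult:
    """Per-residue fits and the residue-averaged dissociation constant."""

    per_residue: pd.DataFrame  # columns kd_hat, dmax_hat, rss, n_points
    aggregate_kd: float  # μM, unweighted mean over fitted residues
    aggregate_sd: float  # μM, sd over fitted residues
    protein_conc: float
    skipped: dict[str, str] = field(default_factory=dict)

    @property
    def n_residues(self) -> int:
        return len(self.per_residue)

    def to_json_dict(self) -> dict:
        return {
            "aggregate_kd_uM": self.aggregate_kd,
            "aggregate_sd_uM": self.aggregate_sd,
            "protein_conc_uM": self.protein_conc,
            "n_residues": self.n_residues,
            "per_residue": {
                rid: {k: float(v) for k, v in row.items()}
                for rid, row in self.per_residue.iterrows()
            },
            "skipped": dict(self.skipped),
        }


def _fit_one(x: np.ndarray, y: np.ndarray, p: float) -> tuple[float, float, float] | None:
    params = lmfit.Parameters()
    params.add("kd", value=p, min=KD_MIN, max=KD_MAX)
    params.add("dmax", value=1.5 * float(np.max(y)), min=DMAX_MIN, max=DMAX_MAX)

    def residual(pars):
        return _csp_model(x, pars["kd"].value, pars["dmax"].value, p) - y

    try:
        res = lmfit.minimize(residual, params, method="leastsq")
    except Exception:  # pragma: no cover - lmfit internal failure
        return None
    if not res.success:
        return None
    kd_hat = float(res.params["kd"].value)
    dmax_hat = float(res.params["dmax"].value)
    rss = float(np.sum(np.asarray(res.residual) ** 2))
    return kd_hat, dmax_hat, rss


def fit_kd(
    profile: CSPProfile,
    protein_conc: float,
    residues: list[str] | None = None,
    min_points: int = 3,
) -> FitResult:
    """Fit K_D and Δδ_max per residue; average K_D over residues.

    Residues with fewer than ``min_points`` usable (non-lost) titration
    points, with no detectable shift, or whose fit does not converge are
    skipped and recorded in ``FitResult.skipped``.  The fit is
    deterministic: fixed initialization (K_D₀ = p, Δδ_max₀ = 1.5 × max
    observed CSP) and bounds K_D ∈ [1e-3, 1e6] μM, Δδ_max ∈ (0, 10] ppm.
    """
    if protein_conc <= 0:
        raise ValueError("protein_conc must be positive (μM)")
    ratios = profile.ratios
    if ratios.size and not (ratios.min() < 1.0 < ratios.max()):
        logger.warning(
            "ratio schedule does not span both sub- and super-stoichiometric "
            "points; K_D and Δδ_max may be poorly determined"
        )
    subset = residues if residues is not None else profile.residues
    rows, index, skipped = [], [], {}
    for rid in subset:
        if rid not in profile.values.index:
            skipped[rid] = "not in profile"
            continue
        y_all = profile.values.loc[rid].to_numpy(dtype=float)
        mask = np.isfinite(y_all)
        x, y = ratios[mask], y_all[mask]
        if len(x) < min_points:
            skipped[rid] = f"only {len(x)} usable points"
            logger.info("residue %s skipped: %s", rid, skipped[rid])
            continue
        if np.max(y) <= 0:
            skipped[rid] = "no detectable shift (non-identifiable)"
            logger.info("residue %s skipped: %s", rid, skipped[rid])
            continue
        fit = _fit_one(x, y, protein_conc)
        if fit is None:
            skipped[rid] = "fit did not converge"
            logger.warning("residue %s skipped: %s", rid, skipped[rid])
            continue
        rows.append((*fit, len(x)))
        index.append(rid)
    per_residue = pd.DataFrame(
        rows, index=index, columns=["kd_hat", "dmax_hat", "rss", "n_points"]
    )
    if len(per_residue):
        agg = float(per_residue["kd_hat"].mean())
        sd = float(per_residue["kd_hat"].std(ddof=1)) if len(per_residue) > 1 else 0.0
    else:
        agg, sd = float("nan"), float("nan")
    return FitResult(per_residue, agg, sd, protein_conc, skipped)


def bootstrap_aggregate_kd(
    profile: CSPProfile,
    protein_conc: float,
    residues: list[str] | None = None,
    n_boot: int = 200,
    seed: int | None = None,
    ci: float = 0.95,
) -> tuple[float, float]:
    """Residual-bootstrap confidence interval for the aggregate K_D.

    Residuals of the per-residue fits are resampled with replacement
    within each residue, added back to the fitted curves, and the whole
    fit-and-average procedure repeated ``n_boot`` times.
    """
    base = fit_kd(profile, protein_conc, residues)
    if not len(base.per_residue):
        raise ValueError("no fitted residues to bootstrap")
    rng = np.random.default_rng(seed)
    ratios = profile.ratios
    aggs = []
    fitted = {}
    for rid in base.per_residue.index:
        y_all = profile.values.loc[rid].to_numpy(dtype=float)
        mask = np.isfinite(y_all)
        x, y = ratios[mask], y_all[mask]
        yhat = _csp_model(
            x,
            base.per_residue.loc[rid, "kd_hat"],
            base.per_residue.loc[rid, "dmax_hat"],
            protein_conc,
        )
        fitted[rid] = (x, yhat, y - yhat)
    for _ in range(n_boot):
        kds = []
        for rid, (x, yhat, resid) in fitted.items():
            y_star = yhat + rng.choice(resid, size=len(resid), replace=True)
            y_star = np.clip(y_star, 0.0, None)
            y_star[x == 0] = 0.0
            fit = _fit_one(x, y_star, protein_conc)
            if fit is not None:
                kds.append(fit[0])
        if kds:
            aggs.append(float(np.mean(kds)))
    lo, hi = np.quantile(aggs, [(1 - ci) / 2, 1 - (1 - ci) / 2])
    return float(lo), float(hi)


@dataclass(frozen=True)
class SelectivityResult:
    """Fold selectivity between two binding assays (always ≥ 1)."""

    fold: float
    tighter: str  # label of the tighter-binding (lower K_D) assay
    kd_tighter: float
    kd_weaker: float


def selectivity_ratio(
    fit_a: FitResult, fit_b: FitResult, labels: tuple[str, str] = ("a", "b")
) -> SelectivityResult:
    """K_D(weaker)/K_D(tighter) between two fits, with orientation."""
    ka, kb = fit_a.aggregate_kd, fit_b.aggregate_kd
    for label, k in zip(labels, (ka, kb)):
        if not np.isfinite(k) or k <= 0:
            raise ValueError(f"fit {label!r} has no usable aggregate K_D")
    if ka <= kb:
        return SelectivityResult(kb / ka, labels[0], ka, kb)
    return SelectivityResult(ka / kb, labels[1], kb, ka)
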