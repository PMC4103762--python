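"""Fluorescence-polarization (FP) assay analytics.

An FP competition assay reads fluorescence parallel and perpendicular to the
excitation plane; polarization in millipolarization units is

    mP = (I_par − I_perp) / (I_par + I_perp) × G × 1000

with instrument G-factor ``G`` (default 0.998).  Bound, slowly tumbling
fluorescent peptide polarizes strongly; a displacing inhibitor drives mP
toward the free-peptide floor.  Percent inhibition normalizes a compound
well between the DMSO (no inhibition) and free-peptide (full displacement)
controls; when no free-peptide control exists the single-point
DMSO normalization 100·(1 − mP/mP_DMSO) is used instead.

IC50s come from a four-parameter logistic (4PL) fit

    y(x) = bottom + (top − bottom) / (1 + (IC50 / x)^hill)

with hill > 0 meaning inhibition increases with dose, fit by least squares
from a multi-start IC50 grid spanning the dose ladder.  The canonical design
is a 12-point 2-fold dilution series (e.g. 100 µM down to ~49 nM).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from enum import Enum

import numpy as np
import pandas as pd
from scipy.optimize import least_squares

__all__ = [
    "WellRole",
    "FPReading",
    "DoseResponseFit",
    "compute_mP",
    "percent_inhibition",
    "fit_ic50",
    "screen_summary",
    "read_plate_csv",
    "DEFAULT_SEED",
]

DEFAULT_SEED = 20140718


class WellRole(str, Enum):
    TEST = "TEST"
    DMSO_CONTROL = "DMSO_CONTROL"
    FREE_PEPTIDE_CONTROL = "FREE_PEPTIDE_CONTROL"


@dataclass(frozen=True)
class FPReading:
    """One well: compound, concentration (molar; 0 for controls), intensities."""

    well: str
    compound: str
    concentration: float
    int_parallel: float
    int_perpendicular: float
    role: WellRole = WellRole.TEST

    def __post_init__(self) -> None:
        if self.int_parallel < 0 or self.int_perpendicular < 0:
            raise ValueError(f"well {self.well}: negative intensity")


@dataclass
class DoseResponseFit:
    """4PL parameters with fit diagnostics."""

    ic50: float
    hill: float
    top: float
    bottom: float
    rss: float
    converged: bool
    ci95: tuple[float, float] | None = None
    message: str = ""

    def predict(self, x: np.ndarray) -> np.ndarray:
        return four_pl(np.asarray(x, dtype=float), self.bottom, self.top, self.ic50, self.hill)


def compute_mP(reading: FPReading, g_factor: float = 0.998) -> float:
    """Millipolarization: (I∥ − I⊥)/(I∥ + I⊥) × g_factor × 1000."""
    total = reading.int_parallel + reading.int_perpendicular
    if total <= 0:
        raise ValueError(f"well {reading.well}: zero total intensity")
    return (reading.int_parallel - reading.int_perpendicular) / total * g_factor * 1000.0


def percent_inhibition(
    plate: list[FPReading], g_factor: float = 0.998
) -> pd.DataFrame:
    """Per-(compound, concentration) percent inhibition.

    Two-point normalization 100·(mP_DMSO − mP)/(mP_DMSO − mP_free) when
    free-peptide controls exist; otherwise single-point DMSO normalization.
    Control replicates are averaged.  Raises if no DMSO control is present.
    """
    dmso = [compute_mP(r, g_factor) for r in plate if r.role == WellRole.DMSO_CONTROL]
    if not dmso:
        raise ValueError("plate has no DMSO control wells")
    free = [
        compute_mP(r, g_factor) for r in plate if r.role == WellRole.FREE_PEPTIDE_CONTROL
    ]
    mp_dmso = float(np.mean(dmso))
    mp_free = float(np.mean(free)) if free else None

    groups: dict[tuple[str, float], list[float]] = {}
    for r in plate:
        if r.role != WellRole.TEST:
            continue
        groups.setdefault((r.compound, r.concentration), []).append(
            compute_mP(r, g_factor)
        )
    rows = []
    for (compound, conc), values in sorted(groups.items()):
        mp = float(np.mean(values))
        if mp_free is not None:
            span = mp_dmso - mp_free
            if abs(span) < 1e-12:
                raise ValueError("DMSO and free-peptide controls coincide")
            pct = 100.0 * (mp_dmso - mp) / span
        else:
            if abs(mp_dmso) < 1e-12:
                raise ValueError("DMSO control mP is zero; cannot normalize")
            pct = 100.0 * (1.0 - mp / mp_dmso)
        rows.append(
            {
                "compound": compound,
                "concentration": conc,
                "mP": mp,
                "percent_inhibition": pct,
                "n_wells": len(values),
            }
        )
    return pd.DataFrame(
        rows, columns=["compound", "concentration", "mP", "percent_inhibition", "n_wells"]
    )


def four_pl(x: np.ndarray, bottom: float, top: float, ic50: float, hill: float) -> np.ndarray:
    return bottom + (top - bottom) / (1.0 + (ic50 / x) ** hill)


def fit_ic50(
    doses: np.ndarray,
    responses: np.ndarray,
    n_starts: int = 7,
    bootstrap: int = 0,
    seed: int = DEFAULT_SEED,
    fix_bottom: float | None = None,
    fix_top: float | None = None,
) -> DoseResponseFit:
    """Least-squares 4PL fit of responses (e.g. %inhibition) vs molar doses.

    Initialization is multi-start: IC50 over a geometric grid spanning the
    dose range crossed with hill ∈ {0.5, 1, 2}; the best local optimum wins.
    Degenerate data (flat responses, <5 distinct doses) yields
    ``converged=False`` with a message, never a silent number.  Optional
    residual-resampling bootstrap (seeded) gives a 95% CI on the IC50.

    ``fix_bottom`` / ``fix_top`` pin the asymptotes — the constrained
    variants appropriate for control-normalized percent-inhibition data,
    where 0% and 100% are defined by the plate controls rather than
    estimated from the titration.
    """
    doses = np.asarray(doses, dtype=float)
    responses = np.asarray(responses, dtype=float)
    if doses.shape != responses.shape:
        raise ValueError("doses and responses must have equal length")
    if np.any(doses <= 0):
        raise ValueError("doses must be positive (molar)")
    if not np.all(np.isfinite(responses)):
        raise ValueError("responses must be finite")

    failed = DoseResponseFit(np.nan, np.nan, np.nan, np.nan, np.nan, False)
    if len(np.unique(doses)) < 5:
        failed.message = "fewer than 5 distinct doses"
        return failed
    if np.ptp(responses) < 1e-9:
        failed.message = "responses are constant (degenerate)"
        return failed

    lo, hi = float(responses.min()), float(responses.max())
    span = hi - lo

    def residuals(theta, x, y):
        bottom = fix_bottom if fix_bottom is not None else theta[0]
        top = fix_top if fix_top is not None else theta[1]
        log_ic50, hill = theta[2], theta[3]
        return four_pl(x, bottom, top, np.exp(log_ic50), hill) - y

    lower = [lo - 2 * span, lo - 2 * span, np.log(doses.min()) - 7, 0.05]
    upper = [hi + 2 * span, hi + 2 * span, np.log(doses.max()) + 7, 10.0]
    if fix_bottom is not None:
        lower[0], upper[0] = fix_bottom - 1e-9, fix_bottom + 1e-9
    if fix_top is not None:
        lower[1], upper[1] = fix_top - 1e-9, fix_top + 1e-9

    grid = np.geomspace(doses.min(), doses.max(), n_starts)
    best = None
    for ic50_0 in grid:
        for hill_0 in (0.5, 1.0, 2.0):
            theta0 = [
                fix_bottom if fix_bottom is not None else lo,
                fix_top if fix_top is not None else hi,
                np.log(ic50_0),
                hill_0,
            ]
            try:
                sol = least_squares(
                    residuals, theta0, args=(doses, responses),
                    bounds=(lower, upper), method="trf",
                )
            except Exception:
                continue
            rss = float(np.sum(sol.fun**2))
            if sol.success and (best is None or rss < best[0]):
                best = (rss, sol.x)

    if best is None:
        failed.message = "no start converged"
        return failed

    rss, (bottom, top, log_ic50, hill) = best
    if fix_bottom is not None:
        bottom = fix_bottom
    if fix_top is not None:
        top = fix_top
    if bottom > top:
        # re-express with the response increasing toward 'top'
        bottom, top, hill = top, bottom, -hill
    fit = DoseResponseFit(
        ic50=float(np.exp(log_ic50)), hill=float(hill),
        top=float(top), bottom=float(bottom), rss=rss, converged=True,
    )

    if bootstrap > 0:
        rng = np.random.default_rng(seed)
        fitted = fit.predict(doses)
        resid = responses - fitted
        estimates = []
        for _ in range(bootstrap):
            resampled = fitted + rng.choice(resid, size=len(resid), replace=True)
            rep = fit_ic50(
                doses, resampled, n_starts=3, bootstrap=0,
                fix_bottom=fix_bottom, fix_top=fix_top,
            )
            if rep.converged:
                estimates.append(rep.ic50)
        if len(estimates) >= max(10, bootstrap // 4):
            low, high = np.percentile(estimates, [2.5, 97.5])
            fit.ci95 = (float(low), float(high))
        else:
            warnings.warn("too few bootstrap replicates converged for a CI")
    return fit


def screen_summary(
    plate: list[FPReading],
    threshold: float = 50.0,
    g_factor: float = 0.998,
) -> pd.DataFrame:
    """Single-dose screen table: per compound, %inhibition and a >threshold
    flag, sorted by inhibition descending (compound id breaks ties)."""
    table = percent_inhibition(plate, g_factor)
    if table.empty:
        return pd.DataFrame(columns=["compound", "percent_inhibition", "hit"])
    summary = (
        table.groupby("compound", as_index=False)["percent_inhibition"].mean()
    )
    summary["hit"] = summary["percent_inhibition"] > threshold
    return summary.sort_values(
        ["percent_inhibition", "compound"], ascending=[False, True]
    ).reset_index(drop=True)


def read_plate_csv(path) -> list[FPReading]:
    """Plate CSV with columns well, compound, role, conc_M, int_par, int_perp."""
    df = pd.read_csv(path)
    required = {"well", "compound", "role", "conc_M", "int_par", "int_perp"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"plate CSV missing columns: {sorted(missing)}")
    return [
        FPReading(
            well=str(r.well), compound=str(r.compound),
            concentration=float(r.conc_M),
            int_parallel=float(r.int_par), int_perpendicular=float(r.int_perp),
            role=WellRole(str(r.role)),
        )
        for r in df.itertuples()
    ]
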