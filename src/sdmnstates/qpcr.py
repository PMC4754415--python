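"""Quantification of qPCR amplification curves.

Each raw curve is fitted with a four-parameter logistic (4PL); the cycle
threshold CT is the (fractional) cycle of maximum second derivative of the
fit, the amplification efficiency E is recovered from a log-linear
regression over the exponential window of the curve, and the relative
initial template concentration is

    R0 = (1 + E)^(-CT)

computed in the log domain to avoid underflow at late CTs. Target-gene R0
values are normalised to the reference gene of the same fish x nucleus
sample to give relative expression.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit
from scipy.stats import linregress

logger = logging.getLogger(__name__)

#: offset between the logistic midpoint and the second-derivative maximum,
#: in units of 1/slope: CT = midpoint - log(2 + sqrt(3)) / slope
_SD_MAX_OFFSET = math.log(2.0 + math.sqrt(3.0))

FLAG_NO_AMPLIFICATION = "no-amplification"
FLAG_FIT_FAILED = "fit-failed"
FLAG_UNRELIABLE_EFFICIENCY = "unreliable-efficiency"
FLAG_EFFICIENCY_CAPPED = "efficiency-capped"

#: efficiency values above this are biologically implausible and are clipped
MAX_EFFICIENCY = 1.1


@dataclass
class AmplificationCurve:
    """One reaction's raw fluorescence trace."""

    reaction_id: str
    cycles: np.ndarray
    fluorescence: np.ndarray
    fish_id: str | None = None
    nucleus: str | None = None
    gene: str | None = None

    def __post_init__(self) -> None:
        self.cycles = np.asarray(self.cycles, dtype=float)
        self.fluorescence = np.asarray(self.fluorescence, dtype=float)
        if self.cycles.shape != self.fluorescence.shape:
            raise ValueError("cycles and fluorescence must have equal length")
        if len(self.cycles) < 20:
            raise ValueError("curve must have at least 20 cycles")
        if np.any(np.diff(self.cycles) <= 0):
            raise ValueError("cycles must be strictly increasing")


@dataclass
class FourPLFit:
    """Four-parameter logistic fit of an amplification curve.

    fitted(c) = baseline + amplitude / (1 + exp(-slope * (c - midpoint)))
    """

    baseline: float
    amplitude: float
    midpoint: float
    slope: float
    rms_residual: float
    flags: tuple[str, ...] = ()

    @property
    def ok(self) -> bool:
        return FLAG_NO_AMPLIFICATION not in self.flags and FLAG_FIT_FAILED not in self.flags

    def predict(self, cycles: np.ndarray) -> np.ndarray:
        return _logistic4(np.asarray(cycles, dtype=float),
                          self.baseline, self.amplitude, self.midpoint, self.slope)


@dataclass
class QpcrMeasurement:
    """Efficiency, cycle threshold and relative initial template amount.

    ``R0 = (1+E)^(-CT)`` holds exactly by construction (log-domain
    evaluation).
    """

    reaction_id: str
    E: float
    CT: float
    R0: float
    rms_residual: float
    flags: tuple[str, ...] = ()
    fish_id: str | None = None
    nucleus: str | None = None
    gene: str | None = None

    @property
    def accepted(self) -> bool:
        return not any(
            f in self.flags
            for f in (FLAG_NO_AMPLIFICATION, FLAG_FIT_FAILED, FLAG_UNRELIABLE_EFFICIENCY)
        )


def _logistic4(c, baseline, amplitude, midpoint, slope):
    return baseline + amplitude / (1.0 + np.exp(-slope * (c - midpoint)))


# ----------------------------------------------------------------------


def fit_amplification(
    curve: AmplificationCurve, min_dynamic_range: float = 0.2
) -> FourPLFit:
    """Fit a 4PL to one curve by nonlinear least squares.

    A curve whose dynamic range (max - min fluorescence) is below
    ``min_dynamic_range`` is flagged ``no-amplification`` and not fitted.
    """
    c = curve.cycles
    f = curve.fluorescence
    rng_f = float(f.max() - f.min())
    if rng_f < min_dynamic_range:
        return FourPLFit(float(np.median(f)), 0.0, math.nan, math.nan,
                         float(np.std(f)), flags=(FLAG_NO_AMPLIFICATION,))
    # start values from curve quantiles
    base0 = float(np.quantile(f, 0.05))
    amp0 = rng_f
    half = base0 + amp0 / 2.0
    above = np.nonzero(f >= half)[0]
    mid0 = float(c[above[0]]) if len(above) else float(c[len(c) // 2])
    # slope from quarter-to-three-quarter crossing spacing (logit span 2.197)
    q1 = np.nonzero(f >= base0 + 0.25 * amp0)[0]
    q3 = np.nonzero(f >= base0 + 0.75 * amp0)[0]
    if len(q1) and len(q3) and c[q3[0]] > c[q1[0]]:
        slope0 = 2.197 / float(c[q3[0]] - c[q1[0]])
    else:
        slope0 = 0.7
    try:
        popt, _ = curve_fit(
            _logistic4, c, f,
            p0=[base0, amp0, mid0, slope0],
            bounds=([-np.inf, 1e-9, c[0] - 20.0, 1e-3],
                    [np.inf, np.inf, c[-1] + 20.0, 10.0]),
            maxfev=20000,
        )
    except RuntimeError:
        return FourPLFit(base0, amp0, mid0, slope0, math.inf, flags=(FLAG_FIT_FAILED,))
    resid = f - _logistic4(c, *popt)
    return FourPLFit(
        baseline=float(popt[0]), amplitude=float(popt[1]),
        midpoint=float(popt[2]), slope=float(popt[3]),
        rms_residual=float(np.sqrt(np.mean(resid**2))),
    )


def estimate_efficiency_ct(
    curve: AmplificationCurve,
    fit: FourPLFit,
    window: tuple[float, float] = (0.05, 0.5),
) -> tuple[float, float, tuple[str, ...]]:
    """Estimate (E, CT) from an accepted 4PL fit.

    CT is the cycle of maximum second derivative of the fitted logistic
    (threshold-free, fractional). E comes from a linear regression of the
    logit of the background-subtracted observed fluorescence,
    ``log(F / (amplitude - F))``, on cycle over the exponential window —
    the cycles where the fitted signal lies between 5% and 50% of the
    plateau amplitude; the logit removes the onset of saturation exactly
    for a logistic curve and reduces to a plain log-linear fit deep in the
    exponential phase. ``E = exp(slope) - 1``, clipped at 1.1 with a flag.

    Returns ``(E, CT, flags)``; a window shorter than 3 cycles yields the
    ``unreliable-efficiency`` flag and ``E = exp(fit.slope) - 1``.
    """
    if not fit.ok:
        raise ValueError(f"cannot estimate (E, CT) from rejected fit: {fit.flags}")
    ct = fit.midpoint - _SD_MAX_OFFSET / fit.slope
    fitted_sig = fit.predict(curve.cycles) - fit.baseline
    lo, hi = window[0] * fit.amplitude, window[1] * fit.amplitude
    mask = (fitted_sig >= lo) & (fitted_sig <= hi)
    flags: list[str] = []
    if mask.sum() < 3:
        flags.append(FLAG_UNRELIABLE_EFFICIENCY)
        e = math.expm1(fit.slope)
    else:
        sig = curve.fluorescence[mask] - fit.baseline
        # guard observed values against noise outside (0, amplitude)
        eps = 1e-9 * fit.amplitude
        sig = np.clip(sig, eps, fit.amplitude - eps)
        logit = np.log(sig / (fit.amplitude - sig))
        res = linregress(curve.cycles[mask], logit)
        e = math.expm1(res.slope)
    if e > MAX_EFFICIENCY:
        logger.warning(
            "reaction %s: efficiency %.3f above %.2f, clipped",
            curve.reaction_id, e, MAX_EFFICIENCY,
        )
        e = MAX_EFFICIENCY
        flags.append(FLAG_EFFICIENCY_CAPPED)
    if e <= 0:
        flags.append(FLAG_UNRELIABLE_EFFICIENCY)
    return float(e), float(ct), tuple(flags)


def relative_quantity(E: float, CT: float) -> float:
    """Relative initial template concentration ``(1+E)^(-CT)``.

    Evaluated as ``exp(-CT * log1p(E))`` so late-CT reactions do not
    underflow prematurely.
    """
    if E < 0:
        raise ValueError(f"efficiency must be >= 0, got {E}")
    return math.exp(-CT * math.log1p(E))


# ----------------------------------------------------------------------


def measure_curve(curve: AmplificationCurve, min_dynamic_range: float = 0.2) -> QpcrMeasurement:
    """Full quantification of one curve: fit, (E, CT), R0."""
    fit = fit_amplification(curve, min_dynamic_range=min_dynamic_range)
    if not fit.ok:
        return QpcrMeasurement(
            reaction_id=curve.reaction_id, E=math.nan, CT=math.nan, R0=math.nan,
            rms_residual=fit.rms_residual, flags=fit.flags,
            fish_id=curve.fish_id, nucleus=curve.nucleus, gene=curve.gene,
        )
    e, ct, flags = estimate_efficiency_ct(curve, fit)
    r0 = relative_quantity(max(e, 0.0), ct) if ct > 0 and e > 0 else math.nan
    return QpcrMeasurement(
        reaction_id=curve.reaction_id, E=e, CT=ct, R0=r0,
        rms_residual=fit.rms_residual, flags=flags,
        fish_id=curve.fish_id, nucleus=curve.nucleus, gene=curve.gene,
    )


def curves_from_frame(curves: pd.DataFrame) -> list[AmplificationCurve]:
    """Build curve objects from a long table
    (reaction_id, cycle, fluorescence [+ fish_id, nucleus, gene])."""
    out = []
    meta_cols = [c for c in ("fish_id", "nucleus", "gene") if c in curves.columns]
    for rid, grp in curves.groupby("reaction_id", sort=True):
        grp = grp.sort_values("cycle")
        meta = {c: grp[c].iloc[0] for c in meta_cols}
        out.append(
            AmplificationCurve(
                reaction_id=str(rid),
                cycles=grp["cycle"].to_numpy(dtype=float),
                fluorescence=grp["fluorescence"].to_numpy(dtype=float),
                **meta,
            )
        )
    return out


def quantify_curves(
    curves: pd.DataFrame | Iterable[AmplificationCurve],
    min_dynamic_range: float = 0.2,
) -> pd.DataFrame:
    """Quantify every reaction; returns one row per reaction with
    (fish_id, nucleus, gene, E, CT, R0, rms_residual, flags, accepted)."""
    if isinstance(curves, pd.DataFrame):
        curves = curves_from_frame(curves)
    rows = []
    for cv in curves:
        m = measure_curve(cv, min_dynamic_range=min_dynamic_range)
        rows.append(
            (m.reaction_id, m.fish_id, m.nucleus, m.gene, m.E, m.CT, m.R0,
             m.rms_residual, ";".join(m.flags), m.accepted)
        )
    return pd.DataFrame(
        rows,
        columns=["reaction_id", "fish_id", "nucleus", "gene", "E", "CT", "R0",
                 "rms_residual", "flags", "accepted"],
    )


def normalize_expression(
    measurements: pd.DataFrame,
    reference_gene: str,
    fish_meta: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Reference-normalised relative expression per fish x nucleus x gene.

    ``relative_expression = R0_target / R0_reference`` of the same
    fish x nucleus; rows from flagged reactions are dropped, and a cell
    whose reference reaction is missing or rejected loses all its genes
    (logged as a warning). If ``fish_meta`` is given (fish_id, dyad_id,
    treatment) those columns are merged in.
    """
    meas = measurements.copy()
    if "accepted" in meas.columns:
        dropped = meas.loc[~meas["accepted"].astype(bool)]
        for r in dropped.itertuples():
            logger.info("dropping flagged reaction %s (%s)", r.reaction_id, r.flags)
        meas = meas.loc[meas["accepted"].astype(bool)]
    ref = meas.loc[meas["gene"] == reference_gene, ["fish_id", "nucleus", "R0"]]
    ref = ref.rename(columns={"R0": "R0_ref"})
    tgt = meas.loc[meas["gene"] != reference_gene].copy()
    merged = tgt.merge(ref, on=["fish_id", "nucleus"], how="left")
    missing_ref = merged["R0_ref"].isna()
    for r in merged.loc[missing_ref].itertuples():
        logger.warning(
            "no accepted reference reaction for fish %s nucleus %s; "
            "gene %s emitted as missing", r.fish_id, r.nucleus, r.gene,
        )
    merged = merged.loc[~missing_ref].copy()
    # ratio in log space: exp(log R0_t - log R0_ref)
    merged["relative_expression"] = np.exp(
        np.log(merged["R0"].to_numpy()) - np.log(merged["R0_ref"].to_numpy())
    )
    out = merged[["fish_id", "nucleus", "gene", "relative_expression"]]
    if fish_meta is not None:
        out = out.merge(
            fish_meta[["fish_id", "dyad_id", "treatment"]], on="fish_id", how="left"
        )
        out = out[["fish_id", "dyad_id", "treatment", "nucleus", "gene", "relative_expression"]]
    return out.reset_index(drop=True)
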