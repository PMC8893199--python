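"""Backbone amide spin-relaxation analysis.

Per-residue longitudinal (R1) and transverse (R2) relaxation rates are
extracted by non-linear least-squares fitting of peak heights versus
relaxation delay to a single exponential decay, ``h(t) = A exp(-R t)``.
The steady-state heteronuclear NOE is the ratio of peak heights recorded
with and without proton saturation.  The R1*R2 product is carried with
first-order propagated uncertainty; it flags residues with microsecond to
millisecond exchange while suppressing artefacts of anisotropic tumbling.

Delays are supplied in milliseconds (the unit in which pulse programs are
written) and converted to seconds internally, so all rates are in 1/s.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit

logger = logging.getLogger(__name__)

#: Inversion-recovery delay schedule (ms) used for R1 measurements.
T1_DELAYS_MS = [20.0, 60.0, 100.0, 200.0, 600.0, 800.0, 1200.0]

#: CPMG total relaxation delay schedule (ms) used for R2 measurements.
T2_DELAYS_MS = [1.0, 2.0, 4.0, 8.0, 10.0, 12.0]


@dataclass
class DecaySeries:
    """Peak heights of one residue as a function of relaxation delay.

    Replicate measurements are encoded as repeated delay values; points
    sharing a delay form a replicate group.
    """

    residue: int
    delays_ms: np.ndarray
    heights: np.ndarray

    def __post_init__(self) -> None:
        self.delays_ms = np.asarray(self.delays_ms, dtype=float)
        self.heights = np.asarray(self.heights, dtype=float)
        if self.delays_ms.shape != self.heights.shape:
            raise ValueError("delays and heights must have the same length")
        if not np.all(np.isfinite(self.heights)):
            raise ValueError("heights must be finite")
        if np.any(self.delays_ms < 0):
            raise ValueError("delays must be non-negative")

    @property
    def replicate_mask(self) -> np.ndarray:
        """True for points whose delay occurs more than once."""
        _, inv, counts = np.unique(self.delays_ms, return_inverse=True,
                                   return_counts=True)
        return counts[inv] > 1


@dataclass
class RateEstimate:
    """Single-exponential fit result for one residue."""

    residue: int
    rate: float          # 1/s
    rate_sd: float       # 1/s; NaN when no uncertainty is available
    amplitude: float
    fit_rss: float
    converged: bool = True


@dataclass
class NOERecord:
    """Heteronuclear NOE (saturated/unsaturated peak-height ratio)."""

    residue: int
    noe: float
    noe_sd: float
    reliable: bool = True


def _exp_decay(t, amplitude, rate):
    return amplitude * np.exp(-rate * t)


def _initial_guess(t_s: np.ndarray, h: np.ndarray) -> tuple[float, float]:
    pos = h > 0
    if pos.sum() >= 2:
        slope, intercept = np.polyfit(t_s[pos], np.log(h[pos]), 1)
        rate0 = max(-slope, 1e-3)
        amp0 = float(np.exp(intercept))
    else:
        amp0 = float(h.max())
        rate0 = 1.0 / max(t_s.max(), 1e-6)
    return amp0, rate0


def fit_single_exponential(series: DecaySeries,
                           with_offset: bool = False,
                           max_iter: int = 500) -> RateEstimate:
    """Fit ``h(t) = A exp(-R t)`` to a decay series by least squares.

    The initial guess comes from a log-linear regression on the positive
    heights.  ``with_offset`` adds a constant baseline term (off by
    default: peak-height decays are fit to a plain single exponential).

    Raises
    ------
    ValueError
        For fewer than 4 distinct delays or all-nonpositive heights.
    """
    t_s = series.delays_ms / 1000.0
    h = series.heights
    if np.unique(series.delays_ms).size < 4:
        raise ValueError(
            f"residue {series.residue}: need >= 4 distinct delays for a fit")
    if not np.any(h > 0):
        raise ValueError(
            f"residue {series.residue}: all peak heights non-positive")

    amp0, rate0 = _initial_guess(t_s, h)
    model = (lambda t, a, r, c: a * np.exp(-r * t) + c) if with_offset \
        else _exp_decay
    p0 = [amp0, rate0, 0.0] if with_offset else [amp0, rate0]
    try:
        popt, pcov = curve_fit(model, t_s, h, p0=p0, maxfev=max_iter * 10,
                               xtol=1e-12, ftol=1e-12)
        converged = np.all(np.isfinite(popt)) and popt[1] > 0
    except RuntimeError:
        popt, pcov = np.array(p0), np.full((len(p0), len(p0)), np.nan)
        converged = False

    resid = h - model(t_s, *popt)
    rate_sd = float(np.sqrt(pcov[1, 1])) if np.all(np.isfinite(pcov)) else np.nan
    return RateEstimate(residue=series.residue, rate=float(popt[1]),
                        rate_sd=rate_sd, amplitude=float(popt[0]),
                        fit_rss=float(resid @ resid), converged=bool(converged))


def pooled_replicate_sd(series: DecaySeries) -> float:
    """Pooled per-point standard deviation from replicate groups.

    Points sharing a delay are a replicate group; the pooled sd is
    ``sqrt(sum of within-group squared deviations / sum of (n_g - 1))``.
    For a pair differing by d this reduces to the paired-difference
    estimator d/sqrt(2).

    Raises
    ------
    ValueError
        If no delay is replicated.
    """
    delays, inv, counts = np.unique(series.delays_ms, return_inverse=True,
                                    return_counts=True)
    if not np.any(counts > 1):
        raise ValueError(f"residue {series.residue}: no replicated delays")
    ss, df = 0.0, 0
    for g in np.nonzero(counts > 1)[0]:
        x = series.heights[inv == g]
        ss += float(np.sum((x - x.mean()) ** 2))
        df += x.size - 1
    return float(np.sqrt(ss / df))


def rate_uncertainty_from_replicates(series: DecaySeries, fit: RateEstimate,
                                     n_draws: int = 200,
                                     seed: int = 0) -> float:
    """Monte-Carlo rate uncertainty anchored to replicate scatter.

    The per-point noise sd is pooled from replicate groups, then the fit
    is repeated on ``n_draws`` copies of the observed heights perturbed by
    Gaussian noise of that sd; the sd of the refit rates (converged draws
    only) is returned.  Returns NaN, with a warning, when the series
    carries no replicates.
    """
    try:
        point_sd = pooled_replicate_sd(series)
    except ValueError:
        logger.warning("residue %d: no replicates; rate sd unavailable",
                       series.residue)
        return float("nan")
    if point_sd == 0.0:
        return 0.0
    rng = np.random.default_rng(seed)
    rates = []
    for _ in range(n_draws):
        noisy = DecaySeries(series.residue, series.delays_ms,
                            series.heights +
                            rng.normal(0.0, point_sd, series.heights.size))
        est = fit_single_exponential(noisy)
        if est.converged:
            rates.append(est.rate)
    return float(np.std(rates, ddof=1))


def compute_hetnoe(residue: int, saturated: float, unsaturated: float,
                   noise_sd_pair: tuple[float, float] = (0.0, 0.0)) -> NOERecord:
    """Heteronuclear NOE from saturated/unsaturated peak heights.

    ``noe = h_sat / h_unsat`` with first-order error propagation
    ``sd = |noe| * sqrt((s_sat/h_sat)^2 + (s_unsat/h_unsat)^2)``.
    The record is flagged unreliable when the unsaturated height is below
    3x its noise sd (the ratio is then dominated by noise).
    """
    if unsaturated == 0:
        raise ValueError(f"residue {residue}: unsaturated height is zero")
    s_sat, s_unsat = noise_sd_pair
    noe = saturated / unsaturated
    if saturated == 0:
        sd = s_sat / abs(unsaturated)
    else:
        sd = abs(noe) * np.sqrt((s_sat / saturated) ** 2 +
                                (s_unsat / unsaturated) ** 2)
    reliable = not (s_unsat > 0 and abs(unsaturated) < 3.0 * s_unsat)
    if not reliable:
        logger.warning("residue %d: unsaturated peak below 3x noise", residue)
    return NOERecord(residue=residue, noe=float(noe), noe_sd=float(sd),
                     reliable=reliable)


def build_profile(r1: list[RateEstimate], r2: list[RateEstimate],
                  noe: list[NOERecord] | None = None) -> pd.DataFrame:
    """Assemble a per-residue dynamics profile with the R1*R2 product.

    Unconverged rate estimates are dropped.  ``r1r2`` is present only where
    both rates exist; its sd follows first-order propagation,
    ``sd = r1r2 * sqrt((s1/R1)^2 + (s2/R2)^2)``.  Missing residues stay
    missing (NaN) — partial overlap between the tables is allowed.
    """
    def rate_frame(estimates, name):
        rows = {e.residue: (e.rate, e.rate_sd)
                for e in estimates if e.converged}
        return pd.DataFrame.from_dict(
            rows, orient="index", columns=[name, f"{name}_sd"],
            dtype=float)

    frames = [rate_frame(r1, "R1"), rate_frame(r2, "R2")]
    if noe is not None:
        frames.append(pd.DataFrame.from_dict(
            {n.residue: (n.noe, n.noe_sd) for n in noe if n.reliable},
            orient="index", columns=["noe", "noe_sd"]))
    prof = pd.concat(frames, axis=1).sort_index()
    prof.index.name = "residue"

    prof["r1r2"] = prof["R1"] * prof["R2"]
    with np.errstate(divide="ignore", invalid="ignore"):
        rel = np.sqrt((prof["R1_sd"] / prof["R1"]) ** 2 +
                      (prof["R2_sd"] / prof["R2"]) ** 2)
    prof["r1r2_sd"] = prof["r1r2"] * rel
    # zero-uncertainty inputs give a zero-uncertainty product
    both_zero = (prof["R1_sd"] == 0) & (prof["R2_sd"] == 0)
    prof.loc[both_zero, "r1r2_sd"] = 0.0
    return prof


# ---------------------------------------------------------------------------
# tabular I/O

def read_decay_csv(path) -> list[DecaySeries]:
    """Read decay tables with columns residue, delay_ms, height.

    An optional ``replicate_id`` column is accepted and ignored: replicate
    structure is carried by repeated delay values.
    """
    df = pd.read_csv(path)
    return [DecaySeries(int(res), g["delay_ms"].to_numpy(),
                        g["height"].to_numpy())
            for res, g in df.groupby("residue")]


def write_decay_csv(series: list[DecaySeries], path) -> None:
    rows = []
    for s in series:
        rep = s.replicate_mask
        for i in range(s.delays_ms.size):
            rows.append((s.residue, s.delays_ms[i], s.heights[i], int(rep[i])))
    pd.DataFrame(rows, columns=["residue", "delay_ms", "height",
                                "replicate"]).to_csv(path, index=False)


def write_rates_csv(estimates: list[RateEstimate], path) -> None:
    pd.DataFrame(
        [(e.residue, e.rate, e.rate_sd, e.converged) for e in estimates],
        columns=["residue", "rate", "sd", "converged"],
    ).to_csv(path, index=False)
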