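"""Mixed-trimer assembly accounting and solution assays.

Co-expressing a SNAP-His-tagged variant monomer with untagged WT monomer
yields trimer species indexed by the number of tagged subunits k = 0..3.
Under random co-assembly the species follow a binomial law in the tagged
monomer fraction; Ni-affinity purification retains only k >= 1 (the
untagged homotrimer flows through), modelled as conditioning on k >= 1.
Species masses are additive in the monomer masses, and expected SDS-PAGE
band ratios assume Coomassie stain intensity proportional to the mass of
protein in the band, normalised to the tagged-monomer band.

Assay fitting covers Michaelis-Menten initial rates (tautomerase assay
read at 306 nm) and two-state van 't Hoff thermal melts with linear
folded/unfolded baselines.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit
from scipy.stats import binom

logger = logging.getLogger(__name__)

#: Gas constant, J/(mol K).
R_GAS = 8.314

#: Default monomer masses (kDa): one third of the tagged Y99C homotrimer
#: (96.1 kDa) and of the untagged WT trimer (37.9 kDa).
M_TAGGED_DEFAULT = 96.1 / 3
M_UNTAGGED_DEFAULT = 37.9 / 3

#: Molar absorptivity of the enol-borate complex at 306 nm, 1/(M cm).
EPSILON_306 = 11400.0


@dataclass
class KineticsFit:
    kcat: float                  # 1/s
    km: float                    # mM
    efficiency: float            # kcat/Km, 1/(s mM)
    kcat_sd: float = float("nan")
    km_sd: float = float("nan")
    relative_efficiency: float | None = None   # % of reference
    converged: bool = True


@dataclass
class MeltFit:
    tm: float                    # degrees C
    dh: float                    # kJ/mol
    baselines: tuple             # ((bf0, bf1), (bu0, bu1))
    tm_sd: float = float("nan")
    dtm_vs_reference: float | None = None


# ---------------------------------------------------------------------------
# stoichiometry

def species_mass(k_tagged: int, m_tagged: float = M_TAGGED_DEFAULT,
                 m_untagged: float = M_UNTAGGED_DEFAULT) -> float:
    """Mass (kDa) of a trimer with ``k_tagged`` tagged monomers."""
    if k_tagged not in (0, 1, 2, 3):
        raise ValueError("k_tagged must be in 0..3")
    return k_tagged * m_tagged + (3 - k_tagged) * m_untagged


def assembly_distribution(f_tagged: float,
                          condition_tagged: bool = False) -> np.ndarray:
    """Binomial species probabilities P(k), k = 0..3, at tagged fraction f.

    ``condition_tagged`` renormalises on k >= 1, modelling Ni-affinity
    retention of tagged species only.
    """
    if not 0.0 <= f_tagged <= 1.0:
        raise ValueError("f_tagged must be in [0, 1]")
    p = binom.pmf(np.arange(4), 3, f_tagged)
    if condition_tagged:
        p[0] = 0.0
        total = p.sum()
        if total == 0:
            raise ValueError("no tagged species at f_tagged = 0")
        p = p / total
    return p


def expected_band_ratio(k_tagged: int, m_tagged: float = M_TAGGED_DEFAULT,
                        m_untagged: float = M_UNTAGGED_DEFAULT) -> float:
    """Expected untagged/tagged SDS-PAGE band intensity ratio for one species.

    Under mass-proportional staining, a trimer with k tagged monomers
    loads k*m_tagged into the tagged-monomer band and (3-k)*m_untagged
    into the untagged band; the ratio is normalised so the tagged band
    is 1.  Undefined for k = 0 (no tagged band to normalise to).
    """
    if k_tagged not in (1, 2, 3):
        raise ValueError("band ratio needs k_tagged >= 1 (tagged band present)")
    return ((3 - k_tagged) * m_untagged) / (k_tagged * m_tagged)


def trimer_species_table(f_tagged: float,
                         m_tagged: float = M_TAGGED_DEFAULT,
                         m_untagged: float = M_UNTAGGED_DEFAULT,
                         condition_tagged: bool = False) -> pd.DataFrame:
    """Species table: k, mass, assembly probability, expected band ratio."""
    probs = assembly_distribution(f_tagged, condition_tagged)
    rows = []
    for k in range(4):
        ratio = expected_band_ratio(k, m_tagged, m_untagged) if k else np.nan
        rows.append((k, species_mass(k, m_tagged, m_untagged), probs[k], ratio))
    return pd.DataFrame(rows, columns=["k_tagged", "mass_kda", "probability",
                                       "band_ratio"])


# ---------------------------------------------------------------------------
# Michaelis-Menten kinetics

def rate_from_absorbance(slope_per_time: float,
                         epsilon: float = EPSILON_306,
                         path_cm: float = 1.0) -> float:
    """Convert an absorbance slope to a rate in uM per the slope's time unit
    via Beer-Lambert (v = dA/dt / (epsilon * l))."""
    return slope_per_time / (epsilon * path_cm) * 1e6


def fit_michaelis_menten(table: pd.DataFrame, enzyme_conc_nm: float,
                         reference: KineticsFit | None = None) -> KineticsFit:
    """Fit v = Vmax S / (Km + S) to an initial-rate table.

    ``table`` has columns ``S_mM`` and ``v`` (uM/s).  kcat = Vmax/E0 and
    the catalytic efficiency kcat/Km are reported; with a reference fit,
    also the relative efficiency in percent.  The fit is flagged
    non-converged when Km lands outside 100x the substrate range.
    """
    if enzyme_conc_nm <= 0:
        raise ValueError("enzyme concentration must be positive")
    s = table["S_mM"].to_numpy(dtype=float)
    v = table["v"].to_numpy(dtype=float)
    if np.unique(s[s > 0]).size < 5:
        raise ValueError("need >= 5 non-zero substrate levels")

    def mm(x, vmax, km):
        return vmax * x / (km + x)

    p0 = [float(v.max()) * 1.2, float(np.median(s[s > 0]))]
    try:
        popt, pcov = curve_fit(mm, s, v, p0=p0, maxfev=10000)
        converged = True
    except RuntimeError:
        popt, pcov = np.array(p0), np.full((2, 2), np.nan)
        converged = False
    vmax, km = float(popt[0]), float(popt[1])
    smax = float(s.max())
    if not (smax / 100 / 100 < km < smax * 100):
        logger.warning("Km = %.3g mM lies far outside the data range", km)
        converged = False
    e0_um = enzyme_conc_nm / 1000.0
    kcat = vmax / e0_um
    sds = np.sqrt(np.diag(pcov)) if np.all(np.isfinite(pcov)) else [np.nan] * 2
    fit = KineticsFit(kcat=kcat, km=km, efficiency=kcat / km,
                      kcat_sd=float(sds[0]) / e0_um, km_sd=float(sds[1]),
                      converged=converged)
    if reference is not None:
        fit.relative_efficiency = 100.0 * fit.efficiency / reference.efficiency
    return fit


# ---------------------------------------------------------------------------
# thermal melts

def two_state_signal(t_c, tm_c, dh_kj, bf0, bf1, bu0, bu1):
    """Two-state van 't Hoff melt signal with linear baselines.

    theta(T) = (theta_f + theta_u K) / (1 + K) with
    K = exp[-(dH/R)(1/T - 1/Tm)], temperatures in kelvin; the folded and
    unfolded baselines are theta_f = bf0 + bf1*T_C, theta_u = bu0 + bu1*T_C.
    At T = Tm, K = 1 and the signal is the baseline midpoint.
    """
    t_c = np.asarray(t_c, dtype=float)
    t_k = t_c + 273.15
    tm_k = tm_c + 273.15
    k_eq = np.exp(-(dh_kj * 1000.0 / R_GAS) * (1.0 / t_k - 1.0 / tm_k))
    theta_f = bf0 + bf1 * t_c
    theta_u = bu0 + bu1 * t_c
    return (theta_f + theta_u * k_eq) / (1.0 + k_eq)


def fit_melt(curve: pd.DataFrame, reference_tm: float | None = None) -> MeltFit:
    """Fit a two-state melt (Tm, dH, linear baselines) to a melt curve.

    ``curve`` has columns ``T_C`` and ``signal`` spanning at least 30 C.
    Raises ValueError when no two-state transition is present (baselines
    indistinguishable, Tm at the range edge, or non-positive dH).
    """
    t = curve["T_C"].to_numpy(dtype=float)
    y = curve["signal"].to_numpy(dtype=float)
    order = np.argsort(t)
    t, y = t[order], y[order]
    if t.max() - t.min() < 30:
        raise ValueError("melt curve must span >= 30 C")

    n_edge = max(3, t.size // 7)
    bf = np.polyfit(t[:n_edge], y[:n_edge], 1)       # slope, intercept
    bu = np.polyfit(t[-n_edge:], y[-n_edge:], 1)
    t_mid = 0.5 * (t.min() + t.max())
    span_mid = (bu[1] + bu[0] * t_mid) - (bf[1] + bf[0] * t_mid)
    if abs(span_mid) < 0.05 * max(np.ptp(y), 1e-12):
        raise ValueError("no unfolding transition detected "
                         "(baselines indistinguishable)")
    frac = (y - (bf[1] + bf[0] * t)) / ((bu[1] + bu[0] * t) -
                                        (bf[1] + bf[0] * t))
    tm0 = float(t[np.argmin(np.abs(frac - 0.5))])

    p0 = [tm0, 300.0, bf[1], bf[0], bu[1], bu[0]]
    try:
        popt, pcov = curve_fit(two_state_signal, t, y, p0=p0, maxfev=20000)
    except RuntimeError as exc:
        raise ValueError(f"melt fit did not converge: {exc}") from None
    tm, dh = float(popt[0]), float(popt[1])
    if not (t.min() < tm < t.max()):
        raise ValueError(f"fitted Tm = {tm:.1f} C outside the data range")
    if dh <= 0:
        raise ValueError("fitted dH is non-positive; no two-state transition")
    tm_sd = float(np.sqrt(pcov[0, 0])) if np.all(np.isfinite(pcov)) else np.nan
    fit = MeltFit(tm=tm, dh=dh,
                  baselines=((float(popt[2]), float(popt[3])),
                             (float(popt[4]), float(popt[5]))),
                  tm_sd=tm_sd)
    if reference_tm is not None:
        fit.dtm_vs_reference = tm - reference_tm
    return fit
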