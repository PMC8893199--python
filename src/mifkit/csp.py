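"""Combined 1H-15N chemical-shift perturbation (CSP) scoring.

Given assigned backbone amide shift tables for a reference and a variant
state, the combined perturbation per residue is

    delta = sqrt(ddH^2 + (alpha * ddN)^2)      [ppm]

with alpha = 0.14, the conventional 15N scaling for backbone amides.
Residues present in the reference but missing from the variant spectrum
are "broadened beyond detection" (exchange-broadened): they carry no
delta but are always reported as significant-by-broadening.

Significance uses a trimmed-mean rule: the cutoff is the 10% trimmed mean
of all combined shifts plus ``k_sigma`` standard deviations.  By default
sigma is computed over the full (untrimmed) set of deltas, so genuine
hotspots inflate sigma and push the cutoff above the jitter baseline —
this is what keeps the false-positive rate low when real perturbations
are present.  ``sigma_mode="trimmed"`` computes sigma on the trimmed set
instead.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: Standard 15N scaling factor for backbone amide combined shifts.
DEFAULT_ALPHA = 0.14


@dataclass
class CSPThreshold:
    """Significance cutoff: ``trimmed_mean + k_sigma * sigma`` (ppm)."""

    trimmed_mean: float
    sigma: float
    cutoff: float
    n_used: int
    trim_fraction: float = 0.10
    k_sigma: float = 1.5
    sigma_mode: str = "full"


def combined_shift(d_dH, d_dN, alpha: float = DEFAULT_ALPHA):
    """Combined amide perturbation ``sqrt(ddH^2 + (alpha*ddN)^2)`` in ppm."""
    if alpha <= 0:
        raise ValueError("alpha must be positive")
    return np.sqrt(np.asarray(d_dH, dtype=float) ** 2 +
                   (alpha * np.asarray(d_dN, dtype=float)) ** 2)


def csp_table(reference: pd.DataFrame, variant: pd.DataFrame,
              alpha: float = DEFAULT_ALPHA) -> pd.DataFrame:
    """Per-residue shift differences between two assigned shift tables.

    Both tables are indexed by residue with columns ``dH_ppm, dN_ppm``.
    Residues of the reference missing from the variant are marked
    broadened (delta = NaN); residues only in the variant are skipped
    with a warning.  Returns columns d_dH, d_dN, delta, broadened.
    """
    extra = variant.index.difference(reference.index)
    if len(extra):
        logger.warning("skipping %d residues absent from reference: %s",
                       len(extra), list(extra))
    common = reference.index.intersection(variant.index)
    if len(common) == 0:
        raise ValueError("no residues shared between reference and variant")

    out = pd.DataFrame(index=reference.index.copy())
    out.index.name = "residue"
    out["d_dH"] = variant["dH_ppm"].reindex(reference.index) - reference["dH_ppm"]
    out["d_dN"] = variant["dN_ppm"].reindex(reference.index) - reference["dN_ppm"]
    out["delta"] = combined_shift(out["d_dH"], out["d_dN"], alpha)
    out["broadened"] = ~reference.index.isin(variant.index)
    out.loc[out["broadened"], ["d_dH", "d_dN", "delta"]] = np.nan
    return out


def significance_threshold(records: pd.DataFrame,
                           trim_fraction: float = 0.10,
                           k_sigma: float = 1.5,
                           sigma_mode: str = "full") -> CSPThreshold:
    """Trimmed-mean significance cutoff over the non-broadened deltas.

    ``floor(n * trim_fraction)`` values are dropped from EACH tail before
    computing the trimmed mean; sigma is the sample sd (ddof=1) of either
    the full delta set (default) or the trimmed set.  Broadened records
    never enter the statistics.
    """
    if not 0 <= trim_fraction < 0.5:
        raise ValueError("trim_fraction must be in [0, 0.5)")
    deltas = records.loc[~records["broadened"], "delta"].dropna().to_numpy()
    if deltas.size < 10:
        raise ValueError(
            f"need >= 10 usable records, got {deltas.size}")
    deltas = np.sort(deltas)
    k = int(np.floor(deltas.size * trim_fraction))
    trimmed = deltas[k:deltas.size - k] if k else deltas
    if sigma_mode == "full":
        sigma = float(np.std(deltas, ddof=1))
    elif sigma_mode == "trimmed":
        sigma = float(np.std(trimmed, ddof=1))
    else:
        raise ValueError(f"unknown sigma_mode {sigma_mode!r}")
    mean = float(trimmed.mean())
    return CSPThreshold(trimmed_mean=mean, sigma=sigma,
                        cutoff=mean + k_sigma * sigma, n_used=trimmed.size,
                        trim_fraction=trim_fraction, k_sigma=k_sigma,
                        sigma_mode=sigma_mode)


def score_csp(reference: pd.DataFrame, variant: pd.DataFrame,
              alpha: float = DEFAULT_ALPHA, trim_fraction: float = 0.10,
              k_sigma: float = 1.5, sigma_mode: str = "full",
              ) -> tuple[pd.DataFrame, CSPThreshold]:
    """Full CSP scoring: table, threshold and significance flags.

    Significance is a strict comparison, ``delta > cutoff``; broadened
    residues are significant by broadening.
    """
    table = csp_table(reference, variant, alpha)
    thr = significance_threshold(table, trim_fraction, k_sigma, sigma_mode)
    table["significant"] = (table["delta"] > thr.cutoff) | table["broadened"]
    return table, thr


def read_shift_csv(path) -> pd.DataFrame:
    """Read a shift table CSV (residue, dH_ppm, dN_ppm) indexed by residue."""
    return pd.read_csv(path).set_index("residue")[["dH_ppm", "dN_ppm"]]
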