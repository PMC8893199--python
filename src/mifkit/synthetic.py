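"""Synthetic data with known ground truth for every pipeline stage.

Each generator emulates the statistical structure of one experimental
input — exponential peak-height decays at the standard T1/CPMG delay
schedules, amide shift tables with localized perturbation hotspots and
exchange-broadened residues, C3-symmetric coordinate shells with a known
channel gate radius, Michaelis-Menten initial rates, and two-state melt
curves — so parameter recovery can be tested end to end without raw
spectra.  Noise is Gaussian with sd expressed as a fraction of the
noiseless initial height (or signal span); a fixed seed gives
bit-identical output.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .assembly import two_state_signal
from .geometry import StructureModel, ATOM_COLUMNS
from .relaxation import DecaySeries, T1_DELAYS_MS, T2_DELAYS_MS


@dataclass
class GroundTruth:
    """Ground-truth parameters shared by the generators.

    ``per_residue_rates`` maps residue -> (R1 1/s, R2 1/s, NOE);
    ``perturbation_hotspots`` maps residue -> (ddH ppm, ddN ppm);
    ``broadened_set`` residues vanish from the variant spectrum.
    """

    per_residue_rates: dict[int, tuple[float, float, float]]
    perturbation_hotspots: dict[int, tuple[float, float]] = field(
        default_factory=dict)
    broadened_set: set[int] = field(default_factory=set)
    gate_radius_true: float = 3.4            # Angstrom
    kinetics_true: tuple[float, float] = (10.0, 0.5)   # kcat 1/s, Km mM
    melt_true: tuple[float, float] = (76.9, 400.0)     # Tm C, dH kJ/mol
    seed: int = 0

    def __post_init__(self) -> None:
        for res, (r1, r2, noe) in self.per_residue_rates.items():
            if r1 <= 0 or r2 <= 0:
                raise ValueError(f"residue {res}: rates must be positive")
            if not -1.0 <= noe <= 1.2:
                raise ValueError(f"residue {res}: NOE outside [-1, 1.2]")
        if self.gate_radius_true <= 0:
            raise ValueError("gate radius must be positive")
        if self.kinetics_true[0] <= 0 or self.kinetics_true[1] <= 0:
            raise ValueError("kcat and Km must be positive")

    @classmethod
    def default(cls, n_residues: int = 100, seed: int = 0,
                n_hotspots: int = 8, n_broadened: int = 4) -> "GroundTruth":
        """Default truth for recovery testing.

        R1 is centred at 1.1 1/s (a slowly tumbling trimer); R2 is centred
        at 55 1/s so the CPMG delay list (1-12 ms) samples roughly one
        half-life — the regime that schedule is designed to measure; NOE
        near 0.78 as for a rigid backbone.  Hotspot offsets are
        0.06-0.15 ppm (1H) and 0.3-1.0 ppm (15N), well above the
        0.005 ppm peak-position jitter of a well-resolved TROSY spectrum.
        """
        rng = np.random.default_rng(seed)
        rates = {}
        for res in range(1, n_residues + 1):
            r1 = float(np.clip(rng.normal(1.1, 0.12), 0.4, None))
            r2 = float(np.clip(rng.normal(55.0, 7.0), 10.0, None))
            noe = float(np.clip(rng.normal(0.78, 0.08), -0.5, 0.95))
            rates[res] = (r1, r2, noe)
        picks = rng.choice(np.arange(1, n_residues + 1),
                           size=n_hotspots + n_broadened, replace=False)
        hotspots = {
            int(r): (float(rng.choice([-1, 1]) * rng.uniform(0.06, 0.15)),
                     float(rng.choice([-1, 1]) * rng.uniform(0.3, 1.0)))
            for r in picks[:n_hotspots]}
        broadened = {int(r) for r in picks[n_hotspots:]}
        return cls(per_residue_rates=rates, perturbation_hotspots=hotspots,
                   broadened_set=broadened, seed=seed)

    def to_json(self, path) -> None:
        """Write a truth sidecar (JSON) recording every generator input."""
        d = asdict(self)
        d["broadened_set"] = sorted(self.broadened_set)
        d["per_residue_rates"] = {str(k): v
                                  for k, v in self.per_residue_rates.items()}
        d["perturbation_hotspots"] = {
            str(k): v for k, v in self.perturbation_hotspots.items()}
        with open(path, "w") as fh:
            json.dump(d, fh, indent=2, sort_keys=True)


# ---------------------------------------------------------------------------
# relaxation decays

def gen_decay_series(truth: GroundTruth, kind: str = "R1",
                     schedule: list[float] | None = None,
                     noise_sd: float = 0.02, n_replicates: int = 2,
                     replicate_delays: tuple | None = None,
                     h0: float = 100.0,
                     seed: int | None = None) -> list[DecaySeries]:
    """Exponential peak-height decays for every residue of the truth.

    ``kind`` selects R1 or R2 from the truth rates; the default schedule
    is the standard T1 list (20...1200 ms) or the CPMG list (1...12 ms).
    Designated delays carry ``n_replicates`` measurements each; by
    default every delay is duplicated, emulating a fully interleaved
    replicate series (the acquisition mode behind replicate-based
    uncertainty estimates).  Pass ``replicate_delays`` to restrict
    replication to chosen delays.  Noise is Gaussian with sd
    ``noise_sd * h0``.
    """
    if schedule is None:
        schedule = T1_DELAYS_MS if kind == "R1" else T2_DELAYS_MS
    schedule = list(schedule)
    if not schedule:
        raise ValueError("delay schedule is empty")
    if any(d <= 0 for d in schedule):
        raise ValueError("delays must be strictly positive")
    if noise_sd < 0:
        raise ValueError("noise_sd must be non-negative")
    if kind not in ("R1", "R2"):
        raise ValueError("kind must be 'R1' or 'R2'")
    if replicate_delays is None:
        replicate_delays = tuple(schedule)

    delays = []
    for d in schedule:
        reps = n_replicates if d in replicate_delays else 1
        delays.extend([d] * reps)
    delays = np.array(delays, dtype=float)

    rng = np.random.default_rng(truth.seed if seed is None else seed)
    idx = 0 if kind == "R1" else 1
    out = []
    for res in sorted(truth.per_residue_rates):
        rate = truth.per_residue_rates[res][idx]
        clean = h0 * np.exp(-rate * delays / 1000.0)
        noise = rng.normal(0.0, noise_sd * h0, delays.size) if noise_sd else 0.0
        out.append(DecaySeries(res, delays.copy(), clean + noise))
    return out


def gen_noe_pair(truth: GroundTruth, noise_sd: float = 0.02,
                 h0: float = 100.0, seed: int | None = None) -> pd.DataFrame:
    """Saturated/unsaturated peak-height pairs realizing the truth NOEs.

    Returns a frame (residue, saturated, unsaturated, noise_sd) where
    noise_sd is the absolute per-peak noise, ``noise_sd * h0``.
    """
    if noise_sd < 0:
        raise ValueError("noise_sd must be non-negative")
    rng = np.random.default_rng(truth.seed if seed is None else seed)
    rows = []
    for res in sorted(truth.per_residue_rates):
        noe = truth.per_residue_rates[res][2]
        unsat = h0 + (rng.normal(0.0, noise_sd * h0) if noise_sd else 0.0)
        sat = noe * h0 + (rng.normal(0.0, noise_sd * h0) if noise_sd else 0.0)
        rows.append((res, sat, unsat, noise_sd * h0))
    return pd.DataFrame(rows, columns=["residue", "saturated", "unsaturated",
                                       "noise_sd"]).set_index("residue")


# ---------------------------------------------------------------------------
# chemical shifts

def gen_shift_pair(truth: GroundTruth, n_residues: int = 100,
                   baseline_jitter_sd: float = 0.005,
                   seed: int | None = None):
    """Reference and variant amide shift tables.

    The variant equals the reference plus hotspot offsets plus Gaussian
    jitter (same sd on both dimensions, in ppm); broadened residues are
    omitted from the variant table.  A residue that is both broadened and
    a hotspot is treated as broadened (logged).
    """
    import logging
    log = logging.getLogger(__name__)
    residues = np.arange(1, n_residues + 1)
    bad_hot = set(truth.perturbation_hotspots) - set(residues)
    bad_broad = truth.broadened_set - set(residues)
    if bad_hot or bad_broad:
        raise ValueError("hotspot/broadened residues outside 1..n_residues: "
                         f"{sorted(bad_hot | bad_broad)}")
    overlap = truth.broadened_set & set(truth.perturbation_hotspots)
    if overlap:
        log.warning("residues %s are both broadened and hotspots; "
                    "broadening wins", sorted(overlap))

    rng = np.random.default_rng(truth.seed if seed is None else seed)
    ref = pd.DataFrame({
        "dH_ppm": rng.uniform(6.5, 10.5, n_residues),
        "dN_ppm": rng.uniform(105.0, 130.0, n_residues),
    }, index=pd.Index(residues, name="residue"))

    var = ref.copy()
    for res, (ddh, ddn) in truth.perturbation_hotspots.items():
        var.loc[res, "dH_ppm"] += ddh
        var.loc[res, "dN_ppm"] += ddn
    if baseline_jitter_sd:
        var["dH_ppm"] += rng.normal(0.0, baseline_jitter_sd, n_residues)
        var["dN_ppm"] += rng.normal(0.0, baseline_jitter_sd, n_residues)
    var = var.drop(index=sorted(truth.broadened_set))
    return ref, var


# ---------------------------------------------------------------------------
# trimer shell

def gen_trimer_shell(ring_radius: float = 5.0, gate_radius_offset: float = 0.0,
                     vdw_radius: float = 1.7, n_rings: int = 7,
                     ring_spacing: float = 1.5, n_per_ring: int = 12,
                     gate_ring: int | None = None,
                     thiol_distance: float | None = None,
                     decimals: int | None = None) -> StructureModel:
    """Analytic C3-symmetric pseudo-atom shell around the z-axis.

    ``n_rings`` rings of ``n_per_ring`` carbon pseudo-atoms (Bondi radius
    1.70 A) are stacked along z; the gate ring (middle by default) is
    constricted by ``gate_radius_offset``, so the true free channel
    radius there is ``ring_radius - gate_radius_offset - vdw_radius`` and
    ``ring_radius - vdw_radius`` elsewhere.  Atoms are split into chains
    A/B/C by 120-degree sector so the shell is exactly C3-symmetric.
    ``thiol_distance`` optionally places one SG sulfur per chain in the
    gate plane with that inter-chain separation.  ``decimals=3`` rounds
    coordinates to PDB precision so a write/read round-trip is exact;
    unrounded coordinates (default) keep the C3 symmetry exact to
    machine precision.
    """
    if ring_radius <= vdw_radius:
        raise ValueError("ring_radius must exceed the vdW radius")
    if n_rings < 3:
        raise ValueError("need at least 3 rings")
    if n_per_ring % 3:
        raise ValueError("n_per_ring must be divisible by 3")
    if (ring_radius - gate_radius_offset) - vdw_radius <= 0:
        raise ValueError("closed channel: constriction <= vdW radius")
    if gate_ring is None:
        gate_ring = n_rings // 2

    per_chain = n_per_ring // 3
    rows = []
    z0 = (n_rings - 1) / 2.0 * ring_spacing
    for i in range(n_rings):
        z = i * ring_spacing - z0
        radius = ring_radius - (gate_radius_offset if i == gate_ring else 0.0)
        phase = np.radians(7.0 * i)          # stagger rings
        for c, chain in enumerate("ABC"):
            for j in range(per_chain):
                ang = phase + np.radians(120.0 * c + 120.0 * j / per_chain)
                rows.append((chain, i + 1, "SHL", f"C{j + 1}", "", "C",
                             radius * np.cos(ang), radius * np.sin(ang),
                             z, 1.0))
    if thiol_distance is not None:
        r_sg = thiol_distance / np.sqrt(3.0)
        z = gate_ring * ring_spacing - z0
        for c, chain in enumerate("ABC"):
            ang = np.radians(120.0 * c)
            rows.append((chain, gate_ring + 1, "SHL", "SG", "", "S",
                         r_sg * np.cos(ang), r_sg * np.sin(ang), z, 1.0))
    atoms = pd.DataFrame(rows, columns=ATOM_COLUMNS)
    if decimals is not None:
        atoms[["x", "y", "z"]] = atoms[["x", "y", "z"]].round(decimals)
    return StructureModel(atoms=atoms, vdw={"C": vdw_radius, "S": 1.80})


# ---------------------------------------------------------------------------
# assays

def gen_mm_dataset(kcat: float, km: float, enzyme_conc_nm: float = 50.0,
                   substrate_grid: list[float] | None = None,
                   noise_sd: float = 0.0, seed: int = 0,
                   n_replicates: int = 3) -> pd.DataFrame:
    """Michaelis-Menten initial rates v = kcat*E0*S/(Km+S) in uM/s.

    The default substrate grid spans 0-2 mM with each level measured in
    triplicate (standard plate-assay practice); noise is Gaussian with
    sd ``noise_sd * v`` (proportional).
    """
    if enzyme_conc_nm <= 0:
        raise ValueError("enzyme concentration must be positive")
    if substrate_grid is None:
        substrate_grid = [0.05, 0.1, 0.2, 0.4, 0.8, 1.2, 1.6, 2.0]
    s = np.asarray(substrate_grid, dtype=float)
    if np.any(s < 0):
        raise ValueError("substrate concentrations must be non-negative")
    if n_replicates < 1:
        raise ValueError("n_replicates must be >= 1")
    s = np.repeat(s, n_replicates)
    e0_um = enzyme_conc_nm / 1000.0
    v = kcat * e0_um * s / (km + s)
    if noise_sd:
        rng = np.random.default_rng(seed)
        v = v + rng.normal(0.0, noise_sd * np.abs(v), s.size)
    return pd.DataFrame({"S_mM": s, "v": v})


def gen_melt_curve(tm: float = 76.9, dh: float = 400.0,
                   baselines=((-20.0, 0.01), (-4.0, 0.01)),
                   t_grid: np.ndarray | None = None,
                   noise_sd: float = 0.0, seed: int = 0) -> pd.DataFrame:
    """Two-state melt curve (T_C, signal) with linear baselines.

    ``baselines`` is ((folded intercept, slope), (unfolded intercept,
    slope)); the default grid is 20-100 C in 0.5 C steps; noise sd is a
    fraction of the folded/unfolded signal span.
    """
    if dh <= 0:
        raise ValueError("dH must be positive")
    if t_grid is None:
        t_grid = np.arange(20.0, 100.0 + 1e-9, 0.5)
    t_grid = np.asarray(t_grid, dtype=float)
    if not (t_grid.min() < tm < t_grid.max()):
        raise ValueError("Tm must lie inside the temperature grid")
    (bf0, bf1), (bu0, bu1) = baselines
    y = two_state_signal(t_grid, tm, dh, bf0, bf1, bu0, bu1)
    if noise_sd:
        t_mid = 0.5 * (t_grid.min() + t_grid.max())
        span = abs((bu0 + bu1 * t_mid) - (bf0 + bf1 * t_mid))
        rng = np.random.default_rng(seed)
        y = y + rng.normal(0.0, noise_sd * span, t_grid.size)
    return pd.DataFrame({"T_C": t_grid, "signal": y})
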