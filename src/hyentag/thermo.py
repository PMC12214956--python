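"""Two-state duplex thermodynamics and bit-exchange leakage over storage.

The blocked region of a 0 bit (the blocker ``<U T>`` bound to the tag
strand's T*.U* prefix, 21 bp at the default domain lengths) must stay
duplexed at the working temperature.  Melting temperature and equilibrium
bound fraction are computed from summed nearest-neighbor ΔH/ΔS parameters
(the unified SantaLucia sets shipped with Biopython) with initiation terms
and a monovalent-salt entropy correction, under the usual two-state
approximation with equal strand concentrations.

Because tags store the message in a *metastable* partition of blockers
(0 bits fully blocked, 1 bits fully free), blockers slowly exchange toward
the uniform equilibrium.  :func:`leakage_sim` integrates that mass-action
exchange network — dissociation at k_off derived from ΔG, reassociation at a
diffusion-limited k_on — over a storage horizon to check that no bit drifts
across the binarization threshold.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from Bio.SeqUtils import MeltingTemp as _mt
from scipy.integrate import solve_ivp

__all__ = [
    "ThermoParams",
    "LeakageParams",
    "LeakageResult",
    "nn_sum",
    "duplex_tm",
    "duplex_fraction",
    "melting_curve",
    "leakage_sim",
]

R_CAL = 1.987204  # gas constant, cal/mol/K

_NN_TABLES = {
    "DNA_NN1": _mt.DNA_NN1,
    "DNA_NN2": _mt.DNA_NN2,
    "DNA_NN3": _mt.DNA_NN3,  # Allawi & SantaLucia 1997 (unified)
    "DNA_NN4": _mt.DNA_NN4,  # SantaLucia 2004
}

_COMP = str.maketrans("ACGT", "TGCA")


@dataclass(frozen=True)
class ThermoParams:
    """Conditions for duplex stability calculations.

    ``strand_concentration`` is the per-strand molar concentration (equal for
    both strands); ``monovalent_mM`` drives the 0.368*(N-1)*ln[Na+] entropy
    salt correction.
    """

    nn_table: str = "DNA_NN3"
    temperature: float = 25.0  # °C
    strand_concentration: float = 4e-6  # M
    monovalent_mM: float = 50.0

    def __post_init__(self):
        if self.nn_table not in _NN_TABLES:
            raise ValueError(f"unknown nn_table {self.nn_table!r}")
        if not (-20 <= self.temperature <= 120):
            raise ValueError("temperature out of supported range")
        if self.strand_concentration <= 0 or self.monovalent_mM <= 0:
            raise ValueError("concentrations must be positive")


def nn_sum(duplex_region: str, params: ThermoParams) -> tuple[float, float]:
    """Summed (ΔH kcal/mol, ΔS cal/mol/K) for a perfectly matched duplex,
    including initiation and terminal-AT terms and the salt correction."""
    seq = duplex_region.upper()
    if len(seq) < 2:
        raise ValueError("duplex region must be at least 2 nt")
    if set(seq) - set("ACGT"):
        raise ValueError(f"non-ACGT base in {seq!r}")
    table = _NN_TABLES[params.nn_table]
    dh, ds = table["init"]
    for end in (seq[0], seq[-1]):
        key = "init_A/T" if end in "AT" else "init_G/C"
        dh += table[key][0]
        ds += table[key][1]
    for i in range(len(seq) - 1):
        d = seq[i : i + 2]
        key = f"{d}/{d.translate(_COMP)}"
        if key not in table:
            rd = d.translate(_COMP)[::-1]
            key = f"{rd}/{rd.translate(_COMP)}"
        dh += table[key][0]
        ds += table[key][1]
    ds += 0.368 * (len(seq) - 1) * math.log(params.monovalent_mM / 1000.0)
    return dh, ds


def duplex_tm(duplex_region: str, params: ThermoParams | None = None) -> float:
    """Two-state melting temperature in °C.

    Uses the CT/4 convention for non-self-complementary duplexes at equal
    strand concentrations (half the strands are duplexed at Tm).
    """
    if params is None:
        params = ThermoParams()
    dh, ds = nn_sum(duplex_region, params)
    ct = 2.0 * params.strand_concentration
    return dh * 1000.0 / (ds + R_CAL * math.log(ct / 4.0)) - 273.15


def _equilibrium_k(duplex_region: str, params: ThermoParams, T_celsius: float) -> float:
    """Association constant K (per molar) at the given temperature."""
    dh, ds = nn_sum(duplex_region, params)
    t_k = T_celsius + 273.15
    ln_k = -(dh * 1000.0 - t_k * ds) / (R_CAL * t_k)
    return math.exp(min(ln_k, 700.0))


def duplex_fraction(
    duplex_region: str, params: ThermoParams | None = None, T: float | None = None
) -> float:
    """Equilibrium fraction of strands bound in duplex at temperature T (°C).

    Solves the two-state mass-action equilibrium A + B <-> AB at equal total
    strand concentrations; equals 0.5 exactly at Tm under the CT/4
    convention, approaches 1 far below Tm and 0 far above.
    """
    if params is None:
        params = ThermoParams()
    if T is None:
        T = params.temperature
    a = _equilibrium_k(duplex_region, params, T) * params.strand_concentration
    if a == 0:
        return 0.0
    # a*(1-f)^2 = f  =>  a f^2 - (2a+1) f + a = 0, root in [0, 1]
    disc = math.sqrt((2 * a + 1) ** 2 - 4 * a * a)
    return (2 * a + 1 - disc) / (2 * a)


def melting_curve(
    duplex_region: str,
    params: ThermoParams | None = None,
    t_min: float = 0.0,
    t_max: float = 95.0,
    step: float = 1.0,
) -> pd.DataFrame:
    """Bound fraction across a temperature sweep (for CSV export)."""
    temps = np.arange(t_min, t_max + step / 2, step)
    fracs = [duplex_fraction(duplex_region, params, t) for t in temps]
    return pd.DataFrame({"temperature_C": temps, "bound_fraction": fracs})


# ---------------------------------------------------------------------------
# bit-exchange leakage

@dataclass(frozen=True)
class LeakageParams:
    """Mass-action exchange settings.

    ``k_on`` defaults to a textbook diffusion-limited hybridization rate;
    k_off is derived from the blocked-region ΔG at ``temperature``.  The
    annealing blocker excess is excluded by default (``include_free_excess``)
    so the simulation starts from the nominal intact partition.
    """

    k_on: float = 1e6  # /M/s
    temperature: float = 25.0  # °C
    horizon_years: float = 10.0
    n_timepoints: int = 41
    include_free_excess: bool = False

    def __post_init__(self):
        if self.k_on <= 0 or self.horizon_years <= 0:
            raise ValueError("rates and horizon must be positive")


@dataclass
class LeakageResult:
    times_years: np.ndarray
    blocked_fraction: np.ndarray  # (n_times, n_bits)
    initial_blocked: np.ndarray
    conservation_drift: float  # max relative drift of conserved totals

    @property
    def max_drift(self) -> float:
        """Largest |change in blocked fraction| over the horizon, any bit."""
        return float(np.abs(self.blocked_fraction - self.initial_blocked).max())


_SECONDS_PER_YEAR = 365.25 * 24 * 3600


def leakage_sim(
    tag,
    leakage: LeakageParams | None = None,
    thermo: ThermoParams | None = None,
    k_off: float | None = None,
) -> LeakageResult:
    """Integrate blocker exchange among tag strands over the storage horizon.

    Species: per-bit free tag strand x_i and blocked complex c_i, plus the
    shared free blocker pool L; reactions x_i + L -> c_i (k_on) and
    c_i -> x_i + L (k_off).  All binding sites are identical, so equilibrium
    is the uniform blocker distribution — the same endpoint the thermal
    attack reaches instantly.  Strand and blocker totals are conserved to
    integrator tolerance.  ``k_off`` may be given directly (e.g. 0 to freeze
    kinetics); otherwise it is k_on / K(T) for the blocked T.U region.
    """
    if leakage is None:
        leakage = LeakageParams()
    if thermo is None:
        thermo = ThermoParams(
            temperature=leakage.temperature,
            strand_concentration=tag.mix.per_bit_concentration * 1e-6,
        )
    if k_off is None:
        region = tag.library.shared_domains["U"] + tag.library.shared_domains["T"]
        k_off = leakage.k_on / _equilibrium_k(region, thermo, leakage.temperature)

    conc = tag.mix.per_bit_concentration * 1e-6  # M
    f0 = np.asarray(tag.blocked_fraction, dtype=float)
    n = len(f0)
    c0 = f0 * conc
    x0 = (1.0 - f0) * conc
    free0 = max(0.0, tag.free_blocker) * conc if leakage.include_free_excess else 0.0
    y0 = np.concatenate([x0, c0, [free0]])

    k_on = leakage.k_on

    def rhs(_t, y):
        x, c, L = y[:n], y[n : 2 * n], y[-1]
        bind = k_on * x * L
        unbind = k_off * c
        dx = unbind - bind
        dc = bind - unbind
        return np.concatenate([dx, dc, [bind.sum() * -1 + unbind.sum()]])

    t_end = leakage.horizon_years * _SECONDS_PER_YEAR
    times = np.linspace(0.0, t_end, leakage.n_timepoints)
    sol = solve_ivp(
        rhs, (0.0, t_end), y0, t_eval=times, method="LSODA",
        rtol=1e-10, atol=1e-20,
    )
    if not sol.success:
        raise RuntimeError(f"leakage integration failed: {sol.message}")
    x = sol.y[:n].T
    c = sol.y[n : 2 * n].T
    L = sol.y[-1]
    strand_tot = x + c
    blocker_tot = c.sum(axis=1) + L
    drift_strand = np.abs(strand_tot - conc).max() / conc
    b0 = c0.sum() + free0
    drift_blocker = 0.0 if b0 == 0 else np.abs(blocker_tot - b0).max() / b0
    return LeakageResult(
        times_years=times / _SECONDS_PER_YEAR,
        blocked_fraction=c / conc,
        initial_blocked=f0,
        conservation_drift=float(max(drift_strand, drift_blocker)),
    )
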