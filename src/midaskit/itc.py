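"""One-site isothermal-titration-calorimetry isotherms: simulate and fit.

The cumulative heat after injection *i* follows the single-site (Wiseman)
isotherm,

    Q(i) = (n*Mt*dH*V0/2) * [1 + Xt/(n*Mt) + 1/(n*K*Mt)
                             - sqrt((1 + Xt/(n*Mt) + 1/(n*K*Mt))^2 - 4*Xt/(n*Mt))]

with Mt, Xt the current cell concentrations of macromolecule and titrant.
A perfusion cell of fixed volume V0 expels liquid as it is injected; the
standard displaced-volume bookkeeping is used: with cumulative injected
volume dV and f = dV/(2*V0),

    Mt = Mt0 * (1 - f) / (1 + f),     Xt = X_syringe * (dV/V0) / (1 + f),

and the measured heat of injection *i* includes the heat carried out with
the expelled liquid:

    q(i) = Q(i) - Q(i-1) + (v_i/V0) * (Q(i) + Q(i-1)) / 2.

Units follow calorimetry convention: kcal/mol for dH and dG, cal/(mol K)
for dS, microcalories for per-injection heats, K in 1/M.  The curve shape
is governed by c = n*K*Mt0.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import lmfit
import numpy as np

__all__ = [
    "R_KCAL",
    "TitrationSchedule",
    "OneSiteParams",
    "Thermogram",
    "ITCFit",
    "cumulative_heat",
    "injection_heats",
    "simulate_titration",
    "fit_one_site",
    "free_metal",
    "write_thermogram",
    "read_thermogram",
]

#: Gas constant in kcal mol^-1 K^-1.
R_KCAL = 1.9872e-3


@dataclass(frozen=True)
class TitrationSchedule:
    """Cell/syringe concentrations and the injection sequence.

    Defaults mirror a VP-ITC-class experiment on an I domain: 1.4 mL cell,
    100 uM macromolecule, 20 mM metal titrant, 2 uL injections, 20 C.
    """

    cell_conc: float  # mol/L macromolecule in the cell, Mt0
    syringe_conc: float  # mol/L titrant
    injections: tuple[float, ...]  # injection volumes, L
    cell_volume: float = 1.4e-3  # L
    temperature: float = 293.15  # K

    def __post_init__(self) -> None:
        if min(self.cell_conc, self.syringe_conc, self.cell_volume, self.temperature) <= 0:
            raise ValueError("schedule values must be positive")
        if not self.injections or min(self.injections) <= 0:
            raise ValueError("need at least one positive injection volume")

    @classmethod
    def uniform(
        cls,
        n_injections: int = 35,
        injection_volume: float = 2e-6,
        cell_conc: float = 100e-6,
        syringe_conc: float = 20e-3,
        **kw,
    ) -> "TitrationSchedule":
        return cls(
            cell_conc=cell_conc,
            syringe_conc=syringe_conc,
            injections=(injection_volume,) * n_injections,
            **kw,
        )

    def cumulative_volumes(self) -> np.ndarray:
        return np.cumsum(self.injections)

    def concentrations(self) -> tuple[np.ndarray, np.ndarray]:
        """(Mt, Xt) in the cell after each injection (displaced-volume model)."""
        dv = self.cumulative_volumes()
        f = dv / (2.0 * self.cell_volume)
        mt = self.cell_conc * (1.0 - f) / (1.0 + f)
        xt = self.syringe_conc * (dv / self.cell_volume) / (1.0 + f)
        return mt, xt


@dataclass(frozen=True)
class OneSiteParams:
    """Single-site binding parameters: stoichiometry n, K (1/M), dH (kcal/mol)."""

    K: float
    dH: float
    n: float = 1.0

    def __post_init__(self) -> None:
        if self.K <= 0 or self.n <= 0:
            raise ValueError("K and n must be positive")


@dataclass
class Thermogram:
    """Per-injection integrated heats (microcal), optionally blank-corrected."""

    schedule: TitrationSchedule
    heats: np.ndarray  # ucal
    blank_heats: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.heats = np.asarray(self.heats, dtype=float)
        if len(self.heats) != len(self.schedule.injections):
            raise ValueError("one heat per injection required")
        if self.blank_heats is not None:
            self.blank_heats = np.asarray(self.blank_heats, dtype=float)
            if len(self.blank_heats) != len(self.heats):
                raise ValueError("blank length mismatch")

    def corrected(self) -> np.ndarray:
        if self.blank_heats is None:
            return self.heats
        return self.heats - self.blank_heats


@dataclass
class ITCFit:
    """Fitted one-site model with derived state functions.

    Identities: Kd = 1/K; dG = -R*T*ln(K) (kcal/mol);
    dS = (dH - dG)/T * 1000 (cal mol^-1 K^-1).
    """

    params: OneSiteParams
    dG: float
    dS: float
    Kd: float
    param_uncertainties: dict[str, float | None]
    residual_norm: float
    temperature: float
    n_injections_used: int


def _q_total(mt: np.ndarray, xt: np.ndarray, params: OneSiteParams, v0: float) -> np.ndarray:
    """Cumulative heat (ucal) after each injection from the Wiseman isotherm."""
    n, k, dh = params.n, params.K, params.dH
    with np.errstate(invalid="raise"):
        term = 1.0 + xt / (n * mt) + 1.0 / (n * k * mt)
        disc = term * term - 4.0 * xt / (n * mt)
        if np.any(disc < -1e-12):
            raise FloatingPointError("negative discriminant in binding quadratic")
        root = np.sqrt(np.clip(disc, 0.0, None))
    # dH kcal/mol -> cal/mol (1e3); cal -> ucal (1e6)
    return (n * mt * dh * 1e9 * v0 / 2.0) * (term - root)


def cumulative_heat(
    schedule: TitrationSchedule, params: OneSiteParams, after_injection_i: int
) -> float:
    """Q(i) in microcal, with cell concentrations diluted per the perfusion model."""
    if not 1 <= after_injection_i <= len(schedule.injections):
        raise IndexError("injection index out of range")
    mt, xt = schedule.concentrations()
    q = _q_total(mt, xt, params, schedule.cell_volume)
    return float(q[after_injection_i - 1])


def injection_heats(schedule: TitrationSchedule, params: OneSiteParams) -> np.ndarray:
    """Noise-free per-injection heats q(i) (ucal), displaced-volume corrected."""
    mt, xt = schedule.concentrations()
    q = _q_total(mt, xt, params, schedule.cell_volume)
    qprev = np.concatenate([[0.0], q[:-1]])
    vi = np.asarray(schedule.injections)
    return q - qprev + (vi / schedule.cell_volume) * (q + qprev) / 2.0


def simulate_titration(
    schedule: TitrationSchedule,
    params: OneSiteParams,
    noise_sd: float = 0.0,
    seed: int | None = None,
) -> Thermogram:
    """Simulate a blank-corrected thermogram with Gaussian noise (ucal)."""
    if noise_sd < 0:
        raise ValueError("noise_sd must be non-negative")
    heats = injection_heats(schedule, params)
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        heats = heats + rng.normal(0.0, noise_sd, size=heats.shape)
    return Thermogram(schedule=schedule, heats=heats)


def fit_one_site(
    t: Thermogram,
    fix_n: bool = True,
    initial: OneSiteParams | None = None,
    exclude_first: bool = False,
) -> ITCFit:
    """Least-squares fit of (K, dH) — and n if ``fix_n`` is False.

    The stoichiometry is fixed at 1 by default (fewer parameters, smaller
    uncertainties, and the structures show a single MIDAS site).  The first
    injection may be excluded, the common remedy for the diffusion artifact
    of the initial injection.  Derived dG/dS/Kd come from the fitted K and
    dH via the thermodynamic identities; uncertainties are 1-sigma values
    from the fit covariance.
    """
    heats = t.corrected()
    sched = t.schedule
    idx = np.arange(len(heats))
    if exclude_first:
        idx = idx[1:]
    if len(idx) < 5:
        raise ValueError("need at least 5 informative injections")
    if np.allclose(heats[idx], 0.0):
        raise ValueError("degenerate thermogram: all heats are zero")

    if initial is None:
        total = float(np.sum(heats[idx]))
        dh0 = total / (sched.cell_conc * sched.cell_volume * 1e9)
        dh0 = dh0 if abs(dh0) > 1e-6 else math.copysign(1.0, total or -1.0)
        initial = OneSiteParams(K=1.0 / sched.cell_conc, dH=dh0)

    p = lmfit.Parameters()
    p.add("logK", value=math.log10(initial.K), min=-2, max=12)
    p.add("dH", value=initial.dH)
    p.add("n", value=initial.n, min=1e-3, vary=not fix_n)

    def residual(pars):
        model = injection_heats(
            sched, OneSiteParams(K=10.0 ** pars["logK"].value, dH=pars["dH"].value, n=pars["n"].value)
        )
        return model[idx] - heats[idx]

    out = lmfit.minimize(residual, p, method="leastsq")
    if not out.success:
        raise RuntimeError(f"one-site fit did not converge: {out.message}")
    logk = out.params["logK"]
    k = 10.0 ** logk.value
    dh = out.params["dH"].value
    nfit = out.params["n"].value
    temp = sched.temperature
    dg = -R_KCAL * temp * math.log(k)
    ds = (dh - dg) / temp * 1e3

    k_err = (
        abs(k * math.log(10.0) * logk.stderr) if logk.stderr is not None else None
    )
    fitted = OneSiteParams(K=k, dH=dh, n=nfit)
    return ITCFit(
        params=fitted,
        dG=dg,
        dS=ds,
        Kd=1.0 / k,
        param_uncertainties={
            "K": k_err,
            "dH": out.params["dH"].stderr,
            "n": out.params["n"].stderr if not fix_n else None,
        },
        residual_norm=float(np.sqrt(np.sum(out.residual**2))),
        temperature=temp,
        n_injections_used=len(idx),
    )


def free_metal(total_metal: float, buffer_conc: float, logK_buffer: float) -> float:
    """Free metal concentration under 1:1 buffer-metal complexation.

    Solves ``Kb*M^2 + (1 + Kb*(B - Mtot))*M - Mtot = 0`` for the physical
    root (stable quadratic formula).  Good buffers still chelate divalent
    cations weakly — e.g. ACES binds Ca2+ with log K 3.38 and Mg2+ with
    log K 3.55 — so the free concentration can sit well below total.
    """
    if total_metal < 0 or buffer_conc < 0:
        raise ValueError("concentrations must be non-negative")
    if total_metal == 0:
        return 0.0
    kb = 10.0 ** logK_buffer
    if kb == 0 or buffer_conc == 0:
        return total_metal
    a = kb
    b = 1.0 + kb * (buffer_conc - total_metal)
    c = -total_metal
    disc = b * b - 4.0 * a * c
    if disc < 0:
        raise FloatingPointError("no physical root in buffer mass balance")
    # numerically stable: q = -(b + sign(b)*sqrt(disc))/2
    sq = math.sqrt(disc)
    q = -0.5 * (b + math.copysign(sq, b))
    roots = [r for r in (q / a, c / q if q != 0 else math.inf) if 0 <= r <= total_metal + 1e-30]
    if not roots:
        raise FloatingPointError("no physical root in buffer mass balance")
    return min(roots)


# ---------------------------------------------------------------------------
# delimited-text thermogram I/O: injection_index, volume_uL, heat_ucal
# ---------------------------------------------------------------------------

def write_thermogram(t: Thermogram, path, sep: str = "\t") -> None:
    with open(path, "w") as fh:
        fh.write(sep.join(["injection", "volume_uL", "heat_ucal"]) + "\n")
        for i, (v, q) in enumerate(zip(t.schedule.injections, t.heats), start=1):
            fh.write(sep.join([str(i), f"{v * 1e6:.4f}", f"{q:.6f}"]) + "\n")


def read_thermogram(
    path,
    cell_conc: float,
    syringe_conc: float,
    cell_volume: float = 1.4e-3,
    temperature: float = 293.15,
    sep: str | None = None,
) -> Thermogram:
    """Read (injection, volume_uL, heat_ucal) rows; header optional."""
    vols: list[float] = []
    heats: list[float] = []
    with open(path) as fh:
        for line in fh:
            parts = line.split(sep) if sep else line.split()
            if not parts or not parts[0].strip():
                continue
            try:
                float(parts[0])
            except ValueError:
                continue  # header
            if len(parts) < 3:
                raise ValueError(f"bad thermogram row: {line!r}")
            vols.append(float(parts[1]) * 1e-6)
            heats.append(float(parts[2]))
    if not vols:
        raise ValueError(f"no data rows in {path}")
    sched = TitrationSchedule(
        cell_conc=cell_conc,
        syringe_conc=syringe_conc,
        injections=tuple(vols),
        cell_volume=cell_volume,
        temperature=temperature,
    )
    return Thermogram(schedule=sched, heats=np.array(heats))
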