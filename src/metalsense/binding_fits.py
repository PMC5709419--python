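"""Simulation and fitting of in vitro titrations.

Two experiment families determine the sensor constants:

* **Chelator competition** — metal is titrated into a mixture of protein
  and a spectroscopic probe of known metal affinity (fura-2, EGTA,
  magfura-2 or quin-2).  The observed signal tracks either the probe–metal
  complex (fluorescence/absorbance quenching, decreasing) or the
  protein–metal complex (d–d absorbance, increasing).  Protein sites are
  counted per monomer ("molar equivalents") and treated as identical and
  independent.
* **Fluorescence anisotropy** — protein is titrated into a labelled
  operator–promoter duplex.  Binding is per non-dissociable assembly
  (dimer or tetramer), either one assembly per DNA or two sequential
  assemblies sharing one dissociation constant; each bound assembly adds a
  fixed anisotropy increment.

All forward models solve the exact depletion equilibria — no
excess-ligand approximations — so fitted constants are meaningful even
when totals are far above the Kd.  The fits profile an affine signal map
(offset + span, solved linearly) over a 1-D bounded search on log10(Kd),
and report tenfold tighter/weaker envelope curves around the fitted value.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import brentq, minimize_scalar

from .speciation import solve_two_component

__all__ = [
    "CHELATOR_KD",
    "CompetitionModel",
    "DnaBindingModel",
    "TitrationCurve",
    "FitResult",
    "simulate_competition",
    "fit_metal_affinity",
    "simulate_anisotropy",
    "fit_dna_affinity",
    "COMPETITION_DESIGNS",
    "ANISOTROPY_DESIGNS",
]

# probe metal dissociation constants at pH 7.0, molar
CHELATOR_KD = {
    "fura-2": 8.64e-9,  # Co(II)
    "egta": 7.89e-9,  # Co(II), conditional
    "magfura-2": 2e-8,  # Zn(II)
    "quin-2": 3.7e-12,  # Zn(II)
}

DELTA_R_DEFAULT = 0.025  # anisotropy increment per bound assembly
R0_DEFAULT = 0.15

_LOG10_KD_RANGE = (-15.0, -1.0)
_EDGE_MARGIN = 0.3  # best fit this close to the search edge => non-identifiable


@dataclass(frozen=True)
class CompetitionModel:
    """Design of one chelator-competition titration."""

    probe: str
    probe_kd: float  # molar
    probe_total: float  # molar
    protein_total: float  # molar, monomer basis
    equivalents: float = 1.0  # metal sites per monomer
    signal_source: str = "probe_metal_complex"  # or "protein_metal_complex"
    signal_direction: str = "decreasing"  # or "increasing"

    def __post_init__(self) -> None:
        if not (self.probe_kd > 0):
            raise ValueError("probe_kd must be > 0")
        if not (self.equivalents > 0):
            raise ValueError("equivalents must be > 0")
        if self.probe_total < 0 or self.protein_total < 0:
            raise ValueError("totals must be >= 0")
        if self.signal_source not in ("probe_metal_complex", "protein_metal_complex"):
            raise ValueError(f"unknown signal_source {self.signal_source!r}")
        if self.signal_direction not in ("decreasing", "increasing"):
            raise ValueError(f"unknown signal_direction {self.signal_direction!r}")

    @property
    def site_total(self) -> float:
        return self.protein_total * self.equivalents


@dataclass(frozen=True)
class DnaBindingModel:
    """Design of one anisotropy titration."""

    stoichiometry: str  # one_assembly_per_dna | two_sequential_assemblies_per_dna
    dna_total: float  # molar
    assembly_size: int  # monomers per non-dissociable assembly
    delta_r_per_event: float | None = None  # None => fitted; value => fixed
    r0: float = R0_DEFAULT
    max_titrant: float | None = None  # monomer basis; truncate fits above this

    def __post_init__(self) -> None:
        if self.stoichiometry not in (
            "one_assembly_per_dna",
            "two_sequential_assemblies_per_dna",
        ):
            raise ValueError(f"unknown stoichiometry {self.stoichiometry!r}")
        if not (self.dna_total > 0):
            raise ValueError("dna_total must be > 0")
        if self.assembly_size < 1:
            raise ValueError("assembly_size must be >= 1")
        if self.delta_r_per_event is not None and not (self.delta_r_per_event > 0):
            raise ValueError("delta_r_per_event must be > 0 when fixed")

    @property
    def events_per_dna(self) -> int:
        return 1 if self.stoichiometry == "one_assembly_per_dna" else 2


@dataclass
class TitrationCurve:
    """Titrant totals (molar) versus observed signal."""

    titrant_total: np.ndarray
    signal: np.ndarray
    sd: np.ndarray | None = None
    titrant: str = "metal"  # or "protein"
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.titrant_total = np.asarray(self.titrant_total, dtype=float)
        self.signal = np.asarray(self.signal, dtype=float)
        if np.any(np.diff(self.titrant_total) < 0):
            raise ValueError("titrant totals must be non-decreasing")
        if self.titrant_total.shape != self.signal.shape:
            raise ValueError("titrant_total and signal must have equal length")

    def to_frame(self) -> pd.DataFrame:
        data = {"titrant_total_M": self.titrant_total, "signal": self.signal}
        if self.sd is not None:
            data["sd"] = self.sd
        return pd.DataFrame(data)


@dataclass
class FitResult:
    kd: float | None
    kd_sd: float | None
    residual_rms: float
    converged: bool
    envelope: dict[str, TitrationCurve] = field(default_factory=dict)
    nuisance: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.converged and not (self.kd is not None and self.kd > 0):
            raise ValueError("a converged fit must carry a positive Kd")


# ---------------------------------------------------------------------------
# competition forward model and fit


def _competition_complexes(
    model: CompetitionModel, protein_kd: float, metal_totals: np.ndarray
) -> np.ndarray:
    """Concentration of the signal-bearing complex at each metal total.

    Exact speciation: the two binding sites compete for one metal pool, so
    the metal mass balance
    ``m + probe_tot*m/(Kp+m) + site_tot*m/(Ks+m) = M_tot``
    is monotone in the free metal m and solved by bracketed root finding.
    """
    kp, ks = model.probe_kd, protein_kd
    p_tot, s_tot = model.probe_total, model.site_total
    out = np.empty(len(metal_totals))
    for i, m_tot in enumerate(metal_totals):
        if m_tot == 0.0:
            out[i] = 0.0
            continue
        if s_tot == 0.0:
            st = solve_two_component(1.0 / kp, m_tot, p_tot)
            probe_m, site_m = st["AB"], 0.0
        else:

            def balance(m: float) -> float:
                return m + p_tot * m / (kp + m) + s_tot * m / (ks + m) - m_tot

            m_free = brentq(balance, 0.0, m_tot, xtol=1e-300, rtol=1e-14)
            probe_m = p_tot * m_free / (kp + m_free)
            site_m = s_tot * m_free / (ks + m_free)
        out[i] = probe_m if model.signal_source == "probe_metal_complex" else site_m
    return out


def simulate_competition(
    model: CompetitionModel,
    protein_kd: float,
    metal_totals,
    signal_offset: float | None = None,
    signal_span: float | None = None,
) -> TitrationCurve:
    """Noise-free competition titration.

    The signal is affine in the designated complex concentration.  By
    default a decreasing signal runs 1 -> 0 as the probe saturates and an
    increasing signal runs 0 -> 1 as the protein sites fill.
    """
    if not (protein_kd > 0):
        raise ValueError("protein_kd must be > 0")
    metal_totals = np.asarray(metal_totals, dtype=float)
    complexes = _competition_complexes(model, protein_kd, metal_totals)
    scale = (
        model.probe_total
        if model.signal_source == "probe_metal_complex"
        else max(model.site_total, 1e-30)
    )
    if signal_offset is None or signal_span is None:
        if model.signal_direction == "decreasing":
            signal_offset, signal_span = 1.0, -1.0 / scale
        else:
            signal_offset, signal_span = 0.0, 1.0 / scale
    return TitrationCurve(
        metal_totals,
        signal_offset + signal_span * complexes,
        titrant="metal",
        meta={"model": model, "protein_kd": protein_kd},
    )


def _profile_fit(
    log10_grid: np.ndarray,
    sse_of_log10kd,
    n_points: int,
    n_params: int,
):
    """1-D bounded minimisation of a profiled sum of squares over log10(Kd).

    Coarse deterministic grid scan followed by local bounded refinement;
    returns (log10kd, sse, sd_log10kd, at_edge).
    """
    sses = np.array([sse_of_log10kd(x) for x in log10_grid])
    i0 = int(np.argmin(sses))
    lo = log10_grid[max(i0 - 1, 0)]
    hi = log10_grid[min(i0 + 1, len(log10_grid) - 1)]
    res = minimize_scalar(sse_of_log10kd, bounds=(lo, hi), method="bounded")
    best_x, best_sse = float(res.x), float(res.fun)
    if sses[i0] < best_sse:
        best_x, best_sse = float(log10_grid[i0]), float(sses[i0])
    at_edge = (
        best_x < log10_grid[0] + _EDGE_MARGIN or best_x > log10_grid[-1] - _EDGE_MARGIN
    )
    # curvature-based uncertainty on log10(Kd)
    h = 0.05
    curv = (
        sse_of_log10kd(best_x + h) - 2.0 * best_sse + sse_of_log10kd(best_x - h)
    ) / (h * h)
    dof = max(n_points - n_params, 1)
    sigma2 = best_sse / dof
    sd_log10 = math.sqrt(2.0 * sigma2 / curv) if curv > 0 else None
    return best_x, best_sse, sd_log10, at_edge


def fit_metal_affinity(curve: TitrationCurve, model: CompetitionModel) -> FitResult:
    """Least-squares protein metal Kd from a competition titration.

    The affine signal parameters are profiled out linearly at each trial
    Kd.  A fit whose optimum sits at the edge of the search window (the
    protein never competes detectably) or whose signal is degenerate is
    flagged non-converged and carries no Kd.
    """
    if len(curve.titrant_total) < 6:
        raise ValueError("need at least 6 titration points to fit")
    y = curve.signal
    if float(np.ptp(y)) <= 1e-12:
        return FitResult(None, None, float(np.std(y)), False)

    def sse(log10kd: float) -> float:
        c = _competition_complexes(model, 10.0**log10kd, curve.titrant_total)
        A = np.column_stack([np.ones_like(c), c])
        coef, *_ = np.linalg.lstsq(A, y, rcond=None)
        return float(np.sum((y - A @ coef) ** 2))

    grid = np.arange(_LOG10_KD_RANGE[0], _LOG10_KD_RANGE[1] + 1e-9, 0.25)
    best_x, best_sse, sd_log10, at_edge = _profile_fit(
        grid, sse, len(y), n_params=3
    )
    kd = 10.0**best_x
    c = _competition_complexes(model, kd, curve.titrant_total)
    A = np.column_stack([np.ones_like(c), c])
    coef, *_ = np.linalg.lstsq(A, y, rcond=None)
    rms = math.sqrt(best_sse / len(y))
    if at_edge:
        return FitResult(None, None, rms, False)
    envelope = {
        "tenfold_tighter": simulate_competition(
            model, kd / 10.0, curve.titrant_total, coef[0], coef[1]
        ),
        "tenfold_weaker": simulate_competition(
            model, kd * 10.0, curve.titrant_total, coef[0], coef[1]
        ),
    }
    kd_sd = kd * math.log(10.0) * sd_log10 if sd_log10 is not None else None
    return FitResult(
        kd,
        kd_sd,
        rms,
        True,
        envelope=envelope,
        nuisance={"signal_offset": float(coef[0]), "signal_span": float(coef[1])},
    )


# ---------------------------------------------------------------------------
# anisotropy forward model and fit


def _bound_assemblies_per_dna(
    model: DnaBindingModel, dna_kd: float, protein_totals_monomer: np.ndarray
) -> np.ndarray:
    """Mean number of bound assemblies per DNA at each protein total."""
    k = 1.0 / dna_kd
    out = np.empty(len(protein_totals_monomer))
    for i, p_mono in enumerate(protein_totals_monomer):
        a_tot = p_mono / model.assembly_size
        if a_tot == 0.0:
            out[i] = 0.0
        elif model.stoichiometry == "one_assembly_per_dna":
            st = solve_two_component(k, a_tot, model.dna_total)
            out[i] = st["AB"] / model.dna_total
        else:
            # sequential identical-Kd events: for free assembly a the DNA
            # partition is 1 : k*a : (k*a)^2, and the assembly mass balance
            # a + D_tot*(k*a + 2*(k*a)^2)/(1 + k*a + (k*a)^2) = A_tot
            # is monotone in a
            d_tot = model.dna_total

            def balance(a: float) -> float:
                ka = k * a
                denom = 1.0 + ka + ka * ka
                return a + d_tot * (ka + 2.0 * ka * ka) / denom - a_tot

            a_free = brentq(balance, 0.0, a_tot, xtol=1e-300, rtol=1e-14)
            ka = k * a_free
            denom = 1.0 + ka + ka * ka
            out[i] = (ka + 2.0 * ka * ka) / denom
    return out


def simulate_anisotropy(
    model: DnaBindingModel, dna_kd: float, protein_totals
) -> TitrationCurve:
    """Noise-free anisotropy titration; protein totals on the monomer basis."""
    if not (dna_kd > 0):
        raise ValueError("dna_kd must be > 0")
    protein_totals = np.asarray(protein_totals, dtype=float)
    bound = _bound_assemblies_per_dna(model, dna_kd, protein_totals)
    dr = model.delta_r_per_event if model.delta_r_per_event is not None else DELTA_R_DEFAULT
    return TitrationCurve(
        protein_totals,
        model.r0 + dr * bound,
        titrant="protein",
        meta={"model": model, "dna_kd": dna_kd},
    )


def fit_dna_affinity(curve: TitrationCurve, model: DnaBindingModel) -> FitResult:
    """Least-squares DNA Kd from an anisotropy titration.

    The baseline (and the per-event anisotropy increment, unless the design
    fixes it) are profiled linearly.  Supports truncating the fitted range
    to the first binding event via ``model.max_titrant``.
    """
    if len(curve.titrant_total) < 6:
        raise ValueError("need at least 6 titration points to fit")
    mask = (
        curve.titrant_total <= model.max_titrant
        if model.max_titrant is not None
        else np.ones(len(curve.titrant_total), dtype=bool)
    )
    x = curve.titrant_total[mask]
    y = curve.signal[mask]
    if len(x) < 6:
        raise ValueError("fewer than 6 points remain after truncation")
    if float(np.ptp(y)) <= 1e-12:
        return FitResult(None, None, float(np.std(y)), False)
    fixed_dr = model.delta_r_per_event

    def sse(log10kd: float) -> float:
        b = _bound_assemblies_per_dna(model, 10.0**log10kd, x)
        if fixed_dr is None:
            A = np.column_stack([np.ones_like(b), b])
            coef, *_ = np.linalg.lstsq(A, y, rcond=None)
            return float(np.sum((y - A @ coef) ** 2))
        r0 = float(np.mean(y - fixed_dr * b))
        return float(np.sum((y - r0 - fixed_dr * b) ** 2))

    grid = np.arange(_LOG10_KD_RANGE[0], _LOG10_KD_RANGE[1] + 1e-9, 0.25)
    n_params = 2 if fixed_dr is None else 1
    best_x, best_sse, sd_log10, at_edge = _profile_fit(
        grid, sse, len(y), n_params=n_params + 1
    )
    kd = 10.0**best_x
    rms = math.sqrt(best_sse / len(y))
    if at_edge:
        return FitResult(None, None, rms, False)
    b = _bound_assemblies_per_dna(model, kd, x)
    if fixed_dr is None:
        A = np.column_stack([np.ones_like(b), b])
        coef, *_ = np.linalg.lstsq(A, y, rcond=None)
        r0, dr = float(coef[0]), float(coef[1])
    else:
        dr = float(fixed_dr)
        r0 = float(np.mean(y - dr * b))
    fitted_model = DnaBindingModel(
        model.stoichiometry, model.dna_total, model.assembly_size, dr, r0
    )
    envelope = {
        "tenfold_tighter": simulate_anisotropy(fitted_model, kd / 10.0, curve.titrant_total),
        "tenfold_weaker": simulate_anisotropy(fitted_model, kd * 10.0, curve.titrant_total),
    }
    kd_sd = kd * math.log(10.0) * sd_log10 if sd_log10 is not None else None
    return FitResult(
        kd,
        kd_sd,
        rms,
        True,
        envelope=envelope,
        nuisance={"r0": r0, "delta_r_per_event": dr},
    )


# ---------------------------------------------------------------------------
# the seven published experimental designs (truth values from the study)

COMPETITION_DESIGNS: dict[str, tuple[CompetitionModel, float]] = {
    # fura-2 (15.4 uM) + ZntR (9.8 uM), one Co(II) equivalent per monomer
    "fura2_zntr_co": (
        CompetitionModel("fura-2", CHELATOR_KD["fura-2"], 15.4e-6, 9.8e-6, 1.0),
        9.5e-8,
    ),
    # fura-2 (14.6 uM) + Zur (9.8 uM), two Co(II) equivalents per monomer
    "fura2_zur_co": (
        CompetitionModel("fura-2", CHELATOR_KD["fura-2"], 14.6e-6, 9.8e-6, 2.0),
        1.5e-8,
    ),
    # EGTA (50 uM) + Zur (52 uM); signal is the Co(II)-protein d-d absorbance
    "egta_zur_co": (
        CompetitionModel(
            "egta",
            CHELATOR_KD["egta"],
            50e-6,
            52e-6,
            2.0,
            signal_source="protein_metal_complex",
            signal_direction="increasing",
        ),
        1.5e-8,
    ),
    # quin-2 (18.0 uM) + RcnR (14.9 uM), one Zn(II) equivalent per monomer
    "quin2_rcnr_zn": (
        CompetitionModel("quin-2", CHELATOR_KD["quin-2"], 18.0e-6, 14.9e-6, 1.0),
        9.4e-12,
    ),
}

ANISOTROPY_DESIGNS: dict[str, tuple[DnaBindingModel, float]] = {
    # Zn(II)-Zur on znuA promoter: two sequential dimers, 10 nM DNA
    "zur_znua": (
        DnaBindingModel("two_sequential_assemblies_per_dna", 10e-9, 2),
        5.4e-8,
    ),
    # ZntR on zntA promoter: one dimer, delta-r fixed at 0.025, first event only
    "zntr_znta": (
        DnaBindingModel("one_assembly_per_dna", 10e-9, 2, DELTA_R_DEFAULT,
                        max_titrant=1500e-9),
        1.1e-6,
    ),
    # Co(II)-FrmR_E64H on frmRA promoter: two sequential tetramers, 10 nM DNA
    "frmre64h_frmra_co": (
        DnaBindingModel("two_sequential_assemblies_per_dna", 10e-9, 4),
        2.3e-6,
    ),
}
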