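"""Pharmacodynamic biomarker models driven by the liver-cell RNP signal.

Three models, all on a percent-of-baseline scale and in units of 1/day:

* serum TTR — type-I indirect response with Hill inhibition of production;
* serum PCSK9 — transit-compartment model (rate n/MTT) with synthesis
  inhibition and an optional production feedback term (PCSK9_0/PCSK9)^gamma;
* serum LDL-C — precursor-dependent turnover whose production scales with
  the PCSK9 signal raised to a power.

All models are exactly stationary at baseline when the RNP signal is zero,
because production rates are constructed from the corresponding degradation
rate and baseline (k_in = k_out * baseline).
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass
from importlib import resources

import numpy as np
import yaml


@dataclass(frozen=True)
class TTRParameters:
    TTR0: float = 100.0  # % baseline
    k_out_TTR: float = 0.493  # 1/d
    Imax: float = 0.961
    IC50: float = 4.77  # ug/mL
    gamma: float = 0.31

    def __post_init__(self) -> None:
        if self.TTR0 <= 0:
            raise ValueError("TTR0 must be positive")
        if not 0.0 < self.Imax <= 1.0:
            raise ValueError(f"Imax must lie in (0, 1], got {self.Imax}")
        if self.IC50 <= 0:
            raise ValueError("IC50 must be positive")
        if self.gamma <= 0:
            raise ValueError("gamma must be positive")
        if self.k_out_TTR <= 0:
            raise ValueError("k_out_TTR must be positive")


@dataclass(frozen=True)
class PCSK9Parameters:
    PCSK9_0: float = 100.0  # % baseline
    MTT: float = 14.5  # d
    n_transit: int = 3
    Imax_P: float = 0.771
    IC50_P: float = 21.5  # ug/mL
    gamma_P: float = 1.1  # Hill exponent
    gamma_feedback: float = 1.1  # production feedback exponent; 0 disables feedback

    def __post_init__(self) -> None:
        if self.MTT <= 0:
            raise ValueError("MTT must be positive")
        if self.n_transit < 1 or int(self.n_transit) != self.n_transit:
            raise ValueError("n_transit must be an integer >= 1")
        if not 0.0 < self.Imax_P <= 1.0:
            raise ValueError(f"Imax_P must lie in (0, 1], got {self.Imax_P}")
        if self.IC50_P <= 0 or self.gamma_P <= 0:
            raise ValueError("IC50_P and gamma_P must be positive")

    @property
    def k_tr(self) -> float:
        """Transit rate constant (1/d): n_transit / MTT."""
        return self.n_transit / self.MTT


@dataclass(frozen=True)
class LDLParameters:
    LDL0: float = 100.0  # % baseline
    Gamma_LDL: float = 0.672
    k_deg_LDL: float = 4.66  # 1/d

    def __post_init__(self) -> None:
        if self.k_deg_LDL <= 0:
            raise ValueError("k_deg_LDL must be positive")
        if self.LDL0 <= 0:
            raise ValueError("LDL0 must be positive")


def hill_inhibition(C, Imax: float, IC50: float, gamma: float):
    """Fractional inhibition Imax * C^g / (IC50^g + C^g), clipped for C >= 0."""
    C = np.asarray(C, dtype=float)
    if np.any(C < -1e-12):
        raise ValueError("hill_inhibition: negative concentration")
    if IC50 <= 0:
        raise ValueError("IC50 must be positive")
    Cg = np.where(C > 0, C, 0.0) ** gamma
    out = Imax * Cg / (IC50**gamma + Cg)
    return float(out) if out.ndim == 0 else out


def ttr_rhs(TTR: float, C_RNP: float, p: TTRParameters) -> float:
    """dTTR/dt (%/d): production inhibition with baseline-stationary k_in."""
    k_in = p.k_out_TTR * p.TTR0
    return k_in * (1.0 - hill_inhibition(C_RNP, p.Imax, p.IC50, p.gamma)) - p.k_out_TTR * TTR


def ttr_steady_state_fraction(C_RNP, p: TTRParameters):
    """TTR_ss/TTR0 at a constant RNP concentration (independent of k_out_TTR)."""
    return 1.0 - hill_inhibition(C_RNP, p.Imax, p.IC50, p.gamma)


def pcsk9_rhs(transit_states: np.ndarray, PCSK9: float, C_RNP: float, p: PCSK9Parameters) -> tuple[np.ndarray, float]:
    """Derivatives of the transit chain and observable PCSK9 (%/d).

    Synthesis into the first transit compartment is inhibited by the RNP
    Hill term and amplified by the feedback term (PCSK9_0/PCSK9)^gamma_feedback.
    """
    transit_states = np.asarray(transit_states, dtype=float)
    if transit_states.shape != (p.n_transit,):
        raise ValueError(f"expected {p.n_transit} transit states, got {transit_states.shape}")
    if np.any(transit_states < -1e-9) or PCSK9 < -1e-9:
        raise ValueError("pcsk9_rhs: negative state")
    k_tr = p.k_tr
    inhibition = hill_inhibition(C_RNP, p.Imax_P, p.IC50_P, p.gamma_P)
    feedback = (p.PCSK9_0 / max(PCSK9, 1e-9)) ** p.gamma_feedback if p.gamma_feedback != 0 else 1.0
    production = k_tr * p.PCSK9_0 * (1.0 - inhibition) * feedback
    d_transit = np.empty(p.n_transit)
    d_transit[0] = production - k_tr * transit_states[0]
    for i in range(1, p.n_transit):
        d_transit[i] = k_tr * (transit_states[i - 1] - transit_states[i])
    d_obs = k_tr * (transit_states[-1] - PCSK9)
    return d_transit, d_obs


def ldl_rhs(LDL: float, PCSK9: float, p: LDLParameters, PCSK9_0: float = 100.0) -> float:
    """dLDL/dt (%/d): production scales with the PCSK9 precursor signal."""
    if PCSK9_0 <= 0:
        raise ValueError("PCSK9_0 must be positive")
    if LDL < -1e-9 or PCSK9 < -1e-9:
        raise ValueError("ldl_rhs: negative state")
    k_in = p.k_deg_LDL * p.LDL0
    return k_in * (max(PCSK9, 0.0) / PCSK9_0) ** p.Gamma_LDL - p.k_deg_LDL * LDL


def load_pd_parameters(species: str, model: str):
    """Load bundled PD parameters: model in {'ttr', 'pcsk9', 'ldl'}."""
    if species not in ("mouse", "nhp", "human"):
        raise ValueError(f"unknown species {species!r}")
    text = resources.files("crisprqsp.data").joinpath(f"params_{species}.yaml").read_text()
    raw = yaml.safe_load(text)
    pd_block = raw.get("pd", {})
    if model not in pd_block:
        raise ValueError(f"no bundled {model!r} PD parameters for species {species!r}")
    cls = {"ttr": TTRParameters, "pcsk9": PCSK9Parameters, "ldl": LDLParameters}[model]
    return cls(**pd_block[model])
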