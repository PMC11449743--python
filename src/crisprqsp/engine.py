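"""Simulation engine: PK/PD coupling, observation mapping, AUC.

The coupled system is integrated in hours; biomarker sub-models are defined
in days and are converted internally.  PK drives PD one-way through the
liver-cell RNP concentration; there is no PD-to-PK feedback.  Infusion
regimens are integrated in two segments split at the end of the infusion so
the right-hand side stays smooth within each segment.

Biomarker states are integrated as deviations from baseline (drop = 100 -
value), which is algebraically identical to the natural form but keeps the
solver's relative error control on the deflection itself, so responses far
below baseline-scale absolute tolerance remain resolved.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.integrate import solve_ivp

from crisprqsp.biodistribution import IDX, N_PK_STATES, PKModel
from crisprqsp.dosing import DoseRegimen
from crisprqsp.pd_response import TTRParameters, hill_inhibition

_H_PER_DAY = 24.0

#: Registered observable vocabulary with reporting units.
OUTPUT_IDS = {
    "plasma_LNP": "ug/mL",
    "plasma_sgRNA": "ug/mL",
    "plasma_mRNA": "ug/mL",
    "serum_TTR_pct": "pct_baseline",
    "serum_PCSK9_pct": "pct_baseline",
    "serum_LDL_pct": "pct_baseline",
}

OBSERVATION_COLUMNS = ("time", "time_unit", "species", "dose_group", "output_id", "value", "unit")


@dataclass
class Trajectory:
    """Simulation output: time grid (h), state matrix and observable series."""

    time: np.ndarray
    states: np.ndarray
    observables: dict[str, np.ndarray]
    model: PKModel
    regimen: DoseRegimen
    pd_selector: str | None
    pd_params: object | None = None
    _segments: list = field(default_factory=list, repr=False)
    _pd_state_names: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if np.any(np.diff(self.time) <= 0):
            raise ValueError("trajectory time grid must be strictly increasing")

    @property
    def t_span(self) -> tuple[float, float]:
        return float(self._segments[0].t[0]), float(self._segments[-1].t[-1])

    def eval_states(self, t_h) -> np.ndarray:
        """Dense-output evaluation of the full state at times ``t_h`` (hours)."""
        t_h = np.atleast_1d(np.asarray(t_h, dtype=float))
        lo, hi = self.t_span
        if np.any(t_h < lo - 1e-9) or np.any(t_h > hi + 1e-9):
            raise ValueError(f"extrapolation request outside [{lo}, {hi}]")
        out = np.empty((t_h.size, self.states.shape[1]))
        for i, t in enumerate(np.clip(t_h, lo, hi)):
            seg = self._segments[0]
            for s in self._segments:
                if t <= s.t[-1] + 1e-12:
                    seg = s
                    break
                seg = s
            out[i] = seg.sol(t)
        return out

    def eval_observable(self, output_id: str, t_h) -> np.ndarray:
        states = self.eval_states(t_h)
        return _extract_observable(states, output_id, self.model, self.pd_selector, self.pd_params)


def _pd_state_layout(pd_selector: str | None, pd_params) -> tuple[tuple[str, ...], np.ndarray]:
    """Names and initial values of the appended PD deviation states (all 0 at baseline)."""
    if pd_selector is None:
        return (), np.empty(0)
    if pd_selector == "ttr":
        return ("TTR_drop",), np.zeros(1)
    if pd_selector == "pcsk9_ldl":
        p9, _ = pd_params
        names = tuple(f"PCSK9_transit_drop_{i+1}" for i in range(p9.n_transit)) + (
            "PCSK9_drop",
            "LDL_drop",
        )
        return names, np.zeros(p9.n_transit + 2)
    raise ValueError(f"unknown pd selector {pd_selector!r}; expected None, 'ttr' or 'pcsk9_ldl'")


def _extract_observable(states: np.ndarray, output_id: str, model: PKModel, pd_selector: str | None, pd_params=None):
    V = model.phys.V_plasma
    if output_id == "plasma_LNP":
        return (states[:, IDX["pl_LNP_free"]] + states[:, IDX["pl_LNP_ops"]]) / V
    if output_id == "plasma_sgRNA":
        return states[:, IDX["pl_sgRNA"]] / V
    if output_id == "plasma_mRNA":
        return states[:, IDX["pl_mRNA"]] / V
    if output_id == "liver_RNP":
        return states[:, IDX["lc_RNP"]] / model.phys.V_liver_cell
    if output_id == "serum_TTR_pct":
        if pd_selector != "ttr":
            raise ValueError("serum_TTR_pct requires pd='ttr'")
        return pd_params.TTR0 - states[:, N_PK_STATES]
    if output_id in ("serum_PCSK9_pct", "serum_LDL_pct"):
        if pd_selector != "pcsk9_ldl":
            raise ValueError(f"{output_id} requires pd='pcsk9_ldl'")
        p9, pl = pd_params
        if output_id == "serum_LDL_pct":
            return pl.LDL0 - states[:, -1]
        return p9.PCSK9_0 - states[:, -2]
    raise ValueError(f"unknown output_id {output_id!r}; registered: {sorted(OUTPUT_IDS)}")


def _pd_deviation_rhs(pd_selector: str, pd_params, y_pd: np.ndarray, C_rnp: float) -> np.ndarray:
    """Deviation-form biomarker derivatives (per day), cancellation-safe.

    For TTR (drop u): du/dt = k_out * (TTR0 * I(C) - u).  For PCSK9 the
    production shortfall 1 - (1 - I) * (PCSK9_0/PCSK9)^g_fb is evaluated via
    expm1/log1p so sub-epsilon inhibition survives; LDL-C analogously with
    its precursor power law.
    """
    if pd_selector == "ttr":
        p: TTRParameters = pd_params
        u = y_pd[0]
        inhibition = hill_inhibition(C_rnp, p.Imax, p.IC50, p.gamma)
        return np.array([p.k_out_TTR * (p.TTR0 * inhibition - u)])

    p9, pl = pd_params
    n = p9.n_transit
    v = y_pd[:n]
    vP = min(y_pd[n], p9.PCSK9_0 * (1.0 - 1e-12))
    w = y_pd[n + 1]
    k_tr = p9.k_tr
    inhibition = hill_inhibition(C_rnp, p9.Imax_P, p9.IC50_P, p9.gamma_P)
    # production shortfall g = 1 - (1 - I) * (1 - vP/P0)^(-gamma_fb)
    log_term = np.log1p(-min(inhibition, 1.0 - 1e-15)) - p9.gamma_feedback * np.log1p(-vP / p9.PCSK9_0)
    g = -np.expm1(log_term)
    d = np.empty(n + 2)
    d[0] = k_tr * (p9.PCSK9_0 * g - v[0])
    for i in range(1, n):
        d[i] = k_tr * (v[i - 1] - v[i])
    d[n] = k_tr * (v[n - 1] - vP)
    # LDL production shortfall 1 - (PCSK9/PCSK9_0)^Gamma
    ldl_short = -np.expm1(pl.Gamma_LDL * np.log1p(-vP / p9.PCSK9_0))
    d[n + 1] = pl.k_deg_LDL * (pl.LDL0 * ldl_short - w)
    return d


def simulate(
    model: PKModel,
    regimen: DoseRegimen,
    t_grid,
    pd: str | None = None,
    pd_params=None,
    rtol: float = 1e-8,
    atol: float = 1e-10,
    method: str = "LSODA",
) -> Trajectory:
    """Simulate the coupled PK/PD system on ``t_grid`` (hours).

    ``pd`` selects the biomarker block: None (PK only), 'ttr', or
    'pcsk9_ldl' (PCSK9 and LDL-C always run coupled).  Deterministic: the
    same inputs yield bitwise-identical output.
    """
    t_grid = np.asarray(t_grid, dtype=float)
    if t_grid.ndim != 1 or t_grid.size < 2 or np.any(np.diff(t_grid) <= 0):
        raise ValueError("t_grid must be a strictly increasing 1-D array with >= 2 points")
    if t_grid[0] < 0:
        raise ValueError("t_grid must start at t >= 0")

    pd_names, pd_init = _pd_state_layout(pd, pd_params)
    n_total = N_PK_STATES + len(pd_names)
    y0 = np.concatenate([model.initial_state(regimen), pd_init])
    Vlc = model.phys.V_liver_cell

    def full_rhs(t: float, y: np.ndarray) -> np.ndarray:
        d = np.zeros(n_total)
        d[:N_PK_STATES] = model.rhs(t, y[:N_PK_STATES], regimen)
        if pd is not None:
            C = max(y[IDX["lc_RNP"]], 0.0) / Vlc
            d[N_PK_STATES:] = _pd_deviation_rhs(pd, pd_params, y[N_PK_STATES:], C) / _H_PER_DAY
        return d

    t_end = float(t_grid[-1])
    breaks = [float(t_grid[0])]
    if regimen.route == "infusion" and t_grid[0] < regimen.infusion_duration < t_end:
        breaks.append(float(regimen.infusion_duration))
    breaks.append(t_end)

    segments = []
    y_start = y0.copy()
    for a, b in zip(breaks[:-1], breaks[1:]):
        sol = solve_ivp(
            full_rhs,
            (a, b),
            y_start,
            method=method,
            rtol=rtol,
            atol=atol,
            dense_output=True,
        )
        if not sol.success:
            norm = float(np.linalg.norm(y_start))
            raise RuntimeError(
                f"integrator failure on [{a}, {b}]: {sol.message} (last t={sol.t[-1]}, state norm={norm:.3g})"
            )
        segments.append(sol)
        y_start = sol.y[:, -1].copy()

    # evaluate on the requested grid
    states = np.empty((t_grid.size, n_total))
    for i, t in enumerate(t_grid):
        for sol in segments:
            if t <= sol.t[-1] + 1e-12:
                states[i] = sol.sol(t)
                break
        else:
            states[i] = segments[-1].sol(t)

    observables = {
        "plasma_LNP": _extract_observable(states, "plasma_LNP", model, pd),
        "plasma_sgRNA": _extract_observable(states, "plasma_sgRNA", model, pd),
        "plasma_mRNA": _extract_observable(states, "plasma_mRNA", model, pd),
        "liver_RNP": _extract_observable(states, "liver_RNP", model, pd),
    }
    if pd == "ttr":
        observables["serum_TTR_pct"] = _extract_observable(states, "serum_TTR_pct", model, pd, pd_params)
        observables["serum_TTR_drop"] = states[:, N_PK_STATES].copy()
    elif pd == "pcsk9_ldl":
        observables["serum_PCSK9_pct"] = _extract_observable(states, "serum_PCSK9_pct", model, pd, pd_params)
        observables["serum_LDL_pct"] = _extract_observable(states, "serum_LDL_pct", model, pd, pd_params)

    return Trajectory(
        time=t_grid,
        states=states,
        observables=observables,
        model=model,
        regimen=regimen,
        pd_selector=pd,
        pd_params=pd_params,
        _segments=segments,
        _pd_state_names=pd_names,
    )


def auc(time, conc, t_start: float | None = None, t_end: float | None = None) -> float:
    """Linear-trapezoid AUC of ``conc`` over [t_start, t_end] (ug*h/mL).

    Window endpoints interior to the grid are linearly interpolated;
    requires at least two points in the window.
    """
    time = np.asarray(time, dtype=float)
    conc = np.asarray(conc, dtype=float)
    if time.ndim != 1 or time.shape != conc.shape:
        raise ValueError("time and conc must be matching 1-D arrays")
    if time.size < 2:
        raise ValueError("AUC requires at least 2 points")
    t0 = time[0] if t_start is None else float(t_start)
    t1 = time[-1] if t_end is None else float(t_end)
    if t1 <= t0:
        raise ValueError(f"empty AUC window [{t0}, {t1}]")
    if t0 < time[0] - 1e-12 or t1 > time[-1] + 1e-12:
        raise ValueError("AUC window outside the sampled range")
    inside = (time > t0) & (time < t1)
    tt = np.concatenate([[t0], time[inside], [t1]])
    cc = np.concatenate([[np.interp(t0, time, conc)], conc[inside], [np.interp(t1, time, conc)]])
    return float(np.trapezoid(cc, tt))


def observe(
    trajectory: Trajectory,
    schedule: dict[str, tuple],
    species: str | None = None,
    dose_group=None,
) -> pd.DataFrame:
    """Interpolate observables at scheduled times; returns observation records.

    ``schedule`` maps output_id -> (times, time_unit) with time_unit 'h' or
    'd'; biomarkers are reported as percent of baseline.  Requests outside
    the simulated span raise.
    """
    rows = []
    species = species if species is not None else trajectory.model.phys.species_id
    dose_group = dose_group if dose_group is not None else trajectory.regimen.total_rna_mgkg
    for output_id, (times, unit) in schedule.items():
        if output_id not in OUTPUT_IDS:
            raise ValueError(f"unknown output_id {output_id!r}")
        if unit not in ("h", "d"):
            raise ValueError(f"time_unit must be 'h' or 'd', got {unit!r}")
        times = np.asarray(times, dtype=float)
        t_h = times * _H_PER_DAY if unit == "d" else times
        values = trajectory.eval_observable(output_id, t_h)
        for t, v in zip(times, np.atleast_1d(values)):
            rows.append(
                {
                    "time": float(t),
                    "time_unit": unit,
                    "species": species,
                    "dose_group": dose_group,
                    "output_id": output_id,
                    "value": float(v),
                    "unit": OUTPUT_IDS[output_id],
                }
            )
    return pd.DataFrame(rows, columns=list(OBSERVATION_COLUMNS))


def validate_observations(df: pd.DataFrame) -> pd.DataFrame:
    """Schema-check an observation table (column set, vocabulary, signs)."""
    missing = set(OBSERVATION_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"observation table missing columns: {sorted(missing)}")
    extra = set(df.columns) - set(OBSERVATION_COLUMNS)
    if extra:
        raise ValueError(f"observation table has unknown columns: {sorted(extra)}")
    bad = set(df["output_id"]) - set(OUTPUT_IDS)
    if bad:
        raise ValueError(f"unregistered output ids: {sorted(bad)}")
    if (df["value"] < 0).any():
        raise ValueError("observation values must be >= 0")
    if not set(df["time_unit"]).issubset({"h", "d"}):
        raise ValueError("time_unit must be 'h' or 'd'")
    return df


def write_observations(df: pd.DataFrame, path) -> None:
    validate_observations(df).to_csv(path, index=False)


def read_observations(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    return validate_observations(df)
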