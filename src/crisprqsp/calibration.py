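"""Fixed-effect maximum-likelihood calibration with a proportional error model.

The objective is -2 log L under Var_i = sigma_slope * Y_i^2 per output.
sigma_slope can be profiled analytically (it equals the mean squared
relative residual at fixed structural parameters), which removes it from
the search space.  Optimization runs in log-parameter space with bounds and
optional seeded Latin-hypercube multi-start; relative standard errors come
from the inverse numerical Hessian of -2LL at the optimum.

The canonical stepwise masks mirror the staged workflow: a reduced
mechanistic fit (step1), the mouse QSP fit (step2, exocytosis and RNA
degradation with sgRNA tied to mRNA), NHP PK and TTR PD fits (step3) and
human PK and TTR PD fits (step4).
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import minimize
from scipy.stats import qmc

from crisprqsp._rng import rng_for
from crisprqsp.biodistribution import ModelOptions, PKParameters, build_model, load_parameters
from crisprqsp.dosing import build_regimen
from crisprqsp.engine import simulate
from crisprqsp.pd_response import LDLParameters, PCSK9Parameters, TTRParameters
from crisprqsp.physiology import SpeciesPhysiology, load_physiology
from crisprqsp.synthetic_data import StudyDesign, get_design, _default_pd_params

_H_PER_DAY = 24.0
# profiled-sigma floor: once residuals are below ~1e-5 relative (the ODE
# solver noise scale) the likelihood plateaus instead of chasing log of
# integrator jitter; irrelevant for data with real noise
_SIGMA_FLOOR = 1e-10

STEP_IDS = (
    "step1_reduced",
    "step2_mouse",
    "step3_nhp_pk",
    "step3_nhp_pd",
    "step4_human_pk",
    "step4_human_pd",
)

_PK_FIELDS = {f.name for f in dataclasses.fields(PKParameters)}
_PHYS_FIELDS = {f.name for f in dataclasses.fields(SpeciesPhysiology)} - {"species_id"}
_TTR_FIELDS = {f.name for f in dataclasses.fields(TTRParameters)}
_PCSK9_FIELDS = {f.name for f in dataclasses.fields(PCSK9Parameters)}
_LDL_FIELDS = {f.name for f in dataclasses.fields(LDLParameters)}


@dataclass
class FitSpec:
    """Estimation problem: design, estimated mask with bounds, fixed values."""

    step_id: str
    design: StudyDesign
    estimated: dict[str, float]  # name -> initial value
    bounds: dict[str, tuple[float, float]] = field(default_factory=dict)
    fixed_overrides: dict[str, float] = field(default_factory=dict)
    tied: dict[str, str] = field(default_factory=dict)  # target <- source after each update
    sigma_slope: dict[str, float] | None = None  # per output; None -> profiled
    n_starts: int = 1
    max_nfev: int | None = None  # objective-evaluation cap per start
    seed: int = 0
    rtol: float = 1e-6
    atol: float = 1e-9
    base_params: PKParameters | None = None
    base_phys: SpeciesPhysiology | None = None
    base_pd: object | None = None

    def __post_init__(self) -> None:
        if self.step_id not in STEP_IDS and not self.step_id.startswith("custom"):
            raise ValueError(f"unknown step_id {self.step_id!r}; expected one of {STEP_IDS} or 'custom*'")
        if not self.estimated:
            raise ValueError("estimated mask is empty")
        overlap = set(self.estimated) & set(self.fixed_overrides)
        if overlap:
            raise ValueError(f"parameters both estimated and fixed: {sorted(overlap)}")
        if self.base_params is None:
            self.base_params = load_parameters(self.design.species_id)
        if self.base_phys is None:
            self.base_phys = load_physiology(self.design.species_id)
        if self.base_pd is None:
            self.base_pd = _default_pd_params(self.design)
        for name, (lo, hi) in self.bounds.items():
            if not (0 < lo < hi):
                raise ValueError(f"bounds for {name} must satisfy 0 < lo < hi, got ({lo}, {hi})")
        for name in self.estimated:
            self.bounds.setdefault(name, _default_bounds(name, self.estimated[name]))

    @property
    def species_id(self) -> str:
        return self.design.species_id


@dataclass
class FitResult:
    estimates: dict[str, float]
    rse: dict[str, float | None]  # % RSE; only for estimated parameters
    neg2ll: float
    converged: bool
    sigma_slope: dict[str, float]
    n_obs: int
    step_id: str
    seed: int
    message: str = ""
    history: list[float] = field(default_factory=list)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "parameter": list(self.estimates),
                "estimate": list(self.estimates.values()),
                "rse_pct": [self.rse.get(k) for k in self.estimates],
            }
        )


def _default_bounds(name: str, value: float) -> tuple[float, float]:
    if name in ("Imax", "Imax_P"):
        return (1e-3, 1.0)
    if value <= 0:
        raise ValueError(f"cannot derive default bounds for non-positive init of {name}")
    return (value / 100.0, value * 100.0)


def parameter_value(name: str, params: PKParameters, spec: FitSpec) -> float:
    """Resolve a parameter name (PK, physiology or PD) to its current value."""
    if name in _PK_FIELDS:
        return getattr(params, name)
    if name in _PHYS_FIELDS:
        return getattr(spec.base_phys, name)
    pd_obj = spec.base_pd
    if isinstance(pd_obj, TTRParameters) and name in _TTR_FIELDS:
        return getattr(pd_obj, name)
    if isinstance(pd_obj, tuple):
        p9, pl = pd_obj
        if name in _PCSK9_FIELDS:
            return getattr(p9, name)
        if name in _LDL_FIELDS:
            return getattr(pl, name)
    raise KeyError(name)


def _apply_updates(spec: FitSpec, updates: dict[str, float]):
    """Apply fixed overrides + candidate updates to params/physiology/PD."""
    all_updates = {**spec.fixed_overrides, **updates}
    for target, source in spec.tied.items():
        if source in all_updates:
            all_updates[target] = all_updates[source]
    pk_up = {k: v for k, v in all_updates.items() if k in _PK_FIELDS}
    phys_up = {k: v for k, v in all_updates.items() if k in _PHYS_FIELDS}
    rest = {k: v for k, v in all_updates.items() if k not in _PK_FIELDS and k not in _PHYS_FIELDS}

    params = spec.base_params.replace(**pk_up) if pk_up else spec.base_params
    phys = spec.base_phys.replace(**phys_up) if phys_up else spec.base_phys

    pd_obj = spec.base_pd
    if rest:
        if isinstance(pd_obj, TTRParameters):
            ttr_up = {k: v for k, v in rest.items() if k in _TTR_FIELDS}
            unknown = set(rest) - set(ttr_up)
            if unknown:
                raise ValueError(f"unknown parameter names: {sorted(unknown)}")
            pd_obj = dataclasses.replace(pd_obj, **ttr_up)
        elif isinstance(pd_obj, tuple):
            p9, pl = pd_obj
            p9_up = {k: v for k, v in rest.items() if k in _PCSK9_FIELDS}
            pl_up = {k: v for k, v in rest.items() if k in _LDL_FIELDS}
            unknown = set(rest) - set(p9_up) - set(pl_up)
            if unknown:
                raise ValueError(f"unknown parameter names: {sorted(unknown)}")
            pd_obj = (dataclasses.replace(p9, **p9_up), dataclasses.replace(pl, **pl_up))
        else:
            raise ValueError(f"unknown parameter names: {sorted(rest)}")
    return params, phys, pd_obj


def predictions_for(spec: FitSpec, data: pd.DataFrame, updates: dict[str, float]) -> np.ndarray:
    """Model predictions aligned row-by-row with the observation table."""
    params, phys, pd_obj = _apply_updates(spec, updates)
    model = build_model(phys, params, options=ModelOptions())
    pd_sel = spec.design.pd_selector
    horizon = max(spec.design.horizon_h, 1.0)
    t_grid = np.linspace(0.0, horizon * 1.0001, 61)
    arm_by_dose = {arm.dose_mgkg: arm for arm in spec.design.arms}
    pred = np.empty(len(data))
    for dose, group in data.groupby("dose_group", sort=False):
        arm = arm_by_dose.get(float(dose))
        if arm is None:
            raise ValueError(f"dataset dose group {dose!r} not present in design {spec.design.name}")
        regimen = build_regimen(
            arm.dose_mgkg,
            phys,
            route=arm.route,
            infusion_duration=arm.infusion_duration,
            lnp_dose_mgkg=arm.lnp_dose_mgkg,
        )
        traj = simulate(
            model, regimen, t_grid, pd=pd_sel, pd_params=pd_obj, rtol=spec.rtol, atol=spec.atol
        )
        for output_id, sub in group.groupby("output_id", sort=False):
            t = sub["time"].to_numpy(dtype=float)
            unit = sub["time_unit"].iloc[0]
            t_h = t * _H_PER_DAY if unit == "d" else t
            pred[sub.index.to_numpy()] = traj.eval_observable(output_id, t_h)
    return pred


def neg2ll(predictions, observations, sigma_slope: float) -> float:
    """-2 log-likelihood under Var_i = sigma_slope * Y_i^2.

    Raises on a zero/negative prediction at an observation (the proportional
    variance is undefined there) rather than silently flooring it.
    """
    Y = np.asarray(predictions, dtype=float)
    y = np.asarray(observations, dtype=float)
    if Y.shape != y.shape:
        raise ValueError("predictions and observations must align")
    if np.any(Y <= 0):
        bad = int(np.argmax(Y <= 0))
        raise ValueError(f"prediction {bad} is <= 0; proportional variance undefined")
    if sigma_slope <= 0:
        raise ValueError("sigma_slope must be > 0")
    var = sigma_slope * Y**2
    return float(np.sum(np.log(2.0 * np.pi * var) + (y - Y) ** 2 / var))


def profile_sigma(predictions, observations) -> float:
    """Analytic ML profile of sigma_slope: mean squared relative residual."""
    Y = np.asarray(predictions, dtype=float)
    y = np.asarray(observations, dtype=float)
    return float(np.mean(((y - Y) / Y) ** 2))


def _total_neg2ll(spec: FitSpec, data: pd.DataFrame, updates: dict[str, float], floor: float | None = None):
    pred = predictions_for(spec, data, updates)
    if floor is not None:
        # inside the optimizer only: a candidate whose predictions underflow
        # to <= 0 gets a large but smoothly graded objective, not a cliff
        pred = np.maximum(pred, floor)
    total = 0.0
    sigmas = {}
    for output_id, sub in data.groupby("output_id", sort=False):
        idx = sub.index.to_numpy()
        if spec.sigma_slope is not None:
            sigma = spec.sigma_slope[output_id]
        else:
            sigma = max(profile_sigma(pred[idx], sub["value"].to_numpy()), _SIGMA_FLOOR)
        sigmas[output_id] = sigma
        total += neg2ll(pred[idx], sub["value"].to_numpy(), sigma)
    return total, sigmas, pred


def fit(spec: FitSpec, data: pd.DataFrame) -> FitResult:
    """Bounded local MLE (log-space L-BFGS-B) with optional seeded multi-start."""
    data = data.reset_index(drop=True)
    outputs_in_data = set(data["output_id"])
    outputs_in_design = set(spec.design.schedule)
    uncovered = outputs_in_data - outputs_in_design
    if uncovered:
        raise ValueError(f"dataset outputs not covered by the design: {sorted(uncovered)}")

    names = list(spec.estimated)
    x0 = np.log([spec.estimated[n] for n in names])
    log_bounds = [(np.log(spec.bounds[n][0]), np.log(spec.bounds[n][1])) for n in names]

    history: list[float] = []
    incumbent = [np.inf]

    def objective(x: np.ndarray) -> float:
        updates = {n: float(np.exp(v)) for n, v in zip(names, x)}
        try:
            total, _, _ = _total_neg2ll(spec, data, updates, floor=1e-12)
        except (RuntimeError, FloatingPointError, ValueError):
            return 1e12
        incumbent[0] = min(incumbent[0], total)
        return total

    def callback(xk: np.ndarray) -> None:
        # per-iteration incumbent: the accepted value of a direct search
        if np.isfinite(incumbent[0]):
            history.append(incumbent[0])

    starts = [x0]
    if spec.n_starts > 1:
        sampler = qmc.LatinHypercube(d=len(names), rng=rng_for(spec.seed, "fit-multistart"))
        unit = sampler.random(spec.n_starts - 1)
        lo = np.array([b[0] for b in log_bounds])
        hi = np.array([b[1] for b in log_bounds])
        starts.extend(lo + unit * (hi - lo))

    best = None
    for x_start in starts:
        options = {
            "maxiter": 200,
            "xtol": 3e-4,
            "ftol": 1e-9,
            # sub-unit initial directions keep the first line searches near
            # the start instead of leaping across the noise-floor-jagged
            # surface (fresh array: Powell mutates it)
            "direc": 0.3 * np.eye(len(names)),
        }
        if spec.max_nfev is not None:
            options["maxfev"] = spec.max_nfev
        # derivative-free bounded search: the profiled objective has an
        # ODE-solver noise floor that defeats finite-difference gradients
        res = minimize(
            objective,
            x_start,
            method="Powell",
            bounds=log_bounds,
            callback=callback,
            options=options,
        )
        if best is None or res.fun < best.fun:
            best = res

    estimates = {n: float(np.exp(v)) for n, v in zip(names, best.x)}
    total, sigmas, _ = _total_neg2ll(spec, data, estimates)

    rse = _rse_from_hessian(spec, data, names, best.x, sigmas)
    return FitResult(
        estimates=estimates,
        rse=rse,
        neg2ll=total,
        converged=bool(best.success),
        sigma_slope=sigmas,
        n_obs=len(data),
        step_id=spec.step_id,
        seed=spec.seed,
        message=str(best.message),
        history=history,
    )


def _rse_from_hessian(
    spec: FitSpec,
    data: pd.DataFrame,
    names: list[str],
    x_opt: np.ndarray,
    sigmas: dict[str, float],
    h: float = 1e-2,
) -> dict[str, float | None]:
    """RSE%% from the central-difference Hessian of -2LL in log space.

    With log parameters, SE(log theta) is directly the relative SE, so
    RSE%% = 100 * sqrt(diag(2 H^-1)).  sigma_slope is held at its profiled
    optimum.  A singular or non-positive Hessian yields None.
    """
    frozen = dataclasses.replace(spec, sigma_slope=dict(sigmas))

    def f(x: np.ndarray) -> float:
        updates = {n: float(np.exp(v)) for n, v in zip(names, x)}
        try:
            total, _, _ = _total_neg2ll(frozen, data, updates, floor=1e-12)
        except (RuntimeError, FloatingPointError, ValueError):
            return np.nan
        return total

    d = len(names)
    H = np.empty((d, d))
    f0 = f(x_opt)
    for i in range(d):
        ei = np.zeros(d)
        ei[i] = h
        H[i, i] = (f(x_opt + ei) - 2 * f0 + f(x_opt - ei)) / h**2
        for j in range(i + 1, d):
            ej = np.zeros(d)
            ej[j] = h
            H[i, j] = H[j, i] = (
                f(x_opt + ei + ej) - f(x_opt + ei - ej) - f(x_opt - ei + ej) + f(x_opt - ei - ej)
            ) / (4 * h**2)
    none = {n: None for n in names}
    if not np.all(np.isfinite(H)):
        return none
    try:
        cov = 2.0 * np.linalg.inv(H)
    except np.linalg.LinAlgError:
        return none
    diag = np.diag(cov)
    return {
        n: (float(100.0 * np.sqrt(v)) if v > 0 else None) for n, v in zip(names, diag)
    }


def predictive_check(observed, predicted) -> tuple[pd.DataFrame, dict]:
    """Observed-vs-fitted table with identity-line concordance summary.

    Reports the through-origin regression slope of observed on predicted and
    the identity-line R^2 (1 - SS_res/SS_tot); flags degenerate fits.
    """
    y = np.asarray(observed, dtype=float)
    Y = np.asarray(predicted, dtype=float)
    if y.shape != Y.shape:
        raise ValueError("observed and predicted must align")
    table = pd.DataFrame({"observed": y, "predicted": Y})
    denom = float(np.sum(Y**2))
    degenerate = denom == 0.0
    slope = float(np.sum(y * Y) / denom) if not degenerate else np.nan
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 - float(np.sum((y - Y) ** 2)) / ss_tot if ss_tot > 0 else np.nan
    summary = {"slope": slope, "r2": r2, "n": int(y.size), "degenerate": degenerate}
    return table, summary


def plot_predictive_check(observed, predicted, path) -> None:
    """Observed-vs-fitted scatter with the identity line (diagnostic figure)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    y = np.asarray(observed, dtype=float)
    Y = np.asarray(predicted, dtype=float)
    fig, ax = plt.subplots(figsize=(4.5, 4.5))
    ax.scatter(Y, y, s=18, alpha=0.7)
    lim = [0, max(float(y.max()), float(Y.max())) * 1.05 or 1.0]
    ax.plot(lim, lim, "k--", lw=1)
    ax.set_xlabel("fitted")
    ax.set_ylabel("observed")
    ax.set_xlim(lim)
    ax.set_ylim(lim)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


# ----------------------------------------------------------------------
# Canonical stepwise masks
# ----------------------------------------------------------------------

def default_fitspec(step_id: str, **kwargs) -> FitSpec:
    """The bundled fixed/estimated mask for each calibration step."""
    if step_id == "step1_reduced":
        # reduced mechanistic fit on mouse data; plasma volume at the
        # reported reduced-model estimate
        return FitSpec(
            step_id=step_id,
            design=get_design("mouse_pk"),
            estimated={
                "k_ass": 1550.34,
                "k_dis": 0.47,
                "k_deg_DR": 2.04,
                "k_trans": 0.36,
                "k_deg_sgRNA": 0.378,
                "k_off_RNP": 0.00188,
            },
            fixed_overrides={"V_plasma": 0.718},
            **kwargs,
        )
    if step_id == "step2_mouse":
        return FitSpec(
            step_id=step_id,
            design=get_design("mouse_pk"),
            estimated={"k_out_exo": 6.84, "k_deg_mRNA": 0.378},
            tied={"k_deg_sgRNA": "k_deg_mRNA"},
            **kwargs,
        )
    if step_id == "step3_nhp_pk":
        return FitSpec(
            step_id=step_id,
            design=get_design("nhp_pk"),
            estimated={
                "k_in_endo": 0.039,
                "k_out_exo": 2690.0,
                "k_deg_DR": 2.04,
                "LDL_tot": 539.0,
                "k_dis": 8.64,
                "k_ass": 5.06,
                "k_release": 0.634,
            },
            **kwargs,
        )
    if step_id == "step3_nhp_pd":
        return FitSpec(
            step_id=step_id,
            design=get_design("nhp_ttr"),
            estimated={"k_out_TTR": 0.493, "Imax": 0.961, "IC50": 4.77, "gamma": 0.31},
            **kwargs,
        )
    if step_id == "step4_human_pk":
        return FitSpec(
            step_id=step_id,
            design=get_design("human_pk"),
            estimated={
                "k_in_endo": 0.007,
                "k_out_exo": 775.0,
                "k_deg_DR": 5.15,
                "LDL_tot": 84.5,
                "k_dis": 0.186,
                "k_ass": 56.8,
                "k_deg_LNP": 0.101,
                "k_el": 0.009,
            },
            **kwargs,
        )
    if step_id == "step4_human_pd":
        return FitSpec(
            step_id=step_id,
            design=get_design("human_ttr"),
            estimated={"k_out_TTR": 0.247, "IC50": 0.3, "Imax": 0.959},
            **kwargs,
        )
    raise ValueError(f"unknown step_id {step_id!r}; expected one of {STEP_IDS}")
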