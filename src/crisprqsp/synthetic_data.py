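"""Synthetic observation studies with the analysis' statistical structure.

Datasets are model predictions at the bundled sampling designs perturbed by
mean-zero multiplicative noise, y_i = Y_i * (1 + sqrt(sigma_slope) * eps_i)
with standard-normal eps (variance Var_i = sigma_slope * Y_i^2), truncated
at zero.  Truth parameters default to the bundled per-species values, so
"recover the bundled table" is the canonical recovery exercise.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from crisprqsp._rng import rng_for
from crisprqsp.biodistribution import ModelOptions, PKParameters, build_model, load_parameters
from crisprqsp.dosing import build_regimen
from crisprqsp.engine import OUTPUT_IDS, observe, simulate, validate_observations
from crisprqsp.pd_response import load_pd_parameters
from crisprqsp.physiology import SpeciesPhysiology, load_physiology

_H_PER_DAY = 24.0


@dataclass(frozen=True)
class Arm:
    """One dose arm: total RNA in mg/kg, route, optional printed LNP dose override."""

    dose_mgkg: float
    route: str = "infusion"
    infusion_duration: float = 2.0
    lnp_dose_mgkg: float | None = None


@dataclass(frozen=True)
class StudyDesign:
    """A sampling design: arms, per-output schedules and the noise level."""

    name: str
    species_id: str
    arms: tuple[Arm, ...]
    schedule: dict[str, tuple[tuple[float, ...], str]]  # output_id -> (times, 'h'|'d')
    sigma_slope: float = 0.04

    def __post_init__(self) -> None:
        if not self.arms:
            raise ValueError("design needs at least one arm")
        if not self.schedule:
            raise ValueError("design needs a non-empty schedule")
        for output_id, (times, unit) in self.schedule.items():
            if output_id not in OUTPUT_IDS:
                raise ValueError(f"unregistered output_id {output_id!r}")
            if len(times) == 0:
                raise ValueError(f"empty schedule for {output_id}")
            if unit not in ("h", "d"):
                raise ValueError(f"bad time unit {unit!r}")
        if self.sigma_slope < 0:
            raise ValueError("sigma_slope must be >= 0")

    @property
    def pd_selector(self) -> str | None:
        outputs = set(self.schedule)
        if "serum_TTR_pct" in outputs:
            return "ttr"
        if outputs & {"serum_PCSK9_pct", "serum_LDL_pct"}:
            return "pcsk9_ldl"
        return None

    @property
    def horizon_h(self) -> float:
        t_max = 0.0
        for times, unit in self.schedule.values():
            scale = _H_PER_DAY if unit == "d" else 1.0
            t_max = max(t_max, scale * max(times))
        return t_max


_MOUSE_PK_TIMES = (0.0, 0.2, 0.4, 0.6, 0.8, 1.0, 10.0, 25.0)


def bundled_designs() -> list[StudyDesign]:
    """The six sampling designs of the source datasets (doses, routes, schedules)."""
    return [
        StudyDesign(
            name="mouse_pk",
            species_id="mouse",
            arms=(Arm(2.0, route="bolus", lnp_dose_mgkg=36.7),),
            schedule={
                "plasma_sgRNA": (_MOUSE_PK_TIMES, "h"),
                "plasma_mRNA": (_MOUSE_PK_TIMES, "h"),
            },
        ),
        StudyDesign(
            name="nhp_pk",
            species_id="nhp",
            arms=(
                Arm(1.0),
                Arm(2.0, lnp_dose_mgkg=36.7),
                Arm(3.0),
            ),
            schedule={"plasma_LNP": ((1.5, 4.0, 8.0), "h")},
        ),
        StudyDesign(
            name="nhp_ttr",
            species_id="nhp",
            arms=(
                Arm(1.5, lnp_dose_mgkg=27.75),
                Arm(3.0, lnp_dose_mgkg=68.82),
                Arm(6.0, lnp_dose_mgkg=137.64),
            ),
            # sampling days are not printed for the NHP TTR study; early
            # points are included so the turnover rate is informed
            schedule={"serum_TTR_pct": ((1.0, 4.0, 7.0, 14.0, 28.0), "d")},
        ),
        StudyDesign(
            name="nhp_pcsk9_ldl",
            species_id="nhp",
            arms=(
                Arm(0.75, lnp_dose_mgkg=17.2),
                Arm(1.5, lnp_dose_mgkg=27.75),
            ),
            schedule={
                "serum_PCSK9_pct": ((7.0, 14.0, 21.0, 28.0), "d"),
                "serum_LDL_pct": ((7.0, 14.0, 21.0, 28.0), "d"),
            },
        ),
        StudyDesign(
            name="human_pk",
            species_id="human",
            arms=(
                Arm(0.1),
                Arm(0.3),
                Arm(0.7, lnp_dose_mgkg=12.9),
                Arm(1.0),
            ),
            schedule={"plasma_LNP": ((0.5, 1.0, 2.0, 4.0, 8.0, 24.0, 50.0), "h")},
        ),
        StudyDesign(
            name="human_ttr",
            species_id="human",
            arms=(Arm(0.1), Arm(0.3), Arm(0.7, lnp_dose_mgkg=12.9), Arm(1.0)),
            schedule={"serum_TTR_pct": ((7.0, 14.0, 28.0), "d")},
        ),
    ]


def get_design(name: str) -> StudyDesign:
    for d in bundled_designs():
        if d.name == name:
            return d
    raise ValueError(f"unknown design {name!r}; available: {[d.name for d in bundled_designs()]}")


def _default_pd_params(design: StudyDesign):
    if design.pd_selector == "ttr":
        return load_pd_parameters(design.species_id, "ttr")
    if design.pd_selector == "pcsk9_ldl":
        return (
            load_pd_parameters(design.species_id, "pcsk9"),
            load_pd_parameters(design.species_id, "ldl"),
        )
    return None


def predict_dataset(
    design: StudyDesign,
    params: PKParameters | None = None,
    phys: SpeciesPhysiology | None = None,
    pd_params=None,
    options: ModelOptions | None = None,
    rtol: float = 1e-8,
    atol: float = 1e-10,
) -> pd.DataFrame:
    """Noiseless model predictions at the design's schedules (long format)."""
    params = params if params is not None else load_parameters(design.species_id)
    phys = phys if phys is not None else load_physiology(design.species_id)
    pd_sel = design.pd_selector
    if pd_sel is not None and pd_params is None:
        pd_params = _default_pd_params(design)
    model = build_model(phys, params, options=options)
    frames = []
    horizon = max(design.horizon_h, 1.0)
    t_grid = np.linspace(0.0, horizon * 1.0001, 121)
    for arm in design.arms:
        regimen = build_regimen(
            arm.dose_mgkg,
            phys,
            route=arm.route,
            infusion_duration=arm.infusion_duration,
            lnp_dose_mgkg=arm.lnp_dose_mgkg,
        )
        traj = simulate(model, regimen, t_grid, pd=pd_sel, pd_params=pd_params, rtol=rtol, atol=atol)
        frames.append(
            observe(traj, design.schedule, species=design.species_id, dose_group=arm.dose_mgkg)
        )
    return pd.concat(frames, ignore_index=True)


def generate_dataset(
    design: StudyDesign,
    params: PKParameters | None = None,
    phys: SpeciesPhysiology | None = None,
    seed: int = 0,
    sigma_slope: float | None = None,
    predictions: pd.DataFrame | None = None,
    **predict_kwargs,
) -> pd.DataFrame:
    """Generate one noisy synthetic study; reproducible under ``seed``.

    Pass a precomputed ``predictions`` table (from :func:`predict_dataset`)
    to reuse the deterministic simulation across replicate draws.
    """
    sigma = design.sigma_slope if sigma_slope is None else sigma_slope
    if sigma < 0:
        raise ValueError("sigma_slope must be >= 0")
    if predictions is not None:
        df = predictions
    else:
        df = predict_dataset(design, params=params, phys=phys, **predict_kwargs)
    rng = rng_for(seed, f"synthetic:{design.name}")
    eps = rng.standard_normal(len(df))
    values = df["value"].to_numpy() * (1.0 + np.sqrt(sigma) * eps)
    df = df.copy()
    df["value"] = np.maximum(values, 0.0)
    return validate_observations(df)


def write_study(
    design: StudyDesign,
    outdir,
    params: PKParameters | None = None,
    phys: SpeciesPhysiology | None = None,
    seed: int = 0,
    **kwargs,
) -> dict[str, Path]:
    """Emit the observation CSV plus truth-parameter and design metadata files."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    params = params if params is not None else load_parameters(design.species_id)
    df = generate_dataset(design, params=params, phys=phys, seed=seed, **kwargs)
    obs_path = outdir / f"{design.name}_observations.csv"
    df.to_csv(obs_path, index=False)
    truth_path = outdir / f"{design.name}_truth_params.yaml"
    truth_path.write_text(yaml.safe_dump(dataclasses.asdict(params), sort_keys=True))
    meta_path = outdir / f"{design.name}_design.json"
    meta = dataclasses.asdict(design)
    meta["seed"] = int(seed)
    meta_path.write_text(json.dumps(meta, indent=2, default=list))
    return {"observations": obs_path, "truth": truth_path, "design": meta_path}


def recovery_report(
    design: StudyDesign,
    truth_params: PKParameters,
    fit_spec,
    phys: SpeciesPhysiology | None = None,
    seed: int = 0,
    sigma_slope: float | None = None,
) -> pd.DataFrame:
    """Generate -> fit -> compare: per-parameter relative error and 2-SE coverage."""
    from crisprqsp.calibration import fit as run_fit  # local import avoids a cycle

    unknown = set(fit_spec.estimated) - set(_truth_lookup(truth_params, fit_spec))
    if unknown:
        raise ValueError(f"fit spec estimates parameters without a truth value: {sorted(unknown)}")
    data = generate_dataset(design, params=truth_params, phys=phys, seed=seed, sigma_slope=sigma_slope)
    result = run_fit(fit_spec, data)
    rows = []
    truths = _truth_lookup(truth_params, fit_spec)
    for name, est in result.estimates.items():
        truth = truths[name]
        rse = result.rse.get(name)
        se = abs(est) * rse / 100.0 if rse is not None else None
        covered = None if se is None else bool(abs(est - truth) <= 2.0 * se)
        rows.append(
            {
                "parameter": name,
                "truth": truth,
                "estimate": est,
                "rel_error": (est - truth) / truth if truth != 0 else np.nan,
                "rse_pct": rse,
                "covered_2se": covered,
            }
        )
    return pd.DataFrame(rows)


def _truth_lookup(truth_params: PKParameters, fit_spec) -> dict[str, float]:
    from crisprqsp.calibration import parameter_value

    out = {}
    for name in fit_spec.estimated:
        try:
            out[name] = parameter_value(name, truth_params, fit_spec)
        except KeyError:
            continue
    return out
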