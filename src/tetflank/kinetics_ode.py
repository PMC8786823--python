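"""Four-species TET oxidation kinetics and progress-curve fitting.

The model is the linear first-order chain

    d c_5mC /dt = -k1 c_5mC - k12 c_5mC
    d c_5hmC/dt =  k1 c_5mC - k2 c_5hmC
    d c_5fC /dt =  k12 c_5mC + k2 c_5hmC - k3 c_5fC
    d c_5caC/dt =  k3 c_5fC

where k12 is a processive branch converting 5mC directly to 5fC without
release of the 5hmC intermediate; the three-rate variant fixes k12 = 0.
Rates are per minute.  Two integrators are provided: forward Euler at
dt = 0.01 min (the procedure used to analyze the original LC-MS data) and
the exact matrix-exponential solution of the linear system, which serves
as the accuracy oracle and as the fast model evaluation inside fits.

Measured species signals are mapped to model concentrations through
per-species multiplicative intensity factors and additive baselines
(nuisance parameters); the 5mC intensity is pinned at 1 for
identifiability.  Fitting minimizes the RMSD between model and data with
seeded multi-start to guard against local minima.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.linalg import expm
from scipy.optimize import least_squares

SPECIES = ("5mC", "5hmC", "5fC", "5caC")

INTENSITY_BOUNDS = (0.1, 10.0)
BASELINE_BOUNDS = (-0.05, 0.05)
RATE_MAX = 50.0  # per minute; generous for sub-stoichiometric enzyme


@dataclass
class ODEParameters:
    k1: float
    k2: float
    k12: float
    k3: float
    intensities: dict[str, float] = field(
        default_factory=lambda: {s: 1.0 for s in SPECIES}
    )
    baselines: dict[str, float] = field(default_factory=lambda: {s: 0.0 for s in SPECIES})

    def __post_init__(self) -> None:
        for name in ("k1", "k2", "k12", "k3"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if not np.isclose(self.intensities.get("5mC", 1.0), 1.0):
            raise ValueError("the 5mC intensity is the gauge and must equal 1")

    @property
    def rates(self) -> tuple[float, float, float, float]:
        return (self.k1, self.k2, self.k12, self.k3)


@dataclass
class ProgressCurves:
    """Measured species fractions over time for one reaction."""

    times: np.ndarray  # minutes
    fractions: pd.DataFrame  # columns: species
    substrate: str = "5mC"  # start species of the reaction
    enzyme: str = ""
    enzyme_concentration: float | None = None  # e.g. uM

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        if np.any(self.times < 0) or np.any(np.diff(self.times) <= 0):
            raise ValueError("times must be non-negative and strictly increasing")
        if (self.fractions.to_numpy() < 0).any():
            raise ValueError("fractions must be >= 0")
        if self.substrate not in ("5mC", "5hmC"):
            raise ValueError("substrate must be '5mC' or '5hmC'")

    @classmethod
    def from_tsv(cls, path: str | Path, **kwargs) -> "ProgressCurves":
        df = pd.read_csv(path, sep="\t")
        cols = {c: c.lstrip("c") for c in df.columns if c != "time_min"}
        frac = df.drop(columns="time_min").rename(columns=cols)
        return cls(times=df["time_min"].to_numpy(), fractions=frac, **kwargs)

    def to_tsv(self, path: str | Path) -> None:
        out = self.fractions.copy()
        out.insert(0, "time_min", self.times)
        out.to_csv(path, sep="\t", index=False)


def initial_state(substrate: str) -> np.ndarray:
    return np.array([1.0, 0.0, 0.0, 0.0]) if substrate == "5mC" else np.array([0.0, 1.0, 0.0, 0.0])


def rate_matrix(k1: float, k2: float, k12: float, k3: float) -> np.ndarray:
    return np.array(
        [
            [-(k1 + k12), 0.0, 0.0, 0.0],
            [k1, -k2, 0.0, 0.0],
            [k12, k2, -k3, 0.0],
            [0.0, 0.0, k3, 0.0],
        ]
    )


# ---------------------------------------------------------------------------
# normalization of raw per-species signals
# ---------------------------------------------------------------------------


def normalize_species(
    raw: pd.DataFrame,
    reference: str | pd.Series = "C",
    calibration: Mapping[str, float] | None = None,
    **curve_kwargs,
) -> ProgressCurves:
    """Normalize raw per-species signals into species fractions.

    ``raw`` has a ``time_min`` column plus one column per species signal;
    ``reference`` names the internal-reference column (a species that does
    not participate in the oxidation pathway, e.g. unmodified cytosine) or
    supplies the reference series directly.  Each species signal is
    divided by the reference, multiplied by its calibration factor, and
    the modified-cytosine vector of every time point is rescaled to sum
    to 1.
    """
    times = raw["time_min"].to_numpy(dtype=float)
    ref = raw[reference] if isinstance(reference, str) else reference
    ref = np.asarray(ref, dtype=float)
    if np.any(ref <= 0):
        raise ValueError("reference signal must be positive at every time point")

    cols = [c for c in raw.columns if c in SPECIES]
    sig = raw[cols].to_numpy(dtype=float) / ref[:, None]
    if calibration is not None:
        sig = sig * np.array([calibration.get(c, 1.0) for c in cols])
    total = sig.sum(axis=1)
    if np.any(total <= 0):
        raise ValueError("zero modified-species sum at some time point")
    frac = sig / total[:, None]
    return ProgressCurves(times=times, fractions=pd.DataFrame(frac, columns=cols), **curve_kwargs)


# ---------------------------------------------------------------------------
# integration
# ---------------------------------------------------------------------------


def integrate(
    params: ODEParameters,
    initial: Sequence[float],
    t_end: float,
    dt: float = 0.01,
) -> pd.DataFrame:
    """Forward-Euler trajectory of the four-species chain.

    Returns a DataFrame indexed by time (minutes) with one column per
    species.  The step must satisfy dt * (total exit rate) < 1 for
    stability and positivity.
    """
    if dt <= 0:
        raise ValueError("dt must be > 0")
    k1, k2, k12, k3 = params.rates
    if dt * max(k1 + k12, k2, k3) >= 1.0:
        raise ValueError("Euler unstable: dt * rate >= 1; reduce dt")
    a = rate_matrix(*params.rates)
    n_steps = int(round(t_end / dt))
    traj = np.empty((n_steps + 1, 4))
    traj[0] = np.asarray(initial, dtype=float)
    step = np.eye(4) + dt * a
    for i in range(n_steps):
        traj[i + 1] = step @ traj[i]
    times = np.arange(n_steps + 1) * dt
    return pd.DataFrame(traj, index=pd.Index(times, name="time_min"), columns=SPECIES)


def integrate_exact(
    params: ODEParameters, initial: Sequence[float], times: Sequence[float]
) -> pd.DataFrame:
    """Closed-form (matrix exponential) solution at the given times."""
    a = rate_matrix(*params.rates)
    y0 = np.asarray(initial, dtype=float)
    out = np.vstack([expm(a * t) @ y0 for t in np.asarray(times, dtype=float)])
    return pd.DataFrame(out, index=pd.Index(np.asarray(times, float), name="time_min"), columns=SPECIES)


# ---------------------------------------------------------------------------
# fitting
# ---------------------------------------------------------------------------


@dataclass
class ProgressFitResult:
    params: ODEParameters
    rmsd: float
    model: str
    fitted: pd.DataFrame
    diagnostics: dict = field(default_factory=dict)

    def params_to_json(self, path: str | Path) -> None:
        Path(path).write_text(
            json.dumps(
                {
                    "model": self.model,
                    "k1": self.params.k1,
                    "k2": self.params.k2,
                    "k12": self.params.k12,
                    "k3": self.params.k3,
                    "intensities": self.params.intensities,
                    "baselines": self.params.baselines,
                    "rmsd": self.rmsd,
                    "diagnostics": self.diagnostics,
                },
                indent=2,
            )
            + "\n"
        )


def _pack_names(model: str, substrate: str, species: Sequence[str]) -> list[str]:
    if substrate == "5mC":
        names = ["k1", "k2", "k3"] + (["k12"] if model == "four_rate" else [])
    else:
        # 5hmC substrate: k1 and k12 never act
        names = ["k2", "k3"]
    names += [f"I_{s}" for s in species if s != "5mC"]
    names += [f"B_{s}" for s in species]
    return names


def fit_progress(
    curves: ProgressCurves,
    model: str = "four_rate",
    restarts: int = 5,
    seed: int | None = None,
    init: ODEParameters | None = None,
) -> ProgressFitResult:
    """Least-RMSD fit of the oxidation chain to measured progress curves.

    ``model='three_rate'`` fixes the processive branch k12 = 0.  Intensity
    and baseline nuisance parameters are fitted per measured species
    (5mC intensity pinned at 1).  ``restarts`` seeded jittered starts are
    run in addition to the default start (and ``init`` if given); the
    best optimum is returned.
    """
    if model not in ("three_rate", "four_rate"):
        raise ValueError("model must be 'three_rate' or 'four_rate'")
    species = [s for s in SPECIES if s in curves.fractions.columns]
    names = _pack_names(model, curves.substrate, species)
    n_free = len(names)
    if len(curves.times) < 4:
        raise ValueError("need at least 4 time points")
    if len(curves.times) * len(species) < n_free:
        raise ValueError(
            f"{len(curves.times)} time points x {len(species)} species < {n_free} free parameters"
        )

    y = curves.fractions[species].to_numpy(dtype=float)
    y0 = initial_state(curves.substrate)
    sp_idx = [SPECIES.index(s) for s in species]
    n_obs = y.size

    rate_names = [n for n in names if n.startswith("k")]
    lower = np.array(
        [0.0] * len(rate_names)
        + [INTENSITY_BOUNDS[0]] * sum(n.startswith("I_") for n in names)
        + [BASELINE_BOUNDS[0]] * len(species)
    )
    upper = np.array(
        [RATE_MAX] * len(rate_names)
        + [INTENSITY_BOUNDS[1]] * sum(n.startswith("I_") for n in names)
        + [BASELINE_BOUNDS[1]] * len(species)
    )

    def unpack(theta: np.ndarray) -> ODEParameters:
        vals = dict(zip(names, theta))
        return ODEParameters(
            k1=vals.get("k1", 0.0),
            k2=vals.get("k2", 0.0),
            k12=vals.get("k12", 0.0),
            k3=vals.get("k3", 0.0),
            intensities={s: (1.0 if s == "5mC" else vals.get(f"I_{s}", 1.0)) for s in SPECIES},
            baselines={s: vals.get(f"B_{s}", 0.0) for s in SPECIES},
        )

    def predict(p: ODEParameters) -> np.ndarray:
        conc = integrate_exact(p, y0, curves.times).to_numpy()[:, sp_idx]
        inten = np.array([p.intensities[s] for s in species])
        base = np.array([p.baselines[s] for s in species])
        return conc * inten + base

    def residuals(theta: np.ndarray) -> np.ndarray:
        return (predict(unpack(theta)) - y).ravel()

    def pack(p: ODEParameters) -> np.ndarray:
        vals = {
            "k1": p.k1,
            "k2": p.k2,
            "k12": p.k12,
            "k3": p.k3,
            **{f"I_{s}": p.intensities.get(s, 1.0) for s in SPECIES},
            **{f"B_{s}": p.baselines.get(s, 0.0) for s in SPECIES},
        }
        return np.clip(np.array([vals[n] for n in names]), lower, upper)

    default_rates = {"k1": 0.1, "k2": 0.05, "k12": 0.02, "k3": 0.02}
    theta0 = np.array(
        [
            default_rates.get(n, 1.0 if n.startswith("I_") else 0.0)
            for n in names
        ]
    )
    starts = [theta0]
    if init is not None:
        starts.append(pack(init))
    rng = np.random.default_rng(seed)
    for _ in range(restarts):
        jitter = theta0.copy()
        nk = len(rate_names)
        jitter[:nk] = theta0[:nk] * rng.lognormal(0.0, 1.0, size=nk)
        starts.append(np.clip(jitter, lower, upper))

    best = None
    for start in starts:
        sol = least_squares(residuals, start, bounds=(lower, upper), method="trf", xtol=1e-12, ftol=1e-12, gtol=1e-12)
        if best is None or sol.cost < best.cost:
            best = sol

    params = unpack(best.x)
    rmsd = float(np.sqrt(2.0 * best.cost / n_obs))
    pred = predict(params)
    fitted = pd.DataFrame(pred, index=pd.Index(curves.times, name="time_min"), columns=species)
    return ProgressFitResult(
        params=params,
        rmsd=rmsd,
        model=model,
        fitted=fitted,
        diagnostics={"nfev": int(best.nfev), "status": int(best.status), "n_starts": len(starts)},
    )


def fit_progress_shared(
    mc_curves: ProgressCurves,
    hmc_curves: ProgressCurves,
    model: str = "four_rate",
    restarts: int = 5,
    seed: int | None = None,
) -> dict[str, ProgressFitResult]:
    """Joint fit of a 5mC- and a 5hmC-substrate reaction with shared k2, k3.

    The two reactions probe overlapping steps of the same chain: the
    5hmC-substrate curves constrain k2 and k3 directly, the 5mC-substrate
    curves add k1 (and k12 for the four-rate model).  Nuisance intensities
    and baselines stay per-reaction.  The default mode of the package fits
    the reactions separately; this joint mode is for when the same enzyme
    preparation and conditions justify sharing the later steps.
    """
    if mc_curves.substrate != "5mC" or hmc_curves.substrate != "5hmC":
        raise ValueError("expected one 5mC-substrate and one 5hmC-substrate reaction")
    if model not in ("three_rate", "four_rate"):
        raise ValueError("model must be 'three_rate' or 'four_rate'")

    datasets = {"5mC": mc_curves, "5hmC": hmc_curves}
    species = {
        label: [s for s in SPECIES if s in c.fractions.columns] for label, c in datasets.items()
    }
    # parameter vector: k1 [, k12], shared k2, k3, then per-dataset nuisances
    names = ["k1"] + (["k12"] if model == "four_rate" else []) + ["k2", "k3"]
    for label in datasets:
        names += [f"I_{label}_{s}" for s in species[label] if s != "5mC"]
        names += [f"B_{label}_{s}" for s in species[label]]
    lower = np.array(
        [0.0 if n.startswith("k") else INTENSITY_BOUNDS[0] if n.startswith("I_") else BASELINE_BOUNDS[0] for n in names]
    )
    upper = np.array(
        [RATE_MAX if n.startswith("k") else INTENSITY_BOUNDS[1] if n.startswith("I_") else BASELINE_BOUNDS[1] for n in names]
    )

    def residuals(theta: np.ndarray) -> np.ndarray:
        vals = dict(zip(names, theta))
        out = []
        for label, curves in datasets.items():
            p = ODEParameters(
                k1=vals["k1"] if label == "5mC" else 0.0,
                k2=vals["k2"],
                k12=vals.get("k12", 0.0) if label == "5mC" else 0.0,
                k3=vals["k3"],
                intensities={
                    s: (1.0 if s == "5mC" else vals.get(f"I_{label}_{s}", 1.0)) for s in SPECIES
                },
                baselines={s: vals.get(f"B_{label}_{s}", 0.0) for s in SPECIES},
            )
            conc = integrate_exact(p, initial_state(label), curves.times).to_numpy()
            sp_idx = [SPECIES.index(s) for s in species[label]]
            inten = np.array([p.intensities[s] for s in species[label]])
            base = np.array([p.baselines[s] for s in species[label]])
            pred = conc[:, sp_idx] * inten + base
            out.append((pred - curves.fractions[species[label]].to_numpy()).ravel())
        return np.concatenate(out)

    theta0 = np.array(
        [{"k1": 0.1, "k12": 0.02, "k2": 0.05, "k3": 0.02}.get(n, 1.0 if n.startswith("I_") else 0.0) for n in names]
    )
    rng = np.random.default_rng(seed)
    nk = sum(n.startswith("k") for n in names)
    starts = [theta0]
    for _ in range(restarts):
        jitter = theta0.copy()
        jitter[:nk] = theta0[:nk] * rng.lognormal(0.0, 1.0, size=nk)
        starts.append(np.clip(jitter, lower, upper))
    best = None
    for start in starts:
        sol = least_squares(residuals, start, bounds=(lower, upper), method="trf",
                            xtol=1e-12, ftol=1e-12, gtol=1e-12)
        if best is None or sol.cost < best.cost:
            best = sol
    vals = dict(zip(names, best.x))

    results = {}
    for label, curves in datasets.items():
        p = ODEParameters(
            k1=vals["k1"] if label == "5mC" else 0.0,
            k2=vals["k2"],
            k12=vals.get("k12", 0.0) if label == "5mC" else 0.0,
            k3=vals["k3"],
            intensities={s: (1.0 if s == "5mC" else vals.get(f"I_{label}_{s}", 1.0)) for s in SPECIES},
            baselines={s: vals.get(f"B_{label}_{s}", 0.0) for s in SPECIES},
        )
        conc = integrate_exact(p, initial_state(label), curves.times).to_numpy()
        sp_idx = [SPECIES.index(s) for s in species[label]]
        inten = np.array([p.intensities[s] for s in species[label]])
        base = np.array([p.baselines[s] for s in species[label]])
        pred = conc[:, sp_idx] * inten + base
        y = curves.fractions[species[label]].to_numpy()
        results[label] = ProgressFitResult(
            params=p,
            rmsd=float(np.sqrt(np.mean((pred - y) ** 2))),
            model=model,
            fitted=pd.DataFrame(pred, index=pd.Index(curves.times, name="time_min"), columns=species[label]),
            diagnostics={"shared": ["k2", "k3"], "nfev": int(best.nfev), "n_starts": len(starts)},
        )
    return results


def compare_models(
    curves: ProgressCurves, restarts: int = 5, seed: int | None = None
) -> dict[str, ProgressFitResult]:
    """Fit the three-rate and four-rate models for model selection.

    The four-rate fit is additionally seeded from the three-rate optimum
    (the models are nested), so its RMSD cannot exceed the three-rate
    RMSD for optimizer reasons alone — any improvement reflects the
    processive branch.
    """
    three = fit_progress(curves, model="three_rate", restarts=restarts, seed=seed)
    four = fit_progress(
        curves, model="four_rate", restarts=restarts, seed=seed, init=three.params
    )
    return {"three_rate": three, "four_rate": four}


def rate_ratio_summary(
    preferred: ProgressFitResult,
    disfavored: ProgressFitResult,
    preferred_concentration: float,
    disfavored_concentration: float,
) -> dict:
    """Preferred/disfavored rate ratios, corrected for enzyme amounts.

    Reactions on disfavored substrates typically use more enzyme; rates
    are therefore scaled by 1/concentration before forming the per-step
    ratio.  Steps with a zero disfavored rate are skipped.
    """
    if preferred_concentration <= 0 or disfavored_concentration <= 0:
        raise ValueError("enzyme concentrations must be positive")
    ratios = {}
    for step in ("k1", "k2", "k12", "k3"):
        kp = getattr(preferred.params, step) / preferred_concentration
        kd = getattr(disfavored.params, step) / disfavored_concentration
        if kd > 0:
            ratios[step] = kp / kd
    if not ratios:
        raise ValueError("no step has a positive disfavored rate")
    return {"ratios": ratios, "mean_ratio": float(np.mean(list(ratios.values())))}
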