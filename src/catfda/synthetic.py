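"""Seeded synthetic cohorts with the statistical structure of cat actigraphy.

Latent model, on the ln(1 + count) scale and the 288-point daily grid:

    L_i^{daytype}(t) = template(group_i, daytype)(t)
                       + sum_k xi_ik^{daytype} phi_k(t)
                       + sum_p x_ip beta_p(t)

Templates are a constant baseline plus two Gaussian bumps (a sharp morning
peak, a broad evening peak) and a negative Gaussian trough in the small
hours — the bimodal crepuscular pattern of indoor cats.  Weekend templates
delay and flatten the morning peak (owners rise later and less uniformly);
DJD templates multiply all peak/trough excursions by an attenuation factor in
(0, 1], producing muted peaks and shallower troughs rather than a uniform
shift.  Inter-cat variability enters through a low-rank orthonormal
eigenfunction basis with planted eigenvalues; weekday and weekend scores for
each component are drawn from a bivariate Gaussian with a planted
correlation.  Scalar covariates (age, BCS, pain and DJD scores) are drawn
with group-dependent, mutually correlated distributions and can carry planted
time-varying effects beta_p(t) on the standardized scale.

Per-minute counts invert the analysis transform: the latent curve is held
constant within each 5-minute bin, lognormal noise is added per minute, and
counts = round(exp(latent + noise) - 1) clipped at zero.  Identical configs
(including seed) produce bit-identical cohorts.
"""

from __future__ import annotations

import datetime as _dt
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
import yaml

from .grid import BIN_MINUTES, DEFAULT_GRID, N_BINS, TimeGrid
from .io import EpochSeries
from .preprocessing import WEEKDAY, WEEKEND, split_daytype

NORMAL = "Normal"
DJD = "DJD"


class GeneratorError(ValueError):
    pass


@dataclass(frozen=True)
class PeakParams:
    """One template's shape parameters (hours / log-count units)."""

    baseline: float = 3.6
    morning_center: float = 7.0
    morning_width: float = 0.9
    morning_amp: float = 1.1
    evening_center: float = 20.0
    evening_width: float = 2.2
    evening_amp: float = 0.8
    trough_center: float = 3.5
    trough_width: float = 1.1
    trough_depth: float = 0.9


@dataclass(frozen=True)
class GeneratorConfig:
    """Everything needed to generate one synthetic cohort, deterministically."""

    seed: int = 0
    n_per_group: tuple[tuple[str, int], ...] = ((NORMAL, 15), (DJD, 83))
    n_days: int = 7
    anchor_date: _dt.date = _dt.date(2015, 6, 1)  # a Monday
    #: hours by which the weekend morning peak is delayed
    weekend_shift: float = 1.5
    #: multiplicative flattening of the weekend morning peak amplitude
    weekend_morning_flatten: float = 0.65
    #: multiplicative widening of the weekend morning peak
    weekend_morning_widen: float = 1.3
    #: mild flattening of the weekend evening peak
    weekend_evening_flatten: float = 0.9
    #: multiplicative factor in (0, 1] applied to DJD peak/trough excursions
    djd_attenuation: float = 0.6
    #: per-minute latent lognormal noise SD (log-count units)
    noise_sd: float = 0.6
    #: planted correlation of a subject's weekend vs weekday component scores
    score_xcorr: float = 0.6
    #: (eigenfunction id, eigenvalue) pairs, eigenvalues non-increasing
    eigen_spec: tuple[tuple[int, float], ...] = ((1, 1.0), (2, 0.5), (3, 0.25))
    #: planted standardized-covariate effect curves; None -> default age effect
    beta_spec: dict[str, np.ndarray] | None = None
    #: optional per (group, daytype) template overrides
    peak_params: dict[tuple[str, str], PeakParams] | None = None

    def __post_init__(self) -> None:
        if not 0 < self.djd_attenuation <= 1:
            raise GeneratorError(
                f"djd_attenuation must be in (0, 1], got {self.djd_attenuation}"
            )
        if self.noise_sd < 0:
            raise GeneratorError("noise_sd must be >= 0")
        if not -1 <= self.score_xcorr <= 1:
            raise GeneratorError("score_xcorr must be in [-1, 1]")
        lams = [lam for _, lam in self.eigen_spec]
        if any(lam < 0 for lam in lams):
            raise GeneratorError("eigenvalues must be >= 0")
        if any(a < b for a, b in zip(lams, lams[1:])):
            raise GeneratorError("eigenvalues must be listed in non-increasing order")
        for g, n in self.n_per_group:
            if g not in (NORMAL, DJD):
                raise GeneratorError(f"unknown group label {g!r}")
            if n < 1:
                raise GeneratorError(f"group {g}: need at least 1 subject")
        if self.n_days >= 7:
            dts = [
                split_daytype(self.anchor_date + _dt.timedelta(days=d))
                for d in range(self.n_days)
            ]
            if dts.count(WEEKEND) < 2 or dts.count(WEEKDAY) < 5:
                raise GeneratorError(
                    "n_days >= 7 must include at least 5 weekday and 2 weekend days"
                )

    @property
    def groups(self) -> dict[str, int]:
        return dict(self.n_per_group)

    def template_params(self, group: str, daytype: str) -> PeakParams:
        """Template parameters for a group x day type, applying defaults."""
        if group not in (NORMAL, DJD):
            raise GeneratorError(f"unknown group label {group!r}")
        if daytype not in (WEEKDAY, WEEKEND):
            raise GeneratorError(f"unknown daytype label {daytype!r}")
        if self.peak_params and (group, daytype) in self.peak_params:
            return self.peak_params[(group, daytype)]
        p = PeakParams()
        if daytype == WEEKEND:
            p = replace(
                p,
                morning_center=p.morning_center + self.weekend_shift,
                morning_amp=p.morning_amp * self.weekend_morning_flatten,
                morning_width=p.morning_width * self.weekend_morning_widen,
                evening_amp=p.evening_amp * self.weekend_evening_flatten,
            )
        if group == DJD:
            a = self.djd_attenuation
            p = replace(
                p,
                morning_amp=p.morning_amp * a,
                evening_amp=p.evening_amp * a,
                trough_depth=p.trough_depth * a,
            )
        return p

    @classmethod
    def from_yaml(cls, path) -> "GeneratorConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        kwargs = {}
        for key in (
            "seed",
            "n_days",
            "weekend_shift",
            "weekend_morning_flatten",
            "weekend_morning_widen",
            "weekend_evening_flatten",
            "djd_attenuation",
            "noise_sd",
            "score_xcorr",
        ):
            if key in raw:
                kwargs[key] = raw[key]
        if "anchor_date" in raw:
            kwargs["anchor_date"] = _dt.date.fromisoformat(str(raw["anchor_date"]))
        if "n_per_group" in raw:
            kwargs["n_per_group"] = tuple(
                (str(g), int(n)) for g, n in raw["n_per_group"].items()
            )
        if "eigen_spec" in raw:
            kwargs["eigen_spec"] = tuple(
                (int(k), float(lam)) for k, lam in raw["eigen_spec"]
            )
        return cls(**kwargs)


@dataclass
class SyntheticTruth:
    """Ground truth planted by the generator, for recovery-test oracles."""

    seed: int
    templates: dict[tuple[str, str], np.ndarray]
    eigenfunctions: np.ndarray            # (K, 288), orthonormal by quadrature
    eigenvalues: np.ndarray               # (K,)
    beta: dict[str, np.ndarray]           # planted standardized-effect curves
    scores_weekday: dict[str, np.ndarray]  # cat_id -> (K,)
    scores_weekend: dict[str, np.ndarray]
    latent: dict[tuple[str, str], np.ndarray]  # cat_id x daytype -> 288 curve

    def latent_curve(self, cat_id: str, daytype: str) -> np.ndarray:
        return self.latent[(cat_id, daytype)]


def _gauss(t: np.ndarray, center: float, width: float) -> np.ndarray:
    return np.exp(-0.5 * ((t - center) / width) ** 2)


def bimodal_template(
    group: str, daytype: str, config: GeneratorConfig, grid: TimeGrid = DEFAULT_GRID
) -> np.ndarray:
    """The group x day-type mean latent curve on the 288-point grid."""
    p = config.template_params(group, daytype)
    t = grid.t
    return (
        p.baseline
        + p.morning_amp * _gauss(t, p.morning_center, p.morning_width)
        + p.evening_amp * _gauss(t, p.evening_center, p.evening_width)
        - p.trough_depth * _gauss(t, p.trough_center, p.trough_width)
    )


def planted_eigenfunctions(
    config: GeneratorConfig, grid: TimeGrid = DEFAULT_GRID
) -> np.ndarray:
    """Orthonormal (quadrature) eigenfunction basis for the planted components.

    Eigenfunction ids map to low-order Fourier shapes on the 24-h day
    (1: sin 2pi t/24, 2: cos 2pi t/24, 3: sin 4pi t/24, ...), Gram-Schmidt
    orthonormalized on the grid to 1e-10.
    """
    t = grid.t
    funcs = []
    for k, _lam in config.eigen_spec:
        if k < 1:
            raise GeneratorError(f"eigenfunction id must be >= 1, got {k}")
        harmonic = (k + 1) // 2
        phase = np.sin if k % 2 == 1 else np.cos
        funcs.append(phase(2.0 * np.pi * harmonic * t / grid.day_hours))
    phi = np.array(funcs, dtype=float)
    # modified Gram-Schmidt under the quadrature inner product
    for i in range(phi.shape[0]):
        for j in range(i):
            phi[i] -= grid.inner(phi[i], phi[j]) * phi[j]
        nrm = grid.norm(phi[i])
        if nrm < 1e-12:
            raise GeneratorError(f"degenerate eigenfunction basis at id {i + 1}")
        phi[i] /= nrm
    return phi


def default_beta_spec(grid: TimeGrid = DEFAULT_GRID) -> dict[str, np.ndarray]:
    """Default planted effects: older cats are less active around both peaks."""
    t = grid.t
    age = -0.12 * _gauss(t, 7.0, 2.0) - 0.12 * _gauss(t, 20.0, 2.0)
    return {"age": age}


def curve_to_counts(
    latent: np.ndarray, rng: np.random.Generator, noise_sd: float = 0.0
) -> np.ndarray:
    """Invert the analysis transform: latent log-scale minutes -> integer counts.

    counts = round(exp(latent + noise) - 1) clipped at 0, with iid Gaussian
    noise of SD ``noise_sd`` per minute on the log scale (lognormal counts,
    matching the right-skew of real accelerometer output).
    """
    latent = np.asarray(latent, dtype=float)
    if not np.all(np.isfinite(latent)):
        raise GeneratorError("latent curve contains non-finite values")
    z = latent
    if noise_sd > 0:
        z = latent + rng.normal(0.0, noise_sd, size=latent.shape)
    return np.clip(np.rint(np.expm1(z)), 0, None).astype(np.int64)


def _sample_covariates(
    group: str, cat_id: str, rng: np.random.Generator
) -> dict[str, object]:
    """Group-dependent covariates with severity-driven correlation in DJD cats."""
    sex = "MC" if rng.random() < 0.5 else "FS"
    if group == NORMAL:
        age = float(np.clip(np.round(rng.normal(6.0, 2.0), 1), 1.5, 14.0))
        bcs = int(np.clip(np.rint(rng.normal(5.0, 1.3)), 1, 9))
        tpain = int(rng.integers(0, 3))
        tdjd = int(rng.integers(0, 4))
        max_joint = min(tpain, 1)
        study = NORMAL
    else:
        s = rng.normal()  # latent severity ties age, pain and DJD burden together
        age = float(np.clip(np.round(12.0 + 1.5 * s + rng.normal(0.0, 1.5), 1), 2.0, 20.0))
        bcs = int(np.clip(np.rint(rng.normal(6.5, 1.3)), 1, 9))
        tpain = int(np.clip(np.rint(15.0 + 5.0 * s + rng.normal(0.0, 3.0)), 5, 80))
        tdjd = int(np.clip(np.rint(22.0 + 8.0 * s + rng.normal(0.0, 5.0)), 4, 200))
        max_joint = int(np.clip(np.rint(2.5 + 0.5 * rng.normal()), 2, 4))
        study = "FMPI" if rng.random() < 25.0 / 83.0 else "LowDose"
    return {
        "cat_id": cat_id,
        "group": group,
        "study": study,
        "age": age,
        "bcs": bcs,
        "sex": sex,
        "tpain": tpain,
        "tdjd": tdjd,
        "max_single_joint_pain": max_joint,
    }


def generate_cohort(
    config: GeneratorConfig, grid: TimeGrid = DEFAULT_GRID
) -> tuple[list[EpochSeries], pd.DataFrame, SyntheticTruth]:
    """Generate a full cohort: per-minute counts, covariate table, ground truth."""
    rng = np.random.default_rng(config.seed)
    phi = planted_eigenfunctions(config, grid)
    lam = np.array([l for _, l in config.eigen_spec], dtype=float)
    K = len(lam)
    beta = config.beta_spec if config.beta_spec is not None else default_beta_spec(grid)
    for term, curve in beta.items():
        if np.asarray(curve).shape != (grid.n_bins,):
            raise GeneratorError(f"beta_spec[{term!r}] must be a {grid.n_bins}-point curve")

    # 1. covariates for every subject, in a fixed order
    rows = []
    for group, n in config.n_per_group:
        prefix = group[0]
        for i in range(n):
            rows.append(_sample_covariates(group, f"{prefix}{i + 1:03d}", rng))
    covariates = pd.DataFrame(rows)

    # planted effects act on cohort-standardized covariates
    effect = np.zeros((len(covariates), grid.n_bins))
    for term, curve in beta.items():
        raw = covariates[term].to_numpy(dtype=float)
        sd = raw.std(ddof=1)
        if sd > 0:
            effect += np.outer((raw - raw.mean()) / sd, np.asarray(curve, dtype=float))

    # 2. component scores: weekday/weekend pairs with the planted correlation
    rho = config.score_xcorr
    L = np.linalg.cholesky(np.array([[1.0, rho], [rho, 1.0]]))
    scores_wd: dict[str, np.ndarray] = {}
    scores_we: dict[str, np.ndarray] = {}
    for cat_id in covariates["cat_id"]:
        z = rng.standard_normal((K, 2))
        pair = z @ L.T * np.sqrt(lam)[:, None]
        scores_wd[cat_id] = pair[:, 0]
        scores_we[cat_id] = pair[:, 1]

    # 3. latent curves and per-minute counts
    templates = {
        (g, d): bimodal_template(g, d, config, grid)
        for g in config.groups
        for d in (WEEKDAY, WEEKEND)
    }
    latent: dict[tuple[str, str], np.ndarray] = {}
    series: list[EpochSeries] = []
    for idx, row in covariates.iterrows():
        cat_id, group = row["cat_id"], row["group"]
        for daytype, scores in ((WEEKDAY, scores_wd), (WEEKEND, scores_we)):
            latent[(cat_id, daytype)] = (
                templates[(group, daytype)] + scores[cat_id] @ phi + effect[idx]
            )
        for d in range(config.n_days):
            date = config.anchor_date + _dt.timedelta(days=d)
            curve = latent[(cat_id, split_daytype(date))]
            minutes = np.repeat(curve, BIN_MINUTES)
            series.append(
                EpochSeries(
                    cat_id=cat_id,
                    date=date,
                    counts=curve_to_counts(minutes, rng, config.noise_sd),
                )
            )

    truth = SyntheticTruth(
        seed=config.seed,
        templates=templates,
        eigenfunctions=phi,
        eigenvalues=lam,
        beta={t: np.asarray(c, dtype=float) for t, c in beta.items()},
        scores_weekday=scores_wd,
        scores_weekend=scores_we,
        latent=latent,
    )
    return series, covariates, truth
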