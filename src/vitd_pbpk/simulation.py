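"""Virtual-population construction and forward simulation.

Builds virtual cohorts by percentile-uniform sampling from growth and
baseline-status tables (a draw lands in a percentile stratum with its
nominal probability mass and is uniform within it, with configurable
bounds closing the tails), simulates per-child or cohort prediction
bands under fixed-effect uncertainty + inter-individual variability +
additive residual error, and evaluates dose-requirement questions
(threshold attainment, clearance/C50 scenarios, coverage of observed
data by predicted percentile ranges).

Simulations are anchored at each subject's observed baseline: the
endogenous input is calibrated per child and the proportional residual
component is not sampled.
"""

from __future__ import annotations

import importlib.resources as resources
import logging
import math
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from scipy.special import ndtri

from .config import HOURS_PER_WEEK, HOURS_PER_YEAR
from .errors import ConfigurationError, DataError, InvalidInputError
from .pbpk import DoseEvent
from .population import PopulationModel
from .predict import EtaGridInterpolator, predict_child
from .records import ChildRecord

__all__ = [
    "PercentileBand",
    "sample_between_percentiles",
    "percentile_z_score",
    "load_percentile_table",
    "build_virtual_cohort",
    "daily_regimen",
    "weekly_regimen",
    "prediction_intervals",
    "threshold_attainment",
    "scenario_modify",
    "coverage_metrics",
    "compliance",
]

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# percentile-uniform sampling
# ---------------------------------------------------------------------------


def _as_percentile_table(table) -> tuple[np.ndarray, np.ndarray]:
    if isinstance(table, dict):
        items = sorted(table.items())
        p = np.array([k for k, _ in items], dtype=float)
        v = np.array([x for _, x in items], dtype=float)
    else:
        ser = pd.Series(table).sort_index()
        p = ser.index.to_numpy(dtype=float)
        v = ser.to_numpy(dtype=float)
    if np.any(np.diff(p) <= 0) or np.any(np.diff(v) <= 0):
        raise DataError("percentile table must be strictly increasing in p and value")
    if np.any(p <= 0) or np.any(p >= 100):
        raise DataError("percentile levels must lie strictly inside (0, 100)")
    return p, v


def sample_between_percentiles(
    table, n: int, bounds: tuple[float, float], seed_or_rng=0
) -> np.ndarray:
    """Draw n values matching a printed percentile table.

    A stratum between neighbouring percentiles is selected with its
    nominal probability mass and the value is uniform within the stratum;
    ``bounds`` = (lo, hi) close the two tails.
    """
    rng = (
        np.random.default_rng(seed_or_rng)
        if isinstance(seed_or_rng, (int, np.integer))
        else seed_or_rng
    )
    p, v = _as_percentile_table(table)
    lo, hi = bounds
    if lo > v[0] or hi < v[-1]:
        raise DataError("bounds must enclose the percentile values")
    edges = np.concatenate([[lo], v, [hi]])
    probs = np.diff(np.concatenate([[0.0], p / 100.0, [1.0]]))
    if n == 0:
        return np.empty(0)
    strata = rng.choice(probs.size, size=n, p=probs)
    u = rng.random(n)
    return edges[strata] + u * (edges[strata + 1] - edges[strata])


def percentile_z_score(table, values, bounds: tuple[float, float]) -> np.ndarray:
    """Z-score of values against a percentile table (piecewise-linear CDF)."""
    p, v = _as_percentile_table(table)
    lo, hi = bounds
    xp = np.concatenate([[lo], v, [hi]])
    fp = np.concatenate([[0.001], p / 100.0, [0.999]])
    q = np.interp(np.asarray(values, dtype=float), xp, fp)
    return ndtri(np.clip(q, 0.001, 0.999))


# ---------------------------------------------------------------------------
# virtual cohorts
# ---------------------------------------------------------------------------

_DATA_FILES = {
    "weight_6y": "synthetic_weight_for_age_6y.csv",
    "bmi_11y": "synthetic_bmi_for_age_11y.csv",
    "height_11y": "synthetic_height_for_age_11y.csv",
    "baseline_25ohd": "synthetic_baseline_25ohd_eu.csv",
}

#: baseline 25(OH)D sampling bounds for the European cohort, nmol/L
BASELINE_BOUNDS = (10.0, 90.0)


def load_percentile_table(key_or_path, column: str | None = None) -> pd.Series:
    """Load a packaged (or user CSV) percentile table as a Series.

    Packaged tables are synthetic, WHO-like fixtures (the engine only
    requires strictly monotone tables); substitute official values by
    passing a path to a CSV with a ``percentile`` column.
    """
    if key_or_path in _DATA_FILES:
        ref = resources.files("vitd_pbpk").joinpath("data", _DATA_FILES[key_or_path])
        with resources.as_file(ref) as path:
            df = pd.read_csv(path)
    else:
        df = pd.read_csv(key_or_path)
    df = df.set_index("percentile")
    col = column or df.columns[0]
    return df[col]


def daily_regimen(dose_ug: float, n_days: int) -> list[DoseEvent]:
    """One dose every 24 h starting at time 0 (100% compliance)."""
    return [DoseEvent(24.0 * i, dose_ug) for i in range(n_days)]


def weekly_regimen(dose_ug: float, n_weeks: int) -> list[DoseEvent]:
    """One dose every 168 h starting at time 0 (100% compliance)."""
    return [DoseEvent(HOURS_PER_WEEK * i, dose_ug) for i in range(n_weeks)]


def build_virtual_cohort(
    age_group: str,
    n: int,
    seed: int = 0,
    tables: dict | None = None,
    bounds: dict | None = None,
) -> list[ChildRecord]:
    """Virtual children for the European dose-requirement simulation.

    ``age_group`` is '6y' or '11y'; n is split equally between boys and
    girls (the reference design uses 1250 + 1250 per age group). For
    6-year-olds weight is sampled from a weight-for-age percentile table
    and the weight-for-age Z-score serves as the BMI Z-score proxy; for
    11-year-olds BMI and height are sampled independently and weight =
    BMI * height^2, with the BMI Z-score used directly. Baseline
    25(OH)D is sampled between its reported percentiles within
    [10, 90] nmol/L.
    """
    rng = np.random.default_rng(seed)
    tables = tables or {}
    bounds = bounds or {}
    c25_tab = tables.get("baseline_25ohd", load_percentile_table("baseline_25ohd"))
    c25_bounds = bounds.get("baseline_25ohd", BASELINE_BOUNDS)
    children: list[ChildRecord] = []
    n_boys = n // 2
    sexes = ["boy"] * n_boys + ["girl"] * (n - n_boys)
    if age_group == "6y":
        age = 6.0
        for sex in ("boy", "girl"):
            key = f"weight_6y_{sex}"
            tab = tables.get(key, load_percentile_table("weight_6y", f"{sex}s"))
            wb = bounds.get(key, (0.75 * tab.iloc[0], 1.3 * tab.iloc[-1]))
            k = sexes.count(sex)
            wt = sample_between_percentiles(tab, k, wb, rng)
            z = percentile_z_score(tab, wt, wb)
            c25 = sample_between_percentiles(c25_tab, k, c25_bounds, rng)
            children += _make_children(age_group, sex, age, wt, z, c25)
    elif age_group == "11y":
        age = 11.0
        for sex in ("boy", "girl"):
            bmi_tab = tables.get(
                f"bmi_11y_{sex}", load_percentile_table("bmi_11y", f"{sex}s")
            )
            ht_tab = tables.get(
                f"height_11y_{sex}", load_percentile_table("height_11y", f"{sex}s")
            )
            bb = bounds.get(f"bmi_11y_{sex}", (0.8 * bmi_tab.iloc[0], 1.35 * bmi_tab.iloc[-1]))
            hb = bounds.get(f"height_11y_{sex}", (0.9 * ht_tab.iloc[0], 1.1 * ht_tab.iloc[-1]))
            k = sexes.count(sex)
            bmi = sample_between_percentiles(bmi_tab, k, bb, rng)
            ht = sample_between_percentiles(ht_tab, k, hb, rng)
            wt = bmi * ht ** 2
            z = percentile_z_score(bmi_tab, bmi, bb)
            c25 = sample_between_percentiles(c25_tab, k, c25_bounds, rng)
            children += _make_children(age_group, sex, age, wt, z, c25)
    else:
        raise ConfigurationError(f"unknown age group {age_group!r} (use '6y' or '11y')")
    return children


def _make_children(age_group, sex, age, wt, z, c25) -> list[ChildRecord]:
    from .config import DEFAULT_CONFIG

    slope = DEFAULT_CONFIG.weight_slope_girl if sex == "girl" else DEFAULT_CONFIG.weight_slope_boy
    return [
        ChildRecord(
            id=f"{age_group}-{sex}-{i:04d}",
            sex=sex,
            age=age,
            wt0=float(w),
            wt_final=float(w + 3.0 * slope),
            zbmi=float(zz),
            baseline_c25=float(cc),
        )
        for i, (w, zz, cc) in enumerate(zip(wt, z, c25))
    ]


# ---------------------------------------------------------------------------
# prediction bands
# ---------------------------------------------------------------------------


@dataclass
class PercentileBand:
    """Simulated percentile trajectories with across-study prediction intervals.

    ``percentiles[l, t]`` is the across-study median of percentile level
    ``levels[l]`` at ``times_h[t]``; ``pi_lo``/``pi_hi`` bracket its 95%
    prediction interval across the virtual studies.
    """

    times_h: np.ndarray
    levels: tuple[float, ...]
    percentiles: np.ndarray
    pi_lo: np.ndarray
    pi_hi: np.ndarray

    @property
    def times_weeks(self) -> np.ndarray:
        return self.times_h / HOURS_PER_WEEK

    def level(self, q: float) -> np.ndarray:
        try:
            i = self.levels.index(q)
        except ValueError:
            raise InvalidInputError(f"level {q} not among {self.levels}") from None
        return self.percentiles[i]

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for i, q in enumerate(self.levels):
            for j, t in enumerate(self.times_h):
                rows.append(
                    (t, t / HOURS_PER_WEEK, q, self.percentiles[i, j],
                     self.pi_lo[i, j], self.pi_hi[i, j])
                )
        return pd.DataFrame(
            rows, columns=["time_h", "time_weeks", "percentile", "value", "pi_lo", "pi_hi"]
        )


def _sample_theta(pop: PopulationModel, rng, uncertainty: bool) -> PopulationModel:
    if not uncertainty:
        return pop
    theta = dict(pop.theta)
    for name, se in pop.theta_se.items():
        if name in theta and se > 0:
            theta[name] = theta[name] + rng.normal(0.0, se)
    return pop.replace(theta=theta)


def prediction_intervals(
    subject,
    dosing: list[DoseEvent] | None,
    pop: PopulationModel,
    n_studies: int = 30,
    n_samples: int = 2500,
    seed: int = 0,
    times_h: np.ndarray | None = None,
    levels: tuple[float, ...] = (2.5, 50.0, 97.5),
    pi_level: float = 95.0,
    include_proportional_error: bool = False,
) -> PercentileBand:
    """Simulated percentile band for one child or a virtual cohort.

    Outer loop: ``n_studies`` realisations of the fixed-effect
    uncertainty (lognormal, using the fitted standard errors). Inner
    loop: for a single subject, ``n_samples`` draws of the CLmax random
    effect plus additive residual error (via the eta-grid interpolator);
    for a cohort, one random-effect draw per virtual child. Percentiles
    are computed within each study and summarised across studies by
    their median and ``pi_level``% prediction interval. Trajectories are
    anchored at each subject's observed baseline; by default the
    proportional residual component is not sampled (so the band starts
    exactly at the baseline). Set ``include_proportional_error`` to
    sample the full observation model — required when the band is meant
    to have nominal coverage of noisy observations.
    """
    rng = np.random.default_rng(seed)
    cohort = isinstance(subject, (list, tuple))
    if times_h is None:
        times_h = np.arange(0.0, 3.0 * HOURS_PER_YEAR + 1, HOURS_PER_WEEK)
    times_h = np.asarray(times_h, dtype=float)
    uncertainty = any(se > 0 for se in pop.theta_se.values())
    if not uncertainty and n_studies > 1:
        logger.warning(
            "population model carries no fixed-effect SEs; "
            "uncertainty sampling disabled"
        )
    levels_arr = np.asarray(levels, dtype=float)
    per_study = np.empty((n_studies, levels_arr.size, times_h.size))
    sd_eta = math.sqrt(pop.omega.get("clmax", 0.0))
    for s in range(n_studies):
        pop_s = _sample_theta(pop, rng, uncertainty)
        if cohort:
            f = np.empty((len(subject), times_h.size))
            for i, child in enumerate(subject):
                eta = {"clmax": rng.normal(0.0, sd_eta)} if sd_eta > 0 else None
                f[i] = predict_child(pop_s, child, eta, times_h, doses=dosing)
        else:
            interp = EtaGridInterpolator(pop_s, subject, times_h, doses=dosing)
            eta = rng.normal(0.0, sd_eta, size=n_samples) if sd_eta > 0 else np.zeros(n_samples)
            f = interp(eta)
        if include_proportional_error:
            f = f * (1.0 + rng.normal(0.0, 1.0, size=f.shape) * pop.sigma_prop)
        f = f + rng.normal(0.0, 1.0, size=f.shape) * pop.sigma_add
        per_study[s] = np.percentile(f, levels_arr, axis=0)
    alpha = (100.0 - pi_level) / 2.0
    return PercentileBand(
        times_h=times_h,
        levels=tuple(levels),
        percentiles=np.median(per_study, axis=0),
        pi_lo=np.percentile(per_study, alpha, axis=0),
        pi_hi=np.percentile(per_study, 100.0 - alpha, axis=0),
    )


def threshold_attainment(band: PercentileBand, threshold: float) -> float | None:
    """First time (weeks) the band's lowest percentile reaches threshold.

    Returns None when the lowest simulated percentile never reaches the
    threshold within the band's time span ("not attained").
    """
    low = band.percentiles[int(np.argmin(band.levels))]
    above = low >= threshold
    if not above.any():
        return None
    return float(band.times_weeks[int(np.argmax(above))])


def scenario_modify(
    pop: PopulationModel,
    clmax_multiplier: float = 1.0,
    c50_override: float | None = None,
) -> PopulationModel:
    """Scenario copy of a population model (e.g. 4x CLmax, C50 = 10 nmol/L)."""
    if clmax_multiplier <= 0:
        raise InvalidInputError("clmax_multiplier must be > 0")
    theta = dict(pop.theta)
    theta["clmax"] = theta["clmax"] + math.log(clmax_multiplier)
    cfg = pop.config
    if c50_override is not None:
        if c50_override <= 0:
            raise InvalidInputError("c50_override must be > 0")
        cfg = replace(cfg, c50=float(c50_override))
        if "c50" in theta:
            theta["c50"] = math.log(c50_override)
    return pop.replace(theta=theta, config=cfg)


def coverage_metrics(observations: pd.DataFrame, band: PercentileBand) -> dict:
    """Coverage of observations by the outer percentile range.

    ``observations`` needs columns time_h and dv, time-matched to the
    band grid (nearest grid point within half a step). Returns the %
    within [lowest, highest] percentile, the mean observation - median
    difference, and the empirical 90% interval of those differences.
    """
    t = observations["time_h"].to_numpy(dtype=float)
    y = observations["dv"].to_numpy(dtype=float)
    idx = np.searchsorted(band.times_h, t)
    idx = np.clip(idx, 0, band.times_h.size - 1)
    left = np.clip(idx - 1, 0, band.times_h.size - 1)
    use_left = np.abs(band.times_h[left] - t) < np.abs(band.times_h[idx] - t)
    idx = np.where(use_left, left, idx)
    lo = band.percentiles[int(np.argmin(band.levels))][idx]
    hi = band.percentiles[int(np.argmax(band.levels))][idx]
    med = band.level(50.0)[idx] if 50.0 in band.levels else band.percentiles[1][idx]
    inside = (y >= lo) & (y <= hi)
    diffs = y - med
    return {
        "pct_within_pi": float(100.0 * inside.mean()),
        "mean_error": float(diffs.mean()),
        "error_ci90": (
            float(np.percentile(diffs, 5)),
            float(np.percentile(diffs, 95)),
        ),
        "n": int(y.size),
    }


def compliance(received_doses: int, n_weeks: int) -> float:
    """Received doses / scheduled weeks * 100 (%)."""
    if not 0 <= received_doses <= n_weeks:
        raise InvalidInputError("need 0 <= received_doses <= n_weeks")
    return 100.0 * received_doses / n_weeks
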