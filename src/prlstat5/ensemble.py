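"""Monte Carlo ensemble exploration of the eight model structures.

Each draw samples every free kinetic parameter and non-zero initial value of
a structure from a log-uniform distribution spanning two orders of magnitude
above and below its baseline, simulates six hours of 200 ng/mL PRL
stimulation, and classifies the total-pSTAT5 time course: coarsely by the
number of peaks, and in detail by a decision tree anchored at the published
thresholds (1% activation floor, 70% attenuation, 1-h first peak, 3-h
reactivation).  Peaks are local maxima filtered by a 20-min minimum distance
and a prominence of 0.1% of the total STAT5 pool.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.signal import find_peaks
from scipy.stats import pearsonr

from .network import (
    ConfigurationError,
    ModelStructure,
    ParameterSet,
    default_initial_values,
    default_parameters,
    free_parameter_names,
)
from .simulate import CompiledModel, compile_network, simulate, total_pstat5

__all__ = [
    "ShapeLabel",
    "TimeCourseFeatures",
    "EnsembleResult",
    "sample_parameter_sets",
    "detect_peaks",
    "compute_features",
    "classify_coarse",
    "classify_detailed",
    "run_ensemble",
    "correlate_features",
]

#: classification constants (published thresholds; the rest configurable)
WEAK_FRACTION = 0.01          # < 1% of STAT5 pool phosphorylated
ATTENUATION_FRACTION = 0.70   # trough below 70% of first peak
FIRST_PEAK_MAX_H = 1.0        # first peak must come within 1 h
SECOND_PEAK_MIN_H = 3.0       # reactivation must come after 3 h
BLOWUP_FACTOR = 3.0           # unstable positive feedback criterion
MIN_PEAK_DISTANCE_MIN = 20.0
PROMINENCE_FRACTION = 0.001   # 0.1% of the STAT5 pool
EARLY_TROUGH_H = 2.0          # minimal-attenuation sub-bins
LATE_TROUGH_H = 4.0
REACTIVATION_SMOOTH_MIN = 20.0


class ShapeLabel(str, enum.Enum):
    WEAK = "WEAK"
    NO_PEAK = "NO_PEAK"
    SINGLE_PEAK = "SINGLE_PEAK"
    MULTI_OSCILLATION = "MULTI_OSCILLATION"
    DAMPED_SECOND_PEAK = "DAMPED_SECOND_PEAK"
    UNSTABLE_POSITIVE_FB = "UNSTABLE_POSITIVE_FB"
    MINIMAL_ATTENUATION_EARLY = "MINIMAL_ATTENUATION_EARLY"
    MINIMAL_ATTENUATION_INTERMEDIATE = "MINIMAL_ATTENUATION_INTERMEDIATE"
    MINIMAL_ATTENUATION_LATE = "MINIMAL_ATTENUATION_LATE"
    WRONG_TIMING = "WRONG_TIMING"
    DESIRED = "DESIRED"


MULTI_PEAK_LABELS = frozenset(
    {
        ShapeLabel.MULTI_OSCILLATION,
        ShapeLabel.DAMPED_SECOND_PEAK,
        ShapeLabel.UNSTABLE_POSITIVE_FB,
        ShapeLabel.MINIMAL_ATTENUATION_EARLY,
        ShapeLabel.MINIMAL_ATTENUATION_INTERMEDIATE,
        ShapeLabel.MINIMAL_ATTENUATION_LATE,
        ShapeLabel.WRONG_TIMING,
        ShapeLabel.DESIRED,
    }
)


# --------------------------------------------------------------------------
# sampling


def sample_parameter_sets(
    n: int,
    structure: ModelStructure,
    seed: int | np.random.Generator,
    baseline_params: ParameterSet | None = None,
    baseline_init: Mapping[str, float] | None = None,
    decades: float = 2.0,
) -> pd.DataFrame:
    """Draw n log-uniform parameter/initial-value sets around the baseline.

    Every free parameter of the structure and every sampled (non-zero)
    initial value is drawn independently from log-uniform on
    ``[baseline/10**decades, baseline*10**decades]``.  ``deg_ratio`` is
    additionally floored at 1 (ligand-bound complexes never outlive unbound
    ones).  Columns are parameter names; initial-value columns keep their
    species names.  A fixed seed reproduces the draw matrix bit for bit.
    """
    if n < 1:
        raise ConfigurationError("need at least one draw")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    params = baseline_params if baseline_params is not None else default_parameters(structure)
    init = dict(default_initial_values(structure) if baseline_init is None else baseline_init)

    names: list[str] = []
    base: list[float] = []
    for name in free_parameter_names(structure):
        names.append(name)
        base.append(params[name])
    for sp, v in init.items():
        if v > 0:
            names.append(sp)
            base.append(v)
    base_arr = np.asarray(base, dtype=float)
    if np.any(base_arr <= 0):
        bad = [names[i] for i in np.nonzero(base_arr <= 0)[0]]
        raise ConfigurationError(f"non-positive baseline for sampled entries: {bad}")

    lo = np.log10(base_arr) - decades
    hi = np.log10(base_arr) + decades
    u = rng.random((n, base_arr.size))
    draws = 10.0 ** (lo + u * (hi - lo))
    df = pd.DataFrame(draws, columns=names)
    if "deg_ratio" in df.columns:
        df["deg_ratio"] = df["deg_ratio"].clip(lower=1.0)
    return df


def draw_to_model_inputs(
    row: Mapping[str, float],
    structure: ModelStructure,
    baseline_params: ParameterSet | None = None,
    baseline_init: Mapping[str, float] | None = None,
) -> tuple[ParameterSet, dict[str, float]]:
    """Split one sampled row into a ParameterSet and initial-value dict."""
    params = baseline_params if baseline_params is not None else default_parameters(structure)
    init = dict(default_initial_values(structure) if baseline_init is None else baseline_init)
    p_up = {k: v for k, v in row.items() if k in params}
    for sp in init:
        if sp in row:
            init[sp] = float(row[sp])
    return params.with_updates(p_up), init


# --------------------------------------------------------------------------
# peak detection and features


def detect_peaks(
    series: np.ndarray,
    dt_min: float = 1.0,
    pool: float | None = None,
    min_distance_min: float = MIN_PEAK_DISTANCE_MIN,
    prominence_fraction: float = PROMINENCE_FRACTION,
) -> tuple[np.ndarray, np.ndarray]:
    """Local maxima filtered by minimum distance and prominence.

    Returns (times_min, heights).  ``pool`` is the total STAT5 material the
    0.1% prominence threshold refers to; it defaults to the series maximum
    scale only if not given (callers in the ensemble always pass the pool).
    Ties inside a distance window keep the higher peak, then the earlier
    (scipy's priority rule).
    """
    series = np.asarray(series, dtype=float)
    if dt_min > min_distance_min:
        raise ConfigurationError("grid step must not exceed the peak distance")
    scale = float(pool) if pool is not None else float(np.max(series)) if series.size else 1.0
    distance = max(1, int(math.ceil(min_distance_min / dt_min)))
    idx, _ = find_peaks(series, distance=distance, prominence=prominence_fraction * scale)
    t = idx * dt_min
    return t, series[idx]


@dataclass
class TimeCourseFeatures:
    """The five characteristics of a pSTAT5 activation time course."""

    activation_strength: float
    negative_fb_strength: float | None = None
    positive_fb_strength: float | None = None
    time_of_attenuation_h: float | None = None
    time_of_reactivation_h: float | None = None

    def as_dict(self) -> dict[str, float | None]:
        return {
            "activation_strength": self.activation_strength,
            "negative_fb_strength": self.negative_fb_strength,
            "positive_fb_strength": self.positive_fb_strength,
            "time_of_attenuation_h": self.time_of_attenuation_h,
            "time_of_reactivation_h": self.time_of_reactivation_h,
        }


FEATURE_NAMES = (
    "activation_strength",
    "negative_fb_strength",
    "positive_fb_strength",
    "time_of_attenuation_h",
    "time_of_reactivation_h",
)


def _moving_average(x: np.ndarray, window: int) -> np.ndarray:
    if window <= 1:
        return x
    kernel = np.ones(window) / window
    pad = window // 2
    xp = np.pad(x, pad, mode="edge")
    sm = np.convolve(xp, kernel, mode="valid")
    return sm[: x.size]


def time_of_reactivation(
    series: np.ndarray,
    dt_min: float = 1.0,
    after_index: int = 0,
    smooth_min: float = REACTIVATION_SMOOTH_MIN,
) -> float | None:
    """First time (hours) the smoothed series turns from decreasing to
    increasing, at or after ``after_index``; None if it never does."""
    window = max(1, int(round(smooth_min / dt_min)) | 1)  # odd window
    sm = _moving_average(np.asarray(series, float), window)
    d = np.diff(sm)
    for j in range(max(after_index, 1), d.size):
        if d[j - 1] < 0 and d[j] > 0:
            return (j + 1) * dt_min / 60.0
    return None


def compute_features(
    series: np.ndarray,
    dt_min: float = 1.0,
    pool: float | None = None,
) -> TimeCourseFeatures:
    """Extract the five pSTAT5 characteristics from a uniform-grid series.

    ``activation_strength`` is the maximum relative to the total STAT5 pool;
    the after-first-peak features are absent (None) when there is no peak.
    """
    series = np.asarray(series, dtype=float)
    scale = float(pool) if pool is not None else (float(series.max()) or 1.0)
    act = float(series.max()) / scale
    pk_t, pk_h = detect_peaks(series, dt_min=dt_min, pool=pool)
    if pk_t.size == 0:
        return TimeCourseFeatures(activation_strength=act)
    i0 = int(round(pk_t[0] / dt_min))
    h1 = float(series[i0])
    after = series[i0 + 1:]
    neg = 1.0 - float(after.min()) / h1 if after.size else None
    pos = float(after.max()) / h1 if after.size else None
    t_att = pk_t[0] / 60.0
    t_re = time_of_reactivation(series, dt_min=dt_min, after_index=i0)
    return TimeCourseFeatures(act, neg, pos, t_att, t_re)


# --------------------------------------------------------------------------
# classification


def classify_coarse(series: np.ndarray, dt_min: float = 1.0, pool: float | None = None) -> str:
    """NO_PEAK / SINGLE_PEAK / MULTIPLE_PEAKS by peak count."""
    n = detect_peaks(series, dt_min=dt_min, pool=pool)[0].size
    return "NO_PEAK" if n == 0 else ("SINGLE_PEAK" if n == 1 else "MULTIPLE_PEAKS")


def classify_detailed(
    series: np.ndarray,
    dt_min: float = 1.0,
    pool: float | None = None,
    blowup_factor: float = BLOWUP_FACTOR,
    early_trough_h: float = EARLY_TROUGH_H,
    late_trough_h: float = LATE_TROUGH_H,
) -> ShapeLabel:
    """Decision tree assigning exactly one qualitative shape per trajectory.

    Order of checks: weak activation (< 1% of the STAT5 pool), peak count,
    more-than-two oscillations, unstable positive feedback (final value above
    ``blowup_factor`` times the first peak and still rising at 6 h), damped
    second peak, minimal attenuation (trough >= 70% of the first peak, binned
    by trough time), wrong timing (first peak > 1 h or second peak < 3 h),
    otherwise the desired experimental shape.
    """
    series = np.asarray(series, dtype=float)
    scale = float(pool) if pool is not None else (float(series.max()) or 1.0)
    if float(series.max()) < WEAK_FRACTION * scale:
        return ShapeLabel.WEAK
    pk_t, pk_h = detect_peaks(series, dt_min=dt_min, pool=pool)
    if pk_t.size == 0:
        return ShapeLabel.NO_PEAK
    if pk_t.size == 1:
        return ShapeLabel.SINGLE_PEAK
    if pk_t.size > 2:
        return ShapeLabel.MULTI_OSCILLATION
    (t1, t2), (h1, h2) = pk_t, pk_h
    i1, i2 = int(round(t1 / dt_min)), int(round(t2 / dt_min))
    still_rising = series[-1] > series[-2]
    if series[-1] > blowup_factor * h1 and still_rising:
        return ShapeLabel.UNSTABLE_POSITIVE_FB
    if h2 < h1:
        return ShapeLabel.DAMPED_SECOND_PEAK
    trough_idx = i1 + int(np.argmin(series[i1 : i2 + 1]))
    trough = series[trough_idx]
    if trough >= ATTENUATION_FRACTION * h1:
        trough_h = trough_idx * dt_min / 60.0
        if trough_h <= early_trough_h:
            return ShapeLabel.MINIMAL_ATTENUATION_EARLY
        if trough_h <= late_trough_h:
            return ShapeLabel.MINIMAL_ATTENUATION_INTERMEDIATE
        return ShapeLabel.MINIMAL_ATTENUATION_LATE
    if t1 / 60.0 > FIRST_PEAK_MAX_H or t2 / 60.0 < SECOND_PEAK_MIN_H:
        return ShapeLabel.WRONG_TIMING
    return ShapeLabel.DESIRED


# --------------------------------------------------------------------------
# ensemble driver


@dataclass
class EnsembleResult:
    """Per-draw records and tallies from a Monte Carlo ensemble run."""

    draws: pd.DataFrame  # sampled values + features + labels, per draw
    seed: int
    n_per_structure: int
    structures: list[str] = field(default_factory=list)

    @property
    def n_failed(self) -> int:
        return int((~self.draws["ok"]).sum())

    def ok_draws(self) -> pd.DataFrame:
        return self.draws[self.draws["ok"]]

    def tally(self, coarse: bool = False) -> pd.DataFrame:
        """Counts and fractions per structure and label (failures excluded)."""
        col = "coarse" if coarse else "label"
        ok = self.ok_draws()
        rows = []
        for s, grp in ok.groupby("structure", sort=False):
            total = len(grp)
            for label, cnt in grp[col].value_counts().items():
                rows.append(
                    dict(structure=s, label=label, count=int(cnt), fraction=cnt / total)
                )
        return pd.DataFrame(rows)

    def fraction(self, label: str, structure: str | None = None, coarse: bool = False) -> float:
        col = "coarse" if coarse else "label"
        ok = self.ok_draws()
        if structure is not None:
            ok = ok[ok["structure"] == structure]
        if len(ok) == 0:
            return float("nan")
        return float((ok[col] == label).mean())


def run_ensemble(
    structures: Sequence[ModelStructure] | None = None,
    n_per_structure: int = 1000,
    seed: int = 0,
    dose_ng_ml: float = 200.0,
    horizon_min: float = 360.0,
    grid_dt: float = 1.0,
    rtol: float = 1e-6,
    overrides: Mapping[str, float] | None = None,
) -> EnsembleResult:
    """Sample, simulate and classify n draws for each requested structure.

    Failed integrations are kept in the record with ``ok=False`` and excluded
    from all tallies and fractions.  The run is reproducible from ``seed``.
    ``overrides`` pins named parameters to fixed values in every draw
    (useful for ablations such as forcing the phosphorylation rate to zero).
    """
    if structures is None:
        structures = ModelStructure.enumerate()
    master = np.random.SeedSequence(seed)
    frames = []
    for struct, child in zip(structures, master.spawn(len(structures))):
        rng = np.random.default_rng(child)
        params = default_parameters(struct)
        init0 = default_initial_values(struct)
        cm = compile_network(struct)
        pool0 = None
        df = sample_parameter_sets(
            n_per_structure, struct, rng, baseline_params=params, baseline_init=init0
        )
        records = []
        for i in range(len(df)):
            row = df.iloc[i]
            p, init = draw_to_model_inputs(row, struct, params, init0)
            if overrides:
                p = p.with_updates(overrides)
            tr = simulate(
                cm, p, init=init, dose_ng_ml=dose_ng_ml,
                horizon_min=horizon_min, grid_dt=grid_dt, rtol=rtol,
            )
            pool = sum(
                init.get(k, 0.0)
                for k in ("STAT5A", "STAT5B", "STAT5A_nuc", "STAT5B_nuc")
            )
            rec = dict(structure=struct.label, draw=i, ok=bool(tr.ok))
            if tr.ok:
                series = total_pstat5(tr)
                feats = compute_features(series, dt_min=grid_dt, pool=pool)
                rec.update(feats.as_dict())
                rec["coarse"] = classify_coarse(series, dt_min=grid_dt, pool=pool)
                rec["label"] = classify_detailed(series, dt_min=grid_dt, pool=pool).value
            else:
                rec.update({k: None for k in FEATURE_NAMES})
                rec["coarse"] = None
                rec["label"] = None
            records.append(rec)
        out = pd.DataFrame(records)
        frames.append(pd.concat([out, df.add_prefix("in_")], axis=1))
    import warnings

    with warnings.catch_warnings():
        # structures differ in sampled columns; all-NA padding is intended
        warnings.simplefilter("ignore", FutureWarning)
        draws = pd.concat(frames, ignore_index=True)
    return EnsembleResult(
        draws, seed, n_per_structure, [s.label for s in structures]
    )


# --------------------------------------------------------------------------
# parameter-feature correlations


def correlate_features(
    result: EnsembleResult,
    structure: str = "abc",
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Pearson correlation of log10 sampled inputs against the five features.

    Activation strength uses all successful draws; the feedback strengths and
    attenuation time use draws with at least one peak; reactivation time uses
    draws with reactivation.  Correlations with p >= alpha are masked
    (``significant=False`` and ``r_masked=NaN``); subsets smaller than three
    draws yield NaN.
    """
    ok = result.ok_draws()
    ok = ok[ok["structure"] == structure]
    if len(ok) == 0:
        raise ConfigurationError(f"no successful draws for structure {structure}")
    input_cols = [c for c in ok.columns if c.startswith("in_")]
    subsets = {
        "activation_strength": ok,
        "negative_fb_strength": ok.dropna(subset=["negative_fb_strength"]),
        "positive_fb_strength": ok.dropna(subset=["positive_fb_strength"]),
        "time_of_attenuation_h": ok.dropna(subset=["time_of_attenuation_h"]),
        "time_of_reactivation_h": ok.dropna(subset=["time_of_reactivation_h"]),
    }
    rows = []
    for feat, sub in subsets.items():
        y = sub[feat].astype(float).to_numpy()
        for col in input_cols:
            name = col[3:]
            if len(sub) < 3:
                rows.append(dict(parameter=name, feature=feat, r=np.nan, p=np.nan,
                                 n=len(sub), significant=False))
                continue
            x = np.log10(sub[col].astype(float).to_numpy())
            if np.allclose(x, x[0]) or np.allclose(y, y[0]):
                rows.append(dict(parameter=name, feature=feat, r=np.nan, p=np.nan,
                                 n=len(sub), significant=False))
                continue
            r, p = pearsonr(x, y)
            rows.append(dict(parameter=name, feature=feat, r=float(r), p=float(p),
                             n=len(sub), significant=bool(p < alpha)))
    df = pd.DataFrame(rows)
    df["r_masked"] = np.where(df["significant"], df["r"], np.nan)
    return df
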