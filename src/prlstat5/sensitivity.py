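"""eFAST global sensitivity analysis and fit-parameter selection.

The extended Fourier Amplitude Sensitivity Test assigns each input a driving
frequency, samples the input space along space-filling search curves, and
decomposes the variance of the model output in the frequency domain.  The
first-order index Si is the fraction of output variance explained by input i
alone; the total-order index STi = 1 - SCi, where SCi is the summed index of
the complementary set (everything except input i).

A dummy input with no effect on the model provides the selection floor:
inputs whose mean STi does not beat the dummy's are considered
non-influential and excluded from calibration.  The STAT5B/AB dimerization,
import and export rates are reparameterized as multiplicative factors
relative to their STAT5A counterparts (mult8B = k8B/k8A and so on) to
deconvolute correlated pairs.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd

from .network import ConfigurationError, ModelStructure, ParameterSet

__all__ = [
    "SensitivityIndices",
    "FitParameterization",
    "MULT_FACTORS",
    "efast_sample",
    "efast_indices",
    "select_fit_parameters",
]

DUMMY = "dummy"

#: factor name -> (numerator rate, denominator rate)
MULT_FACTORS: dict[str, tuple[str, str]] = {
    "mult8B": ("k8B", "k8A"),
    "mult8AB": ("k8AB", "k8A"),
    "mult14B": ("k14B", "k14A"),
    "mult14AB": ("k14AB", "k14A"),
    "mult17B": ("k17B", "k17A"),
}


# --------------------------------------------------------------------------
# eFAST core


def _frequencies(n_inputs: int, Ns: int, M: int) -> tuple[int, np.ndarray]:
    """Driving frequency for the focus input and complementary frequencies.

    Complementary inputs stay below ``omega_max/(2M)`` so their order-M
    combination tones cannot contaminate the focus harmonics.  When few
    enough inputs are analyzed, they get distinct frequencies counting down
    from that bound (avoiding the low-order harmonic relations, e.g. 1 and
    2, that correlate inputs along a search curve); otherwise the standard
    cycled assignment is used and the residual bias is averaged out over the
    resample curves.
    """
    omega_max = (Ns - 1) // (2 * M)
    if omega_max < 1:
        raise ConfigurationError("too few samples per curve for eFAST validity")
    bound = max(1, omega_max // (4 * M))
    n_c = n_inputs - 1
    if n_c <= max(1, bound // 2):
        compl = bound - np.arange(n_c)
    else:
        compl = 1 + (np.arange(n_c) % bound)
    return omega_max, compl.astype(float)


def efast_sample(
    n_inputs: int,
    Ns: int = 257,
    M: int = 4,
    Nr: int = 5,
    seed: int | np.random.Generator = 0,
) -> np.ndarray:
    """Unit-cube eFAST design, shape (n_inputs, Nr, Ns, n_inputs).

    Axis 0 is the focus input (assigned the high frequency); for each of the
    Nr resample curves a random phase shift is drawn per input.
    """
    if Ns <= 4 * M**2:
        raise ConfigurationError(
            f"eFAST needs more than 4*M^2 = {4 * M * M} samples per curve; got {Ns}"
        )
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    s = 2.0 * np.pi * np.arange(Ns) / Ns
    omega_max, compl = _frequencies(n_inputs, Ns, M)
    X = np.empty((n_inputs, Nr, Ns, n_inputs))
    for i in range(n_inputs):
        omegas = np.empty(n_inputs)
        omegas[i] = omega_max
        others = [j for j in range(n_inputs) if j != i]
        for j, w in zip(others, compl):
            omegas[j] = w
        for r in range(Nr):
            phi = rng.uniform(0, 2 * np.pi, n_inputs)
            angles = np.outer(s, omegas) + phi  # (Ns, n_inputs)
            X[i, r] = 0.5 + np.arcsin(np.sin(angles)) / np.pi
    return X


def _spectrum_power(y: np.ndarray) -> np.ndarray:
    """Power at each positive frequency (variance contribution)."""
    Ns = y.size
    Y = np.fft.rfft(y) / Ns
    power = 2.0 * np.abs(Y) ** 2
    power[0] = 0.0
    return power


@dataclass
class SensitivityIndices:
    """First-order (Si), total-order (STi) and complementary (SCi) indices.

    ``si``/``sti`` are (n_inputs, n_outputs) arrays; ``mean_sti`` averages
    over outputs, which is the quantity compared against the dummy input.
    """

    names: list[str]
    si: np.ndarray
    sti: np.ndarray
    output_names: list[str] = field(default_factory=list)

    @property
    def sci(self) -> np.ndarray:
        return 1.0 - self.sti

    def mean_si(self) -> pd.Series:
        return pd.Series(self.si.mean(axis=1), index=self.names)

    def mean_sti(self) -> pd.Series:
        return pd.Series(self.sti.mean(axis=1), index=self.names)

    def dummy_mean_sti(self) -> float:
        if DUMMY not in self.names:
            raise ConfigurationError("indices do not include a dummy input")
        return float(self.mean_sti()[DUMMY])

    def frame(self) -> pd.DataFrame:
        rows = []
        outs = self.output_names or [f"y{k}" for k in range(self.si.shape[1])]
        for i, name in enumerate(self.names):
            for k, out in enumerate(outs):
                rows.append(dict(input=name, output=out,
                                 Si=float(self.si[i, k]), STi=float(self.sti[i, k])))
        return pd.DataFrame(rows)


def efast_indices(
    model: Callable[[np.ndarray], np.ndarray],
    names: Sequence[str],
    bounds: Mapping[str, tuple[float, float]],
    Ns: int = 257,
    M: int = 4,
    Nr: int = 5,
    seed: int = 0,
    log_scale: bool = False,
    add_dummy: bool = True,
    output_names: Sequence[str] | None = None,
) -> SensitivityIndices:
    """Compute Si and STi for each named input of a vector-valued model.

    ``model`` maps one input vector (natural units, ordered as ``names``)
    to a 1-D output vector; indices are computed per output and can be
    averaged via :meth:`SensitivityIndices.mean_sti`.  With ``log_scale``
    the unit-cube design is mapped log-uniformly between the bounds.  A
    dummy input (ignored by the model) is appended unless ``add_dummy``
    is False.
    """
    names = list(names)
    all_names = names + [DUMMY] if add_dummy else names
    n = len(all_names)
    X = efast_sample(n, Ns=Ns, M=M, Nr=Nr, seed=seed)
    lo = np.empty(n)
    hi = np.empty(n)
    default_bounds = (1.0, 10.0) if log_scale else (0.0, 1.0)  # dummy
    for j, nm in enumerate(all_names):
        lo[j], hi[j] = bounds.get(nm, default_bounds)
    if log_scale:
        lo, hi = np.log10(lo), np.log10(hi)

    omega_max = (Ns - 1) // (2 * M)
    cutoff = max(1, omega_max // 2)
    si_acc = None
    sti_acc = None
    for i in range(n):
        si_curves = []
        sti_curves = []
        for r in range(X.shape[1]):
            U = X[i, r]  # (Ns, n)
            Z = lo + U * (hi - lo)
            if log_scale:
                Z = 10.0 ** Z
            ys = np.array([np.atleast_1d(model(Z[j, : len(names)])) for j in range(Ns)],
                          dtype=float)
            si_out = np.empty(ys.shape[1])
            sti_out = np.empty(ys.shape[1])
            for k in range(ys.shape[1]):
                power = _spectrum_power(ys[:, k])
                half = (Ns - 1) // 2
                D = power[1 : half + 1].sum()
                if D <= 0:
                    si_out[k] = 0.0
                    sti_out[k] = 0.0
                    continue
                harmonics = [p * omega_max for p in range(1, M + 1) if p * omega_max <= half]
                Di = power[harmonics].sum()
                Dc = power[1 : cutoff + 1].sum()
                si_out[k] = Di / D
                sti_out[k] = 1.0 - Dc / D
            si_curves.append(si_out)
            sti_curves.append(sti_out)
        si_i = np.mean(si_curves, axis=0)
        sti_i = np.mean(sti_curves, axis=0)
        if si_acc is None:
            si_acc = np.empty((n, si_i.size))
            sti_acc = np.empty((n, si_i.size))
        si_acc[i] = si_i
        sti_acc[i] = sti_i
    return SensitivityIndices(
        all_names, si_acc, sti_acc,
        list(output_names) if output_names else [],
    )


# --------------------------------------------------------------------------
# fit parameterization


@dataclass
class FitParameterization:
    """The set of quantities adjusted during calibration.

    ``names`` are fitted quantities: kinetic rates, initial values, and the
    multiplicative factors replacing the STAT5B/AB rates.  ``baseline``
    holds their baseline values in the same (mult-) space, defining the
    center of the log-uniform prior.
    """

    names: list[str]
    baseline: dict[str, float]

    def __post_init__(self):
        missing = [n for n in self.names if n not in self.baseline]
        if missing:
            raise ConfigurationError(f"no baseline for fitted quantities: {missing}")
        bad = [n for n in self.names if self.baseline[n] <= 0]
        if bad:
            raise ConfigurationError(f"non-positive baseline for: {bad}")

    @property
    def k(self) -> int:
        return len(self.names)

    def center_log10(self) -> np.ndarray:
        return np.log10([self.baseline[n] for n in self.names])

    def to_model_values(
        self,
        theta: np.ndarray,
        params: ParameterSet,
        init: Mapping[str, float],
    ) -> tuple[ParameterSet, dict[str, float]]:
        """Map a fitted vector (natural units, mult-space) onto model inputs.

        Multiplicative factors are expanded exactly: k8B = mult8B * k8A uses
        the fitted k8A when present, else the baseline one.
        """
        values = dict(zip(self.names, np.asarray(theta, float)))
        p_up: dict[str, float] = {}
        i_up: dict[str, float] = {}
        for name, v in values.items():
            if name in MULT_FACTORS:
                continue
            if name in params:
                p_up[name] = v
            elif name in init:
                i_up[name] = v
            else:
                raise ConfigurationError(f"fitted name {name} is neither parameter nor initial")
        for fac, (num, den) in MULT_FACTORS.items():
            if fac in values:
                base_rate = p_up.get(den, params[den])
                p_up[num] = values[fac] * base_rate
        new_init = dict(init)
        new_init.update(i_up)
        return params.with_updates(p_up), new_init

    @staticmethod
    def rates_to_factors(params: Mapping[str, float]) -> dict[str, float]:
        return {fac: params[num] / params[den] for fac, (num, den) in MULT_FACTORS.items()}

    @staticmethod
    def factors_to_rates(factors: Mapping[str, float], params: Mapping[str, float]) -> dict[str, float]:
        return {
            num: factors[fac] * params[den]
            for fac, (num, den) in MULT_FACTORS.items()
            if fac in factors
        }


def select_fit_parameters(
    indices: SensitivityIndices,
    baseline_params: ParameterSet,
    baseline_init: Mapping[str, float],
    force_include: Sequence[str] = ("k30a",),
) -> FitParameterization:
    """Choose the calibration set from eFAST indices via the dummy criterion.

    Every input whose mean STi exceeds the dummy's is kept; ``force_include``
    names (k30a by default, the only handle on the positive-feedback module)
    are added regardless.  STAT5B/AB rates are replaced by their
    multiplicative factors.  Selection only depends on STi relative to the
    dummy, so it is invariant to a common positive rescaling of all indices.
    """
    mean_sti = indices.mean_sti()
    floor = indices.dummy_mean_sti()
    chosen = [n for n in indices.names if n != DUMMY and mean_sti[n] > floor]
    for name in force_include:
        if name not in chosen:
            chosen.append(name)

    replaced: list[str] = []
    factors_present: list[str] = []
    rate_to_factor = {num: fac for fac, (num, den) in MULT_FACTORS.items()}
    for n in chosen:
        if n in rate_to_factor:
            fac = rate_to_factor[n]
            if fac not in factors_present:
                factors_present.append(fac)
        elif n not in replaced:
            replaced.append(n)
    names = replaced + factors_present

    baseline: dict[str, float] = {}
    factor_base = FitParameterization.rates_to_factors(baseline_params)
    for n in names:
        if n in MULT_FACTORS:
            baseline[n] = factor_base[n]
        elif n in baseline_params:
            baseline[n] = baseline_params[n]
        elif n in baseline_init:
            baseline[n] = float(baseline_init[n])
        else:
            raise ConfigurationError(f"selected input {n} has no baseline value")
    return FitParameterization(names, baseline)
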