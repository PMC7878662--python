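"""ODE integration of the signaling network and the derived observables.

Concentrations are in nM, time in minutes.  The right-hand side is a generic
mass-action/Hill rate evaluator compiled with numba and shared by every model
structure, so tens of thousands of Monte Carlo integrations stay cheap.
Integration uses LSODA (stiff-capable, via ``scipy.integrate.odeint``).

The six observable streams mirror the experimental readouts the model is
calibrated against: pJAK2 (activated receptor:JAK2 complexes) normalized to
its 10-min value, phosphorylated STAT5A/STAT5B material normalized to their
30-min values, nuclear-to-cytosolic ratios of total STAT5A and STAT5B
material, and the Bcl-xL protein fold change over its pre-stimulus level.
Dimers count per molecule of STAT5 they contain: a homodimer carries two.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import numpy as np
from numba import njit
from scipy.integrate import odeint

from .network import (
    ConfigurationError,
    ModelStructure,
    ParameterSet,
    ReactionNetwork,
    build_network,
    default_parameters,
    initial_state,
)

__all__ = [
    "CompiledModel",
    "Trajectory",
    "ObservableSet",
    "UndefinedObservableError",
    "compile_network",
    "simulate",
    "total_pstat5",
    "total_pstat5_weights",
    "observables",
    "OBSERVATION_STREAMS",
]


class UndefinedObservableError(ValueError):
    """Raised when a normalization anchor has a zero denominator."""


_MASS, _ZERO, _HILL = 0, 1, 2


@njit(cache=True)
def _rhs(y, k, K, basal, kind, r1, r2, S, dimer_idx):
    n_rxn = kind.size
    n_sp = y.size
    D = 0.0
    for ii in range(dimer_idx.size):
        c = y[dimer_idx[ii]]
        if c > 0.0:
            D += c
    dy = np.zeros(n_sp)
    for j in range(n_rxn):
        if kind[j] == _MASS:
            c1 = y[r1[j]]
            if c1 < 0.0:
                c1 = 0.0
            v = k[j] * c1
            if r2[j] >= 0:
                c2 = y[r2[j]]
                if c2 < 0.0:
                    c2 = 0.0
                v *= c2
        elif kind[j] == _ZERO:
            v = k[j]
        else:
            v = basal[j] + k[j] * D / (K[j] + D)
        for i in range(n_sp):
            s = S[i, j]
            if s != 0.0:
                dy[i] += s * v
    return dy


@njit(cache=True)
def _rk4(y0, t_grid, substeps, k, K, basal, kind, r1, r2, S, dimer_idx):
    """Fixed-step classic Runge-Kutta on a grid; reference integrator."""
    n = t_grid.size
    out = np.empty((n, y0.size))
    out[0] = y0
    y = y0.copy()
    for m in range(1, n):
        h = (t_grid[m] - t_grid[m - 1]) / substeps
        for _ in range(substeps):
            k1 = _rhs(y, k, K, basal, kind, r1, r2, S, dimer_idx)
            k2 = _rhs(y + 0.5 * h * k1, k, K, basal, kind, r1, r2, S, dimer_idx)
            k3 = _rhs(y + 0.5 * h * k2, k, K, basal, kind, r1, r2, S, dimer_idx)
            k4 = _rhs(y + h * k3, k, K, basal, kind, r1, r2, S, dimer_idx)
            y = y + (h / 6.0) * (k1 + 2.0 * k2 + 2.0 * k3 + k4)
        out[m] = y
    return out


class CompiledModel:
    """Array representation of a :class:`ReactionNetwork` for fast integration."""

    def __init__(self, network: ReactionNetwork):
        self.network = network
        idx = network.species_index()
        n_rxn = network.n_reactions
        self.kind = np.zeros(n_rxn, dtype=np.int8)
        self.r1 = np.full(n_rxn, -1, dtype=np.int64)
        self.r2 = np.full(n_rxn, -1, dtype=np.int64)
        self.S = network.stoichiometry()
        from .network import NUCLEAR_DIMERS

        self.dimer_idx = np.array([idx[n] for n in NUCLEAR_DIMERS], dtype=np.int64)
        for j, r in enumerate(network.reactions):
            if r.kind == "mass_action":
                self.kind[j] = _MASS
                flat = []
                for sp, n in r.reactants:
                    flat.extend([idx[sp]] * n)
                if not 1 <= len(flat) <= 2:
                    raise ConfigurationError(
                        f"mass-action reaction {r.name} must have 1-2 reactant molecules"
                    )
                self.r1[j] = flat[0]
                if len(flat) == 2:
                    self.r2[j] = flat[1]
            elif r.kind == "zero_order":
                self.kind[j] = _ZERO
            elif r.kind == "hill":
                self.kind[j] = _HILL
            else:
                raise ConfigurationError(f"unknown rate-law kind {r.kind}")

    def rate_arrays(self, params: ParameterSet | Mapping[str, float]):
        n_rxn = len(self.network.reactions)
        k = np.zeros(n_rxn)
        K = np.ones(n_rxn)
        basal = np.zeros(n_rxn)
        for j, r in enumerate(self.network.reactions):
            vals = r.rate_values(params)
            k[j] = vals[0]
            if r.kind == "hill":
                K[j], basal[j] = vals[1], vals[2]
        if np.any(k < 0) or np.any(K <= 0) or np.any(basal < 0):
            raise ConfigurationError("rate constants must be non-negative (K > 0)")
        return k, K, basal

    def rhs(self, y, t, k, K, basal):
        return _rhs(y, k, K, basal, self.kind, self.r1, self.r2, self.S, self.dimer_idx)


def compile_network(network_or_structure) -> CompiledModel:
    if isinstance(network_or_structure, ReactionNetwork):
        return CompiledModel(network_or_structure)
    return CompiledModel(build_network(network_or_structure))


@dataclass
class Trajectory:
    """Raw species time courses from one integration."""

    t: np.ndarray  # minutes, strictly increasing
    y: np.ndarray  # time x species, nM
    species_names: list[str]
    structure: ModelStructure
    dose_ng_ml: float
    ok: bool = True

    def __post_init__(self):
        # negative excursions beyond solver noise are clipped to zero
        self.y = np.where(self.y < 0, np.where(self.y > -1e-9, 0.0, self.y), self.y)

    @property
    def dose_nm(self) -> float:
        from .network import NG_PER_ML_TO_NM

        return self.dose_ng_ml * NG_PER_ML_TO_NM

    def index(self, name: str) -> int:
        return self.species_names.index(name)

    def series(self, name: str) -> np.ndarray:
        return self.y[:, self.index(name)]

    def weighted(self, weights: Mapping[str, float]) -> np.ndarray:
        out = np.zeros(len(self.t))
        for name, w in weights.items():
            if name in self.species_names:
                out += w * self.series(name)
        return out

    def at(self, t_min: float) -> np.ndarray:
        """State interpolated at a time point (linear)."""
        return np.array([np.interp(t_min, self.t, self.y[:, i]) for i in range(self.y.shape[1])])


def simulate(
    model: CompiledModel | ReactionNetwork,
    params: ParameterSet | Mapping[str, float],
    init: Mapping[str, float] | None = None,
    dose_ng_ml: float = 200.0,
    horizon_min: float = 360.0,
    grid_dt: float = 1.0,
    t_eval: np.ndarray | None = None,
    rtol: float = 1e-6,
    atol: float = 1e-9,
) -> Trajectory:
    """Integrate the network ODEs with LSODA on a uniform output grid.

    A non-finite state flags the trajectory (``ok=False``); callers in the
    ensemble exclude flagged runs from denominators.
    """
    if horizon_min <= 0:
        raise ConfigurationError("horizon must be positive")
    cm = model if isinstance(model, CompiledModel) else compile_network(model)
    net = cm.network
    p = params if isinstance(params, ParameterSet) else ParameterSet(dict(params))
    if t_eval is None:
        t_eval = np.arange(0.0, horizon_min + 0.5 * grid_dt, grid_dt)
    t_eval = np.asarray(t_eval, dtype=float)
    y0 = initial_state(net, p, init=init, dose_ng_ml=dose_ng_ml)
    k, K, basal = cm.rate_arrays(p)
    args = (cm.kind, cm.r1, cm.r2, cm.S, cm.dimer_idx)

    def f(y, t):
        return _rhs(y, k, K, basal, *args)

    ok = True
    with np.errstate(all="ignore"):
        try:
            y, info = odeint(
                f, y0, t_eval, rtol=rtol, atol=atol, mxstep=50000,
                full_output=True, printmessg=False,
            )
            if info["message"] != "Integration successful." or not np.all(np.isfinite(y)):
                ok = False
        except Exception:
            y = np.full((t_eval.size, y0.size), np.nan)
            ok = False
    return Trajectory(t_eval, y, net.species_names, net.structure, dose_ng_ml, ok)


def simulate_reference_rk4(
    model: CompiledModel | ReactionNetwork,
    params,
    init=None,
    dose_ng_ml: float = 200.0,
    horizon_min: float = 360.0,
    grid_dt: float = 1.0,
    dt: float = 0.01,
) -> Trajectory:
    """Fixed-step RK4 integration of the same right-hand side (oracle)."""
    cm = model if isinstance(model, CompiledModel) else compile_network(model)
    p = params if isinstance(params, ParameterSet) else ParameterSet(dict(params))
    t_eval = np.arange(0.0, horizon_min + 0.5 * grid_dt, grid_dt)
    y0 = initial_state(cm.network, p, init=init, dose_ng_ml=dose_ng_ml)
    k, K, basal = cm.rate_arrays(p)
    substeps = max(1, int(round(grid_dt / dt)))
    y = _rk4(y0, t_eval, substeps, k, K, basal, cm.kind, cm.r1, cm.r2, cm.S, cm.dimer_idx)
    return Trajectory(t_eval, y, cm.network.species_names, cm.network.structure, dose_ng_ml)


# --------------------------------------------------------------------------
# observables


def total_pstat5_weights(network: ReactionNetwork) -> dict[str, float]:
    """Audit-able weight of each species in total phosphorylated STAT5.

    Monomeric pSTAT5 (free or PPX-bound) counts once; dimers (cytosolic or
    nuclear) carry two phosphorylated STAT5 molecules and count twice.
    """
    w: dict[str, float] = {}
    for s in network.species:
        if s.name in ("pSTAT5A", "pSTAT5B", "PPX_pSTAT5A", "PPX_pSTAT5B"):
            w[s.name] = 1.0
        elif s.name in ("AA_cyt", "BB_cyt", "AB_cyt", "AA_nuc", "BB_nuc", "AB_nuc"):
            w[s.name] = 2.0
    return w


def total_pstat5(traj: Trajectory) -> np.ndarray:
    weights = {
        "pSTAT5A": 1.0, "pSTAT5B": 1.0, "PPX_pSTAT5A": 1.0, "PPX_pSTAT5B": 1.0,
        "AA_cyt": 2.0, "BB_cyt": 2.0, "AB_cyt": 2.0,
        "AA_nuc": 2.0, "BB_nuc": 2.0, "AB_nuc": 2.0,
    }
    return traj.weighted(weights)


def stat5_pool(traj: Trajectory, isoform: str | None = None) -> float:
    """Total STAT5 material at t=0 (the pool a peak is measured against)."""
    total = 0.0
    for iso in ([isoform] if isoform else ["A", "B"]):
        total += nuclear_stat5(traj, iso)[0] + cytosolic_stat5(traj, iso)[0]
    return float(total)


def _iso_weights(isoform: str, where: str) -> dict[str, float]:
    x = isoform.upper()
    if x not in ("A", "B"):
        raise ConfigurationError("isoform must be 'A' or 'B'")
    if where == "nucleus":
        return {f"{x}{x}_nuc": 2.0, "AB_nuc": 1.0, f"STAT5{x}_nuc": 1.0}
    return {
        f"STAT5{x}": 1.0, f"pSTAT5{x}": 1.0, f"PPX_pSTAT5{x}": 1.0,
        f"{x}{x}_cyt": 2.0, "AB_cyt": 1.0,
    }


def nuclear_stat5(traj: Trajectory, isoform: str) -> np.ndarray:
    """Total nuclear STAT5A or STAT5B material (per molecule)."""
    return traj.weighted(_iso_weights(isoform, "nucleus"))


def cytosolic_stat5(traj: Trajectory, isoform: str) -> np.ndarray:
    return traj.weighted(_iso_weights(isoform, "cytosol"))


def phospho_stat5(traj: Trajectory, isoform: str) -> np.ndarray:
    """Total phosphorylated STAT5A or STAT5B material."""
    x = isoform.upper()
    return traj.weighted(
        {f"pSTAT5{x}": 1.0, f"PPX_pSTAT5{x}": 1.0,
         f"{x}{x}_cyt": 2.0, f"{x}{x}_nuc": 2.0, "AB_cyt": 1.0, "AB_nuc": 1.0}
    )


def pjak2(traj: Trajectory) -> np.ndarray:
    """Phosphorylated JAK2 proxy: activated receptor complexes (any form)."""
    return traj.weighted({"PRL_RJ2a": 1.0, "PRL_RJ2a_SOCS": 1.0, "PRL_RJ2a_SOCS2": 1.0})


OBSERVATION_STREAMS = ("pJAK2", "pSTAT5A", "pSTAT5B", "ratioA", "ratioB", "bclxl")


@dataclass
class ObservableSet:
    """The six derived observation streams on the trajectory grid."""

    t: np.ndarray
    total_pSTAT5: np.ndarray
    pJAK2_norm10: np.ndarray
    pSTAT5A_norm30: np.ndarray
    pSTAT5B_norm30: np.ndarray
    ratio_STAT5A_nc: np.ndarray
    ratio_STAT5B_nc: np.ndarray
    bclxl_fold: np.ndarray

    def stream(self, name: str) -> np.ndarray:
        mapping = {
            "pJAK2": self.pJAK2_norm10,
            "pSTAT5A": self.pSTAT5A_norm30,
            "pSTAT5B": self.pSTAT5B_norm30,
            "ratioA": self.ratio_STAT5A_nc,
            "ratioB": self.ratio_STAT5B_nc,
            "bclxl": self.bclxl_fold,
            "total_pSTAT5": self.total_pSTAT5,
        }
        return mapping[name]

    def at(self, name: str, times_min: np.ndarray) -> np.ndarray:
        return np.interp(np.asarray(times_min, float), self.t, self.stream(name))

    def frame(self):
        import pandas as pd

        rows = []
        for name in OBSERVATION_STREAMS + ("total_pSTAT5",):
            vals = self.stream(name)
            rows.append(pd.DataFrame({"stream": name, "time_min": self.t, "value": vals}))
        return pd.concat(rows, ignore_index=True)


def _anchor(t: np.ndarray, series: np.ndarray, t_anchor: float) -> float:
    if t_anchor < t[0] or t_anchor > t[-1]:
        raise UndefinedObservableError(
            f"trajectory does not cover anchor time {t_anchor} min"
        )
    return float(np.interp(t_anchor, t, series))


def observables(traj: Trajectory) -> ObservableSet:
    """Compute the six observation streams with their normalization anchors.

    Raises :class:`UndefinedObservableError` if an anchor denominator is zero
    (e.g. no activation at all at the 10- or 30-min anchor).
    """
    t = traj.t
    tot = total_pstat5(traj)
    pj = pjak2(traj)
    pa = phospho_stat5(traj, "A")
    pb = phospho_stat5(traj, "B")
    na, ca = nuclear_stat5(traj, "A"), cytosolic_stat5(traj, "A")
    nb, cb = nuclear_stat5(traj, "B"), cytosolic_stat5(traj, "B")
    bcl = traj.series("Bclxl")

    denom_pj = _anchor(t, pj, 10.0)
    denom_pa = _anchor(t, pa, 30.0)
    denom_pb = _anchor(t, pb, 30.0)
    denom_bcl = bcl[0]
    for name, d in [("pJAK2@10min", denom_pj), ("pSTAT5A@30min", denom_pa),
                    ("pSTAT5B@30min", denom_pb), ("Bclxl@0", denom_bcl)]:
        if d == 0:
            raise UndefinedObservableError(f"zero normalization anchor for {name}")
    with np.errstate(divide="ignore", invalid="ignore"):
        ra = np.where(ca > 0, na / np.where(ca > 0, ca, 1.0), np.inf)
        rb = np.where(cb > 0, nb / np.where(cb > 0, cb, 1.0), np.inf)
    return ObservableSet(
        t=t,
        total_pSTAT5=tot,
        pJAK2_norm10=pj / denom_pj,
        pSTAT5A_norm30=pa / denom_pa,
        pSTAT5B_norm30=pb / denom_pb,
        ratio_STAT5A_nc=ra,
        ratio_STAT5B_nc=rb,
        bclxl_fold=bcl / denom_bcl,
    )
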