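"""Reaction network for prolactin-receptor JAK2-STAT5 signaling in beta cells.

The model is a mass-action ODE network describing how prolactin (PRL) binding
to preformed prolactin-receptor:JAK2 complexes (RJ) activates STAT5A/B
phosphorylation, dimerization and nuclear import, attenuated by the
phosphatases SHP-2 (receptor level), PPX (cytosol) and PPN (nucleus), with
transcription of the pro-survival protein Bcl-xL as the downstream readout.
One PRL ligand bridges two RJ complexes (2:1 receptor:ligand stoichiometry).

Three regulatory modules can be toggled independently, giving eight model
structures:

* ``a`` (SOCS feedback): nuclear pSTAT5 dimers drive SOCS transcription;
  SOCS binds ligand-bound receptor complexes competitively (blocking STAT5
  phosphorylation) and targets them for degradation.
* ``b`` (receptor up-regulation): nuclear pSTAT5 dimers drive PRLR mRNA
  transcription; nascent receptor associates with JAK2 to replenish RJ.
* ``c`` (receptor internalization): ligand-bound receptor complexes degrade
  ``deg_ratio``-fold faster than unbound RJ.  This module changes rate
  constants only, never stoichiometry.

The species/reaction encoding is frozen so that the core network has exactly
24 species and 31 reactions and the full network (all modules) 32 species and
47 reactions.  Two catalytic steps are lumped to keep that count: SHP-2 and
PPN act through single catalytic mass-action reactions, and receptor-mediated
STAT5 phosphorylation uses the quasi-steady-state rate constant
``k5*k6/(k_5+k6)`` in place of an explicit receptor:STAT5 complex (so k6 = 0
still abolishes phosphorylation).  PPX:pSTAT5 complexes are explicit, with
binding rate k11 and dephosphorylating release rate k12.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from importlib import resources
from typing import Callable, Iterable, Mapping

import numpy as np
import pandas as pd

__all__ = [
    "ConfigurationError",
    "ModelStructure",
    "Species",
    "Reaction",
    "ReactionNetwork",
    "ParameterSet",
    "StructureReport",
    "NG_PER_ML_TO_NM",
    "PRL_MW_KDA",
    "build_network",
    "default_parameters",
    "default_initial_values",
    "initial_state",
    "structure_report",
]

#: prolactin molecular weight used for dose conversion (kDa)
PRL_MW_KDA = 23.0
#: 1 ng/mL of PRL in nM at 23 kDa
NG_PER_ML_TO_NM = 1000.0 / (PRL_MW_KDA * 1000.0) * 1000.0 / 1000.0  # = 1/0.023


class ConfigurationError(ValueError):
    """Raised for unknown parameter names or invalid configuration."""


# --------------------------------------------------------------------------
# model structure


@dataclass(frozen=True, order=True)
class ModelStructure:
    """Inclusion flags for the three regulatory modules (a, b, c)."""

    socs_feedback: bool = False
    receptor_upregulation: bool = False
    receptor_internalization: bool = False

    @property
    def bits(self) -> int:
        """Integer id with bit order (a, b, c): a is the high bit."""
        return (
            (self.socs_feedback << 2)
            | (self.receptor_upregulation << 1)
            | int(self.receptor_internalization)
        )

    @property
    def label(self) -> str:
        """Compact label such as ``'ab-'`` or ``'---'`` (order a, b, c)."""
        return (
            ("a" if self.socs_feedback else "-")
            + ("b" if self.receptor_upregulation else "-")
            + ("c" if self.receptor_internalization else "-")
        )

    @classmethod
    def from_label(cls, label: str) -> "ModelStructure":
        """Parse labels like ``'abc'``, ``'ab-'``, ``'-b-'``, ``'none'``."""
        s = label.strip().lower()
        if s in {"none", "---", ""}:
            return cls()
        allowed = set("abc-")
        if not set(s) <= allowed:
            raise ConfigurationError(f"unrecognized structure label: {label!r}")
        return cls("a" in s, "b" in s, "c" in s)

    @classmethod
    def enumerate(cls) -> list["ModelStructure"]:
        """All eight structures, in the canonical row order used throughout:
        ---, a--, -b-, --c, ab-, a-c, -bc, abc (none, singles, pairs, full).
        """
        singles = [(True, False, False), (False, True, False), (False, False, True)]
        pairs = [(True, True, False), (True, False, True), (False, True, True)]
        rows = [(False, False, False)] + singles + pairs + [(True, True, True)]
        return [cls(*flags) for flags in rows]


CORE = ModelStructure()
FULL = ModelStructure(True, True, True)


# --------------------------------------------------------------------------
# species and reactions


@dataclass(frozen=True)
class Species:
    name: str
    compartment: str  # 'extracellular' | 'cytosol' | 'nucleus'


@dataclass(frozen=True)
class Reaction:
    """A single reaction with a rate law.

    ``kind`` is one of:

    * ``mass_action`` -- rate = k * prod(reactant concentrations)
    * ``zero_order``  -- rate = k (constant synthesis)
    * ``hill``        -- rate = basal + V*D/(K+D), D = total nuclear pSTAT5
      dimer concentration (saturable transcription)

    ``rate_values(params)`` returns the numeric rate-law constants:
    ``(k,)`` for mass_action/zero_order and ``(V, K, basal)`` for hill.
    """

    name: str
    reactants: tuple[tuple[str, int], ...]
    products: tuple[tuple[str, int], ...]
    kind: str
    module: str  # 'core' | 'socs' | 'upregulation'
    rate_expr: str
    _rate_fn: Callable[[Mapping[str, float]], tuple] = field(repr=False)

    def rate_values(self, params: Mapping[str, float]) -> tuple:
        return self._rate_fn(params)

    def equation(self) -> str:
        def side(terms):
            if not terms:
                return "0"
            return " + ".join(f"{n} {s}" if n > 1 else s for s, n in terms)

        return f"{side(self.reactants)} -> {side(self.products)}"


NUCLEAR_DIMERS = ("AA_nuc", "BB_nuc", "AB_nuc")


def _ma(name, reactants, products, expr, module="core"):
    """Mass-action reaction whose rate constant is a parameter expression."""
    if "*" in expr or "/" in expr:
        names = [t for t in expr.replace("(", " ").replace(")", " ")
                 .replace("*", " ").replace("/", " ").replace("+", " ").split()]

        def fn(p, _names=tuple(names), _expr=expr):
            local = {n: p[n] for n in _names}
            return (eval(_expr, {"__builtins__": {}}, local),)
    else:
        def fn(p, _n=expr):
            return (p[_n],)
    return Reaction(name, tuple(reactants), tuple(products), "mass_action", module, expr, fn)


def _zero(name, products, expr, module="core"):
    def fn(p, _n=expr):
        return (p[_n],)
    return Reaction(name, (), tuple(products), "zero_order", module, expr, fn)


def _hill(name, products, v, K, basal, module="core"):
    def fn(p, _v=v, _K=K, _b=basal):
        return (p[_v], p[_K], 0.0 if _b is None else p[_b])
    expr = f"{basal} + {v}*D/({K}+D)" if basal else f"{v}*D/({K}+D)"
    return Reaction(name, (), tuple(products), "hill", module, expr, fn)


@dataclass
class ReactionNetwork:
    species: list[Species]
    reactions: list[Reaction]
    structure: ModelStructure

    def __post_init__(self):
        names = {s.name for s in self.species}
        for r in self.reactions:
            for sp, _ in itertools.chain(r.reactants, r.products):
                if sp not in names:
                    raise ConfigurationError(
                        f"reaction {r.name} references unknown species {sp}"
                    )

    @property
    def n_species(self) -> int:
        return len(self.species)

    @property
    def n_reactions(self) -> int:
        return len(self.reactions)

    @property
    def species_names(self) -> list[str]:
        return [s.name for s in self.species]

    def species_index(self) -> dict[str, int]:
        return {s.name: i for i, s in enumerate(self.species)}

    def stoichiometry(self) -> np.ndarray:
        """Net stoichiometry matrix, species x reactions."""
        idx = self.species_index()
        S = np.zeros((self.n_species, self.n_reactions))
        for j, r in enumerate(self.reactions):
            for sp, n in r.reactants:
                S[idx[sp], j] -= n
            for sp, n in r.products:
                S[idx[sp], j] += n
        return S

    def to_frame(self) -> pd.DataFrame:
        """Human-readable reaction listing, exportable as CSV."""
        rows = []
        for j, r in enumerate(self.reactions):
            rows.append(
                dict(index=j, name=r.name, reaction=r.equation(), kind=r.kind,
                     module=r.module, rate=r.rate_expr)
            )
        return pd.DataFrame(rows)

    def species_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [dict(name=s.name, compartment=s.compartment) for s in self.species]
        )


# --------------------------------------------------------------------------
# parameters


@dataclass
class ParameterSet:
    """Named kinetic parameters (nM, min) with provenance metadata.

    Behaves like a read-only mapping; ``with_updates`` returns a modified
    copy and rejects unknown names.
    """

    values: dict[str, float]
    meta: pd.DataFrame | None = None

    def __getitem__(self, name: str) -> float:
        return self.values[name]

    def __contains__(self, name: str) -> bool:
        return name in self.values

    def keys(self):
        return self.values.keys()

    def items(self):
        return self.values.items()

    def with_updates(self, updates: Mapping[str, float] | None = None, **kw) -> "ParameterSet":
        merged = dict(updates or {})
        merged.update(kw)
        unknown = set(merged) - set(self.values)
        if unknown:
            raise ConfigurationError(f"unknown parameter name(s): {sorted(unknown)}")
        vals = dict(self.values)
        vals.update({k: float(v) for k, v in merged.items()})
        return ParameterSet(vals, self.meta)

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame({"name": list(self.values), "value": list(self.values.values())})
        if self.meta is not None:
            df = df.merge(self.meta.drop(columns=["value"]), on="name", how="left")
        return df


def _load_table(fname: str) -> pd.DataFrame:
    with resources.files("prlstat5.data").joinpath(fname).open() as fh:
        return pd.read_csv(fh)


_MODULE_OF_STRUCTURE = {
    "core": lambda s: True,
    "socs": lambda s: s.socs_feedback,
    "upregulation": lambda s: s.receptor_upregulation,
    "internalization": lambda s: s.receptor_internalization,
}


def default_parameters(structure: ModelStructure = CORE) -> ParameterSet:
    """Baseline parameter table for a structure.

    Parameters of excluded modules are retained in the table (so the table
    schema is structure-independent) but ``deg_ratio`` is forced to 1 when
    receptor internalization is off, and module parameters are only sampled
    or fitted when their module is active.
    """
    df = _load_table("parameters.csv")
    vals = dict(zip(df["name"], df["value"].astype(float)))
    if not structure.receptor_internalization:
        vals["deg_ratio"] = 1.0
    return ParameterSet(vals, df)


def default_initial_values(structure: ModelStructure = CORE) -> dict[str, float]:
    """Baseline non-zero initial concentrations (nM), keyed by species name."""
    df = _load_table("initial_values.csv")
    return dict(zip(df["species"], df["value"].astype(float)))


def free_parameter_names(structure: ModelStructure) -> list[str]:
    """Parameters sampled/fit for a structure: all rates of active modules."""
    df = _load_table("parameters.csv")
    keep = []
    for name, module in zip(df["name"], df["module"]):
        if _MODULE_OF_STRUCTURE[module](structure):
            keep.append(name)
    return keep


# --------------------------------------------------------------------------
# network assembly


def _core_species() -> list[Species]:
    ext = ["PRL"]
    cyt = [
        "RJ", "PRL_RJ", "PRL_RJ2", "PRL_RJ2a", "SHP2",
        "STAT5A", "STAT5B", "pSTAT5A", "pSTAT5B",
        "AA_cyt", "BB_cyt", "AB_cyt",
        "PPX", "PPX_pSTAT5A", "PPX_pSTAT5B",
        "mBclxl", "Bclxl",
    ]
    nuc = ["AA_nuc", "BB_nuc", "AB_nuc", "PPN", "STAT5A_nuc", "STAT5B_nuc"]
    return (
        [Species(n, "extracellular") for n in ext]
        + [Species(n, "cytosol") for n in cyt]
        + [Species(n, "nucleus") for n in nuc]
    )


def build_network(structure: ModelStructure = CORE) -> ReactionNetwork:
    """Assemble the reaction network for one of the eight model structures."""
    species = _core_species()
    rxns: list[Reaction] = []

    bound_deg = "kdeg_RJ*deg_ratio" if structure.receptor_internalization else "kdeg_RJ"
    phospho = "k5*k6/(k_5+k6)"  # QSSA lumping of docking/release

    rxns += [
        _ma("ligand_binding", [("PRL", 1), ("RJ", 1)], [("PRL_RJ", 1)], "k2"),
        _ma("receptor_dimerization", [("PRL_RJ", 1), ("RJ", 1)], [("PRL_RJ2", 1)], "k3"),
        _ma("receptor_undimerization", [("PRL_RJ2", 1)], [("PRL_RJ", 1), ("RJ", 1)], "k_3"),
        _ma("receptor_activation", [("PRL_RJ2", 1)], [("PRL_RJ2a", 1)], "k4"),
        _ma("shp2_dephosphorylation", [("PRL_RJ2a", 1), ("SHP2", 1)],
            [("PRL_RJ2", 1), ("SHP2", 1)], "k7"),
        _ma("stat5a_phosphorylation", [("PRL_RJ2a", 1), ("STAT5A", 1)],
            [("PRL_RJ2a", 1), ("pSTAT5A", 1)], phospho),
        _ma("stat5b_phosphorylation", [("PRL_RJ2a", 1), ("STAT5B", 1)],
            [("PRL_RJ2a", 1), ("pSTAT5B", 1)], phospho),
        _ma("dimerization_AA", [("pSTAT5A", 2)], [("AA_cyt", 1)], "k8A"),
        _ma("dimerization_BB", [("pSTAT5B", 2)], [("BB_cyt", 1)], "k8B"),
        _ma("dimerization_AB", [("pSTAT5A", 1), ("pSTAT5B", 1)], [("AB_cyt", 1)], "k8AB"),
        _ma("import_AA", [("AA_cyt", 1)], [("AA_nuc", 1)], "k14A"),
        _ma("import_BB", [("BB_cyt", 1)], [("BB_nuc", 1)], "k14B"),
        _ma("import_AB", [("AB_cyt", 1)], [("AB_nuc", 1)], "k14AB"),
        _ma("ppn_dephosphorylation_AA", [("AA_nuc", 1), ("PPN", 1)],
            [("STAT5A_nuc", 2), ("PPN", 1)], "k16"),
        _ma("ppn_dephosphorylation_BB", [("BB_nuc", 1), ("PPN", 1)],
            [("STAT5B_nuc", 2), ("PPN", 1)], "k16"),
        _ma("ppn_dephosphorylation_AB", [("AB_nuc", 1), ("PPN", 1)],
            [("STAT5A_nuc", 1), ("STAT5B_nuc", 1), ("PPN", 1)], "k16"),
        _ma("export_STAT5A", [("STAT5A_nuc", 1)], [("STAT5A", 1)], "k17A"),
        _ma("export_STAT5B", [("STAT5B_nuc", 1)], [("STAT5B", 1)], "k17B"),
        _ma("ppx_binding_A", [("pSTAT5A", 1), ("PPX", 1)], [("PPX_pSTAT5A", 1)], "k11"),
        _ma("ppx_binding_B", [("pSTAT5B", 1), ("PPX", 1)], [("PPX_pSTAT5B", 1)], "k11"),
        _ma("ppx_dephosphorylation_A", [("PPX_pSTAT5A", 1)], [("STAT5A", 1), ("PPX", 1)], "k12"),
        _ma("ppx_dephosphorylation_B", [("PPX_pSTAT5B", 1)], [("STAT5B", 1), ("PPX", 1)], "k12"),
        _zero("rj_synthesis", [("RJ", 1)], "k1"),
        _ma("rj_degradation", [("RJ", 1)], [], "kdeg_RJ"),
        _ma("prl_degradation", [("PRL", 1)], [], "kdeg_PRL"),
        _ma("bound_receptor_degradation", [("PRL_RJ2", 1)], [], bound_deg),
        _ma("active_receptor_degradation", [("PRL_RJ2a", 1)], [], bound_deg),
        _hill("bclxl_transcription", [("mBclxl", 1)], "v_bcl", "K_bcl", "a0_bcl"),
        _ma("bclxl_mrna_degradation", [("mBclxl", 1)], [], "kdeg_mbcl"),
        _ma("bclxl_translation", [("mBclxl", 1)], [("mBclxl", 1), ("Bclxl", 1)], "ktl_bcl"),
        _ma("bclxl_degradation", [("Bclxl", 1)], [], "kdeg_bcl"),
    ]

    if structure.socs_feedback:
        species += [
            Species("mSOCS", "cytosol"), Species("SOCS", "cytosol"),
            Species("PRL_RJ_SOCS", "cytosol"), Species("PRL_RJ2_SOCS", "cytosol"),
            Species("PRL_RJ2a_SOCS", "cytosol"), Species("PRL_RJ2a_SOCS2", "cytosol"),
        ]
        m = "socs"
        rxns += [
            _hill("socs_transcription", [("mSOCS", 1)], "v_socs", "K_socs", None, m),
            _ma("socs_mrna_degradation", [("mSOCS", 1)], [], "kdeg_msocs", m),
            _ma("socs_translation", [("mSOCS", 1)], [("mSOCS", 1), ("SOCS", 1)], "ktl_socs", m),
            _ma("socs_degradation", [("SOCS", 1)], [], "kdeg_socs", m),
            _ma("socs_binding_prlrj", [("PRL_RJ", 1), ("SOCS", 1)], [("PRL_RJ_SOCS", 1)],
                "ksocs_on", m),
            _ma("socs_binding_prlrj2", [("PRL_RJ2", 1), ("SOCS", 1)], [("PRL_RJ2_SOCS", 1)],
                "ksocs_on", m),
            _ma("socs_binding_active", [("PRL_RJ2a", 1), ("SOCS", 1)], [("PRL_RJ2a_SOCS", 1)],
                "ksocs_on", m),
            _ma("socs_binding_active2", [("PRL_RJ2a_SOCS", 1), ("SOCS", 1)],
                [("PRL_RJ2a_SOCS2", 1)], "ksocs_on", m),
            _ma("socs_complex_degradation_1", [("PRL_RJ_SOCS", 1)], [], "kdeg_socsr", m),
            _ma("socs_complex_degradation_2", [("PRL_RJ2_SOCS", 1)], [], "kdeg_socsr", m),
            _ma("socs_complex_degradation_3", [("PRL_RJ2a_SOCS", 1)], [], "kdeg_socsr", m),
            _ma("socs_complex_degradation_4", [("PRL_RJ2a_SOCS2", 1)], [], "kdeg_socsr", m),
        ]

    if structure.receptor_upregulation:
        species += [Species("mPRLR", "cytosol"), Species("PRLR", "cytosol")]
        m = "upregulation"
        rxns += [
            _hill("prlr_transcription", [("mPRLR", 1)], "k30a", "K30", None, m),
            _ma("prlr_mrna_degradation", [("mPRLR", 1)], [], "kdeg_mprlr", m),
            _ma("prlr_translation", [("mPRLR", 1)], [("mPRLR", 1), ("PRLR", 1)], "ktl_prlr", m),
            _ma("prlr_jak2_association", [("PRLR", 1)], [("RJ", 1)], "kassoc_prlr", m),
        ]

    return ReactionNetwork(species, rxns, structure)


def initial_state(
    network: ReactionNetwork,
    params: ParameterSet,
    init: Mapping[str, float] | None = None,
    dose_ng_ml: float = 200.0,
) -> np.ndarray:
    """Initial concentration vector (nM) for a simulation.

    Free STAT5 starts mostly cytosolic with a basal nuclear pool; Bcl-xL mRNA
    and protein start at the pre-stimulus steady state implied by the basal
    transcription rate, so that the fold change is 1 at t = 0.
    """
    if dose_ng_ml < 0:
        raise ConfigurationError("dose must be non-negative")
    init = dict(default_initial_values(network.structure) if init is None else init)
    y0 = np.zeros(network.n_species)
    idx = network.species_index()
    for name, value in init.items():
        if name not in idx:
            raise ConfigurationError(f"unknown species in initial values: {name}")
        if value < 0:
            raise ConfigurationError(f"negative initial value for {name}")
        y0[idx[name]] = value
    y0[idx["PRL"]] = dose_ng_ml * NG_PER_ML_TO_NM
    mbcl0 = params["a0_bcl"] / params["kdeg_mbcl"]
    y0[idx["mBclxl"]] = mbcl0
    y0[idx["Bclxl"]] = params["ktl_bcl"] * mbcl0 / params["kdeg_bcl"]
    return y0


# --------------------------------------------------------------------------
# reporting


@dataclass
class StructureReport:
    structure: ModelStructure
    n_species: int
    n_reactions: int
    reactions_per_module: dict[str, int]
    listing: pd.DataFrame

    def __str__(self) -> str:
        mods = ", ".join(f"{k}: {v}" for k, v in self.reactions_per_module.items())
        return (
            f"structure {self.structure.label}: {self.n_species} species, "
            f"{self.n_reactions} reactions ({mods})"
        )


def structure_report(network: ReactionNetwork) -> StructureReport:
    per_module: dict[str, int] = {}
    for r in network.reactions:
        per_module[r.module] = per_module.get(r.module, 0) + 1
    return StructureReport(
        network.structure, network.n_species, network.n_reactions,
        per_module, network.to_frame(),
    )
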