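"""Mass-action ODE model of LPS-stimulated TLR4 signalling.

The model tracks molecule counts per cell of the receptor-proximal species
(CD14, MD2, TLR4 and the bridging adaptors TRAM and MAL), the
adaptor/kinase cascade (TRIF, MyD88, RP1, IRAK1/4, TRAF6, TAK1, the IKK
complex) including the preformed complexes carried with non-zero initial
abundance (IRAK4_MyD88, RP1_TRIF, IkB_NFkB, IRAK1_IRAK4_MyD88,
RP1_TRIF_TRAF6), and the NF-kB module: IKK-mediated degradation of
IkB-alpha releases NF-kB, which drives TNF production and resynthesizes
IkB-alpha (the negative feedback that re-sequesters NF-kB).

Topology choices that matter:

* MAL competes with TRAM for the activated receptor and the MAL-bound
  receptor is non-signalling, giving MAL a net inhibitory (negative
  sensitivity) effect on the TNF peak;
* signalling is terminated by first-order receptor internalization and
  first-order decay of every activated kinase species, which together with
  the IkB feedback produce a single transient TNF peak;
* the IkB-alpha resynthesis feedback is NF-kB-induced but promoter-mediated:
  NF-kB occupies a small fixed pool of IkB gene copies, so the resynthesis
  flux saturates at high NF-kB.  Large released NF-kB pools therefore
  outlast the fixed resequestration capacity, and stronger stimulation
  scenarios give longer (not just taller) TNF responses;
* TNF is a terminal synthesized readout with first-order decay.

All reactions are elementary mass action.  Rate constants are a documented,
version-pinned default set chosen to give a single transient peak under the
default LPS dose; an externally parameterized model can be loaded from the
same config schema (YAML/JSON) in place of the default.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml
from scipy.integrate import solve_ivp
from scipy.optimize import brentq

__all__ = [
    "Reaction", "PathwayModel", "TimeCourse", "PeakMetrics",
    "build_default_network", "simulate", "peak_metrics",
    "DEFAULT_BASE_CONCENTRATIONS",
]

#: Oocyte-presence (base) initial abundances, molecules per cell.
DEFAULT_BASE_CONCENTRATIONS: dict[str, float] = {
    "CD14": 10000, "MD2": 10000, "TLR4": 10000, "TRAM": 10000, "MAL": 10000,
    "TRIF": 285, "MyD88": 285, "RP1": 285, "IRAK1": 1100, "IRAK4": 285,
    "TRAF6": 1100, "TAK1": 10000, "Ikk_Complex": 10000, "IkB-alpha": 31.6,
    "NFkB": 31.6, "IRAK4_MyD88": 812, "RP1_TRIF": 812, "IkB_NFkB": 9970,
    "IRAK1_IRAK4_MyD88": 8900, "RP1_TRIF_TRAF6": 8900,
}


@dataclass(frozen=True)
class Reaction:
    """Elementary mass-action reaction with integer stoichiometries."""
    reactants: tuple[tuple[str, int], ...]
    products: tuple[tuple[str, int], ...]
    rate_constant: float
    name: str = ""

    def __post_init__(self) -> None:
        if self.rate_constant < 0:
            raise ValueError("rate constant must be >= 0")


def _rx(reactants: Sequence[str], products: Sequence[str], k: float,
        name: str = "") -> Reaction:
    def pack(ids):
        counts: dict[str, int] = {}
        for s in ids:
            counts[s] = counts.get(s, 0) + 1
        return tuple(sorted(counts.items()))
    return Reaction(pack(reactants), pack(products), k, name)


@dataclass
class PathwayModel:
    """Species, reactions and stimulus of a mass-action network."""

    species: list[str]
    initial: dict[str, float]
    reactions: list[Reaction]
    stimulus_species: str = "LPS"
    stimulus_dose: float = 1000.0
    readout: str = "TNF"

    def __post_init__(self) -> None:
        known = set(self.species)
        if self.readout not in known:
            raise ValueError(f"readout {self.readout!r} not a model species")
        for r in self.reactions:
            for s, _ in r.reactants + r.products:
                if s not in known:
                    raise ValueError(f"reaction {r.name!r} uses unknown species {s!r}")
        for s, c in self.initial.items():
            if c < 0:
                raise ValueError(f"negative initial concentration for {s!r}")

    def initial_vector(self) -> np.ndarray:
        x0 = np.array([self.initial.get(s, 0.0) for s in self.species])
        idx = self.species.index(self.stimulus_species)
        x0[idx] = self.stimulus_dose
        return x0

    # --- config round-trip -------------------------------------------------
    def to_config(self) -> dict:
        return {
            "species": {s: float(self.initial.get(s, 0.0)) for s in self.species},
            "reactions": [
                {
                    "name": r.name,
                    "reactants": {s: n for s, n in r.reactants},
                    "products": {s: n for s, n in r.products},
                    "rate_constant": r.rate_constant,
                }
                for r in self.reactions
            ],
            "stimulus": {"species": self.stimulus_species, "dose": self.stimulus_dose},
            "readout": self.readout,
        }

    @classmethod
    def from_config(cls, cfg: Mapping) -> "PathwayModel":
        reactions = [
            Reaction(
                tuple(sorted((s, int(n)) for s, n in r["reactants"].items())),
                tuple(sorted((s, int(n)) for s, n in r["products"].items())),
                float(r["rate_constant"]),
                r.get("name", ""),
            )
            for r in cfg["reactions"]
        ]
        return cls(
            species=list(cfg["species"]),
            initial={s: float(c) for s, c in cfg["species"].items()},
            reactions=reactions,
            stimulus_species=cfg["stimulus"]["species"],
            stimulus_dose=float(cfg["stimulus"]["dose"]),
            readout=cfg["readout"],
        )

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_config(), fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "PathwayModel":
        with open(path) as fh:
            return cls.from_config(yaml.safe_load(fh))


@dataclass
class TimeCourse:
    """Dense trajectories on a strictly increasing time grid (minutes)."""
    time: np.ndarray
    concentrations: pd.DataFrame  # columns: species

    def readout(self, species: str) -> np.ndarray:
        return self.concentrations[species].to_numpy()

    def to_csv(self, path) -> None:
        out = self.concentrations.copy()
        out.insert(0, "time_min", self.time)
        out.to_csv(path, index=False)


@dataclass
class PeakMetrics:
    peak_height: float
    time_to_peak: float
    fwhm: float | None
    non_transient: bool = False  # peak sits on the horizon boundary


# Version-pinned default rate constants (per-minute; bimolecular constants
# per molecule per minute).  Chosen so the base scenario yields one
# transient TNF peak within a 360-minute horizon.
DEFAULT_RATE_CONSTANTS: dict[str, float] = {
    "lps_cd14_bind": 1e-4,
    "cd14_md2_bind": 1e-4,
    "md2_tlr4_bind": 1e-4,
    "tram_engage": 1e-4,
    "mal_engage": 1e-4,
    "receptor_internalize": 0.02,
    "irak4_myd88_assemble": 1e-6,
    "irak1_join": 1e-6,
    "irak1_activate": 1e-5,
    "irak1_traf6": 1e-5,
    "rp1_trif_assemble": 1e-6,
    "traf6_join": 1e-6,
    "trif_traf6_activate": 1e-5,
    "tak1_activate": 1e-5,
    "ikk_activate": 1e-5,
    "ikb_nfkb_degrade": 1e-4,
    "nfkb_activate": 1e-4,
    "ikb_free_degrade": 1e-4,
    "tnf_synthesis": 1.0,
    "ikb_gene_on": 1e-3,
    "ikb_gene_off": 0.1,
    "ikb_synthesis": 200.0,
    "nfkb_resequester": 1e-4,
    "tnf_decay": 0.05,
    "irak1_act_decay": 0.05,
    "traf6_act_decay": 0.05,
    "tak1_act_decay": 0.05,
    "ikk_act_decay": 0.05,
}

#: Copies of the IkB-alpha gene available for NF-kB binding.
IKB_GENE_COPIES = 2.0


def build_default_network(scenario_table: pd.DataFrame | None = None,
                          scenario: str = "base",
                          rate_constants: Mapping[str, float] | None = None,
                          lps_dose: float = 1000.0) -> PathwayModel:
    """Assemble the default TLR4 network with scenario initial conditions.

    ``scenario`` is one of ``base``, ``min_resp``, ``avg_resp``,
    ``max_resp``; for the non-base scenarios initial abundances come from
    the corresponding concentration column of ``scenario_table`` (a table
    built by :mod:`tlr4sim.scenarios` or the packaged reference fixture).
    """
    k = dict(DEFAULT_RATE_CONSTANTS)
    if rate_constants:
        k.update(rate_constants)

    if scenario == "base":
        initial = dict(DEFAULT_BASE_CONCENTRATIONS)
        if scenario_table is not None:
            initial.update({s: float(b) for s, b in
                            zip(scenario_table["species"], scenario_table["base_conc"])})
    elif scenario in ("min_resp", "avg_resp", "max_resp"):
        if scenario_table is None:
            raise ValueError(f"scenario {scenario!r} needs a scenario table")
        col = f"c_{scenario}"
        initial = dict(DEFAULT_BASE_CONCENTRATIONS)
        initial.update({s: float(c) for s, c in
                        zip(scenario_table["species"], scenario_table[col])})
    else:
        raise ValueError(f"unknown scenario {scenario!r}")

    missing = [s for s in DEFAULT_BASE_CONCENTRATIONS if s not in initial]
    if missing:
        raise ValueError(f"missing species {missing}")

    intermediates = [
        "LPS", "LPS_CD14", "LPS_CD14_MD2", "R_act", "R_sig", "R_seq",
        "R_inact", "IRAK1_act", "TRAF6_act", "TAK1_act", "IKK_act",
        "NFkB_act", "IKBA_GENE", "IKBA_GENE_ON", "TNF",
    ]
    species = list(DEFAULT_BASE_CONCENTRATIONS) + intermediates
    for s in intermediates:
        initial.setdefault(s, 0.0)
    initial["IKBA_GENE"] = IKB_GENE_COPIES

    reactions = [
        # receptor assembly and branch choice
        _rx(["LPS", "CD14"], ["LPS_CD14"], k["lps_cd14_bind"], "lps_cd14_bind"),
        _rx(["LPS_CD14", "MD2"], ["LPS_CD14_MD2"], k["cd14_md2_bind"], "cd14_md2_bind"),
        _rx(["LPS_CD14_MD2", "TLR4"], ["R_act"], k["md2_tlr4_bind"], "md2_tlr4_bind"),
        _rx(["R_act", "TRAM"], ["R_sig"], k["tram_engage"], "tram_engage"),
        # MAL sequesters the activated receptor into a non-signalling state
        _rx(["R_act", "MAL"], ["R_seq"], k["mal_engage"], "mal_engage"),
        _rx(["R_sig"], ["R_inact"], k["receptor_internalize"], "receptor_internalize"),
        # MyD88-dependent branch
        _rx(["IRAK4", "MyD88"], ["IRAK4_MyD88"], k["irak4_myd88_assemble"],
            "irak4_myd88_assemble"),
        _rx(["IRAK4_MyD88", "IRAK1"], ["IRAK1_IRAK4_MyD88"], k["irak1_join"],
            "irak1_join"),
        _rx(["R_sig", "IRAK1_IRAK4_MyD88"], ["R_sig", "IRAK1_act"],
            k["irak1_activate"], "irak1_activate"),
        _rx(["IRAK1_act", "TRAF6"], ["IRAK1_act", "TRAF6_act"],
            k["irak1_traf6"], "irak1_traf6"),
        # TRIF-dependent branch
        _rx(["RP1", "TRIF"], ["RP1_TRIF"], k["rp1_trif_assemble"], "rp1_trif_assemble"),
        _rx(["RP1_TRIF", "TRAF6"], ["RP1_TRIF_TRAF6"], k["traf6_join"], "traf6_join"),
        _rx(["R_sig", "RP1_TRIF_TRAF6"], ["R_sig", "TRAF6_act"],
            k["trif_traf6_activate"], "trif_traf6_activate"),
        # core kinase cascade to NF-kB
        _rx(["TRAF6_act", "TAK1"], ["TRAF6_act", "TAK1_act"], k["tak1_activate"],
            "tak1_activate"),
        _rx(["TAK1_act", "Ikk_Complex"], ["TAK1_act", "IKK_act"], k["ikk_activate"],
            "ikk_activate"),
        # IKK releases NF-kB from the inhibited complex and activates the
        # free cytoplasmic pool; only activated NF-kB transcribes
        _rx(["IKK_act", "IkB_NFkB"], ["IKK_act", "NFkB_act"],
            k["ikb_nfkb_degrade"], "ikb_nfkb_degrade"),
        _rx(["IKK_act", "NFkB"], ["IKK_act", "NFkB_act"],
            k["nfkb_activate"], "nfkb_activate"),
        _rx(["IKK_act", "IkB-alpha"], ["IKK_act"], k["ikb_free_degrade"],
            "ikb_free_degrade"),
        # readout and negative feedback (promoter-mediated IkB resynthesis)
        _rx(["NFkB_act"], ["NFkB_act", "TNF"], k["tnf_synthesis"], "tnf_synthesis"),
        _rx(["NFkB_act", "IKBA_GENE"], ["IKBA_GENE_ON"], k["ikb_gene_on"],
            "ikb_gene_on"),
        _rx(["IKBA_GENE_ON"], ["IKBA_GENE", "NFkB_act"], k["ikb_gene_off"],
            "ikb_gene_off"),
        _rx(["IKBA_GENE_ON"], ["IKBA_GENE_ON", "IkB-alpha"], k["ikb_synthesis"],
            "ikb_synthesis"),
        _rx(["IkB-alpha", "NFkB_act"], ["IkB_NFkB"], k["nfkb_resequester"],
            "nfkb_resequester"),
        _rx(["TNF"], [], k["tnf_decay"], "tnf_decay"),
        # signal termination
        _rx(["IRAK1_act"], [], k["irak1_act_decay"], "irak1_act_decay"),
        _rx(["TRAF6_act"], [], k["traf6_act_decay"], "traf6_act_decay"),
        _rx(["TAK1_act"], [], k["tak1_act_decay"], "tak1_act_decay"),
        _rx(["IKK_act"], [], k["ikk_act_decay"], "ikk_act_decay"),
    ]

    return PathwayModel(species=species, initial=initial, reactions=reactions,
                        stimulus_dose=lps_dose)


def _stoichiometry(model: PathwayModel):
    index = {s: i for i, s in enumerate(model.species)}
    n_sp, n_rx = len(model.species), len(model.reactions)
    reactant = np.zeros((n_rx, n_sp))
    net = np.zeros((n_rx, n_sp))
    ks = np.empty(n_rx)
    for j, r in enumerate(model.reactions):
        ks[j] = r.rate_constant
        for s, n in r.reactants:
            reactant[j, index[s]] += n
            net[j, index[s]] -= n
        for s, n in r.products:
            net[j, index[s]] += n
    return reactant, net, ks


def simulate(model: PathwayModel, t_end: float = 360.0,
             rel_tol: float = 1e-6, abs_tol: float = 1e-8,
             n_points: int = 2001, method: str = "LSODA") -> TimeCourse:
    """Integrate the mass-balance ODEs and return dense trajectories.

    Each reaction rate is k·∏ c_i^{n_i}; species balances are production
    minus consumption.  A stiff-capable adaptive solver is used and the
    solution is reported on a uniform grid of ``n_points`` over
    [0, t_end] minutes.
    """
    if t_end <= 0:
        raise ValueError("t_end must be > 0")
    if rel_tol <= 0 or abs_tol <= 0:
        raise ValueError("tolerances must be > 0")
    reactant, net, ks = _stoichiometry(model)
    net_T = net.T

    def rhs(_t, x):
        xc = np.clip(x, 0.0, None)
        with np.errstate(divide="ignore", invalid="ignore"):
            log_rates = reactant @ np.log(np.where(xc > 0, xc, 1.0))
        zero_mask = (reactant[:, xc <= 0] > 0).any(axis=1) if (xc <= 0).any() else None
        rates = ks * np.exp(log_rates)
        if zero_mask is not None:
            rates = np.where(zero_mask, 0.0, rates)
        return net_T @ rates

    t_eval = np.linspace(0.0, t_end, n_points)
    sol = solve_ivp(rhs, (0.0, t_end), model.initial_vector(), method=method,
                    rtol=rel_tol, atol=abs_tol, t_eval=t_eval)
    if not sol.success:
        raise RuntimeError(f"integration failed: {sol.message}")
    y = sol.y.T
    neg_tol = 1e-6 * max(1.0, float(np.abs(y).max()))
    if (y < -neg_tol).any():
        raise RuntimeError("negative concentrations beyond tolerance")
    return TimeCourse(time=sol.t,
                      concentrations=pd.DataFrame(y, columns=model.species))


def peak_metrics(tc: TimeCourse, readout: str = "TNF") -> PeakMetrics:
    """Peak height, time to peak and FWHM of a readout trajectory.

    The grid maximum is refined with a local quadratic through the three
    samples around it; the FWHM is the width of the contiguous half-height
    interval containing the peak, with linearly interpolated crossings.
    """
    if readout not in tc.concentrations.columns:
        raise KeyError(f"readout {readout!r} not in time course")
    y = tc.readout(readout)
    t = tc.time
    i = int(np.argmax(y))
    h = float(y[i])
    t_peak = float(t[i])
    if h <= 0:
        return PeakMetrics(0.0, t_peak, None)
    if 0 < i < len(y) - 1:
        # quadratic refinement through the three points around the maximum
        y0, y1, y2 = y[i - 1], y[i], y[i + 1]
        denom = y0 - 2 * y1 + y2
        if denom < 0:
            delta = 0.5 * (y0 - y2) / denom
            dt = t[i + 1] - t[i]
            t_peak = float(t[i] + delta * dt)
            h = float(y1 - 0.25 * (y0 - y2) * delta)
    non_transient = i == len(y) - 1
    if non_transient:
        return PeakMetrics(h, float(t[-1]), None, non_transient=True)

    half = h / 2.0
    # walk out from the peak to the first samples below half height
    left = i
    while left > 0 and y[left - 1] >= half:
        left -= 1
    right = i
    while right < len(y) - 1 and y[right + 1] >= half:
        right += 1

    def cross(j0, j1):
        y0, y1 = y[j0], y[j1]
        if y1 == y0:
            return float(t[j0])
        return float(t[j0] + (half - y0) * (t[j1] - t[j0]) / (y1 - y0))

    t_left = cross(left - 1, left) if left > 0 else float(t[0])
    t_right = cross(right, right + 1) if right < len(y) - 1 else float(t[-1])
    return PeakMetrics(h, t_peak, t_right - t_left, non_transient=False)
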