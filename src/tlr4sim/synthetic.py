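"""Synthetic paired-design microarray data and packaged reference fixtures.

The experimental design emulated here is a within-animal paired comparison:
each sow contributes two uterine-horn samples, one from the inseminated side
(embryos present) and one from the contralateral non-inseminated side
(oocytes present), each hybridized to its own array.  Probe-level raw
intensities are generated on a log-normal scale as

    intensity = 2 ** (baseline + probe offset + animal effect + array effect
                      + planted log2FC * [inseminated] + noise)

so that the downstream per-probe-set mixed model (treatment + probe fixed
effects, random array effect) sees exactly the variance components it
assumes.  Planted effects are expressed as the log2 fold change of the
inseminated over the non-inseminated side, matching the ratio convention
(inseminated / non-inseminated) used throughout the scenario construction.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

CONDITIONS = ("inseminated", "non_inseminated")

#: Constituent map for the protein complexes carried in the pathway model.
COMPLEX_CONSTITUENTS: dict[str, tuple[str, ...]] = {
    "IRAK4_MyD88": ("IRAK4", "MyD88"),
    "RP1_TRIF": ("RP1", "TRIF"),
    "IkB_NFkB": ("IkB-alpha", "NFkB"),
    "IRAK1_IRAK4_MyD88": ("IRAK1", "IRAK4", "MyD88"),
    "RP1_TRIF_TRAF6": ("RP1", "TRIF", "TRAF6"),
}


@dataclass(frozen=True)
class ArrayDesign:
    """One array: which animal it came from and which uterine horn."""

    animal_id: str
    condition: str
    array_id: str

    def __post_init__(self) -> None:
        if self.condition not in CONDITIONS:
            raise ValueError(f"unknown condition {self.condition!r}")


@dataclass(frozen=True)
class ProbeAnnotation:
    """Probe → gene (and optionally pathway species) mapping."""

    probe_id: str
    gene_symbol: str | None = None
    pathway_species: str | None = None


@dataclass
class SimulationSpec:
    """Parameters of the synthetic paired-design experiment.

    Defaults mirror the study layout: 3 animals, two paired conditions per
    animal, log2-scale Gaussian noise.  ``planted_effects`` maps gene symbol
    to the log2 fold change of the inseminated side.
    """

    n_probes: int = 2000
    n_animals: int = 3
    baseline_mean: float = 8.0
    noise_sd: float = 0.25
    animal_sd: float = 0.2
    array_sd: float = 0.1
    probe_sd: float = 1.5
    planted_effects: Mapping[str, float] = field(default_factory=dict)
    seed: int = 0

    def validate(self) -> None:
        if self.noise_sd <= 0:
            raise ValueError("noise_sd must be > 0")
        if self.n_animals < 2:
            raise ValueError("n_animals must be >= 2")
        if self.n_probes < 1:
            raise ValueError("n_probes must be >= 1")
        if self.animal_sd < 0 or self.array_sd < 0 or self.probe_sd < 0:
            raise ValueError("random-effect SDs must be >= 0")


@dataclass
class ProbeIntensityTable:
    """Probe-set × array raw intensities with the paired design attached.

    ``values`` holds raw (linear-scale) intensities; the differential
    expression stage log2-transforms and normalizes them.
    """

    values: pd.DataFrame  # rows: probe_id, columns: array_id
    design: list[ArrayDesign]
    log2: bool = False

    def __post_init__(self) -> None:
        design_ids = [d.array_id for d in self.design]
        if list(self.values.columns) != design_ids:
            raise ValueError("value columns must match design array_ids 1:1")
        if not self.log2 and (self.values.to_numpy() <= 0).any():
            raise ValueError("raw intensities must be strictly positive")

    @property
    def probe_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def array_ids(self) -> list[str]:
        return list(self.values.columns)

    def arrays_for(self, condition: str) -> list[str]:
        return [d.array_id for d in self.design if d.condition == condition]

    def to_tsv(self, values_path, design_path) -> None:
        self.values.rename_axis("probe_id").to_csv(values_path, sep="\t")
        pd.DataFrame(
            [(d.array_id, d.animal_id, d.condition) for d in self.design],
            columns=["array_id", "animal_id", "condition"],
        ).to_csv(design_path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, values_path, design_path, log2: bool = False) -> "ProbeIntensityTable":
        values = pd.read_csv(values_path, sep="\t", index_col="probe_id")
        values.index.name = None
        meta = pd.read_csv(design_path, sep="\t")
        design = [
            ArrayDesign(str(r.animal_id), str(r.condition), str(r.array_id))
            for r in meta.itertuples()
        ]
        return cls(values=values, design=design, log2=log2)


def paired_design(n_animals: int) -> list[ArrayDesign]:
    """One array per (animal, condition): the within-sow paired layout."""
    design = []
    for a in range(1, n_animals + 1):
        for cond in CONDITIONS:
            suffix = "ins" if cond == "inseminated" else "non"
            design.append(ArrayDesign(f"animal{a}", cond, f"array_{a}_{suffix}"))
    return design


def default_annotation(n_probes: int, planted_genes: Sequence[str] = (),
                       probes_per_gene: int = 2) -> list[ProbeAnnotation]:
    """Annotation where each planted gene gets ``probes_per_gene`` probes
    (genes commonly have several probe sets on the array) and remaining
    probes are unannotated background."""
    ann: list[ProbeAnnotation] = []
    i = 0
    for gene in planted_genes:
        for _ in range(probes_per_gene):
            if i >= n_probes:
                break
            ann.append(ProbeAnnotation(f"probe_{i:05d}", gene_symbol=gene))
            i += 1
    while i < n_probes:
        ann.append(ProbeAnnotation(f"probe_{i:05d}"))
        i += 1
    return ann


def generate_intensities(spec: SimulationSpec,
                         annotation: Sequence[ProbeAnnotation] | None = None,
                         ) -> ProbeIntensityTable:
    """Generate a raw probe × array intensity table under ``spec``.

    Noise, animal, and array effects are additive Gaussians on the log2
    scale; planted log2 fold changes apply to every probe of the named gene
    on the inseminated arrays only.  Output is fully determined by
    ``spec.seed``.
    """
    spec.validate()
    if annotation is None:
        annotation = default_annotation(
            spec.n_probes, planted_genes=sorted(spec.planted_effects))
    if len(annotation) != spec.n_probes:
        raise ValueError(
            f"annotation covers {len(annotation)} probes, spec has {spec.n_probes}")

    rng = np.random.default_rng(spec.seed)
    design = paired_design(spec.n_animals)
    n_arrays = len(design)

    probe_offsets = rng.normal(0.0, spec.probe_sd, size=spec.n_probes)
    animal_effects = rng.normal(0.0, spec.animal_sd, size=spec.n_animals)
    array_effects = rng.normal(0.0, spec.array_sd, size=n_arrays)
    noise = rng.normal(0.0, spec.noise_sd, size=(spec.n_probes, n_arrays))

    effects = np.array([spec.planted_effects.get(a.gene_symbol or "", 0.0)
                        for a in annotation])

    log2_values = (spec.baseline_mean
                   + probe_offsets[:, None]
                   + noise)
    for j, d in enumerate(design):
        a_idx = int(d.animal_id.removeprefix("animal")) - 1
        log2_values[:, j] += animal_effects[a_idx] + array_effects[j]
        if d.condition == "inseminated":
            log2_values[:, j] += effects

    values = pd.DataFrame(
        np.exp2(log2_values),
        index=[a.probe_id for a in annotation],
        columns=[d.array_id for d in design],
    )
    return ProbeIntensityTable(values=values, design=design)


def _data_path(name: str):
    return resources.files("tlr4sim.data").joinpath(name)


def mal_fixture() -> pd.DataFrame:
    """The six published MAL inseminated/non-inseminated probe ratios.

    Two array probes bind the MAL transcript; with three animals that gives
    six ratio measurements.  Returned with (probe_id, animal_id) labels,
    exactly as printed.
    """
    with resources.as_file(_data_path("mal_probe_ratios.csv")) as p:
        return pd.read_csv(p)


def table2_fixture() -> pd.DataFrame:
    """The published 20-row scenario table for the TLR4 pathway species.

    Columns: species, base concentration (molecules per cell, oocyte-presence
    base), sensitivity (% peak-TNF change per 1% abundance increase), and the
    concentration/multiplier pairs for the minimum-, maximum- and
    average-response scenarios.
    """
    with resources.as_file(_data_path("reference_scenarios.csv")) as p:
        df = pd.read_csv(p)
    return df
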