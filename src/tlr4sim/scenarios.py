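"""Expression-ratio → protein-abundance scenario construction.

For every pathway species the raw microarray data supply one
inseminated/non-inseminated intensity ratio per (probe, animal).  The three
simulation scenarios summarize those ratios as their minimum, maximum and
geometric mean, and route the extremes by the species' sensitivity sign:

* positive sensitivity (more protein → bigger TNF peak): the maximum ratio
  feeds the maximum-response scenario and the minimum the minimum-response
  scenario;
* negative sensitivity (inhibitory species): swapped, so that each scenario
  bounds the response rather than the expression.

The average-response scenario always uses the geometric mean.  Protein
complexes carry no transcript of their own: assuming fast equilibrium with
their constituents, a complex's candidate ratios are the products of its
constituents' extremes (mins together, maxes together, geometric means
together), routed by the complex's own sensitivity sign.  Multipliers are
carried at two-decimal precision and scenario concentrations are
base × rounded multiplier, which is the convention the published table
follows exactly.

Species with no mapped probe keep multiplier 1.00 in every scenario.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Mapping, NamedTuple, Sequence

import numpy as np
import pandas as pd

from .synthetic import COMPLEX_CONSTITUENTS

__all__ = [
    "RatioSummary", "ScenarioMultipliers", "summarize_ratios",
    "assign_scenarios", "complex_multipliers", "build_scenario_table",
    "summary_from_multipliers", "ratios_from_table",
]

SCENARIOS = ("min_resp", "max_resp", "avg_resp")


class RatioSummary(NamedTuple):
    """Min / max / geometric mean of a species' expression ratios."""
    min: float
    max: float
    geomean: float


class ScenarioMultipliers(NamedTuple):
    """Relative-expression multipliers for the three response scenarios."""
    r_min_resp: float
    r_max_resp: float
    r_avg_resp: float


def _round2(x: float) -> float:
    return float(np.round(x, 2))


def summarize_ratios(ratios: Iterable[float]) -> RatioSummary:
    """Summarize expression ratios; an unmapped species (no ratios) is
    neutral: (1, 1, 1)."""
    r = np.asarray(list(ratios), dtype=float)
    if r.size == 0:
        return RatioSummary(1.0, 1.0, 1.0)
    if (r <= 0).any() or not np.isfinite(r).all():
        raise ValueError("ratios must be positive and finite")
    geomean = float(np.exp(np.mean(np.log(r))))
    return RatioSummary(float(r.min()), float(r.max()), geomean)


def assign_scenarios(summary: RatioSummary, sensitivity: float) -> ScenarioMultipliers:
    """Route the ratio extremes into scenarios by the sensitivity sign."""
    if sensitivity == 0:
        warnings.warn("zero sensitivity treated as positive", stacklevel=2)
    lo, hi, mid = (_round2(v) for v in summary)
    if sensitivity >= 0:
        return ScenarioMultipliers(lo, hi, mid)
    return ScenarioMultipliers(hi, lo, mid)


def complex_multipliers(constituent_summaries: Sequence[RatioSummary],
                        complex_sensitivity: float) -> ScenarioMultipliers:
    """Scenario multipliers for a complex from its constituents' summaries.

    Candidate products: all-mins, all-maxes, all-geomeans, each constituent
    carried at two decimals before multiplying (table precision); the
    products are then routed by the complex's own sensitivity sign.
    """
    if len(constituent_summaries) == 0:
        raise ValueError("complex needs at least one constituent")
    lo = float(np.prod([_round2(s.min) for s in constituent_summaries]))
    hi = float(np.prod([_round2(s.max) for s in constituent_summaries]))
    mid = float(np.prod([_round2(s.geomean) for s in constituent_summaries]))
    return assign_scenarios(RatioSummary(lo, hi, mid), complex_sensitivity)


def summary_from_multipliers(r_min_resp: float, r_max_resp: float,
                             r_avg_resp: float, sensitivity: float) -> RatioSummary:
    """Invert :func:`assign_scenarios`: recover (min, max, geomean) ratios
    from published scenario multipliers and the sensitivity sign."""
    if sensitivity >= 0:
        return RatioSummary(r_min_resp, r_max_resp, r_avg_resp)
    return RatioSummary(r_max_resp, r_min_resp, r_avg_resp)


def ratios_from_table(intensity_table, annotation) -> dict[str, list[float]]:
    """Per-species inseminated/non-inseminated ratios from a raw table.

    One ratio per (probe, animal): probe intensity on the animal's
    inseminated array divided by the same probe on its non-inseminated
    array.  ``annotation`` is a sequence of ProbeAnnotation; only probes
    with a ``pathway_species`` contribute.
    """
    by_animal: dict[str, dict[str, str]] = {}
    for d in intensity_table.design:
        by_animal.setdefault(d.animal_id, {})[d.condition] = d.array_id
    vals = intensity_table.values
    if intensity_table.log2:
        vals = np.exp2(vals)
    out: dict[str, list[float]] = {}
    for ann in annotation:
        if ann.pathway_species is None:
            continue
        for cols in by_animal.values():
            num = float(vals.at[ann.probe_id, cols["inseminated"]])
            den = float(vals.at[ann.probe_id, cols["non_inseminated"]])
            out.setdefault(ann.pathway_species, []).append(num / den)
    return out


@dataclass
class ScenarioRow:
    species: str
    base_conc: float
    sensitivity: float
    multipliers: ScenarioMultipliers

    def concentrations(self) -> tuple[float, float, float]:
        return tuple(self.base_conc * r for r in self.multipliers)


def build_scenario_table(ratio_sets: Mapping[str, Sequence[float]],
                         sensitivities: Mapping[str, float],
                         base_concs: Mapping[str, float],
                         complex_defns: Mapping[str, Sequence[str]] | None = None,
                         constituent_summaries: Mapping[str, RatioSummary] | None = None,
                         triple_complex_rule: str = "product") -> pd.DataFrame:
    """Build the full scenario table (one row per species).

    Single-protein species are summarized from ``ratio_sets``; complexes
    (``complex_defns``, default: the packaged pathway complexes) from their
    constituents' summaries via the product rule.  ``constituent_summaries``
    may pre-supply summaries (e.g. recovered from a published table) which
    take precedence over ratio-derived ones.

    ``triple_complex_rule``: "product" applies the constituent-product rule
    uniformly; "largest_constituent" makes complexes of three or more
    constituents inherit the max/avg multipliers of their most variable
    constituent (the behaviour the published triple-complex row exhibits;
    its provenance is undocumented, so "product" is the default).
    """
    if complex_defns is None:
        complex_defns = COMPLEX_CONSTITUENTS
    if triple_complex_rule not in ("product", "largest_constituent"):
        raise ValueError(f"unknown triple_complex_rule {triple_complex_rule!r}")

    summaries: dict[str, RatioSummary] = {}
    for sp in sensitivities:
        if constituent_summaries and sp in constituent_summaries:
            summaries[sp] = constituent_summaries[sp]
        elif sp not in complex_defns:
            summaries[sp] = summarize_ratios(ratio_sets.get(sp, ()))

    rows = []
    for sp, sens in sensitivities.items():
        if sp not in base_concs:
            raise ValueError(f"species {sp!r} has no base concentration")
        base = float(base_concs[sp])
        if sp in complex_defns and not (constituent_summaries and sp in constituent_summaries):
            constituents = complex_defns[sp]
            missing = [c for c in constituents if c not in summaries]
            if missing:
                raise ValueError(f"complex {sp!r}: unsummarized constituents {missing}")
            cs = [summaries[c] for c in constituents]
            if triple_complex_rule == "largest_constituent" and len(constituents) >= 3:
                spread = [abs(np.log(s.max / s.min)) if s.min > 0 else 0.0 for s in cs]
                dominant = cs[int(np.argmax(spread))]
                lo = _round2(dominant.min)
                hi = _round2(dominant.max)
                mid = _round2(dominant.geomean)
                # minimum-side candidate still uses the full product
                prod = complex_multipliers(cs, sens)
                if sens >= 0:
                    mult = ScenarioMultipliers(prod.r_min_resp, hi, mid)
                else:
                    mult = ScenarioMultipliers(prod.r_min_resp, lo, mid)
            else:
                mult = complex_multipliers(cs, sens)
        else:
            mult = assign_scenarios(summaries[sp], sens)
        mult = ScenarioMultipliers(*(_round2(m) for m in mult))
        rows.append({
            "species": sp,
            "base_conc": base,
            "sensitivity": float(sens),
            "r_min_resp": mult.r_min_resp,
            "r_max_resp": mult.r_max_resp,
            "r_avg_resp": mult.r_avg_resp,
            "c_min_resp": base * mult.r_min_resp,
            "c_max_resp": base * mult.r_max_resp,
            "c_avg_resp": base * mult.r_avg_resp,
        })
    return pd.DataFrame(rows).set_index("species", drop=False)
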