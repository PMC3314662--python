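"""Sensitivity of the peak TNF response to species initial abundances.

The sensitivity coefficient of a species is the percentage change in the
TNF peak height caused by a 1% increase in that species' initial abundance,
estimated by a forward finite difference of two simulations:

    s = 100 * (H(c0 * 1.01) - H(c0)) / H(c0)

A central-difference variant is available but not the default.  Species
with zero base abundance have no defined relative perturbation and are
reported as not applicable.
"""

from __future__ import annotations

from dataclasses import replace

import numpy as np
import pandas as pd

from .network import PathwayModel, peak_metrics, simulate

__all__ = ["sensitivity_coefficient", "sensitivity_report"]


def _peak(model: PathwayModel, t_end: float, rel_tol: float, abs_tol: float) -> float:
    tc = simulate(model, t_end=t_end, rel_tol=rel_tol, abs_tol=abs_tol)
    return peak_metrics(tc, model.readout).peak_height


def _perturbed(model: PathwayModel, species: str, factor: float) -> PathwayModel:
    initial = dict(model.initial)
    initial[species] = initial.get(species, 0.0) * factor
    return replace(model, initial=initial)


def sensitivity_coefficient(model: PathwayModel, species: str,
                            delta: float = 0.01, scheme: str = "forward",
                            t_end: float = 360.0, rel_tol: float = 1e-8,
                            abs_tol: float = 1e-10,
                            baseline_peak: float | None = None) -> float:
    """% change in peak TNF per 1% increase of ``species`` initial abundance."""
    if species not in model.species:
        raise KeyError(f"unknown species {species!r}")
    if model.initial.get(species, 0.0) <= 0:
        raise ValueError(f"species {species!r} has zero base abundance")
    h0 = (baseline_peak if baseline_peak is not None
          else _peak(model, t_end, rel_tol, abs_tol))
    if h0 <= 0:
        raise ValueError("baseline peak is zero; relative sensitivity undefined")
    if scheme == "forward":
        h_up = _peak(_perturbed(model, species, 1.0 + delta), t_end, rel_tol, abs_tol)
        return 100.0 * (h_up - h0) / h0 * (0.01 / delta)
    if scheme == "central":
        h_up = _peak(_perturbed(model, species, 1.0 + delta), t_end, rel_tol, abs_tol)
        h_dn = _peak(_perturbed(model, species, 1.0 - delta), t_end, rel_tol, abs_tol)
        return 100.0 * (h_up - h_dn) / (2.0 * h0) * (0.01 / delta)
    raise ValueError(f"unknown scheme {scheme!r}")


def sensitivity_report(model: PathwayModel, species: list[str] | None = None,
                       delta: float = 0.01, t_end: float = 360.0,
                       rel_tol: float = 1e-8, abs_tol: float = 1e-10) -> pd.DataFrame:
    """Coefficients for every species with nonzero initial abundance,
    ranked by |s|; zero-abundance species appear with s = NaN."""
    if species is None:
        species = [s for s in model.species
                   if s not in (model.stimulus_species, model.readout)]
    h0 = _peak(model, t_end, rel_tol, abs_tol)
    if h0 <= 0:
        raise RuntimeError("baseline simulation produced no peak")
    rows = []
    for sp in species:
        base = model.initial.get(sp, 0.0)
        if base <= 0:
            rows.append((sp, base, np.nan, False))
            continue
        s = sensitivity_coefficient(model, sp, delta=delta, t_end=t_end,
                                    rel_tol=rel_tol, abs_tol=abs_tol,
                                    baseline_peak=h0)
        rows.append((sp, base, s, True))
    df = pd.DataFrame(rows, columns=["species", "base_conc", "sensitivity",
                                     "applicable"])
    df["abs_s"] = df["sensitivity"].abs()
    df = df.sort_values("abs_s", ascending=False, na_position="last")
    df["rank"] = np.where(df["applicable"], np.arange(1, len(df) + 1), -1)
    df.attrs["baseline_peak"] = h0
    return df.drop(columns="abs_s").set_index("species", drop=False)
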