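"""Normalization and per-probe-set mixed-model differential expression.

The analysis chain is: log2 transform → per-array lowess normalization
against a median pseudo-reference → per-probe-set linear mixed model

    y_ijk = mu + T_i + P_j + A_k + eps_ijk

with fixed effects for treatment (inseminated vs non-inseminated horn) and
probe, and a random intercept for array.  The reported contrast is the
least-squares-mean treatment difference oriented N − Y (non-inseminated
minus inseminated), so a transcript that is *higher* in the embryo-bearing
horn has a negative difference.  Raw p-values are Bonferroni-adjusted over
all probe sets tested.

Also provides the comparative-CT (ΔΔCT) relative quantification used for
qPCR validation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.nonparametric.smoothers_lowess import lowess as _sm_lowess
from statsmodels.regression.mixed_linear_model import MixedLM
from statsmodels.stats.multitest import multipletests

from .synthetic import ArrayDesign, ProbeIntensityTable

__all__ = [
    "lowess_normalize", "fit_probe_set", "fit_single_probe_table",
    "bonferroni", "volcano_table", "ddct", "DEResult", "QpcrResult",
]


@dataclass
class DEResult:
    probe_set_id: str
    lsmean_diff: float  # N - Y, log2 units
    p_raw: float
    p_adj: float = np.nan
    degenerate: bool = False

    @property
    def direction(self) -> str:
        return "down_in_embryo" if self.lsmean_diff > 0 else "up_in_embryo"


@dataclass
class QpcrResult:
    delta_ct: dict
    delta_delta_ct: float
    fold_change: float


# ---------------------------------------------------------------------------
# normalization

def lowess_normalize(table: ProbeIntensityTable, span: float = 0.3) -> ProbeIntensityTable:
    """Log2-transform and lowess-normalize each array.

    Each array is compared with a median pseudo-reference array on the
    (A, M) scale, A = (array + reference)/2 and M = array − reference in
    log2 units; the locally weighted fit of M on A is the array's
    intensity-dependent bias and is subtracted.  Returns a table on the
    log2 scale.
    """
    if table.values.empty:
        raise ValueError("empty intensity table")
    if table.log2:
        log2v = table.values.to_numpy(dtype=float).copy()
    else:
        vals = table.values.to_numpy(dtype=float)
        if (vals <= 0).any():
            raise ValueError("intensities must be strictly positive")
        log2v = np.log2(vals)

    reference = np.median(log2v, axis=1)
    normalized = np.empty_like(log2v)
    for j in range(log2v.shape[1]):
        m = log2v[:, j] - reference
        a = 0.5 * (log2v[:, j] + reference)
        if np.allclose(m, m[0]):
            # constant offset (includes the identical-array case): the local
            # fit is exactly that constant
            bias = np.full_like(m, m.mean())
        else:
            fit = _sm_lowess(m, a, frac=span, return_sorted=False)
            bias = fit
        normalized[:, j] = log2v[:, j] - bias

    out = pd.DataFrame(normalized, index=table.values.index,
                       columns=table.values.columns)
    return ProbeIntensityTable(values=out, design=list(table.design), log2=True)


# ---------------------------------------------------------------------------
# per-probe-set mixed model

def _design_frame(values: np.ndarray, design: list[ArrayDesign]) -> pd.DataFrame:
    """Long-format frame: one row per (probe, array) observation."""
    values = np.atleast_2d(np.asarray(values, dtype=float))
    n_probes, n_arrays = values.shape
    if n_arrays != len(design):
        raise ValueError("value columns must match design")
    rows = []
    for p in range(n_probes):
        for k, d in enumerate(design):
            rows.append((values[p, k], d.condition, f"p{p}", d.array_id))
    df = pd.DataFrame(rows, columns=["y", "treatment", "probe", "array"])
    conds = set(df["treatment"])
    if len(conds) < 2:
        raise ValueError("both conditions must be present")
    return df


def fit_probe_set(values, design: list[ArrayDesign]) -> DEResult:
    """Fit the treatment + probe + random-array model for one probe set.

    ``values`` is (n_probes, n_arrays) log2 intensities.  The treatment
    effect is estimated by REML (Wald test on the contrast); when the probe
    set has a single probe the array effect is confounded with the residual
    and the model reduces to ordinary least squares, as it also does when
    the array-variance estimate collapses to zero.
    """
    df = _design_frame(values, design)
    n_animals = len({d.animal_id for d in design})
    if n_animals < 2:
        raise ValueError("need >= 2 animals")
    # numeric coding: +1 for non-inseminated so the coefficient is N - Y
    df["t_n"] = (df["treatment"] == "non_inseminated").astype(float)
    single_probe = df["probe"].nunique() == 1

    if not single_probe:
        formula = "y ~ t_n + C(probe)"
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            try:
                fit = MixedLM.from_formula(formula, groups="array", data=df).fit(reml=True)
                var_array = float(fit.cov_re.iloc[0, 0])
                if np.isfinite(fit.bse["t_n"]) and var_array > 1e-10:
                    return DEResult(
                        probe_set_id="",
                        lsmean_diff=float(fit.params["t_n"]),
                        p_raw=float(fit.pvalues["t_n"]),
                    )
            except Exception:
                pass  # singular fit: fall back to OLS below

    # OLS path (single probe, or degenerate array variance)
    y = df["y"].to_numpy()
    X_cols = [np.ones(len(df)), df["t_n"].to_numpy()]
    if not single_probe:
        probes = sorted(df["probe"].unique())
        for p in probes[1:]:
            X_cols.append((df["probe"] == p).to_numpy(dtype=float))
    X = np.column_stack(X_cols)
    beta, _, rank, _ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ beta
    dof = len(y) - rank
    rss = float(resid @ resid)
    diff = float(beta[1])
    if dof <= 0 or rss <= 1e-12 * max(1.0, float(y @ y)):
        # zero residual variance: the test statistic is degenerate
        scale = max(1.0, float(np.abs(y).max()))
        p = 0.0 if abs(diff) > 1e-10 * scale else 1.0
        return DEResult("", diff, p, degenerate=True)
    sigma2 = rss / dof
    xtx_inv = np.linalg.pinv(X.T @ X)
    se = float(np.sqrt(sigma2 * xtx_inv[1, 1]))
    tstat = diff / se
    p = 2.0 * stats.t.sf(abs(tstat), dof)
    return DEResult("", diff, float(p))


def fit_single_probe_table(table: ProbeIntensityTable) -> pd.DataFrame:
    """Vectorized OLS treatment test for tables of single-probe probe sets.

    Equivalent to calling :func:`fit_probe_set` row by row when every probe
    set has exactly one probe (verified by test), but runs on the whole
    matrix at once.  Expects a log2-scale table.
    """
    if not table.log2:
        raise ValueError("expects a log2-scale (normalized) table")
    vals = table.values.to_numpy(dtype=float)
    n_cols = [i for i, d in enumerate(table.design) if d.condition == "non_inseminated"]
    y_cols = [i for i, d in enumerate(table.design) if d.condition == "inseminated"]
    if not n_cols or not y_cols:
        raise ValueError("both conditions must be present")
    n1, n2 = len(n_cols), len(y_cols)
    mean_n = vals[:, n_cols].mean(axis=1)
    mean_y = vals[:, y_cols].mean(axis=1)
    diff = mean_n - mean_y
    rss = (((vals[:, n_cols] - mean_n[:, None]) ** 2).sum(axis=1)
           + ((vals[:, y_cols] - mean_y[:, None]) ** 2).sum(axis=1))
    dof = n1 + n2 - 2
    sigma2 = rss / dof
    se = np.sqrt(sigma2 * (1.0 / n1 + 1.0 / n2))
    with np.errstate(divide="ignore", invalid="ignore"):
        tstat = diff / se
    p = 2.0 * stats.t.sf(np.abs(tstat), dof)
    p = np.where(se == 0, np.where(diff == 0, 1.0, 0.0), p)
    return pd.DataFrame({
        "probe_set_id": table.probe_ids,
        "lsmean_diff": diff,
        "p_raw": p,
        "degenerate": se == 0,
    }).set_index("probe_set_id", drop=False)


def fit_table(table: ProbeIntensityTable,
              probe_sets: dict[str, list[str]] | None = None) -> pd.DataFrame:
    """Fit every probe set of a normalized table.

    ``probe_sets`` maps probe-set id → member probe ids; when omitted each
    probe is its own probe set and the fast vectorized path is used.
    """
    if probe_sets is None:
        return fit_single_probe_table(table)
    rows = []
    for ps_id, members in probe_sets.items():
        res = fit_probe_set(table.values.loc[members].to_numpy(), table.design)
        res.probe_set_id = ps_id
        rows.append((ps_id, res.lsmean_diff, res.p_raw, res.degenerate))
    return pd.DataFrame(rows, columns=["probe_set_id", "lsmean_diff", "p_raw",
                                       "degenerate"]).set_index("probe_set_id",
                                                                drop=False)


# ---------------------------------------------------------------------------
# multiplicity and reporting

def bonferroni(p_raw, alpha: float = 0.05):
    """Bonferroni family-wise adjustment: p_adj = min(1, m·p)."""
    p = np.asarray(p_raw, dtype=float)
    if p.size == 0:
        raise ValueError("empty p-value list")
    if ((p < 0) | (p > 1)).any() or not np.isfinite(p).all():
        raise ValueError("p-values must lie in [0, 1]")
    flags, p_adj, _, _ = multipletests(p, alpha=alpha, method="bonferroni")
    return p_adj, flags


def volcano_table(results: pd.DataFrame, alpha: float = 0.05) -> pd.DataFrame:
    """Volcano coordinates: effect size vs −log10 adjusted p, plus flag."""
    if results.empty:
        raise ValueError("no results")
    p_adj, flags = bonferroni(results["p_raw"].to_numpy(), alpha=alpha)
    with np.errstate(divide="ignore"):
        neg_log10 = -np.log10(p_adj)
    out = pd.DataFrame({
        "probe_set_id": results["probe_set_id"],
        "lsmean_diff": results["lsmean_diff"],
        "p_adj": p_adj,
        "neg_log10_p_adj": neg_log10,
        "significant": flags,
    })
    out["direction"] = np.where(out["lsmean_diff"] > 0,
                                "down_in_embryo", "up_in_embryo")
    return out.set_index("probe_set_id", drop=False)


# ---------------------------------------------------------------------------
# qPCR comparative CT

def ddct(ct_gene: dict, ct_reference: dict,
         group1: str = "inseminated", group2: str = "non_inseminated") -> QpcrResult:
    """Comparative-CT relative quantification.

    ΔCT per group is the target-gene CT minus the reference-gene
    (beta-actin) CT; ΔΔCT = ΔCT(group1) − ΔCT(group2) and the fold change
    is 2^(−ΔΔCT).  CT inputs are per-group mean cycle thresholds.
    """
    for g in (group1, group2):
        if g not in ct_gene or g not in ct_reference:
            raise ValueError(f"missing group {g!r}")
    if not all(np.isfinite([ct_gene[group1], ct_gene[group2],
                            ct_reference[group1], ct_reference[group2]])):
        raise ValueError("CT values must be finite")
    delta = {g: float(ct_gene[g]) - float(ct_reference[g]) for g in (group1, group2)}
    ddct_value = delta[group1] - delta[group2]
    return QpcrResult(delta_ct=delta, delta_delta_ct=ddct_value,
                      fold_change=float(2.0 ** (-ddct_value)))
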