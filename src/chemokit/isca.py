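"""Chemotactic-index statistics for ISCA microwell assays.

The chemotactic index I_C of a treatment is the pooled cell concentration in
its wells divided by the same-plate concentration in the filtered-seawater
control wells; attraction corresponds to I_C > 1. This module computes I_C
per plate, summarises it across biological replicates (mean +- SD), tests
attraction with a one-sided treatment-versus-control contrast, and provides
the fold-change, log2-enrichment, molarity and environmental-correlation
arithmetic used around the assay.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

__all__ = [
    "ChemotaxisResult",
    "chemotactic_index",
    "summarize_ic",
    "test_attraction",
    "attraction_results",
    "fold_change",
    "log2_enrichment",
    "mean_log2_enrichment",
    "molar_concentration",
    "polymer_molarity_range",
    "environment_correlation",
]


@dataclass(frozen=True)
class ChemotaxisResult:
    """Replicate-level chemotaxis outcome for one treatment."""

    treatment: str
    ic_mean: float
    ic_sd: float
    n_replicates: int
    p_one_sided: float
    significant: bool


# ---------------------------------------------------------------------------
# chemotactic index
# ---------------------------------------------------------------------------

def _control_by_plate(table: pd.DataFrame) -> pd.Series:
    req = {"plate", "treatment", "cells_per_ml", "is_control"}
    missing = req - set(table.columns)
    if missing:
        raise ValueError(f"well count table missing columns: {sorted(missing)}")
    ctrl = table[table["is_control"]]
    counts = ctrl.groupby("plate").size()
    for plate in table["plate"].unique():
        if plate not in counts.index:
            raise ValueError(f"plate {plate!r} has no control treatment")
        if counts[plate] != 1:
            raise ValueError(f"plate {plate!r} has {counts[plate]} control rows, "
                             "expected exactly 1")
    control = ctrl.set_index("plate")["cells_per_ml"]
    zero = control[control <= 0]
    if len(zero):
        raise ValueError(
            f"control concentration is zero on plate(s) {list(zero.index)}")
    return control


def chemotactic_index(table: pd.DataFrame) -> pd.DataFrame:
    """Per-plate I_C for every treatment.

    ``table`` needs columns ``plate``, ``treatment``, ``cells_per_ml``,
    ``is_control`` with exactly one control row per plate and strictly
    positive control concentrations. Returns a table with columns ``plate``,
    ``treatment``, ``ic`` (control rows included, with I_C identically 1).
    """
    control = _control_by_plate(table)
    out = table[["plate", "treatment", "cells_per_ml"]].copy()
    out["ic"] = out["cells_per_ml"] / control.reindex(out["plate"]).to_numpy()
    return out[["plate", "treatment", "ic"]]


def summarize_ic(ic_table: pd.DataFrame) -> pd.DataFrame:
    """Mean +- SD of I_C across plates, per treatment."""
    g = ic_table.groupby("treatment")["ic"]
    return pd.DataFrame({
        "ic_mean": g.mean(),
        "ic_sd": g.std(ddof=1),
        "n_replicates": g.size(),
    }).reset_index()


# ---------------------------------------------------------------------------
# attraction test
# ---------------------------------------------------------------------------

def test_attraction(
    treatment: np.ndarray,
    control: np.ndarray | None = None,
    alpha: float = 0.05,
) -> tuple[float, bool]:
    """One-sided test that the treatment response exceeds the control.

    With per-plate ``treatment`` and ``control`` concentrations this is the
    one-sided Welch t-test (H1: mean treatment > mean control), the
    two-group case of a one-way ANOVA with a one-sided treatment-versus-
    control contrast. With only I_C replicates (``control=None``) it is a
    one-sample t-test of H1: mean I_C > 1. Returns ``(p, significant)``.
    """
    treatment = np.asarray(treatment, dtype=np.float64)
    if len(treatment) < 2:
        raise ValueError("need >= 2 treatment replicates")
    if control is None:
        res = stats.ttest_1samp(treatment, popmean=1.0, alternative="greater")
    else:
        control = np.asarray(control, dtype=np.float64)
        if len(control) < 2:
            raise ValueError("need >= 2 control replicates")
        res = stats.ttest_ind(treatment, control, equal_var=False,
                              alternative="greater")
    p = float(res.pvalue)
    if np.isnan(p):            # identical constant samples: no evidence
        p = 1.0
    return p, bool(p < alpha)


def attraction_results(
    table: pd.DataFrame,
    alpha: float = 0.05,
) -> tuple[list[ChemotaxisResult], float]:
    """Per-treatment chemotaxis outcomes plus the global one-way ANOVA F p.

    For every non-control treatment: per-plate I_C summarised across
    replicates, and the one-sided Welch contrast of its per-plate
    concentrations against the same plates' control concentrations. The
    second return value is the p-value of the global F-test across all
    treatment groups (control included), reported for reference.
    """
    ic = chemotactic_index(table)
    summary = summarize_ic(ic).set_index("treatment")
    control = _control_by_plate(table)

    groups = [g["cells_per_ml"].to_numpy()
              for _, g in table.groupby("treatment")]
    if len(groups) > 1 and all(len(g) > 1 for g in groups):
        global_p = float(stats.f_oneway(*groups).pvalue)
    else:
        global_p = float("nan")

    results = []
    for name, g in table[~table["is_control"]].groupby("treatment"):
        tr = g.set_index("plate")["cells_per_ml"]
        ctrl = control.reindex(tr.index).to_numpy()
        p, sig = test_attraction(tr.to_numpy(), ctrl, alpha=alpha)
        row = summary.loc[name]
        results.append(ChemotaxisResult(
            treatment=str(name),
            ic_mean=float(row["ic_mean"]),
            ic_sd=float(row["ic_sd"]),
            n_replicates=int(row["n_replicates"]),
            p_one_sided=p,
            significant=sig,
        ))
    return results, global_p


# ---------------------------------------------------------------------------
# fold changes and enrichment
# ---------------------------------------------------------------------------

def fold_change(ic_amended: float, ic_unamended: float,
                ndigits: int | None = None) -> float:
    """Ratio of mean chemotactic indices (e.g. with / without DMSP).

    Full precision by default; pass ``ndigits=1`` for the conventional
    one-decimal report.
    """
    if ic_unamended == 0:
        raise ValueError("unamended I_C must be non-zero")
    if ic_amended <= 0 or ic_unamended <= 0:
        raise ValueError("I_C values must be > 0")
    ratio = ic_amended / ic_unamended
    return round(ratio, ndigits) if ndigits is not None else ratio


def log2_enrichment(well_concentration: float, bulk_concentration: float) -> float:
    """log2 fold change of a well concentration relative to bulk seawater."""
    if well_concentration <= 0 or bulk_concentration <= 0:
        raise ValueError("concentrations must be > 0")
    return float(np.log2(well_concentration / bulk_concentration))


def mean_log2_enrichment(wells, bulks) -> tuple[float, float]:
    """Replicate-averaged log2 enrichment: (mean, SD across replicates)."""
    wells = np.asarray(wells, dtype=np.float64)
    bulks = np.asarray(bulks, dtype=np.float64)
    if wells.shape != bulks.shape:
        raise ValueError("wells and bulks must have the same length")
    vals = np.array([log2_enrichment(w, b) for w, b in zip(wells, bulks)])
    return float(vals.mean()), float(vals.std(ddof=1)) if len(vals) > 1 else 0.0


# ---------------------------------------------------------------------------
# molarity arithmetic
# ---------------------------------------------------------------------------

def molar_concentration(mass_concentration_mg_ml: float,
                        molecular_weight_g_mol: float) -> float:
    """Convert mg/mL to mM: (mg/mL) / (g/mol) * 1000."""
    if mass_concentration_mg_ml <= 0 or molecular_weight_g_mol <= 0:
        raise ValueError("mass concentration and molecular weight must be > 0")
    return mass_concentration_mg_ml / molecular_weight_g_mol * 1000.0


#: mass of one anhydro-glucose residue inside a glucan chain (g/mol)
GLUCAN_RESIDUE_MASS = 162.14


def polymer_molarity_range(
    mass_concentration_mg_ml: float,
    monomer_count_range: tuple[float, float],
    residue_mass_g_mol: float = GLUCAN_RESIDUE_MASS,
) -> tuple[float, float]:
    """Molarity range (mM) of a polydisperse polymer solution.

    The molecular weight of an n-mer is ``n * residue_mass``; the longest
    chains give the lower molarity bound. For laminarin (15-33 glucose
    residues) at 10 mg/mL this yields roughly 1.9-4.1 mM.
    """
    n_min, n_max = monomer_count_range
    if not (0 < n_min <= n_max):
        raise ValueError("monomer counts must satisfy 0 < n_min <= n_max")
    lo = molar_concentration(mass_concentration_mg_ml, n_max * residue_mass_g_mol)
    hi = molar_concentration(mass_concentration_mg_ml, n_min * residue_mass_g_mol)
    return lo, hi


# ---------------------------------------------------------------------------
# environmental correlation screen
# ---------------------------------------------------------------------------

def environment_correlation(
    env_table: pd.DataFrame,
    ic_series: pd.Series,
    min_n: int = 4,
) -> pd.DataFrame:
    """Spearman screen of environmental covariates against an I_C series.

    For every column of ``env_table`` (indexed like ``ic_series``): pairwise
    deletion of missing values, Spearman's rank correlation (average ranks
    on ties, two-sided p), then Benjamini-Hochberg adjustment across all
    testable variables. Constant or too-short variables are reported with
    NaN statistics and a reason. Rows are sorted by |rho| descending.
    """
    env_table, ic_series = env_table.align(ic_series, join="inner", axis=0)
    rows = []
    for name in env_table.columns:
        x = env_table[name]
        mask = x.notna() & ic_series.notna()
        n = int(mask.sum())
        if n < min_n:
            rows.append({"variable": name, "rho": np.nan, "p_raw": np.nan,
                         "n": n, "note": f"fewer than {min_n} paired observations"})
            continue
        xv = x[mask].to_numpy(dtype=np.float64)
        yv = ic_series[mask].to_numpy(dtype=np.float64)
        if np.all(xv == xv[0]) or np.all(yv == yv[0]):
            rows.append({"variable": name, "rho": np.nan, "p_raw": np.nan,
                         "n": n, "note": "constant variable, rho undefined"})
            continue
        rho, p = stats.spearmanr(xv, yv)
        rows.append({"variable": name, "rho": float(rho), "p_raw": float(p),
                     "n": n, "note": ""})

    out = pd.DataFrame(rows)
    tested = out["p_raw"].notna()
    out["p_adjusted"] = np.nan
    if tested.any():
        _, adj, _, _ = multipletests(out.loc[tested, "p_raw"], method="fdr_bh")
        out.loc[tested, "p_adjusted"] = adj
    out.attrs["adjustment"] = "benjamini-hochberg"
    out = out.sort_values("rho", key=lambda s: s.abs(), ascending=False,
                          na_position="last")
    cols = ["variable", "rho", "p_raw", "p_adjusted", "n", "note"]
    return out[cols].reset_index(drop=True)
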