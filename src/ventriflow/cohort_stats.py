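"""Per-subject indexing and cohort-level statistics.

Takes a per-subject table (demographics, LV volumes, flow-component ratios
and KE ratios), derives body-surface-area-indexed volumes, and runs the
cohort analyses: Pearson correlations between LV volume indices and 4D-flow
measures, two-group comparisons (t-test or Mann-Whitney U, chosen by a
Shapiro-Wilk normality gate), paired inflow/outflow equivalence, and
three-group subgroup comparisons (one-way ANOVA with Tukey HSD post hoc)
after stratifying patients by LVEDVI (cutoff 74 ml/m^2; the boundary value is
assigned to the lower group, the higher group is strictly > 74) or by LGE
status.

BSA uses the Mosteller formula, sqrt(height_cm * weight_kg / 3600).
Mild LV remodeling is flagged when LVEDVI > 90 ml/m^2 and LVESVI > 30 ml/m^2
(strict inequalities, conjunction); mild systolic dysfunction when LVEF < 59 %.

Missing data policy: pairwise deletion for correlations, listwise within each
group comparison; the number of records used is always reported.  No
multiple-testing correction is applied across the correlation table by
default (a Holm option is available).
"""

from __future__ import annotations

from dataclasses import dataclass, field as dc_field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multicomp import pairwise_tukeyhsd
from statsmodels.stats.multitest import multipletests

__all__ = [
    "CANONICAL_COLUMNS",
    "CohortTable",
    "bsa_mosteller",
    "classify_remodeling",
    "load_cohort",
    "save_cohort",
    "correlation_analysis",
    "group_compare",
    "paired_compare",
    "subgroup_analysis",
    "cohort_report",
]

LVEDVI_CUTOFF_ML_M2 = 74.0
MILD_REMODELING_LVEDVI = 90.0
MILD_REMODELING_LVESVI = 30.0
MILD_DYSFUNCTION_LVEF = 59.0

#: canonical column names; loaders map arbitrary file columns onto these
CANONICAL_COLUMNS = [
    "subject_id",
    "group",            # 'control' | 'patient'
    "age_y",
    "sex",
    "height_cm",
    "weight_kg",
    "lvedv_ml",
    "lvesv_ml",
    "lvef_pct",
    "lv_mass_g",
    "lge",              # 'pos' | 'neg' | 'na'
    "df_volume_ratio",
    "ne_volume_ratio",
    "def_volume_ratio",
    "df_ke_ratio",
    "ne_ke_ratio",
    "inflow_ml",
    "outflow_ml",
]

REQUIRED_COLUMNS = ["subject_id", "group"]

FLOW_VARS = ["df_volume_ratio", "ne_volume_ratio", "df_ke_ratio", "ne_ke_ratio"]


def bsa_mosteller(height_cm, weight_kg):
    """Body surface area in m^2 by the Mosteller formula (vectorised)."""
    h = np.asarray(height_cm, dtype=float)
    w = np.asarray(weight_kg, dtype=float)
    if np.any(h[~np.isnan(h)] <= 0) or np.any(w[~np.isnan(w)] <= 0):
        raise ValueError("height and weight must be positive")
    out = np.sqrt(h * w / 3600.0)
    return float(out) if out.ndim == 0 else out


def classify_remodeling(lvedvi=None, lvesvi=None, lvef=None, record=None) -> dict:
    """Mild-remodeling and mild-systolic-dysfunction flags.

    Mild remodeling requires both LVEDVI > 90 ml/m^2 and LVESVI > 30 ml/m^2;
    mild systolic dysfunction is LVEF < 59 % (all strict).  Missing inputs
    yield ``None`` flags rather than a guess.
    """
    if record is not None:
        lvedvi = record.get("lvedvi_ml_m2", lvedvi)
        lvesvi = record.get("lvesvi_ml_m2", lvesvi)
        lvef = record.get("lvef_pct", lvef)

    def _missing(x):
        return x is None or (isinstance(x, float) and np.isnan(x))

    remodeling = (
        None
        if _missing(lvedvi) or _missing(lvesvi)
        else bool(lvedvi > MILD_REMODELING_LVEDVI and lvesvi > MILD_REMODELING_LVESVI)
    )
    dysfunction = None if _missing(lvef) else bool(lvef < MILD_DYSFUNCTION_LVEF)
    return {"mild_remodeling": remodeling, "mild_systolic_dysfunction": dysfunction}


@dataclass
class CohortTable:
    """A validated per-subject table with derived indexed volumes.

    ``df`` holds one row per subject in canonical columns plus derived
    ``bsa_m2``, ``lvedvi_ml_m2``, ``lvesvi_ml_m2``, ``lvmi_g_m2`` and an
    ``lvef_consistent`` flag.
    """

    df: pd.DataFrame
    provenance: str = ""

    def __post_init__(self) -> None:
        if self.df["subject_id"].duplicated().any():
            dupes = self.df.loc[self.df["subject_id"].duplicated(), "subject_id"].tolist()
            raise ValueError(f"duplicate subject ids: {dupes}")
        self.df = _derive_fields(self.df)

    @property
    def n(self) -> int:
        return len(self.df)

    def subset(self, group: str) -> pd.DataFrame:
        return self.df[self.df["group"] == group]


def _derive_fields(df: pd.DataFrame) -> pd.DataFrame:
    df = df.copy()
    for col in CANONICAL_COLUMNS:
        if col not in df.columns:
            df[col] = np.nan
    h, w = df["height_cm"].astype(float), df["weight_kg"].astype(float)
    with np.errstate(invalid="ignore"):
        df["bsa_m2"] = np.sqrt(h * w / 3600.0)
        df["lvedvi_ml_m2"] = df["lvedv_ml"] / df["bsa_m2"]
        df["lvesvi_ml_m2"] = df["lvesv_ml"] / df["bsa_m2"]
        df["lvmi_g_m2"] = df["lv_mass_g"] / df["bsa_m2"]
        # LVEF must agree with (LVEDV - LVESV)/LVEDV within 1 % when all present
        implied = 100.0 * (df["lvedv_ml"] - df["lvesv_ml"]) / df["lvedv_ml"]
        have = df[["lvedv_ml", "lvesv_ml", "lvef_pct"]].notna().all(axis=1)
        df["lvef_consistent"] = np.where(
            have, np.abs(implied - df["lvef_pct"]) <= 1.0, np.nan
        )
    return df


def load_cohort(path: str | Path, schema_map: dict | None = None) -> CohortTable:
    """Read a cohort CSV/XLSX; ``schema_map`` binds file columns to canonical names."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"cohort table not found: {path}")
    if path.suffix.lower() in (".xlsx", ".xls"):
        df = pd.read_excel(path)
    else:
        df = pd.read_csv(path)
    if schema_map:
        missing = [src for src in schema_map if src not in df.columns]
        if missing:
            raise ValueError(f"schema map names absent file columns: {missing}")
        df = df.rename(columns=schema_map)
    absent = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if absent:
        raise ValueError(f"required columns missing after mapping: {absent}")
    return CohortTable(df=df, provenance=f"loaded from {path.name}")


def save_cohort(cohort: CohortTable, path: str | Path) -> Path:
    path = Path(path)
    cohort.df.to_csv(path, index=False)
    return path


# ---------------------------------------------------------------------------
# Statistics


def correlation_analysis(
    cohort: CohortTable,
    x_vars: list[str],
    y_vars: list[str],
    group: str | None = None,
    holm: bool = False,
) -> pd.DataFrame:
    """Pearson correlations for every (x, y) pair, pairwise-complete.

    ``group`` restricts to one group ('patient'/'control'); the default pools
    all subjects.  Zero-variance variables yield NaN r with a note.  ``holm``
    adds Holm-adjusted p-values (off by default).
    """
    df = cohort.df if group is None else cohort.subset(group)
    rows = []
    for x in x_vars:
        for y in y_vars:
            sub = df[[x, y]].dropna()
            n = len(sub)
            if n < 3:
                rows.append({"x": x, "y": y, "n": n, "r": np.nan, "p": np.nan,
                             "note": "fewer than 3 complete pairs"})
                continue
            if sub[x].nunique() < 2 or sub[y].nunique() < 2:
                rows.append({"x": x, "y": y, "n": n, "r": np.nan, "p": np.nan,
                             "note": "zero variance"})
                continue
            r, p = stats.pearsonr(sub[x], sub[y])
            rows.append({"x": x, "y": y, "n": n, "r": float(r), "p": float(p), "note": ""})
    out = pd.DataFrame(rows)
    if holm:
        ok = out["p"].notna()
        adj = np.full(len(out), np.nan)
        if ok.any():
            adj[ok.to_numpy()] = multipletests(out.loc[ok, "p"], method="holm")[1]
        out["p_holm"] = adj
    return out


def _normality_ok(x: np.ndarray, alpha: float = 0.05) -> bool:
    x = np.asarray(x, float)
    if len(x) < 3 or np.ptp(x) == 0:
        return True  # Shapiro undefined; fall back to the parametric branch
    return stats.shapiro(x).pvalue > alpha


def group_compare(
    cohort: CohortTable,
    var: str,
    group_col: str = "group",
    groups: tuple[str, str] | None = None,
    method: str = "auto",
    pooled: bool = False,
) -> dict:
    """Compare ``var`` between two groups.

    ``method='auto'`` applies a Shapiro-Wilk gate (alpha 0.05) per group and
    chooses a two-sided t-test (Welch by default; ``pooled=True`` for pooled
    variance) when both pass, otherwise a Mann-Whitney U test (normal
    approximation with tie correction).  Returns the statistic, p-value,
    per-group mean +/- SD and the number of records used per group.
    """
    df = cohort.df
    if groups is None:
        groups = tuple(pd.unique(df[group_col].dropna()))
    if len(groups) != 2:
        raise ValueError(f"need exactly two groups, got {groups}")
    samples = []
    for g in groups:
        x = df.loc[df[group_col] == g, var].dropna().to_numpy(float)
        if len(x) < 2:
            raise ValueError(f"group {g!r} has fewer than 2 observations of {var!r}")
        samples.append(x)
    a, b = samples

    chosen = method
    if method == "auto":
        chosen = "t" if (_normality_ok(a) and _normality_ok(b)) else "mwu"
    if chosen == "t":
        res = stats.ttest_ind(a, b, equal_var=pooled)
        stat, p = float(res.statistic), float(res.pvalue)
    elif chosen == "mwu":
        res = stats.mannwhitneyu(a, b, alternative="two-sided", method="asymptotic")
        stat, p = float(res.statistic), float(res.pvalue)
    else:
        raise ValueError(f"unknown method {method!r}")
    return {
        "var": var,
        "method": chosen,
        "statistic": stat,
        "p": p,
        "groups": {
            g: {"n": len(x), "mean": float(np.mean(x)), "sd": float(np.std(x, ddof=1))}
            for g, x in zip(groups, samples)
        },
    }


def paired_compare(x, y) -> dict:
    """Two-sided paired t-test (e.g. per-subject inflow vs outflow volume)."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    ok = ~(np.isnan(x) | np.isnan(y))
    x, y = x[ok], y[ok]
    if len(x) < 2:
        raise ValueError("need at least 2 complete pairs")
    res = stats.ttest_rel(x, y)
    return {
        "n": len(x),
        "mean_x": float(np.mean(x)),
        "sd_x": float(np.std(x, ddof=1)),
        "mean_y": float(np.mean(y)),
        "sd_y": float(np.std(y, ddof=1)),
        "statistic": float(res.statistic),
        "p": float(res.pvalue),
    }


def tukey_hsd(values, group_labels, alpha: float = 0.05) -> pd.DataFrame:
    """Tukey HSD pairwise comparisons; returns (group1, group2, meandiff, p_adj, reject)."""
    res = pairwise_tukeyhsd(np.asarray(values, float), np.asarray(group_labels), alpha=alpha)
    frame = pd.DataFrame(res.summary().data[1:], columns=res.summary().data[0])
    frame = frame.rename(columns={"p-adj": "p_adj"})
    return frame[["group1", "group2", "meandiff", "p_adj", "reject"]]


def _strata(cohort: CohortTable, stratifier: str, cutoff: float) -> pd.Series:
    """Three-level partition: controls plus two patient strata."""
    df = cohort.df
    strata = pd.Series(index=df.index, dtype=object)
    strata[df["group"] == "control"] = "control"
    patients = df["group"] == "patient"
    if stratifier == "lvedvi":
        # boundary LVEDVI == cutoff goes to the lower group; higher is strictly >
        strata[patients & (df["lvedvi_ml_m2"] <= cutoff)] = "lower_lvedvi"
        strata[patients & (df["lvedvi_ml_m2"] > cutoff)] = "higher_lvedvi"
    elif stratifier == "lge":
        strata[patients & (df["lge"] == "neg")] = "lge_negative"
        strata[patients & (df["lge"] == "pos")] = "lge_positive"
    else:
        raise ValueError(f"unknown stratifier {stratifier!r} (expected 'lvedvi' or 'lge')")
    return strata


def subgroup_analysis(
    cohort: CohortTable,
    stratifier: str = "lvedvi",
    vars: list[str] | None = None,
    cutoff: float = LVEDVI_CUTOFF_ML_M2,
    alpha: float = 0.05,
) -> dict:
    """Three-group comparison: controls vs two patient strata.

    Patients split at the LVEDVI cutoff (boundary to the lower group) or by
    LGE status.  For each variable: per-group mean +/- SD and n, one-way
    ANOVA F and p, and Tukey HSD adjusted pairwise p-values with significance
    at p < alpha.
    """
    vars = vars or FLOW_VARS + ["lvef_pct"]
    strata = _strata(cohort, stratifier, cutoff)
    expected = {
        "lvedvi": ["control", "lower_lvedvi", "higher_lvedvi"],
        "lge": ["control", "lge_negative", "lge_positive"],
    }[stratifier]
    present = set(pd.unique(strata.dropna()))
    for lv in expected:
        if lv not in present:
            raise ValueError(f"stratum {lv!r} is empty")
    levels = expected
    results = {}
    for var in vars:
        ok = strata.notna() & cohort.df[var].notna()
        values = cohort.df.loc[ok, var].to_numpy(float)
        labels = strata[ok].to_numpy()
        groups = {}
        for lv in levels:
            x = values[labels == lv]
            if len(x) < 2:
                raise ValueError(f"stratum {lv!r} has fewer than 2 observations of {var!r}")
            groups[lv] = {"n": len(x), "mean": float(np.mean(x)), "sd": float(np.std(x, ddof=1))}
        f, p = stats.f_oneway(*[values[labels == lv] for lv in levels])
        tukey = tukey_hsd(values, labels, alpha=alpha)
        results[var] = {
            "groups": groups,
            "anova_F": float(f),
            "anova_p": float(p),
            "tukey": tukey,
        }
    return results


def cohort_report(cohort: CohortTable, cutoff: float = LVEDVI_CUTOFF_ML_M2) -> dict:
    """Assemble the full statistics stage: correlations, subgroup tables, QC.

    The correlation table is produced both pooled across all subjects and for
    patients only (which population the published correlations pool is
    ambiguous, so both are reported, flagged by the ``population`` column).
    """
    if cohort.n < 3:
        raise ValueError(f"need at least 3 subjects for cohort statistics, got {cohort.n}")
    out: dict = {}
    x_vars = ["lvedvi_ml_m2", "lvesvi_ml_m2", "lvef_pct"]
    frames = []
    for population, group in (("all", None), ("patients", "patient")):
        corr = correlation_analysis(cohort, FLOW_VARS, x_vars, group=group)
        corr.insert(0, "population", population)
        frames.append(corr)
    out["correlations"] = pd.concat(frames, ignore_index=True)
    for strat, key in (("lvedvi", "subgroups_lvedvi"), ("lge", "subgroups_lge")):
        try:
            out[key] = subgroup_analysis(cohort, stratifier=strat, cutoff=cutoff)
        except ValueError as exc:
            out[key] = {"error": str(exc)}
    io = cohort.df[["inflow_ml", "outflow_ml"]].dropna()
    if len(io) >= 2:
        out["inflow_vs_outflow"] = paired_compare(io["inflow_ml"], io["outflow_ml"])
    return out
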