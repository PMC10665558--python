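"""Specimen and species-level volumetric traits.

Ingests tables of brain-compartment volumes (cerebellum, cerebrum, ansiform
area, optionally body mass), computes robust per-species summaries (median,
raw median absolute deviation, MAD as % of median), screens intraspecific
outliers (Shapiro--Wilk normality plus the +/- 1.5 IQR boxplot rule), forms
volume-ratio tables, and applies the log10 transform used by all the
comparative models.  Encephalization quotients and standardized brain--body
residuals support cross-clade visualisation.

Volumes are in cubic millimetres internally; body mass in grams.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "TRAIT_COLUMNS",
    "TraitTableError",
    "load_trait_table",
    "raw_mad",
    "summarize_species",
    "screen_outliers",
    "compute_ratios",
    "log10_transform",
    "round_half_away",
    "encephalization_quotient",
    "brain_body_residuals",
]

#: canonical trait column names, in mm^3
TRAIT_COLUMNS = ("cerebellum", "cerebrum", "ansiform")

#: species with at least this many specimens get MAD% and outlier screening
MIN_N_FOR_VARIABILITY = 4


class TraitTableError(ValueError):
    """Trait-table load or validation failure; message cites row numbers."""


def round_half_away(x: float, ndigits: int = 2) -> float:
    """Round half away from zero (the convention of the printed ratio table;
    banker's rounding would flip some .xx5 cells)."""
    if np.isnan(x):
        return x
    q = 10.0 ** ndigits
    return math.copysign(math.floor(abs(x) * q + 0.5) / q, x)


def raw_mad(values: Sequence[float]) -> float:
    """Raw median absolute deviation: median(|x - median(x)|).

    Deliberately *not* scaled by the 1.4826 normal-consistency factor; the
    summaries here report spread in the trait's own units.
    """
    v = np.asarray(values, dtype=float)
    return float(np.median(np.abs(v - np.median(v))))


def load_trait_table(path, unit: str | None = None) -> pd.DataFrame:
    """Load a specimen- or species-level trait table from CSV/TSV.

    The file must name a ``species`` column and at least one volume column
    among ``cerebellum``, ``cerebrum``, ``ansiform`` (a ``unit`` column or the
    ``unit=`` argument may declare ``mm3`` (default) or ``cm3``, the latter
    converted on load).  Optional columns (``specimen``, ``body_mass_g``,
    ``sex``, ``age``, ``source``, ...) pass through.
    """
    sep = "\t" if str(path).endswith((".tsv", ".txt")) else ","
    df = pd.read_csv(path, sep=sep, comment="#")
    df.columns = [c.strip().lower() for c in df.columns]
    if "species" not in df.columns:
        raise TraitTableError(f"{path}: no 'species' column (found {list(df.columns)})")
    present = [c for c in TRAIT_COLUMNS if c in df.columns]
    if not present:
        raise TraitTableError(f"{path}: no volume column among {TRAIT_COLUMNS}")
    unit_col = df.pop("unit") if "unit" in df.columns else None
    for col in present:
        df[col] = pd.to_numeric(df[col], errors="coerce")
        scale = np.ones(len(df))
        declared = unit_col if unit_col is not None else pd.Series([unit or "mm3"] * len(df))
        scale[declared.str.lower().isin(["cm3", "cm^3", "cc"]).to_numpy()] = 1000.0
        df[col] = df[col] * scale
        bad = df.index[df[col] <= 0].tolist()
        if bad:
            raise TraitTableError(f"{path}: non-positive {col} volume at rows {bad}")
    if "specimen" in df.columns and df["specimen"].notna().all():
        dup = df.loc[df["specimen"].duplicated(), "specimen"].tolist()
        if dup:
            raise TraitTableError(f"{path}: duplicate specimen ids {dup}")
    if df["species"].isna().any():
        rows = df.index[df["species"].isna()].tolist()
        raise TraitTableError(f"{path}: missing species name at rows {rows}")
    return df


def summarize_species(
    table: pd.DataFrame,
    min_n_for_variability: int = MIN_N_FOR_VARIABILITY,
    traits: Sequence[str] = TRAIT_COLUMNS,
) -> pd.DataFrame:
    """Per-species median, raw MAD and MAD% per trait.

    MAD% = 100 * MAD / median is reported only for species with at least
    ``min_n_for_variability`` observations of that trait (spread estimated
    from one or two specimens is noise, not variability).
    """
    if table.empty:
        raise TraitTableError("empty trait table")
    rows = []
    for species, grp in table.groupby("species", sort=False):
        rec: dict = {"species": species, "n": len(grp)}
        for trait in traits:
            if trait not in grp.columns:
                continue
            vals = grp[trait].dropna().to_numpy(dtype=float)
            if vals.size == 0:
                continue
            rec[f"{trait}_n"] = vals.size
            rec[f"{trait}_median"] = float(np.median(vals))
            rec[f"{trait}_mad"] = raw_mad(vals)
            if vals.size >= min_n_for_variability:
                rec[f"{trait}_mad_pct"] = 100.0 * rec[f"{trait}_mad"] / rec[f"{trait}_median"]
        rows.append(rec)
    return pd.DataFrame(rows).set_index("species")


def screen_outliers(
    table: pd.DataFrame,
    min_n: int = MIN_N_FOR_VARIABILITY,
    traits: Sequence[str] = TRAIT_COLUMNS,
) -> pd.DataFrame:
    """Intraspecific normality and outlier screen.

    For every species x trait with >= ``min_n`` observations: a Shapiro--Wilk
    normality p-value and boxplot-rule flags for specimens outside
    [Q1 - 1.5 IQR, Q3 + 1.5 IQR].  Species below ``min_n`` are skipped, never
    an error.  Returns one row per screened species x trait with the flagged
    specimen row indices.
    """
    out = []
    for species, grp in table.groupby("species", sort=False):
        for trait in traits:
            if trait not in grp.columns:
                continue
            sub = grp[grp[trait].notna()]
            vals = sub[trait].to_numpy(dtype=float)
            if vals.size < min_n:
                continue
            q1, q3 = np.percentile(vals, [25, 75])
            iqr = q3 - q1
            lo, hi = q1 - 1.5 * iqr, q3 + 1.5 * iqr
            mask = (vals < lo) | (vals > hi)
            if np.ptp(vals) == 0:
                shapiro_p = np.nan  # degenerate: all equal, normality untestable
            else:
                shapiro_p = float(stats.shapiro(vals).pvalue)
            out.append(
                {
                    "species": species,
                    "trait": trait,
                    "n": vals.size,
                    "shapiro_p": shapiro_p,
                    "fence_low": lo,
                    "fence_high": hi,
                    "n_outliers": int(mask.sum()),
                    "outlier_rows": list(sub.index[mask]),
                    "outlier_values": list(vals[mask]),
                }
            )
    return pd.DataFrame(
        out,
        columns=[
            "species", "trait", "n", "shapiro_p", "fence_low", "fence_high",
            "n_outliers", "outlier_rows", "outlier_values",
        ],
    )


def exclude_flagged(table: pd.DataFrame, screen: pd.DataFrame) -> pd.DataFrame:
    """Drop the specimens flagged by :func:`screen_outliers` (two-stage
    policy: flags are always computed, exclusion is an explicit opt-in)."""
    drop: set = set()
    for rows in screen["outlier_rows"]:
        drop.update(rows)
    return table.drop(index=sorted(drop))


def compute_ratios(summary: pd.DataFrame, table: pd.DataFrame | None = None) -> pd.DataFrame:
    """Volume-ratio table: cerebellum/cerebrum % and ansiform/cerebellum %.

    Ratios of species medians, displayed to 2 decimals (half away from zero)
    with the unrounded value kept alongside.  When the specimen-level table is
    supplied, species with several specimens also get the median of
    per-specimen ratios and its MAD — the quantity the source table prints
    for multi-specimen species.
    """
    pairs = [("cerebellum", "cerebrum", "cbl_cbr"), ("ansiform", "cerebellum", "ans_cbl")]
    out = pd.DataFrame(index=summary.index)
    for num, den, tag in pairs:
        ncol, dcol = f"{num}_median", f"{den}_median"
        if ncol not in summary.columns or dcol not in summary.columns:
            continue
        ratio = 100.0 * summary[ncol] / summary[dcol]
        out[f"{tag}_pct"] = ratio
        out[f"{tag}_pct_display"] = ratio.map(lambda v: round_half_away(v, 2))
    if table is not None:
        for num, den, tag in pairs:
            if num not in table.columns or den not in table.columns:
                continue
            med, mad = {}, {}
            for species, grp in table.groupby("species", sort=False):
                r = (100.0 * grp[num] / grp[den]).dropna().to_numpy(dtype=float)
                if r.size >= 2:
                    med[species] = float(np.median(r))
                    mad[species] = raw_mad(r)
            out[f"{tag}_specimen_median_pct"] = pd.Series(med)
            out[f"{tag}_specimen_mad_pct"] = pd.Series(mad)
    return out


def log10_transform(table: pd.DataFrame, traits: Sequence[str] = TRAIT_COLUMNS) -> pd.DataFrame:
    """Append ``log_<trait>`` columns (log10 of the mm^3 volume).

    Works on specimen tables and on species summaries (``<trait>_median``
    columns), whichever columns are present.
    """
    out = table.copy()
    for trait in traits:
        for col, new in ((trait, f"log_{trait}"), (f"{trait}_median", f"log_{trait}")):
            if col in out.columns:
                vals = out[col].astype(float)
                if (vals <= 0).any():
                    raise TraitTableError(f"non-positive {col} value; cannot log-transform")
                out[new] = np.log10(vals)
                break
    return out


def encephalization_quotient(
    brain: float | np.ndarray,
    body_mass: float | np.ndarray,
    coefficient: float = 0.12,
    exponent: float = 2.0 / 3.0,
) -> float | np.ndarray:
    """Jerison's encephalization quotient: observed / expected brain size.

    EQ = brain / (coefficient * P**exponent) with P the body mass.  The
    classic mammalian reference allometry (coefficient 0.12, exponent 2/3) is
    stated for brain mass in grams against body mass in grams; pass a
    different coefficient for other unit conventions.  Callers are expected
    to keep brain and body in the convention the coefficient was derived for.
    """
    brain = np.asarray(brain, dtype=float)
    body = np.asarray(body_mass, dtype=float)
    if np.any(brain <= 0) or np.any(body <= 0):
        raise ValueError("brain and body mass must be positive")
    eq = brain / (coefficient * body ** exponent)
    return float(eq) if eq.ndim == 0 else eq


def brain_body_residuals(log_brain: Sequence[float], log_body: Sequence[float]) -> np.ndarray:
    """Standardized residuals from the OLS fit of log brain on log body.

    Each species' deviation from the regression, in units of the residual
    standard deviation — the quantity plotted to compare encephalization
    across clades without committing to a reference allometry.
    """
    y = np.asarray(log_brain, dtype=float)
    x = np.asarray(log_body, dtype=float)
    if y.size != x.size or y.size < 3:
        raise ValueError("need >= 3 paired observations")
    X = np.column_stack([np.ones_like(x), x])
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ beta
    sd = np.sqrt(resid @ resid / (y.size - 2))
    if sd <= 1e-12 * max(1.0, float(np.abs(y).max())):  # numerically collinear
        return np.zeros_like(resid)
    return resid / sd
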