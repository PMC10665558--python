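"""Robustness battery for the allometric conclusions.

Postmortem and museum brains shrink, and different compartments may shrink
differently; intraspecific sampling is thin.  These analyses ask how much of
that uncertainty the allometric slope can absorb: Monte-Carlo perturbation of
the volumes with random multiplicative factors (within one brain, between
compartments; or across brains, all compartments together), provenance-subset
refits with a grade-shift test, and exclusion of observations that disagree
with literature reference volumes by more than a set factor.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal, Mapping, Sequence

import numpy as np
import pandas as pd

from .pgls import GradeShiftTest, isometry_test, pancova, pgls_fit
from .tree import Phylogeny

__all__ = [
    "RobustnessReport",
    "shrinkage_simulation",
    "subset_compare",
    "literature_outlier_filter",
]


@dataclass
class RobustnessReport:
    """Per-replicate slopes/intercepts/isometry calls plus their summary."""

    replicates: pd.DataFrame          # slope, intercept, isometry95 per replicate
    baseline_slope: float
    baseline_intercept: float
    slope_quantiles: dict             # 2.5 / 50 / 97.5 %
    isometry_fractions: dict          # fraction of replicates per class at 95%
    config: dict

    @property
    def n_sims(self) -> int:
        return len(self.replicates)


def _draw_factors(rng: np.random.Generator, lo: float, hi: float, size: int,
                  distribution: str) -> np.ndarray:
    if distribution == "log-uniform":
        return np.exp(rng.uniform(np.log(lo), np.log(hi), size))
    if distribution == "uniform":
        return rng.uniform(lo, hi, size)
    raise ValueError(f"unknown factor distribution {distribution!r}")


def shrinkage_simulation(
    tree: Phylogeny,
    traits: pd.DataFrame,
    mode: Literal["within_brain", "across_brain"] = "within_brain",
    factor_range: tuple[float, float] = (0.91, 1.1),
    n_sims: int = 10_000,
    seed: int | None = None,
    y: str = "cerebellum",
    x: str = "cerebrum",
    perturbed_trait: str | None = None,
    distribution: str = "log-uniform",
) -> RobustnessReport:
    """Re-fit the y ~ x PGLS under random multiplicative volume errors.

    ``traits`` holds species-level volumes in mm^3 (columns ``y`` and ``x``).
    Per replicate and per species, factors are drawn from a log-uniform (by
    default) distribution on ``factor_range``:

    - ``within_brain``: one trait (``perturbed_trait``, default ``y``) is
      multiplied by an independent per-species draw — differential shrinkage
      between compartments of the same brain.  Which compartment carries the
      factor is immaterial to the slope; it only mirrors the intercept.
    - ``across_brain``: both traits share one per-species draw — whole-brain
      scale error, which on the log-log regression perturbs leverage but not
      the pairing of x and y.

    Factors are per species (a single global factor would cancel exactly in
    log space and could never move the slope).  The report is bit-identical
    for identical seed and config.
    """
    lo, hi = factor_range
    if not (0 < lo <= hi):
        raise ValueError(f"factor range must satisfy 0 < lo <= hi, got {factor_range}")
    if n_sims < 1:
        raise ValueError("n_sims must be >= 1")
    for col in (y, x):
        if col not in traits.columns:
            raise ValueError(f"traits table lacks column {col!r}")
    data = traits[[y, x]].dropna()
    species = list(data.index)
    work = tree.prune_to(species)
    rng = np.random.default_rng(seed)
    target = perturbed_trait or y
    if target not in (y, x):
        raise ValueError(f"perturbed_trait must be {y!r} or {x!r}")

    from .tree import phylo_vcv
    Cm = phylo_vcv(work, order=species).matrix   # fixed across replicates
    base = pgls_fit(None, np.log10(data[x]).rename(x), np.log10(data[y]).rename(y),
                    cov_model="BM", C=Cm)
    rows = []
    n = len(species)
    for _ in range(n_sims):
        vols = data.copy()
        if mode == "within_brain":
            vols[target] = vols[target] * _draw_factors(rng, lo, hi, n, distribution)
        elif mode == "across_brain":
            f = _draw_factors(rng, lo, hi, n, distribution)
            vols[y] = vols[y] * f
            vols[x] = vols[x] * f
        else:
            raise ValueError(f"unknown mode {mode!r}")
        fit = pgls_fit(None, np.log10(vols[x]).rename(x), np.log10(vols[y]).rename(y),
                       cov_model="BM", C=Cm)
        rows.append((fit.slope, fit.intercept, isometry_test(fit)["at95"]))
    reps = pd.DataFrame(rows, columns=["slope", "intercept", "isometry95"])
    q = np.percentile(reps["slope"], [2.5, 50, 97.5])
    fractions = reps["isometry95"].value_counts(normalize=True).to_dict()
    return RobustnessReport(
        replicates=reps,
        baseline_slope=base.slope,
        baseline_intercept=base.intercept,
        slope_quantiles={"q2.5": float(q[0]), "q50": float(q[1]), "q97.5": float(q[2])},
        isometry_fractions={k: float(v) for k, v in sorted(fractions.items())},
        config={
            "mode": mode, "factor_range": [lo, hi], "n_sims": n_sims,
            "seed": seed, "y": y, "x": x, "perturbed_trait": target,
            "distribution": distribution,
        },
    )


def subset_compare(
    tree: Phylogeny,
    specimens: pd.DataFrame,
    subset_mask: pd.Series | Sequence[bool],
    label: str = "subset",
    y: str = "cerebellum",
    x: str = "cerebrum",
) -> dict:
    """PGLS inside and outside a specimen subset, plus a grade-shift test.

    ``subset_mask`` marks specimens (rows of the specimen table); species are
    assigned to the subset containing the majority of their specimens (ties
    fall inside).  Both subsets must retain >= 3 species.  Returns the two
    fits and a species-level phylogenetic ANCOVA on the grouping.
    """
    mask = pd.Series(np.asarray(subset_mask, dtype=bool), index=specimens.index)
    if mask.all() or (~mask).all():
        raise ValueError(f"{label}: mask must leave both subsets nonempty")
    from .traits import summarize_species

    in_frac = mask.groupby(specimens["species"]).mean()
    group = pd.Series(np.where(in_frac >= 0.5, label, f"non-{label}"), index=in_frac.index)

    fits = {}
    for side, tag in ((mask, label), (~mask, f"non-{label}")):
        summ = summarize_species(specimens[side])
        data = summ[[f"{y}_median", f"{x}_median"]].dropna()
        if len(data) < 3:
            raise ValueError(f"{tag}: fewer than 3 species with both traits")
        sub = tree.prune_to(list(data.index))
        fits[tag] = pgls_fit(sub, np.log10(data[f"{x}_median"]).rename(x),
                             np.log10(data[f"{y}_median"]).rename(y))

    summ_all = summarize_species(specimens)
    data_all = summ_all[[f"{y}_median", f"{x}_median"]].dropna()
    work = tree.prune_to(list(data_all.index))
    shift = pancova(work, np.log10(data_all[f"{x}_median"]).rename(x),
                    np.log10(data_all[f"{y}_median"]).rename(y),
                    groups=group.loc[data_all.index], vary="both")
    return {"fit_in": fits[label], "fit_out": fits[f"non-{label}"],
            "grade_shift": shift, "groups": group}


def literature_outlier_filter(
    specimens: pd.DataFrame,
    reference: pd.DataFrame | Mapping,
    factor: float = 2.0,
    traits: Sequence[str] = ("cerebellum",),
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Drop observations disagreeing with literature volumes by > ``factor``.

    ``reference`` is species x trait reference volumes (mm^3).  An
    observation v is excluded iff v > factor * ref or v < ref / factor; the
    boundary itself is retained.  Returns the filtered table and an exclusion
    log with both values, which round-trips: dropping the logged rows from
    the original table reproduces the filtered table.
    """
    if factor <= 1:
        raise ValueError("factor must exceed 1")
    ref = pd.DataFrame(reference)
    log_rows = []
    drop: list = []
    for idx, row in specimens.iterrows():
        sp = row["species"]
        if sp not in ref.index:
            continue
        for trait in traits:
            if trait not in specimens.columns or trait not in ref.columns:
                continue
            v, r = row[trait], ref.loc[sp, trait]
            if pd.isna(v) or pd.isna(r):
                continue
            if v > factor * r or v < r / factor:
                drop.append(idx)
                log_rows.append({"row": idx, "species": sp, "trait": trait,
                                 "value": float(v), "reference": float(r),
                                 "ratio": float(v / r)})
                break
    log = pd.DataFrame(log_rows, columns=["row", "species", "trait", "value",
                                          "reference", "ratio"])
    return specimens.drop(index=drop), log
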