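"""Descriptive and summary outputs: frequency tables, cost decomposition,
parity distributions, and the sire EBV vs daughter-mean regression."""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .treatments import CATEGORIES, SPECIFIC_TREATMENTS, TREATMENT_TYPES


def round_half_away(x: float, ndigits: int = 0) -> float:
    """Round half away from zero (the convention for all printed tables)."""
    factor = 10.0**ndigits
    return math.copysign(math.floor(abs(x) * factor + 0.5), x) / factor


def percent_of_total(component: float, total: float) -> tuple[float, int]:
    """Component as a percent of total: (unrounded, integer for display)."""
    if total <= 0:
        raise ValueError("total must be positive")
    pct = 100.0 * component / total
    return pct, int(round_half_away(pct))


def treatment_frequency(
    events: pd.DataFrame,
    phenotypes: pd.DataFrame,
    group: str,
    parity: int = 1,
) -> float:
    """Percent of cows at risk with >= 1 deduplicated event in a category
    (or a specific treatment code) during the given parity."""
    at_risk = phenotypes.loc[phenotypes["parity"] == parity, "cow_id"].unique()
    if len(at_risk) == 0:
        raise ValueError("no cows at risk")
    if events.empty:
        return 0.0
    ev = events[events["parity"] == parity] if "parity" in events.columns else events
    if group in CATEGORIES:
        codes = [c for c, t in TREATMENT_TYPES.items() if t.category.value == group]
    else:
        codes = [group]
    treated = ev.loc[ev["treatment_code"].isin(codes), "cow_id"].unique()
    n_treated = len(set(treated) & set(at_risk))
    return 100.0 * n_treated / len(at_risk)


def parity_distribution(phenotypes: pd.DataFrame) -> pd.DataFrame:
    """Lactation counts per parity with integer-rounded percent of total."""
    counts = phenotypes.groupby("parity")["cow_id"].count()
    counts = counts.reindex(sorted(counts.index), fill_value=0)
    total = int(counts.sum())
    rows = []
    for p, n in counts.items():
        pct = 100.0 * n / total if total else 0.0
        rows.append({"parity": p, "n": int(n), "percent": int(round_half_away(pct))})
    return pd.DataFrame(rows)


def category_cost_table(
    phenotypes: pd.DataFrame,
    events: pd.DataFrame | None = None,
    lsm: dict | None = None,
    parity: int = 1,
) -> pd.DataFrame:
    """Per-category cost summary: LSM (or raw mean), SEM, percent of THC,
    and treatment frequency; plus the four specific treatments.

    ``lsm`` maps row label -> (estimate, sem) from univariate fits; raw
    phenotypic means are used where no fit is supplied.
    """
    phen1 = phenotypes[phenotypes["parity"] == parity]
    lsm = lsm or {}

    def _mean_sem(col):
        if col in lsm:
            est, sem = lsm[col]
            return float(est), (float(sem) if sem is not None else np.nan)
        x = phen1[col].to_numpy(dtype=float)
        return float(x.mean()), float(x.std(ddof=1) / np.sqrt(len(x)))

    thc_est, thc_sem = _mean_sem("THC")
    rows = []
    for cat in CATEGORIES:
        est, sem = _mean_sem(cat)
        pct, pct_int = percent_of_total(est, thc_est)
        freq = (
            treatment_frequency(events, phenotypes, cat, parity)
            if events is not None
            else np.nan
        )
        rows.append(
            {"trait": cat, "lsm": est, "sem": sem, "percent_of_thc": pct_int,
             "percent_unrounded": pct, "frequency": freq}
        )
    rows.append(
        {"trait": "THC", "lsm": thc_est, "sem": thc_sem, "percent_of_thc": 100,
         "percent_unrounded": 100.0, "frequency": np.nan}
    )
    for code in SPECIFIC_TREATMENTS:
        col = f"{code}_cost"
        est, sem = _mean_sem(col)
        pct, pct_int = percent_of_total(est, thc_est)
        freq = (
            treatment_frequency(events, phenotypes, code, parity)
            if events is not None
            else np.nan
        )
        rows.append(
            {"trait": code, "lsm": est, "sem": sem, "percent_of_thc": pct_int,
             "percent_unrounded": pct, "frequency": freq}
        )
    return pd.DataFrame(rows)


@dataclass
class SireRegression:
    """OLS of daughter trait means on sire EBVs over well-represented sires."""

    table: pd.DataFrame  # sire_id, n_daughters, ebv, daughter_mean
    slope: float
    intercept: float
    min_daughters: int

    @property
    def ebv_range(self) -> float:
        return float(self.table["ebv"].max() - self.table["ebv"].min())


def sire_daughter_regression(
    ebv_table: pd.DataFrame,
    phenotypes: pd.DataFrame,
    pedigree_frame: pd.DataFrame,
    trait: str = "THC",
    min_daughters: int = 10,
    parity: int = 1,
    herd_adjust: bool = False,
) -> SireRegression:
    """Regress per-sire daughter means on sire EBVs.

    Only sires with at least ``min_daughters`` daughters having records are
    included (default 10).  With ``herd_adjust`` the daughter phenotypes are
    first centered on herd means.
    """
    phen = phenotypes[phenotypes["parity"] == parity].copy()
    if herd_adjust:
        phen[trait] = phen[trait] - phen.groupby("herd_id")[trait].transform("mean") + phen[trait].mean()
    sire_of = pedigree_frame.set_index("animal_id")["sire_id"]
    phen["sire_id"] = phen["cow_id"].map(sire_of)
    grouped = phen.dropna(subset=["sire_id", trait]).groupby("sire_id")[trait].agg(["count", "mean"])
    grouped = grouped[grouped["count"] >= min_daughters]
    if len(grouped) < 3:
        raise ValueError(
            f"fewer than 3 sires have {min_daughters}+ daughters with records"
        )
    col = trait if trait in ebv_table.columns else ebv_table.columns[0]
    ebvs = ebv_table[col]
    tab = pd.DataFrame(
        {
            "sire_id": grouped.index,
            "n_daughters": grouped["count"].to_numpy(),
            "ebv": ebvs.reindex(grouped.index).to_numpy(),
            "daughter_mean": grouped["mean"].to_numpy(),
        }
    ).dropna()
    slope, intercept = np.polyfit(tab["ebv"], tab["daughter_mean"], 1)
    if not np.isfinite(slope):
        raise ValueError("regression slope is not finite")
    return SireRegression(
        table=tab.reset_index(drop=True),
        slope=float(slope),
        intercept=float(intercept),
        min_daughters=min_daughters,
    )


def genetic_parameter_table(fits: dict) -> pd.DataFrame:
    """Heritabilities (diagonal) with genetic/phenotypic correlations from a
    dict of pairwise bivariate fits keyed by (trait_a, trait_b), plus
    univariate fits keyed by a single trait name."""
    rows = []
    for key, fit in fits.items():
        if isinstance(key, str):
            pe = fit.heritability[key]
            rows.append(
                {"trait_a": key, "trait_b": key, "parameter": "h2",
                 "estimate": pe.estimate, "se": pe.se, "significant": pe.significant}
            )
        else:
            a, b = key
            for name, d in (("r_g", fit.genetic_corr), ("r_p", fit.phenotypic_corr)):
                pe = d.get((a, b)) or d.get((b, a))
                if pe is None:
                    continue
                rows.append(
                    {"trait_a": a, "trait_b": b, "parameter": name,
                     "estimate": pe.estimate, "se": pe.se, "significant": pe.significant}
                )
    return pd.DataFrame(rows)


def render_summary(table: pd.DataFrame, title: str) -> str:
    """Plain-text rendering of a summary table (currency to 2 decimals)."""
    out = [title, "-" * len(title)]
    df = table.copy()
    for col in df.columns:
        if df[col].dtype.kind == "f":
            df[col] = df[col].map(lambda v: "" if pd.isna(v) else f"{v:.2f}")
    out.append(df.to_string(index=False))
    return "\n".join(out) + "\n"
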