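"""Heat-stress biomarker aggregation and statistics.

Two biomarkers are carried per individual snail after an 8 h exposure at one
of the design temperatures (25 is the control, then 33, 38, 40, 43, 45,
48 °C):

* the relative Hsp70 level (optical blot volume relative to an internal
  standard, dimensionless, n = 10 per population x temperature), and
* three semi-quantitative histopathology scores on a 1-5 scale (1 = control
  status, 3 = reaction, 5 = destruction) for hepatopancreas tubules,
  digestive cells, and calcium cells (n = 8 per cell).

Aggregations: per-cell mean assessment values (MAV +/- SD), Hsp70 group means
expressed as a percentage of the 25 °C control mean (control = 100%), the
temperature of maximum Hsp70 induction, and the digestive/calcium integrity
ratio (< 1 means digestive cells are in better condition).

Tests: two-sided Mann-Whitney rank-sum comparisons of each exposure group
against the control with Bonferroni-corrected significance tiers, and a
one-way ANOVA with Tukey-Kramer HSD pairwise comparisons rendered as a
compact letter display.

The canonical data container is a tidy DataFrame with columns
``individual_id, population_id, temperature, hsp70_rel, tubule_score,
digestive_score, calcium_score`` (empty measurement cells allowed).
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass
from functools import lru_cache as _lru_cache
from math import comb
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)

#: Exposure temperatures of the study design (°C); 25 °C is the control.
TEMPERATURES = (25, 33, 38, 40, 43, 45, 48)
CONTROL_TEMPERATURE = 25

SCORE_COLUMNS = ("tubule_score", "digestive_score", "calcium_score")
MEASUREMENT_COLUMNS = ("hsp70_rel",) + SCORE_COLUMNS

#: Exposure temperatures compared against the control for each variable;
#: the Bonferroni m equals the number of comparisons (4 for histology,
#: 6 for Hsp70).
HSP70_TEST_TEMPS = (33, 38, 40, 43, 45, 48)
HISTOLOGY_TEST_TEMPS = (33, 40, 43, 48)


def validate_physiology(df: pd.DataFrame) -> pd.DataFrame:
    """Validate the tidy per-individual table; returns it with numeric dtypes."""
    required = {"population_id", "temperature"} | set(MEASUREMENT_COLUMNS)
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"physiology table missing columns: {sorted(missing)}")
    df = df.copy()
    df["population_id"] = df["population_id"].astype(str)
    for col in ("temperature",) + MEASUREMENT_COLUMNS:
        df[col] = pd.to_numeric(df[col], errors="coerce")
    bad_t = set(df["temperature"].dropna().unique()) - set(TEMPERATURES)
    if bad_t:
        raise ValueError(f"temperatures outside the study design: {sorted(bad_t)}")
    for col in SCORE_COLUMNS:
        vals = df[col].dropna()
        if ((vals < 1) | (vals > 5)).any():
            raise ValueError(f"{col} outside the 1-5 scale")
    if (df["hsp70_rel"].dropna() < 0).any():
        raise ValueError("hsp70_rel must be non-negative")
    if df[list(MEASUREMENT_COLUMNS)].isna().all(axis=1).any():
        raise ValueError("some individuals carry no measurement at all")
    return df


def read_physiology(path: str | Path) -> pd.DataFrame:
    return validate_physiology(pd.read_csv(path))


def mean_assessment_value(
    df: pd.DataFrame, population_id: str, temperature: int, tissue: str
) -> tuple[float, float]:
    """MAV: arithmetic mean and sample SD of the 1-5 scores of one cell."""
    col = tissue if tissue.endswith("_score") else f"{tissue}_score"
    if col not in SCORE_COLUMNS:
        raise ValueError(f"unknown tissue {tissue!r}")
    sel = df[
        (df["population_id"] == str(population_id))
        & (df["temperature"] == temperature)
    ][col].dropna()
    if sel.empty:
        raise ValueError(
            f"no {col} records for population {population_id!r} at "
            f"{temperature} °C"
        )
    mean = float(sel.mean())
    sd = float(sel.std(ddof=1)) if len(sel) > 1 else 0.0
    return mean, sd


def hsp70_percent_of_control(df: pd.DataFrame, population_id: str) -> pd.Series:
    """Per-temperature 100 x mean(hsp70) / mean(hsp70 at 25 °C)."""
    sub = df[df["population_id"] == str(population_id)].dropna(subset=["hsp70_rel"])
    means = sub.groupby("temperature")["hsp70_rel"].mean()
    if CONTROL_TEMPERATURE not in means.index or means[CONTROL_TEMPERATURE] <= 0:
        raise ValueError(
            f"population {population_id!r} lacks a positive-mean 25 °C control"
        )
    return 100.0 * means / means[CONTROL_TEMPERATURE]


def max_induction(df: pd.DataFrame, population_id: str) -> tuple[int, float]:
    """(temperature, %) of the maximum Hsp70 percent-of-control.

    The control temperature is excluded from the argmax; ties go to the lower
    temperature.
    """
    pct = hsp70_percent_of_control(df, population_id)
    noncontrol = pct.drop(CONTROL_TEMPERATURE)
    if noncontrol.empty:
        raise ValueError("need at least two temperature groups")
    best = noncontrol.max()
    winners = sorted(noncontrol[noncontrol == best].index)
    if len(winners) > 1:
        logger.info(
            "max induction tie for population %s at %s; choosing %s",
            population_id, winners, winners[0],
        )
    return int(winners[0]), float(best)


def integrity_ratio(df: pd.DataFrame, population_id: str, temperature: int) -> float:
    """MAV(digestive) / MAV(calcium); < 1 means digestive cells in better shape."""
    dig, _ = mean_assessment_value(df, population_id, temperature, "digestive")
    cal, _ = mean_assessment_value(df, population_id, temperature, "calcium")
    return dig / cal


def summarize(df: pd.DataFrame) -> pd.DataFrame:
    """Per population x temperature summary of all biomarkers.

    Columns: n and mean/SD for Hsp70 and the three MAVs, percent of control,
    and the integrity ratio; rows where a biomarker was not measured hold NaN.
    """
    rows = []
    for pop, sub in df.groupby("population_id"):
        try:
            pct = hsp70_percent_of_control(df, pop)
        except ValueError:
            pct = pd.Series(dtype=float)
        for temp, cell in sub.groupby("temperature"):
            row = {"population_id": pop, "temperature": int(temp)}
            hsp = cell["hsp70_rel"].dropna()
            row["hsp70_n"] = len(hsp)
            row["hsp70_mean"] = hsp.mean() if len(hsp) else np.nan
            row["hsp70_sd"] = hsp.std(ddof=1) if len(hsp) > 1 else np.nan
            row["hsp70_percent_of_control"] = pct.get(temp, np.nan)
            for col in SCORE_COLUMNS:
                name = col.replace("_score", "")
                vals = cell[col].dropna()
                row[f"mav_{name}_n"] = len(vals)
                row[f"mav_{name}"] = vals.mean() if len(vals) else np.nan
                row[f"mav_{name}_sd"] = vals.std(ddof=1) if len(vals) > 1 else np.nan
            if row["mav_digestive_n"] and row["mav_calcium_n"]:
                row["integrity_ratio"] = row["mav_digestive"] / row["mav_calcium"]
            else:
                row["integrity_ratio"] = np.nan
            rows.append(row)
    return pd.DataFrame(rows).sort_values(
        ["population_id", "temperature"]
    ).reset_index(drop=True)


@_lru_cache(maxsize=32)
def _subset_index(n_total: int, n_first: int) -> np.ndarray:
    import itertools

    return np.array(list(itertools.combinations(range(n_total), n_first)))


def rank_sum_test(x: np.ndarray, y: np.ndarray,
                  max_enumeration: int = 250_000) -> float:
    """Two-sided rank-sum (Mann-Whitney) p-value between two samples.

    Semi-quantitative scores tie heavily and the normal approximation is
    unreliable at the study's group sizes (8-10), so for small groups the
    p-value is computed by exact enumeration of the permutation distribution
    of the rank-sum statistic (ties handled through midranks; two-sided tail
    defined symmetrically around the null mean).  Groups too large to
    enumerate fall back to the tie-corrected normal approximation with
    continuity correction.  All-identical pooled data give p = 1.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    pooled = np.concatenate([x, y])
    if np.all(pooled == pooled[0]):
        logger.warning(
            "degenerate rank-sum comparison (all values identical): p = 1"
        )
        return 1.0
    n1, n2 = len(x), len(y)
    if comb(n1 + n2, n1) <= max_enumeration:
        ranks = stats.rankdata(pooled)
        mu = n1 * n2 / 2.0
        obs = ranks[:n1].sum() - n1 * (n1 + 1) / 2.0  # observed U of x
        idx = _subset_index(n1 + n2, n1)
        us = ranks[idx].sum(axis=1) - n1 * (n1 + 1) / 2.0
        p = float(np.mean(np.abs(us - mu) >= abs(obs - mu) - 1e-9))
        return p
    res = stats.mannwhitneyu(x, y, alternative="two-sided",
                             method="asymptotic", use_continuity=True)
    return float(min(res.pvalue, 1.0))


def wilcoxon_vs_control(
    df: pd.DataFrame, population_id: str, variable: str, temperature: int
) -> float:
    """Two-sided rank-sum p-value of one exposure group against the control."""
    sub = df[df["population_id"] == str(population_id)]
    x = sub[sub["temperature"] == CONTROL_TEMPERATURE][variable].dropna().to_numpy()
    y = sub[sub["temperature"] == temperature][variable].dropna().to_numpy()
    if len(x) == 0 or len(y) == 0:
        raise ValueError(
            f"empty group for population {population_id!r}, {variable}, "
            f"{temperature} °C"
        )
    return rank_sum_test(x, y)


def bonferroni_tier(p: float, m: int) -> str:
    """Significance tier under a Bonferroni correction for m comparisons.

    Half-open intervals on the corrected thresholds: '***' for
    p <= 0.001/m, '**' for 0.001/m < p <= 0.01/m, '*' for
    0.01/m < p <= 0.05/m, otherwise 'ns'.  Thresholds are applied at their
    reported precision (see :func:`bonferroni_thresholds`), so e.g. at
    m = 6 the '**' boundary is 0.0017 inclusive.
    """
    if not 0.0 <= p <= 1.0:
        raise ValueError("p must lie in [0, 1]")
    slight, significant, high = bonferroni_thresholds(m)
    if p <= high:
        return "***"
    if p <= significant:
        return "**"
    if p <= slight:
        return "*"
    return "ns"


def bonferroni_thresholds(m: int) -> tuple[float, float, float]:
    """Corrected (slight, significant, highly significant) thresholds.

    Rounded to the precision at which significance tiers are conventionally
    reported: 4 decimal places for the 0.05/m and 0.01/m boundaries, 5 for
    the 0.001/m boundary (e.g. m = 6 gives 0.0083 / 0.0017 / 0.00017).
    """
    if m < 1:
        raise ValueError("m must be >= 1")
    return round(0.05 / m, 4), round(0.01 / m, 4), round(0.001 / m, 5)


@dataclass
class AnovaTukeyResult:
    f_statistic: float
    df_between: int
    df_within: int
    p_value: float
    groups: list[str]
    pairwise_p: pd.DataFrame
    letters: dict[str, str]


def _letter_display(groups: list[str], pairwise_p: pd.DataFrame,
                    alpha: float = 0.05) -> dict[str, str]:
    """Insert-and-absorb compact letter display.

    Groups sharing a letter are not significantly different at ``alpha``.
    """
    letters: list[set[str]] = [set(groups)]
    for a, b in itertools.combinations(groups, 2):
        if pairwise_p.loc[a, b] > alpha:
            continue
        for s in [s for s in letters if a in s and b in s]:
            letters.remove(s)
            for new in (s - {a}, s - {b}):
                # absorb: keep only maximal sets
                if new and not any(new <= other for other in letters):
                    letters.append(new)
                    letters = [t for t in letters if not (t < new)]
    letters.sort(key=lambda s: min(groups.index(g) for g in s))
    alphabet = "abcdefghijklmnopqrstuvwxyz"
    out = {g: "" for g in groups}
    for i, s in enumerate(letters):
        for g in groups:
            if g in s:
                out[g] += alphabet[i]
    return out


def anova_tukey(
    df: pd.DataFrame, variable: str, temperature: int | None = None,
    alpha: float = 0.05,
) -> AnovaTukeyResult:
    """One-way ANOVA across populations plus Tukey-Kramer HSD letters.

    With ``temperature`` given, only that exposure group is analyzed (the
    typical use: comparing populations within the 40 °C group).  Pairwise
    p-values come from the studentized-range distribution with the
    Tukey-Kramer unequal-n correction.
    """
    sub = df if temperature is None else df[df["temperature"] == temperature]
    samples = {
        str(pop): grp[variable].dropna().to_numpy()
        for pop, grp in sub.groupby("population_id")
    }
    samples = {k: v for k, v in samples.items() if len(v) >= 2}
    if len(samples) < 2:
        raise ValueError("need at least 2 groups with >= 2 observations each")
    groups = sorted(samples)
    arrays = [samples[g] for g in groups]
    grand = np.concatenate(arrays).mean()
    ss_between = sum(len(a) * (a.mean() - grand) ** 2 for a in arrays)
    if ss_between == 0.0:
        # identical group means: no between-group signal at all
        f, p = 0.0, 1.0
        pw = pd.DataFrame(1.0, index=groups, columns=groups)
    else:
        f, p = stats.f_oneway(*arrays)
        tukey = stats.tukey_hsd(*arrays)
        pw = pd.DataFrame(tukey.pvalue, index=groups, columns=groups).fillna(1.0)
    letters = _letter_display(groups, pw, alpha)
    n_tot = sum(len(a) for a in arrays)
    return AnovaTukeyResult(
        f_statistic=float(f),
        df_between=len(groups) - 1,
        df_within=n_tot - len(groups),
        p_value=float(p),
        groups=groups,
        pairwise_p=pw,
        letters=letters,
    )


def induction_table(df: pd.DataFrame) -> pd.DataFrame:
    """Per-population maximum Hsp70 induction (temperature and percent)."""
    rows = []
    for pop in sorted(df["population_id"].unique()):
        t, pct = max_induction(df, pop)
        rows.append({"population_id": pop, "temperature": t,
                     "max_induction_pct": round(pct, 1)})
    return pd.DataFrame(rows)


def significance_table(df: pd.DataFrame) -> pd.DataFrame:
    """Rank-sum p and Bonferroni tier for every population x variable x temp.

    Hsp70 comparisons run at 33-48 °C (m = 6), histology at 33/40/43/48 °C
    (m = 4), each exposure group against the 25 °C control.
    """
    plan = [("hsp70_rel", HSP70_TEST_TEMPS)] + [
        (col, HISTOLOGY_TEST_TEMPS) for col in SCORE_COLUMNS
    ]
    rows = []
    for pop in sorted(df["population_id"].unique()):
        for variable, temps in plan:
            m = len(temps)
            for t in temps:
                try:
                    p = wilcoxon_vs_control(df, pop, variable, t)
                except ValueError:
                    continue
                rows.append({
                    "population_id": pop, "variable": variable,
                    "temperature": t, "p_value": p, "m": m,
                    "tier": bonferroni_tier(p, m),
                })
    return pd.DataFrame(rows)
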