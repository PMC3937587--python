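"""Balanced split-plot ANOVA screen for the Monte Carlo results.

Each (design cell, replication) pair is a subject measured once per
classification method, so method is the within-subject (repeated) factor and
the design factors (sample size, group-size ratio, mislabeling proportion,
separation) are between-subject factors.  The decomposition is the classical
balanced one: between-subject terms are tested against subjects-within-cells
variation, method terms against the method-by-subject interaction, with no
sphericity correction.  Effect size is the classical eta squared,
SS_term / SS_total, and the screening rule keeps a term when it is both
significant and explains at least 10% of the total variation.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import chain, combinations

import numpy as np
import pandas as pd
from scipy.stats import f as f_dist

__all__ = ["AnovaEffect", "repeated_anova", "flag_important"]

DEFAULT_BETWEEN = ("n_total", "ratio", "pi", "d")


@dataclass(frozen=True)
class AnovaEffect:
    """One term of the decomposition: F test, degrees of freedom, eta squared."""

    term: str
    ss: float
    df_num: int
    df_den: int
    F: float
    p: float
    eta_sq: float
    stratum: str  # "between" or "within"


def _subsets(items):
    return chain.from_iterable(combinations(items, r)
                               for r in range(1, len(items) + 1))


def repeated_anova(results: pd.DataFrame, outcome: str = "overall",
                   between: tuple[str, ...] = DEFAULT_BETWEEN,
                   within: str = "method", rep: str = "rep"
                   ) -> list[AnovaEffect]:
    """Full-factorial split-plot decomposition of a balanced results table.

    ``results`` must contain one row per (between-cell, replication, method);
    unbalanced or duplicated tables are rejected with a diagnostic (average or
    filter extra design columns, e.g. topology, before calling).
    """
    cols = [*between, rep, within, outcome]
    missing = [c for c in cols if c not in results.columns]
    if missing:
        raise ValueError(f"missing columns: {missing}")
    df = results[cols].copy()

    sizes = df.groupby([*between, rep, within], observed=True).size()
    if (sizes != 1).any():
        raise ValueError(
            "table is not balanced: expected exactly one row per "
            "(between-cell, replication, method); found counts "
            f"{sorted(sizes.unique())}. Filter or aggregate extra design "
            "columns (e.g. topology) first.")
    cell_sizes = df.groupby(list(between), observed=True)[rep].nunique()
    if cell_sizes.nunique() != 1:
        raise ValueError("unequal replication counts across between-cells")

    y = df[outcome].to_numpy(dtype=float)
    N = len(y)
    grand = y.mean()
    ss_total = float(((y - grand) ** 2).sum())

    n_methods = df[within].nunique()
    n_cells = int(np.prod([df[c].nunique() for c in between]))
    n_subjects = n_cells * int(cell_sizes.iloc[0])

    factors = [*between, within]
    levels = {c: df[c].nunique() for c in factors}

    # balanced factorial SS via recursive effect decomposition over subsets
    ss = {}
    for T in _subsets(factors):
        cell_mean = df.groupby(list(T), observed=True)[outcome].transform("mean")
        raw = float(((cell_mean - grand) ** 2).sum())
        ss[T] = raw - sum(ss[S] for S in _subsets(T) if S != T)

    # error strata
    subj_mean = df.groupby([*between, rep], observed=True)[outcome].transform("mean")
    ss_subjects = float(((subj_mean - grand) ** 2).sum())
    ss_between_model = sum(ss[T] for T in _subsets(tuple(between)))
    ss_err_between = max(ss_subjects - ss_between_model, 0.0)
    df_err_between = n_subjects - n_cells
    ss_within_model = sum(v for T, v in ss.items() if within in T)
    ss_err_within = max(ss_total - ss_subjects - ss_within_model, 0.0)
    df_err_within = df_err_between * (n_methods - 1)

    effects = []
    for T, ss_T in ss.items():
        df_num = int(np.prod([levels[c] - 1 for c in T]))
        if within in T:
            df_den, ss_err = df_err_within, ss_err_within
            stratum = "within"
        else:
            df_den, ss_err = df_err_between, ss_err_between
            stratum = "between"
        ms_num = ss_T / df_num if df_num else 0.0
        ms_den = ss_err / df_den if df_den else 0.0
        if ms_den > 0:
            F = ms_num / ms_den
            p = float(f_dist.sf(F, df_num, df_den))
        else:
            F = 0.0 if ss_T <= 1e-12 else np.inf
            p = 1.0 if ss_T <= 1e-12 else 0.0
        eta = ss_T / ss_total if ss_total > 0 else 0.0
        effects.append(AnovaEffect(" x ".join(T), float(ss_T), df_num,
                                   df_den, float(F), p, float(eta), stratum))
    return effects


def flag_important(effects: list[AnovaEffect], alpha: float = 0.05,
                   min_eta_sq: float = 0.1) -> list[AnovaEffect]:
    """Terms that are both significant and explain >= 10% of total variation."""
    return [e for e in effects if e.p < alpha and e.eta_sq >= min_eta_sq]


def effects_frame(effects: list[AnovaEffect], alpha: float = 0.05,
                  min_eta_sq: float = 0.1) -> pd.DataFrame:
    """Tabular view of the decomposition with the importance flag applied."""
    flagged = {e.term for e in flag_important(effects, alpha, min_eta_sq)}
    return pd.DataFrame([{
        "term": e.term, "stratum": e.stratum, "ss": e.ss, "df_num": e.df_num,
        "df_den": e.df_den, "F": e.F, "p": e.p, "eta_sq": e.eta_sq,
        "flagged": e.term in flagged} for e in effects])
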