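"""Phenome-wide correlation scan of adjusted acoustic measures against
an external phenotype library.

Each measure/trait pair is tested with a Pearson correlation on the
pairwise-complete intersection (point-biserial for case-control
traits), with a two-sided P from the t transform and a Fisher-z 95%
CI. Pairs with an intersection of 100 or fewer, or with a degenerate
column, are suppressed (recorded with a reason, not reported).
Significance is controlled with a Bonferroni threshold over the full
measure x trait grid, and per-sex effects are compared with a normal
heterogeneity test.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

MIN_INTERSECTION = 100


@dataclass
class CorrelationResult:
    measure: str
    trait: str
    r: float
    n: int
    p: float
    ci95: tuple[float, float]
    suppressed: bool = False
    reason: str = ""
    r_male: float = float("nan")
    se_male: float = float("nan")
    r_female: float = float("nan")
    se_female: float = float("nan")
    p_het: float = float("nan")


def bonferroni_threshold(alpha: float, n_measures: int, n_traits: int) -> float:
    """alpha / (n_measures x n_traits)."""
    if alpha <= 0 or n_measures <= 0 or n_traits <= 0:
        raise ValueError("all Bonferroni inputs must be positive")
    return alpha / (n_measures * n_traits)


def sex_heterogeneity(effect_m: float, se_m: float,
                      effect_f: float, se_f: float) -> float:
    """Two-sided P for a difference in effects between strata.

    z = (b_m - b_f) / sqrt(se_m^2 + se_f^2); equivalent to a
    two-stratum Cochran Q on 1 df.
    """
    if se_m <= 0 or se_f <= 0:
        raise ValueError("standard errors must be positive")
    z = (effect_m - effect_f) / math.sqrt(se_m ** 2 + se_f ** 2)
    return float(2.0 * stats.norm.sf(abs(z)))


def _fisher_ci(r: float, n: int) -> tuple[float, float]:
    if n <= 3 or abs(r) >= 1.0:
        return (float("nan"), float("nan"))
    z = np.arctanh(r)
    half = 1.959963984540054 / math.sqrt(n - 3)
    return (float(np.tanh(z - half)), float(np.tanh(z + half)))


def correlate(measure: pd.Series, trait: pd.Series, trait_type: str = "quantitative",
              measure_name: str = "measure", trait_name: str = "trait",
              min_n: int = MIN_INTERSECTION) -> CorrelationResult:
    """Pearson (point-biserial) correlation on the pairwise-complete
    intersection, with suppression rules."""
    x, y = measure.align(trait, join="inner")
    ok = x.notna() & y.notna()
    n = int(ok.sum())

    def suppressed(reason: str) -> CorrelationResult:
        return CorrelationResult(measure_name, trait_name, float("nan"), n,
                                 float("nan"), (float("nan"), float("nan")),
                                 suppressed=True, reason=reason)

    if n <= min_n:
        return suppressed(f"intersection {n} <= {min_n}")
    xv, yv = x[ok].to_numpy(dtype=float), y[ok].to_numpy(dtype=float)
    if trait_type == "case-control":
        n_case = int(np.sum(yv == 1))
        if n_case == 0 or n_case == n:
            return suppressed("needs at least one case and one control")
    if np.ptp(xv) == 0.0 or np.ptp(yv) == 0.0:
        return suppressed("zero variance")
    r, p = stats.pearsonr(xv, yv)
    return CorrelationResult(measure_name, trait_name, float(r), n, float(p),
                             _fisher_ci(float(r), n))


def scan(catalog: pd.DataFrame, library: pd.DataFrame,
         trait_types: dict[str, str] | None = None,
         sex: pd.Series | None = None,
         alpha: float = 0.05) -> pd.DataFrame:
    """All measure x trait correlations with Bonferroni flags.

    The threshold divides ``alpha`` by the full grid size (all pairs,
    including suppressed ones). When ``sex`` is given, per-sex r values
    and the heterogeneity P are included (per-sex results need the same
    intersection rule to hold within each stratum).
    """
    trait_types = trait_types or {}
    if catalog.empty or library.empty:
        return pd.DataFrame(
            columns=["measure", "trait", "r", "n", "p", "ci_low", "ci_high",
                     "suppressed", "reason", "r_male", "r_female", "p_het",
                     "significant"]
        )
    threshold = bonferroni_threshold(alpha, catalog.shape[1], library.shape[1])
    rows = []
    for m in catalog.columns:
        for t in library.columns:
            res = correlate(catalog[m], library[t],
                            trait_types.get(t, "quantitative"), m, t)
            if sex is not None and not res.suppressed:
                strata = {}
                for label in ("male", "female"):
                    ids = sex.index[sex == label]
                    sub = correlate(catalog[m].reindex(ids), library[t].reindex(ids),
                                    trait_types.get(t, "quantitative"), m, t)
                    strata[label] = sub
                rm, rf = strata["male"], strata["female"]
                if not rm.suppressed and not rf.suppressed:
                    zm, zf = np.arctanh(rm.r), np.arctanh(rf.r)
                    sem = 1.0 / math.sqrt(rm.n - 3)
                    sef = 1.0 / math.sqrt(rf.n - 3)
                    res.r_male, res.se_male = rm.r, sem
                    res.r_female, res.se_female = rf.r, sef
                    res.p_het = sex_heterogeneity(zm, sem, zf, sef)
            rows.append(res)
    df = pd.DataFrame(
        {
            "measure": [r.measure for r in rows],
            "trait": [r.trait for r in rows],
            "r": [r.r for r in rows],
            "n": [r.n for r in rows],
            "p": [r.p for r in rows],
            "ci_low": [r.ci95[0] for r in rows],
            "ci_high": [r.ci95[1] for r in rows],
            "suppressed": [r.suppressed for r in rows],
            "reason": [r.reason for r in rows],
            "r_male": [r.r_male for r in rows],
            "r_female": [r.r_female for r in rows],
            "p_het": [r.p_het for r in rows],
        }
    )
    df["significant"] = ~df["suppressed"] & (df["p"] < threshold)
    df.attrs["bonferroni_threshold"] = threshold
    return df.sort_values("p", na_position="last").reset_index(drop=True)
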