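"""Per-speaker measure catalog: QC cascade, per-sex covariate
adjustment of log measures, and rank-based inverse normal transform.

The QC cascade removes manually flagged recordings first, then
recordings for which fewer than 70% of the catalog measures could be
estimated. Surviving log-measures are adjusted, separately for each
sex, for age, BMI, height and microphone by ordinary least squares, and
the residuals are mapped onto standard-normal quantiles with the Blom
rank offset before association testing.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

COVARIATE_COLUMNS = ("age", "bmi", "height")
MICROPHONES = ("DPA", "AKG", "Aston")

PITCH_TASKS = ("reading", "vowels", "words", "sustained_a", "global")
PITCH_STATS = ("f0_median", "f0_sd", "f0_skew")
VOWELS = ("i", "e", "a", "o", "u")
FORMANT_STATS = ("f1_median", "f2_median", "f3_median", "f4_median",
                 "f1_sd", "f2_sd", "f3_sd", "f4_sd")
AGGREGATE_MEASURES = ("vsa4", "fcr", "vtl")


def default_manifest() -> pd.DataFrame:
    """The default measure enumeration: per-task pitch statistics,
    per-vowel and all-vowel-average formant statistics, and the three
    aggregate vowel measures."""
    rows = []
    for task in PITCH_TASKS:
        for stat in PITCH_STATS:
            rows.append({"name": f"{stat}_{task}", "task": task, "vowel": "",
                         "statistic": stat})
    for vowel in VOWELS + ("avg",):
        for stat in FORMANT_STATS:
            rows.append({"name": f"{stat}_vowel_{vowel}", "task": "vowels",
                         "vowel": vowel, "statistic": stat})
    for m in AGGREGATE_MEASURES:
        rows.append({"name": m, "task": "vowels", "vowel": "", "statistic": m})
    return pd.DataFrame(rows)


@dataclass
class QCReport:
    n_total: int
    n_manual_bad: int
    n_incomplete: int
    n_retained: int
    completeness: pd.Series = field(repr=False)

    def __post_init__(self) -> None:
        if self.n_total != self.n_manual_bad + self.n_incomplete + self.n_retained:
            raise ValueError("QC counts do not add up to the total")

    @property
    def pct_manual_bad(self) -> float:
        """Manual removals as a percentage of all samples."""
        return 100.0 * self.n_manual_bad / self.n_total

    @property
    def pct_incomplete(self) -> float:
        """Completeness removals as a percentage of the post-manual set."""
        return 100.0 * self.n_incomplete / (self.n_total - self.n_manual_bad)


def qc_cascade(measures: pd.DataFrame, manual_bad=(),
               completeness_threshold: float = 0.70) -> tuple[pd.DataFrame, QCReport]:
    """Two-step QC: drop manually flagged speakers, then speakers whose
    fraction of non-missing measures is below the threshold."""
    if not 0.0 < completeness_threshold <= 1.0:
        raise ValueError("completeness threshold must be in (0, 1]")
    if measures.empty:
        raise ValueError("empty measure table")
    manual_bad = set(manual_bad)
    n_total = len(measures)
    after_manual = measures.loc[[i for i in measures.index if i not in manual_bad]]
    completeness = after_manual.notna().mean(axis=1)
    retained = after_manual.loc[completeness >= completeness_threshold]
    report = QCReport(
        n_total=n_total,
        n_manual_bad=n_total - len(after_manual),
        n_incomplete=len(after_manual) - len(retained),
        n_retained=len(retained),
        completeness=completeness,
    )
    return retained, report


def adjust_measure(log_values: pd.Series, speakers: pd.DataFrame) -> pd.Series:
    """Within-sex OLS adjustment for age, BMI, height and microphone.

    ``speakers`` is indexed like ``log_values`` with columns sex, age,
    bmi, height, microphone. Speakers with a missing measure or any
    missing covariate get NaN residuals. A constant measure within a
    stratum yields all-zero residuals (degenerate but defined).
    """
    out = pd.Series(np.nan, index=log_values.index, dtype=float)
    for sex, stratum in speakers.groupby("sex"):
        y = log_values.reindex(stratum.index)
        X_parts = [pd.Series(1.0, index=stratum.index, name="intercept")]
        X_parts += [stratum[c].astype(float) for c in COVARIATE_COLUMNS]
        mics = pd.get_dummies(
            pd.Categorical(stratum["microphone"], categories=MICROPHONES),
            drop_first=True, dtype=float,
        ).set_axis(stratum.index)
        X = pd.concat(X_parts + [mics], axis=1)
        ok = y.notna() & X.notna().all(axis=1)
        if ok.sum() < X.shape[1] + 1:
            continue
        Xo = X.loc[ok].to_numpy()
        yo = y.loc[ok].to_numpy()
        if np.ptp(yo) == 0.0:
            out.loc[ok[ok].index] = 0.0
            continue
        beta, *_ = np.linalg.lstsq(Xo, yo, rcond=None)
        out.loc[ok[ok].index] = yo - Xo @ beta
    return out


def inverse_normal_transform(values: pd.Series, offset: float = 3.0 / 8.0) -> pd.Series:
    """Rank-based INT: Phi^-1((rank - c) / (n - 2c + 1)), Blom c = 3/8.

    Ties get average ranks; missing values stay missing. Raises when
    all non-missing values are identical (degenerate ranking).
    """
    v = values.astype(float)
    ok = v.notna()
    n = int(ok.sum())
    if n < 3:
        raise ValueError("need at least 3 non-missing values")
    x = v[ok].to_numpy()
    if np.ptp(x) == 0.0:
        raise ValueError("all values identical; rank transform undefined")
    ranks = stats.rankdata(x, method="average")
    out = pd.Series(np.nan, index=v.index, dtype=float)
    out[ok] = stats.norm.ppf((ranks - offset) / (n - 2.0 * offset + 1.0))
    return out


@dataclass
class MeasureCatalog:
    """Speakers x measures matrix with its manifest and completeness."""

    values: pd.DataFrame
    manifest: pd.DataFrame
    qc: QCReport | None = None

    @property
    def completeness(self) -> pd.Series:
        return self.values.notna().mean(axis=0)

    def write(self, matrix_path, manifest_path) -> None:
        self.values.to_csv(matrix_path, sep="\t")
        self.manifest.to_csv(manifest_path, sep="\t", index=False)


def build_catalog(summaries: pd.DataFrame,
                  manifest: pd.DataFrame | None = None) -> MeasureCatalog:
    """Assemble the per-speaker raw measure matrix from tidy summaries.

    ``summaries`` columns: speaker, measure, value (one row per
    speaker/measure; measures not in the manifest are ignored, manifest
    measures absent for a speaker stay missing).
    """
    manifest = default_manifest() if manifest is None else manifest
    if manifest["name"].duplicated().any():
        dupes = manifest.loc[manifest["name"].duplicated(), "name"].tolist()
        raise ValueError(f"duplicate measure names in manifest: {dupes}")
    wide = summaries.pivot_table(index="speaker", columns="measure",
                                 values="value", aggfunc="first")
    values = wide.reindex(columns=manifest["name"])
    return MeasureCatalog(values=values, manifest=manifest)


def normalize_catalog(catalog: MeasureCatalog, speakers: pd.DataFrame,
                      log_transform: bool = True) -> pd.DataFrame:
    """Log -> per-sex covariate adjustment -> per-sex INT, column by column.

    Skew measures can be negative and are adjusted on the raw scale;
    everything else is log-transformed first. The INT is applied within
    each sex (each sex standardized on its own ranks, so pooled
    analyses are scale-free). Degenerate columns (fewer than 3 values,
    or constant) become all-NaN.
    """
    sex = speakers.loc[catalog.values.index, "sex"]
    out = {}
    for name in catalog.values.columns:
        col = catalog.values[name]
        if log_transform and not name.startswith("f0_skew"):
            with np.errstate(invalid="ignore", divide="ignore"):
                col = np.log(col.where(col > 0))
        adj = adjust_measure(col, speakers.loc[col.index])
        res = pd.Series(np.nan, index=col.index, dtype=float)
        for _, idx in adj.groupby(sex).groups.items():
            try:
                res.loc[idx] = inverse_normal_transform(adj.loc[idx])
            except ValueError:
                pass
        out[name] = res
    return pd.DataFrame(out, index=catalog.values.index)
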