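"""Association post-processing: annotation-weighted significance,
Hz-scale effects, LD, Wakefield credible sets, and LD-overlap
colocalization lookup.

Genome-wide significance uses a weighted Bonferroni adjustment in
which variant classes with predicted functional impact get easier
thresholds: 2.5e-7 (loss-of-function), 5.0e-8 (moderate impact),
4.5e-9 (low impact), 2.3e-9 (other variants inside DNase
hypersensitivity sites), 7.5e-10 (all remaining variants).

Fine-mapping uses Wakefield approximate Bayes factors
ABF_i = sqrt(V_i / (V_i + W)) * exp(z_i^2 W / (2 (V_i + W))) with
V = SE^2 and z = beta / SE; normalized ABFs are posterior
probabilities and the 95% credible set is the smallest posterior-sorted
prefix reaching 0.95 mass.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

DEFAULT_WAKEFIELD_W = 0.04  # prior variance: SD 0.2 on the SD-unit effect


@dataclass(frozen=True)
class SignificanceWeights:
    """Impact-class specific genome-wide significance thresholds."""

    lof: float = 2.5e-7
    moderate: float = 5.0e-8
    low: float = 4.5e-9
    dhs: float = 2.3e-9
    remaining: float = 7.5e-10

    def __post_init__(self) -> None:
        t = [self.lof, self.moderate, self.low, self.dhs, self.remaining]
        if any(a < b for a, b in zip(t, t[1:])):
            raise ValueError("thresholds must be ordered LoF >= moderate >= "
                             "low >= DHS >= remaining")

    def threshold(self, impact: str, dhs: bool = False) -> float:
        impact = impact.lower()
        if impact in ("lof", "high", "loss_of_function"):
            return self.lof
        if impact == "moderate":
            return self.moderate
        if impact == "low":
            return self.low
        if impact == "other":
            return self.dhs if dhs else self.remaining
        raise KeyError(f"unknown impact class {impact!r}")


def is_significant(p: float, impact: str, weights: SignificanceWeights | None = None,
                   dhs: bool = False) -> bool:
    """p < the class-specific threshold."""
    weights = weights or SignificanceWeights()
    return p < weights.threshold(impact, dhs)


def effect_in_hz(beta_sd: float, trait_sd_hz: float) -> tuple[float, float]:
    """(per-allele Hz, homozygote Hz): the homozygote effect is twice
    the per-allele effect under the additive model."""
    if trait_sd_hz <= 0:
        raise ValueError("trait SD must be positive")
    per_allele = beta_sd * trait_sd_hz
    return per_allele, 2.0 * per_allele


def ld_r2(g1, g2) -> float:
    """Squared Pearson correlation of two dosage vectors; NaN when
    either is monomorphic."""
    a = np.asarray(g1, dtype=float)
    b = np.asarray(g2, dtype=float)
    if np.ptp(a) == 0.0 or np.ptp(b) == 0.0:
        return float("nan")
    r = np.corrcoef(a, b)[0, 1]
    return float(r * r)


@dataclass
class CredibleSet:
    """Posterior-ranked 95% credible set for one association region."""

    members: pd.DataFrame  # variant, beta, se, abf, posterior; sorted desc
    mass: float
    lead: str
    target: float = 0.95
    r2_to_lead: dict = field(default_factory=dict)

    @property
    def variants(self) -> list[str]:
        return self.members["variant"].tolist()

    @property
    def size(self) -> int:
        return len(self.members)


def wakefield_abf(beta, se, W: float = DEFAULT_WAKEFIELD_W) -> np.ndarray:
    """Approximate Bayes factor for H1 vs H0, computed in log space."""
    beta = np.asarray(beta, dtype=float)
    V = np.asarray(se, dtype=float) ** 2
    z2 = beta ** 2 / V
    log_abf = 0.5 * np.log(V / (V + W)) + z2 * W / (2.0 * (V + W))
    return np.exp(log_abf - log_abf.max())  # relative scale; normalized later


def credible_set(region: pd.DataFrame, W: float = DEFAULT_WAKEFIELD_W,
                 target: float = 0.95,
                 dosages: np.ndarray | None = None) -> CredibleSet:
    """95% credible set from a region's per-variant beta/se table.

    ``region`` needs columns variant, beta, se. Posteriors are
    normalized ABFs; the set is the minimal posterior-sorted prefix
    whose cumulative mass reaches ``target``. When ``dosages``
    (n x m, region order) is given, each member's r^2 to the lead
    variant is attached.
    """
    if region.empty:
        raise ValueError("empty region")
    abf = wakefield_abf(region["beta"].to_numpy(), region["se"].to_numpy(), W)
    posterior = abf / abf.sum()
    order = np.argsort(-posterior, kind="stable")
    cum = np.cumsum(posterior[order])
    k = int(np.searchsorted(cum, target) + 1)
    k = min(k, len(order))
    chosen = order[:k]
    members = region.iloc[chosen].copy().reset_index(drop=True)
    members["abf"] = abf[chosen]
    members["posterior"] = posterior[chosen]
    lead = str(members.iloc[0]["variant"])
    r2 = {}
    if dosages is not None:
        lead_idx = int(order[0])
        for pos, i in enumerate(chosen):
            r2[str(region.iloc[int(i)]["variant"])] = ld_r2(
                dosages[:, lead_idx], dosages[:, int(i)]
            )
    return CredibleSet(members=members, mass=float(cum[k - 1]), lead=lead,
                       target=target, r2_to_lead=r2)


def plot_manhattan(results: pd.DataFrame, positions=None, ax=None,
                   weights: SignificanceWeights | None = None):
    """Manhattan plot of -log10 P against position.

    ``results`` needs variant/p columns (skipped variants are dropped);
    ``positions`` maps variant id -> coordinate (defaults to rank
    order). The strictest and most lenient weighted thresholds are
    drawn as guide lines. Returns the axes.
    """
    import matplotlib
    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt

    weights = weights or SignificanceWeights()
    df = results.dropna(subset=["p"])
    if "skipped" in df.columns:
        df = df[~df["skipped"]]
    x = (np.arange(len(df)) if positions is None
         else df["variant"].map(positions).to_numpy())
    if ax is None:
        _, ax = plt.subplots(figsize=(8, 3))
    ax.scatter(x, -np.log10(df["p"]), s=8, c="0.2")
    for thr, style in ((weights.lof, ":"), (weights.remaining, "--")):
        ax.axhline(-math.log10(thr), color="firebrick", ls=style, lw=0.8)
    ax.set_xlabel("position")
    ax.set_ylabel(r"$-\log_{10} P$")
    return ax


def coloc_overlap(lead: str, external: pd.DataFrame, r2_to_lead: dict[str, float],
                  r2_threshold: float = 0.8) -> pd.DataFrame:
    """LD-overlap colocalization lookup (no statistical model).

    Returns the external association records whose variant has
    r^2 > threshold with the lead. ``external`` needs a ``variant``
    column plus whatever effect/P columns the source provides.
    """
    if lead not in r2_to_lead:
        raise KeyError(f"lead variant {lead!r} absent from the LD reference")
    out = external.copy()
    out["r2_to_lead"] = out["variant"].map(r2_to_lead)
    out = out[out["r2_to_lead"] > r2_threshold]
    return out.reset_index(drop=True)
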