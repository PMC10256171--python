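"""Scan for human-fixed derived coding variants against primate
outgroups, with archaic-genome checks and per-gene summaries.

A site is called fixed-derived when chimpanzee, bonobo and rhesus
macaque all carry the same (ancestral) allele, the human major allele
differs from it at a frequency above 99.99%, and the predicted impact
is high or moderate. Sites with any missing outgroup call, or where
the outgroups disagree among themselves, are excluded (strict rule:
no call without a confident ancestral state).
"""

from __future__ import annotations

import numpy as np
import pandas as pd

VALID_ALLELES = {"A", "C", "G", "T"}
MISSING = {".", "", "N", "nan"}
OUTGROUP_COLUMNS = ("chimp_allele", "bonobo_allele", "macaque_allele")
DEFAULT_AF_THRESHOLD = 0.9999
DEFAULT_IMPACT_FILTER = frozenset({"high", "moderate"})


class AlleleError(ValueError):
    """Raised for a malformed allele code, with the offending position."""


def _check_allele(value, position) -> str | None:
    """Normalized allele or None for missing; raises on malformed codes."""
    s = str(value).strip().upper()
    if s in {m.upper() for m in MISSING}:
        return None
    if s not in VALID_ALLELES:
        raise AlleleError(f"position {position}: malformed allele code {value!r}")
    return s


def call_fixed_derived(table: pd.DataFrame,
                       af_threshold: float = DEFAULT_AF_THRESHOLD,
                       impact_filter=DEFAULT_IMPACT_FILTER) -> pd.DataFrame:
    """Apply the fixed-derived rule row by row.

    ``table`` needs columns position, human_allele, human_af,
    chimp_allele, bonobo_allele, macaque_allele, impact_class (extra
    columns, e.g. archaic genotypes, pass through). Returns the calls
    with an added ``ancestral_allele`` column.
    """
    impact_filter = set(impact_filter)
    calls = []
    for _, row in table.iterrows():
        pos = row["position"]
        human = _check_allele(row["human_allele"], pos)
        outs = [_check_allele(row[c], pos) for c in OUTGROUP_COLUMNS]
        if human is None or any(o is None for o in outs):
            continue  # strict: no call without all four alleles
        if len(set(outs)) != 1:
            continue  # outgroups disagree on the ancestral state
        ancestral = outs[0]
        if human == ancestral:
            continue
        if not float(row["human_af"]) > af_threshold:
            continue
        if str(row["impact_class"]).lower() not in impact_filter:
            continue
        rec = row.to_dict()
        rec["ancestral_allele"] = ancestral
        calls.append(rec)
    cols = list(table.columns) + ["ancestral_allele"]
    return pd.DataFrame(calls, columns=cols)


def archaic_check(calls: pd.DataFrame, archaic: pd.DataFrame,
                  genomes=("vindija", "altai", "chagyrskaya", "denisovan")
                  ) -> pd.DataFrame:
    """Annotate each call with the archaic-genome status.

    ``archaic`` is keyed by position with one diploid genotype column
    per genome ("T/T", "T/C", "./."). Status per genome:
    ``homozygous-fixed`` (both alleles are the human-fixed allele),
    ``carries-ancestral`` (at least one non-fixed allele), ``missing``.
    """
    out = calls.copy()
    by_pos = archaic.set_index("position") if "position" in archaic.columns else archaic
    for g in genomes:
        statuses = []
        for _, row in out.iterrows():
            status = "missing"
            if row["position"] in by_pos.index and g in by_pos.columns:
                gt = str(by_pos.loc[row["position"], g])
                alleles = [a for a in gt.replace("|", "/").split("/") if a]
                if alleles and all(a not in MISSING for a in alleles):
                    if all(a == row["human_allele"] for a in alleles):
                        status = "homozygous-fixed"
                    else:
                        status = "carries-ancestral"
            statuses.append(status)
        out[f"{g}_status"] = statuses
    return out


def gene_summary(calls: pd.DataFrame, genes: pd.DataFrame) -> tuple[pd.DataFrame, float]:
    """Per-gene call counts and the fraction of genes with >= 1 call.

    ``genes`` follows BED conventions: 0-based, half-open [start, end)
    with columns chrom, start, end, name. Call positions are 1-based,
    so position p falls in a gene iff start < p <= end. Calls outside
    every gene are counted under an ``intergenic`` bucket (excluded
    from the fraction's denominator).
    """
    if genes["name"].duplicated().any():
        dupes = genes.loc[genes["name"].duplicated(), "name"].tolist()
        raise ValueError(f"duplicate gene ids: {dupes}")
    counts = {name: 0 for name in genes["name"]}
    intergenic = 0
    for pos in calls["position"]:
        hit = genes[(genes["start"] < pos) & (pos <= genes["end"])]
        if hit.empty:
            intergenic += 1
        else:
            for name in hit["name"]:
                counts[name] += 1
    summary = pd.DataFrame({"gene": list(counts), "n_calls": list(counts.values())})
    summary.loc[len(summary)] = ["intergenic", intergenic]
    with_call = sum(1 for v in counts.values() if v > 0)
    fraction = with_call / len(counts) if counts else float("nan")
    return summary, fraction


def bed_to_internal(genes_bed: pd.DataFrame) -> pd.DataFrame:
    """BED 0-based half-open -> 1-based inclusive [first, last]."""
    out = genes_bed.copy()
    out["first"] = out["start"] + 1
    out["last"] = out["end"]
    return out


def internal_to_bed(genes: pd.DataFrame) -> pd.DataFrame:
    """Inverse of :func:`bed_to_internal`; round-trips exactly."""
    out = genes.copy()
    out["start"] = out["first"] - 1
    out["end"] = out["last"]
    return out.drop(columns=["first", "last"])
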