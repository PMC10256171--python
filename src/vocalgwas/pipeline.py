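"""End-to-end pipeline: synthetic study -> acoustic phenotypes ->
catalog -> correlation scan -> kinship GWAS -> fine-mapping ->
fixed-derived scan.

Every stage writes plain TSV (plus WAV/VCF where appropriate) into the
run directory, and a run log records the configuration hash and the
parameters actually used, so reruns with the same config are
reproducible.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import acoustics, assoc, compgen, phenotab, phewas, simulate, vowelspace
from .genotypes import GenotypeSet, write_dosage_tsv, write_kinship_tsv, write_vcf
from .mixedlm import KinshipMixedLM


@dataclass
class RunConfig:
    """Configuration of a full synthetic-study run."""

    seed: int = 1
    n_speakers: int = 200
    n_variants: int = 500
    causal_effect_hz: float = 12.0  # demo effect, detectable at n=200
    causal_af: float = 0.48
    pedigree: str = "sibpairs"
    sample_rate: float = 16000.0
    reading_duration: float = 8.0
    vowel_duration: float = 0.5
    sustained_duration: float = 4.0
    noise_snr_db: float = 50.0
    n_library_traits: int = 20
    planted_trait_r: float = 0.5
    wakefield_w: float = 0.04
    n_alignment_sites: int = 100
    n_fixed_derived: int = 7
    assoc_measure: str = "f0_median_reading"
    write_wav: bool = False
    stages: tuple = ("simulate", "acoustics", "phenotab", "phewas",
                     "assoc", "finemap", "compgen")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        if "stages" in data:
            data["stages"] = tuple(data["stages"])
        return cls(**data)

    def to_yaml(self, path) -> None:
        data = dataclasses.asdict(self)
        data["stages"] = list(data["stages"])
        with open(path, "w") as fh:
            yaml.safe_dump(data, fh, sort_keys=False)

    def digest(self) -> str:
        payload = json.dumps(dataclasses.asdict(self), sort_keys=True, default=list)
        return hashlib.sha256(payload.encode()).hexdigest()[:12]


def measures_from_battery(battery, sex: str) -> dict[str, float]:
    """Acoustic measures for one speaker from a labeled task battery.

    Per-recording pitch statistics are aggregated per task by the mean
    of per-recording values; vowel formant statistics are aggregated
    over tokens; aggregate vowel-space measures come from the
    token-averaged per-vowel formant medians.
    """
    pitch_by_task: dict[str, list] = {}
    formants_by_vowel: dict[str, list] = {}

    for seg, truth in battery:
        label = seg.label
        task = ("reading" if label == "reading"
                else "sustained_a" if label == "sustained_a"
                else "words" if label.startswith("word_")
                else "vowels" if label.startswith("vowel_")
                else None)
        if task is None:
            continue
        try:
            trimmed = acoustics.trim_silence(seg)
            contour = acoustics.estimate_f0_contour(trimmed, sex)
            summ = acoustics.summarize_pitch(acoustics.refine_contour(contour))
        except (ValueError, acoustics.EmptyAudioError):
            summ = None
        if summ is not None:
            pitch_by_task.setdefault(task, []).append(summ)
        if label.startswith("vowel_"):
            vowel = label.split("_")[1]
            try:
                track = acoustics.estimate_formant_track(seg, sex)
                fsum = acoustics.gate_and_summarize_formants(track)
            except ValueError:
                fsum = None
            if fsum is not None:
                formants_by_vowel.setdefault(vowel, []).append(fsum)

    out: dict[str, float] = {}
    task_stats: dict[str, dict[str, float]] = {}
    for task, summaries in pitch_by_task.items():
        task_stats[task] = {
            "f0_median": vowelspace.aggregate_tokens([s.f0_median for s in summaries]),
            "f0_sd": vowelspace.aggregate_tokens([s.f0_sd for s in summaries]),
            "f0_skew": vowelspace.aggregate_tokens([s.f0_skew for s in summaries]),
        }
    for task, stats_ in task_stats.items():
        for stat, value in stats_.items():
            out[f"{stat}_{task}"] = value
    for stat in ("f0_median", "f0_sd", "f0_skew"):
        vals = [task_stats[t][stat] for t in task_stats]
        out[f"{stat}_global"] = vowelspace.aggregate_tokens(vals)

    vowel_medians: dict[str, tuple] = {}
    for vowel, fsums in formants_by_vowel.items():
        meds = [vowelspace.aggregate_tokens([f.medians[i] for f in fsums])
                for i in range(4)]
        sds = [vowelspace.aggregate_tokens([f.sds[i] for f in fsums])
               for i in range(4)]
        vowel_medians[vowel] = tuple(meds)
        for i in range(4):
            out[f"f{i+1}_median_vowel_{vowel}"] = meds[i]
            out[f"f{i+1}_sd_vowel_{vowel}"] = sds[i]
    for i in range(4):
        out[f"f{i+1}_median_vowel_avg"] = vowelspace.aggregate_tokens(
            [vowel_medians[v][i] for v in vowel_medians])
        out[f"f{i+1}_sd_vowel_avg"] = vowelspace.aggregate_tokens(
            [out.get(f"f{i+1}_sd_vowel_{v}", float("nan")) for v in vowel_medians])

    metrics = vowelspace.vowel_space_metrics(vowel_medians)
    out["vsa4"] = metrics.vsa4
    out["fcr"] = metrics.fcr
    out["vtl"] = metrics.vtl_cm
    return out


def _trait_library(normalized: pd.DataFrame, cfg: RunConfig,
                   rng: np.random.Generator) -> tuple[pd.DataFrame, dict]:
    """Synthetic phenotype library: one trait correlated with the
    association measure (planted), the rest independent noise."""
    n = len(normalized)
    idx = normalized.index
    lib = {}
    target = normalized[cfg.assoc_measure]
    filled = target.fillna(0.0).to_numpy()
    r = cfg.planted_trait_r
    lib["planted_trait"] = r * filled + np.sqrt(1 - r ** 2) * rng.normal(size=n)
    for i in range(cfg.n_library_traits - 1):
        lib[f"null_trait_{i:03d}"] = rng.normal(size=n)
    types = {name: "quantitative" for name in lib}
    return pd.DataFrame(lib, index=idx), types


def run_all(cfg: RunConfig, outdir) -> dict:
    """Execute the configured stages; returns a results dictionary."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    log: dict = {"config_hash": cfg.digest(),
                 "config": dataclasses.asdict(cfg), "stages": {}}
    results: dict = {"log": log}
    cfg.to_yaml(outdir / "config.yaml")

    def stage_enabled(name: str) -> bool:
        return name in cfg.stages

    covariates = gset = truth = None
    if stage_enabled("simulate"):
        spec = simulate.CohortSpec(
            n_speakers=cfg.n_speakers, n_variants=cfg.n_variants,
            causal_effect_hz=cfg.causal_effect_hz, causal_af=cfg.causal_af,
            pedigree=cfg.pedigree, seed=cfg.seed,
        )
        covariates, gset, truth = simulate.simulate_cohort(spec)
        covariates.to_csv(outdir / "covariates.tsv", sep="\t", index=False)
        write_vcf(outdir / "genotypes.vcf", gset)
        write_dosage_tsv(outdir / "dosages.tsv", gset)
        write_kinship_tsv(outdir / "kinship.tsv", gset.kinship, gset.speaker_ids)
        align, align_truth = simulate.make_alignment_fixture(
            cfg.n_alignment_sites, cfg.n_fixed_derived, seed=cfg.seed + 1)
        align.to_csv(outdir / "alignment.tsv", sep="\t", index=False)
        results["simulate"] = {"truth": truth, "alignment_truth": align_truth,
                               "covariates": covariates, "genotypes": gset,
                               "alignment": align}
        log["stages"]["simulate"] = {"n_speakers": cfg.n_speakers,
                                     "n_variants": cfg.n_variants,
                                     "causal_id": truth["causal_id"]}

    raw_catalog = None
    if stage_enabled("acoustics") and covariates is not None:
        rows = []
        rng = np.random.default_rng(cfg.seed + 2)
        for _, spk in covariates.iterrows():
            battery = simulate.synth_task_battery(
                spk["sex"], pitch_hz=spk["true_pitch_hz"],
                seed=int(rng.integers(0, 2 ** 31 - 1)),
                reading_duration=cfg.reading_duration,
                vowel_duration=cfg.vowel_duration,
                sustained_duration=cfg.sustained_duration,
                sample_rate=cfg.sample_rate, noise_snr_db=cfg.noise_snr_db,
            )
            if cfg.write_wav:
                wav_dir = outdir / "wav" / str(spk["id"])
                wav_dir.mkdir(parents=True, exist_ok=True)
                from .audio import write_wav
                for seg, _t in battery:
                    write_wav(wav_dir / f"{seg.label}.wav", seg)
            for name, value in measures_from_battery(battery, spk["sex"]).items():
                rows.append({"speaker": spk["id"], "measure": name, "value": value})
        summaries = pd.DataFrame(rows)
        summaries.to_csv(outdir / "summaries.tsv", sep="\t", index=False)
        results["summaries"] = summaries
        log["stages"]["acoustics"] = {"n_recordspeakers": covariates.shape[0]}

    normalized = None
    if stage_enabled("phenotab") and "summaries" in results:
        catalog = phenotab.build_catalog(results["summaries"])
        retained, report = phenotab.qc_cascade(catalog.values)
        catalog.values = retained
        catalog.qc = report
        speakers = covariates.set_index("id")
        normalized = phenotab.normalize_catalog(catalog, speakers)
        catalog.write(outdir / "catalog_raw.tsv", outdir / "manifest.tsv")
        normalized.to_csv(outdir / "catalog_normalized.tsv", sep="\t")
        results["catalog"] = catalog
        results["normalized"] = normalized
        log["stages"]["phenotab"] = {
            "n_total": report.n_total, "n_manual_bad": report.n_manual_bad,
            "n_incomplete": report.n_incomplete, "n_retained": report.n_retained,
            "n_measures": catalog.values.shape[1],
        }

    if stage_enabled("phewas") and normalized is not None:
        rng = np.random.default_rng(cfg.seed + 3)
        library, types = _trait_library(normalized, cfg, rng)
        library.to_csv(outdir / "trait_library.tsv", sep="\t")
        sex = covariates.set_index("id").loc[normalized.index, "sex"]
        phew = phewas.scan(normalized, library, types, sex=sex)
        phew.to_csv(outdir / "phewas.tsv", sep="\t", index=False)
        results["phewas"] = phew
        log["stages"]["phewas"] = {
            "threshold": phew.attrs.get("bonferroni_threshold"),
            "n_significant": int(phew["significant"].sum()),
        }

    assoc_df = None
    if stage_enabled("assoc") and normalized is not None:
        speakers = covariates.set_index("id")
        y = normalized[cfg.assoc_measure]
        keep = y.dropna().index
        order = [gset.speaker_ids.index(i) for i in keep]
        K = gset.kinship[np.ix_(order, order)]
        model = KinshipMixedLM(y.loc[keep].to_numpy(), None, K)
        fit = model.fit()
        # Hz-per-allele conversion: residual SD of the raw Hz measure
        # after sex adjustment (the catalog column is sex-standardized).
        raw = results["catalog"].values["f0_median_reading"].reindex(keep)
        sd_hz = float(np.nanmean(
            [raw[speakers.loc[keep, "sex"] == s].std() for s in ("male", "female")]
        ))
        assoc_df = fit.test_variants(gset.dosages[order, :],
                                     gset.variants["id"], trait_sd_hz=sd_hz)
        meta = gset.variants.set_index("id")
        weights = assoc.SignificanceWeights()
        assoc_df["impact"] = meta.loc[assoc_df["variant"], "impact"].to_numpy()
        assoc_df["dhs"] = meta.loc[assoc_df["variant"], "dhs"].to_numpy()
        assoc_df["significant"] = [
            not row.skipped and assoc.is_significant(row.p, row.impact,
                                                     weights, row.dhs)
            for row in assoc_df.itertuples()
        ]
        assoc_df.to_csv(outdir / "assoc.tsv", sep="\t", index=False)
        results["assoc"] = assoc_df
        results["assoc_fit"] = fit
        results["assoc_sd_hz"] = sd_hz
        log["stages"]["assoc"] = {
            "h2": fit.h2, "n": int(fit.model.nobs), "trait_sd_hz": sd_hz,
            "n_significant": int(assoc_df["significant"].sum()),
        }

    if stage_enabled("finemap") and assoc_df is not None:
        tested = assoc_df[~assoc_df["skipped"]]
        top = tested.loc[tested["p"].idxmin()]
        idx = int(np.where(gset.variants["id"] == top["variant"])[0][0])
        lo, hi = max(0, idx - 50), min(gset.n_variants, idx + 51)
        region = tested[tested["variant"].isin(gset.variants["id"][lo:hi])]
        region = region.rename(columns={"variant": "variant"})
        order_idx = [gset.speaker_ids.index(i) for i in
                     results["normalized"][cfg.assoc_measure].dropna().index]
        dos = gset.dosages[np.ix_(order_idx, np.arange(lo, hi))]
        region_tbl = region[["variant", "beta", "se"]].reset_index(drop=True)
        keep_cols = [i for i, vid in enumerate(gset.variants["id"][lo:hi])
                     if vid in set(region_tbl["variant"])]
        cs = assoc.credible_set(region_tbl, W=cfg.wakefield_w,
                                dosages=dos[:, keep_cols])
        cs.members.to_csv(outdir / "credible_set.tsv", sep="\t", index=False)
        results["credible_set"] = cs
        log["stages"]["finemap"] = {"lead": cs.lead, "size": cs.size,
                                    "mass": cs.mass, "W": cfg.wakefield_w}

    if stage_enabled("compgen") and "simulate" in results:
        align = results["simulate"]["alignment"]
        calls = compgen.call_fixed_derived(align)
        calls = compgen.archaic_check(calls, align)
        calls.to_csv(outdir / "fixed_derived_calls.tsv", sep="\t", index=False)
        results["fixed_calls"] = calls
        log["stages"]["compgen"] = {"n_calls": len(calls)}

    with open(outdir / "run_log.json", "w") as fh:
        json.dump(log, fh, indent=2, default=str)
    results["log"] = log
    return results
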