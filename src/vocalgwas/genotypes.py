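"""Genotype containers and plain-text genotype/kinship I/O.

Dosages are additive allele counts in [0, 2] (speakers x variants).
Kinship is the coefficient-of-kinship matrix phi (0.5 on the diagonal,
0.25 for full siblings); the mixed model uses it only up to a scale
factor. Variant coordinates are 1-based (GRCh38 convention).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

VARIANT_COLUMNS = ["id", "chrom", "pos", "ref", "alt", "af", "impact", "dhs"]


@dataclass
class GenotypeSet:
    """Dosage matrix plus variant metadata and a kinship matrix."""

    speaker_ids: list
    variants: pd.DataFrame  # columns VARIANT_COLUMNS
    dosages: np.ndarray  # (n_speakers, n_variants), values in [0, 2]
    kinship: np.ndarray  # (n_speakers, n_speakers), symmetric PSD

    def __post_init__(self) -> None:
        self.dosages = np.asarray(self.dosages, dtype=float)
        self.kinship = np.asarray(self.kinship, dtype=float)
        n, m = self.dosages.shape
        if len(self.speaker_ids) != n:
            raise ValueError("speaker_ids length does not match dosage rows")
        if len(self.variants) != m:
            raise ValueError("variant table length does not match dosage columns")
        if self.kinship.shape != (n, n):
            raise ValueError("kinship matrix shape does not match cohort size")
        if self.dosages.size and (self.dosages.min() < 0 or self.dosages.max() > 2):
            raise ValueError("dosages must lie in [0, 2]")
        if not np.allclose(self.kinship, self.kinship.T):
            raise ValueError("kinship matrix must be symmetric")

    @property
    def n_speakers(self) -> int:
        return self.dosages.shape[0]

    @property
    def n_variants(self) -> int:
        return self.dosages.shape[1]


def write_dosage_tsv(path, gset: GenotypeSet) -> None:
    """Variant metadata columns followed by one dosage column per speaker."""
    dosage_cols = pd.DataFrame(gset.dosages.T,
                               columns=[str(s) for s in gset.speaker_ids],
                               index=gset.variants.index)
    pd.concat([gset.variants, dosage_cols], axis=1).to_csv(path, sep="\t", index=False)


def read_dosage_tsv(path, kinship: np.ndarray) -> GenotypeSet:
    df = pd.read_csv(path, sep="\t")
    meta = df[VARIANT_COLUMNS]
    speaker_ids = [c for c in df.columns if c not in VARIANT_COLUMNS]
    dosages = df[speaker_ids].to_numpy(dtype=float).T
    return GenotypeSet(speaker_ids, meta.reset_index(drop=True), dosages, kinship)


def write_kinship_tsv(path, kinship: np.ndarray, speaker_ids) -> None:
    pd.DataFrame(kinship, index=speaker_ids, columns=speaker_ids).to_csv(path, sep="\t")


def read_kinship_tsv(path) -> tuple[np.ndarray, list]:
    df = pd.read_csv(path, sep="\t", index_col=0)
    return df.to_numpy(dtype=float), list(df.columns)


def write_vcf(path, gset: GenotypeSet) -> None:
    """Write genotypes as an uncompressed VCF 4.2 with GT and DS fields.

    GT is the dosage rounded to the nearest integer genotype; DS carries
    the exact dosage.
    """
    gt_codes = {0: "0/0", 1: "0/1", 2: "1/1"}
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write('##FORMAT=<ID=DS,Number=1,Type=Float,Description="Dosage">\n')
        fh.write('##INFO=<ID=AF,Number=A,Type=Float,Description="Allele frequency">\n')
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(str(s) for s in gset.speaker_ids)
            + "\n"
        )
        for i, row in gset.variants.iterrows():
            calls = []
            for j in range(gset.n_speakers):
                ds = gset.dosages[j, i]
                calls.append(f"{gt_codes[int(round(ds))]}:{ds:g}")
            fh.write(
                f"{row['chrom']}\t{row['pos']}\t{row['id']}\t{row['ref']}\t"
                f"{row['alt']}\t.\tPASS\tAF={row['af']:g}\tGT:DS\t" + "\t".join(calls) + "\n"
            )


def read_vcf(path, kinship: np.ndarray) -> GenotypeSet:
    """Read a VCF written by :func:`write_vcf` (DS field preferred over GT)."""
    meta_rows = []
    dosage_rows = []
    speaker_ids: list = []
    with open(path) as fh:
        for line in fh:
            if line.startswith("##"):
                continue
            fields = line.rstrip("\n").split("\t")
            if line.startswith("#CHROM"):
                speaker_ids = fields[9:]
                continue
            chrom, pos, vid, ref, alt, _, _, info, fmt = fields[:9]
            af = np.nan
            for kv in info.split(";"):
                if kv.startswith("AF="):
                    af = float(kv[3:])
            keys = fmt.split(":")
            row = []
            for call in fields[9:]:
                parts = dict(zip(keys, call.split(":")))
                if "DS" in parts:
                    row.append(float(parts["DS"]))
                else:
                    row.append(float(sum(int(a) for a in parts["GT"].replace("|", "/").split("/"))))
            meta_rows.append(
                {"id": vid, "chrom": chrom, "pos": int(pos), "ref": ref, "alt": alt,
                 "af": af, "impact": "other", "dhs": False}
            )
            dosage_rows.append(row)
    variants = pd.DataFrame(meta_rows, columns=VARIANT_COLUMNS)
    dosages = np.asarray(dosage_rows, dtype=float).T
    return GenotypeSet(speaker_ids, variants, dosages, kinship)
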