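"""Readers and writers for the pipeline's file formats.

Genotypes travel as PLINK text PED/MAP; everything else is headered
tab-separated text. All coordinates are 1-based inclusive. Readers reject
malformed rows rather than repairing them; every writer emits files its
paired reader accepts.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .datatypes import (
    GENE_COLUMNS,
    PHENOTYPE_COLUMNS,
    GenotypeMatrix,
    validate_gene_table,
    validate_phenotypes,
)
from .errors import ParseError, SchemaError
from .simulate import orient_to_minor

_MISSING_ALLELE = "0"


# ---------------------------------------------------------------------------
# PLINK text genotypes
# ---------------------------------------------------------------------------

def read_plink_text(
    ped_path, map_path, breed_map: dict[str, str] | None = None
) -> GenotypeMatrix:
    """Load a PED/MAP pair into a dosage matrix.

    Allele pairs are recoded to dosages of the minor allele, counted over the
    loaded samples (frequency ties resolve to the lexicographically smaller
    allele). ``0 0`` genotypes become missing. The breed label is taken from
    the PED family-ID column unless ``breed_map`` (sample id -> breed)
    overrides it.
    """
    map_rows = []
    with open(map_path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip():
                continue
            parts = line.split()
            if len(parts) != 4:
                raise ParseError(f"{map_path}:{lineno}: expected 4 MAP columns, got {len(parts)}")
            chrom, snp, _cm, pos = parts
            map_rows.append((chrom, snp, int(pos)))
    if not map_rows:
        raise ParseError(f"{map_path}: empty MAP file")
    n_snps = len(map_rows)

    fam, iid, rows = [], [], []
    with open(ped_path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip():
                continue
            parts = line.split()
            if len(parts) != 6 + 2 * n_snps:
                raise ParseError(
                    f"{ped_path}:{lineno}: expected {6 + 2 * n_snps} PED columns, got {len(parts)}"
                )
            fam.append(parts[0])
            iid.append(parts[1])
            alleles = parts[6:]
            a = alleles[0::2]
            b = alleles[1::2]
            for j in range(n_snps):
                if (a[j] == _MISSING_ALLELE) != (b[j] == _MISSING_ALLELE):
                    raise ParseError(
                        f"{ped_path}:{lineno}: half-missing genotype for SNP "
                        f"'{map_rows[j][1]}'"
                    )
            rows.append((a, b))
    if not rows:
        raise ParseError(f"{ped_path}: empty PED file")

    n = len(rows)
    dosages = np.full((n, n_snps), np.nan)
    a1 = np.empty(n_snps, dtype=object)
    a2 = np.empty(n_snps, dtype=object)
    for j in range(n_snps):
        seen = sorted(
            {r[0][j] for r in rows if r[0][j] != _MISSING_ALLELE}
            | {r[1][j] for r in rows if r[1][j] != _MISSING_ALLELE}
        )
        if len(seen) > 2:
            raise ParseError(f"SNP '{map_rows[j][1]}' has more than two alleles: {seen}")
        if len(seen) == 0:
            a1[j], a2[j] = "N", "N"
            continue
        ref = seen[0]  # count allele `ref`; orientation fixed afterwards
        alt = seen[1] if len(seen) == 2 else seen[0]
        a1[j], a2[j] = ref, alt
        for i, (ra, rb) in enumerate(rows):
            if ra[j] == _MISSING_ALLELE:
                continue
            dosages[i, j] = (ra[j] == ref) + (rb[j] == ref)

    snps = pd.DataFrame(
        {
            "snp": [r[1] for r in map_rows],
            "chrom": [r[0] for r in map_rows],
            "pos": [r[2] for r in map_rows],
            "a1": a1,
            "a2": a2,
        }
    )
    dosages, snps = orient_to_minor(dosages, snps)
    breeds = [breed_map.get(s, f) if breed_map else f for s, f in zip(iid, fam)]
    samples = pd.DataFrame({"sample": iid, "breed": breeds})
    return GenotypeMatrix(dosages, snps, samples)


def write_plink_text(g: GenotypeMatrix, prefix) -> tuple[Path, Path]:
    """Write ``<prefix>.ped`` / ``<prefix>.map`` for a genotype matrix."""
    prefix = Path(prefix)
    prefix.parent.mkdir(parents=True, exist_ok=True)
    map_path = prefix.with_suffix(".map")
    ped_path = prefix.with_suffix(".ped")
    with open(map_path, "w") as fh:
        for r in g.snps.itertuples(index=False):
            fh.write(f"{r.chrom}\t{r.snp}\t0\t{r.pos}\n")
    a1 = g.snps["a1"].to_numpy(dtype=object)
    a2 = g.snps["a2"].to_numpy(dtype=object)
    with open(ped_path, "w") as fh:
        for i, s in enumerate(g.samples.itertuples(index=False)):
            fields = [s.breed, s.sample, "0", "0", "0", "-9"]
            row = g.dosages[i]
            for j, d in enumerate(row):
                if np.isnan(d):
                    fields += [_MISSING_ALLELE, _MISSING_ALLELE]
                elif d == 2:
                    fields += [a1[j], a1[j]]
                elif d == 1:
                    fields += [a1[j], a2[j]]
                else:
                    fields += [a2[j], a2[j]]
            fh.write(" ".join(fields) + "\n")
    return ped_path, map_path


# ---------------------------------------------------------------------------
# tab-separated tables
# ---------------------------------------------------------------------------

def _read_tsv(path, required: tuple[str, ...]) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", float_precision="round_trip")
    for col in required:
        if col not in df.columns:
            raise SchemaError(f"{path}: missing required column '{col}'")
    return df


def read_phenotypes(path) -> pd.DataFrame:
    """Read the breed phenotype table (TSV) and validate its invariants."""
    return validate_phenotypes(_read_tsv(path, PHENOTYPE_COLUMNS))


def write_phenotypes(df: pd.DataFrame, path) -> None:
    validate_phenotypes(df)
    df.to_csv(path, sep="\t", index=False, float_format="%.17g")


def read_gene_table(path) -> pd.DataFrame:
    """Read a gene-interval table (gene, chrom, start, end; 1-based inclusive)."""
    df = _read_tsv(path, GENE_COLUMNS)
    df["chrom"] = df["chrom"].astype(str)
    return validate_gene_table(df)


def write_gene_table(df: pd.DataFrame, path) -> None:
    validate_gene_table(df)
    df.to_csv(path, sep="\t", index=False)


ASSOCIATION_COLUMNS = ("snp", "chrom", "pos", "n_used", "beta", "se", "raw_p", "corrected_p", "tier")


def write_association_table(table: pd.DataFrame, path) -> None:
    """Write an association table at full float precision (round-trip exact)."""
    for col in ASSOCIATION_COLUMNS:
        if col not in table.columns:
            raise SchemaError(f"association table missing required column '{col}'")
    table.to_csv(path, sep="\t", index=False, float_format="%.17g")


def read_association_table(path) -> pd.DataFrame:
    return _read_tsv(path, ASSOCIATION_COLUMNS)


def write_manhattan_table(table: pd.DataFrame, path) -> None:
    """Association table plus a cumulative genome coordinate per SNP.

    Chromosomes are laid end to end in natural order (numeric labels first,
    then alphabetic), giving an x-axis a Manhattan plot can use directly.
    """
    for col in ("snp", "chrom", "pos"):
        if col not in table.columns:
            raise SchemaError(f"manhattan table missing required column '{col}'")
    t = table.copy()

    def _key(label: str):
        s = str(label)
        return (0, int(s)) if s.isdigit() else (1, s)

    offsets: dict[str, int] = {}
    running = 0
    for chrom in sorted(t["chrom"].astype(str).unique(), key=_key):
        offsets[chrom] = running
        running += int(t.loc[t["chrom"].astype(str) == chrom, "pos"].max())
    t["genome_pos"] = [
        offsets[str(c)] + int(p) for c, p in zip(t["chrom"], t["pos"])
    ]
    t.to_csv(path, sep="\t", index=False, float_format="%.17g")


def write_truth_table(truth: pd.DataFrame, path) -> None:
    truth.to_csv(path, sep="\t", index=False)


def read_breed_map(path) -> dict[str, str]:
    """Optional sample -> breed override file (two tab-separated columns)."""
    df = _read_tsv(path, ("sample", "breed"))
    if df["sample"].duplicated().any():
        raise SchemaError(f"{path}: duplicate sample id in breed map")
    return dict(zip(df["sample"].astype(str), df["breed"].astype(str)))
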