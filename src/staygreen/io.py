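"""Readers and writers for the plain-text interchange formats.

Phenotype tables, weather, green-leaf scorings, genotype matrices with a
marker map, and BLUE tables all travel as CSV/TSV; a minimal VCF writer
and reader handle the same dosages for interoperability. Readers validate
rather than silently coerce: missing columns and duplicate keys raise with
the offending rows named.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .synthetic_data import GenotypeMatrix

__all__ = [
    "read_phenotypes",
    "write_phenotypes",
    "read_weather",
    "read_scorings",
    "read_blues",
    "write_blues",
    "read_genotypes",
    "write_genotypes",
    "read_vcf",
    "write_vcf",
]

_PHENO_REQUIRED = ["cultivar", "season", "rep", "trait", "value"]


def read_phenotypes(path) -> pd.DataFrame:
    """Read a long-format phenotype CSV and validate its structure.

    Requires columns cultivar, season, rep, trait, value (subgroup and
    year_of_release are optional); rejects duplicate
    (cultivar, season, rep, trait) keys, naming the first offenders.
    """
    df = pd.read_csv(path, skipinitialspace=True)
    df.columns = [c.strip() for c in df.columns]
    missing = [c for c in _PHENO_REQUIRED if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing required column(s) {missing}")
    for c in ("cultivar", "trait"):
        df[c] = df[c].astype(str).str.strip()
    bad = pd.to_numeric(df["value"], errors="coerce").isna() & df["value"].notna()
    if bad.any():
        lines = (df.index[bad] + 2).tolist()
        raise ValueError(f"{path}: non-numeric value(s) at line(s) {lines[:5]}")
    df["value"] = pd.to_numeric(df["value"], errors="coerce")
    key = ["cultivar", "season", "rep", "trait"]
    dup = df.duplicated(key, keep=False)
    if dup.any():
        first = df.loc[dup, key].iloc[0].tolist()
        raise ValueError(f"{path}: duplicate phenotype rows, first key {tuple(first)}")
    return df


def write_phenotypes(df: pd.DataFrame, path) -> None:
    cols = [c for c in ("cultivar", "year_of_release", "season", "rep", "subgroup",
                        "trait", "value") if c in df.columns]
    df[cols].to_csv(path, index=False)


def read_weather(path) -> pd.DataFrame:
    df = pd.read_csv(path, skipinitialspace=True)
    df.columns = [c.strip() for c in df.columns]
    if "date" not in df.columns:
        raise ValueError(f"{path}: weather table needs a 'date' column")
    if "tmean" not in df.columns and not {"tmin", "tmax"}.issubset(df.columns):
        raise ValueError(f"{path}: need 'tmean' or 'tmin'+'tmax'")
    df["date"] = pd.to_datetime(df["date"])
    return df


def read_scorings(path) -> pd.DataFrame:
    """Green-leaf scoring CSV: plot identifiers + tt + green_pct."""
    df = pd.read_csv(path, skipinitialspace=True)
    df.columns = [c.strip() for c in df.columns]
    for c in ("tt", "green_pct"):
        if c not in df.columns:
            raise ValueError(f"{path}: scoring table needs a {c!r} column")
    if not ({"plot"} <= set(df.columns) or {"cultivar"} <= set(df.columns)):
        raise ValueError(f"{path}: scoring table needs 'plot' or 'cultivar' ids")
    out_of_range = (df["green_pct"] < 0) | (df["green_pct"] > 100)
    if out_of_range.any():
        lines = (df.index[out_of_range] + 2).tolist()
        raise ValueError(f"{path}: green_pct outside [0, 100] at line(s) {lines[:5]}")
    return df


def read_blues(path) -> pd.DataFrame:
    df = pd.read_csv(path, skipinitialspace=True)
    df.columns = [c.strip() for c in df.columns]
    for c in ("cultivar", "trait", "blue"):
        if c not in df.columns:
            raise ValueError(f"{path}: BLUE table needs a {c!r} column")
    if "season" not in df.columns:
        df["season"] = np.nan
    return df


def write_blues(df: pd.DataFrame, path) -> None:
    df.to_csv(path, index=False)


def write_genotypes(g: GenotypeMatrix, prefix) -> tuple[Path, Path]:
    """Write dosages as TSV (markers x cultivars) plus a marker-map CSV."""
    prefix = Path(prefix)
    mat_path = prefix.with_suffix(".tsv")
    map_path = prefix.parent / (prefix.name + "_map.csv")
    mat = pd.DataFrame(g.dosages.T, index=g.markers, columns=g.cultivars)
    mat.index.name = "marker"
    mat.to_csv(mat_path, sep="\t", na_rep="NA")
    g.marker_map.to_csv(map_path, index=False)
    return mat_path, map_path


def read_genotypes(matrix_path, map_path) -> GenotypeMatrix:
    """Read a markers x cultivars dosage TSV and its marker map CSV."""
    mat = pd.read_csv(matrix_path, sep="\t", index_col=0, na_values=["NA", ""])
    mm = pd.read_csv(map_path)
    for c in ("marker", "chromosome", "position_mbp"):
        if c not in mm.columns:
            raise ValueError(f"{map_path}: marker map needs a {c!r} column")
    markers = list(mat.index.astype(str))
    mm["marker"] = mm["marker"].astype(str)
    return GenotypeMatrix(
        cultivars=list(mat.columns.astype(str)),
        markers=markers,
        dosages=mat.to_numpy(dtype=float).T,
        marker_map=mm,
    )


def write_vcf(g: GenotypeMatrix, path) -> None:
    """Minimal uncompressed VCF (GT only) for the dosage matrix.

    Positions are written in bp (map Mbp x 1e6, rounded); alleles are
    placeholders A/T since only dosages are modelled.
    """
    mm = g.marker_map.set_index("marker")
    gt_code = {0.0: "0/0", 1.0: "0/1", 2.0: "1/1"}
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t")
        fh.write("\t".join(g.cultivars) + "\n")
        order = np.lexsort(
            (mm.loc[g.markers, "position_mbp"].to_numpy(),
             mm.loc[g.markers, "chromosome"].to_numpy())
        )
        for j in order:
            m = g.markers[j]
            chrom = mm.loc[m, "chromosome"]
            pos = int(round(float(mm.loc[m, "position_mbp"]) * 1e6))
            gts = [gt_code.get(d, "./.") if not np.isnan(d) else "./." for d in g.dosages[:, j]]
            fh.write(f"{chrom}\t{pos}\t{m}\tA\tT\t.\tPASS\t.\tGT\t" + "\t".join(gts) + "\n")


def read_vcf(path) -> GenotypeMatrix:
    """Read a biallelic GT-only VCF into a dosage matrix (alt-allele counts)."""
    cultivars: list[str] = []
    markers, chroms, poss, rows = [], [], [], []
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if line.startswith("##") or not line:
                continue
            if line.startswith("#CHROM"):
                cultivars = line.split("\t")[9:]
                continue
            parts = line.split("\t")
            chrom, pos, mid, ref, alt = parts[0], parts[1], parts[2], parts[3], parts[4]
            if "," in alt:
                continue  # biallelic records only
            fmt = parts[8].split(":")
            gi = fmt.index("GT")
            dos = []
            for cell in parts[9:]:
                gt = cell.split(":")[gi].replace("|", "/")
                if "." in gt:
                    dos.append(np.nan)
                else:
                    dos.append(float(sum(int(a) for a in gt.split("/"))))
            markers.append(mid)
            chroms.append(chrom)
            poss.append(float(pos) / 1e6)
            rows.append(dos)
    if not cultivars:
        raise ValueError(f"{path}: no #CHROM header line")
    mm = pd.DataFrame({"marker": markers, "chromosome": chroms, "position_mbp": poss})
    return GenotypeMatrix(
        cultivars=cultivars,
        markers=markers,
        dosages=np.asarray(rows, dtype=float).T,
        marker_map=mm,
    )
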