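"""Readers and writers for the pipeline's plain-text formats.

The canonical interchange is TSV: a genotype matrix (lines × SNPs, calls
``A``/``H``/``B``/``NA`` with A = elite homozygote and B = wild homozygote,
or ``-1``/``0``/``1``/``NA`` in the numeric dialect), a genetic map
(``snp``, ``chrom``, ``cm``), a long trait table (``line``, ``trait``,
``value``) and the result tables. VCF import is a convenience for callers
whose genotypes live in variant files; physical positions stand in for map
coordinates there and should be replaced with a real genetic map when one
exists.
"""

from __future__ import annotations

import json
import warnings
from pathlib import Path

import numpy as np
import pandas as pd

from .matrix import ELITE_HOM, HET, MISSING, WILD_HOM, GenotypeMatrix

__all__ = [
    "read_genotype_matrix",
    "write_genotype_matrix",
    "read_genetic_map",
    "write_genetic_map",
    "read_trait_table",
    "read_vcf_as_matrix",
    "write_outputs",
]

_DIALECTS = {
    "letters": {"A": ELITE_HOM, "H": HET, "B": WILD_HOM, "NA": MISSING},
    "numeric": {"-1": ELITE_HOM, "0": HET, "1": WILD_HOM, "NA": MISSING},
}
_FLOAT_FMT = "%.6g"


def read_genetic_map(path: str | Path) -> pd.DataFrame:
    gmap = pd.read_csv(path, sep="\t", dtype={"snp": str, "chrom": str})
    missing = {"snp", "chrom", "cm"} - set(gmap.columns)
    if missing:
        raise ValueError(f"map file {path} lacks columns: {sorted(missing)}")
    gmap["cm"] = gmap["cm"].astype(float)
    return gmap


def write_genetic_map(gmap: pd.DataFrame, path: str | Path) -> None:
    gmap[["snp", "chrom", "cm"]].to_csv(
        path, sep="\t", index=False, float_format=_FLOAT_FMT
    )


def read_genotype_matrix(
    path: str | Path,
    gmap: pd.DataFrame,
    dialect: str = "letters",
    family_path: str | Path | None = None,
) -> GenotypeMatrix:
    """Read a genotype TSV (first column line ids, one column per SNP).

    Unknown symbols raise with the offending line id and SNP; duplicate
    line or SNP identifiers are rejected. Family assignment comes from the
    optional sidecar TSV (``line``, ``family``) or, failing that, from the
    line-identifier prefix before the first underscore.
    """
    if dialect not in _DIALECTS:
        raise ValueError(f"unknown dialect {dialect!r}; use 'letters' or 'numeric'")
    table = pd.read_csv(path, sep="\t", dtype=str, index_col=0, keep_default_na=False)
    if table.index.duplicated().any():
        raise ValueError(f"{path}: duplicated line identifiers")
    if table.columns.duplicated().any():
        raise ValueError(f"{path}: duplicated SNP identifiers")
    mapping = _DIALECTS[dialect]
    coded = table.apply(lambda col: col.map(mapping))
    bad = coded.isna()
    if bad.to_numpy().any():
        i, j = np.argwhere(bad.to_numpy())[0]
        raise ValueError(
            f"{path}: unknown call {table.iat[i, j]!r} at line "
            f"{table.index[i]!r}, SNP {table.columns[j]!r}"
        )
    family = None
    if family_path is not None:
        fam = pd.read_csv(family_path, sep="\t", dtype=str)
        family = fam.set_index("line")["family"].reindex(table.index)
    return GenotypeMatrix(calls=coded.astype(np.int8), gmap=gmap, family=family)


def write_genotype_matrix(
    g: GenotypeMatrix, path: str | Path, dialect: str = "letters"
) -> None:
    if dialect not in _DIALECTS:
        raise ValueError(f"unknown dialect {dialect!r}")
    reverse = {code: sym for sym, code in _DIALECTS[dialect].items()}
    out = g.calls.apply(lambda col: col.map(reverse))
    out.index.name = "line"
    out.to_csv(path, sep="\t")


def read_trait_table(path: str | Path) -> pd.DataFrame:
    """Long trait TSV (line, trait, value) -> lines × traits frame."""
    table = pd.read_csv(path, sep="\t", dtype={"line": str, "trait": str})
    missing = {"line", "trait", "value"} - set(table.columns)
    if missing:
        raise ValueError(f"trait file {path} lacks columns: {sorted(missing)}")
    dup = table.duplicated(["line", "trait"])
    if dup.any():
        raise ValueError(f"trait file {path}: duplicate line × trait values")
    return table.pivot(index="line", columns="trait", values="value").astype(float)


def read_vcf_as_matrix(path: str | Path) -> GenotypeMatrix:
    """Read a biallelic VCF into the four-state coding.

    GT 0/0 -> elite homozygote, 0/1 or 1/0 -> heterozygous, 1/1 -> wild
    homozygote, missing -> no call (phase is ignored). Multi-allelic
    records are skipped with a warning. The map uses physical positions
    (bp in the ``cm`` column) as placeholder coordinates.
    """
    import pysam

    with pysam.VariantFile(str(path)) as vcf:
        samples = list(vcf.header.samples)
        if not samples:
            raise ValueError(f"{path}: VCF has no samples")
        snp_ids, chroms, positions, rows, skipped = [], [], [], [], []
        for rec in vcf:
            if rec.alts is None or len(rec.alts) != 1:
                skipped.append(rec.id or f"{rec.chrom}:{rec.pos}")
                continue
            calls = np.empty(len(samples), dtype=np.int8)
            for k, sample in enumerate(samples):
                gt = rec.samples[sample].get("GT")
                if gt is None:
                    raise ValueError(f"{path}: record {rec.chrom}:{rec.pos} lacks GT")
                alleles = [a for a in gt if a is not None]
                if len(alleles) < 2:
                    calls[k] = MISSING
                else:
                    dosage = sum(alleles)
                    calls[k] = (ELITE_HOM, HET, WILD_HOM)[dosage]
            snp_ids.append(rec.id or f"{rec.chrom}:{rec.pos}")
            chroms.append(rec.chrom)
            positions.append(float(rec.pos))
            rows.append(calls)
    if skipped:
        warnings.warn(
            f"{path}: skipped {len(skipped)} multi-allelic records "
            f"(first: {skipped[:3]})"
        )
    if not snp_ids:
        raise ValueError(f"{path}: no usable biallelic records")
    calls = pd.DataFrame(
        np.column_stack(rows), index=pd.Index(samples, name="line"), columns=snp_ids
    )
    gmap = pd.DataFrame({"snp": snp_ids, "chrom": chroms, "cm": positions})
    return GenotypeMatrix(calls=calls, gmap=gmap)


def write_outputs(
    prefix: str | Path,
    summaries: pd.DataFrame | None = None,
    windows: pd.DataFrame | None = None,
    fixation=None,
    manifest: dict | None = None,
) -> list[Path]:
    """Write result tables under a common prefix; returns the paths written.

    Emits ``<prefix>.snp_summary.tsv``, ``<prefix>.windows.tsv``, a
    BED-like window track ``<prefix>.windows.bed`` (0-based half-open cM
    intervals — genetic, not physical, coordinates), the fixation matrix
    TSV and a JSON run manifest. Floats use 6 significant digits and rows
    keep a deterministic order, so identical runs produce identical files.
    """
    prefix = Path(prefix)
    prefix.parent.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []

    if summaries is not None:
        p = Path(str(prefix) + ".snp_summary.tsv")
        out = summaries.copy()
        out.index.name = "snp"
        out.to_csv(p, sep="\t", float_format=_FLOAT_FMT)
        written.append(p)
    if windows is not None:
        p = Path(str(prefix) + ".windows.tsv")
        windows.to_csv(p, sep="\t", index=False, float_format=_FLOAT_FMT)
        written.append(p)
        bed = Path(str(prefix) + ".windows.bed")
        with open(bed, "w") as fh:
            for _, row in windows.iterrows():
                sig = int(bool(row.get("significant", False)))
                p_str = _FLOAT_FMT % row["p"] if np.isfinite(row["p"]) else "NA"
                fh.write(
                    f"{row['chrom']}\t{_FLOAT_FMT % row['start_cm']}\t"
                    f"{_FLOAT_FMT % row['end_cm']}\t"
                    f"{_FLOAT_FMT % row['mean_rfd']}\t{p_str}\t{sig}\n"
                )
        written.append(bed)
    if fixation is not None:
        p = Path(str(prefix) + ".fixation.tsv")
        vals = fixation.values.copy()
        out = vals.where(fixation.defined, other=np.nan)
        text = out.map(lambda v: "NA" if pd.isna(v) else str(int(v)))
        text.index.name = "line"
        text.to_csv(p, sep="\t")
        written.append(p)
    if manifest is not None:
        p = Path(str(prefix) + ".manifest.json")
        with open(p, "w") as fh:
            json.dump(manifest, fh, indent=2, sort_keys=True, default=str)
            fh.write("\n")
        written.append(p)
    return written
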