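"""Genotype-call containers shared across the pipeline.

Calls are coded as small integers so that line × SNP matrices stay compact
and vectorised operations stay cheap:

====================  =====  =========================================
constant              code   meaning
====================  =====  =========================================
``ELITE_HOM``         0      homozygous for the recurrent elite allele
``HET``               1      heterozygous (or reconstructed het)
``WILD_HOM``          2      homozygous for the wild-donor allele
``MISSING``           -1     no call
====================  =====  =========================================

The integer codes double as wild-allele dosage for the non-missing states.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

ELITE_HOM: int = 0
HET: int = 1
WILD_HOM: int = 2
MISSING: int = -1

CALL_CODES = (ELITE_HOM, HET, WILD_HOM, MISSING)

#: map-ordered columns expected of a genetic map frame
MAP_COLUMNS = ("snp", "chrom", "cm")


def validate_genetic_map(gmap: pd.DataFrame) -> pd.DataFrame:
    """Check a genetic map frame and return it sorted in map order.

    Expects columns ``snp`` (unique identifiers), ``chrom`` and ``cm``
    (centiMorgan position, non-negative). Ties on position are broken by
    SNP identifier so the order is deterministic.
    """
    missing = set(MAP_COLUMNS) - set(gmap.columns)
    if missing:
        raise ValueError(f"genetic map lacks columns: {sorted(missing)}")
    if gmap["snp"].duplicated().any():
        dups = gmap.loc[gmap["snp"].duplicated(), "snp"].tolist()
        raise ValueError(f"duplicate SNP identifiers in map: {dups[:5]}")
    if (gmap["cm"] < 0).any():
        raise ValueError("genetic map contains negative cM positions")
    out = gmap.sort_values(["chrom", "cm", "snp"], kind="mergesort")
    return out.reset_index(drop=True)


@dataclass
class GenotypeMatrix:
    """Line × SNP genotype calls tied to a genetic map.

    Parameters
    ----------
    calls
        DataFrame indexed by line identifier with one column per SNP, values
        in :data:`CALL_CODES`. Columns follow the map order.
    gmap
        Genetic map (``snp``, ``chrom``, ``cm``) covering every column.
    family
        Family assignment per line. If omitted it is parsed from the line
        identifier prefix before the first underscore.
    """

    calls: pd.DataFrame
    gmap: pd.DataFrame
    family: pd.Series | None = field(default=None)

    def __post_init__(self) -> None:
        self.gmap = validate_genetic_map(self.gmap)
        if self.calls.index.duplicated().any():
            raise ValueError("duplicate line identifiers")
        vals = self.calls.to_numpy()
        bad = ~np.isin(vals, CALL_CODES)
        if bad.any():
            i, j = np.argwhere(bad)[0]
            raise ValueError(
                f"invalid call code {vals[i, j]!r} at line "
                f"{self.calls.index[i]!r}, SNP {self.calls.columns[j]!r}"
            )
        mapped = set(self.gmap["snp"])
        unknown = [c for c in self.calls.columns if c not in mapped]
        if unknown:
            raise ValueError(f"SNPs absent from the genetic map: {unknown[:5]}")
        # restrict the map to present SNPs and order columns accordingly
        present = self.gmap[self.gmap["snp"].isin(self.calls.columns)]
        self.gmap = present.reset_index(drop=True)
        self.calls = self.calls.loc[:, self.gmap["snp"].tolist()]
        self.calls = self.calls.astype(np.int8)
        if self.family is None:
            prefixes = [str(l).split("_", 1)[0] for l in self.calls.index]
            self.family = pd.Series(prefixes, index=self.calls.index, name="family")
        else:
            self.family = self.family.reindex(self.calls.index)
            if self.family.isna().any():
                lost = self.family.index[self.family.isna()].tolist()
                raise ValueError(f"lines without family assignment: {lost[:5]}")

    # -- convenience accessors -------------------------------------------------

    @property
    def lines(self) -> pd.Index:
        return self.calls.index

    @property
    def snps(self) -> pd.Index:
        return self.calls.columns

    @property
    def n_lines(self) -> int:
        return self.calls.shape[0]

    @property
    def n_snps(self) -> int:
        return self.calls.shape[1]

    def subset(self, lines=None, snps=None) -> "GenotypeMatrix":
        """Return a new matrix restricted to the given lines and/or SNPs."""
        calls = self.calls
        if lines is not None:
            calls = calls.loc[[l for l in calls.index if l in set(lines)]]
        if snps is not None:
            keep = set(snps)
            calls = calls.loc[:, [s for s in calls.columns if s in keep]]
        fam = self.family.reindex(calls.index) if self.family is not None else None
        return GenotypeMatrix(calls=calls.copy(), gmap=self.gmap.copy(), family=fam)

    def align_with(self, other: "GenotypeMatrix") -> tuple["GenotypeMatrix", "GenotypeMatrix"]:
        """Restrict both matrices to their shared lines and SNPs (map order)."""
        lines = [l for l in self.lines if l in set(other.lines)]
        snps = [s for s in self.snps if s in set(other.snps)]
        if not lines:
            raise ValueError("matrices share no line identifiers")
        if not snps:
            raise ValueError("matrices share no SNP identifiers")
        a = self.subset(lines=lines, snps=snps)
        b = other.subset(lines=lines, snps=snps)
        b.calls = b.calls.loc[a.lines, a.snps]
        return a, b
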