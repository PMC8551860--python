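"""Marker- and line-level quality control for paired genotype matrices.

Markers are retained when they are polymorphic within at least one family,
have a no-call rate below 10% and a heterozygous-call rate below 12.5%
(twice the expectation in the base generation); markers with identical
call vectors are collapsed to one representative; lines whose two
generations are clearly inconsistent — opposite homozygotes where the base
generation was already fixed — are dropped. The fixation statistics add a
final rule: a marker enters the AFR/RFD computation only with at least 10
heterozygous lines in the base generation.

All thresholds are strict inequalities and all rules are evaluated on the
input matrix, so filters are idempotent and order-independent.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .matrix import ELITE_HOM, HET, MISSING, WILD_HOM, GenotypeMatrix

__all__ = [
    "QCReport",
    "filter_snps",
    "remove_duplicate_snps",
    "filter_lines",
    "min_het_snp_filter",
]


@dataclass
class QCReport:
    """Per-rule outcomes of the marker filters plus summary counts."""

    snp_rules: pd.DataFrame  # index snp; polymorphic, failure_ok, het_ok, retained
    summary: dict


def filter_snps(
    g: GenotypeMatrix,
    max_failure: float = 0.10,
    max_het: float = 0.125,
) -> tuple[pd.Index, QCReport]:
    """Apply the marker quality rules; return retained SNPs and a report.

    A marker is retained iff (a) at least one family shows two distinct
    non-missing genotype classes, (b) its missing fraction over all lines
    is strictly below ``max_failure`` and (c) its heterozygous fraction
    among non-missing calls is strictly below ``max_het``.
    """
    if g.n_lines == 0 or g.n_snps == 0:
        raise ValueError("empty genotype matrix")
    if g.family is None:
        raise ValueError("family assignment required for the polymorphism rule")
    calls = g.calls.to_numpy()
    n_lines = calls.shape[0]

    missing = calls == MISSING
    n_missing = missing.sum(axis=0)
    n_nonmissing = n_lines - n_missing
    failure_ok = (n_missing / n_lines) < max_failure

    n_het = (calls == HET).sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        het_frac = np.where(n_nonmissing > 0, n_het / np.maximum(n_nonmissing, 1), 1.0)
    het_ok = het_frac < max_het

    polymorphic = np.zeros(g.n_snps, dtype=bool)
    for _, idx in g.family.groupby(g.family).groups.items():
        block = g.calls.loc[idx].to_numpy()
        present = block != MISSING
        seen = [
            present.any(axis=0) & (block == code).any(axis=0)
            for code in (ELITE_HOM, HET, WILD_HOM)
        ]
        n_classes = np.sum(seen, axis=0)
        polymorphic |= n_classes >= 2

    retained = polymorphic & failure_ok & het_ok
    snp_rules = pd.DataFrame(
        {
            "polymorphic": polymorphic,
            "failure_ok": failure_ok,
            "het_ok": het_ok,
            "retained": retained,
        },
        index=g.snps,
    )
    report = QCReport(
        snp_rules=snp_rules,
        summary={
            "n_snps": int(g.n_snps),
            "n_retained": int(retained.sum()),
            "n_fail_polymorphic": int((~polymorphic).sum()),
            "n_fail_failure_rate": int((~failure_ok).sum()),
            "n_fail_het_rate": int((~het_ok).sum()),
        },
    )
    return g.snps[retained], report


def remove_duplicate_snps(g: GenotypeMatrix) -> tuple[pd.Index, dict]:
    """Collapse markers with identical call vectors across all lines.

    Markers in perfect agreement (including the missingness pattern)
    carry no independent information; only the first in map order is kept.
    Returns the retained SNPs and a mapping dropped SNP -> kept SNP.
    """
    calls = g.calls
    first_of: dict[bytes, str] = {}
    dropped: dict[str, str] = {}
    keep = []
    arr = np.ascontiguousarray(calls.to_numpy().T)
    for j, snp in enumerate(calls.columns):
        key = arr[j].tobytes()
        if key in first_of:
            dropped[snp] = first_of[key]
        else:
            first_of[key] = snp
            keep.append(snp)
    return pd.Index(keep), dropped


def filter_lines(
    g0: GenotypeMatrix,
    g8: GenotypeMatrix,
    max_mismatch: float = 0.05,
) -> tuple[pd.Index, pd.Series]:
    """Drop lines whose later calls contradict already-fixed base calls.

    The mismatch rate of a line is the fraction of markers homozygous in
    the base generation whose later call is the *opposite* homozygote —
    transitions that selfing cannot produce, so a high rate indicates a
    sample mix-up. Lines with rate > ``max_mismatch`` are dropped.
    Returns the retained lines and the per-line mismatch rates.
    """
    a, b = g0.align_with(g8)
    c0 = a.calls.to_numpy()
    c8 = b.calls.to_numpy()
    hom0 = (c0 == ELITE_HOM) | (c0 == WILD_HOM)
    opposite = ((c0 == ELITE_HOM) & (c8 == WILD_HOM)) | (
        (c0 == WILD_HOM) & (c8 == ELITE_HOM)
    )
    n_hom = hom0.sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        rate = np.where(n_hom > 0, opposite.sum(axis=1) / np.maximum(n_hom, 1), 0.0)
    rates = pd.Series(rate, index=a.lines, name="mismatch_rate")
    retained = a.lines[rate <= max_mismatch]
    return retained, rates


def min_het_snp_filter(g0: GenotypeMatrix, min_het_lines: int = 10) -> pd.Index:
    """Markers with at least ``min_het_lines`` heterozygous base-generation calls.

    Fixation rates estimated from very few initially heterozygous lines are
    unstable; the default of 10 lines mirrors the scan's inclusion rule.
    """
    n_het = (g0.calls.to_numpy() == HET).sum(axis=0)
    return g0.snps[n_het >= min_het_lines]
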