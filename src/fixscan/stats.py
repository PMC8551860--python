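"""Allele-fixation statistics and the sliding-window selection scan.

The central objects are the *fixation matrix* and two per-marker rates.
For every line × marker entry that was heterozygous in the base
generation, the later pooled call is recoded as

* ``-1`` — fixed for the elite allele,
* ``0``  — still heterozygous (reconstructed heterozygosity),
* ``+1`` — fixed for the wild allele,

with entries masked wherever the base call was not heterozygous. Per
marker,

.. math::

    AFR = \\frac{n_{elite} + n_{wild}}{n_{het,0}}, \\qquad
    RFD = \\frac{n_{wild} - n_{elite}}{n_{het,0}},

so AFR ∈ [0, 1] measures how much initial heterozygosity was lost and
RFD ∈ [−1, 1] which allele it was lost to (positive = wild). Deviations
from symmetric fixation are tested per window of 10 consecutive markers
with a chi-square goodness-of-fit test of the summed elite/wild counts
against a 1:1 ratio, Bonferroni-controlled over all testable windows.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from .matrix import ELITE_HOM, HET, MISSING, WILD_HOM, GenotypeMatrix

__all__ = [
    "FixationMatrix",
    "build_fixation_matrix",
    "snp_summaries",
    "afr",
    "rfd",
    "sliding_windows",
    "bonferroni_scan",
]


@dataclass
class FixationMatrix:
    """Line × SNP fixation values with the initially-heterozygous mask.

    ``values`` holds −1/0/+1 as floats with NaN where the later call is
    missing; ``defined`` marks entries whose base call was heterozygous —
    only those entries exist for the statistics. The genetic map travels
    along for the window scan.
    """

    values: pd.DataFrame
    defined: pd.DataFrame
    gmap: pd.DataFrame

    @property
    def lines(self) -> pd.Index:
        return self.values.index

    @property
    def snps(self) -> pd.Index:
        return self.values.columns

    def counts(self) -> pd.DataFrame:
        """Per-SNP counts: n_het0, n_elite, n_wild, n_zero, n_missing."""
        vals = self.values.to_numpy()
        defined = self.defined.to_numpy()
        n_het0 = defined.sum(axis=0)
        n_elite = ((vals == -1) & defined).sum(axis=0)
        n_wild = ((vals == 1) & defined).sum(axis=0)
        n_zero = ((vals == 0) & defined).sum(axis=0)
        n_missing = (np.isnan(vals) & defined).sum(axis=0)
        return pd.DataFrame(
            {
                "n_het0": n_het0,
                "n_elite": n_elite,
                "n_wild": n_wild,
                "n_zero": n_zero,
                "n_missing": n_missing,
            },
            index=self.snps,
        )


def build_fixation_matrix(g0: GenotypeMatrix, g8: GenotypeMatrix) -> FixationMatrix:
    """Recode later-generation calls at initially heterozygous entries.

    Both matrices must cover the same lines and markers (run QC and
    alignment first). Entries where the base call is not heterozygous are
    masked; where it is, the later call maps to −1 (elite homozygote),
    0 (heterozygous), +1 (wild homozygote) or NaN (no call).
    """
    if list(g0.lines) != list(g8.lines) or list(g0.snps) != list(g8.snps):
        raise ValueError(
            "matrices must share identical line and SNP identifiers; "
            "align and QC-filter them first"
        )
    c0 = g0.calls.to_numpy()
    c8 = g8.calls.to_numpy()
    defined = c0 == HET
    vals = np.full(c0.shape, np.nan)
    vals[defined & (c8 == ELITE_HOM)] = -1.0
    vals[defined & (c8 == HET)] = 0.0
    vals[defined & (c8 == WILD_HOM)] = 1.0
    # defined & c8 == MISSING stays NaN; undefined entries stay NaN too but
    # are excluded by the mask
    return FixationMatrix(
        values=pd.DataFrame(vals, index=g0.lines.copy(), columns=g0.snps.copy()),
        defined=pd.DataFrame(defined, index=g0.lines.copy(), columns=g0.snps.copy()),
        gmap=g0.gmap.copy(),
    )


def snp_summaries(fm: FixationMatrix, denominator: str = "initial") -> pd.DataFrame:
    """Per-SNP fixation summary: counts, AFR and RFD, joined to the map.

    ``denominator`` controls how missing later calls enter the rates:
    ``"initial"`` (default) divides by all initially heterozygous lines,
    the literal reading of the rate definitions; ``"observed"`` divides by
    the initially heterozygous lines with a non-missing later call.
    Markers with a zero denominator get NaN rates.
    """
    if denominator not in ("initial", "observed"):
        raise ValueError("denominator must be 'initial' or 'observed'")
    counts = fm.counts()
    denom = counts["n_het0"].to_numpy().astype(float)
    if denominator == "observed":
        denom = denom - counts["n_missing"].to_numpy()
    with np.errstate(invalid="ignore", divide="ignore"):
        afr_vals = np.where(
            denom > 0, (counts["n_elite"] + counts["n_wild"]) / denom, np.nan
        )
        rfd_vals = np.where(
            denom > 0, (counts["n_wild"] - counts["n_elite"]) / denom, np.nan
        )
    out = counts.copy()
    out["afr"] = afr_vals
    out["rfd"] = rfd_vals
    gmap = fm.gmap.set_index("snp")
    out.insert(0, "chrom", gmap["chrom"].reindex(out.index))
    out.insert(1, "cm", gmap["cm"].reindex(out.index))
    return out


def afr(fm: FixationMatrix, denominator: str = "initial") -> pd.Series:
    """Per-SNP allele fixation rate (fraction of initial hets now fixed)."""
    return snp_summaries(fm, denominator=denominator)["afr"].rename("afr")


def rfd(fm: FixationMatrix, denominator: str = "initial") -> pd.Series:
    """Per-SNP relative fixation direction (positive = wild allele)."""
    return snp_summaries(fm, denominator=denominator)["rfd"].rename("rfd")


def sliding_windows(
    summaries: pd.DataFrame,
    window: int = 10,
    step: int = 1,
) -> pd.DataFrame:
    """Chi-square scan of summed fixation counts in marker windows.

    ``summaries`` is the output of :func:`snp_summaries` (map order is
    taken from its ``chrom``/``cm`` columns). Windows of ``window``
    consecutive markers advance by ``step`` markers and never span
    chromosome boundaries; chromosomes with fewer markers than ``window``
    yield no windows. Per window the elite- and wild-fixed counts are
    summed and tested against a 1:1 ratio with

    .. math:: \\chi^2 = (n_{elite} - n_{wild})^2 / (n_{elite} + n_{wild})

    on 1 df. Windows with no fixed alleles are flagged untestable.
    """
    if window < 1:
        raise ValueError("window must be >= 1")
    if step < 1:
        raise ValueError("step must be >= 1")
    required = {"chrom", "cm", "n_elite", "n_wild", "afr", "rfd"}
    missing = required - set(summaries.columns)
    if missing:
        raise ValueError(f"summaries lack columns: {sorted(missing)}")
    rows = []
    widx = 0
    ordered = summaries.sort_values(["chrom", "cm"], kind="mergesort")
    for chrom, block in ordered.groupby("chrom", sort=False):
        n = len(block)
        if n < window:
            continue
        ne = block["n_elite"].to_numpy(float)
        nw = block["n_wild"].to_numpy(float)
        for start in range(0, n - window + 1, step):
            stop = start + window
            e = float(ne[start:stop].sum())
            w = float(nw[start:stop].sum())
            total = e + w
            if total > 0:
                chi2 = (e - w) ** 2 / total
                p = float(sps.chi2.sf(chi2, df=1))
                testable = True
            else:
                chi2, p, testable = np.nan, np.nan, False
            rows.append(
                {
                    "window": widx,
                    "chrom": chrom,
                    "start_snp": block.index[start],
                    "end_snp": block.index[stop - 1],
                    "start_cm": float(block["cm"].iloc[start]),
                    "end_cm": float(block["cm"].iloc[stop - 1]),
                    "n_snps": window,
                    "n_elite": int(e),
                    "n_wild": int(w),
                    "chi2": chi2,
                    "p": p,
                    "testable": testable,
                    "mean_afr": float(block["afr"].iloc[start:stop].mean()),
                    "mean_rfd": float(block["rfd"].iloc[start:stop].mean()),
                }
            )
            widx += 1
    return pd.DataFrame(
        rows,
        columns=[
            "window", "chrom", "start_snp", "end_snp", "start_cm", "end_cm",
            "n_snps", "n_elite", "n_wild", "chi2", "p", "testable",
            "mean_afr", "mean_rfd",
        ],
    )


def bonferroni_scan(windows: pd.DataFrame, alpha: float = 0.01) -> pd.DataFrame:
    """Flag windows significant at a Bonferroni-corrected level.

    The correction divides ``alpha`` by the number of *testable* windows
    (those with at least one fixed allele); untestable windows are never
    significant and do not enter the denominator. The result carries the
    denominator in ``windows.attrs['n_testable']``.
    """
    if not 0.0 < alpha < 1.0:
        raise ValueError("alpha must lie in (0, 1)")
    out = windows.copy()
    n_testable = int(out["testable"].sum()) if len(out) else 0
    if n_testable == 0:
        raise ValueError("no testable windows")
    threshold = alpha / n_testable
    out["significant"] = out["testable"] & (out["p"] < threshold)
    out.attrs["n_testable"] = n_testable
    out.attrs["alpha"] = alpha
    out.attrs["threshold"] = threshold
    return out
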