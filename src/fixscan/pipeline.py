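"""End-to-end selection scan: QC → fixation matrix → window tests.

One call takes the paired genotype matrices and runs the standard chain:
marker quality filters on each generation (retained set = intersection),
duplicate-marker collapse, line-consistency filter, the ≥10-initially-
heterozygous-lines rule, fixation recoding, per-marker AFR/RFD and the
Bonferroni-controlled sliding-window chi-square scan.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

from . import qc
from .matrix import GenotypeMatrix
from .stats import (
    FixationMatrix,
    bonferroni_scan,
    build_fixation_matrix,
    sliding_windows,
    snp_summaries,
)

__all__ = ["ScanParams", "ScanResult", "run_scan"]


@dataclass(frozen=True)
class ScanParams:
    """Tunable thresholds of the scan, defaulting to the standard rules."""

    max_failure: float = 0.10
    max_het: float = 0.125
    max_mismatch: float = 0.05
    min_het_lines: int = 10
    window: int = 10
    step: int = 1
    alpha: float = 0.01
    denominator: str = "initial"


@dataclass
class ScanResult:
    g0: GenotypeMatrix
    g8: GenotypeMatrix
    fixation: FixationMatrix
    summaries: pd.DataFrame
    windows: pd.DataFrame
    qc_report: qc.QCReport
    log: dict = field(default_factory=dict)


def run_scan(
    g0: GenotypeMatrix, g8: GenotypeMatrix, params: ScanParams | None = None
) -> ScanResult:
    """Run the full scan on a paired pair of generations.

    Returns the filtered matrices, the fixation matrix, per-marker
    summaries restricted to markers passing the minimum-heterozygous-lines
    rule, and the window table with Bonferroni flags. ``log`` records the
    row/column counts after every stage.
    """
    params = params or ScanParams()
    g0, g8 = g0.align_with(g8)
    log: dict = {"n_lines_in": g0.n_lines, "n_snps_in": g0.n_snps}

    keep0, report = qc.filter_snps(g0, params.max_failure, params.max_het)
    keep8, _ = qc.filter_snps(g8, params.max_failure, params.max_het)
    snps = [s for s in g0.snps if s in set(keep0) and s in set(keep8)]
    log["n_snps_qc"] = len(snps)
    g0 = g0.subset(snps=snps)
    g8 = g8.subset(snps=snps)

    unique_snps, dropped = qc.remove_duplicate_snps(g0)
    log["n_snps_duplicate_dropped"] = len(dropped)
    g0 = g0.subset(snps=unique_snps)
    g8 = g8.subset(snps=unique_snps)

    lines, mismatch = qc.filter_lines(g0, g8, params.max_mismatch)
    log["n_lines_dropped_inconsistent"] = int(g0.n_lines - len(lines))
    g0 = g0.subset(lines=lines)
    g8 = g8.subset(lines=lines)

    fixation = build_fixation_matrix(g0, g8)
    informative = qc.min_het_snp_filter(g0, params.min_het_lines)
    log["n_snps_min_het"] = len(informative)
    summaries = snp_summaries(fixation, denominator=params.denominator)
    summaries = summaries.loc[summaries.index.isin(set(informative))]

    windows = sliding_windows(summaries, window=params.window, step=params.step)
    if len(windows) and windows["testable"].any():
        windows = bonferroni_scan(windows, alpha=params.alpha)
        log["n_testable_windows"] = windows.attrs["n_testable"]
        log["n_significant_windows"] = int(windows["significant"].sum())
    else:
        windows["significant"] = False
        log["n_testable_windows"] = 0
        log["n_significant_windows"] = 0
    log["n_windows"] = len(windows)
    log["mean_mismatch_rate"] = float(mismatch.mean()) if len(mismatch) else 0.0
    return ScanResult(
        g0=g0, g8=g8, fixation=fixation, summaries=summaries,
        windows=windows, qc_report=report, log=log,
    )
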