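"""Per-marker trait effects and their correlation with fixation direction.

Wild-allele effects are estimated marker by marker with ordinary least
squares of the line trait value on wild-allele dosage (0/1/2), intercept
included, slope reported in trait units per allele copy. Correlating the
effects with per-marker RFD asks whether alleles that move a trait were
preferentially fixed during propagation.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats as sps

from .matrix import MISSING, GenotypeMatrix

__all__ = ["genotype_to_dosage", "snp_effects", "rfd_effect_correlation"]


def genotype_to_dosage(g: GenotypeMatrix) -> pd.DataFrame:
    """Wild-allele dosage per line × SNP: 0, 1, 2, NaN for missing calls."""
    calls = g.calls.to_numpy().astype(float)
    calls[calls == MISSING] = np.nan
    return pd.DataFrame(calls, index=g.lines.copy(), columns=g.snps.copy())


def snp_effects(
    trait: pd.Series,
    dosage: pd.DataFrame,
    family: pd.Series | None = None,
    min_pairs: int = 3,
) -> pd.Series:
    """Per-SNP OLS slope of trait on wild-allele dosage (complete pairs).

    Markers with fewer than ``min_pairs`` complete observations or with
    constant dosage get NaN. Passing ``family`` centres both trait and
    dosage within families before the fit, removing between-family level
    differences (an optional adjustment; the default is the plain fit).
    """
    common = dosage.index.intersection(trait.index)
    x = dosage.loc[common].to_numpy(float)
    y = trait.loc[common].to_numpy(float)
    if family is not None:
        fam = family.reindex(common)
        frame = pd.DataFrame(x, index=common)
        frame["__y"] = y
        centred = frame.groupby(fam.to_numpy()).transform(lambda c: c - c.mean())
        y = centred["__y"].to_numpy()
        x = centred.drop(columns="__y").to_numpy()
    valid = ~np.isnan(x) & ~np.isnan(y)[:, None]
    n = valid.sum(axis=0).astype(float)
    xv = np.where(valid, x, 0.0)
    yv = np.where(valid, y[:, None], 0.0)
    sx = xv.sum(axis=0)
    sy = yv.sum(axis=0)
    sxx = (xv * xv).sum(axis=0)
    sxy = (xv * yv).sum(axis=0)
    denom = n * sxx - sx * sx
    with np.errstate(invalid="ignore", divide="ignore"):
        slope = (n * sxy - sx * sy) / denom
    # scale-aware guard against constant dosage (denom numerically zero)
    slope[(n < min_pairs) | (denom <= 1e-9 * np.maximum(n * sxx, 1.0))] = np.nan
    return pd.Series(slope, index=dosage.columns, name="effect")


def rfd_effect_correlation(
    effects: pd.Series, rfd: pd.Series
) -> tuple[float, int]:
    """Pearson correlation of marker effects with RFD over complete pairs.

    Returns ``(r, n)`` where ``n`` is the number of markers contributing.
    A positive r means trait-increasing wild alleles tended to be fixed.
    """
    joined = pd.concat({"effect": effects, "rfd": rfd}, axis=1).dropna()
    if len(joined) < 3:
        raise ValueError("need at least 3 markers with both effect and RFD")
    r = sps.pearsonr(joined["effect"], joined["rfd"]).statistic
    return float(r), int(len(joined))
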