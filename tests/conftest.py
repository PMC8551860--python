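import numpy as np
import pandas as pd
import pytest

from fixscan.matrix import GenotypeMatrix


def make_gmap(n_snps: int, chrom: str = "1H", spacing_cm: float = 1.0) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "snp": [f"{chrom}_{i + 1:05d}" for i in range(n_snps)],
            "chrom": chrom,
            "cm": np.arange(n_snps) * spacing_cm,
        }
    )


def make_matrix(calls, families=None, chrom="1H") -> GenotypeMatrix:
    """GenotypeMatrix from a 2-D int array; lines L001.., SNPs 1H_00001.."""
    calls = np.asarray(calls, dtype=np.int8)
    n_lines, n_snps = calls.shape
    lines = [f"L{i + 1:03d}" for i in range(n_lines)]
    gmap = make_gmap(n_snps, chrom=chrom)
    fam = None
    if families is not None:
        fam = pd.Series(list(families), index=lines, name="family")
    frame = pd.DataFrame(calls, index=lines, columns=gmap["snp"].tolist())
    return GenotypeMatrix(calls=frame, gmap=gmap, family=fam)


@pytest.fixture
def tiny_gmap():
    return make_gmap(12)
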