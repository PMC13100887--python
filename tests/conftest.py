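import numpy as np
import pandas as pd
import pytest

from uhedge.genotype_io import GenotypeMatrix
from uhedge.resistance import ResistanceSurface, load_hypotheses


def make_gm(genotypes, samples=None, locus_ids=None) -> GenotypeMatrix:
    """Small genotype matrix from a plain nested list (-1 = missing)."""
    g = np.asarray(genotypes, dtype=np.int8)
    n, m = g.shape
    samples = samples or [f"s{i + 1}" for i in range(n)]
    locus_ids = locus_ids or [f"uce-{j + 1}" for j in range(m)]
    loci = pd.DataFrame(
        {
            "chrom": locus_ids,
            "pos": np.arange(1, m + 1) * 10,
            "ref": "A",
            "alt": "T",
            "locus_id": locus_ids,
        }
    )
    return GenotypeMatrix(samples, loci, g)


def uniform_surface(nrows, ncols, resistance=1.0, resolution=1.0) -> ResistanceSurface:
    return ResistanceSurface(
        np.full((nrows, ncols), float(resistance)),
        np.zeros((nrows, ncols), dtype=bool),
        "NULL",
        resolution,
    )


def points_frame(coords, ids=None) -> pd.DataFrame:
    ids = ids or [f"p{i + 1}" for i in range(len(coords))]
    return pd.DataFrame(
        {"id": ids, "x": [c[0] for c in coords], "y": [c[1] for c in coords]}
    )


@pytest.fixture(scope="session")
def hypotheses():
    return load_hypotheses()
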