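import numpy as np
import pandas as pd
import pytest

from markwriter.annotation import GeneModel, GenomeAnnotation
from markwriter.tracks import CoverageTrack


@pytest.fixture
def toy_annotation() -> GenomeAnnotation:
    """Six genes on two chromosomes, both strands, assorted lengths."""
    genes = [
        GeneModel("gA", "chr1", 1000, 3000, "+"),
        GeneModel("gB", "chr1", 5000, 5600, "-"),
        GeneModel("gC", "chr1", 8000, 12000, "+"),
        GeneModel("gD", "chr2", 500, 1400, "-"),
        GeneModel("gE", "chr2", 3000, 3490, "+"),  # below the 500 bp filter
        GeneModel("gF", "chr2", 6000, 9000, "-"),
    ]
    return GenomeAnnotation(records=genes, chromosome_sizes={"chr1": 20000, "chr2": 10000})


@pytest.fixture
def point_track() -> CoverageTrack:
    """Deterministic 1-bp fragments spread over chr1/chr2."""
    rng = np.random.default_rng(42)
    frags = {
        "chr1": [(int(p), int(p) + 1) for p in rng.integers(0, 20000, 500)],
        "chr2": [(int(p), int(p) + 1) for p in rng.integers(0, 10000, 300)],
    }
    return CoverageTrack.from_fragments("mark", frags)


def make_labels(ids, bound_ids):
    from markwriter.binding_rf import BindingLabels

    s = pd.Series({g: g in set(bound_ids) for g in ids}, dtype=bool).loc[list(ids)]
    return BindingLabels(labels=s, n_bound=int(s.sum()))
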