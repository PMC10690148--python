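"""Small construction helpers shared across test modules."""

import numpy as np

from edisim.gc import GCPopulation


def make_population(affinities, epitopes, gc_ids, n_gc):
    n = len(affinities)
    return GCPopulation(
        epitope=np.asarray(epitopes, dtype=np.int8),
        affinity=np.asarray(affinities, dtype=float),
        lineage=np.arange(n, dtype=np.int64),
        n_mutations=np.zeros(n, dtype=np.int32),
        gc_id=np.asarray(gc_ids, dtype=np.int32),
        n_gc=n_gc,
    )
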