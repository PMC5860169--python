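"""Default settings and per-rank clustering thresholds.

The defaults are the grid points that performed best for whole-genome
phage classification: amino-acid data with word length 3, e-value 0.1,
greedy-with-trimming and formula d6; nucleotide data with word length 11,
e-value 1.0, greedy-with-trimming and formula d0.  The per-rank distance
thresholds below delineate species, genus, subfamily and family clusters
with the fraction-linkage parameter F = 0.5.
"""

from .alignment import AMINO_ACID, NUCLEOTIDE
from .gbdp import GBDPSettings

RANKS = ("species", "genus", "subfamily", "family")

DEFAULT_THRESHOLDS = {
    AMINO_ACID: {
        "species": 0.118980,
        "genus": 0.749680,
        "subfamily": 0.888940,
        "family": 0.985225,
    },
    NUCLEOTIDE: {
        "species": 0.022085,
        "genus": 0.842700,
        "subfamily": 0.997270,
        "family": 0.997455,
    },
}

DEFAULT_F = 0.5


def default_settings(seq_type: str, seed: int = 0, n_replicates: int = 100) -> GBDPSettings:
    if seq_type == AMINO_ACID:
        return GBDPSettings(
            seq_type=AMINO_ACID, word_length=3, evalue_max=0.1,
            algorithm="trimming", formula="d6",
            n_replicates=n_replicates, seed=seed,
        )
    return GBDPSettings(
        seq_type=NUCLEOTIDE, word_length=11, evalue_max=1.0,
        algorithm="trimming", formula="d0",
        n_replicates=n_replicates, seed=seed,
    )
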