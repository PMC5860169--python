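import numpy as np
import pytest

from gbdphylo import gbdp, phylo, synthetic
from gbdphylo.alignment import HSP


def make_hsp(qs, qe, ss, se, score, ident=None, strand="+", pair=("A", "B")):
    length = qe - qs
    return HSP(
        query_id=pair[0], subject_id=pair[1],
        q_start=qs, q_end=qe, s_start=ss, s_end=se,
        strand=strand, length=length,
        identities=float(length if ident is None else ident),
        raw_score=score, bit_score=float(score), evalue=1e-10,
    )


def random_hsps(rng, n, genome_len=300, pair=("A", "B")):
    out = []
    for _ in range(n):
        length = int(rng.integers(10, 80))
        qs = int(rng.integers(0, genome_len - length))
        ss = int(rng.integers(0, genome_len - length))
        score = int(rng.integers(10, 200))
        ident = float(rng.uniform(0.5, 1.0) * length)
        out.append(make_hsp(qs, qs + length, ss, ss + length, score, ident, pair=pair))
    return out


def tree_path_matrix(tree):
    """Leaf-to-leaf path-length matrix of a dendropy tree (labels sorted)."""
    pdm = tree.phylogenetic_distance_matrix()
    taxa = sorted(tree.taxon_namespace, key=lambda t: t.label)
    labels = [t.label for t in taxa]
    n = len(labels)
    m = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            m[i, j] = m[j, i] = pdm.distance(taxa[i], taxa[j])
    return labels, m


@pytest.fixture(scope="session")
def separated_dataset():
    """Eight genomes in four cleanly separated two-member species.

    With a power-of-two taxon count the balanced tree's cherries coincide
    with the consecutive-block species assignment, so the taxonomy matches
    the generating tree by construction.
    """
    spec = synthetic.SimulationSpec(
        n_taxa=8, tree_shape="balanced", genome_length=8000,
        fixed_terminal_length=0.004, fixed_internal_length=0.08,
        taxa_per_species=2, species_per_genus=2, genera_per_family=2, seed=11,
    )
    return synthetic.simulate_dataset(spec)


@pytest.fixture(scope="session")
def separated_matrix(separated_dataset):
    _, genomes, _, _ = separated_dataset
    settings = gbdp.GBDPSettings(
        seq_type="nucleotide", evalue_max=1.0, algorithm="trimming",
        formula="d6", n_replicates=20, seed=7,
    )
    return gbdp.build_matrix(genomes, settings)
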