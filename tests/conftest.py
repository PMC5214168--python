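import numpy as np
import pytest

from popgenscan.seqdata import LocusAlignment, exclude_indels


def seq_matrix(strings):
    """Byte matrix from equal-length DNA strings."""
    return np.array([np.frombuffer(s.encode(), dtype="S1") for s in strings])


def make_alignment(ingroup, outgroup, exons=(), species=None, populations=None,
                   locus_id="toy", frame=0):
    n = len(ingroup)
    species = species or ["sp1"] * n
    populations = populations or ["p1"] * n
    return LocusAlignment(
        locus_id=locus_id, ids=[f"h{i}" for i in range(n)], species=species,
        populations=populations, seqs=seq_matrix(ingroup),
        outgroup_id="out", outgroup_seq=seq_matrix([outgroup])[0],
        exons=list(exons), frame=frame)


@pytest.fixture
def toy_locus():
    """5-haplotype, 2-species toy with one exon and hand-checkable variants."""
    ingroup = [
        "ATGTTTAAACCGT",
        "ATGTTCAAACCGT",   # synonymous TTT->TTC
        "ATGTTTAAACCGT",
        "ATGCTTAAACCGT",   # nonsynonymous TTT->CTT
        "ATGTTTAAATCGT",   # noncoding C->T at col 9
    ]
    outgroup = "ATGTTTAAACCAT"  # noncoding fixed difference at col 11 (G->A)
    aln = make_alignment(ingroup, outgroup, exons=[(0, 9)],
                         species=["sp1"] * 3 + ["sp2"] * 2,
                         populations=["p1", "p1", "p2", "q1", "q1"])
    return aln, exclude_indels(aln)


@pytest.fixture(scope="session")
def neutral_dataset():
    """Small fully neutral synthetic dataset shared across tests."""
    from popgenscan.synthdata import GeneratorConfig, generate_dataset

    cfg = GeneratorConfig.neutral(n_candidate_loci=3, n_reference_loci=5,
                                  length_range=(400, 1200))
    return generate_dataset(cfg, seed=42)
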