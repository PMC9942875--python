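import numpy as np
import pytest

from bescan.genome_model import GeneModel, revcomp

# Hand-built two-exon plus-strand gene:
#   [0,20)   intergenic
#   [20,32)  5' UTR        (exon 1 starts at 20)
#   [32,41)  CDS part 1    "ATGAAACCC"
#   [41,61)  intron        GT...AG
#   [61,70)  CDS part 2    "CAAGGGTAG"
#   [70,82)  3' UTR        (exon 2 ends at 82)
#   [82,102) intergenic
# spliced CDS = ATGAAACCCCAAGGGTAG -> protein MKPQG*
TOY_PARTS = dict(
    inter5="GATTACAGATTACAGATTAC",
    utr5="TTGACTTGACTT",
    cds1="ATGAAACCC",
    intron="GT" + "CATCATCATCATCATC" + "AG",
    cds2="CAAGGGTAG",
    utr3="AGCTAGCTAGCT",
    inter3="CCGGAACCGGAACCGGAACC",
)
TOY_CONTIG = "".join(TOY_PARTS.values())
TOY_PROTEIN = "MKPQG*"


@pytest.fixture
def toy_contigs():
    return {"chr1": TOY_CONTIG}


@pytest.fixture
def toy_gene():
    return GeneModel("TOY1", "chr1", "+", [(20, 41), (61, 82)], (32, 70))


@pytest.fixture
def toy_gene_minus():
    """The same gene mirrored onto the reverse strand of a flipped contig."""
    L = len(TOY_CONTIG)
    exons = [(L - 82, L - 61), (L - 41, L - 20)]
    return GeneModel("TOY1R", "chr1R", "-", exons, (L - 70, L - 32))


@pytest.fixture
def toy_contigs_minus():
    return {"chr1R": revcomp(TOY_CONTIG)}


def random_gene(rng: np.random.Generator, contig_name="chrR", n_exons=None, n_codons=None):
    """Small random gene + contig for property tests (package generator
    deliberately not reused; assembled inline)."""
    from bescan.synthetic_data import SENSE_CODONS

    n_exons = n_exons or int(rng.integers(1, 4))
    n_codons = n_codons or int(rng.integers(10, 40))
    stops = ["TAA", "TAG", "TGA"]
    cds = "ATG" + "".join(rng.choice(SENSE_CODONS, n_codons - 2)) + stops[rng.integers(3)]
    cuts = sorted(rng.choice(np.arange(1, len(cds)), size=n_exons - 1, replace=False)) if n_exons > 1 else []
    pieces = [cds[a:b] for a, b in zip([0] + list(cuts), list(cuts) + [len(cds)])]
    bases = np.array(list("ACGT"))
    flank = "".join(rng.choice(bases, 25))
    utr = "".join(rng.choice(bases, 8))
    seq = flank + utr
    exons, pos = [], len(flank)
    cds_start = len(seq)
    exon_start = pos
    for i, piece in enumerate(pieces):
        seq += piece
        if i < len(pieces) - 1:
            exons.append((exon_start, len(seq)))
            intron = "GT" + "".join(rng.choice(bases, 12)) + "AG"
            exon_start = len(seq) + len(intron)
            seq += intron
    cds_end = len(seq)
    utr3 = "".join(rng.choice(bases, 8))
    seq += utr3
    exons.append((exon_start, len(seq)))
    seq += "".join(rng.choice(bases, 25))
    gene = GeneModel(f"R{rng.integers(1e6)}", contig_name, "+", exons, (cds_start, cds_end))
    return {contig_name: seq}, gene
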