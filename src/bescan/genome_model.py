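"""Sequences, gene models, coordinate mapping and translation.

All internal genomic coordinates are 0-based half-open intervals; variant
tables emitted elsewhere use 1-based positions (VCF convention).  A gene
model is a single transcript: an ordered set of exons plus one CDS span on
a named contig.  Multi-isoform selection is upstream of this package — one
model per gene.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Iterable

from Bio import SeqIO
from Bio.Seq import Seq

logger = logging.getLogger(__name__)

STANDARD_START = "ATG"


class SiteCategory(str, Enum):
    CDS = "CDS"
    FIVE_PRIME_UTR = "five_prime_UTR"
    THREE_PRIME_UTR = "three_prime_UTR"
    INTRON = "intron"
    SPLICE_REGION = "splice_region"
    INTERGENIC = "intergenic"


@dataclass(frozen=True)
class SiteLabel:
    """Label of one genomic position relative to a gene model.

    ``cds_offset`` is the 0-based offset of the position within the spliced,
    strand-oriented CDS; it is present iff the position is coding.
    ``codon_index`` is ``cds_offset // 3``.
    """

    category: SiteCategory
    cds_offset: int | None = None
    codon_index: int | None = None

    def __post_init__(self):
        if (self.cds_offset is not None) != (self.category == SiteCategory.CDS):
            raise ValueError("cds_offset present iff category is CDS")


class GeneModelError(ValueError):
    pass


@dataclass
class GeneModel:
    id: str
    chrom: str
    strand: str
    exons: list[tuple[int, int]]
    cds_span: tuple[int, int]

    def __post_init__(self):
        if self.strand not in ("+", "-"):
            raise GeneModelError(f"{self.id}: strand must be '+' or '-'")
        self.exons = [(int(a), int(b)) for a, b in self.exons]
        self.exons.sort(key=lambda iv: iv[0])
        for a, b in self.exons:
            if b - a < 1:
                raise GeneModelError(f"{self.id}: exon [{a},{b}) has length < 1")
        for (a1, b1), (a2, b2) in zip(self.exons, self.exons[1:]):
            if a2 < b1:
                raise GeneModelError(f"{self.id}: overlapping exons [{a1},{b1}) and [{a2},{b2})")
        c0, c1 = self.cds_span
        if not (self.span[0] <= c0 < c1 <= self.span[1]):
            raise GeneModelError(f"{self.id}: cds_span outside exon span")

    @property
    def span(self) -> tuple[int, int]:
        return self.exons[0][0], self.exons[-1][1]

    def cds_intervals(self) -> list[tuple[int, int]]:
        """Exon ∩ cds_span, genomic order."""
        c0, c1 = self.cds_span
        out = []
        for a, b in self.exons:
            lo, hi = max(a, c0), min(b, c1)
            if lo < hi:
                out.append((lo, hi))
        return out

    def validate_cds(self, contigs: dict[str, str], permissive: bool = False) -> None:
        """Check spliced CDS length (multiple of 3) and start codon."""
        cds, _ = spliced_cds_and_protein(self, contigs, _validate=False)
        problems = []
        if len(cds) == 0 or len(cds) % 3 != 0:
            problems.append(f"CDS length {len(cds)} is not a positive multiple of 3")
        elif cds[:3] != STANDARD_START:
            problems.append(f"CDS does not begin with {STANDARD_START} (got {cds[:3]})")
        for msg in problems:
            if permissive:
                logger.warning("%s: %s", self.id, msg)
            else:
                raise GeneModelError(f"{self.id}: {msg}")


# ---------------------------------------------------------------------------
# readers / writers
# ---------------------------------------------------------------------------

def read_fasta(path: str | Path) -> dict[str, str]:
    """Multi-record FASTA → {id: uppercased sequence}. Ambiguity codes kept."""
    contigs: dict[str, str] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in contigs:
            raise GeneModelError(f"duplicate FASTA id {rec.id!r}")
        contigs[rec.id] = str(rec.seq).upper()
    return contigs


def write_fasta(contigs: dict[str, str], path: str | Path) -> None:
    with open(path, "w") as fh:
        for name, seq in contigs.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), 70):
                fh.write(seq[i : i + 70] + "\n")


def _parse_gxf_attributes(attr: str) -> dict[str, str]:
    out: dict[str, str] = {}
    if "=" in attr and '"' not in attr:  # GFF3 key=value;...
        for part in attr.strip().split(";"):
            if part and "=" in part:
                k, v = part.split("=", 1)
                out[k.strip()] = v.strip()
    else:  # GTF key "value"; ...
        for part in attr.strip().split(";"):
            part = part.strip()
            if not part:
                continue
            k, _, v = part.partition(" ")
            out[k] = v.strip().strip('"')
    return out


def _read_gxf(path: Path) -> list[GeneModel]:
    """Minimal GTF/GFF3 subset reader: exon and CDS features only."""
    exons: dict[str, list[tuple[int, int]]] = {}
    cds: dict[str, list[tuple[int, int]]] = {}
    meta: dict[str, tuple[str, str]] = {}
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith("#"):
                continue
            cols = line.rstrip("\n").split("\t")
            if len(cols) < 9:
                continue
            chrom, _src, feature, start, end, _score, strand, _frame, attr = cols[:9]
            if feature not in ("exon", "CDS"):
                continue
            attrs = _parse_gxf_attributes(attr)
            gid = (
                attrs.get("transcript_id")
                or attrs.get("gene_id")
                or attrs.get("Parent")
                or attrs.get("ID")
            )
            if gid is None:
                raise GeneModelError(f"feature without gene/transcript id: {line.strip()}")
            iv = (int(start) - 1, int(end))  # 1-based inclusive → 0-based half-open
            meta.setdefault(gid, (chrom, strand))
            (exons if feature == "exon" else cds).setdefault(gid, []).append(iv)
    models = []
    for gid, exon_ivs in exons.items():
        chrom, strand = meta[gid]
        if gid not in cds:
            raise GeneModelError(f"{gid}: no CDS features")
        c = cds[gid]
        models.append(
            GeneModel(
                id=gid,
                chrom=chrom,
                strand=strand,
                exons=sorted(exon_ivs),
                cds_span=(min(a for a, _ in c), max(b for _, b in c)),
            )
        )
    return models


def _read_json_models(path: Path) -> list[GeneModel]:
    with open(path) as fh:
        doc = json.load(fh)
    genes = doc["genes"] if isinstance(doc, dict) else doc
    return [
        GeneModel(
            id=g["id"],
            chrom=g["chrom"],
            strand=g["strand"],
            exons=[tuple(iv) for iv in g["exons"]],
            cds_span=tuple(g["cds"]),
        )
        for g in genes
    ]


def write_json_models(models: Iterable[GeneModel], path: str | Path) -> None:
    doc = {
        "genes": [
            {
                "id": m.id,
                "chrom": m.chrom,
                "strand": m.strand,
                "exons": [list(iv) for iv in m.exons],
                "cds": list(m.cds_span),
            }
            for m in models
        ]
    }
    with open(path, "w") as fh:
        json.dump(doc, fh, indent=1)
        fh.write("\n")


def read_inputs(
    fasta_path: str | Path,
    model_path: str | Path,
    permissive: bool = False,
) -> tuple[dict[str, str], list[GeneModel]]:
    """Load contig sequences and gene models; validate every model.

    ``model_path`` may be a JSON gene-model file (canonical dialect) or a
    GTF/GFF3 subset with exon and CDS features.  A model whose contig is
    missing, or whose CDS fails the frame/start checks, is a fatal error
    unless ``permissive`` is set (frame/start problems then downgrade to
    logged warnings).
    """
    contigs = read_fasta(fasta_path)
    model_path = Path(model_path)
    if model_path.suffix.lower() == ".json":
        models = _read_json_models(model_path)
    else:
        models = _read_gxf(model_path)
    for m in models:
        if m.chrom not in contigs:
            raise GeneModelError(f"{m.id}: contig {m.chrom!r} not in FASTA")
        if m.span[1] > len(contigs[m.chrom]):
            raise GeneModelError(f"{m.id}: exon span exceeds contig length")
        m.validate_cds(contigs, permissive=permissive)
    return contigs, models


# ---------------------------------------------------------------------------
# sequence operations
# ---------------------------------------------------------------------------

def revcomp(seq: str) -> str:
    return str(Seq(seq).reverse_complement())


def spliced_cds_and_protein(
    gene: GeneModel, contigs: dict[str, str], _validate: bool = True
) -> tuple[str, str]:
    """Spliced, strand-oriented CDS and its translation.

    The terminal stop is rendered as ``*``.  An internal stop before the
    final codon is a warning, not an error: nonsense alleles are exactly
    what this package predicts.
    """
    seq = contigs[gene.chrom]
    cds = "".join(seq[a:b] for a, b in gene.cds_intervals()).upper()
    if gene.strand == "-":
        cds = revcomp(cds)
    protein = str(Seq(cds[: len(cds) - len(cds) % 3]).translate())
    if _validate and "*" in protein[:-1]:
        logger.warning("%s: internal stop codon in CDS translation", gene.id)
    return cds, protein


def locate(
    gene: GeneModel,
    genomic_pos: int,
    contig_length: int | None = None,
    splice_window: int = 2,
) -> SiteLabel:
    """Classify one genomic position against a gene model.

    Splice region = the ``splice_window`` intronic bases flanking each exon
    (±2 covers the canonical GT/AG dinucleotides); it takes precedence over
    plain intron.  UTR sides follow the CDS span and strand.
    """
    if genomic_pos < 0 or (contig_length is not None and genomic_pos >= contig_length):
        raise ValueError(f"position {genomic_pos} outside contig")
    lo, hi = gene.span
    if genomic_pos < lo or genomic_pos >= hi:
        return SiteLabel(SiteCategory.INTERGENIC)
    in_exon = any(a <= genomic_pos < b for a, b in gene.exons)
    if not in_exon:
        near_boundary = any(
            0 < genomic_pos - (b - 1) <= splice_window or 0 < a - genomic_pos <= splice_window
            for a, b in gene.exons
        )
        return SiteLabel(
            SiteCategory.SPLICE_REGION if near_boundary else SiteCategory.INTRON
        )
    c0, c1 = gene.cds_span
    if c0 <= genomic_pos < c1:
        offset = 0
        for a, b in gene.cds_intervals():
            if genomic_pos < a:
                break
            if genomic_pos < b:
                offset += genomic_pos - a
                break
            offset += b - a
        if gene.strand == "-":
            cds_len = sum(b - a for a, b in gene.cds_intervals())
            offset = cds_len - 1 - offset
        return SiteLabel(SiteCategory.CDS, cds_offset=offset, codon_index=offset // 3)
    upstream_of_cds = genomic_pos < c0
    five_prime = upstream_of_cds if gene.strand == "+" else not upstream_of_cds
    return SiteLabel(
        SiteCategory.FIVE_PRIME_UTR if five_prime else SiteCategory.THREE_PRIME_UTR
    )
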