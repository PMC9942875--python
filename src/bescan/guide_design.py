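"""Tiling-guide enumeration and per-guide editability profiling.

Guides are 20-nt protospacers read 5'→3' on their strand, with the PAM at
positions 21–23.  ``Guide.start`` is the leftmost genomic (reference-strand)
coordinate of the protospacer 20-mer; for a minus-strand guide the PAM
therefore lies immediately 5' of ``start`` on the reference.

Uniqueness is exact-match uniqueness of the protospacer within the provided
contigs (both strands).  A genome-wide single-mismatch search needs a genome
index and is out of scope; ``count_near_matches`` offers the single-mismatch
count for desk-scale inputs when asked.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

from .editors import COMPLEMENT, EditorConfig, matches_iupac
from .genome_model import GeneModel, revcomp

PROTOSPACER_LEN = 20
PAM_LEN = 3

LIBRARY_COLUMNS = ["guide_id", "protospacer", "pam", "contig", "start", "strand", "category"]

GUIDE_CATEGORIES = (
    "targeting",
    "stop_control_essential",
    "stop_control_nonessential",
    "non_targeting",
    "intergenic",
)


@dataclass(frozen=True)
class Guide:
    id: str
    protospacer: str
    pam: str
    contig: str
    start: int          # leftmost genomic coordinate of the protospacer, 0-based
    strand: str

    def __post_init__(self):
        if len(self.protospacer) != PROTOSPACER_LEN:
            raise ValueError(f"{self.id}: protospacer must be {PROTOSPACER_LEN} nt")
        if len(self.pam) != PAM_LEN:
            raise ValueError(f"{self.id}: PAM must be {PAM_LEN} nt")
        if self.strand not in ("+", "-"):
            raise ValueError(f"{self.id}: strand must be '+' or '-'")

    def genomic_position(self, protospacer_pos: int) -> int:
        """Reference coordinate (0-based) of protospacer position 1..20."""
        if not 1 <= protospacer_pos <= PROTOSPACER_LEN:
            raise ValueError("protospacer position must be in 1..20")
        if self.strand == "+":
            return self.start + protospacer_pos - 1
        return self.start + PROTOSPACER_LEN - protospacer_pos

    def protospacer_position(self, genomic_pos: int) -> int | None:
        """Inverse of :meth:`genomic_position`; None if outside the 20-mer."""
        if self.strand == "+":
            p = genomic_pos - self.start + 1
        else:
            p = self.start + PROTOSPACER_LEN - genomic_pos
        return p if 1 <= p <= PROTOSPACER_LEN else None


def genomic_slice(guide: Guide, contigs: dict[str, str]) -> str:
    """Protospacer+PAM as read off the genome at (start, strand)."""
    seq = contigs[guide.contig]
    if guide.strand == "+":
        return seq[guide.start : guide.start + PROTOSPACER_LEN + PAM_LEN]
    return revcomp(seq[guide.start - PAM_LEN : guide.start + PROTOSPACER_LEN])


@dataclass(frozen=True)
class GuideProfile:
    """Editor-specific editability flags for one guide.

    ``no_target``: no source base in the editing window.
    ``exclusively_gc_context``: every window source base is a C immediately
    preceded 5' by a G on the protospacer strand — the sequence context the
    APOBEC deaminase disfavours.
    ``polyT``: the protospacer contains TTTT, a U6 termination signal.
    """

    guide_id: str
    editable_positions: frozenset[int]
    no_target: bool
    exclusively_gc_context: bool
    polyT: bool
    unique_in_input: bool = True


def _count_occurrences(haystack: str, needle: str) -> int:
    n, start = 0, 0
    while True:
        i = haystack.find(needle, start)
        if i < 0:
            return n
        n += 1
        start = i + 1


def protospacer_match_count(protospacer: str, contigs: dict[str, str]) -> int:
    """Exact matches of the 20-mer over both strands of all contigs."""
    rc = revcomp(protospacer)
    total = 0
    for seq in contigs.values():
        total += _count_occurrences(seq, protospacer)
        total += _count_occurrences(seq, rc)
    return total


def count_near_matches(protospacer: str, contigs: dict[str, str]) -> int:
    """Matches with at most one mismatch (exact matches included). O(L·20)."""
    targets = [protospacer, revcomp(protospacer)]
    total = 0
    k = len(protospacer)
    for seq in contigs.values():
        for i in range(len(seq) - k + 1):
            window = seq[i : i + k]
            for t in targets:
                if sum(a != b for a, b in zip(window, t)) <= 1:
                    total += 1
                    break
    return total


def enumerate_guides(
    contigs: dict[str, str],
    contig: str,
    region: tuple[int, int] | None = None,
    pam_pattern: str = "NGG",
    id_prefix: str = "g",
) -> list[Guide]:
    """All guides whose protospacer 20-mer lies inside ``region``.

    Both strands are scanned; a guide is emitted wherever the 3-mer adjacent
    to a 20-mer matches ``pam_pattern``.  Regions shorter than 23 nt yield
    an empty list.
    """
    seq = contigs[contig]
    lo, hi = region if region is not None else (0, len(seq))
    lo, hi = max(0, lo), min(len(seq), hi)
    guides: list[Guide] = []
    # plus strand: protospacer [i, i+20), PAM [i+20, i+23)
    for i in range(lo, hi - PROTOSPACER_LEN + 1):
        if i + PROTOSPACER_LEN + PAM_LEN > len(seq):
            break
        pam = seq[i + PROTOSPACER_LEN : i + PROTOSPACER_LEN + PAM_LEN]
        if matches_iupac(pam, pam_pattern):
            guides.append(
                Guide(
                    id="",
                    protospacer=seq[i : i + PROTOSPACER_LEN],
                    pam=pam,
                    contig=contig,
                    start=i,
                    strand="+",
                )
            )
    # minus strand: protospacer occupies [i, i+20) with PAM at [i-3, i)
    for i in range(max(lo, PAM_LEN), hi - PROTOSPACER_LEN + 1):
        pam = revcomp(seq[i - PAM_LEN : i])
        if matches_iupac(pam, pam_pattern):
            guides.append(
                Guide(
                    id="",
                    protospacer=revcomp(seq[i : i + PROTOSPACER_LEN]),
                    pam=pam,
                    contig=contig,
                    start=i,
                    strand="-",
                )
            )
    guides.sort(key=lambda g: (g.start, g.strand))
    return [
        Guide(
            id=f"{id_prefix}{k:04d}_{g.contig}_{g.start}{g.strand}",
            protospacer=g.protospacer,
            pam=g.pam,
            contig=g.contig,
            start=g.start,
            strand=g.strand,
        )
        for k, g in enumerate(guides)
    ]


def profile_guide(
    guide: Guide,
    editor: EditorConfig,
    contigs: dict[str, str] | None = None,
) -> GuideProfile:
    """Editability flags for one guide under one editor.

    Ambiguity codes (N etc.) in the window are treated as non-editable.  The
    5' context of protospacer position 1 is read from the genome when
    ``contigs`` is given, otherwise taken as unknown (not G).
    """
    src = editor.source_base
    editable = frozenset(
        p for p in editor.window_positions() if guide.protospacer[p - 1] == src
    )
    gc_context = False
    if src == "C" and editable:
        def ctx(p: int) -> str:
            if p >= 2:
                return guide.protospacer[p - 2]
            if contigs is None:
                return "?"
            g = guide.genomic_position(1)
            seq = contigs[guide.contig]
            if guide.strand == "+":
                return seq[g - 1] if g >= 1 else "?"
            base = seq[g + 1] if g + 1 < len(seq) else "?"
            return base.translate(COMPLEMENT) if base != "?" else "?"

        gc_context = all(ctx(p) == "G" for p in sorted(editable))
    unique = True
    if contigs is not None:
        unique = protospacer_match_count(guide.protospacer, contigs) == 1
    return GuideProfile(
        guide_id=guide.id,
        editable_positions=editable,
        no_target=not editable,
        exclusively_gc_context=gc_context,
        polyT="TTTT" in guide.protospacer,
        unique_in_input=unique,
    )


def design_controls(
    genes: list[GeneModel],
    contigs: dict[str, str],
    editor: EditorConfig,
):
    """Stop-introducing control guides: every guide in each gene's span whose
    prioritized predicted consequence is stop_gained.

    Returns a list of (Guide, gene id, annotated PredictedOutcome) triples,
    one per stop-introducing outcome's guide (the highest-priority stop
    outcome is reported for each qualifying guide).
    """
    from .edit_prediction import Consequence, annotate, enumerate_outcomes

    hits = []
    for gene in genes:
        lo, hi = gene.span
        margin = PROTOSPACER_LEN + PAM_LEN
        region = (max(0, lo - margin), min(len(contigs[gene.chrom]), hi + margin))
        for guide in enumerate_guides(
            contigs, gene.chrom, region, editor.pam_pattern, id_prefix=f"{gene.id}_ctl"
        ):
            profile = profile_guide(guide, editor, contigs)
            stop_outcome = None
            for outcome in enumerate_outcomes(guide, editor, profile):
                ann = annotate(outcome, gene, contigs)
                if ann.consequence == Consequence.STOP_GAINED:
                    stop_outcome = ann
                    break
            if stop_outcome is not None:
                hits.append((guide, gene.id, stop_outcome))
    return hits


# ---------------------------------------------------------------------------
# library tables
# ---------------------------------------------------------------------------

def guides_to_table(guides: list[Guide], category: str = "targeting") -> pd.DataFrame:
    return pd.DataFrame(
        {
            "guide_id": [g.id for g in guides],
            "protospacer": [g.protospacer for g in guides],
            "pam": [g.pam for g in guides],
            "contig": [g.contig for g in guides],
            "start": [g.start for g in guides],
            "strand": [g.strand for g in guides],
            "category": category,
        }
    )


def table_to_guides(table: pd.DataFrame) -> list[Guide]:
    """Genomic rows of a library table back into Guide objects.

    Rows without coordinates (non-targeting controls: empty contig or
    start < 0) are skipped — they have no genomic identity to reconstruct.
    """
    guides = []
    for row in table.itertuples(index=False):
        if not isinstance(row.contig, str) or row.contig == "" or int(row.start) < 0:
            continue
        guides.append(
            Guide(
                id=row.guide_id,
                protospacer=row.protospacer,
                pam=row.pam,
                contig=row.contig,
                start=int(row.start),
                strand=row.strand,
            )
        )
    return guides


def read_library(path) -> pd.DataFrame:
    table = pd.read_csv(path, sep="\t", dtype={"contig": str})
    missing = set(LIBRARY_COLUMNS[:6]) - set(table.columns)
    if missing:
        raise ValueError(f"library table missing columns: {sorted(missing)}")
    if table["guide_id"].duplicated().any():
        raise ValueError("duplicate guide_id in library table")
    return table


def write_library(table: pd.DataFrame, path) -> None:
    table.to_csv(path, sep="\t", index=False)
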