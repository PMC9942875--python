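"""Edited-allele prediction and protein-consequence annotation.

For a guide with k editable window positions the outcome space is the k
single edits plus, when k >= 2, the joint edit of every window source base
— the alleles a deaminase plausibly leaves behind at high editing
efficiency.  Consequences are annotated by applying the variants to a copy
of the reference, re-splicing and re-translating, then consolidated by the
deleteriousness order

    stop gained > start loss > splice variant > missense > UTR > synonymous

with intergenic below synonymous.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, replace

from .editors import COMPLEMENT, EditorConfig, matches_iupac
from .genome_model import (
    GeneModel,
    SiteCategory,
    locate,
    spliced_cds_and_protein,
)
from .guide_design import Guide, GuideProfile, profile_guide

logger = logging.getLogger(__name__)


class Consequence:
    STOP_GAINED = "stop_gained"
    START_LOST = "start_lost"
    SPLICE_VARIANT = "splice_variant"
    MISSENSE = "missense"
    UTR = "UTR"
    SYNONYMOUS = "synonymous"
    INTERGENIC = "intergenic"


# most deleterious first
PRIORITY_ORDER = (
    Consequence.STOP_GAINED,
    Consequence.START_LOST,
    Consequence.SPLICE_VARIANT,
    Consequence.MISSENSE,
    Consequence.UTR,
    Consequence.SYNONYMOUS,
    Consequence.INTERGENIC,
)
_RANK = {c: i for i, c in enumerate(PRIORITY_ORDER)}


def prioritize(labels) -> str:
    """Most deleterious label of a non-empty multiset."""
    labels = list(labels)
    if not labels:
        raise ValueError("prioritize() requires at least one consequence label")
    unknown = [l for l in labels if l not in _RANK]
    if unknown:
        raise ValueError(f"unknown consequence labels: {unknown}")
    return min(labels, key=_RANK.__getitem__)


@dataclass(frozen=True)
class Variant:
    """Reference-strand substitution; ``pos`` is 0-based internally."""

    contig: str
    pos: int
    ref: str
    alt: str

    def vcf_fields(self) -> tuple[str, int, str, str]:
        return self.contig, self.pos + 1, self.ref, self.alt


@dataclass(frozen=True)
class ProteinChange:
    residue: int  # 1-based residue index
    ref_aa: str
    alt_aa: str

    def __str__(self) -> str:
        return f"p.{self.ref_aa}{self.residue}{self.alt_aa}"


@dataclass(frozen=True)
class PredictedOutcome:
    guide_id: str
    edited_positions: frozenset[int]   # protospacer positions, 1-based
    variants: tuple[Variant, ...]
    consequence: str | None = None
    protein_changes: tuple[ProteinChange, ...] = ()


def enumerate_outcomes(
    guide: Guide,
    editor: EditorConfig,
    profile: GuideProfile | None = None,
    contigs: dict[str, str] | None = None,
    combinatorial: bool = False,
) -> list[PredictedOutcome]:
    """Unannotated predicted alleles for one guide.

    Singles plus the all-window joint edit; ``combinatorial`` enumerates all
    2^k − 1 non-empty subsets instead (small k only).
    """
    if not matches_iupac(guide.pam, editor.pam_pattern):
        raise ValueError(
            f"{guide.id}: PAM {guide.pam} does not match editor pattern "
            f"{editor.pam_pattern}"
        )
    if profile is None:
        profile = profile_guide(guide, editor, contigs)
    editable = sorted(profile.editable_positions)
    if not editable:
        return []
    if combinatorial:
        subsets = [
            frozenset(c)
            for r in range(1, len(editable) + 1)
            for c in itertools.combinations(editable, r)
        ]
    else:
        subsets = [frozenset([p]) for p in editable]
        if len(editable) >= 2:
            subsets.append(frozenset(editable))
    src, prod = editor.source_base, editor.product_base
    if guide.strand == "+":
        ref, alt = src, prod
    else:
        ref, alt = src.translate(COMPLEMENT), prod.translate(COMPLEMENT)
    outcomes = []
    for subset in subsets:
        variants = tuple(
            sorted(
                (
                    Variant(guide.contig, guide.genomic_position(p), ref, alt)
                    for p in subset
                ),
                key=lambda v: v.pos,
            )
        )
        outcomes.append(PredictedOutcome(guide.id, subset, variants))
    return outcomes


def _apply_variants(seq: str, variants) -> str:
    chars = list(seq)
    for v in variants:
        if chars[v.pos].upper() != v.ref:
            raise ValueError(
                f"variant ref mismatch at {v.contig}:{v.pos + 1}: genome has "
                f"{chars[v.pos]}, variant says {v.ref} — guide and genome out of sync"
            )
        chars[v.pos] = v.alt
    return "".join(chars)


def annotate(
    outcome: PredictedOutcome,
    gene: GeneModel,
    contigs: dict[str, str],
    splice_window: int = 2,
) -> PredictedOutcome:
    """Attach consequence and protein changes for one gene.

    The mutant protein is obtained by applying all variants jointly and
    re-translating, so bystander edits sharing a codon are handled as one
    codon change.  A change of the terminal stop codon is reported as
    missense (the closest coding category).
    """
    seq = contigs[gene.chrom]
    mutant = _apply_variants(seq, outcome.variants)
    _, protein_ref = spliced_cds_and_protein(gene, contigs, _validate=False)
    _, protein_alt = spliced_cds_and_protein(gene, {**contigs, gene.chrom: mutant}, _validate=False)

    changes = tuple(
        ProteinChange(i + 1, a, b)
        for i, (a, b) in enumerate(zip(protein_ref, protein_alt))
        if a != b
    )
    labels: list[str] = []
    coding_codons = set()
    start_hit = False
    for v in outcome.variants:
        site = locate(gene, v.pos, len(seq), splice_window=splice_window)
        if site.category == SiteCategory.CDS:
            coding_codons.add(site.codon_index)
            if site.codon_index == 0:
                start_hit = True
        elif site.category == SiteCategory.SPLICE_REGION:
            labels.append(Consequence.SPLICE_VARIANT)
        elif site.category in (SiteCategory.FIVE_PRIME_UTR, SiteCategory.THREE_PRIME_UTR):
            labels.append(Consequence.UTR)
        else:  # intron beyond the splice window, or intergenic
            labels.append(Consequence.INTERGENIC)
    if start_hit:
        labels.append(Consequence.START_LOST)
    changed_residues = {c.residue - 1 for c in changes}
    for codon in coding_codons:
        if codon not in changed_residues:
            labels.append(Consequence.SYNONYMOUS)
    for c in changes:
        if c.residue - 1 not in coding_codons:
            continue  # residue changed by splicing bookkeeping, not an edited codon
        if c.alt_aa == "*" and c.residue < len(protein_ref):
            labels.append(Consequence.STOP_GAINED)
        elif c.residue - 1 == 0:
            labels.append(Consequence.START_LOST)
        else:
            labels.append(Consequence.MISSENSE)
    return replace(
        outcome,
        consequence=prioritize(labels) if labels else Consequence.INTERGENIC,
        protein_changes=changes,
    )


def annotate_multi(
    outcome: PredictedOutcome,
    genes: list[GeneModel],
    contigs: dict[str, str],
    splice_window: int = 2,
) -> PredictedOutcome:
    """Annotate against several genes; report the most deleterious reading.

    Ties break by gene id order, making the result deterministic.
    """
    annotated = [
        annotate(outcome, g, contigs, splice_window)
        for g in sorted(genes, key=lambda g: g.id)
        if g.chrom == outcome.variants[0].contig
    ]
    if not annotated:
        return replace(outcome, consequence=Consequence.INTERGENIC)
    return min(annotated, key=lambda o: _RANK[o.consequence])


NONSYN = (Consequence.STOP_GAINED, Consequence.START_LOST, Consequence.MISSENSE)


def aa_coverage(
    gene: GeneModel,
    contigs: dict[str, str],
    guides_by_editor: dict[str, tuple[EditorConfig, list[Guide]]],
    include_union: bool = True,
) -> dict[str, float]:
    """Fraction of protein residues reachable by ≥1 non-synonymous edit.

    Computed per editor and, when requested, for the union of all editors.
    The denominator is the protein length excluding the terminal stop.
    """
    _, protein = spliced_cds_and_protein(gene, contigs, _validate=False)
    n_res = len(protein) - (1 if protein.endswith("*") else 0)
    if n_res == 0:
        return {name: 0.0 for name in guides_by_editor}
    per_editor: dict[str, set[int]] = {}
    for name, (editor, guides) in guides_by_editor.items():
        residues: set[int] = set()
        for guide in guides:
            try:
                outcomes = enumerate_outcomes(guide, editor, contigs=contigs)
            except ValueError:
                continue  # PAM incompatible with this editor
            for outcome in outcomes:
                ann = annotate(outcome, gene, contigs)
                for change in ann.protein_changes:
                    if change.residue <= n_res:
                        residues.add(change.residue)
        per_editor[name] = residues
    coverage = {name: len(res) / n_res for name, res in per_editor.items()}
    if include_union and per_editor:
        union: set[int] = set().union(*per_editor.values())
        coverage["union"] = len(union) / n_res
    return coverage


def outcomes_to_table(outcomes):
    """Outcome table with 1-based variant coordinates (VCF convention)."""
    import pandas as pd

    rows = []
    for o in outcomes:
        rows.append(
            {
                "guide_id": o.guide_id,
                "edited_positions": ",".join(str(p) for p in sorted(o.edited_positions)),
                "variants": ";".join(
                    "{}:{}:{}:{}".format(*v.vcf_fields()) for v in o.variants
                ),
                "consequence": o.consequence,
                "protein_changes": ";".join(str(c) for c in o.protein_changes),
            }
        )
    return pd.DataFrame(
        rows,
        columns=["guide_id", "edited_positions", "variants", "consequence", "protein_changes"],
    )
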