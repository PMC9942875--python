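"""Synthetic inputs with the statistical structure the pipeline assumes.

The generators emulate, at desk scale, the four data layers of a
base-editing mutagenesis screen:

* a toy locus (one protein-coding gene plus a small "essential" control
  gene) and a tiling guide library with planted LOF / GOF / SOF / neutral
  element effects, non-targeting controls and stop-introducing controls;
* negative-binomial guide counts over the screen arms (plasmid, T0,
  control, IFN-γ, FACS-sorted), where the IFN-γ arm applies each element's
  selection effect in log2 units and the FACS sort recovers LOF cells only;
* cell × guide UMI matrices whose log normalized intensities follow a
  two-component skew-t mixture, with doublets at a configurable rate;
* amplicon and per-cell variant observations with a position-dependent
  editing-efficiency profile peaked inside the editor window, synonymous
  bystander edits, and a configurable het/homo zygosity mix at a given
  ploidy.

Identical config + seed gives byte-identical outputs.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .editors import COMPLEMENT, EditorConfig, get_editor
from .genome_model import GeneModel, write_fasta, write_json_models
from .guide_design import (
    Guide,
    design_controls,
    enumerate_guides,
    guides_to_table,
    profile_guide,
)
from .screen_stats import CountMatrix

BASES = np.array(list("ACGT"))
STOPS = {"TAA", "TAG", "TGA"}
CODONS = [a + b + c for a in "ACGT" for b in "ACGT" for c in "ACGT"]
SENSE_CODONS = [c for c in CODONS if c not in STOPS]


@dataclass
class GeneSpec:
    n_exons: int = 3
    cds_codons: int = 450
    intron_length: int = 150
    utr_length: int = 60
    flank: int = 300


@dataclass
class LibrarySpec:
    editor: str = "BE3-NGG"
    n_lof_elements: int = 6
    n_gof_elements: int = 3
    n_sof_elements: int = 3
    n_neutral_elements: int = 20
    guides_per_element: int = 5
    n_non_targeting: int = 100
    n_stop_controls: int = 10


@dataclass
class ScreenSpec:
    depth: float = 1000.0          # mean reads per guide
    dispersion: float = 0.05       # NB dispersion (1/size)
    lof_effect: float = 2.0        # log2 enrichment under IFN-γ selection
    gof_effect: float = -2.0
    sof_effect: float = 2.0
    stop_control_dropout: float = -2.0   # essential-gene depletion, all post-transduction arms
    replicates: int = 2


@dataclass
class SingleCellSpec:
    n_cells: int = 500
    n_guides: int = 20
    doublet_rate: float = 0.05
    total_umi: float = 2000.0
    background: tuple = (-7.0, 0.6, 5.0, 1.0)   # skew-t (loc, scale, df, skew) of log fraction
    present: tuple = (-0.8, 0.35, 5.0, -1.0)


@dataclass
class AmpliconSpec:
    in_window_efficiency: float = 0.40
    out_window_efficiency: float = 0.02
    synonymous_co_edit_rate: float = 0.6
    homo_fraction: float = 0.5
    cells_per_guide: int = 10
    depth: int = 200
    ploidy: int = 3


@dataclass
class SimulationConfig:
    seed: int = 0
    gene: GeneSpec = field(default_factory=GeneSpec)
    library: LibrarySpec = field(default_factory=LibrarySpec)
    screen: ScreenSpec = field(default_factory=ScreenSpec)
    single_cell: SingleCellSpec = field(default_factory=SingleCellSpec)
    amplicon: AmpliconSpec = field(default_factory=AmpliconSpec)

    def validate(self) -> None:
        if self.screen.depth <= 0 or self.screen.dispersion <= 0:
            raise ValueError("depth and dispersion must be > 0")
        if not 0.0 <= self.single_cell.doublet_rate <= 1.0:
            raise ValueError("doublet_rate must be in [0, 1]")
        for r in (
            self.amplicon.in_window_efficiency,
            self.amplicon.out_window_efficiency,
            self.amplicon.homo_fraction,
            self.amplicon.synonymous_co_edit_rate,
        ):
            if not 0.0 <= r <= 1.0:
                raise ValueError("amplicon rates must be in [0, 1]")

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass
class LocusSim:
    contigs: dict[str, str]
    gene: GeneModel
    essential_gene: GeneModel
    library: pd.DataFrame
    truth: pd.DataFrame
    guides: list[Guide]


def _random_seq(rng: np.random.Generator, n: int) -> str:
    return "".join(rng.choice(BASES, size=n))


def _random_cds(rng: np.random.Generator, n_codons: int) -> str:
    body = rng.choice(SENSE_CODONS, size=n_codons - 2)
    stop = rng.choice(sorted(STOPS))
    return "ATG" + "".join(body) + stop


def _build_gene(
    rng: np.random.Generator, spec: GeneSpec, gene_id: str, offset: int
) -> tuple[str, GeneModel]:
    """Sequence for one gene (UTRs + exons + introns) and its model."""
    cds = _random_cds(rng, spec.cds_codons)
    # split CDS across exons at random interior cut points
    n_cuts = spec.n_exons - 1
    if n_cuts > 0:
        cuts = sorted(rng.choice(np.arange(1, len(cds)), size=n_cuts, replace=False))
    else:
        cuts = []
    pieces = [cds[a:b] for a, b in zip([0] + cuts, cuts + [len(cds)])]
    seq_parts: list[str] = []
    exons: list[tuple[int, int]] = []
    pos = offset
    utr5 = _random_seq(rng, spec.utr_length)
    seq_parts.append(utr5)
    exon_start = pos
    pos += len(utr5)
    for i, piece in enumerate(pieces):
        if i == 0:
            cds_start = pos
        seq_parts.append(piece)
        pos += len(piece)
        if i < len(pieces) - 1:
            exons.append((exon_start, pos))
            intron = "GT" + _random_seq(rng, spec.intron_length - 4) + "AG"
            seq_parts.append(intron)
            exon_start = pos + len(intron)
            pos += len(intron)
    cds_end = pos
    utr3 = _random_seq(rng, spec.utr_length)
    seq_parts.append(utr3)
    pos += len(utr3)
    exons.append((exon_start, pos))
    gene = GeneModel(gene_id, "chrS", "+", exons, (cds_start, cds_end))
    return "".join(seq_parts), gene


def simulate_locus_and_library(config: SimulationConfig) -> LocusSim:
    """Toy contig, gene models, guide library table and planted truth table."""
    config.validate()
    rng = np.random.default_rng(config.seed)
    spec, lib = config.gene, config.library
    editor = get_editor(lib.editor)

    flank = _random_seq(rng, spec.flank)
    gene_seq, gene = _build_gene(rng, spec, "GENE1", spec.flank)
    spacer = _random_seq(rng, spec.flank)
    ess_spec = GeneSpec(n_exons=1, cds_codons=150, utr_length=20, flank=0)
    ess_offset = spec.flank + len(gene_seq) + spec.flank
    ess_seq, ess_gene = _build_gene(rng, ess_spec, "ESS1", ess_offset)
    tail = _random_seq(rng, spec.flank)
    contig = flank + gene_seq + spacer + ess_seq + tail
    contigs = {"chrS": contig}
    gene.validate_cds(contigs)
    ess_gene.validate_cds(contigs)

    lo, hi = gene.span
    guides = enumerate_guides(contigs, "chrS", (lo - 23, hi + 23), editor.pam_pattern)
    guides = [g for g in guides if profile_guide(g, editor, contigs).editable_positions]
    classes = (
        ["lof"] * lib.n_lof_elements
        + ["gof"] * lib.n_gof_elements
        + ["sof"] * lib.n_sof_elements
        + ["neutral"] * lib.n_neutral_elements
    )
    needed = len(classes) * lib.guides_per_element
    if needed > len(guides):
        raise ValueError(
            f"requested {needed} targeting guides but only {len(guides)} "
            f"editable guides exist on the locus"
        )
    picked = rng.choice(len(guides), size=needed, replace=False)
    effects = {
        "lof": config.screen.lof_effect,
        "gof": config.screen.gof_effect,
        "sof": config.screen.sof_effect,
        "neutral": 0.0,
    }
    rows, truth_rows = [], []
    counters = {c: 0 for c in set(classes)}
    for i, cls in enumerate(classes):
        counters[cls] += 1
        element = f"{cls.upper()}_{counters[cls]:02d}"
        for j in range(lib.guides_per_element):
            g = guides[picked[i * lib.guides_per_element + j]]
            gid = f"{element}_g{j + 1}"
            rows.append(
                dict(guide_id=gid, protospacer=g.protospacer, pam=g.pam,
                     contig=g.contig, start=g.start, strand=g.strand,
                     category="targeting")
            )
            truth_rows.append(
                dict(guide_id=gid, category="targeting", cls=cls, element=element,
                     effect=effects[cls], dropout_effect=0.0)
            )
    # non-targeting controls: random 20-mers absent from the contig
    n_nt = 0
    while n_nt < lib.n_non_targeting:
        proto = _random_seq(rng, 20)
        if proto in contig or proto.translate(COMPLEMENT)[::-1] in contig:
            continue
        n_nt += 1
        gid = f"NT_{n_nt:03d}"
        rows.append(
            dict(guide_id=gid, protospacer=proto, pam="NNN", contig="",
                 start=-1, strand="+", category="non_targeting")
        )
        truth_rows.append(
            dict(guide_id=gid, category="non_targeting", cls="control",
                 element=gid, effect=0.0, dropout_effect=0.0)
        )
    stop_hits = design_controls([ess_gene], contigs, editor)
    for k, (g, target, _outcome) in enumerate(stop_hits[: lib.n_stop_controls]):
        gid = f"STOP_{target}_{k + 1:02d}"
        rows.append(
            dict(guide_id=gid, protospacer=g.protospacer, pam=g.pam,
                 contig=g.contig, start=g.start, strand=g.strand,
                 category="stop_control_essential")
        )
        truth_rows.append(
            dict(guide_id=gid, category="stop_control_essential", cls="stop_control",
                 element=gid, effect=0.0,
                 dropout_effect=config.screen.stop_control_dropout)
        )
    library = pd.DataFrame(rows)
    truth = pd.DataFrame(truth_rows)
    picked_guides = [
        Guide(r["guide_id"], r["protospacer"], r["pam"], r["contig"], r["start"], r["strand"])
        for r in rows
        if r["contig"]
    ]
    return LocusSim(contigs, gene, ess_gene, library, truth, picked_guides)


def _nb_draw(rng: np.random.Generator, mean: np.ndarray, dispersion: float) -> np.ndarray:
    size = 1.0 / dispersion
    p = size / (size + mean)
    return rng.negative_binomial(size, p)


def simulate_screen_counts(
    library: pd.DataFrame,
    truth: pd.DataFrame,
    spec: ScreenSpec,
    seed: int,
) -> CountMatrix:
    """NB counts for plasmid / T0 / control / IFN-γ / FACS arms × replicates.

    Per-guide plasmid abundance is log-normal around the target depth; the
    IFN-γ arm multiplies expected counts by 2^effect; the FACS arm enriches
    LOF guides only (binomial capture in expectation: sorted non-responder
    cells carry LOF guides, so other classes stay at baseline); essential
    stop controls drop out of every post-transduction arm.
    """
    rng = np.random.default_rng(seed)
    t = truth.set_index("guide_id").loc[library["guide_id"]]
    n = len(library)
    sigma = 0.5
    abundance = rng.lognormal(np.log(spec.depth) - sigma**2 / 2, sigma, n)
    effect = t["effect"].to_numpy()
    dropout = t["dropout_effect"].to_numpy()
    is_lof = (t["cls"] == "lof").to_numpy()
    facs_effect = np.where(is_lof, effect, 0.0)

    columns, meta = {}, []
    for rep in range(1, spec.replicates + 1):
        arm_means = {
            "plasmid": abundance,
            "T0": abundance * 2.0**dropout,
            "control": abundance * 2.0**dropout,
            "IFNg": abundance * 2.0 ** (dropout + effect),
            "FACS_sorted": abundance * 2.0 ** (dropout + facs_effect),
        }
        for assay, mean in arm_means.items():
            name = f"{assay}_R{rep}"
            columns[name] = _nb_draw(rng, mean, spec.dispersion)
            meta.append({"sample": name, "assay": assay, "replicate": f"R{rep}"})
    counts = pd.DataFrame(columns, index=pd.Index(library["guide_id"], name="guide_id"))
    samples = pd.DataFrame(meta).set_index("sample")
    return CountMatrix(counts, samples)


def simulate_umi_matrix(
    spec: SingleCellSpec, seed: int
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Cell × guide UMI counts plus the planted truth assignments.

    Each entry's latent log UMI fraction is drawn from the background or
    present skew-t component; counts are Poisson around fraction × total.
    Doublet cells carry two distinct present guides.
    """
    from .skewt import skewt_rvs

    rng = np.random.default_rng(seed)
    n, g = spec.n_cells, spec.n_guides
    guide_names = [f"g{j + 1:03d}" for j in range(g)]
    cell_names = [f"cell{i + 1:04d}" for i in range(n)]
    primary = rng.integers(0, g, n)
    is_doublet = rng.random(n) < spec.doublet_rate
    secondary = np.full(n, -1)
    for i in np.flatnonzero(is_doublet):
        choices = [j for j in range(g) if j != primary[i]]
        secondary[i] = rng.choice(choices)

    bg = skewt_rvs(n * g, *spec.background, rng=rng).reshape(n, g)
    fg = skewt_rvs(n * g, *spec.present, rng=rng).reshape(n, g)
    present = np.zeros((n, g), dtype=bool)
    present[np.arange(n), primary] = True
    present[is_doublet, secondary[is_doublet]] = True
    logfrac = np.where(present, fg, bg)
    lam = np.exp(logfrac) * spec.total_umi
    counts = rng.poisson(lam)
    # per-cell totals must be positive for normalization; guarantee the
    # primary guide leaves at least one molecule
    counts[np.arange(n), primary] = np.maximum(counts[np.arange(n), primary], 1)
    umi = pd.DataFrame(counts, index=pd.Index(cell_names, name="cell"), columns=guide_names)
    truth = pd.DataFrame(
        {
            "cell": cell_names,
            "guide": [guide_names[j] for j in primary],
            "second_guide": [guide_names[j] if j >= 0 else "" for j in secondary],
            "doublet": is_doublet,
        }
    ).set_index("cell")
    return umi, truth


def simulate_amplicon_calls(
    locus: LocusSim,
    editor: EditorConfig,
    spec: AmpliconSpec,
    seed: int,
    max_guides: int | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Bulk amplicon observations and per-cell allele calls.

    Per protospacer position the editing efficiency is ``in_window`` inside
    the editor window and ``out_window`` outside; positions whose lone edit
    is synonymous are scaled by the synonymous co-edit rate.  Cells draw a
    zygosity (homo: all alleles; het: one allele) and per-position edits,
    and report binomial read support at the configured depth and ploidy.
    """
    from .edit_prediction import Consequence, PredictedOutcome, Variant, annotate

    rng = np.random.default_rng(seed)
    gene, contigs = locus.gene, locus.contigs
    guides = [g for g in locus.guides if not g.id.startswith("STOP_")]
    if max_guides is not None:
        guides = guides[:max_guides]
    bulk_rows, cell_rows = [], []
    cell_counter = 0
    for guide in guides:
        src = editor.source_base
        ref_plus = src if guide.strand == "+" else src.translate(COMPLEMENT)
        alt_plus = (
            editor.product_base
            if guide.strand == "+"
            else editor.product_base.translate(COMPLEMENT)
        )
        positions = [
            p for p in range(1, 21) if guide.protospacer[p - 1] == src
        ]
        if not positions:
            continue
        effs, variants = [], []
        for p in positions:
            gpos = guide.genomic_position(p)
            if contigs["chrS"][gpos] != ref_plus:
                continue
            v = Variant("chrS", gpos, ref_plus, alt_plus)
            in_win = editor.window[0] <= p <= editor.window[1]
            eff = spec.in_window_efficiency if in_win else spec.out_window_efficiency
            try:
                ann = annotate(PredictedOutcome(guide.id, frozenset(), (v,)), gene, contigs)
                if ann.consequence == Consequence.SYNONYMOUS:
                    eff *= spec.synonymous_co_edit_rate
            except ValueError:
                continue
            effs.append(eff)
            variants.append(v)
        # bulk: mean VAF across an edited-cell population ≈ efficiency
        for v, eff in zip(variants, effs):
            alt_reads = int(rng.binomial(spec.depth, eff))
            bulk_rows.append(
                dict(sample=f"bulk_{guide.id}", contig=v.contig, pos=v.pos + 1,
                     ref=v.ref, alt=v.alt, alt_reads=alt_reads,
                     total_reads=spec.depth, guide_id=guide.id)
            )
        # per-cell allele calls
        for _ in range(spec.cells_per_guide):
            cell_counter += 1
            cell = f"sc{cell_counter:05d}"
            homo = rng.random() < spec.homo_fraction
            n_alt = spec.ploidy if homo else 1
            af_true = n_alt / spec.ploidy
            for v, eff in zip(variants, effs):
                if rng.random() >= eff:
                    continue
                alt_reads = int(rng.binomial(spec.depth, af_true))
                cell_rows.append(
                    dict(sample=cell, contig=v.contig, pos=v.pos + 1,
                         ref=v.ref, alt=v.alt, alt_reads=alt_reads,
                         total_reads=spec.depth, guide_id=guide.id,
                         zygosity_truth="homo" if homo else "het")
                )
    cols = ["sample", "contig", "pos", "ref", "alt", "alt_reads", "total_reads", "guide_id"]
    bulk = pd.DataFrame(bulk_rows, columns=cols)
    cells = pd.DataFrame(cell_rows, columns=cols + ["zygosity_truth"])
    return bulk, cells


def write_simulation(config: SimulationConfig, outdir: str | Path) -> dict[str, Path]:
    """Run every generator and write the artifact files to ``outdir``."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    locus = simulate_locus_and_library(config)
    editor = get_editor(config.library.editor)
    paths = {
        "fasta": outdir / "locus.fa",
        "model": outdir / "genes.json",
        "library": outdir / "library.tsv",
        "truth": outdir / "truth.tsv",
        "counts": outdir / "counts.tsv",
        "samples": outdir / "samples.tsv",
        "umi": outdir / "umi.tsv",
        "umi_truth": outdir / "umi_truth.tsv",
        "amplicon_bulk": outdir / "amplicon_bulk.tsv",
        "amplicon_cells": outdir / "amplicon_cells.tsv",
    }
    write_fasta(locus.contigs, paths["fasta"])
    write_json_models([locus.gene, locus.essential_gene], paths["model"])
    locus.library.to_csv(paths["library"], sep="\t", index=False)
    locus.truth.to_csv(paths["truth"], sep="\t", index=False)
    matrix = simulate_screen_counts(locus.library, locus.truth, config.screen, config.seed + 1)
    matrix.counts.to_csv(paths["counts"], sep="\t")
    matrix.samples.to_csv(paths["samples"], sep="\t")
    umi, umi_truth = simulate_umi_matrix(config.single_cell, config.seed + 2)
    umi.to_csv(paths["umi"], sep="\t")
    umi_truth.to_csv(paths["umi_truth"], sep="\t")
    bulk, cells = simulate_amplicon_calls(locus, editor, config.amplicon, config.seed + 3)
    bulk.to_csv(paths["amplicon_bulk"], sep="\t", index=False)
    cells.to_csv(paths["amplicon_cells"], sep="\t", index=False)
    return paths
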