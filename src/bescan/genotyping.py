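"""Genotype verification: amplicon VAF profiles, skew-t guide-to-cell
assignment, zygosity and consensus-edit calling, and error-rate estimation.

Variant observations are VCF-style rows (CHROM, 1-based POS, REF, ALT) with
either amplicon read support (alt_reads / total_reads) or per-cell allele
calls.  Variant allele fraction is alt/total, and sites below 1% VAF are
discarded as caller noise.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .editors import EditorConfig
from .genome_model import GeneModel, SiteCategory
from .guide_design import Guide
from .skewt import SkewTMixture

logger = logging.getLogger(__name__)

VAF_FLOOR = 0.01

VARIANT_COLUMNS = ["sample", "contig", "pos", "ref", "alt", "alt_reads", "total_reads", "guide_id"]


def read_variant_table(path) -> pd.DataFrame:
    table = pd.read_csv(path, sep="\t", dtype={"contig": str, "ref": str, "alt": str})
    missing = set(VARIANT_COLUMNS[:7]) - set(table.columns)
    if missing:
        raise ValueError(f"variant table missing columns: {sorted(missing)}")
    bad = table["alt_reads"] > table["total_reads"]
    if bad.any():
        raise ValueError("alt_reads exceeds total_reads")
    return table


@dataclass
class GuideEditingProfile:
    guide_id: str
    vaf_by_position: dict[int, float]      # protospacer position 1–20 (0 = outside)
    in_window_fraction: float
    synonymous_co_occurrence: float | None


def vaf_profile(
    observations: pd.DataFrame,
    guides: list[Guide],
    editor: EditorConfig,
    gene: GeneModel | None = None,
    contigs: dict[str, str] | None = None,
    blocklist: set[tuple[str, int]] | None = None,
) -> dict[str, GuideEditingProfile]:
    """Per-guide editing profile from amplicon variant observations.

    VAF = alt/total; entries with VAF < 1% are removed (absolute filter),
    as are positions on the germline-SNP ``blocklist`` (contig, 1-based
    pos).  Positions are mapped into the protospacer frame of the linked
    guide; the in-window fraction counts retained edit observations inside
    the editor window.  Synonymous co-occurrence — the fraction of samples
    carrying both a non-synonymous and a synonymous retained edit — needs
    gene + contigs to annotate, otherwise it is None.
    """
    obs = observations.copy()
    zero = obs["total_reads"] == 0
    if zero.any():
        logger.warning("vaf_profile: skipping %d observations with zero depth", int(zero.sum()))
        obs = obs[~zero]
    obs["vaf"] = obs["alt_reads"] / obs["total_reads"]
    obs = obs[obs["vaf"] >= VAF_FLOOR]
    if blocklist:
        keep = [
            (c, int(p)) not in blocklist
            for c, p in zip(obs["contig"], obs["pos"])
        ]
        obs = obs[keep]
    guide_by_id = {g.id: g for g in guides}
    lo, hi = editor.window

    annotate_syn = gene is not None and contigs is not None
    if annotate_syn:
        from .edit_prediction import Consequence, PredictedOutcome, Variant, annotate

        def is_synonymous(contig, pos1, ref, alt) -> bool | None:
            try:
                out = annotate(
                    PredictedOutcome("", frozenset(), (Variant(contig, int(pos1) - 1, ref, alt),)),
                    gene, contigs,
                )
            except ValueError:
                return None
            return out.consequence == Consequence.SYNONYMOUS

    profiles: dict[str, GuideEditingProfile] = {}
    for gid, sub in obs.groupby("guide_id"):
        guide = guide_by_id.get(gid)
        positions = []
        for pos1 in sub["pos"]:
            p = guide.protospacer_position(int(pos1) - 1) if guide else None
            positions.append(p if p is not None else 0)
        sub = sub.assign(protospacer_position=positions)
        vaf_by_pos = sub.groupby("protospacer_position")["vaf"].mean().to_dict()
        in_window = sub["protospacer_position"].between(lo, hi)
        total_vaf = float(sub["vaf"].sum())
        # VAF-weighted so trace out-of-window edits count by their abundance
        frac = float(sub.loc[in_window, "vaf"].sum() / total_vaf) if total_vaf > 0 else 0.0
        co = None
        if annotate_syn:
            per_sample = []
            for _, srows in sub.groupby("sample"):
                syn = [
                    is_synonymous(r.contig, r.pos, r.ref, r.alt)
                    for r in srows.itertuples(index=False)
                ]
                syn = [s for s in syn if s is not None]
                if syn:
                    per_sample.append(any(syn) and not all(syn))
            co = float(np.mean(per_sample)) if per_sample else 0.0
        profiles[gid] = GuideEditingProfile(
            guide_id=gid,
            vaf_by_position={int(k): float(v) for k, v in vaf_by_pos.items()},
            in_window_fraction=frac,
            synonymous_co_occurrence=co,
        )
    return profiles


# ---------------------------------------------------------------------------
# single-cell guide assignment
# ---------------------------------------------------------------------------

@dataclass
class CellAssignment:
    cell: str
    p_at_least_one: float
    p_multiple: float
    assigned_guide: str | None
    posteriors: dict[str, float]


def read_umi_matrix(path) -> pd.DataFrame:
    """Cell × guide UMI counts from a dense TSV (index = cell) or a triplet
    TSV with columns cell, guide, umi."""
    head = pd.read_csv(path, sep="\t", nrows=1)
    if set(head.columns) >= {"cell", "guide", "umi"}:
        trip = pd.read_csv(path, sep="\t")
        return trip.pivot_table(index="cell", columns="guide", values="umi",
                                aggfunc="sum", fill_value=0)
    return pd.read_csv(path, sep="\t", index_col=0)


def assign_guides(
    umi: pd.DataFrame,
    p_one_min: float = 0.99,
    p_multi_max: float = 0.01,
    mixture: SkewTMixture | None = None,
    pseudocount: float = 0.5,
    max_fit_entries: int = 5000,
    seed: int = 0,
) -> tuple[pd.DataFrame, SkewTMixture]:
    """Assign guides to cells via a pooled two-component skew-t mixture.

    UMI counts are normalized by each cell's total (with a half-count
    pseudocount so empty entries stay finite) and log-transformed; one
    mixture is fit over all cell × guide entries.  The higher-location
    component is "guide present".  Per cell, P(≥1 guide) and P(≥2 guides)
    follow from the per-entry posteriors under cross-guide independence; a
    cell is assigned its maximum-posterior guide iff P(≥1) ≥ 0.99 and
    P(≥2) ≤ 0.01.  A non-converged fit voids all assignments from it.
    """
    if (umi.to_numpy() < 0).any():
        raise ValueError("negative UMI counts")
    totals = umi.sum(axis=1)
    if (totals <= 0).any():
        raise ValueError("cells with zero total UMI counts")
    x = np.log((umi.to_numpy() + pseudocount) / totals.to_numpy()[:, None])
    mixture = mixture or SkewTMixture(n_components=2, tol=1e-6, max_iter=500)
    flat = x.ravel()
    if flat.size > max_fit_entries:
        # fit on a seeded subsample for tractability; posteriors are then
        # evaluated for every entry under the fitted model
        idx = np.random.default_rng(seed).choice(flat.size, max_fit_entries, replace=False)
        mixture.fit(flat[idx])
    else:
        mixture.fit(flat)
    if not mixture.converged_:
        logger.warning("assign_guides: EM did not converge; excluding all cells from this fit")
        frame = pd.DataFrame(
            {
                "p_at_least_one": np.nan,
                "p_multiple": np.nan,
                "assigned_guide": None,
                "converged": False,
            },
            index=umi.index,
        )
        return frame, mixture
    post = mixture.predict_proba(x.ravel())[:, 1].reshape(umi.shape)  # P(present)
    log_not = np.log1p(-np.clip(post, 0.0, 1.0 - 1e-12))
    p_none = np.exp(log_not.sum(axis=1))
    # P(exactly one) = Σ_g p_g Π_{h≠g} (1 − p_h)
    with np.errstate(divide="ignore"):
        ratio = post / np.clip(1.0 - post, 1e-12, None)
    p_exactly_one = p_none * ratio.sum(axis=1)
    p_one = 1.0 - p_none
    p_multi = np.clip(1.0 - p_none - p_exactly_one, 0.0, 1.0)
    best = umi.columns.to_numpy()[post.argmax(axis=1)]
    ok = (p_one >= p_one_min) & (p_multi <= p_multi_max)
    frame = pd.DataFrame(
        {
            "p_at_least_one": p_one,
            "p_multiple": p_multi,
            "assigned_guide": np.where(ok, best, None),
            "converged": True,
        },
        index=umi.index,
    )
    return frame, mixture


# ---------------------------------------------------------------------------
# zygosity / consensus / error rates
# ---------------------------------------------------------------------------

ZYGOSITY = ("wild_type", "het", "homo", "low_confidence")


def call_zygosity(
    af: float,
    ploidy: int = 3,
    homo_threshold: float = 0.60,
    total_reads: int | None = None,
    min_depth: int = 10,
) -> tuple[str, str]:
    """(zygosity class, penetrance string) for one cell-level allele fraction.

    Defaults follow a triploid line: AF > 0.60 (two or three of three
    alleles) is a high-confidence homozygous call written 1/1/1; any lower
    non-zero AF is heterozygous (e.g. 0/1/1).  Thin coverage (when depth is
    supplied) downgrades to low_confidence.
    """
    if not 0.0 <= af <= 1.0:
        raise ValueError(f"allele fraction {af} outside [0, 1]")
    if ploidy < 1:
        raise ValueError("ploidy must be >= 1")
    if af == 0.0:
        return "wild_type", "/".join(["0"] * ploidy)
    if total_reads is not None and total_reads < min_depth:
        return "low_confidence", ""
    n_alt = max(1, min(ploidy, round(af * ploidy)))
    if af > homo_threshold:
        return "homo", "/".join(["1"] * ploidy)
    n_alt = min(n_alt, ploidy - 1)
    pen = ["0"] * (ploidy - n_alt) + ["1"] * n_alt
    return "het", "/".join(pen)


def consensus_edits(
    cell_edits: pd.DataFrame,
    min_cells: int = 3,
    min_fraction: float = 0.25,
) -> pd.DataFrame:
    """Retained edits per guide from per-cell edit calls.

    ``cell_edits`` columns: cell, guide_id, edit (an edit identifier; one
    row per cell × detected edit; cells without edits appear with edit =
    NaN so the per-guide cell count is right).  An edit is retained iff
    seen in ≥ ``min_cells`` cells AND in ≥ ``min_fraction`` of the guide's
    cells; guides with fewer than ``min_cells`` uniquely assigned cells are
    not reported.
    """
    rows = []
    for gid, sub in cell_edits.groupby("guide_id"):
        n_cells = sub["cell"].nunique()
        if n_cells < min_cells:
            continue
        with_edit = sub.dropna(subset=["edit"])
        for edit, esub in with_edit.groupby("edit"):
            k = esub["cell"].nunique()
            if k >= min_cells and k / n_cells >= min_fraction:
                rows.append(
                    {"guide_id": gid, "edit": edit, "n_cells": k,
                     "n_guide_cells": n_cells, "fraction": k / n_cells}
                )
    return pd.DataFrame(rows, columns=["guide_id", "edit", "n_cells", "n_guide_cells", "fraction"])


def estimate_false_negative_rate(
    n_detected: int,
    n_undetected: int,
    n_excluded_no_target: int = 0,
    n_excluded_gc_only: int = 0,
    n_excluded_polyT: int = 0,
) -> float:
    """Screen false-negative rate as a percentage.

    Guides undetected for a structural reason — no window target base,
    exclusively GC-context targets, or a poly-T tract silencing U6
    expression — are excluded from the numerator; the denominator is the
    detected-guide count, the reading under which undetected-but-editable
    guides are expressed relative to demonstrated editing events.
    """
    if n_detected <= 0:
        raise ValueError("false-negative rate undefined with zero detected guides")
    excluded = n_excluded_no_target + n_excluded_gc_only + n_excluded_polyT
    if excluded > n_undetected:
        raise ValueError("more exclusions than undetected guides")
    return 100.0 * (n_undetected - excluded) / n_detected


def estimate_misassignment_rate(n_controls_with_target_edit: int, n_controls: int) -> float:
    """Control-guide misassignment rate as a percentage."""
    if n_controls <= 0:
        raise ValueError("no control guides")
    if not 0 <= n_controls_with_target_edit <= n_controls:
        raise ValueError("misassigned count outside [0, n_controls]")
    return 100.0 * n_controls_with_target_edit / n_controls


def estimate_rates_from_flags(
    detected_guides,
    undetected_profiles,
) -> float:
    """FNR from per-guide editability flags (see GuideProfile)."""
    n_det = len(list(detected_guides))
    no_tgt = sum(1 for p in undetected_profiles if p.no_target)
    gc = sum(1 for p in undetected_profiles if (not p.no_target) and p.exclusively_gc_context)
    polyt = sum(
        1 for p in undetected_profiles
        if p.polyT and not p.no_target and not p.exclusively_gc_context
    )
    n_undet = len(list(undetected_profiles))
    return estimate_false_negative_rate(n_det, n_undet, no_tgt, gc, polyt)
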