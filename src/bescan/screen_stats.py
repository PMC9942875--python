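"""Screen enrichment statistics: QC, normalization, empirical-Bayes z-scores,
element aggregation and LOF/GOF/SOF classification.

Counts are a guide × sample integer matrix; each sample carries an assay
label (plasmid, T0, control, IFNg, FACS_sorted) and a replicate id.
Normalized abundance is reads-per-million plus one pseudocount, exactly

    norm_rpm = reads / total_reads_for_sample * 1e6 + 1

so that sum(norm_rpm − 1) = 1e6 in every sample.  Log2 fold-changes are
taken between a treated and a reference sample; per-guide z-scores use an
empirical-Bayes standard deviation pooled over guides of similar reference
abundance, and element scores are normZ = Σz/√n with a two-sided normal
p-value and Benjamini–Hochberg FDR.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

logger = logging.getLogger(__name__)

ASSAYS = ("plasmid", "T0", "control", "IFNg", "FACS_sorted")


@dataclass
class CountMatrix:
    """Guide × sample counts plus per-sample assay/replicate metadata."""

    counts: pd.DataFrame              # index: guide_id, columns: sample names
    samples: pd.DataFrame             # index: sample names; columns assay, replicate

    def __post_init__(self):
        if self.counts.index.duplicated().any():
            raise ValueError("duplicate guide ids in count matrix")
        missing = set(self.counts.columns) - set(self.samples.index)
        if missing:
            raise ValueError(f"samples without metadata: {sorted(missing)}")
        for col in ("assay", "replicate"):
            if col not in self.samples.columns:
                raise ValueError(f"sample sheet lacks {col!r} column")
        if (self.counts.to_numpy() < 0).any():
            raise ValueError("negative counts")
        self.counts = self.counts.astype(np.int64)

    def samples_for(self, assay: str) -> list[str]:
        return list(self.samples.index[self.samples["assay"] == assay])

    @classmethod
    def from_tsv(cls, counts_path, samples_path) -> "CountMatrix":
        counts = pd.read_csv(counts_path, sep="\t", index_col=0)
        samples = pd.read_csv(samples_path, sep="\t", index_col=0)
        return cls(counts, samples)


@dataclass
class QCRules:
    """Guide-removal rules, applied in declaration order.

    ``min_reads_any_sample`` applies the minimum-coverage rule ("<100 reads
    in any sample of either replicate") at the guide level — dropping whole
    samples would break the paired replicate design.  Set a field to None
    to disable that rule.
    """

    zero_in_reference: bool = True
    reference_assays: tuple[str, ...] = ("plasmid", "T0", "control")
    min_reads_any_sample: int | None = 100
    max_plasmid_reads: int | None = 50_000
    max_control_fold_diff: float | None = None   # e.g. 3.0 to enable


def qc_filter(matrix: CountMatrix, rules: QCRules | None = None) -> tuple[CountMatrix, pd.DataFrame]:
    """Apply removal rules; returns the filtered matrix and a removal log.

    Removing every guide is fatal.  The log has one row per removed guide
    with the first rule that triggered.
    """
    rules = rules or QCRules()
    counts = matrix.counts
    removed: dict[str, str] = {}

    def mark(mask: pd.Series, rule: str) -> None:
        for gid in counts.index[mask]:
            removed.setdefault(gid, rule)

    if rules.zero_in_reference:
        ref_cols = [
            s for s in counts.columns
            if matrix.samples.loc[s, "assay"] in rules.reference_assays
        ]
        if ref_cols:
            mark((counts[ref_cols] == 0).any(axis=1), "zero_reads_in_reference_sample")
    if rules.min_reads_any_sample is not None:
        mark(
            (counts < rules.min_reads_any_sample).any(axis=1),
            f"below_min_reads_{rules.min_reads_any_sample}",
        )
    if rules.max_plasmid_reads is not None:
        plasmid_cols = [
            s for s in counts.columns if matrix.samples.loc[s, "assay"] == "plasmid"
        ]
        if plasmid_cols:
            mark(
                (counts[plasmid_cols] > rules.max_plasmid_reads).any(axis=1),
                f"over_represented_gt_{rules.max_plasmid_reads}",
            )
    if rules.max_control_fold_diff is not None:
        ctl = [s for s in counts.columns if matrix.samples.loc[s, "assay"] == "control"]
        if len(ctl) >= 2:
            c = counts[ctl].astype(float) + 1.0
            fold = c.max(axis=1) / c.min(axis=1)
            mark(fold > rules.max_control_fold_diff,
                 f"control_fold_diff_gt_{rules.max_control_fold_diff}")

    keep = [g for g in counts.index if g not in removed]
    if not keep:
        raise ValueError("QC filtering removed every guide")
    log = pd.DataFrame(
        {"guide_id": list(removed), "rule": list(removed.values())}
    )
    for row in log.itertuples(index=False):
        logger.info("qc_filter: removed %s (%s)", row.guide_id, row.rule)
    return CountMatrix(counts.loc[keep], matrix.samples), log


def normalize_rpm(counts: pd.DataFrame) -> pd.DataFrame:
    """reads/total × 1e6 + 1 per sample; fatal on a zero-total sample."""
    totals = counts.sum(axis=0)
    zero = totals[totals == 0]
    if len(zero):
        raise ValueError(f"zero total reads in sample(s): {list(zero.index)}")
    return counts / totals * 1e6 + 1.0


def normalize_and_l2fc(
    matrix: CountMatrix, treated: str, reference: str
) -> pd.DataFrame:
    """Per-guide norm_rpm for both samples and their log2 fold change."""
    for s in (treated, reference):
        if s not in matrix.counts.columns:
            raise KeyError(f"sample {s!r} not in count matrix")
    norm = normalize_rpm(matrix.counts[[treated, reference]])
    return pd.DataFrame(
        {
            "norm_rpm_treated": norm[treated],
            "norm_rpm_reference": norm[reference],
            "l2fc": np.log2(norm[treated] / norm[reference]),
        }
    )


def eb_zscore(
    l2fc: pd.Series,
    control_guides,
    reference_abundance: pd.Series,
    window: int = 800,
    min_controls: int = 20,
) -> pd.Series:
    """Empirical-Bayes z-scores for guide log2 fold changes.

    L2FCs are centered by the mean over control guides.  The per-guide
    standard deviation is estimated by sorting guides by reference-sample
    abundance (descending) and taking a sliding-window sample sd over
    neighbours, then enforced monotone: a lower-abundance guide never
    receives a smaller sd than any higher-abundance one (count noise only
    grows as coverage falls).
    """
    control_guides = [g for g in control_guides if g in l2fc.index]
    if len(control_guides) < min_controls:
        raise ValueError(
            f"only {len(control_guides)} control guides present; "
            f"at least {min_controls} required (min_controls={min_controls})"
        )
    centered = l2fc - l2fc.loc[control_guides].mean()
    order = reference_abundance.loc[l2fc.index].sort_values(ascending=False).index
    x = centered.loc[order]
    w = int(min(window, len(x)))
    w = max(w, 2)
    half = max(w // 2, 2)
    sd = x.rolling(window=w, center=True, min_periods=half).std(ddof=1)
    sd = sd.bfill().ffill()
    # monotone non-decreasing as abundance falls: isotonic (PAVA) projection
    # rather than a running max, which is upward-biased under homoscedasticity
    from scipy.optimize import isotonic_regression

    sd = pd.Series(isotonic_regression(sd.to_numpy(), increasing=True).x, index=sd.index)
    sd = sd.replace(0.0, np.nan).bfill().ffill()
    if sd.isna().any():
        raise ValueError("could not estimate a positive sd (degenerate l2fc input)")
    z = (x / sd).reindex(l2fc.index)
    return z


def aggregate_elements(z: pd.Series, element_of: pd.Series) -> pd.DataFrame:
    """Element-level normZ = Σz/√n with two-sided normal p and BH FDR.

    ``element_of`` maps guide id → element id; guides missing from the map
    are dropped.  An empty mapping yields an empty frame.
    """
    joined = pd.DataFrame({"z": z}).join(element_of.rename("element"), how="inner")
    joined = joined.dropna(subset=["element"])
    if joined.empty:
        return pd.DataFrame(columns=["element", "n_guides", "normZ", "p", "fdr"]).set_index("element")
    grouped = joined.groupby("element")["z"]
    out = pd.DataFrame(
        {"n_guides": grouped.size(), "normZ": grouped.sum() / np.sqrt(grouped.size())}
    )
    out["p"] = 2.0 * stats.norm.sf(np.abs(out["normZ"]))
    out["fdr"] = multipletests(out["p"], method="fdr_bh")[1]
    return out


CALL_LEVELS = ("LOF", "GOF", "SOF", "neutral")


@dataclass
class Thresholds:
    lof_z: float
    gof_z: float
    facs_z: float | None


def benchmark_thresholds(
    prolif: pd.DataFrame,
    facs: pd.DataFrame | None,
    benchmark_lof,
    benchmark_gof,
    quantile: float = 0.05,
) -> Thresholds:
    """|z| thresholds from benchmark element sets (default 5th percentile),
    the in-silico analogue of calibrating on a validation cohort."""
    lof = [e for e in benchmark_lof if e in prolif.index]
    gof = [e for e in benchmark_gof if e in prolif.index]
    if not lof or not gof:
        raise ValueError("benchmark LOF and GOF sets must be non-empty and scored")
    lof_thr = float(np.quantile(np.abs(prolif.loc[lof, "normZ"]), quantile))
    gof_thr = float(np.quantile(np.abs(prolif.loc[gof, "normZ"]), quantile))
    facs_thr = None
    if facs is not None:
        lof_f = [e for e in lof if e in facs.index]
        if lof_f:
            facs_thr = float(np.quantile(np.abs(facs.loc[lof_f, "normZ"]), quantile))
    return Thresholds(lof_z=lof_thr, gof_z=gof_thr, facs_z=facs_thr)


def classify_variants(
    prolif: pd.DataFrame,
    facs: pd.DataFrame | None = None,
    benchmark_lof=None,
    benchmark_gof=None,
    quantile: float = 0.05,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """LOF / GOF / SOF / neutral calls per element.

    Any non-neutral call requires BH FDR ≤ ``alpha`` in the proliferation
    assay.  LOF = enriched (positive normZ) with FACS support; GOF =
    depleted (negative normZ; the FACS sort cannot recover GOF cells, so no
    FACS support is asked); SOF = proliferation-significant enrichment
    whose FACS signal stays below the support threshold.  FACS support is
    judged against benchmark-derived |z| thresholds when benchmark sets are
    supplied, otherwise against FACS FDR ≤ alpha.  Without FACS data the
    classification degrades to single-assay calls (logged).
    """
    thresholds = None
    if benchmark_lof is not None and benchmark_gof is not None:
        thresholds = benchmark_thresholds(prolif, facs, benchmark_lof, benchmark_gof, quantile)
    if facs is None:
        logger.warning("classify_variants: no FACS assay — single-assay calls only")

    out = prolif.copy()
    calls = []
    for element, row in prolif.iterrows():
        z, fdr = row["normZ"], row["fdr"]
        sig = fdr <= alpha
        depleted = sig and z < 0
        if thresholds is not None:
            depleted = depleted and abs(z) >= thresholds.gof_z
        if depleted:
            calls.append("GOF")
            continue
        if not (sig and z > 0):
            calls.append("neutral")
            continue
        # proliferation-significant enrichment: LOF needs FACS support (and
        # the benchmark threshold when one is set); unsupported = SOF
        passes_lof_threshold = thresholds is None or abs(z) >= thresholds.lof_z
        if facs is None or element not in facs.index:
            calls.append("LOF" if passes_lof_threshold else "neutral")
            continue
        fz = facs.loc[element, "normZ"]
        if thresholds is not None and thresholds.facs_z is not None:
            supported = fz >= thresholds.facs_z
        else:
            supported = facs.loc[element, "fdr"] <= alpha and fz > 0
        if not supported:
            calls.append("SOF")
        else:
            calls.append("LOF" if passes_lof_threshold else "neutral")
    out["call"] = calls
    return out


def average_replicate_z(z_by_replicate: dict[str, pd.Series]) -> pd.Series:
    """Combine replicates by averaging guide z-scores across them."""
    return pd.concat(z_by_replicate, axis=1).mean(axis=1)


def score_assay(
    matrix: CountMatrix,
    control_guides,
    element_of: pd.Series,
    treated_assay: str = "IFNg",
    reference_assay: str = "control",
    window: int = 800,
    min_controls: int = 20,
) -> tuple[pd.Series, pd.DataFrame]:
    """Guide z (replicate-averaged) and element scores for one assay contrast.

    Treated and reference samples are paired by replicate id; each
    replicate yields an L2FC vector and an empirical-Bayes z vector, the
    per-guide z are averaged across replicates, and elements aggregated by
    normZ.  Returns (guide_z, element frame).
    """
    reps = {}
    for rep in matrix.samples["replicate"].unique():
        sel = matrix.samples[matrix.samples["replicate"] == rep]
        treated = sel.index[sel["assay"] == treated_assay]
        reference = sel.index[sel["assay"] == reference_assay]
        if len(treated) != 1 or len(reference) != 1:
            continue
        scores = normalize_and_l2fc(matrix, treated[0], reference[0])
        reps[rep] = eb_zscore(
            scores["l2fc"], control_guides, scores["norm_rpm_reference"],
            window=window, min_controls=min_controls,
        )
    if not reps:
        raise ValueError(
            f"no replicate has both a {treated_assay} and a {reference_assay} sample"
        )
    guide_z = average_replicate_z(reps)
    return guide_z, aggregate_elements(guide_z, element_of)


def library_summary(library: pd.DataFrame, gene_of: pd.Series | None = None) -> dict:
    """Headline counts for a guide library table: guide total, guides per
    gene (median, when a gene map is given)."""
    out = {"n_guides": int(len(library))}
    if gene_of is not None:
        per_gene = gene_of.loc[gene_of.index.intersection(library["guide_id"])].value_counts()
        out["median_guides_per_gene"] = float(per_gene.median()) if len(per_gene) else 0.0
    return out
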