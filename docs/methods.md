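# Methods

This note documents the models and numerical choices behind `bescan`:
what each stage computes, the parameters that matter, what the synthetic
generators do and do not emulate, and the design decisions taken where
the problem left the design open.

## Coordinate frame and gene models

Genomic coordinates are 0-based half-open internally; emitted variant
tables are 1-based (VCF convention). A gene model is a single transcript
(one model per gene — isoform selection is the caller's responsibility):
sorted non-overlapping exons plus one CDS span. At load time the spliced
CDS must be a positive multiple of 3 and begin with ATG; a `permissive`
flag downgrades these to logged warnings for deliberately broken
fixtures. Protospacers are numbered 1–20 with the PAM at 21–23.

`locate()` classifies a position as CDS / 5′ UTR / 3′ UTR / splice region
/ intron / intergenic. The splice region is the two intronic bases
flanking each exon — the canonical GT/AG dinucleotides — and takes
precedence over plain intron. Two is the minimal defensible window and no
authoritative width exists for the annotation this mirrors, so it is
exposed as `splice_window`.

## Editors and outcome space

An editor is (source base, product base, window, PAM pattern). Presets:
BE3-NGG and BE3.9max-NGN (C→T, window 4–9), YE1-BE4max-NGN (C→T, 5–7,
the narrowed engineered deaminase), ABE8e-NGN (A→G, 4–9). The outcome
space per guide is each editable window position alone plus, when k ≥ 2,
the joint edit of all of them — the two regimes a deaminase realistically
produces (single edit at low activity, full window conversion at high
activity). A `combinatorial` flag enumerates all 2ᵏ−1 subsets for small k
but is off by default: intermediate combinations explode and are rarely
the dominant alleles.

Consequences are computed by applying the variants to a copy of the
reference, re-splicing, re-translating, and diffing proteins codon-wise,
then consolidating per-position labels by the fixed deleteriousness
order stop gained > start loss > splice variant > missense > UTR >
synonymous, with intergenic below synonymous. Degenerate cases: an edit
in the annotated start codon is start-lost regardless of the encoded
amino acid; a change of the terminal stop codon is reported as missense
(the enum carries no stop-lost class); ambiguity codes (N) are never
editable. Amino-acid coverage counts a residue as reachable if any
outcome changes it non-synonymously; the denominator is the protein
length excluding the terminal stop.

## Screen statistics

Normalization is exactly `reads / sample_total × 10⁶ + 1`; consequently
Σ(norm_rpm − 1) = 10⁶ in every sample, which the tests assert to
floating precision. QC removes, in order: guides with zero reads in any
reference sample (plasmid/T0/control), guides below 100 reads in any
sample (a guide-level reading — dropping whole samples would break the
paired replicate design), guides above 50,000 plasmid reads, and
optionally guides with >3-fold control-count differences between
experiments. Removals are logged with the triggering rule; removing
everything is fatal.

Guide z-scores are empirical-Bayes: L2FCs are centred on the mean of the
control guides (non-targeting/intergenic/non-essential), and each
guide's SD is estimated from a sliding window (default 800 guides,
shrunk to the library size) over guides sorted by reference-sample
abundance. The SD profile is then projected onto the monotone cone
(non-decreasing as abundance falls) by isotonic regression: count noise
only grows as coverage drops, and PAVA enforces this without the upward
bias a running maximum introduces under homoscedasticity (the suite
checks recovery of a flat SD within 5 % at n = 2,000). At least 20
control guides are required. Element scores are normZ = Σz/√n over the
guide→element map (by gene, or by predicted amino-acid position), with
two-sided normal p-values and Benjamini–Hochberg FDR; replicates are
combined by averaging guide z before aggregation.

Classification uses two assays: a proliferation contrast (IFN-γ vs
control) and a FACS marker-induction contrast in which only LOF cells
can be recovered by sorting. Any non-neutral call requires proliferation
FDR ≤ α (default 0.05). Enriched elements are LOF when the FACS signal
supports them and SOF when it does not; depleted elements are GOF with
no FACS requirement. When benchmark LOF/GOF element sets are supplied
(the analogue of calibrating on a validated cohort), |z| thresholds are
taken at a configurable quantile (default 5th percentile) of the
benchmark scores and additionally gate the calls; otherwise FACS support
means FACS FDR ≤ α with positive z. Without FACS data entirely, calls
degrade to single-assay LOF/GOF and the degradation is logged.

## Skew-t mixture and guide-to-cell assignment

Single-cell guide assignment pools all cell × guide entries of
log((UMI + ½) / cell total) and fits one two-component Azzalini skew-t
mixture: f(x) = (2/ω)·t_ν(z)·T_{ν+1}(αz√((ν+1)/(ν+z²))). At α = 0 this
is exactly the symmetric location-scale t (asserted to 1e−9). Fitting is
generalized EM: responsibilities in the E-step; each component's
weighted log-likelihood is improved by bounded L-BFGS-B from the current
parameters in the M-step, and a step is accepted only if it does not
decrease the objective — so the observed log-likelihood is monotone by
construction (asserted per iteration). Parameters are optimized as
(loc, log ω, log(ν−1), α) with box constraints (ω ≥ 0.01, 1.05 ≤ ν ≤ 200,
|α| ≤ 30) that stop a component collapsing onto a discrete spike such as
the zero-UMI mass. Initialisation is deterministic: the data are split
at the midrange of the 2nd–98th percentile span, components start at the
group medians with the group proportions as weights (robust when the
guide-present mode is a few percent of entries). Tolerance 1e−6 on the
log-likelihood, at most 500 iterations; with more than 5,000 entries the
fit uses a seeded subsample and posteriors are then evaluated for every
entry. A non-converged fit voids all assignments from it.

Per cell, P(≥1 guide) and P(≥2 guides) follow from the per-entry
posteriors of the higher-location ("present") component under
independence across guides; a cell is assigned its maximum-posterior
guide iff P(≥1) ≥ 0.99 and P(≥2) ≤ 0.01. The component count (2), the
pooled fit and the independence assumption are package decisions — the
procedure this models is documented only by its thresholds.

## Amplicon profiles, zygosity, consensus, error rates

VAF = alt/total; sites under 1 % VAF are removed (an absolute floor —
the suite asserts no profile ever reports less), zero-depth observations
are skipped with a warning, and an optional (contig, position) blocklist
drops known germline SNPs. Per guide the profile reports mean VAF by
protospacer position, the VAF-weighted fraction of editing inside the
editor window (weighting prevents trace out-of-window edits from
counting equally with real ones), and the fraction of samples carrying
both a non-synonymous and a synonymous edit (bystander co-editing).

Zygosity, triploid default: AF > 0.60 — two or three of three alleles —
is a high-confidence homozygous call (penetrance 1/1/1); any lower
non-zero AF is heterozygous; AF 0 is wild type; thin coverage (depth
below 10 when supplied) downgrades to low-confidence. The call is
monotone in AF (property-tested). Consensus edits per guide require ≥3
cells and ≥25 % of that guide's uniquely assigned cells, and guides are
only reported with ≥3 such cells. The false-negative rate divides
undetected-but-editable guides (undetected minus those excluded for no
window target, exclusively 5′-GC-context targets, or poly-T tracts) by
the number of *detected* guides — the only denominator consistent with
the published worked example (87 detected, 37 undetected, 4+6+2
excluded → 28.7 %).

## Synthetic data: what it emulates, and what it does not

The generators define the conditions every test runs under. One contig
carries a 3-exon, 450-codon plus-strand gene (GT/AG introns, UTRs,
flanks) and a single-exon 150-codon "essential" gene used to pick
stop-introducing controls. The library plants 6 LOF, 3 GOF and 3 SOF
elements and 20 neutral elements at 5 guides each, drawn from the real
enumerated guides, plus 100 non-targeting controls and up to 10 stop
controls. Effects in log₂ units: LOF +2, SOF +2 (proliferation only),
GOF −2; essential stop controls drop 2 log₂ units in all
post-transduction arms.

Counts are negative binomial (dispersion 0.05) around log-normal guide
abundances (σ = 0.5) at 1,000× mean coverage — a realistic pooled-screen
depth at which the 100-read QC floor does not systematically censor
2-fold-depleted guides. The IFN-γ arm multiplies expected counts by
2^effect; the FACS arm applies the effect to LOF guides only, modelling
the sort's capture probability in expectation (sorted non-responder
cells carry LOF guides) rather than its physics. Because strongly
enriched guides consume sequencing depth, all other guides shift down
compositionally; planted effects are therefore defined, and tested,
relative to the non-targeting-control baseline — precisely the control
centring the scoring applies.

UMI matrices draw each entry's latent log fraction from the background
or present skew-t component (defaults: locations −7 and −0.8 on the
natural-log scale, scales 0.6/0.35, ν = 5, skews ±1, 2,000 expected UMIs
per cell) with Poisson counts around fraction × total and a 5 % doublet
rate. Amplicon simulation edits window positions at 40 % efficiency and
out-of-window positions at 2 %, scales synonymous-only positions by a
0.6 co-edit rate, and draws per-cell zygosity (50 % homozygous at
ploidy 3) with binomial read support at 200×.

Deliberately not modelled: read-level errors and FASTQ simulation, PCR
jackpotting, editing-efficiency sequence-context models, indel
byproducts, off-target editing, and regulatory effects of
promoter-region guides. Passing tests therefore demonstrate that the
statistics recover planted truth under the stated noise model, not that
the pipeline is robust to artefacts these generators omit.

## Problem sizes and determinism

Defaults were chosen so the full suite and the acceptance script run in
minutes on one core: ~270-guide libraries (1,100 guides for the null
calibration across three seeds), 500-cell UMI matrices, 5,000-entry
mixture-recovery fits, 200-outcome annotation oracles. Every generator
is a pure function of (config, seed); identical inputs give
byte-identical files, and all test seeds are fixed in the suite.

## Known limitations

Guide uniqueness is exact-match uniqueness within the supplied contigs
(single-mismatch counting is available but O(L·20) per guide); there is
no genome-index search. Promoter-targeting guides receive no
regulatory-effect annotation. The empirical-Bayes SD is contaminated by
true effects when a large fraction of the library carries them, which
inflates the SD and makes calls conservative; this is intrinsic to
pooling and mitigated by the mostly-neutral library composition. The
skew-t likelihood is multimodal; the deterministic initialisation avoids
the degenerate spike solutions observed with naive quantile starts, but
a global optimum is not guaranteed.
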