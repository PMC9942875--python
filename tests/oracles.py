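"""Independent brute-force oracles used by the test suite.

Everything here is deliberately written from first principles (literal
codon table, dictionary complement, exhaustive scans) so it shares no code
path with the package under test.
"""

CODON_TABLE = {
    "TTT": "F", "TTC": "F", "TTA": "L", "TTG": "L",
    "CTT": "L", "CTC": "L", "CTA": "L", "CTG": "L",
    "ATT": "I", "ATC": "I", "ATA": "I", "ATG": "M",
    "GTT": "V", "GTC": "V", "GTA": "V", "GTG": "V",
    "TCT": "S", "TCC": "S", "TCA": "S", "TCG": "S",
    "CCT": "P", "CCC": "P", "CCA": "P", "CCG": "P",
    "ACT": "T", "ACC": "T", "ACA": "T", "ACG": "T",
    "GCT": "A", "GCC": "A", "GCA": "A", "GCG": "A",
    "TAT": "Y", "TAC": "Y", "TAA": "*", "TAG": "*",
    "CAT": "H", "CAC": "H", "CAA": "Q", "CAG": "Q",
    "AAT": "N", "AAC": "N", "AAA": "K", "AAG": "K",
    "GAT": "D", "GAC": "D", "GAA": "E", "GAG": "E",
    "TGT": "C", "TGC": "C", "TGA": "*", "TGG": "W",
    "CGT": "R", "CGC": "R", "CGA": "R", "CGG": "R",
    "AGT": "S", "AGC": "S", "AGA": "R", "AGG": "R",
    "GGT": "G", "GGC": "G", "GGA": "G", "GGG": "G",
}

_COMP = {"A": "T", "C": "G", "G": "C", "T": "A", "N": "N"}


def oracle_revcomp(seq: str) -> str:
    return "".join(_COMP[b] for b in reversed(seq))


def oracle_translate(cds: str) -> str:
    return "".join(
        CODON_TABLE.get(cds[i : i + 3], "X") for i in range(0, len(cds) - 2, 3)
    )


def oracle_spliced_protein(contig, exons, cds_span, strand):
    c0, c1 = cds_span
    cds = ""
    for a, b in sorted(exons):
        lo, hi = max(a, c0), min(b, c1)
        if lo < hi:
            cds += contig[lo:hi]
    if strand == "-":
        cds = oracle_revcomp(cds)
    return oracle_translate(cds)


def oracle_locate(pos, exons, cds_span, strand, splice_window=2):
    """Interval-scan position classifier, written independently."""
    exons = sorted(exons)
    span_lo, span_hi = exons[0][0], exons[-1][1]
    if pos < span_lo or pos >= span_hi:
        return "intergenic"
    for a, b in exons:
        if a <= pos < b:
            c0, c1 = cds_span
            if c0 <= pos < c1:
                return "CDS"
            if strand == "+":
                return "five_prime_UTR" if pos < c0 else "three_prime_UTR"
            return "three_prime_UTR" if pos < c0 else "five_prime_UTR"
    for a, b in exons:
        for k in range(1, splice_window + 1):
            if pos == b - 1 + k or pos == a - k:
                return "splice_region"
    return "intron"


IUPAC_SETS = {
    "A": {"A"}, "C": {"C"}, "G": {"G"}, "T": {"T"},
    "R": set("AG"), "Y": set("CT"), "S": set("CG"), "W": set("AT"),
    "K": set("GT"), "M": set("AC"), "B": set("CGT"), "D": set("AGT"),
    "H": set("ACT"), "V": set("ACG"), "N": set("ACGT"),
}


def oracle_scan_guides(seq: str, pam_pattern: str):
    """Exhaustive both-strand guide scan; returns {(start, strand)}."""
    found = set()
    for i in range(len(seq) - 22):
        pam = seq[i + 20 : i + 23]
        if all(b in IUPAC_SETS[p] for b, p in zip(pam, pam_pattern)):
            found.add((i, "+"))
    rc = oracle_revcomp(seq)
    L = len(seq)
    for i in range(len(rc) - 22):
        pam = rc[i + 20 : i + 23]
        if all(b in IUPAC_SETS[p] for b, p in zip(pam, pam_pattern)):
            # protospacer on rc occupies rc[i:i+20] = seq[L-i-20 : L-i]
            found.add((L - i - 20, "-"))
    return found


def oracle_bh(pvals):
    """Benjamini–Hochberg adjusted p-values, direct definition."""
    m = len(pvals)
    order = sorted(range(m), key=lambda i: pvals[i])
    adj = [0.0] * m
    prev = 1.0
    for rank_from_end, idx in enumerate(reversed(order)):
        rank = m - rank_from_end
        val = min(prev, pvals[idx] * m / rank)
        adj[idx] = val
        prev = val
    return adj
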