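"""Base-editor configurations.

A base editor is described by the transition it installs on the protospacer
strand (C→T for cytidine editors, A→G for adenine editors), the protospacer
positions where deamination is efficient (the editing window, inclusive,
with the protospacer numbered 1–20 and the PAM at 21–23), and the PAM
pattern its Cas9 variant requires.
"""

from __future__ import annotations

from dataclasses import dataclass

IUPAC = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT", "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG", "N": "ACGT",
}

COMPLEMENT = str.maketrans("ACGTRYSWKMBDHVN", "TGCAYRSWMKVHDBN")


def matches_iupac(seq: str, pattern: str) -> bool:
    """Exact-length IUPAC pattern match; ambiguous bases in ``seq`` never match."""
    if len(seq) != len(pattern):
        return False
    return all(b in IUPAC.get(p, "") for b, p in zip(seq, pattern))


@dataclass(frozen=True)
class EditorConfig:
    name: str
    source_base: str      # base edited, on the protospacer strand ("C" or "A")
    product_base: str     # base installed ("T" or "G")
    window: tuple[int, int]  # inclusive protospacer positions, 1-based
    pam_pattern: str      # IUPAC triplet

    def __post_init__(self):
        if self.source_base not in ("C", "A"):
            raise ValueError("source_base must be C or A")
        lo, hi = self.window
        if not (1 <= lo <= hi <= 20):
            raise ValueError("window must satisfy 1 <= start <= end <= 20")
        if len(self.pam_pattern) != 3:
            raise ValueError("pam_pattern must be an IUPAC triplet")

    def window_positions(self) -> range:
        return range(self.window[0], self.window[1] + 1)


PRESETS: dict[str, EditorConfig] = {
    "BE3-NGG": EditorConfig("BE3-NGG", "C", "T", (4, 9), "NGG"),
    "BE3.9max-NGN": EditorConfig("BE3.9max-NGN", "C", "T", (4, 9), "NGN"),
    "YE1-BE4max-NGN": EditorConfig("YE1-BE4max-NGN", "C", "T", (5, 7), "NGN"),
    "ABE8e-NGN": EditorConfig("ABE8e-NGN", "A", "G", (4, 9), "NGN"),
}


def get_editor(name: str) -> EditorConfig:
    try:
        return PRESETS[name]
    except KeyError:
        raise KeyError(
            f"unknown editor {name!r}; presets: {', '.join(PRESETS)}"
        ) from None
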