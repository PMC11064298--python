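"""Standard-code codon arithmetic shared by the simulator and the dS estimator."""

from __future__ import annotations

from functools import lru_cache
from itertools import product

from Bio.Data.CodonTable import standard_dna_table

BASES = "ACGT"
CODONS = ["".join(c) for c in product(BASES, repeat=3)]
STOP_CODONS = frozenset(standard_dna_table.stop_codons)  # TAA, TAG, TGA

_AA = dict(standard_dna_table.forward_table)
for _stop in STOP_CODONS:
    _AA[_stop] = "*"

TRANSITIONS = {"A": "G", "G": "A", "C": "T", "T": "C"}

COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")


def revcomp(seq: str) -> str:
    return seq.translate(COMPLEMENT)[::-1]


def translate_codon(codon: str) -> str:
    """One-letter amino acid; '*' for stop, 'X' for any codon with a non-ACGT base."""
    return _AA.get(codon, "X")


def translate(cds: str, *, internal_stop_as: str = "*") -> str:
    """Translate an in-frame CDS (trailing partial codon ignored)."""
    aas = [translate_codon(cds[i : i + 3]) for i in range(0, len(cds) - 2, 3)]
    return "".join(internal_stop_as if a == "*" else a for a in aas)


def is_transition(a: str, b: str) -> bool:
    return TRANSITIONS.get(a) == b


@lru_cache(maxsize=None)
def syn_fractions(codon: str) -> tuple[float, float, float]:
    """Fraction of the three possible changes at each codon position that are
    synonymous.  Changes to stop codons count as nonsynonymous; stop codons
    themselves have no synonymous sites here (they are excluded upstream)."""
    if codon in STOP_CODONS or any(b not in BASES for b in codon):
        return (0.0, 0.0, 0.0)
    aa = translate_codon(codon)
    out = []
    for pos in range(3):
        syn = 0
        for b in BASES:
            if b == codon[pos]:
                continue
            alt = codon[:pos] + b + codon[pos + 1 :]
            if alt not in STOP_CODONS and translate_codon(alt) == aa:
                syn += 1
        out.append(syn / 3.0)
    return tuple(out)


def syn_sites(cds: str) -> float:
    """Nei-Gojobori synonymous site count of an in-frame CDS (no stops)."""
    return sum(sum(syn_fractions(cds[i : i + 3])) for i in range(0, len(cds) - 2, 3))
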