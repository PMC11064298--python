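"""Core domain records passed between pipeline stages."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .codons import revcomp


@dataclass
class ChromosomeRecord:
    """A named chromosome sequence with its true (simulation) or inferred class.

    ``copy_number`` maps sex -> copies: autosomes 2/2, Z 2 (male) / 1 (female),
    W 0 (male) / 1 (female).
    """

    name: str
    sequence: str
    true_class: str | None = None  # autosome | Z | W
    copy_number: dict[str, int] = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass
class GeneModel:
    """A CDS-only gene model: exons are coding, coordinates 0-based half-open
    on the forward genome strand, sorted by start regardless of gene strand."""

    gene_id: str
    chrom: str
    strand: str  # '+' | '-'
    exons: list[tuple[int, int]]

    @property
    def start(self) -> int:
        return self.exons[0][0]

    @property
    def end(self) -> int:
        return self.exons[-1][1]

    @property
    def intron_count(self) -> int:
        if not self.exons:
            raise ValueError(f"gene {self.gene_id} has an empty exon list")
        return len(self.exons) - 1

    def cds_length(self) -> int:
        return sum(e - s for s, e in self.exons)

    def extract_cds(self, chrom_seq: str) -> str:
        """Spliced coding sequence, reported 5'->3' on the coding strand."""
        spliced = "".join(chrom_seq[s:e] for s, e in self.exons)
        return revcomp(spliced) if self.strand == "-" else spliced


@dataclass
class CoverageTrack:
    """Per-base read depth for one sample on one chromosome."""

    chrom: str
    depths: np.ndarray  # non-negative ints, length == chromosome length
    sample_id: str
    sex: str  # 'male' | 'female'

    def __post_init__(self) -> None:
        self.depths = np.asarray(self.depths)
        if (self.depths < 0).any():
            raise ValueError("coverage depths must be non-negative")
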