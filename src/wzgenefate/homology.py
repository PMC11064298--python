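"""Reciprocal-best-hit paralog discovery between W proteins and the rest of
the proteome.

Scoring uses Smith-Waterman local alignment with BLOSUM62 and affine gaps
(open 11, extend 1) via Biopython's PairwiseAligner; ranking by raw local
score with a minimum-score floor is the deterministic counterpart of a
seeded database search with an e-value cutoff.  Percent identity is
identical residue pairs over aligned (ungapped) columns, and pairs are
binned at 80 and 90 percent identity.
"""

from __future__ import annotations

from dataclasses import dataclass


from Bio.Align import PairwiseAligner, substitution_matrices

VALID_AA = frozenset("ACDEFGHIKLMNPQRSTVWYX")
DEFAULT_SCORE_FLOOR = 50.0


def _aligner() -> PairwiseAligner:
    a = PairwiseAligner()
    a.mode = "local"
    a.substitution_matrix = substitution_matrices.load("BLOSUM62")
    a.open_gap_score = -11.0
    a.extend_gap_score = -1.0
    return a


_ALIGNER = _aligner()


def _check_protein(seq: str, name: str = "sequence") -> None:
    if not seq:
        raise ValueError(f"empty protein {name}")
    bad = set(seq.upper()) - VALID_AA
    if bad:
        raise ValueError(f"protein {name} contains invalid characters {sorted(bad)}")


def identity_bin(identity: float) -> str:
    """Fig-4-style bins: high >= 90, mid 80-<90, low < 80."""
    if identity >= 90.0:
        return "high"
    if identity >= 80.0:
        return "mid"
    return "low"


@dataclass
class ParalogPair:
    """A W gene and its reciprocal best partner elsewhere in the genome."""

    w_gene: str
    partner: str
    partner_chrom: str
    score: float
    identity: float

    @property
    def bin(self) -> str:
        return identity_bin(self.identity)


def align_proteins(a: str, b: str) -> tuple[float, float] | None:
    """(local alignment score, percent identity), or None if no
    positive-scoring local alignment exists."""
    _check_protein(a, "a")
    _check_protein(b, "b")
    score = _ALIGNER.score(a.upper(), b.upper())
    if score <= 0:
        return None
    return float(score), _identity(a.upper(), b.upper())


def _identity(a: str, b: str) -> float:
    aln = _ALIGNER.align(a, b)[0]
    counts = aln.counts()
    aligned = counts.identities + counts.mismatches
    return 100.0 * counts.identities / aligned if aligned else 0.0


class _ScoreCache:
    """Symmetric score/identity cache over a fixed set of sequences."""

    def __init__(self, proteins: dict[str, str]):
        self.seqs = {k: v.upper() for k, v in proteins.items()}
        for name, seq in self.seqs.items():
            _check_protein(seq, name)
        self._score: dict[tuple[str, str], float] = {}
        self._ident: dict[tuple[str, str], float] = {}

    @staticmethod
    def _key(a: str, b: str) -> tuple[str, str]:
        return (a, b) if a <= b else (b, a)

    def score(self, a: str, b: str) -> float:
        k = self._key(a, b)
        if k not in self._score:
            self._score[k] = float(_ALIGNER.score(self.seqs[a], self.seqs[b]))
        return self._score[k]

    def identity(self, a: str, b: str) -> float:
        k = self._key(a, b)
        if k not in self._ident:
            self._ident[k] = _identity(self.seqs[a], self.seqs[b])
        return self._ident[k]


def _best_from_cache(
    query: str, targets: list[str], cache: _ScoreCache, score_floor: float
) -> str | None:
    scored = [(cache.score(query, t), t) for t in targets]
    scored = [(s, t) for s, t in scored if s >= score_floor]
    if not scored:
        return None
    top = max(s for s, _ in scored)
    tied = [t for s, t in scored if s == top]
    if len(tied) == 1:
        return tied[0]
    # tie-break: higher identity, then lexicographic gene id
    return min(tied, key=lambda t: (-cache.identity(query, t), t))


def best_hit(
    query: str,
    targets: dict[str, str],
    *,
    score_floor: float = DEFAULT_SCORE_FLOOR,
) -> tuple[str, float, float] | None:
    """Best-scoring target for a query protein.

    Returns (target id, score, percent identity) or None when no target
    reaches the score floor.  Ties break by higher identity, then
    lexicographically smaller gene id.
    """
    if not targets:
        raise ValueError("empty target set")
    cache = _ScoreCache({"__query__": query, **targets})
    best = _best_from_cache("__query__", list(targets), cache, score_floor)
    if best is None:
        return None
    return best, cache.score("__query__", best), cache.identity("__query__", best)


def reciprocal_best_hits(
    w_proteins: dict[str, str],
    other_proteins: dict[str, str],
    gene_chrom: dict[str, str] | None = None,
    *,
    score_floor: float = DEFAULT_SCORE_FLOOR,
    exclude_chroms: frozenset[str] = frozenset({"mt", "MT", "mitochondrion"}),
) -> list[ParalogPair]:
    """Reciprocal best hits between W proteins and the remaining proteome.

    A pair (w, p) is retained iff p is w's best hit over the non-W set and
    w is p's best hit over the W set.  Mitochondrial targets are excluded
    by default when a gene->chromosome map is supplied.
    """
    overlap = set(w_proteins) & set(other_proteins)
    if overlap:
        raise ValueError(f"W and non-W protein sets overlap: {sorted(overlap)[:3]}")
    gene_chrom = gene_chrom or {}
    targets = [
        g for g in other_proteins if gene_chrom.get(g, "") not in exclude_chroms
    ]
    cache = _ScoreCache({**w_proteins, **{g: other_proteins[g] for g in targets}})
    w_ids = sorted(w_proteins)
    forward = {w: _best_from_cache(w, targets, cache, score_floor) for w in w_ids}
    pairs: list[ParalogPair] = []
    for w in w_ids:
        p = forward[w]
        if p is None:
            continue
        back = _best_from_cache(p, w_ids, cache, score_floor)
        if back == w:
            pairs.append(
                ParalogPair(
                    w_gene=w,
                    partner=p,
                    partner_chrom=gene_chrom.get(p, ""),
                    score=cache.score(w, p),
                    identity=cache.identity(w, p),
                )
            )
    return pairs
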