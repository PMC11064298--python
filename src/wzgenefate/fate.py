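"""W-gene fate classification: pseudogenization, retrotransposition,
expression retention, and copy number.

Pseudogene detection aligns the W coding sequence against its partner's
protein with a protein-guided dynamic program that may consume 1, 2, 4 or 5
nucleotides per amino acid (a frameshift step, penalized) in addition to
the usual codon match, codon deletion and amino-acid insertion moves.  The
optimal path therefore *explains* a 1-2 bp indel by shifting frame, so the
downstream sequence is read in its true frame instead of dissolving into
spurious stop codons.  A premature stop is an in-frame stop codon on the
optimal path before the final codon; a frameshift is any non-codon step in
the body of the CDS (indels within the terminal 5% are ignored as
annotation-edge noise).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from Bio.Align import substitution_matrices

from .codons import STOP_CODONS, translate_codon
from .homology import DEFAULT_SCORE_FLOOR, _best_from_cache, _ScoreCache
from .models import GeneModel

_BLOSUM = substitution_matrices.load("BLOSUM62")

# DP move codes: nucleotides consumed per partner amino acid (0 = aa insertion)
_DIAG3, _FS2, _FS4, _FS1, _FS5, _DEL_CODON, _INS_AA = 1, 2, 3, 4, 5, 6, 7
_CONSUME = {_DIAG3: (3, 1), _FS2: (2, 1), _FS4: (4, 1), _FS1: (1, 1), _FS5: (5, 1),
            _DEL_CODON: (3, 0), _INS_AA: (0, 1)}
_FS_MOVES = frozenset({_FS1, _FS2, _FS4, _FS5})


@dataclass
class PseudogeneCall:
    is_pseudogene: bool
    reasons: list[str] = field(default_factory=list)
    stop_positions: list[int] = field(default_factory=list)  # CDS nt offsets
    frameshift_positions: list[int] = field(default_factory=list)


def _blosum_rows(prot: str) -> dict[str, list[float]]:
    alphabet = set(prot) | set("ACDEFGHIKLMNPQRSTVWYX*")
    rows = {}
    for aa in alphabet:
        key = aa if aa in _BLOSUM.alphabet else "X"
        rows[aa] = [float(_BLOSUM[key][p if p in _BLOSUM.alphabet else "X"]) for p in prot]
    return rows


def _guided_alignment_events(
    dna: str,
    prot: str,
    *,
    fs_penalty: float = -15.0,
    stop_penalty: float = -8.0,
    gap_penalty: float = -11.0,
) -> tuple[list[int], list[int]]:
    """Run the protein-guided DP; return (stop positions, frameshift
    positions) on the optimal global path, as nucleotide offsets."""
    n, m = len(dna), len(prot)
    aa_at = [translate_codon(dna[i : i + 3]) for i in range(n - 2)]
    rows = _blosum_rows(prot)
    NEG = -1e18
    S = np.full((n + 1, m + 1), NEG)
    ptr = np.zeros((n + 1, m + 1), dtype=np.int8)
    S[0, 0] = 0.0
    for i in range(n + 1):
        Si = S[i]
        for j in range(m + 1):
            if i == 0 and j == 0:
                continue
            best, arg = NEG, 0
            if j >= 1:
                if i >= 3:
                    aa = aa_at[i - 3]
                    sc = stop_penalty if aa == "*" else rows[aa][j - 1]
                    v = S[i - 3][j - 1] + sc
                    if v > best:
                        best, arg = v, _DIAG3
                if i >= 2:
                    v = S[i - 2][j - 1] + fs_penalty
                    if v > best:
                        best, arg = v, _FS2
                if i >= 4:
                    v = S[i - 4][j - 1] + fs_penalty
                    if v > best:
                        best, arg = v, _FS4
                if i >= 1:
                    v = S[i - 1][j - 1] + fs_penalty
                    if v > best:
                        best, arg = v, _FS1
                if i >= 5:
                    v = S[i - 5][j - 1] + fs_penalty
                    if v > best:
                        best, arg = v, _FS5
                v = Si[j - 1] + gap_penalty
                if v > best:
                    best, arg = v, _INS_AA
            if i >= 3:
                v = S[i - 3][j] + gap_penalty
                if v > best:
                    best, arg = v, _DEL_CODON
            Si[j] = best
            ptr[i][j] = arg
    # traceback
    stops: list[int] = []
    shifts: list[int] = []
    i, j = n, m
    while i > 0 or j > 0:
        move = int(ptr[i][j])
        if move == 0:
            break
        di, dj = _CONSUME[move]
        i -= di
        j -= dj
        if move == _DIAG3 and aa_at[i] == "*":
            stops.append(i)
        elif move in _FS_MOVES:
            shifts.append(i)
    return sorted(stops), sorted(shifts)


def detect_pseudogene(
    w_cds: str,
    partner_protein: str,
    *,
    edge_fraction: float = 0.05,
) -> PseudogeneCall:
    """Flag a W coding sequence as pseudogenized against its partner.

    Reasons are ``premature_stop`` (in-frame stop before the final codon on
    the best protein-guided alignment) and/or ``frameshift`` (a 1-2 bp
    indel step in the CDS body; indels within ``edge_fraction`` of either
    end are ignored).  Intact in-frame sequences short-circuit without the
    dynamic program.
    """
    if not partner_protein:
        raise ValueError("partner protein must be non-empty")
    w_cds = w_cds.upper()
    if len(w_cds) < 3:
        raise ValueError("coding sequence shorter than one codon")
    if len(w_cds) % 3 == 0 and w_cds[-3:] in STOP_CODONS:
        w_cds = w_cds[:-3]
    in_frame = len(w_cds) % 3 == 0
    if in_frame:
        has_stop = any(
            w_cds[i : i + 3] in STOP_CODONS for i in range(0, len(w_cds) - 2, 3)
        )
        if not has_stop:
            return PseudogeneCall(False)
    stops, shifts = _guided_alignment_events(w_cds, partner_protein.upper())
    lo, hi = edge_fraction * len(w_cds), (1 - edge_fraction) * len(w_cds)
    shifts = [p for p in shifts if lo <= p <= hi]
    stops = [p for p in stops if p < len(w_cds) - 3]  # not the final codon
    reasons = []
    if stops:
        reasons.append("premature_stop")
    if shifts:
        reasons.append("frameshift")
    return PseudogeneCall(bool(reasons), reasons, stops, shifts)


def compare_introns(w_gene: GeneModel, partner_gene: GeneModel) -> str:
    """Retrocopy call from intron counts: fewer introns than the partner is
    retro evidence; an intronless partner is uninformative."""
    wi, pi = w_gene.intron_count, partner_gene.intron_count
    if pi == 0:
        return "uninformative"
    if wi < pi:
        return "retro_candidate"
    return "dna_duplication"


def compute_fpkm(fragment_count: float, exonic_length_bp: int, total_mapped_fragments: int) -> float:
    """Fragments per kilobase of exon per million mapped fragments."""
    if exonic_length_bp <= 0 or total_mapped_fragments <= 0:
        raise ValueError("exonic length and total mapped fragments must be positive")
    if fragment_count < 0:
        raise ValueError("fragment count must be non-negative")
    return fragment_count * 1e9 / (exonic_length_bp * total_mapped_fragments)


def classify_expression(fpkm_values, threshold: float = 0.5) -> tuple[bool, float]:
    """(expressed, mean FPKM): the mean of the samples is compared strictly
    against the threshold, so a gene at exactly the threshold is silent."""
    values = list(fpkm_values)
    if not values:
        raise ValueError("need at least one FPKM value")
    # fsum: correctly rounded, so the call is invariant to sample order
    mean = math.fsum(values) / len(values)
    # round at 1e-12 so a replicate mean landing exactly on the threshold is
    # silent regardless of how the inputs were accumulated upstream
    return round(mean, 12) > threshold, mean


def assign_symbols(
    proteins: dict[str, str],
    reference_proteins: dict[str, str],
    *,
    score_floor: float = DEFAULT_SCORE_FLOOR,
) -> dict[str, str | None]:
    """Symbol assignment by best local-alignment hit against a reference
    protein set (None when no hit reaches the score floor)."""
    if not reference_proteins:
        raise ValueError("empty reference protein set")
    ref_ids = [f"ref::{r}" for r in reference_proteins]
    cache = _ScoreCache({**proteins, **{f"ref::{r}": s for r, s in reference_proteins.items()}})
    symbol: dict[str, str | None] = {}
    for g in proteins:
        hit = _best_from_cache(g, ref_ids, cache, score_floor)
        symbol[g] = hit[len("ref::"):] if hit else None
    return symbol


def copy_number(
    symbol: dict[str, str | None],
    gene_chrom: dict[str, str],
    rbh_pairs: list,
    *,
    w_chrom: str = "W",
) -> pd.DataFrame:
    """Per-symbol copy counts on the W versus the Z/autosomes.

    ``symbol`` maps each gene to its reference-protein symbol (see
    :func:`assign_symbols`); a symbol is retained only when a W gene and
    its reciprocal best partner map to the same reference protein.  Counts
    are genes per symbol per compartment.
    """
    retained = set()
    for pair in rbh_pairs:
        sw, sp = symbol.get(pair.w_gene), symbol.get(pair.partner)
        if sw is not None and sw == sp:
            retained.add(sw)
    rows = []
    for sym in sorted(retained):
        members = [g for g, s in symbol.items() if s == sym]
        w_copies = sum(1 for g in members if gene_chrom.get(g) == w_chrom)
        rows.append(
            {
                "symbol": sym,
                "w_copies": w_copies,
                "other_copies": len(members) - w_copies,
            }
        )
    return pd.DataFrame(rows, columns=["symbol", "w_copies", "other_copies"])


def classify_gene_fates(
    w_genes: list[GeneModel],
    gene_models: dict[str, GeneModel],
    rbh_pairs: list,
    cds_map: dict[str, str],
    prot_map: dict[str, str],
    fpkm: pd.DataFrame,
    *,
    fpkm_threshold: float = 0.5,
    copy_counts: pd.DataFrame | None = None,
    symbol_of: dict[str, str] | None = None,
) -> pd.DataFrame:
    """Assemble the per-W-gene fate table.

    ``fpkm`` must carry a ``mixed`` column and one or more ``gonad_*``
    replicate columns; gonad expression is called on the replicate mean.
    Genes without a reciprocal best partner have no partner-dependent calls.
    """
    partner_of = {p.w_gene: p.partner for p in rbh_pairs}
    gonad_cols = [c for c in fpkm.columns if c.startswith("gonad")]
    rows = []
    for g in w_genes:
        partner = partner_of.get(g.gene_id)
        row: dict = {
            "gene_id": g.gene_id,
            "chrom": g.chrom,
            "intron_count": g.intron_count,
            "partner": partner,
            "partner_intron_count": pd.NA,
            "retrocopy_call": "uninformative",
            "pseudogene": pd.NA,
            "pseudogene_reasons": "",
        }
        if partner is not None:
            pg = gene_models[partner]
            row["partner_intron_count"] = pg.intron_count
            row["retrocopy_call"] = compare_introns(g, pg)
            call = detect_pseudogene(cds_map[g.gene_id], prot_map[partner])
            row["pseudogene"] = call.is_pseudogene
            row["pseudogene_reasons"] = ",".join(call.reasons)
        mixed = float(fpkm.loc[g.gene_id, "mixed"])
        exp_mixed, _ = classify_expression([mixed], fpkm_threshold)
        exp_gonad, gonad_mean = classify_expression(
            fpkm.loc[g.gene_id, gonad_cols].tolist(), fpkm_threshold
        )
        row.update(
            fpkm_mixed=mixed,
            fpkm_gonad_mean=gonad_mean,
            expressed_mixed=exp_mixed,
            expressed_gonad=exp_gonad,
        )
        if copy_counts is not None and symbol_of is not None and partner is not None:
            sym = symbol_of.get(g.gene_id)
            hit = copy_counts[copy_counts["symbol"] == sym] if sym else None
            if hit is not None and len(hit):
                row["w_symbol_copies"] = int(hit["w_copies"].iloc[0])
                row["partner_symbol_copies"] = int(hit["other_copies"].iloc[0])
        rows.append(row)
    return pd.DataFrame(rows)
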