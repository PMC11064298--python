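"""Pairwise synonymous divergence: codon-aware alignment, Nei-Gojobori
(1986) site/difference counting, and Jukes-Cantor multiple-hit correction.

The estimator composes four steps: trim terminal stop codons and translate;
globally align the proteins and thread the codons through that alignment;
drop codon columns containing a gap or an ambiguous base; count synonymous
and nonsynonymous sites (per-position synonymous fractions from the
standard code, averaged between the two sequences) and differences
(equal-weight averaging over all orderings of multi-hit codons, steps
through stop codons scored nonsynonymous); correct the proportions with
d = -3/4 ln(1 - 4p/3).  Estimates with dS > 3 are flagged saturated and
excluded from downstream densities; p >= 3/4 leaves the distance undefined.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from functools import lru_cache
from itertools import permutations

import pandas as pd
from Bio.Align import PairwiseAligner, substitution_matrices

from .codons import STOP_CODONS, syn_fractions, translate_codon

DEFAULT_MAX_DS = 3.0


class InternalStopError(ValueError):
    """An in-frame internal stop codon: the pair should be routed to
    pseudogene handling, not aligned here."""

    def __init__(self, name: str):
        super().__init__(f"internal stop codon in sequence {name!r}")
        self.sequence_name = name


class FrameError(ValueError):
    """CDS length not a multiple of 3 after terminal-stop trimming."""

    def __init__(self, name: str, length: int):
        super().__init__(f"sequence {name!r} has CDS length {length} not divisible by 3")
        self.sequence_name = name


def _protein_aligner() -> PairwiseAligner:
    a = PairwiseAligner()
    a.mode = "global"
    a.substitution_matrix = substitution_matrices.load("BLOSUM62")
    a.open_gap_score = -11.0
    a.extend_gap_score = -1.0
    return a


_PROT_ALIGNER = _protein_aligner()


@dataclass
class CodonAlignment:
    """Two gap-aligned CDSs (gaps in whole-codon units) plus the codon
    columns retained after filtering."""

    aligned_a: str
    aligned_b: str
    retained_columns: list[int]

    def __post_init__(self) -> None:
        if len(self.aligned_a) != len(self.aligned_b) or len(self.aligned_a) % 3:
            raise ValueError("aligned sequences must have equal lengths divisible by 3")

    @property
    def n_columns(self) -> int:
        return len(self.aligned_a) // 3

    def column(self, i: int) -> tuple[str, str]:
        return self.aligned_a[3 * i : 3 * i + 3], self.aligned_b[3 * i : 3 * i + 3]

    def retained_pairs(self) -> list[tuple[str, str]]:
        return [self.column(i) for i in self.retained_columns]


def _prepare_cds(cds: str, name: str) -> tuple[str, str]:
    """Trim a terminal stop codon, verify frame, translate; returns
    (trimmed cds, protein)."""
    cds = cds.upper()
    if len(cds) % 3:
        raise FrameError(name, len(cds))
    if cds[-3:] in STOP_CODONS:
        cds = cds[:-3]
    if not cds:
        raise ValueError(f"sequence {name!r} is empty after stop trimming")
    aas = []
    for i in range(0, len(cds), 3):
        cod = cds[i : i + 3]
        if cod in STOP_CODONS:
            raise InternalStopError(name)
        aas.append(translate_codon(cod))
    return cds, "".join(aas)


def codon_align(cds_a: str, cds_b: str, names: tuple[str, str] = ("a", "b")) -> CodonAlignment:
    """Align two coding sequences codon-wise by threading codons through a
    global protein alignment.  Terminal stop codons are removed first;
    internal stops raise :class:`InternalStopError`."""
    a_cds, a_prot = _prepare_cds(cds_a, names[0])
    b_cds, b_prot = _prepare_cds(cds_b, names[1])
    aln = _PROT_ALIGNER.align(a_prot, b_prot)[0]
    out_a: list[str] = []
    out_b: list[str] = []
    ai = bi = 0
    for (a_s, a_e), (b_s, b_e) in zip(*aln.aligned):
        while ai < a_s:
            out_a.append(a_cds[3 * ai : 3 * ai + 3])
            out_b.append("---")
            ai += 1
        while bi < b_s:
            out_a.append("---")
            out_b.append(b_cds[3 * bi : 3 * bi + 3])
            bi += 1
        for k in range(a_e - a_s):
            out_a.append(a_cds[3 * (a_s + k) : 3 * (a_s + k) + 3])
            out_b.append(b_cds[3 * (b_s + k) : 3 * (b_s + k) + 3])
        ai, bi = a_e, b_e
    while ai < len(a_prot):
        out_a.append(a_cds[3 * ai : 3 * ai + 3])
        out_b.append("---")
        ai += 1
    while bi < len(b_prot):
        out_a.append("---")
        out_b.append(b_cds[3 * bi : 3 * bi + 3])
        bi += 1
    aligned_a, aligned_b = "".join(out_a), "".join(out_b)
    return CodonAlignment(aligned_a, aligned_b, list(range(len(aligned_a) // 3)))


def filter_columns(alignment: CodonAlignment) -> CodonAlignment:
    """Retain codon columns with no gap, no ambiguous (non-ACGT) base and
    no stop codon in either sequence — the deterministic stand-in for a
    conserved-block extractor."""
    keep = []
    for i in alignment.retained_columns:
        ca, cb = alignment.column(i)
        if "-" in ca or "-" in cb:
            continue
        if any(ch not in "ACGT" for ch in ca + cb):
            continue
        if ca in STOP_CODONS or cb in STOP_CODONS:
            continue
        keep.append(i)
    return CodonAlignment(alignment.aligned_a, alignment.aligned_b, keep)


@lru_cache(maxsize=None)
def _codon_pair_differences(ca: str, cb: str) -> tuple[float, float]:
    """(synonymous, nonsynonymous) differences for one codon pair, averaged
    with equal weight over all orderings of the differing positions; any
    step into or out of a stop codon counts as nonsynonymous."""
    diff = [i for i in range(3) if ca[i] != cb[i]]
    if not diff:
        return 0.0, 0.0
    syn_total = non_total = 0
    n_paths = 0
    for path in permutations(diff):
        cur = ca
        for pos in path:
            nxt = cur[:pos] + cb[pos] + cur[pos + 1 :]
            if (
                cur not in STOP_CODONS
                and nxt not in STOP_CODONS
                and translate_codon(cur) == translate_codon(nxt)
            ):
                syn_total += 1
            else:
                non_total += 1
            cur = nxt
        n_paths += 1
    return syn_total / n_paths, non_total / n_paths


def ng86_counts(alignment: CodonAlignment) -> tuple[float, float, float, float]:
    """Nei-Gojobori site and difference counts (S, N, Sd, Nd) over the
    retained codon columns.  S + N = 3 x retained codon count."""
    pairs = alignment.retained_pairs()
    if not pairs:
        raise ValueError("empty filtered alignment")
    s_a = sum(sum(syn_fractions(ca)) for ca, _ in pairs)
    s_b = sum(sum(syn_fractions(cb)) for _, cb in pairs)
    S = 0.5 * (s_a + s_b)
    N = 3.0 * len(pairs) - S
    Sd = Nd = 0.0
    for ca, cb in pairs:
        sd, nd = _codon_pair_differences(ca, cb)
        Sd += sd
        Nd += nd
    return S, N, Sd, Nd


def jukes_cantor(p: float) -> float | None:
    """Jukes-Cantor correction d = -3/4 ln(1 - 4p/3); None when p >= 3/4
    (saturation makes the distance undefined)."""
    if not 0.0 <= p <= 1.0:
        raise ValueError(f"proportion must be in [0, 1], got {p}")
    if p >= 0.75:
        return None
    return -0.75 * math.log1p(-4.0 * p / 3.0)


@dataclass
class DivergenceEstimate:
    """NG86 + Jukes-Cantor estimate for one coding pair."""

    s_sites: float
    n_sites: float
    sd: float
    nd: float
    ps: float | None
    pn: float | None
    ds: float | None
    dn: float | None
    undefined: bool
    saturated: bool
    retained_codons: int


def estimate_ds(
    cds_a: str,
    cds_b: str,
    *,
    max_ds: float = DEFAULT_MAX_DS,
    names: tuple[str, str] = ("a", "b"),
) -> DivergenceEstimate:
    """Full pipeline for one pair: align, filter, count, correct.

    ``saturated`` is set when dS exceeds ``max_ds`` strictly (such pairs are
    excluded from density summaries); ``undefined`` when a proportion
    reaches the Jukes-Cantor domain boundary or no columns survive
    filtering."""
    aln = filter_columns(codon_align(cds_a, cds_b, names))
    if not aln.retained_columns:
        return DivergenceEstimate(0, 0, 0, 0, None, None, None, None, True, False, 0)
    S, N, Sd, Nd = ng86_counts(aln)
    ps = Sd / S if S > 0 else None
    pn = Nd / N if N > 0 else None
    ds = jukes_cantor(ps) if ps is not None else None
    dn = jukes_cantor(pn) if pn is not None else None
    undefined = ps is None or pn is None or ds is None or dn is None
    saturated = ds is not None and ds > max_ds
    return DivergenceEstimate(
        S, N, Sd, Nd, ps, pn, ds, dn, undefined, saturated, len(aln.retained_columns)
    )


def filter_saturated(ds_values, max_ds: float = DEFAULT_MAX_DS):
    """Retention mask over dS values: kept iff dS <= max_ds (strict > is
    excluded as saturated); NaN/None estimates are never retained."""
    import numpy as np

    arr = np.asarray(
        [float("nan") if v is None else float(v) for v in ds_values], dtype=float
    )
    return arr <= max_ds


def estimate_pairs(
    pairs: list,
    cds_map: dict[str, str],
    *,
    max_ds: float = DEFAULT_MAX_DS,
) -> pd.DataFrame:
    """Estimate dS for a list of :class:`~wzgenefate.homology.ParalogPair`.

    Pairs whose W member carries an internal stop or a broken frame are not
    aligned; they come back flagged (``internal_stop`` / ``frame_error``) as
    a routed pseudogene signal."""
    rows = []
    for pair in pairs:
        w, p = pair.w_gene, pair.partner
        row = {
            "w_gene": w,
            "partner": p,
            "internal_stop": False,
            "frame_error": False,
            "undefined": False,
            "saturated": False,
        }
        try:
            est = estimate_ds(cds_map[w], cds_map[p], max_ds=max_ds, names=(w, p))
        except InternalStopError:
            row["internal_stop"] = True
        except FrameError:
            row["frame_error"] = True
        else:
            row.update(
                S=est.s_sites,
                N=est.n_sites,
                Sd=est.sd,
                Nd=est.nd,
                pS=est.ps,
                pN=est.pn,
                dS=est.ds,
                dN=est.dn,
                undefined=est.undefined,
                saturated=est.saturated,
                retained_codons=est.retained_codons,
            )
        rows.append(row)
    return pd.DataFrame(rows)
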