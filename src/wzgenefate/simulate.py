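"""Synthetic ZW genomes with a recorded truth table.

The generator emulates the data a lepidopteran W-chromosome study consumes:
a multi-chromosome genome (autosomes at two copies in both sexes, Z at 2
male / 1 female, W female-limited), CDS-only gene models, W genes created by
duplication or retrotransposition from donors genome-wide with controlled
synonymous divergence, a pseudogenized fraction carrying a single premature
stop or 1-2 bp frameshift, Poisson sexed coverage tracks, and FPKM tables
with a largely silenced W.

Truth (donor, mechanism, realized dS, lesion, expression) is recorded per W
gene so every downstream classifier can be scored against known answers.

Synonymous divergence is realized mechanistically: synonymous and
nonsynonymous substitution events are drawn as Poisson counts at the target
per-site rates and applied sequentially to the coding sequence (transition:
transversion-biased target bases, stop-creating changes rejected), so
multiple hits at a site occur naturally and the recorded truth is the
realized event count per synonymous site — independent of any estimator.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .codons import CODONS, STOP_CODONS, TRANSITIONS, revcomp, syn_sites, translate, translate_codon
from .models import ChromosomeRecord, CoverageTrack, GeneModel

_NONSTOP_CODONS = [c for c in CODONS if c not in STOP_CODONS]
_STOP_LIST = sorted(STOP_CODONS)
_SEXES = ("male", "female")

# stage tags for hierarchical seeding: one global seed, independent streams
_STAGE_GENOME, _STAGE_COVERAGE, _STAGE_EXPRESSION, _STAGE_ANNOTATION = 11, 12, 13, 14


class ConfigError(ValueError):
    """Raised when a simulation configuration is infeasible or invalid."""


@dataclass
class SimulationConfig:
    """Parameters of the synthetic study.

    Coverage and replication defaults follow the emulated study design
    (five resequenced pupae per sex at ~25-fold genome coverage); genome
    shape, divergence and silencing defaults are documented artifact
    choices (see docs/methods.md).
    """

    seed: int = 0
    n_autosomes: int = 3
    chrom_length_bp: int = 100_000
    genes_per_chromosome: int = 15
    exons_per_gene_range: tuple[int, int] = (1, 6)
    cds_codons_range: tuple[int, int] = (150, 400)
    intron_length_range: tuple[int, int] = (60, 200)
    n_w_duplicates: int = 40
    retro_fraction: float = 0.42
    pseudogene_fraction: float = 0.4
    target_ds_distribution: dict = field(default_factory=lambda: {"name": "exponential", "mean": 0.4})
    transition_transversion_ratio: float = 2.0
    nonsynonymous_load: float = 0.2  # dN/dS-style ratio of applied event rates
    samples_per_sex: int = 5
    mean_depth_x: float = 25.0
    fpkm_silenced_fraction: float = 0.8
    fpkm_threshold: float = 0.5

    def __post_init__(self) -> None:
        for name in ("retro_fraction", "pseudogene_fraction", "fpkm_silenced_fraction"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ConfigError(f"{name} must be in [0, 1], got {v}")
        for name in (
            "n_autosomes",
            "chrom_length_bp",
            "genes_per_chromosome",
            "n_w_duplicates",
            "samples_per_sex",
        ):
            if getattr(self, name) <= 0:
                raise ConfigError(f"{name} must be positive")
        if self.mean_depth_x <= 0:
            raise ConfigError("mean_depth_x must be positive")
        lo, hi = self.exons_per_gene_range
        if lo < 1 or hi < lo:
            raise ConfigError(f"exons_per_gene_range must be 1 <= lo <= hi, got {self.exons_per_gene_range}")
        if self.transition_transversion_ratio <= 0:
            raise ConfigError("transition_transversion_ratio must be positive")


# ------------------------------------------------------------------ helpers

def _draw_target_ds(dist: dict, rng: np.random.Generator) -> float:
    name = dist.get("name", "exponential")
    if name == "exponential":
        return float(rng.exponential(dist["mean"]))
    if name == "constant":
        return float(dist["value"])
    if name == "uniform":
        return float(rng.uniform(dist["low"], dist["high"]))
    raise ConfigError(f"unknown target_ds_distribution {name!r}")


def _random_cds(n_codons: int, rng: np.random.Generator) -> str:
    """ATG + random non-stop codons + one stop codon."""
    body = rng.choice(len(_NONSTOP_CODONS), size=n_codons - 2)
    return "ATG" + "".join(_NONSTOP_CODONS[i] for i in body) + _STOP_LIST[rng.integers(3)]


def _random_seq(n: int, rng: np.random.Generator) -> str:
    return "".join("ACGT"[i] for i in rng.integers(0, 4, size=n))


def diverge_cds(
    body: str,
    target_ds: float,
    *,
    kappa: float = 2.0,
    omega: float = 0.2,
    rng: np.random.Generator,
) -> tuple[str, float]:
    """Apply substitution events to an in-frame, stop-free CDS body.

    Synonymous events are drawn Poisson(target_ds * S) and nonsynonymous
    events Poisson(omega * target_ds * N) where S/N are the sequence's
    synonymous/nonsynonymous site counts.  Each event mutates one base
    (transition chosen with probability kappa/(kappa+2)); stop-creating
    changes are rejected.  Returns the mutated body and the realized
    per-site synonymous divergence: applied synonymous events divided by
    the mean of the start and end synonymous site counts.
    """
    L = len(body)
    if L % 3 or not body:
        raise ConfigError("CDS body length must be a positive multiple of 3")
    s0 = syn_sites(body)
    n_syn = int(rng.poisson(target_ds * s0))
    n_non = int(rng.poisson(omega * target_ds * (L - s0)))
    kinds = np.array([1] * n_syn + [0] * n_non)
    rng.shuffle(kinds)
    seq = list(body)
    p_ts = kappa / (kappa + 2.0)
    for want_syn in kinds:
        for _ in range(100_000):
            i = int(rng.integers(L))
            old = seq[i]
            if rng.random() < p_ts:
                new = TRANSITIONS[old]
            else:
                tvs = [b for b in "ACGT" if b != old and b != TRANSITIONS[old]]
                new = tvs[int(rng.integers(2))]
            c0 = 3 * (i // 3)
            cur = "".join(seq[c0 : c0 + 3])
            alt = cur[: i - c0] + new + cur[i - c0 + 1 :]
            if alt in STOP_CODONS:
                continue
            if (translate_codon(alt) == translate_codon(cur)) == bool(want_syn):
                seq[i] = new
                break
        else:  # pragma: no cover - requires a degenerate sequence
            raise ConfigError("could not place a substitution event; sequence too constrained")
    mutated = "".join(seq)
    s_mean = 0.5 * (s0 + syn_sites(mutated))
    realized = n_syn / s_mean if s_mean > 0 else 0.0
    return mutated, realized


def inject_lesion(cds: str, rng: np.random.Generator) -> tuple[str, str, int, int]:
    """Insert exactly one pseudogenizing lesion in the interior 10-90% of the CDS.

    Returns (mutated cds, lesion type, CDS position, net length change).
    """
    n_cod = len(cds) // 3
    lo_c, hi_c = max(1, int(0.1 * n_cod)), int(0.9 * n_cod)
    if rng.random() < 0.5:
        # premature stop: single-base substitution turning a codon into a stop
        candidates = []
        for ci in range(lo_c, hi_c):
            cod = cds[3 * ci : 3 * ci + 3]
            if cod in STOP_CODONS:
                continue
            for pos in range(3):
                for b in "ACGT":
                    if b != cod[pos] and cod[:pos] + b + cod[pos + 1 :] in STOP_CODONS:
                        candidates.append((ci, pos, b))
        if candidates:
            ci, pos, b = candidates[int(rng.integers(len(candidates)))]
            i = 3 * ci + pos
            return cds[:i] + b + cds[i + 1 :], "premature_stop", i, 0
        ci = int(rng.integers(lo_c, hi_c))  # no 1-bp route: overwrite a codon
        return cds[: 3 * ci] + "TAA" + cds[3 * ci + 3 :], "premature_stop", 3 * ci, 0
    # frameshift: 1-2 bp insertion or deletion within the CDS body
    k = int(rng.integers(1, 3))
    i = int(rng.integers(int(0.1 * len(cds)), int(0.9 * len(cds)) - k))
    if rng.random() < 0.5:
        return cds[:i] + cds[i + k :], "frameshift", i, -k
    ins = _random_seq(k, rng)
    return cds[:i] + ins + cds[i:], "frameshift", i, k


# ------------------------------------------------------------------ gene construction

def _split_exons(cds_len: int, n_exons: int, rng: np.random.Generator, *, min_exon: int = 10) -> list[int]:
    """Random exon lengths summing to cds_len, each >= min_exon."""
    if cds_len < n_exons * min_exon:
        n_exons = max(1, cds_len // min_exon)
    if n_exons == 1:
        return [cds_len]
    free = cds_len - n_exons * min_exon
    cuts = np.sort(rng.integers(0, free + 1, size=n_exons - 1))
    parts = np.diff(np.concatenate(([0], cuts, [free])))
    return [int(p) + min_exon for p in parts]


def _random_intron(rng: np.random.Generator, length_range: tuple[int, int]) -> str:
    n = int(rng.integers(length_range[0], length_range[1] + 1))
    return "GT" + _random_seq(max(0, n - 4), rng) + "AG"


@dataclass
class _GeneBuild:
    """A gene laid out on its coding strand, before chromosome placement."""

    gene_id: str
    exon_lengths: list[int]  # coding-strand order
    introns: list[str]  # coding-strand order, len = exons - 1
    cds: str

    def region(self) -> str:
        parts = []
        off = 0
        for i, el in enumerate(self.exon_lengths):
            parts.append(self.cds[off : off + el])
            off += el
            if i < len(self.introns):
                parts.append(self.introns[i])
        return "".join(parts)


def _place_genes(
    builds: list[_GeneBuild],
    chrom_name: str,
    chrom_len: int,
    rng: np.random.Generator,
    *,
    min_gap: int = 50,
) -> tuple[str, list[GeneModel]]:
    """Assemble a chromosome sequence with the given genes placed without
    overlap on random strands, separated by random intergenic filler."""
    regions = [b.region() for b in builds]
    total = sum(len(r) for r in regions)
    n = len(builds)
    slack = chrom_len - total - (n + 1) * min_gap
    if slack < 0:
        raise ConfigError(
            f"genes do not fit chromosome length: {chrom_name} needs "
            f">= {total + (n + 1) * min_gap} bp but chrom_length_bp = {chrom_len}"
        )
    gaps = rng.multinomial(slack, [1.0 / (n + 1)] * (n + 1)) + min_gap
    seq_parts: list[str] = []
    genes: list[GeneModel] = []
    pos = 0
    for i, (b, region) in enumerate(zip(builds, regions)):
        filler = _random_seq(gaps[i], rng)
        seq_parts.append(filler)
        pos += len(filler)
        strand = "+" if rng.random() < 0.5 else "-"
        placed = region if strand == "+" else revcomp(region)
        seq_parts.append(placed)
        # exon coordinates on the forward strand
        exons_cs: list[tuple[int, int]] = []  # coding-strand offsets
        off = 0
        for j, el in enumerate(b.exon_lengths):
            exons_cs.append((off, off + el))
            off += el + (len(b.introns[j]) if j < len(b.introns) else 0)
        R = len(region)
        if strand == "+":
            exons = [(pos + s, pos + e) for s, e in exons_cs]
        else:
            exons = sorted((pos + R - e, pos + R - s) for s, e in exons_cs)
        genes.append(GeneModel(gene_id=b.gene_id, chrom=chrom_name, strand=strand, exons=exons))
        pos += R
    tail = chrom_len - pos
    seq_parts.append(_random_seq(tail, rng))
    return "".join(seq_parts), genes


def _new_gene_build(gene_id: str, config: SimulationConfig, rng: np.random.Generator) -> _GeneBuild:
    n_codons = int(rng.integers(config.cds_codons_range[0], config.cds_codons_range[1] + 1))
    cds = _random_cds(n_codons, rng)
    n_exons = int(rng.integers(config.exons_per_gene_range[0], config.exons_per_gene_range[1] + 1))
    exon_lengths = _split_exons(len(cds), n_exons, rng)
    introns = [_random_intron(rng, config.intron_length_range) for _ in range(len(exon_lengths) - 1)]
    return _GeneBuild(gene_id=gene_id, exon_lengths=exon_lengths, introns=introns, cds=cds)


# ------------------------------------------------------------------ simulators

def simulate_genome(
    config: SimulationConfig,
) -> tuple[list[ChromosomeRecord], list[GeneModel], pd.DataFrame]:
    """Build the synthetic genome.

    Returns (chromosomes, gene models, truth table).  Chromosomes are
    ``chr1..chrN`` (autosomes), ``Z`` and ``W``; W genes are duplicates of
    unique donors drawn from the autosomes and Z.
    """
    rng = np.random.default_rng([config.seed, _STAGE_GENOME])
    chrom_names = [f"chr{i + 1}" for i in range(config.n_autosomes)] + ["Z"]
    genome: list[ChromosomeRecord] = []
    genes: list[GeneModel] = []
    builds: dict[str, _GeneBuild] = {}
    for name in chrom_names:
        chrom_builds = [
            _new_gene_build(f"{name}_g{i + 1:03d}", config, rng)
            for i in range(config.genes_per_chromosome)
        ]
        seq, placed = _place_genes(chrom_builds, name, config.chrom_length_bp, rng)
        cls = "Z" if name == "Z" else "autosome"
        cn = {"male": 2, "female": 1} if name == "Z" else {"male": 2, "female": 2}
        genome.append(ChromosomeRecord(name=name, sequence=seq, true_class=cls, copy_number=cn))
        genes.extend(placed)
        builds.update({b.gene_id: b for b in chrom_builds})

    donors_pool = [g.gene_id for g in genes]
    if config.n_w_duplicates > len(donors_pool):
        raise ConfigError(
            f"n_w_duplicates = {config.n_w_duplicates} exceeds the "
            f"{len(donors_pool)} available donor genes"
        )
    donor_ids = list(rng.choice(donors_pool, size=config.n_w_duplicates, replace=False))

    w_builds: list[_GeneBuild] = []
    truth_rows = []
    for i, donor_id in enumerate(donor_ids):
        donor = builds[donor_id]
        w_id = f"W_g{i + 1:03d}"
        mechanism = "retrotransposition" if rng.random() < config.retro_fraction else "dna_duplication"
        target_ds = _draw_target_ds(config.target_ds_distribution, rng)
        body, stop = donor.cds[:-3], donor.cds[-3:]
        mut_body, realized_ds = diverge_cds(
            body,
            target_ds,
            kappa=config.transition_transversion_ratio,
            omega=config.nonsynonymous_load,
            rng=rng,
        )
        cds = mut_body + stop
        pseudo = rng.random() < config.pseudogene_fraction
        lesion_type, lesion_pos, delta = "none", -1, 0
        if pseudo:
            cds, lesion_type, lesion_pos, delta = inject_lesion(cds, rng)
        if mechanism == "retrotransposition":
            exon_lengths, introns = [len(cds)], []
        else:
            exon_lengths = list(donor.exon_lengths)
            introns = list(donor.introns)
            if delta:  # the frameshift indel lives inside one exon
                cum = 0
                for j, el in enumerate(exon_lengths):
                    if lesion_pos < cum + el or j == len(exon_lengths) - 1:
                        exon_lengths[j] = el + delta
                        break
                    cum += el
        w_builds.append(_GeneBuild(gene_id=w_id, exon_lengths=exon_lengths, introns=introns, cds=cds))
        expressed = (not pseudo) and rng.random() >= config.fpkm_silenced_fraction
        truth_rows.append(
            {
                "w_gene": w_id,
                "donor_gene": donor_id,
                "mechanism": mechanism,
                "target_ds": target_ds,
                "realized_ds": realized_ds,
                "pseudogene": pseudo,
                "lesion_type": lesion_type,
                "expressed": expressed,
            }
        )

    w_seq, w_genes = _place_genes(w_builds, "W", config.chrom_length_bp, rng)
    genome.append(
        ChromosomeRecord(
            name="W", sequence=w_seq, true_class="W", copy_number={"male": 0, "female": 1}
        )
    )
    genes.extend(w_genes)
    truth = pd.DataFrame(truth_rows)
    return genome, genes, truth


def simulate_coverage(
    genome: list[ChromosomeRecord],
    sex: str,
    config: SimulationConfig,
    *,
    sample_index: int = 0,
) -> list[CoverageTrack]:
    """Poisson per-base depth for one sample of the given sex.

    Depth at every base is Poisson with mean ``mean_depth_x * copy_number / 2``;
    the stream is keyed by (seed, sex, sample index) so tracks are
    reproducible independently of generation order.
    """
    if sex not in _SEXES:
        raise ValueError(f"unknown sex label {sex!r}; expected one of {_SEXES}")
    rng = np.random.default_rng([config.seed, _STAGE_COVERAGE, _SEXES.index(sex), sample_index])
    sample_id = f"{sex}_{sample_index + 1}"
    tracks = []
    for chrom in genome:
        lam = config.mean_depth_x * chrom.copy_number[sex] / 2.0
        depths = rng.poisson(lam, size=len(chrom)) if lam > 0 else np.zeros(len(chrom), dtype=np.int64)
        tracks.append(CoverageTrack(chrom=chrom.name, depths=depths, sample_id=sample_id, sex=sex))
    return tracks


def simulate_coverage_all(
    genome: list[ChromosomeRecord], config: SimulationConfig
) -> tuple[list[CoverageTrack], dict[str, str]]:
    """All samples of both sexes plus the sample->sex manifest."""
    tracks: list[CoverageTrack] = []
    manifest: dict[str, str] = {}
    for sex in _SEXES:
        for i in range(config.samples_per_sex):
            sample_tracks = simulate_coverage(genome, sex, config, sample_index=i)
            tracks.extend(sample_tracks)
            manifest[sample_tracks[0].sample_id] = sex
    return tracks, manifest


def simulate_expression(
    genes: list[GeneModel], truth: pd.DataFrame, config: SimulationConfig
) -> pd.DataFrame:
    """FPKM table (gene x condition): one ``mixed`` column and
    ``samples_per_sex`` gonad replicate columns.

    W genes flagged expressed draw FPKM strictly above the threshold in
    every condition; silenced or pseudogenized W genes draw strictly below
    it; autosomal/Z genes draw from a log-normal background.
    """
    rng = np.random.default_rng([config.seed, _STAGE_EXPRESSION])
    thr = config.fpkm_threshold
    w_truth = truth.set_index("w_gene") if len(truth) else pd.DataFrame()
    cols = ["mixed"] + [f"gonad_{i + 1}" for i in range(config.samples_per_sex)]
    rows = {}
    for g in genes:
        if g.chrom == "W":
            expressed = bool(w_truth.loc[g.gene_id, "expressed"]) if g.gene_id in w_truth.index else False
            if expressed:
                vals = thr + rng.lognormal(mean=0.5, sigma=1.0, size=len(cols))
            else:
                vals = rng.uniform(0.0, 0.9 * thr, size=len(cols))
        else:
            vals = rng.lognormal(mean=1.5, sigma=1.2, size=len(cols))
        rows[g.gene_id] = vals
    fpkm = pd.DataFrame.from_dict(rows, orient="index", columns=cols)
    fpkm.index.name = "gene_id"
    return fpkm


def simulate_annotation(
    genes: list[GeneModel],
    truth: pd.DataFrame,
    config: SimulationConfig,
    *,
    n_background_terms: int = 20,
    signal_background_rate: float = 0.05,
) -> pd.DataFrame:
    """Gene -> term map with one planted signal.

    Random background terms are scattered over all genes; one term
    ("negative regulation of DNA recombination", echoing the functions
    retained on real Ws) is attached to every expressed W gene and to
    ``signal_background_rate`` of the background, so the enrichment stage
    has a recoverable positive."""
    rng = np.random.default_rng([config.seed, _STAGE_ANNOTATION])
    categories = ["Biological", "Molecular", "Cellular"]
    terms = [
        (f"T{i + 1:03d}", f"background process {i + 1}", categories[i % 3])
        for i in range(n_background_terms)
    ]
    rows = []
    gene_ids = [g.gene_id for g in genes]
    for gid in gene_ids:
        for _ in range(int(rng.poisson(1.5))):
            tid, tname, cat = terms[int(rng.integers(len(terms)))]
            rows.append({"gene_id": gid, "term_id": tid, "term_name": tname, "category": cat})
    expressed_w = set(truth.loc[truth["expressed"], "w_gene"]) if len(truth) else set()
    for gid in gene_ids:
        if gid in expressed_w or rng.random() < signal_background_rate:
            rows.append(
                {
                    "gene_id": gid,
                    "term_id": "T_SIG",
                    "term_name": "negative regulation of DNA recombination",
                    "category": "Biological",
                }
            )
    return pd.DataFrame(rows).drop_duplicates(ignore_index=True)


# ------------------------------------------------------------------ sequence exports

def extract_sequences(
    genome: list[ChromosomeRecord], genes: list[GeneModel]
) -> tuple[dict[str, str], dict[str, str]]:
    """(CDS map, protein map) for all genes.

    Proteins are the frame-0 translation of the annotated CDS with the
    terminal stop removed and internal stops rendered as X — what a naive
    annotator would emit for a pseudogenized model."""
    chrom_seq = {c.name: c.sequence for c in genome}
    cds_map, prot_map = {}, {}
    for g in genes:
        cds = g.extract_cds(chrom_seq[g.chrom])
        cds_map[g.gene_id] = cds
        aa = translate(cds[: 3 * (len(cds) // 3)], internal_stop_as="X")
        prot_map[g.gene_id] = aa[:-1] if aa.endswith("X") and cds[-3:] in STOP_CODONS else aa
    return cds_map, prot_map
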