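"""End-to-end orchestration of the W-chromosome workflow.

Stages: (simulate) -> sexdetect -> paralogs -> ds -> fate -> enrich.
Every stage writes a flat TSV so it can be re-run and diffed in isolation;
a machine-readable summary (and, in simulation mode, a truth-comparison
table) is emitted at the end.  Any stage failure halts the run with the
stage name and cause; outputs of completed stages are left in place.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import io
from .coverage import classify_chromosomes, summarize_coverage, windowed_ratio
from .divergence import estimate_pairs
from .enrichment import enrich
from .fate import assign_symbols, classify_gene_fates, copy_number
from .homology import ParalogPair, reciprocal_best_hits
from .models import CoverageTrack, GeneModel
from .simulate import (
    SimulationConfig,
    extract_sequences,
    simulate_annotation,
    simulate_coverage_all,
    simulate_expression,
    simulate_genome,
)

logger = logging.getLogger("wzgenefate")


class StageError(RuntimeError):
    """A pipeline stage failed; carries the stage name and the cause."""

    def __init__(self, stage: str, cause: BaseException | str):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage


@dataclass
class RunConfig:
    """Declarative run configuration: either ``simulate=True`` with a
    :class:`SimulationConfig`, or paths to real inputs."""

    output_dir: str = "wzgenefate_out"
    simulate: bool = True
    sim: SimulationConfig = field(default_factory=SimulationConfig)
    # real-mode inputs
    genome_fasta: str | None = None
    gff3: str | None = None
    bedgraph_dir: str | None = None
    manifest: str | None = None
    cds_fasta: str | None = None
    protein_fasta: str | None = None
    fpkm_tsv: str | None = None
    annotation_tsv: str | None = None
    reference_protein_fasta: str | None = None
    w_chrom: str | None = None  # override the coverage-inferred W
    # thresholds
    window_bp: int = 1000
    pseudocount: float = 0.01
    fpkm_threshold: float = 0.5
    max_ds: float = 3.0
    score_floor: float = 50.0
    log_level: str = "INFO"

    def __post_init__(self) -> None:
        if self.window_bp < 1 or self.fpkm_threshold <= 0 or self.max_ds <= 0 or self.pseudocount <= 0:
            raise ValueError("thresholds must be positive")
        if not self.simulate and not (self.bedgraph_dir and self.manifest):
            raise ValueError("real-mode runs need at least bedgraph_dir and manifest (or set simulate=true)")

    @classmethod
    def from_yaml(cls, path: str) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        if "sim" in raw and isinstance(raw["sim"], dict):
            sim = dict(raw["sim"])
            for k in ("exons_per_gene_range", "cds_codons_range", "intron_length_range"):
                if k in sim:
                    sim[k] = tuple(sim[k])
            raw["sim"] = SimulationConfig(**sim)
        return cls(**raw)


def _require(condition: bool, stage: str, message: str) -> None:
    if not condition:
        raise StageError(stage, message)


def run_all(config: RunConfig) -> dict:
    """Execute the full workflow; returns the summary dictionary.

    All stage outputs land in ``config.output_dir``.
    """
    logging.basicConfig(level=config.log_level, format="%(levelname)s %(name)s: %(message)s")
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    summary: dict = {}

    # ----------------------------------------------------------- inputs
    truth: pd.DataFrame | None = None
    if config.simulate:
        stage = "simulate"
        logger.info("simulating genome (seed=%d)", config.sim.seed)
        try:
            genome, genes, truth = simulate_genome(config.sim)
            tracks, manifest = simulate_coverage_all(genome, config.sim)
            fpkm = simulate_expression(genes, truth, config.sim)
            annotation = simulate_annotation(genes, truth, config.sim)
            cds_map, prot_map = extract_sequences(genome, genes)
            io.genome_to_fasta(genome, out / "genome.fa")
            io.write_gff3(genes, out / "genes.gff3")
            io.write_manifest(manifest, out / "manifest.tsv")
            cov_dir = out / "coverage"
            cov_dir.mkdir(exist_ok=True)
            by_sample: dict[str, list[CoverageTrack]] = {}
            for t in tracks:
                by_sample.setdefault(t.sample_id, []).append(t)
            for sample_id, ts in by_sample.items():
                with open(cov_dir / f"{sample_id}.bedgraph", "w") as fh:
                    pass
                for t in ts:
                    _append_bedgraph(t, cov_dir / f"{sample_id}.bedgraph")
            io.write_fasta(cds_map, out / "cds.fa")
            io.write_fasta(prot_map, out / "proteins.fa")
            io.write_tsv(fpkm.reset_index(), out / "fpkm.tsv")
            io.write_tsv(annotation, out / "annotation.tsv")
            io.write_tsv(truth, out / "truth.tsv")
        except StageError:
            raise
        except Exception as exc:
            raise StageError(stage, exc) from exc
        gene_models = {g.gene_id: g for g in genes}
        reference_proteins = {g: s for g, s in prot_map.items() if gene_models[g].chrom != "W"}
    else:
        stage = "load-inputs"
        try:
            _require(Path(config.bedgraph_dir).is_dir(), "sexdetect", f"missing bedgraph dir {config.bedgraph_dir}")
            _require(Path(config.manifest).is_file(), "sexdetect", f"missing manifest file {config.manifest}")
            manifest = io.read_manifest(config.manifest)
            tracks = []
            for bg in sorted(Path(config.bedgraph_dir).glob("*.bedgraph")):
                sample_id = bg.stem
                tracks.extend(
                    io.read_bedgraph(bg, sample_id=sample_id, sex=manifest.get(sample_id, ""))
                )
            genes = io.read_gff3(config.gff3) if config.gff3 else []
            gene_models = {g.gene_id: g for g in genes}
            cds_map = io.read_fasta(config.cds_fasta) if config.cds_fasta else {}
            prot_map = io.read_fasta(config.protein_fasta) if config.protein_fasta else {}
            fpkm = (
                io.read_tsv(config.fpkm_tsv, index_col="gene_id") if config.fpkm_tsv else pd.DataFrame()
            )
            annotation = io.read_tsv(config.annotation_tsv) if config.annotation_tsv else pd.DataFrame()
            reference_proteins = (
                io.read_fasta(config.reference_protein_fasta)
                if config.reference_protein_fasta
                else {}
            )
        except StageError:
            raise
        except Exception as exc:
            raise StageError(stage, exc) from exc

    # ----------------------------------------------------------- sexdetect
    stage = "sexdetect"
    logger.info("summarizing coverage (%d tracks)", len(tracks))
    try:
        cov = summarize_coverage(tracks, manifest, pseudocount=config.pseudocount)
        cov["inferred_class"] = classify_chromosomes(cov)
        windows = windowed_ratio(tracks, manifest, config.window_bp, config.pseudocount)
        io.write_tsv(cov.reset_index(), out / "coverage_summary.tsv")
        io.write_tsv(windows, out / "windows.tsv")
    except StageError:
        raise
    except Exception as exc:
        raise StageError(stage, exc) from exc
    inferred_w = list(cov.index[cov["inferred_class"] == "W"])
    w_chrom = config.w_chrom or (inferred_w[0] if len(inferred_w) == 1 else None)
    summary["chromosomes"] = {c: cov.loc[c, "inferred_class"] for c in cov.index}
    summary["w_chrom"] = w_chrom

    # ----------------------------------------------------------- paralogs
    stage = "paralogs"
    _require(w_chrom is not None, stage, "no single W chromosome inferred; set w_chrom explicitly")
    gene_chrom = {g.gene_id: g.chrom for g in gene_models.values()}
    w_prot = {g: s for g, s in prot_map.items() if gene_chrom.get(g) == w_chrom}
    other_prot = {g: s for g, s in prot_map.items() if gene_chrom.get(g) != w_chrom}
    logger.info("reciprocal best hits: %d W proteins vs %d others", len(w_prot), len(other_prot))
    try:
        pairs = reciprocal_best_hits(w_prot, other_prot, gene_chrom, score_floor=config.score_floor)
        pair_df = pd.DataFrame(
            [
                {
                    "w_gene": p.w_gene,
                    "partner": p.partner,
                    "partner_chrom": p.partner_chrom,
                    "score": p.score,
                    "identity": p.identity,
                    "bin": p.bin,
                }
                for p in pairs
            ],
            columns=["w_gene", "partner", "partner_chrom", "score", "identity", "bin"],
        )
        io.write_tsv(pair_df, out / "rbh_pairs.tsv")
    except StageError:
        raise
    except Exception as exc:
        raise StageError(stage, exc) from exc
    summary["n_w_genes"] = len(w_prot)
    summary["n_rbh_pairs"] = len(pairs)

    # ----------------------------------------------------------- ds
    stage = "ds"
    logger.info("estimating dS for %d pairs", len(pairs))
    try:
        ds = estimate_pairs(pairs, cds_map, max_ds=config.max_ds)
        io.write_tsv(ds, out / "ds_estimates.tsv")
        if len(ds) and "dS" in ds.columns:
            retained = ds[~ds["saturated"] & ~ds["undefined"] & ds["dS"].notna()]
        else:
            retained = ds.iloc[0:0]
        # along-chromosome dS track for Fig-5B-style plots
        if len(retained):
            pos = {g.gene_id: (g.start + g.end) // 2 for g in gene_models.values()}
            track = retained.assign(position=[pos.get(w, -1) for w in retained["w_gene"]])
            io.write_tsv(track[["w_gene", "position", "dS"]], out / "ds_track.tsv")
    except StageError:
        raise
    except Exception as exc:
        raise StageError(stage, exc) from exc
    summary["n_ds_retained"] = int(len(retained))
    summary["n_ds_saturated"] = int(ds["saturated"].fillna(False).sum()) if len(ds) else 0

    # ----------------------------------------------------------- fate
    stage = "fate"
    logger.info("classifying gene fates")
    try:
        w_genes = [g for g in gene_models.values() if g.chrom == w_chrom]
        symbol_of = None
        counts = None
        if reference_proteins:
            symbol_of = assign_symbols(prot_map, reference_proteins, score_floor=config.score_floor)
            counts = copy_number(symbol_of, gene_chrom, pairs, w_chrom=w_chrom)
            io.write_tsv(counts, out / "copy_number.tsv")
        fate = classify_gene_fates(
            sorted(w_genes, key=lambda g: g.gene_id),
            gene_models,
            pairs,
            cds_map,
            prot_map,
            fpkm,
            fpkm_threshold=config.fpkm_threshold,
            copy_counts=counts,
            symbol_of=symbol_of,
        )
        io.write_tsv(fate, out / "gene_fate.tsv")
    except StageError:
        raise
    except Exception as exc:
        raise StageError(stage, exc) from exc
    summary["n_pseudogenes"] = int(fate["pseudogene"].fillna(False).astype(bool).sum())
    summary["n_retro_candidates"] = int((fate["retrocopy_call"] == "retro_candidate").sum())
    summary["n_expressed_mixed"] = int(fate["expressed_mixed"].sum())
    summary["n_expressed_gonad"] = int(fate["expressed_gonad"].sum())

    # ----------------------------------------------------------- enrich
    stage = "enrich"
    logger.info("term enrichment among expressed W genes")
    try:
        expressed = set(fate.loc[fate["expressed_mixed"], "gene_id"])
        background = set(gene_models)
        if len(annotation) and expressed:
            result = enrich(expressed, annotation, background)
        else:
            result = pd.DataFrame(columns=["term_id", "set_hits", "bg_hits", "p_value", "fdr"])
        io.write_tsv(result, out / "enrichment.tsv")
    except StageError:
        raise
    except Exception as exc:
        raise StageError(stage, exc) from exc
    summary["n_enriched_terms"] = int((result["fdr"] < 0.05).sum()) if len(result) else 0

    # ----------------------------------------------------------- truth comparison
    if truth is not None:
        comparison = _truth_comparison(truth, cov, pairs, fate, gene_models)
        io.write_tsv(comparison, out / "truth_comparison.tsv")
        summary["truth_comparison"] = {
            f"{r.classifier}:{r.outcome}": int(r.count) for r in comparison.itertuples()
        }

    with open(out / "summary.json", "w") as fh:
        json.dump(summary, fh, indent=2, sort_keys=True, default=str)
    logger.info("done: %s", out / "summary.json")
    return summary


def _append_bedgraph(track: CoverageTrack, path: Path) -> None:
    import numpy as np

    d = np.asarray(track.depths)
    change = np.flatnonzero(np.diff(d)) + 1
    starts = np.concatenate(([0], change))
    ends = np.concatenate((change, [len(d)]))
    with open(path, "a") as fh:
        for s, e in zip(starts, ends):
            fh.write(f"{track.chrom}\t{s}\t{e}\t{int(d[s])}\n")


def _truth_comparison(
    truth: pd.DataFrame,
    cov: pd.DataFrame,
    pairs: list[ParalogPair],
    fate: pd.DataFrame,
    gene_models: dict[str, GeneModel],
) -> pd.DataFrame:
    """Confusion counts of every classifier against the simulation truth."""
    rows = []

    def add(classifier: str, outcome: str, count: int) -> None:
        rows.append({"classifier": classifier, "outcome": outcome, "count": count})

    true_class = {"Z": "Z", "W": "W"}
    for chrom in cov.index:
        t = true_class.get(chrom, "autosome")
        add("chromosome", f"{t}->{cov.loc[chrom, 'inferred_class']}", 1)

    partner_of = {p.w_gene: p.partner for p in pairs}
    tt = truth.set_index("w_gene")
    informative = tt[~tt["pseudogene"]]
    correct = sum(1 for w in informative.index if partner_of.get(w) == informative.loc[w, "donor_gene"])
    add("rbh_donor", "correct", correct)
    add("rbh_donor", "total", len(informative))

    f = fate.set_index("gene_id")
    scored = [w for w in tt.index if w in f.index and f.loc[w, "partner"] is not None and pd.notna(f.loc[w, "pseudogene"])]
    for w in scored:
        t = "pseudo" if tt.loc[w, "pseudogene"] else "intact"
        p = "pseudo" if bool(f.loc[w, "pseudogene"]) else "intact"
        add("pseudogene", f"{t}->{p}", 1)

    for w in scored:
        mech = tt.loc[w, "mechanism"]
        donor = tt.loc[w, "donor_gene"]
        if gene_models[donor].intron_count == 0:
            continue
        call = f.loc[w, "retrocopy_call"]
        short = {"retrotransposition": "retro", "dna_duplication": "dna"}[mech]
        add("retrocopy", f"{short}->{call}", 1)

    for w in tt.index:
        if w not in f.index:
            continue
        t = "expressed" if tt.loc[w, "expressed"] else "silent"
        p = "expressed" if bool(f.loc[w, "expressed_mixed"]) else "silent"
        add("expression", f"{t}->{p}", 1)

    agg = (
        pd.DataFrame(rows)
        .groupby(["classifier", "outcome"], as_index=False)["count"]
        .sum()
        .sort_values(["classifier", "outcome"], ignore_index=True)
    )
    return agg
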