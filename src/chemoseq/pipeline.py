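"""End-to-end pipeline: simulate (or load) -> trim -> map -> count -> call.

The pipeline runs either on a simulated design (in which case recovery
metrics against the ground truth are produced) or on user-supplied FASTA /
annotation / FASTQ inputs. Every stage's parameters are echoed into the log
and all numeric outputs are deterministic given the master seed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

from chemoseq import comparative, io
from chemoseq.enhance import SignificancePolicy, run_comparison, volcano_table
from chemoseq.mapping import TrimSpec, build_index, map_library, trim_library
from chemoseq.quantify import (
    CountTable,
    rpkm_table,
    summarize_expression,
    weight_counts,
)
from chemoseq.simulate import (
    BODY_OF,
    SimulationConfig,
    build_transcriptome,
    simulate_expression,
    simulate_reads,
)

logger = logging.getLogger(__name__)

DEFAULT_COMPARISONS = (("FA", "FB"), ("FP", "FB"), ("MA", "MB"), ("MP", "MB"))


@dataclass
class PipelineConfig:
    """Full-run configuration.

    Exactly one of ``simulation`` or (``transcriptome_path``,
    ``annotation_path``, ``fastq_paths``) must be provided.
    """

    simulation: SimulationConfig | None = None
    transcriptome_path: str | None = None
    annotation_path: str | None = None
    fastq_paths: dict[str, str] = field(default_factory=dict)
    trim: TrimSpec = field(default_factory=TrimSpec)
    max_mismatches: int = 3
    seed_length: int = 6
    best_stratum: bool = False
    weighting: str = "equal"
    policy: SignificancePolicy = field(default_factory=SignificancePolicy)
    n_tests: int | None = None  # default: annotation size
    comparisons: tuple[tuple[str, str], ...] = DEFAULT_COMPARISONS
    seed: int = 0

    def validate(self) -> None:
        simulated = self.simulation is not None
        external = bool(self.fastq_paths)
        if simulated == external:
            raise ValueError("provide either a simulation block or input paths")
        if external and (not self.transcriptome_path or not self.annotation_path):
            raise ValueError("external runs need transcriptome and annotation paths")
        if external:
            paths = [self.transcriptome_path, self.annotation_path,
                     *self.fastq_paths.values()]
            if len(set(paths)) != len(paths):
                raise ValueError("input paths must be distinct")
        declared = (
            set(self.simulation.samples) if simulated else set(self.fastq_paths)
        )
        for s1, s2 in self.comparisons:
            if s1 not in declared or s2 not in declared:
                raise ValueError(f"comparison ({s1}, {s2}) references undeclared sample")
        if self.weighting not in ("equal", "rescue"):
            raise ValueError(f"unknown weighting scheme {self.weighting!r}")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        data = io.load_yaml(path)
        sim = data.get("simulate")
        sim_cfg = None
        if sim is not None:
            if "samples" in sim:
                sim["samples"] = tuple(sim["samples"])
            if "transcript_length_range" in sim:
                sim["transcript_length_range"] = tuple(sim["transcript_length_range"])
            if "base_expression" in sim:
                sim["base_expression"] = tuple(sim["base_expression"])
            if "enhanced_design" in sim:
                sim["enhanced_design"] = {
                    s: {int(k): float(v) for k, v in d.items()}
                    for s, d in sim["enhanced_design"].items()
                }
            sim_cfg = SimulationConfig(**sim)
        trim = TrimSpec(**data.get("trim", {}))
        policy = SignificancePolicy(**data.get("policy", {}))
        inputs = data.get("inputs", {})
        comparisons = tuple(
            tuple(pair) for pair in data.get("comparisons", DEFAULT_COMPARISONS)
        )
        cfg = cls(
            simulation=sim_cfg,
            transcriptome_path=inputs.get("transcriptome"),
            annotation_path=inputs.get("annotation"),
            fastq_paths=dict(inputs.get("fastq", {})),
            trim=trim,
            max_mismatches=int(data.get("max_mismatches", 3)),
            seed_length=int(data.get("seed_length", 6)),
            best_stratum=bool(data.get("best_stratum", False)),
            weighting=data.get("weighting", "equal"),
            policy=policy,
            n_tests=data.get("n_tests"),
            comparisons=comparisons,
            seed=int(data.get("seed", 0)),
        )
        if sim_cfg is not None and "seed" not in (sim or {}):
            sim_cfg.seed = cfg.seed
        cfg.validate()
        return cfg


def run_pipeline(config: PipelineConfig, outdir: str | Path) -> dict:
    """Execute every stage and write the output bundle under ``outdir``.

    Returns a dict with the in-memory objects: annotation, counts, expr,
    mapping summaries, per-comparison records/summaries, enhanced sets,
    pfam tally, venn results and (for simulated runs) recovery metrics.
    """
    config.validate()
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    logger.info("pipeline parameters: %s", asdict(config))

    truth = None
    if config.simulation is not None:
        sim = config.simulation
        transcriptome, annotation = build_transcriptome(sim)
        truth = simulate_expression(sim)
        io.write_fasta(transcriptome, outdir / "transcriptome.fasta")
        io.write_annotation(annotation, outdir / "annotation.tsv")
        io.write_truth(truth.abundance, outdir / "truth_abundance.tsv",
                       "relative abundance per sample (columns sum to 1)")
        io.write_truth(truth.enhanced_labels, outdir / "truth_labels.tsv",
                       "designed enhancement label per comparison")
        isoforms = list(transcriptome.isoforms())
        libraries = {}
        for sample in sim.samples:
            reads = simulate_reads(truth, transcriptome, sim, sample)
            io.write_fastq(reads, outdir / f"{sample}.fastq")
            libraries[sample] = [(r.read_id, r.seq) for r in reads]
    else:
        isoforms = io.read_transcriptome_fasta(config.transcriptome_path)
        annotation = io.read_annotation(config.annotation_path)
        libraries = {}
        for sample, path in config.fastq_paths.items():
            if not Path(path).exists():
                raise FileNotFoundError(f"FASTQ for sample {sample} not found: {path}")
            libraries[sample] = list(io.read_fastq(path))

    index = build_index(isoforms, seed_length=config.seed_length)
    gene_ids = list(annotation.index)

    columns = {}
    summaries = {}
    for sample, reads in libraries.items():
        trimmed, n_short = trim_library(reads, config.trim)
        hitsets, summary = map_library(
            trimmed, index, config.max_mismatches, config.best_stratum
        )
        columns[sample] = weight_counts(hitsets, gene_ids, config.weighting)
        summaries[sample] = {
            "reads": summary.n_reads + n_short,
            "too_short": n_short,
            "mapped": summary.n_mapped,
            "fraction_mapped": summary.fraction_mapped,
        }
    counts = CountTable.from_columns(columns)
    expr = rpkm_table(counts, annotation["length"])
    io.write_mapping_summary(summaries, outdir / "mapping_summary.tsv")
    io.write_counts_table(counts, expr, annotation, outdir / "expression_table.tsv")

    expr_summaries = {s: summarize_expression(expr, counts, s) for s in counts.samples}
    io.write_json(expr_summaries, outdir / "expression_summary.json")

    n_tests = config.n_tests if config.n_tests is not None else len(gene_ids)
    policy = SignificancePolicy(
        alpha=config.policy.alpha,
        n_tests=n_tests,
        fold_threshold=config.policy.fold_threshold,
        pseudo_rpkm=config.policy.pseudo_rpkm,
    )

    comparisons = {}
    comp_summaries = {}
    enhanced_sets: dict[str, set[str]] = {}
    for s1, s2 in config.comparisons:
        records, summary = run_comparison(counts, expr, s1, s2, policy)
        name = f"{s1}_vs_{s2}"
        comparisons[name] = records
        comp_summaries[name] = summary
        io._write_tsv(records, outdir / f"comparison_{name}.tsv",
                      ["per-gene enhancement records; p two-sided Fisher exact"])
        volcano = volcano_table(records, annotation["family"])
        io._write_tsv(volcano, outdir / f"volcano_{name}.tsv",
                      [f"volcano table; -log10 p capped at {volcano.attrs['neg_log10_cap']}"])
        enhanced_sets[f"{s1}-enhanced"] = set(records.index[records["call"] == s1])
    io.write_json(comp_summaries, outdir / "comparison_summary.json")

    tally = comparative.pfam_tally(enhanced_sets, annotation)
    io._write_tsv(tally, outdir / "pfam_tally.tsv",
                  ["per-PfamA enhancement tally, ranked by total enhanced count"])

    venn_results = {}
    labels = list(enhanced_sets)
    for i in range(len(labels)):
        for j in range(i + 1, len(labels)):
            v = comparative.venn(enhanced_sets[labels[i]], enhanced_sets[labels[j]])
            venn_results[f"{labels[i]}|{labels[j]}"] = {
                "a_only": v.a_only,
                "shared": v.shared,
                "b_only": v.b_only,
                "pct_shared_of_a": v.pct_shared_of_a,
                "pct_shared_of_b": v.pct_shared_of_b,
            }
    io.write_json(venn_results, outdir / "venn.json")

    recovery = {}
    if truth is not None:
        for name, records in comparisons.items():
            if name in truth.enhanced_labels.columns:
                m = comparative.recovery_metrics(records, truth, name)
                recovery[name] = {
                    "sensitivity": m.sensitivity,
                    "false_discovery_proportion": m.false_discovery_proportion,
                    "direction_errors": m.direction_errors,
                    "n_true": m.n_true,
                    "n_called": m.n_called,
                }
        io.write_json(recovery, outdir / "recovery.json")

    return {
        "annotation": annotation,
        "counts": counts,
        "expr": expr,
        "mapping_summaries": summaries,
        "expression_summaries": expr_summaries,
        "comparisons": comparisons,
        "comparison_summaries": comp_summaries,
        "enhanced_sets": enhanced_sets,
        "pfam_tally": tally,
        "venn": venn_results,
        "recovery": recovery,
        "truth": truth,
    }
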