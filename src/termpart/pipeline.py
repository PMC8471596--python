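"""End-to-end pipeline orchestration with config validation and a
checksummed run report.

A run executes, in dependency order: data simulation (or loading of
user-supplied inputs), annotation feature statistics, expression
ranking, terminator-candidate selection, and plate-screen analytics.
Every output file is listed in the report with its SHA-256 checksum and
all effective parameters are echoed, so a rerun with the same config and
seed is byte-identical and auditable.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import pandas as pd
import yaml

from termpart import presets
from termpart.annotation_features import (
    feature_lengths,
    intergenic_distances,
    length_histogram,
    parse_gff3,
    summarize_lengths,
)
from termpart.expression_rank import load_fpkm, rank_expression
from termpart.part_engineering import SelectionConfig, select_candidates
from termpart.screen_stats import (
    bubble_summary,
    compare_constructs,
    counts_from_frame,
    records_from_frame,
    stability_curve,
    summarize_screen,
)
from termpart.synthetic_data import (
    FpkmGenConfig,
    GenomeGenConfig,
    gen_fpkm,
    gen_genome,
    gen_screen,
)

logger = logging.getLogger("termpart")

__all__ = ["RunConfig", "RunReport", "run_pipeline", "load_config", "sha256_file"]


@dataclass
class RunConfig:
    """Validated configuration for one pipeline run."""

    out_dir: Path
    stages: list[str] = field(
        default_factory=lambda: ["simulate", "features", "rank", "select", "screen"]
    )
    seed: int = 0
    preset: str | None = "paper"
    gff3: Path | None = None  # user inputs override simulation
    genome_fasta: Path | None = None
    fpkm: Path | None = None
    plates: Path | None = None
    colonies: Path | None = None
    max_rank: int = 350
    rank_exceptions: list[str] = field(default_factory=list)
    max_len: int = 1000
    binsize: int = 100
    baseline: str = "RBCS2"
    alpha: float = 0.05
    n_genes: int = 30
    params: dict[str, Any] = field(default_factory=dict)

    def validate(self) -> list[str]:
        problems = []
        if not 0 < self.alpha < 1:
            problems.append(f"alpha must be in (0, 1), got {self.alpha}")
        if self.binsize <= 0:
            problems.append(f"binsize must be positive, got {self.binsize}")
        if self.max_len <= 0:
            problems.append(f"max_len must be positive, got {self.max_len}")
        known = {"simulate", "features", "rank", "select", "screen"}
        for s in self.stages:
            if s not in known:
                problems.append(f"unknown stage {s!r}")
        for name in ("gff3", "genome_fasta", "fpkm", "plates", "colonies"):
            p = getattr(self, name)
            if p is not None and not Path(p).exists():
                problems.append(f"{name} input does not exist: {p}")
        if "simulate" not in self.stages:
            if "features" in self.stages and self.gff3 is None:
                problems.append("features stage needs a gff3 input or the simulate stage")
            if "rank" in self.stages and self.fpkm is None:
                problems.append("rank stage needs an fpkm input or the simulate stage")
            if "screen" in self.stages and self.plates is None:
                problems.append("screen stage needs a plates input or the simulate stage")
        return problems


class ConfigError(ValueError):
    """Raised when a run config fails validation; message lists every problem."""


def load_config(path: str | Path) -> RunConfig:
    raw = yaml.safe_load(Path(path).read_text()) or {}
    for key in ("out_dir", "gff3", "genome_fasta", "fpkm", "plates", "colonies"):
        if raw.get(key) is not None:
            raw[key] = Path(raw[key])
    return RunConfig(**raw)


@dataclass
class RunReport:
    config_echo: dict
    stages: dict[str, str]
    outputs: dict[str, str]  # path -> sha256
    headline: dict

    def write(self, path: Path) -> None:
        path.write_text(
            json.dumps(
                {
                    "config": self.config_echo,
                    "stages": self.stages,
                    "outputs": self.outputs,
                    "headline": self.headline,
                },
                indent=2,
                default=str,
            )
        )


def sha256_file(path: Path) -> str:
    h = hashlib.sha256()
    h.update(Path(path).read_bytes())
    return h.hexdigest()


def run_pipeline(cfg: RunConfig) -> RunReport:
    """Execute the configured stages; raises :class:`ConfigError` listing
    every validation problem before touching the filesystem."""
    problems = cfg.validate()
    if problems:
        raise ConfigError("; ".join(problems))
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    outputs: dict[str, str] = {}
    stage_status: dict[str, str] = {}
    headline: dict[str, Any] = {}

    def record(path: Path) -> None:
        outputs[str(path)] = sha256_file(path)

    gff3_path, fasta_path, fpkm_path = cfg.gff3, cfg.genome_fasta, cfg.fpkm
    plates_path, colonies_path = cfg.plates, cfg.colonies

    if "simulate" in cfg.stages:
        logger.info("simulating inputs (seed=%d)", cfg.seed)
        sim_dir = out / "simulated"
        genome = gen_genome(GenomeGenConfig(n_genes=cfg.n_genes, seed=cfg.seed))
        f, g, t = genome.write(sim_dir)
        fasta_path = fasta_path or f
        gff3_path = gff3_path or g
        record(f), record(g), record(t)
        fpkm = gen_fpkm(FpkmGenConfig(n_genes=cfg.n_genes, seed=cfg.seed + 1))
        # reuse the genome's gene ids so ranking joins onto the annotation
        fpkm.matrix.index = genome.truth["gene_id"].tolist()[: len(fpkm.matrix)] + [
            f"x{i}" for i in range(len(fpkm.matrix) - len(genome.truth))
        ]
        fpkm.matrix.index.name = "gene_id"
        mp, tp = fpkm.write(sim_dir)
        fpkm_path = fpkm_path or mp
        record(mp), record(tp)
        screen = gen_screen(presets.paper_screen_config(seed=cfg.seed + 2))
        pp, cp = screen.write(sim_dir)
        plates_path = plates_path or pp
        colonies_path = colonies_path or cp
        record(pp), record(cp), record(sim_dir / "screen_truth.json")
        stage_status["simulate"] = "ok"

    models = None
    if "features" in cfg.stages:
        logger.info("computing annotation feature statistics")
        models = parse_gff3(gff3_path)
        fl = feature_lengths(models, "utr3")
        lengths = [l for _, l in fl.lengths]
        table = pd.DataFrame(fl.lengths, columns=["gene_id", "utr3_length"])
        from termpart.annotation_features import classify_length

        table["size_class"] = table["utr3_length"].map(classify_length)
        fpath = out / "utr3_lengths.tsv"
        table.to_csv(fpath, sep="\t", index=False)
        record(fpath)
        hist = length_histogram(lengths, cfg.binsize)
        hpath = out / "utr3_histogram.tsv"
        pd.DataFrame(hist.to_rows(), columns=["bin_lo", "bin_hi", "count"]).to_csv(
            hpath, sep="\t", index=False
        )
        record(hpath)
        summary = summarize_lengths(lengths, thresholds=(cfg.max_len,))
        dists = [d.distance for d in intergenic_distances(models)]
        headline["utr3_median_bp"] = summary.median
        headline["utr3_n_genes"] = summary.n
        headline["class_counts"] = table["size_class"].value_counts().to_dict()
        if dists:
            headline["intergenic_median_bp"] = summarize_lengths(
                [max(d, 0) for d in dists]
            ).median
        stage_status["features"] = "ok"

    rank_table = None
    if "rank" in cfg.stages:
        logger.info("ranking expression")
        matrix = load_fpkm(fpkm_path)
        rank_table = rank_expression(matrix)
        rpath = out / "rank_table.tsv"
        rank_table.to_csv(rpath, sep="\t", index_label="gene_id")
        record(rpath)
        stage_status["rank"] = "ok"

    if "select" in cfg.stages:
        if models is None or rank_table is None:
            stage_status["select"] = "skipped: needs features and rank stages"
        else:
            logger.info("selecting terminator candidates")
            import pyfaidx

            fa = pyfaidx.Fasta(str(fasta_path))
            genome_map = {name: str(fa[name][:]) for name in fa.keys()}
            parts = select_candidates(
                models,
                genome_map,
                rank_table,
                SelectionConfig(
                    max_rank=cfg.max_rank,
                    exceptions=frozenset(cfg.rank_exceptions),
                    max_len=cfg.max_len,
                ),
            )
            ppath = out / "candidates.tsv"
            pd.DataFrame(
                [
                    {
                        "name": p.name,
                        "source_gene": p.source_gene,
                        "length": p.length,
                        "size_class": p.size_class,
                        "rank": p.rank,
                        "motif_positions": ",".join(map(str, p.motif_hits)),
                    }
                    for p in parts
                ]
            ).to_csv(ppath, sep="\t", index=False)
            record(ppath)
            fasta_out = out / "candidates.fasta"
            with open(fasta_out, "w") as fh:
                for p in parts:
                    fh.write(f">{p.name}\n{p.sequence}\n")
            record(fasta_out)
            headline["n_candidates"] = len(parts)
            stage_status["select"] = "ok"

    if "screen" in cfg.stages:
        logger.info("analysing plate screen")
        records = records_from_frame(pd.read_csv(plates_path, sep="\t"))
        counts = (
            counts_from_frame(pd.read_csv(colonies_path, sep="\t"))
            if colonies_path
            else []
        )
        summaries = summarize_screen(records, counts)
        spath = out / "screen_summary.tsv"
        bubble = bubble_summary(summaries)
        bubble.to_csv(spath, sep="\t", index=False)
        record(spath)
        per_exp: dict[str, list[float]] = {}
        for s in summaries:
            group = [r for r in records if (r.construct, r.strain) == (s.construct, s.strain)]
            by_exp: dict[str, list] = {}
            for r in group:
                by_exp.setdefault(r.experiment_id, []).append(r)
            per_exp[s.construct] = [
                stability_curve(v)[-1] for _, v in sorted(by_exp.items())
            ]
        if cfg.baseline in per_exp:
            tests = compare_constructs(per_exp, cfg.baseline, alpha=cfg.alpha)
            tpath = out / "screen_tests.tsv"
            pd.DataFrame(
                [
                    {
                        "construct": t.group_x,
                        "baseline": t.group_y,
                        "U": t.U,
                        "p_two_tailed": t.p_two_tailed,
                        "method": t.method,
                        "significant": t.significant,
                    }
                    for t in tests
                ]
            ).to_csv(tpath, sep="\t", index=False)
            record(tpath)
        headline["screen"] = {
            s.construct: {
                "pct_viable_final": round(s.pct_viable_final, 2),
                "pct_gfp_positive": (
                    round(s.pct_gfp_positive, 2) if s.pct_gfp_positive is not None else None
                ),
                "efficiency_mean": s.efficiency_mean,
            }
            for s in summaries
        }
        stage_status["screen"] = "ok"

    report = RunReport(
        config_echo={
            k: str(v) if isinstance(v, Path) else v for k, v in vars(cfg).items()
        },
        stages=stage_status,
        outputs=outputs,
        headline=headline,
    )
    report.write(out / "run_report.json")
    return report
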