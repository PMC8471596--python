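"""Synthetic genomes, FPKM matrices and plate-screen datasets.

Every generator returns both the files the analysis readers consume
(GFF3/FASTA/TSV text) and a ground-truth table, so downstream modules
can be validated by round-trip recovery.  Generation is deterministic:
one named NumPy generator per run, seeded from the config.

The genome generator plants genes with controlled 3'UTR length
mixtures (targeting the short/<100, medium/100-600 and long/>600 bp
classes observed in the *C. reinhardtii* annotation) and places a TGTAA
polyadenylation motif near the 3' end of each UTR.  The screen
generator draws colony counts from a Poisson law and line viability
from per-round Bernoulli survival, monotone by construction, with GFP
calls only for final-round survivors.
"""

from __future__ import annotations

from dataclasses import dataclass, field as dc_field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "GenomeGenConfig",
    "FpkmGenConfig",
    "ScreenGenConfig",
    "ConstructParams",
    "SyntheticGenome",
    "SyntheticFpkm",
    "SyntheticScreen",
    "gen_genome",
    "gen_fpkm",
    "gen_screen",
]

_MOTIF = "TGTAA"
_REV_MOTIF = "TTACA"


@dataclass
class GenomeGenConfig:
    """Parameters for the synthetic genome/annotation generator.

    ``utr3_class_weights`` are the (short, medium, long) mixture weights
    for planted 3'UTR lengths; the defaults follow the class proportions
    of the real annotation (~686 : ~7,407 : ~11,000 genes).
    ``motif_prob`` is the probability a 3'UTR carries a planted TGTAA,
    placed so that the motif ends 10-20 nt upstream of the cleavage
    point (the annotated UTR end).
    """

    n_genes: int = 30
    chrom_sizes: Mapping[str, int] = dc_field(
        default_factory=lambda: {"chr_1": 300_000}
    )
    utr3_class_weights: tuple[float, float, float] = (0.036, 0.388, 0.576)
    utr3_length_ranges: tuple[tuple[int, int], ...] = ((30, 99), (100, 600), (601, 2500))
    utr3_lengths: Sequence[int] | None = None  # explicit lengths override the mixture
    motif_prob: float = 0.9
    gap_mean_log: float = 8.0  # lognormal intergenic gaps, median exp(8) ~ 2981 bp
    gap_sigma_log: float = 0.5
    gc_content: float = 0.64
    seed: int = 0

    def __post_init__(self) -> None:
        if abs(sum(self.utr3_class_weights) - 1.0) > 1e-9:
            raise ValueError("utr3_class_weights must sum to 1")
        if not 0.0 <= self.motif_prob <= 1.0:
            raise ValueError("motif_prob must be in [0, 1]")


@dataclass
class SyntheticGenome:
    fasta: dict[str, str]
    gff3_text: str
    truth: pd.DataFrame  # gene_id, chrom, strand, utr3_length, size_class, motif_offset

    def write(self, out_dir: str | Path) -> tuple[Path, Path, Path]:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        fasta_path = out / "genome.fasta"
        with open(fasta_path, "w") as fh:
            for chrom, seq in self.fasta.items():
                fh.write(f">{chrom}\n")
                for i in range(0, len(seq), 80):
                    fh.write(seq[i : i + 80] + "\n")
        gff_path = out / "genome.gff3"
        gff_path.write_text(self.gff3_text)
        truth_path = out / "genome_truth.tsv"
        self.truth.to_csv(truth_path, sep="\t", index=False)
        return fasta_path, gff_path, truth_path


def _random_dna(rng: np.random.Generator, n: int, gc: float) -> np.ndarray:
    probs = [(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2]
    return rng.choice(np.frombuffer(b"ACGT", dtype="S1"), size=n, p=probs)


def gen_genome(cfg: GenomeGenConfig) -> SyntheticGenome:
    """Generate a FASTA + GFF3 pair with known 3'UTR lengths and motifs.

    Genes are laid left to right per chromosome with lognormal
    intergenic gaps; each gene is 5'UTR + CDS + 3'UTR (single interval
    per feature).  Minus-strand genes are placed reverse-complemented so
    the annotated 3'UTR reads sense after strand-aware extraction.
    Raises when the requested genes do not fit the chromosome sizes.
    """
    rng = np.random.default_rng(cfg.seed)
    chroms = {c: bytearray() for c in cfg.chrom_sizes}
    gff_lines = ["##gff-version 3"]
    truth_rows = []

    if cfg.utr3_lengths is not None:
        utr3_lengths = list(cfg.utr3_lengths)
        if len(utr3_lengths) != cfg.n_genes:
            raise ValueError("utr3_lengths must have n_genes entries")
    else:
        comps = rng.choice(3, size=cfg.n_genes, p=cfg.utr3_class_weights)
        utr3_lengths = [
            int(rng.integers(*cfg.utr3_length_ranges[c])) for c in comps
        ]

    chrom_names = list(cfg.chrom_sizes)
    per_chrom = np.array_split(np.arange(cfg.n_genes), len(chrom_names))
    gene_idx = 0
    for chrom, idxs in zip(chrom_names, per_chrom):
        pos = 0  # 0-based cursor on the chromosome being built
        buf = chroms[chrom]
        for _ in idxs:
            gap = int(np.exp(rng.normal(cfg.gap_mean_log, cfg.gap_sigma_log)))
            gap = max(gap, 50)
            buf.extend(_random_dna(rng, gap, cfg.gc_content).tobytes())
            pos += gap

            utr5_len = int(rng.integers(50, 301))
            cds_len = int(rng.integers(100, 501)) * 3
            utr3_len = utr3_lengths[gene_idx]
            strand = "+" if rng.random() < 0.5 else "-"
            gene_id = f"g{gene_idx + 1:04d}"

            # build the gene in transcript orientation, plant the motif
            gene_seq = bytearray(
                _random_dna(rng, utr5_len + cds_len + utr3_len, cfg.gc_content).tobytes()
            )
            motif_offset = None  # 0-based offset within the 3'UTR (sense)
            if rng.random() < cfg.motif_prob and utr3_len >= 25:
                upstream = int(rng.integers(10, 21))  # motif end 10-20 nt before UTR end
                motif_offset = utr3_len - upstream - len(_MOTIF)
                start = utr5_len + cds_len + motif_offset
                gene_seq[start : start + len(_MOTIF)] = _MOTIF.encode()
            gene_len = len(gene_seq)
            placed = gene_seq if strand == "+" else _revcomp_bytes(gene_seq)
            buf.extend(placed)

            g_start = pos + 1  # 1-based inclusive
            g_end = pos + gene_len
            if strand == "+":
                iv_utr5 = (g_start, g_start + utr5_len - 1)
                iv_cds = (g_start + utr5_len, g_start + utr5_len + cds_len - 1)
                iv_utr3 = (g_end - utr3_len + 1, g_end)
            else:
                iv_utr3 = (g_start, g_start + utr3_len - 1)
                iv_cds = (g_start + utr3_len, g_start + utr3_len + cds_len - 1)
                iv_utr5 = (g_end - utr5_len + 1, g_end)
            mrna_id = f"{gene_id}.t1"
            gff_lines += [
                _gff(chrom, "gene", g_start, g_end, strand, f"ID={gene_id};Name={gene_id}"),
                _gff(chrom, "mRNA", g_start, g_end, strand, f"ID={mrna_id};Parent={gene_id}"),
                _gff(chrom, "five_prime_UTR", *iv_utr5, strand, f"ID={mrna_id}.utr5;Parent={mrna_id}"),
                _gff(chrom, "CDS", *iv_cds, strand, f"ID={mrna_id}.cds;Parent={mrna_id}"),
                _gff(chrom, "three_prime_UTR", *iv_utr3, strand, f"ID={mrna_id}.utr3;Parent={mrna_id}"),
            ]
            from termpart.annotation_features import classify_length

            truth_rows.append(
                {
                    "gene_id": gene_id,
                    "chrom": chrom,
                    "strand": strand,
                    "utr3_length": utr3_len,
                    "size_class": classify_length(utr3_len),
                    "motif_offset": motif_offset if motif_offset is not None else -1,
                }
            )
            pos += gene_len
            gene_idx += 1
            if pos > cfg.chrom_sizes[chrom]:
                raise ValueError(
                    f"genes do not fit on {chrom} ({pos} > {cfg.chrom_sizes[chrom]} bp); "
                    "increase chrom_sizes or reduce n_genes"
                )
        # pad to the declared size
        pad = cfg.chrom_sizes[chrom] - pos
        if pad > 0:
            buf.extend(_random_dna(rng, pad, cfg.gc_content).tobytes())

    truth = pd.DataFrame(
        truth_rows,
        columns=["gene_id", "chrom", "strand", "utr3_length", "size_class", "motif_offset"],
    )
    return SyntheticGenome(
        fasta={c: bytes(b).decode() for c, b in chroms.items()},
        gff3_text="\n".join(gff_lines) + "\n",
        truth=truth,
    )


def _gff(chrom, ftype, start, end, strand, attrs) -> str:
    return f"{chrom}\ttermpart_sim\t{ftype}\t{start}\t{end}\t.\t{strand}\t.\t{attrs}"


def _revcomp_bytes(seq: bytearray) -> bytes:
    return bytes(seq).translate(bytes.maketrans(b"ACGT", b"TGCA"))[::-1]


@dataclass
class FpkmGenConfig:
    """Parameters for the diurnal FPKM matrix generator.

    Gene baselines are log-normal; each gene gets a sinusoidal diurnal
    component (random amplitude and phase) around its baseline, plus
    truncated Gaussian noise with SD ``noise_cv`` times the baseline.
    Over a full cycle of evenly spaced timepoints the sinusoid averages
    to zero, so the planted ranking is the ranking of the baselines.
    """

    n_genes: int = 200
    n_timepoints: int = 12  # evenly spaced over 24 h
    log_mean: float = 3.0  # natural-log scale of baseline FPKM
    log_sigma: float = 1.5
    amplitude_max: float = 0.5  # relative diurnal amplitude, U(0, max)
    noise_cv: float = 0.0
    seed: int = 0


@dataclass
class SyntheticFpkm:
    matrix: pd.DataFrame
    truth_ranks: pd.Series  # 1 = highest planted baseline

    def write(self, out_dir: str | Path) -> tuple[Path, Path]:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        mpath = out / "fpkm.tsv"
        self.matrix.to_csv(mpath, sep="\t", index_label="gene_id")
        tpath = out / "fpkm_truth_ranks.tsv"
        self.truth_ranks.rename("rank").to_csv(tpath, sep="\t", index_label="gene_id")
        return mpath, tpath


def gen_fpkm(cfg: FpkmGenConfig) -> SyntheticFpkm:
    """Generate a genes x timepoints FPKM matrix with known true ranking."""
    if cfg.n_timepoints < 1:
        raise ValueError("n_timepoints must be >= 1")
    rng = np.random.default_rng(cfg.seed)
    genes = [f"g{i + 1:05d}" for i in range(cfg.n_genes)]
    baselines = np.exp(rng.normal(cfg.log_mean, cfg.log_sigma, size=cfg.n_genes))
    amp = rng.uniform(0, cfg.amplitude_max, size=cfg.n_genes)
    phase = rng.uniform(0, 2 * np.pi, size=cfg.n_genes)
    hours = np.arange(cfg.n_timepoints) * (24.0 / cfg.n_timepoints)
    t = 2 * np.pi * hours / 24.0
    vals = baselines[:, None] * (1 + amp[:, None] * np.sin(t[None, :] + phase[:, None]))
    if cfg.noise_cv > 0:
        vals = vals + rng.normal(0, cfg.noise_cv * baselines[:, None], size=vals.shape)
    vals = np.clip(vals, 0, None)
    matrix = pd.DataFrame(
        vals, index=pd.Index(genes, name="gene_id"), columns=[f"{h:g}h" for h in hours]
    )
    ranks = pd.Series(baselines, index=matrix.index).rank(
        method="min", ascending=False
    ).astype(int)
    return SyntheticFpkm(matrix=matrix, truth_ranks=ranks)


@dataclass(frozen=True)
class ConstructParams:
    """Generating parameters for one construct x strain combination."""

    construct: str
    strain: str
    efficiency_mean: float  # colonies per µg, Poisson mean per technical plate
    survival_probs: tuple[float, ...]  # per-round conditional survival
    gfp_prob: float  # P(GFP-positive | viable at final round)
    selection: str = "zeocin"

    def __post_init__(self) -> None:
        for p in (*self.survival_probs, self.gfp_prob):
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"probability {p} outside [0, 1]")
        if self.efficiency_mean < 0:
            raise ValueError("efficiency_mean must be nonnegative")

    @property
    def final_viability(self) -> float:
        return float(np.prod(self.survival_probs))


@dataclass
class ScreenGenConfig:
    """Parameters for the stochastic plate-screen generator."""

    constructs: Sequence[ConstructParams]
    n_experiments: int = 3
    n_lines: int = 96
    n_technical: int = 6
    dna_ug: float = 1.0
    overdispersion: float | None = None  # negative-binomial alpha, None = Poisson
    seed: int = 0


@dataclass
class SyntheticScreen:
    plates: pd.DataFrame
    colonies: pd.DataFrame
    truth: dict

    def write(self, out_dir: str | Path) -> tuple[Path, Path]:
        import json

        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        ppath = out / "plates.tsv"
        self.plates.to_csv(ppath, sep="\t", index=False)
        cpath = out / "colonies.tsv"
        self.colonies.to_csv(cpath, sep="\t", index=False)
        (out / "screen_truth.json").write_text(json.dumps(self.truth, indent=2))
        return ppath, cpath


def gen_screen(cfg: ScreenGenConfig) -> SyntheticScreen:
    """Simulate colony counts and line fates for each construct x strain.

    Colonies: Poisson(efficiency_mean * dna_ug) per technical plate (or
    negative binomial when ``overdispersion`` is set).  Each picked line
    survives round r with probability ``survival_probs[r-1]`` given
    survival through round r-1, so viability is monotone by
    construction.  GFP is Bernoulli(``gfp_prob``) for final-round
    survivors only; all other lines carry no GFP call.
    """
    rng = np.random.default_rng(cfg.seed)
    plate_rows = []
    colony_rows = []
    for cp in cfg.constructs:
        n_rounds = len(cp.survival_probs)
        for e in range(1, cfg.n_experiments + 1):
            exp_id = f"E{e}"
            lam = cp.efficiency_mean * cfg.dna_ug
            for tech in range(1, cfg.n_technical + 1):
                if cfg.overdispersion:
                    shape = 1.0 / cfg.overdispersion
                    lam_i = rng.gamma(shape, lam / shape)
                    n_col = int(rng.poisson(lam_i))
                else:
                    n_col = int(rng.poisson(lam))
                colony_rows.append(
                    {
                        "construct": cp.construct,
                        "strain": cp.strain,
                        "experiment_id": exp_id,
                        "technical_rep": tech,
                        "colonies": n_col,
                        "dna_ug": cfg.dna_ug,
                    }
                )
            for line in range(1, cfg.n_lines + 1):
                alive = True
                viab = []
                for r in range(n_rounds):
                    if alive:
                        alive = bool(rng.random() < cp.survival_probs[r])
                    viab.append(alive)
                gfp: int | str = ""
                if viab[-1]:
                    gfp = int(rng.random() < cp.gfp_prob)
                row = {
                    "line_id": f"{cp.construct}_{cp.strain}_{exp_id}_L{line:03d}",
                    "construct": cp.construct,
                    "strain": cp.strain,
                    "selection": cp.selection,
                }
                for r in range(n_rounds):
                    row[f"viable_r{r + 1}"] = int(viab[r])
                row["gfp"] = gfp
                row["experiment_id"] = exp_id
                plate_rows.append(row)
    truth = {
        "seed": cfg.seed,
        "n_experiments": cfg.n_experiments,
        "n_lines": cfg.n_lines,
        "n_technical": cfg.n_technical,
        "dna_ug": cfg.dna_ug,
        "constructs": [
            {
                "construct": cp.construct,
                "strain": cp.strain,
                "efficiency_mean": cp.efficiency_mean,
                "survival_probs": list(cp.survival_probs),
                "final_viability": cp.final_viability,
                "gfp_prob": cp.gfp_prob,
            }
            for cp in cfg.constructs
        ],
    }
    return SyntheticScreen(
        plates=pd.DataFrame(plate_rows),
        colonies=pd.DataFrame(colony_rows),
        truth=truth,
    )
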