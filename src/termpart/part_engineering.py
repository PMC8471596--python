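"""Terminator-part engineering: motif scanning, Golden Gate domestication,
type-IIS assembly simulation, plasmid linearization and candidate selection.

The polyadenylation cis-element of *C. reinhardtii* is the UGUAA motif
(DNA sense strand TGTAA); a usable terminator part must carry at least
one copy.  Parts destined for modular cloning (MoClo) must be free of
internal BsaI/BpiI recognition sites on either strand ("domestication");
type-IIS enzymes cut outside their recognition sequence leaving 4-nt
single-strand overhangs that program the assembly order.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

from Bio.Seq import Seq

from termpart.annotation_features import GeneModel, classify_length

__all__ = [
    "EnzymeSpec",
    "SiteHit",
    "TerminatorPart",
    "AssemblyPart",
    "Assembly",
    "LinearizationResult",
    "SelectionConfig",
    "ENZYMES",
    "BSAI",
    "BPII",
    "SCAI",
    "NCOI",
    "ECORV",
    "POLYA_MOTIF",
    "clean_dna",
    "revcomp",
    "scan_motif",
    "trim_to_motif",
    "find_sites",
    "domesticate",
    "simulate_assembly",
    "digest_assembly",
    "linearization_flank",
    "select_candidates",
]

#: DNA form of the UGUAA polyadenylation signal
POLYA_MOTIF = "TGTAA"

_VALID = set("ACGT")
_TRANSVERSIONS = {"A": "CT", "C": "AG", "G": "CT", "T": "AG"}
_TRANSITIONS = {"A": "G", "G": "A", "C": "T", "T": "C"}


def clean_dna(sequence: str) -> str:
    """Uppercase a sequence and map RNA U to T; reject ambiguity codes."""
    seq = sequence.upper().replace("U", "T")
    bad = set(seq) - _VALID
    if bad:
        raise ValueError(f"non-ACGT character(s) in sequence: {sorted(bad)}")
    return seq


def revcomp(sequence: str) -> str:
    return str(Seq(sequence).reverse_complement())


@dataclass(frozen=True)
class EnzymeSpec:
    """A restriction enzyme: recognition sequence and cut geometry.

    ``cut_offset_top``/``cut_offset_bottom`` are measured from the 3' end
    of the recognition sequence on the strand carrying it; negative
    offsets describe enzymes cutting within their (palindromic) site.
    ``overhang_len`` is 4 for the type-IIS MoClo enzymes, 0 for blunt
    cutters.
    """

    name: str
    recognition: str
    cut_offset_top: int
    cut_offset_bottom: int
    overhang_len: int = 4

    @property
    def is_palindromic(self) -> bool:
        return self.recognition == revcomp(self.recognition)

    def cut_position(self, rec_start: int) -> int:
        """Top-strand cut coordinate (0-based, cut before this index) for
        a recognition occurrence starting at ``rec_start`` on the plus
        strand."""
        return rec_start + len(self.recognition) + self.cut_offset_top


BSAI = EnzymeSpec("BsaI", "GGTCTC", 1, 5, 4)
BPII = EnzymeSpec("BpiI", "GAAGAC", 2, 6, 4)
SCAI = EnzymeSpec("ScaI", "AGTACT", -3, -3, 0)
NCOI = EnzymeSpec("NcoI", "CCATGG", -5, -1, 4)
ECORV = EnzymeSpec("EcoRV", "GATATC", -3, -3, 0)

ENZYMES: dict[str, EnzymeSpec] = {e.name: e for e in (BSAI, BPII, SCAI, NCOI, ECORV)}


@dataclass(frozen=True)
class SiteHit:
    """A recognition-site occurrence, reported at plus-strand coordinates."""

    enzyme: str
    position: int
    strand: str


@dataclass
class TerminatorPart:
    """A candidate terminator element extracted in transcript (sense)
    orientation."""

    name: str
    source_gene: str
    sequence: str
    rank: int | None = None
    domesticated: bool = False
    mutations: list[tuple[int, str, str]] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.sequence = clean_dna(self.sequence)

    @property
    def length(self) -> int:
        return len(self.sequence)

    @property
    def size_class(self) -> str:
        return classify_length(self.length)

    @property
    def motif_hits(self) -> list[int]:
        return scan_motif(self.sequence, POLYA_MOTIF)


@dataclass(frozen=True)
class AssemblyPart:
    """A Golden Gate level-0 part; the sequence includes both 4-nt fusion
    sites (overhangs) at its ends."""

    name: str
    sequence: str
    upstream_overhang: str
    downstream_overhang: str
    role: str = "part"

    def __post_init__(self) -> None:
        object.__setattr__(self, "sequence", clean_dna(self.sequence))
        for oh in (self.upstream_overhang, self.downstream_overhang):
            if len(oh) != 4:
                raise ValueError(f"overhang must be 4 nt, got {oh!r}")
        if not self.sequence.startswith(self.upstream_overhang):
            raise ValueError(f"{self.name}: sequence does not start with upstream overhang")
        if not self.sequence.endswith(self.downstream_overhang):
            raise ValueError(f"{self.name}: sequence does not end with downstream overhang")


def scan_motif(sequence: str, motif: str = POLYA_MOTIF) -> list[int]:
    """All (overlapping) occurrences of ``motif`` on the given strand,
    as ascending 0-based start positions."""
    if not motif:
        raise ValueError("motif must be nonempty")
    seq = clean_dna(sequence)
    motif = clean_dna(motif)
    hits = []
    start = seq.find(motif)
    while start != -1:
        hits.append(start)
        start = seq.find(motif, start + 1)
    return hits


def trim_to_motif(sequence: str, motif: str = POLYA_MOTIF, tail: int = 33) -> str:
    """Shorten a part to end ``tail`` bp after the last motif occurrence
    that still leaves the full tail; if no occurrence does, the last
    occurrence is used with the shorter available tail (warning)."""
    if tail < 0:
        raise ValueError("tail must be >= 0")
    seq = clean_dna(sequence)
    hits = scan_motif(seq, motif)
    if not hits:
        raise ValueError(f"motif {motif!r} not found in sequence")
    usable = [p for p in hits if p + len(motif) + tail <= len(seq)]
    if usable:
        cut = usable[-1] + len(motif) + tail
    else:
        cut = len(seq)
        warnings.warn(
            f"no motif occurrence leaves a {tail}-bp tail; keeping the "
            f"{len(seq) - hits[-1] - len(motif)}-bp tail after the last occurrence",
            stacklevel=2,
        )
    return seq[:cut]


def find_sites(sequence: str, enzymes: Sequence[EnzymeSpec] = (BSAI, BPII)) -> list[SiteHit]:
    """Recognition-site occurrences for each enzyme on both strands.

    Minus-strand sites are located by matching the reverse complement of
    the recognition sequence and reported at their plus-strand start
    coordinate.  Palindromic sites are reported once, as plus strand.
    """
    seq = clean_dna(sequence)
    hits: list[SiteHit] = []
    for enz in enzymes:
        for pos in scan_motif(seq, enz.recognition):
            hits.append(SiteHit(enz.name, pos, "+"))
        if not enz.is_palindromic:
            for pos in scan_motif(seq, revcomp(enz.recognition)):
                hits.append(SiteHit(enz.name, pos, "-"))
    return sorted(hits, key=lambda h: (h.position, h.enzyme, h.strand))


def _protected(positions: Iterable[int], intervals: Iterable[tuple[int, int]]) -> set[int]:
    covered = set()
    for lo, hi in intervals:
        covered.update(range(lo, hi))
    covered.update(positions)
    return covered


def domesticate(
    part: TerminatorPart,
    enzymes: Sequence[EnzymeSpec] = (BSAI, BPII),
    protected: Sequence[tuple[int, int]] | None = None,
) -> TerminatorPart:
    """Remove every internal recognition site by single-base substitution.

    Each site is fixed by one substitution at the leftmost mutable
    position inside its recognition occurrence that is not in a
    protected interval, preferring transversions; an edit is only
    accepted if it removes the site without creating a new site of any
    listed enzyme.  Protected intervals default to (and always include)
    the part's polyadenylation-motif hits.  Raises ``ValueError`` when a
    site admits no legal edit.  Idempotent: a site-free part is returned
    unchanged with no mutations recorded.
    """
    motif_intervals = [(p, p + len(POLYA_MOTIF)) for p in part.motif_hits]
    intervals = list(protected) if protected is not None else []
    intervals.extend(motif_intervals)
    blocked: set[int] = set()
    for lo, hi in intervals:
        blocked.update(range(lo, hi))

    seq = part.sequence
    mutations = list(part.mutations)
    guard = 0
    while True:
        sites = find_sites(seq, enzymes)
        if not sites:
            break
        guard += 1
        if guard > len(part.sequence):
            raise ValueError("domestication did not converge")
        site = sites[0]
        enz = next(e for e in enzymes if e.name == site.enzyme)
        window = range(site.position, site.position + len(enz.recognition))
        edited = None
        for pos in window:
            if pos in blocked:
                continue
            base = seq[pos]
            for new in _TRANSVERSIONS[base] + _TRANSITIONS[base]:
                trial = seq[:pos] + new + seq[pos + 1 :]
                trial_sites = find_sites(trial, enzymes)
                if len(trial_sites) < len(sites) and not _new_sites(sites, trial_sites):
                    edited = (pos, base, new, trial)
                    break
            if edited:
                break
        if edited is None:
            raise ValueError(
                f"no legal edit for {site.enzyme} site at position {site.position} "
                f"(strand {site.strand}); site overlaps protected interval(s)"
            )
        pos, old, new, seq = edited
        mutations.append((pos, old, new))

    return replace(part, sequence=seq, domesticated=True, mutations=mutations)


def _new_sites(before: list[SiteHit], after: list[SiteHit]) -> bool:
    return bool(set(after) - set(before))


@dataclass
class Assembly:
    """A closed (circular) Golden Gate assembly product.

    ``junctions`` holds, for each fusion event in order (part1/part2,
    ..., last-part/backbone, backbone/part1), the start index of the
    shared 4-nt overhang in ``sequence`` and the overhang itself.
    """

    sequence: str
    junctions: list[tuple[int, str]]
    part_names: list[str]

    @property
    def length(self) -> int:
        return len(self.sequence)


def simulate_assembly(parts: Sequence[AssemblyPart], backbone: AssemblyPart) -> Assembly:
    """Assemble ordered parts and a backbone into one circular product.

    Consecutive parts must share identical fusion sites; the chain closes
    through the backbone.  Any overhang used at two junctions makes the
    ligation ambiguous and is an error.  Each shared overhang is counted
    once in the product length.
    """
    if not parts:
        raise ValueError("no parts to assemble")
    segments = list(parts) + [backbone]
    overhangs = []
    for a, b in zip(segments, segments[1:]):
        if a.downstream_overhang != b.upstream_overhang:
            raise ValueError(
                f"overhang mismatch at junction {a.name}/{b.name}: "
                f"{a.downstream_overhang} vs {b.upstream_overhang}"
            )
        overhangs.append(a.downstream_overhang)
    if backbone.downstream_overhang != parts[0].upstream_overhang:
        raise ValueError(
            f"overhang mismatch at junction {backbone.name}/{parts[0].name}: "
            f"{backbone.downstream_overhang} vs {parts[0].upstream_overhang}"
        )
    overhangs.append(backbone.downstream_overhang)
    dupes = {oh for oh in overhangs if overhangs.count(oh) > 1}
    if dupes:
        raise ValueError(f"ambiguous assembly: overhang(s) used at two junctions: {sorted(dupes)}")

    oh = 4
    seq = segments[0].sequence
    junctions = []
    for seg in segments[1:]:
        junctions.append((len(seq) - oh, seg.upstream_overhang))
        seq += seg.sequence[oh:]
    # the closing junction: backbone's downstream overhang is the first
    # part's upstream overhang, already present at position 0
    seq = seq[:-oh]
    junctions.append((0, parts[0].upstream_overhang))
    return Assembly(sequence=seq, junctions=junctions, part_names=[s.name for s in segments])


def digest_assembly(assembly: Assembly) -> list[str]:
    """Cut the circular product at every junction overhang, recovering
    the original part/backbone sequences (each with both fusion sites)."""
    L = assembly.length
    starts = [assembly.junctions[-1][0]] + [p for p, _ in assembly.junctions[:-1]]
    fragments = []
    for i, start in enumerate(starts):
        end = starts[(i + 1) % len(starts)]
        span = (end - start) % L
        doubled = assembly.sequence + assembly.sequence
        fragments.append(doubled[start : start + span + 4])
    return fragments


@dataclass
class LinearizationResult:
    is_unique: bool
    flank_bp: int | None
    cut_positions: list[int]
    cuts_in_cassette: list[int]


def linearization_flank(
    plasmid: str,
    enzyme: EnzymeSpec,
    cassette: tuple[int, int],
) -> LinearizationResult:
    """Locate cut sites on a circular plasmid and measure the flank.

    ``cassette`` is the (start, end) of the expression cassette in
    0-based plasmid coordinates.  If the enzyme cuts exactly once
    outside the cassette, ``flank_bp`` is the number of bp between the
    cut and the nearer cassette boundary along the shorter arc.  Cuts
    inside the cassette are flagged, not raised; no site at all is an
    error.
    """
    seq = clean_dna(plasmid)
    L = len(seq)
    c_start, c_end = cassette
    if not (0 <= c_start <= c_end < L):
        raise ValueError(f"cassette {cassette} invalid on a {L}-bp plasmid")
    doubled = seq + seq[: len(enzyme.recognition) - 1]
    rec_starts = set(scan_motif(doubled, enzyme.recognition))
    if not enzyme.is_palindromic:
        rec_starts |= set(scan_motif(doubled, revcomp(enzyme.recognition)))
    cuts = sorted({enzyme.cut_position(p) % L for p in rec_starts if p < L})
    if not cuts:
        raise ValueError(f"{enzyme.name} does not cut this plasmid")
    inside = [c for c in cuts if c_start <= c <= c_end]
    outside = [c for c in cuts if c not in inside]
    if len(outside) != 1:
        return LinearizationResult(False, None, cuts, inside)
    cut = outside[0]
    d_after = (cut - c_end - 1) % L
    d_before = (c_start - cut - 1) % L
    return LinearizationResult(True, min(d_after, d_before), cuts, inside)


@dataclass
class SelectionConfig:
    """Rules for picking terminator candidates from annotated 3'UTRs."""

    max_rank: int = 350
    exceptions: frozenset[str] = frozenset()
    max_len: int = 1000
    motif: str = POLYA_MOTIF
    extend_3prime: int = 0


def select_candidates(
    models: Iterable[GeneModel],
    genome: Mapping[str, str] | str | Path,
    rank_table,
    config: SelectionConfig | None = None,
) -> list[TerminatorPart]:
    """Select terminator parts: highly ranked genes whose annotated 3'UTR
    is at most ``max_len`` bp and carries the polyadenylation motif.

    ``genome`` is a chrom -> sequence mapping or a FASTA path.  Parts
    are extracted strand-aware so the returned sequence reads in
    transcript orientation; ``extend_3prime`` appends genomic sequence
    downstream of the annotated UTR end.  Output order is by gene id,
    independent of input order.
    """
    from termpart.expression_rank import rank_filter

    cfg = config or SelectionConfig()
    if not isinstance(genome, Mapping):
        import pyfaidx

        fa = pyfaidx.Fasta(str(genome))
        genome = {name: str(fa[name][:]) for name in fa.keys()}

    passing = rank_filter(rank_table, cfg.max_rank, cfg.exceptions)
    parts: list[TerminatorPart] = []
    for model in sorted(models, key=lambda m: m.gene_id):
        if not model.has_utr3 or model.gene_id not in passing:
            continue
        if model.utr3_length > cfg.max_len:
            continue
        if model.chrom not in genome:
            raise KeyError(f"chromosome {model.chrom!r} missing from genome FASTA")
        chrom_seq = clean_dna(genome[model.chrom])
        ivs = sorted(model.utr3, key=lambda iv: iv.start)
        seq = "".join(chrom_seq[iv.start - 1 : iv.end] for iv in ivs)
        if cfg.extend_3prime:
            if model.strand == "+":
                end = ivs[-1].end
                seq += chrom_seq[end : end + cfg.extend_3prime]
            else:
                start = ivs[0].start - 1
                seq = chrom_seq[max(0, start - cfg.extend_3prime) : start] + seq
        if model.strand == "-":
            seq = revcomp(seq)
        if not scan_motif(seq, cfg.motif):
            continue
        rank = None
        if model.gene_id in rank_table.index:
            rank = int(rank_table.loc[model.gene_id, "rank"])
        parts.append(
            TerminatorPart(
                name=f"t{model.gene_id}",
                source_gene=model.gene_id,
                sequence=seq,
                rank=rank,
            )
        )
    return parts
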