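"""Motif scanning, domestication, assembly and candidate selection."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from termpart.annotation_features import GeneModel, GenomicInterval
from termpart.part_engineering import (
    BPII,
    BSAI,
    ECORV,
    NCOI,
    SCAI,
    AssemblyPart,
    SelectionConfig,
    TerminatorPart,
    digest_assembly,
    domesticate,
    find_sites,
    linearization_flank,
    revcomp,
    scan_motif,
    select_candidates,
    simulate_assembly,
    trim_to_motif,
)

dna = st.text(alphabet="ACGT", min_size=0, max_size=80)


class TestScanMotif:
    def test_motif_at_start(self):
        assert scan_motif("TGTAA") == [0]

    def test_overlapping_occurrences(self):
        assert scan_motif("TGTAATGTAA") == [0, 5]

    def test_no_hit(self):
        assert scan_motif("AAAAA") == []

    def test_rna_input_mapped_to_dna(self):
        assert scan_motif("uguaa") == [0]

    def test_ambiguity_codes_rejected(self):
        with pytest.raises(ValueError, match="non-ACGT"):
            scan_motif("TGTNA")


class TestTrimToMotif:
    def test_tail_after_last_full_occurrence(self):
        seq = "A" * 7 + "TGTAA" + "C" * 38
        assert trim_to_motif(seq, tail=33) == "A" * 7 + "TGTAA" + "C" * 33

    def test_tail_zero_with_motif_at_end_is_identity(self):
        seq = "GGGTGTAA"
        assert trim_to_motif(seq, tail=0) == seq

    def test_short_tail_warns_and_keeps_what_exists(self):
        seq = "AATGTAACC"  # only 2 bp after the motif
        with pytest.warns(UserWarning, match="tail"):
            assert trim_to_motif(seq, tail=33) == seq

    def test_motif_absent_is_an_error(self):
        with pytest.raises(ValueError, match="not found"):
            trim_to_motif("ACGTACGT")


class TestFindSites:
    def test_plus_strand_bsai(self):
        hits = find_sites("AAGGTCTCAA", [BSAI])
        assert [(h.enzyme, h.position, h.strand) for h in hits] == [("BsaI", 2, "+")]

    def test_minus_strand_bsai_via_revcomp(self):
        hits = find_sites("TTGAGACCTT", [BSAI])
        assert [(h.enzyme, h.strand) for h in hits] == [("BsaI", "-")]

    def test_clean_sequence_has_no_hits(self):
        assert find_sites("ATATATATATAT", [BSAI, BPII]) == []

    def test_palindromic_site_reported_once(self):
        assert len(find_sites("AAGATATCAA", [ECORV])) == 1

    @given(dna)
    @settings(deadline=None, max_examples=100)
    def test_strand_symmetry(self, seq):
        fwd = find_sites(seq, [BSAI, BPII])
        rev = find_sites(revcomp(seq) if seq else "A", [BSAI, BPII]) if seq else []
        if seq:
            assert len(fwd) == len(rev)

    def test_agrees_with_biopython_restriction(self):
        # independent oracle: Biopython's enzyme catalogue on random sequence
        from Bio.Restriction import BsaI as BioBsaI
        from Bio.Restriction import BpiI as BioBpiI
        from Bio.Seq import Seq

        rng = np.random.default_rng(11)
        for _ in range(25):
            # A-padding gives every recognition site room for its offset cut,
            # which Biopython requires before it reports a site on linear DNA
            seq = "A" * 12 + "".join(rng.choice(list("ACGT"), size=200)) + "A" * 12
            ours = find_sites(seq, [BSAI, BPII])
            bio_n = len(BioBsaI.search(Seq(seq))) + len(BioBpiI.search(Seq(seq)))
            assert len(ours) == bio_n


class TestDomesticate:
    def test_single_site_removed_with_one_substitution(self):
        part = TerminatorPart("t", "g", "AAGGTCTCAATGTAAGG")
        dom = domesticate(part, (BSAI, BPII))
        assert dom.domesticated
        assert len(dom.mutations) == 1
        assert find_sites(dom.sequence, (BSAI, BPII)) == []
        assert dom.motif_hits == part.motif_hits  # poly(A) motif untouched

    def test_site_free_part_returned_unchanged(self):
        part = TerminatorPart("t", "g", "ATGTAAATATATAT")
        dom = domesticate(part, (BSAI, BPII))
        assert dom.sequence == part.sequence and dom.mutations == []

    def test_idempotent(self):
        part = TerminatorPart("t", "g", "AAGGTCTCAA" + "TGTAA" + "GTCTTCAA")
        once = domesticate(part, (BSAI, BPII))
        twice = domesticate(once, (BSAI, BPII))
        assert twice.sequence == once.sequence
        assert twice.mutations == once.mutations

    def test_site_inside_protected_motif_is_an_error(self):
        # BsaI site fully covered by a protected interval
        part = TerminatorPart("t", "g", "AAGGTCTCAA")
        with pytest.raises(ValueError, match="protected"):
            domesticate(part, (BSAI,), protected=[(0, 10)])

    @given(
        left=dna,
        right=dna,
        enzyme_seq=st.sampled_from(["GGTCTC", "GAGACC", "GAAGAC", "GTCTTC"]),
    )
    @settings(deadline=None, max_examples=100)
    def test_postcondition_on_planted_sites(self, left, right, enzyme_seq):
        seq = left + "TGTAA" + enzyme_seq + right
        part = TerminatorPart("t", "g", seq)
        try:
            dom = domesticate(part, (BSAI, BPII))
        except ValueError:
            return  # no legal edit exists for this construction
        assert find_sites(dom.sequence, (BSAI, BPII)) == []
        assert len(dom.sequence) == len(seq)
        # every recorded mutation is a genuine single-base difference
        diffs = [i for i, (a, b) in enumerate(zip(seq, dom.sequence)) if a != b]
        assert diffs == sorted(p for p, _, _ in dom.mutations)


def _part(name, core, up, down):
    return AssemblyPart(name, up + core + down, up, down)


class TestSimulateAssembly:
    def test_two_parts_and_backbone_circle_length(self):
        p1 = _part("p1", "C" * 12, "AATG", "GCTT")
        p2 = _part("p2", "A" * 12, "GCTT", "CGCT")
        bb = _part("bb", "T" * 20, "CGCT", "AATG")
        asm = simulate_assembly([p1, p2], bb)
        # three junctions, each 4-nt overhang counted once
        assert asm.length == 20 + 20 + 28 - 3 * 4

    def test_single_part_circle(self):
        p = _part("p", "G" * 10, "AATG", "GCTT")
        bb = _part("bb", "T" * 10, "GCTT", "AATG")
        asm = simulate_assembly([p], bb)
        assert asm.length == 18 + 18 - 2 * 4

    def test_mismatched_overhangs_name_the_junction(self):
        p1 = _part("p1", "C" * 8, "AATG", "GCTT")
        p2 = _part("p2", "A" * 8, "TTCG", "CGCT")
        bb = _part("bb", "T" * 8, "CGCT", "AATG")
        with pytest.raises(ValueError, match="p1/p2"):
            simulate_assembly([p1, p2], bb)

    def test_duplicate_overhang_is_ambiguous(self):
        p1 = _part("p1", "C" * 8, "AATG", "AATG")
        bb = _part("bb", "T" * 8, "AATG", "AATG")
        with pytest.raises(ValueError, match="ambiguous"):
            simulate_assembly([p1], bb)

    def test_digestion_recovers_every_part(self):
        rng = np.random.default_rng(3)
        overhangs = ["AATG", "GCTT", "CGCT", "TGCC"]
        parts = []
        for i in range(3):
            core = "".join(rng.choice(list("ACGT"), size=int(rng.integers(5, 30))))
            parts.append(_part(f"p{i}", core, overhangs[i], overhangs[i + 1]))
        bb = _part("bb", "T" * 25, overhangs[3], overhangs[0])
        asm = simulate_assembly(parts, bb)
        frags = digest_assembly(asm)
        assert frags == [p.sequence for p in parts] + [bb.sequence]


class TestLinearizationFlank:
    def _plasmid_with_site(self, site, pos, length=5000):
        rng = np.random.default_rng(0)
        seq = "".join(rng.choice(list("AC"), size=length))  # cannot contain any site
        return seq[:pos] + site + seq[pos + len(site) :]

    def test_unique_cut_shorter_arc(self):
        # ScaI cuts AGT^ACT: recognition at 4197 puts the cut at 4200
        seq = self._plasmid_with_site("AGTACT", 4197)
        res = linearization_flank(seq, SCAI, (1000, 3000))
        assert res.is_unique and res.flank_bp == 1199

    def test_two_sites_not_unique(self):
        seq = self._plasmid_with_site("AGTACT", 3500)
        seq = seq[:4200] + "AGTACT" + seq[4206:]
        res = linearization_flank(seq, SCAI, (1000, 3000))
        assert not res.is_unique and res.flank_bp is None

    def test_no_site_is_an_error(self):
        seq = self._plasmid_with_site("AGTACT", 3500)
        with pytest.raises(ValueError, match="NcoI"):
            linearization_flank(seq, NCOI, (1000, 3000))

    def test_cut_inside_cassette_flagged_not_raised(self):
        seq = self._plasmid_with_site("AGTACT", 2000)
        res = linearization_flank(seq, SCAI, (1000, 3000))
        assert res.cuts_in_cassette and not res.is_unique

    def test_site_spanning_the_origin_is_found(self):
        seq = self._plasmid_with_site("AGTACT", 0)
        rotated = seq[3:] + seq[:3]  # recognition now wraps the origin
        res = linearization_flank(rotated, SCAI, (1000, 3000))
        assert res.is_unique


class TestSelectCandidates:
    def _models_and_genome(self):
        rng = np.random.default_rng(7)
        genome = "".join(rng.choice(list("AC"), size=12_000))  # motif-free background
        models = []
        seq = genome
        specs = [
            ("gA", 100, 200, "+", True),
            ("gB", 1000, 400, "-", True),
            ("gC", 2000, 150, "+", False),   # motif rule violated
            ("gD", 3000, 90, "-", False),    # motif rule violated
            ("gE", 4000, 1500, "+", True),   # too long
            ("gF", 6000, 700, "+", True),
        ]
        for gene_id, start, ln, strand, motif in specs:
            m, seq = self._apply(seq, gene_id, start, ln, strand, motif)
            models.append(m)
        return models, {"chr_1": seq}

    @staticmethod
    def _apply(genome, gene_id, start, utr3_len, strand, motif):
        end = start + utr3_len - 1
        seq = list(genome)
        if motif:
            planted = "TGTAA" if strand == "+" else revcomp("TGTAA")
            mid = start - 1 + utr3_len // 2
            seq[mid : mid + 5] = planted
        model = GeneModel(
            gene_id=gene_id,
            transcript_id=f"{gene_id}.t1",
            span=GenomicInterval("chr_1", start, end, strand),
            utr3=[GenomicInterval("chr_1", start, end, strand)],
        )
        return model, "".join(seq)

    def _ranks(self, gene_ids):
        return pd.DataFrame(
            {
                "mean_fpkm": range(len(gene_ids), 0, -1),
                "sd_fpkm": [0] * len(gene_ids),
                "rank": range(1, len(gene_ids) + 1),
            },
            index=gene_ids,
        )

    def test_empty_model_set(self):
        ranks = self._ranks([])
        assert select_candidates([], {"chr_1": "ACGT"}, ranks) == []

    def test_filters_motif_and_length(self):
        models, genome = self._models_and_genome()
        ranks = self._ranks([m.gene_id for m in models])
        parts = select_candidates(models, genome, ranks, SelectionConfig(max_rank=350))
        assert sorted(p.source_gene for p in parts) == ["gA", "gB", "gF"]
        for p in parts:
            assert p.motif_hits  # sense-strand motif present after extraction
            assert p.length <= 1000

    def test_minus_strand_part_reads_sense(self):
        models, genome = self._models_and_genome()
        ranks = self._ranks([m.gene_id for m in models])
        parts = select_candidates(models, genome, ranks)
        gB = next(p for p in parts if p.source_gene == "gB")
        assert "TGTAA" in gB.sequence

    def test_input_order_invariance(self):
        models, genome = self._models_and_genome()
        ranks = self._ranks([m.gene_id for m in models])
        a = select_candidates(models, genome, ranks)
        b = select_candidates(models[::-1], genome, ranks)
        assert [(p.name, p.sequence) for p in a] == [(p.name, p.sequence) for p in b]

    def test_rank_cutoff_and_exception(self):
        models, genome = self._models_and_genome()
        ids = [m.gene_id for m in models]
        ranks = self._ranks(ids)
        ranks.loc["gF", "rank"] = 15537
        without = select_candidates(models, genome, ranks, SelectionConfig(max_rank=350))
        withexc = select_candidates(
            models, genome, ranks,
            SelectionConfig(max_rank=350, exceptions=frozenset({"gF"})),
        )
        assert "gF" not in {p.source_gene for p in without}
        assert "gF" in {p.source_gene for p in withexc}

    def test_missing_chromosome_is_an_error(self):
        models, _ = self._models_and_genome()
        ranks = self._ranks([m.gene_id for m in models])
        with pytest.raises(KeyError, match="chr_1"):
            select_candidates(models, {"other": "ACGT"}, ranks)
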