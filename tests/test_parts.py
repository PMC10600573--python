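"""Promoter/terminator extraction, truncation rules and part filters."""

import warnings

import pytest

from promoterforge import parts, simulate
from promoterforge.parts import GeneModel

RC = str.maketrans("ACGT", "TGCA")


def revcomp(s):
    return s.translate(RC)[::-1]


class TestReadAnnotation:
    def test_models_match_generator_truth(self, genome_fixture, annotation):
        fx, _ = genome_fixture
        models, _ = annotation
        assert len(models) == len(fx.truth)
        for m in models:
            t = fx.truth.loc[m.gene_id]
            assert (m.start, m.end, m.tss, m.tes) == (t.start, t.end, t.tss, t.tes)
            assert (m.cds_start, m.cds_end) == (t.cds_start, t.cds_end)

    def test_utr_feature_defines_tss(self, tmp_path):
        (tmp_path / "g.fa").write_text(">c1\n" + "A" * 50 + "ATGAAATGA" + "A" * 41 + "\n")
        gff = (
            "##gff-version 3\n"
            "c1\tx\tgene\t41\t65\t.\t+\t.\tID=g1\n"
            "c1\tx\tfive_prime_UTR\t41\t50\t.\t+\t.\tParent=g1\n"
            "c1\tx\tCDS\t51\t59\t.\t+\t0\tID=g1.c;Parent=g1\n"
        )
        (tmp_path / "a.gff3").write_text(gff)
        models, _ = parts.read_annotation(tmp_path / "a.gff3", tmp_path / "g.fa")
        assert models[0].tss == 40  # UTR start, 0-based

    def test_gene_span_fallback_warns(self, tmp_path):
        (tmp_path / "g.fa").write_text(">c1\n" + "A" * 100 + "\n")
        gff = (
            "##gff-version 3\n"
            "c1\tx\tgene\t41\t70\t.\t+\t.\tID=g1\n"
            "c1\tx\tCDS\t41\t70\t.\t+\t0\tID=g1.c;Parent=g1\n"
        )
        (tmp_path / "a.gff3").write_text(gff)
        with pytest.warns(UserWarning, match="gene span"):
            models, _ = parts.read_annotation(tmp_path / "a.gff3", tmp_path / "g.fa")
        assert models[0].tss == 40 and models[0].tes == 69

    def test_missing_chromosome_errors(self, tmp_path):
        (tmp_path / "g.fa").write_text(">c1\nAAAA\n")
        gff = (
            "##gff-version 3\n"
            "c9\tx\tgene\t1\t4\t.\t+\t.\tID=g1\n"
            "c9\tx\tCDS\t1\t3\t.\t+\t0\tID=g1.c;Parent=g1\n"
        )
        (tmp_path / "a.gff3").write_text(gff)
        with pytest.raises(ValueError, match="missing chromosome"):
            parts.read_annotation(tmp_path / "a.gff3", tmp_path / "g.fa")


def _gene(gid, start, end, strand="+", chrom="c1", utr5=50, utr3=50):
    if strand == "+":
        return GeneModel(gid, chrom, strand, start, end, start, end - 1,
                         start + utr5, end - utr3)
    return GeneModel(gid, chrom, strand, start, end, end - 1, start,
                     start + utr3, end - utr5)


class TestNeighbours:
    def test_no_neighbour_gives_chromosome_bounds(self):
        g = _gene("a", 5000, 6000)
        assert parts.find_neighbours(g, [g], 20000) == (0, 20000)

    def test_strand_aware_distance(self):
        # - strand gene with a + strand neighbour genomically 3' (5' of its TSS)
        g = _gene("a", 5000, 6000, strand="-")
        nb = _gene("b", 6300, 7000, strand="+")
        left, right = parts.find_neighbours(g, [g, nb], 20000)
        assert right == 6300  # promoter side for the - strand gene
        assert right - g.end == 300

    def test_overlapping_gene_clamps_to_zero_distance(self):
        g = _gene("a", 5000, 6000)
        nb = _gene("b", 4000, 5500)
        left, _ = parts.find_neighbours(g, [g, nb], 20000)
        assert left == 5000


class TestExtraction:
    def test_cap_bound_promoter_length(self, genome_fixture, annotation):
        # gene 0 has a 6 kb clear flank and a 120 bp 5'UTR
        models, genome = annotation
        g = next(m for m in models if m.gene_id == "G000")
        nb = parts.find_neighbours(g, models, len(genome[g.chrom]))
        p = parts.extract_promoter_part(g, genome, nb)
        assert p.upstream_extent_from_tss == 2000
        assert p.length == 2120
        assert not p.truncated_by_neighbour

    def test_neighbour_bound_promoter(self):
        genome = {"c1": "ACGT" * 3000}
        g = _gene("a", 5000, 6000)
        p = parts.extract_promoter_part(g, genome, (4200, 12000))
        assert p.upstream_extent_from_tss == 800
        assert p.truncated_by_neighbour

    def test_terminator_cap_and_truncation(self, annotation):
        models, genome = annotation
        g = next(m for m in models if m.gene_id == "G000")
        nb = parts.find_neighbours(g, models, len(genome[g.chrom]))
        t = parts.extract_terminator_part(g, genome, nb)
        assert t.downstream_extent_from_tes == 250
        assert t.length == 250 + 150  # cap + 3'UTR
        t2 = parts.extract_terminator_part(g, genome, (nb[0], g.tes + 1 + 100))
        assert t2.downstream_extent_from_tes == 100

    def test_minus_strand_sequence_is_reverse_complement(self, annotation):
        models, genome = annotation
        g = next(m for m in models if m.strand == "-")
        nb = parts.find_neighbours(g, models, len(genome[g.chrom]))
        for part in (
            parts.extract_promoter_part(g, genome, nb),
            parts.extract_terminator_part(g, genome, nb),
        ):
            raw = genome[g.chrom][part.start : part.end]
            assert part.sequence == revcomp(raw)

    def test_extents_never_exceed_caps(self, annotation):
        models, genome = annotation
        for pair in parts.extract_parts(models, genome).values():
            prom, term = pair
            assert prom.upstream_extent_from_tss <= 2000
            assert term.downstream_extent_from_tes <= 250
            assert len(prom.sequence) == prom.length
            assert len(term.sequence) == term.length

    def test_neighbour_inside_utr_excludes_part(self):
        genome = {"c1": "ACGT" * 3000}
        g = _gene("a", 5000, 6000)
        p = parts.extract_promoter_part(g, genome, (5020, 12000))  # inside 5'UTR
        assert p.excluded and "zero_length" in p.filter_flags

    def test_mirror_symmetry_under_genome_reverse_complement(self, annotation):
        models, genome = annotation
        n = len(genome["chr1"])
        flipped_genome = {"chr1": revcomp(genome["chr1"])}
        flipped = [
            GeneModel(
                m.gene_id, m.chrom, "-" if m.strand == "+" else "+",
                n - m.end, n - m.start, n - 1 - m.tss, n - 1 - m.tes,
                n - m.cds_end, n - m.cds_start,
            )
            for m in models
        ]
        orig = parts.extract_parts(models, genome)
        mirror = parts.extract_parts(flipped, flipped_genome)
        for gid in orig:
            for a, b in zip(orig[gid], mirror[gid]):
                assert a.sequence == b.sequence
                assert a.truncated_by_neighbour == b.truncated_by_neighbour


class TestOverlapFilter:
    def _parts_for(self, models, genome):
        return parts.extract_parts(models, genome)

    def test_part_ending_at_neighbour_boundary_kept(self):
        genome = {"c1": "ACGT" * 5000}
        a = _gene("a", 8000, 9000)
        b = _gene("b", 5999, 6500)  # a's promoter [6000, ...] starts 1 bp after b
        pairs = parts.extract_parts([a, b], genome)
        assert pairs["a"][0].start == 6500  # truncated at the neighbour
        survivors = parts.overlap_filter({"a": pairs["a"]}, [a, b])
        assert survivors == ["a"]

    def test_one_bp_overlap_removes_gene(self):
        genome = {"c1": "ACGT" * 5000}
        a = _gene("a", 8000, 9000)
        pairs = parts.extract_parts([a], genome)
        intruder = _gene("b", 1000, pairs["a"][0].start + 1)
        survivors = parts.overlap_filter({"a": pairs["a"]}, [a, intruder])
        assert survivors == []
        assert "overlaps_neighbour" in pairs["a"][0].filter_flags

    def test_matches_all_pairs_intersection(self, annotation):
        models, genome = annotation
        pairs = parts.extract_parts(models, genome)
        survivors = set(parts.overlap_filter(pairs, models))
        expected = set()
        for gid, pr in pairs.items():
            hit = False
            for part in pr:
                for m in models:
                    if m.gene_id == gid:
                        continue
                    if part.start < m.end and m.start < part.end:
                        hit = True
            if not hit:
                expected.add(gid)
        assert survivors == expected


class TestRestrictionScan:
    def test_bsai_plus_strand(self):
        hits = parts.scan_restriction_sites("AAGGTCTCAA", {"BsaI": "GGTCTC"})
        assert hits == [("BsaI", 2, "+")]

    def test_bsai_minus_strand(self):
        hits = parts.scan_restriction_sites("AAGAGACCAA", {"BsaI": "GGTCTC"})
        assert hits == [("BsaI", 2, "-")]

    def test_n_never_matches(self):
        assert parts.scan_restriction_sites("AAGGTCNCAA", {"BsaI": "GGTCTC"}) == []

    def test_matches_naive_substring_scan(self, rng):
        seq = "".join("ACGT"[i] for i in rng.integers(0, 4, 10000))
        hits = set(parts.scan_restriction_sites(seq))
        expected = set()
        for name, site in parts.DEFAULT_ENZYMES.items():
            rc = revcomp(site)
            for i in range(len(seq) - len(site) + 1):
                if seq[i : i + len(site)] == site:
                    expected.add((name, i, "+"))
                if seq[i : i + len(site)] == rc:
                    expected.add((name, i, "-"))
        assert hits == expected


class TestDomestication:
    def test_planted_site_removes_gene(self, genome_fixture, annotation):
        fx, _ = genome_fixture
        models, genome = annotation
        pairs = parts.extract_parts(models, genome)
        survivors = parts.domestication_filter(pairs)
        planted_genes = {g for g, _, _, _ in fx.planted_sites}
        assert planted_genes & set(survivors) == set()
        assert set(pairs) - set(survivors) == planted_genes

    def test_filters_commute(self, annotation):
        models, genome = annotation
        pairs = parts.extract_parts(models, genome)
        d_then_o = parts.overlap_filter(
            {g: pairs[g] for g in parts.domestication_filter(pairs)}, models
        )
        o_then_d = parts.domestication_filter(
            {g: pairs[g] for g in parts.overlap_filter(pairs, models)}
        )
        assert sorted(d_then_o) == sorted(o_then_d)


def test_part_sequences_reconstructible(annotation):
    """Every part is exactly the (strand-adjusted) genome slice it claims."""
    models, genome = annotation
    for pair in parts.extract_parts(models, genome).values():
        for p in pair:
            raw = genome[p.chrom][p.start : p.end]
            assert p.sequence == (raw if p.strand == "+" else revcomp(raw))
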