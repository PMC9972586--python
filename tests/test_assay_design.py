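import random

import pytest

from intronq.assay_design import (
    DesignParams,
    PrimerPair,
    cross_species_specificity,
    design_primer_pairs,
    enumerate_candidate_sites,
    insilico_pcr,
    melting_temperature,
    place_probe,
    verify_genomic_only,
)
from intronq.genome_io import GeneModel, GenomeSequence, Interval, reverse_complement
from oracles import naive_insilico_pcr, tm_nearest_neighbor


class TestMeltingTemperature:
    def test_matches_hand_summed_oracle_homopolymer(self):
        # all-identical steps: the oracle is a sum of one repeated NN term
        assert melting_temperature("A" * 10) == pytest.approx(
            tm_nearest_neighbor("A" * 10), abs=1e-9
        )

    def test_acgt_20mer_frozen_value(self):
        # independently hand-summed before the implementation existed
        assert melting_temperature("ACGT" * 5, 50.0, 500.0) == pytest.approx(
            58.0093, abs=1e-3
        )

    def test_matches_oracle_on_random_sequences(self):
        rng = random.Random(42)
        for _ in range(100):
            seq = "".join(rng.choice("ACGT") for _ in range(rng.randint(8, 30)))
            assert melting_temperature(seq) == pytest.approx(
                tm_nearest_neighbor(seq), abs=1e-9
            )

    def test_reverse_complement_symmetry(self):
        seq = "CTGACTCAGCCCTGCAAAG"
        assert melting_temperature(seq) == pytest.approx(
            melting_temperature(reverse_complement(seq)), abs=1e-9
        )

    def test_n_rejected(self):
        with pytest.raises(ValueError):
            melting_temperature("ACGTNACGT")

    def test_too_short_rejected(self):
        with pytest.raises(ValueError, match="short"):
            melting_temperature("ACGTACG")


class TestEnumerateCandidateSites:
    def _model(self, exon_lens, intron_lens):
        exons = []
        pos = 0
        for i, el in enumerate(exon_lens):
            exons.append(Interval(pos, pos + el))
            pos += el
            if i < len(intron_lens):
                pos += intron_lens[i]
        return GeneModel(gene_id="g", chrom="c", strand="+", exons=tuple(exons))

    def test_long_exon_excluded(self):
        model = self._model([90, 400, 100, 90, 80], [300, 300, 300, 300])
        sites = enumerate_candidate_sites(model)
        # internal exons are #2..#4; #2 (400 nt) is too long
        assert [s.exon.length for s in sites] == [100, 90]

    def test_single_exon_gene_empty(self):
        model = self._model([100], [])
        assert enumerate_candidate_sites(model) == []

    def test_short_intron_excludes_site(self):
        model = self._model([90, 100, 90], [10, 300])
        assert enumerate_candidate_sites(model) == []

    def test_sites_ordered_by_position(self):
        model = self._model([90, 100, 90, 100, 90], [300, 300, 300, 300])
        sites = enumerate_candidate_sites(model)
        starts = [s.exon.start for s in sites]
        assert starts == sorted(starts)


def _single_window_site():
    """A site engineered so exactly one primer window survives per intron.

    Each intron is poly-A (fails GC) except for one embedded 20-mer with
    ~55% GC that passes every filter.
    """
    good_f = "TGCACTGGATCCGCATGACT"  # 55% GC, no homopolymer > 2
    good_r = "AGTCATGCGGATCCAGTCCA"
    intron_up = "A" * 40 + good_f + "A" * 40
    exon = "ACGT" * 25  # 100 nt
    intron_down = "A" * 40 + good_r + "A" * 40
    flank = "T" * 30
    seq = flank + intron_up + exon + intron_down + flank
    genome = GenomeSequence(id="c", seq=seq)
    up = Interval(30, 30 + 100)
    ex = Interval(130, 230)
    down = Interval(230, 330)
    # Tm gate tuned so only the embedded windows themselves survive:
    # shifted windows land at <=60.13 or >=61.3 is impossible here
    params = DesignParams(
        primer_len_min=20,
        primer_len_max=20,
        tm_min=60.2,
        tm_opt=60.7,
        tm_max=61.3,
        amplicon_len_min=80,
        amplicon_len_max=300,
    )
    from intronq.assay_design import CandidateSite

    return CandidateSite(up, ex, down), genome, params, good_f, good_r


class TestDesignPrimerPairs:
    def test_engineered_single_pair(self):
        site, genome, params, good_f, good_r = _single_window_site()
        result = design_primer_pairs(site, genome, params, top_k=5)
        assert len(result.pairs) == 1
        pair = result.pairs[0]
        assert pair.forward_seq == good_f
        assert pair.reverse_seq == reverse_complement(good_r)
        # amplicon spans the exon
        assert pair.amplicon.contains(site.exon)
        # brute-force check: the oracle finds the same single product
        oracle = naive_insilico_pcr(pair.forward_seq, pair.reverse_seq, genome.seq)
        assert oracle == [(pair.amplicon.start, pair.amplicon.end)]

    def test_infeasible_tm_range_yields_tally(self):
        site, genome, params, *_ = _single_window_site()
        import dataclasses

        tight = dataclasses.replace(params, tm_min=90.0, tm_opt=95.0, tm_max=99.0)
        result = design_primer_pairs(site, genome, tight)
        assert result.pairs == ()
        assert result.rejections.get("tm", 0) > 0

    def test_deterministic(self, genome_pair):
        from intronq.genome_io import build_gene_models, parse_gff3

        import tempfile

        with tempfile.NamedTemporaryFile("w", suffix=".gff3") as fh:
            fh.write(genome_pair.gff_a)
            fh.flush()
            feats = parse_gff3(fh.name)
        model = max(build_gene_models(feats), key=lambda m: len(m.exons))
        sites = enumerate_candidate_sites(model)
        r1 = design_primer_pairs(sites[0], genome_pair.genome_a, top_k=5)
        r2 = design_primer_pairs(sites[0], genome_pair.genome_a, top_k=5)
        assert r1.pairs == r2.pairs

    def test_every_pair_is_genomic_only(self, genome_pair):
        from intronq.genome_io import build_gene_models, parse_gff3
        import tempfile

        with tempfile.NamedTemporaryFile("w", suffix=".gff3") as fh:
            fh.write(genome_pair.gff_a)
            fh.flush()
            feats = parse_gff3(fh.name)
        model = max(build_gene_models(feats), key=lambda m: len(m.exons))
        for site in enumerate_candidate_sites(model):
            for pair in design_primer_pairs(site, genome_pair.genome_a, top_k=5).pairs:
                ok, why = verify_genomic_only(pair, model)
                assert ok, why


class TestInsilicoPcr:
    def test_constructed_template_arithmetic(self):
        f = "TGCACTGGATCCGCATGACT"
        r = "AGTCATGCGGATCCAGTGGA"
        spacer = "A" * 150
        template = f + spacer + reverse_complement(r)
        products = insilico_pcr((f, r), template)
        assert len(products) == 1
        assert products[0].length == len(f) + 150 + len(r)
        assert products[0].sequence == template

    def test_missing_site_no_product(self):
        f = "TGCACTGGATCCGCATGACT"
        r = "AGTCATGCGGATCCAGTGGA"
        template = f + "A" * 200  # no reverse site
        assert insilico_pcr((f, r), template) == []

    def test_max_product_len_bound(self):
        f = "TGCACTGGATCCGCATGACT"
        r = "AGTCATGCGGATCCAGTGGA"
        template = f + "A" * 500 + reverse_complement(r)
        assert insilico_pcr((f, r), template, max_product_len=100) == []
        assert len(insilico_pcr((f, r), template, max_product_len=1000)) == 1

    def test_agrees_with_naive_oracle_random(self):
        rng = random.Random(123)
        for _ in range(100):
            n = rng.randint(200, 3000)
            template = "".join(rng.choice("ACGT") for _ in range(n))
            i = rng.randrange(0, n - 60)
            f = template[i : i + 20]
            j = rng.randrange(i + 20, min(n - 20, i + 1500))
            r = reverse_complement(template[j : j + 20])
            got = [
                (a.interval.start, a.interval.end) for a in insilico_pcr((f, r), template)
            ]
            assert got == naive_insilico_pcr(f, r, template)


class TestCrossSpeciesSpecificity:
    F = "TGCACTGGATCCGCATGACT"
    R = "ACGGTTCAGCTGAGACCTGA"  # unrelated to F on either strand

    def _amplicon(self):
        return self.F + "A" * 100 + reverse_complement(self.R)

    def test_planted_amplicon_fails(self):
        off = "T" * 50 + self._amplicon() + "T" * 50
        report = cross_species_specificity((self.F, self.R), off)
        assert report.verdict == "fail"
        assert len(report.off_target_products) == 1

    def test_forward_site_only_passes(self):
        off = "T" * 50 + self.F + "T" * 200
        report = cross_species_specificity((self.F, self.R), off)
        assert report.verdict == "pass"

    def test_two_mismatches_outside_seed_still_bind(self):
        f_mut = "ACCACTGGATCCGCATGACT"  # 2 mismatches at 5' end, seed intact
        off = "T" * 50 + f_mut + "A" * 100 + reverse_complement(self.R) + "T" * 50
        report = cross_species_specificity((self.F, self.R), off)
        assert report.verdict == "fail"

    def test_three_mismatches_do_not_bind(self):
        f_mut = "ACCTCTGGATCCGCATGACT"  # 3 mismatches outside seed
        off = "T" * 50 + f_mut + "A" * 100 + reverse_complement(self.R) + "T" * 50
        report = cross_species_specificity((self.F, self.R), off)
        assert report.verdict == "pass"

    def test_seed_mismatch_blocks_binding(self):
        # one mismatch inside the 12 nt 3' seed of the forward site
        f_mut = self.F[:-3] + "C" + self.F[-2:]
        assert f_mut != self.F
        off = "T" * 50 + f_mut + "A" * 100 + reverse_complement(self.R) + "T" * 50
        report = cross_species_specificity((self.F, self.R), off)
        assert report.verdict == "pass"


class TestVerifyGenomicOnly:
    def _pair(self, f_iv, r_iv):
        return PrimerPair(
            forward_seq="A" * f_iv.length,
            reverse_seq="T" * r_iv.length,
            forward_interval=f_iv,
            reverse_interval=r_iv,
            species_tag="x",
            tm_f=60.0,
            tm_r=60.0,
            gc_f=50.0,
            gc_r=50.0,
            amplicon=Interval(f_iv.start, r_iv.end),
            penalty=0.0,
        )

    def test_valid_pair_true(self, three_exon_model):
        # introns are [150,350) and [450,650)
        pair = self._pair(Interval(200, 220), Interval(500, 520))
        ok, why = verify_genomic_only(pair, three_exon_model)
        assert ok
        assert "exon" in why

    def test_primer_overlapping_exon_boundary(self, three_exon_model):
        pair = self._pair(Interval(331, 351), Interval(500, 520))  # 1 nt into exon 2
        ok, why = verify_genomic_only(pair, three_exon_model)
        assert not ok
        assert "exon 2" in why

    def test_same_intron_no_exon_spanned(self, three_exon_model):
        pair = self._pair(Interval(160, 180), Interval(300, 320))
        ok, why = verify_genomic_only(pair, three_exon_model)
        assert not ok
        assert "no exon spanned" in why


class TestPlaceProbe:
    def _pair_on(self, genome_seq, f_start, f_len, r_start, r_len):
        f_iv = Interval(f_start, f_start + f_len)
        r_iv = Interval(r_start, r_start + r_len)
        f = genome_seq[f_iv.start : f_iv.end]
        r = reverse_complement(genome_seq[r_iv.start : r_iv.end])
        return PrimerPair(
            forward_seq=f,
            reverse_seq=r,
            forward_interval=f_iv,
            reverse_interval=r_iv,
            species_tag="x",
            tm_f=melting_temperature(f),
            tm_r=melting_temperature(r),
            gc_f=50.0,
            gc_r=50.0,
            amplicon=Interval(f_iv.start, r_iv.end),
            penalty=0.0,
        )

    def test_gc_rich_internal_window_found(self):
        probe_core = "ACCGCGTGCGCACCGGCGCATCGCGG"  # high Tm, no leading G
        seq = "ATGCATGCATGCATGCATGA" + "ATAT" * 5 + probe_core + "ATAT" * 5 + "TCATGCATGCATGCATGCAT"
        pair = self._pair_on(seq, 0, 20, len(seq) - 20, 20)
        probe = place_probe(pair, seq)
        assert probe is not None
        assert probe.tm >= max(pair.tm_f, pair.tm_r) + 5.0
        assert not probe.seq.startswith("G")
        assert pair.forward_interval.end <= probe.interval.start
        assert probe.interval.end <= pair.reverse_interval.start

    def test_no_room_returns_none(self):
        seq = "ATGCATGCATGCATGCATGAATTCATGCATGCATGCATGCAT"
        pair = self._pair_on(seq, 0, 20, len(seq) - 20, 20)
        assert place_probe(pair, seq) is None


class TestPenaltyRankingTotalOrder:
    def test_top_k_stable_under_permutation(self, genome_pair):
        # the ranking key (penalty, f.start, r.start) is a total order, so
        # re-running on the same site can never reorder the result
        from intronq.genome_io import build_gene_models, parse_gff3
        import tempfile

        with tempfile.NamedTemporaryFile("w", suffix=".gff3") as fh:
            fh.write(genome_pair.gff_a)
            fh.flush()
            feats = parse_gff3(fh.name)
        model = max(build_gene_models(feats), key=lambda m: len(m.exons))
        site = enumerate_candidate_sites(model)[0]
        results = [
            design_primer_pairs(site, genome_pair.genome_a, top_k=8) for _ in range(3)
        ]
        assert results[0].pairs == results[1].pairs == results[2].pairs
        penalties = [p.penalty for p in results[0].pairs]
        assert penalties == sorted(penalties)
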