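"""Six-frame translation, profile scanning with splice snapping, chain DP."""

import itertools

import numpy as np
import pytest

from paraloscope.exon_profiles import build_profile_set
from paraloscope.genome_search import (
    ContigRecord,
    ExonHit,
    chain_hits_to_gene_models,
    revcomp,
    scan_for_exon_hits,
    six_frame_translate,
)
from paraloscope.pipeline import queries_from_bundle

UNIFORM = np.full(20, 0.05)


class TestSixFrame:
    def test_standard_code_forward(self):
        frames = six_frame_translate(ContigRecord("c", "ATGGCC"))
        fwd1 = next(f for f in frames if f.strand == "+" and f.frame == 1)
        assert fwd1.peptide == "MA"
        assert fwd1.codon_interval(0) == (1, 3)
        assert fwd1.codon_interval(1) == (4, 6)

    def test_frame_lengths_identity(self):
        frames = six_frame_translate(ContigRecord("c", "ATGCA"))
        for f in frames:
            assert len(f.peptide) == (5 - f.frame + 1) // 3

    def test_stops_and_ns(self):
        frames = six_frame_translate(ContigRecord("c", "TAANNN"))
        fwd1 = next(f for f in frames if f.strand == "+" and f.frame == 1)
        assert fwd1.peptide == "*X"

    @pytest.mark.parametrize("seed", range(4))
    def test_reverse_coordinate_map_self_consistency(self, seed, rng):
        # re-translating the mapped codon interval reproduces each residue
        seq = "".join(np.random.default_rng(seed).choice(list("ACGT"), size=61))
        contig = ContigRecord("c", seq)
        from paraloscope.genome_search import translate_cds

        for f in six_frame_translate(contig):
            for j, aa in enumerate(f.peptide):
                lo, hi = f.codon_interval(j)
                codon = seq[lo - 1: hi]
                if f.strand == "-":
                    codon = revcomp(codon)
                assert translate_cds(codon) == aa


def _plant_exon(rng, pep_nt, flank=40):
    left = "".join(rng.choice(list("ACGT"), size=flank))
    right = "".join(rng.choice(list("ACGT"), size=flank))
    return left + pep_nt, len(left)


class TestScan:
    def _profile_for(self, peptide, **kw):
        from paraloscope.exon_profiles import build_exon_profile

        return build_exon_profile([peptide], background=UNIFORM, **kw)

    def test_pure_n_contig_is_empty(self):
        prof = self._profile_for("MKWLVRAPGY")
        assert scan_for_exon_hits(prof, ContigRecord("c", "N" * 200)) == []

    def test_planted_undiverged_exon_found_exactly(self, easy_bundle):
        # generator truth is the oracle: interior exon boundaries snap to truth
        from paraloscope import io as pio

        queries, _ = queries_from_bundle(easy_bundle)
        ps = build_profile_set(queries)
        contigs = {cid: seq for cid, seq in easy_bundle.genome.contigs}
        # the query taxon's own genes are undiverged relative to the queries
        qt = "T01"
        checked = 0
        for t in easy_bundle.truth.by_taxon(qt):
            record = ContigRecord(t.exons[0].contig, contigs[t.exons[0].contig])
            for ex in t.exons:
                prof = ps.profiles.get((t.subfamily, ex.exon_number))
                if prof is None:
                    continue
                hits = scan_for_exon_hits(prof, record)
                overlapping = [
                    h for h in hits
                    if h.strand == t.strand and h.start <= ex.end and ex.start <= h.end
                ]
                assert len(overlapping) == 1
                h = overlapping[0]
                if 1 < ex.exon_number:
                    assert h.start == ex.start
                if ex.exon_number < len(t.exons):
                    assert h.end == ex.end
                checked += 1
        assert checked > 0

    def test_threshold_monotonicity(self, easy_bundle):
        queries, _ = queries_from_bundle(easy_bundle)
        ps = build_profile_set(queries)
        cid, seq = easy_bundle.genome.contigs[0]
        contig = ContigRecord(cid, seq)
        prof = next(iter(ps.profiles.values()))
        lo = scan_for_exon_hits(prof, contig, min_bits=0.3 * prof.max_score)
        hi = scan_for_exon_hits(prof, contig, min_bits=0.6 * prof.max_score)
        lo_keys = {(h.contig_id, h.strand, h.frame, h.start, h.end) for h in lo}
        hi_keys = {(h.contig_id, h.strand, h.frame, h.start, h.end) for h in hi}
        assert hi_keys <= lo_keys

    def test_strand_symmetry(self, easy_bundle):
        queries, _ = queries_from_bundle(easy_bundle)
        ps = build_profile_set(queries)
        cid, seq = easy_bundle.genome.contigs[0]
        prof = next(iter(ps.profiles.values()))
        fwd = scan_for_exon_hits(prof, ContigRecord(cid, seq))
        rev = scan_for_exon_hits(prof, ContigRecord(cid, revcomp(seq)))
        L = len(seq)
        reflect = {
            (L - h.end + 1, L - h.start + 1, "-" if h.strand == "+" else "+",
             round(h.score, 6))
            for h in fwd
        }
        got = {(h.start, h.end, h.strand, round(h.score, 6)) for h in rev}
        assert got == reflect


def _mk_hit(contig, strand, exon, start, end, score):
    return ExonHit(
        contig_id=contig, strand=strand, frame=1, start=start, end=end,
        peptide="M" * ((end - start + 1) // 3), paralog="P", exon_index=exon,
        score=score, acceptor_status="unsnapped", donor_status="unsnapped",
    )


def _chain_valid(subset, bounds, allow_split):
    from paraloscope.genome_search import _compatible

    chain = sorted(subset, key=lambda h: h.exon_index)
    if any(a.exon_index >= b.exon_index for a, b in zip(chain, chain[1:])):
        return False
    return all(
        _compatible(a, b, bounds, allow_split) for a, b in zip(chain, chain[1:])
    )


class TestChaining:
    BOUNDS = (40, 20000)

    def test_collinear_three_exons_form_one_chain(self):
        hits = [
            _mk_hit("c", "+", 1, 100, 199, 10.0),
            _mk_hit("c", "+", 2, 300, 399, 12.0),
            _mk_hit("c", "+", 3, 500, 599, 11.0),
        ]
        out = chain_hits_to_gene_models(hits, self.BOUNDS)
        assert len(out) == 1
        assert [h.exon_index for h in out[0].hits] == [1, 2, 3]
        assert out[0].total_score == pytest.approx(33.0)

    def test_wrong_genomic_order_never_chained(self):
        hits = [
            _mk_hit("c", "+", 2, 100, 199, 10.0),
            _mk_hit("c", "+", 1, 300, 399, 12.0),
        ]
        out = chain_hits_to_gene_models(hits, self.BOUNDS)
        assert all(len(c.hits) == 1 for c in out)

    def test_minus_strand_order(self):
        # on the minus strand, later exons have smaller forward coordinates
        hits = [
            _mk_hit("c", "-", 1, 500, 599, 10.0),
            _mk_hit("c", "-", 2, 300, 399, 10.0),
        ]
        out = chain_hits_to_gene_models(hits, self.BOUNDS)
        assert len(out) == 1 and len(out[0].hits) == 2

    def test_conflicting_duplicate_hits_rejected(self):
        hits = [
            _mk_hit("c", "+", 1, 100, 199, 10.0),
            _mk_hit("c", "+", 1, 100, 199, 11.0),
        ]
        with pytest.raises(ValueError):
            chain_hits_to_gene_models(hits, self.BOUNDS)

    @pytest.mark.parametrize("allow_split", [False, True])
    def test_dp_matches_exhaustive_enumeration(self, allow_split):
        # brute force over all hit subsets is the oracle for the first chain
        rng = np.random.default_rng(42)
        for _ in range(300):
            n = int(rng.integers(2, 7))
            hits = []
            for k in range(n):
                contig = f"c{rng.integers(1, 3)}"
                strand = "+" if rng.random() < 0.8 else "-"
                start = int(rng.integers(1, 4000))
                end = start + 3 * int(rng.integers(10, 40)) - 1
                hits.append(
                    _mk_hit(contig, strand, int(rng.integers(1, 5)), start, end,
                            float(rng.uniform(1, 20)))
                )
            try:
                out = chain_hits_to_gene_models(hits, self.BOUNDS, allow_split)
            except ValueError:
                continue  # duplicate coordinates drawn
            best_dp = out[0].total_score
            best_brute = 0.0
            for r in range(1, n + 1):
                for subset in itertools.combinations(hits, r):
                    idx = [h.exon_index for h in subset]
                    if len(set(idx)) != len(idx):
                        continue
                    if _chain_valid(subset, self.BOUNDS, allow_split):
                        best_brute = max(
                            best_brute, sum(h.score for h in subset)
                        )
            assert best_dp == pytest.approx(best_brute)
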