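"""Variant post-processing: pileup, filters, spectra, rescue, host check."""

import itertools
from math import comb, log10

import numpy as np
import pytest

import xenopart as xp
from xenopart.readio import AlignmentObservation
from xenopart.variants import (
    FILTER_LOW_DEPTH,
    FILTER_LOW_QUAL,
    FILTER_SNP_CLUSTER,
    FILTER_STRAND_BIAS,
    SPECTRUM_CLASSES,
    substitution_class,
)


def _vr(chrom="c", pos=100, ref="G", alt="A", qual=200.0, depth=50,
        ad=(40, 10), sb=(20, 20, 5, 5), **kw):
    return xp.VariantRecord(chrom=chrom, pos=pos, ref=ref, alt=alt, qual=qual,
                            depth=depth, allele_depths=ad, strand_table=sb, **kw)


def _obs(fid, pos, seq, strand="+", mapq=60, proper=True, dup=False, quals=None):
    return AlignmentObservation(
        id=fid, mate=1, mapped=True, mapq=mapq, proper_pair=proper,
        reference="c", position=pos, strand=strand, duplicate=dup,
        sequence=seq, qualities=quals or [30] * len(seq), ref_span=len(seq),
    )


class TestPileup:
    def test_all_ref_reads(self):
        obs = [_obs(f"F{i}", 95, "ACGTACGTAC") for i in range(10)]
        pile = xp.pileup_allele_counts(obs, "c", 100)
        # offset 5 within each read -> base 'C'
        assert pile.depth_after_filters == 10
        assert pile.count_of("C") == 10

    def test_exclusions_tallied(self):
        good = _obs("F1", 95, "ACGTACGTAC")
        mapq255 = _obs("F2", 95, "ACGTACGTAC", mapq=255)
        dup = _obs("F3", 95, "ACGTACGTAC", dup=True)
        improper = _obs("F4", 95, "ACGTACGTAC", proper=False)
        lowq = _obs("F5", 95, "ACGTACGTAC", quals=[5] * 10)
        pile = xp.pileup_allele_counts([good, mapq255, dup, improper, lowq], "c", 100)
        assert pile.depth_after_filters == 1
        assert pile.excluded_mapq_unavailable == 1
        assert pile.excluded_duplicate == 1
        assert pile.excluded_improper == 1
        assert pile.excluded_low_baseq == 1

    def test_uncovered_locus_zero_depth(self):
        pile = xp.pileup_allele_counts([_obs("F1", 95, "ACGT")], "c", 5000)
        assert pile.depth_after_filters == 0

    def test_matches_bruteforce_base_extraction(self):
        rng = np.random.default_rng(61)
        obs = []
        locus = 500
        for i in range(200):
            start = int(rng.integers(locus - 120, locus + 5))
            seq = "".join(rng.choice(list("ACGT"), size=101))
            strand = "+" if rng.random() < 0.5 else "-"
            quals = list(rng.integers(10, 41, size=101))
            obs.append(_obs(f"F{i}", start, seq, strand=strand, quals=quals))
        pile = xp.pileup_allele_counts(obs, "c", locus, min_base_q=20)
        expected = {}
        for o in obs:
            off = locus - o.position
            if not 0 <= off < 101 or o.qualities[off] < 20:
                continue
            f, r = expected.get(o.sequence[off], (0, 0))
            expected[o.sequence[off]] = (f + 1, r) if o.strand == "+" else (f, r + 1)
        assert pile.base_counts == expected

    def test_spiked_vaf_one_alt_equals_depth(self):
        pair = xp.evolve_genomes(3000, 0.12, seed=62)
        params = xp.SimParams(n_pairs=400, host_fraction=0.0, error_rate=0.0, seed=62)
        reads, labels = xp.simulate_mixture(pair, params)
        site = 1500
        ref = pair.graft_sequence[site]
        alt = "T" if ref != "T" else "A"
        spiked = xp.spike_variants(
            pair, reads, labels, [xp.SpikeVariant(site, ref, alt, 1.0)], seed=63
        )
        obs = xp.truth_alignments(spiked, labels)
        pile = xp.pileup_allele_counts(obs, "graft", site + 1)
        assert pile.depth_after_filters > 10
        assert pile.count_of(alt) == pile.depth_after_filters


def _fisher_oracle(a, b, c, d):
    """Two-sided Fisher exact p by exhaustive hypergeometric enumeration."""
    r1, r2, c1 = a + b, c + d, a + c
    n = r1 + r2
    denom = comb(n, c1)
    p_obs = comb(r1, a) * comb(r2, c) / denom
    total = 0.0
    for x in range(max(0, c1 - r2), min(r1, c1) + 1):
        p = comb(r1, x) * comb(r2, c1 - x) / denom
        if p <= p_obs * (1 + 1e-7):
            total += p
    return min(total, 1.0)


class TestFisherStrand:
    def test_balanced_table_zero(self):
        assert xp.fisher_strand_phred((5, 5, 5, 5)) == pytest.approx(0.0)

    @pytest.mark.parametrize("k", [1, 3, 10, 25])
    def test_scaled_balanced_tables_zero(self, k):
        assert xp.fisher_strand_phred((k, k, k, k)) == pytest.approx(0.0)

    def test_extreme_table_matches_enumeration(self):
        got = xp.fisher_strand_phred((10, 0, 0, 10))
        want = -10 * log10(_fisher_oracle(10, 0, 0, 10))
        assert got == pytest.approx(want, rel=1e-6)

    def test_random_tables_match_enumeration(self):
        rng = np.random.default_rng(71)
        for _ in range(300):
            a, b, c, d = (int(x) for x in rng.integers(0, 25, size=4))
            if a + b + c + d == 0:
                continue
            got = xp.fisher_strand_phred((a, b, c, d))
            want = min(10_000.0, -10 * log10(max(_fisher_oracle(a, b, c, d), 1e-1000)))
            assert got == pytest.approx(want, rel=1e-4, abs=1e-6)

    def test_all_zero_rejected(self):
        with pytest.raises(ValueError):
            xp.fisher_strand_phred((0, 0, 0, 0))


def _cluster_oracle(records, count, window):
    """All-windows scan: tag SNVs in any run of >= count SNVs within window."""
    snvs = [(i, r) for i, r in enumerate(records) if r.is_snv]
    tagged = set()
    for js in itertools.combinations(range(len(snvs)), count):
        rs = [snvs[j][1] for j in js]
        if len({r.chrom for r in rs}) != 1:
            continue
        if rs[-1].pos - rs[0].pos <= window and all(
            js[i + 1] == js[i] + 1 for i in range(count - 1)
        ):
            tagged.update(snvs[j][0] for j in js)
    return tagged


class TestSnpClusters:
    def test_three_snvs_in_window_all_tagged(self):
        recs = [_vr(pos=p) for p in (100, 104, 108)]
        out = xp.flag_snp_clusters(recs, 3, 10)
        assert all(FILTER_SNP_CLUSTER in r.filters for r in out)

    def test_two_snvs_not_enough(self):
        recs = [_vr(pos=p) for p in (100, 105)]
        out = xp.flag_snp_clusters(recs, 3, 10)
        assert not any(FILTER_SNP_CLUSTER in r.filters for r in out)

    def test_indels_do_not_participate(self):
        recs = [_vr(pos=100), _vr(pos=104, ref="GA", alt="G"), _vr(pos=108)]
        out = xp.flag_snp_clusters(recs, 3, 10)
        assert not any(FILTER_SNP_CLUSTER in r.filters for r in out)

    def test_unsorted_input_rejected(self):
        with pytest.raises(ValueError, match="sorted"):
            xp.flag_snp_clusters([_vr(pos=200), _vr(pos=100)], 3, 10)

    def test_matches_sliding_enumeration_oracle(self):
        rng = np.random.default_rng(81)
        for _ in range(20):
            positions = sorted(int(p) for p in rng.integers(1, 300, size=30))
            recs = [_vr(pos=p) for p in positions]
            out = xp.flag_snp_clusters(recs, 3, 10)
            got = {i for i, r in enumerate(out) if FILTER_SNP_CLUSTER in r.filters}
            assert got == _cluster_oracle(recs, 3, 10)


class TestHardFilters:
    def test_clean_record_passes(self):
        (out,) = xp.apply_hard_filters([_vr(depth=100, qual=200.0, sb=(25, 25, 25, 25))])
        assert out.filters == set()

    def test_boundary_depth(self):
        (out,) = xp.apply_hard_filters([_vr(depth=4)])
        assert FILTER_LOW_DEPTH in out.filters
        (out,) = xp.apply_hard_filters([_vr(depth=5)])
        assert FILTER_LOW_DEPTH not in out.filters

    def test_low_qual_and_strand_bias(self):
        (out,) = xp.apply_hard_filters([_vr(qual=49.9, sb=(30, 0, 0, 30))])
        assert {FILTER_LOW_QUAL, FILTER_STRAND_BIAS} <= out.filters

    def test_missing_strand_table_errors(self):
        with pytest.raises(ValueError, match="strand table"):
            xp.apply_hard_filters([_vr(sb=None)])

    def _random_records(self, n, seed):
        rng = np.random.default_rng(seed)
        recs = []
        pos = 0
        for _ in range(n):
            pos += int(rng.integers(1, 40))
            sb = tuple(int(x) for x in rng.integers(0, 30, size=4))
            if sum(sb) == 0:
                sb = (1, 1, 0, 0)
            recs.append(
                _vr(
                    pos=pos,
                    depth=int(rng.integers(0, 30)),
                    qual=float(rng.integers(0, 200)),
                    sb=sb,
                )
            )
        return recs

    def test_pass_set_matches_bruteforce_reapplication(self):
        recs = self._random_records(1000, seed=91)
        cfg = xp.FilterConfig()
        out = xp.apply_hard_filters(recs, cfg)
        clustered = set()
        for i in range(len(recs) - cfg.cluster_count + 1):
            run = recs[i : i + cfg.cluster_count]
            if run[-1].pos - run[0].pos <= cfg.cluster_window:
                clustered.update(range(i, i + cfg.cluster_count))
        for i, (r, o) in enumerate(zip(recs, out)):
            expected = set()
            if r.depth < 5:
                expected.add(FILTER_LOW_DEPTH)
            if r.qual < 50:
                expected.add(FILTER_LOW_QUAL)
            if xp.fisher_strand_phred(r.strand_table) >= 60:
                expected.add(FILTER_STRAND_BIAS)
            if i in clustered:
                expected.add(FILTER_SNP_CLUSTER)
            assert o.filters == expected

    def test_idempotence(self):
        recs = self._random_records(300, seed=92)
        once = xp.apply_hard_filters(recs)
        twice = xp.apply_hard_filters(once)
        assert [r.filters for r in once] == [r.filters for r in twice]


class TestSomaticAndKnown:
    def test_shared_variant_excluded(self):
        s = [_vr(pos=100), _vr(pos=200)]
        c = [_vr(pos=100)]
        assert [r.pos for r in xp.subtract_germline(s, c)] == [200]

    def test_empty_control_identity(self):
        s = [_vr(pos=p) for p in (1, 2, 3)]
        assert xp.subtract_germline(s, []) == s

    def test_matches_bruteforce_membership(self):
        rng = np.random.default_rng(93)
        sample = [_vr(pos=int(p)) for p in rng.choice(10_000, 500, replace=False)]
        control = [_vr(pos=int(p)) for p in rng.choice(10_000, 500, replace=False)]
        got = {r.key for r in xp.subtract_germline(sample, control)}
        ckeys = {r.key for r in control}
        assert got == {r.key for r in sample if r.key not in ckeys}

    def test_annotate_known_flags_and_ratio(self):
        recs = [_vr(pos=p) for p in (10, 20, 30)]
        out, summary = xp.annotate_known(recs, {("c", 10, "G", "A"), ("c", 30, "G", "A")})
        assert [r.known for r in out] == [True, False, True]
        assert summary.n_known == 2 and summary.n_novel == 1
        assert summary.known_to_novel_ratio == pytest.approx(2.0)

    def test_annotate_empty_table_all_novel(self):
        out, summary = xp.annotate_known([_vr(pos=1)], set())
        assert out[0].known is False and summary.n_known == 0

    def test_known_sites_loader_rejects_malformed(self, tmp_path):
        path = tmp_path / "known.tsv"
        path.write_text("c\t10\tG\tA\nc\tbad\tG\tA\n")
        with pytest.raises(ValueError, match=":2"):
            xp.variants.load_known_sites(path)


class TestSpectrum:
    def test_c_to_t_collapses_with_g_to_a(self):
        counts, _ = xp.mutation_spectrum([_vr(ref="C", alt="T")])
        assert counts["G>A/C>T"] == 1

    def test_twelve_raw_substitutions_spread_evenly(self):
        recs = [
            _vr(ref=r, alt=a)
            for r in "ACGT" for a in "ACGT" if r != a
        ]
        counts, props = xp.mutation_spectrum(recs)
        assert all(c == 2 for c in counts.values())
        assert all(p == pytest.approx(1 / 6) for p in props.values())

    def test_complement_involution(self):
        rng = np.random.default_rng(94)
        comp = {"A": "T", "C": "G", "G": "C", "T": "A"}
        recs = []
        for _ in range(100):
            r, a = rng.choice(list("ACGT"), size=2, replace=False)
            recs.append(_vr(ref=str(r), alt=str(a)))
        flipped = [_vr(ref=comp[r.ref], alt=comp[r.alt]) for r in recs]
        assert xp.mutation_spectrum(recs)[0] == xp.mutation_spectrum(flipped)[0]

    def test_proportions_sum_to_one(self):
        recs = [_vr(ref="G", alt="T") for _ in range(7)] + [_vr(ref="A", alt="G")]
        counts, props = xp.mutation_spectrum(recs)
        assert sum(counts.values()) == 8
        assert sum(props.values()) == pytest.approx(1.0)

    def test_ref_equals_alt_rejected(self):
        with pytest.raises(ValueError):
            substitution_class("A", "A")

    def test_transition_biased_simulation_recovers_proportions(self):
        pair = xp.evolve_genomes(150_000, 0.12, seed=95)
        ts_frac = 0.8
        variants = xp.generate_spike_variants(
            pair, n_variants=400, vaf=0.5, transition_fraction=ts_frac, seed=96
        )
        recs = [
            _vr(chrom="graft", pos=v.position + 1, ref=v.ref_base, alt=v.alt_base)
            for v in variants
        ]
        _, props = xp.mutation_spectrum(recs)
        ts_classes = {"A>G/T>C", "G>A/C>T"}
        got_ts = sum(props[c] for c in ts_classes)
        assert abs(got_ts - ts_frac) < 5 * np.sqrt(ts_frac * (1 - ts_frac) / 400)


def _pile(alt_count, depth, alt="A", ref="G"):
    return xp.PileupCounts(
        chrom="c", pos=100,
        base_counts={ref: (depth - alt_count, 0), alt: (alt_count, 0)},
    )


class TestRescue:
    def test_subclonal_detection(self):
        cat = xp.rescue_classify(_vr(), _pile(5, 100))
        assert cat == xp.RescueCategory.DETECTED_BELOW_THRESHOLD

    def test_low_depth(self):
        assert xp.rescue_classify(_vr(), _pile(2, 8)) == (
            xp.RescueCategory.NOT_DETECTED_LOW_DEPTH
        )

    def test_no_alt(self):
        assert xp.rescue_classify(_vr(), _pile(0, 50)) == (
            xp.RescueCategory.NOT_DETECTED_NO_ALT
        )

    def test_called_at_threshold(self):
        assert xp.rescue_classify(_vr(), _pile(2, 10)) == xp.RescueCategory.CALLED

    def test_rule_table_at_boundaries(self):
        cfg = xp.FilterConfig()

        def oracle(alt, depth):
            if depth < 10:
                return xp.RescueCategory.NOT_DETECTED_LOW_DEPTH
            if depth and alt / depth >= 0.2:
                return xp.RescueCategory.CALLED
            if alt >= 1:
                return xp.RescueCategory.DETECTED_BELOW_THRESHOLD
            return xp.RescueCategory.NOT_DETECTED_NO_ALT

        for depth in (9, 10, 11, 50, 100):
            for alt in range(0, depth + 1):
                got = xp.rescue_classify(_vr(), _pile(alt, depth), cfg)
                assert got == oracle(alt, depth), (alt, depth)


class TestHostWindowCheck:
    def test_graft_reads_not_host_alignable(self, genome_pair, host_index):
        params = xp.SimParams(n_pairs=60, host_fraction=0.0, error_rate=0.001, seed=97)
        reads, labels = xp.simulate_mixture(genome_pair, params)
        obs = xp.truth_alignments(reads, labels)
        locus = 10_000
        examined, alignable = xp.host_window_check(
            "graft", locus, obs, host_index, window=1000
        )
        assert examined > 0
        assert alignable == 0

    def test_injected_host_reads_recovered_exactly(self, genome_pair, host_index):
        params = xp.SimParams(n_pairs=40, host_fraction=0.0, error_rate=0.001, seed=98)
        reads, labels = xp.simulate_mixture(genome_pair, params)
        obs = xp.truth_alignments(reads, labels)
        locus = 10_000
        k = 5
        hseq = genome_pair.host_sequence
        injected = [
            _obs(f"HOSTREAD{i}", locus - 50 + i, hseq[2000 + 200 * i : 2101 + 200 * i])
            for i in range(k)
        ]
        for o in injected:
            o.reference = "graft"
        examined, alignable = xp.host_window_check(
            "graft", locus, obs + injected, host_index, window=1000
        )
        assert alignable == k

    def test_empty_window(self, host_index):
        assert xp.host_window_check("graft", 10, [], host_index) == (0, 0)
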