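"""Filter cascade, class codes, novelty partition, summary statistics."""

import numpy as np
import pytest

from lincscan.models import GeneLocus, TranscriptModel, ValidationError
from lincscan.transcripts import (FilterThresholds, call_novel,
                                  classify_class_code, filter_candidates,
                                  summarize_transcripts)

from conftest import random_transcript


def make_tx(tid="t1", exons=((0, 100), (200, 400)), fpkm=5.0, cov=10.0,
            cpc=-1.0, hits=(), chrom="chr1"):
    return TranscriptModel(id=tid, chrom=chrom, strand="+",
                           exons=list(exons), fpkm=fpkm, coverage=cov,
                           cpc_score=cpc, homology_hits=list(hits))


def test_malformed_exon_structure_names_the_transcript():
    with pytest.raises(ValidationError, match="bad_tx"):
        TranscriptModel(id="bad_tx", chrom="chr1", strand="+",
                        exons=[(100, 200), (150, 300)], fpkm=1, coverage=1)
    with pytest.raises(ValidationError, match="empty_tx"):
        TranscriptModel(id="empty_tx", chrom="chr1", strand="+",
                        exons=[(100, 100)], fpkm=1, coverage=1)


class TestFilterCascade:
    def test_single_exon_rejected_even_if_otherwise_strong(self):
        t = make_tx(exons=[(0, 500)], fpkm=5, cov=10, cpc=-1)
        kept, log = filter_candidates([t])
        assert not kept and log.failed_rule.tolist() == ["exon_count"]

    def test_length_rule_is_inclusive_at_200(self):
        short = make_tx("short", exons=[(0, 100), (200, 299)])  # 199 nt
        exact = make_tx("exact", exons=[(0, 100), (200, 300)])  # 200 nt
        kept, log = filter_candidates([short, exact])
        assert [t.id for t in kept] == ["exact"]
        assert log.set_index("transcript_id").failed_rule["short"] == "length"

    def test_conjunction_of_all_rules_retains(self):
        kept, log = filter_candidates([make_tx()])
        assert len(kept) == 1 and log.empty

    def test_boundary_values_are_exclusive_for_fpkm_and_coverage(self):
        assert not filter_candidates([make_tx(fpkm=1.0)])[0]
        assert not filter_candidates([make_tx(cov=3.0)])[0]
        assert not filter_candidates([make_tx(cpc=0.0)])[0]

    def test_significant_hit_needs_both_length_and_evalue(self):
        assert not filter_candidates([make_tx(hits=[(31, 1e-4)])])[0]
        assert filter_candidates([make_tx(hits=[(30, 1e-4)])])[0]
        assert filter_candidates([make_tx(hits=[(31, 1e-3)])])[0]

    def test_random_transcripts_match_naive_reevaluation(self):
        rng = np.random.default_rng(42)
        txs = [random_transcript(rng, f"t{i}") for i in range(500)]
        for t in txs:
            if rng.random() < 0.3:
                t.homology_hits = [(float(rng.integers(10, 100)),
                                    float(10 ** rng.uniform(-8, 0)))]
        kept, _ = filter_candidates(txs)
        # independent per-rule re-check
        def naive(t):
            sig = any(ln > 30 and ev < 1e-3 for ln, ev in t.homology_hits)
            return (t.exon_count >= 2 and t.fpkm > 1 and t.coverage > 3
                    and t.length >= 200 and t.cpc_score < 0 and not sig)
        assert {t.id for t in kept} == {t.id for t in txs if naive(t)}

    def test_filtering_is_idempotent(self):
        rng = np.random.default_rng(1)
        txs = [random_transcript(rng, f"t{i}") for i in range(200)]
        kept, _ = filter_candidates(txs)
        again, log = filter_candidates(kept)
        assert [t.id for t in again] == [t.id for t in kept] and log.empty

    def test_locus_with_a_hit_transcript_is_abandoned_whole(self):
        clean = make_tx("a1")
        hit = make_tx("a2", hits=[(100, 1e-30)])
        locus = GeneLocus(id="L1", chrom="chr1", start=0, end=400,
                          biotype="lincRNA_candidate",
                          transcript_ids=["a1", "a2"])
        kept, log = filter_candidates([clean, hit], loci=[locus])
        assert not kept
        rules = dict(zip(log.transcript_id, log.failed_rule))
        assert rules == {"a1": "homology_locus", "a2": "homology"}

    def test_missing_cpc_score_is_an_error_when_filter_enabled(self):
        t = make_tx()
        t.cpc_score = None
        with pytest.raises(ValidationError, match="cpc_score"):
            filter_candidates([t])


class TestClassCodes:
    def test_identical_intron_chain_is_equals(self):
        q = make_tx("q", exons=[(0, 100), (200, 300)])
        r = make_tx("r", exons=[(10, 100), (200, 310)])
        assert classify_class_code(q, [r]) == ("=", "r")

    def test_disjoint_and_distant_is_u(self):
        q = make_tx("q", exons=[(0, 100), (200, 300)])
        r = make_tx("r", exons=[(10_000, 10_500)])
        assert classify_class_code(q, [r])[0] == "u"
        assert classify_class_code(q, []) == ("u", None)

    def test_runon_distance_controls_p(self):
        q = make_tx("q", exons=[(1000, 1400)])
        r = make_tx("r", exons=[(0, 100), (200, 500)])
        assert classify_class_code(q, [r], runon_distance=2000)[0] == "p"
        assert classify_class_code(q, [r], runon_distance=400)[0] == "u"

    def test_contained_single_exon_is_c(self):
        q = make_tx("q", exons=[(220, 280)])
        r = make_tx("r", exons=[(0, 100), (200, 300)])
        assert classify_class_code(q, [r])[0] == "c"

    def test_random_pairs_match_exhaustive_predicate_oracle(self):
        """1000 random (query, reference) pairs vs a base-set oracle that
        evaluates the five predicates from scratch."""
        rng = np.random.default_rng(7)

        def oracle(q, r, runon=2000):
            qb = {p for s, e in q.exons for p in range(s, e)}
            rb = {p for s, e in r.exons for p in range(s, e)}
            qi, ri = set(q.introns), set(r.introns)
            if q.introns and list(q.introns) == list(r.introns):
                return "="
            if qb <= rb and qi <= ri:
                return "c"
            if qi & ri:
                return "j"
            if qb & rb:
                return "o"
            gap = max(r.start - q.end, q.start - r.end)
            if 0 <= gap <= runon:
                return "p"
            return "u"

        for i in range(1000):
            q = random_transcript(rng, "q", max_start=3000)
            if rng.random() < 0.5:
                # derive the reference from the query to hit =, c, j often
                r = TranscriptModel(id="r", chrom="chr1", strand="+",
                                    exons=list(q.exons), fpkm=0, coverage=0)
                if rng.random() < 0.5 and len(r.exons) > 1:
                    r = TranscriptModel(id="r", chrom="chr1", strand="+",
                                        exons=r.exons[:-1], fpkm=0, coverage=0)
            else:
                r = random_transcript(rng, "r", max_start=6000)
            assert classify_class_code(q, [r])[0] == oracle(q, r), (q.exons,
                                                                    r.exons)

    def test_equals_implies_shared_junction_predicate(self):
        rng = np.random.default_rng(3)
        for _ in range(200):
            q = random_transcript(rng, "q", n_exons=int(rng.integers(2, 5)))
            r = TranscriptModel(id="r", chrom="chr1", strand="+",
                                exons=list(q.exons), fpkm=0, coverage=0)
            code, _ = classify_class_code(q, [r])
            assert code == "="
            assert set(q.introns) & set(r.introns)  # the 'j' predicate holds


class TestNoveltyPartition:
    def _locus(self, lid, tids):
        return GeneLocus(id=lid, chrom="chr1", start=0, end=1000,
                         biotype="lincRNA_candidate", transcript_ids=tids)

    def test_any_known_code_makes_locus_known(self):
        known, novel = call_novel([self._locus("L", ["a", "b"])],
                                  {"a": "=", "b": "u"})
        assert [l.id for l in known] == ["L"] and not novel

    def test_all_u_is_novel(self):
        known, novel = call_novel([self._locus("L", ["a", "b"])],
                                  {"a": "u", "b": "u"})
        assert [l.id for l in novel] == ["L"] and not known

    def test_missing_code_is_an_error(self):
        with pytest.raises(ValidationError):
            call_novel([self._locus("L", ["a"])], {})

    def test_partition_matches_set_arithmetic(self):
        rng = np.random.default_rng(5)
        loci = [self._locus(f"L{i}", [f"t{i}_{j}" for j in range(
            rng.integers(1, 4))]) for i in range(100)]
        codes = {t: rng.choice(list("=cjopu"))
                 for l in loci for t in l.transcript_ids}
        known, novel = call_novel(loci, codes)
        expect_known = {l.id for l in loci
                        if any(codes[t] in "=cjop" for t in l.transcript_ids)}
        assert {l.id for l in known} == expect_known
        assert {l.id for l in novel} == {l.id for l in loci} - expect_known
        assert len(known) + len(novel) == len(loci)


class TestSummary:
    def test_hand_cases(self):
        txs = [make_tx("a", exons=[(0, 100)]),
               make_tx("b", exons=[(0, 100), (200, 300)]),
               make_tx("c", exons=[(0, 200), (300, 400)])]
        s = summarize_transcripts(txs)
        assert s["median_length"] == 200  # lengths 100, 200, 300
        assert summarize_transcripts(txs[1:])["mean_exon_count"] == 2.0

    def test_mean_exons(self):
        txs = [make_tx("a", exons=[(0, 100), (200, 250)]),
               make_tx("b", exons=[(0, 50), (100, 150), (200, 250)])]
        assert summarize_transcripts(txs)["mean_exon_count"] == 2.5

    def test_empty_list_rejected(self):
        with pytest.raises(ValidationError):
            summarize_transcripts([])
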