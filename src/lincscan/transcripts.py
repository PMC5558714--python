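"""Candidate lincRNA filtering, structural class codes, and novelty calls.

The filter cascade keeps assembled intergenic transcripts that look like
credible lincRNAs: multi-exonic, expressed, well covered, >=200 nt, with a
negative coding-potential score and no significant protein homology. Loci
containing any transcript with a significant protein hit are abandoned
whole, since one coding transcript discredits the locus.

Class codes describe a query transcript's structural relation to the best
matching reference transcript ('=' identical intron chain, 'c' contained,
'j' shared junction, 'o' exonic overlap, 'p' possible run-on within a
configurable distance, 'u' unrelated). Loci whose transcripts match a known
lncRNA reference (any code other than 'u') are known; the rest are novel.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

from .models import GeneLocus, TranscriptModel, ValidationError


@dataclass(frozen=True)
class FilterThresholds:
    """Retention thresholds; a transcript must satisfy ALL rules.

    Defaults: exon number > 1, FPKM > 1, coverage > 3, length >= 200 nt,
    coding-potential score < 0, and no homology hit with alignment length
    > 30 bp at e-value < 0.001.
    """

    min_exons: int = 2
    min_fpkm: float = 1.0  # exclusive
    min_coverage: float = 3.0  # exclusive
    min_length: int = 200  # inclusive
    max_cpc: float = 0.0  # exclusive upper bound (score must be < this)
    hit_min_aln_len: float = 30.0  # hits longer than this ...
    hit_max_evalue: float = 1e-3  # ... and below this e-value are significant
    require_cpc: bool = True
    require_homology: bool = True


RULE_ORDER = ("exon_count", "fpkm", "coverage", "length", "cpc", "homology")


def has_significant_hit(t: TranscriptModel, th: FilterThresholds) -> bool:
    return any(ln > th.hit_min_aln_len and ev < th.hit_max_evalue
               for ln, ev in t.homology_hits)


def _first_failed_rule(t: TranscriptModel, th: FilterThresholds) -> str | None:
    if t.exon_count < th.min_exons:
        return "exon_count"
    if not t.fpkm > th.min_fpkm:
        return "fpkm"
    if not t.coverage > th.min_coverage:
        return "coverage"
    if t.length < th.min_length:
        return "length"
    if th.require_cpc:
        if t.cpc_score is None:
            raise ValidationError(f"transcript {t.id}: cpc_score missing")
        if not t.cpc_score < th.max_cpc:
            return "cpc"
    if th.require_homology and has_significant_hit(t, th):
        return "homology"
    return None


def filter_candidates(
    transcripts: list[TranscriptModel],
    thresholds: FilterThresholds = FilterThresholds(),
    loci: list[GeneLocus] | None = None,
) -> tuple[list[TranscriptModel], pd.DataFrame]:
    """Apply the six-rule cascade; returns (retained, rejection_log).

    The rejection log records the first failed rule per rejected transcript.
    When `loci` is given, the homology rule acts at locus level: every
    transcript of a locus containing a significantly-hit transcript is
    dropped (logged as 'homology_locus' unless it failed a rule itself).
    """
    failed = {t.id: _first_failed_rule(t, thresholds) for t in transcripts}

    doomed_loci: set[str] = set()
    if loci is not None and thresholds.require_homology:
        hit_tids = {t.id for t in transcripts if has_significant_hit(t, thresholds)}
        for locus in loci:
            if any(tid in hit_tids for tid in locus.transcript_ids):
                doomed_loci.add(locus.id)
        tid_to_locus = {tid: l.id for l in loci for tid in l.transcript_ids}
        for t in transcripts:
            if failed[t.id] is None and tid_to_locus.get(t.id) in doomed_loci:
                failed[t.id] = "homology_locus"

    retained = [t for t in transcripts if failed[t.id] is None]
    log = pd.DataFrame(
        [{"transcript_id": tid, "failed_rule": rule}
         for tid, rule in failed.items() if rule is not None],
        columns=["transcript_id", "failed_rule"],
    )
    return retained, log


# --- structural class codes -------------------------------------------------

CODE_PRECEDENCE = ("=", "c", "j", "o", "p", "u")


def _exonic_overlap_bp(a: TranscriptModel, b: TranscriptModel) -> int:
    total = 0
    for s1, e1 in a.exons:
        for s2, e2 in b.exons:
            total += max(0, min(e1, e2) - max(s1, s2))
    return total


def _contained_in(query: TranscriptModel, ref: TranscriptModel) -> bool:
    """Query exon chain contained in the reference's with a consistent
    intron subset: every query intron is a reference intron and every query
    exon base falls inside reference exons."""
    ref_introns = set(ref.introns)
    if any(i not in ref_introns for i in query.introns):
        return False
    ref_exons = ref.exons
    for qs, qe in query.exons:
        if not any(rs <= qs and qe <= re_ for rs, re_ in ref_exons):
            return False
    return True


def _code_vs_reference(query: TranscriptModel, ref: TranscriptModel,
                       runon_distance: int) -> str:
    if ref.chrom != query.chrom:
        return "u"
    q_introns, r_introns = query.introns, ref.introns
    shared_junctions = len(set(q_introns) & set(r_introns))
    if q_introns and q_introns == r_introns:
        return "="
    if _contained_in(query, ref):
        return "c"
    if shared_junctions >= 1:
        return "j"
    if _exonic_overlap_bp(query, ref) >= 1:
        return "o"
    gap = max(ref.start - query.end, query.start - ref.end)
    if 0 <= gap <= runon_distance:
        return "p"
    return "u"


def classify_class_code(
    query: TranscriptModel,
    reference: list[TranscriptModel],
    runon_distance: int = 2000,
) -> tuple[str, str | None]:
    """Best class code of `query` against a reference set.

    Returns (code, reference transcript id) with the highest-precedence code
    over all references (= > c > j > o > p > u). Ties between references at
    the same code are broken by more shared junctions, then larger exonic
    overlap, then lexicographic reference id. An empty reference set yields
    ('u', None).
    """
    best: tuple[int, int, int, str] | None = None  # rank, -shared, -overlap, id
    best_code = "u"
    for ref in reference:
        code = _code_vs_reference(query, ref, runon_distance)
        rank = CODE_PRECEDENCE.index(code)
        shared = len(set(query.introns) & set(ref.introns))
        overlap = _exonic_overlap_bp(query, ref)
        key = (rank, -shared, -overlap, ref.id)
        if best is None or key < best:
            best, best_code = key, code
    if best is None or best_code == "u":
        return "u", None
    return best_code, best[3]


KNOWN_MATCHING_CODES = frozenset("=cjop")


def call_novel(
    loci: list[GeneLocus], codes: dict[str, str]
) -> tuple[list[GeneLocus], list[GeneLocus]]:
    """Partition loci into (known_matching, novel).

    A locus matches the known reference iff any member transcript carries a
    code in {=, c, j, o, p}; loci whose transcripts are all 'u' are novel.
    """
    known, novel = [], []
    for locus in loci:
        for tid in locus.transcript_ids:
            if tid not in codes:
                raise ValidationError(f"transcript {tid} has no class code")
        if any(codes[tid] in KNOWN_MATCHING_CODES for tid in locus.transcript_ids):
            known.append(locus)
        else:
            novel.append(locus)
    return known, novel


def summarize_transcripts(transcripts: list[TranscriptModel]) -> dict[str, float]:
    """Median transcript length (bp) and mean exon count."""
    if not transcripts:
        raise ValidationError("cannot summarize an empty transcript list")
    lengths = sorted(t.length for t in transcripts)
    n = len(lengths)
    median = (lengths[n // 2] if n % 2 else
              (lengths[n // 2 - 1] + lengths[n // 2]) / 2)
    mean_exons = sum(t.exon_count for t in transcripts) / n
    return {"median_length": float(median), "mean_exon_count": mean_exons}
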