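"""Guide off-target scanning and the whole-exome variant filter chain.

The screen has two halves:

* :func:`scan_sites` enumerates every position in a reference sequence
  (both strands) where a 20-mer followed by an NRG/NGG PAM matches the
  guide protospacer under the permissive rule used for embryo exome
  screens: at most ``max_mismatches`` Hamming mismatches over the full
  protospacer, **or** a perfect match of the PAM-proximal ``seed_len``
  bases (the 3' seed).  The seed clause carries no cap on total
  mismatches — a site with 8 distal mismatches but a perfect 10-nt seed
  still qualifies, matching observed Cas9 behaviour at paralogous loci.
* The filter chain (:func:`run_chain`) takes an exome variant table and
  applies, in fixed order: exon overlap, read support (> 2 reads),
  low-complexity overlap, flanking homopolymer (> 7 bp run in the
  +/-100 bp flank), and finally flank adjudication, which re-scans each
  surviving variant's flank for a guide match and splits survivors into
  on-target and off-target calls.

Every variant carries a :class:`FilterTrace` recording, stage by stage,
whether it was retained and why — the audit trail that makes attrition
tables and ablation tests possible.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from intervaltree import IntervalTree
from numpy.lib.stride_tricks import sliding_window_view

from .errors import InputError

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")

#: Fixed stage order of the exome filter chain.
CHAIN_STAGES = (
    "exonic",
    "read_support",
    "low_complexity",
    "homopolymer",
    "flank_match",
)

# PAM patterns as per-position allowed-base sets (protospacer strand, 5'->3').
_PAM_PATTERNS = {
    "NRG": ("ACGT", "AG", "G"),
    "NGG": ("ACGT", "G", "G"),
}


def revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def longest_homopolymer(seq: str) -> int:
    """Length of the longest single-base run in ``seq`` (0 for empty)."""
    best = run = 0
    prev = ""
    for base in seq:
        run = run + 1 if base == prev else 1
        prev = base
        if run > best:
            best = run
    return best


@dataclass(frozen=True)
class GuideRule:
    """Matching rule for one guide.

    Parameters mirror the exome off-target screen: 20-nt protospacer,
    <=6 mismatches or a perfect 3' 10-nt seed, NRG PAM, and +/-100 bp
    flanks around candidate variants.
    """

    protospacer: str
    max_mismatches: int = 6
    seed_len: int = 10
    pam_pattern: str = "NRG"
    flank: int = 100

    def __post_init__(self) -> None:
        if len(self.protospacer) != 20:
            raise InputError(
                f"protospacer must be 20 nt, got {len(self.protospacer)}"
            )
        if set(self.protospacer) - set("ACGT"):
            raise InputError("protospacer must be over ACGT")
        if not 1 <= self.seed_len <= len(self.protospacer):
            raise InputError("seed_len must lie in [1, protospacer length]")
        if self.pam_pattern not in _PAM_PATTERNS:
            raise InputError(f"unknown PAM pattern {self.pam_pattern!r}")
        if self.max_mismatches < 0 or self.flank < 0:
            raise InputError("max_mismatches and flank must be non-negative")


@dataclass(frozen=True)
class OffTargetHit:
    """One guide match in a reference sequence.

    ``start`` is the 0-based coordinate of the leftmost protospacer base
    on the forward (+) strand of the scanned sequence, regardless of hit
    strand.  ``site_seq``/``pam_seq`` are strand-oriented (read 5'->3'
    on the hit strand).
    """

    seq_id: str
    start: int
    strand: str
    site_seq: str
    pam_seq: str
    n_mismatches: int
    seed_perfect: bool
    qualifies_by: str  # mismatch_rule | seed_rule | both


def _scan_oriented(seq: str, rule: GuideRule) -> list[tuple[int, str, str, int, bool]]:
    """Scan one orientation; returns (start, site, pam, n_mm, seed) tuples."""
    n = len(rule.protospacer)
    width = n + 3
    if len(seq) < width:
        return []
    arr = np.frombuffer(seq.encode("ascii"), dtype="S1")
    windows = sliding_window_view(arr, width)
    guide = np.frombuffer(rule.protospacer.encode("ascii"), dtype="S1")
    # N in the reference never matches a guide base; byte inequality covers it.
    mm = (windows[:, :n] != guide).sum(axis=1)
    seed = (windows[:, n - rule.seed_len : n] == guide[n - rule.seed_len :]).all(axis=1)
    pam_ok = np.ones(len(windows), dtype=bool)
    for k, allowed in enumerate(_PAM_PATTERNS[rule.pam_pattern]):
        col = windows[:, n + k]
        ok = np.zeros(len(windows), dtype=bool)
        for base in allowed:
            ok |= col == base.encode("ascii")
        pam_ok &= ok
    qualifies = pam_ok & ((mm <= rule.max_mismatches) | seed)
    out = []
    for i in np.nonzero(qualifies)[0]:
        i = int(i)
        out.append((i, seq[i : i + n], seq[i + n : i + n + 3], int(mm[i]), bool(seed[i])))
    return out


def scan_sites(references, rule: GuideRule) -> list[OffTargetHit]:
    """Enumerate guide matches on both strands of each reference sequence.

    ``references`` is an iterable of ``(seq_id, sequence)`` pairs or a
    mapping ``{seq_id: sequence}``.  A position qualifies when a PAM of
    the configured pattern immediately follows the 20-mer *and* either
    the Hamming mismatch count is within ``rule.max_mismatches`` or the
    3' seed matches perfectly (no cap on total mismatches).  Hits are
    sorted by (seq_id, start, strand).
    """
    if hasattr(references, "items"):
        references = references.items()
    hits: list[OffTargetHit] = []
    for seq_id, seq in references:
        seq = str(seq).upper()
        if set(seq) - set("ACGTN"):
            bad = sorted(set(seq) - set("ACGTN"))
            raise InputError(f"sequence {seq_id!r} contains non-ACGTN characters {bad}")
        n = len(rule.protospacer)
        for start, site, pam, n_mm, seed in _scan_oriented(seq, rule):
            hits.append(
                OffTargetHit(seq_id, start, "+", site, pam, n_mm, seed,
                             _qualifier(n_mm, seed, rule))
            )
        rc = revcomp(seq)
        for start, site, pam, n_mm, seed in _scan_oriented(rc, rule):
            genomic_start = len(seq) - start - n
            hits.append(
                OffTargetHit(seq_id, genomic_start, "-", site, pam, n_mm, seed,
                             _qualifier(n_mm, seed, rule))
            )
    hits.sort(key=lambda h: (h.seq_id, h.start, h.strand))
    return hits


def _qualifier(n_mm: int, seed_perfect: bool, rule: GuideRule) -> str:
    by_mm = n_mm <= rule.max_mismatches
    if by_mm and seed_perfect:
        return "both"
    return "mismatch_rule" if by_mm else "seed_rule"


# ---------------------------------------------------------------------------
# Variant records and filter traces
# ---------------------------------------------------------------------------


@dataclass
class VariantRecord:
    """One exome variant (VCF-style 1-based position)."""

    id: str
    chrom: str
    pos: int
    ref: str
    alt: str
    support: int
    flank_seq: str | None = None

    @property
    def vtype(self) -> str:
        return "snv" if len(self.ref) == len(self.alt) == 1 else "indel"

    @property
    def span(self) -> tuple[int, int]:
        """0-based half-open interval covered by the REF allele."""
        return (self.pos - 1, self.pos - 1 + len(self.ref))


@dataclass
class FilterTrace:
    variant_id: str
    stages: list[tuple[str, bool, str]] = field(default_factory=list)

    @property
    def final(self) -> str:
        return "retained" if all(ok for _, ok, _ in self.stages) else "removed"

    def add(self, stage: str, retained: bool, reason: str) -> None:
        self.stages.append((stage, retained, reason))


def _ensure_traces(records, traces):
    if traces is None:
        traces = {}
    for rec in records:
        traces.setdefault(rec.id, FilterTrace(rec.id))
    return traces


def _interval_trees(intervals):
    trees: dict[str, IntervalTree] = {}
    for chrom, start, end in intervals:
        if end <= start:
            raise InputError(f"malformed interval {chrom}:{start}-{end} (end <= start)")
        trees.setdefault(chrom, IntervalTree()).addi(start, end)
    return trees


def _overlaps(trees, rec: VariantRecord) -> bool:
    tree = trees.get(rec.chrom)
    if tree is None:
        return False
    start, end = rec.span
    return bool(tree.overlap(start, end))


def filter_exonic(records, exon_intervals, traces=None):
    """Retain variants overlapping any exon interval (0-based half-open)."""
    traces = _ensure_traces(records, traces)
    trees = _interval_trees(exon_intervals)
    kept = []
    for rec in records:
        inside = _overlaps(trees, rec)
        traces[rec.id].add("exonic", inside,
                           "overlaps exon" if inside else "outside exon regions")
        if inside:
            kept.append(rec)
    return kept, traces


def filter_support(records, traces=None, min_reads: int = 3):
    """Retain variants with read support of at least ``min_reads``.

    The default of 3 encodes 'more than two reads'.
    """
    traces = _ensure_traces(records, traces)
    kept = []
    for rec in records:
        if rec.support < 0:
            raise InputError(f"variant {rec.id}: negative read support")
        ok = rec.support >= min_reads
        traces[rec.id].add("read_support", ok,
                           f"support={rec.support} (threshold >= {min_reads})")
        if ok:
            kept.append(rec)
    return kept, traces


def filter_low_complexity(records, lc_intervals, traces=None):
    """Remove variants overlapping supplied low-complexity intervals.

    With ``lc_intervals=None`` the stage passes everything and says so in
    the trace (the annotation track is an input, not computed here).
    """
    traces = _ensure_traces(records, traces)
    if lc_intervals is None:
        for rec in records:
            traces[rec.id].add("low_complexity", True, "no low-complexity intervals supplied")
        return list(records), traces
    trees = _interval_trees(lc_intervals)
    kept = []
    for rec in records:
        hit = _overlaps(trees, rec)
        traces[rec.id].add("low_complexity", not hit,
                           "overlaps low-complexity region" if hit else "clear")
        if not hit:
            kept.append(rec)
    return kept, traces


def filter_homopolymer(records, traces=None, max_run: int = 7):
    """Remove variants whose flank contains a homopolymer longer than ``max_run``.

    '> 7 bp' is read strictly: an 8-base run removes, a 7-base run does not.
    """
    traces = _ensure_traces(records, traces)
    kept = []
    for rec in records:
        if rec.flank_seq is None:
            raise InputError(f"variant {rec.id}: flank sequence missing")
        run = longest_homopolymer(rec.flank_seq)
        ok = run <= max_run
        traces[rec.id].add("homopolymer", ok,
                           f"longest run {run} (threshold > {max_run} removes)")
        if ok:
            kept.append(rec)
    return kept, traces


def adjudicate_flank(records, rule: GuideRule, target_sites=(), traces=None):
    """Final stage: re-scan each survivor's flank for a guide match.

    A variant whose flank contains no qualifying site is removed as
    background.  A hit whose genomic coordinates coincide exactly with a
    declared target site makes the variant an on-target call; any other
    hit makes it off-target.  Returns ``(calls, traces)`` where calls
    maps variant id -> ("on_target" | "off_target", best hit).
    """
    traces = _ensure_traces(records, traces)
    site_set = {(c, int(s), st) for c, s, st in target_sites}
    calls: dict[str, tuple[str, OffTargetHit]] = {}
    for rec in records:
        if rec.flank_seq is None:
            raise InputError(f"variant {rec.id}: flank sequence missing")
        hits = scan_sites([(rec.id, rec.flank_seq)], rule)
        if not hits:
            traces[rec.id].add("flank_match", False, "no guide match in flank")
            continue
        offset = rec.pos - 1 - rule.flank  # local flank coord -> genomic coord
        on_hits = [h for h in hits
                   if (rec.chrom, h.start + offset, h.strand) in site_set]
        if on_hits:
            best = min(on_hits, key=lambda h: h.n_mismatches)
            calls[rec.id] = ("on_target", best)
            reason = "matches designed target site"
        else:
            best = min(hits, key=lambda h: (h.n_mismatches, h.start))
            calls[rec.id] = ("off_target", best)
            reason = f"guide match ({best.qualifies_by}, {best.n_mismatches} mm)"
        traces[rec.id].add("flank_match", True, reason)
    return calls, traces


@dataclass
class ChainResult:
    survivors: list[tuple[VariantRecord, str, OffTargetHit]]
    traces: dict[str, FilterTrace]
    attrition: pd.DataFrame


def run_chain(records, exons, lc, rule: GuideRule, target_sites=()) -> ChainResult:
    """Run the full filter chain in fixed order and tabulate attrition.

    Order: exonic -> read_support -> low_complexity -> homopolymer ->
    flank adjudication.  The attrition table reports, per stage, how many
    variants entered, were removed, and the removal percentage; removed
    counts plus final survivors always sum to the input count.
    """
    traces: dict[str, FilterTrace] = {}
    rows = []
    current = list(records)

    def record_stage(name, before, after):
        n_in, n_out = len(before), len(after)
        rows.append({
            "stage": name,
            "n_in": n_in,
            "n_removed": n_in - n_out,
            "pct_removed": round(100.0 * (n_in - n_out) / n_in, 2) if n_in else 0.0,
        })

    step = current
    current, traces = filter_exonic(step, exons, traces)
    record_stage("exonic", step, current)
    step = current
    current, traces = filter_support(step, traces)
    record_stage("read_support", step, current)
    step = current
    current, traces = filter_low_complexity(step, lc, traces)
    record_stage("low_complexity", step, current)
    step = current
    current, traces = filter_homopolymer(step, traces)
    record_stage("homopolymer", step, current)
    step = current
    calls, traces = adjudicate_flank(step, rule, target_sites, traces)
    survivors = [(rec, calls[rec.id][0], calls[rec.id][1])
                 for rec in step if rec.id in calls]
    record_stage("flank_match", step, survivors)

    return ChainResult(survivors=survivors, traces=traces,
                       attrition=pd.DataFrame(rows))


def trace_table(traces: dict[str, FilterTrace]) -> pd.DataFrame:
    """Flatten traces into a tidy per-(variant, stage) table."""
    rows = []
    for trace in traces.values():
        for stage, retained, reason in trace.stages:
            rows.append({"variant_id": trace.variant_id, "stage": stage,
                         "retained": retained, "reason": reason})
        rows.append({"variant_id": trace.variant_id, "stage": "FINAL",
                     "retained": trace.final == "retained", "reason": trace.final})
    return pd.DataFrame(rows)
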