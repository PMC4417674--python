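"""Conversion-tract extraction and crossover vs non-crossover assessment.

When the target locus in an embryo shows paralog-templated HDR (a run of
paralog bases at the discriminating positions), the repair may have been
reciprocal (crossover: the paralog locus picks up target bases) or
uni-directional (non-crossover DSBR or SDSA: the paralog stays intact).
Sequencing the *paralog* locus from the same embryo distinguishes the
two — provided it amplified at all.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass

import pandas as pd

from .errors import ContractError
from .outcomes import CallParams, ReadCall, align_read
from .synthetic import COMPLEX, HDR_PARALOG, HDR_PARTIAL, LocusPair

VERDICTS = ("non_crossover", "crossover", "indeterminate")


@dataclass(frozen=True)
class ConversionTract:
    embryo_id: str
    positions_converted: tuple[int, ...]
    tract_bounds: tuple[int, int]  # minimal half-open interval covering them
    n_converted: int


def detect_tract(call: ReadCall, locus: LocusPair) -> ConversionTract:
    """Extract the gene-conversion footprint from a paralog-HDR read."""
    if call.category not in (HDR_PARALOG, COMPLEX):
        raise ContractError(
            f"detect_tract expects HDR_PARALOG or COMPLEX, got {call.category}"
        )
    disc = set(locus.disc_coords)
    converted = tuple(p for p, s in call.signature_states if s == "paralog" and p in disc)
    if not converted:
        return ConversionTract(call.embryo_id, (), (0, 0), 0)
    return ConversionTract(
        embryo_id=call.embryo_id,
        positions_converted=converted,
        tract_bounds=(min(converted), max(converted) + 1),
        n_converted=len(converted),
    )


@dataclass(frozen=True)
class CrossoverCall:
    embryo_id: str
    paralog_amplified: bool
    paralog_has_target_bases: bool
    paralog_has_cut_indel: bool  # reported separately from the verdict
    verdict: str

    def __post_init__(self):
        assert self.verdict in VERDICTS


def assess_crossover(embryo_id: str, paralog_reads, locus: LocusPair,
                     paralog_amplified: bool = True, min_support: int = 1,
                     params: CallParams = CallParams()) -> CrossoverCall:
    """Decide crossover vs non-crossover from paralog-locus clone reads.

    Reads are aligned to the paralog reference.  The paralog carries
    target bases when any discriminating position reads the *target*
    base in at least ``min_support`` reads (1 by default: clones are
    single molecules).  Crossover requires amplification plus target
    bases; an intact paralog gives non-crossover; a failed amplification
    is indeterminate.  Cut-window indels on the paralog are flagged
    separately — they break "intact" but are not sequence exchange.

    The verdict is invariant to read order and read duplication.
    """
    reads = [r if isinstance(r, str) else r.seq for r in paralog_reads]
    if not paralog_amplified:
        if reads:
            raise ContractError(f"embryo {embryo_id}: reads supplied but paralog not amplified")
        return CrossoverCall(embryo_id, False, False, False, "indeterminate")
    if not reads:
        raise ContractError(f"embryo {embryo_id}: paralog amplified but no reads supplied")

    cut = locus.cut_site
    r = params.cut_window_radius
    support = Counter()
    has_cut_indel = False
    for seq in set(reads):  # duplicates carry no extra evidence for min_support=1
        n_copies = reads.count(seq)
        aln = align_read(seq, locus.paralog_seq)
        if any(i.overlaps(cut - r, cut + r) for i in aln.indels):
            has_cut_indel = True
        for pos, tb, _pb in locus.discriminating_positions:
            if aln.base_at(pos) == tb:
                support[pos] += n_copies
    has_target = any(n >= min_support for n in support.values())
    verdict = "crossover" if has_target else "non_crossover"
    return CrossoverCall(embryo_id, True, has_target, has_cut_indel, verdict)


def pathway_report(crossover_calls, partial_conversion_calls=()) -> pd.DataFrame:
    """Tabulate repair-pathway evidence across embryos.

    One row per verdict with counts over both denominators (amplified
    paralog loci only, and all assessed embryos), plus a row counting
    partial-conversion alleles.  Partial conversions are annotated
    'SDSA-consistent': sequence alone cannot distinguish SDSA from
    non-crossover DSBR, so this is an annotation, not a mechanism call.
    """
    calls = list(crossover_calls)
    partials = [c for c in partial_conversion_calls if c.category == HDR_PARTIAL]
    n_amplified = sum(c.paralog_amplified for c in calls)
    rows = []
    for verdict in VERDICTS:
        n = sum(c.verdict == verdict for c in calls)
        rows.append({
            "row": verdict,
            "count": n,
            "denominator_amplified": n_amplified,
            "denominator_all": len(calls),
            "note": "",
        })
    rows.append({
        "row": "partial_conversion_alleles",
        "count": len(partials),
        "denominator_amplified": n_amplified,
        "denominator_all": len(calls),
        "note": "SDSA-consistent (annotation only)",
    })
    return pd.DataFrame(rows)
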