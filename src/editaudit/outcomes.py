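"""Per-read outcome classification and per-embryo/experiment summaries.

Each clone read is globally aligned to the target reference (affine-gap
Needleman-Wunsch via Biopython's PairwiseAligner: match +2, mismatch -2,
gap of length L scores -(6 + L)), indels are left-normalized, and the
read is classified by a fixed precedence rule:

1. an indel overlapping the cut window ([cut-5, cut+5) by default) is
   Cas9-attributed: NHEJ_INDEL, or COMPLEX if HDR signatures are also
   present on the same read;
2. all donor signature positions reading the donor base -> HDR_OLIGO;
3. a run of >= ``min_tract_run`` consecutive discriminating positions
   reading the paralog base -> HDR_PARALOG (gene conversion);
4. some but not all donor signatures, no cut indel -> HDR_PARTIAL;
5. otherwise WT when the read is identical to the reference, COMPLEX
   when it carries anything else (stray substitutions, indels far from
   the cut).

Categories are mutually exclusive and exhaustive under this rule.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass

import pandas as pd
from Bio import Align

from .errors import ContractError, InputError
from .synthetic import (
    COMPLEX,
    HDR_OLIGO,
    HDR_PARALOG,
    HDR_PARTIAL,
    NHEJ_INDEL,
    WT,
    DonorOligo,
    LocusPair,
)

_ALPHABET = set("ACGTN")


def _make_aligner() -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score = 2.0
    aligner.mismatch_score = -2.0
    # gap of length L costs 6 + L: open -6 plus -1 per gapped base
    aligner.open_gap_score = -7.0
    aligner.extend_gap_score = -1.0
    return aligner


_ALIGNER = _make_aligner()


@dataclass(frozen=True)
class Indel:
    """One indel in target coordinates (left-normalized)."""

    pos: int  # deletion: first deleted base; insertion: bases enter before pos
    length: int
    kind: str  # "del" | "ins"
    bases: str = ""  # inserted bases (empty for deletions)

    @property
    def descriptor(self) -> str:
        if self.kind == "del":
            return f"del@{self.pos}x{self.length}"
        return f"ins@{self.pos}:{self.bases}"

    def overlaps(self, start: int, end: int) -> bool:
        # an insertion occupies no reference space; treat it as the point [pos, pos+1)
        lo, hi = (self.pos, self.pos + self.length) if self.kind == "del" else (self.pos, self.pos + 1)
        return lo < end and hi > start


@dataclass
class ReadAlignment:
    """Global alignment of a read against the target reference."""

    target: str
    read: str
    score: float
    indels: tuple[Indel, ...]
    _read_index: dict[int, int]  # target pos -> read pos (matched columns only)

    def base_at(self, target_pos: int) -> str:
        """Read base aligned to ``target_pos``, or '-' if deleted."""
        idx = self._read_index.get(target_pos)
        return "-" if idx is None else self.read[idx]


def _left_normalize(indel: Indel, target: str) -> Indel:
    pos, length = indel.pos, indel.length
    if indel.kind == "del":
        while pos > 0 and target[pos - 1] == target[pos + length - 1]:
            pos -= 1
        return Indel(pos, length, "del")
    bases = indel.bases
    while pos > 0 and target[pos - 1] == bases[-1]:
        bases = bases[-1] + bases[:-1]
        pos -= 1
    return Indel(pos, length, "ins", bases)


def align_read(read: str, target_seq: str) -> ReadAlignment:
    """Globally align ``read`` to ``target_seq`` and extract indels.

    Deterministic: among co-optimal alignments Biopython's first is
    taken, and every indel is then shifted to its leftmost equivalent
    placement, so descriptors are canonical regardless of repeat
    context.
    """
    read = read.upper()
    target_seq = target_seq.upper()
    if not read or not target_seq:
        raise InputError("read and target must be non-empty")
    if set(read) - _ALPHABET or set(target_seq) - _ALPHABET:
        raise InputError("sequences must be over ACGTN")
    aln = _ALIGNER.align(target_seq, read)[0]
    coords = aln.coordinates  # rows: target, read
    indels: list[Indel] = []
    read_index: dict[int, int] = {}
    for k in range(coords.shape[1] - 1):
        t0, t1 = int(coords[0, k]), int(coords[0, k + 1])
        r0, r1 = int(coords[1, k]), int(coords[1, k + 1])
        if t1 > t0 and r1 > r0:  # aligned block
            for off in range(t1 - t0):
                read_index[t0 + off] = r0 + off
        elif t1 > t0:  # gap in read: deletion of target[t0:t1]
            indels.append(Indel(t0, t1 - t0, "del"))
        elif r1 > r0:  # gap in target: insertion before t0
            indels.append(Indel(t0, r1 - r0, "ins", read[r0:r1]))
    indels = tuple(_left_normalize(i, target_seq) for i in indels)
    return ReadAlignment(target=target_seq, read=read, score=float(aln.score),
                         indels=indels, _read_index=read_index)


# ---------------------------------------------------------------------------
# Classification
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class CallParams:
    """Classifier knobs.

    ``cut_window_radius``: indels overlapping [cut-r, cut+r) are
    attributed to Cas9.  ``min_tract_run``: minimum number of
    *consecutive* discriminating positions reading the paralog base to
    call gene conversion (2 by default; a single converted base could be
    a PCR or sequencing artifact).
    """

    cut_window_radius: int = 5
    min_tract_run: int = 2


@dataclass
class ReadCall:
    """Outcome call for one clone read."""

    read_id: str
    embryo_id: str
    category: str
    indel: Indel | None
    signature_states: tuple[tuple[int, str], ...]  # (target pos, ref|donor|paralog|other)
    alignment_score: float
    cut_disrupted: bool  # an indel overlapped the cut window

    @property
    def allele_key(self) -> str:
        """Canonical allele pattern: indel descriptor + signature states."""
        ind = self.indel.descriptor if self.indel else "-"
        states = ",".join(f"{p}:{s[0]}" for p, s in self.signature_states)
        return f"{ind}|{states}"

    @property
    def has_hdr_signature(self) -> bool:
        return any(s in ("donor", "paralog") for _, s in self.signature_states)


def _max_paralog_run(states: dict[int, str], disc_coords) -> int:
    best = run = 0
    for pos in disc_coords:
        run = run + 1 if states.get(pos) == "paralog" else 0
        best = max(best, run)
    return best


def call_read(alignment: ReadAlignment, locus: LocusPair, donor: DonorOligo | None,
              params: CallParams = CallParams(), read_id: str = "",
              embryo_id: str = "") -> ReadCall:
    """Classify one aligned read under the precedence rule.

    Total on valid alignments: every read receives exactly one category.
    ``donor=None`` disables the oligo-HDR branches (no exogenous
    template in the experiment).
    """
    if alignment.target != locus.target_seq:
        raise ContractError("alignment was not produced against this locus target")
    cut = locus.cut_site
    r = params.cut_window_radius
    win_lo, win_hi = cut - r, cut + r

    sig_positions = donor.signature_positions if donor else ()
    informative = sorted(
        {p for p, _, _ in sig_positions} | set(locus.disc_coords)
    )
    donor_by_pos = {p: db for p, _rb, db in sig_positions}
    paralog_by_pos = {p: pb for p, _tb, pb in locus.discriminating_positions}

    states: dict[int, str] = {}
    for pos in informative:
        base = alignment.base_at(pos)
        if base == locus.target_seq[pos]:
            states[pos] = "ref"
        elif base == donor_by_pos.get(pos):
            states[pos] = "donor"
        elif base == paralog_by_pos.get(pos):
            states[pos] = "paralog"
        else:
            states[pos] = "other"

    cut_indels = [i for i in alignment.indels if i.overlaps(win_lo, win_hi)]
    cut_disrupted = bool(cut_indels)
    donor_states = [states[p] for p in donor_by_pos]
    donor_all = bool(donor_states) and all(s == "donor" for s in donor_states)
    donor_any = any(s == "donor" for s in donor_states)
    tract_run = _max_paralog_run(states, locus.disc_coords)
    has_signature = donor_any or tract_run >= params.min_tract_run

    if cut_disrupted:
        category = COMPLEX if has_signature else NHEJ_INDEL
    elif donor_all:
        category = HDR_OLIGO
    elif tract_run >= params.min_tract_run:
        category = HDR_PARALOG
    elif donor_any:
        category = HDR_PARTIAL
    else:
        identical = not alignment.indels and all(s == "ref" for s in states.values()) \
            and alignment.read == locus.target_seq
        category = WT if identical else COMPLEX

    recorded = cut_indels[0] if cut_indels else (alignment.indels[0] if alignment.indels else None)
    return ReadCall(
        read_id=read_id,
        embryo_id=embryo_id,
        category=category,
        indel=recorded,
        signature_states=tuple((p, states[p]) for p in informative),
        alignment_score=alignment.score,
        cut_disrupted=cut_disrupted,
    )


def classify_reads(reads, locus: LocusPair, donor: DonorOligo | None,
                   params: CallParams = CallParams()) -> list[ReadCall]:
    """Align and classify a batch of (read_id, embryo_id, seq) records."""
    calls = []
    for read_id, embryo_id, seq in reads:
        aln = align_read(seq, locus.target_seq)
        calls.append(call_read(aln, locus, donor, params, read_id=read_id,
                               embryo_id=embryo_id))
    return calls


# ---------------------------------------------------------------------------
# Summaries
# ---------------------------------------------------------------------------


@dataclass
class EmbryoSummary:
    embryo_id: str
    amplified: bool
    cleaved: bool
    hdr_oligo: bool
    hdr_paralog: bool
    allele_spectrum: dict[str, int]
    n_distinct_alleles: int

    @property
    def mosaic(self) -> bool:
        return self.n_distinct_alleles >= 2


def summarize_embryo(calls: list[ReadCall], embryo_id: str,
                     amplified: bool = True) -> EmbryoSummary:
    """Aggregate one embryo's read calls into cleavage/HDR flags and an
    allele spectrum.

    An embryo is 'cleaved' when at least one read shows Cas9 evidence: a
    cut-window indel or an HDR signature (donor or paralog bases cannot
    appear without a repaired break).
    """
    if amplified and not calls:
        raise ContractError(f"embryo {embryo_id}: amplified but no reads supplied")
    if any(c.embryo_id != embryo_id for c in calls):
        raise ContractError("calls from multiple embryos passed to summarize_embryo")
    if not amplified and calls:
        raise ContractError(f"embryo {embryo_id}: reads supplied for a dropout embryo")
    spectrum = Counter(c.allele_key for c in calls)
    cleaved = any(c.cut_disrupted or c.has_hdr_signature for c in calls)
    return EmbryoSummary(
        embryo_id=embryo_id,
        amplified=amplified,
        cleaved=cleaved,
        hdr_oligo=any(c.category == HDR_OLIGO for c in calls),
        hdr_paralog=any(c.category == HDR_PARALOG for c in calls),
        allele_spectrum=dict(sorted(spectrum.items())),
        n_distinct_alleles=len(spectrum),
    )


@dataclass
class ExperimentSummary:
    """Cohort-level counts; percentages are always recomputed from them."""

    n_embryos_injected: int
    n_amplified: int
    n_cleaved: int
    n_hdr_oligo: int
    n_hdr_paralog: int

    @property
    def pct_cleaved(self) -> float:
        if self.n_amplified == 0:
            raise ContractError("percent cleaved undefined: no amplified embryos")
        return 100.0 * self.n_cleaved / self.n_amplified

    @property
    def pct_hdr_oligo_of_cleaved(self) -> float:
        return 100.0 * self.n_hdr_oligo / self.n_cleaved if self.n_cleaved else 0.0

    @property
    def pct_hdr_paralog_of_cleaved(self) -> float:
        return 100.0 * self.n_hdr_paralog / self.n_cleaved if self.n_cleaved else 0.0

    def as_row(self) -> dict:
        return {
            "n_embryos_injected": self.n_embryos_injected,
            "n_amplified": self.n_amplified,
            "n_cleaved": self.n_cleaved,
            "n_hdr_oligo": self.n_hdr_oligo,
            "n_hdr_paralog": self.n_hdr_paralog,
            "pct_cleaved": round(self.pct_cleaved, 1),
            "pct_hdr_oligo_of_cleaved": round(self.pct_hdr_oligo_of_cleaved, 1),
            "pct_hdr_paralog_of_cleaved": round(self.pct_hdr_paralog_of_cleaved, 1),
        }


def summarize_experiment(summaries: list[EmbryoSummary]) -> ExperimentSummary:
    amplified = [s for s in summaries if s.amplified]
    return ExperimentSummary(
        n_embryos_injected=len(summaries),
        n_amplified=len(amplified),
        n_cleaved=sum(s.cleaved for s in amplified),
        n_hdr_oligo=sum(s.hdr_oligo for s in amplified),
        n_hdr_paralog=sum(s.hdr_paralog for s in amplified),
    )


def indel_spectrum(calls: list[ReadCall]) -> pd.DataFrame:
    """Histogram of Cas9-attributed indels, ordered by (position, length)."""
    counter: Counter[Indel] = Counter(
        c.indel for c in calls
        if c.category in (NHEJ_INDEL, COMPLEX) and c.cut_disrupted and c.indel
    )
    rows = [
        {"descriptor": ind.descriptor, "pos": ind.pos, "length": ind.length,
         "kind": ind.kind, "count": n}
        for ind, n in counter.items()
    ]
    df = pd.DataFrame(rows, columns=["descriptor", "pos", "length", "kind", "count"])
    return df.sort_values(["pos", "length", "kind"], kind="stable").reset_index(drop=True)
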