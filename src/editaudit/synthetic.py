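"""Synthetic fixtures: locus pairs, donor oligos, mosaic embryo reads, exomes.

Everything downstream of wet-lab sequencing is testable against data
generated here.  The generator emulates the study design of a Cas9
editing experiment at a locus (think HBB) that has a near-identical
paralog (think HBD, ~1 substitution per few dozen bases near the cut):

* :func:`generate_locus_pair` — a target/paralog pair differing only at
  a small set of discriminating positions clustered near the guide cut
  site, with the protospacer + PAM embedded in the target.
* :func:`generate_donor` — a single-stranded oligo donor spanning the
  cut with a configurable number of signature substitutions (6 in the
  default scenario, mirroring a 126-nt ssODN with 6 silent mutations).
* :func:`simulate_embryo_reads` — a mosaic per-embryo clone-read
  mixture over outcome categories (wild type, NHEJ indel, oligo HDR,
  paralog HDR, partial conversion), with whole-embryo amplification
  dropout as a boolean.
* :func:`generate_exome_variants` — an exome-style variant table on a
  synthetic chromosome with planted on-target/off-target indels and
  nuisance variants each designed to be removed by exactly one stage of
  the off-target filter chain.

All coordinates are 0-based half-open in target coordinates unless a
field is explicitly VCF-style.  Identical seeds give byte-identical
output.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .errors import ConfigError, ContractError, InputError, SizingError
from .offtarget import GuideRule, VariantRecord, longest_homopolymer, revcomp, scan_sites

DNA = "ACGT"

# Outcome categories shared with the classifier.
WT = "WT"
NHEJ_INDEL = "NHEJ_INDEL"
HDR_OLIGO = "HDR_OLIGO"
HDR_PARALOG = "HDR_PARALOG"
HDR_PARTIAL = "HDR_PARTIAL"
COMPLEX = "COMPLEX"
CATEGORIES = (WT, NHEJ_INDEL, HDR_OLIGO, HDR_PARALOG, HDR_PARTIAL, COMPLEX)
SIMULATABLE = (WT, NHEJ_INDEL, HDR_OLIGO, HDR_PARALOG, HDR_PARTIAL)

#: Default G1-style protospacer (the guide used throughout the default
#: scenarios; its PAM-proximal end sits 3 bp from the blunt cut).
DEFAULT_PROTOSPACER = "GTAACGGCAGACTTCTCCTC"

#: Default NHEJ indel spectrum: (offset from cut, length, kind, weight).
#: Offsets stay within the classifier's +/-5 bp cut window.
DEFAULT_INDEL_SPECTRUM = (
    (-1, 1, "del", 2.0),
    (0, 2, "del", 2.0),
    (-3, 4, "del", 1.0),
    (0, 1, "ins", 1.5),
    (1, 2, "ins", 0.5),
)


def _rng(seed) -> np.random.Generator:
    return np.random.default_rng(seed)


def random_dna(length: int, rng: np.random.Generator, max_run: int = 5) -> str:
    """Random sequence with homopolymer runs capped at ``max_run``."""
    bases = list(rng.choice(list(DNA), size=length))
    run = 1
    for i in range(1, length):
        run = run + 1 if bases[i] == bases[i - 1] else 1
        if run > max_run:
            others = [b for b in DNA if b != bases[i]]
            bases[i] = others[int(rng.integers(len(others)))]
            run = 1
    return "".join(bases)


def _other_base(base: str, rng: np.random.Generator) -> str:
    others = [b for b in DNA if b != base]
    return others[int(rng.integers(3))]


# ---------------------------------------------------------------------------
# Locus pair
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class GuideSpec:
    """Where and how the guide sits in a generated target."""

    protospacer: str = DEFAULT_PROTOSPACER
    strand: str = "+"
    cut_offset: int = 3  # blunt cut this many bp 5' of the PAM

    def __post_init__(self):
        if set(self.protospacer) - set(DNA):
            raise InputError("protospacer must be over ACGT")
        if self.strand not in "+-":
            raise InputError("guide strand must be '+' or '-'")


@dataclass(frozen=True)
class LocusPair:
    """Target and paralog references plus the guide geometry.

    ``discriminating_positions`` lists (target coordinate, target base,
    paralog base) for every position where the two sequences differ in
    the modeled homology window; these are the only differences.
    """

    target_seq: str
    paralog_seq: str
    discriminating_positions: tuple[tuple[int, str, str], ...]
    guide_start: int
    guide_strand: str = "+"
    cut_offset: int = 3
    protospacer_len: int = 20

    def __post_init__(self):
        if len(self.target_seq) != len(self.paralog_seq):
            raise InputError("target and paralog must have equal length")
        for pos, tb, pb in self.discriminating_positions:
            if tb == pb:
                raise InputError(f"discriminating position {pos} lists equal bases")
            if self.target_seq[pos] != tb or self.paralog_seq[pos] != pb:
                raise InputError(f"discriminating position {pos} disagrees with sequences")
        if self.guide_strand == "+":
            if self.guide_start < 0 or self.guide_start + self.protospacer_len + 3 > len(self.target_seq):
                raise InputError("guide protospacer + PAM must lie inside target_seq")
        else:
            if self.guide_start < 3 or self.guide_start + self.protospacer_len > len(self.target_seq):
                raise InputError("guide protospacer + PAM must lie inside target_seq")
        if not 0 <= self.cut_site <= len(self.target_seq):
            raise InputError("cut site outside target_seq")

    @property
    def cut_site(self) -> int:
        """0-based boundary where the blunt cut falls in target coordinates."""
        if self.guide_strand == "+":
            return self.guide_start + self.protospacer_len - self.cut_offset
        return self.guide_start + self.cut_offset

    @property
    def protospacer(self) -> str:
        seg = self.target_seq[self.guide_start : self.guide_start + self.protospacer_len]
        return seg if self.guide_strand == "+" else revcomp(seg)

    @property
    def pam(self) -> str:
        if self.guide_strand == "+":
            return self.target_seq[self.guide_start + self.protospacer_len : self.guide_start + self.protospacer_len + 3]
        return revcomp(self.target_seq[self.guide_start - 3 : self.guide_start])

    @property
    def disc_coords(self) -> tuple[int, ...]:
        return tuple(p for p, _, _ in self.discriminating_positions)


def generate_locus_pair(
    length: int,
    n_discriminating: int,
    guide_spec: GuideSpec | None = None,
    seed: int = 0,
    disc_window: int = 50,
    cut_exclusion: int = 8,
) -> LocusPair:
    """Generate a target/paralog pair differing at ``n_discriminating`` positions.

    The guide (protospacer + NGG PAM) is embedded so that the cut falls
    at the center of the target.  Discriminating positions are placed in
    a cluster within ``disc_window`` bp of the cut but outside the
    ``cut_exclusion`` zone, so NHEJ indels at the cut never delete them.
    Deterministic given ``seed``.
    """
    guide_spec = guide_spec or GuideSpec()
    if n_discriminating < 1:
        raise ConfigError("n_discriminating must be >= 1")
    n = len(guide_spec.protospacer)
    min_len = n + 3 + 2 * (disc_window + 10)
    if length < min_len:
        raise SizingError(f"length {length} too small; need >= {min_len}")
    rng = _rng(seed)
    target = list(random_dna(length, rng))
    cut = length // 2
    if guide_spec.strand == "+":
        guide_start = cut - (n - guide_spec.cut_offset)
        target[guide_start : guide_start + n] = guide_spec.protospacer
        pam = str(rng.choice(list(DNA))) + str(rng.choice(["A", "G"])) + "G"
        target[guide_start + n : guide_start + n + 3] = pam
    else:
        guide_start = cut - guide_spec.cut_offset
        target[guide_start : guide_start + n] = revcomp(guide_spec.protospacer)
        pam = str(rng.choice(list(DNA))) + str(rng.choice(["A", "G"])) + "G"
        target[guide_start - 3 : guide_start] = revcomp(pam)
    target = "".join(target)

    lo = max(0, cut - disc_window)
    hi = min(length, cut + disc_window)
    candidates = [p for p in range(lo, hi) if not (cut - cut_exclusion <= p < cut + cut_exclusion)]
    if n_discriminating > len(candidates):
        raise SizingError("not enough room for discriminating positions")
    # cluster the positions (tandem-style): walk from a random anchor with
    # small random spacing, wrapping to remaining candidates if needed
    positions: list[int] = []
    anchor_idx = int(rng.integers(len(candidates)))
    idx = anchor_idx
    while len(positions) < n_discriminating:
        if idx >= len(candidates):
            remaining = [p for p in candidates if p not in positions]
            positions.extend(remaining[: n_discriminating - len(positions)])
            break
        positions.append(candidates[idx])
        idx += int(rng.integers(1, 4))
    positions = sorted(positions[:n_discriminating])

    paralog = list(target)
    disc = []
    for pos in positions:
        pb = _other_base(target[pos], rng)
        paralog[pos] = pb
        disc.append((pos, target[pos], pb))
    lp = LocusPair(
        target_seq=target,
        paralog_seq="".join(paralog),
        discriminating_positions=tuple(disc),
        guide_start=guide_start,
        guide_strand=guide_spec.strand,
        cut_offset=guide_spec.cut_offset,
        protospacer_len=n,
    )
    assert lp.cut_site == cut
    return lp


# ---------------------------------------------------------------------------
# Donor oligo
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class DonorOligo:
    """Single-stranded oligo donor in target coordinates.

    ``seq`` covers ``homology_arm_bounds`` (half-open) of the target and
    differs from it only at ``signature_positions`` (target coordinate,
    reference base, donor base).
    """

    seq: str
    signature_positions: tuple[tuple[int, str, str], ...]
    homology_arm_bounds: tuple[int, int]

    @property
    def signature_coords(self) -> tuple[int, ...]:
        return tuple(p for p, _, _ in self.signature_positions)


def generate_donor(
    locus: LocusPair,
    n_signatures: int = 6,
    arm_length: int = 63,
    seed: int = 0,
    cut_exclusion: int = 8,
    avoid_discriminating: bool = True,
) -> DonorOligo:
    """Generate an oligo donor spanning the cut with signature substitutions.

    The donor covers [cut - arm_length, cut + arm_length); signatures
    are placed inside the arms, outside the cut-exclusion zone, and (by
    default) away from the paralog's discriminating positions so the two
    HDR footprints stay distinguishable.
    """
    if n_signatures < 1:
        raise ConfigError("n_signatures must be >= 1")
    cut = locus.cut_site
    start, end = cut - arm_length, cut + arm_length
    if start < 0 or end > len(locus.target_seq):
        raise SizingError("homology arms exceed the target sequence")
    rng = _rng(seed)
    excluded = set(range(cut - cut_exclusion, cut + cut_exclusion))
    if avoid_discriminating:
        excluded |= set(locus.disc_coords)
    candidates = [p for p in range(start, end) if p not in excluded]
    if n_signatures > len(candidates):
        raise SizingError("not enough room for signature positions in the arms")
    positions = sorted(rng.choice(candidates, size=n_signatures, replace=False).tolist())
    donor = list(locus.target_seq[start:end])
    sigs = []
    for pos in positions:
        db = _other_base(locus.target_seq[pos], rng)
        donor[pos - start] = db
        sigs.append((pos, locus.target_seq[pos], db))
    return DonorOligo(seq="".join(donor), signature_positions=tuple(sigs),
                      homology_arm_bounds=(start, end))


# ---------------------------------------------------------------------------
# Embryo read simulation
# ---------------------------------------------------------------------------


@dataclass
class EmbryoScenario:
    """Mixture recipe for one embryo's clone reads.

    ``mixture`` maps outcome category to proportion (must sum to 1);
    proportions are realized exactly by largest-remainder rounding over
    ``n_reads``, so truth-table counts are deterministic.  ``amplified``
    False models whole-embryo amplification dropout: no reads at all.
    """

    embryo_id: str
    mixture: dict[str, float]
    n_reads: int = 50
    indel_spectrum: tuple = DEFAULT_INDEL_SPECTRUM
    conversion_tract: tuple[int, int] | None = None
    partial_k: int = 4
    amplified: bool = True
    seed: int = 0

    def validate(self) -> None:
        bad = set(self.mixture) - set(SIMULATABLE)
        if bad:
            raise ConfigError(f"unknown categories in mixture: {sorted(bad)}")
        total = sum(self.mixture.values())
        if abs(total - 1.0) > 1e-9:
            raise ConfigError(f"mixture proportions sum to {total}, not 1")
        if any(v < 0 for v in self.mixture.values()):
            raise ConfigError("mixture proportions must be non-negative")
        if self.n_reads < 0:
            raise ConfigError("n_reads must be non-negative")


@dataclass(frozen=True)
class SimulatedRead:
    read_id: str
    embryo_id: str
    seq: str
    true_category: str
    detail: str = ""


def largest_remainder(weights: dict[str, float], n: int, order=SIMULATABLE) -> dict[str, int]:
    """Apportion ``n`` items to categories, matching proportions exactly.

    Floor each share, then hand remaining items to the largest
    fractional remainders; ties break by the canonical category order so
    the result is deterministic.
    """
    keys = [k for k in order if k in weights] + [k for k in weights if k not in order]
    shares = {k: weights[k] * n for k in keys}
    counts = {k: int(np.floor(shares[k])) for k in keys}
    leftover = n - sum(counts.values())
    by_rem = sorted(keys, key=lambda k: (-(shares[k] - counts[k]), keys.index(k)))
    for k in itertools.islice(itertools.cycle(by_rem), leftover):
        counts[k] += 1
    return counts


def _apply_indel(target: str, cut: int, offset: int, length: int, kind: str,
                 rng: np.random.Generator) -> tuple[str, str]:
    pos = cut + offset
    if kind == "del":
        if pos < 0 or pos + length > len(target):
            raise ConfigError("deletion falls outside the target")
        return target[:pos] + target[pos + length:], f"del@{pos}x{length}"
    if kind == "ins":
        ins = "".join(rng.choice(list(DNA), size=length))
        return target[:pos] + ins + target[pos:], f"ins@{pos}:{ins}"
    raise ConfigError(f"unknown indel kind {kind!r}")


def simulate_embryo_reads(locus: LocusPair, donor: DonorOligo,
                          scenario: EmbryoScenario) -> list[SimulatedRead]:
    """Emit clone reads for one embryo according to its mixture.

    Reads are full-length copies of the target with the category's edit
    applied: NHEJ reads carry one indel drawn from the spectrum at the
    cut; oligo-HDR reads carry every donor signature; paralog-HDR reads
    carry the paralog base at every discriminating position inside the
    conversion tract; partial reads carry a fixed ``partial_k``-subset
    of donor signatures (one allele per embryo).  Returns an empty list
    when the embryo failed to amplify.
    """
    scenario.validate()
    if not scenario.amplified:
        return []
    tract = scenario.conversion_tract
    if tract is None and locus.disc_coords:
        tract = (min(locus.disc_coords), max(locus.disc_coords) + 1)
    if scenario.mixture.get(HDR_PARALOG, 0) > 0:
        in_tract = [p for p in locus.disc_coords if tract[0] <= p < tract[1]]
        if not in_tract:
            raise ConfigError("conversion tract covers no discriminating position")
    rng = _rng(scenario.seed)
    counts = largest_remainder(scenario.mixture, scenario.n_reads)
    target = locus.target_seq
    cut = locus.cut_site

    n_sig = len(donor.signature_positions)
    if counts.get(HDR_PARTIAL, 0) > 0:
        if not 1 <= scenario.partial_k < n_sig:
            raise ConfigError("partial_k must be >= 1 and fewer than all signatures")
        partial_idx = sorted(rng.choice(n_sig, size=scenario.partial_k, replace=False).tolist())
    spectrum = list(scenario.indel_spectrum)
    weights = np.array([w for *_, w in spectrum], dtype=float)
    weights = weights / weights.sum() if len(weights) else weights

    reads: list[SimulatedRead] = []
    for category in SIMULATABLE:
        for _ in range(counts.get(category, 0)):
            detail = ""
            if category == WT:
                seq = target
            elif category == NHEJ_INDEL:
                off, length, kind, _w = spectrum[int(rng.choice(len(spectrum), p=weights))]
                seq, detail = _apply_indel(target, cut, off, length, kind, rng)
            elif category == HDR_OLIGO:
                s = list(target)
                for pos, _rb, db in donor.signature_positions:
                    s[pos] = db
                seq = "".join(s)
            elif category == HDR_PARALOG:
                s = list(target)
                converted = []
                for pos, _tb, pb in locus.discriminating_positions:
                    if tract[0] <= pos < tract[1]:
                        s[pos] = pb
                        converted.append(pos)
                seq = "".join(s)
                detail = "tract=" + ",".join(map(str, converted))
            else:  # HDR_PARTIAL
                s = list(target)
                kept = [donor.signature_positions[i] for i in partial_idx]
                for pos, _rb, db in kept:
                    s[pos] = db
                seq = "".join(s)
                detail = "signatures=" + ",".join(str(p) for p, _, _ in kept)
            reads.append(SimulatedRead("", scenario.embryo_id, seq, category, detail))
    perm = rng.permutation(len(reads))
    return [replace(reads[int(j)], read_id=f"{scenario.embryo_id}_r{i:03d}")
            for i, j in enumerate(perm)]


def truth_table(reads: list[SimulatedRead]) -> pd.DataFrame:
    return pd.DataFrame(
        [{"read_id": r.read_id, "embryo_id": r.embryo_id,
          "true_category": r.true_category, "detail": r.detail} for r in reads]
    )


def simulate_paralog_reads(locus: LocusPair, embryo_id: str, n_reads: int = 10,
                           crossover: bool = False,
                           tract: tuple[int, int] | None = None,
                           seed: int = 0) -> list[SimulatedRead]:
    """Clone reads of the *paralog* locus from one embryo.

    Non-crossover repair leaves the paralog identical to its reference;
    with ``crossover=True`` the reads carry the target base at every
    discriminating position inside the tract (reciprocal exchange).
    """
    if tract is None and locus.disc_coords:
        tract = (min(locus.disc_coords), max(locus.disc_coords) + 1)
    seq = locus.paralog_seq
    if crossover:
        s = list(seq)
        for pos, tb, _pb in locus.discriminating_positions:
            if tract[0] <= pos < tract[1]:
                s[pos] = tb
        seq = "".join(s)
    label = "crossover" if crossover else "non_crossover"
    return [SimulatedRead(f"{embryo_id}_p{i:03d}", embryo_id, seq, label)
            for i in range(n_reads)]


# ---------------------------------------------------------------------------
# Exome variant planting
# ---------------------------------------------------------------------------

PLANT_LABELS = (
    "on_target",
    "off_target",
    "nuisance_exon",
    "nuisance_support",
    "nuisance_low_complexity",
    "nuisance_homopolymer",
    "background",
)


@dataclass
class PlantedVariantSet:
    """A variant table with per-record ground truth and companion tracks."""

    records: list[VariantRecord]
    truth_labels: dict[str, str]
    reference: dict[str, str]
    exon_intervals: list[tuple[str, int, int]]
    lc_intervals: list[tuple[str, int, int]]
    target_sites: tuple[tuple[str, int, str], ...]


def _plant_guide_site(block: list[str], at: int, rule: GuideRule,
                      n_mismatches: int, rng: np.random.Generator,
                      distal_only: bool = True) -> None:
    """Write a (possibly mutated) protospacer + NRG PAM into ``block``."""
    site = list(rule.protospacer)
    n = len(site)
    if n_mismatches:
        region = range(n - rule.seed_len) if distal_only else range(n)
        picks = rng.choice(list(region), size=n_mismatches, replace=False)
        for i in picks:
            site[int(i)] = _other_base(site[int(i)], rng)
    pam = ("T" if n_mismatches else "A") + "GG"
    block[at : at + n] = site
    block[at + n : at + n + 3] = pam


def generate_exome_variants(rule: GuideRule, plant_spec: dict[str, int],
                            seed: int = 0, spacing: int = 1000,
                            off_target_mismatches: int | None = None) -> PlantedVariantSet:
    """Build a synthetic exome variant table with known chain behaviour.

    Each variant gets its own ``spacing``-bp block on a synthetic
    chromosome.  Plants by label:

    - ``on_target``: 2-bp deletion whose flank holds a perfect guide
      match registered as the designed target site.
    - ``off_target``: deletion whose flank holds a guide match with
      mismatches confined to the PAM-distal region (perfect seed).
    - ``nuisance_*``: each violates exactly its named filter and passes
      every earlier stage, so single-stage ablations are unambiguous.
    - ``background``: exonic, well-supported, clean flank, no guide
      match — removed only at flank adjudication.

    Running the full chain on the result retains exactly the on/off
    target plants.
    """
    bad = set(plant_spec) - set(PLANT_LABELS)
    if bad:
        raise ConfigError(f"unknown plant labels: {sorted(bad)}")
    labels = [lab for lab in PLANT_LABELS for _ in range(plant_spec.get(lab, 0))]
    rng = _rng(seed)
    if off_target_mismatches is None:
        off_target_mismatches = 4
    if off_target_mismatches > len(rule.protospacer) - rule.seed_len:
        raise ConfigError("off-target mismatches must fit in the PAM-distal region")

    chrom = "chrS"
    flank = rule.flank
    blocks: list[str] = []
    records: list[VariantRecord] = []
    truth: dict[str, str] = {}
    exons: list[tuple[str, int, int]] = []
    lcs: list[tuple[str, int, int]] = []
    target_sites: list[tuple[str, int, str]] = []

    half = spacing // 2
    for i, label in enumerate(labels):
        c = i * spacing + half  # 0-based variant anchor on the chromosome
        for _attempt in range(50):
            block = list(random_dna(spacing, rng))
            at = half % spacing + 15  # local offset of any planted guide site
            if label == "on_target":
                _plant_guide_site(block, at, rule, 0, rng)
            elif label == "off_target":
                _plant_guide_site(block, at, rule, off_target_mismatches, rng)
            elif label == "nuisance_homopolymer":
                block[half % spacing + 30 : half % spacing + 38] = "A" * 8
            local = half % spacing
            flank_seq = "".join(block[local - flank : local + flank + 1])
            hits = scan_sites([("f", flank_seq)], rule)
            want_hits = label in ("on_target", "off_target")
            if want_hits != bool(hits):
                continue
            if label != "nuisance_homopolymer" and longest_homopolymer(flank_seq) > 7:
                continue
            break
        else:
            raise ConfigError(f"could not realize plant label {label!r}")
        blocks.append("".join(block))

        rid = f"v{i:04d}"
        ref = "".join(block[local : local + 2])
        alt = ref[0]
        support = 2 if label == "nuisance_support" else int(rng.integers(3, 40))
        records.append(VariantRecord(id=rid, chrom=chrom, pos=c + 1, ref=ref,
                                     alt=alt, support=support, flank_seq=flank_seq))
        truth[rid] = label
        if label != "nuisance_exon":
            exons.append((chrom, c - 150, c + 150))
        if label == "nuisance_low_complexity":
            lcs.append((chrom, c - 5, c + 5))
        if label == "on_target":
            target_sites.append((chrom, i * spacing + at, "+"))

    reference = {chrom: "".join(blocks)}
    return PlantedVariantSet(records=records, truth_labels=truth,
                             reference=reference, exon_intervals=exons,
                             lc_intervals=lcs, target_sites=tuple(target_sites))
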