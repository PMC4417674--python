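"""File-format adapters: FASTA, TSV/VCF variant tables, BED, YAML.

Conventions: FASTA descriptions carry ``key=value`` tokens (embryo id,
truth labels); BED is 0-based half-open 3-column (a dialect switch
shifts 1-based inputs); the variant TSV has the header
``chrom pos ref alt support`` with 1-based positions as in VCF.  All
round-trips are lossless for the fields the pipeline consumes.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import pandas as pd
import yaml
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .errors import InputError
from .offtarget import VariantRecord
from .synthetic import SimulatedRead

VARIANT_COLUMNS = ["chrom", "pos", "ref", "alt", "support"]


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------


def parse_header_tokens(description: str) -> dict[str, str]:
    """Extract key=value tokens from a FASTA description line."""
    tokens = {}
    for part in description.split()[1:]:
        if "=" in part:
            key, value = part.split("=", 1)
            tokens[key] = value
    return tokens


def write_reads_fasta(reads, path) -> None:
    """Write simulated/observed reads with embryo and truth metadata tokens."""
    records = []
    for r in reads:
        desc = f"embryo={r.embryo_id}"
        if getattr(r, "true_category", None):
            desc += f" label={r.true_category}"
        if getattr(r, "detail", ""):
            desc += f" detail={r.detail}"
        records.append(SeqRecord(Seq(r.seq), id=r.read_id, description=desc))
    SeqIO.write(records, str(path), "fasta")


def read_reads_fasta(path) -> list[SimulatedRead]:
    """Read a reads FASTA; embryo id comes from the ``embryo=`` token."""
    reads = []
    for rec in SeqIO.parse(str(path), "fasta"):
        tokens = parse_header_tokens(rec.description)
        reads.append(SimulatedRead(
            read_id=rec.id,
            embryo_id=tokens.get("embryo", ""),
            seq=str(rec.seq).upper(),
            true_category=tokens.get("label", ""),
            detail=tokens.get("detail", ""),
        ))
    return reads


def write_fasta(sequences: dict[str, str], path) -> None:
    SeqIO.write(
        [SeqRecord(Seq(seq), id=name, description="") for name, seq in sequences.items()],
        str(path), "fasta",
    )


def read_fasta(path) -> dict[str, str]:
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


# ---------------------------------------------------------------------------
# Variant tables
# ---------------------------------------------------------------------------


def write_variants_tsv(records: list[VariantRecord], path) -> None:
    rows = [{"chrom": r.chrom, "pos": r.pos, "ref": r.ref, "alt": r.alt,
             "support": r.support, "id": r.id} for r in records]
    pd.DataFrame(rows, columns=VARIANT_COLUMNS + ["id"]).to_csv(path, sep="\t", index=False)


def read_variants_tsv(path) -> list[VariantRecord]:
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str, "ref": str, "alt": str})
    missing = [c for c in VARIANT_COLUMNS if c not in df.columns]
    if missing:
        raise InputError(f"variant TSV {path}: missing columns {missing}")
    records = []
    for i, row in enumerate(df.itertuples(index=False)):
        rid = getattr(row, "id", None) or f"v{i:04d}"
        try:
            records.append(VariantRecord(id=str(rid), chrom=str(row.chrom),
                                         pos=int(row.pos), ref=str(row.ref),
                                         alt=str(row.alt), support=int(row.support)))
        except (TypeError, ValueError) as exc:
            raise InputError(f"variant TSV {path}, line {i + 2}: {exc}") from exc
    return records


def write_vcf(records: list[VariantRecord], path, contigs: dict[str, int] | None = None) -> None:
    """Emit a minimal VCF 4.2 with read support in INFO/SUPPORT."""
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##INFO=<ID=SUPPORT,Number=1,Type=Integer,'
                 'Description="Supporting read count">\n')
        for name, length in (contigs or {}).items():
            fh.write(f"##contig=<ID={name},length={length}>\n")
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\n")
        for r in records:
            fh.write(f"{r.chrom}\t{r.pos}\t{r.id}\t{r.ref}\t{r.alt}\t.\t.\t"
                     f"SUPPORT={r.support}\n")


def read_vcf(path) -> list[VariantRecord]:
    from cyvcf2 import VCF

    records = []
    for i, v in enumerate(VCF(str(path))):
        support = v.INFO.get("SUPPORT")
        records.append(VariantRecord(
            id=v.ID or f"v{i:04d}", chrom=v.CHROM, pos=v.POS, ref=v.REF,
            alt=v.ALT[0] if v.ALT else ".",
            support=int(support) if support is not None else 0,
        ))
    return records


def attach_flanks(records: list[VariantRecord], reference: dict[str, str],
                  flank: int = 100) -> None:
    """Fill ``flank_seq`` (2*flank+1 bp centered on POS) from a reference."""
    for rec in records:
        if rec.chrom not in reference:
            raise InputError(f"variant {rec.id}: chrom {rec.chrom} not in reference")
        seq = reference[rec.chrom]
        center = rec.pos - 1
        lo, hi = center - flank, center + flank + 1
        if lo < 0 or hi > len(seq):
            raise InputError(f"variant {rec.id}: flank extends past contig end")
        rec.flank_seq = seq[lo:hi]


# ---------------------------------------------------------------------------
# BED intervals
# ---------------------------------------------------------------------------


def read_bed(path, one_based: bool = False) -> list[tuple[str, int, int]]:
    intervals = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise InputError(f"{path}, line {lineno}: need 3 BED columns")
            try:
                chrom, start, end = parts[0], int(parts[1]), int(parts[2])
            except ValueError as exc:
                raise InputError(f"{path}, line {lineno}: {exc}") from exc
            if one_based:
                start -= 1
            if end <= start:
                raise InputError(f"{path}, line {lineno}: end <= start")
            intervals.append((chrom, start, end))
    return intervals


def write_bed(intervals, path) -> None:
    with open(path, "w") as fh:
        for chrom, start, end in intervals:
            fh.write(f"{chrom}\t{start}\t{end}\n")


# ---------------------------------------------------------------------------
# YAML config / manifest
# ---------------------------------------------------------------------------


def load_yaml(path) -> dict:
    with open(path) as fh:
        data = yaml.safe_load(fh)
    if not isinstance(data, dict):
        raise InputError(f"{path}: expected a YAML mapping at top level")
    return data


def config_hash(config: dict) -> str:
    return hashlib.sha256(
        json.dumps(config, sort_keys=True, default=str).encode()
    ).hexdigest()[:16]


def write_manifest(outdir, config: dict, seed: int, files: list[str]) -> None:
    rows = [{"key": "config_hash", "value": config_hash(config)},
            {"key": "seed", "value": seed}]
    rows += [{"key": "file", "value": f} for f in sorted(files)]
    pd.DataFrame(rows).to_csv(Path(outdir) / "manifest.tsv", sep="\t", index=False)
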