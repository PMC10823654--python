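"""Clinical variant catalog: parsing, coordinates, effect annotation.

Normalizes ClinVar-style variant tables into three working classes —
PV (pathogenic / likely pathogenic), BV (benign / likely benign) and VUS
(uncertain significance) — dropping records with conflicting
interpretations.  Converts transcript-level HGVS c. names (including
intronic offsets such as ``c.208-3C>T``) to forward-strand genomic
coordinates against simple exon/CDS transcript models, and back; assigns
minimal effect categories (missense, stopgain, splice, frameshift, ...)
by direct codon translation.

Genomic coordinates are 1-based throughout (VCF convention); indels are
VCF-style anchored on the base before the event.
"""

from __future__ import annotations

import json
import logging
import re
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
from Bio.Seq import Seq

from .stats_report import proportion

logger = logging.getLogger(__name__)

__all__ = [
    "VariantRecord",
    "TranscriptModel",
    "CatalogSummary",
    "CoordinateError",
    "parse_catalog",
    "cds_to_genomic",
    "genomic_to_cds",
    "annotate_effect",
    "summarize_catalog",
    "load_transcripts",
    "write_transcripts",
    "load_founder_ids",
    "write_catalog_vcf",
]

# ClinVar clinical-significance vocabulary → working class
SIGNIFICANCE_MAP = {
    "pathogenic": "PV",
    "likely pathogenic": "PV",
    "pathogenic/likely pathogenic": "PV",
    "benign": "BV",
    "likely benign": "BV",
    "benign/likely benign": "BV",
    "uncertain significance": "VUS",
}
CONFLICTING_LABELS = {
    "conflicting interpretations of pathogenicity",
    "conflicting classifications of pathogenicity",
    "conflicting interpretations",
}

EFFECT_TYPES = (
    "synonymous",
    "missense",
    "stopgain",
    "stoploss",
    "splice",
    "frameshift deletion",
    "frameshift insertion",
    "nonframeshift deletion",
    "nonframeshift insertion",
    "intronic",
)

_DNA = set("ACGT")


class CoordinateError(ValueError):
    """A c. or genomic position that cannot be mapped on the given model."""


@dataclass
class VariantRecord:
    """One normalized catalog entry.

    ``pos`` is 1-based on the genome forward strand; ``ref``/``alt`` are
    explicit VCF-style allele strings (indels anchored).  ``clin_class``
    is exactly one of PV/BV/VUS — conflicting interpretations never become
    records.
    """

    gene: str
    chrom: str
    pos: int
    ref: str
    alt: str
    hgvs_c: str
    clin_class: str
    variant_type: str = ""
    founder: bool = False

    def __post_init__(self) -> None:
        if self.ref == self.alt:
            raise ValueError(f"ref == alt for {self}")
        for allele in (self.ref, self.alt):
            if not allele or not set(allele) <= _DNA:
                raise ValueError(f"malformed allele {allele!r} in {self.gene} {self.hgvs_c}")
        if self.clin_class not in ("PV", "BV", "VUS"):
            raise ValueError(f"bad clin_class {self.clin_class!r}")

    @property
    def variant_id(self) -> str:
        return f"{self.chrom}:{self.pos}:{self.ref}:{self.alt}"

    @property
    def name(self) -> str:
        return f"{self.gene}:{self.hgvs_c}"

    @property
    def is_snv(self) -> bool:
        return len(self.ref) == 1 and len(self.alt) == 1

    @property
    def is_deletion(self) -> bool:
        return len(self.ref) > 1 and len(self.alt) == 1

    @property
    def is_insertion(self) -> bool:
        return len(self.ref) == 1 and len(self.alt) > 1

    @property
    def key(self) -> tuple:
        return (self.chrom, self.pos, self.ref, self.alt)


@dataclass
class TranscriptModel:
    """Exon/CDS structure of one transcript on the genome.

    ``exons`` are 1-based closed intervals sorted by genomic position and
    non-overlapping.  ``cds_start``/``cds_end`` are the genomic positions of
    the first and last base of the coding sequence *in transcript order*
    (so on a minus-strand transcript ``cds_start > cds_end`` numerically).
    """

    gene: str
    chrom: str
    strand: str
    exons: tuple
    cds_start: int
    cds_end: int
    _cds_pos: list = field(default=None, repr=False, compare=False)
    _g2c: dict = field(default=None, repr=False, compare=False)

    def __post_init__(self) -> None:
        if self.strand not in "+-":
            raise ValueError(f"bad strand {self.strand!r}")
        self.exons = tuple((int(a), int(b)) for a, b in self.exons)
        prev_end = 0
        for a, b in self.exons:
            if a > b or a <= prev_end:
                raise ValueError(f"exons must be sorted, non-overlapping: {self.exons}")
            prev_end = b
        for g in (self.cds_start, self.cds_end):
            if not any(a <= g <= b for a, b in self.exons):
                raise ValueError(f"CDS bound {g} outside exons")

    # -- coordinate scaffolding -------------------------------------------
    def cds_positions(self) -> list[int]:
        """Genomic positions of every CDS base, in transcript order."""
        if self._cds_pos is None:
            lo, hi = sorted((self.cds_start, self.cds_end))
            pos = [
                g
                for a, b in self.exons
                for g in range(max(a, lo), min(b, hi) + 1)
            ]
            if self.strand == "-":
                pos = pos[::-1]
            self._cds_pos = pos
        return self._cds_pos

    def g_to_c_index(self) -> dict[int, int]:
        """Genomic position → 1-based CDS coordinate, for CDS bases."""
        if self._g2c is None:
            self._g2c = {g: i + 1 for i, g in enumerate(self.cds_positions())}
        return self._g2c

    @property
    def cds_length(self) -> int:
        return len(self.cds_positions())

    def cds_sequence(self, reference: str) -> str:
        """Coding sequence in transcript orientation from a forward reference."""
        seq = "".join(reference[g - 1] for g in self.cds_positions())
        return str(Seq(seq).complement()) if self.strand == "-" else seq

    def is_exonic(self, gpos: int) -> bool:
        return any(a <= gpos <= b for a, b in self.exons)

    def span(self) -> tuple[int, int]:
        return self.exons[0][0], self.exons[-1][1]

    def to_dict(self) -> dict:
        return {
            "gene": self.gene,
            "chrom": self.chrom,
            "strand": self.strand,
            "exons": [list(e) for e in self.exons],
            "cds_start": self.cds_start,
            "cds_end": self.cds_end,
        }


@dataclass
class CatalogSummary:
    """Counts and rounded percentages per class, and effect types per gene."""

    class_counts: dict
    class_percent: dict
    per_gene_types: pd.DataFrame
    total: int
    dropped_conflicting: int = 0

    def to_dict(self) -> dict:
        return {
            "total": self.total,
            "dropped_conflicting": self.dropped_conflicting,
            "class_counts": self.class_counts,
            "class_percent": self.class_percent,
            "per_gene_types": self.per_gene_types.to_dict(),
        }


# ---------------------------------------------------------------------------
# Catalog parsing
# ---------------------------------------------------------------------------

def parse_catalog(
    table,
    founder_ids: set[str] | None = None,
    strict: bool = False,
) -> list[VariantRecord]:
    """Parse a ClinVar-style TSV into normalized :class:`VariantRecord` s.

    Expected columns: gene, chrom, pos_1based, ref, alt, hgvs_c,
    clinical_significance, variant_type.  Significance strings map to
    PV/BV/VUS; rows with conflicting interpretations are dropped (the drop
    count is logged).  Unknown significance strings are skipped with a
    warning, or raise when ``strict=True``; malformed alleles always raise.
    """
    if not isinstance(table, pd.DataFrame):
        table = pd.read_csv(table, sep="\t", dtype=str)
    founder_ids = founder_ids or set()
    records: list[VariantRecord] = []
    dropped = 0
    for _, row in table.iterrows():
        sig = str(row["clinical_significance"]).strip().lower()
        if sig in CONFLICTING_LABELS:
            dropped += 1
            continue
        if sig not in SIGNIFICANCE_MAP:
            msg = f"unknown clinical significance {row['clinical_significance']!r}"
            if strict:
                raise ValueError(msg)
            logger.warning("%s; record skipped", msg)
            continue
        rec = VariantRecord(
            gene=str(row["gene"]),
            chrom=str(row["chrom"]),
            pos=int(row["pos_1based"]),
            ref=str(row["ref"]).upper(),
            alt=str(row["alt"]).upper(),
            hgvs_c=str(row["hgvs_c"]),
            clin_class=SIGNIFICANCE_MAP[sig],
            variant_type=str(row.get("variant_type", "") or ""),
        )
        rec.founder = rec.name in founder_ids
        records.append(rec)
    logger.info(
        "parsed %d records; dropped %d with conflicting interpretations",
        len(records),
        dropped,
    )
    parse_catalog.last_dropped = dropped
    return records


# ---------------------------------------------------------------------------
# HGVS c. <-> genomic
# ---------------------------------------------------------------------------

_POS = r"(\d+)([+-]\d+)?"
_RE_SUB = re.compile(rf"^c\.{_POS}([ACGT])>([ACGT])$")
_RE_DEL = re.compile(rf"^c\.{_POS}(?:_{_POS})?del([ACGT]*)$")
_RE_INS = re.compile(rf"^c\.{_POS}_{_POS}ins([ACGT]+)$")
_RE_DUP = re.compile(rf"^c\.{_POS}(?:_{_POS})?dup([ACGT]*)$")


def _revcomp(seq: str) -> str:
    return str(Seq(seq).reverse_complement())


def _resolve_c(model: TranscriptModel, base: str, offset: str | None) -> int:
    """Genomic position of a c. coordinate (with optional intronic offset)."""
    n = int(base)
    if not 1 <= n <= model.cds_length:
        raise CoordinateError(
            f"c.{base} outside CDS of length {model.cds_length} ({model.gene})"
        )
    g = model.cds_positions()[n - 1]
    if not offset:
        return g
    m = int(offset)  # signed
    step = m if model.strand == "+" else -m
    g_off = g + step
    if model.is_exonic(g_off):
        raise CoordinateError(
            f"c.{base}{offset} resolves to an exonic position ({model.gene})"
        )
    return g_off


def cds_to_genomic(
    model: TranscriptModel, hgvs_c: str, reference: str | None = None
) -> tuple[str, int, str, str]:
    """Convert a c. name to ``(chrom, pos, ref, alt)`` on the forward strand.

    Supports substitutions, del/ins/dup with explicit spans, and intronic
    ``±M`` offsets counted from the nearest exon boundary.  Indels require
    the forward-strand ``reference`` to build anchored VCF-style alleles;
    alleles of minus-strand transcripts are reverse-complemented.
    """
    m = _RE_SUB.match(hgvs_c)
    if m:
        base, off, ref, alt = m.groups()
        g = _resolve_c(model, base, off)
        if model.strand == "-":
            ref, alt = _revcomp(ref), _revcomp(alt)
        if reference is not None and reference[g - 1].upper() != ref:
            raise CoordinateError(
                f"{hgvs_c}: reference has {reference[g - 1]!r} at "
                f"{model.chrom}:{g}, expected {ref!r}"
            )
        return model.chrom, g, ref, alt

    m = _RE_DEL.match(hgvs_c) or _RE_DUP.match(hgvs_c)
    if m:
        is_dup = "dup" in hgvs_c
        b1, o1, b2, o2, seq = m.groups()
        g1 = _resolve_c(model, b1, o1)
        g2 = _resolve_c(model, b2, o2) if b2 else g1
        lo, hi = sorted((g1, g2))
        if reference is None:
            raise CoordinateError(f"{hgvs_c}: indel conversion needs the reference")
        span = reference[lo - 1 : hi].upper()
        if seq:
            expect = span if model.strand == "+" else _revcomp(span)
            if expect != seq:
                raise CoordinateError(f"{hgvs_c}: stated bases {seq} != reference {expect}")
        if is_dup:
            anchor = reference[lo - 2].upper()
            return model.chrom, lo - 1, anchor, anchor + span
        anchor = reference[lo - 2].upper()
        return model.chrom, lo - 1, anchor + span, anchor

    m = _RE_INS.match(hgvs_c)
    if m:
        b1, o1, b2, o2, seq = m.groups()
        g1 = _resolve_c(model, b1, o1)
        g2 = _resolve_c(model, b2, o2)
        if abs(g1 - g2) != 1:
            raise CoordinateError(f"{hgvs_c}: insertion flanks are not adjacent")
        if reference is None:
            raise CoordinateError(f"{hgvs_c}: indel conversion needs the reference")
        anchor_pos = min(g1, g2)
        fwd_seq = seq if model.strand == "+" else _revcomp(seq)
        anchor = reference[anchor_pos - 1].upper()
        return model.chrom, anchor_pos, anchor, anchor + fwd_seq

    raise CoordinateError(f"unsupported HGVS c. name: {hgvs_c!r}")


def _g_to_c_string(model: TranscriptModel, gpos: int) -> str:
    """c. coordinate string ("50", "50+2", "51-3") for one genomic position."""
    g2c = model.g_to_c_index()
    if gpos in g2c:
        return str(g2c[gpos])
    lo, hi = model.span()
    if not lo <= gpos <= hi or model.is_exonic(gpos):
        raise CoordinateError(f"position {gpos} not a CDS or intronic base of {model.gene}")
    cds = model.cds_positions()
    below = [g for g in cds if g < gpos]
    above = [g for g in cds if g > gpos]
    if not below or not above:
        raise CoordinateError(f"position {gpos} outside the CDS span of {model.gene}")
    gl, gr = max(below), min(above)
    dl, dr = gpos - gl, gr - gpos
    if model.strand == "+":
        # gl is transcript-upstream
        return f"{g2c[gl]}+{dl}" if dl <= dr else f"{g2c[gr]}-{dr}"
    # minus strand: the genomically-higher neighbour is transcript-upstream
    return f"{g2c[gr]}+{dr}" if dr <= dl else f"{g2c[gl]}-{dl}"


def intron_boundary_distance(model: TranscriptModel, gpos: int) -> int | None:
    """Bases from an intronic position to its nearest exon boundary (1 = first
    intronic base); ``None`` for exonic positions."""
    if model.is_exonic(gpos):
        return None
    dist = None
    for a, b in model.exons:
        for edge in (a, b):
            d = abs(gpos - edge)
            if dist is None or d < dist:
                dist = d
    return dist


def genomic_to_cds(
    model: TranscriptModel, pos: int, ref: str, alt: str
) -> str:
    """Inverse of :func:`cds_to_genomic` for anchored forward-strand alleles."""
    ref, alt = ref.upper(), alt.upper()
    if len(ref) == 1 and len(alt) == 1:
        c = _g_to_c_string(model, pos)
        if model.strand == "-":
            ref, alt = _revcomp(ref), _revcomp(alt)
        return f"c.{c}{ref}>{alt}"
    if len(ref) > 1 and len(alt) == 1 and ref[0] == alt:
        lo, hi = pos + 1, pos + len(ref) - 1
        c_lo, c_hi = _g_to_c_string(model, lo), _g_to_c_string(model, hi)
        if model.strand == "-":
            c_lo, c_hi = c_hi, c_lo
        return f"c.{c_lo}del" if lo == hi else f"c.{c_lo}_{c_hi}del"
    if len(alt) > 1 and len(ref) == 1 and alt[0] == ref:
        g1, g2 = pos, pos + 1
        c1, c2 = _g_to_c_string(model, g1), _g_to_c_string(model, g2)
        ins = alt[1:]
        if model.strand == "-":
            c1, c2 = c2, c1
            ins = _revcomp(ins)
        return f"c.{c1}_{c2}ins{ins}"
    raise CoordinateError(f"unsupported allele pair {ref}>{alt} at {pos}")


# ---------------------------------------------------------------------------
# Effect annotation
# ---------------------------------------------------------------------------

def annotate_effect(
    record: VariantRecord, model: TranscriptModel, reference: str
) -> str:
    """Minimal effect classifier against one transcript model.

    Splice = within 2 bp of an exon/intron boundary on the intron side;
    frameshift iff the CDS length change is not a multiple of three; CDS
    SNVs are classified by translating the affected codon.  A reference
    mismatch at the variant position is a hard error (it guards against
    coordinate-system bugs upstream).
    """
    seen = reference[record.pos - 1 : record.pos - 1 + len(record.ref)].upper()
    if seen != record.ref:
        raise ValueError(
            f"reference mismatch at {record.chrom}:{record.pos}: "
            f"catalog says {record.ref!r}, reference has {seen!r}"
        )
    g2c = model.g_to_c_index()
    if record.is_snv:
        if record.pos in g2c:
            c = g2c[record.pos]
            cds = model.cds_sequence(reference)
            alt_t = record.alt if model.strand == "+" else _revcomp(record.alt)
            i0 = c - 1
            codon_start = (i0 // 3) * 3
            ref_codon = cds[codon_start : codon_start + 3]
            alt_codon = (
                ref_codon[: i0 % 3] + alt_t + ref_codon[i0 % 3 + 1 :]
            )
            if len(ref_codon) < 3:  # truncated terminal codon
                return "missense"
            ref_aa = str(Seq(ref_codon).translate())
            alt_aa = str(Seq(alt_codon).translate())
            if ref_aa == alt_aa:
                return "synonymous"
            if alt_aa == "*":
                return "stopgain"
            if ref_aa == "*":
                return "stoploss"
            return "missense"
        d = intron_boundary_distance(model, record.pos)
        if d is None:
            raise CoordinateError(
                f"SNV at {record.pos} is exonic but outside the CDS of {model.gene}"
            )
        return "splice" if d <= 2 else "intronic"
    # indel: positions actually altered (after the anchor base)
    if record.is_deletion:
        changed = range(record.pos + 1, record.pos + len(record.ref))
        kind = "deletion"
        delta = len(record.ref) - len(record.alt)
    else:
        changed = [record.pos]
        kind = "insertion"
        delta = len(record.alt) - len(record.ref)
    in_cds = [g in g2c for g in changed]
    if all(in_cds):
        frame = "frameshift" if delta % 3 else "nonframeshift"
        return f"{frame} {kind}"
    dists = [intron_boundary_distance(model, g) for g in changed if g not in g2c]
    if any(d is not None and d <= 2 for d in dists) or any(in_cds):
        return "splice"
    return "intronic"


# ---------------------------------------------------------------------------
# Summaries and IO
# ---------------------------------------------------------------------------

def summarize_catalog(
    records: list[VariantRecord], dropped_conflicting: int = 0
) -> CatalogSummary:
    """Per-class counts/percentages and per-gene effect-type breakdown."""
    counts = {"PV": 0, "BV": 0, "VUS": 0}
    for rec in records:
        counts[rec.clin_class] += 1
    total = len(records)
    percent = {
        k: (proportion(v, total) if total else 0.0) for k, v in counts.items()
    }
    if records:
        per_gene = (
            pd.DataFrame(
                [(r.gene, r.variant_type or "unannotated") for r in records],
                columns=["gene", "variant_type"],
            )
            .value_counts()
            .unstack(fill_value=0)
            .sort_index()
        )
    else:
        per_gene = pd.DataFrame()
    return CatalogSummary(
        class_counts=counts,
        class_percent=percent,
        per_gene_types=per_gene,
        total=total,
        dropped_conflicting=dropped_conflicting,
    )


def load_transcripts(path) -> dict[str, TranscriptModel]:
    """Load transcript models from JSON keyed by gene symbol."""
    data = json.loads(Path(path).read_text())
    return {d["gene"]: TranscriptModel(**d) for d in data}


def write_transcripts(models, path) -> None:
    Path(path).write_text(
        json.dumps([m.to_dict() for m in models], indent=2) + "\n"
    )


def load_founder_ids(path) -> set[str]:
    """Founder-variant ids (``GENE:c.name``), one per line; '#' comments."""
    out = set()
    for line in Path(path).read_text().splitlines():
        line = line.strip()
        if line and not line.startswith("#"):
            out.add(line)
    return out


def write_catalog_vcf(records: list[VariantRecord], path, contigs=None) -> None:
    """Write the normalized catalog as a VCF with CLNCLASS/VTYPE/FOUNDER INFO."""
    lines = [
        "##fileformat=VCFv4.2",
        '##INFO=<ID=CLNCLASS,Number=1,Type=String,Description="Clinical class (PV/BV/VUS)">',
        '##INFO=<ID=VTYPE,Number=1,Type=String,Description="Variant effect type">',
        '##INFO=<ID=FOUNDER,Number=0,Type=Flag,Description="Haplotype-verified founder variant">',
        '##INFO=<ID=GENE,Number=1,Type=String,Description="Gene symbol">',
        '##INFO=<ID=HGVSC,Number=1,Type=String,Description="Transcript-level name">',
    ]
    for name, length in (contigs or {}).items():
        lines.append(f"##contig=<ID={name},length={length}>")
    lines.append("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO")
    for rec in sorted(records, key=lambda r: (r.chrom, r.pos, r.ref, r.alt)):
        info = [
            f"GENE={rec.gene}",
            f"HGVSC={rec.hgvs_c}",
            f"CLNCLASS={rec.clin_class}",
        ]
        if rec.variant_type:
            info.append(f"VTYPE={rec.variant_type.replace(' ', '_')}")
        if rec.founder:
            info.append("FOUNDER")
        lines.append(
            f"{rec.chrom}\t{rec.pos}\t{rec.name}\t{rec.ref}\t{rec.alt}\t.\t.\t"
            + ";".join(info)
        )
    Path(path).write_text("\n".join(lines) + "\n")
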