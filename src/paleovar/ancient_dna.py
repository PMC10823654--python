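"""Ancient-genome arm: damage profiling, rescaling, calling, filtering.

Ancient DNA carries postmortem deamination artifacts: cytosine in
single-stranded overhangs deaminates to uracil, read as C→T near the 5′
end of the molecule and as G→A near the 3′ end (the complementary-strand
image).  This module estimates that damage profile from aligned reads,
caps the base qualities of likely damage products, performs mpileup-style
presence/absence variant calling at a minimum base quality of 1, applies
the terminal-2-bp exclusion rule (C>T calls supported only within 2 bp of
read starts, and G>A within 2 bp of read ends, are discarded), matches the
surviving calls against the modern variant catalog, and summarizes the
matched carriers over time, geography and hominin group.

All read-end offsets are computed in original-molecule orientation: for a
reverse-strand alignment the molecule's 5′ end is the rightmost reference
position.  Deamination chemistry is molecule-relative, not
reference-relative.
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass, field
from hashlib import md5
from pathlib import Path

import numpy as np
import pandas as pd
import pysam
from scipy.optimize import curve_fit

logger = logging.getLogger(__name__)

__all__ = [
    "AlignedRead",
    "DamageProfile",
    "VariantCall",
    "AncientSample",
    "MMR_GENE_REGIONS_HG19",
    "read_sam",
    "estimate_damage_profile",
    "fit_damage_model",
    "rescale_qualities",
    "pileup_call",
    "damage_filter",
    "match_catalog",
    "chronology_summary",
    "write_calls_vcf",
    "load_sample_metadata",
]

#: Genomic intervals of the four human mismatch-repair genes on hg19
#: (1-based, inclusive), used to window real-world calling.
MMR_GENE_REGIONS_HG19 = {
    "MLH1": ("chr3", 37034823, 37107380),
    "MSH2": ("chr2", 47630108, 47789450),
    "MSH6": ("chr2", 47922669, 48037240),
    "PMS2": ("chr7", 6012870, 6048756),
}

_COMPLEMENT = str.maketrans("ACGTacgt", "TGCAtgca")

#: Terminal window (in bp) of the damage exclusion rule: offsets 0 and 1.
TERMINAL_BP = 2


@dataclass
class AlignedRead:
    """One aligned read in reference-forward orientation.

    ``pos`` is the 1-based leftmost reference position; ``sequence`` and
    ``qualities`` are as stored in the SAM record (reference-forward).
    ``reverse`` means the molecule was sequenced from the opposite strand,
    so its 5′ end is the rightmost reference position.
    """

    id: str
    chrom: str
    pos: int
    reverse: bool
    sequence: str
    qualities: list
    duplicate: bool = False
    unmapped: bool = False

    def __post_init__(self) -> None:
        if len(self.sequence) != len(self.qualities):
            raise ValueError(f"read {self.id}: sequence/quality length mismatch")

    def __len__(self) -> int:
        return len(self.sequence)

    # -- molecule-orientation helpers -------------------------------------
    def offset5(self, i: int) -> int:
        """Distance of sequence index ``i`` from the molecule's 5′ end."""
        return len(self) - 1 - i if self.reverse else i

    def offset3(self, i: int) -> int:
        """Distance of sequence index ``i`` from the molecule's 3′ end."""
        return i if self.reverse else len(self) - 1 - i

    def molecule_base(self, i: int) -> str:
        base = self.sequence[i]
        return base.translate(_COMPLEMENT) if self.reverse else base


def read_sam(path) -> list[AlignedRead]:
    """Load a SAM/BAM file into :class:`AlignedRead` s (pysam-backed)."""
    reads = []
    with pysam.AlignmentFile(str(path), "r", check_sq=False) as fh:
        for aln in fh:
            if aln.is_unmapped or aln.query_sequence is None:
                continue
            reads.append(
                AlignedRead(
                    id=aln.query_name,
                    chrom=aln.reference_name,
                    pos=aln.reference_start + 1,
                    reverse=aln.is_reverse,
                    sequence=aln.query_sequence.upper(),
                    qualities=list(aln.query_qualities),
                    duplicate=aln.is_duplicate,
                )
            )
    return reads


# ---------------------------------------------------------------------------
# Damage profile
# ---------------------------------------------------------------------------

@dataclass
class DamageProfile:
    """C→T rate by 5′ offset and G→A rate by 3′ offset, with opportunities.

    Rates are ``None`` at offsets with zero opportunities (undefined, not
    zero).
    """

    ct5: list
    ga3: list
    ct5_counts: list = field(default_factory=list)
    ct5_opportunities: list = field(default_factory=list)
    ga3_counts: list = field(default_factory=list)
    ga3_opportunities: list = field(default_factory=list)

    def rate_ct5(self, offset: int) -> float:
        if 0 <= offset < len(self.ct5) and self.ct5[offset] is not None:
            return self.ct5[offset]
        return 0.0

    def rate_ga3(self, offset: int) -> float:
        if 0 <= offset < len(self.ga3) and self.ga3[offset] is not None:
            return self.ga3[offset]
        return 0.0

    def to_dict(self) -> dict:
        return {"ct5": self.ct5, "ga3": self.ga3}


def estimate_damage_profile(
    reads: list[AlignedRead], reference: str, max_offset: int = 25
) -> DamageProfile:
    """Empirical terminal-substitution rates from reads vs the reference.

    For each offset ``o`` from the molecule 5′ end, ``ct5[o]`` is the
    fraction of reference-C positions read as T among all reference-C
    positions at that offset; symmetrically ``ga3`` from the 3′ end.
    Reverse-strand alignments are flipped into molecule coordinates first.
    """
    if not any(not r.duplicate and not r.unmapped for r in reads):
        raise ValueError("no usable mapped reads")
    k = max_offset + 1
    ct_n, ct_d = [0] * k, [0] * k
    ga_n, ga_d = [0] * k, [0] * k
    for read in reads:
        if read.duplicate or read.unmapped:
            continue
        ref_span = reference[read.pos - 1 : read.pos - 1 + len(read)].upper()
        for i in range(len(read)):
            if i >= len(ref_span):
                break
            ref_base = ref_span[i]
            mol_ref = ref_base.translate(_COMPLEMENT) if read.reverse else ref_base
            mol_read = read.molecule_base(i)
            o5, o3 = read.offset5(i), read.offset3(i)
            if mol_ref == "C" and o5 < k:
                ct_d[o5] += 1
                if mol_read == "T":
                    ct_n[o5] += 1
            if mol_ref == "G" and o3 < k:
                ga_d[o3] += 1
                if mol_read == "A":
                    ga_n[o3] += 1
    ct5 = [n / d if d else None for n, d in zip(ct_n, ct_d)]
    ga3 = [n / d if d else None for n, d in zip(ga_n, ga_d)]
    return DamageProfile(ct5, ga3, ct_n, ct_d, ga_n, ga_d)


def fit_damage_model(profile: DamageProfile) -> tuple[float, float]:
    """Fit ``rate(o) = d0·exp(−λ·o)`` to the profile; returns ``(d0, λ)``.

    Both read ends are pooled; offsets are weighted by opportunity counts
    (weighted least squares via ``scipy.optimize.curve_fit``).
    """
    offsets, rates, weights = [], [], []
    for rate_list, opp_list in (
        (profile.ct5, profile.ct5_opportunities),
        (profile.ga3, profile.ga3_opportunities),
    ):
        for o, rate in enumerate(rate_list):
            if rate is None:
                continue
            offsets.append(o)
            rates.append(rate)
            weights.append(opp_list[o] if o < len(opp_list) else 1)
    if len(offsets) < 3:
        raise ValueError("too few informative offsets to fit a decay model")
    offsets = np.asarray(offsets, float)
    rates = np.asarray(rates, float)
    sigma = 1.0 / np.sqrt(np.maximum(np.asarray(weights, float), 1.0))
    popt, _ = curve_fit(
        lambda o, d0, lam: d0 * np.exp(-lam * o),
        offsets,
        rates,
        p0=(max(rates.max(), 1e-3), 0.1),
        sigma=sigma,
        bounds=([0.0, 0.0], [1.0, 10.0]),
        maxfev=10000,
    )
    return float(popt[0]), float(popt[1])


# ---------------------------------------------------------------------------
# Quality rescaling
# ---------------------------------------------------------------------------

def rescale_qualities(
    read: AlignedRead, profile: DamageProfile, reference: str
) -> AlignedRead:
    """Cap qualities of likely damage products; everything else unchanged.

    A base is a candidate damage product when it reads T over a reference
    C near the molecule 5′ end, or A over a reference G near the 3′ end
    (molecule orientation).  Its quality is capped at the Phred score of
    the profiled damage rate at that offset, ``round(−10·log10 p)`` — e.g.
    a rate of 0.5 caps at Q3.  A zero/undefined rate leaves the base
    untouched.
    """
    ref_span = reference[read.pos - 1 : read.pos - 1 + len(read)].upper()
    quals = list(read.qualities)
    for i in range(min(len(read), len(ref_span))):
        mol_ref = (
            ref_span[i].translate(_COMPLEMENT) if read.reverse else ref_span[i]
        )
        mol_read = read.molecule_base(i)
        p = 0.0
        if mol_ref == "C" and mol_read == "T":
            p = profile.rate_ct5(read.offset5(i))
        elif mol_ref == "G" and mol_read == "A":
            p = profile.rate_ga3(read.offset3(i))
        if p > 0.0:
            cap = max(0, round(-10.0 * math.log10(p)))
            quals[i] = min(quals[i], cap)
    return AlignedRead(
        id=read.id,
        chrom=read.chrom,
        pos=read.pos,
        reverse=read.reverse,
        sequence=read.sequence,
        qualities=quals,
        duplicate=read.duplicate,
        unmapped=read.unmapped,
    )


# ---------------------------------------------------------------------------
# Pileup calling
# ---------------------------------------------------------------------------

@dataclass
class SupportingRead:
    """Bookkeeping for one alt-supporting read at a call site."""

    read_id: str
    offset5: int
    offset3: int
    reverse: bool


@dataclass
class VariantCall:
    chrom: str
    pos: int  # 1-based
    ref: str
    alt: str
    depth: int
    alt_count: int
    terminal_alt_count: int = 0
    filter: str = "PASS"
    support: list = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.alt_count > self.depth:
            raise ValueError("alt_count exceeds depth")
        if self.terminal_alt_count > self.alt_count:
            raise ValueError("terminal_alt_count exceeds alt_count")

    @property
    def key(self) -> tuple:
        return (self.chrom, self.pos, self.ref, self.alt)

    @property
    def substitution(self) -> str:
        return f"{self.ref}>{self.alt}"


def _is_terminal(call_sub: str, sup: SupportingRead) -> bool:
    """Is this supporting read's site within the damage-relevant terminal
    window?  For C>T the relevant end is the molecule 5′; the molecule
    image of C>T on a reverse-aligned read is G>A at the molecule 3′ end,
    so the relevant offset there is ``offset3``.  Symmetric for G>A."""
    if call_sub == "C>T":
        off = sup.offset3 if sup.reverse else sup.offset5
        return off < TERMINAL_BP
    if call_sub == "G>A":
        off = sup.offset5 if sup.reverse else sup.offset3
        return off < TERMINAL_BP
    return False


def pileup_call(
    reads: list[AlignedRead],
    reference: str,
    region: tuple[str, int, int] | None = None,
    min_bq: int = 1,
    min_alt: int = 1,
) -> list[VariantCall]:
    """mpileup-style presence/absence SNV calling.

    Bases with quality ≥ ``min_bq`` from mapped, non-duplicate reads are
    piled per position; any non-reference allele with at least ``min_alt``
    qualifying reads is emitted.  ``region`` is a 1-based inclusive
    ``(chrom, start, end)`` window.  Depth at a position is the number of
    counted bases, so allele counts always sum to depth.
    """
    counts: dict[int, dict[str, int]] = {}
    support: dict[tuple[int, str], list[SupportingRead]] = {}
    chrom = None
    for read in reads:
        if read.duplicate or read.unmapped:
            continue
        if region and read.chrom != region[0]:
            continue
        chrom = chrom or read.chrom
        for i, base in enumerate(read.sequence):
            pos = read.pos + i  # 1-based; ungapped alignments
            if region and not (region[1] <= pos <= region[2]):
                continue
            if pos > len(reference):
                raise ValueError(
                    f"read {read.id} extends past the reference at {pos}"
                )
            if read.qualities[i] < min_bq:
                continue
            counts.setdefault(pos, {}).setdefault(base, 0)
            counts[pos][base] += 1
            support.setdefault((pos, base), []).append(
                SupportingRead(read.id, read.offset5(i), read.offset3(i), read.reverse)
            )
    calls = []
    for pos in sorted(counts):
        ref_base = reference[pos - 1].upper()
        depth = sum(counts[pos].values())
        for base, n in sorted(counts[pos].items()):
            if base == ref_base or base == "N" or n < min_alt:
                continue
            sup = support[(pos, base)]
            call = VariantCall(
                chrom=chrom or (region[0] if region else "ref"),
                pos=pos,
                ref=ref_base,
                alt=base,
                depth=depth,
                alt_count=n,
                support=sup,
            )
            call.terminal_alt_count = sum(
                1 for s in sup if _is_terminal(call.substitution, s)
            )
            calls.append(call)
    return calls


def damage_filter(call: VariantCall, min_alt: int = 1) -> VariantCall:
    """Apply the terminal-2-bp deamination exclusion rule to one call.

    Alt-supporting reads whose site lies within 2 bp of the damage-relevant
    molecule end are discounted for C>T and G>A calls.  If no support
    survives the call is marked DAMAGE; if fewer than ``min_alt`` survive,
    LOWSUPPORT; otherwise PASS with the surviving alt count.  Calls of any
    other substitution pass untouched.
    """
    if call.substitution not in ("C>T", "G>A"):
        call.filter = "PASS"
        return call
    surviving = [s for s in call.support if not _is_terminal(call.substitution, s)]
    n = len(surviving)
    if n == 0:
        call.filter = "DAMAGE"
    elif n < min_alt:
        call.filter = "LOWSUPPORT"
        call.alt_count = n
    else:
        call.filter = "PASS"
        call.alt_count = n
    return call


# ---------------------------------------------------------------------------
# Catalog matching
# ---------------------------------------------------------------------------

def reference_checksum(reference: str) -> str:
    return md5(reference.upper().encode()).hexdigest()


def match_catalog(
    calls: list[VariantCall],
    records,
    reference: str | None = None,
    expected_checksum: str | None = None,
) -> dict[str, list[str]]:
    """Exact-allele matches of PASS calls against the catalog.

    Returns ``{"PV": [...], "BV": [...], "VUS": [...]}`` variant ids.  When
    both ``reference`` and ``expected_checksum`` are given, a checksum
    mismatch (wrong build / coordinate system) is a hard error.
    """
    if reference is not None and expected_checksum is not None:
        if reference_checksum(reference) != expected_checksum:
            raise ValueError(
                "reference checksum mismatch: calls and catalog are on "
                "different coordinate systems"
            )
    by_key = {}
    for rec in records:
        by_key[rec.key] = rec
    out = {"PV": [], "BV": [], "VUS": []}
    for call in calls:
        if call.filter != "PASS":
            continue
        rec = by_key.get(call.key)
        if rec is not None:
            out[rec.clin_class].append(rec.variant_id)
    return out


# ---------------------------------------------------------------------------
# Samples and chronology
# ---------------------------------------------------------------------------

HOMININ_GROUPS = ("modern_human", "neanderthal", "denisovan", "hybrid")


@dataclass
class AncientSample:
    """One ancient individual with dates (years BP), location and calls."""

    id: str
    date_lo: float  # younger bound, years before present
    date_hi: float  # older bound
    lat: float
    lon: float
    region: str
    group: str = "modern_human"
    calls: list = field(default_factory=list)
    shared_pvs: list = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.date_lo > self.date_hi:
            raise ValueError(f"{self.id}: date_lo (younger) must be <= date_hi")
        if not -90 <= self.lat <= 90 or not -180 <= self.lon <= 180:
            raise ValueError(f"{self.id}: coordinates out of range")
        if self.group not in HOMININ_GROUPS:
            raise ValueError(f"{self.id}: unknown hominin group {self.group!r}")

    @property
    def date_mid(self) -> float:
        return (self.date_lo + self.date_hi) / 2.0


def load_sample_metadata(path) -> dict[str, AncientSample]:
    df = pd.read_csv(path, sep="\t")
    out = {}
    for _, row in df.iterrows():
        out[str(row["sample_id"])] = AncientSample(
            id=str(row["sample_id"]),
            date_lo=float(row["date_lo"]),
            date_hi=float(row["date_hi"]),
            lat=float(row["lat"]),
            lon=float(row["lon"]),
            region=str(row["region"]),
            group=str(row["group"]),
        )
    return out


def chronology_summary(
    samples: list[AncientSample], cutoff_bp: float = 10_000.0
) -> dict:
    """Time, geography and hominin-group summaries of PV-sharing samples.

    Date ranges are resolved to their midpoint; a midpoint exactly at the
    cutoff counts as within.  Carrier-level fractions are over sharing
    modern-human samples; PV-level fractions date each PV by the oldest
    midpoint among its modern-human carriers (archaic hominins are
    tabulated separately and never enter the modern-human time bins).
    """
    sharing = [s for s in samples if s.shared_pvs]
    modern = [s for s in sharing if s.group == "modern_human"]
    within = [s for s in modern if s.date_mid <= cutoff_bp]
    carrier_total = len(modern)

    pv_oldest: dict[str, float] = {}
    pv_newest: dict[str, float] = {}
    pv_carriers: dict[str, int] = {}
    for s in modern:
        for pv in set(s.shared_pvs):
            pv_carriers[pv] = pv_carriers.get(pv, 0) + 1
            pv_oldest[pv] = max(pv_oldest.get(pv, 0.0), s.date_mid)
            pv_newest[pv] = min(pv_newest.get(pv, math.inf), s.date_mid)
    pv_within = sum(1 for v in pv_oldest.values() if v <= cutoff_bp)

    from .stats_report import proportion  # local import avoids cycle at import time

    per_region: dict[str, int] = {}
    per_group: dict[str, int] = {g: 0 for g in HOMININ_GROUPS}
    for s in sharing:
        per_group[s.group] += 1
        if s.group == "modern_human":
            per_region[s.region] = per_region.get(s.region, 0) + 1

    return {
        "cutoff_bp": cutoff_bp,
        "n_sharing_samples": len(sharing),
        "n_sharing_modern": carrier_total,
        "carriers_within_cutoff": len(within),
        "carrier_within_percent": (
            proportion(len(within), carrier_total) if carrier_total else None
        ),
        "n_shared_pvs": len(pv_oldest),
        "pvs_within_cutoff": pv_within,
        "pv_within_percent": (
            proportion(pv_within, len(pv_oldest)) if pv_oldest else None
        ),
        "per_region": per_region,
        "per_group": per_group,
        "pv_carrier_counts": pv_carriers,
        "pv_oldest_bp": pv_oldest,
        "pv_newest_bp": pv_newest,
    }


def samples_geojson(samples: list[AncientSample]) -> dict:
    """GeoJSON FeatureCollection of sample locations with sharing status."""
    feats = []
    for s in samples:
        feats.append(
            {
                "type": "Feature",
                "geometry": {"type": "Point", "coordinates": [s.lon, s.lat]},
                "properties": {
                    "id": s.id,
                    "date_lo": s.date_lo,
                    "date_hi": s.date_hi,
                    "region": s.region,
                    "group": s.group,
                    "shared_pvs": list(s.shared_pvs),
                },
            }
        )
    return {"type": "FeatureCollection", "features": feats}


def write_calls_vcf(calls: list[VariantCall], path, sample_id: str = "sample") -> None:
    """Per-sample VCF with FILTER in {PASS, DAMAGE, LOWSUPPORT}."""
    lines = [
        "##fileformat=VCFv4.2",
        '##FILTER=<ID=DAMAGE,Description="Alt support only within 2bp of damage-relevant read ends">',
        '##FILTER=<ID=LOWSUPPORT,Description="Too few surviving alt reads">',
        '##INFO=<ID=DP,Number=1,Type=Integer,Description="Read depth">',
        '##INFO=<ID=AC,Number=1,Type=Integer,Description="Alt-supporting reads">',
        '##INFO=<ID=TAC,Number=1,Type=Integer,Description="Terminal alt-supporting reads">',
        f"##sample=<ID={sample_id}>",
        "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO",
    ]
    for c in sorted(calls, key=lambda c: (c.chrom, c.pos, c.alt)):
        lines.append(
            f"{c.chrom}\t{c.pos}\t.\t{c.ref}\t{c.alt}\t.\t{c.filter}\t"
            f"DP={c.depth};AC={c.alt_count};TAC={c.terminal_alt_count}"
        )
    Path(path).write_text("\n".join(lines) + "\n")


def write_geojson(samples, path) -> None:
    Path(path).write_text(json.dumps(samples_geojson(samples), indent=2) + "\n")
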