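"""Cross-species allele sharing through multiple-genome alignments.

Walks MAF (multiple alignment format) blocks anchored on a reference
("human-analog") genome to extract, for each catalog variant, the aligned
base(s) of every other species at the orthologous columns; classifies each
observation as shared (the species' aligned state equals the human
alternate allele), not shared, or missing (unaligned or gapped — treated
as missing data); and aggregates the resulting variant × species matrix by
phylogenetic clade for the downstream rank tests.

Conventions: MAF coordinates are 0-based, strand-relative, with the block
text column-aligned across rows; catalog coordinates are 1-based forward
strand and converted at this module's boundary.  Soft-masked (lowercase)
bases are compared case-insensitively but flagged.  When overlapping
blocks cover a variant the highest-scoring block wins (ties: file order).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import pandas as pd

from .phylogeny import PhyloTree, heatmap_order, patristic_distance
from .variant_catalog import VariantRecord

logger = logging.getLogger(__name__)

MISSING = "missing"
SHARED = "shared"
NOT_SHARED = "not_shared"
STATES = (SHARED, NOT_SHARED, MISSING)

__all__ = [
    "AlignmentBlock",
    "AlleleObservation",
    "SharingMatrix",
    "read_maf",
    "write_maf",
    "MafIndex",
    "lookup_species_allele",
    "classify_sharing",
    "build_sharing_matrix",
    "aggregate_by_clade",
    "domain_overlap_table",
]


@dataclass
class MafRow:
    species: str  # source name up to the first '.', e.g. "hg38.chr1" -> "hg38"
    src: str
    start: int  # 0-based, strand-relative
    size: int
    strand: str
    src_size: int
    text: str

    @property
    def forward_start(self) -> int:
        """0-based forward-strand start of this row's interval."""
        if self.strand == "+":
            return self.start
        return self.src_size - self.start - self.size

    @property
    def forward_end(self) -> int:
        return self.forward_start + self.size


@dataclass
class AlignmentBlock:
    score: float
    rows: list

    def row_for(self, species: str) -> MafRow | None:
        for row in self.rows:
            if row.species == species:
                return row
        return None


@dataclass
class AlleleObservation:
    """What one species shows over a variant's footprint in the alignment."""

    species: str
    bases: str | None  # None == missing
    masked: bool = False
    block_score: float | None = None
    reason: str = ""

    @property
    def missing(self) -> bool:
        return self.bases is None


def _species_of(src: str) -> str:
    return src.split(".", 1)[0]


def read_maf(stream):
    """Yield :class:`AlignmentBlock` s from a MAF stream or path.

    Preserves score, strand and srcSize; silently skips e/i/q annotation
    lines.  Rows of unequal text length within a block raise ``ValueError``
    naming the block ordinal.
    """
    close = False
    if isinstance(stream, (str, bytes)) or hasattr(stream, "__fspath__"):
        stream = open(stream)
        close = True
    try:
        ordinal = 0
        score = None
        rows: list[MafRow] = []

        def flush():
            nonlocal rows, score
            if not rows:
                return None
            widths = {len(r.text) for r in rows}
            if len(widths) > 1:
                raise ValueError(
                    f"MAF block {ordinal}: rows have unequal text lengths {sorted(widths)}"
                )
            for r in rows:
                ungapped = len(r.text) - r.text.count("-")
                if ungapped != r.size:
                    raise ValueError(
                        f"MAF block {ordinal}: row {r.src} size {r.size} != "
                        f"ungapped length {ungapped}"
                    )
            block = AlignmentBlock(score=score if score is not None else 0.0, rows=rows)
            rows, score = [], None
            return block

        for line in stream:
            line = line.rstrip("\n")
            if not line.strip():
                block = flush()
                if block:
                    ordinal += 1
                    yield block
                continue
            if line.startswith("#"):
                continue
            if line.startswith("a"):
                block = flush()
                if block:
                    ordinal += 1
                    yield block
                score = 0.0
                for tok in line.split()[1:]:
                    if tok.startswith("score="):
                        score = float(tok[6:])
                continue
            if line.startswith("s "):
                _, src, start, size, strand, src_size, text = line.split()
                rows.append(
                    MafRow(
                        species=_species_of(src),
                        src=src,
                        start=int(start),
                        size=int(size),
                        strand=strand,
                        src_size=int(src_size),
                        text=text,
                    )
                )
                continue
            # e/i/q annotation lines: tolerated, not used
            if line[0] in "eiq":
                continue
        block = flush()
        if block:
            yield block
    finally:
        if close:
            stream.close()


def write_maf(blocks, path) -> None:
    """Write blocks back out as a standard ##maf file."""
    with open(path, "w") as fh:
        fh.write("##maf version=1 scoring=synthetic\n")
        for block in blocks:
            fh.write(f"a score={block.score:.1f}\n")
            width = max(len(r.src) for r in block.rows)
            for r in block.rows:
                fh.write(
                    f"s {r.src:<{width}} {r.start} {r.size} {r.strand} "
                    f"{r.src_size} {r.text}\n"
                )
            fh.write("\n")


class MafIndex:
    """Blocks indexed by the reference species' forward-strand interval."""

    def __init__(self, blocks, reference_species: str):
        self.reference = reference_species
        self.entries = []  # (fwd_start, fwd_end, file_order, block)
        for order, block in enumerate(blocks):
            row = block.row_for(reference_species)
            if row is None:
                logger.warning("block %d lacks the reference species; skipped", order)
                continue
            self.entries.append((row.forward_start, row.forward_end, order, block))

    def covering(self, start0: int, end0: int) -> list[AlignmentBlock]:
        """Blocks whose reference interval covers [start0, end0), best score first."""
        hits = [
            (b, order)
            for (s, e, order, b) in self.entries
            if s <= start0 and end0 <= e
        ]
        hits.sort(key=lambda t: (-t[0].score, t[1]))
        return [b for b, _ in hits]


def _columns_for_positions(row: MafRow, positions0: list[int]) -> list[int]:
    """Alignment column index for each 0-based forward reference position.

    The reference row is required to be '+' strand (MAF convention for the
    anchoring genome).
    """
    wanted = set(positions0)
    cols = {}
    pos = row.forward_start
    for col, ch in enumerate(row.text):
        if ch != "-":
            if pos in wanted:
                cols[pos] = col
            pos += 1
    return [cols[p] for p in positions0]


def lookup_species_allele(
    variant: VariantRecord, index: MafIndex, species: str
) -> AlleleObservation:
    """Aligned base(s) of ``species`` over the variant's reference footprint.

    The footprint is the ref-allele span (one column for a SNV, the deleted
    span for a deletion, the anchor base for an insertion).  Gapped or
    unaligned spans are missing data.  For insertions the observation also
    collects any species bases in reference-gap columns immediately after
    the anchor, so an inserted allele can be recognized.
    """
    start0 = variant.pos - 1
    span = len(variant.ref)
    blocks = index.covering(start0, start0 + span)
    if not blocks:
        return AlleleObservation(species, None, reason="uncovered")
    block = blocks[0]
    href = block.row_for(index.reference)
    srow = block.row_for(species)
    if srow is None:
        return AlleleObservation(
            species, None, block_score=block.score, reason="species_absent"
        )
    cols = _columns_for_positions(href, list(range(start0, start0 + span)))

    if variant.is_insertion:
        # anchor base plus species bases in the reference-gap columns that follow
        anchor_col = cols[0]
        obs = srow.text[anchor_col]
        col = anchor_col + 1
        while col < len(href.text) and href.text[col] == "-":
            obs += srow.text[col]
            col += 1
        if obs[0] == "-":
            return AlleleObservation(
                species, None, block_score=block.score, reason="gap"
            )
        bases = obs.replace("-", "")
        return AlleleObservation(
            species,
            bases.upper(),
            masked=any(c.islower() for c in obs),
            block_score=block.score,
        )

    chars = [srow.text[c] for c in cols]
    if variant.is_snv:
        if chars[0] == "-":
            return AlleleObservation(species, None, block_score=block.score, reason="gap")
    elif all(ch == "-" for ch in chars):
        return AlleleObservation(species, None, block_score=block.score, reason="gap")
    bases = "".join(ch for ch in chars if ch != "-")
    if not bases:
        return AlleleObservation(species, None, block_score=block.score, reason="gap")
    return AlleleObservation(
        species,
        bases.upper(),
        masked=any(c.islower() for c in chars),
        block_score=block.score,
    )


def classify_sharing(variant: VariantRecord, obs: AlleleObservation) -> str:
    """shared / not_shared / missing for one (variant, species) observation.

    Shared iff the species' observed footprint equals the variant's
    alternate-allele footprint, case-insensitively: the alt base for a SNV,
    the post-deletion haplotype (anchor base only) for a deletion, the
    anchor-plus-inserted sequence for an insertion.  Missing propagates.
    """
    if obs.missing:
        return MISSING
    return SHARED if obs.bases == variant.alt.upper() else NOT_SHARED


@dataclass
class SharingMatrix:
    """Variant × species grid of sharing states with roll-up counts."""

    grid: pd.DataFrame  # index: variant_id, columns: species, values in STATES
    records: dict = field(default_factory=dict)  # variant_id -> VariantRecord

    def per_variant_counts(self) -> pd.DataFrame:
        out = pd.DataFrame(
            {state: (self.grid == state).sum(axis=1) for state in STATES}
        )
        out["n_species"] = len(self.grid.columns)
        return out

    def per_species_counts(self) -> pd.DataFrame:
        """Shared-variant counts per species, split by clinical class."""
        classes = {vid: rec.clin_class for vid, rec in self.records.items()}
        rows = []
        for species in self.grid.columns:
            shared_ids = self.grid.index[self.grid[species] == SHARED]
            row = {"species": species, "shared_total": len(shared_ids)}
            for cls in ("PV", "BV", "VUS"):
                row[f"shared_{cls}"] = sum(
                    1 for vid in shared_ids if classes.get(vid) == cls
                )
            rows.append(row)
        return pd.DataFrame(rows).set_index("species")

    def to_long(self) -> pd.DataFrame:
        long = self.grid.stack().rename("state").reset_index()
        long.columns = ["variant_id", "species", "state"]
        return long


def build_sharing_matrix(
    records: list[VariantRecord],
    maf_blocks,
    species_list: list[str],
    reference_species: str,
) -> SharingMatrix:
    """Classify every variant against every non-reference species.

    ``species_list`` comes from the tree; species present in the MAF but
    absent from it are excluded with a warning.
    """
    blocks = list(maf_blocks)
    maf_species = {r.species for b in blocks for r in b.rows}
    extra = maf_species - set(species_list) - {reference_species}
    if extra:
        logger.warning("species in MAF absent from species list, excluded: %s", sorted(extra))
    index = MafIndex(blocks, reference_species)
    targets = [s for s in species_list if s != reference_species]
    data = {}
    records_by_id = {}
    for rec in records:
        records_by_id[rec.variant_id] = rec
        states = {}
        for sp in targets:
            obs = lookup_species_allele(rec, index, sp)
            states[sp] = classify_sharing(rec, obs)
        data[rec.variant_id] = states
    grid = pd.DataFrame.from_dict(data, orient="index", columns=targets)
    grid = grid.reindex(columns=targets)
    return SharingMatrix(grid=grid, records=records_by_id)


def aggregate_by_clade(
    matrix: SharingMatrix, clade_map: dict[str, str], tree: PhyloTree
) -> tuple[pd.DataFrame, dict, list[str]]:
    """Per-species table (tree order), per-clade PV-share groups, display order.

    Returns ``(per_species, clade_groups, order)`` where ``per_species``
    carries each species' shared counts by class, its clade and its
    patristic distance to the reference leaf, in heatmap order;
    ``clade_groups`` maps clade → list of per-species shared-PV counts,
    ready for the Kruskal–Wallis comparison.
    """
    missing = [s for s in matrix.grid.columns if s not in clade_map]
    if missing:
        raise ValueError(f"clade_map does not cover species: {missing}")
    order = [s for s in heatmap_order(tree) if s in matrix.grid.columns]
    per_species = matrix.per_species_counts().reindex(order)
    per_species["clade"] = [clade_map[s] for s in per_species.index]
    if tree.reference is not None:
        per_species["distance_to_reference"] = [
            patristic_distance(tree, tree.reference, s) for s in per_species.index
        ]
    clade_groups: dict[str, list[float]] = {}
    for sp, row in per_species.iterrows():
        clade_groups.setdefault(row["clade"], []).append(int(row["shared_PV"]))
    return per_species, clade_groups, order


def _merge_intervals(intervals):
    """Merge overlapping half-open intervals; warn when any overlap."""
    merged = []
    overlap = False
    for start, end, name in sorted(intervals):
        if merged and start < merged[-1][1]:
            overlap = True
            prev = merged.pop()
            merged.append((prev[0], max(prev[1], end), f"{prev[2]}+{name}"))
        else:
            merged.append((start, end, name))
    if overlap:
        logger.warning("overlapping domain intervals were merged")
    return merged


def read_bed(path):
    """(start0, end0, name) triples from a BED file (0-based half-open)."""
    out = []
    for line in open(path):
        line = line.strip()
        if not line or line.startswith(("#", "track", "browser")):
            continue
        fields = line.split("\t")
        name = fields[3] if len(fields) > 3 else f"{fields[0]}:{fields[1]}-{fields[2]}"
        out.append((int(fields[1]), int(fields[2]), name))
    return out


def domain_overlap_table(
    shared_ids: set[str],
    records: list[VariantRecord],
    domains,
) -> pd.DataFrame:
    """Contingency counts of shared vs unshared variants in/outside domains.

    ``domains`` are (start0, end0, name) half-open genomic intervals (BED
    convention: a variant exactly at a domain start is inside, at the end
    outside).  Overlapping intervals are merged with a warning.  With no
    domains, a single "outside" stratum holds every variant.
    """
    merged = _merge_intervals(list(domains))

    def stratum(rec: VariantRecord) -> str:
        p0 = rec.pos - 1
        for start, end, name in merged:
            if start <= p0 < end:
                return name
        return "outside"

    rows = []
    strata = [name for _, _, name in merged] + ["outside"]
    counts = {s: {"shared": 0, "not_shared": 0} for s in strata}
    for rec in records:
        key = "shared" if rec.variant_id in shared_ids else "not_shared"
        counts[stratum(rec)][key] += 1
    for s in strata:
        rows.append(
            {"domain": s, "shared": counts[s]["shared"], "not_shared": counts[s]["not_shared"]}
        )
    return pd.DataFrame(rows).set_index("domain")
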