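"""Synthetic study generator: every input the pipeline consumes.

Emulates, at desk scale, the three real-world inputs of the analysis —
a clinical variant catalog with PV/BV/VUS/conflicting classes, a
multi-species whole-genome alignment over a clade-structured phylogeny
with planted allele sharing, and ancient-genome read data carrying true
variants plus exponential-decay terminal deamination artifacts — together
with machine-readable truth sets so every downstream stage can be checked
against what was planted.

The generator is fully deterministic: the same :class:`SimConfig` (same
seed) reproduces byte-identical MAF/TSV/SAM/FASTA outputs.  Planted
sharing follows the empirical gradient of interest: pathogenic variants
are planted mostly in clades distant from the reference species, benign
variants broadly; damage follows a single-stranded-overhang-style model
of independent per-base flips with rate ``d0·exp(−λ·offset)`` from each
molecule end (C→T from 5′, G→A from 3′).
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .cross_species import MISSING, NOT_SHARED, SHARED, AlignmentBlock, MafRow, write_maf
from .variant_catalog import (
    TranscriptModel,
    VariantRecord,
    annotate_effect,
    genomic_to_cds,
    parse_catalog,
    write_transcripts,
)

_BASES = "ACGT"
_COMPLEMENT = str.maketrans("ACGT", "TGCA")

REFERENCE_SPECIES = "Human"
CHROM = "ref1"

#: Default clade layout mirroring an eight-clade vertebrate panel with the
#: reference species in the first clade.
DEFAULT_CLADES = (
    ("Primate", 3),
    ("Euarchontoglires", 2),
    ("Laurasiatheria", 2),
    ("Afrotheria", 2),
    ("Mammal", 3),
    ("Aves", 3),
    ("Sarcopterygii", 2),
    ("Fish", 3),
)

#: Per-class base probability that a given species shares a given variant;
#: scaled up with clade distance from the reference (distal clades share
#: more, reproducing the planted gradient the clade comparison must find).
SHARING_BASE_PROB = {"PV": 0.12, "BV": 0.55, "VUS": 0.30}
MISSING_PROB = 0.05

DEFAULT_VARIANTS_PER_CLASS = {"PV": 14, "BV": 14, "VUS": 14, "conflicting": 4}

_EFFECT_CYCLE = (
    "missense",
    "stopgain",
    "synonymous",
    "splice",
    "frameshift deletion",
    "nonframeshift deletion",
    "frameshift insertion",
)

GENES = ("MLH1", "MSH2", "MSH6", "PMS2")


def _default_samples() -> list[tuple]:
    """20 ancient individuals: mostly recent modern humans across six
    continents, two deep-time moderns, two Neanderthals and a Denisovan
    (dates in years BP, youngest bound first)."""
    rows = [
        ("AH001", 150, 250, 48.1, 11.5, "Europe", "modern_human"),
        ("AH002", 639, 784, 47.9, 106.9, "Asia", "modern_human"),
        ("AH003", 1100, 1300, 51.5, -0.1, "Europe", "modern_human"),
        ("AH004", 2123, 2318, 43.9, 81.3, "Asia", "modern_human"),
        ("AH005", 2900, 3100, 37.9, 23.7, "Europe", "modern_human"),
        ("AH006", 3650, 3950, 47.5, 19.0, "Europe", "modern_human"),
        ("AH007", 4250, 4440, 31.9, 35.9, "Asia", "modern_human"),
        ("AH008", 5000, 5400, -34.6, -58.4, "South America", "modern_human"),
        ("AH009", 6100, 6500, 40.7, -74.0, "North America", "modern_human"),
        ("AH010", 7000, 7300, -12.0, -77.0, "South America", "modern_human"),
        ("AH011", 7900, 8200, 55.8, 37.6, "Europe", "modern_human"),
        ("AH012", 8700, 9100, 34.0, 108.9, "Asia", "modern_human"),
        ("AH013", 9300, 9600, 59.3, 18.1, "Europe", "modern_human"),
        ("AH014", 9700, 9900, 30.0, 31.2, "Africa", "modern_human"),
        ("AH015", 600, 900, -33.9, 151.2, "Oceania", "modern_human"),
        ("AH016", 4800, 5100, 64.2, -51.7, "North America", "modern_human"),
        ("AH017", 12050, 12400, 36.2, 137.2, "Asia", "modern_human"),
        ("AH018", 32360, 34324, 45.8, 126.6, "Asia", "modern_human"),
        ("NEA01", 42960, 44600, 44.2, 40.0, "Europe", "neanderthal"),
        ("DEN01", 52000, 76000, 51.4, 84.7, "Asia", "denisovan"),
    ]
    return rows


@dataclass
class SimConfig:
    """All knobs of the synthetic study, with the default study conditions.

    ``planted_sharing`` may pin specific variant→species sharing sets;
    left ``None``, sharing is drawn per class with the clade-distance
    gradient.  ``damage_d0``/``damage_lambda`` parameterize the terminal
    deamination model (probability at offset 0, decay per base).
    """

    seed: int = 0
    n_species: int = 20
    clade_spec: tuple = DEFAULT_CLADES
    ref_length: int = 8000
    n_variants_per_class: dict = field(
        default_factory=lambda: dict(DEFAULT_VARIANTS_PER_CLASS)
    )
    planted_sharing: dict | None = None
    coverage: float = 30.0
    read_length: int = 60
    damage_d0: float = 0.3
    damage_lambda: float = 0.3
    sample_dates_bp: list = field(default_factory=_default_samples)

    def __post_init__(self) -> None:
        if not 0.0 <= self.damage_d0 <= 1.0:
            raise ValueError("damage_d0 must lie in [0, 1]")
        if self.damage_lambda < 0:
            raise ValueError("damage_lambda must be >= 0")
        if self.coverage <= 0:
            raise ValueError("coverage must be positive")
        if self.n_species < 2:
            raise ValueError("need at least two species")
        total = sum(n for _, n in self.clade_spec)
        if total != self.n_species:
            raise ValueError(
                f"clade_spec species counts sum to {total}, not n_species={self.n_species}"
            )
        if self.ref_length < 100:
            raise ValueError("reference must be at least 100 bases")
        if self.planted_sharing:
            names = set(self.species_names())
            for vid, spset in self.planted_sharing.items():
                unknown = set(spset) - names
                if unknown:
                    raise ValueError(
                        f"planted_sharing for {vid} names unknown species {sorted(unknown)}"
                    )

    def species_names(self) -> list[str]:
        """Reference species first, then clade-by-clade synthetic names."""
        names = []
        for clade, count in self.clade_spec:
            for i in range(count):
                if not names:
                    names.append(REFERENCE_SPECIES)
                else:
                    names.append(f"{clade}_{i + 1}")
        return names

    def clade_map(self) -> dict[str, str]:
        out = {}
        idx = 0
        names = self.species_names()
        for clade, count in self.clade_spec:
            for _ in range(count):
                out[names[idx]] = clade
                idx += 1
        return out

    def clade_index(self) -> dict[str, int]:
        return {clade: i for i, (clade, _) in enumerate(self.clade_spec)}

    def _rng(self, stream: int) -> np.random.Generator:
        return np.random.default_rng([self.seed, stream])


@dataclass
class TruthSet:
    """What was planted, for exact downstream checks."""

    planted_variants: list = field(default_factory=list)  # (vid, pos, ref, alt, carriers)
    planted_sharing: dict = field(default_factory=dict)  # vid -> sorted list of species
    sharing_grid: dict = field(default_factory=dict)  # vid -> {species: state}
    damage_artifacts: dict = field(default_factory=dict)  # sample -> [(read, off, sub)]
    carriers: dict = field(default_factory=dict)  # sample -> [vid, ...]

    def to_dict(self) -> dict:
        return {
            "planted_variants": self.planted_variants,
            "planted_sharing": {k: sorted(v) for k, v in self.planted_sharing.items()},
            "sharing_grid": self.sharing_grid,
            "damage_artifacts": self.damage_artifacts,
            "carriers": self.carriers,
        }


# ---------------------------------------------------------------------------
# Reference and phylogeny
# ---------------------------------------------------------------------------

def make_reference(config: SimConfig) -> str:
    rng = config._rng(0)
    return "".join(rng.choice(list(_BASES), size=config.ref_length))


def make_phylogeny(config: SimConfig) -> tuple[str, dict[str, str]]:
    """Binary species tree with monophyletic clades, as newick text.

    Clades hang off a backbone ladder in the order given by ``clade_spec``
    (the reference-containing clade nearest the root tip), with backbone
    branch lengths growing outward so patristic distance to the reference
    increases with clade index.  Strictly positive branch lengths drawn
    deterministically from the seed.
    """
    rng = config._rng(1)
    names = config.species_names()
    clade_map = config.clade_map()
    by_clade: dict[str, list[str]] = {}
    for name in names:
        by_clade.setdefault(clade_map[name], []).append(name)

    def ladder(leaves: list[str]) -> str:
        # binary ladder within a clade; subtree string without outer length
        node = leaves[0]
        for leaf in leaves[1:]:
            node = (
                f"({node}:{rng.uniform(0.05, 0.15):.4f},"
                f"{leaf}:{rng.uniform(0.05, 0.15):.4f})"
            )
        return node

    clade_nodes = [ladder(by_clade[clade]) for clade, _ in config.clade_spec]
    # backbone ladder: reference clade splits off nearest the tip; deeper
    # clades hang on progressively longer stems
    n = len(clade_nodes)
    tree = clade_nodes[-1]
    for i in range(n - 2, -1, -1):
        clade_stem = 0.05 + rng.uniform(0.0, 0.05)
        back_stem = 0.1 + 0.15 * (n - 1 - i) + rng.uniform(0.0, 0.05)
        tree = f"({clade_nodes[i]}:{clade_stem:.4f},{tree}:{back_stem:.4f})"
    return tree + ";", clade_map


# ---------------------------------------------------------------------------
# Transcript models
# ---------------------------------------------------------------------------

def make_transcript_models(config: SimConfig) -> list[TranscriptModel]:
    """Four three-exon gene models tiled over the reference, alternating
    strand, with intron lengths large enough to exercise splice offsets."""
    span = config.ref_length // len(GENES)
    if span < 1400:
        raise ValueError("reference too short for four gene models")
    models = []
    for gi, gene in enumerate(GENES):
        s = gi * span + 101  # 1-based start of exon 1
        exons = ((s, s + 199), (s + 400, s + 699), (s + 900, s + 1199))
        strand = "+" if gi % 2 == 0 else "-"
        lo_bound, hi_bound = s + 30, s + 1169
        # trim the transcript-terminal CDS bound until length is a codon multiple
        def cds_len(lo, hi):
            return sum(
                max(0, min(b, hi) - max(a, lo) + 1) for a, b in exons
            )
        while cds_len(lo_bound, hi_bound) % 3:
            if strand == "+":
                hi_bound -= 1
            else:
                lo_bound += 1
        cds_start, cds_end = (
            (lo_bound, hi_bound) if strand == "+" else (hi_bound, lo_bound)
        )
        models.append(
            TranscriptModel(
                gene=gene,
                chrom=CHROM,
                strand=strand,
                exons=exons,
                cds_start=cds_start,
                cds_end=cds_end,
            )
        )
    return models


# ---------------------------------------------------------------------------
# Catalog simulation
# ---------------------------------------------------------------------------

_SIG_CYCLE = {
    "PV": ("Pathogenic", "Likely pathogenic", "Pathogenic/Likely pathogenic"),
    "BV": ("Benign", "Likely benign", "Benign/Likely benign"),
    "VUS": ("Uncertain significance",),
    "conflicting": ("Conflicting interpretations of pathogenicity",),
}


def _free(used: set[int], positions) -> bool:
    return all(p not in used for p in positions)


def _reserve(used: set[int], positions, pad: int = 4) -> None:
    for p in positions:
        for q in range(p - pad, p + pad + 1):
            used.add(q)


def _make_snv_of_effect(model, reference, rng, used, wanted: str):
    """Find a CDS SNV whose codon-translation effect is ``wanted``."""
    from .variant_catalog import VariantRecord as VR

    cds = model.cds_positions()
    order = rng.permutation(len(cds))
    for idx in order:
        g = cds[idx]
        if not _free(used, [g]):
            continue
        ref_base = reference[g - 1]
        for alt in rng.permutation(list(_BASES)):
            if alt == ref_base:
                continue
            probe = VR(
                gene=model.gene, chrom=model.chrom, pos=g, ref=ref_base,
                alt=str(alt), hgvs_c="c.0", clin_class="VUS",
            )
            try:
                effect = annotate_effect(probe, model, reference)
            except ValueError:
                continue
            if effect == wanted:
                return g, ref_base, str(alt)
    return None


def _make_variant(model, reference, rng, used, effect: str):
    """One (pos, ref, alt, hgvs_c, effect) of the requested effect type."""
    if effect in ("missense", "stopgain", "synonymous"):
        found = _make_snv_of_effect(model, reference, rng, used, effect)
        if found is None:
            return None
        g, ref, alt = found
        _reserve(used, [g])
        return g, ref, alt, genomic_to_cds(model, g, ref, alt), effect
    g2c = model.g_to_c_index()
    if effect == "splice":
        # 1-2 bp into an intron from an internal CDS exon boundary
        cds = model.cds_positions()
        boundaries = []
        for a, b in model.exons[1:-1]:
            boundaries.extend([(a, -1), (b, +1)])
        rng.shuffle(boundaries)
        for edge, direction in boundaries:
            off = int(rng.integers(1, 3))  # 1 or 2
            g = edge + direction * off
            if g in g2c or not _free(used, [g]):
                continue
            ref = reference[g - 1]
            alt = str(rng.choice([b for b in _BASES if b != ref]))
            _reserve(used, [g])
            return g, ref, alt, genomic_to_cds(model, g, ref, alt), effect
        return None
    if effect.endswith("deletion"):
        dlen = 2 if effect.startswith("frameshift") else 3
        cds = model.cds_positions()
        order = rng.permutation(len(cds))
        for idx in order:
            anchor = cds[idx]
            span = list(range(anchor, anchor + dlen + 1))
            if not all(p in g2c for p in span) or not _free(used, span):
                continue
            ref = reference[anchor - 1 : anchor + dlen]
            alt = ref[0]
            _reserve(used, span)
            return anchor, ref, alt, genomic_to_cds(model, anchor, ref, alt), effect
    if effect == "frameshift insertion":
        cds = model.cds_positions()
        order = rng.permutation(len(cds))
        for idx in order:
            anchor = cds[idx]
            if anchor + 1 not in g2c or not _free(used, [anchor, anchor + 1]):
                continue
            ref = reference[anchor - 1]
            alt = ref + str(rng.choice(list(_BASES)))
            _reserve(used, [anchor, anchor + 1])
            return anchor, ref, alt, genomic_to_cds(model, anchor, ref, alt), effect
    return None


def simulate_catalog(
    config: SimConfig, transcripts: list[TranscriptModel], reference: str
) -> tuple[pd.DataFrame, list[str]]:
    """ClinVar-style table with all four label groups.

    Effect types cycle through SNV/splice/indel categories per gene; every
    emitted c. name is produced by the genomic→c. converter on the emitted
    genomic alleles, so the two namings are consistent by construction.
    Returns ``(table, founder_ids)`` where founder ids (``GENE:c.name``)
    mark a small tracked subset of PVs.
    """
    rng = config._rng(2)
    used: set[int] = set()
    rows = []
    for cls in ("PV", "BV", "VUS", "conflicting"):
        count = config.n_variants_per_class.get(cls, 0)
        sigs = _SIG_CYCLE[cls]
        made = 0
        attempt = 0
        while made < count:
            attempt += 1
            if attempt > 50 * count + 50:
                raise RuntimeError(
                    f"could not place {count} {cls} variants; reference too crowded"
                )
            model = transcripts[(made + attempt) % len(transcripts)]
            effect = _EFFECT_CYCLE[made % len(_EFFECT_CYCLE)]
            if cls != "PV" and effect.endswith(("deletion", "insertion")):
                effect = "missense"  # indels concentrated in the PV class
            out = _make_variant(model, reference, rng, used, effect)
            if out is None:
                continue
            pos, ref, alt, hgvs_c, eff = out
            rows.append(
                {
                    "gene": model.gene,
                    "chrom": model.chrom,
                    "pos_1based": pos,
                    "ref": ref,
                    "alt": alt,
                    "hgvs_c": hgvs_c,
                    "clinical_significance": sigs[made % len(sigs)],
                    "variant_type": eff,
                }
            )
            made += 1
    table = pd.DataFrame(rows)
    founders = [
        f"{r['gene']}:{r['hgvs_c']}"
        for r in rows
        if r["clinical_significance"].startswith("Patho")
        and len(r["ref"]) == 1
        and len(r["alt"]) == 1
    ][:3]
    return table, founders


# ---------------------------------------------------------------------------
# Alignment simulation
# ---------------------------------------------------------------------------

def plant_sharing(
    config: SimConfig, records: list[VariantRecord]
) -> tuple[dict, dict]:
    """Draw the planted sharing and missing sets per (variant, species).

    Sharing probability = class base rate × clade-distance factor, so the
    distal clades accumulate more shared pathogenic variants.  An explicit
    ``config.planted_sharing`` overrides the draw for the variants it names.
    """
    rng = config._rng(3)
    clade_map = config.clade_map()
    clade_idx = config.clade_index()
    n_clades = len(config.clade_spec)
    species = [s for s in config.species_names() if s != REFERENCE_SPECIES]
    sharing: dict[str, set] = {}
    missing: dict[str, set] = {}
    for rec in records:
        share, miss = set(), set()
        for sp in species:
            factor = (clade_idx[clade_map[sp]] + 1) / n_clades
            p = SHARING_BASE_PROB[rec.clin_class] * factor
            u = rng.random()
            if u < p:
                share.add(sp)
            elif rng.random() < MISSING_PROB:
                miss.add(sp)
        if config.planted_sharing and rec.variant_id in config.planted_sharing:
            share = set(config.planted_sharing[rec.variant_id])
            miss -= share
        sharing[rec.variant_id] = share
        missing[rec.variant_id] = miss
    return sharing, missing


def simulate_alignment(
    config: SimConfig,
    reference: str,
    records: list[VariantRecord],
    sharing: dict[str, set],
    missing: dict[str, set],
    block_size: int = 40,
) -> tuple[list[AlignmentBlock], dict]:
    """MAF blocks over all species with the planted sharing structure.

    For each variant and species: planted-shared species carry the
    alternate footprint at the orthologous columns (gap columns for
    deletions, extra reference-gap columns for insertions), planted-missing
    species are gapped, everyone else carries the reference allele.
    Neutral substitutions (never at variant footprints) give each species
    clade-scaled divergence; ~10% of columns are soft-masked (lowercase);
    some non-reference rows are emitted on the negative strand.  Returns
    the blocks plus the exact truth grid.
    """
    rng = config._rng(4)
    species = [s for s in config.species_names() if s != REFERENCE_SPECIES]
    clade_idx = config.clade_index()
    clade_map = config.clade_map()
    L = len(reference)

    snv, dele, ins = {}, {}, {}
    footprint: set[int] = set()
    for rec in records:
        if rec.is_snv:
            snv[rec.pos] = rec
            footprint.add(rec.pos)
        elif rec.is_deletion:
            dele[rec.pos] = rec
            footprint.update(range(rec.pos, rec.pos + len(rec.ref)))
        else:
            ins[rec.pos] = rec
            footprint.update((rec.pos, rec.pos + 1))

    truth: dict[str, dict[str, str]] = {
        rec.variant_id: {} for rec in records
    }

    def state(rec: VariantRecord, sp: str) -> str:
        if sp in sharing.get(rec.variant_id, ()):  # planted shared
            return SHARED
        if sp in missing.get(rec.variant_id, ()):
            return MISSING
        return NOT_SHARED

    # per-species divergence rate away from variant columns
    div = {
        sp: 0.01 + 0.01 * clade_idx[clade_map[sp]] for sp in species
    }

    # column groups: one per reference base, plus insert columns after anchors
    human_cols: list[str] = []
    species_cols: dict[str, list[str]] = {sp: [] for sp in species}
    col_ref_index: list[int] = []  # reference 0-based position that owns the group

    for p0 in range(L):
        pos = p0 + 1
        hbase = reference[p0]
        human_cols.append(hbase)
        col_ref_index.append(p0)
        for sp in species:
            base = hbase
            rec = snv.get(pos)
            if rec is not None:
                st = state(rec, sp)
                truth[rec.variant_id][sp] = st
                base = rec.alt if st == SHARED else ("-" if st == MISSING else hbase)
            else:
                owner = None
                for rec2 in dele.values():
                    if rec2.pos < pos < rec2.pos + len(rec2.ref):
                        owner = rec2
                        break
                if owner is not None:
                    st = state(owner, sp)
                    base = "-" if st in (SHARED, MISSING) else hbase
                elif pos in dele or pos in ins:
                    rec2 = dele.get(pos, ins.get(pos))
                    st = state(rec2, sp)
                    truth[rec2.variant_id][sp] = st
                    base = "-" if st == MISSING else hbase
                elif pos in footprint:
                    pass  # never mutate variant footprints neutrally
                elif rng.random() < div[sp]:
                    base = str(
                        rng.choice([b for b in _BASES if b != hbase])
                    )
            species_cols[sp].append(base)
        # insertion columns right after the anchor
        rec = ins.get(pos)
        if rec is not None:
            insert = rec.alt[1:]
            for ch in insert:
                human_cols.append("-")
                col_ref_index.append(p0)
                for sp in species:
                    st = state(rec, sp)
                    species_cols[sp].append(ch if st == SHARED else "-")

    # soft-mask ~10% of columns (entire column, all rows)
    mask = rng.random(len(human_cols)) < 0.10
    for ci in np.flatnonzero(mask):
        human_cols[ci] = human_cols[ci].lower()
        for sp in species:
            species_cols[sp][ci] = species_cols[sp][ci].lower()

    # chop into blocks on reference-position boundaries, never cutting
    # through a variant footprint (each variant must sit in one block)
    bad_cut = set()
    for rec in records:
        for p in range(rec.pos, rec.pos + len(rec.ref) - 1):
            bad_cut.add(p)  # cutting between 0-based p-1 and p splits rec
    edges = []
    start_col = 0
    while start_col < len(human_cols):
        end_ref = min(col_ref_index[start_col] + block_size, L)
        while end_ref < L and end_ref in bad_cut:
            end_ref += 1
        end_col = start_col
        while end_col < len(human_cols) and col_ref_index[end_col] < end_ref:
            end_col += 1
        edges.append((start_col, end_col))
        start_col = end_col

    # negative-strand rows need each species' total source length
    src_size = {
        sp: sum(1 for ch in species_cols[sp] if ch != "-") for sp in species
    }
    offset = {sp: 0 for sp in species}
    blocks = []
    for start_col, end_col in edges:
        htext = "".join(human_cols[start_col:end_col])
        ref_start0 = col_ref_index[start_col]
        rows = [
            MafRow(
                species=REFERENCE_SPECIES,
                src=f"{REFERENCE_SPECIES}.{CHROM}",
                start=ref_start0,
                size=len(htext) - htext.count("-"),
                strand="+",
                src_size=L,
                text=htext,
            )
        ]
        for sp in species:
            text = "".join(species_cols[sp][start_col:end_col])
            size = len(text) - text.count("-")
            fwd_start = offset[sp]
            offset[sp] += size
            if rng.random() < 0.3:
                strand, start = "-", src_size[sp] - fwd_start - size
            else:
                strand, start = "+", fwd_start
            rows.append(
                MafRow(
                    species=sp,
                    src=f"{sp}.chr1",
                    start=start,
                    size=size,
                    strand=strand,
                    src_size=src_size[sp],
                    text=text,
                )
            )
        blocks.append(
            AlignmentBlock(score=float(round(rng.uniform(1000, 30000), 1)), rows=rows)
        )
    return blocks, truth


# ---------------------------------------------------------------------------
# Ancient reads
# ---------------------------------------------------------------------------

def _revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def assign_carriers(
    config: SimConfig, pv_records: list[VariantRecord]
) -> dict[str, list[tuple[VariantRecord, int]]]:
    """Plant 4 distinct SNV PVs into 7 distinct samples (het/hom mix).

    Only samples listed in ``config.sample_dates_bp`` can carry; archaic
    samples are eligible (the real data has Neanderthal carriers).
    """
    rng = config._rng(5)
    snv_pvs = [r for r in pv_records if r.is_snv]
    if len(snv_pvs) < 4:
        raise ValueError("need at least 4 SNV pathogenic variants to plant")
    chosen = [snv_pvs[i] for i in rng.choice(len(snv_pvs), size=4, replace=False)]
    sample_ids = [row[0] for row in config.sample_dates_bp]
    if len(sample_ids) < 7:
        raise ValueError("need at least 7 samples to plant 7 carriers")
    carrier_ids = [sample_ids[i] for i in rng.choice(len(sample_ids), size=7, replace=False)]
    out: dict[str, list] = {}
    for k, sid in enumerate(carrier_ids):
        rec = chosen[k % len(chosen)]
        genotype = 2 if rng.random() < 0.3 else 1
        out.setdefault(sid, []).append((rec, genotype))
    return out


def simulate_ancient_reads(
    config: SimConfig,
    reference: str,
    carriers: dict[str, list[tuple[VariantRecord, int]]],
    sample_ids: list[str] | None = None,
) -> tuple[dict[str, str], TruthSet]:
    """Damaged reads per sample as SAM text, plus the artifact truth set.

    Reads are uniform over the reference at fixed length; per read, each
    molecule-5′ C at offset ``i`` flips to T with probability
    ``d0·exp(−λ·i)`` and symmetrically G→A from the 3′ end.  Carrier
    variant alleles appear at heterozygous (p=0.5 per read) or homozygous
    dosage.  Base qualities are constant Phred 37 — artifacts keep the
    same emitted quality; distinguishing them is the rescaler's job.
    """
    rng = config._rng(6)
    L = len(reference)
    rl = config.read_length
    if rl > L:
        raise ValueError("read_length exceeds reference length")
    for variants in carriers.values():
        for rec, _ in variants:
            if not rec.is_snv:
                raise ValueError(f"carrier variant {rec.name} is not a SNV")
            if not 1 <= rec.pos <= L:
                raise ValueError(f"carrier variant {rec.name} outside reference")
    if sample_ids is None:
        sample_ids = [row[0] for row in config.sample_dates_bp]
    n_reads = int(round(config.coverage * L / rl))
    d0, lam = config.damage_d0, config.damage_lambda
    header = (
        "@HD\tVN:1.6\tSO:coordinate\n"
        f"@SQ\tSN:{CHROM}\tLN:{L}\n"
    )
    truth = TruthSet()
    sams: dict[str, str] = {}
    for sid in sample_ids:
        sample_variants = carriers.get(sid, [])
        artifacts = []
        reads = []
        for j in range(n_reads):
            start0 = int(rng.integers(0, L - rl + 1))
            reverse = bool(rng.random() < 0.5)
            frag = list(reference[start0 : start0 + rl])
            for rec, genotype in sample_variants:
                p0 = rec.pos - 1
                if start0 <= p0 < start0 + rl:
                    if genotype == 2 or rng.random() < 0.5:
                        frag[p0 - start0] = rec.alt
            molecule = list(_revcomp("".join(frag))) if reverse else frag
            rid = f"{sid}_r{j:06d}"
            for i in range(rl):
                if molecule[i] == "C" and rng.random() < d0 * math.exp(-lam * i):
                    molecule[i] = "T"
                    artifacts.append([rid, i, "C>T"])
            for o3 in range(rl):
                i = rl - 1 - o3
                if molecule[i] == "G" and rng.random() < d0 * math.exp(-lam * o3):
                    molecule[i] = "A"
                    artifacts.append([rid, o3, "G>A"])
            seq = _revcomp("".join(molecule)) if reverse else "".join(molecule)
            flag = 16 if reverse else 0
            reads.append(
                (start0 + 1, f"{rid}\t{flag}\t{CHROM}\t{start0 + 1}\t60\t{rl}M\t*\t0\t0\t{seq}\t{'F' * rl}")
            )
        reads.sort(key=lambda t: t[0])
        sams[sid] = header + "\n".join(r[1] for r in reads) + "\n"
        truth.damage_artifacts[sid] = artifacts
        truth.carriers[sid] = sorted(
            {rec.variant_id for rec, _ in sample_variants}
        )
    return sams, truth


# ---------------------------------------------------------------------------
# Orchestrator
# ---------------------------------------------------------------------------

@dataclass
class SimulationResult:
    """Everything one simulated study produced, in memory and on disk."""

    config: SimConfig
    reference: str
    newick: str
    clade_map: dict
    transcripts: list
    catalog: pd.DataFrame
    founder_ids: list
    records: list
    blocks: list
    truth: TruthSet
    sam_texts: dict
    metadata: pd.DataFrame


def simulate_all(config: SimConfig, outdir=None) -> SimulationResult:
    """Run every generator and (optionally) write the full input bundle.

    Files written: reference.fa, tree.nwk, clades.tsv, transcripts.json,
    catalog.tsv, founders.txt, alignment.maf, metadata.tsv, truth.json and
    samples/<id>.sam.
    """
    reference = make_reference(config)
    newick, clade_map = make_phylogeny(config)
    transcripts = make_transcript_models(config)
    catalog, founder_ids = simulate_catalog(config, transcripts, reference)
    records = parse_catalog(catalog, founder_ids=set(founder_ids))
    sharing, missing = plant_sharing(config, records)
    blocks, grid = simulate_alignment(config, reference, records, sharing, missing)
    carriers = assign_carriers(config, [r for r in records if r.clin_class == "PV"])
    sams, truth = simulate_ancient_reads(config, reference, carriers)
    truth.planted_sharing = {k: sorted(v) for k, v in sharing.items()}
    truth.sharing_grid = grid
    truth.planted_variants = [
        [
            rec.variant_id,
            rec.pos,
            rec.ref,
            rec.alt,
            sorted(sid for sid, vs in carriers.items() if any(r.variant_id == rec.variant_id for r, _ in vs)),
        ]
        for rec in records
    ]
    metadata = pd.DataFrame(
        config.sample_dates_bp,
        columns=["sample_id", "date_lo", "date_hi", "lat", "lon", "region", "group"],
    )
    result = SimulationResult(
        config=config,
        reference=reference,
        newick=newick,
        clade_map=clade_map,
        transcripts=transcripts,
        catalog=catalog,
        founder_ids=founder_ids,
        records=records,
        blocks=blocks,
        truth=truth,
        sam_texts=sams,
        metadata=metadata,
    )
    if outdir is not None:
        outdir = Path(outdir)
        (outdir / "samples").mkdir(parents=True, exist_ok=True)
        (outdir / "reference.fa").write_text(
            f">{CHROM}\n" + "\n".join(
                reference[i : i + 70] for i in range(0, len(reference), 70)
            ) + "\n"
        )
        (outdir / "tree.nwk").write_text(newick + "\n")
        (outdir / "clades.tsv").write_text(
            "species\tclade\n"
            + "".join(f"{s}\t{c}\n" for s, c in clade_map.items())
        )
        write_transcripts(transcripts, outdir / "transcripts.json")
        catalog.to_csv(outdir / "catalog.tsv", sep="\t", index=False)
        (outdir / "founders.txt").write_text("".join(f"{f}\n" for f in founder_ids))
        write_maf(blocks, outdir / "alignment.maf")
        metadata.to_csv(outdir / "metadata.tsv", sep="\t", index=False)
        for sid, text in sams.items():
            (outdir / "samples" / f"{sid}.sam").write_text(text)
        (outdir / "truth.json").write_text(
            json.dumps(truth.to_dict(), indent=2, sort_keys=True) + "\n"
        )
    return result
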