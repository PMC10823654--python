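"""Shared fixtures: toy transcript models and one full synthetic study.

The expensive pieces (the default simulated study and the per-sample
ancient-calling pipeline over it) are session-scoped so the whole suite
pays for them once.
"""

from __future__ import annotations

import pytest

from paleovar import ancient_dna as ad
from paleovar.synthetic_data import SimConfig, simulate_all
from paleovar.variant_catalog import TranscriptModel


def make_toy_reference() -> str:
    """500 bp deterministic reference with pinned bases for the toy models."""
    ref = list("ACGT" * 125)
    ref[150] = "A"  # plus-strand c.1
    ref[201] = "T"  # plus-strand c.50+2
    ref[370] = "G"  # minus-strand c.10 (transcript C)
    return "".join(ref)


@pytest.fixture(scope="session")
def toy_reference() -> str:
    return make_toy_reference()


@pytest.fixture(scope="session")
def plus_model() -> TranscriptModel:
    # exon1 g.101-200 (CDS from g.151 = c.1), exon2 g.301-400 (CDS to g.380)
    return TranscriptModel(
        gene="TOYP",
        chrom="toy",
        strand="+",
        exons=((101, 200), (301, 400)),
        cds_start=151,
        cds_end=379,  # CDS length 129, a codon multiple
    )


@pytest.fixture(scope="session")
def minus_model() -> TranscriptModel:
    # transcript runs g.380 -> g.121; c.10 sits at g.371
    return TranscriptModel(
        gene="TOYM",
        chrom="toy",
        strand="-",
        exons=((101, 200), (301, 400)),
        cds_start=380,
        cds_end=122,  # CDS length 159, a codon multiple
    )


@pytest.fixture(scope="session")
def sim(tmp_path_factory):
    """Default synthetic study (seed 1), written to a session directory."""
    outdir = tmp_path_factory.mktemp("sim")
    config = SimConfig(seed=1)
    result = simulate_all(config, outdir)
    result.outdir = outdir
    return result


@pytest.fixture(scope="session")
def ancient_results(sim):
    """Full damage-aware calling pipeline over every simulated sample.

    Returns ``{sample_id: (calls, matches)}`` with calls already
    damage-filtered and matches keyed PV/BV/VUS.
    """
    out = {}
    for sid in sim.truth.carriers:
        reads = ad.read_sam(sim.outdir / "samples" / f"{sid}.sam")
        profile = ad.estimate_damage_profile(reads, sim.reference)
        reads = [ad.rescale_qualities(r, profile, sim.reference) for r in reads]
        calls = [
            ad.damage_filter(c)
            for c in ad.pileup_call(reads, sim.reference)
        ]
        matches = ad.match_catalog(calls, sim.records)
        out[sid] = (calls, matches)
    return out
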