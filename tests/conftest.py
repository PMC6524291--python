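"""Shared fixtures: a small labeled reference panel and derived genomes.

Everything is generated programmatically from fixed seeds; session scope
keeps the alignment indexes warm across test modules.
"""

from __future__ import annotations

import numpy as np
import pytest

from novitax.panel import panel_from_records
from novitax.seqcore import SequenceRecord
from novitax.simulate import mutate_genome, simulate_genome

PANEL_SPECS = [
    ("bifA", "Bifidobacterium", "adolescentis", 0.56, 101),
    ("bifB", "Bifidobacterium", "breve", 0.54, 102),
    ("lacA", "Lactobacillus", "gasseri", 0.43, 103),
    ("strA", "Streptococcus", "salivarius", 0.46, 104),
]

PANEL_GENOME_LEN = 100_000


@pytest.fixture(scope="session")
def panel_genomes() -> dict[str, SequenceRecord]:
    out = {}
    for gid, _, _, gc, seed in PANEL_SPECS:
        g, _ = simulate_genome(PANEL_GENOME_LEN, gc=gc, seed=seed, genome_id=gid)
        out[gid] = g
    return out


@pytest.fixture(scope="session")
def panel_truths() -> dict:
    out = {}
    for gid, _, _, gc, seed in PANEL_SPECS:
        _, t = simulate_genome(PANEL_GENOME_LEN, gc=gc, seed=seed, genome_id=gid)
        out[gid] = t
    return out


@pytest.fixture(scope="session")
def panel(panel_genomes):
    taxonomy = {gid: (genus, sp, f"T{gid}") for gid, genus, sp, _, _ in PANEL_SPECS}
    return panel_from_records(panel_genomes, taxonomy)


@pytest.fixture(scope="session")
def novel_genome(panel_genomes) -> SequenceRecord:
    """A 'novel species' genome at 12% nucleotide divergence from bifA."""
    g, _ = mutate_genome(panel_genomes["bifA"], 0.12, seed=777, new_id="novelX")
    return g


@pytest.fixture(scope="session")
def near_known_genome(panel_genomes) -> SequenceRecord:
    """A conspecific strain at 2% divergence from bifA."""
    g, _ = mutate_genome(panel_genomes["bifA"], 0.02, seed=778, new_id="strain2pc")
    return g


@pytest.fixture(scope="session")
def its_references() -> dict[str, SequenceRecord]:
    rng = np.random.default_rng(555)
    refs = {}
    for i, sp in enumerate(
        ["Bifidobacterium adolescentis", "Bifidobacterium breve",
         "Bifidobacterium longum", "Bifidobacterium bifidum"]
    ):
        seq = "".join(rng.choice(list("ACGT"), 500))
        refs[sp] = SequenceRecord(f"its{i}", seq, description=f"species={sp}")
    return refs
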