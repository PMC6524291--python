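"""Genus-level classification of contigs/reads and abundance profiling.

A contig is classified by its proteome: each called gene's best panel hit
votes for the hit genome's genus, weighted by alignment score; the genus
with the highest summed score wins.  Short records (< 300 nt) — and
contigs on which no gene could be called — fall back to direct nucleotide
mapping against the panel genomes, since ORF calling is unreliable there.
Abundance profiles are base-pair weighted: the fraction of assembled bp
assigned to each genus.
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass, field
from typing import Sequence

from . import seqcore
from .mapping import GenomeIndex
from .panel import ReferencePanel, best_hits
from .seqcore import PROTEIN, SequenceRecord

UNCLASSIFIED = "unclassified"

NT_MODE_MAX_LEN = 300          # records shorter than this skip ORF voting
NT_MODE_MIN_IDENTITY = 80.0    # nucleotide fallback acceptance
NT_MODE_MIN_COV = 0.5


@dataclass(frozen=True)
class TaxonAssignment:
    seq_id: str
    genus: str
    support: float     # fraction of classified genes voting for the winner
    n_genes: int
    bp: int


class _PanelGenomeIndexes:
    """Lazily built nucleotide indexes of the panel genomes (concatenated
    per genome), cached on the panel object."""

    def __init__(self, panel: ReferencePanel):
        self.indexes: dict[str, GenomeIndex] = {}
        for gid, recs in sorted(panel.genomes.items()):
            self.indexes[gid] = GenomeIndex("N".join(r.seq for r in recs))


def _genome_indexes(panel: ReferencePanel) -> dict[str, GenomeIndex]:
    cache = getattr(panel, "_nt_indexes", None)
    if cache is None:
        cache = _PanelGenomeIndexes(panel)
        object.__setattr__(panel, "_nt_indexes", cache)
    return cache.indexes


def _classify_nucleotide(record: SequenceRecord, panel: ReferencePanel) -> TaxonAssignment:
    best_gid = None
    best_key = None
    for gid, idx in _genome_indexes(panel).items():
        hit = idx.map_fragment(record.seq)
        if hit is None or hit.identity < NT_MODE_MIN_IDENTITY or hit.coverage < NT_MODE_MIN_COV:
            continue
        key = (-hit.identity, gid)
        if best_key is None or key < best_key:
            best_key, best_gid = key, gid
    if best_gid is None:
        return TaxonAssignment(record.id, UNCLASSIFIED, 0.0, 0, len(record.seq))
    return TaxonAssignment(record.id, panel.genus(best_gid), 1.0, 0, len(record.seq))


def classify_contig(
    contig: SequenceRecord,
    panel: ReferencePanel,
    min_identity: float = 30.0,
    min_cov: float = 0.5,
    min_aa: int = 80,
    min_hit_fraction: float = 0.3,
) -> TaxonAssignment:
    """Genus assignment by score-weighted best-hit voting over the contig's
    proteome; nucleotide fallback for short or gene-free records.

    With the loose per-gene search thresholds, an isolated spurious hit
    would otherwise claim a whole contig, so a contig is only assigned when
    at least *min_hit_fraction* of its genes found any panel hit; genuinely
    related contigs place nearly all their genes.
    """
    if contig.kind != "nucleotide":
        raise TypeError("classify_contig expects a nucleotide record")
    if len(contig.seq) < NT_MODE_MAX_LEN:
        return _classify_nucleotide(contig, panel)
    genes = seqcore.contig_proteome(contig, min_aa=min_aa)
    if not genes:
        return _classify_nucleotide(contig, panel)
    queries = [SequenceRecord(gid, prot, kind=PROTEIN) for gid, prot in genes]
    hits = best_hits(queries, panel, min_identity=min_identity, min_cov=min_cov)
    if not hits or len(hits) < min_hit_fraction * len(genes):
        return TaxonAssignment(contig.id, UNCLASSIFIED, 0.0, len(genes), len(contig.seq))
    score_by_genus: dict[str, float] = defaultdict(float)
    votes_by_genus: dict[str, int] = defaultdict(int)
    for h in hits:
        genus = panel.genus(h.genome_id)
        score_by_genus[genus] += h.score
        votes_by_genus[genus] += 1
    winner = min(score_by_genus, key=lambda g: (-score_by_genus[g], g))
    support = votes_by_genus[winner] / len(hits)
    return TaxonAssignment(contig.id, winner, support, len(genes), len(contig.seq))


def classify_sample(
    records: Sequence[SequenceRecord], panel: ReferencePanel, **kw
) -> list[TaxonAssignment]:
    return [classify_contig(r, panel, **kw) for r in records]


@dataclass
class AbundanceProfile:
    fractions: dict[str, float]      # every genus incl. "unclassified", exact
    total_bp: int
    min_fraction_reported: float

    def rendered(self) -> dict[str, float]:
        """Report view: genera below the reporting floor folded into 'other'."""
        shown: dict[str, float] = {}
        other = 0.0
        for genus, f in sorted(self.fractions.items(), key=lambda kv: (-kv[1], kv[0])):
            if f >= self.min_fraction_reported or genus == UNCLASSIFIED:
                shown[genus] = f
            else:
                other += f
        if other > 0:
            shown["other"] = other
        return shown

    def fraction(self, genus: str) -> float:
        return self.fractions.get(genus, 0.0)

    def detected(self, genus: str) -> bool:
        return self.fractions.get(genus, 0.0) > 0.0


def abundance_profile(
    assignments: Sequence[TaxonAssignment], min_fraction: float = 0.002
) -> AbundanceProfile:
    """bp-weighted genus fractions; the machine-readable profile keeps every
    genus exactly, the rendered view applies the reporting floor."""
    if not assignments:
        raise ValueError("no assignments to profile")
    bp_by_genus: dict[str, int] = defaultdict(int)
    for a in assignments:
        bp_by_genus[a.genus] += a.bp
    total = sum(bp_by_genus.values())
    fractions = {g: bp / total for g, bp in sorted(bp_by_genus.items())}
    return AbundanceProfile(fractions=fractions, total_bp=total, min_fraction_reported=min_fraction)


def profiles_to_wide_tsv(profiles: dict[str, AbundanceProfile], path) -> None:
    """Heatmap-ready genus x sample table of abundance fractions."""
    genera = sorted({g for p in profiles.values() for g in p.fractions})
    samples = sorted(profiles)
    with open(path, "w") as fh:
        fh.write("genus\t" + "\t".join(samples) + "\n")
        for g in genera:
            fh.write(g + "\t" + "\t".join(f"{profiles[s].fraction(g):.6f}" for s in samples) + "\n")


def assignments_to_tsv(assignments: Sequence[TaxonAssignment], path) -> None:
    with open(path, "w") as fh:
        fh.write("seq_id\tgenus\tsupport\tn_genes\tbp\n")
        for a in assignments:
            fh.write(f"{a.seq_id}\t{a.genus}\t{a.support:.4f}\t{a.n_genes}\t{a.bp}\n")
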