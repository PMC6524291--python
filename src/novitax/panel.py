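"""Labeled reference databases: genomes + taxonomy, proteomes, ITS
references, a glycosyl-hydrolase reference set and mobile-element markers.

The panel is what every screening stage compares against.  Proteomes are
auto-predicted (six-frame ORF calling with nested-ORF cleanup) for genomes
that do not ship one.  Protein search uses an exact 5-mer prefilter before
affine-gap alignment so that all-vs-all comparisons stay feasible on a
single CPU.

The packaged GH and mobile-marker FASTAs are synthetic placeholder
exemplars (generated sequences carrying the family/subfamily labels the
pipeline needs); production use substitutes curated databases via
``build_panel`` arguments or the CLI config.
"""

from __future__ import annotations

import json
import logging
from collections import defaultdict
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

from . import seqcore
from .seqcore import PROTEIN, SequenceRecord, align

logger = logging.getLogger(__name__)

PREFILTER_K = 5
PREFILTER_MIN_SHARED = 2


def packaged_gh_reference() -> list[SequenceRecord]:
    with resources.as_file(resources.files("novitax.data") / "gh_reference.synthetic.faa") as p:
        return seqcore.read_fasta(p, kind=PROTEIN)


def packaged_mobile_markers() -> list[SequenceRecord]:
    with resources.as_file(resources.files("novitax.data") / "mobile_markers.synthetic.faa") as p:
        return seqcore.read_fasta(p, kind=PROTEIN)


def _attr(description: str, key: str) -> str:
    for tok in description.split():
        if tok.startswith(key + "="):
            return tok.split("=", 1)[1]
    return ""


@dataclass(frozen=True)
class ProteinHit:
    query_id: str
    genome_id: str
    subject_id: str
    identity: float
    coverage: float
    score: float


class ProteinIndex:
    """Exact amino-acid k-mer prefilter over a protein collection.

    A query is aligned only against subjects sharing at least
    ``PREFILTER_MIN_SHARED`` distinct 5-mers — loose enough that any pair
    with >= 70% identity over >= 100 residues is retained (property-tested
    against exhaustive alignment).
    """

    def __init__(self, records: Sequence[SequenceRecord], k: int = PREFILTER_K):
        self.records = list(records)
        self.k = k
        self._by_kmer: dict[str, list[int]] = defaultdict(list)
        for i, rec in enumerate(self.records):
            for km in set(rec.seq[j : j + k] for j in range(len(rec.seq) - k + 1)):
                self._by_kmer[km].append(i)

    def candidates(self, query: str, min_shared: int = PREFILTER_MIN_SHARED) -> list[int]:
        counts: dict[int, int] = defaultdict(int)
        for km in set(query[j : j + self.k] for j in range(len(query) - self.k + 1)):
            for i in self._by_kmer.get(km, ()):
                counts[i] += 1
        return [i for i, c in counts.items() if c >= min_shared]

    def best_hit(
        self, query: SequenceRecord, min_identity: float, min_cov: float,
        tie_key=None,
    ) -> tuple[SequenceRecord, "seqcore.PairwiseAlignment"] | None:
        """Highest-scoring subject passing both thresholds.

        Ties on score break by higher identity, then by *tie_key* of the
        subject record (default: subject id) — deterministic across runs.
        """
        best = None
        best_rank = None
        for i in self.candidates(query.seq):
            subj = self.records[i]
            aln = align(query, subj, mode="local")
            if aln.identity < min_identity or aln.query_coverage < min_cov:
                continue
            key = tie_key(subj) if tie_key else subj.id
            rank = (-aln.score, -aln.identity, key)
            if best_rank is None or rank < best_rank:
                best_rank = rank
                best = (subj, aln)
        return best


@dataclass
class ReferencePanel:
    genomes: dict[str, list[SequenceRecord]]
    taxonomy: dict[str, tuple[str, str, str]]   # genome_id -> (genus, species, strain)
    proteins: dict[str, list[SequenceRecord]]
    its: dict[str, SequenceRecord] = field(default_factory=dict)
    gh_reference: list[SequenceRecord] = field(default_factory=list)
    mobile_markers: list[SequenceRecord] = field(default_factory=list)
    _protein_index: ProteinIndex | None = None
    _genome_of_protein: dict[str, str] | None = None

    def genus(self, genome_id: str) -> str:
        return self.taxonomy[genome_id][0]

    def species(self, genome_id: str) -> str:
        g, s, _ = self.taxonomy[genome_id]
        return f"{g} {s}"

    @property
    def protein_index(self) -> ProteinIndex:
        if self._protein_index is None:
            recs = []
            self._genome_of_protein = {}
            for gid, prots in sorted(self.proteins.items()):
                for p in prots:
                    recs.append(p)
                    self._genome_of_protein[p.id] = gid
            self._protein_index = ProteinIndex(recs)
        return self._protein_index

    def genome_of_protein(self, protein_id: str) -> str:
        self.protein_index  # ensure built
        return self._genome_of_protein[protein_id]

    def summary(self) -> dict:
        return {
            "n_genomes": len(self.genomes),
            "genera": sorted({t[0] for t in self.taxonomy.values()}),
            "n_proteins": {g: len(p) for g, p in sorted(self.proteins.items())},
            "n_its": len(self.its),
            "n_gh_reference": len(self.gh_reference),
            "n_mobile_markers": len(self.mobile_markers),
        }


def predict_proteome(genome_records: Sequence[SequenceRecord], genome_id: str,
                     min_aa: int = 80) -> list[SequenceRecord]:
    out = []
    for rec in genome_records:
        for gene_id, prot in seqcore.contig_proteome(rec, min_aa=min_aa):
            out.append(SequenceRecord(id=f"{genome_id}|{gene_id}", seq=prot, kind=PROTEIN))
    return out


def build_panel(
    genome_fastas: dict[str, str | Path] | Sequence[str | Path],
    metadata: str | Path | pd.DataFrame,
    its_fasta: str | Path | None = None,
    gh_fasta: str | Path | None = None,
    mobile_fasta: str | Path | None = None,
    proteomes: dict[str, Sequence[SequenceRecord]] | None = None,
    min_aa: int = 80,
) -> ReferencePanel:
    """Assemble a reference panel from FASTA files plus a taxonomy TSV.

    *metadata* needs columns genome_id, genus, species, strain.  When
    *genome_fastas* is a plain sequence of paths the file stem is the
    genome_id.  Genomes without a supplied proteome get one predicted on
    the fly.  GH and mobile references default to the packaged synthetic
    exemplar sets.
    """
    if isinstance(metadata, pd.DataFrame):
        meta = metadata.copy()
    else:
        meta = pd.read_csv(metadata, sep="\t", dtype=str).fillna("")
    required = {"genome_id", "genus", "species", "strain"}
    if not required.issubset(meta.columns):
        raise ValueError(f"metadata must have columns {sorted(required)}")
    if meta["genome_id"].duplicated().any():
        dups = meta.loc[meta["genome_id"].duplicated(), "genome_id"].tolist()
        raise ValueError(f"duplicate genome_id in metadata: {dups}")
    if (meta["genus"].str.len() == 0).any():
        raise ValueError("every taxonomy row must name a non-empty genus")

    if not isinstance(genome_fastas, dict):
        genome_fastas = {Path(p).stem: p for p in genome_fastas}
    taxonomy = {
        row.genome_id: (row.genus, row.species, row.strain)
        for row in meta.itertuples()
    }
    orphans = sorted(set(genome_fastas) - set(taxonomy))
    if orphans:
        raise ValueError(f"genomes absent from metadata: {orphans}")
    missing = sorted(set(taxonomy) - set(genome_fastas))
    if missing:
        raise ValueError(f"metadata rows without a genome FASTA: {missing}")

    genomes = {gid: seqcore.read_fasta(path) for gid, path in genome_fastas.items()}
    prots: dict[str, list[SequenceRecord]] = {}
    for gid, recs in sorted(genomes.items()):
        if proteomes and gid in proteomes:
            prots[gid] = list(proteomes[gid])
        else:
            prots[gid] = predict_proteome(recs, gid, min_aa=min_aa)

    its = {}
    if its_fasta:
        for rec in seqcore.read_fasta(its_fasta):
            species = _attr(rec.description, "species") or rec.id
            its[species] = rec
    gh = seqcore.read_fasta(gh_fasta, kind=PROTEIN) if gh_fasta else packaged_gh_reference()
    mobile = (
        seqcore.read_fasta(mobile_fasta, kind=PROTEIN) if mobile_fasta else packaged_mobile_markers()
    )
    panel = ReferencePanel(
        genomes=genomes, taxonomy=taxonomy, proteins=prots,
        its=its, gh_reference=gh, mobile_markers=mobile,
    )
    logger.info("panel built: %s", panel.summary())
    return panel


def panel_from_records(
    genomes: dict[str, SequenceRecord | list[SequenceRecord]],
    taxonomy: dict[str, tuple[str, str, str]],
    **kw,
) -> ReferencePanel:
    """In-memory panel constructor (the fixture-friendly path)."""
    gdict = {
        gid: (recs if isinstance(recs, list) else [recs]) for gid, recs in genomes.items()
    }
    orphans = sorted(set(gdict) - set(taxonomy))
    if orphans:
        raise ValueError(f"genomes absent from metadata: {orphans}")
    prots = kw.pop("proteomes", None) or {}
    built = {}
    for gid, recs in sorted(gdict.items()):
        built[gid] = list(prots[gid]) if gid in prots else predict_proteome(recs, gid)
    return ReferencePanel(
        genomes=gdict, taxonomy=dict(taxonomy), proteins=built,
        its=kw.pop("its", {}),
        gh_reference=kw.pop("gh_reference", None) or packaged_gh_reference(),
        mobile_markers=kw.pop("mobile_markers", None) or packaged_mobile_markers(),
    )


def best_hits(
    query_proteins: Sequence[SequenceRecord],
    panel: ReferencePanel,
    min_identity: float = 30.0,
    min_cov: float = 0.5,
) -> list[ProteinHit]:
    """Best panel protein per query passing both thresholds.

    Ties break by (higher identity, lexicographically smallest genome id).
    """
    idx = panel.protein_index
    hits = []
    for q in query_proteins:
        got = idx.best_hit(
            q, min_identity, min_cov,
            tie_key=lambda s: (panel.genome_of_protein(s.id), s.id),
        )
        if got is None:
            continue
        subj, aln = got
        hits.append(
            ProteinHit(
                query_id=q.id,
                genome_id=panel.genome_of_protein(subj.id),
                subject_id=subj.id,
                identity=aln.identity,
                coverage=aln.query_coverage,
                score=aln.score,
            )
        )
    return hits


def save_panel(panel: ReferencePanel, outdir: str | Path) -> None:
    """Persist as a directory of FASTA/TSV plus a JSON manifest."""
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = {"genomes": {}, "taxonomy": {}, "files": {}}
    for gid, recs in sorted(panel.genomes.items()):
        f = f"genome_{gid}.fasta"
        seqcore.write_fasta(recs, out / f)
        manifest["genomes"][gid] = f
        g, s, st = panel.taxonomy[gid]
        manifest["taxonomy"][gid] = {"genus": g, "species": s, "strain": st}
        pf = f"proteins_{gid}.faa"
        seqcore.write_fasta(panel.proteins[gid], out / pf)
    if panel.its:
        seqcore.write_fasta(
            [SequenceRecord(r.id, r.seq, f"species={sp}") for sp, r in sorted(panel.its.items())],
            out / "its.fasta",
        )
        manifest["files"]["its"] = "its.fasta"
    seqcore.write_fasta(panel.gh_reference, out / "gh_reference.faa")
    seqcore.write_fasta(panel.mobile_markers, out / "mobile_markers.faa")
    manifest["files"]["gh_reference"] = "gh_reference.faa"
    manifest["files"]["mobile_markers"] = "mobile_markers.faa"
    (out / "manifest.json").write_text(json.dumps(manifest, indent=1, sort_keys=True))


def load_panel(indir: str | Path) -> ReferencePanel:
    ind = Path(indir)
    manifest = json.loads((ind / "manifest.json").read_text())
    genomes = {}
    proteins = {}
    taxonomy = {}
    for gid, f in manifest["genomes"].items():
        genomes[gid] = seqcore.read_fasta(ind / f)
        proteins[gid] = seqcore.read_fasta(ind / f"proteins_{gid}.faa", kind=PROTEIN)
        t = manifest["taxonomy"][gid]
        taxonomy[gid] = (t["genus"], t["species"], t["strain"])
    its = {}
    if "its" in manifest["files"]:
        for rec in seqcore.read_fasta(ind / manifest["files"]["its"]):
            its[_attr(rec.description, "species") or rec.id] = rec
    gh = seqcore.read_fasta(ind / manifest["files"]["gh_reference"], kind=PROTEIN)
    mobile = seqcore.read_fasta(ind / manifest["files"]["mobile_markers"], kind=PROTEIN)
    return ReferencePanel(genomes, taxonomy, proteins, its, gh, mobile)
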