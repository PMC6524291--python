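"""Dark-matter extraction: decide per contig whether it belongs to a known
species, is a mobile element (phage/plasmid), or is a putative novel taxon.

A genus-assigned contig longer than the length floor is screened in three
ways against every panel genome:

1. nucleotide level — the contig is cut into ~1 kb fragments and each is
   seed-mapped to the genome; a genome "claims" the contig when fragments
   at identity >= ``nt_known_identity`` cover >= ``nt_known_cov`` of it;
2. protein level — mean identity of the contig's gene best-hits restricted
   to one genome, requiring hits for at least half of the genes;
3. chromosome level — collinear chains of mapped fragments (a lightweight
   whole-genome alignment) covering >= ``wga_known_cov`` of the contig at
   known-species identity.

Any passing genome makes the contig ``known_species``.  Before that, a
mobile-element test flags contigs most of whose genes look more like
phage/plasmid markers than like any panel protein — the automated
surrogate for manual phage/plasmid removal, with a review band for
borderline cases.  Everything else is a ``novel_candidate``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

from . import seqcore
from .binning import _genome_indexes
from .panel import ProteinIndex, ReferencePanel
from .seqcore import PROTEIN, SequenceRecord

KNOWN = "known_species"
NOVEL = "novel_candidate"
MOBILE = "mobile_element"
TOO_SHORT = "too_short"

FRAGMENT_LEN = 1000
MIN_TAIL_FRAGMENT = 300


@dataclass(frozen=True)
class ScreenThresholds:
    min_len: int = 5000                 # strict: contigs must be > min_len
    nt_known_identity: float = 95.0     # aligned with the ANI species boundary
    nt_known_cov: float = 0.75
    prot_known_identity: float = 96.0
    wga_known_cov: float = 0.75
    mobile_gene_fraction: float = 0.5
    mobile_review_fraction: float = 0.3
    prot_min_identity: float = 30.0     # search floor for gene best-hits
    prot_min_cov: float = 0.5

    def __post_init__(self):
        for name in ("nt_known_identity", "prot_known_identity"):
            v = getattr(self, name)
            if not (0 < v <= 100):
                raise ValueError(f"{name} must lie in (0, 100]")
        for name in ("nt_known_cov", "wga_known_cov", "mobile_gene_fraction"):
            v = getattr(self, name)
            if not (0 < v <= 1):
                raise ValueError(f"{name} must lie in (0, 1]")

    def as_dict(self) -> dict:
        return {k: getattr(self, k) for k in self.__dataclass_fields__}


@dataclass
class ContigVerdict:
    contig_id: str
    status: str
    bp: int
    matched_species: str | None = None
    evidence: dict = field(default_factory=dict)


def _fragments(seq: str) -> list[tuple[int, str]]:
    frags = []
    for i in range(0, len(seq), FRAGMENT_LEN):
        piece = seq[i : i + FRAGMENT_LEN]
        if len(piece) >= MIN_TAIL_FRAGMENT:
            frags.append((i, piece))
    return frags


def _nt_evidence(contig: SequenceRecord, panel: ReferencePanel, thresholds: ScreenThresholds):
    """Per-genome fragment-mapping summary.

    Returns dict genome_id -> (covered_frac_at_known_identity,
    mean_identity_of_mapped, chain_cov, chain_identity, any_hit).
    """
    frags = _fragments(contig.seq)
    L = len(contig.seq)
    out = {}
    for gid, idx in _genome_indexes(panel).items():
        mapped = []   # (query offset, fragment length, identity, subject start)
        for off, piece in frags:
            hit = idx.map_fragment(piece)
            if hit is None:
                continue
            mapped.append((off, len(piece), hit.identity, hit.subject_start))
        if not mapped:
            continue
        known_bp = sum(l for _, l, ident, _ in mapped if ident >= thresholds.nt_known_identity)
        mean_ident = sum(ident * l for _, l, ident, _ in mapped) / sum(l for _, l, _, _ in mapped)
        # collinear chain: longest run of fragments whose subject positions
        # increase with query offset (either orientation), the poor man's
        # whole-genome alignment
        chain = _longest_collinear(mapped)
        chain_bp = sum(l for _, l, ident, _ in chain if ident >= thresholds.nt_known_identity)
        out[gid] = {
            "known_cov": known_bp / L,
            "mean_identity": mean_ident,
            "chain_cov": chain_bp / L,
            "n_mapped": len(mapped),
        }
    return out


def _longest_collinear(mapped: list[tuple[int, int, float, int]]):
    """Longest subject-monotone subsequence of mapped fragments (checked in
    both orientations); fragments are already query-sorted."""
    if not mapped:
        return []
    best: list = []
    for sign in (1, -1):
        seq = [(off, l, ident, sign * spos) for off, l, ident, spos in mapped]
        # longest increasing subsequence on subject position, O(n^2) n<=contig/1kb
        n = len(seq)
        lis = [1] * n
        prev = [-1] * n
        for i in range(n):
            for j in range(i):
                if seq[j][3] <= seq[i][3] and lis[j] + 1 > lis[i]:
                    lis[i] = lis[j] + 1
                    prev[i] = j
        i = max(range(n), key=lambda x: lis[x])
        chain = []
        while i != -1:
            chain.append(mapped[i])
            i = prev[i]
        chain.reverse()
        if len(chain) > len(best):
            best = chain
    return best


def _mobile_fraction(
    gene_records: Sequence[SequenceRecord],
    panel: ReferencePanel,
    thresholds: ScreenThresholds,
) -> tuple[float, int]:
    """Fraction of genes whose best mobile-marker hit outscores their best
    panel-protein hit."""
    if not gene_records:
        return 0.0, 0
    cache = getattr(panel, "_mobile_index", None)
    if cache is None:
        cache = ProteinIndex(panel.mobile_markers)
        setattr(panel, "_mobile_index", cache)
    panel_idx = panel.protein_index
    mobile_votes = 0
    for q in gene_records:
        m = cache.best_hit(q, thresholds.prot_min_identity, thresholds.prot_min_cov)
        if m is None:
            continue
        p = panel_idx.best_hit(q, thresholds.prot_min_identity, thresholds.prot_min_cov)
        if p is None or m[1].score > p[1].score:
            mobile_votes += 1
    return mobile_votes / len(gene_records), mobile_votes


def _protein_evidence(
    gene_records: Sequence[SequenceRecord],
    panel: ReferencePanel,
    thresholds: ScreenThresholds,
) -> dict[str, dict]:
    """Per-genome mean best-hit identity over the contig's genes."""
    out: dict[str, list[float]] = {}
    idx = panel.protein_index
    for q in gene_records:
        got = idx.best_hit(
            q, thresholds.prot_min_identity, thresholds.prot_min_cov,
            tie_key=lambda s: (panel.genome_of_protein(s.id), s.id),
        )
        if got is None:
            continue
        gid = panel.genome_of_protein(got[0].id)
        out.setdefault(gid, []).append(got[1].identity)
    n = len(gene_records)
    return {
        gid: {
            "mean_identity": sum(ids) / len(ids),
            "gene_fraction": len(ids) / n if n else 0.0,
            "n_hits": len(ids),
        }
        for gid, ids in out.items()
    }


def screen_contig(
    contig: SequenceRecord,
    panel: ReferencePanel,
    thresholds: ScreenThresholds = ScreenThresholds(),
    min_aa: int = 80,
) -> ContigVerdict:
    """Classify one genus-assigned contig as known / mobile / novel."""
    L = len(contig.seq)
    if L <= thresholds.min_len:
        return ContigVerdict(contig.id, TOO_SHORT, L)

    genes = seqcore.contig_proteome(contig, min_aa=min_aa)
    gene_records = [SequenceRecord(gid, prot, kind=PROTEIN) for gid, prot in genes]

    mobile_frac, mobile_votes = _mobile_fraction(gene_records, panel, thresholds)
    evidence: dict = {
        "n_genes": len(genes),
        "mobile_gene_fraction": mobile_frac,
        "mobile_review": thresholds.mobile_review_fraction <= mobile_frac < thresholds.mobile_gene_fraction,
    }
    if mobile_frac >= thresholds.mobile_gene_fraction:
        return ContigVerdict(contig.id, MOBILE, L, evidence=evidence)

    nt_ev = _nt_evidence(contig, panel, thresholds)
    prot_ev = _protein_evidence(gene_records, panel, thresholds)

    best_nt = max(nt_ev.items(), key=lambda kv: kv[1]["known_cov"], default=(None, None))
    if best_nt[0] is not None:
        evidence["nt_best_genome"] = best_nt[0]
        evidence["nt_best"] = best_nt[1]
    best_prot = max(prot_ev.items(), key=lambda kv: kv[1]["mean_identity"], default=(None, None))
    if best_prot[0] is not None:
        evidence["prot_best_genome"] = best_prot[0]
        evidence["prot_best"] = best_prot[1]

    matched = None
    for gid in sorted(set(nt_ev) | set(prot_ev)):
        nt = nt_ev.get(gid)
        pr = prot_ev.get(gid)
        nt_pass = nt is not None and nt["known_cov"] >= thresholds.nt_known_cov
        wga_pass = nt is not None and nt["chain_cov"] >= thresholds.wga_known_cov
        prot_pass = (
            pr is not None
            and pr["mean_identity"] >= thresholds.prot_known_identity
            and pr["gene_fraction"] >= 0.5
        )
        if nt_pass or wga_pass or prot_pass:
            matched = gid
            evidence["known_tests"] = {
                "genome": gid, "nt": nt_pass, "wga": wga_pass, "protein": prot_pass,
            }
            break
    if matched is not None:
        return ContigVerdict(contig.id, KNOWN, L, matched_species=panel.species(matched), evidence=evidence)

    if not genes and not nt_ev:
        evidence["no_evidence"] = True
    return ContigVerdict(contig.id, NOVEL, L, evidence=evidence)


@dataclass
class ScreenReport:
    verdicts: list[ContigVerdict]
    thresholds: ScreenThresholds

    @property
    def counts(self) -> dict[str, int]:
        out = {s: 0 for s in (KNOWN, NOVEL, MOBILE, TOO_SHORT)}
        for v in self.verdicts:
            out[v.status] += 1
        return out

    @property
    def bp(self) -> dict[str, int]:
        out = {s: 0 for s in (KNOWN, NOVEL, MOBILE, TOO_SHORT)}
        for v in self.verdicts:
            out[v.status] += v.bp
        return out

    def to_dict(self) -> dict:
        return {
            "thresholds": self.thresholds.as_dict(),
            "counts": self.counts,
            "bp": self.bp,
            "verdicts": [
                {
                    "contig_id": v.contig_id, "status": v.status, "bp": v.bp,
                    "matched_species": v.matched_species,
                }
                for v in self.verdicts
            ],
        }


def screen_sample(
    contigs: Sequence[SequenceRecord],
    panel: ReferencePanel,
    thresholds: ScreenThresholds = ScreenThresholds(),
    novel_fasta: str | None = None,
) -> ScreenReport:
    """Screen every contig; optionally write the novel candidates to FASTA
    (the input to glycobiome profiling)."""
    verdicts = [screen_contig(c, panel, thresholds) for c in contigs]
    if novel_fasta:
        novel_ids = {v.contig_id for v in verdicts if v.status == NOVEL}
        seqcore.write_fasta([c for c in contigs if c.id in novel_ids], novel_fasta)
    return ScreenReport(verdicts=verdicts, thresholds=thresholds)


def verdicts_to_tsv(report: ScreenReport, path) -> None:
    with open(path, "w") as fh:
        fh.write("# thresholds: " + repr(report.thresholds.as_dict()) + "\n")
        fh.write("contig_id\tstatus\tbp\tmatched_species\tmobile_gene_fraction\n")
        for v in report.verdicts:
            fh.write(
                f"{v.contig_id}\t{v.status}\t{v.bp}\t{v.matched_species or '.'}\t"
                f"{v.evidence.get('mobile_gene_fraction', '')}\n"
            )
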