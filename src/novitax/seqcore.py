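"""Sequence records, translation, ORF calling, and pairwise alignment.

These are the primitives every downstream stage (binning, novelty
screening, ANI, ortholog clustering) is built on.  Conventions:

* nucleotide sequences are normalized to uppercase ``ACGTN`` (``U`` folded
  to ``T``); anything else is rejected at parse time;
* coordinates are 0-based half-open internally; GFF3 output converts to
  1-based inclusive;
* alignment identity is percent identical positions over aligned columns,
  where columns containing ``N`` are excluded from the denominator (an
  ambiguity code is neither a match nor a mismatch).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Sequence

from Bio import SeqIO
from Bio.Align import PairwiseAligner, substitution_matrices

NUCLEOTIDE = "nucleotide"
PROTEIN = "protein"

_NT_ALPHABET = set("ACGTN")

# NCBI translation table 11 (bacterial, archaeal and plant plastid code).
# Authored as an explicit lookup so the translator has no library
# dependency; the test suite cross-checks it against an independent engine.
_TABLE11 = {
    "TTT": "F", "TTC": "F", "TTA": "L", "TTG": "L",
    "CTT": "L", "CTC": "L", "CTA": "L", "CTG": "L",
    "ATT": "I", "ATC": "I", "ATA": "I", "ATG": "M",
    "GTT": "V", "GTC": "V", "GTA": "V", "GTG": "V",
    "TCT": "S", "TCC": "S", "TCA": "S", "TCG": "S",
    "CCT": "P", "CCC": "P", "CCA": "P", "CCG": "P",
    "ACT": "T", "ACC": "T", "ACA": "T", "ACG": "T",
    "GCT": "A", "GCC": "A", "GCA": "A", "GCG": "A",
    "TAT": "Y", "TAC": "Y", "TAA": "*", "TAG": "*",
    "CAT": "H", "CAC": "H", "CAA": "Q", "CAG": "Q",
    "AAT": "N", "AAC": "N", "AAA": "K", "AAG": "K",
    "GAT": "D", "GAC": "D", "GAA": "E", "GAG": "E",
    "TGT": "C", "TGC": "C", "TGA": "*", "TGG": "W",
    "CGT": "R", "CGC": "R", "CGA": "R", "CGG": "R",
    "AGT": "S", "AGC": "S", "AGA": "R", "AGG": "R",
    "GGT": "G", "GGC": "G", "GGA": "G", "GGG": "G",
}

_GENETIC_CODES = {11: _TABLE11, 1: _TABLE11}  # table 1 differs only in start-codon policy

START_CODONS = ("ATG", "GTG", "TTG")
STOP_CODONS = ("TAA", "TAG", "TGA")

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


class SequenceParseError(ValueError):
    """Raised when a sequence contains characters outside its alphabet."""


@dataclass
class SequenceRecord:
    """A named nucleotide or protein sequence."""

    id: str
    seq: str
    description: str = ""
    kind: str = NUCLEOTIDE

    def __post_init__(self) -> None:
        if not self.id:
            raise ValueError("sequence id must be non-empty")
        if self.kind == NUCLEOTIDE:
            self.seq = normalize_nucleotide(self.seq, where=self.id)

    def __len__(self) -> int:
        return len(self.seq)

    def reverse_complement(self) -> "SequenceRecord":
        if self.kind != NUCLEOTIDE:
            raise TypeError("reverse complement is defined for nucleotide records only")
        return SequenceRecord(
            id=self.id, seq=self.seq.translate(_COMPLEMENT)[::-1],
            description=self.description, kind=NUCLEOTIDE,
        )


@dataclass(frozen=True)
class GeneCall:
    """An ORF call on a contig: forward-strand half-open coordinates."""

    contig_id: str
    start: int
    end: int
    strand: str
    protein: str

    @property
    def gene_id(self) -> str:
        return f"{self.contig_id}|{self.start}-{self.end}({self.strand})"


@dataclass(frozen=True)
class PairwiseAlignment:
    query_id: str
    subject_id: str
    mode: str
    identity: float      # percent over aligned columns (N columns excluded)
    query_coverage: float
    score: float


def normalize_nucleotide(seq: str, where: str = "sequence") -> str:
    """Uppercase, fold U->T and validate the ACGTN alphabet."""
    s = seq.upper().replace("U", "T")
    for i, c in enumerate(s):
        if c not in _NT_ALPHABET:
            raise SequenceParseError(
                f"{where}: invalid nucleotide {c!r} at position {i + 1}"
            )
    return s


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def translate(dna: str, table: int = 11) -> str:
    """Translate codon by codon; stops rendered '*', trailing partial codon
    ignored, codons containing N rendered 'X'."""
    if len(dna) < 3:
        raise ValueError("need at least one full codon (3 nt)")
    code = _GENETIC_CODES.get(table)
    if code is None:
        raise ValueError(f"unsupported genetic code table {table}")
    s = normalize_nucleotide(dna)
    aa = []
    for i in range(0, len(s) - len(s) % 3, 3):
        codon = s[i : i + 3]
        aa.append("X" if "N" in codon else code[codon])
    return "".join(aa)


def _orfs_one_strand(seq: str, contig_id: str, min_aa: int, table: int) -> list[tuple[int, int, str]]:
    """Maximal stop-to-stop ORFs on the forward strand of *seq*.

    Returns (start, end, protein) in coordinates of *seq*; end includes the
    stop codon.  Within each stop-delimited segment the ORF starts at the
    first ATG/GTG/TTG.
    """
    out = []
    n = len(seq)
    for frame in range(3):
        seg_start_codon = None  # first start codon seen since the last stop
        i = frame
        while i + 3 <= n:
            codon = seq[i : i + 3]
            if codon in STOP_CODONS:
                if seg_start_codon is not None:
                    start, end = seg_start_codon, i + 3
                    aa_len = (end - start) // 3 - 1
                    if aa_len >= min_aa:
                        prot = translate(seq[start:end], table=table)[:-1]
                        out.append((start, end, prot))
                seg_start_codon = None
            elif seg_start_codon is None and codon in START_CODONS:
                seg_start_codon = i
            i += 3
    return out


def find_orfs(contig: SequenceRecord, min_aa: int = 80, table: int = 11) -> list[GeneCall]:
    """Six-frame stop-to-stop ORF calling with ATG/GTG/TTG starts.

    Coordinates always refer to the forward strand (half-open); only
    complete ORFs (with a terminal stop codon) are reported.  An empty
    sequence yields an empty list.
    """
    if contig.kind != NUCLEOTIDE:
        raise TypeError("find_orfs expects a nucleotide record")
    if min_aa < 30:
        raise ValueError("min_aa must be >= 30")
    seq = contig.seq
    calls: list[GeneCall] = []
    for start, end, prot in _orfs_one_strand(seq, contig.id, min_aa, table):
        calls.append(GeneCall(contig.id, start, end, "+", prot))
    n = len(seq)
    rc = reverse_complement(seq)
    for start, end, prot in _orfs_one_strand(rc, contig.id, min_aa, table):
        calls.append(GeneCall(contig.id, n - end, n - start, "-", prot))
    calls.sort(key=lambda c: (c.start, c.end, c.strand))
    return calls


def filter_nested_orfs(calls: Sequence[GeneCall], max_overlap: float = 0.5) -> list[GeneCall]:
    """Greedy longest-first ORF dedup: drop calls whose nucleotide span is
    covered more than *max_overlap* of their own length by an already kept
    (longer) call on either strand.

    Six-frame calling necessarily reports shadow ORFs antisense or
    off-frame to real genes; this is the standard cleanup before treating
    the calls as "the proteome" of a contig.
    """
    kept: list[GeneCall] = []
    for c in sorted(calls, key=lambda c: (-(c.end - c.start), c.start, c.strand)):
        own = c.end - c.start
        covered = 0
        for k in kept:
            lo, hi = max(c.start, k.start), min(c.end, k.end)
            if hi > lo:
                covered += hi - lo
                if covered > max_overlap * own:
                    break
        else:
            kept.append(c)
    kept.sort(key=lambda c: (c.start, c.end, c.strand))
    return kept


def contig_proteome(contig: SequenceRecord, min_aa: int = 80) -> list[tuple[str, str]]:
    """(gene_id, protein) pairs for a contig: ORF calls after nested-ORF
    filtering — the working definition of a contig's proteome."""
    calls = filter_nested_orfs(find_orfs(contig, min_aa=min_aa))
    return [(c.gene_id, c.protein) for c in calls]


# ---------------------------------------------------------------------------
# pairwise alignment


def _nt_matrix() -> substitution_matrices.Array:
    m = substitution_matrices.Array(alphabet="ACGTN", dims=2)
    for a in "ACGT":
        for b in "ACGT":
            m[a, b] = 1.0 if a == b else -1.0
    # N is scored neutrally and excluded from the identity denominator
    for a in "ACGTN":
        m["N", a] = 0.0
        m[a, "N"] = 0.0
    return m


def _aligner(kind: str, mode: str) -> PairwiseAligner:
    al = PairwiseAligner()
    al.mode = mode
    if kind == NUCLEOTIDE:
        al.substitution_matrix = _nt_matrix()
        al.open_gap_score = -5.0
        al.extend_gap_score = -2.0
    else:
        al.substitution_matrix = substitution_matrices.load("BLOSUM62")
        al.open_gap_score = -11.0
        al.extend_gap_score = -1.0
    return al


def _sanitize_protein(seq: str) -> str:
    """Map residues outside the BLOSUM62 alphabet to X."""
    alpha = set("ARNDCQEGHILKMFPSTWYVBZX*")
    return "".join(c if c in alpha else "X" for c in seq.upper())


def align(query: SequenceRecord, subject: SequenceRecord, mode: str = "local") -> PairwiseAlignment:
    """Affine-gap pairwise alignment.

    Nucleotide scoring: match +1 / mismatch -1 / gap open -5 / extend -2.
    Protein scoring: BLOSUM62 with gap open -11 / extend -1.  Identity is
    computed over aligned columns; columns containing N (nucleotide) do not
    enter the denominator; gap columns do.
    """
    if query.kind != subject.kind:
        raise TypeError(f"cannot align {query.kind} against {subject.kind}")
    if mode not in ("local", "global"):
        raise ValueError("mode must be 'local' or 'global'")
    qs, ss = query.seq, subject.seq
    if query.kind == PROTEIN:
        qs, ss = _sanitize_protein(qs), _sanitize_protein(ss)
    al = _aligner(query.kind, mode)
    best = al.align(qs, ss)[0]

    ident = 0
    denom = 0
    qaligned = 0
    qblocks, sblocks = best.aligned
    prev_qe = prev_se = None
    for (q0, q1), (s0, s1) in zip(qblocks, sblocks):
        if prev_qe is not None:
            # internal gap columns count in the denominator
            denom += (q0 - prev_qe) + (s0 - prev_se)
        for a, b in zip(qs[q0:q1], ss[s0:s1]):
            if query.kind == NUCLEOTIDE and ("N" in (a, b)):
                continue
            denom += 1
            if a == b:
                ident += 1
        qaligned += q1 - q0
        prev_qe, prev_se = q1, s1
    if mode == "global":
        # terminal gaps are part of a global alignment's columns
        if qblocks.size:
            denom += qblocks[0][0] + sblocks[0][0]
            denom += (len(qs) - qblocks[-1][1]) + (len(ss) - sblocks[-1][1])
        coverage = 1.0
    else:
        coverage = qaligned / len(qs) if len(qs) else 0.0
    identity = 100.0 * ident / denom if denom else 0.0
    return PairwiseAlignment(
        query_id=query.id, subject_id=subject.id, mode=mode,
        identity=identity, query_coverage=coverage, score=float(best.score),
    )


# ---------------------------------------------------------------------------
# FASTA / GFF3 I/O


def read_fasta(path: str | Path, kind: str = NUCLEOTIDE) -> list[SequenceRecord]:
    records = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seen:
            raise ValueError(f"{path}: duplicate record id {rec.id!r}")
        seen.add(rec.id)
        desc = rec.description[len(rec.id):].strip() if rec.description.startswith(rec.id) else rec.description
        seq = str(rec.seq)
        if kind == PROTEIN:
            seq = seq.upper()
        records.append(SequenceRecord(id=rec.id, seq=seq, description=desc, kind=kind))
    return records


def write_fasta(records: Iterable[SequenceRecord], path: str | Path, width: int = 80) -> None:
    with open(path, "w") as fh:
        for rec in records:
            header = f">{rec.id}" + (f" {rec.description}" if rec.description else "")
            fh.write(header + "\n")
            for i in range(0, len(rec.seq), width):
                fh.write(rec.seq[i : i + width] + "\n")


def write_gff3(calls: Iterable[GeneCall], path: str | Path, source: str = "novitax") -> None:
    """Gene calls as GFF3 CDS features (1-based inclusive coordinates)."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for i, c in enumerate(calls, 1):
            fh.write(
                "\t".join([
                    c.contig_id, source, "CDS",
                    str(c.start + 1), str(c.end), ".", c.strand, "0",
                    f"ID=cds{i};protein_length={len(c.protein)}",
                ]) + "\n"
            )
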