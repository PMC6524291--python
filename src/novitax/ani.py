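"""Fragment-based average nucleotide identity and the <95% species rule.

The query genome is cut into consecutive non-overlapping fragments
(default 1020 nt, the standard fragment-based convention); each fragment is
mapped to the subject and its percent identity recorded.  Fragments passing
identity/coverage floors are averaged into a one-way ANI; the reciprocal
ANI is the mean of the two directions.  Two genomes with reciprocal ANI
below 95% are called distinct species (strict '<': exactly 95.0 is not
distinct).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .mapping import GenomeIndex
from .seqcore import SequenceRecord

SAME = "same_species"
DISTINCT = "distinct_species"
UNDEFINED = "undefined"


@dataclass(frozen=True)
class ANIResult:
    query_id: str
    subject_id: str
    one_way_ani: float | None          # query -> subject; None if no homology
    reciprocal_ani: float | None
    n_fragments_used: int
    fragment_len: int

    @property
    def no_homology(self) -> bool:
        return self.reciprocal_ani is None


def _one_way(
    query: SequenceRecord,
    subject_index: GenomeIndex,
    fragment_len: int,
    min_frag_identity: float,
    min_frag_cov: float,
) -> tuple[float | None, int]:
    idents = []
    seq = query.seq
    n_full = len(seq) // fragment_len
    for i in range(n_full):
        frag = seq[i * fragment_len : (i + 1) * fragment_len]
        hit = subject_index.map_fragment(frag)
        if hit is None:
            continue
        if hit.identity >= min_frag_identity and hit.coverage >= min_frag_cov:
            idents.append(hit.identity)
    if not idents:
        return None, 0
    return float(np.mean(idents)), len(idents)


def compute_ani(
    query: SequenceRecord,
    subject: SequenceRecord,
    fragment_len: int = 1020,
    min_frag_identity: float = 30.0,
    min_frag_cov: float = 0.7,
) -> ANIResult:
    """Reciprocal fragment-based ANI between two genomes.

    Both genomes must be at least 10 fragment lengths long.  If no fragment
    passes the filters in either direction the result is an explicit
    no-homology ANIResult (reciprocal_ani None), never 0.
    """
    for g in (query, subject):
        if len(g.seq) < 10 * fragment_len:
            raise ValueError(f"genome {g.id} shorter than 10 fragments; ANI not meaningful")
    fwd, n_fwd = _one_way(query, GenomeIndex(subject.seq), fragment_len, min_frag_identity, min_frag_cov)
    rev, n_rev = _one_way(subject, GenomeIndex(query.seq), fragment_len, min_frag_identity, min_frag_cov)
    if fwd is None or rev is None:
        return ANIResult(query.id, subject.id, fwd, None, n_fwd + n_rev, fragment_len)
    return ANIResult(query.id, subject.id, fwd, (fwd + rev) / 2.0, n_fwd + n_rev, fragment_len)


def species_boundary(ani: ANIResult, threshold: float = 95.0) -> str:
    """Species delineation: distinct iff reciprocal ANI < threshold."""
    if ani.reciprocal_ani is None:
        return UNDEFINED
    return DISTINCT if ani.reciprocal_ani < threshold else SAME


def ani_matrix(
    genomes: Sequence[SequenceRecord], **kw
) -> tuple[list[str], np.ndarray]:
    """Symmetric reciprocal-ANI matrix over a genome set.

    Diagonal is 100; pairs with no homology are NaN.
    """
    if len(genomes) < 2:
        raise ValueError("need at least 2 genomes")
    ids = [g.id for g in genomes]
    n = len(genomes)
    M = np.full((n, n), np.nan)
    np.fill_diagonal(M, 100.0)
    for i in range(n):
        for j in range(i + 1, n):
            r = compute_ani(genomes[i], genomes[j], **kw)
            if r.reciprocal_ani is not None:
                M[i, j] = M[j, i] = r.reciprocal_ani
    return ids, M


def matrix_to_tsv(ids: list[str], M: np.ndarray, path) -> None:
    with open(path, "w") as fh:
        fh.write("genome\t" + "\t".join(ids) + "\n")
        for i, gid in enumerate(ids):
            cells = ["" if np.isnan(M[i, j]) else f"{M[i, j]:.2f}" for j in range(len(ids))]
            fh.write(gid + "\t" + "\t".join(cells) + "\n")
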