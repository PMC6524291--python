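"""Glycosyl-hydrolase (GH) profiling of dark-matter contigs and carbon-
source recommendation for selective cultivation.

Genes from novel-candidate contigs are assigned to GH families by best hit
against a labeled GH reference set; the family-level relative-abundance
vector (the "glycobiome") is then matched against an editable rule table
mapping GH patterns to fermentable glycans (default vocabulary:
arabinogalactan, pullulan, starch, xylan).  A rule is a conjunction of
clauses, each clause a disjunction of ``family`` or ``family:subfamily``
terms, e.g. ``GH10|GH11 & GH43|GH3:beta-xylosidase -> xylan``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Sequence

from .panel import ProteinIndex, _attr
from .seqcore import PROTEIN, SequenceRecord


@dataclass(frozen=True)
class GHAssignment:
    gene_id: str
    gh_family: str
    subfamily_label: str
    identity: float
    coverage: float


@dataclass
class GlycobiomeProfile:
    counts: dict[str, int]              # per gh_family
    relative: dict[str, float]          # fractions over assigned genes
    n_genes_total: int
    assignments: list[GHAssignment] = field(default_factory=list)

    @property
    def empty(self) -> bool:
        return not self.counts


def assign_gh(
    proteins: Sequence[SequenceRecord],
    gh_reference: Sequence[SequenceRecord],
    min_identity: float = 40.0,
    min_cov: float = 0.7,
) -> list[GHAssignment]:
    """Best GH-reference hit per protein passing both thresholds; family and
    subfamily labels are inherited from the reference record."""
    if not gh_reference:
        raise ValueError("GH reference set is empty")
    idx = ProteinIndex(list(gh_reference))
    out = []
    for q in proteins:
        got = idx.best_hit(q, min_identity, min_cov)
        if got is None:
            continue
        subj, aln = got
        out.append(
            GHAssignment(
                gene_id=q.id,
                gh_family=_attr(subj.description, "family") or subj.id.split("_")[0],
                subfamily_label=_attr(subj.description, "subfamily"),
                identity=aln.identity,
                coverage=aln.query_coverage,
            )
        )
    return out


def profile(assignments: Sequence[GHAssignment], n_genes_total: int | None = None) -> GlycobiomeProfile:
    counts: dict[str, int] = {}
    for a in assignments:
        counts[a.gh_family] = counts.get(a.gh_family, 0) + 1
    total = sum(counts.values())
    rel = {f: c / total for f, c in sorted(counts.items())} if total else {}
    return GlycobiomeProfile(
        counts=dict(sorted(counts.items())),
        relative=rel,
        n_genes_total=n_genes_total if n_genes_total is not None else total,
        assignments=list(assignments),
    )


# ---------------------------------------------------------------------------
# substrate rules


@dataclass(frozen=True)
class SubstrateRule:
    clauses: tuple[tuple[tuple[str, str], ...], ...]  # AND of OR of (family, subfamily-or-"")
    substrate: str
    weight: float

    @property
    def pattern(self) -> str:
        return " & ".join(
            "|".join(f"{fam}:{sub}" if sub else fam for fam, sub in clause)
            for clause in self.clauses
        )


@dataclass
class SubstrateMap:
    rules: list[SubstrateRule]

    @classmethod
    def default(cls) -> "SubstrateMap":
        with resources.as_file(resources.files("novitax.data") / "substrate_rules.tsv") as p:
            return cls.from_tsv(p)

    @classmethod
    def from_tsv(cls, path: str | Path) -> "SubstrateMap":
        rules = []
        with open(path) as fh:
            header = fh.readline().rstrip("\n").split("\t")
            if header[:3] != ["pattern", "substrate", "weight"]:
                raise ValueError("rule file must have columns pattern, substrate, weight")
            for line in fh:
                if not line.strip() or line.startswith("#"):
                    continue
                pattern, substrate, weight = line.rstrip("\n").split("\t")[:3]
                rules.append(_parse_rule(pattern, substrate, float(weight)))
        return cls(rules)


def _parse_rule(pattern: str, substrate: str, weight: float) -> SubstrateRule:
    clauses = []
    for clause in pattern.split("&"):
        terms = []
        for term in clause.split("|"):
            term = term.strip()
            fam, _, sub = term.partition(":")
            terms.append((fam.strip(), sub.strip()))
        clauses.append(tuple(terms))
    return SubstrateRule(tuple(clauses), substrate.strip(), weight)


@dataclass(frozen=True)
class SubstrateCall:
    substrate: str
    score: float
    supporting_genes: tuple[str, ...]
    rule_pattern: str


def _matches(term: tuple[str, str], a: GHAssignment) -> bool:
    fam, sub = term
    if a.gh_family != fam:
        return False
    return (not sub) or (a.subfamily_label == sub)


def recommend_substrates(
    prof: GlycobiomeProfile,
    smap: SubstrateMap | None = None,
    top_k: int | None = None,
) -> list[SubstrateCall]:
    """Fire every rule whose GH pattern is satisfied; score = weight times
    the summed relative abundance of the families supporting it.  Ranking
    is score-descending with ties broken by substrate name; scores are
    scale-invariant in the underlying counts.  An empty profile yields an
    empty recommendation (no GH evidence)."""
    if smap is None:
        smap = SubstrateMap.default()
    if prof.empty:
        return []
    calls = []
    for rule in smap.rules:
        support: list[str] = []
        fams: set[str] = set()
        ok = True
        for clause in rule.clauses:
            clause_genes = [
                a for a in prof.assignments if any(_matches(t, a) for t in clause)
            ]
            if not clause_genes:
                ok = False
                break
            support.extend(a.gene_id for a in clause_genes)
            fams.update(a.gh_family for a in clause_genes)
        if not ok:
            continue
        score = rule.weight * sum(prof.relative.get(f, 0.0) for f in sorted(fams))
        calls.append(
            SubstrateCall(
                substrate=rule.substrate,
                score=score,
                supporting_genes=tuple(dict.fromkeys(support)),
                rule_pattern=rule.pattern,
            )
        )
    # merge duplicate substrates (keep max score, union support)
    merged: dict[str, SubstrateCall] = {}
    for c in calls:
        if c.substrate in merged:
            prev = merged[c.substrate]
            merged[c.substrate] = SubstrateCall(
                c.substrate,
                max(prev.score, c.score),
                tuple(dict.fromkeys(prev.supporting_genes + c.supporting_genes)),
                prev.rule_pattern,
            )
        else:
            merged[c.substrate] = c
    ranked = sorted(merged.values(), key=lambda c: (-c.score, c.substrate))
    return ranked[:top_k] if top_k else ranked


def assignments_to_tsv(assignments: Sequence[GHAssignment], path) -> None:
    with open(path, "w") as fh:
        fh.write("gene_id\tgh_family\tsubfamily\tidentity\tcoverage\n")
        for a in assignments:
            fh.write(
                f"{a.gene_id}\t{a.gh_family}\t{a.subfamily_label}\t{a.identity:.2f}\t{a.coverage:.3f}\n"
            )
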