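"""End-to-end orchestration: discovery (bin -> screen -> glycobiome ->
substrate ranking) and confirmation (ITS -> ANI -> phylogenomic placement).

Reports are plain JSON with every threshold echoed and a config hash for
provenance; no timestamps, so identical config + seed reproduces
byte-identical output.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Sequence

import yaml

from . import __version__, glycobiome
from .ani import compute_ani, species_boundary
from .binning import abundance_profile, assignments_to_tsv, classify_sample
from .glycobiome import SubstrateMap, assign_gh, recommend_substrates
from .its import classify_its
from .novelty import NOVEL, ScreenThresholds, screen_sample, verdicts_to_tsv
from .pangenome import (
    bootstrap_supports,
    cluster_orthologs,
    core_distances,
    core_single_copy,
    nj_tree,
)
from .panel import ReferencePanel, predict_proteome
from .seqcore import PROTEIN, SequenceRecord

logger = logging.getLogger(__name__)


class StageError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


@dataclass
class RunConfig:
    target_genus: str = "Bifidobacterium"
    seed: int = 0
    min_fraction: float = 0.002         # abundance reporting floor
    bin_min_identity: float = 30.0
    bin_min_cov: float = 0.5
    min_aa: int = 80
    screen: ScreenThresholds = field(default_factory=ScreenThresholds)
    gh_min_identity: float = 40.0
    gh_min_cov: float = 0.7
    its_species_identity: float = 98.0
    its_min_cov: float = 0.9
    ani_fragment_len: int = 1020
    ani_threshold: float = 95.0
    ortho_min_identity: float = 50.0
    ortho_min_cov: float = 0.5
    bootstrap_reps: int = 100
    outgroup: str | None = None
    log_level: str = "INFO"

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        return cls.from_dict(raw)

    @classmethod
    def from_dict(cls, raw: dict) -> "RunConfig":
        known = set(cls.__dataclass_fields__)
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        screen_raw = raw.pop("screen", None)
        cfg = cls(**raw)
        if screen_raw:
            bad = set(screen_raw) - set(ScreenThresholds.__dataclass_fields__)
            if bad:
                raise ValueError(f"unknown screen threshold keys: {sorted(bad)}")
            cfg.screen = ScreenThresholds(**screen_raw)
        return cfg

    def to_dict(self) -> dict:
        d = asdict(self)
        return d

    def hash(self) -> str:
        return hashlib.sha256(
            json.dumps(self.to_dict(), sort_keys=True).encode()
        ).hexdigest()[:12]


def _provenance(config: RunConfig) -> dict:
    return {"tool": "novitax", "version": __version__, "config_hash": config.hash(),
            "config": config.to_dict()}


def run_discovery(
    contigs: Sequence[SequenceRecord],
    panel: ReferencePanel,
    config: RunConfig = RunConfig(),
    outdir: str | Path | None = None,
) -> dict:
    """The dark-matter discovery workflow on one sample.

    Classifies every contig to genus, profiles abundances, screens the
    target-genus contigs for novelty, profiles the GH repertoire of the
    novel candidates, and ranks cultivation substrates.
    """
    if not contigs:
        raise ValueError("empty contig set")
    out = Path(outdir) if outdir else None
    if out:
        out.mkdir(parents=True, exist_ok=True)
    report: dict = {"provenance": _provenance(config), "stages": {}}

    stage = "binning"
    try:
        t0 = time.monotonic()
        assignments = classify_sample(
            contigs, panel,
            min_identity=config.bin_min_identity, min_cov=config.bin_min_cov,
            min_aa=config.min_aa,
        )
        prof = abundance_profile(assignments, min_fraction=config.min_fraction)
        logger.info("stage=%s contigs=%d wall=%.1fs", stage, len(contigs), time.monotonic() - t0)
        report["stages"]["binning"] = {
            "n_records": len(contigs),
            "abundance": prof.fractions,
            "abundance_rendered": prof.rendered(),
            "total_bp": prof.total_bp,
        }
        if out:
            assignments_to_tsv(assignments, out / "assignments.tsv")
    except Exception as e:  # pragma: no cover - defensive
        raise StageError(stage, e) from e

    target_frac = prof.fraction(config.target_genus)
    report["target_genus"] = config.target_genus
    report["target_fraction"] = target_frac
    if target_frac < config.min_fraction:
        report["flags"] = [
            f"target genus below the {config.min_fraction:.1%} reporting floor; "
            "detection limit should be established by spike-in titration"
        ]

    target_ids = {a.seq_id for a in assignments if a.genus == config.target_genus}
    target_contigs = [c for c in contigs if c.id in target_ids]

    stage = "novelty_screen"
    try:
        t0 = time.monotonic()
        screen = screen_sample(
            target_contigs, panel, config.screen,
            novel_fasta=str(out / "novel_candidates.fasta") if out else None,
        )
        logger.info("stage=%s contigs=%d wall=%.1fs", stage, len(target_contigs), time.monotonic() - t0)
        report["stages"]["novelty_screen"] = screen.to_dict()
        if out:
            verdicts_to_tsv(screen, out / "verdicts.tsv")
    except Exception as e:
        raise StageError(stage, e) from e

    stage = "glycobiome"
    try:
        novel_ids = {v.contig_id for v in screen.verdicts if v.status == NOVEL}
        novel_contigs = [c for c in contigs if c.id in novel_ids]
        from .seqcore import contig_proteome

        proteins = [
            SequenceRecord(gid, prot, kind=PROTEIN)
            for c in novel_contigs
            for gid, prot in contig_proteome(c, min_aa=config.min_aa)
        ]
        gh_calls = assign_gh(
            proteins, panel.gh_reference,
            min_identity=config.gh_min_identity, min_cov=config.gh_min_cov,
        )
        prof_gh = glycobiome.profile(gh_calls, n_genes_total=len(proteins))
        recs = recommend_substrates(prof_gh, SubstrateMap.default())
        report["stages"]["glycobiome"] = {
            "n_novel_contigs": len(novel_contigs),
            "n_genes": len(proteins),
            "gh_counts": prof_gh.counts,
            "gh_relative": prof_gh.relative,
            "substrates": [
                {"substrate": r.substrate, "score": r.score,
                 "supporting_genes": list(r.supporting_genes)}
                for r in recs
            ],
            "notice": None if gh_calls else "no GH evidence",
        }
        if out:
            glycobiome.assignments_to_tsv(gh_calls, out / "gh_assignments.tsv")
    except Exception as e:
        raise StageError(stage, e) from e

    if out:
        (out / "discovery_report.json").write_text(json.dumps(report, indent=1, sort_keys=True))
    return report


def run_confirmation(
    isolates: Sequence[SequenceRecord],
    panel: ReferencePanel,
    config: RunConfig = RunConfig(),
    its_seqs: dict[str, SequenceRecord] | None = None,
    outdir: str | Path | None = None,
) -> dict:
    """Confirm isolate novelty: ITS triage, nearest panel genome by ANI,
    species-boundary call, and placement on a bootstrapped core-genome NJ
    tree of panel + isolates."""
    if not isolates:
        raise ValueError("need at least one isolate genome")
    out = Path(outdir) if outdir else None
    if out:
        out.mkdir(parents=True, exist_ok=True)
    report: dict = {"provenance": _provenance(config), "isolates": {}}

    panel_genomes = {
        gid: SequenceRecord(gid, "N".join(r.seq for r in recs))
        for gid, recs in sorted(panel.genomes.items())
    }
    for iso in isolates:
        entry: dict = {}
        if its_seqs and iso.id in its_seqs and panel.its:
            call = classify_its(
                its_seqs[iso.id], panel.its,
                species_identity=config.its_species_identity, min_cov=config.its_min_cov,
            )
            entry["its"] = {
                "verdict": call.verdict, "best_species": call.best_species,
                "identity": call.identity,
            }
        best = None
        for gid, ref in panel_genomes.items():
            try:
                r = compute_ani(iso, ref, fragment_len=config.ani_fragment_len)
            except ValueError:
                continue
            if r.reciprocal_ani is None:
                continue
            if best is None or r.reciprocal_ani > best[1].reciprocal_ani:
                best = (gid, r)
        if best is None:
            entry["ani"] = {"nearest": None, "value": None, "boundary": "undefined"}
        else:
            gid, r = best
            entry["ani"] = {
                "nearest": gid,
                "nearest_species": panel.species(gid),
                "value": r.reciprocal_ani,
                "boundary": species_boundary(r, threshold=config.ani_threshold),
            }
        report["isolates"][iso.id] = entry

    stage = "phylogenomics"
    try:
        proteomes = {gid: list(prots) for gid, prots in panel.proteins.items()}
        for iso in isolates:
            proteomes[iso.id] = predict_proteome([iso], iso.id, min_aa=config.min_aa)
        clusters = cluster_orthologs(
            proteomes, min_identity=config.ortho_min_identity, min_cov=config.ortho_min_cov
        )
        core, single, n_paralog = core_single_copy(clusters, len(proteomes))
        tree_block: dict = {
            "n_clusters": len(clusters), "n_core": len(core),
            "n_single_copy_core": len(single), "n_paralogous_core": n_paralog,
        }
        if len(single) >= 1 and len(proteomes) >= 3:
            taxa, D, mats, lens = core_distances(single, proteomes)
            outgroup = config.outgroup if config.outgroup in taxa else None
            tree = nj_tree(D, taxa, outgroup=outgroup)
            tree = bootstrap_supports(
                tree, mats, lens, taxa, outgroup=outgroup,
                n_reps=config.bootstrap_reps, seed=config.seed,
            )
            tree_block["newick"] = tree.newick()
            tree_block["outgroup"] = outgroup
            tree_block["bootstrap_reps"] = config.bootstrap_reps
        else:
            tree_block["warning"] = "core genome empty or too few taxa; tree not built"
        report["phylogenomics"] = tree_block
    except Exception as e:
        raise StageError(stage, e) from e

    if out:
        (out / "confirmation_report.json").write_text(json.dumps(report, indent=1, sort_keys=True))
        if "newick" in report["phylogenomics"]:
            (out / "core_tree.nwk").write_text(report["phylogenomics"]["newick"] + "\n")
    return report
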