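"""End-to-end orchestration: library audit, assignment runs, reports.

The audit chains the stages of a reference-library evaluation — length
filter, K2P distances, divergence/overlap summaries, histogram, NJ tree
with bootstrap supports, haplotype accounting, the species-differentiation
tally and the NB-system comparison — and writes every headline number into
one machine-readable JSON summary alongside the per-stage TSV/newick
outputs.  Stage failures are isolated: a failed stage is recorded in the
summary and the remaining stages still run.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import pandas as pd

from . import __version__
from .seqio import Library, SequenceRecord, collapse_haplotypes, filter_by_length, haplotype_summary
from .distances import distance_matrix, divergence_summaries, histogram_export, overlap_analysis
from .trees import bootstrap_supports, differentiation_report, write_newick
from .assignment import assign, candidate_matrices, loo_validate
from .rflp import NBWindows, nb_vs_barcode_report
from ._encoding import encode_many

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Configuration of one audit/assignment run."""

    length_threshold: int = 600
    bootstrap_replicates: int = 100
    overlap_window: tuple[float, float] = (2.0, 4.0)
    min_overlap: int = 300
    outgroup: Optional[str] = None
    level: str = "species"
    seed: int = 0
    windows: NBWindows = field(default_factory=NBWindows)

    def __post_init__(self):
        if self.bootstrap_replicates < 1:
            raise ValueError("bootstrap_replicates must be >= 1")

    def config_hash(self) -> str:
        payload = json.dumps(dataclasses.asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:12]


def _stage(summary: dict, name: str):
    """Record stage failures without aborting the whole audit."""
    class _Ctx:
        def __enter__(self):
            return self

        def __exit__(self, exc_type, exc, tb):
            if exc is not None:
                logger.error("stage %s failed: %s", name, exc)
                summary.setdefault("failed_stages", {})[name] = str(exc)
                return True
            return False

    return _Ctx()


def run_library_audit(lib: Library, cfg: RunConfig, outdir=None) -> dict:
    """Full reference-library audit; returns (and optionally writes) the
    machine-readable summary."""
    out = Path(outdir) if outdir is not None else None
    if out is not None:
        out.mkdir(parents=True, exist_ok=True)
    summary: dict = {
        "version": __version__,
        "config_hash": cfg.config_hash(),
        "seed": cfg.seed,
        "n_records_input": len(lib),
    }

    filtered = filter_by_length(lib, cfg.length_threshold)
    if len(filtered) < 3:
        raise ValueError("fewer than 3 records pass the length filter")
    summary["n_records_filtered"] = len(filtered)
    summary["n_species"] = len(set(filtered.species_of.values()))

    species_of = filtered.species_of
    dm = distance_matrix(filtered)
    summary["n_flagged_pairs"] = dm.n_flagged_pairs

    with _stage(summary, "divergence"):
        intra, inter = divergence_summaries(dm, species_of)
        summary["intra"] = dataclasses.asdict(intra)
        summary["inter"] = dataclasses.asdict(inter)
        if intra.n and inter.n:
            summary["fold_ratio"] = inter.mean / intra.mean

    with _stage(summary, "overlap"):
        ov = overlap_analysis(dm, species_of, *cfg.overlap_window)
        summary["overlap"] = {
            "n_intra_total": ov.n_intra_total,
            "n_intra_in_window": ov.n_intra_in_window,
            "n_inter_total": ov.n_inter_total,
            "n_inter_in_window": ov.n_inter_in_window,
            "offending_taxa": ov.offending_taxa,
            "offending_pairs": [list(p) for p in ov.offending_pairs],
        }

    with _stage(summary, "histogram"):
        hist = histogram_export(dm, species_of)
        if out is not None:
            hist.to_csv(out / "histogram.tsv", sep="\t", index=False,
                        float_format="%.2f")

    haps, excluded = collapse_haplotypes(filtered, cfg.min_overlap)
    summary["n_haplotypes"] = len(haps)
    summary["n_shared_haplotypes"] = sum(1 for h in haps if h.shared_between_species)
    summary["n_records_excluded_from_collapse"] = len(excluded)

    with _stage(summary, "tree"):
        tree = bootstrap_supports(filtered, cfg.bootstrap_replicates, seed=cfg.seed)
        if out is not None:
            write_newick(tree, out / "tree.nwk")
        report = differentiation_report(tree, haps, species_of, outgroup=cfg.outgroup)
        summary["differentiation"] = {
            "n_species": report.n_species,
            "n_success": report.n_success,
            "success_fraction": report.success_fraction,
        }
        if out is not None:
            report.per_species.to_csv(out / "differentiation.tsv", sep="\t", index=False)

    with _stage(summary, "nb_system"):
        nb = nb_vs_barcode_report(filtered, cfg.windows, cfg.min_overlap)
        summary["nb"] = {
            "class_summary": nb.class_summary.to_dict(orient="records"),
            "n_collisions": len(nb.collisions),
            "barcode_haplotypes_species_unique": nb.barcode_haplotypes_species_unique,
        }
        if out is not None:
            nb.per_species.to_csv(out / "nb_per_species.tsv", sep="\t", index=False)
            nb.class_summary.to_csv(out / "nb_class_summary.tsv", sep="\t", index=False)

    if out is not None:
        dm.to_tsv(out / "distance_matrix.tsv")
        haplotype_summary(haps).to_csv(out / "haplotypes.tsv", sep="\t", index=False)
        with open(out / "summary.json", "w") as fh:
            json.dump(summary, fh, indent=2, default=float)
    return summary


def run_assignment(lib: Library, queries: list[SequenceRecord], cfg: RunConfig,
                   outdir=None) -> pd.DataFrame:
    """Assign query sequences against a reference library at cfg.level.

    Emits an assignment-table-shaped frame (taxon, query id, sample size,
    diagnostic sites, posterior, risk); unassignable queries are listed
    with a flag rather than raising.
    """
    out = Path(outdir) if outdir is not None else None
    if out is not None:
        out.mkdir(parents=True, exist_ok=True)
    if not queries:
        logger.warning("no query sequences supplied; empty report")
        df = pd.DataFrame(columns=["taxon", "query_id", "n", "n_diagnostic_sites",
                                   "posterior", "risk", "unassignable"])
    else:
        cands = candidate_matrices(lib, cfg.level)
        rows = []
        for q in queries:
            res = assign(q, cands)
            rows.append({
                "taxon": res.assigned,
                "query_id": q.id,
                "n": 0 if res.assigned is None else cands[res.assigned].shape[0],
                "n_diagnostic_sites": res.n_diagnostic_sites,
                "posterior": res.posterior,
                "risk": res.risk,
                "unassignable": res.unassignable,
            })
        df = pd.DataFrame(rows)
    if out is not None:
        df.to_csv(out / f"assignment_{cfg.level}.tsv", sep="\t", index=False)
        meta = {"version": __version__, "seed": cfg.seed,
                "config_hash": cfg.config_hash(), "level": cfg.level,
                "n_queries": len(queries),
                "n_unassignable": int(df["unassignable"].sum()) if len(df) else 0}
        with open(out / "assignment_meta.json", "w") as fh:
            json.dump(meta, fh, indent=2)
    return df


def run_loo(lib: Library, cfg: RunConfig, outdir=None) -> pd.DataFrame:
    """Leave-one-out validation at cfg.level, seeded from cfg.seed."""
    df = loo_validate(lib, level=cfg.level, seed=cfg.seed)
    if outdir is not None:
        out = Path(outdir)
        out.mkdir(parents=True, exist_ok=True)
        df.to_csv(out / f"loo_{cfg.level}.tsv", sep="\t", index=False)
    return df
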