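"""End-to-end orchestration: scan -> date -> dnds -> diet.

One reproducible run over a config (YAML or RunConfig): validates inputs up
front, executes the stages in order writing one TSV per stage plus a summary
and a machine-readable manifest (config echo, config hash, seed, library
versions). A stage failure raises :class:`PipelineStageError` naming the
stage; outputs of completed stages are retained.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from .chronomap import timing_table
from .codonml import mark_foreground, test_vs_average, test_vs_neutral
from .dietassoc import DietRecord, crosstab
from .lesionscan import (
    annotate_cpg,
    events_table,
    gene_status,
    merge_events,
    scan_alignment,
)
from .seqio import CodonAlignment, read_fasta
from .trees import DatedTree

__all__ = ["RunConfig", "PipelineStageError", "load_config", "run_pipeline"]

log = logging.getLogger(__name__)


class PipelineStageError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"pipeline stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


@dataclass
class RunConfig:
    alignment: str
    tree: str
    outdir: str
    ref_id: str | None = None
    ages: str | None = None
    diet: str | None = None
    missing: tuple[str, ...] = ()  # tips with no sequence data
    foreground: dict[str, list[str]] = field(default_factory=dict)
    null_policy: str = "average"  # "average" | "neutral"
    freq_model: str = "F3x4"
    mask: str = "any"
    seed: int = 0

    def validate(self):
        for name in ("alignment", "tree", "ages", "diet"):
            path = getattr(self, name)
            if path is not None and not Path(path).exists():
                raise FileNotFoundError(f"config {name}: no such file {path!r}")
        if self.null_policy not in ("average", "neutral"):
            raise ValueError(f"unknown null policy {self.null_policy!r}")


def load_config(path) -> RunConfig:
    raw = yaml.safe_load(Path(path).read_text()) or {}
    cfg = RunConfig(**raw)
    cfg.validate()
    return cfg


def _config_hash(cfg: RunConfig) -> str:
    blob = json.dumps(asdict(cfg), sort_keys=True).encode()
    return hashlib.sha256(blob).hexdigest()[:16]


def run_pipeline(cfg: RunConfig) -> dict:
    """Run all stages; returns the summary dict (also written to disk)."""
    cfg.validate()
    out = Path(cfg.outdir)
    out.mkdir(parents=True, exist_ok=True)
    summary: dict = {"seed": cfg.seed}

    # ---- stage: scan ------------------------------------------------------
    stage = "scan"
    try:
        records = read_fasta(cfg.alignment)
        ids = [r.id for r in records]
        ref_id = cfg.ref_id or ("human" if "human" in ids else ids[0])
        if cfg.ref_id is None and "human" not in ids:
            log.warning("no reference specified; defaulting to first record "
                        "%r", ref_id)
        aln = CodonAlignment(records, ref_id=ref_id)
        per_species = scan_alignment(aln)
        events, matrix = merge_events(per_species)
        events = [
            annotate_cpg(ev, aln) if ev.kind == "nonsense" else ev
            for ev in events
        ]
        statuses = gene_status(matrix, events)
        events_table(events).to_csv(out / "events.tsv", sep="\t", index=False)
        cells = matrix.replace({True: "+", False: "-"})
        cells.index.name = "species"
        cells.to_csv(out / "matrix.tsv", sep="\t")
        pd.DataFrame(
            [{"species": s.species, "status": s.status,
              "n_disruptive": s.n_disruptive} for s in statuses]
        ).to_csv(out / "status.tsv", sep="\t", index=False)
        summary["n_events"] = len(events)
        n_scanned = len(matrix.index)
        summary["n_universal_events"] = sum(
            1 for ev in events if len(ev.carriers) == n_scanned
        )
        summary["n_pseudogene_species"] = sum(
            1 for s in statuses if s.status == "pseudogene"
        )
    except Exception as exc:  # noqa: BLE001 - stage boundary
        raise PipelineStageError(stage, exc) from exc

    # ---- stage: date ------------------------------------------------------
    stage = "date"
    try:
        tree = DatedTree.from_newick(cfg.tree, ages=cfg.ages)
        tips = set(tree.tip_labels)
        datable = []
        for ev in events:
            on_tree = ev.carriers & tips
            if on_tree:
                datable.append(
                    type(ev)(ev.kind, ev.ref_start, ev.ref_end, ev.length,
                             frozenset(on_tree), id=ev.id,
                             cpg_hotspot=ev.cpg_hotspot)
                )
        timing = timing_table(tree, datable, missing=set(cfg.missing))
        timing.to_csv(out / "timing.tsv", sep="\t", index=False)
        summary["n_dated_events"] = len(datable)
    except Exception as exc:
        raise PipelineStageError(stage, exc) from exc

    # ---- stage: dnds (optional) ------------------------------------------
    if cfg.foreground:
        stage = "dnds"
        try:
            rows = []
            for name, tip_list in sorted(cfg.foreground.items()):
                import dendropy

                topo = dendropy.Tree.get(
                    data=Path(cfg.tree).read_text()
                    if Path(cfg.tree).exists() else cfg.tree,
                    schema="newick", preserve_underscores=True,
                    suppress_internal_node_taxa=True,
                )
                topo.retain_taxa_with_labels(
                    [t for t in ids if t in {x.taxon.label
                                             for x in topo.leaf_node_iter()}]
                )
                mark_foreground(topo, tip_list, name="fg")
                test = (
                    test_vs_average(aln, topo, "fg", mask=cfg.mask,
                                    freq_model=cfg.freq_model)
                    if cfg.null_policy == "average"
                    else test_vs_neutral(aln, topo, "fg", mask=cfg.mask,
                                         freq_model=cfg.freq_model)
                )
                rows.append(
                    {"lineage": name,
                     "omega_lineage": test.alt.omegas.get("fg"),
                     "omega_background": test.alt.omegas.get("bg"),
                     "kappa": test.alt.kappa,
                     "ll_alt": test.lrt.ll_alt,
                     "ll_null": test.lrt.ll_null,
                     "statistic": test.lrt.statistic,
                     "df": test.lrt.df,
                     "p_value": test.lrt.p_value}
                )
            pd.DataFrame(rows).to_csv(out / "dnds.tsv", sep="\t", index=False)
            summary["n_lineages_tested"] = len(rows)
        except Exception as exc:
            raise PipelineStageError(stage, exc) from exc

    # ---- stage: diet (optional) ------------------------------------------
    if cfg.diet:
        stage = "diet"
        try:
            diet_df = pd.read_csv(cfg.diet, sep="\t")
            diets = [
                DietRecord(row.species, row.category,
                           evidence=getattr(row, "evidence", ""))
                for row in diet_df.itertuples()
            ]
            report = crosstab(statuses, diets)
            report.table.to_csv(out / "diet_crosstab.tsv", sep="\t")
            summary["all_pseudogenes_hypercarnivore"] = (
                report.all_pseudogenes_hypercarnivore
            )
            summary["n_unclassified_diet"] = len(report.unclassified)
        except Exception as exc:
            raise PipelineStageError(stage, exc) from exc

    # ---- summary + manifest ----------------------------------------------
    pd.DataFrame([summary]).to_csv(out / "summary.tsv", sep="\t", index=False)
    manifest = {
        "pseudochron": __version__,
        "seed": cfg.seed,
        "config": asdict(cfg),
        "config_hash": _config_hash(cfg),
        "versions": _versions(),
        "outputs": sorted(p.name for p in out.glob("*.tsv")),
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2,
                                                  sort_keys=True) + "\n")
    return summary


def _versions() -> dict[str, str]:
    import Bio
    import dendropy
    import numpy
    import scipy

    return {
        "numpy": numpy.__version__,
        "scipy": scipy.__version__,
        "pandas": pd.__version__,
        "biopython": Bio.__version__,
        "dendropy": dendropy.__version__,
    }
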