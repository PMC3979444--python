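"""End-to-end orchestration: curation -> typing -> phylogeny -> gene
structure -> selection, from a single YAML config, with a JSON manifest.

Stages run in the order of the underlying analysis; a stage whose inputs
are absent is skipped and logged, and record counts in/out of every filter
are asserted to be conserved (n_input = n_kept + n_dropped) and recorded in
the manifest.  All randomness is routed through one master seed.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import numpy as np
import yaml

from . import genestruct, lp_typing, phylo, selection, seqcore

logger = logging.getLogger(__name__)


class PipelineError(RuntimeError):
    """A stage failed; the message names the stage."""


@dataclass
class RunConfig:
    """Validated run configuration (paths, anchors, thresholds, seed)."""

    proteins: Path
    out_dir: Path
    signal_peptides: Path | None = None
    exclusions: Path | None = None
    cds: Path | None = None
    gene_models: Path | None = None
    msa: Path | None = None
    anchors: dict = field(default_factory=dict)
    outgroups: list[str] = field(default_factory=list)
    strong: float = 90.0
    member: float = 80.0
    intron_window: int = 2
    neb_levels: tuple[float, float] = (0.95, 0.99)
    bootstrap: int = 1000
    seed: int = 1
    selection_models: list[str] = field(
        default_factory=lambda: list(selection.MODEL_NAMES)
    )
    selection_enabled: bool = True

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        inputs = raw.get("inputs", {})
        thresholds = raw.get("thresholds", {})
        sel = raw.get("selection", {})
        cfg = cls(
            proteins=Path(inputs["proteins"]),
            out_dir=Path(raw.get("out_dir", "peroxevol_out")),
            signal_peptides=_opt_path(inputs.get("signal_peptides")),
            exclusions=_opt_path(inputs.get("exclusions")),
            cds=_opt_path(inputs.get("cds")),
            gene_models=_opt_path(inputs.get("gene_models")),
            msa=_opt_path(inputs.get("msa")),
            anchors=raw.get("anchors", {}),
            outgroups=list(raw.get("outgroups", [])),
            strong=float(thresholds.get("strong", 90)),
            member=float(thresholds.get("member", 80)),
            intron_window=int(thresholds.get("intron_window", 2)),
            neb_levels=tuple(thresholds.get("neb_levels", (0.95, 0.99))),
            bootstrap=int(raw.get("bootstrap", 1000)),
            seed=int(raw.get("seed", 1)),
            selection_models=list(sel.get("models", selection.MODEL_NAMES)),
            selection_enabled=bool(sel.get("enabled", True)),
        )
        cfg.validate()
        return cfg

    def validate(self) -> None:
        if not self.proteins.exists():
            raise PipelineError(f"config: proteins path {self.proteins} missing")
        for name in ("signal_peptides", "exclusions", "cds", "gene_models", "msa"):
            p = getattr(self, name)
            if p is not None and not p.exists():
                raise PipelineError(f"config: {name} path {p} missing")
        if not (0 < self.member <= self.strong <= 100):
            raise PipelineError("config: need 0 < member <= strong <= 100")
        if self.intron_window < 0 or self.bootstrap < 1:
            raise PipelineError("config: bad thresholds")
        for lv in self.neb_levels:
            if not (0 < lv < 1):
                raise PipelineError("config: NEB levels must be in (0, 1)")


def _opt_path(value) -> Path | None:
    return Path(value) if value else None


def _build_anchors(cfg: RunConfig) -> lp_typing.ResidueAnchors:
    a = cfg.anchors
    mn_ref = a["mn_reference"]
    trp_ref = a.get("trp_reference", mn_ref)
    heme_ref = a.get("heme_reference", mn_ref)
    mn_pos = a.get("mn_positions", (35, 39, 179))
    trp_pos = a.get("trp_position", 171)
    heme_pos = a.get("heme_positions", (47, 176))
    A = lp_typing.AnchorSite
    return lp_typing.ResidueAnchors(
        mn_site=(
            A(mn_ref, mn_pos[0], "E"),
            A(mn_ref, mn_pos[1], "E"),
            A(mn_ref, mn_pos[2], "D"),
        ),
        trp_site=A(trp_ref, trp_pos, "W"),
        heme_site=(
            A(heme_ref, heme_pos[0], "H"),
            A(heme_ref, heme_pos[1], "H"),
        ),
    )


def run_pipeline(cfg: RunConfig) -> dict[str, Any]:
    """Execute all stages; return (and write) the JSON manifest.

    A stage failure raises :class:`PipelineError` naming the stage after
    persisting the manifest accumulated so far.
    """
    out = cfg.out_dir
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict[str, Any] = {"seed": cfg.seed, "stages": {}, "outputs": {}}

    def finish_stage(name: str, **info) -> None:
        manifest["stages"][name] = {"status": "ok", **info}

    def skip_stage(name: str, reason: str) -> None:
        logger.info("stage %s skipped: %s", name, reason)
        manifest["stages"][name] = {"status": "skipped", "reason": reason}

    def persist() -> None:
        with open(out / "manifest.json", "w") as fh:
            json.dump(manifest, fh, indent=2, default=_jsonable)

    current = "curation"
    try:
        # -- curation -----------------------------------------------------
        records = seqcore.read_fasta(cfg.proteins)
        n_in = len(records)
        excluded: list[str] = []
        if cfg.exclusions:
            flags = seqcore.read_exclusions(cfg.exclusions)
            excluded = [r.id for r in records if r.id in flags]
            records = [r for r in records if r.id not in flags]
        sp_table = (
            seqcore.read_signal_peptides(cfg.signal_peptides)
            if cfg.signal_peptides else {}
        )
        mature = [
            seqcore.strip_signal_peptide(r, sp_table.get(r.id, 0))
            for r in records
        ]
        kept, dropped = seqcore.dedupe_within_species(mature)
        assert n_in == len(kept) + len(dropped) + len(excluded)
        finish_stage(
            "curation", n_input=n_in, n_excluded=len(excluded),
            n_duplicates=len(dropped), n_kept=len(kept),
            dropped=[(r.id, reason) for r, reason in dropped],
        )

        # -- alignment ----------------------------------------------------
        current = "alignment"
        if cfg.msa:
            msa = phylo.Msa.from_fasta(cfg.msa)
            msa = msa.subset([r.id for r in kept if r.id in msa.rows])
            source = "provided"
        else:
            msa = phylo.align_progressive(kept)
            source = "built-in progressive aligner"
        n_col, n_inf = phylo.count_informative(msa)
        msa.to_fasta(out / "alignment.fasta")
        manifest["outputs"]["alignment"] = str(out / "alignment.fasta")
        finish_stage("alignment", source=source, n_col=n_col,
                     n_informative=n_inf, n_rows=len(msa.ids))

        # -- typing -------------------------------------------------------
        current = "typing"
        if not cfg.anchors.get("mn_reference"):
            skip_stage("typing", "no anchor configuration")
            calls = {}
            orders = {r.id: r.order for r in kept}
        else:
            anchors = _build_anchors(cfg)
            kept_ids, discarded = lp_typing.heme_filter(msa, anchors)
            assert len(msa.ids) == len(kept_ids) + len(discarded)
            msa = msa.subset(kept_ids)
            type_calls = lp_typing.classify_all(
                msa, anchors, conservative=bool(cfg.anchors.get("conservative"))
            )
            calls = {c.id: c.call for c in type_calls}
            orders = {r.id: r.order for r in kept}
            census = lp_typing.type_census(
                [c for c in type_calls if c.id in orders], orders
            )
            census.to_csv(out / "type_census.tsv", sep="\t")
            manifest["outputs"]["type_census"] = str(out / "type_census.tsv")
            finish_stage(
                "typing",
                n_discarded_heme=len(discarded),
                discarded=[list(x) for x in discarded],
                counts={t: int(census.loc[t, "total"]) for t in census.index},
            )

        # -- phylogeny ----------------------------------------------------
        current = "phylogeny"
        tree = phylo.bootstrap_support(msa, n_reps=cfg.bootstrap, seed=cfg.seed)
        with open(out / "nj_tree.nwk", "w") as fh:
            fh.write(tree.to_newick() + "\n")
        manifest["outputs"]["tree"] = str(out / "nj_tree.nwk")
        groups = phylo.delineate_groups(
            tree, calls, orders, strong=cfg.strong, member=cfg.member,
            exclude=cfg.outgroups,
        )
        finish_stage(
            "phylogeny", bootstrap=cfg.bootstrap,
            groups={k: v for k, v in groups.groups.items()},
            supports=groups.supports, separate=groups.separate,
        )

        # -- gene structure -----------------------------------------------
        current = "gene_structure"
        if not cfg.gene_models:
            skip_stage("gene_structure", "no gene models provided")
        else:
            gene_models = seqcore.read_gene_models_tsv(cfg.gene_models)
            sp_by_id = {r.id: r.sp_len for r in records}
            mapped = []
            n_introns = 0
            for gid, gm in sorted(gene_models.items()):
                if gid not in msa.rows:
                    logger.info("gene model %s has no aligned row; skipped", gid)
                    continue
                for intron in genestruct.introns_from_gene_model(gm):
                    n_introns += 1
                    mapped.append(
                        genestruct.map_intron_to_alignment(
                            intron, msa, gid, sp_len=sp_by_id.get(gid, 0)
                        )
                    )
            clusters = genestruct.cluster_homologous_introns(
                mapped, window=cfg.intron_window
            )
            gene_ids = [g for g in sorted(gene_models) if g in msa.rows]
            group_of = {
                m: name for name, ms in groups.groups.items() for m in ms
            }
            matrix = genestruct.intron_matrix(clusters, gene_ids, group_of)
            matrix.to_csv(out / "intron_matrix.tsv", sep="\t", na_rep=".")
            manifest["outputs"]["intron_matrix"] = str(out / "intron_matrix.tsv")
            report = genestruct.shared_intron_report(matrix, group_of)
            finish_stage(
                "gene_structure", n_genes=len(gene_ids), n_introns=n_introns,
                n_clusters=len(clusters),
                labels=[c.label for c in clusters],
                private=[l for l, r in report.items() if r["private"]],
                universal=[l for l, r in report.items() if r["universal"]],
            )

        # -- selection ----------------------------------------------------
        current = "selection"
        if not (cfg.cds and cfg.selection_enabled):
            skip_stage("selection", "no coding sequences provided"
                       if not cfg.cds else "disabled in config")
        else:
            cds = seqcore.read_cds_fasta(cfg.cds)
            ingroup = [i for i in msa.ids if i not in cfg.outgroups and i in cds]
            caln = selection.build_codon_alignment(msa.subset(ingroup), cds)
            sel_tree = _prune_to(tree, ingroup)
            fits, lrts = selection.fit_all_models(
                caln, sel_tree, models=cfg.selection_models
            )
            verdict = selection.positive_selection_decision(fits, lrts)
            fit_rows = {
                name: {
                    "lnl": f.lnl, "kappa": f.kappa,
                    "class_omegas": f.class_omegas.tolist(),
                    "class_probs": f.class_probs.tolist(),
                }
                for name, f in fits.items()
            }
            with open(out / "selection_fits.json", "w") as fh:
                json.dump(fit_rows, fh, indent=2)
            manifest["outputs"]["selection_fits"] = str(out / "selection_fits.json")
            for name, f in fits.items():
                tbl = selection.neb_sites(f, levels=cfg.neb_levels)
                if len(tbl):
                    tbl.to_csv(out / f"neb_{name}.tsv", sep="\t", index=False)
            finish_stage(
                "selection", n_sites=caln.L, models=list(fits),
                lnl={k: f.lnl for k, f in fits.items()},
                lrts={
                    k: {"stat": r.stat, "df": r.df, "p": r.p}
                    for k, r in lrts.items()
                },
                verdict={"positive": verdict.positive,
                         "ensured_by": verdict.ensured_by},
            )
    except Exception as exc:
        manifest["stages"][current] = {"status": "failed", "error": str(exc)}
        persist()
        raise PipelineError(f"stage {current!r} failed: {exc}") from exc

    persist()
    return manifest


def _prune_to(tree: phylo.Tree, keep: list[str]) -> phylo.Tree:
    """Restriction of a tree to a leaf subset (supports dropped)."""
    import dendropy

    dt = dendropy.Tree.get(data=tree.to_newick(support_labels=False),
                           schema="newick")
    taxa = [t for t in dt.taxon_namespace if t.label.replace(" ", "_") in keep]
    dt.retain_taxa(taxa)
    return phylo.Tree.from_newick(dt.as_string(schema="newick"))


def _jsonable(obj):
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, Path):
        return str(obj)
    raise TypeError(f"not JSON-serializable: {type(obj)}")


def census_report(manifest: dict[str, Any]) -> str:
    """Human-readable summary of a pipeline manifest."""
    if not manifest or "stages" not in manifest:
        raise PipelineError("empty or malformed manifest")
    lines: list[str] = []
    st = manifest["stages"]
    if "curation" in st and st["curation"]["status"] == "ok":
        c = st["curation"]
        lines.append(
            f"Curation: {c['n_input']} in, {c['n_excluded']} excluded, "
            f"{c['n_duplicates']} within-species duplicates, "
            f"{c['n_kept']} kept"
        )
    if "typing" in st and st["typing"].get("status") == "ok":
        t = st["typing"]
        counts = ", ".join(f"{k}: {v}" for k, v in sorted(t["counts"].items()))
        lines.append(f"Typing: {counts} "
                     f"({t['n_discarded_heme']} failed the heme filter)")
    if "phylogeny" in st and st["phylogeny"]["status"] == "ok":
        p = st["phylogeny"]
        for name, members in p["groups"].items():
            sup = p["supports"].get(name, {})
            sups = ", ".join(f"{m} {v:.0f}%" for m, v in sup.items())
            lines.append(f"Group {name}: {len(members)} members ({sups})")
        if p["separate"]:
            lines.append("Separate LPs: " + ", ".join(p["separate"]))
    if "gene_structure" in st and st["gene_structure"].get("status") == "ok":
        g = st["gene_structure"]
        lines.append(
            f"Gene structure: {g['n_introns']} introns in {g['n_genes']} "
            f"genes -> {g['n_clusters']} positions "
            f"({g['labels'][0]}..{g['labels'][-1]}); "
            f"private: {', '.join(g['private']) or 'none'}; "
            f"universal: {', '.join(g['universal']) or 'none'}"
        )
    if "selection" in st and st["selection"].get("status") == "ok":
        s = st["selection"]
        v = s["verdict"]
        verdict = (
            "positive selection ensured by " + ", ".join(v["ensured_by"])
            if v["positive"] else "positive selection rejected"
        )
        lines.append(f"Selection ({s['n_sites']} codon sites): {verdict}")
    for name, info in st.items():
        if info["status"] == "skipped":
            lines.append(f"[{name} skipped: {info['reason']}]")
    return "\n".join(lines)
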