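"""The composed end-to-end run: simulate -> classify -> associate -> co-occupancy
-> super-enhancers -> fold changes -> report.

Every stage reads its inputs from files on disk (the simulation stage
writes them first), so a run is reproducible from its manifest alone and
a missing input fails with a stage-labelled validation error. All
randomness flows from the single run seed. Outputs are plain TSV/BED/JSON
with parameters echoed in header comments; re-running with the same
configuration yields byte-identical files.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass
from pathlib import Path

from . import __version__
from .activity import classify_activity, grade_peaks_vs_signature
from .cooccupancy import (
    classify_se_binding,
    categorize_gene_list,
    gene_venn,
    share_peaks,
)
from .core import (
    PeakSet,
    read_bed,
    read_gene_table,
    read_genome,
    write_bed,
    write_gene_table,
    write_genome,
)
from .errors import ValidationError
from .gene_association import (
    associate,
    associated_gene_ids,
    build_domains,
    restrict_to_active,
)
from .simulate import (
    SimulationConfig,
    simulate_enhancer_tags,
    simulate_genome_and_genes,
    simulate_knockdown,
    simulate_peaks,
)
from .stats import classify_fold_changes
from .superenhancer import DEFAULT_STITCH_GAP, build_stitched, call_superenhancers, export_curve

__all__ = ["RunConfig", "run_pipeline", "render_report"]

INPUT_FILES = (
    "genome.sizes",
    "genes.tsv",
    "tf_a.bed",
    "tf_b.bed",
    "k27ac.bed",
    "p300.bed",
    "k4me1.bed",
    "enhancers.bed",
    "expression.tsv",
)


@dataclass(frozen=True)
class RunConfig:
    outdir: str
    seed: int = 0
    sim: SimulationConfig | None = None  # defaults to SimulationConfig(seed=seed)
    flank_max: int | None = None  # None: use the simulation's ground-truth value
    stitch_gap: int = DEFAULT_STITCH_GAP
    input_dir: str | None = None  # reuse existing inputs instead of simulating

    def resolved_sim(self) -> SimulationConfig:
        return self.sim if self.sim is not None else SimulationConfig(seed=self.seed)


def _stage(name: str):
    def wrap(exc: Exception) -> Exception:
        exc.args = (f"[{name}] {exc.args[0] if exc.args else exc}",) + exc.args[1:]
        return exc

    return wrap


def _require(path: Path, stage: str) -> Path:
    if not path.exists():
        raise ValidationError(f"[{stage}] missing input file: {path}")
    return path


def run_pipeline(cfg: RunConfig) -> dict:
    """Run every stage; return the report bundle (also written to outdir)."""
    outdir = Path(cfg.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []
    try:
        return _run(cfg, outdir, written)
    except Exception:
        for p in written:  # no partial outputs
            p.unlink(missing_ok=True)
        raise


def _run(cfg: RunConfig, outdir: Path, written: list[Path]) -> dict:
    sim = cfg.resolved_sim()
    flank_max = cfg.flank_max if cfg.flank_max is not None else sim.flank_max

    # --- stage: simulate (or reuse input directory) ----------------------
    if cfg.input_dir is None:
        indir = outdir / "inputs"
        indir.mkdir(exist_ok=True)
        genome, genes = simulate_genome_and_genes(sim)
        peak_sets, peak_truth = simulate_peaks(sim, genes)
        enhancers, planted_se = simulate_enhancer_tags(sim)
        control, knockdown, planted_dep = simulate_knockdown(sim, genes)
        write_genome(genome, indir / "genome.sizes")
        write_gene_table(genes, indir / "genes.tsv")
        for key in ("tf_a", "tf_b", "k27ac", "p300", "k4me1"):
            write_bed(peak_sets[key], indir / f"{key}.bed")
        write_bed(enhancers, indir / "enhancers.bed")
        with open(indir / "expression.tsv", "w") as fh:
            fh.write("gene_id\tcontrol\tknockdown\n")
            for gid in control:
                fh.write(f"{gid}\t{control[gid]:.6g}\t{knockdown[gid]:.6g}\n")
        truth = {
            "peaks": [dataclasses.asdict(t) for t in peak_truth],
            "planted_super": sorted(planted_se),
            "planted_dependent": sorted(planted_dep),
        }
        (indir / "truth.json").write_text(json.dumps(truth, indent=1, sort_keys=True))
    else:
        indir = Path(cfg.input_dir)

    # --- stage: load inputs ----------------------------------------------
    genome = read_genome(_require(indir / "genome.sizes", "load"))
    genes = read_gene_table(_require(indir / "genes.tsv", "load"), genome)
    sets = {
        name: read_bed(_require(indir / f"{name}.bed", "load"), genome, label=name)
        for name in ("tf_a", "tf_b", "k27ac", "p300", "k4me1")
    }
    enhancers = read_bed(_require(indir / "enhancers.bed", "load"), genome, "enhancers")
    expr_path = _require(indir / "expression.tsv", "load")
    control, knockdown = {}, {}
    for line in expr_path.read_text().splitlines()[1:]:
        gid, c, k = line.split("\t")
        control[gid], knockdown[gid] = float(c), float(k)

    def out(name: str) -> Path:
        p = outdir / name
        written.append(p)
        return p

    bundle: dict = {"parameters": {
        "seed": cfg.seed, "flank_max": flank_max, "stitch_gap": cfg.stitch_gap,
        "version": __version__,
    }}

    # --- stage: activity --------------------------------------------------
    try:
        calls_a = classify_activity(sets["tf_a"], sets["k27ac"], flank_max)
        calls_b = classify_activity(sets["tf_b"], sets["k27ac"], flank_max)
    except ValidationError as e:
        raise _stage("activity")(e)
    header = f"flank_max={flank_max}"
    with open(out("activity_tf_a.tsv"), "w") as fh:
        fh.write(f"#{header}\npeak\tchrom\tstart\tend\tstatus\tleft_gap\tright_gap\n")
        for c in calls_a:
            fh.write(
                f"{c.peak.name or '.'}\t{c.peak.chrom}\t{c.peak.start}\t{c.peak.end}"
                f"\t{c.status}\t{'' if c.left_gap is None else c.left_gap}"
                f"\t{'' if c.right_gap is None else c.right_gap}\n"
            )
    active_a = restrict_to_active(sets["tf_a"], calls_a)
    active_b = restrict_to_active(sets["tf_b"], calls_b)
    write_bed(active_a, out("active_tf_a.bed"), header=header)
    n_active = sum(1 for c in calls_a if c.active)
    bundle["activity"] = {
        "n_peaks": len(sets["tf_a"]),
        "n_active": n_active,
        "active_fraction": n_active / len(sets["tf_a"]),
    }

    # --- stage: enhancer signature grading --------------------------------
    try:
        fractions, _ = grade_peaks_vs_signature(
            sets["tf_a"], sets["p300"], sets["k4me1"], flank_max
        )
    except ValidationError as e:
        raise _stage("signature")(e)
    bundle["signature_fractions"] = fractions

    # --- stage: peak sharing ----------------------------------------------
    try:
        shared_a, share_summary = share_peaks(sets["tf_a"], sets["tf_b"])
    except ValidationError as e:
        raise _stage("share")(e)
    bundle["sharing"] = {
        "n_query": share_summary.n_query,
        "n_hit": share_summary.n_hit,
        "percent": share_summary.percent,
    }

    # --- stage: gene association ------------------------------------------
    try:
        domains = build_domains(genes, genome)
        assoc_a = associate(active_a, domains, genes)
        assoc_b = associate(active_b, domains, genes)
        shared_calls = classify_activity(shared_a, sets["k27ac"], flank_max)
        active_shared = restrict_to_active(shared_a, shared_calls)
        assoc_shared = associate(active_shared, domains, genes)
    except ValidationError as e:
        raise _stage("associate")(e)
    genes_a = associated_gene_ids(assoc_a)
    genes_b = associated_gene_ids(assoc_b)
    genes_shared = associated_gene_ids(assoc_shared)
    with open(out("associations_active_tf_a.tsv"), "w") as fh:
        fh.write("#basal_up=5000 basal_down=1000 max_ext=100000\npeak\tgene_id\tdistance\n")
        for r in assoc_a:
            fh.write(
                f"{r.peak_name}\t{r.gene_id or '.'}"
                f"\t{'' if r.distance is None else r.distance}\n"
            )
    venn = gene_venn(genes_a, genes_b)
    out("gene_venn.json").write_text(json.dumps(venn, indent=1, sort_keys=True))
    bundle["gene_venn"] = venn

    # --- stage: gene-list categorization ----------------------------------
    panel_ids = list(control)
    _, cat_summary = categorize_gene_list(panel_ids, genes_a, genes_b, genes_shared)
    bundle["gene_categories"] = cat_summary

    # --- stage: super-enhancers -------------------------------------------
    try:
        stitched = build_stitched(enhancers, cfg.stitch_gap)
        se_result = call_superenhancers(stitched)
        _, se_summary = classify_se_binding(list(se_result.super), sets["tf_a"], sets["tf_b"])
    except ValidationError as e:
        raise _stage("superenhancer")(e)
    se_header = f"stitch_gap={cfg.stitch_gap}"
    write_bed(
        [dataclasses.replace(e.span, name=f"SE_rank{i + 1}", score=e.tag_count)
         for i, e in enumerate(reversed(se_result.super))],
        out("superenhancers.bed"),
        header=se_header,
    )
    with open(out("se_curve.tsv"), "w") as fh:
        fh.write(f"#{se_header}\nnormalized_rank\tnormalized_score\n")
        for x, y in export_curve(se_result):
            fh.write(f"{x:.6f}\t{y:.6f}\n")
    bundle["superenhancers"] = {
        "n_stitched": len(stitched),
        "n_super": len(se_result.super),
        "binding": se_summary,
    }

    # --- stage: fold changes ----------------------------------------------
    records = classify_fold_changes(knockdown, control)
    n_dep = sum(r.dependent for r in records)
    with open(out("fold_changes.tsv"), "w") as fh:
        fh.write("#down_thr=0.7 up_thr=1.25 window=0.2-0.55\ngene_id\tfc\tclass\tdependent\n")
        for r in records:
            fc = "" if r.fc is None else f"{r.fc:.4f}"
            fh.write(f"{r.gene_id}\t{fc}\t{r.cls}\t{int(r.dependent)}\n")
    bundle["fold_changes"] = {
        "n_panel": len(records),
        "n_dependent": n_dep,
        "n_decreased": sum(r.cls == "decreased" for r in records),
        "n_increased": sum(r.cls == "increased" for r in records),
    }

    # --- stage: manifest + report ----------------------------------------
    try:  # record paths relative to the run directory so runs are comparable
        indir_str = str(indir.relative_to(outdir))
    except ValueError:
        indir_str = str(indir)
    manifest = {
        "version": __version__,
        "seed": cfg.seed,
        "parameters": bundle["parameters"],
        "simulation": dataclasses.asdict(sim) if cfg.input_dir is None else None,
        "input_dir": indir_str,
        "inputs": [f"{indir_str}/{f}" for f in INPUT_FILES],
        "stages": [
            "simulate" if cfg.input_dir is None else "load",
            "activity", "signature", "share", "associate",
            "categorize", "superenhancer", "fold_changes", "report",
        ],
        "outputs": [p.name for p in written],
    }
    out("manifest.json").write_text(json.dumps(manifest, indent=1, sort_keys=True))
    bundle["manifest"] = manifest
    out("report.md").write_text(render_report(bundle))
    return bundle


def render_report(bundle: dict) -> str:
    """One-page markdown summary of the headline numbers of a run."""
    act = bundle["activity"]
    sh = bundle["sharing"]
    se = bundle["superenhancers"]
    fc = bundle["fold_changes"]
    venn = bundle["gene_venn"]
    sig = bundle["signature_fractions"]
    lines = [
        "# Co-occupancy pipeline report",
        "",
        f"Package version {bundle['parameters']['version']}, "
        f"seed {bundle['parameters']['seed']}.",
        "",
        "## Peak sharing",
        f"- {sh['n_hit']} of {sh['n_query']} TF-A peaks are shared with TF-B "
        f"(>=1 bp): {sh['percent']}%",
        "",
        "## Activity",
        f"- {act['n_active']} of {act['n_peaks']} TF-A peaks are active "
        f"({100 * act['active_fraction']:.1f}%)",
        f"- enhancer signature grading: {100 * sig['full']:.1f}% full, "
        f"{100 * sig['partial']:.1f}% partial",
        "",
        "## Gene-level co-association",
        f"- genes with active TF-A peaks also hit by TF-B: "
        f"{venn['both']} (A-only {venn['a_only']}, B-only {venn['b_only']})",
        "",
        "## Super-enhancers",
    ]
    if se["n_super"] == 0:
        lines.append("- zero super-enhancers called on this input")
    else:
        lines.append(
            f"- {se['n_super']} super-enhancers among {se['n_stitched']} "
            f"stitched enhancers; {se['binding']['both']} bound by both factors"
        )
    lines += [
        "",
        "## Knockdown panel",
        f"- {fc['n_dependent']} of {fc['n_panel']} panel genes fall in the "
        "0.2-0.55 dependence window",
        f"- {fc['n_decreased']} decreased (<=0.7), {fc['n_increased']} "
        "increased (>=1.25)",
        "",
    ]
    return "\n".join(lines)
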