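"""End-to-end orchestration: simulate → fit → screen → converge → enrich.

A :class:`RunConfig` names the inputs (per-gene codon alignments, species
tree, foreground taxon list, group spec, domain table, annotation map) and
the analysis options; :func:`run_selection` and :func:`run_convergence`
execute the two screens with per-gene fault isolation and write plain-text
artifacts (JSON per gene, TSV summaries). Everything is deterministic given
the config and seed.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass
from pathlib import Path

import yaml

from . import convergence as conv
from . import screen as scr
from .enrich import enrichment_test
from .model import CodonModel
from .seqio import CodonAlignment, SpeciesTree, read_fasta

__all__ = ["RunConfig", "run_selection", "run_convergence", "run_enrichment",
           "generate_demo"]


@dataclass
class RunConfig:
    alignments_dir: str
    tree_path: str
    foreground_path: str
    output_dir: str
    groups_path: str | None = None
    domains_path: str | None = None
    annotation_path: str | None = None
    freq_model: str = "F3x4"
    alpha: float = 0.05
    posterior_threshold: float = 0.95
    ccs_mode: str = "identity"
    min_background_identity: float = 1.0
    fit_starts: int = 2
    seed: int = 0

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text())
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config fields: {sorted(unknown)}")
        return cls(**data)

    def validate(self, need_groups: bool = False) -> None:
        errors = []
        if not 0 < self.alpha < 1:
            errors.append(f"alpha must be in (0,1), got {self.alpha}")
        if not 0 < self.posterior_threshold <= 1:
            errors.append(
                f"posterior_threshold must be in (0,1], got {self.posterior_threshold}"
            )
        for name in ("alignments_dir", "tree_path", "foreground_path"):
            p = getattr(self, name)
            if not Path(p).exists():
                errors.append(f"{name}: path does not exist: {p}")
        if need_groups:
            if self.groups_path is None:
                errors.append("groups_path is required for the convergence screen")
            elif not Path(self.groups_path).exists():
                errors.append(f"groups_path: path does not exist: {self.groups_path}")
        for name in ("domains_path", "annotation_path"):
            p = getattr(self, name)
            if p is not None and not Path(p).exists():
                errors.append(f"{name}: path does not exist: {p}")
        if errors:
            raise ValueError("invalid configuration:\n  " + "\n  ".join(errors))


def _gene_alignments(directory) -> dict[str, Path]:
    paths = sorted(
        p for p in Path(directory).iterdir()
        if p.suffix in (".fa", ".fasta", ".fna")
    )
    return {p.stem: p for p in paths}


def _read_taxon_list(path) -> list[str]:
    return [ln.strip() for ln in Path(path).read_text().splitlines() if ln.strip()]


def load_groups(path) -> conv.GroupSpec:
    data = yaml.safe_load(Path(path).read_text())
    if not data.get("in_list"):
        raise ValueError("groups file: in_list must be nonempty")
    if not data.get("on_list"):
        raise ValueError("groups file: on_list must be nonempty")
    return conv.GroupSpec(
        in_list=frozenset(data["in_list"]),
        on_list=frozenset(data["on_list"]),
        outgroup=frozenset(data.get("outgroup", ())),
    )


def run_selection(config: RunConfig) -> dict:
    """Branch-site PSG screen and branch-model REG screen over all genes.

    Per gene: fit one-ratio (M0) and two-ratio branch models, branch-site
    Model A and its null, run both LRTs, and apply the PSG site filters and
    the REG rate comparison. One failing alignment is recorded and skipped,
    never fatal. Returns the summary dict that is also written to
    ``summary_selection.tsv`` / per-gene JSONs under ``genes/``.
    """
    config.validate()
    out = Path(config.output_dir)
    (out / "genes").mkdir(parents=True, exist_ok=True)
    foreground = _read_taxon_list(config.foreground_path)
    genes = _gene_alignments(config.alignments_dir)
    if not genes:
        raise ValueError(f"no alignments found in {config.alignments_dir}")
    psg_calls, reg_calls, errors = [], [], {}
    rows = []
    for gene, path in genes.items():
        try:
            aln = CodonAlignment.from_fasta(path)
            tree = SpeciesTree.from_newick(
                Path(config.tree_path).read_text(), foreground_taxa=foreground
            )
            model = CodonModel(aln, tree, freq=config.freq_model)
            fit_m0 = model.fit("M0", starts=config.fit_starts, seed=config.seed)
            fit_branch = model.fit("branch", starts=config.fit_starts, seed=config.seed)
            fit_bs0 = model.fit("branch-site-null", starts=config.fit_starts, seed=config.seed)
            fit_bs = model.fit("branch-site", starts=config.fit_starts, seed=config.seed)
            bs_lrt = fit_bs.lrt(fit_bs0, df=1)
            posteriors = fit_bs.site_posteriors()["posterior"].tolist()
            psg = scr.filter_psg(
                gene, bs_lrt, posteriors, aln.n_codons,
                alpha=config.alpha,
                posterior_threshold=config.posterior_threshold,
            )
            reg = scr.call_reg(gene, fit_m0, fit_branch, alpha=config.alpha)
            psg_calls.append(psg)
            reg_calls.append(reg)
            record = {
                "gene": gene,
                "fits": {
                    f.model_name: {
                        "lnL": f.lnL, "params": f.params,
                        "converged": f.converged, "n_iter": f.n_iter,
                    }
                    for f in (fit_m0, fit_branch, fit_bs0, fit_bs)
                },
                "psg": _call_dict(psg),
                "reg": _call_dict(reg),
            }
            (out / "genes" / f"{gene}.json").write_text(
                json.dumps(record, indent=1, sort_keys=True)
            )
            rows.append(
                (gene, psg.verdict, f"{psg.lrt.p:.6g}",
                 ";".join(psg.reject_reasons) or ".",
                 reg.verdict, f"{reg.lrt.p:.6g}",
                 ";".join(reg.reject_reasons) or ".")
            )
        except Exception as exc:  # fault isolation per gene
            errors[gene] = f"{type(exc).__name__}: {exc}"
            rows.append((gene, "error", ".", str(exc)[:80], "error", ".", "."))
    overlap = scr.intersect_calls(psg_calls, reg_calls)
    summary = {
        "n_genes": len(genes),
        "n_psg": sum(c.verdict == "PSG" for c in psg_calls),
        "n_reg": sum(c.verdict == "REG" for c in reg_calls),
        "psg_genes": sorted(c.gene_id for c in psg_calls if c.verdict == "PSG"),
        "reg_genes": sorted(c.gene_id for c in reg_calls if c.verdict == "REG"),
        "overlap_genes": overlap,
        "errors": errors,
    }
    header = (
        "# selection screen summary (alpha=%g, posterior>=%g, freq=%s, seed=%d)\n"
        % (config.alpha, config.posterior_threshold, config.freq_model, config.seed)
        + "gene\tpsg_verdict\tpsg_p\tpsg_reasons\treg_verdict\treg_p\treg_reasons\n"
    )
    (out / "summary_selection.tsv").write_text(
        header + "".join("\t".join(r) + "\n" for r in rows)
    )
    (out / "summary_selection.json").write_text(json.dumps(summary, indent=1))
    return summary


def _call_dict(call: scr.SelectionCall) -> dict:
    return {
        "verdict": call.verdict,
        "p": call.lrt.p,
        "stat": call.lrt.stat,
        "reasons": call.reject_reasons,
        "candidate_sites": call.candidate_sites,
        "params": call.params,
    }


def run_convergence(config: RunConfig) -> dict:
    """Convergent-substitution screen over translated gene alignments."""
    config.validate(need_groups=True)
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    groups = load_groups(config.groups_path)
    genes = _gene_alignments(config.alignments_dir)
    alignments = {}
    for gene, path in genes.items():
        aln = CodonAlignment.from_fasta(path)
        alignments[gene] = aln.to_protein()
    domain_table = None
    if config.domains_path:
        import pandas as pd

        domain_table = pd.read_csv(config.domains_path, sep="\t")
    sites_by_gene, counts = conv.screen_gene_set(
        alignments, groups,
        domain_table=domain_table,
        min_background_identity=config.min_background_identity,
        ccs_mode=config.ccs_mode,
    )
    lines = [
        "# convergence screen (ccs_mode=%s, min_identity=%g)"
        % (config.ccs_mode, config.min_background_identity),
        "gene\tposition\tref_position\tin_residue\ton_residues\tconservation"
        "\tin_domain\tdomain\tproperty_change",
    ]
    for gene in sorted(sites_by_gene):
        for s in sites_by_gene[gene]:
            lines.append(
                "\t".join(
                    [
                        gene,
                        str(s.position),
                        str(s.ref_position or "."),
                        s.in_residue,
                        "".join(s.on_residues),
                        f"{s.conservation_fraction:.3f}",
                        str(bool(s.in_domain)),
                        s.domain_name or ".",
                        s.property_change.label if s.property_change else ".",
                    ]
                )
            )
    (out / "convergent_sites.tsv").write_text("\n".join(lines) + "\n")
    result = {"stage_counts": counts,
              "genes": {g: len(s) for g, s in sites_by_gene.items()}}
    (out / "convergence_counts.json").write_text(json.dumps(result, indent=1))
    return result


def run_enrichment(config: RunConfig, gene_set, universe=None) -> list:
    """Chi-square enrichment of a gene set against the annotation map."""
    if config.annotation_path is None:
        raise ValueError("annotation_path is required for enrichment")
    annotation = {}
    for ln in Path(config.annotation_path).read_text().splitlines():
        if not ln.strip() or ln.startswith("#"):
            continue
        gene, cat = ln.split("\t")[:2]
        annotation.setdefault(gene, []).append(cat)
    if universe is None:
        universe = list(annotation)
    return enrichment_test(gene_set, universe, annotation)


# ---------------------------------------------------------------------------
# Demo dataset
# ---------------------------------------------------------------------------

DEMO_TREE = (
    "((((carn_A:0.08,carn_B:0.08):0.04,(carn_C:0.10,herb_D:0.10):0.02):0.04,"
    "(herb_E:0.12,herb_F:0.12):0.06):0.06,(herb_G:0.15,out_H:0.15):0.09):0.0;"
)
DEMO_FOREGROUND = ["carn_A", "carn_B", "carn_C"]


def _scale_newick(newick: str, factor: float) -> str:
    import re

    return re.sub(
        r":(\d+(?:\.\d+)?)",
        lambda m: f":{float(m.group(1)) * factor:g}",
        newick,
    )


def generate_demo(outdir, seed: int = 0, n_genes: int = 12, n_codons: int = 300):
    """Write a self-contained demo dataset with planted ground truth.

    Twelve synthetic genes on an 8-taxon tree: three carry positive
    selection on the carnivore branches at a handful of interior sites,
    two carry planted convergent substitutions, the rest evolve neutrally
    under purifying selection. Returns the planted-truth dict (also written
    as ``truth.json``).
    """
    from . import simulate as sim

    outdir = Path(outdir)
    (outdir / "alignments").mkdir(parents=True, exist_ok=True)
    (outdir / "tree.nwk").write_text(DEMO_TREE + "\n")
    (outdir / "foreground.txt").write_text("\n".join(DEMO_FOREGROUND) + "\n")
    selected_genes = [f"gene{i:02d}" for i in (1, 5, 9)]
    convergent_genes = [f"gene{i:02d}" for i in (3, 7)]
    truth = {"psg": selected_genes, "convergent": convergent_genes}
    genes = [f"gene{i:02d}" for i in range(1, n_genes + 1)]
    # interior, well-separated sites; scaled so shorter demo genes work too
    sel_positions = sorted(
        {min(n_codons - 1, max(2, round(p * n_codons / 300)))
         for p in (40, 90, 150, 210, 260)}
    )
    conv_position = min(n_codons - 1, max(2, round(71 * n_codons / 300)))
    for i, gene in enumerate(genes):
        tree = SpeciesTree.from_newick(DEMO_TREE, foreground_taxa=DEMO_FOREGROUND)
        cfg = sim.SimulationConfig(
            tree=tree, n_codons=n_codons, kappa=2.0,
            omega_background=0.2, omega_foreground=0.2,
            seed=seed * 1000 + i,
        )
        aln = sim.simulate_alignment(cfg)
        if gene in selected_genes:
            sel_cfg = dataclasses.replace(
                cfg, omega_foreground=8.0, shared_time_scale=True,
                seed=cfg.seed + 500000,
            )
            sel_aln = sim.simulate_alignment(sel_cfg)
            seqs = {t: list(aln.sequences[t]) for t in aln.taxa}
            for pos in sel_positions:
                for t in aln.taxa:
                    seqs[t][3 * (pos - 1): 3 * pos] = sel_aln.codon(t, pos)
            aln = CodonAlignment(aln.taxa, {t: "".join(s) for t, s in seqs.items()})
        if gene in convergent_genes:
            # convergent fixtures mimic strongly conserved proteins: a much
            # slower clock keeps all other columns clean of chance
            # convergence so the planted site is the whole signal
            slow = SpeciesTree.from_newick(
                _scale_newick(DEMO_TREE, 0.1), foreground_taxa=DEMO_FOREGROUND
            )
            aln = sim.simulate_alignment(
                dataclasses.replace(cfg, tree=slow, omega_background=0.05,
                                    omega_foreground=0.05)
            )
            background = set(tree.taxa) - set(DEMO_FOREGROUND)
            pos = conv_position
            aln = sim.conserve_background_columns(aln, background, [pos])
            shared = aln.codon(sorted(background)[0], pos)
            from .genetics import translate_codon

            target = "G" if translate_codon(shared) != "G" else "A"
            aln = sim.plant_convergent_substitutions(
                aln, DEMO_FOREGROUND, [(pos, target)]
            )
            truth.setdefault("convergent_sites", {})[gene] = [pos, target]
        aln.write(outdir / "alignments" / f"{gene}.fasta")
    groups = {
        "in_list": DEMO_FOREGROUND,
        "on_list": ["herb_D", "herb_E", "herb_F", "herb_G"],
        "outgroup": ["out_H"],
    }
    (outdir / "groups.yaml").write_text(yaml.safe_dump(groups))
    annotation, domains = sim.make_annotation_fixture(
        genes, [f"GO:{i:07d}" for i in range(1, 6)], seed=seed,
        enriched_category="GO:0000001", enriched_genes=selected_genes,
    )
    with open(outdir / "annotation.tsv", "w") as fh:
        for gene in genes:
            for cat in annotation[gene]:
                fh.write(f"{gene}\t{cat}\n")
    domains.to_csv(outdir / "domains.tsv", sep="\t", index=False)
    (outdir / "truth.json").write_text(json.dumps(truth, indent=1))
    (outdir / "config.yaml").write_text(
        yaml.safe_dump(
            {
                "alignments_dir": str(outdir / "alignments"),
                "tree_path": str(outdir / "tree.nwk"),
                "foreground_path": str(outdir / "foreground.txt"),
                "groups_path": str(outdir / "groups.yaml"),
                "domains_path": str(outdir / "domains.tsv"),
                "annotation_path": str(outdir / "annotation.tsv"),
                "output_dir": str(outdir / "results"),
                "seed": seed,
            }
        )
    )
    return truth
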