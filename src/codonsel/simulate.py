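"""Synthetic codon alignments, annotation maps and domain tables.

Alignments are evolved on a fixed rooted tree under the Goldman–Yang model,
with a branch-specific dN/dS on foreground lineages, so every downstream
stage of the selection and convergence screens can be exercised against
planted ground truth. The generator deliberately uses uniform codon
frequencies by default while the fitting side estimates F3x4 from the data,
so inference is never handed its own frequency model.

Reproducibility: one root :class:`numpy.random.SeedSequence` is split per
branch in deterministic preorder, so the codons simulated along one branch
do not depend on how sibling subtrees are processed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import genetics
from .model import (
    build_rate_matrix,
    stationary_mean_rate,
    transition_matrix,
    uniform_codon_freqs,
)
from .seqio import CodonAlignment, SpeciesTree

__all__ = [
    "SimulationConfig",
    "simulate_alignment",
    "plant_convergent_substitutions",
    "conserve_background_columns",
    "make_annotation_fixture",
]


@dataclass
class SimulationConfig:
    """Study conditions for one simulated gene.

    omega_background / omega_foreground are the dN/dS ratios applied on
    background and foreground branches; planted_sites lists (1-based codon
    position, target amino acid) pairs forced to identical substitutions on
    every foreground tip after the neutral evolution step.
    """

    tree: SpeciesTree
    n_codons: int
    kappa: float = 2.0
    omega_background: float = 0.2
    omega_foreground: float = 0.2
    codon_freqs: np.ndarray = field(default_factory=uniform_codon_freqs)
    planted_sites: list[tuple[int, str]] = field(default_factory=list)
    shared_time_scale: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_codons < 1:
            raise ValueError("n_codons must be positive")
        for name in ("kappa", "omega_background", "omega_foreground"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be strictly positive")
        pi = np.asarray(self.codon_freqs, dtype=float)
        if pi.shape != (genetics.N_CODONS,) or abs(pi.sum() - 1.0) > 1e-12:
            raise ValueError("codon_freqs must be a distribution over the 61 sense codons")
        self.codon_freqs = pi
        seen = {}
        for pos, aa in self.planted_sites:
            if not 1 <= pos <= self.n_codons:
                raise ValueError(f"planted position {pos} outside [1, {self.n_codons}]")
            if pos in seen and seen[pos] != aa:
                raise ValueError(
                    f"conflicting target residues {seen[pos]}/{aa} planted at position {pos}"
                )
            seen[pos] = aa


def _branch_rng(seed: int, branch_id: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(branch_id,)))


def simulate_alignment(config: SimulationConfig) -> CodonAlignment:
    """Evolve a codon alignment along the tree; bit-reproducible per seed.

    The root sequence is drawn from ``codon_freqs``; each branch applies the
    transition matrix of the GY94 generator with that branch's dN/dS for its
    length. Stop codons never occur: the state space is the 61 sense codons.
    """
    tree = config.tree
    if tree.n_tips() < 3:
        raise ValueError("simulation tree must have at least 3 tips")
    pi = config.codon_freqs
    eff_pi = np.maximum(pi, 1e-12)
    eff_pi = eff_pi / eff_pi.sum()  # rate matrix needs full support
    # per-branch normalisation by default (branch lengths are expected
    # substitutions per codon on every branch); with shared_time_scale the
    # background process sets the clock and a foreground omega > 1 yields
    # genuinely faster foreground evolution, emulating a positively
    # selected site class of the branch-site mixture
    scale = None
    if config.shared_time_scale:
        scale = stationary_mean_rate(config.kappa, config.omega_background, eff_pi)
    Q = {
        False: build_rate_matrix(config.kappa, config.omega_background, eff_pi,
                                 scale=scale),
        True: build_rate_matrix(config.kappa, config.omega_foreground, eff_pi,
                                scale=scale),
    }

    root_rng = _branch_rng(config.seed, 0)
    root_states = root_rng.choice(genetics.N_CODONS, size=config.n_codons, p=pi)

    states: dict = {id(tree.tree.seed_node): root_states}
    tip_states: dict[str, np.ndarray] = {}
    branch_id = 0
    for node in tree.tree.preorder_node_iter():
        if node is tree.tree.seed_node:
            if node.is_leaf():
                raise ValueError("root cannot be a leaf")
            continue
        branch_id += 1
        bl = node.edge.length if node.edge.length is not None else 0.0
        if bl < 0:
            raise ValueError(f"negative branch length above {node}")
        parent_states = states[id(node.parent_node)]
        if bl == 0:
            child = parent_states.copy()
        else:
            is_fg = bool(getattr(node, "is_foreground", False))
            P = transition_matrix(Q[is_fg], eff_pi, bl)
            rng = _branch_rng(config.seed, branch_id)
            child = _evolve(parent_states, P, rng)
        states[id(node)] = child
        if node.is_leaf():
            tip_states[node.taxon.label] = child

    seqs = {
        taxon: "".join(genetics.CODONS[s] for s in tip_states[taxon])
        for taxon in tree.taxa
    }
    aln = CodonAlignment(list(tree.taxa), seqs)
    if config.planted_sites:
        background = set(tree.taxa) - set(tree.foreground_taxa)
        aln = conserve_background_columns(aln, background, [p for p, _ in config.planted_sites])
        aln = plant_convergent_substitutions(
            aln, tree.foreground_taxa, config.planted_sites
        )
    return aln


def _evolve(parent_states: np.ndarray, P: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Sample child codon states site by site, grouped by parent state."""
    child = np.empty_like(parent_states)
    # u-quantile sampling keeps draws independent of how sites are grouped
    u = rng.random(parent_states.size)
    cdf = np.cumsum(P, axis=1)
    for s in np.unique(parent_states):
        mask = parent_states == s
        child[mask] = np.searchsorted(cdf[s], u[mask], side="right")
    np.clip(child, 0, genetics.N_CODONS - 1, out=child)
    return child


def conserve_background_columns(aln: CodonAlignment, background: set[str], positions) -> CodonAlignment:
    """Force background taxa to one shared residue at the given codon columns.

    The majority background residue at the column wins; taxa already coding
    for it keep their codon (synonymous variation is left alone), others are
    rewritten to its canonical codon. Used to prepare conservative columns
    before planting convergent substitutions.
    """
    seqs = {t: list(aln.sequences[t]) for t in aln.taxa}
    for pos in positions:
        residues = [genetics.translate_codon(aln.codon(t, pos)) for t in sorted(background)]
        majority = max(sorted(set(residues)), key=residues.count)
        for t in sorted(background):
            if genetics.translate_codon(aln.codon(t, pos)) != majority:
                seqs[t][3 * (pos - 1) : 3 * pos] = genetics.CANONICAL_CODON[majority]
    return CodonAlignment(aln.taxa, {t: "".join(s) for t, s in seqs.items()})


def plant_convergent_substitutions(
    aln: CodonAlignment, foreground_taxa, planted_sites
) -> CodonAlignment:
    """Write an identical target residue into all foreground tips at each site.

    Every planted position must already be conservative in the background
    (one shared residue across all non-foreground taxa) and the target
    residue must differ from it; otherwise the plant is refused with the
    offending taxa listed. Only the planted columns of foreground sequences
    change.
    """
    planted_sites = list(planted_sites)
    if not planted_sites:
        return aln
    foreground = sorted(set(foreground_taxa))
    if not foreground:
        raise ValueError("no foreground taxa to plant substitutions on")
    background = [t for t in aln.taxa if t not in set(foreground)]
    targets: dict[int, str] = {}
    for pos, aa in planted_sites:
        aa = aa.upper()
        if pos in targets and targets[pos] != aa:
            raise ValueError(
                f"conflicting target residues {targets[pos]}/{aa} at position {pos}"
            )
        targets[pos] = aa
    seqs = {t: list(aln.sequences[t]) for t in aln.taxa}
    for pos, aa in sorted(targets.items()):
        bg_res = {t: genetics.translate_codon(aln.codon(t, pos)) for t in background}
        distinct = set(bg_res.values())
        if len(distinct) != 1:
            minority = min(distinct, key=lambda r: list(bg_res.values()).count(r))
            offenders = sorted(t for t, r in bg_res.items() if r == minority)
            raise ValueError(
                f"position {pos} is not conservative in the background "
                f"(residues {sorted(distinct)}; offending taxa {offenders})"
            )
        (shared,) = distinct
        if shared == aa:
            raise ValueError(
                f"target residue {aa} at position {pos} equals the conserved "
                f"background residue"
            )
        if aa not in genetics.CANONICAL_CODON:
            raise ValueError(f"cannot encode target residue {aa!r}")
        codon = genetics.CANONICAL_CODON[aa]
        for t in foreground:
            seqs[t][3 * (pos - 1) : 3 * pos] = codon
    return CodonAlignment(aln.taxa, {t: "".join(s) for t, s in seqs.items()})


def make_annotation_fixture(
    genes,
    categories,
    seed: int,
    enriched_category: str | None = None,
    enriched_genes=(),
    protein_length_range: tuple[int, int] = (150, 500),
):
    """Deterministic gene→category map plus a per-protein domain table.

    Every gene receives at least one category drawn uniformly; genes listed
    in ``enriched_genes`` additionally all carry ``enriched_category``,
    planting a known enrichment signal. Domain intervals are 1-based closed
    and always lie within the protein.

    Returns ``(annotation, domains)`` where annotation maps gene id to a
    sorted list of categories and domains is a DataFrame with columns
    ``protein_id, domain_name, start, end``.
    """
    genes = list(genes)
    categories = list(categories)
    if not genes or not categories:
        raise ValueError("genes and categories must be nonempty")
    if enriched_genes and enriched_category is None:
        raise ValueError("enriched_genes given without an enriched_category")
    rng = np.random.default_rng(seed)
    annotation: dict[str, list[str]] = {}
    enriched = set(enriched_genes)
    for g in genes:
        n_cat = int(rng.integers(1, min(3, len(categories)) + 1))
        cats = set(rng.choice(categories, size=n_cat, replace=False).tolist())
        if g in enriched:
            cats.add(enriched_category)
        annotation[g] = sorted(cats)
    rows = []
    lo, hi = protein_length_range
    for g in genes:
        plen = int(rng.integers(lo, hi + 1))
        for d in range(int(rng.integers(1, 3))):
            start = int(rng.integers(1, max(2, plen - 20)))
            end = int(min(plen, start + int(rng.integers(10, 80))))
            rows.append((g, f"{g}_dom{d + 1}", start, end))
    domains = pd.DataFrame(rows, columns=["protein_id", "domain_name", "start", "end"])
    return annotation, domains
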