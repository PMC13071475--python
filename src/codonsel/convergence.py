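"""Convergent amino-acid substitution screen between diet-defined taxon groups.

Given per-gene protein alignments and a split of the taxa into a foreground
group (IN_list, e.g. predatory carnivorous fish) and a background group
(ON_list, herbivores), the screen finds alignment columns where every
IN_list taxon carries one identical residue that no ON_list taxon carries,
drops genes where a background taxon shares the same substitution, restricts
to conservative sites (convergence-at-conservative-sites, CCs), annotates
conserved-domain overlap, and classifies the biochemical property change of
each surviving substitution.

Conservation can be judged by strict residue identity or by side-chain
property class; the latter admits cases where the background alternates
between residues of one class (for example Lys and Arg, both basic)
replaced by a single residue of another.
"""

from __future__ import annotations

import warnings
from collections import Counter
from dataclasses import dataclass, field

import pandas as pd

from .genetics import property_class, property_label

__all__ = [
    "GroupSpec",
    "ConvergentSite",
    "PropertyChange",
    "detect_shared_substitutions",
    "filter_background_shared",
    "conservative_site_filter",
    "annotate_domains",
    "classify_property_change",
    "screen_gene_set",
]

_MISSING = set("-X.?*")


@dataclass(frozen=True)
class GroupSpec:
    """Foreground (IN_list) and background (ON_list) taxa, plus outgroups."""

    in_list: frozenset[str]
    on_list: frozenset[str]
    outgroup: frozenset[str] = frozenset()

    def __post_init__(self):
        object.__setattr__(self, "in_list", frozenset(self.in_list))
        object.__setattr__(self, "on_list", frozenset(self.on_list))
        object.__setattr__(self, "outgroup", frozenset(self.outgroup))
        if not self.in_list or not self.on_list:
            raise ValueError("IN_list and ON_list must both be nonempty")
        if self.in_list & self.on_list:
            raise ValueError(
                f"taxa in both groups: {sorted(self.in_list & self.on_list)}"
            )

    @property
    def background(self) -> frozenset[str]:
        """ON_list plus outgroup: the taxa conservation is judged on."""
        return self.on_list | self.outgroup


@dataclass
class PropertyChange:
    """Side-chain property classes of a substitution, with display labels."""

    from_class: str
    to_class: str
    label: str
    no_change: bool


@dataclass
class ConvergentSite:
    """One alignment column shared-derived in all IN_list taxa."""

    gene_id: str
    position: int  # 1-based protein alignment column
    in_residue: str
    on_residues: list[str]  # residue per ON taxon (non-gap), sorted multiset
    conservative: bool | None = None
    conservation_fraction: float | None = None
    conservation_mode: str | None = None
    background_gap: bool = False
    in_domain: bool | None = None
    domain_name: str | None = None
    ref_position: int | None = None
    property_change: PropertyChange | None = None


def _column(aln: dict[str, str], taxa, pos: int) -> dict[str, str]:
    return {t: aln[t][pos - 1].upper() for t in taxa}


def detect_shared_substitutions(
    protein_aln: dict[str, str],
    groups: GroupSpec,
    gene_id: str = "",
    require_absent_in_background: bool = True,
) -> list[ConvergentSite]:
    """Columns where all IN_list taxa share a residue the ON_list lacks.

    Columns with any gap or ambiguity in the IN_list are skipped. With
    ``require_absent_in_background`` (default) a column is called only when
    no ON_list taxon carries the shared IN residue; when False, it suffices
    that the IN residue differs from the single most common ON residue,
    leaving partially shared columns to
    :func:`filter_background_shared` — the two-stage route used by the
    pipeline.
    """
    for taxon in sorted(groups.in_list | groups.on_list | groups.outgroup):
        if taxon not in protein_aln:
            raise ValueError(f"group taxon {taxon!r} missing from alignment")
    lengths = {len(s) for s in protein_aln.values()}
    if len(lengths) != 1:
        raise ValueError("protein alignment rows have unequal lengths")
    (ncol,) = lengths
    in_taxa = sorted(groups.in_list)
    on_taxa = sorted(groups.on_list)
    sites: list[ConvergentSite] = []
    for pos in range(1, ncol + 1):
        in_res = set(_column(protein_aln, in_taxa, pos).values())
        if len(in_res) != 1 or in_res & _MISSING:
            continue
        (r,) = in_res
        on_col = _column(protein_aln, on_taxa, pos)
        on_observed = [a for a in on_col.values() if a not in _MISSING]
        if not on_observed:
            continue
        if require_absent_in_background:
            if r in on_observed:
                continue
        else:
            counts = Counter(on_observed)
            top = counts.most_common()
            consensus = {a for a, c in top if c == top[0][1]}
            if r in consensus:
                continue
        sites.append(
            ConvergentSite(
                gene_id=gene_id,
                position=pos,
                in_residue=r,
                on_residues=sorted(on_observed),
                background_gap=len(on_observed) < len(on_taxa),
            )
        )
    return sites


def filter_background_shared(
    sites_by_gene: dict[str, list[ConvergentSite]], groups: GroupSpec
) -> dict[str, list[ConvergentSite]]:
    """Drop whole genes where a background taxon shares an IN substitution.

    A gene is removed as soon as any called site's IN residue also occurs in
    an ON_list taxon at that same position — partial convergence in the
    background disqualifies the gene, not just the site. Genes retaining at
    least one site survive.
    """
    out: dict[str, list[ConvergentSite]] = {}
    for gene, sites in sites_by_gene.items():
        if not sites:
            continue
        shared = any(s.in_residue in s.on_residues for s in sites)
        if not shared:
            out[gene] = list(sites)
    return out


def conservative_site_filter(
    sites: list[ConvergentSite],
    protein_aln: dict[str, str],
    groups: GroupSpec,
    min_background_identity: float = 1.0,
    mode: str = "identity",
) -> list[ConvergentSite]:
    """Keep sites that are conserved across the background before the change.

    Conservation is the largest fraction of non-gap background residues
    (ON_list plus outgroup) agreeing at the column — on residue identity
    (``mode="identity"``) or on side-chain property class
    (``mode="property"``). A site passes when that fraction reaches
    ``min_background_identity``. Annotations are written onto the sites;
    only passing sites are returned.
    """
    if mode not in ("identity", "property"):
        raise ValueError(f"unknown CCs mode {mode!r}")
    bg_taxa = sorted(groups.background)
    kept = []
    for site in sites:
        col = _column(protein_aln, bg_taxa, site.position)
        observed = [a for a in col.values() if a not in _MISSING]
        if not observed:
            frac = 0.0
        elif mode == "identity":
            frac = Counter(observed).most_common(1)[0][1] / len(observed)
        else:
            classes = Counter(property_class(a) for a in observed)
            frac = classes.most_common(1)[0][1] / len(observed)
        site.conservation_fraction = frac
        site.conservation_mode = mode
        site.conservative = bool(observed) and frac >= min_background_identity
        if site.conservative:
            kept.append(site)
    return kept


def annotate_domains(
    sites: list[ConvergentSite],
    domain_table: pd.DataFrame,
    protein_lengths: dict[str, int] | None = None,
) -> list[ConvergentSite]:
    """Mark each site as inside/outside a conserved domain of its protein.

    ``domain_table`` columns: protein_id, domain_name, start, end (1-based
    closed intervals). The coordinate compared is the site's ungapped
    reference position when set, else the alignment column. Intervals
    exceeding a known protein length are clamped with a warning, never
    fatal. Annotation changes flags only, never the number of sites.
    """
    by_protein: dict[str, list[tuple[str, int, int]]] = {}
    for row in domain_table.itertuples(index=False):
        start, end = int(row.start), int(row.end)
        if protein_lengths and row.protein_id in protein_lengths:
            plen = protein_lengths[row.protein_id]
            if start < 1 or end > plen:
                warnings.warn(
                    f"domain {row.domain_name} [{start},{end}] outside protein "
                    f"{row.protein_id} (length {plen}); clamped",
                    stacklevel=2,
                )
                start, end = max(1, start), min(plen, end)
        by_protein.setdefault(str(row.protein_id), []).append(
            (str(row.domain_name), start, end)
        )
    for site in sites:
        pos = site.ref_position if site.ref_position is not None else site.position
        site.in_domain = False
        site.domain_name = None
        for name, start, end in by_protein.get(site.gene_id, []):
            if start <= pos <= end:
                site.in_domain = True
                site.domain_name = name
                break
    return sites


def classify_property_change(from_residues, to_residue: str) -> PropertyChange:
    """Property-class transition of a substitution, e.g. S→G or {K,R}→Q.

    All "from" residues must share one property class. Labels follow the
    conventional phrasing: hydrophilic→hydrophobic for a polarity change,
    basic→neutral (etc.) when charge is involved.
    """
    if isinstance(from_residues, str):
        from_residues = [from_residues]
    from_classes = {property_class(a) for a in from_residues}
    if len(from_classes) != 1:
        raise ValueError(
            f"source residues {sorted(from_residues)} span several property "
            f"classes: {sorted(from_classes)}"
        )
    (fc,) = from_classes
    tc = property_class(to_residue)
    return PropertyChange(
        from_class=fc,
        to_class=tc,
        label=f"{property_label(fc, tc)}→{property_label(tc, fc)}",
        no_change=fc == tc,
    )


def ungapped_position(aligned_seq: str, column: int) -> int | None:
    """1-based residue index in the ungapped sequence at an alignment column."""
    if aligned_seq[column - 1] == "-":
        return None
    return column - aligned_seq[:column].count("-")


def screen_gene_set(
    alignments: dict[str, dict[str, str]],
    groups: GroupSpec,
    domain_table: pd.DataFrame | None = None,
    min_background_identity: float = 1.0,
    ccs_mode: str = "identity",
    reference_taxon: str | None = None,
) -> tuple[dict[str, list[ConvergentSite]], dict[str, int]]:
    """Run the full screen over per-gene protein alignments.

    Stages: detect shared IN substitutions (relaxed, consensus-based), drop
    genes with background-shared substitutions, keep conservative sites
    (CCs), annotate domains and property changes. Returns the surviving
    sites per gene and the per-stage gene counts
    ``detected / after_background_filter / after_ccs / in_domain``.
    """
    ref = reference_taxon or sorted(groups.in_list)[0]
    detected: dict[str, list[ConvergentSite]] = {}
    for gene in sorted(alignments):
        aln = alignments[gene]
        sites = detect_shared_substitutions(
            aln, groups, gene_id=gene, require_absent_in_background=False
        )
        if sites:
            detected[gene] = sites
    after_bg = filter_background_shared(detected, groups)
    after_ccs: dict[str, list[ConvergentSite]] = {}
    for gene, sites in after_bg.items():
        kept = conservative_site_filter(
            sites, alignments[gene], groups,
            min_background_identity=min_background_identity, mode=ccs_mode,
        )
        if kept:
            after_ccs[gene] = kept
    in_domain_genes = 0
    for gene, sites in after_ccs.items():
        aln = alignments[gene]
        for site in sites:
            if ref in aln:
                site.ref_position = ungapped_position(aln[ref], site.position)
            from_res = sorted(set(site.on_residues))
            try:
                site.property_change = classify_property_change(
                    from_res, site.in_residue
                )
            except ValueError:
                site.property_change = None  # mixed-class background
        if domain_table is not None:
            annotate_domains(sites, domain_table)
            if any(s.in_domain for s in sites):
                in_domain_genes += 1
    counts = {
        "detected": len(detected),
        "after_background_filter": len(after_bg),
        "after_ccs": len(after_ccs),
        "in_domain": in_domain_genes if domain_table is not None else 0,
    }
    return after_ccs, counts
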