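"""Orthogroup-based vetting and rescue of domain-screened candidates.

Domain screening alone cannot separate families whose members carry only
generic domains (an NF-kB inhibitor is just ankyrin repeats at the signature
level), and it misses family members whose diagnostic domains have diverged
beyond detection. Vetting annotates every candidate with whether it shares
an orthogroup with a known reference gene of the same family; rescue admits
focal-species genes on that orthology evidence alone; homology evidence from
tabular BLAST hits provides a third, independent route.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping

from .io import GeneMap, HomologyHit, OrthogroupTable, best_hit_per_query
from .rules import FamilyRule, MatchResult

ReferenceCatalog = Mapping[str, Mapping[str, Iterable[str]]]


def percent(part: int | float, whole: int | float, digits: int = 1) -> float:
    """Share of ``whole`` as a percentage, rounded to ``digits`` decimals."""
    if whole == 0:
        raise ZeroDivisionError("percentage of an empty total")
    return round(100.0 * part / whole, digits)


@dataclass(frozen=True)
class VettingEvidence:
    gene_id: str
    family: str
    domain_clause: str = "none"
    shares_orthogroup_with_reference: bool = False
    orthogroup_id: str | None = None
    homology_rescued: bool = False

    def __post_init__(self):
        if not (self.domain_clause != "none"
                or self.shares_orthogroup_with_reference
                or self.homology_rescued):
            raise ValueError(
                f"{self.gene_id}/{self.family}: record carries no evidence"
            )


@dataclass(frozen=True)
class ImmunomeEntry:
    gene_id: str
    family: str
    category: str
    evidence: VettingEvidence


@dataclass
class OverlapStats:
    total_orthogroups: int
    at_least_two_species: int
    all_species: int
    single_species: int
    focal_unique: int
    named: dict[str, int] = field(default_factory=dict)

    def __post_init__(self):
        if self.at_least_two_species + self.single_species != self.total_orthogroups:
            raise ValueError("species-count partition does not add up")


@dataclass(frozen=True)
class SubsetDef:
    """A named orthogroup subset over the species present in a row.

    ``exact=True``: the non-empty species set must equal ``include``.
    ``exact=False``: every species in ``include`` must be present (for
    grouped includes, see ``include_any``) and every species in ``exclude``
    absent. ``include_any`` lists groups of which at least one member must be
    present (e.g. "any mollusk").
    """

    include: frozenset[str] = frozenset()
    exclude: frozenset[str] = frozenset()
    include_any: tuple[frozenset[str], ...] = ()
    exact: bool = False

    def matches(self, present: frozenset[str]) -> bool:
        if self.exact:
            return present == self.include
        if not self.include <= present:
            return False
        if self.exclude & present:
            return False
        return all(group & present for group in self.include_any)


# ---------------------------------------------------------------------------
# orthogroup overlap statistics
# ---------------------------------------------------------------------------

def overlap_stats(
    orthogroups: OrthogroupTable,
    focal_species: str,
    named_subsets: Mapping[str, SubsetDef] | None = None,
) -> OverlapStats:
    """Orthogroup sharing statistics across the surveyed species."""
    known = set(orthogroups.species)
    if focal_species not in known:
        raise ValueError(f"unknown focal species {focal_species!r}")
    for name, sub in (named_subsets or {}).items():
        bad = (set(sub.include) | set(sub.exclude)
               | {sp for g in sub.include_any for sp in g}) - known
        if bad:
            raise ValueError(f"subset {name!r} references unknown species {sorted(bad)}")

    total = len(orthogroups)
    at_least_two = all_sp = single = focal_unique = 0
    named_counts = {name: 0 for name in (named_subsets or {})}
    n_species = len(orthogroups.species)
    for og_id in orthogroups:
        present = orthogroups.species_present(og_id)
        if len(present) >= 2:
            at_least_two += 1
        else:
            single += 1
        if len(present) == n_species:
            all_sp += 1
        if present == {focal_species}:
            focal_unique += 1
        for name, sub in (named_subsets or {}).items():
            if sub.matches(present):
                named_counts[name] += 1
    return OverlapStats(
        total_orthogroups=total,
        at_least_two_species=at_least_two,
        all_species=all_sp,
        single_species=single,
        focal_unique=focal_unique,
        named=named_counts,
    )


# ---------------------------------------------------------------------------
# vetting and rescue
# ---------------------------------------------------------------------------

def _reference_orthogroups(
    family: str,
    refs: ReferenceCatalog,
    orthogroups: OrthogroupTable,
) -> set[str]:
    """Orthogroups containing any reference gene of the family."""
    import logging

    ogs: set[str] = set()
    for species, gene_ids in (refs.get(family) or {}).items():
        for gid in gene_ids:
            og = orthogroups.orthogroup_of(gid)
            if og is None:
                logging.getLogger(__name__).warning(
                    "reference gene %s (%s, %s) absent from orthogroup table",
                    gid, family, species,
                )
            else:
                ogs.add(og)
    return ogs


def _gene_orthogroup(gene_id: str, gene_map: GeneMap,
                     orthogroups: OrthogroupTable) -> str | None:
    """Orthogroup of a gene, matching either the gene id itself or any
    isoform id (orthogroup tables may be built at either id level)."""
    og = orthogroups.orthogroup_of(gene_id)
    if og is not None:
        return og
    for pid in gene_map.isoforms(gene_id):
        og = orthogroups.orthogroup_of(pid)
        if og is not None:
            return og
    return None


def vet_families(
    screen_results: Mapping[str, list[MatchResult]],
    gene_map: GeneMap,
    orthogroups: OrthogroupTable,
    refs: ReferenceCatalog,
    catalog: Iterable[FamilyRule],
    focal_species: str | None = None,
    require_orthology_for_relaxed: bool = False,
) -> tuple[list[ImmunomeEntry], list[ImmunomeEntry]]:
    """Compile the vetted immunome from domain-screen results.

    Returns ``(entries, rejects)``. Every domain-matched gene is annotated
    with whether it shares an orthogroup with a same-family reference gene;
    genes co-grouped with references but missed by the screen are rescued.
    With ``require_orthology_for_relaxed`` genes holding only relaxed domain
    evidence and no orthology support are diverted to the reject report.
    """
    categories = {r.family: r.category for r in catalog}
    from .rules import collapse_to_genes

    counts, _unmapped = collapse_to_genes(screen_results, gene_map)
    entries: list[ImmunomeEntry] = []
    rejects: list[ImmunomeEntry] = []
    seen: set[tuple[str, str]] = set()

    for family in sorted(set(counts) | set(refs)):
        ref_ogs = _reference_orthogroups(family, refs, orthogroups)
        matched_genes: dict[str, str] = (
            counts[family].gene_labels if family in counts else {}
        )
        for gene_id in sorted(matched_genes):
            og = _gene_orthogroup(gene_id, gene_map, orthogroups)
            supported = og is not None and og in ref_ogs
            ev = VettingEvidence(
                gene_id=gene_id, family=family,
                domain_clause=matched_genes[gene_id],
                shares_orthogroup_with_reference=supported,
                orthogroup_id=og,
            )
            entry = ImmunomeEntry(gene_id, family, categories.get(family, ""), ev)
            if (require_orthology_for_relaxed
                    and ev.domain_clause != "strict" and not supported):
                rejects.append(entry)
            else:
                if (gene_id, family) not in seen:
                    entries.append(entry)
                    seen.add((gene_id, family))
        for gene_id in sorted(orthology_rescue(
                family, refs, orthogroups, set(matched_genes),
                gene_map=gene_map, focal_species=focal_species)):
            og = _gene_orthogroup(gene_id, gene_map, orthogroups)
            ev = VettingEvidence(
                gene_id=gene_id, family=family, domain_clause="none",
                shares_orthogroup_with_reference=True,
                orthogroup_id=og, homology_rescued=True,
            )
            if (gene_id, family) not in seen:
                entries.append(ImmunomeEntry(gene_id, family,
                                             categories.get(family, ""), ev))
                seen.add((gene_id, family))
    return entries, rejects


def orthology_rescue(
    family: str,
    refs: ReferenceCatalog,
    orthogroups: OrthogroupTable,
    already_matched: set[str],
    gene_map: GeneMap | None = None,
    focal_species: str | None = None,
) -> set[str]:
    """Genes co-grouped with family references but absent from the screen.

    Restricted to the focal species' column when given (rescue targets the
    surveyed proteome, not the reference proteomes). Returned ids are gene
    ids when a gene map is supplied (isoform ids are collapsed), otherwise
    whatever id level the orthogroup table carries.
    """
    ref_ogs = _reference_orthogroups(family, refs, orthogroups)
    rescued: set[str] = set()
    ref_ids = {g for sp in (refs.get(family) or {})
               for g in (refs.get(family) or {})[sp]}
    for og_id in sorted(ref_ogs):
        members = orthogroups.members(og_id, focal_species) \
            if focal_species else orthogroups.members(og_id)
        for member in members:
            if member in ref_ids:
                continue
            gene = member
            if gene_map is not None and member in gene_map:
                gene = gene_map.gene_of(member)
            if gene not in already_matched:
                rescued.add(gene)
    return rescued


def attach_homology_evidence(
    entries: list[ImmunomeEntry],
    hits: Iterable[HomologyHit],
    family: str,
    gene_map: GeneMap,
    category: str = "",
    max_evalue: float = 1e-5,
    min_bitscore: float | None = None,
) -> list[ImmunomeEntry]:
    """Flag candidates whose best homology hit passes the thresholds.

    Queries are candidate protein ids; a gene gains ``homology_rescued``
    evidence for ``family`` when the best hit of any isoform passes
    ``evalue <= max_evalue`` (and the bitscore floor when set). Genes not yet
    in the compiled set enter it on homology evidence alone.
    """
    best = best_hit_per_query(hits)
    passing_genes: set[str] = set()
    for query, hit in best.items():
        if hit.evalue > max_evalue:
            continue
        if min_bitscore is not None and hit.bitscore < min_bitscore:
            continue
        gene = gene_map.get(query) or query
        passing_genes.add(gene)

    out: list[ImmunomeEntry] = []
    seen: set[str] = set()
    for entry in entries:
        if entry.family == family and entry.gene_id in passing_genes:
            seen.add(entry.gene_id)
            out.append(replace(
                entry, evidence=replace(entry.evidence, homology_rescued=True)
            ))
        else:
            out.append(entry)
    for gene in sorted(passing_genes - seen):
        ev = VettingEvidence(gene_id=gene, family=family,
                             homology_rescued=True)
        out.append(ImmunomeEntry(gene, family, category, ev))
    return out


def write_immunome_tsv(entries: Iterable[ImmunomeEntry], gene_map: GeneMap,
                       path, header_lines: Iterable[str] = ()) -> None:
    """SFile3-shaped immunome table."""
    with open(path, "w") as fh:
        for line in header_lines:
            fh.write(f"# {line}\n")
        fh.write("gene_id\tprotein_ids\tfamily\tcategory\tclause\t"
                 "orthogroup_id\torthology_flag\thomology_flag\n")
        for e in sorted(entries, key=lambda e: (e.family, e.gene_id)):
            pids = ",".join(gene_map.isoforms(e.gene_id))
            fh.write("\t".join([
                e.gene_id, pids, e.family, e.category,
                e.evidence.domain_clause,
                e.evidence.orthogroup_id or "-",
                str(int(e.evidence.shares_orthogroup_with_reference)),
                str(int(e.evidence.homology_rescued)),
            ]) + "\n")
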