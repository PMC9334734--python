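"""Strict/relaxed domain-signature screening of annotated proteomes.

A family rule is a small disjunctive-normal-form expression over signature
accessions: clauses are evaluated in catalog order (strict before relaxed
before alternates); within a clause every required accession must be present
among the protein's hits (in either the InterPro or the member-database
namespace), no forbidden accession may be present, and the hits carrying
required accessions must span at least ``min_distinct_hits`` distinct
intervals (so "contains 2 TIR domains" is expressible).

Families are not mutually exclusive: one protein may legitimately belong to
several (e.g. a C-type lectin domain contributes to more than one lectin
family's relaxed clause).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from typing import Iterable, Mapping

import yaml

from .io import DomainHit, GeneMap

CLAUSE_LABELS = ("strict", "relaxed", "alternate")
_LABEL_RANK = {"strict": 0, "relaxed": 1, "alternate": 2, "none": 3}


@dataclass(frozen=True)
class RuleClause:
    label: str
    required: frozenset[str]
    forbidden: frozenset[str] = frozenset()
    min_distinct_hits: int = 1

    def __post_init__(self):
        if self.label not in CLAUSE_LABELS:
            raise ValueError(f"unknown clause label {self.label!r}")
        if not self.required:
            raise ValueError("clause with empty required set")
        if self.required & self.forbidden:
            raise ValueError("required and forbidden sets overlap")
        if self.min_distinct_hits < 1:
            raise ValueError("min_distinct_hits must be >= 1")


@dataclass(frozen=True)
class FamilyRule:
    family: str
    category: str
    clauses: tuple[RuleClause, ...]
    reference_genes: Mapping[str, tuple[str, ...]] = field(default_factory=dict)
    homology_based: bool = False
    reported_count: int | None = None

    def __post_init__(self):
        if not self.clauses:
            raise ValueError(f"family {self.family!r} has no clauses")

    @property
    def accessions(self) -> frozenset[str]:
        out: set[str] = set()
        for c in self.clauses:
            out |= c.required
        return frozenset(out)


@dataclass(frozen=True)
class MatchResult:
    protein_id: str
    family: str
    matched: bool
    matched_clause_label: str = "none"
    satisfied_accessions: frozenset[str] = frozenset()

    def __post_init__(self):
        if self.matched != (self.matched_clause_label != "none"):
            raise ValueError("matched flag inconsistent with clause label")


@dataclass
class FamilyCount:
    family: str
    protein_count: int
    gene_count: int
    gene_ids: set[str]
    gene_labels: dict[str, str]

    def __post_init__(self):
        if self.gene_count != len(self.gene_ids):
            raise ValueError("gene_count inconsistent with gene_ids")
        if self.gene_count > self.protein_count:
            raise ValueError("gene_count exceeds protein_count")


# ---------------------------------------------------------------------------
# catalog loading
# ---------------------------------------------------------------------------

_KNOWN_FIELDS = {
    "family", "category", "strict", "relaxed", "alternates", "forbidden",
    "reference_genes", "homology_based", "reported_count",
    "strict_min_hits", "relaxed_min_hits",
}


def _as_clause(label: str, spec, forbidden: frozenset[str], min_hits: int = 1) -> RuleClause:
    if isinstance(spec, Mapping):
        required = frozenset(str(a) for a in spec["required"])
        min_hits = int(spec.get("min_distinct_hits", min_hits))
    else:
        required = frozenset(str(a) for a in spec)
    return RuleClause(label, required, forbidden, min_hits)


def _build_rule(entry: Mapping) -> FamilyRule:
    family = str(entry["family"])
    unknown = set(entry) - _KNOWN_FIELDS
    if unknown:
        raise ValueError(f"family {family!r}: unknown field(s) {sorted(unknown)}")
    forbidden = frozenset(str(a) for a in entry.get("forbidden", ()))
    clauses: list[RuleClause] = []
    if entry.get("strict"):
        clauses.append(_as_clause("strict", entry["strict"], forbidden,
                                  int(entry.get("strict_min_hits", 1))))
    if entry.get("relaxed"):
        clauses.append(_as_clause("relaxed", entry["relaxed"], forbidden,
                                  int(entry.get("relaxed_min_hits", 1))))
    for alt in entry.get("alternates", ()) or ():
        clauses.append(_as_clause("alternate", alt, forbidden))
    if not clauses:
        raise ValueError(f"family {family!r}: no clause with a required set")
    refs = {
        str(sp): tuple(str(g) for g in genes)
        for sp, genes in (entry.get("reference_genes") or {}).items()
    }
    return FamilyRule(
        family=family,
        category=str(entry.get("category", "")),
        clauses=tuple(clauses),
        reference_genes=refs,
        homology_based=bool(entry.get("homology_based", False)),
        reported_count=entry.get("reported_count"),
    )


def load_rule_catalog(source) -> list[FamilyRule]:
    """Load a family-rule catalog from a YAML file path or open stream."""
    if hasattr(source, "read"):
        doc = yaml.safe_load(source)
    else:
        with open(source) as fh:
            doc = yaml.safe_load(fh)
    if doc is None:
        return []
    entries = doc.get("families", []) if isinstance(doc, Mapping) else doc
    rules: list[FamilyRule] = []
    seen: set[str] = set()
    for entry in entries or []:
        rule = _build_rule(entry)
        if rule.family in seen:
            raise ValueError(f"duplicate family {rule.family!r} in catalog")
        seen.add(rule.family)
        rules.append(rule)
    return rules


def default_catalog() -> list[FamilyRule]:
    """The shipped catalog of ~110 immune gene families."""
    ref = resources.files("immunome.data").joinpath("default_rules.yaml")
    with ref.open() as fh:
        return load_rule_catalog(fh)


# ---------------------------------------------------------------------------
# matching
# ---------------------------------------------------------------------------

def _distinct_interval_count(hits: list[DomainHit], required: frozenset[str]) -> int:
    """Count merged intervals among hits carrying any required accession."""
    spans = sorted(
        (h.start, h.stop) for h in hits if h.accessions & required
    )
    count = 0
    cur_stop = None
    for start, stop in spans:
        if cur_stop is None or start > cur_stop + 1:
            count += 1
            cur_stop = stop
        else:
            cur_stop = max(cur_stop, stop)
    return count


def match_protein(hits: Iterable[DomainHit], rule: FamilyRule) -> MatchResult:
    """Evaluate one protein's hits against one family rule.

    Clauses are tried in catalog order and the first satisfied clause is
    reported, so a strict match always dominates a relaxed one.
    """
    hits = list(hits)
    pids = {h.protein_id for h in hits}
    if len(pids) > 1:
        raise ValueError(f"hits from multiple proteins: {sorted(pids)}")
    pid = next(iter(pids)) if pids else ""
    present: set[str] = set()
    for h in hits:
        present |= h.accessions
    for clause in rule.clauses:
        if not clause.required <= present:
            continue
        if clause.forbidden & present:
            continue
        if clause.min_distinct_hits > 1:
            if _distinct_interval_count(hits, clause.required) < clause.min_distinct_hits:
                continue
        return MatchResult(pid, rule.family, True, clause.label,
                           frozenset(clause.required))
    return MatchResult(pid, rule.family, False)


def screen_proteome(
    hits: Iterable[DomainHit] | Mapping[str, list[DomainHit]],
    catalog: Iterable[FamilyRule],
) -> dict[str, list[MatchResult]]:
    """Screen every protein against every family; keep matches only.

    Output is deterministically ordered by (family, protein_id). An inverted
    accession index keeps the scan linear in the number of hits rather than
    |proteins| x |families|.
    """
    from .io import hits_by_protein  # local import to avoid cycle at module load

    if isinstance(hits, Mapping):
        grouped = {pid: list(hs) for pid, hs in hits.items()}
    else:
        grouped = hits_by_protein(hits)
    catalog = list(catalog)

    acc_to_rules: dict[str, set[int]] = {}
    for idx, rule in enumerate(catalog):
        for acc in rule.accessions:
            acc_to_rules.setdefault(acc, set()).add(idx)

    results: dict[str, list[MatchResult]] = {}
    for pid in sorted(grouped):
        phits = grouped[pid]
        present: set[str] = set()
        for h in phits:
            present |= h.accessions
        candidates = sorted({i for acc in present for i in acc_to_rules.get(acc, ())})
        for idx in candidates:
            rule = catalog[idx]
            res = match_protein(phits, rule)
            if res.matched:
                results.setdefault(rule.family, []).append(res)
    return {fam: results[fam] for fam in sorted(results)}


def collapse_to_genes(
    results: Mapping[str, list[MatchResult]],
    gene_map: GeneMap,
) -> tuple[dict[str, FamilyCount], list[str]]:
    """Collapse protein-level matches to gene level.

    A gene matches a family if at least one isoform matches; the gene's label
    is the strongest isoform label (strict > relaxed > alternate). Proteins
    absent from the gene map are not dropped silently: they are returned in
    the side channel and excluded from gene counts.
    """
    counts: dict[str, FamilyCount] = {}
    unmapped: set[str] = set()
    for family in sorted(results):
        matches = results[family]
        gene_labels: dict[str, str] = {}
        n_proteins = 0
        for m in matches:
            if not m.matched:
                continue
            n_proteins += 1
            gid = gene_map.get(m.protein_id)
            if gid is None:
                unmapped.add(m.protein_id)
                continue
            prev = gene_labels.get(gid)
            if prev is None or _LABEL_RANK[m.matched_clause_label] < _LABEL_RANK[prev]:
                gene_labels[gid] = m.matched_clause_label
        counts[family] = FamilyCount(
            family=family,
            protein_count=n_proteins,
            gene_count=len(gene_labels),
            gene_ids=set(gene_labels),
            gene_labels=gene_labels,
        )
    return counts, sorted(unmapped)
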