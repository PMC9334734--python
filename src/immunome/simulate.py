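"""Synthetic proteome bundles and sequence evolution with planted truth.

The generator emulates the pipeline's real inputs -- an InterProScan tabular
annotation, a protein FASTA with multi-isoform genes, a protein->gene map,
and a multi-species orthogroup table -- with fully known ground truth, so
every stage (parsing, screening, vetting, extraction, tree building) is
testable without downloads. Planted immune genes carry the required-domain
suite of their family's clause in the shipped catalog on their longest
isoform; background genes carry only decoy accessions from a disjoint pool.
Sequence content is drawn from JTT stationary frequencies (the screen reads
annotations, not residues, so motif realism is unnecessary).
"""

from __future__ import annotations

import json
import zlib
from dataclasses import dataclass, field
from pathlib import Path

import dendropy
import numpy as np

from . import io as aio
from .jtt import AMINO_ACIDS, JTT_FREQS
from .phylo import Alignment, RateModel
from .rules import FamilyRule, default_catalog, screen_proteome

DEFAULT_SPECIES = ("Aplysia", "Cgigas", "Bglabrata", "Human", "Drosophila")
DEFAULT_PLANTED = {"TLR": 5, "SRCR": 3, "MyD88": 2, "PARP": 2}

_ANALYSIS_BY_PREFIX = (
    ("PF", "Pfam"), ("SM", "SMART"), ("PTHR", "PANTHER"),
    ("G3DSA", "Gene3D"), ("PS", "PROSITE"),
)


@dataclass(frozen=True)
class SimConfig:
    seed: int = 0
    species: tuple[str, ...] = DEFAULT_SPECIES
    focal_species: str = DEFAULT_SPECIES[0]
    planted: dict[str, int] = field(default_factory=lambda: dict(DEFAULT_PLANTED))
    background_genes: int = 50
    max_isoforms: int = 3
    clause_label: str = "strict"
    domain_length_range: tuple[int, int] = (50, 200)
    gap_length_range: tuple[int, int] = (5, 50)

    def __post_init__(self):
        if self.background_genes < 0 or any(v < 0 for v in self.planted.values()):
            raise ValueError("counts must be >= 0")
        if self.focal_species not in self.species:
            raise ValueError("focal species missing from species list")


@dataclass
class PlantedTruth:
    gene_to_family: dict[str, str]              # planted genes only
    gene_to_orthogroup: dict[str, str]
    protein_intervals: dict[str, list[tuple[str, int, int]]]
    reference_genes: dict[str, dict[str, list[str]]]
    background_genes: list[str]


@dataclass
class Bundle:
    ips_tsv: Path
    gene_map_tsv: Path
    fasta: Path
    orthogroups_tsv: Path
    truth: PlantedTruth


def _analysis_for(acc: str) -> str:
    for prefix, name in _ANALYSIS_BY_PREFIX:
        if acc.startswith(prefix):
            return name
    return "SyntheticDB"


def _random_sequence(rng: np.random.Generator, length: int) -> str:
    idx = rng.choice(20, size=length, p=JTT_FREQS)
    return "".join(AMINO_ACIDS[i] for i in idx)


def _clause_for(rule: FamilyRule, label: str):
    for clause in rule.clauses:
        if clause.label == label:
            return clause
    return rule.clauses[0]


def generate_annotation_bundle(
    config: SimConfig,
    outdir,
    catalog: list[FamilyRule] | None = None,
) -> Bundle:
    """Write a synthetic annotation bundle and return it with planted truth.

    The emitted files are byte-identical for a fixed config (seed included).
    Generation self-audits: the bundle is re-parsed and re-screened with the
    catalog, and any mismatch with the planted truth is a hard error.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    if catalog is None:
        catalog = default_catalog()
    rules_by_family = {r.family: r for r in catalog}
    catalog_accessions = {a for r in catalog for c in r.clauses for a in c.required}
    for family in config.planted:
        if family not in rules_by_family:
            raise ValueError(f"planted family {family!r} absent from catalog")

    rng = np.random.default_rng(config.seed)
    hits: list[aio.DomainHit] = []
    lengths: dict[str, int] = {}
    fasta_records: list[aio.ProteinRecord] = []
    p2g: dict[str, str] = {}
    truth = PlantedTruth({}, {}, {}, {}, [])
    og_rows: dict[str, dict[str, list[str]]] = {}

    gene_serial = 0
    prot_serial = 0
    og_serial = 0

    def next_ids(n_isoforms: int) -> tuple[str, list[str]]:
        nonlocal gene_serial, prot_serial
        gene_serial += 1
        gid = f"LOC{800000 + gene_serial}"
        pids = []
        for _ in range(n_isoforms):
            prot_serial += 1
            pids.append(f"XP_{9000000 + prot_serial}.1")
        return gid, pids

    dmin, dmax = config.domain_length_range
    gmin, gmax = config.gap_length_range

    for family in sorted(config.planted):
        rule = rules_by_family[family]
        clause = _clause_for(rule, config.clause_label)
        ref_ids = {
            sp: [] for sp in config.species if sp != config.focal_species
        }
        for copy in range(config.planted[family]):
            n_iso = int(rng.integers(1, config.max_isoforms + 1))
            gid, pids = next_ids(n_iso)
            p2g.update({p: gid for p in pids})
            truth.gene_to_family[gid] = family

            # plant the clause's domain suite on the (future) longest isoform
            pos = 1
            intervals: list[tuple[str, int, int]] = []
            for acc in sorted(clause.required):
                start = pos + int(rng.integers(gmin, gmax + 1))
                stop = start + int(rng.integers(dmin, dmax + 1)) - 1
                intervals.append((acc, start, stop))
                pos = stop
            full_len = pos + int(rng.integers(gmin, gmax + 1))
            longest = pids[0]
            lengths[longest] = full_len
            truth.protein_intervals[longest] = intervals
            for acc, start, stop in intervals:
                if acc.startswith("IPR"):
                    sig = f"SYN{zlib.crc32(acc.encode()) % 100000:05d}"
                    hits.append(aio.DomainHit(
                        protein_id=longest, analysis="SyntheticDB",
                        signature_acc=sig, signature_desc=f"synthetic match {acc}",
                        start=start, stop=stop, score=1e-10, interpro_acc=acc,
                        interpro_desc=f"planted {acc}",
                    ))
                else:
                    hits.append(aio.DomainHit(
                        protein_id=longest, analysis=_analysis_for(acc),
                        signature_acc=acc, signature_desc="planted member-db hit",
                        start=start, stop=stop, score=1e-10,
                    ))
            for pid in pids[1:]:
                lengths[pid] = max(30, int(full_len * rng.uniform(0.4, 0.9)))

            for pid in pids:
                fasta_records.append(aio.ProteinRecord(
                    pid, gene_id=gid, length=lengths[pid],
                    sequence=_random_sequence(rng, lengths[pid]),
                ))

            og_serial += 1
            og_id = f"OG{og_serial:07d}"
            truth.gene_to_orthogroup[gid] = og_id
            row = {sp: [] for sp in config.species}
            row[config.focal_species] = list(pids)
            for sp in config.species:
                if sp == config.focal_species:
                    continue
                ortholog = f"{sp}_{family.replace('/', '_').replace(' ', '_')}_{copy + 1}"
                row[sp] = [ortholog]
                ref_ids[sp].append(ortholog)
            og_rows[og_id] = row
        truth.reference_genes[family] = {sp: list(ids) for sp, ids in ref_ids.items()}

    decoy_pool = [f"IPR9{i:05d}" for i in range(1, 41)]
    decoy_pool = [a for a in decoy_pool if a not in catalog_accessions]
    for _ in range(config.background_genes):
        gid, (pid,) = next_ids(1)
        p2g[pid] = gid
        truth.background_genes.append(gid)
        length = int(rng.integers(100, 600))
        lengths[pid] = length
        n_decoys = int(rng.integers(0, 3))
        pos = 1
        for _d in range(n_decoys):
            acc = decoy_pool[int(rng.integers(0, len(decoy_pool)))]
            start = min(pos + int(rng.integers(1, 20)), length)
            stop = min(start + int(rng.integers(20, 60)), length)
            hits.append(aio.DomainHit(
                protein_id=pid, analysis="SyntheticDB",
                signature_acc=f"SYN{zlib.crc32(acc.encode()) % 100000:05d}",
                signature_desc="decoy", start=start, stop=stop,
                score=0.5, interpro_acc=acc, interpro_desc="decoy domain",
            ))
            pos = stop
        fasta_records.append(aio.ProteinRecord(
            pid, gene_id=gid, length=length,
            sequence=_random_sequence(rng, length),
        ))
        og_serial += 1
        og_id = f"OG{og_serial:07d}"
        truth.gene_to_orthogroup[gid] = og_id
        row = {sp: [] for sp in config.species}
        row[config.focal_species] = [pid]
        og_rows[og_id] = row

    ips_tsv = outdir / "annotations.ips.tsv"
    gene_map_tsv = outdir / "gene_map.tsv"
    fasta = outdir / "proteins.fasta"
    orthogroups_tsv = outdir / "orthogroups.tsv"

    hits.sort(key=lambda h: (h.protein_id, h.start, h.signature_acc))
    aio.write_interproscan_tsv(hits, lengths, ips_tsv)
    aio.write_gene_map(aio.GeneMap(p2g, lengths), gene_map_tsv)
    aio.write_fasta(fasta_records, fasta)
    aio.write_orthogroups(aio.OrthogroupTable(list(config.species), og_rows),
                          orthogroups_tsv)
    with open(outdir / "truth.json", "w") as fh:
        json.dump({
            "gene_to_family": truth.gene_to_family,
            "gene_to_orthogroup": truth.gene_to_orthogroup,
            "background_genes": truth.background_genes,
            "reference_genes": truth.reference_genes,
        }, fh, indent=1, sort_keys=True)

    bundle = Bundle(ips_tsv, gene_map_tsv, fasta, orthogroups_tsv, truth)
    audit_bundle(bundle, catalog)
    return bundle


def audit_bundle(bundle: Bundle, catalog: list[FamilyRule] | None = None) -> None:
    """Re-parse and re-screen the emitted files against the planted truth.

    Raises AssertionError on any discrepancy: a planted gene not recovered in
    its family, a background gene matching any family, or coordinates
    inconsistent with the FASTA.
    """
    if catalog is None:
        catalog = default_catalog()
    hits, prot_records = aio.parse_interproscan_tsv(bundle.ips_tsv)
    records = aio.parse_fasta(bundle.fasta)
    gene_map = aio.load_gene_map(bundle.gene_map_tsv,
                                 {p: r.length for p, r in records.items()})
    for h in hits:
        rec = records.get(h.protein_id)
        assert rec is not None and h.stop <= rec.length, \
            f"hit beyond sequence on {h.protein_id}"

    results = screen_proteome(hits, catalog)
    gene_families: dict[str, set[str]] = {}
    for family, matches in results.items():
        for m in matches:
            gene_families.setdefault(gene_map.gene_of(m.protein_id), set()).add(family)

    truth = bundle.truth
    for gid, family in truth.gene_to_family.items():
        assert gene_families.get(gid) == {family}, (
            f"planted {gid} ({family}) screened as {gene_families.get(gid)}"
        )
    for gid in truth.background_genes:
        assert gid not in gene_families, f"background gene {gid} matched a family"


# ---------------------------------------------------------------------------
# sequence evolution along a tree
# ---------------------------------------------------------------------------

def random_tree(n_taxa: int, rng: np.random.Generator,
                blen_range: tuple[float, float] = (0.05, 0.5),
                prefix: str = "t") -> dendropy.Tree:
    """Random unrooted binary topology with uniform branch lengths."""
    if n_taxa < 3:
        raise ValueError("need at least 3 taxa")
    labels = [f"{prefix}{i + 1}" for i in range(n_taxa)]
    tns = dendropy.TaxonNamespace(labels)
    nodes = [dendropy.Node(taxon=tns.get_taxon(lb)) for lb in labels]
    lo, hi = blen_range
    while len(nodes) > 3:
        i, j = sorted(rng.choice(len(nodes), size=2, replace=False))
        parent = dendropy.Node()
        for child in (nodes[i], nodes[j]):
            parent.add_child(child)
            child.edge.length = float(rng.uniform(lo, hi))
        del nodes[j], nodes[i]
        nodes.append(parent)
    root = dendropy.Node()
    for child in nodes:
        root.add_child(child)
        child.edge.length = float(rng.uniform(lo, hi))
    tree = dendropy.Tree(taxon_namespace=tns, seed_node=root)
    tree.is_rooted = False
    return tree


def patristic_distances(tree: dendropy.Tree) -> dict[tuple[str, str], float]:
    """Leaf-to-leaf path lengths, keyed by sorted label pairs."""
    pdm = tree.phylogenetic_distance_matrix()
    out: dict[tuple[str, str], float] = {}
    taxa = list(tree.taxon_namespace)
    for i, ta in enumerate(taxa):
        for tb in taxa[i + 1:]:
            key = tuple(sorted((ta.label, tb.label)))
            out[key] = pdm.patristic_distance(ta, tb)
    return out


def evolve_sequences(
    tree: dendropy.Tree,
    model: RateModel,
    length: int,
    seed: int,
) -> tuple[Alignment, dict[tuple[str, str], float]]:
    """Simulate gap-free amino-acid sequences along a tree under JTT+I+Gamma.

    The root sequence is drawn from the stationary frequencies; each site
    draws its rate once from the invariant/gamma mixture and evolves
    independently, each branch applying P(b * r). Returns the leaf alignment
    and the true patristic distances.
    """
    if length <= 0:
        raise ValueError("alignment length must be positive")
    rng = np.random.default_rng(seed)
    k = model.gamma_categories
    cat_rates = model.category_rates

    u = rng.random(length)
    site_rates = np.empty(length)
    inv_mask = u < model.p_inv
    site_rates[inv_mask] = 0.0
    cats = rng.integers(0, k, size=length)
    site_rates[~inv_mask] = cat_rates[cats[~inv_mask]]

    root_states = rng.choice(20, size=length, p=JTT_FREQS)
    states: dict[int, np.ndarray] = {id(tree.seed_node): root_states}
    rate_values = np.unique(site_rates)

    for nd in tree.preorder_node_iter():
        if nd.parent_node is None:
            continue
        parent_states = states[id(nd.parent_node)]
        b = nd.edge.length or 0.0
        child = parent_states.copy()
        if b > 0:
            for r in rate_values:
                if r == 0.0:
                    continue
                sites = np.where(site_rates == r)[0]
                if sites.size == 0:
                    continue
                p = model.transition_matrix(b * r)
                cum = np.cumsum(p, axis=1)
                cum[:, -1] = 1.0
                draws = rng.random(sites.size)
                rows = cum[parent_states[sites]]
                child[sites] = (rows < draws[:, np.newaxis]).sum(axis=1)
        states[id(nd)] = child

    taxa, seqs = [], []
    for leaf in tree.leaf_node_iter():
        taxa.append(leaf.taxon.label)
        seq = states[id(leaf)]
        seqs.append("".join(AMINO_ACIDS[s] for s in seq))
    order = np.argsort(taxa)
    alignment = Alignment(tuple(taxa[i] for i in order),
                          tuple(seqs[i] for i in order))
    return alignment, patristic_distances(tree)
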