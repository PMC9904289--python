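"""Deterministic synthetic-world generation.

Every other module is testable offline against worlds produced here: a small
host-parasite-vector ecosystem with planted structure whose ground truth is
recorded alongside the data.  The default world mirrors the data shapes a
functional-association backend serves:

* five species — two mammalian hosts, two congeneric apicomplexan
  parasites, one insect vector — with full taxonomic lineages, so the
  orthology-transfer scope rules (parasites within a genus, hosts within a
  class) are exercised on both admissible and inadmissible pairs;
* per-species association networks with planted modules (tight
  high-confidence blocks on a sparse low-confidence background) for
  clustering;
* cross-species edges between host/parasite, parasite/vector, and
  host/vector, carrying experiments/textmining evidence;
* a physical store whose edge set is a subset of the full store;
* proteomes in which ortholog pairs of known similarity are planted by
  mutating a shared ancestor sequence, so reciprocal-best-hit detection has
  a recorded truth;
* alias, annotation (planted enriched terms), document, localization and
  entity-association tables.

A single integer seed fully determines every output byte.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import yaml

from .enrich import AnnotationTable, Document, DocumentTable, Term
from .errors import WorldSpecError
from .model import (
    DEFAULT_PRIOR,
    Edge,
    EvidenceVector,
    Network,
    Node,
    Species,
    write_taxonomy,
)
from .orthology import OrthologMap, ScoringScheme, reciprocal_best_hits
from .store import AliasTable, ScoreStore

AA = "ACDEFGHIKLMNPQRSTVWY"

#: Default ecosystem: (taxid, name, tag, role, genus, family, order, class)
DEFAULT_SPECIES = (
    (9606, "Homo sapiens", "HS", "host",
     ("Homo", "Hominidae", "Primates", "Mammalia")),
    (10090, "Mus musculus", "MM", "host",
     ("Mus", "Muridae", "Rodentia", "Mammalia")),
    (5833, "Plasmodium falciparum", "PF", "parasite",
     ("Plasmodium", "Plasmodiidae", "Haemosporida", "Aconoidasida")),
    (5855, "Plasmodium vivax", "PV", "parasite",
     ("Plasmodium", "Plasmodiidae", "Haemosporida", "Aconoidasida")),
    (7165, "Anopheles gambiae", "AG", "vector",
     ("Anopheles", "Culicidae", "Diptera", "Insecta")),
)


@dataclass
class WorldSpec:
    """Parameters of the synthetic world; the seed determines everything."""

    seed: int = 0
    proteins_per_species: int = 30
    n_modules: int = 3
    module_size: int = 6
    within_module_mean: float = 0.9
    within_module_sd: float = 0.03
    background_mean: float = 0.15
    background_sd: float = 0.05
    background_edge_frac: float = 0.15
    n_cross_edges: int = 25          # per cross-species pair with interactions
    cross_score_low: float = 0.45
    cross_score_high: float = 0.95
    cross_fraction: float = 1.0      # 0 disables cross-species edges entirely
    physical_fraction: float = 0.5
    n_orthologs: int = 8
    sigma_low: float = 0.6
    sigma_high: float = 0.95
    sequence_length: int = 60
    term_extra_proteins: int = 2
    n_random_terms: int = 8
    n_random_documents: int = 6
    prior: float = DEFAULT_PRIOR

    def __post_init__(self):
        for name in ("background_edge_frac", "cross_fraction", "physical_fraction"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise WorldSpecError(f"{name} must be in [0, 1], got {v}")
        if self.n_modules * self.module_size > self.proteins_per_species:
            raise WorldSpecError(
                f"{self.n_modules} modules of size {self.module_size} exceed "
                f"{self.proteins_per_species} proteins per species"
            )
        if self.n_orthologs > self.proteins_per_species:
            raise WorldSpecError("more planted orthologs than proteins")

    @classmethod
    def from_yaml(cls, path) -> "WorldSpec":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls(**data)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.__dict__, fh, sort_keys=True)


@dataclass
class World:
    """A generated world plus its ground truth."""

    spec: WorldSpec
    species: dict[int, Species]
    roles: dict[str, list[int]]                     # role -> taxids
    full: ScoreStore
    physical: ScoreStore
    aliases: AliasTable
    annotations: AnnotationTable
    documents: DocumentTable
    proteomes: dict[int, dict[str, str]]            # taxid -> id -> sequence
    localization: list[tuple[str, str, str, int]]   # protein, ns, name, score
    entity_links: dict[str, list[tuple[str, float]]]
    truth: dict = field(default_factory=dict)

    def protein_ids(self, taxid: int) -> list[str]:
        return sorted(self.proteomes[taxid])

    @property
    def host_pairs(self) -> dict[tuple[int, int], tuple[int, int]]:
        """Source -> target (host, parasite) species pairs for transfer."""
        (h1, h2), (p1, p2) = self.roles["host"], self.roles["parasite"]
        return {(h1, p1): (h2, p2)}

    def compute_ortholog_maps(
        self,
        scheme: Optional[ScoringScheme] = None,
        min_sigma: float = 0.3,
    ) -> dict[tuple[int, int], OrthologMap]:
        """Run RBH on the generated host and parasite proteome pairs."""
        out = {}
        for role in ("host", "parasite"):
            a, b = self.roles[role]
            out[(a, b)] = reciprocal_best_hits(
                self.proteomes[a], self.proteomes[b],
                scheme=scheme, min_sigma=min_sigma,
                species_a=a, species_b=b,
            )
        return out


def _protein_id(taxid: int, tag: str, i: int) -> str:
    return f"{taxid}.{tag}P{i + 1:04d}"


def _gene_name(tag: str, i: int) -> str:
    return f"{tag}G{i + 1}"


def _clipped(rng, mean, sd, lo, hi, size=None):
    return np.clip(rng.normal(mean, sd, size=size), lo, hi)


def _intra_evidence(rng, score: float, background: bool) -> EvidenceVector:
    # a single channel gives combined == score exactly; background edges stay
    # single-channel so their combined score cannot drift above the planted
    # low-confidence level
    if background:
        return EvidenceVector(textmining=round(score, 3))
    if rng.random() < 0.3:
        return EvidenceVector(
            experiments=round(score, 3),
            database=round(float(rng.uniform(0.15, 0.35)), 3),
        )
    return EvidenceVector(experiments=round(score, 3))


def _cross_evidence(rng, score: float) -> EvidenceVector:
    # cross-species evidence comes from experiments and text mining only
    if rng.random() < 0.4:
        return EvidenceVector(
            experiments=round(score, 3),
            textmining=round(float(rng.uniform(0.3, 0.6)), 3),
        )
    ch = "experiments" if rng.random() < 0.5 else "textmining"
    return EvidenceVector({ch: round(score, 3)})


def _mutate(rng, seq: str, rate: float) -> str:
    out = list(seq)
    for i in range(len(out)):
        if rng.random() < rate:
            choices = AA.replace(out[i], "")
            out[i] = choices[rng.integers(len(choices))]
    return "".join(out)


def generate_world(spec: WorldSpec) -> World:
    """Build the full synthetic world from a spec; pure function of the seed."""
    rng = np.random.default_rng(spec.seed)
    species: dict[int, Species] = {}
    roles: dict[str, list[int]] = {"host": [], "parasite": [], "vector": []}
    tags: dict[int, str] = {}
    for taxid, name, tag, role, (genus, family, order, klass) in DEFAULT_SPECIES:
        species[taxid] = Species(
            taxid=taxid, name=name,
            lineage={"genus": genus, "family": family,
                     "order": order, "class": klass},
        )
        roles[role].append(taxid)
        tags[taxid] = tag

    proteins = {
        taxid: [_protein_id(taxid, tags[taxid], i)
                for i in range(spec.proteins_per_species)]
        for taxid in species
    }

    # --- aliases ----------------------------------------------------------
    aliases = AliasTable()
    for taxid in sorted(species):
        for i, pid in enumerate(proteins[taxid]):
            accession = pid.partition(".")[2]
            aliases.add(taxid, pid, pid, "id")
            aliases.add(taxid, accession, pid, "accession")
            aliases.add(taxid, _gene_name(tags[taxid], i), pid, "preferred")

    # --- intraspecies networks with planted modules -----------------------
    full = ScoreStore(network_type="full", prior=spec.prior)
    physical = ScoreStore(network_type="physical", prior=spec.prior)
    modules: dict[int, list[list[str]]] = {}
    for taxid in sorted(species):
        ids = proteins[taxid]
        mods = [
            ids[m * spec.module_size:(m + 1) * spec.module_size]
            for m in range(spec.n_modules)
        ]
        modules[taxid] = mods
        in_module = {pid: m for m, mod in enumerate(mods) for pid in mod}
        for a_i in range(len(ids)):
            for b_i in range(a_i + 1, len(ids)):
                a, b = ids[a_i], ids[b_i]
                same = (
                    a in in_module and b in in_module
                    and in_module[a] == in_module[b]
                )
                if same:
                    score = float(_clipped(
                        rng, spec.within_module_mean, spec.within_module_sd,
                        0.7, 0.999,
                    ))
                    ev = _intra_evidence(rng, score, background=False)
                elif rng.random() < spec.background_edge_frac:
                    score = float(_clipped(
                        rng, spec.background_mean, spec.background_sd,
                        0.05, 0.35,
                    ))
                    ev = _intra_evidence(rng, score, background=True)
                else:
                    continue
                full.add_pair(a, b, ev)
                if rng.random() < spec.physical_fraction:
                    physical.add_pair(a, b, ev)

    # --- cross-species edges ---------------------------------------------
    h1, h2 = roles["host"]
    p1, p2 = roles["parasite"]
    (v1,) = roles["vector"]
    cross_pairs = [(h1, p1), (p1, v1), (h1, v1)]
    n_cross = round(spec.n_cross_edges * spec.cross_fraction)
    for ta, tb in cross_pairs:
        pool_a = proteins[ta][: max(10, spec.n_orthologs)]
        pool_b = proteins[tb][: max(10, spec.n_orthologs)]
        candidates = [(a, b) for a in pool_a for b in pool_b]
        idx = rng.choice(len(candidates), size=min(n_cross, len(candidates)),
                         replace=False)
        for j in sorted(idx):
            a, b = candidates[j]
            score = float(rng.uniform(spec.cross_score_low, spec.cross_score_high))
            ev = _cross_evidence(rng, score)
            full.add_pair(a, b, ev)
            if rng.random() < spec.physical_fraction:
                physical.add_pair(a, b, ev)

    # --- proteomes with planted orthologs --------------------------------
    proteomes: dict[int, dict[str, str]] = {t: {} for t in species}
    ortholog_truth: list[dict] = []
    targets = np.linspace(spec.sigma_low, spec.sigma_high, spec.n_orthologs)
    planted_pairs = [(roles["host"][0], roles["host"][1]),
                     (roles["parasite"][0], roles["parasite"][1])]
    for ta, tb in planted_pairs:
        for i in range(spec.n_orthologs):
            target = float(targets[i])
            ancestor = "".join(AA[k] for k in rng.integers(len(AA),
                                                           size=spec.sequence_length))
            rate = min(0.95, (1.0 - target) / 1.2)
            proteomes[ta][proteins[ta][i]] = ancestor
            proteomes[tb][proteins[tb][i]] = _mutate(rng, ancestor, rate)
            ortholog_truth.append({
                "proteinA": proteins[ta][i], "proteinB": proteins[tb][i],
                "target_sigma": target,
            })
    for taxid in sorted(species):
        for pid in proteins[taxid]:
            if pid not in proteomes[taxid]:
                proteomes[taxid][pid] = "".join(
                    AA[k] for k in rng.integers(len(AA), size=spec.sequence_length)
                )
    # realized sigmas (alignment-based, recorded in the truth table)
    from .orthology import self_normalized_similarity

    scheme = ScoringScheme()
    for rec in ortholog_truth:
        ta = int(rec["proteinA"].partition(".")[0])
        tb = int(rec["proteinB"].partition(".")[0])
        rec["sigma"] = self_normalized_similarity(
            proteomes[ta][rec["proteinA"]], proteomes[tb][rec["proteinB"]], scheme
        )

    # --- annotations with planted terms ----------------------------------
    annotations = AnnotationTable()
    planted_terms: dict[int, list[str]] = {}
    for taxid in sorted(species):
        planted_terms[taxid] = []
        others = [p for p in proteins[taxid]
                  if p not in {x for mod in modules[taxid] for x in mod}]
        for m, mod in enumerate(modules[taxid]):
            extras = list(
                rng.choice(others, size=min(spec.term_extra_proteins, len(others)),
                           replace=False)
            )
            tid = f"PT:{taxid}:{m + 1}"
            annotations.add(Term(
                term_id=tid, category="Process",
                description=f"planted process of module {m + 1}",
                species=taxid, proteins=frozenset(mod) | frozenset(extras),
            ))
            planted_terms[taxid].append(tid)
        for j in range(spec.n_random_terms):
            size = int(rng.integers(4, 11))
            members = rng.choice(proteins[taxid], size=size, replace=False)
            annotations.add(Term(
                term_id=f"RT:{taxid}:{j + 1}", category="Pathway",
                description=f"random pathway {j + 1}",
                species=taxid, proteins=frozenset(members),
            ))

    # --- documents --------------------------------------------------------
    host = roles["host"][0]
    planted_doc = Document(
        doc_id="PMID:9000001", title="Planted study of host module one",
        year=2021,
        proteins=frozenset(modules[host][0]) | {proteins[host][-1]},
    )
    docs = [planted_doc]
    for j in range(spec.n_random_documents):
        size = int(rng.integers(3, 9))
        members = rng.choice(proteins[host], size=size, replace=False)
        docs.append(Document(
            doc_id=f"PMID:8{j + 1:06d}", title=f"Random report {j + 1}",
            year=int(rng.integers(2000, 2023)),
            proteins=frozenset(members),
        ))
    documents = DocumentTable(docs)

    # --- localization -----------------------------------------------------
    localization: list[tuple[str, str, str, int]] = []
    liver_module = set(modules[host][0])
    for taxid in (roles["host"][0], roles["parasite"][0]):
        for pid in proteins[taxid]:
            if taxid == host:
                score = int(rng.integers(3, 6)) if pid in liver_module \
                    else int(rng.integers(0, 4))
                localization.append((pid, "tissue", "liver", score))
            localization.append(
                (pid, "compartment", "nucleus", int(rng.integers(0, 6)))
            )

    # --- entity associations (disease/topic analog) -----------------------
    entity_links = {
        "malaria": [
            (pid, round(0.95 - 0.04 * r, 3))
            for r, pid in enumerate(modules[host][0] + modules[host][1][:4])
        ],
        "growth": [
            (pid, round(0.9 - 0.05 * r, 3))
            for r, pid in enumerate(modules[roles["parasite"][0]][0])
        ],
    }

    truth = {
        "modules": modules,
        "terms": planted_terms,
        "orthologs": ortholog_truth,
        "planted_document": planted_doc.doc_id,
    }
    return World(
        spec=spec, species=species, roles=roles, full=full, physical=physical,
        aliases=aliases, annotations=annotations, documents=documents,
        proteomes=proteomes, localization=localization,
        entity_links=entity_links, truth=truth,
    )


# --- AP-MS style user table ----------------------------------------------

FOREIGN_TAXID = 2697049  # planted viral species, absent from every table


def generate_apms_table(
    spec: WorldSpec, n_baits: int = 2, preys_per_bait: int = 5
) -> list[dict]:
    """Bait-prey rows with a Bait_ID group column.

    Baits belong to a foreign species with no aliases (unmappable); preys
    are gene names of the first host species (mappable).  Each prey row's
    ``Bait_ID`` is its bait's name.
    """
    if n_baits < 1:
        raise WorldSpecError("n_baits must be >= 1")
    world_rng = np.random.default_rng(spec.seed + 101)
    tag = DEFAULT_SPECIES[0][2]
    n_prot = spec.proteins_per_species
    need = n_baits * preys_per_bait
    if need > n_prot:
        raise WorldSpecError("more preys requested than host proteins")
    prey_idx = world_rng.choice(n_prot, size=need, replace=False)
    rows = []
    for b in range(n_baits):
        bait = f"VP{b + 1}"
        for k in range(preys_per_bait):
            prey = _gene_name(tag, int(prey_idx[b * preys_per_bait + k]))
            rows.append({"bait": bait, "prey": prey, "Bait_ID": bait})
    return rows


def write_apms_tsv(rows: list[dict], path) -> None:
    with open(path, "w", newline="") as fh:
        fh.write("bait\tprey\tBait_ID\n")
        for r in rows:
            fh.write(f"{r['bait']}\t{r['prey']}\t{r['Bait_ID']}\n")


def read_apms_tsv(path) -> list[dict]:
    import csv

    with open(path, newline="") as fh:
        return list(csv.DictReader(fh, delimiter="\t"))


def apms_network(rows: list[dict], host_taxid: int = 9606) -> Network:
    """Build the user network a bait-prey table describes.

    Bait nodes carry the foreign species; prey nodes claim the host species.
    Every node stores its user-facing name under the ``name`` attribute
    (the identifier column used for mapping) and preys carry their bait's
    name under ``Bait_ID``.
    """
    net = Network(network_type="full", cutoff=0.4)
    for r in rows:
        bait, prey = r["bait"], r["prey"]
        if bait not in net.nodes:
            net.add_node(Node(
                id=bait, node_type="protein", species=FOREIGN_TAXID,
                display_name=bait, attributes={"name": bait},
            ))
        if prey not in net.nodes:
            net.add_node(Node(
                id=prey, node_type="protein", species=host_taxid,
                display_name=prey,
                attributes={"name": prey, "Bait_ID": r["Bait_ID"]},
            ))
        net.add_edge(Edge(
            endpoints=(bait, prey), interaction_type="user",
            combined_score=0.0, source="lifted",
        ))
    return net


# --- focused mini-fixtures for statistical replicates ---------------------

def planted_partition_network(
    seed: int,
    n_blocks: int = 3,
    block_size: int = 6,
    within_weight: float = 0.9,
    between_weight: float = 0.15,
    weight_sd: float = 0.03,
    between_frac: float = 1.0,
) -> tuple[Network, list[list[str]]]:
    """A weighted planted-partition network plus its true blocks."""
    rng = np.random.default_rng(seed)
    net = Network(network_type="full", cutoff=0.0)
    blocks: list[list[str]] = []
    for b in range(n_blocks):
        block = [f"9606.BL{b + 1}N{i + 1:02d}" for i in range(block_size)]
        blocks.append(block)
        for pid in block:
            net.add_node(Node(id=pid))
    all_ids = [pid for block in blocks for pid in block]
    member = {pid: b for b, block in enumerate(blocks) for pid in block}
    for i, a in enumerate(all_ids):
        for b_ in all_ids[i + 1:]:
            same = member[a] == member[b_]
            if not same and rng.random() >= between_frac:
                continue
            mean = within_weight if same else between_weight
            w = float(np.clip(rng.normal(mean, weight_sd), 0.05, 0.999))
            w = round(w, 3)
            ev = EvidenceVector(experiments=w)
            net.add_edge(Edge(
                endpoints=(a, b_), evidence=ev, combined_score=w,
                source="store",
            ))
    return net, blocks


def planted_enrichment_case(
    seed: int,
    n_background: int = 500,
    query_size: int = 20,
    coverage: float = 0.8,
    n_random_terms: int = 30,
    species: int = 9606,
) -> tuple[set[str], AnnotationTable, str]:
    """A query with one planted enriched term against a large background.

    The planted term covers ``coverage`` of the query plus a few background
    proteins; random terms of comparable size are added as distractors.
    Returns (query set, annotation table, planted term id).
    """
    rng = np.random.default_rng(seed)
    background = [f"{species}.BG{i + 1:04d}" for i in range(n_background)]
    query = set(rng.choice(background, size=query_size, replace=False))
    covered = set(rng.choice(sorted(query), size=math.ceil(coverage * query_size),
                             replace=False))
    extras = set(rng.choice(
        [p for p in background if p not in query], size=5, replace=False
    ))
    table = AnnotationTable()
    planted_id = "PT:planted"
    table.add(Term(
        term_id=planted_id, category="Process", description="planted term",
        species=species, proteins=frozenset(covered | extras),
    ))
    for j in range(n_random_terms):
        size = int(rng.integers(5, 26))
        members = rng.choice(background, size=size, replace=False)
        table.add(Term(
            term_id=f"RT:{j + 1}", category="Process",
            description=f"random term {j + 1}",
            species=species, proteins=frozenset(members),
        ))
    return query, table, planted_id


# --- world directory writer ----------------------------------------------

def write_world(world: World, directory) -> None:
    """Serialize every world table into a directory (canonical TSV/FASTA)."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    write_taxonomy(world.species.values(), directory / "taxonomy.tsv")
    world.full.write_tsv(directory / "scores.full.tsv")
    world.physical.write_tsv(directory / "scores.physical.tsv")
    world.aliases.write_tsv(directory / "aliases.tsv")
    world.annotations.write_tsv(directory / "annotations.tsv")
    world.documents.write_tsv(directory / "documents.tsv")
    world.spec.to_yaml(directory / "world.yaml")

    with open(directory / "localization.tsv", "w") as fh:
        fh.write("protein\tnamespace\tname\tscore\n")
        for pid, ns, name, score in sorted(world.localization):
            fh.write(f"{pid}\t{ns}\t{name}\t{score}\n")

    with open(directory / "entities.tsv", "w") as fh:
        fh.write("entity\tprotein\tscore\n")
        for entity in sorted(world.entity_links):
            for pid, score in world.entity_links[entity]:
                fh.write(f"{entity}\t{pid}\t{score}\n")

    for taxid in sorted(world.proteomes):
        with open(directory / f"proteome_{taxid}.fasta", "w") as fh:
            for pid in sorted(world.proteomes[taxid]):
                fh.write(f">{pid}\n{world.proteomes[taxid][pid]}\n")

    with open(directory / "truth_modules.tsv", "w") as fh:
        fh.write("taxid\tmodule\tprotein\n")
        for taxid in sorted(world.truth["modules"]):
            for m, mod in enumerate(world.truth["modules"][taxid]):
                for pid in mod:
                    fh.write(f"{taxid}\t{m + 1}\t{pid}\n")

    with open(directory / "truth_orthologs.tsv", "w") as fh:
        fh.write("proteinA\tproteinB\ttarget_sigma\tsigma\n")
        for rec in world.truth["orthologs"]:
            fh.write(
                f"{rec['proteinA']}\t{rec['proteinB']}\t"
                f"{rec['target_sigma']:.4f}\t{rec['sigma']:.6f}\n"
            )

    with open(directory / "truth_terms.tsv", "w") as fh:
        fh.write("taxid\tterm\n")
        for taxid in sorted(world.truth["terms"]):
            for tid in world.truth["terms"][taxid]:
                fh.write(f"{taxid}\t{tid}\n")

    rows = generate_apms_table(world.spec)
    write_apms_tsv(rows, directory / "apms.tsv")


def read_entity_links(path) -> dict[str, list[tuple[str, float]]]:
    import csv

    out: dict[str, list[tuple[str, float]]] = {}
    with open(path, newline="") as fh:
        for rec in csv.DictReader(fh, delimiter="\t"):
            out.setdefault(rec["entity"], []).append(
                (rec["protein"], float(rec["score"]))
            )
    return out


def load_proteome_fasta(path) -> dict[str, str]:
    """Read a proteome FASTA into an id -> sequence map."""
    from Bio import SeqIO

    return {rec.id: str(rec.seq) for rec in SeqIO.parse(str(path), "fasta")}
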