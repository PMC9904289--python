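"""Over-representation enrichment with BH-FDR, group-wise analysis,
redundancy filtering, publication enrichment, and term-node injection.

Each annotation term (or each publication's text-mined gene set) is tested
for over-representation in a query protein set against a background with a
one-sided hypergeometric test; p-values are corrected per category with the
Benjamini-Hochberg procedure and terms with FDR below the cutoff (default
0.05) are reported.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional

from scipy.stats import hypergeom
from statsmodels.stats.multitest import multipletests

from .errors import (
    InvalidArgumentError,
    InvalidBackgroundError,
    NoGroupsError,
    ParseError,
)
from .model import Edge, Network, Node


@dataclass
class Term:
    term_id: str
    category: str
    description: str
    species: int
    proteins: frozenset[str]

    def __post_init__(self):
        if not self.proteins:
            raise InvalidArgumentError(f"term {self.term_id!r} annotates no proteins")


class AnnotationTable:
    """Terms grouped by category, each with its annotated protein set."""

    def __init__(self, terms: Iterable[Term] = ()):
        self.terms: dict[tuple[str, str], Term] = {}
        for t in terms:
            self.add(t)

    def add(self, term: Term) -> None:
        key = (term.category, term.term_id)
        if key in self.terms:
            raise InvalidArgumentError(f"duplicate term {key}")
        self.terms[key] = term

    def for_species(self, species: int) -> list[Term]:
        return [t for t in self.terms.values() if t.species == species]

    def annotated_proteins(self, species: int) -> frozenset[str]:
        out: set[str] = set()
        for t in self.for_species(species):
            out |= t.proteins
        return frozenset(out)

    def write_tsv(self, path) -> None:
        with open(path, "w", newline="") as fh:
            fh.write("term\tcategory\tdescription\tspecies\tproteins\n")
            for key in sorted(self.terms):
                t = self.terms[key]
                fh.write(
                    f"{t.term_id}\t{t.category}\t{t.description}\t{t.species}\t"
                    + ",".join(sorted(t.proteins))
                    + "\n"
                )

    @classmethod
    def read_tsv(cls, path) -> "AnnotationTable":
        table = cls()
        with open(path, newline="") as fh:
            for ln, rec in enumerate(csv.DictReader(fh, delimiter="\t"), start=2):
                try:
                    table.add(
                        Term(
                            term_id=rec["term"],
                            category=rec["category"],
                            description=rec.get("description", ""),
                            species=int(rec["species"]),
                            proteins=frozenset(rec["proteins"].split(",")),
                        )
                    )
                except (KeyError, ValueError) as exc:
                    raise ParseError(f"{path}:{ln}: {exc}") from exc
        return table


@dataclass
class Document:
    doc_id: str
    title: str
    year: int
    proteins: frozenset[str]

    def __post_init__(self):
        if not self.proteins:
            raise InvalidArgumentError(f"document {self.doc_id!r} mentions no proteins")


class DocumentTable:
    """Publications with their text-mined gene mentions."""

    def __init__(self, documents: Iterable[Document] = ()):
        self.documents: dict[str, Document] = {}
        for d in documents:
            self.documents[d.doc_id] = d

    def write_tsv(self, path) -> None:
        with open(path, "w", newline="") as fh:
            fh.write("document\tyear\ttitle\tproteins\n")
            for did in sorted(self.documents):
                d = self.documents[did]
                fh.write(
                    f"{d.doc_id}\t{d.year}\t{d.title}\t"
                    + ",".join(sorted(d.proteins))
                    + "\n"
                )

    @classmethod
    def read_tsv(cls, path) -> "DocumentTable":
        table = cls()
        with open(path, newline="") as fh:
            for ln, rec in enumerate(csv.DictReader(fh, delimiter="\t"), start=2):
                try:
                    table.documents[rec["document"]] = Document(
                        doc_id=rec["document"],
                        title=rec.get("title", ""),
                        year=int(rec["year"]),
                        proteins=frozenset(rec["proteins"].split(",")),
                    )
                except (KeyError, ValueError) as exc:
                    raise ParseError(f"{path}:{ln}: {exc}") from exc
        return table

    def as_annotations(self, species: int) -> AnnotationTable:
        """Recast every document as a term of category 'publication'."""
        return AnnotationTable(
            Term(
                term_id=d.doc_id,
                category="publication",
                description=d.title,
                species=species,
                proteins=d.proteins,
            )
            for d in self.documents.values()
        )


@dataclass
class EnrichmentResult:
    """One enriched term.

    ``k``/``K`` are the numbers of query and background proteins the term
    annotates; ``n``/``N`` the query and background sizes.
    """

    term_id: str
    category: str
    description: str
    p_value: float
    fdr: float
    k: int
    K: int
    n: int
    N: int
    genes: tuple[str, ...]
    group: Optional[str] = None
    extras: dict = field(default_factory=dict)


def bh_fdr(p_values) -> list[float]:
    """Benjamini-Hochberg adjusted p-values, in input order."""
    if len(p_values) == 0:
        return []
    return [float(q) for q in multipletests(p_values, method="fdr_bh")[1]]


def hypergeom_tail(k: int, K: int, n: int, N: int) -> float:
    """Exact upper tail P[X >= k] for X ~ Hypergeometric(N, K, n)."""
    if not (0 <= k <= min(n, K) <= N and n <= N and K <= N):
        raise InvalidArgumentError(
            f"inconsistent counts k={k}, K={K}, n={n}, N={N}"
        )
    return float(hypergeom.sf(k - 1, N, K, n))


def enrich(
    query: Iterable[str],
    species: int,
    annotations: AnnotationTable,
    background: Optional[Iterable[str]] = None,
    fdr_cutoff: float = 0.05,
) -> list[EnrichmentResult]:
    """Over-representation analysis of a query set against a background.

    The background defaults to all annotated proteins of the species.  Terms
    annotating no query protein are not tested (they cannot be enriched and
    would only inflate the BH divisor).  BH correction is applied within
    each category; results with FDR below the cutoff are returned sorted by
    (FDR, term id).
    """
    query = set(query)
    if not query:
        raise InvalidArgumentError("query set is empty")
    terms = annotations.for_species(species)
    bg = (
        set(background)
        if background is not None
        else set(annotations.annotated_proteins(species))
    )
    effective_query = query & bg
    if not effective_query:
        raise InvalidBackgroundError("query is disjoint from the background")
    n, N = len(effective_query), len(bg)

    tested: dict[str, list[tuple[Term, int, int, float, tuple[str, ...]]]] = {}
    for term in terms:
        term_bg = term.proteins & bg
        hits = tuple(sorted(term.proteins & effective_query))
        k, K = len(hits), len(term_bg)
        if k == 0 or K == 0:
            continue
        p = hypergeom_tail(k, K, n, N)
        tested.setdefault(term.category, []).append((term, k, K, p, hits))

    results: list[EnrichmentResult] = []
    for category, rows in tested.items():
        fdrs = bh_fdr([r[3] for r in rows])
        for (term, k, K, p, hits), fdr in zip(rows, fdrs):
            # a cutoff of 1.0 is a no-op filter (adjusted p never exceeds 1)
            if fdr < fdr_cutoff or fdr_cutoff >= 1.0:
                results.append(
                    EnrichmentResult(
                        term_id=term.term_id,
                        category=category,
                        description=term.description,
                        p_value=p,
                        fdr=float(fdr),
                        k=k,
                        K=K,
                        n=n,
                        N=N,
                        genes=hits,
                    )
                )
    results.sort(key=lambda r: (r.fdr, r.term_id))
    return results


def enrich_groups(
    network: Network,
    group_attribute: str,
    species: int,
    annotations: AnnotationTable,
    background: Optional[Iterable[str]] = None,
    fdr_cutoff: float = 0.05,
) -> dict[str, list[EnrichmentResult]]:
    """Independent enrichment for each value of a node attribute.

    Nodes lacking the attribute are excluded; the groups are disjoint by
    construction.  Each group's results equal ``enrich()`` on exactly that
    node subset.  Groups whose members fall outside the background yield an
    empty result list rather than an error.
    """
    groups: dict[str, set[str]] = {}
    for nid, node in network.nodes.items():
        value = node.attributes.get(group_attribute)
        if value is not None:
            groups.setdefault(str(value), set()).add(nid)
    if not groups:
        raise NoGroupsError(
            f"attribute {group_attribute!r} is absent from every node"
        )
    out: dict[str, list[EnrichmentResult]] = {}
    for label in sorted(groups):
        try:
            results = enrich(
                groups[label], species, annotations,
                background=background, fdr_cutoff=fdr_cutoff,
            )
        except InvalidBackgroundError:
            results = []
        for r in results:
            r.group = label
        out[label] = results
    return out


def filter_redundant(
    results: list[EnrichmentResult], jaccard_cutoff: float = 0.5
) -> list[EnrichmentResult]:
    """Greedy redundancy filter over the annotated-query-gene sets.

    Scanning in FDR order, a term is dropped when its gene set has Jaccard
    similarity at or above the cutoff with any already-retained term.
    """
    ordered = sorted(results, key=lambda r: (r.fdr, r.term_id))
    kept: list[EnrichmentResult] = []
    for r in ordered:
        genes = set(r.genes)
        redundant = any(
            len(genes & set(o.genes)) / len(genes | set(o.genes)) >= jaccard_cutoff
            for o in kept
        )
        if not redundant:
            kept.append(r)
    return kept


def enrich_publications(
    query: Iterable[str],
    species: int,
    documents: DocumentTable,
    background: Optional[Iterable[str]] = None,
    fdr_cutoff: float = 0.05,
) -> list[EnrichmentResult]:
    """Publication enrichment: each document's gene set is one term.

    Statistics are identical to :func:`enrich`; results carry the document
    title and year in ``extras``.
    """
    results = enrich(
        query, species, documents.as_annotations(species),
        background=background, fdr_cutoff=fdr_cutoff,
    )
    for r in results:
        doc = documents.documents[r.term_id]
        r.extras["title"] = doc.title
        r.extras["year"] = doc.year
    return results


def term_node_id(result: EnrichmentResult) -> str:
    return f"term:{result.category}:{result.term_id}"


def add_term_node(network: Network, result: EnrichmentResult) -> Network:
    """Inject an enriched term as a node linked to its annotated proteins.

    Adds one node of type ``enriched_term`` (attributes: fdr, category,
    genes annotated in query and background) and one ``enrichment`` edge per
    annotated query protein present in the network.  Idempotent: re-adding
    the same term is a no-op.
    """
    missing = [g for g in result.genes if g not in network.nodes]
    if missing:
        raise InvalidArgumentError(
            f"annotated genes not in network: {missing}"
        )
    nid = term_node_id(result)
    net = network.copy()
    if nid in net.nodes:
        return net
    net.add_node(
        Node(
            id=nid,
            node_type="enriched_term",
            species=None,
            display_name=result.description or result.term_id,
            attributes={
                "fdr": result.fdr,
                "category": result.category,
                "genes in query": result.k,
                "genes in background": result.K,
            },
        )
    )
    for gene in result.genes:
        net.add_edge(
            Edge(
                endpoints=(nid, gene),
                interaction_type="enrichment",
                combined_score=0.0,
                source="store",
            )
        )
    return net


ENRICHMENT_COLUMNS = (
    "term", "category", "description", "p_value", "fdr",
    "genes_in_query", "genes_in_background", "query_size",
    "background_size", "genes", "group",
)


def write_results_tsv(results: Iterable[EnrichmentResult], path) -> None:
    """Export enrichment rows with the on-screen table columns."""
    with open(path, "w", newline="") as fh:
        fh.write("\t".join(ENRICHMENT_COLUMNS) + "\n")
        for r in results:
            fh.write(
                "\t".join(
                    [
                        r.term_id, r.category, r.description,
                        f"{r.p_value:.6g}", f"{r.fdr:.6g}",
                        str(r.k), str(r.K), str(r.n), str(r.N),
                        ",".join(r.genes), r.group or "",
                    ]
                )
                + "\n"
            )
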