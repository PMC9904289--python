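"""Orthology detection and cross-species transfer of interaction evidence.

Interactions observed in one host-parasite species pair are projected onto
orthologous protein pairs in related species pairs ("interolog" transfer).
Orthologs are detected by reciprocal best hits (RBH) of Smith-Waterman local
alignments; each ortholog pair carries a self-normalized similarity

    sigma(a, b) = SW(a, b) / sqrt(SW(a, a) * SW(b, b))

which is 1 for identical sequences and symmetric.  Transfer is restricted to
a taxonomic scope (by default, parasites must share a genus and hosts a
class) and every transferred channel score is penalized multiplicatively by
``(sigma_host * sigma_parasite) ** alpha``.  Transferred evidence is merged
with direct evidence by :func:`assocnet.evidence.aggregate_evidence` and is
itself never re-transferred (no daisy-chaining).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from math import sqrt
from typing import Mapping, Optional

import numpy as np
from Bio import Align
from Bio.Align import substitution_matrices

from .errors import (
    DegenerateSequenceError,
    InvalidArgumentError,
    MissingLineageError,
)
from .model import DEFAULT_PRIOR, EvidenceVector, Species

AA_ALPHABET = "ACDEFGHIKLMNPQRSTVWY"
_EXTENDED = AA_ALPHABET + "X"


def _wildcard_blosum62() -> substitution_matrices.Array:
    """BLOSUM62 with every pairing against X scored 0 (wildcard)."""
    m = substitution_matrices.load("BLOSUM62")
    arr = m.copy()
    for aa in m.alphabet:
        arr["X", aa] = 0
        arr[aa, "X"] = 0
    return arr


@dataclass
class ScoringScheme:
    """Alignment parameters: substitution matrix plus affine gap costs.

    A gap of length L costs ``gap_open + (L - 1) * gap_extend``.
    Defaults are the standard protein settings BLOSUM62 / -11 / -1.
    """

    matrix: substitution_matrices.Array = field(default_factory=_wildcard_blosum62)
    gap_open: int = -11
    gap_extend: int = -1

    def __post_init__(self):
        if self.gap_open >= 0 or self.gap_extend >= 0:
            raise InvalidArgumentError("gap penalties must be negative")

    def substitution(self, a: str, b: str) -> float:
        return float(self.matrix[a, b])

    def aligner(self) -> Align.PairwiseAligner:
        al = Align.PairwiseAligner()
        al.mode = "local"
        al.substitution_matrix = self.matrix
        al.open_gap_score = self.gap_open
        al.extend_gap_score = self.gap_extend
        return al


def _check_sequence(seq: str, label: str) -> None:
    if not seq:
        raise InvalidArgumentError(f"{label}: empty sequence")
    bad = set(seq) - set(_EXTENDED)
    if bad:
        raise InvalidArgumentError(
            f"{label}: illegal residues {sorted(bad)} (alphabet {_EXTENDED})"
        )


def smith_waterman(
    a: str, b: str, scheme: Optional[ScoringScheme] = None
) -> tuple[float, Optional[Align.Alignment]]:
    """Maximal local alignment score of two protein sequences.

    Returns ``(score, alignment)``; the alignment is None when the optimal
    score is 0 (empty local alignment).  Symmetric and non-negative.
    """
    scheme = scheme or ScoringScheme()
    _check_sequence(a, "first sequence")
    _check_sequence(b, "second sequence")
    al = scheme.aligner()
    score = float(al.score(a, b))
    if score <= 0.0:
        return 0.0, None
    return score, next(iter(al.align(a, b)))


def self_normalized_similarity(
    a: str, b: str, scheme: Optional[ScoringScheme] = None
) -> float:
    """Similarity sigma in (0, 1]: SW(a,b) / sqrt(SW(a,a) * SW(b,b))."""
    scheme = scheme or ScoringScheme()
    saa, _ = smith_waterman(a, a, scheme)
    sbb, _ = smith_waterman(b, b, scheme)
    if saa <= 0.0 or sbb <= 0.0:
        raise DegenerateSequenceError(
            "sequence has non-positive self-alignment score; "
            "cannot self-normalize"
        )
    sab, _ = smith_waterman(a, b, scheme)
    return min(1.0, sab / sqrt(saa * sbb))


@dataclass
class OrthologMap:
    """One-to-one RBH ortholog pairs between two species, with sigmas."""

    species_a: int
    species_b: int
    entries: dict[str, tuple[str, float]] = field(default_factory=dict)
    #: reverse index: protein in B -> (protein in A, sigma)
    _reverse: dict[str, tuple[str, float]] = field(default_factory=dict, repr=False)

    def add(self, prot_a: str, prot_b: str, sigma: float) -> None:
        if not 0.0 < sigma <= 1.0:
            raise InvalidArgumentError(f"sigma {sigma} outside (0, 1]")
        if prot_a in self.entries or prot_b in self._reverse:
            raise InvalidArgumentError(
                f"ortholog map not one-to-one at {prot_a!r}/{prot_b!r}"
            )
        self.entries[prot_a] = (prot_b, sigma)
        self._reverse[prot_b] = (prot_a, sigma)

    def lookup(self, prot: str) -> Optional[tuple[str, float]]:
        """Map a protein from either species to its ortholog and sigma."""
        return self.entries.get(prot) or self._reverse.get(prot)

    def pairs(self) -> list[tuple[str, str, float]]:
        return sorted((a, b, s) for a, (b, s) in self.entries.items())

    def __len__(self):
        return len(self.entries)

    def write_tsv(self, path) -> None:
        with open(path, "w") as fh:
            fh.write("proteinA\tproteinB\tsigma\n")
            for a, b, s in self.pairs():
                fh.write(f"{a}\t{b}\t{s:.6f}\n")

    @classmethod
    def read_tsv(cls, path, species_a: int, species_b: int) -> "OrthologMap":
        import csv

        om = cls(species_a, species_b)
        with open(path, newline="") as fh:
            for row in csv.DictReader(fh, delimiter="\t"):
                om.add(row["proteinA"], row["proteinB"], float(row["sigma"]))
        return om


def _best_hits(
    scores: np.ndarray, ids_q: list[str], ids_t: list[str]
) -> dict[str, str]:
    """Unique best hit per query row; ties for the best score discard the query."""
    best: dict[str, str] = {}
    for i, q in enumerate(ids_q):
        row = scores[i]
        top = row.max()
        if top <= 0:
            continue
        winners = np.flatnonzero(row == top)
        if len(winners) == 1:
            best[q] = ids_t[winners[0]]
    return best


def reciprocal_best_hits(
    proteome_a: Mapping[str, str],
    proteome_b: Mapping[str, str],
    scheme: Optional[ScoringScheme] = None,
    min_sigma: float = 0.3,
    species_a: int = 0,
    species_b: int = 0,
) -> OrthologMap:
    """Detect orthologs between two proteomes by reciprocal best hits.

    A pair (x, y) is kept iff y is x's unique best Smith-Waterman hit in B,
    x is y's unique best hit in A, and sigma(x, y) >= ``min_sigma``.  Exact
    best-score ties disqualify the tied query (determinism over guessing).
    """
    if not proteome_a or not proteome_b:
        raise InvalidArgumentError("proteomes must be non-empty")
    scheme = scheme or ScoringScheme()
    al = scheme.aligner()
    ids_a = sorted(proteome_a)
    ids_b = sorted(proteome_b)
    scores = np.zeros((len(ids_a), len(ids_b)))
    for i, x in enumerate(ids_a):
        for j, y in enumerate(ids_b):
            scores[i, j] = al.score(proteome_a[x], proteome_b[y])
    fwd = _best_hits(scores, ids_a, ids_b)
    rev = _best_hits(scores.T, ids_b, ids_a)

    self_scores = {
        x: al.score(proteome_a[x], proteome_a[x]) for x in ids_a
    }
    self_scores.update({y: al.score(proteome_b[y], proteome_b[y]) for y in ids_b})

    omap = OrthologMap(species_a, species_b)
    for x in ids_a:
        y = fwd.get(x)
        if y is None or rev.get(y) != x:
            continue
        saa, sbb = self_scores[x], self_scores[y]
        if saa <= 0 or sbb <= 0:
            continue
        sigma = min(1.0, scores[ids_a.index(x), ids_b.index(y)] / sqrt(saa * sbb))
        if sigma >= min_sigma:
            omap.add(x, y, sigma)
    return omap


@dataclass
class TransferPolicy:
    """Taxonomic scope and similarity penalty for evidence transfer.

    Transfer between species pairs (host_1, parasite_1) -> (host_2,
    parasite_2) is admissible only when the two parasites share the taxon at
    ``parasite_scope`` and the two hosts share the taxon at ``host_scope``.
    Every channel score is multiplied by ``(sigma_h * sigma_p) ** alpha``.
    """

    parasite_scope: str = "genus"
    host_scope: str = "class"
    alpha: float = 1.0

    def __post_init__(self):
        from .model import LINEAGE_RANKS

        for scope in (self.parasite_scope, self.host_scope):
            if scope not in LINEAGE_RANKS:
                raise InvalidArgumentError(f"unknown lineage rank {scope!r}")
        if self.alpha < 0:
            raise InvalidArgumentError("penalty exponent alpha must be >= 0")


def _shared_taxon(
    tax_a: int, tax_b: int, rank: str, taxonomy: Mapping[int, Species]
) -> bool:
    for t in (tax_a, tax_b):
        if t not in taxonomy:
            raise MissingLineageError(f"taxid {t} absent from taxonomy")
    return taxonomy[tax_a].lineage[rank] == taxonomy[tax_b].lineage[rank]


def penalize(ev: EvidenceVector, sigma_host: float, sigma_parasite: float,
             alpha: float = 1.0) -> EvidenceVector:
    """Scale every channel by the similarity penalty."""
    factor = (sigma_host * sigma_parasite) ** alpha
    return EvidenceVector({ch: ev[ch] * factor for ch in ev})


def transfer_pair_evidence(
    host_prot: str,
    parasite_prot: str,
    evidence: EvidenceVector,
    ortho_host: OrthologMap,
    ortho_parasite: OrthologMap,
    policy: TransferPolicy,
    taxonomy: Mapping[int, Species],
) -> Optional[tuple[str, str, EvidenceVector]]:
    """Project one host-parasite pair's evidence onto the orthologous pair.

    Returns ``(host_ortholog, parasite_ortholog, penalized_evidence)`` or
    None when an endpoint lacks an ortholog or the target species pair falls
    outside the policy's taxonomic scope.  Transferred channel scores never
    exceed the source's.
    """
    from .model import species_of

    hit_h = ortho_host.lookup(host_prot)
    hit_p = ortho_parasite.lookup(parasite_prot)
    if hit_h is None or hit_p is None:
        return None
    (host_t, sigma_h), (para_t, sigma_p) = hit_h, hit_p
    if not _shared_taxon(
        species_of(host_prot), species_of(host_t), policy.host_scope, taxonomy
    ):
        return None
    if not _shared_taxon(
        species_of(parasite_prot), species_of(para_t),
        policy.parasite_scope, taxonomy,
    ):
        return None
    return host_t, para_t, penalize(evidence, sigma_h, sigma_p, policy.alpha)


def build_transferred_store(
    store,
    host_pairs: Mapping[tuple[int, int], tuple[int, int]],
    ortholog_maps: Mapping[tuple[int, int], OrthologMap],
    policy: TransferPolicy,
    taxonomy: Mapping[int, Species],
    prior: float = DEFAULT_PRIOR,
):
    """Augment a score store with orthology-transferred evidence.

    ``host_pairs`` maps each source (host_taxid, parasite_taxid) pair to the
    target species pair to transfer toward; ``ortholog_maps`` holds the RBH
    map for every (source_taxid, target_taxid) species combination involved.
    Only rows whose evidence is purely direct act as transfer sources, so
    re-running on the output is a no-op (no daisy-chaining).

    Returns a new store of the same network type; the input is not mutated.
    """
    from .evidence import aggregate_evidence
    from .store import ScoreStore

    out = ScoreStore(network_type=store.network_type, prior=prior)
    # carry over all rows, preserving the direct portion
    for (ta, tb), rows in store.tables.items():
        for (p1, p2), row in rows.items():
            out.add_pair(
                p1, p2, row.evidence,
                transferred=row.transferred, direct=row.direct,
            )

    # collect admissible transfers per target pair
    incoming: dict[tuple[str, str], list[EvidenceVector]] = {}
    for (src_host, src_para), (tgt_host, tgt_para) in host_pairs.items():
        o_host = ortholog_maps.get((src_host, tgt_host)) or ortholog_maps.get(
            (tgt_host, src_host)
        )
        o_para = ortholog_maps.get((src_para, tgt_para)) or ortholog_maps.get(
            (tgt_para, src_para)
        )
        if o_host is None or o_para is None:
            continue
        for host_p, para_p, row in store.iter_cross_pairs(src_host, src_para):
            if row.direct.is_empty():
                continue  # transferred evidence is never a transfer source
            hit = transfer_pair_evidence(
                host_p, para_p, row.direct, o_host, o_para, policy, taxonomy
            )
            if hit is None:
                continue
            host_t, para_t, ev = hit
            if not ev.is_empty():
                incoming.setdefault((host_t, para_t), []).append(ev)

    for (p1, p2), vectors in incoming.items():
        direct_row = out.get_pair(p1, p2)
        direct = direct_row.direct if direct_row is not None else EvidenceVector()
        merged, _ = aggregate_evidence(
            direct, sorted(vectors, key=lambda v: sorted(v.items())), p=prior
        )
        out.add_pair(p1, p2, merged, transferred=True, direct=direct)
    return out
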