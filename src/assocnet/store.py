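"""File-backed evidence-score tables with pair and neighbor lookup.

The backend holds one table per species pair (taxidA <= taxidB), each row a
protein pair with per-channel confidence scores and a combined score.  Two
store instances exist side by side in a typical deployment: the *full*
network of functional associations and the *physical* subnetwork.

Scores are serialized as integers in 0-1000 (thousandths) and parsed back to
[0, 1]; channel scores are snapped to that grid at insertion so round-trips
are lossless and the combined score is always exactly
``combine_channels(evidence, prior)`` recomputed from the stored channels.

Rows keep the direct-evidence vector alongside the merged (direct +
transferred) vector so orthology transfer can be re-run without
daisy-chaining: only the direct portion ever acts as a transfer source.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Optional

from .errors import AmbiguousAliasError, ParseError
from .evidence import combine_channels
from .model import CHANNELS, DEFAULT_PRIOR, EvidenceVector, species_of

#: Largest storable channel score: 0.999.  1000 would denote certainty,
#: which the store never asserts.
MAX_MILLI = 999


def quantize(s: float) -> float:
    """Snap a score to the integer-thousandths grid, capped below 1."""
    return min(MAX_MILLI, round(s * 1000)) / 1000


def _quantize_vector(ev: EvidenceVector) -> EvidenceVector:
    return EvidenceVector({ch: quantize(ev[ch]) for ch in ev})


@dataclass
class Row:
    """One stored protein pair."""

    evidence: EvidenceVector          # merged (direct + transferred)
    combined: float
    direct: EvidenceVector            # direct-only portion
    transferred: bool = False


class ScoreStore:
    """Per-species-pair evidence tables with an index for neighbor lookup."""

    def __init__(self, network_type: str = "full", prior: float = DEFAULT_PRIOR):
        if network_type not in ("full", "physical"):
            raise ParseError(f"unknown network type {network_type!r}")
        self.network_type = network_type
        self.prior = prior
        self.tables: dict[tuple[int, int], dict[tuple[str, str], Row]] = {}
        self._neighbors: dict[str, dict[str, float]] = {}

    # -- construction -----------------------------------------------------

    def add_pair(
        self,
        p1: str,
        p2: str,
        evidence: EvidenceVector,
        transferred: bool = False,
        direct: Optional[EvidenceVector] = None,
    ) -> Row:
        """Insert or replace a pair; channel scores are grid-quantized."""
        if p1 == p2:
            raise ParseError(f"self-pair {p1!r}")
        if p1 > p2:
            p1, p2 = p2, p1
        ta, tb = species_of(p1), species_of(p2)
        if ta is None or tb is None:
            raise ParseError(f"ids must be '<taxid>.<accession>': {p1!r}, {p2!r}")
        key = (ta, tb) if ta <= tb else (tb, ta)
        ev = _quantize_vector(evidence)
        if direct is None:
            direct = evidence if not transferred else EvidenceVector()
        row = Row(
            evidence=ev,
            combined=combine_channels(ev, self.prior),
            direct=_quantize_vector(direct),
            transferred=transferred,
        )
        self.tables.setdefault(key, {})[(p1, p2)] = row
        self._neighbors.setdefault(p1, {})[p2] = row.combined
        self._neighbors.setdefault(p2, {})[p1] = row.combined
        return row

    # -- lookup -----------------------------------------------------------

    def get_pair(self, p1: str, p2: str) -> Optional[Row]:
        if p1 > p2:
            p1, p2 = p2, p1
        ta, tb = species_of(p1), species_of(p2)
        if ta is None or tb is None:
            return None
        key = (min(ta, tb), max(ta, tb))
        return self.tables.get(key, {}).get((p1, p2))

    def neighbors(
        self,
        protein: str,
        species: Optional[set[int]] = None,
        cutoff: float = 0.0,
    ) -> list[tuple[str, float]]:
        """Partners of a protein at or above the cutoff.

        Sorted by combined score descending, then partner id ascending.
        Unknown proteins yield an empty list.
        """
        hits = [
            (partner, score)
            for partner, score in self._neighbors.get(protein, {}).items()
            if score >= cutoff
            and (species is None or species_of(partner) in species)
        ]
        hits.sort(key=lambda t: (-t[1], t[0]))
        return hits

    def pair_scores(
        self, proteins: Iterable[str], cutoff: float = 0.0
    ) -> list[tuple[str, str, Row]]:
        """All stored rows with both endpoints in the set and combined >= cutoff."""
        pset = set(proteins)
        out = []
        for p1 in sorted(pset):
            for p2, score in self._neighbors.get(p1, {}).items():
                if p2 in pset and p1 < p2 and score >= cutoff:
                    out.append((p1, p2, self.get_pair(p1, p2)))
        return out

    def iter_rows(self) -> Iterator[tuple[str, str, Row]]:
        for key in sorted(self.tables):
            for (p1, p2) in sorted(self.tables[key]):
                yield p1, p2, self.tables[key][(p1, p2)]

    def iter_cross_pairs(
        self, taxid_a: int, taxid_b: int
    ) -> Iterator[tuple[str, str, Row]]:
        """Rows of one species-pair table, endpoints ordered (taxid_a, taxid_b)."""
        key = (min(taxid_a, taxid_b), max(taxid_a, taxid_b))
        for (p1, p2), row in sorted(self.tables.get(key, {}).items()):
            if species_of(p1) == taxid_a:
                yield p1, p2, row
            else:
                yield p2, p1, row

    def proteins(self) -> list[str]:
        return sorted(self._neighbors)

    def n_rows(self) -> int:
        return sum(len(t) for t in self.tables.values())

    # -- serialization ----------------------------------------------------

    _COLUMNS = (
        ["protein1", "protein2"]
        + list(CHANNELS)
        + ["combined", "transferred"]
        + [f"direct_{c}" for c in CHANNELS]
    )

    def write_tsv(self, path) -> None:
        """Canonical sorted TSV; scores as integers 0-1000."""
        with open(path, "w", newline="") as fh:
            fh.write("\t".join(self._COLUMNS) + "\n")
            for p1, p2, row in self.iter_rows():
                cells = [p1, p2]
                cells += [str(round(row.evidence[c] * 1000)) for c in CHANNELS]
                cells.append(str(round(row.combined * 1000)))
                cells.append("1" if row.transferred else "0")
                cells += [str(round(row.direct[c] * 1000)) for c in CHANNELS]
                fh.write("\t".join(cells) + "\n")

    @classmethod
    def read_tsv(
        cls, path, network_type: str = "full", prior: float = DEFAULT_PRIOR
    ) -> "ScoreStore":
        store = cls(network_type=network_type, prior=prior)
        with open(path, newline="") as fh:
            reader = csv.DictReader(fh, delimiter="\t")
            if reader.fieldnames is None or "protein1" not in reader.fieldnames:
                raise ParseError(f"{path}: missing score-table header")
            for ln, rec in enumerate(reader, start=2):
                try:
                    ev = EvidenceVector(
                        {c: int(rec[c]) / 1000 for c in CHANNELS if int(rec[c])}
                    )
                    direct = EvidenceVector(
                        {
                            c: int(rec[f"direct_{c}"]) / 1000
                            for c in CHANNELS
                            if int(rec[f"direct_{c}"])
                        }
                    )
                    store.add_pair(
                        rec["protein1"],
                        rec["protein2"],
                        ev,
                        transferred=rec["transferred"] == "1",
                        direct=direct,
                    )
                except (KeyError, ValueError) as exc:
                    raise ParseError(f"{path}:{ln}: {exc}") from exc
        return store


# -- alias resolution -----------------------------------------------------


def _norm(alias: str) -> str:
    return alias.strip().casefold()


class AliasTable:
    """Species-scoped identifier aliases mapping to protein ids.

    Normalization is Unicode casefold plus whitespace trimming; within one
    species an alias must resolve to a single protein.
    """

    def __init__(self):
        self._map: dict[tuple[int, str], set[str]] = {}
        self.rows: list[tuple[int, str, str, str]] = []

    def add(self, taxid: int, alias: str, protein: str, source: str = "") -> None:
        self.rows.append((taxid, alias, protein, source))
        self._map.setdefault((taxid, _norm(alias)), set()).add(protein)

    def resolve(self, alias: str, species: int) -> Optional[str]:
        """Resolve an alias for one species; None when unknown.

        Raises :class:`AmbiguousAliasError` when the normalized alias maps
        to more than one protein.
        """
        hits = self._map.get((species, _norm(alias)), set())
        if len(hits) > 1:
            raise AmbiguousAliasError(alias, species, sorted(hits))
        return next(iter(hits)) if hits else None

    def preferred_name(self, protein: str) -> Optional[str]:
        """First alias tagged 'preferred' for the protein, if any."""
        for taxid, alias, prot, source in self.rows:
            if prot == protein and source == "preferred":
                return alias
        return None

    def write_tsv(self, path) -> None:
        with open(path, "w", newline="") as fh:
            fh.write("taxid\talias\tprotein\tsource\n")
            for taxid, alias, protein, source in sorted(self.rows):
                fh.write(f"{taxid}\t{alias}\t{protein}\t{source}\n")

    @classmethod
    def read_tsv(cls, path) -> "AliasTable":
        table = cls()
        with open(path, newline="") as fh:
            for ln, rec in enumerate(csv.DictReader(fh, delimiter="\t"), start=2):
                try:
                    table.add(
                        int(rec["taxid"]), rec["alias"], rec["protein"],
                        rec.get("source", ""),
                    )
                except (KeyError, ValueError) as exc:
                    raise ParseError(f"{path}:{ln}: {exc}") from exc
        return table


def resolve(alias: str, species: int, aliases: AliasTable) -> Optional[str]:
    """Functional wrapper over :meth:`AliasTable.resolve`."""
    return aliases.resolve(alias, species)


# -- store directories ----------------------------------------------------

STORE_FILES = {"full": "scores.full.tsv", "physical": "scores.physical.tsv"}


def load_store_dir(directory, prior: float = DEFAULT_PRIOR):
    """Load the (full, physical) store pair and alias table from a directory."""
    directory = Path(directory)
    stores = {}
    for ntype, fname in STORE_FILES.items():
        path = directory / fname
        stores[ntype] = (
            ScoreStore.read_tsv(path, network_type=ntype, prior=prior)
            if path.exists()
            else ScoreStore(network_type=ntype, prior=prior)
        )
    alias_path = directory / "aliases.tsv"
    aliases = AliasTable.read_tsv(alias_path) if alias_path.exists() else AliasTable()
    return stores["full"], stores["physical"], aliases
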