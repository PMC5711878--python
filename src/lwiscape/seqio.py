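"""Sequence, topology, species-table and configuration I/O.

All coordinates are 1-based inclusive, matching the convention in which
transmembrane (TM) spans of membrane proteins are printed (e.g. TM1 of rat
TRPV1 as 429-454).  Conversion to 0-based indexing happens only inside
functions, never at module boundaries.
"""

from __future__ import annotations

import io
import json
from dataclasses import dataclass, field, replace
from enum import Enum
from typing import Iterable, Mapping, Sequence, TextIO

import yaml
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

STANDARD_AA = "ACDEFGHIKLMNPQRSTVWY"
#: residues allowed in an ungapped sequence: 20 standard letters plus 'X' (unknown)
SEQ_ALPHABET = frozenset(STANDARD_AA + "X")
#: '-' additionally allowed in aligned context
ALN_ALPHABET = SEQ_ALPHABET | {"-"}

GAP = "-"
UNKNOWN = "X"


class SeqIOError(ValueError):
    """Malformed sequence, topology, species or config input."""


class Side(str, Enum):
    N = "N"
    C = "C"


class Leaflet(str, Enum):
    INNER = "inner"
    OUTER = "outer"


class MembraneSide(str, Enum):
    CYTOPLASMIC = "cytoplasmic"
    EXTRACELLULAR = "extracellular"


class Phylum(str, Enum):
    MAMMAL = "mammal"
    BIRD = "bird"
    REPTILE = "reptile"
    AMPHIBIAN = "amphibian"
    FISH = "fish"


class Thermo(str, Enum):
    COLD = "cold"
    WARM = "warm"


#: ectotherm / endotherm split used for the cold- vs warm-blooded comparisons
PHYLUM_THERMO: dict[Phylum, Thermo] = {
    Phylum.FISH: Thermo.COLD,
    Phylum.AMPHIBIAN: Thermo.COLD,
    Phylum.REPTILE: Thermo.COLD,
    Phylum.BIRD: Thermo.WARM,
    Phylum.MAMMAL: Thermo.WARM,
}


@dataclass(frozen=True)
class SequenceRecord:
    """One protein sequence: accession-or-label id, species label, residues."""

    id: str
    residues: str
    species: str = ""

    def __post_init__(self) -> None:
        if not self.id:
            raise SeqIOError("sequence record requires a non-empty id")
        bad = set(self.residues) - ALN_ALPHABET
        if bad:
            raise SeqIOError(
                f"record {self.id!r}: illegal residue character(s) {sorted(bad)}"
            )

    @property
    def ungapped(self) -> str:
        return self.residues.replace(GAP, "")

    def __len__(self) -> int:
        return len(self.residues)


@dataclass(frozen=True)
class SequenceSet:
    """Ordered collection of sequence records, optionally an alignment."""

    records: tuple[SequenceRecord, ...]
    aligned: bool = False

    def __post_init__(self) -> None:
        ids = [r.id for r in self.records]
        if len(ids) != len(set(ids)):
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            raise SeqIOError(f"duplicate sequence id(s): {dupes}")
        if self.aligned:
            lengths = {len(r) for r in self.records}
            if len(lengths) > 1:
                raise SeqIOError(
                    f"aligned set has ragged lengths: {sorted(lengths)}"
                )

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self):
        return iter(self.records)

    def __getitem__(self, seq_id: str) -> SequenceRecord:
        for r in self.records:
            if r.id == seq_id:
                return r
        raise KeyError(seq_id)

    @property
    def ids(self) -> list[str]:
        return [r.id for r in self.records]

    @property
    def n_columns(self) -> int:
        if not self.records:
            return 0
        return len(self.records[0])


@dataclass(frozen=True)
class TopologyAnnotation:
    """TM helix intervals of a reference protein plus N-terminus sidedness.

    ``tm_spans`` holds (label, start, end) 1-based inclusive, sorted by start
    and pairwise non-overlapping; only these drive flank extraction.
    ``named_regions`` carries loop/pore/motif annotations and is never used
    to derive flanks.
    """

    protein_id: str
    n_term_side: MembraneSide
    tm_spans: tuple[tuple[str, int, int], ...]
    named_regions: tuple[tuple[str, int, int], ...] = ()

    def __post_init__(self) -> None:
        for label, start, end in list(self.tm_spans) + list(self.named_regions):
            if start < 1 or start > end:
                raise SeqIOError(f"region {label!r}: bad interval ({start}, {end})")
        spans = sorted(self.tm_spans, key=lambda t: t[1])
        object.__setattr__(self, "tm_spans", tuple(spans))
        for (la, _, ea), (lb, sb, _) in zip(spans, spans[1:]):
            if sb <= ea:
                raise SeqIOError(f"overlapping TM intervals: {la!r} and {lb!r}")

    @property
    def n_tm(self) -> int:
        return len(self.tm_spans)

    @property
    def last_tm_end(self) -> int:
        return self.tm_spans[-1][2] if self.tm_spans else 0

    def flipped(self) -> "TopologyAnnotation":
        """Same topology with the opposite N-terminus sidedness."""
        other = (
            MembraneSide.EXTRACELLULAR
            if self.n_term_side is MembraneSide.CYTOPLASMIC
            else MembraneSide.CYTOPLASMIC
        )
        return replace(self, n_term_side=other)


@dataclass(frozen=True)
class SpeciesInfo:
    phylum: Phylum
    thermo: Thermo
    accession: str = ""


class SpeciesTable(dict):
    """Mapping species label -> :class:`SpeciesInfo` (vertebrates only)."""

    def thermo_groups(self) -> dict[Thermo, list[str]]:
        out: dict[Thermo, list[str]] = {Thermo.COLD: [], Thermo.WARM: []}
        for sp, info in self.items():
            out[info.thermo].append(sp)
        return out


@dataclass(frozen=True)
class AnalysisConfig:
    """Tunable analysis parameters with field-convention defaults.

    flank_len=5 (the LWI flank width), bootstrap_reps=1000,
    enrichment_threshold=5.0 (percent), multiset pooling, CARC center
    restricted to Tyr.
    """

    flank_len: int = 5
    bootstrap_reps: int = 1000
    enrichment_threshold: float = 5.0
    pooling_mode: str = "multiset"  # or "dedup"
    carc_center: str = "Y_only"  # or "Y_or_F"
    seed: int = 0
    membrane_label: str = ""

    def __post_init__(self) -> None:
        if self.flank_len < 1:
            raise SeqIOError(f"flank_len must be >= 1, got {self.flank_len}")
        if self.bootstrap_reps < 1:
            raise SeqIOError(
                f"bootstrap_reps must be >= 1, got {self.bootstrap_reps}"
            )
        if not (0.0 < self.enrichment_threshold < 100.0):
            raise SeqIOError(
                "enrichment_threshold must lie in (0, 100), "
                f"got {self.enrichment_threshold}"
            )
        if self.pooling_mode not in ("multiset", "dedup"):
            raise SeqIOError(f"unknown pooling_mode {self.pooling_mode!r}")
        if self.carc_center not in ("Y_only", "Y_or_F"):
            raise SeqIOError(f"unknown carc_center {self.carc_center!r}")


# ---------------------------------------------------------------------------
# readers / writers
# ---------------------------------------------------------------------------


def read_fasta(source: TextIO | str, require_aligned: bool = False) -> SequenceSet:
    """Parse multi-FASTA into a :class:`SequenceSet`.

    Record order is preserved, lowercase input is upcased, and the returned
    set is flagged ``aligned`` iff all residue strings have equal length.
    With ``require_aligned`` ragged lengths raise :class:`SeqIOError`.
    """
    if isinstance(source, str):
        source = io.StringIO(source)
    records = []
    for rec in SeqIO.parse(source, "fasta"):
        if not rec.id:
            raise SeqIOError("FASTA header with empty id")
        species = rec.description[len(rec.id):].strip() if rec.description else ""
        records.append(
            SequenceRecord(id=rec.id, residues=str(rec.seq).upper(), species=species)
        )
    lengths = {len(r) for r in records}
    aligned = len(records) > 0 and len(lengths) == 1
    if require_aligned and not aligned:
        raise SeqIOError(
            f"alignment required but sequence lengths are ragged: {sorted(lengths)}"
        )
    return SequenceSet(records=tuple(records), aligned=aligned)


def write_fasta(seq_set: SequenceSet, sink: TextIO) -> None:
    """Write records as plain FASTA; round-trips exactly with read_fasta."""
    bio = [
        SeqRecord(Seq(r.residues), id=r.id, description=r.species)
        for r in seq_set.records
    ]
    SeqIO.write(bio, sink, "fasta-2line")


_TM_PREFIXES = ("TM", "TRANSMEMBRANE")


def _is_tm_label(label: str) -> bool:
    return label.upper().startswith(_TM_PREFIXES)


def read_topology(source: TextIO | str) -> TopologyAnnotation:
    """Parse a topology TSV.

    Format: a header line ``#protein_id=<id>\tn_term_side=<side>`` followed by
    ``label\tstart\tend`` rows, coordinates 1-based inclusive.  Rows whose
    label starts with ``TM`` or ``Transmembrane`` become TM spans; all other
    rows are kept as named regions.
    """
    if isinstance(source, str):
        source = io.StringIO(source)
    protein_id = None
    n_term_side = None
    tm_spans: list[tuple[str, int, int]] = []
    named: list[tuple[str, int, int]] = []
    for raw in source:
        line = raw.strip()
        if not line:
            continue
        if line.startswith("#"):
            for tok in line.lstrip("#").split("\t"):
                tok = tok.strip()
                if tok.startswith("protein_id="):
                    protein_id = tok.split("=", 1)[1]
                elif tok.startswith("n_term_side="):
                    n_term_side = tok.split("=", 1)[1]
            continue
        parts = line.split("\t")
        if len(parts) < 3:
            raise SeqIOError(f"topology row needs label\\tstart\\tend: {line!r}")
        label = parts[0].strip()
        try:
            start, end = int(parts[1]), int(parts[2])
        except ValueError as exc:
            raise SeqIOError(f"non-integer coordinate in row {line!r}") from exc
        (tm_spans if _is_tm_label(label) else named).append((label, start, end))
    if protein_id is None:
        raise SeqIOError("topology header must define protein_id")
    if n_term_side is None:
        raise SeqIOError("topology header must define n_term_side")
    try:
        side = MembraneSide(n_term_side)
    except ValueError as exc:
        raise SeqIOError(f"unknown n_term_side {n_term_side!r}") from exc
    return TopologyAnnotation(
        protein_id=protein_id,
        n_term_side=side,
        tm_spans=tuple(tm_spans),
        named_regions=tuple(named),
    )


def write_topology(topology: TopologyAnnotation, sink: TextIO) -> None:
    sink.write(
        f"#protein_id={topology.protein_id}\t"
        f"n_term_side={topology.n_term_side.value}\n"
    )
    for label, start, end in topology.tm_spans + topology.named_regions:
        sink.write(f"{label}\t{start}\t{end}\n")


def read_species_table(source: TextIO | str) -> SpeciesTable:
    """Parse a species TSV: ``species\tphylum[\tthermo][\taccession]``.

    Thermal class is auto-derived from the phylum (fish/amphibian/reptile ->
    cold; bird/mammal -> warm) when the column is absent or empty; an explicit
    value overrides.  Non-vertebrate phyla are rejected.
    """
    if isinstance(source, str):
        source = io.StringIO(source)
    table = SpeciesTable()
    header: list[str] | None = None
    for raw in source:
        line = raw.rstrip("\n")
        if not line.strip() or line.startswith("#"):
            continue
        parts = [p.strip() for p in line.split("\t")]
        if header is None and parts[0].lower() == "species":
            header = [p.lower() for p in parts]
            continue
        if header is None:
            header = ["species", "phylum", "thermo", "accession"]
        row = dict(zip(header, parts))
        species = row.get("species", "")
        if not species:
            raise SeqIOError(f"species row without species label: {line!r}")
        try:
            phylum = Phylum(row.get("phylum", "").lower())
        except ValueError as exc:
            raise SeqIOError(
                f"species {species!r}: unknown phylum {row.get('phylum')!r} "
                "(expected one of mammal/bird/reptile/amphibian/fish)"
            ) from exc
        thermo_raw = row.get("thermo", "")
        thermo = Thermo(thermo_raw.lower()) if thermo_raw else PHYLUM_THERMO[phylum]
        table[species] = SpeciesInfo(
            phylum=phylum, thermo=thermo, accession=row.get("accession", "")
        )
    return table


def write_species_table(table: SpeciesTable, sink: TextIO) -> None:
    sink.write("species\tphylum\tthermo\taccession\n")
    for sp, info in table.items():
        sink.write(
            f"{sp}\t{info.phylum.value}\t{info.thermo.value}\t{info.accession}\n"
        )


def load_config(
    source: TextIO | str | Mapping | None = None,
    overrides: Mapping | None = None,
) -> AnalysisConfig:
    """Build an :class:`AnalysisConfig` from YAML/JSON text plus overrides.

    All fields are defaulted; overrides win over file values.  Out-of-range
    values raise :class:`SeqIOError`.
    """
    data: dict = {}
    if source is not None:
        if isinstance(source, Mapping):
            data = dict(source)
        else:
            text = source if isinstance(source, str) else source.read()
            if text.strip():
                loaded = yaml.safe_load(text)  # YAML is a superset of JSON
                if loaded is not None:
                    if not isinstance(loaded, dict):
                        raise SeqIOError("config must be a mapping")
                    data = loaded
    if overrides:
        data.update({k: v for k, v in overrides.items() if v is not None})
    known = set(AnalysisConfig.__dataclass_fields__)
    unknown = set(data) - known
    if unknown:
        raise SeqIOError(f"unknown config field(s): {sorted(unknown)}")
    return AnalysisConfig(**data)
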