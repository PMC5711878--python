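"""Lipid-water-interface (LWI) flank segments.

The LWI is the thin (~6 A) layer on each side of the bilayer with little
free water.  Operationally each transmembrane helix contributes two LWI
segments: the ``flank_len`` residues immediately N-terminal of the helix
start and the ``flank_len`` residues immediately C-terminal of its end.
A 6-TM channel such as TRPV1 therefore yields 12 segments (60 positions
with multiplicity at flank_len=5).

Segments carry a leaflet label (inner = cytoplasmic-facing, outer =
extracellular-facing) that alternates with each membrane crossing starting
from the N-terminus side, and can be projected through a multiple sequence
alignment to extract the homologous residues of every ortholog.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, replace

from .seqio import (
    GAP,
    Leaflet,
    MembraneSide,
    SequenceSet,
    Side,
    TopologyAnnotation,
)


class SegmentError(ValueError):
    """Invalid flank extraction, projection or pooling request."""


@dataclass(frozen=True)
class LWISegment:
    """One flank: TM label, side (N/C of that TM), leaflet, 1-based interval."""

    tm_label: str
    side: Side
    interval: tuple[int, int]
    leaflet: Leaflet | None = None

    @property
    def start(self) -> int:
        return self.interval[0]

    @property
    def end(self) -> int:
        return self.interval[1]

    @property
    def name(self) -> str:
        return f"{self.tm_label}{self.side.value}"

    def __len__(self) -> int:
        return self.end - self.start + 1

    @property
    def positions(self) -> range:
        return range(self.start, self.end + 1)


@dataclass(frozen=True)
class SegmentAlignment:
    """A segment projected through an alignment.

    ``ref_columns`` are the 0-based alignment columns where the reference row
    carries the segment's residues; ``sequences`` maps each sequence id to its
    residues at those columns with gaps removed; ``gap_counts`` records how
    many gaps were removed per sequence.
    """

    segment: LWISegment
    ref_id: str
    ref_columns: tuple[int, ...]
    sequences: dict[str, str]
    gap_counts: dict[str, int]


@dataclass(frozen=True)
class ResiduePool:
    """Residues pooled from one or more segments of a single reference frame.

    In ``multiset`` mode every segment contributes all its residues, so
    positions shared by overlapping flanks count twice; ``dedup`` keeps each
    reference position once (first seen).
    """

    entries: tuple[tuple[int, str], ...]  # (reference position, residue)
    mode: str
    source_labels: tuple[str, ...] = ()

    def __len__(self) -> int:
        return len(self.entries)

    @property
    def residues(self) -> str:
        return "".join(res for _, res in self.entries)

    def counts(self) -> Counter:
        return Counter(self.residues)


def extract_flanks(
    topology: TopologyAnnotation, flank_len: int = 5, seq_len: int | None = None
) -> list[LWISegment]:
    """Derive the two LWI flanks of every TM span.

    Each flank is the ``flank_len`` residues immediately preceding (N side)
    or following (C side) the TM interval, clamped at the sequence termini.
    Flanks may run into a neighbouring TM when the connecting loop is shorter
    than ``flank_len``; they are never truncated at loop boundaries.
    """
    if flank_len < 1:
        raise SegmentError(f"flank_len must be >= 1, got {flank_len}")
    if not topology.tm_spans:
        raise SegmentError("topology has no TM spans")
    if seq_len is None:
        seq_len = topology.last_tm_end + flank_len
    if seq_len < topology.last_tm_end:
        raise SegmentError(
            f"sequence length {seq_len} shorter than last TM end "
            f"{topology.last_tm_end}"
        )
    segments: list[LWISegment] = []
    for label, tm_start, tm_end in topology.tm_spans:
        n_start = max(1, tm_start - flank_len)
        n_end = tm_start - 1
        if n_end >= n_start:
            segments.append(
                LWISegment(tm_label=label, side=Side.N, interval=(n_start, n_end))
            )
        c_start = tm_end + 1
        c_end = min(seq_len, tm_end + flank_len)
        if c_end >= c_start:
            segments.append(
                LWISegment(tm_label=label, side=Side.C, interval=(c_start, c_end))
            )
    return assign_leaflets(topology, segments)


def assign_leaflets(
    topology: TopologyAnnotation, segments: list[LWISegment]
) -> list[LWISegment]:
    """Label each flank with its membrane leaflet.

    The leaflet alternates with every membrane crossing: for a cytoplasmic
    N-terminus, TM_k's N-flank sits on the inner leaflet when k is odd and
    the outer leaflet when k is even, and its C-flank on the opposite side.
    An extracellular N-terminus flips the whole assignment.
    """
    order = {label: i for i, (label, _, _) in enumerate(topology.tm_spans)}
    start_inner = topology.n_term_side is MembraneSide.CYTOPLASMIC
    out = []
    for seg in segments:
        if seg.tm_label not in order:
            raise SegmentError(f"segment TM label {seg.tm_label!r} not in topology")
        k = order[seg.tm_label]  # 0-based TM index
        # before TM k the chain has crossed the membrane k times; after, k+1
        crossings = k if seg.side is Side.N else k + 1
        inner = start_inner if crossings % 2 == 0 else not start_inner
        out.append(replace(seg, leaflet=Leaflet.INNER if inner else Leaflet.OUTER))
    return out


def project_segment(
    msa: SequenceSet, ref_id: str, segment: LWISegment
) -> SegmentAlignment:
    """Map a segment's reference coordinates to alignment columns.

    ``ref_columns`` are the columns where the reference row carries its
    (ungapped) positions ``segment.start..segment.end``; every sequence
    contributes its residues at exactly those columns, with gaps stripped
    and their count recorded.
    """
    if not msa.aligned:
        raise SegmentError("projection requires an aligned SequenceSet")
    try:
        ref = msa[ref_id]
    except KeyError:
        raise SegmentError(f"reference id {ref_id!r} not in alignment") from None
    # alignment column of each ungapped reference position
    pos2col: list[int] = [
        col for col, ch in enumerate(ref.residues) if ch != GAP
    ]
    if segment.end > len(pos2col):
        raise SegmentError(
            f"segment {segment.name} ({segment.start}-{segment.end}) exceeds "
            f"reference ungapped length {len(pos2col)}"
        )
    cols = tuple(pos2col[p - 1] for p in segment.positions)
    sequences: dict[str, str] = {}
    gap_counts: dict[str, int] = {}
    for rec in msa:
        chars = [rec.residues[c] for c in cols]
        sequences[rec.id] = "".join(ch for ch in chars if ch != GAP)
        gap_counts[rec.id] = sum(ch == GAP for ch in chars)
    return SegmentAlignment(
        segment=segment,
        ref_id=ref_id,
        ref_columns=cols,
        sequences=sequences,
        gap_counts=gap_counts,
    )


def pool_residues(
    segments_with_residues: list[tuple[LWISegment, str]],
    mode: str = "multiset",
) -> ResiduePool:
    """Pool per-segment residue strings into one :class:`ResiduePool`.

    Input pairs each segment with the residue string extracted from one
    sequence at that segment (ungapped; shorter than the segment when the
    sequence had gaps there, in which case positional bookkeeping pairs
    residues with leading positions).  ``multiset`` concatenates everything;
    ``dedup`` keeps each reference position once, first seen.
    """
    if mode not in ("multiset", "dedup"):
        raise SegmentError(f"unknown pooling mode {mode!r}")
    if not segments_with_residues:
        raise SegmentError("cannot pool zero segments")
    entries: list[tuple[int, str]] = []
    seen: set[int] = set()
    labels: list[str] = []
    for seg, residues in segments_with_residues:
        labels.append(seg.name)
        for offset, res in enumerate(residues):
            pos = seg.start + offset
            if mode == "dedup":
                if pos in seen:
                    continue
                seen.add(pos)
            entries.append((pos, res))
    return ResiduePool(entries=tuple(entries), mode=mode, source_labels=tuple(labels))


def pool_from_sequence(
    sequence: str, segments: list[LWISegment], mode: str = "multiset"
) -> ResiduePool:
    """Pool one ungapped sequence's residues over a list of segments."""
    pairs = []
    for seg in segments:
        if seg.end > len(sequence):
            raise SegmentError(
                f"segment {seg.name} ({seg.start}-{seg.end}) exceeds sequence "
                f"length {len(sequence)}"
            )
        pairs.append((seg, sequence[seg.start - 1 : seg.end]))
    return pool_residues(pairs, mode=mode)


def pool_from_projection(
    projections: list[SegmentAlignment], seq_id: str, mode: str = "multiset"
) -> ResiduePool:
    """Pool one aligned sequence's residues over projected segments."""
    refs = {p.ref_id for p in projections}
    if len(refs) > 1:
        raise SegmentError(f"mixed reference proteins in one pool: {sorted(refs)}")
    pairs = [(p.segment, p.sequences[seq_id]) for p in projections]
    return pool_residues(pairs, mode=mode)
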