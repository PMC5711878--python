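"""Degenerate cholesterol-recognition consensus motif scanning.

The CRAC motif (Cholesterol Recognition Amino acid Consensus) is the
anchor-spacer-anchor pattern L/V - X(1-5) - Y - X(1-5) - R/K read N->C;
CARC is its inversion, R/K - X(1-5) - Y - X(1-5) - L/V (some literature
widens the central aromatic to Y/F, available via ``carc_center``).  Spacer
minimum is 1: X(1-5) never allows a zero-length spacer.

A *triple* is one satisfying anchor assignment (a1, c, a3); because the
spacers are elastic, a single motif-bearing region typically supports many
triples, so the default report merges overlapping triple spans into maximal
intervals, matching how such motifs are quoted as residue ranges.
"""

from __future__ import annotations

from dataclasses import dataclass

from .seqio import GAP, SEQ_ALPHABET


class MotifError(ValueError):
    """Invalid pattern definition or gapped scan input."""


@dataclass(frozen=True)
class MotifPattern:
    """Anchor-spacer-anchor consensus: sets of allowed residues at the three
    anchors, (min, max) wildcard counts for the two spacers."""

    name: str
    anchor1: frozenset[str]
    spacer1: tuple[int, int]
    center: frozenset[str]
    spacer2: tuple[int, int]
    anchor3: frozenset[str]

    def __post_init__(self) -> None:
        for s in (self.anchor1, self.center, self.anchor3):
            if not s:
                raise MotifError("empty anchor set")
        for lo, hi in (self.spacer1, self.spacer2):
            if lo < 1 or hi < lo:
                raise MotifError(f"invalid spacer range ({lo}, {hi})")

    def reversed(self) -> "MotifPattern":
        """The pattern read C->N (anchors and spacers swapped end-for-end)."""
        return MotifPattern(
            name=f"{self.name}_rev",
            anchor1=self.anchor3,
            spacer1=self.spacer2,
            center=self.center,
            spacer2=self.spacer1,
            anchor3=self.anchor1,
        )


@dataclass(frozen=True)
class MotifMatch:
    """One reported hit: 1-based inclusive interval plus anchor positions."""

    pattern: str
    interval: tuple[int, int]
    anchors: tuple[int, int, int]  # (a1, c, a3), 1-based
    substring: str

    @property
    def start(self) -> int:
        return self.interval[0]

    @property
    def end(self) -> int:
        return self.interval[1]

    def __len__(self) -> int:
        return self.end - self.start + 1


def build_pattern(
    kind: str = "crac",
    carc_center: str = "Y_only",
    *,
    name: str | None = None,
    anchor1: str | None = None,
    spacer1: tuple[int, int] = (1, 5),
    center: str | None = None,
    spacer2: tuple[int, int] = (1, 5),
    anchor3: str | None = None,
) -> MotifPattern:
    """Construct a CRAC, CARC or custom anchor-spacer-anchor pattern.

    ``crac`` is {L,V}-X(1..5)-{Y}-X(1..5)-{R,K}; ``carc`` the strict
    inversion {R,K}-X(1..5)-{Y}-X(1..5)-{L,V}, with ``carc_center='Y_or_F'``
    widening the central aromatic.  ``custom`` requires all anchors.
    """
    if kind == "crac":
        return MotifPattern(
            name="CRAC",
            anchor1=frozenset("LV"),
            spacer1=(1, 5),
            center=frozenset("Y"),
            spacer2=(1, 5),
            anchor3=frozenset("RK"),
        )
    if kind == "carc":
        cc = {"Y_only": "Y", "Y_or_F": "YF"}.get(carc_center)
        if cc is None:
            raise MotifError(f"unknown carc_center {carc_center!r}")
        return MotifPattern(
            name="CARC",
            anchor1=frozenset("RK"),
            spacer1=(1, 5),
            center=frozenset(cc),
            spacer2=(1, 5),
            anchor3=frozenset("LV"),
        )
    if kind == "custom":
        if anchor1 is None or center is None or anchor3 is None:
            raise MotifError("custom pattern requires anchor1, center and anchor3")
        return MotifPattern(
            name=name or "custom",
            anchor1=frozenset(anchor1),
            spacer1=tuple(spacer1),
            center=frozenset(center),
            spacer2=tuple(spacer2),
            anchor3=frozenset(anchor3),
        )
    raise MotifError(f"unknown pattern kind {kind!r}")


def _triples(seq: str, pat: MotifPattern) -> list[tuple[int, int, int]]:
    """All 0-based (a1, c, a3) index triples satisfying the pattern."""
    a1_pos = [i for i, ch in enumerate(seq) if ch in pat.anchor1]
    c_pos = [i for i, ch in enumerate(seq) if ch in pat.center]
    a3_pos = [i for i, ch in enumerate(seq) if ch in pat.anchor3]
    lo1, hi1 = pat.spacer1
    lo2, hi2 = pat.spacer2
    out = []
    for c in c_pos:
        firsts = [a for a in a1_pos if lo1 <= c - a - 1 <= hi1]
        if not firsts:
            continue
        for a3 in a3_pos:
            if lo2 <= a3 - c - 1 <= hi2:
                out.extend((a1, c, a3) for a1 in firsts)
    out.sort()
    return out


def scan_pattern(
    seq: str, pattern: MotifPattern, report: str = "maximal_intervals"
) -> list[MotifMatch]:
    """Scan an ungapped sequence for a degenerate consensus pattern.

    ``all_triples`` enumerates every satisfying anchor assignment;
    ``maximal_intervals`` (default) merges overlapping triple spans into
    maximal distinct intervals, reporting one representative triple per
    interval (the leftmost, widest one).
    """
    if GAP in seq:
        raise MotifError("scan requires an ungapped sequence")
    bad = set(seq) - SEQ_ALPHABET
    if bad:
        raise MotifError(f"illegal residue character(s) {sorted(bad)}")
    triples = _triples(seq, pattern)
    if report == "all_triples":
        return [
            MotifMatch(
                pattern=pattern.name,
                interval=(a1 + 1, a3 + 1),
                anchors=(a1 + 1, c + 1, a3 + 1),
                substring=seq[a1 : a3 + 1],
            )
            for a1, c, a3 in triples
        ]
    if report != "maximal_intervals":
        raise MotifError(f"unknown report mode {report!r}")
    # merge overlapping [a1, a3] spans into maximal intervals
    spans = sorted({(a1, a3) for a1, c, a3 in triples})
    merged: list[list[int]] = []
    for s, e in spans:
        if merged and s <= merged[-1][1]:
            merged[-1][1] = max(merged[-1][1], e)
        else:
            merged.append([s, e])
    matches = []
    for s, e in merged:
        inside = [t for t in triples if s <= t[0] and t[2] <= e]
        rep = min(inside, key=lambda t: (t[0], -(t[2] - t[0]), t[1]))
        matches.append(
            MotifMatch(
                pattern=pattern.name,
                interval=(s + 1, e + 1),
                anchors=(rep[0] + 1, rep[1] + 1, rep[2] + 1),
                substring=seq[s : e + 1],
            )
        )
    return matches


def motif_segment_overlap(
    matches: list[MotifMatch],
    regions: list[tuple[str, int, int]],
) -> list[dict]:
    """Overlap lengths between motif matches and labelled intervals.

    Both sides use 1-based inclusive coordinates; pairs with zero overlap
    are omitted.  Returns dicts with pattern, motif interval, region label
    and overlap length.
    """
    report = []
    for m in matches:
        for label, start, end in regions:
            lo = max(m.start, start)
            hi = min(m.end, end)
            if hi >= lo:
                report.append(
                    {
                        "pattern": m.pattern,
                        "motif_start": m.start,
                        "motif_end": m.end,
                        "region": label,
                        "region_start": start,
                        "region_end": end,
                        "overlap": hi - lo + 1,
                    }
                )
    return report
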