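"""Synthetic ortholog families with the statistical structure the LWI
analysis assumes.

The generator draws a star phylogeny: every taxon descends independently
from one common ancestor, and each site mutates with a per-region-class
probability, substituting uniformly among the other 19 residues.  No indels
are introduced, so the output is trivially aligned.  Under this model the
expected p-distance between two tips whose sites each mutated with
probability p has the closed form

    E[d] = 1 - [(1 - p)^2 + p^2 / 19]

(both unchanged, or both changed and coinciding among 19 alternatives),
which the parameter-recovery tests exploit.

Region classes (inner flanks, outer flanks, TM core, elsewhere) are derived
from the same topology object the analysis pipeline consumes, so generator
and analyser agree on coordinates by construction.  Group-specific
composition biases (e.g. a higher Arg rate in cold-blooded taxa) are
imposed by biasing the ancestor-independent residue choice inside flank
regions of the affected taxa.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .segments import LWISegment, extract_flanks
from .seqio import (
    STANDARD_AA,
    Leaflet,
    Phylum,
    PHYLUM_THERMO,
    SequenceRecord,
    SequenceSet,
    SpeciesInfo,
    SpeciesTable,
    TopologyAnnotation,
)

AA_ARRAY = np.frombuffer(STANDARD_AA.encode(), dtype=np.uint8)


class SimulationError(ValueError):
    """Invalid simulation specification."""


@dataclass(frozen=True)
class GroupSpec:
    """One taxon group: label, phylum, size, optional flank composition bias.

    ``flank_composition`` (residue -> probability, remainder spread uniformly
    over unlisted residues) replaces the ancestor's flank residues for this
    group's taxa before divergence is applied — giving the group a distinct
    LWI composition target, e.g. Arg-rich flanks in cold-blooded taxa.
    """

    label: str
    phylum: Phylum
    n_taxa: int
    flank_composition: dict[str, float] = field(default_factory=dict)


@dataclass(frozen=True)
class SimulationSpec:
    """Stated world of one simulation run."""

    topology: TopologyAnnotation
    seq_len: int
    seed: int
    rate_inner_flank: float = 0.05
    rate_outer_flank: float = 0.10
    rate_tm_core: float = 0.10
    rate_elsewhere: float = 0.20
    flank_len: int = 5
    groups: tuple[GroupSpec, ...] = (
        GroupSpec("fish", Phylum.FISH, 4),
        GroupSpec("amphibian", Phylum.AMPHIBIAN, 2),
        GroupSpec("reptile", Phylum.REPTILE, 14),
        GroupSpec("bird", Phylum.BIRD, 4),
        GroupSpec("mammal", Phylum.MAMMAL, 14),
    )
    planted_motifs: tuple[tuple[str, int], ...] = ()  # (instance, 1-based pos)
    reference: str | None = None  # explicit ancestor; random if None

    def __post_init__(self) -> None:
        for r in (
            self.rate_inner_flank,
            self.rate_outer_flank,
            self.rate_tm_core,
            self.rate_elsewhere,
        ):
            if not (0.0 <= r <= 1.0):
                raise SimulationError(f"substitution probability {r} outside [0, 1]")
        if self.seq_len < self.topology.last_tm_end:
            raise SimulationError(
                "seq_len shorter than the topology's last TM end"
            )
        if self.reference is not None and len(self.reference) != self.seq_len:
            raise SimulationError("explicit reference length != seq_len")
        occupied: list[tuple[int, int]] = []
        for inst, pos in self.planted_motifs:
            if pos < 1 or pos + len(inst) - 1 > self.seq_len:
                raise SimulationError(
                    f"planted motif at {pos} (len {len(inst)}) outside sequence"
                )
            iv = (pos, pos + len(inst) - 1)
            for s, e in occupied:
                if iv[0] <= e and s <= iv[1]:
                    raise SimulationError(
                        f"planted motif at {pos} conflicts with another at {s}"
                    )
            occupied.append(iv)

    @property
    def n_taxa(self) -> int:
        return sum(g.n_taxa for g in self.groups)


@dataclass(frozen=True)
class SimTruth:
    """Ground truth of a simulation: per-class rates and their expected
    pairwise p-distance, planted motifs, group composition targets."""

    rates: dict[str, float]
    expected_p_distance: dict[str, float]
    region_classes: dict[str, list[int]]  # class -> 1-based positions
    planted_motifs: tuple[tuple[str, int], ...]
    group_composition: dict[str, dict[str, float]]
    segments: tuple[LWISegment, ...]


def expected_p_distance(p: float) -> float:
    """Closed-form expected tip-to-tip p-distance for per-site rate p.

    Two tips mutate independently from the ancestor: a site matches when
    neither changed, or both changed and hit the same alternative (1/19).
    """
    return 1.0 - ((1.0 - p) ** 2 + p**2 / 19.0)


def region_classes(
    topology: TopologyAnnotation, flank_len: int, seq_len: int
) -> tuple[dict[str, list[int]], tuple[LWISegment, ...]]:
    """Partition 1..seq_len into inner_flank / outer_flank / tm_core /
    elsewhere.  Flank positions win over TM core (overlapping flanks claim
    their TM positions); inner wins over outer on the rare shared position.
    """
    segments = tuple(extract_flanks(topology, flank_len=flank_len, seq_len=seq_len))
    inner: set[int] = set()
    outer: set[int] = set()
    for seg in segments:
        target = inner if seg.leaflet is Leaflet.INNER else outer
        target.update(seg.positions)
    outer -= inner
    tm: set[int] = set()
    for _, s, e in topology.tm_spans:
        tm.update(range(s, e + 1))
    tm -= inner | outer
    everything = set(range(1, seq_len + 1))
    elsewhere = everything - inner - outer - tm
    classes = {
        "inner_flank": sorted(inner),
        "outer_flank": sorted(outer),
        "tm_core": sorted(tm),
        "elsewhere": sorted(elsewhere),
    }
    return classes, segments


def _composition_probs(bias: dict[str, float]) -> np.ndarray:
    """20-vector of residue probabilities from a partial bias mapping."""
    probs = np.zeros(20)
    listed = 0.0
    for aa, p in bias.items():
        if aa not in STANDARD_AA:
            raise SimulationError(f"unknown residue {aa!r} in composition bias")
        if p < 0:
            raise SimulationError(f"negative composition probability for {aa!r}")
        probs[STANDARD_AA.index(aa)] = p
        listed += p
    if listed > 1.0 + 1e-9:
        raise SimulationError(f"composition bias sums to {listed} > 1")
    rest = [i for i in range(20) if STANDARD_AA[i] not in bias]
    if rest:
        probs[rest] = (1.0 - listed) / len(rest)
    return probs


def plant_motif(seq: str, pattern_instance: str, pos: int) -> str:
    """Overwrite ``seq`` with ``pattern_instance`` at 1-based ``pos``."""
    if pos < 1 or pos + len(pattern_instance) - 1 > len(seq):
        raise SimulationError(
            f"motif of length {len(pattern_instance)} at position {pos} "
            f"exceeds sequence length {len(seq)}"
        )
    i = pos - 1
    return seq[:i] + pattern_instance + seq[i + len(pattern_instance):]


def simulate_orthologs(
    spec: SimulationSpec,
) -> tuple[SequenceSet, SpeciesTable, SimTruth]:
    """Draw a star-phylogeny ortholog family.

    Ancestor residues are uniform over the 20 standard letters (or the
    explicit reference); group flank-composition biases redraw the flank
    positions of each affected taxon's ancestral copy; planted motifs are
    written into every taxon verbatim; then each site mutates independently
    with its region-class probability, uniformly among the 19 alternatives.
    Deterministic given ``spec.seed``; the output alignment is gap-free.
    """
    rng = np.random.default_rng(spec.seed)
    L = spec.seq_len
    classes, segments = region_classes(spec.topology, spec.flank_len, L)
    rates = {
        "inner_flank": spec.rate_inner_flank,
        "outer_flank": spec.rate_outer_flank,
        "tm_core": spec.rate_tm_core,
        "elsewhere": spec.rate_elsewhere,
    }
    site_rate = np.empty(L)
    for cls, positions in classes.items():
        site_rate[np.asarray(positions, dtype=int) - 1] = rates[cls]

    if spec.reference is not None:
        ancestor = np.frombuffer(spec.reference.encode(), dtype=np.uint8).copy()
    else:
        ancestor = AA_ARRAY[rng.integers(0, 20, size=L)]

    flank_positions = np.asarray(
        classes["inner_flank"] + classes["outer_flank"], dtype=int
    ) - 1
    group_probs = {
        g.label: _composition_probs(g.flank_composition) if g.flank_composition else None
        for g in spec.groups
    }

    records: list[SequenceRecord] = []
    species_table = SpeciesTable()
    for group in spec.groups:
        probs = group_probs[group.label]
        for t in range(group.n_taxa):
            tip = ancestor.copy()
            if probs is not None:
                draw = rng.choice(20, size=flank_positions.size, p=probs)
                tip[flank_positions] = AA_ARRAY[draw]
            # independent per-site substitution, uniform among the other 19
            hit = rng.random(L) < site_rate
            idx = np.nonzero(hit)[0]
            if idx.size:
                cur = np.searchsorted(AA_ARRAY, tip[idx])  # AA_ARRAY is sorted
                alt = rng.integers(0, 19, size=idx.size)
                alt = np.where(alt >= cur, alt + 1, alt)
                tip[idx] = AA_ARRAY[alt]
            # plant motifs after divergence: planted instances are invariant
            # across taxa, so the scanner always recovers them in every tip
            seq = tip.tobytes().decode()
            for inst, pos in spec.planted_motifs:
                seq = plant_motif(seq, inst, pos)
            label = f"{group.label}_{t + 1}"
            records.append(
                SequenceRecord(id=label, residues=seq, species=label)
            )
            species_table[label] = SpeciesInfo(
                phylum=group.phylum,
                thermo=PHYLUM_THERMO[group.phylum],
                accession=f"SYN_{label}",
            )

    truth = SimTruth(
        rates=rates,
        expected_p_distance={c: expected_p_distance(r) for c, r in rates.items()},
        region_classes=classes,
        planted_motifs=spec.planted_motifs,
        group_composition={
            g.label: dict(g.flank_composition) for g in spec.groups
        },
        segments=segments,
    )
    return (
        SequenceSet(records=tuple(records), aligned=True),
        species_table,
        truth,
    )


def simulate_pool_composition(
    targets: dict[str, float],
    n: int,
    seed: int,
    renormalize: bool = False,
) -> str:
    """Draw a residue string i.i.d. from target percentages.

    ``targets`` maps residue -> percent; they must sum to 100 within 1e-6
    unless ``renormalize`` is set (useful for printed tables whose 1-decimal
    rounding sums to e.g. 99.9).  Deterministic given ``seed``.
    """
    if n < 1:
        raise SimulationError(f"n must be >= 1, got {n}")
    probs = np.zeros(20)
    for aa, pct in targets.items():
        if aa not in STANDARD_AA:
            raise SimulationError(f"unknown residue {aa!r} in targets")
        if pct < 0:
            raise SimulationError(f"negative target percentage for {aa!r}")
        probs[STANDARD_AA.index(aa)] = pct
    total = probs.sum()
    if renormalize:
        if total <= 0:
            raise SimulationError("targets sum to zero")
        probs /= total
    else:
        if abs(total - 100.0) > 1e-6:
            raise SimulationError(f"targets sum to {total}, expected 100")
        probs /= 100.0
    rng = np.random.default_rng(seed)
    draw = rng.choice(20, size=n, p=probs)
    return AA_ARRAY[draw].tobytes().decode()
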