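"""Amino-acid composition, enrichment classes and snorkeling-residue profiles.

Composition tables give the percentage of each of the 20 standard amino
acids in a residue pool (a region class such as the lipid-water interface,
the TM core, or the full-length protein).  An amino acid is called
positively selected in a region when its frequency exceeds a threshold
(default 5%, the uniform expectation over 20 letters), negatively selected
below it, neutral at exactly the threshold.

Snorkeling profiles report the per-species Arg / Tyr content of the LWI
pool — the residues whose long flexible side chains can reach from the
hydrophobic core to the polar interface — for comparison across phyla and
cold- vs warm-blooded groups.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .conservation import TestResult
from .segments import ResiduePool
from .seqio import STANDARD_AA, UNKNOWN, SpeciesTable


class CompositionError(ValueError):
    """Empty pool or malformed group comparison."""


@dataclass(frozen=True)
class AAFrequencyTable:
    """Counts and percentages of the 20 standard amino acids in one region."""

    region: str
    counts: dict[str, int]
    total: int

    @property
    def percentages(self) -> dict[str, float]:
        return {aa: 100.0 * self.counts[aa] / self.total for aa in STANDARD_AA}

    def pct(self, aa: str) -> float:
        return 100.0 * self.counts[aa] / self.total


@dataclass(frozen=True)
class SnorkelProfile:
    """Per-species %Arg, %Tyr and %(Arg+Tyr) over the species' LWI pool."""

    table: pd.DataFrame  # columns: species, phylum, thermo, pct_arg, pct_tyr, pct_arg_tyr


def aa_frequency(pool: ResiduePool | str, region: str = "") -> AAFrequencyTable:
    """Composition table of a residue pool.

    Percentage = 100 * count / total over standard amino acids; 'X' is
    excluded from both numerator and denominator.
    """
    residues = pool.residues if isinstance(pool, ResiduePool) else pool
    counts = {aa: 0 for aa in STANDARD_AA}
    total = 0
    for ch in residues:
        if ch == UNKNOWN:
            continue
        if ch not in counts:
            raise CompositionError(f"non-standard residue {ch!r} in pool")
        counts[ch] += 1
        total += 1
    if total == 0:
        raise CompositionError("empty pool: no countable residues")
    return AAFrequencyTable(region=region, counts=counts, total=total)


def enrichment_classify(
    tables: list[AAFrequencyTable],
    threshold: float = 5.0,
    atol: float = 1e-9,
) -> pd.DataFrame:
    """Three-way selection classes per amino acid per region.

    positive iff percentage > threshold, negative iff < threshold, neutral
    when equal within ``atol``.  Returns a tidy frame with one row per
    (amino acid, region).
    """
    if not (0.0 < threshold < 100.0):
        raise CompositionError(f"threshold must be in (0, 100), got {threshold}")
    rows = []
    for tab in tables:
        for aa in STANDARD_AA:
            p = tab.pct(aa)
            if abs(p - threshold) <= atol:
                cls = "neutral"
            elif p > threshold:
                cls = "positive"
            else:
                cls = "negative"
            rows.append(
                {"amino_acid": aa, "region": tab.region, "pct": p, "class": cls}
            )
    return pd.DataFrame(rows)


def classify_percentage(pct: float, threshold: float = 5.0, atol: float = 1e-9) -> str:
    """Selection class of a single printed percentage."""
    if abs(pct - threshold) <= atol:
        return "neutral"
    return "positive" if pct > threshold else "negative"


def snorkel_profile(
    per_species_pools: dict[str, ResiduePool], species_table: SpeciesTable
) -> SnorkelProfile:
    """Per-species snorkeling-residue (Arg, Tyr) content with group labels."""
    rows = []
    for species, pool in per_species_pools.items():
        if species not in species_table:
            raise CompositionError(f"species {species!r} missing from species table")
        freq = aa_frequency(pool, region=species)
        info = species_table[species]
        pct_r, pct_y = freq.pct("R"), freq.pct("Y")
        rows.append(
            {
                "species": species,
                "phylum": info.phylum.value,
                "thermo": info.thermo.value,
                "pct_arg": pct_r,
                "pct_tyr": pct_y,
                "pct_arg_tyr": pct_r + pct_y,
            }
        )
    return SnorkelProfile(table=pd.DataFrame(rows))


def compare_groups(
    values: list[float], labels: list[str], test: str = "mann_whitney"
) -> TestResult:
    """Group comparison: Mann-Whitney U (two groups, tie-corrected normal
    approximation, min(U1, U2) reported), one-way ANOVA F, or Kruskal-Wallis.
    """
    if len(values) != len(labels):
        raise CompositionError("values and labels differ in length")
    groups: dict[str, list[float]] = {}
    for v, lab in zip(values, labels):
        groups.setdefault(lab, []).append(v)
    if any(len(g) == 0 for g in groups.values()):
        raise CompositionError("empty group")
    arrays = [np.asarray(g, dtype=float) for g in groups.values()]
    k = len(arrays)
    if test == "mann_whitney":
        if k != 2:
            raise CompositionError(f"Mann-Whitney needs exactly 2 groups, got {k}")
        res = stats.mannwhitneyu(arrays[0], arrays[1], alternative="two-sided")
        u1 = float(res.statistic)
        u = min(u1, len(arrays[0]) * len(arrays[1]) - u1)  # smaller-U convention
        return TestResult(name="mann_whitney", statistic=u, p_value=float(res.pvalue))
    if test == "anova":
        if k < 2:
            raise CompositionError("ANOVA needs at least 2 groups")
        ss_within = sum(((a - a.mean()) ** 2).sum() for a in arrays)
        means_equal = len({float(a.mean()) for a in arrays}) == 1
        if ss_within == 0:
            if means_equal:
                raise CompositionError(
                    "ANOVA F undefined: zero within-group variance and equal means"
                )
            # perfectly separated constant groups
            return TestResult(
                name="anova", statistic=float("inf"), p_value=0.0, df=float(k - 1)
            )
        f, p = stats.f_oneway(*arrays)
        return TestResult(name="anova", statistic=float(f), p_value=float(p),
                          df=float(k - 1))
    if test == "kruskal_wallis":
        from .conservation import kruskal_wallis

        return kruskal_wallis([list(a) for a in arrays])
    raise CompositionError(f"unknown test {test!r}")


def group_summary(profile: SnorkelProfile, by: str = "thermo") -> pd.DataFrame:
    """Group means of the snorkel percentages, by 'thermo' or 'phylum'."""
    if by not in ("thermo", "phylum"):
        raise CompositionError(f"group key must be 'thermo' or 'phylum', got {by!r}")
    return (
        profile.table.groupby(by)[["pct_arg", "pct_tyr", "pct_arg_tyr"]]
        .mean()
        .reset_index()
    )
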