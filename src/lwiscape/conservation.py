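"""Region divergence: p-distances, bootstrap, boxplot summaries, PFM/IC.

The divergence measure is the uncorrected p-distance — the proportion of
differing sites between two aligned sequences — computed under *pairwise
deletion*: for each pair, only the columns where both symbols are standard
amino acids are counted (gaps and 'X' are skipped per pair, not per column).
Bootstrap variance comes from resampling alignment columns with replacement.
Lower divergence means stronger conservation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .seqio import GAP, STANDARD_AA, UNKNOWN, SequenceSet
from .segments import SegmentAlignment

AA_INDEX = {aa: i for i, aa in enumerate(STANDARD_AA)}


class ConservationError(ValueError):
    """Undefined distance or malformed alignment."""


@dataclass(frozen=True)
class DistanceMatrix:
    labels: tuple[str, ...]
    d: np.ndarray  # (n, n) p-distances, symmetric, zero diagonal
    n_compared: np.ndarray  # (n, n) jointly counted sites

    def pair_values(self) -> np.ndarray:
        """Off-diagonal upper-triangle distances, row-major order."""
        iu = np.triu_indices(len(self.labels), k=1)
        return self.d[iu]


@dataclass(frozen=True)
class DivergenceSummary:
    """Tukey boxplot statistics of all pairwise distances in a region."""

    values: np.ndarray
    median: float
    q1: float
    q3: float
    whisker_low: float
    whisker_high: float
    outliers: np.ndarray
    n_pairs: int


@dataclass(frozen=True)
class BootstrapResult:
    reps: int
    seed: int
    labels: tuple[str, ...]
    variance: np.ndarray  # (n, n) per-pair bootstrap variance of p-distance
    std_error: np.ndarray


@dataclass(frozen=True)
class PositionFrequencyMatrix:
    """Per-column amino-acid frequencies over non-gap, non-'X' symbols."""

    freqs: np.ndarray  # (n_columns, 20), rows sum to 1 or are flagged empty
    counts: np.ndarray  # (n_columns,) counted residues per column
    gap_counts: np.ndarray  # (n_columns,) gaps per column
    alphabet: str = STANDARD_AA

    @property
    def n_columns(self) -> int:
        return self.freqs.shape[0]

    @property
    def empty_columns(self) -> np.ndarray:
        return self.counts == 0


@dataclass(frozen=True)
class TestResult:
    name: str
    statistic: float
    p_value: float
    df: float | None = None


# ---------------------------------------------------------------------------
# p-distance
# ---------------------------------------------------------------------------

_COUNTED = frozenset(STANDARD_AA)


def p_distance(a: str, b: str) -> tuple[float, int]:
    """Uncorrected p-distance between two aligned residue strings.

    Counts only columns where both symbols are standard amino acids
    (pairwise deletion; 'X' treated like a gap).  Raises when no column is
    comparable — the distance is undefined, not zero.
    """
    if len(a) != len(b):
        raise ConservationError(
            f"aligned strings differ in length: {len(a)} vs {len(b)}"
        )
    n = diff = 0
    for ca, cb in zip(a, b):
        if ca in _COUNTED and cb in _COUNTED:
            n += 1
            if ca != cb:
                diff += 1
    if n == 0:
        raise ConservationError("no comparable sites between the two sequences")
    return diff / n, n


def _encode(aln: SequenceSet) -> np.ndarray:
    """Alignment as (n_seq, n_col) int codes; -1 marks gap/'X' (not counted)."""
    arr = np.frombuffer(
        "".join(r.residues for r in aln).encode("ascii"), dtype=np.uint8
    ).reshape(len(aln), aln.n_columns)
    codes = np.full(arr.shape, -1, dtype=np.int8)
    for aa, i in AA_INDEX.items():
        codes[arr == ord(aa)] = i
    return codes


def _pairwise_from_codes(codes: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    n = codes.shape[0]
    valid = codes >= 0
    d = np.zeros((n, n))
    n_cmp = np.zeros((n, n), dtype=int)
    for i in range(n):
        both = valid[i] & valid[i + 1 :]
        ncol = both.sum(axis=1)
        diff = ((codes[i] != codes[i + 1 :]) & both).sum(axis=1)
        if np.any(ncol == 0):
            j = int(np.nonzero(ncol == 0)[0][0]) + i + 1
            raise ConservationError(
                f"pair ({i}, {j}) has zero comparable sites"
            )
        n_cmp[i, i + 1 :] = n_cmp[i + 1 :, i] = ncol
        d[i, i + 1 :] = d[i + 1 :, i] = diff / ncol
    return d, n_cmp


def distance_matrix(aln: SequenceSet) -> DistanceMatrix:
    """All-pairs p-distance matrix under pairwise deletion."""
    if not aln.aligned:
        raise ConservationError("distance matrix requires an aligned SequenceSet")
    if len(aln) < 2:
        raise ConservationError("need at least 2 sequences")
    codes = _encode(aln)
    d, n_cmp = _pairwise_from_codes(codes)
    return DistanceMatrix(labels=tuple(aln.ids), d=d, n_compared=n_cmp)


def bootstrap_distance(
    aln: SequenceSet, reps: int = 1000, seed: int = 0
) -> BootstrapResult:
    """Column-bootstrap variance of every pairwise p-distance.

    Each replicate resamples alignment columns with replacement to the
    original length and recomputes all pair distances; bit-reproducible
    given (reps, seed).
    """
    if reps < 1:
        raise ConservationError(f"reps must be >= 1, got {reps}")
    base = distance_matrix(aln)  # validates + raises on undefined pairs
    codes = _encode(aln)
    n, ncol = codes.shape
    rng = np.random.default_rng(seed)
    acc = np.zeros((reps, n, n))
    for r in range(reps):
        cols = rng.integers(0, ncol, size=ncol)
        sub = codes[:, cols]
        valid = sub >= 0
        for i in range(n):
            both = valid[i] & valid[i + 1 :]
            nc = both.sum(axis=1)
            diff = ((sub[i] != sub[i + 1 :]) & both).sum(axis=1)
            with np.errstate(invalid="ignore"):
                dv = np.where(nc > 0, diff / np.maximum(nc, 1), np.nan)
            acc[r, i, i + 1 :] = acc[r, i + 1 :, i] = dv
    variance = np.nanvar(acc, axis=0, ddof=1) if reps > 1 else np.zeros((n, n))
    np.fill_diagonal(variance, 0.0)
    return BootstrapResult(
        reps=reps,
        seed=seed,
        labels=base.labels,
        variance=variance,
        std_error=np.sqrt(variance),
    )


def divergence_summary(source: DistanceMatrix | np.ndarray) -> DivergenceSummary:
    """Boxplot statistics (median, quartiles, Tukey 1.5xIQR outliers)."""
    values = (
        source.pair_values()
        if isinstance(source, DistanceMatrix)
        else np.asarray(source, dtype=float)
    )
    if values.size == 0:
        raise ConservationError("no pairwise values to summarize")
    q1, med, q3 = np.percentile(values, [25, 50, 75])
    iqr = q3 - q1
    lo, hi = q1 - 1.5 * iqr, q3 + 1.5 * iqr
    inliers = values[(values >= lo) & (values <= hi)]
    return DivergenceSummary(
        values=values,
        median=float(med),
        q1=float(q1),
        q3=float(q3),
        whisker_low=float(inliers.min()),
        whisker_high=float(inliers.max()),
        outliers=values[(values < lo) | (values > hi)],
        n_pairs=int(values.size),
    )


# ---------------------------------------------------------------------------
# position frequency matrices / information content
# ---------------------------------------------------------------------------


def position_frequency_matrix(
    source: SegmentAlignment | SequenceSet | list[str],
) -> PositionFrequencyMatrix:
    """Per-column amino-acid frequencies of an aligned region.

    Accepts a projected segment (its per-sequence strings must be gap-free,
    i.e. uniform length — use the raw alignment columns otherwise), an
    aligned SequenceSet, or a plain list of equal-length strings.  'X' and
    '-' are excluded from the denominator; gaps are tallied separately.
    """
    if isinstance(source, SegmentAlignment):
        rows = list(source.sequences.values())
        lengths = {len(r) for r in rows}
        if len(lengths) > 1:
            raise ConservationError(
                "projected segment has gapped sequences; build the PFM from "
                "the alignment columns instead"
            )
    elif isinstance(source, SequenceSet):
        if not source.aligned:
            raise ConservationError("PFM requires aligned input")
        rows = [r.residues for r in source]
    else:
        rows = list(source)
        if len({len(r) for r in rows}) > 1:
            raise ConservationError("PFM rows must have equal length")
    if not rows:
        raise ConservationError("PFM requires at least one sequence")
    ncol = len(rows[0])
    freqs = np.zeros((ncol, 20))
    counts = np.zeros(ncol, dtype=int)
    gaps = np.zeros(ncol, dtype=int)
    for row in rows:
        for j, ch in enumerate(row):
            if ch == GAP:
                gaps[j] += 1
            elif ch != UNKNOWN:
                freqs[j, AA_INDEX[ch]] += 1
                counts[j] += 1
    nonzero = counts > 0
    freqs[nonzero] /= counts[nonzero, None]
    return PositionFrequencyMatrix(freqs=freqs, counts=counts, gap_counts=gaps)


def column_information_content(pfm: PositionFrequencyMatrix) -> np.ndarray:
    """Information content per column in bits: log2(20) - Shannon entropy.

    This is the standard sequence-logo letter-stack height over the 20-letter
    alphabet, without small-sample correction.  Empty columns yield NaN.
    """
    f = pfm.freqs
    with np.errstate(divide="ignore", invalid="ignore"):
        plogp = np.where(f > 0, f * np.log2(f), 0.0)
    entropy = -plogp.sum(axis=1)
    ic = np.log2(20.0) - entropy
    ic[pfm.empty_columns] = np.nan
    return ic


def kruskal_wallis(groups: list[list[float]]) -> TestResult:
    """Kruskal-Wallis rank test across >=2 groups (tie-corrected H,
    chi-square p with k-1 df)."""
    if len(groups) < 2:
        raise ConservationError("Kruskal-Wallis needs at least 2 groups")
    if any(len(g) == 0 for g in groups):
        raise ConservationError("empty group")
    arrays = [np.asarray(g, dtype=float) for g in groups]
    concat = np.concatenate(arrays)
    if np.all(concat == concat[0]):
        # all observations tied: H = 0 by convention (scipy raises)
        return TestResult(
            name="kruskal_wallis", statistic=0.0, p_value=1.0,
            df=float(len(groups) - 1),
        )
    h, p = stats.kruskal(*arrays)
    return TestResult(
        name="kruskal_wallis", statistic=float(h), p_value=float(p),
        df=float(len(groups) - 1),
    )
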