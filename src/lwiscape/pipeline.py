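"""End-to-end orchestration: flanks -> projection -> pooling -> divergence,
composition, snorkel profiles, motif scan, PFM/IC -> report bundle on disk.
"""

from __future__ import annotations

import hashlib
import json
import logging
import sys
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import composition as comp
from . import conservation as cons
from . import motifs as mot
from .segments import (
    LWISegment,
    SegmentAlignment,
    pool_from_projection,
    extract_flanks,
    project_segment,
)
from .seqio import (
    AnalysisConfig,
    Leaflet,
    SequenceSet,
    Side,
    SpeciesTable,
    TopologyAnnotation,
)

logger = logging.getLogger("lwiscape")


class PipelineError(ValueError):
    """Inconsistent inputs or unwritable output."""


@dataclass
class ReportBundle:
    """All pipeline outputs plus a manifest sufficient to re-run."""

    segments: list[LWISegment]
    projections: list[SegmentAlignment]
    segment_table: pd.DataFrame
    divergence: pd.DataFrame
    composition: pd.DataFrame
    enrichment: pd.DataFrame
    snorkel: pd.DataFrame
    group_tests: pd.DataFrame
    motif_matches: pd.DataFrame
    overlaps: pd.DataFrame
    pfm: pd.DataFrame
    manifest: dict = field(default_factory=dict)


def _digest(text: str) -> str:
    return hashlib.sha256(text.encode()).hexdigest()[:16]


def _region_groups(
    segments: list[LWISegment],
) -> dict[str, list[LWISegment]]:
    """Per-segment plus pooled region groupings used for the boxplot set."""
    groups: dict[str, list[LWISegment]] = {seg.name: [seg] for seg in segments}
    groups["all_N"] = [s for s in segments if s.side is Side.N]
    groups["all_C"] = [s for s in segments if s.side is Side.C]
    groups["all_inside"] = [s for s in segments if s.leaflet is Leaflet.INNER]
    groups["all_outside"] = [s for s in segments if s.leaflet is Leaflet.OUTER]
    return groups


def _concat_alignment(
    msa: SequenceSet, projections: list[SegmentAlignment]
) -> list[str]:
    """Per-sequence concatenation of the projected columns of segments."""
    cols: list[int] = []
    for p in projections:
        cols.extend(p.ref_columns)
    return ["".join(rec.residues[c] for c in cols) for rec in msa]


def run_full_analysis(
    msa: SequenceSet,
    ref_id: str,
    topology: TopologyAnnotation,
    species_table: SpeciesTable,
    config: AnalysisConfig,
) -> ReportBundle:
    """Execute every analysis stage and collect the report bundle.

    Stages: flank extraction and leaflet assignment on the reference
    topology; alignment projection of every segment; residue pooling per
    species; region-wise p-distance divergence summaries (per segment, all
    N vs all C, inner vs outer, pooled LWI); composition + enrichment for
    LWI / TM-core / full-length; per-species snorkeling profiles with
    cold-vs-warm and per-phylum tests; CRAC/CARC scan of the ungapped
    reference with LWI/named-region overlaps; per-segment PFM and
    information content.
    """
    if not msa.aligned:
        raise PipelineError("pipeline requires an aligned sequence set")
    try:
        ref = msa[ref_id]
    except KeyError:
        raise PipelineError(f"reference {ref_id!r} absent from alignment") from None
    ref_ungapped = ref.ungapped
    if topology.last_tm_end > len(ref_ungapped):
        raise PipelineError(
            f"topology last TM end {topology.last_tm_end} exceeds reference "
            f"ungapped length {len(ref_ungapped)}"
        )

    segments = extract_flanks(
        topology, flank_len=config.flank_len, seq_len=len(ref_ungapped)
    )
    logger.info("extracted %d LWI segments from %d TMs",
                len(segments), topology.n_tm)

    projections = [project_segment(msa, ref_id, seg) for seg in segments]

    seg_rows = []
    for seg, proj in zip(segments, projections):
        for sid, subseq in proj.sequences.items():
            seg_rows.append(
                {
                    "tm_label": seg.tm_label,
                    "side": seg.side.value,
                    "leaflet": seg.leaflet.value,
                    "start": seg.start,
                    "end": seg.end,
                    "sequence_id": sid,
                    "sequence": subseq,
                    "gaps": proj.gap_counts[sid],
                }
            )
    segment_table = pd.DataFrame(seg_rows)

    # --- divergence per region group -------------------------------------
    div_rows = []
    can_distance = len(msa) >= 2
    for region, segs in _region_groups(segments).items():
        projs = [p for p in projections if p.segment in segs]
        rows = _concat_alignment(msa, projs)
        if not can_distance:
            break
        region_set = SequenceSet(
            records=tuple(
                type(msa.records[0])(id=rec.id, residues=row, species=rec.species)
                for rec, row in zip(msa, rows)
            ),
            aligned=True,
        )
        try:
            dm = cons.distance_matrix(region_set)
            summ = cons.divergence_summary(dm)
        except cons.ConservationError as exc:
            logger.warning("region %s: divergence undefined (%s)", region, exc)
            continue
        div_rows.append(
            {
                "region": region,
                "n_pairs": summ.n_pairs,
                "median": summ.median,
                "q1": summ.q1,
                "q3": summ.q3,
                "whisker_low": summ.whisker_low,
                "whisker_high": summ.whisker_high,
                "n_outliers": int(summ.outliers.size),
            }
        )
        logger.info("region %-12s median p-distance %.4f over %d pairs",
                    region, summ.median, summ.n_pairs)
    divergence = pd.DataFrame(div_rows)

    # --- composition + enrichment ----------------------------------------
    pools = {
        rec.id: pool_from_projection(projections, rec.id, mode=config.pooling_mode)
        for rec in msa
    }
    lwi_residues = "".join(p.residues for p in pools.values())
    lwi_tab = comp.aa_frequency(lwi_residues, region="lwi")

    lwi_positions: set[int] = set()
    for seg in segments:
        lwi_positions.update(seg.positions)
    tm_core: list[str] = []
    full: list[str] = []
    ungapped_by_id = {rec.id: rec.ungapped for rec in msa}
    ref_proj_cols = {c for p in projections for c in p.ref_columns}
    # TM-core = TM positions minus flank positions (exclusive mode);
    # positions are reference coordinates projected through the alignment
    tm_positions = sorted(
        {
            pos
            for _, s, e in topology.tm_spans
            for pos in range(s, e + 1)
            if pos not in lwi_positions
        }
    )
    ref_cols_all = [c for c, ch in enumerate(ref.residues) if ch != "-"]
    tm_cols = [ref_cols_all[p - 1] for p in tm_positions]
    for rec in msa:
        tm_core.append(
            "".join(rec.residues[c] for c in tm_cols).replace("-", "")
        )
        full.append(ungapped_by_id[rec.id])
    tm_tab = comp.aa_frequency("".join(tm_core), region="tm_core")
    full_tab = comp.aa_frequency("".join(full), region="full_length")
    composition_tables = [lwi_tab, tm_tab, full_tab]
    enrichment = comp.enrichment_classify(
        composition_tables, threshold=config.enrichment_threshold
    )
    composition_df = pd.DataFrame(
        {
            "amino_acid": list(lwi_tab.percentages),
            "pct_lwi": [lwi_tab.pct(a) for a in lwi_tab.percentages],
            "pct_tm": [tm_tab.pct(a) for a in lwi_tab.percentages],
            "pct_full": [full_tab.pct(a) for a in lwi_tab.percentages],
        }
    )
    logger.info("composition pools: lwi=%d tm_core=%d full=%d residues",
                lwi_tab.total, tm_tab.total, full_tab.total)

    # --- snorkel profiles + group tests -----------------------------------
    species_pools = {
        sid: pool for sid, pool in pools.items() if sid in species_table
    }
    if species_pools:
        profile = comp.snorkel_profile(species_pools, species_table)
        snorkel = profile.table
        test_rows = []
        for metric in ("pct_arg", "pct_tyr", "pct_arg_tyr"):
            thermo_groups = snorkel.groupby("thermo")[metric].apply(list)
            if len(thermo_groups) == 2 and all(len(g) for g in thermo_groups):
                tr = comp.compare_groups(
                    list(snorkel[metric]), list(snorkel["thermo"]),
                    test="mann_whitney",
                )
                test_rows.append(
                    {"comparison": "cold_vs_warm", "metric": metric,
                     "test": tr.name, "statistic": tr.statistic,
                     "p_value": tr.p_value}
                )
            phyla = snorkel.groupby("phylum")[metric].apply(list)
            if len(phyla) >= 2:
                tr = cons.kruskal_wallis([list(g) for g in phyla])
                test_rows.append(
                    {"comparison": "across_phyla", "metric": metric,
                     "test": tr.name, "statistic": tr.statistic,
                     "p_value": tr.p_value}
                )
        group_tests = pd.DataFrame(test_rows)
    else:
        snorkel = pd.DataFrame(
            columns=["species", "phylum", "thermo",
                     "pct_arg", "pct_tyr", "pct_arg_tyr"]
        )
        group_tests = pd.DataFrame(
            columns=["comparison", "metric", "test", "statistic", "p_value"]
        )

    # --- motif scan on the ungapped reference -----------------------------
    crac = mot.build_pattern("crac")
    carc = mot.build_pattern("carc", carc_center=config.carc_center)
    match_rows = []
    all_matches: list[mot.MotifMatch] = []
    for pattern in (crac, carc):
        for m in mot.scan_pattern(ref_ungapped, pattern):
            all_matches.append(m)
            match_rows.append(
                {
                    "sequence_id": ref_id,
                    "pattern": m.pattern,
                    "start": m.start,
                    "end": m.end,
                    "a1": m.anchors[0],
                    "c": m.anchors[1],
                    "a3": m.anchors[2],
                    "substring": m.substring,
                }
            )
    motif_matches = pd.DataFrame(
        match_rows,
        columns=["sequence_id", "pattern", "start", "end",
                 "a1", "c", "a3", "substring"],
    )
    regions = [(seg.name, seg.start, seg.end) for seg in segments]
    regions += [(label, s, e) for label, s, e in topology.named_regions]
    overlaps = pd.DataFrame(
        mot.motif_segment_overlap(all_matches, regions),
        columns=["pattern", "motif_start", "motif_end", "region",
                 "region_start", "region_end", "overlap"],
    )
    logger.info("motif scan: %d matches, %d region overlaps",
                len(motif_matches), len(overlaps))

    # --- PFM / IC per segment ---------------------------------------------
    pfm_rows = []
    for seg, proj in zip(segments, projections):
        cols_matrix = [
            "".join(rec.residues[c] for c in proj.ref_columns) for rec in msa
        ]
        pfm = cons.position_frequency_matrix(cols_matrix)
        ic = cons.column_information_content(pfm)
        for j in range(pfm.n_columns):
            row = {
                "segment": seg.name,
                "position": seg.start + j,
                "bits": float(ic[j]) if np.isfinite(ic[j]) else float("nan"),
                "gaps": int(pfm.gap_counts[j]),
            }
            row.update(
                {aa: pfm.freqs[j, i] for i, aa in enumerate(pfm.alphabet)}
            )
            pfm_rows.append(row)
    pfm_df = pd.DataFrame(pfm_rows)

    manifest = {
        "reference": ref_id,
        "n_sequences": len(msa),
        "n_columns": msa.n_columns,
        "topology_digest": _digest(
            json.dumps([topology.protein_id, topology.n_term_side.value,
                        list(topology.tm_spans)])
        ),
        "msa_digest": _digest("".join(r.id + r.residues for r in msa)),
        "config": {
            "flank_len": config.flank_len,
            "bootstrap_reps": config.bootstrap_reps,
            "enrichment_threshold": config.enrichment_threshold,
            "pooling_mode": config.pooling_mode,
            "carc_center": config.carc_center,
            "seed": config.seed,
            "membrane_label": config.membrane_label,
        },
        "n_segments": len(segments),
        "pool_size_per_sequence": {
            sid: len(pool) for sid, pool in pools.items()
        },
    }

    return ReportBundle(
        segments=segments,
        projections=projections,
        segment_table=segment_table,
        divergence=divergence,
        composition=composition_df,
        enrichment=enrichment,
        snorkel=snorkel,
        group_tests=group_tests,
        motif_matches=motif_matches,
        overlaps=overlaps,
        pfm=pfm_df,
        manifest=manifest,
    )


REPORT_FILES = {
    "segments": "segments.tsv",
    "divergence": "divergence.tsv",
    "composition": "composition.tsv",
    "enrichment": "enrichment.tsv",
    "snorkel": "snorkel.tsv",
    "group_tests": "group_tests.tsv",
    "motif_matches": "motifs.tsv",
    "overlaps": "overlaps.tsv",
    "pfm": "pfm.tsv",
}


def export_report(bundle: ReportBundle, out_dir: str | Path,
                  force: bool = False) -> Path:
    """Write the bundle as fixed-name TSVs plus manifest.json.

    Refuses to write into an existing directory unless ``force``.
    """
    out = Path(out_dir)
    if out.exists() and not force:
        if any(out.iterdir()):
            raise PipelineError(
                f"output directory {out} exists and is not empty "
                "(pass force=True / --force)"
            )
    out.mkdir(parents=True, exist_ok=True)
    frames = {
        "segments": bundle.segment_table,
        "divergence": bundle.divergence,
        "composition": bundle.composition,
        "enrichment": bundle.enrichment,
        "snorkel": bundle.snorkel,
        "group_tests": bundle.group_tests,
        "motif_matches": bundle.motif_matches,
        "overlaps": bundle.overlaps,
        "pfm": bundle.pfm,
    }
    for key, fname in REPORT_FILES.items():
        frames[key].to_csv(out / fname, sep="\t", index=False,
                           float_format="%.10g")
    with open(out / "manifest.json", "w") as fh:
        json.dump(bundle.manifest, fh, indent=2, sort_keys=True)
    return out
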