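"""End-to-end orchestration: screen -> detect -> assign -> consensus -> probes.

The pipeline is a pure composition of the stage functions; every stage's
output can be reproduced by running the corresponding CLI subcommand with
the same parameters.  A run log records every threshold and the seed, so a
run is fully re-derivable from its log.  The per-read dot-plot gallery is a
directory of PNGs plus an index TSV.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Dict, List, Optional

import pandas as pd

from . import catalog as cat
from . import consensus as cns
from . import detect as det
from . import kmer, probes, seqio
from .selfalign import render_dotplot, seed_matches

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    input_fasta: str
    output_dir: str
    seed: int = 0
    screen: kmer.ScreenParams = field(default_factory=kmer.ScreenParams)
    detect: det.DetectParams = field(default_factory=det.DetectParams)
    trf: cns.TrfParams = field(default_factory=cns.TrfParams)
    catalog_path: Optional[str] = None  # JSON catalog to extend; None -> empty
    seed_known_families: bool = False
    dotplots: bool = False
    word: int = 10
    min_continuity_for_probe: float = 0.5
    probe_length: int = 22


def run_pipeline(config: PipelineConfig) -> Path:
    """Run all stages and write every artifact into ``config.output_dir``."""
    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    reads = seqio.read_fasta(config.input_fasta)
    if not reads:
        raise ValueError("empty input FASTA")
    library_size = len(reads)
    reads = seqio.filter_by_length(reads, config.screen.min_read_len)

    # 1. k-mer screen
    retained, stats = kmer.screen_library(reads, config.screen)
    seqio.write_fasta(retained, outdir / "retained.fasta")
    screen_rows = []
    for r in reads:
        rc = kmer.rank_count(kmer.count_kmers(r, config.screen.k), config.screen.rank)
        screen_rows.append((r.read_id, r.length, rc, rc >= config.screen.min_count))
    pd.DataFrame(
        screen_rows, columns=["read_id", "length", "rank_count", "retained"]
    ).to_csv(outdir / "screen_stats.tsv", sep="\t", index=False)

    # 2. detection (+ optional dot-plot gallery)
    gallery = outdir / "dotplots"
    region_rows, pattern_rows = [], []
    per_read: Dict[str, List[det.TRRegion]] = {}
    for r in retained:
        ms = seed_matches(r.sequence, r.sequence, word=config.word,
                          both_strands=False, query_id=r.read_id, target_id=r.read_id)
        regions = det.call_tr_regions(r, ms, config.detect)
        pattern = det.classify_pattern(r, regions, params=config.detect)
        per_read[r.read_id] = regions
        pattern_rows.append((r.read_id, pattern.value))
        for reg in regions:
            region_rows.append(
                (r.read_id, reg.start, reg.end, round(reg.period_bp, 1),
                 round(reg.copy_estimate, 2), round(reg.continuity, 3),
                 int(reg.low_complexity))
            )
        if config.dotplots:
            gallery.mkdir(exist_ok=True)
            render_dotplot(ms, r.length, r.length, gallery / f"{r.read_id}.png")
    pd.DataFrame(
        region_rows,
        columns=["read_id", "start", "end", "period", "copies", "continuity",
                 "low_complexity"],
    ).to_csv(outdir / "regions.tsv", sep="\t", index=False)
    pd.DataFrame(pattern_rows, columns=["read_id", "pattern"]).to_csv(
        outdir / "patterns.tsv", sep="\t", index=False
    )
    if config.dotplots and gallery.exists():
        pd.DataFrame(
            [(p.stem, p.name) for p in sorted(gallery.glob("*.png"))],
            columns=["read_id", "image"],
        ).to_csv(outdir / "dotplot_index.tsv", sep="\t", index=False)

    # 3. catalog assignment, founding new families as they appear
    if config.catalog_path:
        ps = cat.PolySeq.from_json(config.catalog_path)
    elif config.seed_known_families:
        ps = cat.build_polyseq(cat.known_families())
    else:
        ps = cat.PolySeq()
    assignments: List[cat.FamilyAssignment] = []
    units: Dict[str, cns.ConsensusUnit] = {}
    family_units: Dict[str, List[cns.ConsensusUnit]] = {}
    for r in retained:
        regions = per_read[r.read_id]
        for reg in regions:
            if reg.low_complexity:
                continue
            key = f"{r.read_id}:{reg.start}"
            unit = cns.derive_consensus(r, reg, reg.period_bp, config.trf)
            if unit is not None:
                units[key] = unit
        asg = cat.assign_read(r, regions, ps, word=config.word) if ps.families else []
        if not asg and any(not reg.low_complexity for reg in regions):
            asg = [cat.FamilyAssignment(r.read_id, None, cat.NEW_FAMILY, -1, 0.0)]
        resolved: List[cat.FamilyAssignment] = []
        for a in asg:
            if a.family_name == cat.NEW_FAMILY:
                reg = a.region or max(
                    (x for x in regions if not x.low_complexity),
                    key=lambda x: x.support_bp,
                )
                key = f"{r.read_id}:{reg.start}"
                unit = units.get(key)
                if unit is None:
                    continue
                ps, fam = cat.register_new_family(ps, r, reg, unit)
                a = cat.FamilyAssignment(
                    r.read_id, reg, fam.name, fam.block_offset_kb, 1.0
                )
            resolved.append(a)
        assignments.extend(resolved)
        for a in resolved:
            if a.region is None:
                continue
            key = f"{r.read_id}:{a.region.start}"
            if key in units:
                family_units.setdefault(a.family_name, []).append(units[key])
    pd.DataFrame(
        [
            (a.read_id, a.family_name, a.block_offset_kb, round(a.match_fraction, 3))
            for a in assignments
        ],
        columns=["read_id", "family", "block_offset_kb", "match_fraction"],
    ).to_csv(outdir / "assignments.tsv", sep="\t", index=False)
    ps.write(outdir / "polyseq.fasta", outdir / "polyseq_blocks.tsv")
    ps.to_json(outdir / "catalog.json")

    # 4. consensus table + family summary
    cons_rows = []
    for key, u in units.items():
        cons_rows.append(
            (u.read_id, u.region.start, u.region.end, u.rounded_size,
             round(u.copies, 2), u.at_percent, u.array_score)
        )
    pd.DataFrame(
        cons_rows,
        columns=["read_id", "start", "end", "rounded_size", "copies",
                 "at_percent", "score"],
    ).to_csv(outdir / "consensus.tsv", sep="\t", index=False)
    with open(outdir / "consensus.fasta", "w") as fh:
        for key, u in units.items():
            fh.write(f">{u.read_id}_{u.region.start} size={u.rounded_size}\n")
            fh.write(u.consensus + "\n")
    abundance = cat.abundance_table(assignments, library_size)
    fam_meta = {f.name: f for f in ps.families}
    summary_rows = []
    for _, row in abundance.iterrows():
        fam = fam_meta.get(row["family"])
        fam_u = family_units.get(row["family"], [])
        rep = max(fam_u, key=lambda u: u.array_score).read_id if fam_u else (
            fam.discovery_read if fam else ""
        )
        at = (
            max(fam_u, key=lambda u: u.array_score).at_percent if fam_u
            else (cns.at_content(fam.consensus) if fam else "")
        )
        summary_rows.append(
            (row["family"], fam.unit_length_bp if fam else "", row["n_reads"],
             row["reads_per_million"], at, rep)
        )
    pd.DataFrame(
        summary_rows,
        columns=["family", "unit_length", "n_reads", "reads_per_million",
                 "at_percent", "representative_read"],
    ).to_csv(outdir / "family_summary.tsv", sep="\t", index=False)

    # 5. probes from conserved windows of high-continuity consensi
    probe_rows = []
    with open(outdir / "probes.fasta", "w") as fh:
        for fam_name, fam_u in sorted(family_units.items()):
            good = [
                u for u in fam_u if u.region.continuity >= config.min_continuity_for_probe
            ]
            if len(good) < 2:
                continue
            cand = probes.design_probe(
                [u.consensus for u in good], fam_name, length=config.probe_length
            )
            rec = probes.probe_record(cand)
            probe_rows.append(
                (rec["name"], rec["sequence"], rec["fluorophores"],
                 round(cand.conservation, 3), cand.at_percent)
            )
            fh.write(f">{cand.name}\n{cand.sequence}\n")
    pd.DataFrame(
        probe_rows,
        columns=["name", "sequence", "fluorophores", "conservation", "at_percent"],
    ).to_csv(outdir / "probes.tsv", sep="\t", index=False)

    # 6. run log
    log = dict(
        input=str(config.input_fasta),
        seed=config.seed,
        n_input=library_size,
        n_after_length_filter=len(reads),
        n_retained=stats.n_retained,
        enrichment_factor=round(stats.enrichment_factor, 2),
        screen=asdict(config.screen),
        detect=asdict(config.detect),
        trf=asdict(config.trf),
        word=config.word,
        n_families=len(ps.families),
    )
    (outdir / "run_log.json").write_text(json.dumps(log, indent=1))
    return outdir
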