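"""End-to-end pipeline: correct -> dedup -> families -> reconstruct -> map ->
collapse -> events, with optional lncRNA and summary-statistics stages.

Configuration is a single flat model serializing round-trip stable to YAML;
unknown keys are rejected.  Every stage writes its intermediate under
``outdir`` and contributes counts to the run report.
"""

from __future__ import annotations

import json
import logging
import sys
from pathlib import Path
from typing import Dict, List, Optional, Tuple

import yaml
from pydantic import BaseModel, ConfigDict

from . import correct as correct_mod
from . import dedup as dedup_mod
from . import families as families_mod
from . import io_utils, isoforms, orf_lncrna, reconstruct, spliced_map, stats

log = logging.getLogger("unitrans")


class RunConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")

    # inputs / outputs
    transcripts: List[str]
    tissues: Optional[List[str]] = None  # parallel to `transcripts`
    short_reads: Optional[str] = None
    hits: Optional[str] = None
    coding_train: Optional[str] = None
    noncoding_train: Optional[str] = None
    outdir: str = "unitrans_out"
    seed: int = 0

    # stage parameters (defaults per stage module)
    correct_k: int = correct_mod.DEFAULT_K
    correct_solid_threshold: int = correct_mod.DEFAULT_SOLID_THRESHOLD
    correct_max_edits_per_100nt: int = correct_mod.DEFAULT_MAX_EDITS_PER_100NT
    dedup_c: float = dedup_mod.DEFAULT_C
    dedup_aS: float = dedup_mod.DEFAULT_AS_COV
    dedup_AS: int = dedup_mod.DEFAULT_AS_NT
    family_k: int = families_mod.DEFAULT_K
    family_min_similarity: float = families_mod.DEFAULT_MIN_SIMILARITY
    reconstruct_k: int = reconstruct.DEFAULT_K
    map_min_junction_gap: int = spliced_map.DEFAULT_MIN_JUNCTION_GAP
    map_max_read_slop: int = spliced_map.DEFAULT_MAX_READ_SLOP
    collapse_eps: int = 0
    lncrna_evalue_max: float = orf_lncrna.DEFAULT_EVALUE_MAX

    @classmethod
    def from_yaml(cls, path: str) -> "RunConfig":
        with open(path) as fh:
            return cls(**(yaml.safe_load(fh) or {}))

    def to_yaml(self) -> str:
        return yaml.safe_dump(self.model_dump(), sort_keys=True)


def write_bed12(path: Path, alignments: List[spliced_map.SplicedAlignment]) -> None:
    with open(path, "w") as fh:
        for aln in alignments:
            if not aln.mapped:
                continue
            start, end = aln.span
            sizes = ",".join(str(me - ms) for ms, me, _, _ in aln.blocks)
            starts = ",".join(str(ms - start) for ms, me, _, _ in aln.blocks)
            fh.write(
                "\t".join(
                    [
                        aln.model_id,
                        str(start),
                        str(end),
                        aln.transcript_id,
                        str(round(aln.identity * 1000)),
                        "+",
                        str(start),
                        str(end),
                        "0",
                        str(len(aln.blocks)),
                        sizes,
                        starts,
                    ]
                )
                + "\n"
            )


def write_isoform_gtf(path: Path, isos: List[isoforms.Isoform], alignments: Dict[str, spliced_map.SplicedAlignment]) -> None:
    """GTF (1-based inclusive): one transcript per isoform, exons = aligned
    blocks of the representative transcript."""
    with open(path, "w") as fh:
        for iso in isos:
            rep = alignments[iso.representative_id]
            attrs = (
                f'gene_id "{iso.model_id}"; transcript_id "{iso.isoform_id}"; '
                f'support "{iso.support}"; representative "{iso.representative_id}";'
            )
            start, end = rep.span
            fh.write(f"{iso.model_id}\tunitrans\ttranscript\t{start + 1}\t{end}\t.\t+\t.\t{attrs}\n")
            for ms, me, _, _ in rep.blocks:
                fh.write(f"{iso.model_id}\tunitrans\texon\t{ms + 1}\t{me}\t.\t+\t.\t{attrs}\n")


def run_pipeline(config: RunConfig) -> Dict[str, object]:
    """Execute the configured stages; returns the run report dict."""
    for path in config.transcripts:
        if not Path(path).exists():
            raise RuntimeError(f"[load] missing input {path}")
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    report: Dict[str, object] = {"config": config.model_dump(), "stages": {}}
    stage_counts: Dict[str, object] = report["stages"]  # type: ignore[assignment]

    def fail(stage: str, msg: str) -> None:
        raise RuntimeError(f"[{stage}] {msg}")

    # ---- load inputs
    transcripts: Dict[str, str] = {}
    tissue_of: Dict[str, str] = {}
    tissues = config.tissues or ["all"] * len(config.transcripts)
    if len(tissues) != len(config.transcripts):
        fail("load", "tissues must parallel transcripts")
    for path, tissue in zip(config.transcripts, tissues):
        if not Path(path).exists():
            fail("load", f"missing input {path}")
        batch = io_utils.read_fasta(path)
        for tid, seq in batch.items():
            if tid in transcripts:
                fail("load", f"duplicate transcript id across inputs: {tid}")
            transcripts[tid] = seq
            tissue_of[tid] = tissue
    log.info("load: %d transcripts", len(transcripts))
    stage_counts["input_transcripts"] = len(transcripts)

    # ---- correct (optional)
    if config.short_reads:
        reads = io_utils.read_fastx(config.short_reads)
        spectrum = correct_mod.build_spectrum(
            reads.values(), k=config.correct_k, solid_threshold=config.correct_solid_threshold
        )
        transcripts, edits = correct_mod.correct_all(
            transcripts, spectrum, config.correct_max_edits_per_100nt
        )
        io_utils.write_fasta(outdir / "corrected.fasta", transcripts.items())
        stage_counts["correction_edits"] = int(sum(edits.values()))
        log.info("correct: %d edits over %d transcripts", sum(edits.values()), len(transcripts))

    # ---- dedup
    clusters = dedup_mod.cluster_redundant(transcripts, c=config.dedup_c, aS=config.dedup_aS, AS=config.dedup_AS)
    nr = {cl.representative_id: transcripts[cl.representative_id] for cl in clusters}
    io_utils.write_fasta(outdir / "nr.fasta", nr.items())
    with open(outdir / "clusters.tsv", "w") as fh:
        fh.write("cluster_id\trepresentative_id\tmember_id\tidentity\tshorter_coverage\tshorter_unaligned\n")
        for i, cl in enumerate(clusters, 1):
            for m in cl.member_ids:
                ident, cov, un = cl.metrics[m]
                fh.write(f"C{i:05d}\t{cl.representative_id}\t{m}\t{ident:.4f}\t{cov:.4f}\t{un}\n")
    stage_counts["nonredundant_transcripts"] = len(nr)
    log.info("dedup: %d -> %d", len(transcripts), len(nr))

    # ---- families
    partition = families_mod.partition_families(nr, k=config.family_k, min_similarity=config.family_min_similarity)
    with open(outdir / "families.tsv", "w") as fh:
        fh.write("family_id\ttranscript_id\n")
        for fid, members in partition.families.items():
            for tid in members:
                fh.write(f"{fid}\t{tid}\n")
    stage_counts["families"] = len(partition.families)
    log.info("families: %d", len(partition.families))

    # ---- reconstruct
    models: Dict[str, str] = {}
    model_of_transcript: Dict[str, List[str]] = {}
    with open(outdir / "assignments.tsv", "w") as fh:
        fh.write("model_id\ttranscript_id\n")
        for fid, members in partition.families.items():
            fam_seqs = {tid: nr[tid] for tid in members}
            for model in reconstruct.reconstruct_family(fam_seqs, family_id=fid, k=config.reconstruct_k):
                models[model.id] = model.sequence
                for tid in model.assigned_transcripts:
                    model_of_transcript.setdefault(tid, []).append(model.id)
                    fh.write(f"{model.id}\t{tid}\n")
    io_utils.write_fasta(outdir / "models.fasta", models.items())
    stage_counts["unitransmodels"] = len(models)
    log.info("reconstruct: %d models", len(models))

    # ---- map
    alignments = spliced_map.map_all(
        nr,
        models,
        model_of=model_of_transcript,
        min_junction_gap=config.map_min_junction_gap,
        max_read_slop=config.map_max_read_slop,
    )
    write_bed12(outdir / "alignments.bed12", alignments)
    mapped = [a for a in alignments if a.mapped]
    stage_counts["mapped_transcripts"] = len(mapped)
    log.info("map: %d/%d mapped", len(mapped), len(alignments))

    # ---- collapse + events
    isos = isoforms.collapse_isoforms(mapped, eps=config.collapse_eps, tissue_of=tissue_of)
    write_isoform_gtf(outdir / "isoforms.gtf", isos, {a.transcript_id: a for a in mapped})
    by_model: Dict[str, List[isoforms.Isoform]] = {}
    for iso in isos:
        by_model.setdefault(iso.model_id, []).append(iso)
    events: List[isoforms.ASEvent] = []
    for mid in sorted(by_model):
        if len(by_model[mid]) >= 2:
            events.extend(isoforms.classify_events(by_model[mid]))
    with open(outdir / "events.tsv", "w") as fh:
        fh.write("model_id\ttype\tcoordinates\tisoform_a\tisoform_b\n")
        for ev in events:
            coords = ",".join(map(str, ev.coordinates))
            fh.write(f"{ev.model_id}\t{ev.type}\t{coords}\t{ev.isoform_pair[0]}\t{ev.isoform_pair[1]}\n")
    summary = isoforms.isoform_summary(isos)
    stage_counts["isoforms"] = len(isos)
    stage_counts["as_events"] = len(events)
    stage_counts["multi_isoform_fraction"] = summary["multi_isoform_fraction"]
    log.info("collapse: %d isoforms, %d AS events", len(isos), len(events))

    # ---- lncrna (optional)
    if config.hits is not None and config.coding_train and config.noncoding_train:
        hit_rows = _read_hits(config.hits)
        table = orf_lncrna.train_hexamer_tables(
            io_utils.read_fasta(config.coding_train).values(),
            io_utils.read_fasta(config.noncoding_train).values(),
        )
        calls = orf_lncrna.lncrna_pipeline(models, hit_rows, table, evalue_max=config.lncrna_evalue_max)
        _write_lncrna(outdir / "lncrna.tsv", calls)
        stage_counts["lncrnas"] = sum(c.is_lncRNA for c in calls)
        log.info("lncrna: %d calls", sum(c.is_lncRNA for c in calls))

    # ---- stats
    report["n50_input"] = stats.n50([len(s) for s in transcripts.values()])
    report["n50_models"] = stats.n50([len(s) for s in models.values()]) if models else 0
    with open(outdir / "report.json", "w") as fh:
        json.dump(report, fh, indent=2, sort_keys=True)
    return report


def analyze_transcripts(
    transcripts: Dict[str, str],
    short_reads: Optional[List[str]] = None,
    correct_k: int = correct_mod.DEFAULT_K,
    correct_solid_threshold: int = correct_mod.DEFAULT_SOLID_THRESHOLD,
    family_k: int = families_mod.DEFAULT_K,
    reconstruct_k: int = reconstruct.DEFAULT_K,
    collapse_eps: int = 0,
) -> Dict[str, object]:
    """In-memory pipeline (no files): correct -> dedup -> families ->
    reconstruct -> map -> collapse -> events.

    Returns a dict with the intermediates of every stage; the file-writing
    ``run_pipeline`` wraps the same stages.
    """
    if short_reads:
        spectrum = correct_mod.build_spectrum(short_reads, k=correct_k, solid_threshold=correct_solid_threshold)
        transcripts, _ = correct_mod.correct_all(transcripts, spectrum)
    clusters = dedup_mod.cluster_redundant(transcripts)
    nr = {cl.representative_id: transcripts[cl.representative_id] for cl in clusters}
    partition = families_mod.partition_families(nr, k=family_k)
    models: Dict[str, str] = {}
    model_of: Dict[str, List[str]] = {}
    for fid, members in partition.families.items():
        fam_seqs = {tid: nr[tid] for tid in members}
        for model in reconstruct.reconstruct_family(fam_seqs, family_id=fid, k=reconstruct_k):
            models[model.id] = model.sequence
            for tid in model.assigned_transcripts:
                model_of.setdefault(tid, []).append(model.id)
    alignments = spliced_map.map_all(nr, models, model_of=model_of)
    mapped = [a for a in alignments if a.mapped]
    isos = isoforms.collapse_isoforms(mapped, eps=collapse_eps)
    by_model: Dict[str, List[isoforms.Isoform]] = {}
    for iso in isos:
        by_model.setdefault(iso.model_id, []).append(iso)
    events: List[isoforms.ASEvent] = []
    for mid in sorted(by_model):
        if len(by_model[mid]) >= 2:
            events.extend(isoforms.classify_events(by_model[mid]))
    return {
        "corrected": transcripts,
        "clusters": clusters,
        "nonredundant": nr,
        "partition": partition,
        "models": models,
        "model_of": model_of,
        "alignments": alignments,
        "isoforms": isos,
        "events": events,
    }


def _read_hits(path: str) -> List[Tuple[str, float]]:
    """BLAST outfmt-6-compatible TSV: query id in column 1, E-value in column 11
    (two-column transcript_id/evalue files are also accepted)."""
    rows: List[Tuple[str, float]] = []
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith("#"):
                continue
            parts = line.rstrip("\n").split("\t")
            if len(parts) >= 11:
                rows.append((parts[0], float(parts[10])))
            elif len(parts) >= 2:
                rows.append((parts[0], float(parts[1])))
    return rows


def _write_lncrna(path: Path, calls: List[orf_lncrna.LncRNACall]) -> None:
    with open(path, "w") as fh:
        fh.write("transcript_id\tstep_a\tstep_b\tstep_c\tis_lncRNA\tlongest_orf_aa\tcombined_score\n")
        for c in calls:
            fh.write(
                "\t".join(
                    [
                        c.transcript_id,
                        str("no_protein_hit" in c.passed_steps),
                        str("orf_filter" in c.passed_steps),
                        str("coding_potential" in c.passed_steps),
                        str(c.is_lncRNA),
                        str(c.longest_orf_aa),
                        f"{c.combined_score:.4f}",
                    ]
                )
                + "\n"
            )


def setup_logging(verbose: bool = True) -> None:
    handler = logging.StreamHandler(sys.stderr)
    handler.setFormatter(logging.Formatter("[%(name)s] %(levelname)s %(message)s"))
    log.handlers[:] = [handler]
    log.setLevel(logging.INFO if verbose else logging.WARNING)
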