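"""End-to-end orchestration: filter -> demux -> cluster -> consensus -> classify.

One sequencing run carries one marker's amplicon library (markers are run in
separate flow cells so that leftover molecules of the previous run are
recognisable by their primers), but the pipeline equally accepts a single
combined FASTQ and separates markers by primer content.  Stages run in a
fixed order; every intermediate is written to the output directory and all
randomness derives from one global seed by fixed per-stage offsets, so a
rerun with the same configuration is byte-identical.
"""

from __future__ import annotations

import dataclasses
import json
import os
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Mapping, Optional, Sequence, Tuple, Union

import yaml

from . import clustering, consensus, preprocess, primers, taxonomy
from .io_seq import (Read, ReferenceRecord, read_fastq, read_reference_fasta,
                     write_fasta, write_fastq)

_SUBSAMPLE_OFFSET = 10_007
_MSA_OFFSET = 20_011
_MOD = 2**31 - 1


@dataclass
class PipelineConfig:
    """All workflow thresholds, with the printed defaults of the method."""

    # quality/length filter
    min_mean_q: float = 10.0
    min_len: int = 500
    max_len: int = 800
    # primer matching
    max_error_rate: float = 0.20
    min_overlap: int = 15
    # clustering
    cluster_threshold: float = 80.0
    min_cluster_size: int = 5
    kmer_prescreen: Optional[int] = 5
    # consensus
    subsample_cap: int = 100
    consensus_threshold: float = 0.30
    # taxonomy
    min_identity: float = 98.0
    min_coverage: float = 90.0
    score_margin: float = 0.0
    strict_conflict: bool = False
    # misc
    adapters: Tuple[str, ...] = ()
    seed: int = 0
    # inputs; ``reads`` maps marker name -> FASTQ (or in-memory reads) for
    # one-run-per-marker layouts, or holds a single combined input
    reads: Union[str, Mapping, Sequence, None] = None
    primer_sets: List[primers.MarkerPrimerSet] = field(default_factory=list)
    references: Union[str, List[ReferenceRecord], None] = None
    outdir: Optional[str] = None
    absence_labels: Dict[Tuple[str, str], str] = field(default_factory=dict)

    def filter_params(self) -> preprocess.FilterParams:
        return preprocess.FilterParams(self.min_mean_q, self.min_len,
                                       self.max_len)

    def primer_params(self) -> primers.PrimerParams:
        return primers.PrimerParams(self.max_error_rate, self.min_overlap)

    @classmethod
    def from_yaml(cls, path: Union[str, os.PathLike]) -> "PipelineConfig":
        with open(path) as handle:
            raw = yaml.safe_load(handle) or {}
        psets = [primers.MarkerPrimerSet(name, d["forward"], d["reverse"])
                 for name, d in raw.pop("primers", {}).items()]
        absence = {(species, marker): label
                   for species, marker, label in raw.pop("absence_labels", [])}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        if "adapters" in raw and raw["adapters"]:
            raw["adapters"] = tuple(raw["adapters"])
        return cls(primer_sets=psets, absence_labels=absence, **raw)


@dataclass
class MarkerResult:
    marker: str
    n_classified: int = 0
    n_trimmed_empty: int = 0
    n_clusters: int = 0
    n_clusters_used: int = 0
    clusters: List[clustering.Cluster] = field(default_factory=list)
    consensi: List[consensus.ConsensusRecord] = field(default_factory=list)
    assignments: List[taxonomy.TaxonomicAssignment] = field(default_factory=list)


@dataclass
class RunReport:
    seed: int
    n_input: int = 0
    n_filtered: int = 0
    n_classified: int = 0
    n_unassigned: int = 0
    per_marker: Dict[str, MarkerResult] = field(default_factory=dict)
    carryover: Dict[str, dict] = field(default_factory=dict)
    final_conclusions: List[taxonomy.FinalConclusion] = field(default_factory=list)
    config_echo: dict = field(default_factory=dict)

    def to_json(self) -> str:
        def default(o):
            if dataclasses.is_dataclass(o):
                return dataclasses.asdict(o)
            if isinstance(o, (set, tuple)):
                return list(o)
            return str(o)
        payload = {
            "seed": self.seed,
            "n_input": self.n_input,
            "n_filtered": self.n_filtered,
            "n_classified": self.n_classified,
            "n_unassigned": self.n_unassigned,
            "per_marker": {
                m: {
                    "n_classified": r.n_classified,
                    "n_trimmed_empty": r.n_trimmed_empty,
                    "n_clusters": r.n_clusters,
                    "n_clusters_used": r.n_clusters_used,
                    "cluster_sizes": [c.size for c in r.clusters],
                    "consensi": [
                        {"id": c.consensus_id, "length": len(c.sequence),
                         "n_reads_used": c.n_reads_used}
                        for c in r.consensi],
                    "assignments": [
                        {"consensus_id": a.consensus_id, "rank": a.rank,
                         "taxon": a.taxon} for a in r.assignments],
                } for m, r in self.per_marker.items()},
            "carryover": self.carryover,
            "final_conclusions": [
                {"rank": c.final_rank, "taxon": c.final_taxon,
                 "lineage": list(c.lineage), "per_marker": c.per_marker,
                 "conflict": c.conflict}
                for c in self.final_conclusions],
            "config": self.config_echo,
        }
        return json.dumps(payload, indent=2, sort_keys=True)


def _load_references(config: PipelineConfig) -> List[ReferenceRecord]:
    if isinstance(config.references, (str, os.PathLike)):
        return read_reference_fasta(config.references)
    return list(config.references or [])


def _load_runs(config: PipelineConfig) -> List[Tuple[Optional[str], List[Read]]]:
    """(expected marker or None, reads) per input run.

    ``config.reads`` may be one FASTQ path (combined input, demultiplexed
    by primers), a mapping marker -> FASTQ path (one run per marker), or
    either form with in-memory read lists in place of paths.
    """
    if config.reads is None:
        raise ValueError("config.reads is not set")

    def materialise(src):
        if isinstance(src, (str, os.PathLike)):
            return list(read_fastq(src))
        return list(src)

    if isinstance(config.reads, Mapping):
        return [(marker, materialise(src))
                for marker, src in sorted(config.reads.items())]
    return [(None, materialise(config.reads))]


def consensus_for_cluster(cluster: clustering.Cluster,
                          reads_by_id: Mapping[str, Read],
                          config: PipelineConfig, marker: str
                          ) -> Optional[consensus.ConsensusRecord]:
    """Subsample, orient, align and call the majority consensus of one cluster."""
    base = (config.seed + cluster.cluster_id) % _MOD
    member_ids = consensus.subsample_cluster(
        cluster, cap=config.subsample_cap,
        seed=(base + _SUBSAMPLE_OFFSET) % _MOD)
    members = [reads_by_id[rid] for rid in member_ids]
    cid = f"{marker}_cluster{cluster.cluster_id}"
    if len(members) == 1:
        record = consensus.ConsensusRecord(
            consensus_id=cid, sequence=members[0].sequence, n_reads_used=1,
            column_support=[1.0] * len(members[0]), marker=marker)
    else:
        rep = reads_by_id[cluster.representative_id].sequence
        oriented, _ = consensus.orient_reads(members, rep)
        msa = consensus.build_msa(oriented, seed=(base + _MSA_OFFSET) % _MOD)
        record = consensus.majority_consensus(
            msa, threshold=config.consensus_threshold,
            consensus_id=cid, marker=marker)
    record = consensus.strip_primer_residues(record, config.primer_sets,
                                             config.primer_params())
    return record if record.sequence else None


def run_pipeline(config: PipelineConfig) -> RunReport:
    if not config.primer_sets:
        raise ValueError("config.primer_sets must define at least one marker")
    outdir = Path(config.outdir) if config.outdir else None
    if outdir:
        outdir.mkdir(parents=True, exist_ok=True)
    references = _load_references(config)
    marker_names = [p.marker for p in config.primer_sets]
    report = RunReport(seed=config.seed)
    skip = ("primer_sets", "references", "absence_labels", "reads")
    report.config_echo = {f.name: getattr(config, f.name)
                          for f in dataclasses.fields(config)
                          if f.name not in skip}
    if isinstance(config.reads, (str, type(None))):
        report.config_echo["reads"] = config.reads
    elif isinstance(config.reads, Mapping):
        report.config_echo["reads"] = {
            m: (str(src) if isinstance(src, (str, os.PathLike))
                else "<in-memory>") for m, src in config.reads.items()}
    else:
        report.config_echo["reads"] = "<in-memory>"
    report.per_marker = {m: MarkerResult(marker=m) for m in marker_names}

    pparams = config.primer_params()
    per_marker_reads: Dict[str, List[Read]] = {m: [] for m in marker_names}

    for expected_marker, raw_reads in _load_runs(config):
        report.n_input += len(raw_reads)
        kept, fstats = preprocess.filter_reads(raw_reads,
                                               config.filter_params())
        report.n_filtered += len(kept)
        if config.adapters:
            kept = [preprocess.trim_terminal_adapters(
                r, config.adapters, config.max_error_rate,
                config.min_overlap) for r in kept]
            kept = [r for r in kept if len(r) > 0]
        run_label = expected_marker or "combined"
        if outdir:
            write_fastq(kept, outdir / f"filtered_{run_label}.fastq")
        run_counts = {m: 0 for m in marker_names}
        run_counts["unassigned"] = 0
        for read in kept:
            cls = primers.classify_read(read, config.primer_sets, pparams)
            run_counts[cls.marker] += 1
            if cls.marker == "unassigned":
                report.n_unassigned += 1
                continue
            report.n_classified += 1
            if expected_marker is not None and cls.marker != expected_marker:
                continue    # carry-over from a previous run: excluded
            trimmed = primers.trim_primers(read, cls.hits)
            if len(trimmed) == 0:
                report.per_marker[cls.marker].n_trimmed_empty += 1
                continue
            per_marker_reads[cls.marker].append(trimmed)
            report.per_marker[cls.marker].n_classified += 1
        if expected_marker is not None and len(marker_names) > 1:
            n_other = sum(v for m, v in run_counts.items()
                          if m not in ("unassigned", expected_marker))
            n_cls = n_other + run_counts[expected_marker]
            report.carryover[expected_marker] = {
                "n_classified": n_cls,
                "n_other_marker": n_other,
                "fraction_of_classified":
                    (n_other / n_cls) if n_cls else None,
                "fraction_of_total":
                    (n_other / len(kept)) if kept else None,
            }

    per_marker_assignments: Dict[str, List[taxonomy.TaxonomicAssignment]] = {}
    for marker in marker_names:
        result = report.per_marker[marker]
        reads = per_marker_reads[marker]
        if outdir:
            write_fastq(reads, outdir / f"reads_{marker}.fastq")
        if not reads:
            per_marker_assignments[marker] = []
            continue
        clusters = clustering.greedy_cluster(
            reads, threshold=config.cluster_threshold,
            kmer_prescreen=config.kmer_prescreen)
        result.clusters = clusters
        result.n_clusters = len(clusters)
        reads_by_id = {r.read_id: r for r in reads}
        marker_refs = [r for r in references if r.marker == marker]
        for cluster in clusters:
            if cluster.size < config.min_cluster_size:
                continue
            record = consensus_for_cluster(cluster, reads_by_id, config,
                                           marker)
            if record is None:
                continue
            result.n_clusters_used += 1
            result.consensi.append(record)
            if marker_refs:
                result.assignments.append(taxonomy.assign(
                    record, marker_refs,
                    min_identity=config.min_identity,
                    min_coverage=config.min_coverage,
                    score_margin=config.score_margin))
        per_marker_assignments[marker] = result.assignments
        if outdir:
            _write_cluster_tsv(clusters, outdir / f"clusters_{marker}.tsv")
            write_fasta([(c.consensus_id, c.sequence)
                         for c in result.consensi],
                        outdir / f"consensus_{marker}.fasta")

    report.final_conclusions = taxonomy.combine_markers(
        per_marker_assignments, marker_names,
        absence_labels=config.absence_labels,
        strict_conflict=config.strict_conflict)
    if outdir:
        _write_assignment_tsv(report, outdir / "assignments.tsv")
        _write_final_tsv(report.final_conclusions, marker_names,
                         outdir / "final_conclusions.tsv")
        (outdir / "report.json").write_text(report.to_json())
    return report


def _write_cluster_tsv(clusters: Sequence[clustering.Cluster],
                       path: Path) -> None:
    with open(path, "w") as handle:
        handle.write("cluster_id\tread_id\tis_representative\n")
        for cluster in clusters:
            for rid in cluster.member_ids:
                rep = int(rid == cluster.representative_id)
                handle.write(f"{cluster.cluster_id}\t{rid}\t{rep}\n")


def _write_assignment_tsv(report: RunReport, path: Path) -> None:
    with open(path, "w") as handle:
        handle.write("marker\tconsensus_id\trank\ttaxon\tn_hits\n")
        for marker, result in report.per_marker.items():
            for a in result.assignments:
                handle.write(f"{marker}\t{a.consensus_id}\t{a.rank}\t"
                             f"{a.taxon}\t{len(a.hits)}\n")


def _write_final_tsv(conclusions: Sequence[taxonomy.FinalConclusion],
                     marker_names: Sequence[str], path: Path) -> None:
    with open(path, "w") as handle:
        cols = "\t".join(marker_names)
        handle.write(f"taxon\trank\t{cols}\tconflict\n")
        for c in conclusions:
            per = "\t".join(c.per_marker.get(m, "not detected")
                            for m in marker_names)
            handle.write(f"{c.final_taxon}\t{c.final_rank}\t{per}\t"
                         f"{int(c.conflict)}\n")


def summarize(report: RunReport) -> str:
    """Human-readable table mirroring the per-marker/final layout."""
    marker_names = list(report.per_marker)
    header = ["Taxon", *marker_names, "Final", "Flags"]
    rows = [header]
    for c in report.final_conclusions:
        flags = "conflict" if c.conflict else ""
        rows.append([c.final_taxon,
                     *[c.per_marker.get(m, "not detected")
                       for m in marker_names],
                     f"{c.final_taxon} ({c.final_rank})", flags])
    widths = [max(len(r[i]) for r in rows) for i in range(len(header))]
    lines = ["  ".join(cell.ljust(w) for cell, w in zip(row, widths)).rstrip()
             for row in rows]
    lines.insert(1, "  ".join("-" * w for w in widths))
    return "\n".join(lines)
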