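"""End-to-end run: detect CRISPR arrays, scan viral genomes with spacers,
calibrate E-values, call PAMs, compute bias statistics and the archetype
map, and persist every stage as plain TSV/FASTA/JSON so any stage can be
re-run and audited on its own.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import archetype as _arch
from . import biasstats as _bias
from . import pamlogo as _pam
from .annotation import Feature, read_gff3, write_gff3
from .crisprdetect import arrays_to_gff, attach_satellite_arrays, find_arrays
from .evalue import EvalueModel, calibrate, combined_array_significance
from .glocal import (AlignmentParams, SpacerMatch, SubjectGenome,
                     best_match_per_spacer, check_frame_preservation, scan)

log = logging.getLogger(__name__)

_VALID = set("ACGTRYSWKMBDHVN")


class ParseError(ValueError):
    pass


def read_sequences(path, format: str = "fasta"):
    """Read sequences (+ CDS annotations for GenBank).

    Returns (records, annotations): ``records`` is a list of (id, sequence)
    and ``annotations`` maps record id to a list of :class:`Feature` (CDS
    features for GenBank, empty for FASTA).  Non-IUPAC characters raise
    :class:`ParseError` naming the record.
    """
    from Bio import SeqIO

    records, annotations = [], {}
    fmt = {"fasta": "fasta", "genbank": "genbank", "gb": "genbank"}.get(format)
    if fmt is None:
        raise ValueError(f"unsupported format {format!r}")
    try:
        parsed = list(SeqIO.parse(str(path), fmt))
    except Exception as exc:  # biopython raises assorted types
        raise ParseError(f"cannot parse {path}: {exc}") from exc
    if not parsed:
        raise ParseError(f"no records found in {path}")
    for rec in parsed:
        seq = str(rec.seq).upper()
        bad = set(seq) - _VALID
        if bad:
            raise ParseError(
                f"record {rec.id!r}: non-IUPAC characters {sorted(bad)}")
        records.append((rec.id, seq))
        feats = []
        for feat in getattr(rec, "features", []):
            if feat.type != "CDS":
                continue
            name = (feat.qualifiers.get("gene") or
                    feat.qualifiers.get("product") or
                    feat.qualifiers.get("locus_tag") or ["cds"])[0]
            feats.append(Feature(name=str(name),
                                 start=int(feat.location.start),
                                 end=int(feat.location.end),
                                 strand="+" if feat.location.strand != -1 else "-",
                                 kind="gene", seqid=rec.id))
        if feats:
            annotations[rec.id] = feats
    return records, annotations


@dataclass
class RunConfig:
    """Configuration of one pipeline run."""

    host_fasta: str
    viral_fasta: str
    out_dir: str
    viral_annotation: str | None = None   # GFF3
    spacer_fasta: str | None = None       # pre-extracted spacers (skips detection)
    cds_fasta: str | None = None          # CDS set for stop-codon profiling
    evalue_threshold: float = 0.01
    threshold_overrides: dict[str, float] = field(default_factory=dict)
    calib_db_nt: int = 200_000
    calib_replicates: int = 100
    flank_len: int = 10
    min_repeats: int = 4
    satellite_max_distance: int = 10_000
    viral_circular: bool = True
    nonanucleotide: str = "NAGTRTTAC"
    run_local_mode: bool = True
    seed: int = 0
    log_level: str = "INFO"

    def __post_init__(self):
        if self.evalue_threshold <= 0:
            raise ValueError("evalue_threshold must be positive")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            return cls(**yaml.safe_load(fh))

    def digest(self) -> str:
        return hashlib.sha256(
            yaml.safe_dump(self.__dict__, sort_keys=True).encode()).hexdigest()[:12]


@dataclass
class RunReport:
    """All stage outputs of one run, with provenance."""

    arrays: list
    spacers: list
    matches: list[SpacerMatch]
    local_matches: list[SpacerMatch]
    combined_significance: float | None
    strand_bias: _bias.StrandBiasResult | None
    strand_bias_with_local: _bias.StrandBiasResult | None
    pam_upstream: _pam.MotifCall | None
    pfms: dict
    target_density: list
    strand_split: dict
    age_summaries: list
    identity_decay: bool | None
    presence: pd.DataFrame | None
    stop_profile: _bias.StopCodonProfile | None
    archetype: _arch.ArchetypeMap | None
    provenance: dict

    def summary_dict(self) -> dict:
        return {
            "n_arrays": len(self.arrays),
            "n_spacers": len(self.spacers),
            "n_matches": len(self.matches),
            "n_local_matches": len(self.local_matches),
            "combined_significance": self.combined_significance,
            "strand_bias_p": self.strand_bias.one_sided_p if self.strand_bias else None,
            "strand_bias_p_with_local": (self.strand_bias_with_local.one_sided_p
                                         if self.strand_bias_with_local else None),
            "pam_motif": self.pam_upstream.motif if self.pam_upstream else None,
            "pam_completeness": (self.pam_upstream.completeness
                                 if self.pam_upstream else None),
            "identity_decay": self.identity_decay,
            "provenance": self.provenance,
        }


def matches_to_frame(matches: list[SpacerMatch]) -> pd.DataFrame:
    return pd.DataFrame([m.to_dict() for m in matches])


def _write_matches(matches, path):
    cols = ["spacer", "spacer_index", "genome", "strand", "start", "end",
            "score", "evalue", "identity", "gaps_q", "gaps_s",
            "aligned_query", "aligned_subject", "mode"]
    df = (matches_to_frame(matches) if matches
          else pd.DataFrame(columns=cols))
    df.to_csv(path, sep="\t", index=False)


class StageError(RuntimeError):
    def __init__(self, stage, exc):
        super().__init__(f"stage {stage!r} failed: {exc}")
        self.stage = stage


def run_pipeline(config: RunConfig) -> RunReport:
    """Execute the full chain; every stage output lands in ``out_dir``.

    Deterministic under ``config.seed``.  Any stage failure raises
    :class:`StageError`; outputs of completed stages are left in place.
    """
    logging.basicConfig(level=config.log_level)
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    stage = "read-inputs"
    try:
        hosts, _ = read_sequences(config.host_fasta, "fasta")
        viral, viral_ann = [], {}
        try:
            viral, _ = read_sequences(config.viral_fasta, "fasta")
        except ParseError as exc:
            if "no records" not in str(exc):
                raise
            log.warning("viral set is empty")
        if config.viral_annotation:
            for f in read_gff3(config.viral_annotation):
                viral_ann.setdefault(f.seqid, []).append(f)

        # -- CRISPR detection ------------------------------------------------
        stage = "detect-crispr"
        spacers: list[tuple[str, str]] = []
        index_map: dict[str, int] = {}
        arrays = []
        if config.spacer_fasta:
            recs, _ = read_sequences(config.spacer_fasta, "fasta")
            for sid, seq in recs:
                spacers.append((sid, seq))
                if sid.startswith("sp") and sid[2:].isdigit():
                    index_map[sid] = int(sid[2:])
        else:
            for cid, seq in hosts:
                found = find_arrays(seq, min_repeats=2, contig_id=cid)
                found = attach_satellite_arrays(
                    found, config.satellite_max_distance, config.min_repeats)
                arrays.extend(found)
            write_gff3(arrays_to_gff(arrays), out / "arrays.gff3")
            multi = len(arrays) > 1
            for a in arrays:
                for sp in a.spacers:
                    qid = f"{a.array_id}.sp{sp.index}" if multi else sp.id
                    spacers.append((qid, sp.sequence))
                    index_map[qid] = sp.index
            with open(out / "spacers.fasta", "w") as fh:
                for sid, seq in spacers:
                    fh.write(f">{sid}\n{seq}\n")

        # -- viral-sense orientation ------------------------------------------
        stage = "orient"
        genomes, oriented = [], {}
        for gid, seq in viral:
            ann = viral_ann.get(gid, [])
            try:
                og = _arch.orient_genome(gid, seq, config.nonanucleotide, ann)
                oriented[gid] = og
                genomes.append(SubjectGenome(gid, og.seq, config.viral_circular))
            except ValueError as exc:
                log.warning("%s not oriented (%s); using input orientation", gid, exc)
                genomes.append(SubjectGenome(gid, seq, config.viral_circular))

        report = RunReport(arrays=arrays, spacers=spacers, matches=[],
                           local_matches=[], combined_significance=None,
                           strand_bias=None, strand_bias_with_local=None,
                           pam_upstream=None, pfms={}, target_density=[],
                           strand_split={}, age_summaries=[],
                           identity_decay=None, presence=None,
                           stop_profile=None, archetype=None,
                           provenance={"seed": config.seed,
                                       "config_digest": config.digest(),
                                       "version": _version()})
        if not spacers or not genomes:
            _write_matches([], out / "matches.tsv")
            _finalise(report, config, out)
            return report

        # -- E-value calibration ----------------------------------------------
        stage = "calibrate"
        lengths = sorted({len(s) for _, s in spacers})
        model = calibrate(lengths, AlignmentParams(),
                          calib_db_nt=config.calib_db_nt,
                          n_replicates=config.calib_replicates,
                          seed=config.seed)
        model.to_json(out / "evalue_model.json")

        # -- scan ---------------------------------------------------------------
        stage = "scan"
        params = AlignmentParams()
        matches = scan(spacers, genomes, params, model, config.evalue_threshold,
                       threshold_overrides=config.threshold_overrides)
        ann_for = {g.id: (oriented[g.id].annotation if g.id in oriented
                          else viral_ann.get(g.id, [])) for g in genomes}
        for m in matches:
            if m.spacer_id in index_map:
                m.spacer_index = index_map[m.spacer_id]
        local_matches: list[SpacerMatch] = []
        if config.run_local_mode:
            lmodel_params = AlignmentParams(mode="local")
            lmatches = scan(spacers, genomes, lmodel_params, model,
                            config.evalue_threshold,
                            threshold_overrides=config.threshold_overrides)
            glocal_spacers = {m.spacer_id for m in matches}
            local_matches = [m for m in lmatches
                             if m.spacer_id not in glocal_spacers]
            for m in local_matches:
                if m.spacer_id in index_map:
                    m.spacer_index = index_map[m.spacer_id]
        frame_flags = [check_frame_preservation(m, ann_for.get(m.genome_id))
                       for m in matches]
        _write_matches(matches, out / "matches.tsv")
        _write_matches(local_matches, out / "matches_local.tsv")
        report.matches, report.local_matches = matches, local_matches
        log.info("scan: %d glocal matches, %d local-only", len(matches),
                 len(local_matches))

        # -- statistics ---------------------------------------------------------
        stage = "stats"
        best = best_match_per_spacer(matches, [g.id for g in genomes])
        if best:
            report.combined_significance = combined_array_significance(
                [m.evalue for m in best], len(spacers))
            report.strand_bias = _bias.strand_bias_from_matches(matches)
            both = matches + local_matches
            report.strand_bias_with_local = _bias.strand_bias_from_matches(both)
            report.target_density, report.strand_split = _bias.target_density(
                best, ann_for)
            report.age_summaries, report.identity_decay = _bias.identity_by_age(
                matches)
            report.presence = _bias.presence_matrix(matches + local_matches)
            report.presence.to_csv(out / "presence_matrix.tsv", sep="\t")
        if config.cds_fasta:
            recs, _ = read_sequences(config.cds_fasta, "fasta")
            report.stop_profile = _bias.stop_codon_profile(
                [s for _, s in recs], label=Path(config.cds_fasta).stem)

        # -- PAM ---------------------------------------------------------------
        stage = "pam"
        genome_seqs = {g.id: (g.seq, g.circular) for g in genomes}
        if len(best) >= 2:
            for side in ("upstream", "downstream"):
                for sel in ("best-per-spacer", "identical-only"):
                    fl = _pam.extract_flanks(matches, genome_seqs, side,
                                             config.flank_len, sel,
                                             [g.id for g in genomes])
                    if len(fl) >= 2:
                        pfm = _pam.build_pfm(fl)
                        report.pfms[f"{side}:{sel}"] = pfm
                        _pam.pfm_to_tsv(pfm, out / f"pfm_{side}_{sel}.tsv")
                        if side == "upstream" and sel == "best-per-spacer":
                            report.pam_upstream = _pam.call_motif(pfm, fl)
        # -- archetype ----------------------------------------------------------
        stage = "archetype"
        if best and oriented:
            report.archetype = _arch.build_archetype(best, oriented)
            report.archetype.to_json(out / "archetype.json")

        stage = "report"
        with open(out / "frame_flags.tsv", "w") as fh:
            fh.write("spacer\tgenome\tframe\n")
            for m, fl in zip(matches, frame_flags):
                fh.write(f"{m.spacer_id}\t{m.genome_id}\t{fl}\n")
        _finalise(report, config, out)
        return report
    except StageError:
        raise
    except Exception as exc:
        raise StageError(stage, exc) from exc


def _finalise(report: RunReport, config: RunConfig, out: Path) -> None:
    with open(out / "report.json", "w") as fh:
        json.dump(report.summary_dict(), fh, indent=1, default=str)


def _version() -> str:
    from . import __version__
    return __version__
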