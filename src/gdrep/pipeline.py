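"""End-to-end orchestration: simulate/load -> QC -> stats -> diversity ->
overlap -> associate, with file-based stage hand-off and a manifest.

Stages communicate only via TSV files under the output directory, so each
stage is independently runnable and testable.  Every run is reproducible
given the seed; the manifest records a checksum per artifact.
"""

from __future__ import annotations

import hashlib
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import pandas as pd

from . import diversity as dv
from . import overlap as ov
from . import stats as st
from .association import correlate_features
from .io import attach_metadata, parse_airr, read_subjects, write_clonotype_table, write_subjects
from .qc import QCThresholds, preprocess_sample
from .simulate import SimulationConfig, generate_cohort
from .types import Cohort, RepertoireSample

log = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "run_pipeline", "write_report", "save_cohort", "load_cohort"]


@dataclass(slots=True)
class PipelineConfig:
    out_dir: str | Path = "gdrep_out"
    input_dir: Optional[str | Path] = None  # existing cohort directory
    sim: Optional[SimulationConfig] = None  # or simulate one
    thresholds: QCThresholds = field(default_factory=QCThresholds)
    per_segment_diversity: bool = False
    top_n: int = 10
    key_basis: str = "aa"
    covariates: tuple[str, ...] = ("pasi", "age")
    seed: int = 0


def _checksum(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def save_cohort(cohort: Cohort, out_dir: str | Path) -> None:
    """Write a cohort as one AIRR TSV per library plus samples.tsv and
    subjects.tsv descriptors."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rows = []
    for s in cohort.samples:
        fname = f"{s.sample_id}.airr.tsv"
        write_clonotype_table(s, out / fname, dialect="airr")
        rows.append(
            {
                "sample_id": s.sample_id,
                "subject_id": s.subject_id,
                "tissue": s.tissue,
                "chain": s.chain,
                "off_target_reads": s.off_target_reads,
                "file": fname,
            }
        )
    pd.DataFrame(rows).to_csv(out / "samples.tsv", sep="\t", index=False)
    write_subjects(cohort.subjects, out / "subjects.tsv")


def load_cohort(in_dir: str | Path) -> Cohort:
    """Read a cohort directory written by :func:`save_cohort`."""
    in_dir = Path(in_dir)
    meta = pd.read_csv(in_dir / "samples.tsv", sep="\t", dtype=str)
    samples: list[RepertoireSample] = []
    for _, row in meta.iterrows():
        samples.append(
            parse_airr(
                in_dir / row["file"],
                {
                    "sample_id": row["sample_id"],
                    "subject_id": row["subject_id"],
                    "tissue": row["tissue"],
                    "chain": row["chain"],
                    "off_target_reads": int(row["off_target_reads"]),
                },
            )
        )
    subjects = read_subjects(in_dir / "subjects.tsv")
    return attach_metadata(samples, subjects)


def _diversity_table(
    samples: list[RepertoireSample], per_segment: bool, top_n: int
) -> pd.DataFrame:
    rows = []
    for s in samples:
        strata = {"all": s}
        if per_segment:
            strata.update(dv.normalize_within_segment(s))
        for name, sub in strata.items():
            stratum = "all" if name == "all" else name.split(":")[-1]
            res = dv.diversity_result(sub, stratum=stratum)
            comp = dv.compartment_profile(sub.frequencies())
            rows.append(
                {
                    "sample_id": s.sample_id,
                    "subject_id": s.subject_id,
                    "tissue": s.tissue,
                    "chain": s.chain,
                    "stratum": res.stratum,
                    "richness": res.richness,
                    "d50": res.d50,
                    "chao1": res.chao1,
                    "efron_thisted": res.efron_thisted,
                    "shannon": res.shannon,
                    "inv_simpson": res.inv_simpson,
                    "top_n_cumulative": dv.top_n_cumulative(sub, n=top_n),
                    "small_clonotype_fraction": comp.clonotype_fraction["small"],
                    "small_space_fraction": comp.space_fraction["small"],
                    "hyperexpanded_clonotype_fraction": comp.clonotype_fraction["hyperexpanded"],
                    "hyperexpanded_space_fraction": comp.space_fraction["hyperexpanded"],
                }
            )
    return pd.DataFrame(rows)


def run_pipeline(config: PipelineConfig) -> list[dict]:
    """Run every stage; returns the manifest (stage, file, sha256 per artifact).

    Libraries failing QC are excluded from all downstream stages and listed in
    the QC report.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: list[dict] = []

    def emit(stage: str, name: str, df: pd.DataFrame) -> None:
        path = out / name
        df.to_csv(path, sep="\t", index=False)
        manifest.append({"stage": stage, "file": name, "sha256": _checksum(path)})

    # --- stage 0: obtain the cohort -------------------------------------
    if config.sim is not None:
        cohort, truth = generate_cohort(config.sim)
        cohort_dir = out / "cohort"
        save_cohort(cohort, cohort_dir)
        truth.to_csv(cohort_dir / "truth.tsv", sep="\t", index=False)
        for f in sorted(cohort_dir.iterdir()):
            manifest.append({"stage": "simulate", "file": f"cohort/{f.name}", "sha256": _checksum(f)})
    elif config.input_dir is not None:
        cohort = load_cohort(config.input_dir)
    else:
        raise ValueError("PipelineConfig needs input_dir or sim")

    # --- stage 1: QC ------------------------------------------------------
    kept: list[RepertoireSample] = []
    qc_rows = []
    for s in cohort.samples:
        processed, report = preprocess_sample(s, config.thresholds)
        qc_rows.append(
            {
                "sample_id": report.sample_id,
                "verdict": report.verdict,
                "reasons": ",".join(report.reasons),
                "reads_before": report.reads_before,
                "reads_after": report.reads_after,
                "clonotypes_before": report.clonotypes_before,
                "clonotypes_after": report.clonotypes_after,
                "reads_retained_fraction": report.reads_retained_fraction,
            }
        )
        if report.verdict == "pass" and processed.n_clonotypes > 0:
            kept.append(processed)
        else:
            log.warning("library %s excluded downstream (%s)", s.sample_id, report.reasons)
    emit("qc", "qc_report.tsv", pd.DataFrame(qc_rows))
    if not kept:
        log.error("all libraries failed QC; stopping after QC stage")
        _write_manifest(out, manifest)
        return manifest
    cohort = Cohort(samples=kept, subjects=cohort.subjects)

    # --- stage 2: repertoire stats ---------------------------------------
    usage_rows, spec_rows, conv_rows, junc_rows = [], [], [], []
    for s in kept:
        for level in ("V", "VJ"):
            prof = st.segment_usage(s, level=level)
            for seg, frac in sorted(prof.entries.items()):
                usage_rows.append(
                    {"sample_id": s.sample_id, "level": level, "segment": seg, "fraction": frac}
                )
        for unit in ("aa", "nt"):
            prof = st.spectratype(s, unit=unit)
            for length, frac in sorted(prof.bins.items()):
                spec_rows.append(
                    {"sample_id": s.sample_id, "unit": unit, "length": length, "fraction": frac}
                )
        conv_rows.append(
            {
                "sample_id": s.sample_id,
                "convergence_ratio": st.convergence_ratio(s),
                "mean_cdr3_aa": st.mean_cdr3_length(s, unit="aa"),
                "mean_cdr3_nt": st.mean_cdr3_length(s, unit="nt"),
            }
        )
        inserts = [f.total_insert for f in map(st.junction_inserts, s.clonotypes) if f]
        junc_rows.append(
            {
                "sample_id": s.sample_id,
                "n_defined": len(inserts),
                "mean_total_insert": sum(inserts) / len(inserts) if inserts else float("nan"),
            }
        )
    emit("stats", "usage.tsv", pd.DataFrame(usage_rows))
    emit("stats", "spectratype.tsv", pd.DataFrame(spec_rows))
    emit("stats", "convergence.tsv", pd.DataFrame(conv_rows))
    emit("stats", "junctions.tsv", pd.DataFrame(junc_rows))

    # --- stage 3: diversity ----------------------------------------------
    div = _diversity_table(kept, config.per_segment_diversity, config.top_n)
    emit("diversity", "diversity.tsv", div)

    # --- stage 4: overlap -------------------------------------------------
    sharing_frames, summary_rows = [], []
    for tissue in ("blood", "skin"):
        for chain in ("TRG", "TRD"):
            stratum = cohort.select(tissue=tissue, chain=chain)
            if len({s.subject_id for s in stratum}) < 2:
                continue
            table, public_fraction = ov.sharing_counts(
                cohort, basis=config.key_basis, tissue=tissue, chain=chain
            )
            table.insert(0, "tissue", tissue)
            sharing_frames.append(table)
            summary_rows.append(
                {
                    "tissue": tissue,
                    "chain": chain,
                    "n_samples": len(stratum),
                    "n_keys": len(table),
                    "public_fraction": public_fraction,
                }
            )
    emit(
        "overlap",
        "sharing_table.tsv",
        pd.concat(sharing_frames, ignore_index=True) if sharing_frames else pd.DataFrame(),
    )
    emit("overlap", "public_fraction.tsv", pd.DataFrame(summary_rows))
    paired_frames = []
    by_subject: dict[tuple[str, str, str], RepertoireSample] = {
        (s.subject_id, s.tissue, s.chain): s for s in kept
    }
    for (sid, tissue, chain), blood in by_subject.items():
        if tissue != "blood":
            continue
        skin = by_subject.get((sid, "skin", chain))
        if skin is None:
            continue
        shared = ov.paired_overlap(blood, skin, basis=config.key_basis)
        if len(shared):
            shared.insert(0, "subject_id", sid)
            shared.insert(1, "chain", chain)
            paired_frames.append(shared)
    emit(
        "overlap",
        "paired_overlap.tsv",
        pd.concat(paired_frames, ignore_index=True) if paired_frames else pd.DataFrame(),
    )

    # --- stage 5: association ---------------------------------------------
    assoc_frames = []
    blood_all = div[(div["tissue"] == "blood") & (div["stratum"] == "all")]
    for chain in ("TRG", "TRD"):
        feats = blood_all[blood_all["chain"] == chain]
        if feats.empty:
            continue
        features = feats[["subject_id", "richness", "shannon", "d50", "top_n_cumulative"]]
        for covariate in config.covariates:
            res = correlate_features(features, cohort.subjects, covariate=covariate)
            if len(res):
                res.insert(0, "chain", chain)
                assoc_frames.append(res)
    emit(
        "associate",
        "associations.tsv",
        pd.concat(assoc_frames, ignore_index=True) if assoc_frames else pd.DataFrame(),
    )

    _write_manifest(out, manifest)
    return manifest


def _write_manifest(out: Path, manifest: list[dict]) -> None:
    pd.DataFrame(manifest, columns=["stage", "file", "sha256"]).to_csv(
        out / "manifest.tsv", sep="\t", index=False
    )


def write_report(out_dir: str | Path) -> Path:
    """Render a human-readable markdown summary from a run's artifacts."""
    out = Path(out_dir)
    manifest_path = out / "manifest.tsv"
    lines = ["# gdrep pipeline report", ""]
    if not manifest_path.exists():
        lines.append("_No manifest found; nothing to report._")
        report = out / "report.md"
        report.write_text("\n".join(lines) + "\n")
        return report
    manifest = pd.read_csv(manifest_path, sep="\t")
    for stage in manifest["stage"].unique():
        files = manifest[manifest["stage"] == stage]["file"]
        lines.append(f"## Stage: {stage}")
        lines.append("")
        for f in files:
            path = out / f
            if not path.exists():
                lines.append(f"- `{f}` — unavailable")
                continue
            if f.endswith(".tsv"):
                try:
                    n = max(0, sum(1 for _ in path.open()) - 1)
                    lines.append(f"- `{f}` — {n} rows")
                except OSError:
                    lines.append(f"- `{f}` — unreadable")
            else:
                lines.append(f"- `{f}`")
        lines.append("")
    assoc = out / "associations.tsv"
    if assoc.exists() and assoc.stat().st_size > 0:
        df = pd.read_csv(assoc, sep="\t")
        if len(df):
            lines.append("## Association summary")
            lines.append("")
            lines.append("```")
            lines.append(df.to_string(index=False))
            lines.append("```")
            lines.append("")
    report = out / "report.md"
    report.write_text("\n".join(lines) + "\n")
    return report
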