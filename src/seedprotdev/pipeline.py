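"""End-to-end pipeline: marker selection, spot differentials, presence/GO
trends and targeted EIC detection from one configuration.

The configuration is a flat key-value YAML file (see
:class:`PipelineConfig`); every output is regenerated deterministically
from (inputs, config, seed) and a JSON manifest with input checksums is
written for provenance.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict
from importlib.metadata import version as _pkg_version
from pathlib import Path

import pandas as pd
import yaml

from . import eic as eic_mod
from . import io as io_mod
from .markers import MarkerCriteria, PeptideIon, select_marker_peptides
from .masses import ModificationSet
from .presence import (
    build_presence_matrix,
    go_trend_test,
    protein_diversity,
    rank_go_terms,
)
from .spots import GroupScheme, SpotTable, differential_filter, direction_counts, normalize_spot_percentages

log = logging.getLogger("seedprotdev")


class PipelineError(RuntimeError):
    """A pipeline stage failed; the message names the stage and input."""


@dataclass
class PipelineConfig:
    """All inputs, thresholds and labels for one pipeline run.

    ``eic_targets`` entries are mappings with keys ``peptide``, ``charge``
    and optional ``pyroglutamate``; ``mgf_files`` maps a sample label to an
    MGF path.
    """

    out_dir: str = "results"
    seed: int = 0
    # marker selection
    proteome_fasta: str | None = None
    homolog_fasta: str | None = None
    signal_tsv: str | None = None
    target_protein: str | None = None
    min_len: int = 7
    max_len: int = 25
    proline_rule: bool = True
    # spot differentials
    spot_csv: str | None = None
    compare: str = "timepoint"  # or "cultivar"
    stage1: str = "Sep18"
    stage2: str = "Sep25"
    cultivar1: str = "Sumner"
    cultivar2: str = "Desirable"
    fold_min: float = 2.0
    alpha: float = 0.05
    floor_frac: float = 0.25
    # presence / GO
    detections_tsv: str | None = None
    go_tsv: str | None = None
    stages: list[str] = field(
        default_factory=lambda: ["Aug21", "Aug28", "Sep04", "Sep11", "Sep18", "Sep25"]
    )
    go_min_count: int = 10
    # EIC
    mgf_files: dict[str, str] = field(default_factory=dict)
    eic_targets: list[dict] = field(default_factory=list)
    tol_ppm: float = 20.0
    min_scans: int = 3
    min_intensity: float = 0.0

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)


def validate_inputs(config: PipelineConfig) -> pd.DataFrame:
    """Schema checks for every configured input; never mutates anything.

    Returns a frame of (file, level, message) entries; ``level`` is
    ``error`` or ``warning``. An empty frame means all inputs look sound.
    """
    issues: list[tuple[str, str, str]] = []

    def _issue(path, level, msg):
        issues.append((str(path), level, msg))

    for label, path in [
        ("proteome_fasta", config.proteome_fasta),
        ("homolog_fasta", config.homolog_fasta),
        ("signal_tsv", config.signal_tsv),
        ("spot_csv", config.spot_csv),
        ("detections_tsv", config.detections_tsv),
        ("go_tsv", config.go_tsv),
        *[(f"mgf:{k}", v) for k, v in config.mgf_files.items()],
    ]:
        if path is not None and not Path(path).exists():
            _issue(path, "error", f"{label}: file not found")

    for fasta in (config.proteome_fasta, config.homolog_fasta):
        if fasta and Path(fasta).exists():
            text = Path(fasta).read_text()
            seqs = [
                line for line in text.splitlines() if line and not line.startswith(">")
            ]
            if any(c.islower() for line in seqs for c in line):
                _issue(fasta, "warning", "lowercase residues will be uppercased")
            bad = {
                c
                for line in seqs
                for c in line.upper()
                if c not in "ACDEFGHIKLMNPQRSTVWY"
            }
            if bad:
                _issue(fasta, "error", f"non-canonical residues {sorted(bad)}")

    if config.spot_csv and Path(config.spot_csv).exists():
        df = pd.read_csv(config.spot_csv, index_col=0)
        for col in ("pI", "MW"):
            if col not in df.columns:
                _issue(config.spot_csv, "error", f"missing column {col!r}")
        rep_cols = [c for c in df.columns if c not in ("pI", "MW")]
        for col in rep_cols:
            neg = df.index[df[col] < 0].tolist()
            if neg:
                _issue(
                    config.spot_csv,
                    "error",
                    f"negative intensity in column {col!r} for spots {neg[:5]}",
                )

    if config.detections_tsv and Path(config.detections_tsv).exists():
        det = pd.read_csv(config.detections_tsv, sep="\t")
        for col in ("protein_id", "cultivar", "stage", "n_peptides", "score", "p_value"):
            if col not in det.columns:
                _issue(config.detections_tsv, "error", f"missing column {col!r}")
        if "p_value" in det.columns:
            bad = det.index[(det["p_value"] <= 0) | (det["p_value"] > 1)].tolist()
            if bad:
                _issue(
                    config.detections_tsv,
                    "error",
                    f"p_value out of (0, 1] in rows {bad[:5]}",
                )
        if "stage" in det.columns:
            unknown = sorted(set(det["stage"]) - set(config.stages))
            if unknown:
                _issue(config.detections_tsv, "error", f"unknown stages {unknown}")

    return pd.DataFrame(issues, columns=["file", "level", "message"])


def _require(path, stage: str):
    if path is None:
        return None
    if not Path(path).exists():
        raise PipelineError(f"stage {stage!r}: missing input file {path}")
    return path


def run_pipeline(config: PipelineConfig) -> dict:
    """Run every configured stage and write the report bundle.

    Stages with unconfigured inputs are skipped. Returns the summary dict
    (also written to ``summary.json``); a stage failure raises
    :class:`PipelineError` naming the stage.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    summary: dict = {}
    checksums: dict[str, str] = {}

    if config.proteome_fasta:
        _require(config.proteome_fasta, "markers")
        try:
            records = io_mod.read_proteome(
                config.proteome_fasta, signal_tsv=config.signal_tsv
            )
            homologs = (
                io_mod.read_proteome(
                    _require(config.homolog_fasta, "markers"), source_set="homolog"
                )
                if config.homolog_fasta
                else [r for r in records if r.source_set == "homolog"]
            )
            target_id = config.target_protein or records[0].id
            target = next((r for r in records if r.id == target_id), None)
            if target is None:
                raise ValueError(f"target protein {target_id!r} not in proteome")
            criteria = MarkerCriteria(
                min_len=config.min_len,
                max_len=config.max_len,
                proline_rule=config.proline_rule,
            )
            ledger = select_marker_peptides(target, homologs, criteria)
            ledger.to_csv(out / "marker_candidates.csv", index=False)
            summary["marker_candidates"] = int(len(ledger))
            summary["marker_peptides"] = int(ledger["passes_all"].sum())
            checksums[config.proteome_fasta] = io_mod.sha256_of(config.proteome_fasta)
        except PipelineError:
            raise
        except Exception as exc:
            raise PipelineError(
                f"stage 'markers' failed on {config.proteome_fasta}: {exc}"
            ) from exc

    if config.spot_csv:
        _require(config.spot_csv, "spotdiff")
        try:
            table = normalize_spot_percentages(
                SpotTable.read_csv(config.spot_csv)
            )
            if config.compare == "timepoint":
                scheme = GroupScheme.by_stage(table, config.stage1, config.stage2)
            else:
                scheme = GroupScheme.by_cultivar(
                    table, config.cultivar1, config.cultivar2
                )
            results = differential_filter(
                table,
                scheme,
                fold_min=config.fold_min,
                alpha=config.alpha,
                floor_frac=config.floor_frac,
            )
            results.to_csv(out / "spot_differentials.csv", index_label="spot_id")
            n_up, n_down = direction_counts(results)
            summary["differential_spots"] = {"up": n_up, "down": n_down}
            checksums[config.spot_csv] = io_mod.sha256_of(config.spot_csv)
        except PipelineError:
            raise
        except Exception as exc:
            raise PipelineError(
                f"stage 'spotdiff' failed on {config.spot_csv}: {exc}"
            ) from exc

    if config.detections_tsv:
        _require(config.detections_tsv, "presence")
        try:
            det = io_mod.read_detections(config.detections_tsv)
            matrix = build_presence_matrix(det, stage_order=list(config.stages))
            flat = matrix.copy()
            flat.columns = [f"{cv}_{st}" for cv, st in matrix.columns]
            flat.to_csv(out / "presence_matrix.csv", index_label="protein_id")
            protein_diversity(matrix).rename("n_proteins").to_csv(
                out / "protein_diversity.csv"
            )
            summary["proteins_detected"] = int(matrix.any(axis=1).sum())
            checksums[config.detections_tsv] = io_mod.sha256_of(config.detections_tsv)
            if config.go_tsv:
                _require(config.go_tsv, "gotrend")
                ann = io_mod.read_go_annotations(config.go_tsv)
                ranking = rank_go_terms(matrix, ann, min_count=config.go_min_count)
                ranking.to_csv(out / "go_ranking.csv", index=False)
                n_stages = len(config.stages)
                trend = go_trend_test(
                    matrix,
                    ann,
                    early_stages=list(config.stages[: n_stages // 2]),
                    late_stages=list(config.stages[n_stages // 2 :]),
                )
                trend.to_csv(out / "go_trend.csv", index=False)
                summary["go_terms_ranked"] = int(len(ranking))
                summary["go_terms_flagged"] = sorted(
                    trend.loc[trend["flagged"], "go_id"].tolist()
                )
        except PipelineError:
            raise
        except Exception as exc:
            raise PipelineError(
                f"stage 'presence' failed on {config.detections_tsv}: {exc}"
            ) from exc

    if config.mgf_files and config.eic_targets:
        calls = []
        for sample, mgf_path in config.mgf_files.items():
            _require(mgf_path, "eic")
            try:
                peaks = eic_mod.PeakList.read_mgf(mgf_path)
                for tgt in config.eic_targets:
                    ion = PeptideIon.from_sequence(
                        tgt["peptide"],
                        charge=int(tgt["charge"]),
                        mods=ModificationSet(
                            pyroglutamate=bool(tgt.get("pyroglutamate", False))
                        ),
                    )
                    chrom = eic_mod.extract_eic(peaks, ion.mz, tol_ppm=config.tol_ppm)
                    call = eic_mod.detect_ion(
                        chrom,
                        min_intensity=config.min_intensity,
                        min_scans=config.min_scans,
                    )
                    calls.append(
                        {
                            "sample": sample,
                            "peptide": ion.sequence,
                            "charge": ion.charge,
                            "target_mz": round(ion.mz, 4),
                            "present": call.present,
                            "apex_rt": call.apex_rt,
                            "area": call.area,
                        }
                    )
                checksums[mgf_path] = io_mod.sha256_of(mgf_path)
            except PipelineError:
                raise
            except Exception as exc:
                raise PipelineError(
                    f"stage 'eic' failed on {mgf_path}: {exc}"
                ) from exc
        calls_df = pd.DataFrame(calls)
        calls_df.to_csv(out / "presence_calls.csv", index=False)
        summary["ion_presence_calls"] = int(calls_df["present"].sum())

    (out / "summary.json").write_text(json.dumps(summary, indent=1, sort_keys=True))
    try:
        pkg_version = _pkg_version("seedprotdev")
    except Exception:  # pragma: no cover - not installed
        pkg_version = "unknown"
    manifest = {
        "config": asdict(config),
        "seed": config.seed,
        "version": pkg_version,
        "input_checksums": checksums,
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=1, sort_keys=True))
    log.info("pipeline complete: %s", summary)
    return summary
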