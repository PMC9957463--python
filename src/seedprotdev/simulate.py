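"""Synthetic inputs with known ground truth for every pipeline stage.

Raw proteomics and 2-D gel data for developing tree nuts are rarely
deposited; this module generates realistic stand-ins for all the formats
the pipeline consumes — a proteome FASTA with a planted allergen, spot
quantification tables with planted fold changes, shotgun detection tables
with planted presence trajectories, and MGF peak lists with planted marker
ions — together with ground-truth tables that fully determine what every
downstream stage should report. All randomness flows from the single seed
in :class:`SimConfig` through named substreams; the same seed reproduces
byte-identical files.

The default configuration mirrors a two-cultivar nut-development study
design: Sumner and Desirable cultivars, 2-D gels at the dough (Sep 18) and
maturing (Sep 25) stages with two replicate gels per cell and ~1267 spots,
and shotgun detections over six stages from the water stage (late August)
to kernel maturity.
"""

from __future__ import annotations

import json
import zlib
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from pyteomics import mgf as _mgf

from .digest import ProteinRecord
from .markers import PeptideIon
from .spots import SpotTable, normalize_spot_percentages

#: Six-stage development series (water stage through transition to mature).
DEFAULT_STAGES = ["Aug21", "Aug28", "Sep04", "Sep11", "Sep18", "Sep25"]

#: 2-D gel design: 2 cultivars x 2 stages x 2 replicate gels.
DEFAULT_GEL_GROUPS = [
    ("Sumner", "Sep18", 2),
    ("Sumner", "Sep25", 2),
    ("Desirable", "Sep18", 2),
    ("Desirable", "Sep25", 2),
]

AMINO_ACIDS = np.array(list("ACDEFGHIKLMNPQRSTVWY"))

# Planted allergen scaffold: a 2S-albumin-like precursor assembled from
# tryptic segments so that a zero-missed-cleavage digest yields exactly
# seven length-7..25 candidates: one inside the signal span, two shared
# with the homolog, four specific. Two segments are genuine pecan 2S
# albumin marker peptides so that their theoretical ions can be planted in
# peak lists.
_SIGNAL_PEPTIDE = "MALLLVALLALSSAATHAR"  # residues 1-19, cleaved signal
_SPECIFIC_PEPTIDES = (
    "QCCQQLSQMEEQCQCEGLR",
    "QQQQEEGIR",
    "GEEMEEMVQCASDLPK",
    "AYDQQAMQSLR",
)
_SHARED_PEPTIDES = ("VFSNDILVAALNTPR", "QQGQEEQLQR")
_ALLERGEN_SEQ = (
    _SIGNAL_PEPTIDE
    + _SPECIFIC_PEPTIDES[0]
    + _SPECIFIC_PEPTIDES[1]
    + _SPECIFIC_PEPTIDES[2]
    + _SHARED_PEPTIDES[0]
    + _SHARED_PEPTIDES[1]
    + _SPECIFIC_PEPTIDES[3]
    + "GSC"
)
_HOMOLOG_SEQ = (
    "MSEQLK" + _SHARED_PEPTIDES[0] + "AGETWK" + _SHARED_PEPTIDES[1] + "SDLC"
)


@dataclass(frozen=True)
class SimConfig:
    """Study-design parameters for all generators.

    Defaults emulate the two-cultivar development design described in the
    module docstring; noise_cv is the per-replicate coefficient of
    variation of gel spot intensities (a free parameter — real silver-stain
    noise levels are study-specific).
    """

    seed: int = 0
    n_spots: int = 1267
    n_diff_spots: int = 12
    planted_fold: float = 4.0
    noise_cv: float = 0.1
    groups: tuple[tuple[str, str, int], ...] = tuple(DEFAULT_GEL_GROUPS)
    n_proteins: int = 40
    n_go_terms: int = 12
    n_trend_terms: int = 2
    n_scans: int = 120
    rt_range: float = 20.0
    stages: tuple[str, ...] = tuple(DEFAULT_STAGES)
    detection_replicates: int = 3

    def __post_init__(self) -> None:
        if self.n_diff_spots > self.n_spots:
            raise ValueError("n_diff_spots cannot exceed n_spots")
        if self.planted_fold <= 1:
            raise ValueError("planted_fold must be > 1")
        if self.noise_cv < 0:
            raise ValueError("noise_cv must be >= 0")
        if any(n < 1 for _, _, n in self.groups):
            raise ValueError("every group needs at least one replicate")
        if self.n_scans < 1 or self.rt_range <= 0:
            raise ValueError("need n_scans >= 1 and rt_range > 0")

    def rng(self, stream: str) -> np.random.Generator:
        """Named substream of the master seed (independent per generator)."""
        return np.random.default_rng(
            np.random.SeedSequence(
                self.seed, spawn_key=(zlib.crc32(stream.encode()),)
            )
        )

    @property
    def cultivars(self) -> list[str]:
        return sorted({cv for cv, _, _ in self.groups})


def generate_proteome(
    config: SimConfig,
) -> tuple[list[ProteinRecord], dict]:
    """Random proteome with a planted allergen/homolog marker structure.

    Returns the protein records and a ground-truth dict listing the planted
    signal span, specific marker peptides and non-specific (shared)
    peptides. Requires ``n_proteins >= 3`` (allergen + homolog + filler).
    """
    if config.n_proteins < 3:
        raise ValueError("n_proteins must be >= 3 to plant allergen structures")
    rng = config.rng("proteome")
    records = [
        ProteinRecord(
            id="ALLERGEN1",
            sequence=_ALLERGEN_SEQ,
            signal_span=(1, len(_SIGNAL_PEPTIDE)),
            source_set="target",
        ),
        ProteinRecord(id="HOMOLOG1", sequence=_HOMOLOG_SEQ, source_set="homolog"),
    ]
    planted = set(_SPECIFIC_PEPTIDES) | set(_SHARED_PEPTIDES) | {_SIGNAL_PEPTIDE}
    for i in range(config.n_proteins - 2):
        while True:
            n = int(rng.integers(80, 301))
            seq = "".join(rng.choice(AMINO_ACIDS, size=n))
            if not any(p in seq for p in planted):
                break
        records.append(
            ProteinRecord(id=f"P{i + 1:04d}", sequence=seq, source_set="target")
        )
    ground_truth = {
        "allergen_id": "ALLERGEN1",
        "homolog_id": "HOMOLOG1",
        "signal_span": [1, len(_SIGNAL_PEPTIDE)],
        "signal_peptide": _SIGNAL_PEPTIDE,
        "specific_peptides": list(_SPECIFIC_PEPTIDES),
        "shared_peptides": list(_SHARED_PEPTIDES),
        "n_candidates": 1 + len(_SPECIFIC_PEPTIDES) + len(_SHARED_PEPTIDES),
    }
    return records, ground_truth


def write_proteome_fasta(records: list[ProteinRecord], path) -> None:
    """Write records as uncompressed FASTA (60-column wrap)."""
    with open(path, "w") as fh:
        for rec in records:
            fh.write(f">{rec.id}\n")
            for i in range(0, len(rec.sequence), 60):
                fh.write(rec.sequence[i : i + 60] + "\n")


def generate_spot_table(config: SimConfig) -> tuple[SpotTable, pd.DataFrame]:
    """Spot table with log-normal intensities and planted fold changes.

    Baselines are log-normal (silver-stain spot densities are positive and
    right-skewed); ``n_diff_spots`` randomly chosen spots get a
    multiplicative ``planted_fold`` shift in the second stage of every
    cultivar (up with probability 0.75, mirroring the excess of increasing
    spots during maturation), and every replicate gets log-normal noise
    with coefficient of variation ``noise_cv``. The returned table is
    normalized to spot percentages. Ground truth flags the planted spots
    and their direction.
    """
    rng = config.rng("spots")
    n = config.n_spots
    spot_ids = np.arange(1, n + 1)
    # bimodal, mostly acidic pI distribution typical of seed proteomes
    comp = rng.random(n) < 0.75
    pi = np.where(comp, rng.normal(5.3, 0.7, n), rng.normal(8.3, 0.6, n))
    pi = np.clip(pi, 3.0, 10.0).round(2)
    mw = np.exp(rng.normal(np.log(35000), 0.45, n)).round(0)
    baseline = rng.lognormal(mean=np.log(1000.0), sigma=1.0, size=n)

    # Plant fold changes only on spots clearing the abundance floor of the
    # differential filter (0.25 x the mean spot percentage, with margin):
    # planted ground truth must be recoverable in principle, as the spots
    # reported by a gel study are by definition above its floor.
    eligible = np.flatnonzero(baseline >= 0.3 * baseline.mean())
    if len(eligible) < config.n_diff_spots:
        raise ValueError(
            "too few spots above the abundance floor to plant fold changes"
        )
    diff_idx = rng.choice(eligible, size=config.n_diff_spots, replace=False)
    direction = np.zeros(n, dtype=int)
    direction[diff_idx] = np.where(
        rng.random(config.n_diff_spots) < 0.75, 1, -1
    )

    stages = sorted({st for _, st, _ in config.groups})
    if len(stages) != 2:
        raise ValueError("spot simulation expects exactly two stages in groups")
    late = stages[1]

    sigma_n = np.sqrt(np.log1p(config.noise_cv**2))
    data = {"pI": pi, "MW": mw}
    for cultivar, stage, n_rep in config.groups:
        cell_mean = baseline.copy()
        if stage == late:
            cell_mean = np.where(
                direction == 1,
                cell_mean * config.planted_fold,
                np.where(direction == -1, cell_mean / config.planted_fold, cell_mean),
            )
        for rep in range(1, n_rep + 1):
            noise = rng.normal(0.0, sigma_n, n) if sigma_n > 0 else np.zeros(n)
            data[f"{cultivar}_{stage}_{rep}"] = cell_mean * np.exp(
                noise - sigma_n**2 / 2
            )
    table = SpotTable(pd.DataFrame(data, index=pd.Index(spot_ids, name="spot_id")))
    truth = pd.DataFrame(
        {
            "spot_id": spot_ids,
            "planted": direction != 0,
            "direction": np.where(
                direction == 1, "up", np.where(direction == -1, "down", "none")
            ),
            "true_fold": np.where(direction != 0, config.planted_fold, 1.0),
        }
    ).set_index("spot_id")
    return normalize_spot_percentages(table), truth


def generate_detections(
    config: SimConfig,
) -> tuple[pd.DataFrame, pd.DataFrame, dict]:
    """Shotgun detection table, GO annotations and ground truth.

    Plants ``early-only`` proteins (histone-like: detected only in the
    first three stages) annotated to ``n_trend_terms`` GO terms, and stable
    proteins detected at every stage annotated to the remaining terms.
    Every present (protein, cultivar, stage) cell is guaranteed at least
    one record passing the acceptance rule; additional replicate records
    pass stochastically and sub-threshold noise records are sprinkled in,
    so union-merging is exercised.
    """
    rng = config.rng("detections")
    n_early = max(2, round(0.1 * config.n_proteins))
    proteins = [f"P{i + 1:04d}" for i in range(config.n_proteins)]
    early_ids = proteins[:n_early]
    stable_ids = proteins[n_early:]
    early_stages = list(config.stages[:3])

    terms = [f"GO:SIM{i + 1:04d}" for i in range(config.n_go_terms)]
    trend_terms = terms[: config.n_trend_terms]
    other_terms = terms[config.n_trend_terms :]
    ann_rows = []
    for pid in early_ids:
        for t in trend_terms:
            ann_rows.append({"protein_id": pid, "go_id": t, "aspect": "F"})
    for pid in stable_ids:
        k = int(rng.integers(1, min(4, len(other_terms) + 1)))
        for t in rng.choice(other_terms, size=k, replace=False):
            ann_rows.append({"protein_id": pid, "go_id": t, "aspect": "F"})
    annotations = pd.DataFrame(ann_rows, columns=["protein_id", "go_id", "aspect"])

    rows = []
    for pid in proteins:
        present_stages = early_stages if pid in early_ids else list(config.stages)
        for cultivar in config.cultivars:
            for stage in config.stages:
                for rep in range(1, config.detection_replicates + 1):
                    if stage in present_stages:
                        # replicate 1 always passes; others stochastically
                        if rep == 1 or rng.random() < 0.8:
                            rows.append(
                                {
                                    "protein_id": pid,
                                    "cultivar": cultivar,
                                    "stage": stage,
                                    "replicate": rep,
                                    "n_peptides": int(rng.integers(2, 9)),
                                    "score": round(
                                        float(abs(rng.normal(65, 15))) + 1, 1
                                    ),
                                    "p_value": round(
                                        float(rng.uniform(0.0005, 0.045)), 5
                                    ),
                                }
                            )
                    elif rng.random() < 0.1:
                        # sub-threshold noise: fails both acceptance branches
                        rows.append(
                            {
                                "protein_id": pid,
                                "cultivar": cultivar,
                                "stage": stage,
                                "replicate": rep,
                                "n_peptides": 1,
                                "score": round(float(rng.uniform(5, 35)), 1),
                                "p_value": round(float(rng.uniform(0.06, 0.9)), 5),
                            }
                        )
    detections = pd.DataFrame(rows)
    ground_truth = {
        "early_only_proteins": early_ids,
        "stable_proteins": stable_ids,
        "trend_terms": trend_terms,
        "stable_terms": other_terms,
        "early_stages": early_stages,
    }
    return detections, annotations, ground_truth


def generate_peaklist(
    ions: list[PeptideIon],
    config: SimConfig,
    path,
    plant: bool = True,
) -> pd.DataFrame:
    """Write an MGF peak list with planted marker ions; returns ground truth.

    Each ion elutes as a Gaussian peak at a random apex RT with its m/z
    jittered uniformly within +-15 ppm of theoretical per scan — inside a
    +-20 ppm search window by construction. Decoy peaks are kept more than
    50 ppm away from every planted target. With ``plant=False`` only the
    decoys are written (a sample in which the marker ions are absent); the
    ion list still defines the exclusion zones. Ground truth lists each
    ion's apex RT and amplitude.
    """
    if not ions:
        raise ValueError("ions must be non-empty")
    rng = config.rng("peaklist")
    dt = config.rt_range / config.n_scans
    rts = (np.arange(config.n_scans) + 0.5) * dt
    apex = rng.uniform(0.15, 0.85, len(ions)) * config.rt_range
    width = 2.0 * dt
    amp = 10 ** rng.uniform(5.5, 6.5, len(ions))

    targets = np.array([ion.mz for ion in ions])
    spectra = []
    for i, rt in enumerate(rts):
        mzs, ints = [], []
        for j, ion in enumerate(ions):
            inten = amp[j] * np.exp(-0.5 * ((rt - apex[j]) / width) ** 2)
            if plant and inten >= 1.0:
                jitter = rng.uniform(-15e-6, 15e-6)
                mzs.append(ion.mz * (1 + jitter))
                ints.append(inten)
        n_decoys = 15
        k = 0
        while k < n_decoys:
            m = rng.uniform(300.0, 1500.0)
            if np.min(np.abs(m - targets) / targets) * 1e6 > 50.0:
                mzs.append(m)
                ints.append(10 ** rng.uniform(3.0, 5.0))
                k += 1
        order = np.argsort(mzs)
        spectra.append(
            {
                "m/z array": np.round(np.array(mzs)[order], 5),
                "intensity array": np.round(np.array(ints)[order], 2),
                "params": {
                    "title": f"scan={i + 1}",
                    "rtinseconds": round(rt * 60.0, 3),
                    "pepmass": (round(float(targets[0]), 4), None),
                },
            }
        )
    with open(path, "w") as fh:
        _mgf.write(spectra, fh)
    truth = pd.DataFrame(
        {
            "peptide": [ion.sequence for ion in ions],
            "charge": [ion.charge for ion in ions],
            "target_mz": targets,
            "apex_rt": apex,
            "amplitude": np.where(plant, amp, 0.0),
            "planted": plant,
        }
    )
    return truth


def generate_bundle(config: SimConfig, out_dir) -> dict:
    """Write a complete synthetic input bundle plus a pipeline config.

    Produces proteome and homolog FASTAs, the signal-peptide TSV, the spot
    table CSV, detection and GO TSVs, two MGF peak lists (one from a stage
    before allergen accumulation — decoys only — and one from a mature
    stage with the marker ions planted), ground-truth JSONs, and a
    ``pipeline.yaml`` wired to all of them. Returns the ground truths.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    records, prot_truth = generate_proteome(config)
    targets = [r for r in records if r.source_set == "target"]
    homologs = [r for r in records if r.source_set == "homolog"]
    write_proteome_fasta(targets, out / "proteome.fasta")
    write_proteome_fasta(homologs, out / "homologs.fasta")
    (out / "signal.tsv").write_text(
        "protein_id\tsignal_start\tsignal_end\n"
        + f"{prot_truth['allergen_id']}\t{prot_truth['signal_span'][0]}\t"
        + f"{prot_truth['signal_span'][1]}\n"
    )

    table, spot_truth = generate_spot_table(config)
    table.to_csv(out / "spots.csv")

    detections, annotations, det_truth = generate_detections(config)
    detections.to_csv(out / "detections.tsv", sep="\t", index=False)
    annotations.to_csv(out / "go.tsv", sep="\t", index=False)

    ions = [
        PeptideIon.from_sequence(seq, 2)
        for seq in prot_truth["specific_peptides"]
    ]
    early_stage, late_stage = config.stages[2], config.stages[-1]
    generate_peaklist(ions, config, out / f"{early_stage}.mgf", plant=False)
    peak_truth = generate_peaklist(ions, config, out / f"{late_stage}.mgf", plant=True)

    write_ground_truth(prot_truth, out / "truth_proteome.json")
    write_ground_truth(spot_truth, out / "truth_spots.json")
    write_ground_truth(det_truth, out / "truth_detections.json")
    write_ground_truth(peak_truth, out / "truth_peaklist.json")

    pipeline_cfg = {
        "out_dir": str(out / "results"),
        "seed": config.seed,
        "proteome_fasta": str(out / "proteome.fasta"),
        "homolog_fasta": str(out / "homologs.fasta"),
        "signal_tsv": str(out / "signal.tsv"),
        "target_protein": prot_truth["allergen_id"],
        "spot_csv": str(out / "spots.csv"),
        "stage1": sorted({st for _, st, _ in config.groups})[0],
        "stage2": sorted({st for _, st, _ in config.groups})[1],
        "detections_tsv": str(out / "detections.tsv"),
        "go_tsv": str(out / "go.tsv"),
        "stages": list(config.stages),
        "mgf_files": {
            early_stage: str(out / f"{early_stage}.mgf"),
            late_stage: str(out / f"{late_stage}.mgf"),
        },
        "eic_targets": [
            {"peptide": ion.sequence, "charge": ion.charge} for ion in ions
        ],
    }
    import yaml as _yaml

    (out / "pipeline.yaml").write_text(_yaml.safe_dump(pipeline_cfg, sort_keys=True))
    return {
        "proteome": prot_truth,
        "spots": spot_truth,
        "detections": det_truth,
        "peaklist": peak_truth,
    }


def write_ground_truth(obj, path) -> None:
    """Serialize a ground-truth table or dict as JSON."""
    path = Path(path)
    if isinstance(obj, pd.DataFrame):
        obj.reset_index().to_json(path, orient="records", indent=1)
    else:
        path.write_text(json.dumps(obj, indent=1))
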