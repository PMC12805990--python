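"""End-to-end pipeline: simulate -> associate -> quantify -> respond -> logo.

Each stage reads and writes plain TSV artifacts so partial re-runs are
cheap; :func:`run_pipeline` chains them and writes a library accounting
summary (possible / associated / recovered / detected) plus a run manifest
recording the seed and every threshold applied.
"""

from __future__ import annotations

import dataclasses
import logging
import os
from dataclasses import dataclass, field

import pandas as pd
import yaml

from . import __version__
from .association import BarcodeMap, associate_fastq
from .designs import (
    LibraryDesign,
    acgt_core_design,
    acgt_flank_design,
    control_35s_design,
    window_from_key,
)
from .preference import consensus_matrix, motif_group_test, position_stats
from .quantify import (
    attach_dna_column,
    classify_and_rank,
    count_rna_barcodes,
    replicate_pcc,
    variant_strength,
)
from .response import (
    classify_response,
    estimate_dispersion,
    size_factors,
    test_responsiveness,
    variant_count_matrix,
)
from .simulate import (
    SimulationConfig,
    draw_ground_truth,
    emit_fastq,
    rna_sample_names,
    simulate_counts,
)

__all__ = ["PipelineConfig", "run_pipeline", "accounting_report",
           "design_by_name", "PipelineError"]

log = logging.getLogger("synstarr")


class PipelineError(RuntimeError):
    """A pipeline stage failed; the message names the stage."""


def design_by_name(name: str) -> LibraryDesign:
    designs = {
        "ACGT-core": acgt_core_design,
        "ACGT-flank": acgt_flank_design,
        "35S-control": control_35s_design,
    }
    if name not in designs:
        raise ValueError(f"unknown library design {name!r}; "
                         f"choose from {sorted(designs)}")
    return designs[name]()


@dataclass
class PipelineConfig:
    """Declarative description of one pipeline run."""

    outdir: str = "synstarr_run"
    library: str = "ACGT-flank"
    seed: int = 0
    simulate: bool = True  #: generate FASTQ inputs before associating
    assoc_r1: str | None = None
    assoc_r2: str | None = None
    rna_fastqs: dict[str, str] = field(default_factory=dict)
    min_pair_reads: int = 10
    min_barcodes: int = 5
    min_rna_reads: int = 5
    p_max: float = 0.05
    fc_min: float = 1.2
    pseudocount: float = 1.0
    aggregate: str = "sum"
    statistic: str = "ranksum"
    motifs: tuple[str, ...] = ("GGG", "GTG")
    simulation: SimulationConfig = field(default_factory=SimulationConfig)

    def __post_init__(self):
        if isinstance(self.simulation, dict):
            self.simulation = SimulationConfig(**self.simulation)
        for name in ("min_pair_reads", "min_barcodes", "min_rna_reads"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be positive")
        self.simulation.seed = self.seed

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls(**data)

    def to_yaml(self, path) -> None:
        data = dataclasses.asdict(self)
        data["motifs"] = list(self.motifs)
        with open(path, "w") as fh:
            yaml.safe_dump(data, fh, sort_keys=False)


def accounting_report(design: LibraryDesign, bc_map: BarcodeMap,
                      counts: pd.DataFrame | None,
                      possible_variants: int | None = None) -> pd.DataFrame:
    """Library accounting: possible / associated / recovered / detected.

    Mirrors the summary-table bookkeeping of the assay: all possible
    variants; barcodes detected by DNA sequencing (retained in the map);
    associated variants with % of possible; barcodes recovered by RNA
    sequencing (nonzero in at least one RNA sample) with % of detected;
    variants detected by RNA-seq (at least one recovered barcode) with %
    of associated.  ``possible_variants`` overrides the design's full
    variant-space size when only a subset of the library was cloned or
    simulated.
    """
    possible = design.n_variants if possible_variants is None \
        else possible_variants
    barcodes_dna = bc_map.n_barcodes
    associated = len(bc_map.variants)
    if counts is not None and len(counts.columns):
        recovered_mask = counts.sum(axis=1) > 0
        recovered = int(recovered_mask.sum())
        key_of = bc_map.entries.set_index("barcode")["key"]
        detected = int(key_of.reindex(counts.index[recovered_mask])
                       .dropna().nunique())
    else:
        recovered = detected = 0

    def pct(a, b):
        return 100.0 * a / b if b else 0.0

    return pd.DataFrame([{
        "library": design.name,
        "possible_variants": possible,
        "barcodes_dna": barcodes_dna,
        "associated_variants": associated,
        "associated_pct": pct(associated, possible),
        "barcodes_rna": recovered,
        "barcodes_rna_pct": pct(recovered, barcodes_dna),
        "detected_variants": detected,
        "detected_pct": pct(detected, associated),
    }])


def _stage(name):
    log.info("stage: %s", name)


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute the configured stages and write all artifacts.

    Returns a dict of the in-memory results keyed by artifact name.
    Any stage failure raises :class:`PipelineError` naming the stage;
    artifacts written before the failure are retained.
    """
    os.makedirs(config.outdir, exist_ok=True)
    design = design_by_name(config.library)
    artifacts: dict = {"design": design}
    samples = rna_sample_names(config.simulation.n_replicates)

    try:
        _stage("simulate")
        if config.simulate:
            truth = draw_ground_truth(design, config.simulation)
            pair_counts = simulate_counts(truth, config.simulation)
            paths = emit_fastq(truth, pair_counts, design, config.simulation,
                               os.path.join(config.outdir, "fastq"))
            config.assoc_r1 = paths["assoc_r1"]
            config.assoc_r2 = paths["assoc_r2"]
            config.rna_fastqs = paths["rna"]
            artifacts["truth"] = truth
    except Exception as exc:
        raise PipelineError(f"simulate stage failed: {exc}") from exc

    try:
        _stage("associate")
        for path in (config.assoc_r1, config.assoc_r2):
            if path is None or not os.path.exists(path):
                raise FileNotFoundError(f"association FASTQ missing: {path}")
        bc_map = associate_fastq(config.assoc_r1, config.assoc_r2, design,
                                 min_pair_reads=config.min_pair_reads,
                                 min_barcodes=config.min_barcodes)
        bc_map.write(os.path.join(config.outdir, "barcode_map.tsv"))
        artifacts["barcode_map"] = bc_map
    except PipelineError:
        raise
    except Exception as exc:
        raise PipelineError(f"associate stage failed: {exc}") from exc

    try:
        _stage("quantify")
        for sample, path in config.rna_fastqs.items():
            if not os.path.exists(path):
                raise FileNotFoundError(f"RNA FASTQ missing for {sample}: {path}")
        rna = count_rna_barcodes(config.rna_fastqs, bc_map,
                                 min_reads=config.min_rna_reads)
        counts = attach_dna_column(rna, bc_map)
        counts.to_csv(os.path.join(config.outdir, "counts.tsv"), sep="\t")
        act = variant_strength(counts, bc_map,
                               pseudocount=config.pseudocount,
                               aggregate=config.aggregate)
        act = classify_and_rank(act)
        pcc = {cond: replicate_pcc(act, cond) for cond in ("ctrl", "aba")}
        act.to_csv(os.path.join(config.outdir, "activity.tsv"), sep="\t")
        artifacts.update(counts=counts, activity=act, replicate_pcc=pcc)
    except PipelineError:
        raise
    except Exception as exc:
        raise PipelineError(f"quantify stage failed: {exc}") from exc

    try:
        _stage("respond")
        vc = variant_count_matrix(counts, bc_map)
        factors = size_factors(vc)
        disp = estimate_dispersion(vc, factors)
        resp = test_responsiveness(vc, factors, disp)
        resp = classify_response(resp, p_max=config.p_max,
                                 fc_min=config.fc_min)
        resp.to_csv(os.path.join(config.outdir, "response.tsv"), sep="\t")
        artifacts["response"] = resp
    except PipelineError:
        raise
    except Exception as exc:
        raise PipelineError(f"respond stage failed: {exc}") from exc

    try:
        _stage("logo")
        if design.key_length > 0:
            act_det = act[act["detected"]]
            windows = [window_from_key(design, k) for k in act_det.index]
            strengths = act_det["mean_ctrl"].to_numpy()
            high = act_det["activity_class"] == "high"
            if high.sum() >= 1:
                freq, consensus = consensus_matrix(
                    [w for w, h in zip(windows, high) if h], design)
                freq.to_csv(os.path.join(config.outdir,
                                         "consensus_high.tsv"), sep="\t")
            if len(windows) >= 2:
                pstats = position_stats(windows, strengths, design,
                                        statistic=config.statistic)
                pstats.to_csv(os.path.join(config.outdir,
                                           "position_stats.tsv"),
                              sep="\t", index=False)
                artifacts["position_stats"] = pstats
            if design.name == "ACGT-flank" and len(windows) >= 2:
                try:
                    groups = motif_group_test(windows, strengths, design,
                                              motifs=config.motifs)
                    groups.to_csv(os.path.join(config.outdir,
                                               "motif_groups.tsv"),
                                  sep="\t", index=False)
                    artifacts["motif_groups"] = groups
                except ValueError as exc:
                    log.warning("motif group test skipped: %s", exc)
    except PipelineError:
        raise
    except Exception as exc:
        raise PipelineError(f"logo stage failed: {exc}") from exc

    _stage("report")
    possible = len(artifacts["truth"].variants) if "truth" in artifacts else None
    report = accounting_report(design, bc_map, rna, possible_variants=possible)
    report.to_csv(os.path.join(config.outdir, "accounting.tsv"),
                  sep="\t", index=False)
    artifacts["accounting"] = report

    manifest = {
        "synstarr_version": __version__,
        "seed": config.seed,
        "library": config.library,
        "thresholds": {
            "min_pair_reads": config.min_pair_reads,
            "min_barcodes": config.min_barcodes,
            "min_rna_reads": config.min_rna_reads,
            "p_max": config.p_max,
            "fc_min": config.fc_min,
            "pseudocount": config.pseudocount,
        },
        "samples": samples,
        "simulation": dataclasses.asdict(config.simulation),
    }
    with open(os.path.join(config.outdir, "run_manifest.yaml"), "w") as fh:
        yaml.safe_dump(manifest, fh, sort_keys=False)
    return artifacts
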