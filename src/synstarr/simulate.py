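"""Ground-truth simulator for synthetic STARR-seq experiments.

Generates the objects the analysis pipeline consumes — variant activities,
barcode-variant pairings, count tables and FASTQ reads — with the
statistical structure the downstream methods assume:

* per-variant baseline log2 activity ``a_v ~ Normal(activity_mean,
  activity_sd^2)``;
* a minority of variants with a condition (ABA) effect ``delta_v`` of
  ``+effect_log2fc`` (enhancing) or ``-effect_log2fc`` (blunting);
* ~11 random VNN-patterned barcodes per variant with log-normal plasmid
  abundance weights;
* negative-binomial read counts, variance ``mu + alpha*mu^2``, for one
  input-DNA sample and ``n_replicates`` RNA samples per condition;
* per-base substitution sequencing errors in the emitted reads.

All randomness flows from ``SimulationConfig.seed`` through per-stage child
generators, so identical configs give byte-identical FASTQ output.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .designs import (
    ALPHABET,
    BARCODE_LENGTH,
    BARCODE_SPACE_SIZE,
    BARCODE_V_POSITIONS,
    ConstructTemplate,
    DEFAULT_TEMPLATE,
    LibraryDesign,
    VariantSequence,
    assemble_construct,
    enumerate_variants,
    reverse_complement,
)

__all__ = [
    "SimulationConfig",
    "GroundTruth",
    "draw_ground_truth",
    "simulate_counts",
    "barcode_count_matrix",
    "emit_fastq",
    "rna_sample_names",
]

CONTROL = "ctrl"
TREATED = "aba"
DNA_SAMPLE = "dna"


@dataclass
class SimulationConfig:
    """Parameters of one simulated experiment.

    Defaults reproduce the study conditions: three replicates per condition,
    ~11 barcodes per variant, negative-binomial counts and a small minority
    of ABA-responsive variants.
    """

    seed: int = 0
    n_variants: int | None = None  #: subsample of the design space (None = all)
    n_barcodes_per_variant_mean: float = 11.0
    n_barcodes_fixed: int | None = None  #: exact barcodes/variant (overrides mean)
    activity_mean: float = 0.0  #: log2 scale
    activity_sd: float = 1.0
    frac_enhancing: float = 0.05
    frac_blunting: float = 0.05
    effect_log2fc: float = 1.0
    dna_depth: int = 2_000_000  #: total input-DNA reads
    rna_depth: int = 2_000_000  #: total RNA reads per sample
    nb_dispersion: float = 0.05  #: NB alpha; 0 gives Poisson counts
    base_error_rate: float = 0.001
    n_replicates: int = 3
    collision_rate: float = 0.004  #: chance a barcode slot reuses a taken barcode
    weight_sdlog: float = 0.5  #: sigma of log-normal plasmid abundance

    def __post_init__(self):
        if self.frac_enhancing + self.frac_blunting > 1:
            raise ValueError("enhancing + blunting fractions exceed 1")
        if self.dna_depth < 0 or self.rna_depth < 0:
            raise ValueError("depths must be non-negative")
        if not 0 <= self.base_error_rate < 0.25:
            raise ValueError("base_error_rate must be in [0, 0.25)")
        if self.nb_dispersion < 0:
            raise ValueError("nb_dispersion must be >= 0")
        if self.n_replicates < 1:
            raise ValueError("need at least one replicate")

    def rng(self, stage: int) -> np.random.Generator:
        """Deterministic child generator for a pipeline stage."""
        return np.random.default_rng([int(self.seed), stage])


@dataclass
class GroundTruth:
    """True state of a simulated experiment.

    Attributes
    ----------
    variants:
        One row per variant: ``key``, ``window10``, baseline log2 activity
        ``a``, condition effect ``delta`` (log2) and its class.
    pairs:
        One row per (barcode, variant) pairing with its plasmid abundance
        ``weight``.  A barcode appears twice only if it collided.
    """

    design_name: str
    variants: pd.DataFrame
    pairs: pd.DataFrame

    @property
    def barcode_to_variant(self) -> dict[str, str]:
        """Barcode -> variant key, for collision-free barcodes only."""
        counts = self.pairs["barcode"].value_counts()
        unique = self.pairs[self.pairs["barcode"].map(counts) == 1]
        return dict(zip(unique["barcode"], unique["key"]))

    def write(self, directory: str | os.PathLike) -> None:
        directory = os.fspath(directory)
        os.makedirs(directory, exist_ok=True)
        self.variants.to_csv(os.path.join(directory, "truth_variants.tsv"),
                             sep="\t", index=False)
        self.pairs.to_csv(os.path.join(directory, "truth_pairs.tsv"),
                          sep="\t", index=False)


def rna_sample_names(n_replicates: int) -> list[str]:
    """Sample-column names, controls first: ctrl_1..ctrl_n, aba_1..aba_n."""
    return [f"{CONTROL}_{r}" for r in range(1, n_replicates + 1)] + \
           [f"{TREATED}_{r}" for r in range(1, n_replicates + 1)]


def _draw_barcodes(n: int, rng: np.random.Generator) -> list[str]:
    """Draw n distinct barcodes uniformly from the VNN pattern space."""
    if n > BARCODE_SPACE_SIZE:
        raise ValueError("barcode space exhausted")
    seen: set[str] = set()
    out: list[str] = []
    v_bases = np.frombuffer(b"ACG", dtype="S1")
    n_bases = np.frombuffer(b"ACGT", dtype="S1")
    while len(out) < n:
        batch = max(64, int((n - len(out)) * 1.1))
        chars = n_bases[rng.integers(0, 4, size=(batch, BARCODE_LENGTH))]
        chars[:, list(BARCODE_V_POSITIONS)] = v_bases[
            rng.integers(0, 3, size=(batch, len(BARCODE_V_POSITIONS)))]
        for row in chars:
            bc = row.tobytes().decode()
            if bc not in seen:
                seen.add(bc)
                out.append(bc)
                if len(out) == n:
                    break
    return out


def draw_ground_truth(design: LibraryDesign,
                      config: SimulationConfig) -> GroundTruth:
    """Sample true activities, condition effects and barcode pairings."""
    rng = config.rng(1)
    variants = enumerate_variants(design)
    if config.n_variants is not None and config.n_variants < len(variants):
        idx = np.sort(rng.choice(len(variants), size=config.n_variants,
                                 replace=False))
        variants = [variants[i] for i in idx]
    n_var = len(variants)

    a = rng.normal(config.activity_mean, config.activity_sd, size=n_var)
    cls = rng.choice(
        ["enhancing", "blunting", "neutral"], size=n_var,
        p=[config.frac_enhancing, config.frac_blunting,
           1.0 - config.frac_enhancing - config.frac_blunting])
    delta = np.where(cls == "enhancing", config.effect_log2fc,
                     np.where(cls == "blunting", -config.effect_log2fc, 0.0))

    if config.n_barcodes_fixed is not None:
        n_bc = np.full(n_var, config.n_barcodes_fixed)
    else:
        mean_extra = max(config.n_barcodes_per_variant_mean - 1.0, 0.0)
        n_bc = 1 + rng.poisson(mean_extra, size=n_var)
    total_bc = int(n_bc.sum())
    fresh = _draw_barcodes(total_bc, rng)

    rows = []
    pos = 0
    assigned: list[tuple[str, int]] = []  # (barcode, variant index) so far
    for vi, variant in enumerate(variants):
        for _ in range(n_bc[vi]):
            barcode = fresh[pos]
            pos += 1
            if assigned and rng.random() < config.collision_rate:
                # re-use a barcode already owned by some other variant
                j = int(rng.integers(len(assigned)))
                if assigned[j][1] != vi:
                    barcode = assigned[j][0]
            if barcode not in {b for b, w in rows if w == vi}:
                rows.append((barcode, vi))
                assigned.append((barcode, vi))

    weights = rng.lognormal(mean=0.0, sigma=config.weight_sdlog,
                            size=len(rows))
    pairs = pd.DataFrame({
        "barcode": [b for b, _ in rows],
        "key": [variants[vi].key for _, vi in rows],
        "weight": weights,
    })
    vtab = pd.DataFrame({
        "key": [v.key for v in variants],
        "window10": [v.window10 for v in variants],
        "a": a,
        "delta": delta,
        "response_class": cls,
    })
    return GroundTruth(design_name=design.name, variants=vtab, pairs=pairs)


def _nb_draw(rng: np.random.Generator, mu: np.ndarray,
             alpha: float) -> np.ndarray:
    """NB(mu, alpha) with variance mu + alpha*mu^2; Poisson when alpha=0."""
    mu = np.asarray(mu, dtype=float)
    if alpha == 0:
        return rng.poisson(mu)
    n = 1.0 / alpha
    p = n / (n + mu)
    return rng.negative_binomial(n, p)


def simulate_counts(truth: GroundTruth,
                    config: SimulationConfig) -> pd.DataFrame:
    """Simulate the pair-level count table.

    Returns a DataFrame with one row per (barcode, variant) pairing and one
    integer count column per sample: ``dna`` plus the RNA samples from
    :func:`rna_sample_names`.  DNA counts follow the plasmid abundance
    weights; RNA counts scale those weights by ``2**(a_v + delta_v)`` under
    treatment (``2**a_v`` under control), renormalized to the sample depth.
    Collapse to a barcode-level matrix with :func:`barcode_count_matrix`.
    """
    rng = config.rng(2)
    pairs = truth.pairs.merge(truth.variants[["key", "a", "delta"]], on="key")
    w = pairs["weight"].to_numpy()

    out = pairs[["barcode", "key"]].copy()
    mu_dna = config.dna_depth * w / w.sum()
    out[DNA_SAMPLE] = _nb_draw(rng, mu_dna, config.nb_dispersion)

    for sample in rna_sample_names(config.n_replicates):
        treated = sample.startswith(TREATED)
        expr = w * 2.0 ** (pairs["a"].to_numpy()
                           + (pairs["delta"].to_numpy() if treated else 0.0))
        mu = config.rna_depth * expr / expr.sum()
        out[sample] = _nb_draw(rng, mu, config.nb_dispersion)
    return out


def barcode_count_matrix(pair_counts: pd.DataFrame) -> pd.DataFrame:
    """Collapse pair-level counts to a barcode x sample matrix.

    Reads carry only the barcode, so counts of a collided barcode merge.
    """
    cols = [c for c in pair_counts.columns if c not in ("barcode", "key")]
    return pair_counts.groupby("barcode", sort=True)[cols].sum()


# ---------------------------------------------------------------------------
# FASTQ emission

ASSOC_READ_LENGTH = 100
RNA_READ_LENGTH = 50
_QUAL_CHAR = "I"  # constant Q40; the pipeline only uses qualities in merging

_BASE_ARR = np.frombuffer(b"ACGT", dtype="S1")


def _apply_errors(seqs: list[str], rate: float,
                  rng: np.random.Generator) -> list[str]:
    """Independent per-base substitutions at the given rate."""
    if rate == 0 or not seqs:
        return seqs
    out = []
    for s in seqs:
        k = rng.binomial(len(s), rate)
        if k == 0:
            out.append(s)
            continue
        arr = bytearray(s, "ascii")
        for pos in rng.choice(len(s), size=k, replace=False):
            old = arr[pos]
            choices = [b for b in b"ACGT" if b != old]
            arr[pos] = choices[rng.integers(3)]
        out.append(arr.decode())
    return out


def _write_fastq(path: str, names: list[str], seqs: list[str]) -> None:
    with open(path, "w") as fh:
        for name, seq in zip(names, seqs):
            fh.write(f"@{name}\n{seq}\n+\n{_QUAL_CHAR * len(seq)}\n")


def emit_fastq(truth: GroundTruth, pair_counts: pd.DataFrame,
               design: LibraryDesign, config: SimulationConfig,
               outdir: str | os.PathLike,
               template: ConstructTemplate = DEFAULT_TEMPLATE) -> dict:
    """Write association R1/R2 and per-sample RNA FASTQ files.

    Association reads are an overlapping read pair over the construct
    amplicon (window and barcode both covered); RNA reads cover the barcode
    between fixed anchors.  Read multiplicities equal the count table;
    substitution errors are applied at ``config.base_error_rate``.  Truth
    tables are written alongside.  Returns the path manifest.
    """
    rng = config.rng(3)
    outdir = os.fspath(outdir)
    os.makedirs(outdir, exist_ok=True)
    truth.write(outdir)

    windows = dict(zip(truth.variants["key"], truth.variants["window10"]))
    constructs = {}
    for row in pair_counts.itertuples():
        pair = (row.barcode, row.key)
        if pair not in constructs:
            variant = VariantSequence(library=design.name, key=row.key,
                                      window10=windows[row.key])
            constructs[pair] = assemble_construct(variant, row.barcode,
                                                  design, template)

    # association pairs: R1 = 5' read, R2 = reverse-complemented 3' read
    r1_list, r2_list, names = [], [], []
    for i, row in enumerate(pair_counts.itertuples()):
        n = int(getattr(row, DNA_SAMPLE))
        if n == 0:
            continue
        amplicon = constructs[(row.barcode, row.key)]
        r1 = amplicon[:ASSOC_READ_LENGTH]
        r2 = reverse_complement(amplicon[-ASSOC_READ_LENGTH:])
        r1_list.extend([r1] * n)
        r2_list.extend([r2] * n)
        names.extend(f"pair{i}_{j}" for j in range(n))
    r1_list = _apply_errors(r1_list, config.base_error_rate, rng)
    r2_list = _apply_errors(r2_list, config.base_error_rate, rng)
    paths = {
        "assoc_r1": os.path.join(outdir, "assoc_R1.fastq"),
        "assoc_r2": os.path.join(outdir, "assoc_R2.fastq"),
        "rna": {},
    }
    _write_fastq(paths["assoc_r1"], names, r1_list)
    _write_fastq(paths["assoc_r2"], names, r2_list)

    # RNA reads: synJ tail + ATG + barcode + reporter prefix, trimmed to length
    for sample in rna_sample_names(config.n_replicates):
        seqs, names = [], []
        for i, row in enumerate(pair_counts.itertuples()):
            n = int(getattr(row, sample))
            if n == 0:
                continue
            read = (template.synj[-8:] + "ATG" + row.barcode
                    + template.reporter_prefix)[:RNA_READ_LENGTH]
            seqs.extend([read] * n)
            names.extend(f"{sample}_pair{i}_{j}" for j in range(n))
        seqs = _apply_errors(seqs, config.base_error_rate, rng)
        path = os.path.join(outdir, f"rna_{sample}.fastq")
        _write_fastq(path, names, seqs)
        paths["rna"][sample] = path
    return paths
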