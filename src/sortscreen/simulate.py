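"""Synthetic-data generators for every pipeline input, with ground truth.

Each generator is a pure function of its arguments (including the seed):
repeat calls are bit-identical.  The generators emulate

* a FACS-sorted pooled CRISPR reporter screen — cells carry one guide
  each, per-cell reporter fluorescence is Gaussian around a per-gene
  effect (in reporter-SD units), the 1% tails are sorted into "low" and
  "high" subpopulations, and each population is sequenced to a fixed
  depth (multinomial read sampling over its guide composition);
* label-free proteomics (LFQ) matrices with intensity-dependent dropout
  — values below a detection threshold are censored with high
  probability (MNAR) on top of a uniform missing-at-random rate;
* patient cohorts with two anti-correlated latent signature activities,
  expression loading on signature genes, and exponential survival whose
  log-hazard is proportional to one activity, under independent uniform
  censoring;
* genomic interval sets with an exactly planted summit-overlap fraction.

Ground truth (planted effects, per-cell missingness mechanism, latent
activities, planted overlap flags) is returned alongside the data so that
downstream estimators can be tested for parameter recovery.
"""

from __future__ import annotations

import gzip
from dataclasses import dataclass, field
from typing import Dict, Iterator, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import optimize

from .screen_io import CONTROL_GENE, GuideLibrary, ScreenCounts

__all__ = [
    "ScreenSimParams",
    "ScreenTruth",
    "LfqTruth",
    "CohortTruth",
    "IntervalTruth",
    "LfqExperiment",
    "ExpressionCohort",
    "make_guide_library",
    "simulate_sort_screen",
    "counts_to_fastq",
    "write_fastq",
    "simulate_lfq_experiment",
    "simulate_cohort",
    "simulate_interval_sets",
    "write_lfq_table",
    "write_cohort_tables",
    "write_bed",
]

_BASES = np.array(list("ACGT"))


# ---------------------------------------------------------------------------
# sorted reporter screen
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ScreenSimParams:
    """Study-design parameters of the sorted reporter screen.

    Defaults follow the screen design: six guides per gene plus three
    tag-targeting controls, 200 cells per guide (the infection
    redundancy), 1% sort tails, and unit reporter SD.
    """

    n_genes: int
    guides_per_gene: int = 6
    n_control_guides: int = 3
    cells_per_guide: int = 200
    sort_fraction: float = 0.01
    reporter_sd: float = 1.0
    sequencing_depth: int = 1_000_000
    control_effect: float = -5.0
    abundance_jitter_sd: float = 0.0  # log-normal library skew, off by default
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_genes < 1 or self.guides_per_gene < 1:
            raise ValueError("n_genes and guides_per_gene must be positive")
        if self.n_control_guides < 0:
            raise ValueError("n_control_guides must be >= 0")
        if self.cells_per_guide < 1:
            raise ValueError("cells_per_guide must be positive")
        if not 0 < self.sort_fraction < 0.5:
            raise ValueError("sort_fraction must be in (0, 0.5)")
        if self.reporter_sd <= 0:
            raise ValueError("reporter_sd must be > 0")
        if self.sequencing_depth < 1:
            raise ValueError("sequencing_depth must be positive")


@dataclass(frozen=True)
class ScreenTruth:
    """Planted per-gene reporter effects, in reporter-SD units."""

    gene_effects: pd.Series  # index: gene_id


def make_guide_library(
    n_genes: int,
    guides_per_gene: int = 6,
    n_control_guides: int = 3,
    seed: int = 0,
) -> GuideLibrary:
    """Build a guide library with unique random 20-mers.

    Control guides map to the reserved gene id ``CONTROL``.
    """
    if n_genes < 1 or guides_per_gene < 1:
        raise ValueError("n_genes and guides_per_gene must be positive")
    if n_control_guides < 0:
        raise ValueError("n_control_guides must be >= 0")
    rng = np.random.default_rng(seed)
    n_guides = n_genes * guides_per_gene + n_control_guides
    seqs: list[str] = []
    seen: set[str] = set()
    while len(seqs) < n_guides:
        draw = rng.integers(0, 4, size=(n_guides - len(seqs), 20))
        for row in draw:
            s = "".join(_BASES[row])
            if s not in seen:
                seen.add(s)
                seqs.append(s)
    genes = [
        f"gene{g:05d}" for g in range(n_genes) for _ in range(guides_per_gene)
    ] + [CONTROL_GENE] * n_control_guides
    width = len(str(n_guides))
    table = pd.DataFrame(
        {
            "guide_id": [f"guide{i:0{width}d}" for i in range(n_guides)],
            "gene_id": genes,
            "sequence": seqs,
            "is_control": [g == CONTROL_GENE for g in genes],
        }
    )
    return GuideLibrary(table)


def simulate_sort_screen(
    library: GuideLibrary,
    effects: Mapping[str, float],
    params: ScreenSimParams,
) -> Tuple[ScreenCounts, ScreenTruth]:
    """Simulate unsorted/low/high read counts for a sorted reporter screen.

    Cells are assigned to guides by a multinomial draw (uniform library
    composition unless ``abundance_jitter_sd`` adds log-normal skew); each
    cell's reporter value is Normal(effect(gene), reporter_sd); the bottom
    and top ``sort_fraction`` of cells by reporter value form the low and
    high populations; each of the three samples is sequenced as a
    multinomial of ``sequencing_depth`` reads over its guide composition.

    Genes absent from ``effects`` get effect 0; the control gene gets
    ``params.control_effect`` unless explicitly overridden.
    """
    rng = np.random.default_rng(params.seed)
    table = library.table
    n_guides = len(table)
    gene_ids = table["gene_id"].to_numpy()

    eff = np.zeros(n_guides)
    for i, g in enumerate(gene_ids):
        if g in effects:
            eff[i] = effects[g]
        elif g == CONTROL_GENE:
            eff[i] = params.control_effect
    total_cells = params.cells_per_guide * n_guides

    probs = np.full(n_guides, 1.0 / n_guides)
    if params.abundance_jitter_sd > 0:
        w = rng.lognormal(0.0, params.abundance_jitter_sd, size=n_guides)
        probs = w / w.sum()
    cell_counts = rng.multinomial(total_cells, probs)

    guide_of_cell = np.repeat(np.arange(n_guides), cell_counts)
    reporter = rng.normal(eff[guide_of_cell], params.reporter_sd)

    k = int(round(params.sort_fraction * total_cells))
    k = max(k, 1)
    order_low = np.argpartition(reporter, k - 1)[:k]
    order_high = np.argpartition(reporter, total_cells - k)[total_cells - k:]
    low_counts = np.bincount(guide_of_cell[order_low], minlength=n_guides)
    high_counts = np.bincount(guide_of_cell[order_high], minlength=n_guides)

    depth = params.sequencing_depth
    samples = {}
    for name, comp in (
        ("unsorted", cell_counts),
        ("low", low_counts),
        ("high", high_counts),
    ):
        total = comp.sum()
        if total == 0:
            raise RuntimeError(f"empty {name} population")
        samples[name] = rng.multinomial(depth, comp / total)

    counts = ScreenCounts(
        pd.DataFrame(samples, index=pd.Index(table["guide_id"], name="guide_id"))
    )
    truth = ScreenTruth(
        gene_effects=pd.Series(eff, index=gene_ids).groupby(level=0).first()
    )
    return counts, truth


def counts_to_fastq(
    library: GuideLibrary,
    counts: ScreenCounts,
    read_length: int = 50,
    seed: int = 0,
) -> Dict[str, Iterator[str]]:
    """Render a count table back into per-sample FASTQ record streams.

    Each read starts with its guide's sequence; remaining bases are
    random.  Reads within a sample are shuffled.  The returned dict maps
    sample name to a lazy iterator of 4-line FASTQ record strings; guide
    occurrences match the count table exactly (inverse of
    :func:`sortscreen.screen_io.count_reads`).
    """
    L = library.sequence_length
    if read_length < L:
        raise ValueError(f"read_length must be >= {L}")
    seqs = library.table["sequence"].to_numpy()
    result: Dict[str, Iterator[str]] = {}
    arr = counts.counts
    if not arr.index.equals(pd.Index(library.guide_ids)):
        arr = arr.reindex(library.guide_ids, fill_value=0)

    def records(sample: str, sample_seed: int) -> Iterator[str]:
        rng = np.random.default_rng(sample_seed)
        col = arr[sample].to_numpy()
        guide_of_read = np.repeat(np.arange(len(col)), col)
        rng.shuffle(guide_of_read)
        tail_len = read_length - L
        for i, g in enumerate(guide_of_read):
            tail = (
                "".join(_BASES[rng.integers(0, 4, size=tail_len)])
                if tail_len
                else ""
            )
            yield (
                f"@{sample}.read{i}\n{seqs[g]}{tail}\n+\n{'I' * read_length}\n"
            )

    for j, sample in enumerate(arr.columns):
        result[sample] = records(sample, seed + j)
    return result


def write_fastq(
    library: GuideLibrary,
    counts: ScreenCounts,
    paths: Mapping[str, str],
    read_length: int = 50,
    seed: int = 0,
) -> None:
    """Write per-sample FASTQ files (gzipped when the path ends in .gz)."""
    streams = counts_to_fastq(library, counts, read_length=read_length, seed=seed)
    for sample, path in paths.items():
        opener = gzip.open if str(path).endswith(".gz") else open
        with opener(path, "wt") as handle:
            for record in streams[sample]:
                handle.write(record)


# ---------------------------------------------------------------------------
# label-free proteomics
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class LfqTruth:
    """Which proteins are enriched, and the generating mechanism of every
    missing cell ('MNAR' or 'MAR'; empty string for observed cells)."""

    enriched: pd.Series          # bool per protein
    effect_log2: pd.Series       # planted log2 effect per protein
    mechanism: pd.DataFrame      # protein × sample, '', 'MNAR' or 'MAR'


@dataclass
class LfqExperiment:
    """log2 LFQ intensity matrix (NaN = missing) with two groups of samples."""

    intensities: pd.DataFrame    # protein × sample
    groups: pd.Series            # sample -> group label


def simulate_lfq_experiment(
    n_proteins: int,
    n_enriched: int,
    group_sizes: Tuple[int, int] = (3, 3),
    effect_log2: float = 2.0,
    mnar_threshold_quantile: float = 0.15,
    mar_rate: float = 0.05,
    seed: int = 0,
    baseline_mean: float = 25.0,
    baseline_sd: float = 3.0,
    noise_sd: float = 1.0,
    mnar_dropout_prob: float = 0.9,
) -> Tuple[LfqExperiment, LfqTruth]:
    """Simulate a two-group LFQ experiment with intensity-dependent dropout.

    Enriched proteins gain ``effect_log2`` in the second group (the bait
    line).  MNAR dropout censors cells whose true value falls below the
    ``mnar_threshold_quantile`` quantile of all true values, each with
    probability ``mnar_dropout_prob``; MAR dropout removes remaining cells
    uniformly at ``mar_rate``.  Every missing cell carries exactly one
    mechanism label in the truth record.
    """
    if n_enriched > n_proteins:
        raise ValueError("n_enriched must be <= n_proteins")
    if not (0 <= mar_rate < 1) or not (0 <= mnar_threshold_quantile < 1):
        raise ValueError("rates must be in [0, 1)")
    rng = np.random.default_rng(seed)
    n1, n2 = group_sizes
    samples = [f"ctrl_{i+1}" for i in range(n1)] + [
        f"bait_{i+1}" for i in range(n2)
    ]
    groups = pd.Series(
        ["control"] * n1 + ["bait"] * n2, index=samples, name="group"
    )
    proteins = pd.Index(
        [f"P{i:05d}" for i in range(n_proteins)], name="protein_id"
    )
    enriched = np.zeros(n_proteins, bool)
    enriched[:n_enriched] = True
    baseline = rng.normal(baseline_mean, baseline_sd, n_proteins)
    mu = np.tile(baseline[:, None], (1, n1 + n2))
    mu[enriched, n1:] += effect_log2
    X = rng.normal(mu, noise_sd)

    mech = np.full(X.shape, "", dtype=object)
    if mnar_threshold_quantile > 0:
        threshold = np.quantile(X, mnar_threshold_quantile)
        mnar = (X < threshold) & (rng.random(X.shape) < mnar_dropout_prob)
        mech[mnar] = "MNAR"
    if mar_rate > 0:
        mar = (rng.random(X.shape) < mar_rate) & (mech == "")
        mech[mar] = "MAR"
    data = X.copy()
    data[mech != ""] = np.nan

    experiment = LfqExperiment(
        intensities=pd.DataFrame(data, index=proteins, columns=samples),
        groups=groups,
    )
    truth = LfqTruth(
        enriched=pd.Series(enriched, index=proteins, name="enriched"),
        effect_log2=pd.Series(
            np.where(enriched, effect_log2, 0.0), index=proteins
        ),
        mechanism=pd.DataFrame(mech, index=proteins, columns=samples),
    )
    return experiment, truth


def write_lfq_table(experiment: LfqExperiment, path: str) -> None:
    """Write an LFQ TSV (empty cell = missing) plus group header row."""
    experiment.intensities.to_csv(path, sep="\t", na_rep="")


# ---------------------------------------------------------------------------
# patient cohort
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CohortTruth:
    """Latent per-patient signature activities."""

    activities: pd.DataFrame  # columns: trps1_act, yap_act


@dataclass
class ExpressionCohort:
    """Gene × patient expression with clinical annotations and the
    signature gene sets planted by the simulator."""

    expression: pd.DataFrame        # gene × patient
    clinical: pd.DataFrame          # sample_id, time, event, subtype, cnv
    trps1_repressed_set: Sequence[str]
    yap_induced_set: Sequence[str]


def simulate_cohort(
    n_patients: int,
    n_genes: int = 2000,
    trps1_set_size: int = 100,
    yap_set_size: int = 100,
    latent_correlation: float = -0.85,
    hazard_ratio_per_sd: float = 1.0,
    censor_rate: float = 0.2,
    seed: int = 0,
    loading: float = 1.0,
    noise_sd: float = 1.0,
) -> Tuple[ExpressionCohort, CohortTruth]:
    """Simulate a tumour cohort with two anti-correlated latent activities.

    Latent per-patient activities ``(trps1_act, yap_act)`` are standard
    bivariate normal with the given correlation.  Genes in the repressed
    set load negatively on the TRPS1-axis activity (high activity pushes
    them down); genes in the induced set load positively on the YAP-axis
    activity; all other genes are pure noise.  Survival is exponential
    with log-hazard ``log(hazard_ratio_per_sd) * trps1_act`` (high
    TRPS1-axis activity → worse outcome) under independent uniform
    censoring calibrated to the requested censor fraction.
    """
    if not abs(latent_correlation) < 1:
        raise ValueError("|latent_correlation| must be < 1")
    if trps1_set_size + yap_set_size >= n_genes:
        raise ValueError("signature sets must fit disjointly in n_genes")
    if not 0 <= censor_rate < 1:
        raise ValueError("censor_rate must be in [0, 1)")
    if hazard_ratio_per_sd <= 0:
        raise ValueError("hazard_ratio_per_sd must be > 0")
    rng = np.random.default_rng(seed)
    cov = np.array([[1.0, latent_correlation], [latent_correlation, 1.0]])
    act = rng.multivariate_normal([0.0, 0.0], cov, size=n_patients)
    trps1_act, yap_act = act[:, 0], act[:, 1]

    genes = pd.Index([f"G{i:05d}" for i in range(n_genes)], name="gene_id")
    patients = pd.Index(
        [f"PT{i:04d}" for i in range(n_patients)], name="sample_id"
    )
    trps1_set = list(genes[:trps1_set_size])
    yap_set = list(genes[trps1_set_size: trps1_set_size + yap_set_size])

    X = rng.normal(0.0, noise_sd, (n_genes, n_patients))
    X[:trps1_set_size] += -loading * trps1_act  # repressed by TRPS1 activity
    X[trps1_set_size: trps1_set_size + yap_set_size] += loading * yap_act

    beta = np.log(hazard_ratio_per_sd)
    rate = np.exp(beta * trps1_act)
    time = rng.exponential(1.0 / rate)
    event = np.ones(n_patients, dtype=int)
    if censor_rate > 0:
        def censored_fraction(cmax: float) -> float:
            # P(C < T) with C ~ U(0, cmax), given the drawn event times
            return float(np.mean(np.minimum(time / cmax, 1.0)))

        lo, hi = 1e-9, 1e9
        cmax = optimize.brentq(
            lambda c: censored_fraction(c) - censor_rate, lo, hi
        )
        censor_time = rng.uniform(0.0, cmax, n_patients)
        event = (time <= censor_time).astype(int)
        time = np.minimum(time, censor_time)

    subtype = rng.choice(
        ["basal", "luminal_a", "luminal_b", "her2"], size=n_patients
    )
    cnv = np.clip(np.round(trps1_act / 1.5 + rng.normal(0, 0.3, n_patients)),
                  -2, 2).astype(int)
    clinical = pd.DataFrame(
        {
            "sample_id": patients,
            "time": time,
            "event": event,
            "subtype": subtype,
            "cnv": cnv,
        }
    ).set_index("sample_id")

    cohort = ExpressionCohort(
        expression=pd.DataFrame(X, index=genes, columns=patients),
        clinical=clinical,
        trps1_repressed_set=trps1_set,
        yap_induced_set=yap_set,
    )
    truth = CohortTruth(
        activities=pd.DataFrame(
            {"trps1_act": trps1_act, "yap_act": yap_act}, index=patients
        )
    )
    return cohort, truth


def write_cohort_tables(
    cohort: ExpressionCohort, expression_path: str, clinical_path: str
) -> None:
    cohort.expression.to_csv(expression_path, sep="\t")
    cohort.clinical.to_csv(clinical_path, sep="\t")


# ---------------------------------------------------------------------------
# genomic interval sets
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class IntervalTruth:
    """Per-peak flag: was the summit planted inside a region?"""

    planted_overlap: pd.Series


def simulate_interval_sets(
    genome_length: int,
    n_regions: int,
    n_peaks: int,
    planted_overlap_fraction: float,
    seed: int = 0,
    region_width: int = 1000,
    peak_width: int = 200,
) -> Tuple[pd.DataFrame, pd.DataFrame, IntervalTruth]:
    """Plant peak summits inside/outside a set of non-overlapping regions.

    Exactly ``round(planted_overlap_fraction * n_peaks)`` peak summits
    fall inside a region, by construction.  Regions are non-overlapping
    intervals of ``region_width`` on a single chromosome; peaks are
    ``peak_width`` wide with the summit at the centre.
    """
    if not 0 <= planted_overlap_fraction <= 1:
        raise ValueError("planted_overlap_fraction must be in [0, 1]")
    n_slots = genome_length // (2 * region_width) - 1
    if n_regions > n_slots or n_slots < 1:
        raise ValueError("regions do not fit in the genome without overlap")
    rng = np.random.default_rng(seed)
    slots = rng.choice(n_slots, size=n_regions, replace=False)
    # offset by one slot so peaks centred on a region edge stay in-genome
    starts = np.sort((slots + 1) * 2 * region_width - region_width)
    regions = pd.DataFrame(
        {
            "chrom": "chr1",
            "start": starts,
            "end": starts + region_width,
            "name": [f"region{i}" for i in range(n_regions)],
        }
    )

    n_inside = int(round(planted_overlap_fraction * n_peaks))
    half = peak_width // 2
    summits = np.empty(n_peaks, dtype=np.int64)
    region_pick = rng.integers(0, n_regions, size=n_inside)
    summits[:n_inside] = starts[region_pick] + rng.integers(
        0, region_width, size=n_inside
    )
    # outside summits by rejection sampling
    filled = n_inside
    region_starts = starts
    max_tries = 1000
    for _ in range(max_tries):
        if filled == n_peaks:
            break
        cand = rng.integers(half, genome_length - half, size=n_peaks - filled)
        idx = np.searchsorted(region_starts, cand, side="right") - 1
        inside = (idx >= 0) & (cand < region_starts[np.clip(idx, 0, None)] + region_width)
        keep = cand[~inside]
        take = keep[: n_peaks - filled]
        summits[filled: filled + len(take)] = take
        filled += len(take)
    else:
        raise RuntimeError("could not place peak summits outside regions")

    peaks = pd.DataFrame(
        {
            "chrom": "chr1",
            "start": summits - half,
            "end": summits - half + peak_width,
            "name": [f"peak{i}" for i in range(n_peaks)],
            "summit": summits,
        }
    )
    truth = IntervalTruth(
        planted_overlap=pd.Series(
            np.arange(n_peaks) < n_inside, index=peaks["name"].to_numpy()
        )
    )
    return regions, peaks, truth


def write_bed(intervals: pd.DataFrame, path: str) -> None:
    """Write BED3/BED6 (delegates to :mod:`sortscreen.intervals`)."""
    from .intervals import write_bed as _write

    _write(intervals, path)
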