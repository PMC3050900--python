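"""Synthetic genomes, clone libraries, serial-enrichment array scans and growth curves.

Emulates the statistical structure of a pooled genomic-library tolerance screen:
a plasmid library of 2-3 kb genomic inserts is propagated through serial batch
transfers under solvent challenge, per-transfer selection acts multiplicatively
on clone abundance, and two-channel comparative-hybridization arrays read out
per-gene abundance relative to the unchallenged library. Growth phenotypes of
individual strains are emulated with a lagged logistic model read on an OD600
plate reader. Every generator is deterministic under a fixed seed and records
the ground truth needed for recovery tests.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

ARMS = ("butanol", "control")

#: Challenge concentrations (% v/v) applied at successive serial transfers.
DEFAULT_STEPS = (("step1", 0.5), ("step2", 0.9), ("step3", 1.3), ("step4", 1.7))


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class Gene:
    gene_id: str
    start: int  # 0-based, half-open
    end: int
    strand: str
    go_terms: tuple[str, ...] = ()

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass
class GenomeAnnotation:
    """A genome as an annotated coordinate system (no sequence).

    Coordinates are 0-based half-open; strand is stored but ignored by all
    coverage arithmetic (hybridization is strand-agnostic).
    """

    genome_length: int
    genes: list[Gene]
    term_parents: dict[str, tuple[str, ...]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        ids = [g.gene_id for g in self.genes]
        if len(set(ids)) != len(ids):
            raise ValueError("gene_ids must be unique")
        for g in self.genes:
            if not (0 <= g.start < g.end <= self.genome_length):
                raise ValueError(
                    f"gene {g.gene_id} interval [{g.start},{g.end}) outside "
                    f"[0,{self.genome_length})"
                )

    @property
    def gene_ids(self) -> list[str]:
        return [g.gene_id for g in self.genes]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "gene_id": [g.gene_id for g in self.genes],
                "start": [g.start for g in self.genes],
                "end": [g.end for g in self.genes],
                "strand": [g.strand for g in self.genes],
            }
        )

    def go_associations(self) -> pd.DataFrame:
        """Two-column (gene, term) association table."""
        rows = [(g.gene_id, t) for g in self.genes for t in g.go_terms]
        return pd.DataFrame(rows, columns=["gene_id", "term_id"])


@dataclass
class CloneLibrary:
    """A plasmid library of genomic inserts, with fold-coverage bookkeeping."""

    clones: pd.DataFrame  # columns: clone_id, start, end
    insert_length_range: tuple[int, int]
    genome_length: int

    def __post_init__(self) -> None:
        lengths = self.clones["end"] - self.clones["start"]
        lo, hi = self.insert_length_range
        if not ((lengths >= lo) & (lengths <= hi)).all():
            raise ValueError("insert length outside declared range")
        if self.clones["clone_id"].duplicated().any():
            raise ValueError("clone_ids must be unique")

    @property
    def n_clones(self) -> int:
        return len(self.clones)

    @property
    def coverage(self) -> float:
        """Fold coverage: total insert bases / genome length."""
        return float((self.clones["end"] - self.clones["start"]).sum()) / self.genome_length


@dataclass
class StepSchedule:
    """Ordered serial-transfer schedule with a challenged and a control arm."""

    steps: list[tuple[str, float]] = field(default_factory=lambda: list(DEFAULT_STEPS))
    arms: tuple[str, str] = ARMS

    def __post_init__(self) -> None:
        concs = [c for _, c in self.steps]
        if any(b < a for a, b in zip(concs, concs[1:])):
            raise ValueError("challenge concentrations must be non-decreasing")

    @property
    def labels(self) -> list[str]:
        return [s for s, _ in self.steps]

    @property
    def n_steps(self) -> int:
        return len(self.steps)


@dataclass
class ScreenTruth:
    """Ground truth of a simulated screen, for recovery tests.

    ``selection`` maps arm -> per-clone selection coefficient (per transfer,
    natural-log scale); the two arms are drawn independently. ``mu_true``
    maps (strain_id, condition %v/v) -> true maximum specific growth rate.
    The ``*_genes`` lists record which genes the per-clone coefficients were
    derived from (empty when selection was assigned clone-wise).
    """

    selection: dict[str, np.ndarray]
    mu_true: dict[tuple[str, float], float] = field(default_factory=dict)
    seed: int | None = None
    positive_genes: list[str] = field(default_factory=list)
    negative_genes: list[str] = field(default_factory=list)
    control_genes: list[str] = field(default_factory=list)

    def positive_clones(self, arm: str = "butanol") -> np.ndarray:
        return np.flatnonzero(self.selection[arm] > 0)


@dataclass
class ArrayScan:
    """One two-channel array: per-probe sample and reference intensities."""

    step: str
    arm: str
    data: pd.DataFrame  # columns: probe_id, sample, reference

    def __post_init__(self) -> None:
        if self.data["probe_id"].duplicated().any():
            raise ValueError("probe_ids must be unique within a scan")


@dataclass
class GrowthCurve:
    """An OD600 time series for one strain x condition x replicate."""

    strain_id: str
    condition: float  # n-butanol % v/v
    replicate: int
    times: np.ndarray  # hours
    od600: np.ndarray

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.od600 = np.asarray(self.od600, dtype=float)
        if self.times.size == 0:
            raise ValueError("times must be non-empty")
        if np.any(np.diff(self.times) <= 0):
            raise ValueError("times must be strictly increasing")
        if np.any(self.od600 < 0):
            raise ValueError("od600 must be non-negative")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "strain": self.strain_id,
                "condition": self.condition,
                "replicate": self.replicate,
                "time_h": self.times,
                "od600": self.od600,
            }
        )


# ---------------------------------------------------------------------------
# generators
# ---------------------------------------------------------------------------


def _synthetic_ontology(n_terms: int, rng: np.random.Generator) -> dict[str, tuple[str, ...]]:
    """A small random DAG of GO-like terms (each term gets 0-2 parents)."""
    terms = [f"GO:S{i:06d}" for i in range(n_terms)]
    parents: dict[str, tuple[str, ...]] = {terms[0]: ()}
    for i, t in enumerate(terms[1:], start=1):
        k = int(rng.integers(0, min(2, i) + 1))
        if k:
            idx = rng.choice(i, size=k, replace=False)
            parents[t] = tuple(terms[j] for j in sorted(idx))
        else:
            parents[t] = ()
    return parents


def build_genome(
    n_genes: int,
    mean_gene_length: int = 950,
    genome_length: int = 4_641_652,
    seed: int | None = None,
    n_go_terms: int = 50,
    max_terms_per_gene: int = 5,
) -> GenomeAnnotation:
    """Place ``n_genes`` non-overlapping genes uniformly on a linear genome.

    Gene lengths are drawn uniformly in [0.5, 1.5] x ``mean_gene_length``; the
    leftover space is distributed as random inter-genic gaps so placement is
    uniform. Each gene carries 1..``max_terms_per_gene`` terms from a synthetic
    ontology with parent edges.
    """
    rng = np.random.default_rng(seed)
    if n_genes < 0:
        raise ValueError("n_genes must be >= 0")
    term_parents = _synthetic_ontology(n_go_terms, rng)
    if n_genes == 0:
        return GenomeAnnotation(genome_length, [], term_parents)

    lo = max(1, int(0.5 * mean_gene_length))
    hi = max(lo + 1, int(1.5 * mean_gene_length))
    lengths = rng.integers(lo, hi + 1, size=n_genes)
    total = int(lengths.sum())
    if total > genome_length:
        raise ValueError(
            f"cannot pack {n_genes} genes totalling {total} bp without overlap "
            f"into a {genome_length} bp genome"
        )
    slack = genome_length - total
    gaps = np.floor(rng.dirichlet(np.ones(n_genes + 1)) * slack).astype(int)
    terms = sorted(term_parents)
    width = max(4, len(str(n_genes)))
    genes: list[Gene] = []
    pos = 0
    for i in range(n_genes):
        pos += int(gaps[i])
        start, end = pos, pos + int(lengths[i])
        k = int(rng.integers(1, max_terms_per_gene + 1))
        gene_terms = tuple(rng.choice(terms, size=min(k, len(terms)), replace=False))
        genes.append(
            Gene(
                gene_id=f"g{i:0{width}d}",
                start=start,
                end=end,
                strand="+" if rng.random() < 0.5 else "-",
                go_terms=tuple(sorted(gene_terms)),
            )
        )
        pos = end
    return GenomeAnnotation(genome_length, genes, term_parents)


def simulate_library(
    genome: GenomeAnnotation,
    n_clones: int = 14_000,
    insert_range: tuple[int, int] = (2000, 3000),
    seed: int | None = None,
) -> CloneLibrary:
    """Sample a clone library of uniform genomic inserts.

    Fold coverage (sum of insert lengths / genome length) is exposed as
    ``CloneLibrary.coverage``; at the default 14,000 clones of 2-3 kb over a
    4.64 Mb genome this is ~7.5-fold.
    """
    if n_clones <= 0:
        raise ValueError("n_clones must be positive")
    lo, hi = insert_range
    if not (0 < lo <= hi <= genome.genome_length):
        raise ValueError("insert_range must lie within (0, genome_length]")
    rng = np.random.default_rng(seed)
    lengths = rng.integers(lo, hi + 1, size=n_clones)
    starts = np.floor(rng.random(n_clones) * (genome.genome_length - lengths + 1)).astype(int)
    width = max(5, len(str(n_clones)))
    clones = pd.DataFrame(
        {
            "clone_id": [f"c{i:0{width}d}" for i in range(n_clones)],
            "start": starts,
            "end": starts + lengths,
        }
    )
    return CloneLibrary(clones, insert_range, genome.genome_length)


def make_screen_truth(
    library: CloneLibrary,
    genome: GenomeAnnotation | None = None,
    n_positive_genes: int = 0,
    s_positive: float = 2.5,
    n_negative_genes: int = 0,
    s_negative: float = -2.5,
    n_control_genes: int = 0,
    s_control: float = 2.0,
    seed: int | None = None,
) -> ScreenTruth:
    """Draw per-clone selection coefficients for both arms, independently.

    Selection follows gene content: target genes are sampled (well separated
    so no clone links two targets) and every clone whose insert overlaps a
    target inherits that gene's coefficient — tolerance genes confer s > 0
    in the challenged arm, toxic-when-overexpressed genes s < 0, and
    control-arm targets model general growth advantage (the class the
    control-arm subtraction filter exists to remove). Coefficients are per
    transfer on the natural-log scale; the default magnitudes let carriers
    take over a pool of ~10^4 clones within a few transfers, the regime a
    serial enrichment is designed for.
    """
    rng = np.random.default_rng(seed)
    n = library.n_clones
    s_but = np.zeros(n)
    s_ctl = np.zeros(n)
    n_targets = n_positive_genes + n_negative_genes + n_control_genes
    if n_targets == 0:
        return ScreenTruth(selection={"butanol": s_but, "control": s_ctl}, seed=seed)
    if genome is None or not genome.genes:
        raise ValueError("gene-targeted selection requires an annotated genome")

    # sample well-separated target genes: no insert can span two targets
    min_gap = library.insert_length_range[1]
    order = rng.permutation(len(genome.genes))
    chosen: list[Gene] = []
    for idx in order:
        g = genome.genes[idx]
        if all(g.start - h.end >= min_gap or h.start - g.end >= min_gap for h in chosen):
            chosen.append(g)
        if len(chosen) == n_targets:
            break
    if len(chosen) < n_targets:
        raise ValueError(
            f"could only place {len(chosen)} of {n_targets} separated target genes"
        )
    pos = chosen[:n_positive_genes]
    neg = chosen[n_positive_genes : n_positive_genes + n_negative_genes]
    ctl = chosen[n_positive_genes + n_negative_genes :]

    cs = library.clones["start"].to_numpy()
    ce = library.clones["end"].to_numpy()

    def covering(gene: Gene) -> np.ndarray:
        return (cs < gene.end) & (ce > gene.start)

    for g in pos:
        s_but[covering(g)] = s_positive
    for g in neg:
        s_but[covering(g)] = s_negative
    for g in ctl:
        s_ctl[covering(g)] = s_control
    return ScreenTruth(
        selection={"butanol": s_but, "control": s_ctl},
        seed=seed,
        positive_genes=sorted(g.gene_id for g in pos),
        negative_genes=sorted(g.gene_id for g in neg),
        control_genes=sorted(g.gene_id for g in ctl),
    )


def default_dye_bias() -> tuple[float, float, float, float]:
    """Cubic dye-bias coefficients in centered mean log-intensity (A - Ā).

    Scaled so the trend stays within ~±0.5 log2 units across the simulated
    intensity range, the amplitude real two-channel arrays show.
    """
    return (0.3, 0.08, -0.01, -0.003)


def _interval_signal(
    abundance: np.ndarray, clone_start: np.ndarray, clone_end: np.ndarray,
    gene_start: np.ndarray, gene_end: np.ndarray,
) -> np.ndarray:
    """Abundance-weighted count of clones overlapping each gene interval.

    overlap(i, g) <=> clone_start_i < gene_end_g and clone_end_i > gene_start_g;
    computed by inclusion-exclusion with prefix sums over sorted endpoints.
    """
    total = abundance.sum()
    order_end = np.argsort(clone_end, kind="stable")
    ends_sorted = clone_end[order_end]
    cum_by_end = np.concatenate([[0.0], np.cumsum(abundance[order_end])])
    order_start = np.argsort(clone_start, kind="stable")
    starts_sorted = clone_start[order_start]
    cum_by_start = np.concatenate([[0.0], np.cumsum(abundance[order_start])])
    # clones entirely left of gene: end <= gene_start
    left = cum_by_end[np.searchsorted(ends_sorted, gene_start, side="right")]
    # clones entirely right of gene: start >= gene_end
    n_left_of = np.searchsorted(starts_sorted, gene_end, side="left")
    right = cum_by_start[-1] - cum_by_start[n_left_of]
    # cancellation of near-total sums can leave tiny negatives; clamp
    return np.maximum(total - left - right, 0.0)


def simulate_enrichment(
    library: CloneLibrary,
    genome: GenomeAnnotation,
    truth: ScreenTruth,
    schedule: StepSchedule | None = None,
    noise_sd: float = 0.2,
    dye_bias: tuple[float, ...] | None = None,
    seed: int | None = None,
    probes_per_gene: int = 1,
    background: float = 0.0,
    saturation: float | None = None,
    step_weights: tuple[float, ...] | None = None,
) -> tuple[list[ArrayScan], pd.Series]:
    """Simulate two-channel array scans for every challenge step and arm.

    Clone abundance follows the multiplicative recursion a_i <- a_i * exp(s_i)
    with renormalization after every transfer; the per-gene sample channel is
    proportional to the summed abundance of clones covering the gene and the
    reference channel to the unchallenged library. ``dye_bias`` (cubic
    polynomial coefficients in centered A) adds a smooth intensity-dependent
    trend to the log-ratios; Gaussian noise of sd ``noise_sd`` acts on the
    log2 scale. ``background`` adds a constant to both channels after the
    ratio is formed, emulating the hybridization background that floors
    depletion signals on real arrays, and ``saturation`` clips both channels
    at the scanner's ceiling (e.g. 65535 for a 16-bit scanner); both default
    off, and the neutral-selection log-ratio stays exactly 0 either way.
    ``step_weights`` scales the selection coefficients per transfer (one
    weight per scheduled step, default all 1): declining weights model the
    compression of fitness differences as the challenge concentration rises
    toward the tolerance ceiling, which makes enrichment saturate after the
    first transfers rather than grow without bound. Genes covered by no
    clone are omitted (count logged).

    Returns the scans plus a probe -> gene map.
    """
    if background < 0:
        raise ValueError("background must be non-negative")
    if noise_sd < 0:
        raise ValueError("noise_sd must be non-negative")
    if probes_per_gene < 1:
        raise ValueError("probes_per_gene must be >= 1")
    schedule = schedule or StepSchedule()
    if step_weights is None:
        step_weights = tuple(1.0 for _ in schedule.steps)
    if len(step_weights) != schedule.n_steps:
        raise ValueError("need one step weight per scheduled step")
    for arm in schedule.arms:
        if arm not in truth.selection or len(truth.selection[arm]) != library.n_clones:
            raise ValueError(f"truth must hold one selection coefficient per clone for arm {arm!r}")

    rng = np.random.default_rng(seed)
    cs = library.clones["start"].to_numpy()
    ce = library.clones["end"].to_numpy()
    gs = np.array([g.start for g in genome.genes])
    ge = np.array([g.end for g in genome.genes])
    gene_ids = np.array(genome.gene_ids)

    a0 = np.full(library.n_clones, 1.0 / library.n_clones)
    ref_signal = _interval_signal(a0, cs, ce, gs, ge)
    covered = ref_signal > 0
    n_uncovered = int((~covered).sum())
    if n_uncovered:
        logger.info("simulate_enrichment: %d genes covered by no clone, omitted", n_uncovered)
    gs, ge, gene_ids, ref_signal = gs[covered], ge[covered], gene_ids[covered], ref_signal[covered]
    n_genes = len(gene_ids)

    # per-probe baseline intensities, fixed across steps/arms (probe affinity);
    # the wide spread in A exercises intensity-dependent normalization and
    # keeps unchanged spots present in every A window that selection-shifted
    # spots can reach
    n_probes = n_genes * probes_per_gene
    base = 2.0 ** rng.uniform(6.0, 16.0, size=n_probes)
    probe_ids = [
        f"{gid}_p{j + 1}" for gid in gene_ids for j in range(probes_per_gene)
    ]
    probe_gene = np.repeat(gene_ids, probes_per_gene)
    probe_map = pd.Series(probe_gene, index=pd.Index(probe_ids, name="probe_id"), name="gene_id")

    scans: list[ArrayScan] = []
    for arm in schedule.arms:
        s = truth.selection[arm]
        a = a0.copy()
        for (step_label, _conc), w in zip(schedule.steps, step_weights):
            a = a * np.exp(w * s)
            a = a / a.sum()
            sig = _interval_signal(a, cs, ce, gs, ge)
            # neutral selection leaves the abundance field untouched, so the
            # true ratio is exactly 1 for every gene
            ratio = np.repeat(sig / ref_signal, probes_per_gene)
            sample_lin = base * ratio
            live = sample_lin > 0  # fully depleted spots carry no bias/noise
            shift = np.zeros(n_probes)
            if dye_bias is not None:
                a_val = 0.5 * np.log2(sample_lin[live] * base[live])
                z = a_val - a_val.mean()
                shift[live] += np.polyval(list(reversed(dye_bias)), z)
            if noise_sd > 0:
                shift[live] += rng.normal(0.0, noise_sd, size=int(live.sum()))
            sample = sample_lin * 2.0 ** shift + background
            reference = base + background
            if saturation is not None:
                sample = np.minimum(sample, saturation)
                reference = np.minimum(reference, saturation)
            scans.append(
                ArrayScan(
                    step=step_label,
                    arm=arm,
                    data=pd.DataFrame(
                        {"probe_id": probe_ids, "sample": sample, "reference": reference}
                    ),
                )
            )
    return scans, probe_map


def logistic_od(
    times: np.ndarray, mu_max: float, lag: float, carrying_capacity: float, od0: float
) -> np.ndarray:
    """Noise-free lagged logistic OD: flat at od0 until the lag ends, then
    logistic growth at rate ``mu_max`` toward ``carrying_capacity``."""
    t = np.asarray(times, dtype=float)
    k, x0 = carrying_capacity, od0
    if k <= x0:
        raise ValueError("carrying_capacity must exceed od0")
    te = np.clip(t - lag, 0.0, None)
    e = np.exp(mu_max * te)
    return k * x0 * e / (k - x0 + x0 * e)


def simulate_growth(
    mu_max: float,
    lag: float,
    carrying_capacity: float,
    times: np.ndarray,
    noise_sd: float = 0.0,
    seed: int | None = None,
    od0: float = 0.01,
    strain_id: str = "strain",
    condition: float = 0.0,
    replicate: int = 1,
) -> GrowthCurve:
    """Simulate one plate-reader OD600 curve with additive Gaussian noise
    (truncated at zero)."""
    if mu_max < 0:
        raise ValueError("mu_max must be >= 0")
    od = logistic_od(times, mu_max, lag, carrying_capacity, od0)
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        od = np.clip(od + rng.normal(0.0, noise_sd, size=od.shape), 0.0, None)
    return GrowthCurve(strain_id, condition, replicate, np.asarray(times, float), od)


# ---------------------------------------------------------------------------
# tabular output
# ---------------------------------------------------------------------------


def write_scan_tsv(scan: ArrayScan, path) -> None:
    scan.data.to_csv(path, sep="\t", index=False)


def write_growth_tsv(curves: list[GrowthCurve], path) -> None:
    pd.concat([c.to_frame() for c in curves], ignore_index=True).to_csv(
        path, sep="\t", index=False
    )
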