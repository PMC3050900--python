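"""End-to-end orchestration: simulate/load -> normalize -> call -> cluster ->
GO-enrich -> kinetics screen -> consolidated report.

A single :class:`ScreenConfig` fixes every stage parameter and the global
seed; rerunning with the same config reproduces identical tables. Output
tables carry a provenance header (config hash, seed, package version).
"""

from __future__ import annotations

import hashlib
import io
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from . import castclust, cgh, goterms, kinetics, synthdata
from .synthdata import DEFAULT_STEPS, GrowthCurve, StepSchedule

logger = logging.getLogger(__name__)


@dataclass
class ScenarioConfig:
    """Synthetic-screen generator settings.

    Defaults emulate the study conditions of a pooled genomic-library solvent
    challenge on an E. coli-sized genome: ~4.64 Mb, ~14,000 clones of 2-3 kb
    (~7.5-fold coverage), four challenge transfers plus a solvent-free
    control arm, and a plate-reader validation screen with four biological
    replicates at 0% and 0.5% (v/v) n-butanol.
    """

    genome_length: int = 4_641_652
    n_genes: int = 4300
    mean_gene_length: int = 950
    n_go_terms: int = 50
    n_clones: int = 14_000
    insert_min: int = 2000
    insert_max: int = 3000
    steps: list = field(default_factory=lambda: [list(s) for s in DEFAULT_STEPS])
    # selection truth: tolerance genes confer s > 0 on every clone carrying
    # them in the challenged arm; toxic genes s < 0; control-arm targets
    # model general growth advantage
    n_positive_genes: int = 12
    s_positive: float = 2.5
    n_negative_genes: int = 12
    s_negative: float = -2.5
    n_control_genes: int = 6
    s_control: float = 2.0
    # per-transfer selection compression: fitness differences shrink as the
    # challenge concentration approaches the tolerance ceiling, so most of
    # the competitive sorting happens in the first transfer and enrichment
    # profiles saturate instead of ramping without bound
    step_weights: list = field(default_factory=lambda: [1.0, 0.22, 0.10, 0.05])
    # array model
    array_noise_sd: float = 0.2
    dye_bias: bool = True
    probes_per_gene: int = 2
    background: float = 100.0  # hybridization background floor (intensity units)
    saturation: float = 65535.0  # 16-bit scanner ceiling
    # growth screen
    mu_wt_0: float = 0.6  # 1/h
    wt_tolerance: float = 0.5  # T_wt at 0.5% butanol
    true_iie: float = 40.0  # percent, for genes on positively selected clones
    butanol_pct: float = 0.5
    n_replicates: int = 4
    od_noise_sd: float = 0.005
    lag_h: float = 2.0
    carrying_capacity: float = 1.3
    od0: float = 0.05
    sampling_dt_h: float = 0.25
    duration_h: float = 24.0

    def schedule(self) -> StepSchedule:
        return StepSchedule(steps=[(str(s), float(c)) for s, c in self.steps])


@dataclass
class ScreenConfig:
    """All stage parameters plus the global seed."""

    scenario: ScenarioConfig = field(default_factory=ScenarioConfig)
    seed: int = 0
    alpha_cgh: float = 0.05
    cgh_correction: str = "none"  # the screen's convention: raw p < alpha
    lowess_span: float = 0.3
    cast_threshold: float = 0.8
    go_correction: str = "bh"
    go_propagate: bool = True
    alpha_kinetics: float = 0.05
    od_band: tuple = (0.08, 0.45)  # log-linear fit band; bias cancels in ratios
    min_od: float = 0.02
    blank: float = 0.0
    max_kinetics_genes: int = 60  # cap on candidates sent to the growth screen

    @classmethod
    def from_yaml(cls, path) -> "ScreenConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        scen = ScenarioConfig(**raw.pop("scenario", {}))
        return cls(scenario=scen, **raw)

    def to_yaml(self) -> str:
        return yaml.safe_dump(asdict(self), sort_keys=True)

    @property
    def config_hash(self) -> str:
        return hashlib.sha256(self.to_yaml().encode()).hexdigest()[:12]


@dataclass
class ScreenReport:
    config: ScreenConfig
    genome: synthdata.GenomeAnnotation
    truth: synthdata.ScreenTruth
    true_positive_genes: list[str]
    true_negative_genes: list[str]
    linked_genes: list[str]  # all genes sharing a clone with a selection target
    calls_butanol: pd.DataFrame
    calls_control: pd.DataFrame
    filtered_calls: pd.DataFrame
    enriched_candidates: pd.DataFrame
    depleted_candidates: pd.DataFrame
    clusters: pd.DataFrame
    go_enriched: pd.DataFrame
    go_depleted: pd.DataFrame
    tolerance: pd.DataFrame
    stage_counts: dict

    @property
    def provenance(self) -> dict:
        return {
            "config_hash": self.config.config_hash,
            "seed": self.config.seed,
            "version": __version__,
        }


def genes_hit_by_clones(genome: synthdata.GenomeAnnotation, library, clone_idx) -> list[str]:
    """Gene ids overlapped by any of the given clones (half-open intervals)."""
    rows = library.clones.iloc[np.asarray(list(clone_idx), dtype=int)]
    gs = np.array([g.start for g in genome.genes])
    ge = np.array([g.end for g in genome.genes])
    ids = np.array(genome.gene_ids)
    hit = np.zeros(len(ids), dtype=bool)
    for s, e in zip(rows["start"].to_numpy(), rows["end"].to_numpy()):
        hit |= (gs < e) & (ge > s)
    return sorted(ids[hit])


def _simulate_growth_screen(
    genes: list[str],
    true_iie: dict[str, float],
    cfg: ScreenConfig,
    rng: np.random.Generator,
    mode_by_gene: dict[str, str],
) -> pd.DataFrame:
    """Simulate replicate curves per gene (clone vs wild type) and screen them."""
    sc = cfg.scenario
    times = np.arange(0.0, sc.duration_h + 1e-9, sc.sampling_dt_h)
    fit_kwargs = dict(od_band=tuple(cfg.od_band), min_od=cfg.min_od, blank=cfg.blank)
    rows = []
    for gene in genes:
        iie = true_iie.get(gene, 0.0)
        t_clone = sc.wt_tolerance * (1.0 + iie / 100.0)
        mu = {
            ("wt", 0.0): sc.mu_wt_0,
            ("wt", sc.butanol_pct): sc.mu_wt_0 * sc.wt_tolerance,
            ("clone", 0.0): sc.mu_wt_0,
            ("clone", sc.butanol_pct): sc.mu_wt_0 * t_clone,
        }
        curves: dict[str, list[GrowthCurve]] = {"wt": [], "clone": []}
        for strain in ("wt", "clone"):
            for cond in (0.0, sc.butanol_pct):
                for rep in range(1, sc.n_replicates + 1):
                    curves[strain].append(
                        synthdata.simulate_growth(
                            mu_max=mu[(strain, cond)],
                            lag=sc.lag_h,
                            carrying_capacity=sc.carrying_capacity,
                            times=times,
                            noise_sd=sc.od_noise_sd,
                            seed=int(rng.integers(2**31)),
                            od0=sc.od0,
                            strain_id=gene if strain == "clone" else "WT",
                            condition=cond,
                            replicate=rep,
                        )
                    )
        res = kinetics.screen_gene(
            curves["clone"],
            curves["wt"],
            alpha=cfg.alpha_kinetics,
            gene_id=gene,
            mode=mode_by_gene.get(gene, "overexpression"),
            butanol_condition=sc.butanol_pct,
            **fit_kwargs,
        )
        rows.append(
            {
                "gene_id": res.gene_id,
                "mode": res.mode,
                "true_iie": iie,
                "iie": res.iie,
                "iie_sd": res.iie_sd,
                "rsgr": res.rsgr,
                "rsgr_sd": res.rsgr_sd,
                "p_value": res.p_value,
                "significant": res.significant,
                "n_replicates": res.n_replicates,
            }
        )
    return pd.DataFrame(rows)


def run_pipeline(config: ScreenConfig, outdir: str | Path | None = None) -> ScreenReport:
    """Run the full synthetic screen under one seed and return the report.

    Stages: genome/library/truth generation -> array simulation -> LOWESS
    normalization -> per-gene profiles -> differential calling per arm ->
    control-arm subtraction -> CAST clustering of candidates -> GO enrichment
    of enriched/depleted candidate sets -> growth-kinetics screen of the top
    candidates against generator truth. Any stage failure aborts with the
    stage name.
    """
    sc = config.scenario
    rng = np.random.default_rng(config.seed)
    seeds = {k: int(rng.integers(2**31)) for k in ("genome", "library", "truth", "arrays", "growth")}
    counts: dict = {}

    stage = "synthesize"
    try:
        genome = synthdata.build_genome(
            sc.n_genes, sc.mean_gene_length, sc.genome_length,
            seed=seeds["genome"], n_go_terms=sc.n_go_terms,
        )
        library = synthdata.simulate_library(
            genome, sc.n_clones, (sc.insert_min, sc.insert_max), seed=seeds["library"]
        )
        truth = synthdata.make_screen_truth(
            library,
            genome,
            n_positive_genes=sc.n_positive_genes,
            s_positive=sc.s_positive,
            n_negative_genes=sc.n_negative_genes,
            s_negative=sc.s_negative,
            n_control_genes=sc.n_control_genes,
            s_control=sc.s_control,
            seed=seeds["truth"],
        )
        schedule = sc.schedule()
        scans, probe_map = synthdata.simulate_enrichment(
            library, genome, truth, schedule,
            noise_sd=sc.array_noise_sd,
            dye_bias=synthdata.default_dye_bias() if sc.dye_bias else None,
            seed=seeds["arrays"],
            probes_per_gene=sc.probes_per_gene,
            background=sc.background,
            saturation=sc.saturation,
            step_weights=tuple(sc.step_weights),
        )
        pos_genes = truth.positive_genes
        neg_genes = truth.negative_genes
        linked_genes = genes_hit_by_clones(
            genome, library, np.flatnonzero(truth.selection["butanol"] != 0)
        )
        counts["clones"] = library.n_clones
        counts["coverage_fold"] = round(library.coverage, 3)

        stage = "normalize"
        norm = [cgh.lowess_normalize(s, span=config.lowess_span) for s in scans]

        stage = "profiles"
        profiles = cgh.gene_profiles(norm, probe_map, schedule)

        stage = "differential"
        calls_but = cgh.detect_differential(
            profiles["butanol"], alpha=config.alpha_cgh, correction=config.cgh_correction
        )
        calls_ctl = cgh.detect_differential(
            profiles["control"], alpha=config.alpha_cgh, correction=config.cgh_correction
        )
        filtered = cgh.filter_control(calls_but, calls_ctl)
        enr = cgh.candidates(filtered, cgh.ENRICHED)
        dep = cgh.candidates(filtered, cgh.DEPLETED)
        counts["genes_tested"] = len(calls_but)
        counts["enriched_candidates"] = len(enr)
        counts["depleted_candidates"] = len(dep)
        logger.info(
            "differential: %d genes tested, %d enriched / %d depleted candidates",
            len(calls_but), len(enr), len(dep),
        )

        stage = "cluster"
        cand_ids = sorted(set(enr.index) | set(dep.index))
        if len(cand_ids) >= 2:
            aff = castclust.profile_similarity(profiles["butanol"].loc[cand_ids])
            assign = castclust.cast_cluster(aff, t=config.cast_threshold)
            clusters = assign.assignment.rename("cluster").to_frame()
        else:
            clusters = pd.DataFrame(columns=["cluster"])
        counts["clusters"] = int(clusters["cluster"].nunique()) if len(clusters) else 0

        stage = "go"
        annotation = goterms.GOAnnotation(
            {g.gene_id: set(g.go_terms) for g in genome.genes},
            genome.term_parents,
        )
        population = list(calls_but.index)
        go_enr = goterms.enrich(
            list(enr.index), population, annotation,
            correction=config.go_correction, propagate=config.go_propagate,
        ) if len(enr) else pd.DataFrame()
        go_dep = goterms.enrich(
            list(dep.index), population, annotation,
            correction=config.go_correction, propagate=config.go_propagate,
        ) if len(dep) else pd.DataFrame()

        stage = "kinetics"
        # validation mirrors the wet screen: every CGH candidate is grown
        # individually, so only the genes that truly carry the phenotype
        # (the selection targets, not their insert neighbours) get an effect
        grow_rng = np.random.default_rng(seeds["growth"])
        screen_enr = sorted(enr.index)[: config.max_kinetics_genes]
        screen_dep = sorted(dep.index)[: config.max_kinetics_genes]
        true_iie = {g: sc.true_iie for g in set(pos_genes) | set(neg_genes)}
        mode = {g: "overexpression" for g in screen_enr}
        mode.update({g: "deletion" for g in screen_dep})
        tol = _simulate_growth_screen(
            screen_enr + screen_dep, true_iie, config, grow_rng, mode
        )
        counts["kinetics_genes"] = len(tol)
        counts["kinetics_significant"] = int(tol["significant"].sum()) if len(tol) else 0
    except Exception as exc:
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc

    report = ScreenReport(
        config=config,
        genome=genome,
        truth=truth,
        true_positive_genes=pos_genes,
        true_negative_genes=neg_genes,
        linked_genes=linked_genes,
        calls_butanol=calls_but,
        calls_control=calls_ctl,
        filtered_calls=filtered,
        enriched_candidates=enr,
        depleted_candidates=dep,
        clusters=clusters,
        go_enriched=go_enr,
        go_depleted=go_dep,
        tolerance=tol,
        stage_counts=counts,
    )
    if outdir is not None:
        write_report(report, outdir)
    return report


def _write_table(df: pd.DataFrame, path: Path, provenance: dict) -> None:
    buf = io.StringIO()
    for k, v in provenance.items():
        buf.write(f"# {k}: {v}\n")
    df.to_csv(buf, sep="\t", index=df.index.name is not None)
    path.write_text(buf.getvalue())


def write_report(report: ScreenReport, outdir: str | Path) -> None:
    """Write every report table as TSV with a provenance comment header."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    prov = report.provenance
    tables = {
        "calls_butanol.tsv": report.calls_butanol,
        "calls_control.tsv": report.calls_control,
        "filtered_calls.tsv": report.filtered_calls,
        "enriched_candidates.tsv": report.enriched_candidates,
        "depleted_candidates.tsv": report.depleted_candidates,
        "clusters.tsv": report.clusters,
        "go_enriched.tsv": report.go_enriched,
        "go_depleted.tsv": report.go_depleted,
        "tolerance.tsv": report.tolerance,
    }
    for name, df in tables.items():
        _write_table(df, outdir / name, prov)
    (outdir / "report.yaml").write_text(
        yaml.safe_dump({"provenance": prov, "stage_counts": report.stage_counts})
    )


# ---------------------------------------------------------------------------
# input validation for user-supplied tables
# ---------------------------------------------------------------------------


@dataclass
class ValidationReport:
    errors: list[str] = field(default_factory=list)
    warnings: list[str] = field(default_factory=list)

    @property
    def ok(self) -> bool:
        return not self.errors


def validate_inputs(
    scans: list[synthdata.ArrayScan] | None = None,
    schedule: StepSchedule | None = None,
    growth: pd.DataFrame | None = None,
    expected_replicates: int = 4,
) -> ValidationReport:
    """Validate user-supplied inputs; collects errors and warnings rather
    than raising.

    Checks: scan schema and positivity, step labels against the schedule,
    and replicate counts per strain x condition in a long-format growth
    table (fewer than the four-replicate design is a warning).
    """
    rep = ValidationReport()
    schedule = schedule or StepSchedule()
    if scans is not None:
        labels = set(schedule.labels)
        for s in scans:
            if not {"probe_id", "sample", "reference"} <= set(s.data.columns):
                rep.errors.append(f"scan {s.step}/{s.arm}: missing required columns")
                continue
            if s.step not in labels:
                rep.errors.append(f"scan references unknown step label {s.step!r}")
            if s.arm not in schedule.arms:
                rep.errors.append(f"scan references unknown arm {s.arm!r}")
            n_bad = int(((s.data["sample"] <= 0) | (s.data["reference"] <= 0)).sum())
            if n_bad:
                rep.warnings.append(
                    f"scan {s.step}/{s.arm}: {n_bad} rows with non-positive intensity"
                )
    if growth is not None:
        need = {"strain", "condition", "replicate", "time_h", "od600"}
        if not need <= set(growth.columns):
            rep.errors.append(f"growth table missing columns {sorted(need - set(growth.columns))}")
        else:
            reps = growth.groupby(["strain", "condition"])["replicate"].nunique()
            for (strain, cond), n in reps.items():
                if n < expected_replicates:
                    rep.warnings.append(
                        f"{strain} @ {cond}%: {n} replicates "
                        f"(four-replicate design expected)"
                    )
    return rep


def load_growth_tsv(path) -> list[GrowthCurve]:
    """Read a long-format plate-reader TSV into GrowthCurve objects."""
    df = pd.read_csv(path, sep="\t", comment="#")
    curves = []
    for (strain, cond, rep), grp in df.groupby(["strain", "condition", "replicate"]):
        grp = grp.sort_values("time_h")
        curves.append(
            GrowthCurve(str(strain), float(cond), int(rep),
                        grp["time_h"].to_numpy(), grp["od600"].to_numpy())
        )
    return curves
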