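"""Seeded synthetic-cohort generator.

Produces expression matrices, annotations, DEG lists, survival outcomes and
clinical covariate tables with the statistical structure the analysis
pipeline assumes: a two/three-class cohort (normal / primary / metastatic)
carrying a planted signature — a block of up-shifted kinase-like genes plus
a down-shifted ion-channel-like and a down-shifted tumor-suppressor-like
gene — embedded among independent (and optionally correlated) noise genes.

The default preset mirrors the shape of the discovery cohort the pipeline
targets: 9 planted genes (7 up, 2 down, |shift| = 2 within-class sd) among
78 noise genes, 194 primary + 29 metastatic (+ 29 normal) samples. All draws
flow from a single integer seed through fixed per-stage substreams, so a
regenerated study is bit-identical.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import json

import numpy as np
import pandas as pd

from .data_model import DEGTable, ExpressionMatrix, SampleAnnotation, Scale

__all__ = [
    "GeneSpec",
    "SurvivalSpec",
    "DEGSpec",
    "SimulationConfig",
    "SimulatedStudy",
    "hotpam_like_config",
    "simulate_expression_cohort",
    "simulate_deg_lists",
    "simulate_survival_times",
    "simulate_clinical_covariates",
]

ROLES = ("up_kinase", "down_channel", "down_suppressor", "driver", "noise", "correlated_noise")

# fixed substream tags so toggling one stage never perturbs another's draws
_STREAMS = {"expression": 1, "deg": 2, "survival": 3, "clinical": 4}


def _rng(seed: int, stage: str) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([int(seed), _STREAMS[stage]]))


@dataclass(frozen=True)
class GeneSpec:
    """One planted (or noise) gene: its role, the metastatic-class mean shift
    in within-class sd units, and its within-block correlation."""

    name: str
    role: str
    shift: float = 0.0
    correlation: float = 0.0
    block: int | None = None  # genes sharing a block id share a latent factor

    def __post_init__(self) -> None:
        if self.role not in ROLES:
            raise ValueError(f"unknown role {self.role!r}")


@dataclass(frozen=True)
class SurvivalSpec:
    baseline_hazard: float = 0.02  # events per month
    log_hr: Mapping[str, float] = field(default_factory=dict)  # gene -> beta
    censoring_rate: float = 0.3

    def __post_init__(self) -> None:
        if self.baseline_hazard <= 0:
            raise ValueError("baseline hazard must be positive")
        if not (0 <= self.censoring_rate < 1):
            raise ValueError("censoring rate must be in [0,1)")


@dataclass(frozen=True)
class DEGSpec:
    size_a: int
    size_b: int
    overlap: int
    discordant_fraction: float = 0.0

    def __post_init__(self) -> None:
        if self.overlap > min(self.size_a, self.size_b):
            raise ValueError("overlap exceeds a list size")
        if not (0 <= self.discordant_fraction <= 1):
            raise ValueError("discordant fraction must be in [0,1]")


@dataclass(frozen=True)
class SimulationConfig:
    seed: int = 0
    n_normal: int = 29
    n_primary: int = 194
    n_metastatic: int = 29
    genes: tuple[GeneSpec, ...] = ()
    survival: SurvivalSpec = field(default_factory=SurvivalSpec)
    clinical: Mapping[str, Mapping[str, Mapping[str, float]]] = field(default_factory=dict)
    deg: DEGSpec | None = None
    cohort: str = "synthetic"

    def __post_init__(self) -> None:
        if min(self.n_normal, self.n_primary, self.n_metastatic) < 0:
            raise ValueError("cohort sizes must be >= 0")
        names = [g.name for g in self.genes]
        if len(set(names)) != len(names):
            raise ValueError("duplicate gene names in config")
        for cov, per_class in self.clinical.items():
            for cls, probs in per_class.items():
                if abs(sum(probs.values()) - 1.0) > 1e-9:
                    raise ValueError(f"probabilities for {cov}/{cls} do not sum to 1")


@dataclass(frozen=True)
class SimulatedStudy:
    expression: ExpressionMatrix
    annotation: SampleAnnotation
    truth: dict  # role/shift per gene and every planted parameter
    config: SimulationConfig

    def planted_genes(self) -> list[str]:
        return [g for g, r in self.truth["roles"].items() if r in ("up_kinase", "down_channel", "down_suppressor", "driver")]

    def noise_genes(self) -> list[str]:
        return [g for g, r in self.truth["roles"].items() if r in ("noise", "correlated_noise")]

    def signature_panel(self) -> list[str]:
        """The discovery panel: every gene except the designated driver
        (the driver emulates the regulator itself, which is not part of the
        candidate target list)."""
        return [g for g in self.expression.gene_ids if self.truth["roles"][g] != "driver"]

    def write(self, outdir: str | Path) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        self.expression.to_tsv(outdir / "expression.tsv")
        self.annotation.to_tsv(outdir / "annotation.tsv")
        (outdir / "truth.json").write_text(json.dumps(self.truth, indent=2, sort_keys=True))


# ---------------------------------------------------------------------------


def hotpam_like_config(
    seed: int = 0,
    shift: float = 2.0,
    n_noise: int = 78,
    n_normal: int = 29,
    n_primary: int = 194,
    n_metastatic: int = 29,
    suppressor_driver_corr: float = -0.6,
    survival: SurvivalSpec | None = None,
) -> SimulationConfig:
    """The default stated world: 7 up-shifted kinase-like genes, one
    down-shifted channel-like and one down-shifted suppressor-like gene
    (the suppressor inversely correlated with a driver gene), among
    ``n_noise`` independent noise genes."""
    genes = [GeneSpec(f"KIN{i}", "up_kinase", shift) for i in range(1, 8)]
    genes.append(GeneSpec("CHAN1", "down_channel", -shift))
    genes.append(GeneSpec("SUPP1", "down_suppressor", -shift, correlation=suppressor_driver_corr))
    genes.append(GeneSpec("DRIVER1", "driver", shift))
    genes += [GeneSpec(f"NOISE{i:03d}", "noise") for i in range(1, n_noise + 1)]
    return SimulationConfig(
        seed=seed,
        n_normal=n_normal,
        n_primary=n_primary,
        n_metastatic=n_metastatic,
        genes=tuple(genes),
        survival=survival or SurvivalSpec(log_hr={"KIN2": 0.7}),
        cohort="synthetic",
    )


def simulate_expression_cohort(cfg: SimulationConfig) -> SimulatedStudy:
    """Draw a class-conditional Gaussian expression cohort on the log2 scale.

    Planted genes shift their metastatic-class mean by ``shift`` within-class
    sd units (normals sit at the primary mean). Genes sharing a ``block`` id
    mix in a shared per-sample latent factor at the configured correlation;
    the down-suppressor gene shares the driver gene's within-class noise at
    its (negative) configured correlation.
    """
    if not cfg.genes:
        raise ValueError("config lists no genes")
    rng = _rng(cfg.seed, "expression")
    n = cfg.n_normal + cfg.n_primary + cfg.n_metastatic
    classes = (
        ["normal"] * cfg.n_normal + ["primary"] * cfg.n_primary + ["metastatic"] * cfg.n_metastatic
    )
    sample_ids = [f"S{i:04d}" for i in range(1, n + 1)]
    is_met = np.array([c == "metastatic" for c in classes], float)

    base_level = 8.0  # arbitrary log2 baseline so raw matrices look like arrays
    # block latent factors
    blocks = {g.block for g in cfg.genes if g.block is not None}
    latent = {b: rng.standard_normal(n) for b in sorted(blocks)}
    driver_noise: np.ndarray | None = None
    rows = {}
    # driver noise must be drawn before the suppressor can reuse it; draw all
    # gene noises in config order but generate the driver first if present
    noise_draws = {g.name: rng.standard_normal(n) for g in cfg.genes}
    for g in cfg.genes:
        if g.role == "driver":
            driver_noise = noise_draws[g.name]
    for g in cfg.genes:
        eps = noise_draws[g.name]
        if g.block is not None and g.correlation > 0:
            c = np.sqrt(g.correlation)
            noise = c * latent[g.block] + np.sqrt(1 - g.correlation) * eps
        elif g.role == "down_suppressor" and g.correlation != 0 and driver_noise is not None:
            r = g.correlation
            noise = r * driver_noise + np.sqrt(1 - r**2) * eps
        else:
            noise = eps
        rows[g.name] = base_level + g.shift * is_met + noise
    df = pd.DataFrame(rows).T
    df.columns = sample_ids
    expr = ExpressionMatrix(df.astype(float), Scale.RAW_LOG2)
    ann = SampleAnnotation(
        pd.DataFrame({"cohort": cfg.cohort, "disease_class": classes}, index=sample_ids)
    )
    truth = {
        "seed": cfg.seed,
        "roles": {g.name: g.role for g in cfg.genes},
        "shifts": {g.name: g.shift for g in cfg.genes},
        "correlations": {g.name: g.correlation for g in cfg.genes if g.correlation},
        "classes": {s: c for s, c in zip(sample_ids, classes)},
    }
    return SimulatedStudy(expr, ann, truth, cfg)


def simulate_deg_lists(spec: DEGSpec, seed: int = 0) -> tuple[DEGTable, DEGTable]:
    """Two DEG tables with exact configured sizes, overlap and discordance.

    The overlap contains exactly round(discordant_fraction * overlap) genes
    whose directions disagree between the tables.
    """
    rng = _rng(seed, "deg")
    n_universe = spec.size_a + spec.size_b - spec.overlap
    genes = [f"G{i:05d}" for i in range(1, n_universe + 1)]
    shared = genes[: spec.overlap]
    only_a = genes[spec.overlap : spec.size_a]
    only_b = genes[spec.size_a :]

    def table(names: Sequence[str], directions: Sequence[str]) -> DEGTable:
        mag = np.abs(rng.normal(2.0, 0.5, len(names))) + 0.1
        sign = np.where(np.asarray(directions) == "up", 1.0, -1.0)
        df = pd.DataFrame(
            {
                "log2fc": sign * mag,
                "p_value": 10.0 ** rng.uniform(-12, -2, len(names)),
                "p_adj": np.nan,
                "direction": list(directions),
            },
            index=list(names),
        )
        return DEGTable(df)

    dir_a_shared = rng.choice(["up", "down"], size=spec.overlap)
    n_disc = int(round(spec.discordant_fraction * spec.overlap))
    flip = np.zeros(spec.overlap, bool)
    flip[rng.choice(spec.overlap, size=n_disc, replace=False)] = True
    dir_b_shared = np.where(
        flip, np.where(dir_a_shared == "up", "down", "up"), dir_a_shared
    )
    a = table(
        shared + only_a,
        list(dir_a_shared) + list(rng.choice(["up", "down"], size=len(only_a))),
    )
    b = table(
        shared + only_b,
        list(dir_b_shared) + list(rng.choice(["up", "down"], size=len(only_b))),
    )
    return a, b


def simulate_survival_times(cfg: SimulationConfig, study: SimulatedStudy) -> SampleAnnotation:
    """Attach exponential survival times whose hazard depends on planted genes.

    Per-sample hazard = baseline * exp(sum_g beta_g * z_g) with z the
    standardized expression of each gene in ``survival.log_hr``. Censoring is
    independent exponential, its rate solved so the expected censored
    fraction matches ``censoring_rate``.
    """
    rng = _rng(cfg.seed, "survival")
    spec = cfg.survival
    expr = study.expression.values
    n = expr.shape[1]
    eta = np.zeros(n)
    for gene, beta in spec.log_hr.items():
        if gene not in expr.index:
            raise KeyError(f"survival gene {gene!r} not in simulated matrix")
        v = expr.loc[gene].to_numpy(float)
        eta += beta * (v - v.mean()) / v.std(ddof=1)
    hazard = spec.baseline_hazard * np.exp(eta)
    times = rng.exponential(1.0 / hazard)
    if spec.censoring_rate == 0:
        obs, event = times, np.ones(n, int)
    else:
        target = spec.censoring_rate

        def censored_frac(rate: float) -> float:
            return float(np.mean(rate / (rate + hazard)))

        lo, hi = 1e-9, 1e4
        for _ in range(200):
            mid = np.sqrt(lo * hi)
            if censored_frac(mid) < target:
                lo = mid
            else:
                hi = mid
        cens = rng.exponential(1.0 / mid, size=n)
        obs = np.minimum(times, cens)
        event = (times <= cens).astype(int)
    table = study.annotation.table.copy()
    table["os_time"] = np.maximum(obs, 1e-6)
    table["os_event"] = event
    return SampleAnnotation(table)


def simulate_clinical_covariates(cfg: SimulationConfig, study: SimulatedStudy) -> SampleAnnotation:
    """Draw class-conditional categorical covariates per the clinical spec.

    ``cfg.clinical`` maps covariate -> disease class -> {category: prob};
    categories are drawn independently per sample. Classes absent from a
    covariate's spec get NA.
    """
    rng = _rng(cfg.seed, "clinical")
    table = study.annotation.table.copy()
    classes = table["disease_class"]
    for cov, per_class in cfg.clinical.items():
        col = pd.Series(pd.NA, index=table.index, dtype=object)
        for cls, probs in per_class.items():
            idx = classes.index[classes == cls]
            cats = list(probs.keys())
            p = np.array([probs[c] for c in cats], float)
            col.loc[idx] = rng.choice(cats, size=len(idx), p=p)
        table[cov] = col
    return SampleAnnotation(table)
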