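"""Synthetic peptide-array kinome profiling and organoid drug-screen data.

Emulates the data produced by a tyrosine-kinase peptide microarray run
(saturating phosphorylation kinetics read out as Lux over time, in technical
triplicate, ~144 substrate peptides across ~8 organoid lines) together with a
many-to-many peptide -> upstream-kinase annotation, a kinase-gene expression
matrix with tunable rank correlation to kinase activity, and a drug-screen
plate (treated wells, vehicle-control wells, ATP standard-curve wells).

Every generated quantity derives from an explicit ground truth
(:class:`GroundTruth`) so downstream estimators can be scored against planted
structure. All randomness flows through a single seed; identical
(config, seed) pairs produce byte-identical tables.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

__all__ = [
    "SimulationConfig",
    "GroundTruth",
    "generate_kinome_dataset",
    "generate_expression",
    "generate_drug_screen",
    "atp_dilution_series",
    "write_dataset",
]

#: default group layout: three tumor lines, two matched adjacent lines,
#: three healthy-donor lines
DEFAULT_GROUPS = ("tumor",) * 3 + ("adjacent",) * 2 + ("healthy",) * 3

INTERNAL_CONTROL_ID = "ART_003_EAI(pY)AAPFAKKKXC"
NORMALIZATION_CONTROL_ID = "CD79A_181_193"


class ConfigurationError(ValueError):
    """Raised when a simulation configuration is internally inconsistent."""


@dataclass
class SimulationConfig:
    """Parameters of the synthetic kinome / drug-screen study.

    The defaults mirror the array design the package targets: 144 substrate
    peptides (including one internal positive control and one normalization
    control), 37 upstream kinases, 3 technical replicates, and an 8-line
    panel of tumor / adjacent / healthy organoids.
    """

    n_samples: int = 8
    group_labels: tuple[str, ...] | None = None
    n_peptides: int = 144
    n_kinases: int = 37
    n_replicates: int = 3
    #: seconds; must span at least [640, 1840]
    timepoints: tuple[float, ...] = tuple(range(40, 1841, 60))
    #: multiplicative Lux noise, coefficient of variation per (replicate, t)
    noise_cv: float = 0.1
    #: additive sensor-noise SD in Lux; lets near-zero signals dip negative
    noise_floor_lux: float = 2.0
    #: kinase -> (group_hi, group_lo, fold) applied to kinase activity
    planted_fold_changes: dict[str, tuple[str, str, float]] = field(default_factory=dict)
    control_peptide_id: str = NORMALIZATION_CONTROL_ID
    internal_control_id: str = INTERNAL_CONTROL_ID
    #: target rank correlation between kinase activity and gene expression
    rna_activity_correlation: float = 0.0
    #: drug -> (target kinase, effect size beta); beta=inf gives a hard kill
    drug_target_effects: dict[str, tuple[str, float]] = field(default_factory=dict)
    vehicle_cv: float = 0.05
    seed: int = 0
    #: fraction of regular peptides with no annotated upstream kinase
    orphan_fraction: float = 0.05
    #: "saturating" S_max(1-e^{-rt}) or "linear" S_max*r*t (AUC exactly
    #: proportional to rate; used for exactness contracts)
    kinetic_law: str = "saturating"
    #: baseline phosphorylation rate in 1/s at unit kinase activity; the
    #: default keeps the 640-1840 s window in the early, near-linear part of
    #: the saturating curve so activity ratios survive into AUC ratios
    rate_scale: float = 1.5e-5
    #: lognormal sigma of per-sample kinase-activity variation
    activity_cv: float = 0.2
    #: inclusive bounds on kinases annotated per peptide; beyond the first,
    #: each extra kinase is added with probability ``extra_kinase_prob``
    kinases_per_peptide: tuple[int, int] = (1, 3)
    #: probability of each additional (minor) upstream kinase per peptide
    extra_kinase_prob: float = 0.2
    doses_um: tuple[float, ...] = (1.0, 10.0)
    n_treated_wells: int = 3
    n_vehicle_wells: int = 6
    vehicle_mean_rlu: float = 1e5
    atp_slope_rlu_per_um: float = 5000.0

    def __post_init__(self) -> None:
        if self.group_labels is None:
            if self.n_samples == len(DEFAULT_GROUPS):
                self.group_labels = DEFAULT_GROUPS
            else:
                # round-robin over the three canonical groups
                self.group_labels = tuple(
                    ("tumor", "adjacent", "healthy")[i % 3] for i in range(self.n_samples)
                )
        self.group_labels = tuple(self.group_labels)
        self.timepoints = tuple(float(t) for t in self.timepoints)
        self.validate()

    def validate(self) -> None:
        t = np.asarray(self.timepoints, dtype=float)
        if len(t) < 2 or np.any(np.diff(t) <= 0):
            raise ConfigurationError("timepoints must be strictly increasing")
        if np.sum((t >= 640.0) & (t <= 1840.0)) < 2:
            raise ConfigurationError("need at least 2 timepoints inside [640, 1840] s")
        if self.noise_cv < 0:
            raise ConfigurationError("noise_cv must be >= 0")
        if self.n_replicates < 1:
            raise ConfigurationError("n_replicates must be >= 1")
        if len(self.group_labels) != self.n_samples:
            raise ConfigurationError(
                f"group_labels has {len(self.group_labels)} entries for {self.n_samples} samples"
            )
        if not -1.0 <= self.rna_activity_correlation <= 1.0:
            raise ConfigurationError("rna_activity_correlation must lie in [-1, 1]")
        if self.n_peptides < 3:
            raise ConfigurationError("need at least 3 peptides (2 controls + 1 substrate)")
        if self.kinetic_law not in ("saturating", "linear"):
            raise ConfigurationError(f"unknown kinetic_law {self.kinetic_law!r}")
        lo, hi = self.kinases_per_peptide
        if not (1 <= lo <= hi <= self.n_kinases):
            raise ConfigurationError("kinases_per_peptide range invalid")
        kin = set(self.kinase_names())
        for k in self.planted_fold_changes:
            if k not in kin:
                raise ConfigurationError(f"planted kinase {k!r} not in the simulated kinome")
        groups = set(self.group_labels)
        for k, (ga, gb, fold) in self.planted_fold_changes.items():
            if ga not in groups or gb not in groups:
                raise ConfigurationError(f"planted groups for {k!r} not among sample groups")
            if fold <= 0:
                raise ConfigurationError("planted fold must be positive")
        for d, (k, _beta) in self.drug_target_effects.items():
            if k not in kin:
                raise ConfigurationError(f"drug {d!r} targets unknown kinase {k!r}")

    # -- deterministic naming -------------------------------------------------
    def sample_names(self) -> list[str]:
        counts: dict[str, int] = {}
        names = []
        for g in self.group_labels:
            counts[g] = counts.get(g, 0) + 1
            names.append(f"{g}{counts[g]}")
        return names

    def kinase_names(self) -> list[str]:
        return [f"KIN{i + 1:02d}" for i in range(self.n_kinases)]

    def peptide_names(self) -> list[str]:
        n_regular = self.n_peptides - 2
        regular = [f"PEP{i + 1:03d}" for i in range(n_regular)]
        return [self.control_peptide_id, self.internal_control_id] + regular

    def to_yaml(self, path: str | Path) -> None:
        d = asdict(self)
        d["group_labels"] = list(d["group_labels"])
        d["timepoints"] = list(d["timepoints"])
        d["doses_um"] = list(d["doses_um"])
        d["kinases_per_peptide"] = list(d["kinases_per_peptide"])
        d["planted_fold_changes"] = {k: list(v) for k, v in d["planted_fold_changes"].items()}
        d["drug_target_effects"] = {k: list(v) for k, v in d["drug_target_effects"].items()}
        Path(path).write_text(yaml.safe_dump(d, sort_keys=True))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "SimulationConfig":
        d = yaml.safe_load(Path(path).read_text())
        for key in ("group_labels", "timepoints", "doses_um", "kinases_per_peptide"):
            if key in d and d[key] is not None:
                d[key] = tuple(d[key])
        for key in ("planted_fold_changes", "drug_target_effects"):
            if key in d and d[key] is not None:
                d[key] = {k: tuple(v) for k, v in d[key].items()}
        return cls(**d)


@dataclass
class GroundTruth:
    """Planted structure underlying one simulated dataset."""

    #: samples x kinases, nonnegative activity a[s, k]
    kinase_activity: pd.DataFrame
    #: peptides x kinases, nonnegative weights w[p, k]; rows of regular peptides
    peptide_weights: pd.DataFrame
    #: drug -> (kinase, beta)
    true_drug_links: dict[str, tuple[str, float]]
    #: samples x peptides phosphorylation rate in 1/s (controls included)
    rates: pd.DataFrame
    orphan_peptides: list[str]
    sample_groups: dict[str, str]


def _driving_rates(config: SimulationConfig, rng: np.random.Generator):
    """Draw kinase activities and peptide weights; return (activity, weights, rates)."""
    samples = config.sample_names()
    kinases = config.kinase_names()
    peptides = config.peptide_names()
    n_regular = config.n_peptides - 2

    base = rng.lognormal(mean=0.0, sigma=0.5, size=config.n_kinases)
    a = base[None, :] * rng.lognormal(
        mean=0.0, sigma=config.activity_cv, size=(config.n_samples, config.n_kinases)
    )
    groups = np.asarray(config.group_labels)
    for kin, (g_hi, _g_lo, fold) in config.planted_fold_changes.items():
        a[groups == g_hi, kinases.index(kin)] *= fold
    activity = pd.DataFrame(a, index=samples, columns=kinases)

    n_orphans = int(math.floor(config.orphan_fraction * n_regular))
    # orphans are drawn from the peptides beyond the first n_kinases, so every
    # kinase keeps at least one annotated member peptide
    eligible = np.arange(min(config.n_kinases, n_regular), n_regular)
    n_orphans = min(n_orphans, len(eligible))
    orphan_idx = set(rng.choice(eligible, size=n_orphans, replace=False).tolist())

    w = np.zeros((n_regular, config.n_kinases))
    lo, hi = config.kinases_per_peptide
    for p in range(n_regular):
        if p in orphan_idx:
            continue
        n_k = lo
        while n_k < hi and rng.random() < config.extra_kinase_prob:
            n_k += 1
        if p < config.n_kinases:
            # guarantee every kinase at least one member peptide
            chosen = [p]
            others = [k for k in range(config.n_kinases) if k != p]
            extra = rng.choice(others, size=n_k - 1, replace=False) if n_k > 1 else []
            chosen = np.array(chosen + list(extra))
        else:
            chosen = rng.choice(config.n_kinases, size=n_k, replace=False)
        if len(chosen) == 1:
            w[p, chosen] = 1.0
        else:
            # one dominant upstream kinase per peptide, minor contributions
            # from the others
            primary_w = rng.uniform(0.85, 0.97)
            rest = rng.dirichlet(np.ones(len(chosen) - 1)) * (1.0 - primary_w)
            w[p, chosen[0]] = primary_w
            w[p, chosen[1:]] = rest
    regular_names = peptides[2:]
    weights = pd.DataFrame(w, index=regular_names, columns=kinases)

    rates = np.empty((config.n_samples, config.n_peptides))
    rates[:, 0] = config.rate_scale  # normalization control: constant across samples
    rates[:, 1] = 5.0 * config.rate_scale  # internal positive control, strong & constant
    rates[:, 2:] = config.rate_scale * (a @ w.T)
    rates_df = pd.DataFrame(rates, index=samples, columns=peptides)
    orphans = [regular_names[p] for p in sorted(orphan_idx)]
    return activity, weights, rates_df, orphans


def generate_kinome_dataset(
    config: SimulationConfig,
) -> tuple[pd.DataFrame, pd.DataFrame, GroundTruth]:
    """Simulate one kinome-profiling run.

    Returns ``(signals, annotation, truth)`` where ``signals`` is the long
    kinetic table (sample_id, peptide_id, replicate, time_s, signal_lux),
    ``annotation`` maps peptides to upstream kinases, and ``truth`` carries
    the planted activities/weights.

    The noise-free signal follows ``S_max * (1 - exp(-rate * t))`` with
    ``rate[s, p] = rate_scale * sum_k w[p, k] * a[s, k]`` (or the linear law
    ``S_max * rate * t`` when ``kinetic_law == "linear"``); each observed well
    is perturbed multiplicatively by Normal(0, noise_cv) and additively by
    Normal(0, noise_floor_lux).
    """
    rng = np.random.default_rng(config.seed)
    activity, weights, rates, orphans = _driving_rates(config, rng)
    samples = config.sample_names()
    peptides = config.peptide_names()
    t = np.asarray(config.timepoints)

    s_max = rng.lognormal(mean=math.log(800.0), sigma=0.3, size=config.n_peptides)
    r = rates.to_numpy()[:, :, None]  # (S, P, 1)
    if config.kinetic_law == "saturating":
        clean = s_max[None, :, None] * (1.0 - np.exp(-r * t[None, None, :]))
    else:
        clean = s_max[None, :, None] * r * t[None, None, :]
    shape = (config.n_samples, config.n_peptides, config.n_replicates, len(t))
    signal = clean[:, :, None, :] * np.ones(shape)
    if config.noise_cv > 0:
        signal = signal * (1.0 + rng.normal(0.0, config.noise_cv, size=shape))
    if config.noise_floor_lux > 0:
        signal = signal + rng.normal(0.0, config.noise_floor_lux, size=shape)

    idx = pd.MultiIndex.from_product(
        [samples, peptides, range(1, config.n_replicates + 1), t],
        names=["sample_id", "peptide_id", "replicate", "time_s"],
    )
    signals = idx.to_frame(index=False)
    signals["signal_lux"] = signal.reshape(-1)

    ann_rows = []
    for pep in weights.index:
        for j, kin in enumerate(weights.columns):
            if weights.at[pep, kin] > 0:
                ann_rows.append((pep, kin, f"Y{100 + j}"))
    annotation = pd.DataFrame(ann_rows, columns=["peptide_id", "kinase", "site"])

    truth = GroundTruth(
        kinase_activity=activity,
        peptide_weights=weights,
        true_drug_links=dict(config.drug_target_effects),
        rates=rates,
        orphan_peptides=orphans,
        sample_groups=dict(zip(samples, config.group_labels)),
    )
    return signals, annotation, truth


def generate_expression(truth: GroundTruth, config: SimulationConfig) -> pd.DataFrame:
    """Kinase-gene expression (genes x samples) with tunable coupling to activity.

    ``rna_activity_correlation`` of +1 returns expression identical to the
    activity (Pearson r = 1 within every line); -1 returns a decreasing affine
    transform; intermediate values use a Gaussian-copula mix on per-kinase
    standardized activity, exponentiated onto a nonnegative counts-like scale.
    At 0 the expression is generated independently of activity.
    """
    rho = config.rna_activity_correlation
    a = truth.kinase_activity  # samples x kinases
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 7_919]))
    if rho == 1.0:
        expr = a.T.copy()
    elif rho == -1.0:
        expr = (float(a.to_numpy().max()) * 1.05 - a).T
    else:
        vals = a.to_numpy()
        mu = vals.mean(axis=0, keepdims=True)
        sd = vals.std(axis=0, ddof=0, keepdims=True)
        sd[sd == 0] = 1.0
        z_a = (vals - mu) / sd
        eps = rng.normal(size=vals.shape)
        z_e = rho * z_a + math.sqrt(1.0 - rho**2) * eps
        gene_base = rng.lognormal(mean=math.log(100.0), sigma=1.0, size=vals.shape[1])
        expr = pd.DataFrame(
            (gene_base[None, :] * np.exp(0.5 * z_e)).T, index=a.columns, columns=a.index
        )
    expr.index.name = "gene"
    return expr


def atp_dilution_series(top_um: float = 20.0, factor: float = 4.0, n: int = 7) -> np.ndarray:
    """Concentrations of a serial dilution: 20, 5, 1.25, ... µM (n points)."""
    return top_um / factor ** np.arange(n)


def _sigmoid_response(z: np.ndarray, beta: float) -> np.ndarray:
    if math.isinf(beta):
        out = np.where(z > 0, 1.0, 0.0)
        out[z == 0] = 0.5
        return out
    return 1.0 / (1.0 + np.exp(-beta * z))


def generate_drug_screen(truth: GroundTruth, config: SimulationConfig) -> pd.DataFrame:
    """Simulate a viability drug screen linked to planted kinase activities.

    Per drug, the true response (0..1) at the top dose is a logistic function
    of the standardized activity of the drug's target kinase; lower doses
    scale the response by dose/max(dose). Treated wells emit
    ``(1 - response) * vehicle_mean`` luminescence with multiplicative
    vehicle-level noise; vehicle wells and a 4x ATP dilution series
    (20 µM down to ~4.9 nM) are emitted per sample.
    """
    if not config.drug_target_effects:
        raise ConfigurationError("drug_target_effects is empty")
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 104_729]))
    samples = list(truth.kinase_activity.index)
    rows: list[tuple] = []
    max_dose = max(config.doses_um)

    for drug, (kin, beta) in config.drug_target_effects.items():
        act = truth.kinase_activity[kin].to_numpy()
        sd = act.std(ddof=0)
        z = (act - act.mean()) / sd if sd > 0 else np.zeros_like(act)
        top_response = np.clip(_sigmoid_response(z, beta), 0.0, 1.0)
        for dose in config.doses_um:
            response = top_response * (dose / max_dose)
            for s, resp in zip(samples, response):
                base = (1.0 - resp) * config.vehicle_mean_rlu
                for _ in range(config.n_treated_wells):
                    eta = rng.normal(0.0, config.vehicle_cv) if config.vehicle_cv > 0 else 0.0
                    rows.append(("treated", drug, dose, s, np.nan, base * (1.0 + eta)))
    for s in samples:
        for _ in range(config.n_vehicle_wells):
            rlu = rng.normal(config.vehicle_mean_rlu, config.vehicle_cv * config.vehicle_mean_rlu)
            rows.append(("vehicle", "", np.nan, s, np.nan, rlu))
        for conc in atp_dilution_series():
            eta = rng.normal(0.0, config.vehicle_cv) if config.vehicle_cv > 0 else 0.0
            rlu = config.atp_slope_rlu_per_um * conc * (1.0 + eta)
            rows.append(("standard", "", np.nan, s, conc, rlu))
    return pd.DataFrame(
        rows, columns=["well_type", "drug", "dose_um", "sample_id", "conc_um", "rlu"]
    )


FLOAT_FMT = "%.10g"


def write_dataset(
    outdir: str | Path,
    config: SimulationConfig,
    signals: pd.DataFrame,
    annotation: pd.DataFrame,
    truth: GroundTruth,
    expression: pd.DataFrame | None = None,
    drug_screen: pd.DataFrame | None = None,
) -> dict[str, str]:
    """Write all tables as TSV (+ config YAML); returns name -> path map."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths: dict[str, str] = {}

    def _tsv(name: str, df: pd.DataFrame, index: bool) -> None:
        p = outdir / name
        df.to_csv(p, sep="\t", index=index, float_format=FLOAT_FMT)
        paths[name] = str(p)

    _tsv("signals.tsv", signals, index=False)
    _tsv("annotation.tsv", annotation, index=False)
    _tsv("truth_activity.tsv", truth.kinase_activity.rename_axis("sample_id"), index=True)
    _tsv("truth_weights.tsv", truth.peptide_weights.rename_axis("peptide_id"), index=True)
    links = pd.DataFrame(
        [(d, k, b) for d, (k, b) in truth.true_drug_links.items()],
        columns=["drug", "kinase", "beta"],
    )
    _tsv("truth_links.tsv", links, index=False)
    if expression is not None:
        _tsv("expression.tsv", expression, index=True)
    if drug_screen is not None:
        _tsv("drug_screen.tsv", drug_screen, index=False)
    cfg_path = outdir / "config.yaml"
    config.to_yaml(cfg_path)
    paths["config.yaml"] = str(cfg_path)
    return paths
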