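"""End-to-end workbench: configuration, staged pipeline run, fixtures.

`run_pipeline` chains signal preprocessing -> kinase aggregation ->
differential analysis -> (optional) RNA correlation -> (optional) drug
screen -> (optional) biomarker correlation, writing every stage's tables as
TSV and a JSON manifest (config hash, seed, per-stage row counts). All
output is deterministic: rerunning with identical inputs is byte-identical.
"""

from __future__ import annotations

import hashlib
import json
import re
from dataclasses import dataclass, field, asdict
from pathlib import Path

import pandas as pd
import yaml

from . import annotation as ann_mod
from . import biomarker, differential, drugscreen, kinetics, rna, simulate

__all__ = ["RunConfig", "run_pipeline", "make_fixture"]

FLOAT_FMT = simulate.FLOAT_FMT


@dataclass
class RunConfig:
    signals: str
    annotation: str
    outdir: str
    expression: str | None = None
    drug_plates: str | None = None
    internal_control: str = simulate.INTERNAL_CONTROL_ID
    normalization_control: str = simulate.NORMALIZATION_CONTROL_ID
    auc_window: tuple[float, float] = kinetics.AUC_WINDOW
    fc_threshold: float = 2.0
    analysis_dose_um: float = drugscreen.ANALYSIS_DOSE_UM
    alpha: float = 0.05
    fdr_family: str = "per_drug"
    viability_metric: str = "atp"
    #: group label -> sample ids; inferred from sample-name prefixes if empty
    groups: dict[str, list[str]] = field(default_factory=dict)
    #: the two group labels contrasted by fold change
    fc_contrast: tuple[str, str] = ("tumor", "healthy")
    seed: int = 0

    def validate(self) -> None:
        t0, t1 = self.auc_window
        if not t0 < t1:
            raise ValueError("auc_window must satisfy t0 < t1")
        for name in ("signals", "annotation", "expression", "drug_plates"):
            p = getattr(self, name)
            if p is not None and not Path(p).exists():
                raise FileNotFoundError(f"{name} file not found: {p}")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        d = yaml.safe_load(Path(path).read_text())
        if "auc_window" in d:
            d["auc_window"] = tuple(d["auc_window"])
        if "fc_contrast" in d:
            d["fc_contrast"] = tuple(d["fc_contrast"])
        return cls(**d)


def _infer_groups(samples: list[str]) -> dict[str, list[str]]:
    groups: dict[str, list[str]] = {}
    for s in samples:
        label = re.sub(r"\d+$", "", str(s)) or str(s)
        groups.setdefault(label, []).append(s)
    return groups


def _input_hash(config: RunConfig) -> str:
    h = hashlib.sha256()
    settings = asdict(config)
    settings.pop("outdir")  # where output lands is not an input
    h.update(json.dumps(settings, sort_keys=True, default=str).encode())
    for name in ("signals", "annotation", "expression", "drug_plates"):
        p = getattr(config, name)
        if p is not None:
            h.update(Path(p).read_bytes())
    return h.hexdigest()


def _write(df: pd.DataFrame, path: Path, index: bool) -> None:
    df.to_csv(path, sep="\t", index=index, float_format=FLOAT_FMT)


def run_pipeline(config: RunConfig) -> dict:
    """Execute all stages; returns (and writes) the run manifest."""
    config.validate()
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "config_hash": _input_hash(config),
        "seed": config.seed,
        "stages": {},
    }

    def stage(name: str, **info) -> None:
        manifest["stages"][name] = info

    # 1. preprocess ---------------------------------------------------------
    table = kinetics.read_signal_table(config.signals)
    pre = kinetics.preprocess(
        table,
        internal_control=config.internal_control,
        normalization_control=config.normalization_control,
        window=config.auc_window,
    )
    _write(pre.activity.rename_axis("sample_id"), outdir / "activity.tsv", True)
    (outdir / "preprocess_report.json").write_text(
        json.dumps(pre.report(), sort_keys=True, indent=1)
    )
    stage("preprocess", n_samples=int(pre.activity.shape[0]), n_peptides=int(pre.activity.shape[1]))

    # 2. kinase aggregation -------------------------------------------------
    annotation = ann_mod.read_annotation(config.annotation)
    kin_act, support = ann_mod.kinase_activity(pre.activity, annotation)
    _write(kin_act.rename_axis("sample_id"), outdir / "kinase_activity.tsv", True)
    (outdir / "kinase_support.json").write_text(
        json.dumps(support.to_dict(), sort_keys=True, indent=1)
    )
    stage("annotate", n_kinases=int(kin_act.shape[1]))

    # 3. differential -------------------------------------------------------
    groups = config.groups or _infer_groups(list(pre.activity.index))
    ga_label, gb_label = config.fc_contrast
    if ga_label in groups and gb_label in groups:
        fc = differential.kinase_fold_change(
            pre.activity,
            annotation,
            groups[ga_label],
            groups[gb_label],
            threshold=config.fc_threshold,
            label_a=ga_label,
            label_b=gb_label,
        )
        _write(fc, outdir / "fold_changes.tsv", False)
        n_above = int(fc["above_threshold"].sum())
    else:
        fc, n_above = None, 0
    h_stat, p_kw = differential.kruskal_wallis_samples(pre.activity)
    coords, evr, _ = differential.pca_samples(pre.activity)
    _write(coords.rename_axis("sample_id"), outdir / "pca_coordinates.tsv", True)
    labels, cstats = differential.classify_peptides(pre.activity)
    _write(labels.rename_axis("peptide_id").to_frame(), outdir / "peptide_classes.tsv", True)
    stage(
        "differential",
        kruskal_wallis_H=round(h_stat, 9),
        kruskal_wallis_p=float(f"{p_kw:.6g}"),
        n_fold_changes_above_threshold=n_above,
        pc1_explained=round(float(evr[0]), 9),
    )

    # 4. RNA integration ----------------------------------------------------
    if config.expression is not None:
        expr = rna.read_expression(config.expression)
        corr = rna.correlate_per_line(kin_act, expr)
        _write(corr, outdir / "rna_correlation.tsv", False)
        stage("rna_integration", n_lines=int(len(corr)))
    else:
        stage("rna_integration", skipped="no expression matrix provided")

    # 5 & 6. drug screen + biomarker correlation ----------------------------
    if config.drug_plates is not None:
        plates = pd.read_csv(config.drug_plates, sep="\t")
        tumor = groups.get("tumor", [])
        nontumor = [s for g, ss in groups.items() if g != "tumor" for s in ss]
        screen = drugscreen.process_drug_screen(
            plates,
            dose_um=config.analysis_dose_um,
            metric=config.viability_metric,
            tumor_samples=tumor or None,
            nontumor_samples=nontumor or None,
        )
        _write(screen.viability, outdir / "viability.tsv", True)
        _write(screen.response, outdir / "response.tsv", True)
        _write(screen.effective, outdir / "efficacy_calls.tsv", True)
        if not screen.classification.empty:
            _write(screen.classification, outdir / "drug_classes.tsv", True)
        stage("drug_screen", n_drugs=int(screen.viability.shape[0]), dose_um=config.analysis_dose_um)

        corr = biomarker.screen_drug_peptides(
            screen.response, pre.activity, alpha=config.alpha, family=config.fdr_family
        )
        _write(corr, outdir / "biomarker_correlations.tsv", False)
        stage(
            "biomarker_correlation",
            n_pairs=int(len(corr)),
            n_significant=int(corr["significant"].sum()),
        )
    else:
        stage("drug_screen", skipped="no drug plates provided")
        stage("biomarker_correlation", skipped="no drug plates provided")

    (outdir / "manifest.json").write_text(json.dumps(manifest, sort_keys=True, indent=1))
    return manifest


def make_fixture(outdir: str | Path, size: str = "tiny", seed: int = 0) -> dict[str, str]:
    """Write a complete synthetic input set (plus ground truth) to ``outdir``.

    ``tiny`` (12 peptides / 4 kinases / 4 samples / 3 drugs) runs in well
    under a second; ``paper_scale`` mirrors the full array design
    (144 peptides, 37 kinases, 8 organoid lines, 37 drugs).
    """
    if size == "tiny":
        cfg = simulate.SimulationConfig(
            n_samples=4,
            group_labels=("tumor", "tumor", "healthy", "healthy"),
            n_peptides=12,
            n_kinases=4,
            timepoints=tuple(range(40, 1841, 120)),
            planted_fold_changes={"KIN01": ("tumor", "healthy", 4.0)},
            drug_target_effects={
                "DRUG01": ("KIN01", 4.0),
                "DRUG02": ("KIN02", 4.0),
                "DRUG03": ("KIN03", 0.0),
            },
            seed=seed,
        )
    elif size == "paper_scale":
        targets = {}
        for i in range(37):
            kin = f"KIN{(i % 37) + 1:02d}"
            beta = 4.0 if i % 3 else 0.0  # a third of the panel has no real target link
            targets[f"DRUG{i + 1:02d}"] = (kin, beta)
        cfg = simulate.SimulationConfig(
            planted_fold_changes={
                "KIN01": ("tumor", "healthy", 4.0),
                "KIN05": ("tumor", "adjacent", 4.0),
            },
            drug_target_effects=targets,
            seed=seed,
        )
    else:
        raise ValueError(f"unknown fixture size {size!r}")
    signals, annotation, truth = simulate.generate_kinome_dataset(cfg)
    expression = simulate.generate_expression(truth, cfg)
    screen = simulate.generate_drug_screen(truth, cfg)
    return simulate.write_dataset(
        outdir, cfg, signals, annotation, truth, expression=expression, drug_screen=screen
    )
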