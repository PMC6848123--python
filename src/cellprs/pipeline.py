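"""Stage orchestration: configuration, manifests, and artifact flow.

Each stage reads its upstream artifacts from the output directory, writes its
own outputs plus a manifest recording the config hash, the seed and the
SHA-256 of every input and output.  A stage whose manifest still matches is a
no-op unless forced, so re-running ``all`` on an unchanged configuration is
cheap and reproducible down to the byte.
"""
from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import io as cio
from .assoc import AssocConfig, threshold_scan
from .genoqc import QCConfig, run_qc
from .phenoprep import ks_normality, volume_change
from .scoring import ScoringConfig, score_gene_sets
from .simdata import SimConfig, simulate_cohort

logger = logging.getLogger(__name__)

STAGES = ("simulate", "qc", "score", "prepare", "associate", "report")

GENE_SET_LABELS = ("Rad", "OPC", "Oli")


class ConfigError(ValueError):
    """A configuration document failed schema validation."""


class MissingArtifactError(FileNotFoundError):
    """An upstream artifact is absent; the message names the producing stage."""


@dataclass(frozen=True)
class PipelineConfig:
    """Top-level configuration: a seed plus one section per stage."""

    seed: int = 0
    sim: SimConfig = SimConfig()
    qc: QCConfig = QCConfig()
    scoring: ScoringConfig = ScoringConfig()
    assoc: AssocConfig = AssocConfig()

    @classmethod
    def from_dict(cls, raw: dict) -> "PipelineConfig":
        known = {"seed", "sim", "qc", "scoring", "assoc"}
        unknown = set(raw) - known
        if unknown:
            raise ConfigError(f"unknown configuration key(s): {sorted(unknown)}")
        sections = {}
        for name, section_cls in (
            ("sim", SimConfig), ("qc", QCConfig),
            ("scoring", ScoringConfig), ("assoc", AssocConfig),
        ):
            payload = raw.get(name, {}) or {}
            if not isinstance(payload, dict):
                raise ConfigError(f"section '{name}' must be a mapping")
            valid = {f.name for f in dataclasses.fields(section_cls)}
            bad = set(payload) - valid
            if bad:
                raise ConfigError(
                    f"unknown key(s) in section '{name}': {sorted(bad)}"
                )
            # YAML lists arrive as lists; the configs expect tuples
            payload = {
                k: tuple(v) if isinstance(v, list) else v for k, v in payload.items()
            }
            try:
                sections[name] = section_cls(**payload)
            except (TypeError, ValueError) as exc:
                raise ConfigError(f"invalid section '{name}': {exc}") from exc
        seed = raw.get("seed", 0)
        if not isinstance(seed, int):
            raise ConfigError("key 'seed' must be an integer")
        return cls(seed=seed, **sections)

    def to_dict(self) -> dict:
        return {
            "seed": self.seed,
            "sim": dataclasses.asdict(self.sim),
            "qc": dataclasses.asdict(self.qc),
            "scoring": dataclasses.asdict(self.scoring),
            "assoc": dataclasses.asdict(self.assoc),
        }

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        if not isinstance(raw, dict):
            raise ConfigError("configuration document must be a mapping")
        return cls.from_dict(raw)

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))

    def config_hash(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()

    def with_seed(self, seed: int) -> "PipelineConfig":
        return replace(
            self,
            seed=seed,
            sim=replace(self.sim, seed=seed),
            assoc=replace(self.assoc, seed=(seed + 1) % (2**31)),
        )


# ------------------------------------------------------------- manifests

def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _manifest_path(outdir: Path, stage: str) -> Path:
    return outdir / f"{stage}.manifest.json"


def _write_manifest(outdir: Path, stage: str, cfg: PipelineConfig,
                    inputs: list[Path], outputs: list[Path]) -> None:
    payload = {
        "stage": stage,
        "config_hash": cfg.config_hash(),
        "seed": cfg.seed,
        "inputs": {p.name: _sha256(p) for p in inputs},
        "outputs": {p.name: _sha256(p) for p in outputs},
    }
    _manifest_path(outdir, stage).write_text(
        json.dumps(payload, indent=1, sort_keys=True)
    )


def _up_to_date(outdir: Path, stage: str, cfg: PipelineConfig,
                inputs: list[Path]) -> bool:
    mpath = _manifest_path(outdir, stage)
    if not mpath.exists():
        return False
    try:
        manifest = json.loads(mpath.read_text())
    except json.JSONDecodeError:
        return False
    if manifest.get("config_hash") != cfg.config_hash():
        return False
    if manifest.get("seed") != cfg.seed:
        return False
    recorded_in = manifest.get("inputs", {})
    if set(recorded_in) != {p.name for p in inputs}:
        return False
    for p in inputs:
        if not p.exists() or _sha256(p) != recorded_in[p.name]:
            return False
    for name, digest in manifest.get("outputs", {}).items():
        p = outdir / name
        if not p.exists() or _sha256(p) != digest:
            return False
    return True


#: artifact name -> stage that produces it (for targeted failure messages)
_PRODUCED_BY = {
    "genotypes.vcf": "simulate",
    "sumstats.tsv": "simulate",
    "genes.bed": "simulate",
    "phenotypes.csv": "simulate",
    "covariates.csv": "simulate",
    "truth.json": "simulate",
    "qc_genotypes.vcf": "qc",
    "pca_scores.csv": "qc",
    "outcomes.csv": "prepare",
    "association.tsv": "associate",
    "optimal_thresholds.json": "associate",
}
for _label in GENE_SET_LABELS:
    _PRODUCED_BY[f"geneset_{_label}.txt"] = "simulate"
    _PRODUCED_BY[f"prs_{_label}.csv"] = "score"
    _PRODUCED_BY[f"prs_{_label}_variants.tsv"] = "score"


def _require(outdir: Path, names: list[str]) -> list[Path]:
    paths = []
    for name in names:
        p = outdir / name
        if not p.exists():
            producer = _PRODUCED_BY.get(name, "an earlier stage")
            raise MissingArtifactError(
                f"missing artifact '{name}'; run stage '{producer}' first"
            )
        paths.append(p)
    return paths


# ---------------------------------------------------------------- stages

def stage_simulate(cfg: PipelineConfig, outdir: Path, force: bool = False) -> None:
    outdir.mkdir(parents=True, exist_ok=True)
    if not force and _up_to_date(outdir, "simulate", cfg, []):
        logger.info("simulate: up to date")
        return
    cohort = simulate_cohort(cfg.sim)
    cio.write_dosage_vcf(cohort.dosage, outdir / "genotypes.vcf")
    cio.write_summary_stats(cohort.stats, outdir / "sumstats.tsv")
    cio.write_gene_bed(cohort.annotation, outdir / "genes.bed")
    outputs = [
        outdir / "genotypes.vcf", outdir / "sumstats.tsv", outdir / "genes.bed",
    ]
    for gs in cohort.sets:
        p = outdir / f"geneset_{gs.label}.txt"
        cio.write_gene_set(gs, p)
        outputs.append(p)
    cio.write_table_csv(cohort.phenotypes, outdir / "phenotypes.csv")
    cio.write_table_csv(cohort.covariates, outdir / "covariates.csv")
    cio.write_ground_truth(cohort.truth, outdir / "truth.json")
    outputs += [
        outdir / "phenotypes.csv", outdir / "covariates.csv", outdir / "truth.json",
    ]
    _write_manifest(outdir, "simulate", cfg, [], outputs)
    logger.info("simulate: wrote %d artifacts", len(outputs))


def stage_qc(cfg: PipelineConfig, outdir: Path, force: bool = False) -> None:
    inputs = _require(outdir, ["genotypes.vcf"])
    if not force and _up_to_date(outdir, "qc", cfg, inputs):
        logger.info("qc: up to date")
        return
    m = cio.read_dosage_vcf(outdir / "genotypes.vcf")
    clean, report, pcs = run_qc(m, cfg.qc)
    cio.write_dosage_vcf(clean, outdir / "qc_genotypes.vcf")
    report.to_json(outdir / "qc_report.json")
    (outdir / "qc_report.txt").write_text(report.to_text())
    pcs.reset_index().to_csv(outdir / "pca_scores.csv", index=False,
                             float_format="%.8g")
    outputs = [outdir / n for n in
               ("qc_genotypes.vcf", "qc_report.json", "qc_report.txt",
                "pca_scores.csv")]
    _write_manifest(outdir, "qc", cfg, inputs, outputs)
    logger.info("qc: %d variants, %d subjects retained",
                clean.n_variants, clean.n_subjects)


def stage_score(cfg: PipelineConfig, outdir: Path, force: bool = False) -> None:
    names = ["qc_genotypes.vcf", "sumstats.tsv", "genes.bed"]
    names += [f"geneset_{label}.txt" for label in GENE_SET_LABELS]
    inputs = _require(outdir, names)
    if not force and _up_to_date(outdir, "score", cfg, inputs):
        logger.info("score: up to date")
        return
    m = cio.read_dosage_vcf(outdir / "qc_genotypes.vcf")
    stats = cio.read_summary_stats(outdir / "sumstats.tsv")
    ann = cio.read_gene_bed(outdir / "genes.bed")
    sets = [
        cio.read_gene_set(outdir / f"geneset_{label}.txt", label)
        for label in GENE_SET_LABELS
    ]
    profiles = score_gene_sets(stats, m, ann, sets, cfg.scoring)
    outputs = []
    for label, prof in profiles.items():
        score_path = outdir / f"prs_{label}.csv"
        prof.as_frame(standardized=False).reset_index().to_csv(
            score_path, index=False, float_format="%.10g"
        )
        manifest_rows = [
            {"threshold": t, "variant": key}
            for t, keys in zip(prof.thresholds, prof.variant_keys)
            for key in keys
        ]
        var_path = outdir / f"prs_{label}_variants.tsv"
        pd.DataFrame(manifest_rows, columns=["threshold", "variant"]).to_csv(
            var_path, sep="\t", index=False, float_format="%g"
        )
        outputs += [score_path, var_path]
    _write_manifest(outdir, "score", cfg, inputs, outputs)
    logger.info("score: wrote %d gene-set profiles", len(profiles))


def stage_prepare(cfg: PipelineConfig, outdir: Path, force: bool = False) -> None:
    inputs = _require(outdir, ["phenotypes.csv"])
    if not force and _up_to_date(outdir, "prepare", cfg, inputs):
        logger.info("prepare: up to date")
        return
    pheno = cio.read_table_csv(outdir / "phenotypes.csv")
    outcomes = volume_change(pheno)
    cio.write_table_csv(outcomes, outdir / "outcomes.csv")
    screening = {}
    for col in [c for c in outcomes.columns if c.startswith("z_")]:
        res = ks_normality(outcomes[col])
        screening[col] = {
            "statistic": res.statistic, "p_value": res.p_value, "note": res.note,
        }
    (outdir / "normality.json").write_text(
        json.dumps(screening, indent=1, sort_keys=True)
    )
    outputs = [outdir / "outcomes.csv", outdir / "normality.json"]
    _write_manifest(outdir, "prepare", cfg, inputs, outputs)
    logger.info("prepare: outcomes for %d subjects", len(outcomes))


def stage_associate(cfg: PipelineConfig, outdir: Path, force: bool = False) -> None:
    names = ["outcomes.csv", "covariates.csv", "pca_scores.csv"]
    names += [f"prs_{label}.csv" for label in GENE_SET_LABELS]
    inputs = _require(outdir, names)
    if not force and _up_to_date(outdir, "associate", cfg, inputs):
        logger.info("associate: up to date")
        return
    outcomes = cio.read_table_csv(outdir / "outcomes.csv")
    covariates = cio.read_table_csv(outdir / "covariates.csv")
    pcs = cio.read_table_csv(outdir / "pca_scores.csv")
    covariates = covariates.merge(pcs, on="subject_id", how="inner")
    profiles = {}
    from .containers import PRSProfile

    for label in GENE_SET_LABELS:
        df = cio.read_table_csv(outdir / f"prs_{label}.csv")
        thresholds = tuple(
            float(c.removeprefix("pt_")) for c in df.columns if c.startswith("pt_")
        )
        raw = df[[c for c in df.columns if c.startswith("pt_")]].to_numpy()
        variants = pd.read_csv(outdir / f"prs_{label}_variants.tsv", sep="\t")
        counts = [
            int((variants["threshold"] == t).sum()) for t in thresholds
        ]
        keys = [
            list(variants.loc[variants["threshold"] == t, "variant"])
            for t in thresholds
        ]
        profiles[label] = PRSProfile(
            label=label, subjects=list(df["subject_id"]), thresholds=thresholds,
            raw=raw, scores=raw.copy(), n_variants=counts, variant_keys=keys,
        )
    results, optimal = threshold_scan(profiles, outcomes, covariates, cfg.assoc)
    results.to_csv(outdir / "association.tsv", sep="\t", index=False,
                   float_format="%.8g")
    payload = optimal.to_dict(orient="records")
    (outdir / "optimal_thresholds.json").write_text(
        json.dumps(payload, indent=1, sort_keys=True, default=float)
    )
    outputs = [outdir / "association.tsv", outdir / "optimal_thresholds.json"]
    _write_manifest(outdir, "associate", cfg, inputs, outputs)
    n_sig = int(results["significant"].sum())
    logger.info("associate: %d cells, %d significant at alpha=%g",
                len(results), n_sig, cfg.assoc.alpha)


def stage_report(cfg: PipelineConfig, outdir: Path, force: bool = False) -> None:
    from .plots import plot_association  # matplotlib import deferred

    names = ["association.tsv", "outcomes.csv", "covariates.csv", "pca_scores.csv"]
    names += [f"prs_{label}.csv" for label in GENE_SET_LABELS]
    inputs = _require(outdir, names)
    if not force and _up_to_date(outdir, "report", cfg, inputs):
        logger.info("report: up to date")
        return
    results = pd.read_csv(outdir / "association.tsv", sep="\t")
    outcomes = cio.read_table_csv(outdir / "outcomes.csv")
    covariates = cio.read_table_csv(outdir / "covariates.csv")
    pcs = cio.read_table_csv(outdir / "pca_scores.csv")
    covariates = covariates.merge(pcs, on="subject_id", how="inner")
    outputs = []
    for label in GENE_SET_LABELS:
        sub = results[(results["gene_set"] == label) & results["p_empirical"].notna()]
        if sub.empty:
            continue
        best = sub.sort_values(
            ["p_empirical", "partial_r2"], ascending=[True, False], kind="mergesort"
        ).iloc[0]
        prs = cio.read_table_csv(outdir / f"prs_{label}.csv")
        fig_path = outdir / (
            f"fig_{label}_{best['group']}_{best['hemisphere']}_"
            f"{best['subfield']}.png"
        )
        plot_association(
            best, prs, outcomes, covariates, cfg.assoc, fig_path
        )
        outputs.append(fig_path)
    _write_manifest(outdir, "report", cfg, inputs, outputs)
    logger.info("report: %d figures", len(outputs))


_STAGE_FUNCS = {
    "simulate": stage_simulate,
    "qc": stage_qc,
    "score": stage_score,
    "prepare": stage_prepare,
    "associate": stage_associate,
    "report": stage_report,
}


def run_stage(stage: str, cfg: PipelineConfig, outdir: str | Path,
              force: bool = False) -> None:
    """Run one named stage (or ``all``) into the output directory."""
    outdir = Path(outdir)
    if stage == "all":
        for s in STAGES:
            _STAGE_FUNCS[s](cfg, outdir, force=force)
        return
    if stage not in _STAGE_FUNCS:
        raise ValueError(f"unknown stage '{stage}'; choose from {STAGES + ('all',)}")
    _STAGE_FUNCS[stage](cfg, outdir, force=force)
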