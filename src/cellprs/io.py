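"""Readers and writers for the on-disk interchange formats.

Genotypes travel as VCF 4.2 with a per-genotype dosage (``DS``) FORMAT field
and a per-variant imputation quality (``INFO``) key, the convention used by
common imputation servers.  Summary statistics are a tab-separated table with
the classic ``SNP CHR BP A1 A2 OR P INFO`` header (A1 = effect allele).
Gene annotation is BED (0-based half-open on disk, 1-based inclusive in
memory); gene sets are plain one-symbol-per-line text files.
"""
from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
from cyvcf2 import VCF

from .containers import (
    DosageMatrix,
    GeneAnnotation,
    GeneSet,
    GroundTruth,
    SummaryStats,
)

# --------------------------------------------------------------------- VCF

_VCF_HEADER = """\
##fileformat=VCFv4.2
##source=cellprs
##INFO=<ID=INFO,Number=1,Type=Float,Description="Imputation quality score">
##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype (hard call)">
##FORMAT=<ID=DS,Number=1,Type=Float,Description="Expected ALT allele dosage">
"""

_GT_CODES = {0: "0/0", 1: "0/1", 2: "1/1"}


def write_dosage_vcf(m: DosageMatrix, path: str | Path, include_ds: bool = True) -> None:
    """Write a DosageMatrix as an uncompressed VCF 4.2 text file.

    Dosages are written with two decimals, INFO scores with three; missing
    calls become ``./.`` with a missing dosage.  When ``include_ds`` is off
    only hard-call GT fields are written (dosages are rounded).
    """
    path = Path(path)
    lines = [_VCF_HEADER]
    for chrom in pd.unique(m.variants["chrom"].astype(str)):
        lines.append(f"##contig=<ID={chrom}>\n")
    lines.append(
        "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
        + "\t".join(m.subjects)
        + "\n"
    )
    fmt = "GT:DS" if include_ds else "GT"
    hard = m.hardcalls()
    for j, var in m.variants.iterrows():
        info = "." if np.isnan(var["info"]) else f"INFO={var['info']:.3f}"
        vid = f"{var['chrom']}:{var['pos']}:{var['ref']}:{var['alt']}"
        fields = [
            str(var["chrom"]),
            str(int(var["pos"])),
            vid,
            str(var["ref"]),
            str(var["alt"]),
            ".",
            "PASS",
            info,
            fmt,
        ]
        for i in range(m.n_subjects):
            d = m.dosages[i, j]
            if np.isnan(d):
                fields.append("./.:." if include_ds else "./.")
            else:
                gt = _GT_CODES[int(hard[i, j])]
                fields.append(f"{gt}:{d:.2f}" if include_ds else gt)
        lines.append("\t".join(fields) + "\n")
    path.write_text("".join(lines))


def read_dosage_vcf(path: str | Path) -> DosageMatrix:
    """Read a VCF into a DosageMatrix.

    The ``DS`` FORMAT field is preferred when present; otherwise dosages fall
    back to hard-call ALT-allele counts.  Records missing both become missing
    dosages.  Multi-allelic records are rejected outright: the scoring model
    assumes a single effect/other allele pair per site.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    vcf = VCF(str(path))
    subjects = list(vcf.samples)
    chroms: list[str] = []
    positions: list[int] = []
    refs: list[str] = []
    alts: list[str] = []
    infos: list[float] = []
    rows: list[np.ndarray] = []
    for rec in vcf:
        if len(rec.ALT) != 1:
            raise ValueError(
                f"multi-allelic record at {rec.CHROM}:{rec.POS} not supported"
            )
        chroms.append(str(rec.CHROM))
        positions.append(int(rec.POS))
        refs.append(rec.REF)
        alts.append(rec.ALT[0])
        info_val = rec.INFO.get("INFO")
        infos.append(float(info_val) if info_val is not None else np.nan)
        ds = None
        try:
            ds = rec.format("DS")
        except KeyError:
            ds = None
        if ds is not None:
            col = np.asarray(ds, dtype=float).reshape(-1)
            # cyvcf2 encodes missing floats as NaN or huge sentinels
            col = np.where(np.isfinite(col) & (col >= 0) & (col <= 2), col, np.nan)
        else:
            gts = rec.gt_types  # 0=hom ref, 1=het, 2=unknown, 3=hom alt
            col = np.full(len(subjects), np.nan)
            col[gts == 0] = 0.0
            col[gts == 1] = 1.0
            col[gts == 3] = 2.0
        rows.append(col)
    vcf.close()
    dosages = (
        np.column_stack(rows) if rows else np.empty((len(subjects), 0), dtype=float)
    )
    variants = pd.DataFrame(
        {"chrom": chroms, "pos": positions, "ref": refs, "alt": alts, "info": infos}
    )
    return DosageMatrix(subjects=subjects, variants=variants, dosages=dosages)


# ----------------------------------------------------------- summary stats

SUMSTATS_COLUMNS = ["SNP", "CHR", "BP", "A1", "A2", "OR", "P", "INFO"]
_INTERNAL = dict(
    SNP="snp", CHR="chrom", BP="pos", A1="a1", A2="a2", OR="odds_ratio", P="p", INFO="info"
)


def write_summary_stats(stats: SummaryStats, path: str | Path) -> None:
    out = stats.table.rename(columns={v: k for k, v in _INTERNAL.items()})
    out = out[SUMSTATS_COLUMNS]
    out.to_csv(path, sep="\t", index=False, float_format="%.6g", na_rep="NA")


def read_summary_stats(path: str | Path) -> SummaryStats:
    df = pd.read_csv(path, sep="\t", dtype={"CHR": str}, na_values=["NA"])
    missing = [c for c in SUMSTATS_COLUMNS[:7] if c not in df.columns]
    if missing:
        raise ValueError(f"summary statistics file lacks columns {missing}")
    df = df.rename(columns=_INTERNAL)
    return SummaryStats(table=df)


# --------------------------------------------------------------------- BED

def write_gene_bed(ann: GeneAnnotation, path: str | Path) -> None:
    """BED on disk is 0-based half-open; in-memory intervals are 1-based inclusive."""
    out = ann.table.copy()
    out["start0"] = out["start"].astype(int) - 1
    out["end0"] = out["end"].astype(int)
    out[["chrom", "start0", "end0", "gene"]].to_csv(
        path, sep="\t", index=False, header=False
    )


def read_gene_bed(path: str | Path) -> GeneAnnotation:
    df = pd.read_csv(
        path, sep="\t", header=None, names=["chrom", "start0", "end0", "gene"],
        dtype={"chrom": str},
    )
    table = pd.DataFrame(
        {
            "gene": df["gene"],
            "chrom": df["chrom"],
            "start": df["start0"].astype(int) + 1,
            "end": df["end0"].astype(int),
        }
    )
    return GeneAnnotation(table=table)


# --------------------------------------------------------------- gene sets

def write_gene_set(gs: GeneSet, path: str | Path) -> None:
    Path(path).write_text("\n".join(gs.genes) + "\n")


def read_gene_set(path: str | Path, label: str) -> GeneSet:
    genes = [ln.strip() for ln in Path(path).read_text().splitlines() if ln.strip()]
    return GeneSet(label=label, genes=tuple(genes))


# ------------------------------------------------------ phenotypes, truth

def write_table_csv(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, index=False, float_format="%.6f")


def read_table_csv(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path)


def write_ground_truth(truth: GroundTruth, path: str | Path) -> None:
    payload = {
        "true_beta": {k: float(v) for k, v in truth.true_beta.items()},
        "true_prs": {k: float(v) for k, v in truth.true_prs.items()},
        "groups": {k: str(v) for k, v in truth.groups.items()},
        "planted": truth.planted,
    }
    Path(path).write_text(json.dumps(payload, indent=1, sort_keys=True))


def read_ground_truth(path: str | Path) -> GroundTruth:
    payload = json.loads(Path(path).read_text())
    return GroundTruth(
        true_beta=pd.Series(payload["true_beta"], dtype=float),
        true_prs=pd.Series(payload["true_prs"], dtype=float),
        groups=pd.Series(payload["groups"], dtype=object),
        planted=payload["planted"],
    )
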